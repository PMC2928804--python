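"""Survival dimensionality reduction: cell classification, exhaustive
feature selection under k-fold cross-validation, merged-fold (meta) model
validation and permutation testing.

The classification procedure mirrors multifactor dimensionality reduction,
adapted to right-censored outcomes: for a chosen set of n SNPs the cohort is
partitioned into the 3^n multilocus genotype cells; each populated cell's
Kaplan-Meier curve is compared to the whole-cohort curve on the common grid
of observed times; the per-time differences D_c(t_i), shifted by +1 so they
are positive, are averaged by geometric mean, and cells with GM <= 1 are
labelled high-risk, GM > 1 low-risk.  Subjects are pooled by label and the
pooled-group Kaplan-Meier curves serve as each subject's survival
prediction, scored by the integrated censored Brier score (IBS).

Model selection runs in two phases.  Feature selection: for every
n-combination of SNPs, SDR models are fitted on each of the k training
folds and the combination with the lowest mean training IBS wins.  Model
validation: the k testing folds, labelled with their training folds' cell
assignments, are merged into one meta testing set T_M on which a single
meta-IBS is computed; the dimensionality with the lowest meta-IBS is the
final model.  Statistical significance comes from permutation testing.

The heavy lifting is done by private vectorised kernels; the public
``build_cells`` / ``classify_cells`` / ``pooled_predictions`` functions
expose the same computation on explicit cell-table objects.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .data import SurvivalData
from .survival import KMCurve, km_estimate

__all__ = [
    "HIGH_RISK",
    "LOW_RISK",
    "EMPTY",
    "Cell",
    "MultilocusCellTable",
    "DimensionSelection",
    "DimensionResult",
    "SDRModel",
    "build_cells",
    "classify_cells",
    "pooled_predictions",
    "cv_split",
    "feature_select",
    "meta_validate",
    "permutation_test",
    "run_sdr",
]

HIGH_RISK = "high_risk"
LOW_RISK = "low_risk"
EMPTY = "empty"

_EMPTY_CELL_POLICIES = ("majority", "high", "exclude")


# ---------------------------------------------------------------------------
# public cell-table objects
# ---------------------------------------------------------------------------

@dataclass
class Cell:
    """One multilocus genotype cell of an n-SNP combination."""

    genotype: tuple[int, ...]
    members: np.ndarray
    surv: np.ndarray | None = None     # cell KM values on the common grid
    diff: np.ndarray | None = None     # D_c(t_i) = S_c(t_i) - S(t_i)
    gm: float | None = None            # geometric mean of 1 + D_c(t_i)
    label: str = EMPTY


@dataclass
class MultilocusCellTable:
    """All 3^n cells of one SNP combination, with classification results."""

    combo: tuple[str, ...]
    cells: dict[tuple[int, ...], Cell]
    grid: np.ndarray | None = None     # common evaluation grid (set by classify)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def labelled(self, label: str) -> list[Cell]:
        return [c for c in self.cells.values() if c.label == label]


def _combo_indices(data: SurvivalData, combo) -> tuple[int, ...]:
    idx = tuple(c if isinstance(c, (int, np.integer)) else data.column_index(c) for c in combo)
    if len(set(idx)) != len(idx):
        raise ValueError("duplicate SNP in combination")
    for i in idx:
        if not 0 <= i < data.n_snps:
            raise ValueError(f"SNP column index out of range: {i}")
    return idx


def _encode(genotypes: np.ndarray, idx: tuple[int, ...]) -> np.ndarray:
    """Base-3 cell code of each subject for the given SNP columns."""
    codes = genotypes[:, idx[0]].astype(np.int64)
    for j in idx[1:]:
        codes = codes * 3 + genotypes[:, j]
    return codes


def build_cells(data: SurvivalData, combo) -> MultilocusCellTable:
    """Partition the cohort into the 3^n multilocus cells of ``combo``.

    Every potential cell is represented; cells with no members carry the
    ``empty`` label.
    """
    idx = _combo_indices(data, combo)
    names = tuple(data.snp_names[i] for i in idx)
    codes = _encode(data.genotypes, idx)
    n = len(idx)
    cells: dict[tuple[int, ...], Cell] = {}
    order = np.argsort(codes, kind="stable")
    bounds = np.searchsorted(codes[order], np.arange(3 ** n + 1))
    for code in range(3 ** n):
        genotype = tuple((code // 3 ** (n - 1 - j)) % 3 for j in range(n))
        members = order[bounds[code]:bounds[code + 1]]
        cells[genotype] = Cell(genotype=genotype, members=np.sort(members))
    return MultilocusCellTable(combo=names, cells=cells)


def classify_cells(table: MultilocusCellTable, data: SurvivalData) -> MultilocusCellTable:
    """Label every populated cell high- or low-risk.

    The common grid is the set of distinct observed times of ``data``; the
    whole-cohort and per-cell Kaplan-Meier curves are evaluated on it, and
    for each populated cell GM = (prod_i (1 + D_c(t_i)))^(1/n_grid) with
    D_c(t_i) the cell-minus-population survival difference.  GM <= 1 (the
    cell does no better than the cohort) means high-risk.
    """
    grid = np.unique(data.time)
    pop = km_estimate(data.time, data.event).evaluate(grid)
    table.grid = grid
    for cell in table.cells.values():
        if cell.members.size == 0:
            cell.label = EMPTY
            cell.surv = cell.diff = None
            cell.gm = None
            continue
        curve = km_estimate(data.time[cell.members], data.event[cell.members])
        cell.surv = curve.evaluate(grid)
        cell.diff = cell.surv - pop
        cell.gm = float(np.exp(np.mean(np.log1p(cell.diff))))
        cell.label = HIGH_RISK if np.mean(np.log1p(cell.diff)) <= 0 else LOW_RISK
    return table


def pooled_predictions(table: MultilocusCellTable, data: SurvivalData) -> list[KMCurve]:
    """Per-subject predicted survival curve from the pooled risk groups.

    High-risk subjects receive the Kaplan-Meier curve of the pooled
    high-risk group and low-risk subjects that of the low-risk group, both
    fitted on the supplied cohort.  Subjects falling in a cell the table
    labelled ``empty`` (possible when ``data`` differs from the cohort the
    table was classified on) receive the whole-cohort curve.
    """
    idx = _combo_indices(data, table.combo)
    codes = _encode(data.genotypes, idx)
    n = len(idx)
    label_of = np.empty(3 ** n, dtype=object)
    for genotype, cell in table.cells.items():
        code = 0
        for g in genotype:
            code = code * 3 + g
        label_of[code] = cell.label
    labels = label_of[codes]

    pop_curve = km_estimate(data.time, data.event)
    curves: dict[str, KMCurve] = {EMPTY: pop_curve}
    for lab in (HIGH_RISK, LOW_RISK):
        mask = labels == lab
        if mask.any():
            curves[lab] = km_estimate(data.time[mask], data.event[mask])
        else:
            curves[lab] = pop_curve
    return [curves[lab] for lab in labels]


# ---------------------------------------------------------------------------
# vectorised kernels
# ---------------------------------------------------------------------------

class _FoldContext:
    """Precomputed quantities for one training cohort (or the full cohort).

    Holds the common time grid, the population and censoring Kaplan-Meier
    values, and the per-subject Graf weight matrices used by the exact
    step-decomposition of the integrated Brier score, so that scoring one
    SNP combination reduces to a handful of small array operations.
    """

    __slots__ = (
        "n", "time", "eventf", "geno", "grid", "time_idx", "n_grid",
        "pop_surv", "t_max", "seg_left", "seg_len", "seg_gidx", "A", "B",
        "norm",
    )

    def __init__(self, time: np.ndarray, event: np.ndarray, geno: np.ndarray):
        self.n = time.size
        self.time = time
        self.eventf = event.astype(float)
        self.geno = geno
        grid, inv = np.unique(time, return_inverse=True)
        self.grid = grid
        self.time_idx = inv
        self.n_grid = grid.size

        counts = np.bincount(inv, minlength=self.n_grid)
        d = np.bincount(inv, weights=self.eventf, minlength=self.n_grid)
        at_risk = self.n - (np.cumsum(counts) - counts)
        self.pop_surv = np.cumprod(1.0 - d / at_risk)
        g_surv = np.cumprod(1.0 - (counts - d) / at_risk)

        if not (d > 0).any():
            raise ValueError("no events in cohort: IBS horizon undefined")
        self.t_max = float(grid[d > 0][-1])

        interior = (grid > 0) & (grid < self.t_max)
        seg_left = np.concatenate(([0.0], grid[interior]))
        seg_right = np.concatenate((grid[interior], [self.t_max]))
        self.seg_left = seg_left
        self.seg_len = seg_right - seg_left
        seg_gidx = np.searchsorted(grid, seg_left, side="right") - 1
        self.seg_gidx = seg_gidx

        # G(s_j) at segment lefts and G(t_i-) per subject (1 before the grid)
        g_seg = np.where(seg_gidx >= 0, g_surv[np.maximum(seg_gidx, 0)], 1.0)
        g_left = np.where(inv > 0, g_surv[np.maximum(inv - 1, 0)], 1.0)

        had_event = (time[:, None] <= seg_left[None, :]) & (self.eventf[:, None] > 0)
        under_obs = time[:, None] > seg_left[None, :]
        self.A = had_event / g_left[:, None]
        self.B = under_obs / g_seg[None, :]
        self.norm = 1.0 / (self.n * self.t_max)

    def curve_at_segments(self, surv: np.ndarray) -> np.ndarray:
        """Step-evaluate KM value rows (cells x grid) at segment lefts."""
        vals = surv[:, np.maximum(self.seg_gidx, 0)]
        vals[:, self.seg_gidx < 0] = 1.0
        return vals


def _km_matrix(ctx: _FoldContext, codes: np.ndarray, n_cells: int):
    """Kaplan-Meier step values on the common grid for every cell at once."""
    J = ctx.n_grid
    flat = codes * J + ctx.time_idx
    total = np.bincount(flat, minlength=n_cells * J).reshape(n_cells, J)
    d = np.bincount(flat, weights=ctx.eventf, minlength=n_cells * J).reshape(n_cells, J)
    n_members = total.sum(axis=1)
    at_risk = n_members[:, None] - (np.cumsum(total, axis=1) - total)
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = 1.0 - d / at_risk
    factor[at_risk <= 0] = 1.0
    return np.cumprod(factor, axis=1), n_members


def _ibs_for_pred(ctx: _FoldContext, pred: np.ndarray) -> float:
    """Exact IBS for an explicit per-subject prediction matrix (n x segments)."""
    bs = (ctx.A * pred * pred + ctx.B * (1.0 - pred) ** 2).sum(axis=0)
    return float((bs * ctx.seg_len).sum() * ctx.norm)


def _step_eval(grid: np.ndarray, surv: np.ndarray, at: np.ndarray) -> np.ndarray:
    """Evaluate KM step rows (groups x grid) at arbitrary times ``at``."""
    idx = np.searchsorted(grid, at, side="right") - 1
    vals = surv[:, np.maximum(idx, 0)].copy()
    vals[:, idx < 0] = 1.0
    return vals


def _ibs_for_groups(ctx: _FoldContext, group: np.ndarray) -> float:
    """Exact IBS of pooled-group KM predictions for a 0/1 group assignment."""
    surv, _ = _km_matrix(ctx, group, 2)
    C = ctx.curve_at_segments(surv)
    mask0 = group == 0
    SA = np.vstack((ctx.A[mask0].sum(axis=0), ctx.A[~mask0].sum(axis=0)))
    SB = np.vstack((ctx.B[mask0].sum(axis=0), ctx.B[~mask0].sum(axis=0)))
    bs = (SA * C * C + SB * (1.0 - C) ** 2).sum(axis=0)
    return float((bs * ctx.seg_len).sum() * ctx.norm)


def _eval_combo(ctx: _FoldContext, idx: tuple[int, ...]):
    """Classify the cells of one combination and score its training IBS.

    Returns ``(high, n_members, group, ibs)`` where ``high`` is a boolean
    per-cell flag (GM <= 1) and ``group`` the per-subject 0 = high / 1 = low
    assignment.
    """
    n_cells = 3 ** len(idx)
    codes = _encode(ctx.geno, idx)
    surv, n_members = _km_matrix(ctx, codes, n_cells)
    gm_log = np.mean(np.log1p(surv - ctx.pop_surv[None, :]), axis=1)
    high = gm_log <= 0
    group = np.where(high[codes], 0, 1)
    return high, n_members, group, _ibs_for_groups(ctx, group)


def _prepare_folds(data: SurvivalData, folds) -> list[_FoldContext]:
    ctxs = []
    for test_idx in folds:
        mask = np.ones(data.n_subjects, dtype=bool)
        mask[test_idx] = False
        ctxs.append(_FoldContext(data.time[mask], data.event[mask], data.genotypes[mask]))
    return ctxs


# ---------------------------------------------------------------------------
# cross-validation machinery
# ---------------------------------------------------------------------------

def cv_split(data: SurvivalData, k: int, seed: int, stratify: bool = False) -> list[np.ndarray]:
    """Partition subjects into k mutually exclusive testing index sets.

    Fold sizes differ by at most one; the split is deterministic for a
    fixed seed.  With ``stratify`` the shuffle is performed within the
    event and censored strata separately (round-robin deal) so that heavy
    censorship cannot starve a fold of events.
    """
    n = data.n_subjects
    if not 2 <= k <= n:
        raise ValueError("k out of range: need 2 <= k <= n_subjects")
    rng = np.random.default_rng(seed)
    if stratify:
        ev = np.flatnonzero(data.event == 1)
        ce = np.flatnonzero(data.event == 0)
        order = np.concatenate((rng.permutation(ev), rng.permutation(ce)))
        folds = [order[i::k] for i in range(k)]
    else:
        folds = np.array_split(rng.permutation(n), k)
    return [np.sort(f) for f in folds]


@dataclass
class DimensionSelection:
    """Winning n-SNP combination of the feature-selection phase."""

    n: int
    combo: tuple[int, ...]
    combo_names: tuple[str, ...]
    train_ibs: float
    fold_labels: list[np.ndarray]   # per fold: 3^n array, 0 high / 1 low / -1 empty
    fold_majority: list[int]        # per fold: majority pooled group (ties -> high)
    fold_curves: list[tuple[np.ndarray, np.ndarray]]  # per fold: (grid, 2 x grid KM)
    k: int
    seed: int


def feature_select(
    data: SurvivalData,
    n: int,
    k: int = 5,
    seed: int = 0,
    stratify_folds: bool = False,
    folds=None,
    _ctxs=None,
) -> DimensionSelection:
    """Exhaustive search for the n-SNP combination with lowest mean training IBS.

    Every C(n_snps, n) combination is fitted on each of the k training
    folds (cell classification + pooled-group prediction) and scored by the
    training IBS; the k scores are averaged and the minimiser returned.
    Ties break to the lexicographically first combination of column
    indices.
    """
    if n < 1 or n > data.n_snps:
        raise ValueError("interaction order n out of range")
    if folds is None:
        folds = cv_split(data, k, seed, stratify=stratify_folds)
    if _ctxs is None:
        _ctxs = _prepare_folds(data, folds)

    best_idx = None
    best_ibs = np.inf
    for idx in combinations(range(data.n_snps), n):
        total = 0.0
        for ctx in _ctxs:
            total += _eval_combo(ctx, idx)[3]
        mean_ibs = total / len(_ctxs)
        if mean_ibs < best_ibs:
            best_ibs = mean_ibs
            best_idx = idx

    fold_labels, fold_majority, fold_curves = [], [], []
    for ctx in _ctxs:
        high, n_members, group, _ = _eval_combo(ctx, best_idx)
        labels = np.where(n_members == 0, -1, np.where(high, 0, 1)).astype(np.int8)
        fold_labels.append(labels)
        n_high = int((group == 0).sum())
        fold_majority.append(0 if n_high >= ctx.n - n_high else 1)
        surv2, _ = _km_matrix(ctx, group, 2)
        fold_curves.append((ctx.grid, surv2))
    return DimensionSelection(
        n=n,
        combo=best_idx,
        combo_names=tuple(data.snp_names[i] for i in best_idx),
        train_ibs=float(best_ibs),
        fold_labels=fold_labels,
        fold_majority=fold_majority,
        fold_curves=fold_curves,
        k=k,
        seed=seed,
    )


@dataclass
class DimensionResult:
    n: int
    combo_names: tuple[str, ...]
    train_ibs: float
    meta_ibs: float
    n_unseen: int                    # testing subjects in training-empty cells


@dataclass
class SDRModel:
    """Full SDR analysis result across interaction orders 1..max_dim."""

    dimensions: list[DimensionResult]
    final_dimension: int
    final_combo: tuple[str, ...]
    k: int
    seed: int
    empty_cell_policy: str
    degenerate: bool = False
    permutation_pvalue: float | None = None
    n_permutations: int = 0
    n_permutations_as_extreme: int | None = None
    final_table: MultilocusCellTable | None = None

    @property
    def best_meta_ibs(self) -> float:
        return min(d.meta_ibs for d in self.dimensions)


def _meta_labels(data, selection, folds, empty_cell_policy):
    """Label every testing subject with its training fold's cell assignment."""
    labels = np.full(data.n_subjects, -1, dtype=np.int8)
    n_unseen = 0
    for f_i, test_idx in enumerate(folds):
        codes = _encode(data.genotypes[test_idx], selection.combo)
        lbl = selection.fold_labels[f_i][codes].copy()
        unseen = lbl == -1
        n_unseen += int(unseen.sum())
        if empty_cell_policy == "majority":
            lbl[unseen] = selection.fold_majority[f_i]
        elif empty_cell_policy == "high":
            lbl[unseen] = 0
        # "exclude": leave as -1
        labels[test_idx] = lbl
    return labels, n_unseen


def meta_validate(
    data: SurvivalData,
    selections: list[DimensionSelection],
    k: int,
    seed: int,
    stratify_folds: bool = False,
    empty_cell_policy: str = "majority",
    carry_training_curves: bool = True,
    folds=None,
) -> SDRModel:
    """Merge the labelled testing folds into T_M and pick the final dimension.

    For each dimension's winning combination, every testing subject is
    labelled high-/low-risk according to the cell assignments learned on
    its training folds; the k labelled testing sets are concatenated into
    one meta set T_M (individual-patient-data meta-analysis style) and a
    single meta-IBS is computed there.  The censoring weights come from
    T_M, where they are reliably estimable.  With ``carry_training_curves``
    (the default) each subject's predicted survival curve is the pooled-
    group KM curve fitted on its training folds, so the meta-IBS is a true
    out-of-sample score and over-fitted high-order models are penalised;
    otherwise the pooled curves are refitted on T_M and only the grouping
    itself is assessed.  The dimension minimising meta-IBS is the final
    model; ties break to the lower dimension.
    """
    if empty_cell_policy not in _EMPTY_CELL_POLICIES:
        raise ValueError(f"empty_cell_policy must be one of {_EMPTY_CELL_POLICIES}")
    for sel in selections:
        if sel.k != k or sel.seed != seed:
            raise ValueError("fold mismatch: selections built with different k or seed")
    if folds is None:
        folds = cv_split(data, k, seed, stratify=stratify_folds)

    full_ctx = None
    results = []
    for sel in selections:
        labels, n_unseen = _meta_labels(data, sel, folds, empty_cell_policy)
        keep = labels != -1
        if empty_cell_policy == "exclude" and not keep.all():
            ctx = _FoldContext(data.time[keep], data.event[keep], data.genotypes[keep])
        else:
            if full_ctx is None:
                full_ctx = _FoldContext(data.time, data.event, data.genotypes)
            ctx = full_ctx
        if carry_training_curves:
            pred = np.empty((data.n_subjects, ctx.seg_left.size))
            for f_i, test_idx in enumerate(folds):
                grid, surv2 = sel.fold_curves[f_i]
                vals = _step_eval(grid, surv2, ctx.seg_left)
                pred[test_idx] = vals[np.maximum(labels[test_idx], 0)]
            meta_ibs = _ibs_for_pred(ctx, pred[keep])
        else:
            meta_ibs = _ibs_for_groups(ctx, labels[keep])
        results.append(
            DimensionResult(
                n=sel.n,
                combo_names=sel.combo_names,
                train_ibs=sel.train_ibs,
                meta_ibs=meta_ibs,
                n_unseen=n_unseen,
            )
        )

    best = int(np.argmin([r.meta_ibs for r in results]))
    final = results[best]
    table = classify_cells(build_cells(data, final.combo_names), data)
    populated = [c.label for c in table.cells.values() if c.label != EMPTY]
    degenerate = len(set(populated)) < 2
    return SDRModel(
        dimensions=results,
        final_dimension=final.n,
        final_combo=final.combo_names,
        k=k,
        seed=seed,
        empty_cell_policy=empty_cell_policy,
        degenerate=degenerate,
        final_table=table,
    )


def _best_meta_ibs(data, k, max_dim, seed, folds, ctxs, empty_cell_policy,
                   carry_training_curves=True):
    """Best (lowest) meta-IBS across dimensions 1..max_dim; internal."""
    selections = [
        feature_select(data, n, k, seed, folds=folds, _ctxs=ctxs)
        for n in range(1, max_dim + 1)
    ]
    model = meta_validate(
        data, selections, k, seed, empty_cell_policy=empty_cell_policy,
        carry_training_curves=carry_training_curves, folds=folds
    )
    return model, selections


def permutation_test(
    data: SurvivalData,
    k: int = 5,
    max_dim: int = 3,
    n_perm: int = 100,
    seed: int = 0,
    empty_cell_policy: str = "majority",
    stratify_folds: bool = False,
    carry_training_curves: bool = True,
    observed_best: float | None = None,
):
    """Empirical p-value for the best SDR model by outcome permutation.

    Each permutation jointly shuffles the (time, event) pairs against the
    genotype rows, severing any genotype-outcome association while keeping
    both marginals intact, and reruns the whole pipeline (feature selection
    for every dimension up to ``max_dim`` plus meta validation).  The
    p-value uses the add-one correction
    p = (1 + #{permutations with best meta-IBS <= observed}) / (1 + n_perm).

    Returns ``(p_value, n_as_extreme)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    folds = cv_split(data, k, seed, stratify=stratify_folds)
    if observed_best is None:
        ctxs = _prepare_folds(data, folds)
        model, _ = _best_meta_ibs(data, k, max_dim, seed, folds, ctxs,
                                  empty_cell_policy, carry_training_curves)
        observed_best = model.best_meta_ibs

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5D12]))
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(data.n_subjects)
        data_p = SurvivalData(
            genotypes=data.genotypes,
            time=data.time[perm],
            event=data.event[perm],
            snp_names=data.snp_names,
        )
        ctxs_p = _prepare_folds(data_p, folds)
        model_p, _ = _best_meta_ibs(data_p, k, max_dim, seed, folds, ctxs_p,
                                    empty_cell_policy, carry_training_curves)
        if model_p.best_meta_ibs <= observed_best:
            count += 1
    return (1 + count) / (1 + n_perm), count


def run_sdr(
    data: SurvivalData,
    k: int = 5,
    max_dim: int = 3,
    seed: int = 0,
    n_permutations: int = 0,
    empty_cell_policy: str = "majority",
    stratify_folds: bool = False,
    carry_training_curves: bool = True,
) -> SDRModel:
    """Complete SDR analysis: selection, meta validation, optional permutation.

    Output is bit-identical for a fixed ``(data, k, max_dim, seed,
    n_permutations)`` configuration.
    """
    folds = cv_split(data, k, seed, stratify=stratify_folds)
    ctxs = _prepare_folds(data, folds)
    model, _ = _best_meta_ibs(data, k, max_dim, seed, folds, ctxs,
                              empty_cell_policy, carry_training_curves)
    if n_permutations > 0:
        p, count = permutation_test(
            data,
            k=k,
            max_dim=max_dim,
            n_perm=n_permutations,
            seed=seed,
            empty_cell_policy=empty_cell_policy,
            stratify_folds=stratify_folds,
            carry_training_curves=carry_training_curves,
            observed_best=model.best_meta_ibs,
        )
        model.permutation_pvalue = p
        model.n_permutations = n_permutations
        model.n_permutations_as_extreme = count
    return model
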