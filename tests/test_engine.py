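"""SDR engine: cell building, GM classification, pooled predictions,
cross-validation, feature selection, meta validation and permutation."""

from __future__ import annotations

import numpy as np
import pytest

import survdr
from survdr.data import SurvivalData
from survdr.engine import (
    EMPTY,
    HIGH_RISK,
    LOW_RISK,
    _FoldContext,
    _ibs_for_groups,
    cv_split,
)
from conftest import random_dataset


def gm_oracle(cell_times, cell_events, pop_times, pop_events, grid):
    """Brute-force GM: independent loop over the grid, product, n-th root."""
    s_cell = [_km_at(cell_times, cell_events, t) for t in grid]
    s_pop = [_km_at(pop_times, pop_events, t) for t in grid]
    prod = 1.0
    for sc, sp in zip(s_cell, s_pop):
        prod *= 1.0 + (sc - sp)
    return prod ** (1.0 / len(grid))


def _km_at(times, events, t):
    prod = 1.0
    for ti in sorted(set(times)):
        if ti > t:
            break
        n_i = sum(1 for x in times if x >= ti)
        d_i = sum(1 for x, e in zip(times, events) if x == ti and e == 1)
        prod *= 1.0 - d_i / n_i
    return prod


# ---------------------------------------------------------------------------
# build_cells / classify_cells
# ---------------------------------------------------------------------------

def test_build_cells_partitions_cohort():
    rng = np.random.default_rng(1)
    data = random_dataset(rng, n=50, n_snps=3)
    table = survdr.build_cells(data, ["S0", "S2"])
    assert table.n_cells == 9
    members = np.concatenate([c.members for c in table.cells.values()])
    assert sorted(members) == list(range(50))


def test_build_cells_rejects_duplicates():
    rng = np.random.default_rng(2)
    data = random_dataset(rng, n=10, n_snps=2)
    with pytest.raises(ValueError, match="duplicate"):
        survdr.build_cells(data, ["S0", "S0"])


def test_build_cells_hwe_proportions():
    """Cell occupancy of a simulated HWE cohort matches multinomial
    expectation within 4 standard deviations."""
    dist = survdr.solve_distribution("EXP")
    model = survdr.generate_penetrance_model(H2_target=0.0)
    model = survdr.decompose_timepoints(model, dist)
    pop = survdr.simulate_population(model, dist, n=4000, n_noise_snps=0, seed=5)
    table = survdr.build_cells(pop, pop.snp_names)
    q = model.maf
    probs = np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])
    for genotype, cell in table.cells.items():
        p = probs[genotype[0]] * probs[genotype[1]]
        sd = np.sqrt(4000 * p * (1 - p))
        assert abs(cell.members.size - 4000 * p) < 4 * sd + 1


def test_classify_gm_matches_bruteforce():
    rng = np.random.default_rng(3)
    for _ in range(25):
        data = random_dataset(rng, n=60, n_snps=3)
        table = survdr.classify_cells(survdr.build_cells(data, ["S0", "S1"]), data)
        grid = np.unique(data.time)
        for cell in table.cells.values():
            if cell.label == EMPTY:
                continue
            expected = gm_oracle(
                data.time[cell.members], data.event[cell.members],
                data.time, data.event, grid,
            )
            assert cell.gm == pytest.approx(expected, abs=1e-12)
            assert cell.label == (HIGH_RISK if expected <= 1 else LOW_RISK)
            # 1 + D must stay positive for the GM; D = +1 is reachable when
            # the population curve hits 0 but an all-censored cell stays at 1
            assert np.all(cell.diff > -1) and np.all(cell.diff <= 1)


def test_classify_single_cell_boundary_is_high_risk():
    """A monomorphic SNP puts everyone in one cell whose curve equals the
    population curve: D == 0, GM == 1, and the boundary GM <= 1 rule
    labels it high-risk."""
    data = SurvivalData(
        genotypes=np.zeros((10, 1), dtype=np.int8),
        time=np.arange(1.0, 11.0),
        event=[1, 0] * 5,
        snp_names=["S0"],
    )
    table = survdr.classify_cells(survdr.build_cells(data, ["S0"]), data)
    cell = table.cells[(0,)]
    assert cell.gm == pytest.approx(1.0, abs=1e-15)
    assert cell.label == HIGH_RISK
    np.testing.assert_allclose(cell.diff, 0.0, atol=1e-15)


# ---------------------------------------------------------------------------
# pooled predictions
# ---------------------------------------------------------------------------

def test_pooled_predictions_single_group_is_population_curve():
    data = SurvivalData(
        genotypes=np.zeros((8, 1), dtype=np.int8),
        time=np.arange(1.0, 9.0),
        event=[1] * 8,
        snp_names=["S0"],
    )
    table = survdr.classify_cells(survdr.build_cells(data, ["S0"]), data)
    curves = survdr.pooled_predictions(table, data)
    pop = survdr.km_estimate(data.time, data.event)
    for c in curves:
        np.testing.assert_array_equal(c.surv, pop.surv)


def test_pooled_predictions_are_group_km_curves():
    rng = np.random.default_rng(11)
    data = random_dataset(rng, n=60, n_snps=2)
    table = survdr.classify_cells(survdr.build_cells(data, ["S0", "S1"]), data)
    curves = survdr.pooled_predictions(table, data)
    label_of = np.empty(data.n_subjects, dtype=object)
    for cell in table.cells.values():
        label_of[cell.members] = cell.label
    for lab in (HIGH_RISK, LOW_RISK):
        mask = label_of == lab
        if not mask.any():
            continue
        expected = survdr.km_estimate(data.time[mask], data.event[mask])
        i = int(np.flatnonzero(mask)[0])
        np.testing.assert_array_equal(curves[i].surv, expected.surv)


def test_fast_group_ibs_equals_public_path():
    """The vectorised IBS kernel reproduces integrated_brier on pooled
    predictions exactly."""
    rng = np.random.default_rng(13)
    for _ in range(10):
        data = random_dataset(rng, n=40, n_snps=2)
        table = survdr.classify_cells(survdr.build_cells(data, ["S0", "S1"]), data)
        curves = survdr.pooled_predictions(table, data)
        label_of = np.empty(data.n_subjects, dtype=int)
        for cell in table.cells.values():
            label_of[cell.members] = 0 if cell.label == HIGH_RISK else 1
        ctx = _FoldContext(data.time, data.event, data.genotypes)
        fast = _ibs_for_groups(ctx, label_of)
        public = survdr.integrated_brier(curves, data)
        assert fast == pytest.approx(public, abs=1e-12)


# ---------------------------------------------------------------------------
# cv_split
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n,k,sizes", [(10, 5, {2}), (11, 5, {3, 2})])
def test_cv_split_fold_sizes(n, k, sizes):
    rng = np.random.default_rng(17)
    data = random_dataset(rng, n=n, n_snps=1)
    folds = cv_split(data, k, seed=0)
    assert {len(f) for f in folds} == sizes
    assert sorted(np.concatenate(folds)) == list(range(n))


def test_cv_split_deterministic_and_seed_sensitive():
    rng = np.random.default_rng(19)
    data = random_dataset(rng, n=40, n_snps=1)
    a = cv_split(data, 5, seed=3)
    b = cv_split(data, 5, seed=3)
    c = cv_split(data, 5, seed=4)
    for fa, fb in zip(a, b):
        np.testing.assert_array_equal(fa, fb)
    assert any(not np.array_equal(fa, fc) for fa, fc in zip(a, c))


def test_cv_split_stratified_balances_events():
    rng = np.random.default_rng(23)
    data = random_dataset(rng, n=60, n_snps=1)
    folds = cv_split(data, 5, seed=1, stratify=True)
    rates = [data.event[f].mean() for f in folds]
    assert max(rates) - min(rates) < 0.2


def test_cv_split_k_out_of_range():
    rng = np.random.default_rng(29)
    data = random_dataset(rng, n=10, n_snps=1)
    for bad_k in (1, 11):
        with pytest.raises(ValueError, match="k out of range"):
            cv_split(data, bad_k, seed=0)


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

def test_feature_select_single_combination():
    rng = np.random.default_rng(31)
    data = random_dataset(rng, n=40, n_snps=2)
    sel = survdr.feature_select(data, 2, k=4, seed=0)
    assert sel.combo_names == ("S0", "S1")


def test_feature_select_finds_separable_pair():
    """Two SNPs whose joint genotype deterministically separates early
    events from late censoring must win the search."""
    rng = np.random.default_rng(37)
    n = 120
    g_a = rng.integers(0, 3, n).astype(np.int8)
    g_b = rng.integers(0, 3, n).astype(np.int8)
    noise = rng.integers(0, 3, size=(n, 3)).astype(np.int8)
    risky = (g_a + g_b) % 2 == 1  # XOR-like rule, no marginal effect
    time = np.where(risky, 1.0, 5.0) + rng.random(n) * 0.1
    event = np.where(risky, 1, 0)
    event[~risky] = rng.integers(0, 2, (~risky).sum())
    data = SurvivalData(
        genotypes=np.column_stack([noise[:, 0], g_a, noise[:, 1], g_b, noise[:, 2]]),
        time=time,
        event=event,
        snp_names=["N0", "A", "N1", "B", "N2"],
    )
    sel = survdr.feature_select(data, 2, k=5, seed=1)
    assert set(sel.combo_names) == {"A", "B"}


def test_feature_select_column_order_invariance():
    rng = np.random.default_rng(41)
    data = random_dataset(rng, n=60, n_snps=4)
    sel = survdr.feature_select(data, 2, k=4, seed=2)
    perm = [2, 0, 3, 1]
    data_p = SurvivalData(
        genotypes=data.genotypes[:, perm],
        time=data.time,
        event=data.event,
        snp_names=[data.snp_names[i] for i in perm],
    )
    sel_p = survdr.feature_select(data_p, 2, k=4, seed=2)
    assert set(sel.combo_names) == set(sel_p.combo_names)
    assert sel.train_ibs == pytest.approx(sel_p.train_ibs, abs=1e-14)


def test_feature_select_recovers_causative_pair(epistatic_sample):
    sel = survdr.feature_select(epistatic_sample, 2, k=5, seed=7)
    assert set(sel.combo_names) == set(epistatic_sample.meta["causative"])


# ---------------------------------------------------------------------------
# meta validation
# ---------------------------------------------------------------------------

def test_meta_identical_fold_labels_recover_cohort_ibs():
    """With k=2 and both folds learning the same cell labels (and curves
    refitted on T_M), the meta-IBS equals the IBS of labelling the whole
    cohort at once."""
    rng = np.random.default_rng(43)
    n = 80
    g = np.tile([0, 1, 2], n)[:n].astype(np.int8)
    time = np.where(g == 1, 1.0, 4.0) + rng.random(n)
    event = np.ones(n, dtype=np.int8)
    data = SurvivalData(g[:, None], time, event, ["S0"])
    folds = cv_split(data, 2, seed=5)
    sels = [survdr.feature_select(data, 1, k=2, seed=5, folds=folds)]
    assert np.array_equal(sels[0].fold_labels[0], sels[0].fold_labels[1])
    model = survdr.meta_validate(
        data, sels, 2, 5, carry_training_curves=False, folds=folds
    )
    table = survdr.classify_cells(survdr.build_cells(data, ["S0"]), data)
    label_of = np.empty(n, dtype=int)
    for cell in table.cells.values():
        label_of[cell.members] = 0 if cell.label == HIGH_RISK else 1
    ctx = _FoldContext(data.time, data.event, data.genotypes)
    assert model.dimensions[0].meta_ibs == pytest.approx(
        _ibs_for_groups(ctx, label_of), abs=1e-12
    )


def test_meta_manual_assembly_oracle():
    """meta-IBS (refit mode) equals a hand-assembled merged testing set."""
    rng = np.random.default_rng(47)
    data = random_dataset(rng, n=45, n_snps=3)
    folds = cv_split(data, 3, seed=9)
    sel = survdr.feature_select(data, 1, k=3, seed=9, folds=folds)
    model = survdr.meta_validate(
        data, [sel], 3, 9, carry_training_curves=False, folds=folds
    )
    labels = np.full(data.n_subjects, -1)
    for f_i, test_idx in enumerate(folds):
        for i in test_idx:
            code = int(data.genotypes[i, sel.combo[0]])
            lab = sel.fold_labels[f_i][code]
            if lab == -1:
                lab = sel.fold_majority[f_i]
            labels[i] = lab
    ctx = _FoldContext(data.time, data.event, data.genotypes)
    assert model.dimensions[0].meta_ibs == pytest.approx(
        _ibs_for_groups(ctx, labels), abs=1e-12
    )


def test_meta_fold_mismatch_raises():
    rng = np.random.default_rng(53)
    data = random_dataset(rng, n=30, n_snps=2)
    sel = survdr.feature_select(data, 1, k=3, seed=1)
    with pytest.raises(ValueError, match="fold mismatch"):
        survdr.meta_validate(data, [sel], 3, seed=2)


def test_run_sdr_deterministic(epistatic_sample):
    a = survdr.run_sdr(epistatic_sample, k=5, max_dim=2, seed=3)
    b = survdr.run_sdr(epistatic_sample, k=5, max_dim=2, seed=3)
    assert a.final_combo == b.final_combo
    for da, db in zip(a.dimensions, b.dimensions):
        assert da.train_ibs == db.train_ibs
        assert da.meta_ibs == db.meta_ibs


def test_run_sdr_reports_final_model(epistatic_sample):
    model = survdr.run_sdr(epistatic_sample, k=5, max_dim=3, seed=3)
    assert model.final_dimension in (1, 2, 3)
    assert not model.degenerate
    assert len(model.dimensions) == 3
    # training IBS improves with dimension on a strong epistatic signal
    t = [d.train_ibs for d in model.dimensions]
    assert t[0] > t[1] > t[2]


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def test_permutation_pvalue_properties(null_sample):
    p, count = survdr.permutation_test(null_sample, k=5, max_dim=2, n_perm=19, seed=1)
    assert 0 < p <= 1
    assert p == pytest.approx((1 + count) / 20)
    p2, _ = survdr.permutation_test(null_sample, k=5, max_dim=2, n_perm=19, seed=1)
    assert p == p2


def test_permutation_detects_strong_signal(epistatic_sample):
    """A strong epistatic signal should sit in the low tail of the
    permutation distribution."""
    p, _ = survdr.permutation_test(epistatic_sample, k=5, max_dim=2, n_perm=29, seed=5)
    assert p <= 0.2
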