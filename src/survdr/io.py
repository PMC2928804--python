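"""Dataset and report I/O.

Datasets are flat delimited text files (MDR-style genotype matrix extended
with survival columns): a header row, one row per subject, genotype columns
coded 0/1/2, and two mandatory columns ``time`` (non-negative decimal) and
``event`` (0/1).  Tab or comma delimiting is auto-detected from the file
extension (.csv -> comma, anything else -> tab).  Missing values are
rejected with row/column diagnostics; genotype imputation is out of scope.

Analysis reports mirror the structure of the published SDR outputs: a
per-dimension table (dimension, SNPs, training IBS, meta-IBS, p), the
final model's cell grid (genotype tuple, n, % events, GM, label), the
pooled-group Kaplan-Meier curves for plotting, and a JSON file with full
provenance (seeds, k, policies, version).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import SurvivalData
from .engine import HIGH_RISK, LOW_RISK, SDRModel
from .survival import km_estimate

__all__ = ["read_dataset", "write_dataset", "write_results"]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_dataset(path, genotype_map: dict | None = None) -> SurvivalData:
    """Read and validate a delimited genotype-survival dataset.

    ``genotype_map`` optionally maps labelled 3-level factors (e.g. "AA",
    "Aa", "aa") onto {0, 1, 2} before validation.  Errors name the
    offending row (1-based, excluding the header) and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    df.columns = [c.strip() for c in df.columns]
    for col in ("time", "event"):
        if list(df.columns).count(col) != 1:
            raise ValueError(f"dataset must contain exactly one '{col}' column")

    snp_cols = [c for c in df.columns if c not in ("time", "event")]

    # missing cells anywhere are a hard error
    for col in df.columns:
        na = df[col].isna() | (df[col].str.strip() == "")
        if na.any():
            row = int(np.flatnonzero(na)[0]) + 1
            raise ValueError(f"missing value at row {row}, column '{col}'")

    try:
        time = df["time"].astype(float).to_numpy()
    except ValueError as exc:
        raise ValueError(f"non-numeric value in 'time' column: {exc}") from None
    bad = ~np.isfinite(time) | (time < 0)
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 1
        raise ValueError(f"invalid time at row {row}: times must be finite and >= 0")

    event_raw = df["event"].str.strip()
    if not event_raw.isin(["0", "1"]).all():
        row = int(np.flatnonzero(~event_raw.isin(["0", "1"]))[0]) + 1
        raise ValueError(f"invalid event indicator at row {row}: must be 0 or 1")
    event = event_raw.astype(int).to_numpy()

    geno = np.empty((len(df), len(snp_cols)), dtype=np.int8)
    for j, col in enumerate(snp_cols):
        vals = df[col].str.strip()
        if genotype_map:
            vals = vals.map(lambda v: str(genotype_map.get(v, v)))
        ok = vals.isin(["0", "1", "2"])
        if not ok.all():
            row = int(np.flatnonzero(~ok)[0]) + 1
            raise ValueError(
                f"invalid genotype {vals.iloc[row - 1]!r} at row {row}, "
                f"column '{col}': expected 0, 1 or 2"
            )
        geno[:, j] = vals.astype(int).to_numpy()

    return SurvivalData(genotypes=geno, time=time, event=event, snp_names=snp_cols)


def write_dataset(data: SurvivalData, path, manifest: bool = True) -> None:
    """Write a dataset in the dialect of :func:`read_dataset`.

    A sidecar ``<path>.manifest.json`` records the simulation metadata when
    present, for bit-exact reproducibility.
    """
    path = Path(path)
    df = data.to_dataframe()
    df.to_csv(path, sep=_sep_for(path), index=False)
    if manifest and data.meta:
        with open(f"{path}.manifest.json", "w") as fh:
            json.dump(data.meta, fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_results(model: SDRModel, data: SurvivalData, outdir) -> dict[str, Path]:
    """Write the SDR analysis report files; returns the paths written.

    Emits ``dimensions.tsv`` (one row per interaction order),
    ``cells.tsv`` (final model's multilocus cell grid), ``curves.tsv``
    (pooled high-/low-risk Kaplan-Meier curves on the full cohort) and
    ``report.json`` (full provenance).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    rows = []
    for d in model.dimensions:
        rows.append(
            {
                "n_way": d.n,
                "snps": ",".join(d.combo_names),
                "training_ibs": d.train_ibs,
                "meta_ibs": d.meta_ibs,
                "n_unseen": d.n_unseen,
                "p": (
                    model.permutation_pvalue
                    if (model.permutation_pvalue is not None and d.n == model.final_dimension)
                    else ""
                ),
            }
        )
    dims = pd.DataFrame(rows)
    paths["dimensions"] = outdir / "dimensions.tsv"
    dims.to_csv(paths["dimensions"], sep="\t", index=False)

    table = model.final_table
    cell_rows = []
    for genotype, cell in sorted(table.cells.items()):
        n_members = int(cell.members.size)
        pct_events = (
            100.0 * float(data.event[cell.members].mean()) if n_members else float("nan")
        )
        cell_rows.append(
            {
                "genotype": "/".join(map(str, genotype)),
                "n": n_members,
                "events_pct": pct_events,
                "gm": cell.gm if cell.gm is not None else float("nan"),
                "label": cell.label,
            }
        )
    paths["cells"] = outdir / "cells.tsv"
    pd.DataFrame(cell_rows).to_csv(paths["cells"], sep="\t", index=False)

    # pooled-group KM curves on the full cohort, from the final labelling
    label_by_subject = np.empty(data.n_subjects, dtype=object)
    for cell in table.cells.values():
        label_by_subject[cell.members] = cell.label
    curve_rows = []
    for lab in (HIGH_RISK, LOW_RISK):
        mask = label_by_subject == lab
        if not mask.any():
            continue
        curve = km_estimate(data.time[mask], data.event[mask])
        for t, s, r, e in zip(curve.grid, curve.surv, curve.at_risk, curve.n_events):
            curve_rows.append(
                {"group": lab, "time": t, "surv": s, "at_risk": r, "n_events": e}
            )
    paths["curves"] = outdir / "curves.tsv"
    pd.DataFrame(curve_rows).to_csv(paths["curves"], sep="\t", index=False)

    from . import __version__

    report = {
        "version": __version__,
        "k": model.k,
        "seed": model.seed,
        "empty_cell_policy": model.empty_cell_policy,
        "final_dimension": model.final_dimension,
        "final_combo": list(model.final_combo),
        "degenerate": model.degenerate,
        "permutation_pvalue": model.permutation_pvalue,
        "n_permutations": model.n_permutations,
        "n_permutations_as_extreme": model.n_permutations_as_extreme,
        "dimensions": [
            {
                "n_way": d.n,
                "snps": list(d.combo_names),
                "training_ibs": d.train_ibs,
                "meta_ibs": d.meta_ibs,
                "n_unseen": d.n_unseen,
            }
            for d in model.dimensions
        ],
        "n_subjects": data.n_subjects,
        "n_snps": data.n_snps,
        "censorship": data.censorship,
    }
    paths["report"] = outdir / "report.json"
    with open(paths["report"], "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
    return paths
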