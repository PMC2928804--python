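"""Replicated simulation-plus-detection experiments: power of SDR to
recover the causative SNP pair under each survival shape, heritability and
censorship design, with summaries across the condition grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import kruskal
from statsmodels.stats.proportion import proportion_confint

from .engine import feature_select, meta_validate, cv_split, _prepare_folds
from .simulate import (
    decompose_timepoints,
    generate_penetrance_model,
    sample_dataset,
    simulate_population,
    solve_distribution,
)

__all__ = ["PowerResult", "DESIGNS", "run_condition", "run_grid", "summarize"]

# censorship designs: (events drawn, censored drawn) per sample of 400
DESIGNS: dict[str, tuple[int, int]] = {"50%": (200, 200), "70%": (120, 280)}


@dataclass
class PowerResult:
    """Detection power of SDR for one (family, H2, censorship) condition."""

    family: str
    h2: float
    design: str
    n_replicates: int
    n_correct: int
    power: float
    ci_low: float
    ci_high: float
    replicate_seeds: list[int] = field(default_factory=list)
    n_failed: int = 0

    def as_dict(self) -> dict:
        return {
            "family": self.family,
            "h2": self.h2,
            "design": self.design,
            "n_replicates": self.n_replicates,
            "n_correct": self.n_correct,
            "power": self.power,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_failed": self.n_failed,
        }


def run_condition(
    family: str,
    h2: float,
    design: str = "50%",
    n_replicates: int = 25,
    k: int = 5,
    seed: int = 0,
    population_size: int = 65000,
    n_noise_snps: int = 13,
    n_intervals: int = 5,
    maf: float = 0.2,
    prevalence: float = 0.75,
    extra_censor_rate: float = 0.05,
    fresh_model: bool = False,
    score_mode: str = "best2way",
    max_dim: int = 3,
    _population=None,
) -> PowerResult:
    """Estimate detection power for one simulation condition.

    One penetrance model and one population are built per condition (with
    ``fresh_model`` a new model and population are drawn per replicate);
    each replicate draws a stratified study sample, runs SDR feature
    selection with k-fold cross-validation and counts a success when the
    selected SNP pair is exactly the causative pair.  ``score_mode``
    "best2way" scores the winning 2-way combination; "final_model"
    additionally requires meta validation across dimensions 1..max_dim to
    pick the 2-way model as the final one.
    """
    if design not in DESIGNS:
        raise ValueError(f"design must be one of {sorted(DESIGNS)}")
    if score_mode not in ("best2way", "final_model"):
        raise ValueError("score_mode must be 'best2way' or 'final_model'")
    n_events, n_censored = DESIGNS[design]

    master = np.random.default_rng(seed)
    dist = solve_distribution(family, K_target=prevalence)

    def build_population(model_seed, pop_seed):
        if h2 > 0:
            model = generate_penetrance_model(
                maf=maf, K_tn=prevalence, H2_target=h2, seed=model_seed
            )
        else:
            model = generate_penetrance_model(maf=maf, K_tn=prevalence, H2_target=0.0)
        model = decompose_timepoints(model, dist, n_intervals=n_intervals)
        return simulate_population(
            model,
            dist,
            n=population_size,
            n_noise_snps=n_noise_snps,
            extra_censor_rate=extra_censor_rate,
            seed=pop_seed,
        )

    population = _population
    if population is None and not fresh_model:
        population = build_population(
            int(master.integers(2 ** 31)), int(master.integers(2 ** 31))
        )

    n_correct = 0
    n_failed = 0
    seeds = []
    for _ in range(n_replicates):
        rep_seed = int(master.integers(2 ** 31))
        seeds.append(rep_seed)
        pop = population
        if fresh_model:
            pop = build_population(rep_seed, rep_seed + 1)
        try:
            sample = sample_dataset(pop, n_events, n_censored, seed=rep_seed)
            causative = set(pop.meta["causative"])
            if score_mode == "best2way":
                sel = feature_select(sample, 2, k=k, seed=rep_seed)
                correct = set(sel.combo_names) == causative
            else:
                folds = cv_split(sample, k, rep_seed)
                ctxs = _prepare_folds(sample, folds)
                sels = [
                    feature_select(sample, n, k, rep_seed, folds=folds, _ctxs=ctxs)
                    for n in range(1, max_dim + 1)
                ]
                model = meta_validate(sample, sels, k, rep_seed, folds=folds)
                correct = (
                    model.final_dimension == 2
                    and set(model.final_combo) == causative
                )
            n_correct += int(correct)
        except ValueError:
            n_failed += 1

    n_done = n_replicates - n_failed
    power = n_correct / n_done if n_done else float("nan")
    lo, hi = proportion_confint(n_correct, max(n_done, 1), alpha=0.05, method="wilson")
    return PowerResult(
        family=family,
        h2=h2,
        design=design,
        n_replicates=n_done,
        n_correct=n_correct,
        power=float(power),
        ci_low=float(lo),
        ci_high=float(hi),
        replicate_seeds=seeds,
        n_failed=n_failed,
    )


def run_grid(
    families=("EXP", "IFR", "UBT", "DFR", "BT"),
    h2_levels=(0.10, 0.15, 0.20, 0.25),
    designs=("50%", "70%"),
    n_replicates: int = 25,
    k: int = 5,
    seed: int = 0,
    population_size: int = 65000,
    **condition_kwargs,
) -> list[PowerResult]:
    """Power over a (family x heritability x censorship) condition grid.

    One epistatic population is built per (family, heritability) and both
    censorship designs draw their replicate samples from it, so the
    censorship contrast is paired on the same penetrance model.
    """
    master = np.random.default_rng(seed)
    results = []
    for fam in families:
        dist = solve_distribution(fam)
        for h2 in h2_levels:
            model_seed = int(master.integers(2 ** 31))
            pop_seed = int(master.integers(2 ** 31))
            model = generate_penetrance_model(H2_target=h2, seed=model_seed)
            model = decompose_timepoints(model, dist)
            population = simulate_population(
                model, dist, n=population_size, seed=pop_seed
            )
            for design in designs:
                cond_seed = int(master.integers(2 ** 31))
                results.append(
                    run_condition(
                        fam,
                        h2,
                        design=design,
                        n_replicates=n_replicates,
                        k=k,
                        seed=cond_seed,
                        _population=population,
                        **condition_kwargs,
                    )
                )
    return results


def _logistic(h2, a, b):
    return 1.0 / (1.0 + np.exp(-(a + b * np.asarray(h2, dtype=float))))


def summarize(results: list[PowerResult]) -> dict:
    """Aggregate a grid of power results.

    Returns the power grid as a DataFrame (families x censorship designs in
    rows, heritabilities in columns, powers in percent), the median and
    interquartile range of power across conditions, a least-squares
    logistic fit of power against cumulative heritability with its R^2 on
    the fitted scale, and a Kruskal-Wallis test of family independence.
    """
    if not results:
        raise ValueError("no results to summarise")
    rows = [r.as_dict() for r in results]
    df = pd.DataFrame(rows)
    table = (
        df.assign(power_pct=df["power"] * 100)
        .pivot_table(index=["family", "design"], columns="h2", values="power_pct")
        .sort_index()
    )
    powers = df["power"].to_numpy() * 100
    q1, med, q3 = np.percentile(powers, [25, 50, 75])

    out = {
        "table": table,
        "median_power_pct": float(med),
        "iqr_pct": (float(q1), float(q3)),
        "results": rows,
    }

    h2s = df["h2"].to_numpy(dtype=float)
    if np.unique(h2s).size >= 2:
        p = df["power"].to_numpy(dtype=float)
        try:
            popt, _ = curve_fit(_logistic, h2s, p, p0=(-2.0, 20.0), maxfev=10000)
            fitted = _logistic(h2s, *popt)
            ss_res = float(((p - fitted) ** 2).sum())
            ss_tot = float(((p - p.mean()) ** 2).sum())
            out["logistic_fit"] = {
                "a": float(popt[0]),
                "b": float(popt[1]),
                "r2": 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan"),
            }
        except RuntimeError:
            out["logistic_fit"] = None

    fams = df["family"].unique()
    if fams.size >= 2 and df.groupby("family").size().min() >= 2:
        groups = [df.loc[df["family"] == f, "power"].to_numpy() for f in fams]
        stat, pval = kruskal(*groups)
        out["family_independence"] = {"kruskal_h": float(stat), "p_value": float(pval)}
    return out
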