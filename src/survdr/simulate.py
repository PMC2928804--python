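"""Simulation of lifetime cohorts with a purely epistatic two-SNP effect.

The data-generating model has three layers:

1.  A population survival shape S(t) from the logistic-exponential family
    S0(t) = 1 / (1 + (exp(lambda*t) - 1)^kappa), left-shifted and
    renormalised as S(t) = S0(t + theta) / S0(theta) so that S(0) = 1.
    Five named shapes are provided -- EXP (constant hazard), IFR
    (increasing), DFR (decreasing), BT (bathtub) and UBT (upside-down
    bathtub) -- each calibrated so that the cumulative event prevalence at
    the end of observation, K(t_n) = 1 - S(t_n), hits a target value
    (default 0.750 at t_n = 5 time units).

2.  A 3x3 cumulative penetrance table f[g_A, g_B] for two biallelic SNPs in
    Hardy-Weinberg equilibrium, constructed so that the interaction is
    *purely epistatic*: both single-locus marginal penetrances equal the
    population prevalence K (no marginal effect whatsoever).  Effect sizes
    are requested as cumulative broad-sense heritability on the liability
    scale (the convention for reporting binary-trait heritabilities) and
    converted to observed-scale penetrance variance by the Dempster-Lerner
    factor; tables are drawn at random (seeded) from the zero-marginal
    manifold and rescaled exactly to that variance.

3.  A discrete-interval decomposition: the cumulative penetrance tables at
    the interior time points are proportional to the cumulative prevalence,
    F_i[g] = (K(t_i) / K(t_n)) * f[g], which preserves the zero-marginal
    property at every time point; the per-interval (time-point) penetrances
    follow by product-limit inversion,
    G_i[g] = (F_i[g] - F_{i-1}[g]) / (1 - F_{i-1}[g]).

Populations are then simulated interval by interval: given survival to
t_{i-1}, a subject of genotype g has an event in interval i with
probability G_i[g]; an independent censoring clock removes subjects with a
fixed per-interval probability; survivors are right-censored at t_n.
Unlinked noise SNPs are appended and all genotype columns are shuffled so
the causative pair sits at a random position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .data import SurvivalData

__all__ = [
    "FAMILY_SHAPES",
    "SurvivalDistribution",
    "PenetranceModel",
    "logistic_exponential_survival",
    "solve_distribution",
    "generate_penetrance_model",
    "decompose_timepoints",
    "simulate_population",
    "sample_dataset",
]

# (kappa, theta) per family; lambda is solved from the prevalence target.
# kappa = 1 gives the exponential special case; kappa > 1 yields a hazard
# that rises to a peak and then falls to its asymptote lambda*kappa, so the
# shift theta selects the window: theta = 0 keeps the rising branch (IFR),
# a moderate shift straddles the peak (UBT), a large shift lands past it
# (DFR).  kappa < 1 with no shift covers the bathtub (BT) regime.
FAMILY_SHAPES: dict[str, tuple[float, float]] = {
    "EXP": (1.0, 0.0),
    "IFR": (2.0, 0.0),
    "UBT": (2.0, 8.0),
    "DFR": (2.0, 20.0),
    "BT": (0.5, 0.0),
}

_SHAPE_PATTERN = {
    "EXP": "constant",
    "IFR": "increasing",
    "UBT": "up-down",
    "DFR": "decreasing",
    "BT": "down-up",
}


@dataclass
class SurvivalDistribution:
    """A calibrated logistic-exponential survival distribution."""

    family: str
    lam: float          # scale, > 0
    kappa: float        # shape, > 0
    theta: float        # left shift, >= 0
    t_n: float          # end of observation (time units)

    def survival(self, t) -> np.ndarray:
        return logistic_exponential_survival(t, self)

    @property
    def prevalence(self) -> float:
        """Cumulative event prevalence K(t_n) = 1 - S(t_n)."""
        return float(1.0 - self.survival(self.t_n))


def _log_s0(t, lam, kappa):
    # log S0 = -log(1 + (e^{lam t} - 1)^kappa), evaluated in log space so the
    # solver can probe large lam*t without overflow;
    # ln(e^z - 1) = z + ln(1 - e^-z)
    z = lam * np.asarray(t, dtype=float)
    with np.errstate(divide="ignore"):
        log_x = z + np.log1p(-np.exp(-z))          # -inf at z = 0
    return -np.logaddexp(0.0, kappa * log_x)


def logistic_exponential_survival(t, dist: SurvivalDistribution):
    """S(t) = S0(t + theta) / S0(theta) with S0 the logistic-exponential form.

    The shift-renormalisation guarantees S(0) = 1 for any theta >= 0.
    """
    if dist.lam <= 0 or dist.kappa <= 0:
        raise ValueError("lambda and kappa must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = np.exp(
        _log_s0(t + dist.theta, dist.lam, dist.kappa)
        - _log_s0(dist.theta, dist.lam, dist.kappa)
    )
    return out if out.ndim else float(out)


def _hazard_pattern(dist: SurvivalDistribution, m: int = 801) -> str:
    """Numeric monotonicity pattern of the hazard on (0, t_n)."""
    t = np.linspace(dist.t_n / m, dist.t_n, m)
    h = -np.gradient(np.log(dist.survival(t)), t)
    d = np.diff(h)
    # the bathtub's rising tail is shallow (steps ~1e-5) next to its initial
    # hazard; finite-difference noise is ~1e-13, so 1e-8 relative separates them
    tol = 1e-8 * max(np.abs(h).max(), 1e-12)
    rising, falling = d > tol, d < -tol
    if not rising.any() and not falling.any():
        return "constant"
    if not falling.any():
        return "increasing"
    if not rising.any():
        return "decreasing"
    return "up-down" if int(np.argmax(rising)) < int(np.argmax(falling)) else "down-up"


def solve_distribution(family: str, K_target: float = 0.75, t_n: float = 5.0) -> SurvivalDistribution:
    """Calibrate lambda so that 1 - S(t_n) equals ``K_target``.

    kappa and theta are fixed per family (:data:`FAMILY_SHAPES`); the scale
    is solved by bisection to |1 - S(t_n) - K| < 1e-6 and the resulting
    hazard's finite-difference shape is verified against the family's
    monotonicity pattern.
    """
    if family not in FAMILY_SHAPES:
        raise ValueError(f"unknown family {family!r}; choose from {sorted(FAMILY_SHAPES)}")
    if not 0 < K_target < 1:
        raise ValueError("K_target must be in (0, 1)")
    kappa, theta = FAMILY_SHAPES[family]

    def objective(lam):
        d = SurvivalDistribution(family, lam, kappa, theta, t_n)
        return d.survival(t_n) - (1.0 - K_target)

    try:
        lam = brentq(objective, 1e-9, 50.0, xtol=1e-12)
    except ValueError as exc:
        raise RuntimeError(
            f"calibration failed for family {family}: no scale in (1e-9, 50) "
            f"reaches prevalence {K_target} at t_n={t_n}"
        ) from exc
    dist = SurvivalDistribution(family, float(lam), kappa, theta, float(t_n))
    if abs(dist.prevalence - K_target) > 1e-6:
        raise RuntimeError(f"calibration residual too large for family {family}")
    pattern = _hazard_pattern(dist)
    if pattern != _SHAPE_PATTERN[family]:
        raise RuntimeError(
            f"hazard shape check failed for {family}: expected "
            f"{_SHAPE_PATTERN[family]}, observed {pattern}"
        )
    return dist


# ---------------------------------------------------------------------------
# penetrance models
# ---------------------------------------------------------------------------

def _hwe_probs(maf: float) -> np.ndarray:
    if not 0 < maf <= 0.5:
        raise ValueError("minor allele frequency must be in (0, 0.5]")
    q = maf
    p = 1.0 - q
    return np.array([p * p, 2 * p * q, q * q])


def _heritability(f: np.ndarray, probs: np.ndarray, K: float) -> float:
    return float((probs * (f - K) ** 2).sum() / (K * (1.0 - K)))


def liability_to_observed_h2(h2_liability: float, K: float) -> float:
    """Convert a liability-scale heritability to the observed (0/1) scale.

    Binary-trait heritabilities are conventionally reported on the liability
    scale; under the threshold model the observed-scale value is
    h2_obs = h2_liab * phi(z)^2 / (K (1 - K)) with z the standard-normal
    quantile of the prevalence K (Dempster-Lerner transformation).
    """
    if not 0 < K < 1:
        raise ValueError("K must be in (0, 1)")
    z = stats.norm.ppf(1.0 - K)
    return float(h2_liability * stats.norm.pdf(z) ** 2 / (K * (1.0 - K)))


def pooled_hazard_ratio_of_table(
    f: np.ndarray, probs: np.ndarray, K: float, K_t: np.ndarray
) -> float:
    """Asymptotic Cox-type hazard ratio of the table's high vs low cells.

    Cells with penetrance above K form the high-risk group.  Under the
    proportional cumulative decomposition (cumulative tables scale with the
    population prevalence path ``K_t``) the pooled group survival curves
    are mixtures over cells; the event-weighted average of the per-interval
    log cumulative-hazard increments reproduces the large-sample Cox
    estimate to a few parts in a thousand.
    """
    hi = f > K
    if not hi.any() or hi.all():
        return 1.0
    F = np.einsum("i,jk->ijk", K_t / K, f)
    S = np.concatenate((np.ones((1, 3, 3)), 1.0 - F))
    w_hi, w_lo = probs[hi], probs[~hi]
    S_h = (S[:, hi] * w_hi).sum(axis=1) / w_hi.sum()
    S_l = (S[:, ~hi] * w_lo).sum(axis=1) / w_lo.sum()
    d_h = np.diff(-np.log(S_h))
    d_l = np.diff(-np.log(S_l))
    events = w_hi.sum() * (S_h[:-1] - S_h[1:]) + w_lo.sum() * (S_l[:-1] - S_l[1:])
    return float(np.exp((events * np.log(d_h / d_l)).sum() / events.sum()))


@dataclass
class PenetranceModel:
    """Two-locus purely epistatic penetrance model with time decomposition.

    ``cum_penetrance[gA, gB]`` is the probability of an event by the end of
    observation for genotype (gA, gB); its P-weighted mean is the prevalence
    ``K_tn`` and both single-locus marginals equal ``K_tn`` exactly (no
    marginal effect).  ``h2_liability`` is the requested heritability on
    the liability scale; ``H2_tn`` is the corresponding observed-scale
    broad-sense heritability sum_g P(g) (f_g - K)^2 / (K (1 - K)) that the
    table realises exactly.  ``hr`` reports the pooled high/low-risk
    hazard ratio the table implies (informational; see
    :func:`pooled_hazard_ratio_of_table`).  After
    :func:`decompose_timepoints` the model also carries, per interior time
    point t_i, the cumulative tables ``cum_penetrance_t[i]``, the
    per-interval tables ``timepoint_penetrance[i]`` and the cumulative
    heritabilities ``H2_t``.
    """

    maf: float
    genotype_probs: np.ndarray          # 3x3 HWE cell probabilities
    cum_penetrance: np.ndarray          # 3x3, values in [0, 1]
    K_tn: float
    H2_tn: float
    h2_liability: float = 0.0
    hr: float = 1.0
    seed: int | None = None
    intervals: np.ndarray | None = None           # boundaries t_0=0 < ... < t_n
    K_t: np.ndarray | None = None                 # cumulative prevalence per t_i
    cum_penetrance_t: np.ndarray | None = None    # (n_int, 3, 3)
    timepoint_penetrance: np.ndarray | None = None  # (n_int, 3, 3)
    H2_t: np.ndarray | None = None                # cumulative H^2 per t_i

    def marginal_residual(self) -> float:
        """Largest deviation of any single-locus marginal from K (all t_i)."""
        pa = _hwe_probs(self.maf)
        tables = [(self.cum_penetrance, self.K_tn)]
        if self.cum_penetrance_t is not None:
            tables += [(F, K) for F, K in zip(self.cum_penetrance_t, self.K_t)]
        worst = 0.0
        for F, K in tables:
            worst = max(
                worst,
                float(np.abs(F @ pa - K).max()),
                float(np.abs(pa @ F - K).max()),
            )
        return worst


def generate_penetrance_model(
    maf: float = 0.2,
    K_tn: float = 0.75,
    H2_target: float = 0.10,
    seed: int = 0,
    max_tries: int = 5000,
) -> PenetranceModel:
    """Draw a purely epistatic 3x3 penetrance table at the target heritability.

    ``H2_target`` is the cumulative broad-sense heritability on the
    liability scale (the convention in which binary-trait heritabilities
    are reported); it is converted to an observed-scale penetrance variance
    via :func:`liability_to_observed_h2`.  The zero-marginal constraint set
    is a 4-dimensional linear manifold through the constant table f = K; a
    random direction is drawn in that manifold (seeded), scaled exactly to
    the target variance, and accepted if all nine penetrances stay inside
    [0, 1].  ``H2_target = 0`` returns the unique constant table.
    """
    if not 0 < K_tn < 1:
        raise ValueError("K_tn must be in (0, 1)")
    if H2_target < 0:
        raise ValueError("H2_target must be >= 0")
    pa = _hwe_probs(maf)
    probs = np.outer(pa, pa)

    if H2_target == 0:
        f = np.full((3, 3), K_tn)
        return PenetranceModel(maf, probs, f, K_tn, 0.0, h2_liability=0.0, seed=seed)

    h2_obs = liability_to_observed_h2(H2_target, K_tn)
    target_var = h2_obs * K_tn * (1.0 - K_tn)
    # prevalence path (constant hazard) used only for the informational HR
    t_frac = np.arange(1, 6) / 5.0
    K_path = 1.0 - (1.0 - K_tn) ** t_frac

    # orthonormal basis of the zero-P-mean subspace of R^3 (per locus)
    _, _, vt = np.linalg.svd(pa[None, :])
    basis = vt[1:]                       # 2 x 3

    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        c = rng.standard_normal((2, 2))
        delta = np.einsum("kl,ki,lj->ij", c, basis, basis)
        v = (probs * delta * delta).sum()
        if v <= 0:
            continue
        f = K_tn + np.sqrt(target_var / v) * delta
        if (f >= 0).all() and (f <= 1).all():
            model = PenetranceModel(
                maf,
                probs,
                f,
                K_tn,
                _heritability(f, probs, K_tn),
                h2_liability=H2_target,
                hr=pooled_hazard_ratio_of_table(f, probs, K_tn, K_path),
                seed=seed,
            )
            if model.marginal_residual() > 1e-9:
                continue
            return model
    raise ValueError(
        f"infeasible heritability target: no table in [0,1]^9 found for "
        f"H2={H2_target} (observed-scale {h2_obs:.4f}), K={K_tn}, "
        f"MAF={maf} after {max_tries} draws"
    )


def decompose_timepoints(
    model: PenetranceModel,
    dist: SurvivalDistribution,
    n_intervals: int = 5,
) -> PenetranceModel:
    """Split the cumulative model into per-interval penetrance tables.

    Interval boundaries are equally spaced on (0, t_n].  The cumulative
    penetrance tables at every boundary are proportional to the survival
    distribution's cumulative prevalence, which keeps the construction
    purely epistatic at each time point, and the per-interval hazards are
    recovered by product-limit inversion (module docstring).  With a single
    interval the time-point table equals the cumulative table.
    """
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    bounds = np.linspace(0.0, dist.t_n, n_intervals + 1)
    K_t = 1.0 - dist.survival(bounds[1:])
    K_end = K_t[-1]
    if abs(K_end - model.K_tn) > 1e-6:
        raise ValueError(
            "distribution prevalence does not match the penetrance model's K_tn"
        )

    F = np.einsum("i,jk->ijk", K_t / K_end, model.cum_penetrance)
    F_prev = np.concatenate((np.zeros((1, 3, 3)), F[:-1]), axis=0)
    G = (F - F_prev) / (1.0 - F_prev)
    if np.any(G < -1e-12) or np.any(G > 1 + 1e-12):
        raise ValueError("infeasible time decomposition: interval penetrance outside [0, 1]")
    G = np.clip(G, 0.0, 1.0)

    H2_t = np.array([_heritability(Fi, model.genotype_probs, Ki) for Fi, Ki in zip(F, K_t)])
    return PenetranceModel(
        maf=model.maf,
        genotype_probs=model.genotype_probs,
        cum_penetrance=model.cum_penetrance,
        K_tn=model.K_tn,
        H2_tn=model.H2_tn,
        seed=model.seed,
        intervals=bounds,
        K_t=K_t,
        cum_penetrance_t=F,
        timepoint_penetrance=G,
        H2_t=H2_t,
    )


# ---------------------------------------------------------------------------
# population simulation and sampling
# ---------------------------------------------------------------------------

def _draw_hwe(rng, maf, n):
    u = rng.random(n)
    cum = np.cumsum(_hwe_probs(maf))
    return np.searchsorted(cum, u).astype(np.int8)


def simulate_population(
    model: PenetranceModel,
    dist: SurvivalDistribution,
    n: int = 65000,
    n_noise_snps: int = 13,
    noise_maf_range: tuple[float, float] = (0.1, 0.5),
    extra_censor_rate: float = 0.05,
    seed: int = 0,
) -> SurvivalData:
    """Simulate a lifetime population under the epistatic model.

    Per subject: the causative genotype pair is drawn from the HWE cell
    probabilities; interval by interval, an event occurs with the genotype's
    time-point penetrance, otherwise an independent censoring clock fires
    with probability ``extra_censor_rate`` per time unit; event and
    censoring times are recorded at the interval's right boundary and
    survivors are censored at t_n.  Noise SNPs are drawn from HWE at minor
    allele frequencies evenly covering ``noise_maf_range`` and all genotype
    columns are shuffled (seeded) so the causative pair's position is
    random.  The causative column names are recorded in ``meta``.
    """
    if model.timepoint_penetrance is None:
        raise ValueError("model has no time decomposition; call decompose_timepoints first")
    if not 0 <= extra_censor_rate < 1:
        raise ValueError("extra_censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_int = model.timepoint_penetrance.shape[0]
    bounds = model.intervals

    flat_probs = model.genotype_probs.ravel()
    pair = np.searchsorted(np.cumsum(flat_probs), rng.random(n)).astype(np.int8)
    g_a, g_b = pair // 3, pair % 3

    time = np.full(n, float(bounds[-1]))
    event = np.zeros(n, dtype=np.int8)
    alive = np.ones(n, dtype=bool)
    hazards = model.timepoint_penetrance.reshape(n_int, 9)[:, pair]  # (n_int, n)
    for i in range(n_int):
        u_event = rng.random(n)
        u_cens = rng.random(n)
        hit = alive & (u_event < hazards[i])
        time[hit] = bounds[i + 1]
        event[hit] = 1
        cens = alive & ~hit & (u_cens < extra_censor_rate)
        time[cens] = bounds[i + 1]
        alive &= ~(hit | cens)
    # survivors keep time = t_n, event = 0

    cols = [g_a, g_b]
    mafs = np.linspace(noise_maf_range[0], noise_maf_range[1], n_noise_snps) if n_noise_snps else []
    for m in mafs:
        cols.append(_draw_hwe(rng, float(m), n))
    geno = np.column_stack(cols)
    order = rng.permutation(geno.shape[1])
    geno = geno[:, order]
    names = [f"SNP{j + 1:02d}" for j in range(geno.shape[1])]
    causative = [names[int(np.flatnonzero(order == j)[0])] for j in (0, 1)]

    meta = {
        "family": dist.family,
        "lambda": dist.lam,
        "kappa": dist.kappa,
        "theta": dist.theta,
        "t_n": dist.t_n,
        "K_tn": model.K_tn,
        "H2_tn": model.H2_tn,
        "h2_liability": model.h2_liability,
        "hazard_ratio": model.hr,
        "maf": model.maf,
        "n_intervals": n_int,
        "extra_censor_rate": extra_censor_rate,
        "seed": seed,
        "causative": causative,
        "cum_penetrance": model.cum_penetrance.tolist(),
        "timepoint_penetrance": model.timepoint_penetrance.tolist(),
    }
    return SurvivalData(genotypes=geno, time=time, event=event, snp_names=names, meta=meta)


def sample_dataset(
    population: SurvivalData,
    n_events: int,
    n_censored: int,
    seed: int = 0,
) -> SurvivalData:
    """Stratified random draw of a study sample from a simulated population.

    Draws ``n_events`` subjects with an observed event ("cases") and
    ``n_censored`` right-censored subjects ("controls") uniformly without
    replacement, e.g. 200/200 for 50% censorship or 120/280 for 70%.
    """
    rng = np.random.default_rng(seed)
    ev = np.flatnonzero(population.event == 1)
    ce = np.flatnonzero(population.event == 0)
    if ev.size < n_events or ce.size < n_censored:
        raise ValueError(
            f"insufficient stratum: population has {ev.size} events / "
            f"{ce.size} censored, requested {n_events} / {n_censored}"
        )
    idx = np.concatenate(
        (rng.choice(ev, size=n_events, replace=False),
         rng.choice(ce, size=n_censored, replace=False))
    )
    idx = idx[rng.permutation(idx.size)]
    out = population.subset(idx)
    out.meta["sample_seed"] = seed
    out.meta["n_events_drawn"] = n_events
    out.meta["n_censored_drawn"] = n_censored
    return out
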