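"""Shared fixtures: small random cohorts and simulated epistatic samples."""

from __future__ import annotations

import numpy as np
import pytest

import survdr


def random_cohort(rng, n=None, discrete=False):
    """A small random right-censored cohort (times > 0, mixed events)."""
    if n is None:
        n = int(rng.integers(3, 31))
    if discrete:
        times = rng.integers(1, 6, size=n).astype(float)
    else:
        times = np.round(rng.exponential(3.0, size=n), 3) + 0.001
    events = rng.integers(0, 2, size=n)
    if events.sum() == 0:
        events[int(rng.integers(n))] = 1
    return times, events


def random_dataset(rng, n=80, n_snps=4):
    """A random genotype-survival dataset with no built-in association."""
    geno = rng.integers(0, 3, size=(n, n_snps)).astype(np.int8)
    times, events = random_cohort(rng, n=n)
    return survdr.SurvivalData(
        genotypes=geno,
        time=times,
        event=events,
        snp_names=[f"S{i}" for i in range(n_snps)],
    )


@pytest.fixture(scope="session")
def epistatic_sample():
    """A 400-subject sample (200 events / 200 censored) with a strong
    two-SNP purely epistatic effect among 15 SNPs."""
    dist = survdr.solve_distribution("EXP")
    model = survdr.generate_penetrance_model(H2_target=0.25, seed=11)
    model = survdr.decompose_timepoints(model, dist)
    pop = survdr.simulate_population(model, dist, n=30000, seed=12)
    sample = survdr.sample_dataset(pop, 200, 200, seed=13)
    sample.meta["causative"] = pop.meta["causative"]
    return sample


@pytest.fixture(scope="session")
def null_sample():
    """A 200-subject sample with genotypes independent of outcome (8 SNPs)."""
    dist = survdr.solve_distribution("EXP")
    model = survdr.generate_penetrance_model(H2_target=0.0)
    model = survdr.decompose_timepoints(model, dist)
    pop = survdr.simulate_population(model, dist, n=8000, n_noise_snps=6, seed=21)
    return survdr.sample_dataset(pop, 100, 100, seed=22)
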