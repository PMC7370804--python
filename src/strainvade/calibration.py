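"""Calibration and recovery experiments.

Self-contained, seeded experiments that measure how well the pipeline's
statistics behave under known conditions: share recovery of the
demultiplexer on simulated reads, type-I error and oracle agreement of the
PERMANOVA permutation test, coverage and power of the invasion-yield
confidence interval, and recovery of planted strain-success rankings.
These back the test suite and the reproduction script; they are ordinary
library code and can be rerun with any seed.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .demux import BASELINE, END, match_reads, relative_shares, strain_gain_loss
from .ordination import bray_curtis, permanova
from .stats import MicrocosmDesign, diversity_effect, strain_success_summary
from .synthetic import (
    SimulationConfig,
    make_marker_db,
    make_traits,
    simulate_microcosm,
    simulate_reads,
)


def demux_recovery_rate(
    n_seeds: int = 20, depth: int = 10_000, seed: int = 0
) -> dict:
    """Fraction of strain-sample cells whose demultiplexed share lands
    within 3 multinomial standard deviations of the true biomass share.

    Error-free reads, no copy bias; strain richness cycles through 2–10.
    """
    rng = np.random.default_rng(seed)
    n_ok = 0
    n_cells = 0
    for i in range(n_seeds):
        k = 2 + i % 9  # 2..10 strains
        strains = [f"S{j + 1:02d}" for j in range(k)]
        db = make_marker_db(strains, seed=int(rng.integers(2**31)), length=80)
        biomass = dict(zip(strains, rng.uniform(0.1, 1.0, k)))
        total = sum(biomass.values())
        reads = simulate_reads(biomass, db, depth,
                               seed=int(rng.integers(2**31)))
        counts = match_reads(reads, db)
        table = relative_shares(counts, BASELINE, labels=set(strains))
        for s in strains:
            p = biomass[s] / total
            sd = np.sqrt(p * (1 - p) / depth)
            n_cells += 1
            if abs(table.shares[s] - p) <= 3 * sd:
                n_ok += 1
    return {"fraction_within_3sd": n_ok / n_cells, "n_cells": n_cells}


def _block_distance() -> np.ndarray:
    d = np.ones((4, 4)) - np.eye(4)
    d[0, 1] = d[1, 0] = 0.0
    d[2, 3] = d[3, 2] = 0.0
    return d


def permanova_oracle_check(seed: int = 0, n_perm: int = 100_000) -> list[dict]:
    """Sampled vs exhaustive permutation p on small (n ≤ 8) instances.

    Returns one record per instance with both p-values and the Monte-Carlo
    standard error of the sampled estimate; the first instance is the
    constructed two-block case whose exhaustive p is exactly 1/3.
    """
    rng = np.random.default_rng(seed)
    instances = [("two_block_n4", _block_distance(), ["a", "a", "b", "b"])]
    for n, sizes in ((6, (3, 3)), (7, (3, 4)), (8, (4, 4)), (8, (2, 3, 3))):
        m = rng.uniform(0.1, 1.0, (n, 4))
        labels = [chr(97 + g) for g, sz in enumerate(sizes) for _ in range(sz)]
        instances.append((f"random_n{n}_{len(sizes)}groups",
                          bray_curtis(m).to_numpy(), labels))
    out = []
    for name, dist, labels in instances:
        exact = permanova(dist, labels, exhaustive=True)
        sampled = permanova(dist, labels, n_perm=n_perm,
                            seed=int(rng.integers(2**31)), exhaustive=False)
        se = float(np.sqrt(exact.p_value * (1 - exact.p_value) / n_perm))
        out.append({
            "instance": name,
            "p_exhaustive": exact.p_value,
            "p_sampled": sampled.p_value,
            "mc_se": se,
            "within_3se": abs(sampled.p_value - exact.p_value) <= 3 * se
            + 2 / n_perm,
        })
    return out


def permanova_type_i_error(
    n_runs: int = 1000, alpha: float = 0.05, n_perm: int = 199,
    n_samples: int = 12, n_groups: int = 3, n_species: int = 4,
    seed: int = 0,
) -> dict:
    """Rejection rate of the PERMANOVA permutation test on exchangeable
    null communities (lognormal abundances, labels carry no signal)."""
    rng = np.random.default_rng(seed)
    per = n_samples // n_groups
    labels = [chr(97 + g) for g in range(n_groups) for _ in range(per)]
    rejections = 0
    for _ in range(n_runs):
        m = rng.lognormal(0.0, 0.5, (n_samples, n_species))
        d = bray_curtis(m)
        res = permanova(d, labels, n_perm=n_perm,
                        seed=int(rng.integers(2**31)), exhaustive=False)
        rejections += res.p_value <= alpha
    return {"type_i_error": rejections / n_runs, "n_runs": n_runs,
            "alpha": alpha}


def yield_ci_calibration(
    n_runs: int = 1000, n: int = 15, sigma: float = 0.2,
    effect: float = 0.5, seed: int = 0,
) -> dict:
    """Coverage of the 95% Student-t CI under the null (true log-yield 0)
    and power of the positivity rule for a planted diversity benefit."""
    rng = np.random.default_rng(seed)
    covered = 0
    for _ in range(n_runs):
        [res] = diversity_effect({3: rng.normal(0.0, sigma, n).tolist()})
        covered += res.ci_low <= 0.0 <= res.ci_high
    flagged = 0
    for _ in range(n_runs):
        [res] = diversity_effect({3: rng.normal(effect, sigma, n).tolist()})
        flagged += res.positive_effect
    return {
        "null_ci_coverage": covered / n_runs,
        "planted_positive_rate": flagged / n_runs,
        "n_runs": n_runs, "n": n, "sigma": sigma, "effect": effect,
    }


def consistency_recovery_rate(
    n_runs: int = 100, n_strains: int = 5, mixture_size: int = 3,
    depth: int = 10_000, seed: int = 0,
) -> dict:
    """How often the single-vs-mixture Spearman consistency is positive
    when strain growth rates span a planted 2× range.

    Each run simulates monocultures of every strain plus all
    C(n_strains, mixture_size) mixtures (10 for 5 strains in threes),
    generates error-free reads at the given depth, demultiplexes them and
    computes the consistency correlation between single-strain endpoint
    community shares and mean in-mixture share gains.
    """
    rng = np.random.default_rng(seed)
    positive = 0
    rhos = []
    for _ in range(n_runs):
        run_seed = int(rng.integers(2**31))
        rho = _one_consistency_run(run_seed, n_strains, mixture_size, depth)
        rhos.append(rho)
        positive += rho > 0
    return {
        "fraction_rho_positive": positive / n_runs,
        "median_rho": float(np.median(rhos)),
        "n_runs": n_runs,
    }


def _one_consistency_run(seed, n_strains, mixture_size, depth) -> float:
    rng = np.random.default_rng(seed)
    traits = make_traits(n_strains, int(rng.integers(2**31)))
    strains = sorted(traits)
    db = make_marker_db(strains, int(rng.integers(2**31)), length=80)
    config = SimulationConfig(
        herbivore_regime="none", seed=seed, n_strains=n_strains,
        diversity_levels=(1,), replicates_per_level=(1,), read_depth=depth,
    )
    end_day = config.duration_days

    singles = {}
    for s in strains:
        d = MicrocosmDesign(f"single_{s}", "cal", 1, (s,), "none", 0.0)
        sim = simulate_microcosm(d, traits, config, int(rng.integers(2**31)))
        inv = sim.strain_biomass.loc[end_day].sum()
        total = inv + sim.resident_biomass.loc[end_day].sum()
        singles[s] = [inv / total]

    gainloss = []
    mixture_end = {}
    for i, combo in enumerate(combinations(strains, mixture_size)):
        d = MicrocosmDesign(f"mix{i:02d}", "cal", mixture_size, combo,
                            "none", 0.0)
        sim = simulate_microcosm(d, traits, config, int(rng.integers(2**31)))
        tables = {}
        for day, tp in ((config.invasion_day, BASELINE), (end_day, END)):
            biomass = sim.strain_biomass.loc[day].to_dict()
            reads = simulate_reads(biomass, db, depth,
                                   seed=int(rng.integers(2**31)))
            counts = match_reads(reads, db)
            tables[tp] = relative_shares(counts, tp, labels=set(combo))
        gainloss.append(strain_gain_loss(tables[BASELINE], tables[END],
                                         mixture_id=d.microcosm_id))
        for s, share in tables[END].shares.items():
            mixture_end.setdefault(s, []).append(share)

    _, consistency = strain_success_summary(mixture_end, singles, gainloss)
    return consistency["rho"]
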