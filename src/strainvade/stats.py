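"""Invasion-success statistics.

The central quantity is the invasion yield of a multi-strain mixture:
ln(observed / expected), where the observed yield is the invader's endpoint
share of total community biomass and the expected yield derives from the
single-strain treatments under the substitutive-design null — each of the k
strains enters at 1/k of the total inoculum, so the null expectation is the
unweighted mean of the component strains' monoculture yields.  Per
strain-richness level the mean log-yield and its two-sided 95% Student-t
confidence interval are reported; a diversity benefit is called only when
the mean is positive AND the CI excludes zero.

Strain-specific success is summarised by the coefficient of variation of
community shares, dominance counts (end share > 66% in a mixture) and the
Spearman rank consistency between single-strain and in-mixture success.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .demux import DOMINANCE_THRESHOLD, GainLossTable

logger = logging.getLogger(__name__)

HERBIVORE_TYPES = ("none", "generalist", "specialist")


@dataclass(frozen=True)
class MicrocosmDesign:
    """One microcosm: which strains were introduced, under which grazer regime."""

    microcosm_id: str
    experiment_id: str
    diversity_level: int
    strain_set: tuple[str, ...]
    herbivore: str = "none"
    herbivore_initial_density: float = 0.0
    replicate_index: int = 0

    def __post_init__(self) -> None:
        if self.diversity_level < 0:
            raise ValueError("diversity_level must be ≥ 0")
        if len(set(self.strain_set)) != self.diversity_level:
            raise ValueError(
                f"{self.microcosm_id}: |strain_set| must equal diversity_level"
            )
        if self.herbivore not in HERBIVORE_TYPES:
            raise ValueError(f"herbivore must be one of {HERBIVORE_TYPES}")
        if self.herbivore_initial_density < 0:
            raise ValueError("herbivore density must be ≥ 0")


@dataclass
class InvasionYieldResult:
    """Mean log invasion yield of one diversity level with its 95% CI."""

    diversity_level: int
    n: int
    mean_log_yield: float
    ci_low: float
    ci_high: float
    positive_effect: bool
    n_excluded_zero: int = 0
    ci_defined: bool = True


@dataclass
class StrainSuccessSummary:
    """Endpoint performance of one strain across mixtures."""

    strain_id: str
    mean_share: float
    sd_share: float
    n: int
    dominant_count: int


def expected_yield(
    strain_set: Iterable[str], single_strain_yields: Mapping[str, float]
) -> float:
    """Substitutive-design null expectation for a mixture's yield.

    Arithmetic mean of the component strains' mean single-strain yields:
    each strain enters at 1/k of the total inoculum and contributes 1/k of
    its monoculture yield under the null of no diversity effect.
    """
    strains = list(strain_set)
    if not strains:
        raise ValueError("empty strain set")
    missing = [s for s in strains if s not in single_strain_yields]
    if missing:
        raise KeyError(f"no single-strain yield for strain(s): {missing}")
    return float(np.mean([single_strain_yields[s] for s in strains]))


def invasion_yield(observed: float, expected: float) -> float:
    """ln(observed / expected).  observed = 0 returns the −inf sentinel."""
    if expected <= 0:
        raise ValueError("expected yield must be > 0")
    if observed < 0:
        raise ValueError("observed yield must be ≥ 0")
    if observed == 0:
        logger.warning("observed yield 0: returning -inf sentinel (excluded from means)")
        return float("-inf")
    return math.log(observed / expected)


def diversity_effect(
    yields_by_level: Mapping[int, Sequence[float]], ci_level: float = 0.95
) -> list[InvasionYieldResult]:
    """Per-level mean log-yield, Student-t CI and the positivity verdict.

    −inf sentinels (failed invasions) are excluded from the mean with a
    warning and reported in ``n_excluded_zero``.  A level with fewer than
    two finite values gets no CI (``ci_defined=False``) and cannot be
    called positive.
    """
    results = []
    for level in sorted(yields_by_level):
        values = np.asarray(list(yields_by_level[level]), dtype=float)
        finite = values[np.isfinite(values)]
        n_excl = int(values.size - finite.size)
        if n_excl:
            logger.warning(
                "diversity level %d: excluded %d non-finite yield(s)", level, n_excl
            )
        n = finite.size
        if n < 2:
            mean = float(finite.mean()) if n else float("nan")
            results.append(
                InvasionYieldResult(level, n, mean, float("nan"), float("nan"),
                                    positive_effect=False, n_excluded_zero=n_excl,
                                    ci_defined=False)
            )
            continue
        mean = float(finite.mean())
        sem = float(finite.std(ddof=1)) / math.sqrt(n)
        tcrit = float(sps.t.ppf(0.5 + ci_level / 2.0, n - 1))
        lo, hi = mean - tcrit * sem, mean + tcrit * sem
        results.append(
            InvasionYieldResult(level, n, mean, lo, hi,
                                positive_effect=(mean > 0 and lo > 0),
                                n_excluded_zero=n_excl)
        )
    return results


def coefficient_of_variation(values: Sequence[float]) -> float:
    """CV = sample standard deviation (n−1 denominator) / mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("CV needs at least two values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(arr.std(ddof=1) / mean)


def spearman_rho(
    x: Sequence[float], y: Sequence[float], exact: bool | str = "auto"
) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of average ranks (ties get mean rank).
    The p-value uses the t-approximation with n−2 df; for n ≤ 8 with
    ``exact='auto'`` (or ``exact=True``) it is replaced by the exact
    permutation p over all n! orderings.  A constant vector leaves rho
    undefined (NaN, NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-d vectors")
    n = x.size
    if n < 3:
        raise ValueError("need n ≥ 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant vector: Spearman rho undefined")
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    use_exact = exact is True or (exact == "auto" and n <= 8)
    if use_exact:
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        perms = np.array(list(permutations(range(n))))
        permuted = ry[perms]  # (n!, n)
        rxc = rx - rx.mean()
        pyc = permuted - permuted.mean(axis=1, keepdims=True)
        denom = np.sqrt((rxc**2).sum() * (pyc**2).sum(axis=1))
        rhos = pyc @ rxc / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    return float(rho), float(p)


def strain_success_summary(
    mixture_end_shares: Mapping[str, Sequence[float]],
    single_strain_shares: Mapping[str, Sequence[float]],
    gainloss: Sequence[GainLossTable],
    outlier_strains: Iterable[str] = (),
    dominance_threshold: float = DOMINANCE_THRESHOLD,
) -> tuple[list[StrainSuccessSummary], dict]:
    """Per-strain summaries plus single-vs-mixture rank consistency.

    ``mixture_end_shares`` maps strain -> endpoint shares across the
    mixtures it was part of; ``single_strain_shares`` maps strain -> yields
    in its monoculture treatments.  Consistency is the Spearman correlation
    between the single-strain mean yield and the mean in-mixture share gain
    (from the gain/loss tables), reported both with and without the strains
    flagged as outliers.
    """
    summaries = []
    for strain in sorted(mixture_end_shares):
        vals = np.asarray(list(mixture_end_shares[strain]), dtype=float)
        dom = sum(
            1 for t in gainloss if not t.excluded and strain in t.dominant
        )
        summaries.append(
            StrainSuccessSummary(
                strain_id=strain,
                mean_share=float(vals.mean()) if vals.size else float("nan"),
                sd_share=float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
                n=int(vals.size),
                dominant_count=dom,
            )
        )

    mean_delta: dict[str, float] = {}
    for t in gainloss:
        if t.excluded:
            continue
        for strain, d in t.delta.items():
            mean_delta.setdefault(strain, []).append(d)
    mean_delta = {s: float(np.mean(v)) for s, v in mean_delta.items()}

    overlap = sorted(set(single_strain_shares) & set(mean_delta))
    if not overlap:
        raise ValueError("no strains overlap between single-strain and mixture data")
    single_means = {s: float(np.mean(list(single_strain_shares[s]))) for s in overlap}

    def _rho(strains: list[str]):
        if len(strains) < 3:
            return float("nan"), float("nan")
        return spearman_rho([single_means[s] for s in strains],
                            [mean_delta[s] for s in strains])

    rho_all, p_all = _rho(overlap)
    kept = [s for s in overlap if s not in set(outlier_strains)]
    rho_kept, p_kept = _rho(kept)
    consistency = {
        "strains": overlap,
        "rho": rho_all,
        "p": p_all,
        "rho_without_outliers": rho_kept,
        "p_without_outliers": p_kept,
        "outliers": sorted(set(outlier_strains) & set(overlap)),
    }
    return summaries, consistency
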