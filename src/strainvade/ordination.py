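"""Community composition tests: Bray–Curtis, PERMANOVA, PCA.

Whether genetically different invader strains push the resident community
into different states is tested on the resident-only biomass matrix
(invader column removed): Bray–Curtis dissimilarities between samples, a
one-way PERMANOVA of strain identity implemented directly from the
pseudo-F definition with a label-permutation null, and a PCA ordination for
visualisation.

PERMANOVA sum-of-squares partition on a distance matrix d with n samples in
a groups::

    SS_total  = (1/n)  Σ_{i<j} d²ij
    SS_within = Σ_g (1/n_g) Σ_{i<j ∈ g} d²ij
    SS_among  = SS_total − SS_within
    pseudo-F  = (SS_among/(a−1)) / (SS_within/(n−a))

The p-value is (1 + #{F* ≥ F_obs}) / (1 + n_perm) over random label
permutations with a fixed seed, so it can never be exactly 0; for n ≤ 8
samples all n! permutations are enumerated exhaustively instead and the
p-value is the exact fraction #{F* ≥ F_obs}/n! (the identity included).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations as _all_permutations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

#: permutation F-statistics are rounded to this many significant digits
#: before the ≥ comparison, so float noise cannot inflate the count
_TIE_SIG_DIGITS = 12


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int
    seed: int | None
    method: str = "sampled"  # or "exhaustive"
    degenerate: bool = False


@dataclass
class PcaResult:
    """Scores (samples × components), loadings (species × components),
    per-component variance-explained fractions and the column means."""

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    column_means: np.ndarray
    sample_ids: list | None = None
    feature_ids: list | None = None


def bray_curtis(matrix) -> pd.DataFrame:
    """Pairwise Bray–Curtis dissimilarity, d = 1 − 2Σmin(x,y)/Σ(x+y).

    Accepts a samples × species DataFrame or array of non-negative
    abundances/biomasses; an all-zero sample makes the distance undefined
    and raises, naming the sample.
    """
    if isinstance(matrix, pd.DataFrame):
        values = matrix.to_numpy(dtype=float)
        index = list(matrix.index)
    else:
        values = np.asarray(matrix, dtype=float)
        index = list(range(values.shape[0]))
    if values.ndim != 2 or values.shape[0] < 2 or values.shape[1] < 1:
        raise ValueError("need at least 2 samples and 1 species")
    if (values < 0).any():
        raise ValueError("negative abundances not allowed")
    zero = np.where(values.sum(axis=1) == 0)[0]
    if zero.size:
        raise ValueError(
            f"all-zero sample(s): {[index[i] for i in zero]} "
            "(Bray–Curtis undefined)"
        )
    dist = squareform(pdist(values, metric="braycurtis"))
    return pd.DataFrame(dist, index=index, columns=index)


def _ss_within_obs(d2: np.ndarray, codes: np.ndarray, a: int) -> float:
    ssw = 0.0
    for g in range(a):
        idx = np.where(codes == g)[0]
        sub = d2[np.ix_(idx, idx)]
        ssw += sub.sum() / (2.0 * idx.size)
    return ssw


def _f_from_ssw(ss_total, ssw, n, a):
    ss_among = ss_total - ssw
    return (ss_among / (a - 1)) / (ssw / (n - a))


def _round_sig(x: np.ndarray | float, digits: int = _TIE_SIG_DIGITS):
    x = np.asarray(x, dtype=float)
    finite = np.isfinite(x) & (x != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mags = np.where(finite, 10.0 ** np.floor(np.log10(np.abs(x), where=finite,
                                                          out=np.zeros_like(x))), 1.0)
    out = np.where(finite, np.round(x / mags, digits - 1) * mags, x)
    return out


def permanova(
    dist,
    grouping: Sequence,
    n_perm: int = 10_000,
    seed: int | None = None,
    exhaustive: bool | str = "auto",
) -> PermanovaResult:
    """One-way PERMANOVA from the pseudo-F definition.

    ``exhaustive='auto'`` enumerates all n! label permutations whenever
    n ≤ 8; otherwise ``n_perm`` random permutations are drawn with the
    given seed.  A grouping with a single group, or a group holding every
    sample, is an error; a distance matrix that is identically zero leaves
    F undefined (degenerate result).
    """
    d = dist.to_numpy(dtype=float) if isinstance(dist, pd.DataFrame) else \
        np.asarray(dist, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    labels = np.asarray(list(grouping))
    if labels.size != n:
        raise ValueError("grouping length must match the distance matrix")
    uniq, codes = np.unique(labels, return_inverse=True)
    a = uniq.size
    if a < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if np.bincount(codes).max() == n:
        raise ValueError("one group contains every sample")

    d2 = d**2
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    if ss_total == 0:
        logger.warning("all pairwise distances are zero: pseudo-F undefined")
        return PermanovaResult(float("nan"), float("nan"), float("nan"),
                               0, seed, degenerate=True)
    ssw_obs = _ss_within_obs(d2, codes, a)
    if ssw_obs == 0:
        # perfect separation: F is infinite; permutation comparison still works
        f_obs = float("inf")
    else:
        f_obs = _f_from_ssw(ss_total, ssw_obs, n, a)
    r2 = (ss_total - ssw_obs) / ss_total

    use_exhaustive = exhaustive is True or (
        exhaustive == "auto" and n <= 8
    )
    if use_exhaustive:
        perms = np.array(list(_all_permutations(range(n))))
        f_star = _f_for_permutations(d2, codes, perms, ss_total, n, a)
        count = int(np.sum(_round_sig(f_star) >= _round_sig(f_obs)))
        p = count / perms.shape[0]
        return PermanovaResult(float(f_obs), float(r2), float(p),
                               perms.shape[0], seed, method="exhaustive")

    if n_perm < 1:
        raise ValueError("n_perm must be ≥ 1")
    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    f_star = _f_for_permutations(d2, codes, perms, ss_total, n, a)
    count = int(np.sum(_round_sig(f_star) >= _round_sig(f_obs)))
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(float(f_obs), float(r2), float(p),
                           n_perm, seed, method="sampled")


def _f_for_permutations(d2, codes, perms, ss_total, n, a):
    """Vectorised pseudo-F over an array of label permutations (m × n)."""
    permuted = codes[perms]  # (m, n)
    ssw = np.zeros(perms.shape[0])
    for g in range(a):
        mask = (permuted == g).astype(float)
        n_g = int((codes == g).sum())
        ssw += np.einsum("mi,ij,mj->m", mask, d2, mask) / (2.0 * n_g)
    ss_among = ss_total - ssw
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_among / (a - 1)) / (ssw / (n - a))
    f[ssw == 0] = np.inf
    return f


def pca(matrix) -> PcaResult:
    """PCA of a samples × species matrix by SVD of the column-centred data.

    Unscaled (covariance) PCA; the sign of each component is fixed so the
    largest-magnitude loading is positive.  ``scores @ loadings.T +
    column_means`` reconstructs the input.
    """
    if isinstance(matrix, pd.DataFrame):
        values = matrix.to_numpy(dtype=float)
        sample_ids = list(matrix.index)
        feature_ids = list(matrix.columns)
    else:
        values = np.asarray(matrix, dtype=float)
        sample_ids = feature_ids = None
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if not np.isfinite(values).all():
        raise ValueError("matrix contains non-finite values")
    means = values.mean(axis=0)
    centred = values - means
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    # fix signs: largest-|loading| entry of each component positive
    for k in range(s.size):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    scores = u * s
    loadings = vt.T
    var = s**2
    ratio = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    return PcaResult(scores, loadings, ratio, means, sample_ids, feature_ids)


def strain_effect_test(
    community,
    designs,
    n_perm: int = 10_000,
    seed: int | None = None,
    invader_column: str = "invader",
) -> dict:
    """Does invader strain identity shift resident-community composition?

    Restricted to the single-strain (diversity level 1) microcosms, with
    the invader column dropped so only the residents are compared; runs
    Bray–Curtis + PERMANOVA with strain identity as the grouping and also
    reports the mean within-strain vs between-strain distance.

    ``community`` is a samples × species biomass DataFrame indexed by
    microcosm id; ``designs`` a collection of MicrocosmDesign.
    """
    strain_of = {
        d.microcosm_id: d.strain_set[0]
        for d in designs
        if d.diversity_level == 1
    }
    keep = [i for i in community.index if i in strain_of]
    strains = {strain_of[i] for i in keep}
    if len(strains) < 2:
        raise ValueError("need single-strain microcosms of at least 2 strains")
    sub = community.loc[keep]
    if invader_column in sub.columns:
        sub = sub.drop(columns=[invader_column])
    dist = bray_curtis(sub)
    labels = [strain_of[i] for i in keep]
    res = permanova(dist, labels, n_perm=n_perm, seed=seed)

    dmat = dist.to_numpy()
    lab = np.asarray(labels)
    iu = np.triu_indices(len(keep), k=1)
    same = lab[iu[0]] == lab[iu[1]]
    within = float(dmat[iu][same].mean()) if same.any() else float("nan")
    between = float(dmat[iu][~same].mean()) if (~same).any() else float("nan")
    return {
        "permanova": res,
        "n_samples": len(keep),
        "n_strains": len(strains),
        "mean_within_strain_distance": within,
        "mean_between_strain_distance": between,
    }
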