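"""Negative-binomial two-group testing shared by the ChIP and RNA stages.

The differential machinery is deliberately simple and fully specified:

* library-size normalization (given sizes for ChIP counts; median-of-ratios
  size factors for RNA counts),
* a single common dispersion estimated by method of moments from
  within-group replicate variability,
* a conditional exact test on the two group sums (the sum of n iid NB(mu, r)
  variables is NB(n*mu, n*r), so conditioning on the total gives a
  one-dimensional discrete distribution), with a mid-p correction so that
  null p-values are approximately uniform despite discreteness,
* Benjamini-Hochberg FDR control.

It stands in for the edgeR/DESeq2-style tools normally used for this step;
it is not a reimplementation of either.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import logsumexp
from scipy.stats import binom, false_discovery_control, nbinom, norm

__all__ = [
    "estimate_common_dispersion",
    "nb_conditional_exact_test",
    "nb_two_group_pvalues",
    "bh_adjust",
]

# above this total the exact conditional enumeration is replaced by a
# delta-method normal approximation on the log ratio of group sums
_EXACT_TOTAL_LIMIT = 20_000


def estimate_common_dispersion(norm_counts: np.ndarray, groups: np.ndarray) -> float:
    """Method-of-moments common NB dispersion phi (var = mu + phi*mu^2).

    ``norm_counts`` is a regions x samples matrix on a common scale;
    ``groups`` labels columns. Each (region, group) cell with >= 2 replicates
    contributes its sample mean m and variance v; phi solves the weighted
    moment equation sum(v - m) = phi * sum(m^2), which is robust to the
    heavy-tailed per-region variance estimates at small replicate numbers.
    Returns 0.0 (Poisson) when no group has replication.
    """
    norm_counts = np.asarray(norm_counts, dtype=float)
    groups = np.asarray(groups)
    num = 0.0
    den = 0.0
    any_reps = False
    for g in np.unique(groups):
        sub = norm_counts[:, groups == g]
        if sub.shape[1] < 2:
            continue
        any_reps = True
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        num += float(np.sum(v[ok] - m[ok]))
        den += float(np.sum(m[ok] ** 2))
    if not any_reps:
        warnings.warn(
            "no replicated group available for dispersion estimation; "
            "falling back to Poisson (dispersion 0)"
        )
        return 0.0
    if den == 0.0:
        return 0.0
    return max(0.0, num / den)


def nb_conditional_exact_test(
    s1: int,
    s2: int,
    w1: float,
    n1: int,
    n2: int,
    dispersion: float,
    midp: bool = True,
) -> float:
    """Two-sided conditional exact NB test on group sums.

    Conditional on the total T = s1 + s2, the group-1 sum follows the
    normalized product of the two group-sum NB pmfs; outcomes no more
    probable than the observed one are summed (mid-p: half weight on
    equally probable outcomes). ``w1`` is group 1's expected share of the
    total under the null (its fraction of the summed effective library
    sizes); ``n1``/``n2`` are replicate numbers; ``dispersion`` is the
    common per-replicate phi (0 -> Poisson/binomial).
    """
    s1, s2 = int(s1), int(s2)
    T = s1 + s2
    if T == 0:
        return 1.0
    if T > _EXACT_TOTAL_LIMIT:
        return _normal_approx_p(s1, s2, w1, n1, n2, dispersion)
    k = np.arange(T + 1)
    if dispersion <= 0:
        logp = binom.logpmf(k, T, w1)
    else:
        r1 = n1 / dispersion
        r2 = n2 / dispersion
        mu1 = T * w1
        mu2 = T * (1.0 - w1)
        lp = nbinom.logpmf(k, r1, r1 / (r1 + mu1)) + nbinom.logpmf(
            T - k, r2, r2 / (r2 + mu2)
        )
        logp = lp - logsumexp(lp)
    obs = logp[s1]
    tol = 1e-9
    less = logp < obs - tol
    equal = np.abs(logp - obs) <= tol
    p = 0.0
    if np.any(less):
        p += float(np.exp(logsumexp(logp[less])))
    weight = 0.5 if midp else 1.0
    p += weight * float(np.exp(logsumexp(logp[equal])))
    return min(1.0, p)


def _normal_approx_p(s1, s2, w1, n1, n2, dispersion) -> float:
    """Delta-method z-test on log(s1/L1) - log(s2/L2) for large totals."""
    L1, L2 = w1, 1.0 - w1
    a = max(s1, 0.5)
    b = max(s2, 0.5)
    var = 1.0 / a + dispersion / n1 + 1.0 / b + dispersion / n2
    z = (np.log(a / L1) - np.log(b / L2)) / np.sqrt(var)
    return float(2.0 * norm.sf(abs(z)))


def nb_two_group_pvalues(
    counts: np.ndarray,
    groups: np.ndarray,
    effective_sizes: np.ndarray,
    dispersion: float,
    group1_label,
    midp: bool = True,
) -> np.ndarray:
    """Per-region p-values for group1 vs rest from raw counts.

    ``effective_sizes`` scales expected column totals (library sizes or size
    factors); group 1's null share of each region total is its fraction of
    the summed effective sizes.
    """
    counts = np.asarray(counts)
    groups = np.asarray(groups)
    g1 = groups == group1_label
    n1 = int(g1.sum())
    n2 = int((~g1).sum())
    sizes = np.asarray(effective_sizes, dtype=float)
    w1 = sizes[g1].sum() / sizes.sum()
    s1 = counts[:, g1].sum(axis=1)
    s2 = counts[:, ~g1].sum(axis=1)
    return np.array(
        [
            nb_conditional_exact_test(a, b, w1, n1, n2, dispersion, midp=midp)
            for a, b in zip(s1, s2)
        ]
    )


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return false_discovery_control(np.asarray(pvalues, dtype=float), method="bh")
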