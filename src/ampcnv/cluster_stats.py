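"""Per-cluster statistics: outlier pruning, weighted t-test and scores.

Every primer's normalized log2 ratio ``x_i`` is weighted by the total read
count at that site, ``w_i = C_Si + C_Ci``, because deeper primers give more
precise ratios.  With ``W = sum(w_i)`` the cluster-level quantities are

    mu*      = (1/W) * sum(w_i * x_i)                  weighted mean
    sigma_w2 = (1/(W-1)) * sum(w_i * (x_i - mu*)^2)    unbiased weighted variance
    n*       = W^2 / sum(w_i^2)                        effective sampling size
    SE       = z(1 - alpha/2, n* - 1) * sigma_w / sqrt(n*)
    t        = sqrt(n*) * (mu* - mu0) / sigma_w
    p        = 2 * Pr(T_{n*} <= -|t|)

where ``z`` is the t-distribution quantile function.  Note the deliberate
asymmetry: the SE quantile uses ``n* - 1`` degrees of freedom while the
p-value uses ``n*``; both are implemented exactly as defined.  Fractional
degrees of freedom are allowed throughout.

Two Phred-like scores summarize each cluster:

    Q = -10 * log10(p) * phi      with  phi = sqrt(sigma_w) * (1 + |mu*|)
    P = -10 * ln(SE)

``phi`` (the dispersion factor, sqrt of the weighted standard deviation
scaled by the effect magnitude) suppresses suspiciously-low-dispersion
false positives and rescues high-dispersion true events; calls require
``Q >= 50``.  ``P`` grows as the copy-number estimate tightens.

Before any of this, true outliers (primer-site variants, failed reactions)
are pruned: while a Shapiro-Wilk test on the cluster's (unweighted) x
values rejects normality at p <= 0.05, the element farthest from the
current weighted mean is removed, capped at one third of the cluster.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .clustering import Cluster

logger = logging.getLogger(__name__)

SW_ALPHA = 0.05
P_FLOOR = np.nextafter(0.0, 1.0)  # smallest positive double; Q clamp on underflow


@dataclass(frozen=True)
class ClusterStatistics:
    """The full statistical summary of one cluster (log2-ratio scale)."""

    mu_star: float
    sigma_w2: float
    n_star: float
    se: float
    t_stat: float
    p_value: float
    phi: float
    q_score: float
    p_score: float | None
    alpha: float = 0.05
    mu0: float = 0.0


@dataclass(frozen=True)
class CopyNumberEstimate:
    """Copy number of the sample region with its confidence bounds.

    ``n_sample = n_control * 2**mu_star``; the bounds move mu* by +-SE.
    Copy numbers stay real-valued — a reported 3.5 against a true 3 still
    counts as the same direction of change.
    """

    n_control: int
    n_sample: float
    n_min: float
    n_max: float


def weighted_mean(x, w) -> float:
    """mu* = sum(w_i x_i) / sum(w_i)."""
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    if x.size == 0 or x.size != w.size:
        raise ValueError("x and w must be equal-length and non-empty")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    return float(np.sum(w * x) / np.sum(w))


def weighted_variance(x, w, mu_star: float | None = None) -> float:
    """Unbiased weighted variance with denominator W - 1 (W = sum of weights)."""
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    if mu_star is None:
        mu_star = weighted_mean(x, w)
    W = float(np.sum(w))
    if W <= 1:
        raise ValueError(f"sum of weights must exceed 1, got {W}")
    return float(np.sum(w * (x - mu_star) ** 2) / (W - 1.0))


def effective_n(w) -> float:
    """n* = (sum w)^2 / sum(w^2); equals len(w) for equal weights."""
    w = np.asarray(w, dtype=float)
    if w.size == 0:
        raise ValueError("empty weights")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    return float(np.sum(w) ** 2 / np.sum(w**2))


def standard_error(sigma_w: float, n_star: float, alpha: float = 0.05) -> float:
    """SE = t-quantile(1 - alpha/2, df = n* - 1) * sigma_w / sqrt(n*)."""
    if n_star <= 1:
        raise ValueError("effective sample size must exceed 1")
    if sigma_w < 0:
        raise ValueError("sigma_w must be >= 0")
    if sigma_w == 0:
        return 0.0
    z = stats.t.ppf(1.0 - alpha / 2.0, df=n_star - 1.0)
    return float(z * sigma_w / math.sqrt(n_star))


def test_cluster(x, w, mu0: float = 0.0) -> tuple[float, float]:
    """Weighted one-sample t-test of mu* against mu0.

    t = sqrt(n*) (mu* - mu0)/sigma_w; p = 2 Pr(T_{n*} <= -|t|) with the
    effective sampling size n* as (possibly fractional) degrees of freedom.
    A zero-variance cluster is degenerate: p = 0 with infinite t if the mean
    differs from mu0, else t = 0, p = 1.
    """
    mu = weighted_mean(x, w)
    var = weighted_variance(x, w, mu)
    n_star = effective_n(w)
    if var == 0.0:
        if mu == mu0:
            return 0.0, 1.0
        return math.copysign(math.inf, mu - mu0), 0.0
    t = math.sqrt(n_star) * (mu - mu0) / math.sqrt(var)
    p = 2.0 * float(stats.t.cdf(-abs(t), df=n_star))
    return t, min(p, 1.0)


def dispersion_factor(sigma_w: float, mu_star: float) -> float:
    """phi = sqrt(sigma_w) * (1 + |mu*|); radicand is the weighted SD."""
    if sigma_w < 0:
        raise ValueError("sigma_w must be >= 0")
    return math.sqrt(sigma_w) * (1.0 + abs(mu_star))


def q_score(p: float, phi: float) -> float:
    """Q = -10 log10(p) * phi, clamped to the double floor when p underflows."""
    if phi < 0:
        raise ValueError("phi must be >= 0")
    if p <= 0.0:
        logger.warning("p-value underflow: clamping to %g for Q", P_FLOOR)
        p = P_FLOOR
    return -10.0 * math.log10(p) * phi


def p_score(se: float) -> float | None:
    """P = -10 ln(SE); None (reported missing) when SE is not positive."""
    if se <= 0:
        return None
    return -10.0 * math.log(se)


def copy_number(mu_star: float, se: float, n_control: int) -> CopyNumberEstimate:
    """N_S = N_C * 2**mu* with bounds N_C * 2**(mu* +- SE)."""
    if n_control < 1:
        raise ValueError("control copy number must be >= 1 for a callable cluster")
    if se < 0:
        raise ValueError("se must be >= 0")
    n_s = n_control * 2.0**mu_star
    return CopyNumberEstimate(
        n_control=n_control,
        n_sample=n_s,
        n_min=n_control * 2.0 ** (mu_star - se),
        n_max=n_control * 2.0 ** (mu_star + se),
    )


def remove_outliers(cluster: Cluster, sw_alpha: float = SW_ALPHA) -> Cluster:
    """Iterative Shapiro-Wilk pruning of a cluster's x values (fills ``kept``).

    While the SW test on the current subset rejects normality (p <= sw_alpha),
    drop the element with the largest |x_i - mu*| from the current weighted
    mean, then retest.  At most floor(n/3) elements are removed (n = original
    cluster size).  Ties on the distance go to the smaller weight, then to
    the earlier genomic position, so the result is deterministic.
    """
    members = list(cluster.members)
    n = len(members)
    if n < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    max_removals = n // 3
    kept = list(members)
    removed = 0
    while removed < max_removals:
        xs = np.array([p.x for p in kept], dtype=float)
        if np.ptp(xs) == 0.0:
            break  # SW undefined on constant data; nothing is an outlier
        sw_p = float(stats.shapiro(xs).pvalue)
        if sw_p > sw_alpha:
            break
        ws = np.array([p.weight for p in kept], dtype=float)
        mu = weighted_mean(xs, ws)
        worst = max(
            range(len(kept)),
            key=lambda i: (abs(kept[i].x - mu), -kept[i].weight, -kept[i].site.pos),
        )
        kept.pop(worst)
        removed += 1
    cluster.kept = kept
    return cluster


def compute_statistics(cluster: Cluster, alpha: float = 0.05, mu0: float = 0.0) -> ClusterStatistics:
    """Full Eq-chain over the cluster's kept subset X'."""
    xs = np.array([p.x for p in cluster.kept], dtype=float)
    ws = np.array([p.weight for p in cluster.kept], dtype=float)
    mu = weighted_mean(xs, ws)
    var = weighted_variance(xs, ws, mu)
    n_star = effective_n(ws)
    sigma_w = math.sqrt(var)
    se = standard_error(sigma_w, n_star, alpha)
    t, p = test_cluster(xs, ws, mu0)
    phi = dispersion_factor(sigma_w, mu)
    q = q_score(p, phi) if p > 0 else q_score(P_FLOOR, phi)
    return ClusterStatistics(
        mu_star=mu,
        sigma_w2=var,
        n_star=n_star,
        se=se,
        t_stat=t,
        p_value=p,
        phi=phi,
        q_score=q,
        p_score=p_score(se),
        alpha=alpha,
        mu0=mu0,
    )
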