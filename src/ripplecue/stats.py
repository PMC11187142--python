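"""Cluster-based permutation inference, circular V test, rank correlation.

The cluster test controls the family-wise error over time (or time x time /
time x frequency) maps: a dependent-samples t statistic is computed per
sample across units (participants or contacts), thresholded at the
two-sided alpha, contiguous supra-threshold samples are clustered per sign,
and each cluster's summed t (mass) is compared against the permutation
distribution of the maximum |mass| under random unit-wise sign flips.
Monte Carlo p values use the (b + 1) / (n + 1) correction so p > 0 always.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import norm, spearmanr
from scipy.stats import t as t_dist


@dataclass
class Cluster:
    mask: np.ndarray
    mass: float
    sign: int
    p: float


@dataclass
class ClusterResult:
    clusters: list[Cluster] = field(default_factory=list)
    t_obs: np.ndarray | None = None
    threshold: float = 0.0
    n_permutations: int = 0
    alpha: float = 0.05

    def significant(self, alpha: float | None = None) -> list[Cluster]:
        a = self.alpha if alpha is None else alpha
        return [c for c in self.clusters if c.p <= a]

    @property
    def min_p(self) -> float:
        return min((c.p for c in self.clusters), default=1.0)


_T_CAP = 100.0  # zero-variance, nonzero-mean cells: saturated t


def _t_onesample(d: np.ndarray) -> np.ndarray:
    """t statistic across axis 0.

    Degenerate cells (zero variance across units) give t = 0 when the mean
    is also zero and a saturated +-``_T_CAP`` otherwise (identical nonzero
    deviations are maximal evidence, not missing evidence).
    """
    n = d.shape[0]
    mu = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mu / (sd / np.sqrt(n)),
                     np.sign(mu) * _T_CAP)
    return np.clip(t, -_T_CAP, _T_CAP)


def _clusters_of(t: np.ndarray, thr: float) -> list[tuple[np.ndarray, float,
                                                          int]]:
    out = []
    for sign in (1, -1):
        supra = (t * sign) > thr
        if not supra.any():
            continue
        if t.ndim == 1:
            lab, n_lab = ndimage.label(supra)
        else:
            structure = ndimage.generate_binary_structure(t.ndim, 1)
            lab, n_lab = ndimage.label(supra, structure=structure)
        for k in range(1, n_lab + 1):
            mask = lab == k
            out.append((mask, float(t[mask].sum()), sign))
    return out


def cluster_permutation_test(data: np.ndarray,
                             reference: float | np.ndarray = 0.0,
                             n_perm: int = 1000,
                             cluster_alpha: float = 0.05,
                             seed: int | None = None) -> ClusterResult:
    """Two-sided cluster-based sign-flip permutation test.

    ``data`` is units x map (1-D or 2-D map); ``reference`` is either the
    chance value or a paired condition of the same shape (the test then
    runs on the differences, which is the paired test).
    """
    data = np.asarray(data, dtype=float)
    if data.shape[0] < 2:
        raise ValueError("need at least 2 units")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations; p values are coarse")
    d = data - reference
    n = d.shape[0]
    thr = t_dist.ppf(1 - cluster_alpha / 2, n - 1)

    t_obs = _t_onesample(d)
    observed = _clusters_of(t_obs, thr)

    rng = np.random.default_rng(seed)
    null = np.zeros(n_perm)
    for i in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n)
        t_p = _t_onesample(d * signs.reshape((n,) + (1,) * (d.ndim - 1)))
        cl = _clusters_of(t_p, thr)
        null[i] = max((abs(m) for _, m, _ in cl), default=0.0)

    clusters = [Cluster(mask, mass, sign,
                        float((np.sum(null >= abs(mass)) + 1) /
                              (n_perm + 1)))
                for mask, mass, sign in observed]
    clusters.sort(key=lambda c: c.p)
    return ClusterResult(clusters, t_obs, float(thr), n_perm, cluster_alpha)


def v_test(angles, mu: float) -> tuple[float, float]:
    """V test for circular non-uniformity with a specified mean direction.

    V = n R cos(theta_bar - mu); u = V sqrt(2/n); p is the upper tail of
    the standard normal at u.
    """
    angles = np.asarray(angles, dtype=float)
    n = angles.size
    if n < 2:
        raise ValueError("need at least 2 angles")
    z = np.exp(1j * angles).mean()
    r = np.abs(z)
    theta = np.angle(z)
    v = n * r * np.cos(theta - mu)
    u = v * np.sqrt(2.0 / n)
    p = float(norm.sf(u))
    return float(v), p


def rank_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation with its p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for constant input")
    rho, p = spearmanr(x, y)
    return float(rho), float(p)
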