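"""Condition-comparison statistics.

Two tools: a cluster-based permutation test for paired comparisons of
time-frequency coherence maps (family-wise error control via the
max-cluster-mass permutation null, with per-subject condition-label
sign flips -- the exact exchangeable scheme for two paired conditions),
and a one-way repeated-measures ANOVA with planned pairwise t-tests for
scalar gait parameters (stride time, step width, LDE).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as _ndi
from scipy import stats as _st

from .errors import InsufficientDataError, ValidationError

__all__ = ["Cluster", "ClusterResult", "AnovaResult",
           "cluster_permutation_test", "rm_anova_planned"]

#: 4-connectivity on the (time, frequency) grid.
_ADJ4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass
class Cluster:
    """A maximal connected suprathreshold set of grid points."""

    sign: int                 # +1 or -1
    mass: float               # summed t over the cluster (signed)
    p_value: float
    indices: np.ndarray = field(repr=False)   # (n_points, 2) grid indices

    @property
    def size(self) -> int:
        return self.indices.shape[0]


@dataclass
class ClusterResult:
    clusters: list
    t_map: np.ndarray = field(repr=False)
    n_permutations: int = 0
    cluster_alpha: float = 0.05
    seed: int | None = None

    def significant(self, alpha: float = 0.05) -> list:
        return [c for c in self.clusters if c.p_value < alpha]


def _t_map(diffs: np.ndarray) -> np.ndarray:
    """Pointwise paired t statistic of subject difference maps."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    t = np.zeros_like(mean)
    nz = sd > 0
    t[nz] = mean[nz] / (sd[nz] / np.sqrt(n))
    return t


def _clusters_from_t(t: np.ndarray, tcrit: float):
    """Signed suprathreshold clusters under 4-connectivity."""
    out = []
    for sign in (1, -1):
        mask = (sign * t) > tcrit
        labels, n_lab = _ndi.label(mask, structure=_ADJ4)
        for lab in range(1, n_lab + 1):
            where = labels == lab
            out.append((sign, float(t[where].sum()),
                        np.argwhere(where)))
    return out


def cluster_permutation_test(maps_a: np.ndarray, maps_b: np.ndarray,
                             n_permutations: int = 5000,
                             cluster_alpha: float = 0.05,
                             seed: int = 0) -> ClusterResult:
    """Paired cluster-based permutation test between two map sets.

    ``maps_a`` and ``maps_b`` are ``(n_subjects, n_tau, n_freq)`` arrays
    on identical grids; all grid points enter the test (no pre-masking
    by significant coherence).  Pointwise paired t statistics are
    thresholded at the two-sided ``cluster_alpha`` critical value;
    4-connected suprathreshold clusters are scored by their summed t
    (mass).  The null distribution of the maximum absolute cluster mass
    is built by randomly flipping each subject's condition order, and
    each observed cluster gets ``p = (1 + #{null >= |mass|}) /
    (n_permutations + 1)``.
    """
    a = np.asarray(maps_a, dtype=float)
    b = np.asarray(maps_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"grids differ: {a.shape} vs {b.shape}")
    if a.ndim != 3:
        raise ValidationError("maps must be (n_subjects, n_tau, n_freq)")
    n = a.shape[0]
    if n < 2:
        raise InsufficientDataError("need at least 2 subjects")
    grid = a.shape[1:]
    diffs = (a - b).reshape(n, -1)
    tcrit = float(_st.t.ppf(1.0 - cluster_alpha / 2.0, n - 1))

    t_obs = _t_map(diffs).reshape(grid)
    observed = _clusters_from_t(t_obs, tcrit)

    rng = np.random.default_rng(seed)
    ss = (diffs ** 2).sum(axis=0)
    null_max = np.empty(n_permutations)
    chunk = max(1, int(5e7 // max(diffs.size, 1)))
    done = 0
    while done < n_permutations:
        k = min(chunk, n_permutations - done)
        signs = rng.choice([-1.0, 1.0], size=(k, n))
        means = signs @ diffs / n
        var = (ss[None, :] - n * means**2) / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_perm = np.where(var > 0, means / np.sqrt(var / n), 0.0)
        for r in range(k):
            cl = _clusters_from_t(t_perm[r].reshape(grid), tcrit)
            null_max[done + r] = max((abs(m) for _, m, _ in cl), default=0.0)
        done += k

    clusters = []
    for sign, mass, idx in observed:
        p = (1.0 + np.sum(null_max >= abs(mass))) / (n_permutations + 1.0)
        clusters.append(Cluster(sign=sign, mass=mass, p_value=float(p),
                                indices=idx))
    clusters.sort(key=lambda c: abs(c.mass), reverse=True)
    return ClusterResult(clusters=clusters, t_map=t_obs,
                         n_permutations=n_permutations,
                         cluster_alpha=cluster_alpha, seed=seed)


@dataclass
class PairwiseComparison:
    pair: tuple
    mean_difference: float
    t: float
    p_value: float
    undefined: bool = False


@dataclass
class AnovaResult:
    """One-way repeated-measures ANOVA with planned pairwise contrasts."""

    F: float
    df: tuple
    p_value: float
    eta_squared: float          # SS_condition / SS_total
    partial_eta_squared: float  # SS_condition / (SS_condition + SS_error)
    ss: dict
    pairwise: list


def rm_anova_planned(values: np.ndarray,
                     planned_contrasts: Sequence[tuple] = ((0, 1), (0, 2), (0, 3)),
                     condition_names: Sequence[str] | None = None) -> AnovaResult:
    """One-way repeated-measures ANOVA over a subjects-by-conditions table.

    F has degrees of freedom ``(k-1, (k-1)(n-1))``.  Both the classical
    eta squared (SS_condition / SS_total) and the partial variant are
    reported.  Planned contrasts are paired t-tests, uncorrected; a
    contrast with identical values in both conditions is flagged
    undefined.  Missing cells raise -- no imputation.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValidationError("values must be a subjects x conditions table")
    if np.any(~np.isfinite(x)):
        raise ValidationError("missing cells are not allowed")
    n, k = x.shape
    if n < 2 or k < 2:
        raise InsufficientDataError("need >= 2 subjects and >= 2 conditions")
    grand = x.mean()
    ss_total = float(((x - grand) ** 2).sum())
    ss_cond = float(n * ((x.mean(axis=0) - grand) ** 2).sum())
    ss_subj = float(k * ((x.mean(axis=1) - grand) ** 2).sum())
    ss_err = ss_total - ss_cond - ss_subj
    df_b, df_w = k - 1, (k - 1) * (n - 1)
    ms_err = ss_err / df_w
    F = (ss_cond / df_b) / ms_err if ms_err > 0 else (0.0 if ss_cond == 0 else np.inf)
    p = float(_st.f.sf(F, df_b, df_w)) if np.isfinite(F) else 0.0
    eta = ss_cond / ss_total if ss_total > 0 else 0.0
    eta_p = ss_cond / (ss_cond + ss_err) if (ss_cond + ss_err) > 0 else 0.0

    names = list(condition_names) if condition_names else [str(j) for j in range(k)]
    pairwise = []
    for i, j in planned_contrasts:
        if max(i, j) >= k:
            raise ValidationError(f"contrast ({i},{j}) outside {k} conditions")
        d = x[:, i] - x[:, j]
        if np.allclose(d.std(ddof=1), 0.0):
            pairwise.append(PairwiseComparison(
                pair=(names[i], names[j]), mean_difference=float(d.mean()),
                t=np.nan, p_value=np.nan, undefined=True))
        else:
            t_stat, p_val = _st.ttest_rel(x[:, i], x[:, j])
            pairwise.append(PairwiseComparison(
                pair=(names[i], names[j]), mean_difference=float(d.mean()),
                t=float(t_stat), p_value=float(p_val)))
    return AnovaResult(F=float(F), df=(df_b, df_w), p_value=p,
                       eta_squared=float(eta),
                       partial_eta_squared=float(eta_p),
                       ss=dict(condition=ss_cond, subject=ss_subj,
                               error=ss_err, total=ss_total),
                       pairwise=pairwise)
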