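"""Group inference: rank-sum tests with FDR, and permutation/TFCE maps.

Scalar summaries (band powers, whole-brain or ROI ΔTE) are compared across
arousal states with a two-tailed Wilcoxon rank-sum test — midranks for
ties, normal approximation with continuity and tie correction, exact
enumeration for small samples — followed by Benjamini–Hochberg control of
the false discovery rate.  Voxelwise maps are compared with a label-
randomization test whose statistic is the threshold-free cluster
enhancement (TFCE) of the absolute group mean difference, corrected
family-wise by the max-statistic null distribution.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import ndimage
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "TFCEParams",
    "PermutationResult",
    "wilcoxon_ranksum",
    "fdr_adjust",
    "tfce_enhance",
    "permutation_test",
]

_EXACT_N_MAX = 12


@dataclass
class GroupComparison:
    """Standardized rank-sum statistic with raw and FDR-adjusted p-values."""

    z: float
    p: float
    n1: int
    n2: int
    p_adj: float = float("nan")


@dataclass(frozen=True)
class TFCEParams:
    """Threshold-free cluster enhancement parameters.

    ``e`` and ``h`` are the extent and height exponents; ``dh`` the
    threshold step (None -> map max / n_steps); clusters use 6-neighbour
    connectivity in 3D.
    """

    e: float = 0.5
    h: float = 2.0
    dh: float | None = None
    n_steps: int = 100
    connectivity: int = 6

    def __post_init__(self) -> None:
        if self.e <= 0 or self.h <= 0 or (self.dh is not None and self.dh <= 0):
            raise ValueError("TFCE exponents and step must be positive")


@dataclass
class PermutationResult:
    """FWER-corrected voxel p-map from a TFCE randomization test."""

    p_map: np.ndarray
    observed: np.ndarray          # TFCE-enhanced observed statistic
    null_max: np.ndarray          # max-statistic null distribution
    exhaustive: bool


def wilcoxon_ranksum(a, b, two_tailed: bool = True) -> GroupComparison:
    """Wilcoxon rank-sum test of two independent samples.

    The z statistic always uses the normal approximation with midranks,
    tie-corrected variance, and a 0.5 continuity correction.  The p-value
    comes from exact enumeration of all rank assignments when
    n1 + n2 <= 12, otherwise from the normal approximation.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    N = n1 + n2
    W = ranks[:n1].sum()
    mu = n1 * (N + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    var = n1 * n2 * (N + 1) / 12.0 - n1 * n2 * tie_term / (12.0 * N * (N - 1))
    if var <= 0:
        z = 0.0
        p_norm = 1.0
    else:
        dev = W - mu
        z = (dev - 0.5 * np.sign(dev)) / np.sqrt(var) if dev != 0 else 0.0
        p_norm = 2 * norm.sf(abs(z)) if two_tailed else norm.sf(z)
        p_norm = min(1.0, p_norm)
    if N <= _EXACT_N_MAX:
        obs_dev = abs(W - mu)
        count = total = 0
        for idx in combinations(range(N), n1):
            w = ranks[list(idx)].sum()
            total += 1
            if two_tailed:
                count += abs(w - mu) >= obs_dev - 1e-9
            else:
                count += w >= W - 1e-9
        p = count / total
    else:
        p = p_norm
    return GroupComparison(z=float(z), p=float(p), n1=n1, n2=n2)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, original order kept."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6, 18, or 26")


def tfce_enhance(stat_map: np.ndarray, params: TFCEParams | None = None,
                 mask: np.ndarray | None = None) -> np.ndarray:
    """Threshold-free cluster enhancement of a signed voxel map.

    For each voxel the enhanced value is the Riemann sum over thresholds h
    of ``extent(h)^e * h^h_exponent * dh``, where extent(h) is the size of
    the cluster supporting the voxel at threshold h.  Positive and negative
    tails are enhanced separately and recombined with their signs.
    """
    if params is None:
        params = TFCEParams()
    m = np.asarray(stat_map, dtype=float)
    if mask is None:
        mask = np.ones(m.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not np.all(np.isfinite(m[mask])):
        raise ValueError("non-finite values inside the mask")
    structure = _connectivity_structure(params.connectivity)
    out = np.zeros_like(m)
    for sign in (1.0, -1.0):
        tail = sign * m
        tail = np.where(mask, tail, 0.0)
        hmax = tail.max()
        if hmax <= 0:
            continue
        dh = params.dh if params.dh is not None else hmax / params.n_steps
        heights = np.arange(dh, hmax + dh * 1e-9, dh)
        acc = np.zeros_like(m)
        for h in heights:
            sup = tail >= h
            labels, n_lab = ndimage.label(sup, structure=structure)
            if n_lab == 0:
                break
            sizes = np.bincount(labels.ravel())
            sizes[0] = 0
            acc[sup] += (sizes.astype(float) ** params.e)[labels[sup]] * h ** params.h * dh
        out += sign * acc
    out[~mask] = 0.0
    return out


def permutation_test(
    maps_a,
    maps_b,
    mask: np.ndarray | None = None,
    n_perm: int = 5000,
    params: TFCEParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> PermutationResult:
    """Randomization test on voxel maps with TFCE max-statistic correction.

    The two-sided statistic is the absolute difference of group mean maps,
    TFCE-enhanced.  Group labels are shuffled exhaustively when the number
    of distinct splits is at most ``n_perm``, otherwise by Monte-Carlo
    sampling (the observed labelling is included in the null).  The
    FWER-corrected voxel p-value is the rank of the observed enhanced value
    within the null distribution of the map-wise maximum.
    """
    A = np.asarray(maps_a, dtype=float)
    B = np.asarray(maps_b, dtype=float)
    if A.ndim != 4 or B.ndim != 4 or A.shape[1:] != B.shape[1:]:
        raise ValueError("maps must be stacked (n, x, y, z) with matching grids")
    na, nb = A.shape[0], B.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need at least two maps per group")
    stacked = np.concatenate([A, B], axis=0)
    if np.allclose(stacked, stacked[0]):
        raise ValueError("degenerate input: all maps identical")
    if mask is None:
        mask = np.ones(A.shape[1:], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if params is None:
        params = TFCEParams()
    N = na + nb

    def enhanced_stat(idx_a: np.ndarray) -> np.ndarray:
        sel = np.zeros(N, dtype=bool)
        sel[idx_a] = True
        diff = np.abs(stacked[sel].mean(axis=0) - stacked[~sel].mean(axis=0))
        return tfce_enhance(diff, params, mask)

    observed = enhanced_stat(np.arange(na))
    n_total = comb(N, na)
    exhaustive = n_total <= n_perm
    if exhaustive:
        null_max = np.empty(n_total)
        for i, idx in enumerate(combinations(range(N), na)):
            null_max[i] = enhanced_stat(np.asarray(idx)).max()
    else:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        null_max = np.empty(n_perm + 1)
        null_max[0] = observed.max()        # observed labelling included
        for i in range(n_perm):
            idx = rng.permutation(N)[:na]
            null_max[i + 1] = enhanced_stat(idx).max()
    p_map = np.full(mask.shape, np.nan)
    obs_in = observed[mask]
    # rank of each voxel's observed value within the null max distribution
    p_map[mask] = (null_max[None, :] >= obs_in[:, None]).mean(axis=1)
    return PermutationResult(p_map=p_map, observed=observed,
                             null_max=null_max, exhaustive=exhaustive)
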