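"""Group-level inference on classification-image maps.

Individual templates are z-scored and averaged into group maps; the
mass-univariate tests come from functional neuroimaging: a per-pixel
one-sample t-test against zero with Benjamini-Hochberg FDR masking for
within-group maps, and a cluster-based permutation test (suprathreshold
pixels grouped by 4-connectivity, cluster mass = sum of |t|, null from
group-label permutations of the max cluster mass) for between-group
differences.

Weight sets are regions of interest extracted from the pooled maps:
pixels whose one-sample t-test beats p < 1e-10, grouped by adjacency,
kept when at least 7 pixels survive together, and characterized by
size, sign, centroid and extent in physical (ms, Hz) units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
EIGHT_CONN = np.ones((3, 3), dtype=int)


def _stack(maps) -> np.ndarray:
    arr = np.asarray([np.asarray(m, dtype=np.float64) for m in maps])
    if arr.ndim != 3:
        raise ValueError("maps must share one 2-D grid")
    return arr


def group_mean(z_maps) -> np.ndarray:
    """Pixelwise arithmetic mean of individually z-scored maps."""
    return _stack(z_maps).mean(axis=0)


def pixel_ttest_fdr(z_maps, q: float = 0.01):
    """One-sample t against zero per pixel with BH-FDR masking at rate q.

    Returns (t_map, p_map, fdr_mask).  Pixels with undefined t (zero
    variance across maps) are excluded from the mask with a warning.
    """
    arr = _stack(z_maps)
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 maps for a per-pixel t-test")
    with np.errstate(divide="ignore", invalid="ignore"):
        t_map, p_map = stats.ttest_1samp(arr, 0.0, axis=0)
    finite = np.isfinite(p_map)
    mask = np.zeros(arr.shape[1:], dtype=bool)
    if not finite.any():
        warnings.warn("t undefined at every pixel; empty FDR mask")
        return t_map, p_map, mask
    if not finite.all():
        warnings.warn("t undefined at some pixels; excluded from FDR mask")
    rej, *_ = multipletests(p_map[finite], alpha=q, method="fdr_bh")
    mask[finite] = rej
    return t_map, p_map, mask


@dataclass(frozen=True)
class Cluster:
    pixels: tuple  # tuple of (t_idx, f_idx)
    mass: float
    p_value: float
    sign: int


def _two_sample_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per pixel (vectorized)."""
    n1, n2 = a.shape[0], b.shape[0]
    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    v1 = a.var(axis=0, ddof=1)
    v2 = b.var(axis=0, ddof=1)
    sp = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (m1 - m2) / np.sqrt(sp * (1 / n1 + 1 / n2))


def _max_cluster_mass(tmap: np.ndarray, tcrit: float,
                      structure: np.ndarray) -> float:
    supra = np.abs(tmap) > tcrit
    if not supra.any():
        return 0.0
    best = 0.0
    for sign_mask in (supra & (tmap > 0), supra & (tmap < 0)):
        if not sign_mask.any():
            continue
        lab, nlab = ndimage.label(sign_mask, structure=structure)
        masses = ndimage.sum_labels(np.abs(tmap), lab,
                                    index=np.arange(1, nlab + 1))
        if len(masses):
            best = max(best, float(np.max(masses)))
    return best


def cluster_permutation_test(maps_group1, maps_group2,
                             alpha_threshold: float = 0.05,
                             n_permutations: int = 1000, rng=None,
                             connectivity: np.ndarray = FOUR_CONN):
    """Cluster-based permutation test for a group difference in the maps.

    Pixels whose two-sample |t| exceeds the two-sided ``alpha_threshold``
    quantile form clusters under the given connectivity; the cluster
    statistic is the mass (sum of |t|), and each observed cluster is
    referred to the permutation null of the maximum cluster mass over
    random group relabelings.  Cluster p-values use the add-one rule
    (b + 1)/(m + 1).  Returns (clusters, t_map).
    """
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations; p-values are coarse")
    rng = rng if rng is not None else np.random.default_rng(0)
    a = _stack(maps_group1)
    b = _stack(maps_group2)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 maps per group")
    n1 = a.shape[0]
    pooled = np.concatenate([a, b], axis=0)
    df = a.shape[0] + b.shape[0] - 2
    tcrit = float(stats.t.ppf(1 - alpha_threshold / 2, df))
    tmap = _two_sample_t(a, b)
    tmap = np.nan_to_num(tmap)

    # observed clusters, split by sign
    clusters = []
    supra = np.abs(tmap) > tcrit
    observed = []
    for sign in (1, -1):
        mask = supra & ((tmap > 0) if sign > 0 else (tmap < 0))
        lab, nlab = ndimage.label(mask, structure=connectivity)
        for k in range(1, nlab + 1):
            px = np.argwhere(lab == k)
            mass = float(np.abs(tmap)[lab == k].sum())
            observed.append((tuple(map(tuple, px)), mass, sign))
    if not observed:
        return [], tmap

    null = np.empty(n_permutations)
    idx = np.arange(pooled.shape[0])
    for m in range(n_permutations):
        perm = rng.permutation(idx)
        pt = _two_sample_t(pooled[perm[:n1]], pooled[perm[n1:]])
        null[m] = _max_cluster_mass(np.nan_to_num(pt), tcrit, connectivity)
    for px, mass, sign in observed:
        p = (np.sum(null >= mass) + 1.0) / (n_permutations + 1.0)
        clusters.append(Cluster(pixels=px, mass=mass, p_value=float(p),
                                sign=sign))
    clusters.sort(key=lambda c: c.p_value)
    return clusters, tmap


@dataclass(frozen=True)
class WeightSet:
    """A region of consistently signed template weight across listeners."""

    id: int
    pixels: tuple                  # tuple of (t_idx, f_idx)
    size: int
    sign: str                      # 'positive' or 'negative'
    centroid_ms: float
    centroid_hz: float
    extent_ms: float
    extent_hz: float

    def mask(self, grid_shape) -> np.ndarray:
        m = np.zeros(grid_shape, dtype=bool)
        for t, f in self.pixels:
            m[t, f] = True
        return m


def extract_weight_sets(all_maps, time_bin: float, center_freqs,
                        p_threshold: float = 1e-10, min_size: int = 7,
                        connectivity: np.ndarray = FOUR_CONN):
    """Extract weight sets from maps pooled across all listeners.

    Per-pixel one-sample t against zero; pixels with p below
    ``p_threshold`` are grouped by adjacency, and components of at
    least ``min_size`` pixels become WeightSets annotated with sign,
    centroid and extent through the grid metadata (time in ms, frequency
    in Hz).  Deterministic; an empty list is a valid result.
    """
    arr = _stack(all_maps)
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 maps")
    center_freqs = np.asarray(center_freqs, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_map, p_map = stats.ttest_1samp(arr, 0.0, axis=0)
    sig = np.nan_to_num(p_map, nan=1.0) < p_threshold
    mean_map = arr.mean(axis=0)
    sets = []
    sid = 0
    for sign in (1, -1):
        mask = sig & ((mean_map > 0) if sign > 0 else (mean_map <= 0))
        lab, nlab = ndimage.label(mask, structure=connectivity)
        for k in range(1, nlab + 1):
            px = np.argwhere(lab == k)
            if len(px) < min_size:
                continue
            t_idx, f_idx = px[:, 0], px[:, 1]
            sid += 1
            sets.append(WeightSet(
                id=sid, pixels=tuple(map(tuple, px)), size=len(px),
                sign="positive" if sign > 0 else "negative",
                centroid_ms=float((t_idx.mean() + 0.5) * time_bin * 1000),
                centroid_hz=float(center_freqs[f_idx].mean()),
                extent_ms=float((t_idx.max() - t_idx.min() + 1)
                                * time_bin * 1000),
                extent_hz=float(center_freqs[f_idx.max()]
                                - center_freqs[f_idx.min()]),
            ))
    sets.sort(key=lambda s: (s.centroid_ms, s.centroid_hz))
    return [WeightSet(id=i + 1, pixels=s.pixels, size=s.size, sign=s.sign,
                      centroid_ms=s.centroid_ms, centroid_hz=s.centroid_hz,
                      extent_ms=s.extent_ms, extent_hz=s.extent_hz)
            for i, s in enumerate(sets)]


def roi_group_test(weight_sets, maps_group1, maps_group2) -> pd.DataFrame:
    """Two-sample t-test on mean in-set weight per listener, per weight set.

    One row per set: per-group mean and SD of the in-set mean weights,
    the uncorrected t-test p-value, and a Bonferroni-adjusted column.
    """
    a = _stack(maps_group1) if len(maps_group1) else None
    b = _stack(maps_group2) if len(maps_group2) else None
    rows = []
    n_sets = len(weight_sets)
    for ws in weight_sets:
        mask = ws.mask(a.shape[1:]) if a is not None else None
        m1 = a[:, mask].mean(axis=1)
        m2 = b[:, mask].mean(axis=1)
        t, p = stats.ttest_ind(m1, m2)
        rows.append({
            "set_id": ws.id, "size_px": ws.size, "sign": ws.sign,
            "centroid_ms": ws.centroid_ms, "centroid_hz": ws.centroid_hz,
            "extent_ms": ws.extent_ms, "extent_hz": ws.extent_hz,
            "group1_mean": float(m1.mean()), "group1_sd": float(m1.std(ddof=1)),
            "group2_mean": float(m2.mean()), "group2_sd": float(m2.std(ddof=1)),
            "t": float(t), "p": float(p),
            "p_bonferroni": float(min(1.0, p * n_sets)),
        })
    return pd.DataFrame(rows)
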