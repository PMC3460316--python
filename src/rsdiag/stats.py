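"""Massively univariate group statistics and cluster feature selection.

Voxelwise one- and two-sample t-maps; |t| thresholding with
connected-component cluster-size filtering (positive and negative
suprathreshold voxels form separate components, since the contrasts are
two-tailed); Monte-Carlo calibration of the minimum cluster size; a
peak-based cluster extractor ordered by statistical mass (sum of |t|
over member voxels); per-cluster mean features; and the robust
sub-iteration voxel selection that intersects significance across
leave-two-folds-out map sets.

The cluster extractor is governed by the parameter vector
``[theta_t, theta_cs, n_clusters, d_min, v_min]``: |t| threshold,
minimum component volume (mm^3), number of clusters retained (inf
allowed), minimum inter-peak distance (mm), and minimum extracted
cluster volume (mm^3).
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import Cluster, ClusterSet, GridMismatchError, Mask, StatMap

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class ClusterFeatureSpec:
    """The five-parameter cluster feature-selection recipe."""

    theta_t: float
    theta_cs: float  # mm^3
    n_clusters: float  # may be math.inf
    d_min: float  # mm
    v_min: float  # mm^3
    n_comparisons: int = 1

    def __post_init__(self) -> None:
        if self.theta_t < 0 or self.theta_cs < 0 or self.d_min < 0 or self.v_min < 0:
            raise ValueError("cluster spec parameters must be non-negative")
        if not (self.n_clusters >= 1):
            raise ValueError("n_clusters must be >= 1 (or inf)")
        if self.n_comparisons not in (1, 2):
            raise ValueError("n_comparisons must be 1 or 2")

    @classmethod
    def parse(cls, text: str, n_comparisons: int = 1) -> "ClusterFeatureSpec":
        """Parse the bracket syntax, e.g. ``"[2.582, 1701, inf, 30, 540]"``."""
        body = text.strip().lstrip("[").rstrip("]")
        parts = [p.strip() for p in re.split(r"[,\s]+", body) if p.strip()]
        if len(parts) != 5:
            raise ValueError(f"expected 5 parameters, got {len(parts)}: {text!r}")
        vals = [math.inf if p.lower() in ("inf", "∞") else float(p) for p in parts]
        return cls(vals[0], vals[1], vals[2], vals[3], vals[4], n_comparisons)


# ---------------------------------------------------------------------------
# t-maps
# ---------------------------------------------------------------------------


def two_sample_tmap(volumes_a: np.ndarray, volumes_b: np.ndarray, mask: Mask,
                    contrast: str = "A-vs-B", voxel_mm: float = 3.0) -> StatMap:
    """Pooled-variance two-sample t at each masked voxel (df = nA + nB - 2).

    ``volumes_a``/``volumes_b`` have shape (n_subjects, nx, ny, nz).
    Voxels with zero pooled variance get t = 0 with a warning.
    """
    A = np.asarray(volumes_a, dtype=float)
    B = np.asarray(volumes_b, dtype=float)
    if A.shape[1:] != mask.grid_dims or B.shape[1:] != mask.grid_dims:
        raise GridMismatchError("volume grids do not match mask")
    na, nb = A.shape[0], B.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 volumes per group")
    ma, mb = A.mean(axis=0), B.mean(axis=0)
    va = A.var(axis=0, ddof=1)
    vb = B.var(axis=0, ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    t = np.zeros(mask.grid_dims)
    sel = mask.data & (se > 0)
    degenerate = mask.data & (se == 0)
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} masked voxels have zero pooled "
                      "variance; their t set to 0")
    t[sel] = (ma[sel] - mb[sel]) / se[sel]
    return StatMap(t, df=na + nb - 2, contrast=contrast, mask=mask, voxel_mm=voxel_mm)


def one_sample_tmap(volumes: np.ndarray, mask: Mask, contrast: str = "localizer",
                    voxel_mm: float = 3.0) -> StatMap:
    """One-sample t against zero at each masked voxel (df = n - 1)."""
    V = np.asarray(volumes, dtype=float)
    if V.shape[1:] != mask.grid_dims:
        raise GridMismatchError("volume grid does not match mask")
    n = V.shape[0]
    if n < 2:
        raise ValueError("need at least 2 volumes")
    m = V.mean(axis=0)
    sd = V.std(axis=0, ddof=1)
    t = np.zeros(mask.grid_dims)
    sel = mask.data & (sd > 0)
    if (mask.data & (sd == 0) & (m != 0)).any():
        warnings.warn("zero-variance voxels with nonzero mean; their t set to 0")
    t[sel] = m[sel] / (sd[sel] / np.sqrt(n))
    return StatMap(t, df=n - 1, contrast=contrast, mask=mask, voxel_mm=voxel_mm)


# ---------------------------------------------------------------------------
# thresholding and cluster-size filtering
# ---------------------------------------------------------------------------


def threshold_and_size_filter(stat_map: StatMap, theta_t: float, theta_cs: float,
                              connectivity: int = 26) -> StatMap:
    """Zero |t| <= theta_t, then drop small connected components.

    Positive and negative suprathreshold voxels are clustered
    separately (sign split) and components with volume (mm^3) below
    ``theta_cs`` are zeroed.
    """
    struct = _STRUCTS[connectivity]
    t = stat_map.t.copy()
    t[np.abs(t) <= theta_t] = 0.0
    if theta_cs > 0:
        vox_mm3 = stat_map.voxel_mm ** 3
        keep = np.zeros_like(t, dtype=bool)
        for sign_sel in (t > 0, t < 0):
            labels, n_lab = ndimage.label(sign_sel, structure=struct)
            if n_lab == 0:
                continue
            sizes = ndimage.sum_labels(np.ones_like(t), labels, range(1, n_lab + 1))
            good = np.flatnonzero(sizes * vox_mm3 >= theta_cs) + 1
            keep |= np.isin(labels, good)
        t[~keep] = 0.0
    return stat_map.copy_with(t)


def monte_carlo_cluster_threshold(mask: Mask, smoothness_fwhm_mm: float,
                                  theta_t: float, alpha: float = 0.05,
                                  n_sim: int = 1000, seed: int = 0,
                                  voxel_mm: float = 3.0,
                                  group_sizes: tuple[int, int] | None = None,
                                  connectivity: int = 26) -> int:
    """Minimum cluster size (voxels) controlling family-wise error at alpha.

    Simulates null fields on the mask grid: Gaussian white noise smoothed
    to ``smoothness_fwhm_mm`` and variance-normalized.  With
    ``group_sizes=None`` the smoothed field itself is thresholded at
    ``theta_t`` (a z-field null); with ``group_sizes=(nA, nB)`` each
    simulation draws nA+nB smoothed subject fields and thresholds the
    two-sample t-field, matching a group-comparison null.  Returns the
    smallest s such that the fraction of simulations whose largest
    suprathreshold component reaches s is <= alpha.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100 for a stable calibration")
    if mask.n_voxels == 0:
        raise ValueError("degenerate (empty) mask")
    rng = np.random.default_rng(seed)
    struct = _STRUCTS[connectivity]
    sigma = smoothness_fwhm_mm / voxel_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    def smooth_field() -> np.ndarray:
        f = rng.standard_normal(mask.grid_dims)
        if sigma > 0:
            f = ndimage.gaussian_filter(f, sigma)
        sd = f[mask.data].std()
        return f / sd if sd > 0 else f

    max_sizes = np.zeros(n_sim, dtype=int)
    for i in range(n_sim):
        if group_sizes is None:
            field = smooth_field()
        else:
            na, nb = group_sizes
            A = np.stack([smooth_field() for _ in range(na)])
            B = np.stack([smooth_field() for _ in range(nb)])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                field = two_sample_tmap(A, B, mask, voxel_mm=voxel_mm).t
        supra = (np.abs(field) > theta_t) & mask.data
        best = 0
        for sign_sel in (supra & (field > 0), supra & (field < 0)):
            labels, n_lab = ndimage.label(sign_sel, structure=struct)
            if n_lab:
                sizes = ndimage.sum_labels(np.ones(mask.grid_dims), labels,
                                           range(1, n_lab + 1))
                best = max(best, int(sizes.max()))
        max_sizes[i] = best
    for s in range(1, int(max_sizes.max()) + 2):
        if np.mean(max_sizes >= s) <= alpha:
            return s
    return int(max_sizes.max()) + 1


# ---------------------------------------------------------------------------
# cluster extraction
# ---------------------------------------------------------------------------


def extract_clusters(stat_map: StatMap, d_min: float = 0.0, v_min: float = 0.0,
                     n_clusters: float = math.inf,
                     connectivity: int = 26) -> ClusterSet:
    """Peak-based cluster extraction from a thresholded map.

    Local |t| maxima over the suprathreshold voxels are the candidate
    peaks; peaks closer than ``d_min`` mm are merged (the higher-|t| peak
    wins, ties broken by lower linear voxel index).  Every suprathreshold
    voxel is assigned to the nearest surviving peak (Euclidean mm; ties
    to the peak with lower linear index).  Clusters smaller than
    ``v_min`` mm^3 are discarded; survivors are ordered by decreasing
    statistical mass and the top ``n_clusters`` returned.
    """
    t = stat_map.t
    vm = stat_map.voxel_mm
    supra = t != 0
    if not supra.any():
        return ClusterSet([], voxel_mm=vm)
    abs_t = np.abs(t)
    struct = _STRUCTS[connectivity]
    neighborhood_max = ndimage.maximum_filter(abs_t, footprint=struct, mode="constant")
    is_peak = supra & (abs_t >= neighborhood_max)
    peak_coords = np.argwhere(is_peak)
    lin = np.ravel_multi_index(peak_coords.T, t.shape)
    order = np.lexsort((lin, -abs_t[tuple(peak_coords.T)]))
    peak_coords = peak_coords[order]

    kept: list[np.ndarray] = []
    for pc in peak_coords:
        if d_min > 0 and any(np.linalg.norm((pc - kc) * vm) < d_min for kc in kept):
            continue
        kept.append(pc)
    kept_arr = np.array(kept)  # (P, 3), in decreasing |t| order
    kept_lin = np.ravel_multi_index(kept_arr.T, t.shape)
    # order peaks by linear index for deterministic distance tie-breaks
    by_lin = np.argsort(kept_lin)
    kept_arr = kept_arr[by_lin]

    vox = np.argwhere(supra)  # (N, 3)
    d2 = ((vox[:, None, :] - kept_arr[None, :, :]) ** 2).sum(axis=2)
    assign = np.argmin(d2, axis=1)  # first minimum -> lowest linear index peak

    clusters = []
    for p in range(len(kept_arr)):
        members = vox[assign == p]
        if len(members) == 0:
            continue
        volume = len(members) * vm ** 3
        if volume < v_min:
            continue
        mass = float(abs_t[tuple(members.T)].sum())
        clusters.append(Cluster(members, tuple(int(c) for c in kept_arr[p]),
                                volume, mass))
    peak_lin_of = {tuple(cl.peak): np.ravel_multi_index(cl.peak, t.shape)
                   for cl in clusters}
    clusters.sort(key=lambda cl: (-cl.mass, peak_lin_of[tuple(cl.peak)]))
    if math.isfinite(n_clusters):
        clusters = clusters[: int(n_clusters)]
    return ClusterSet(clusters, voxel_mm=vm)


def cluster_mean_features(volume_sets, cluster_sets) -> np.ndarray:
    """Per-participant cluster-mean feature vectors.

    ``volume_sets`` is a sequence (one per statistical map) of arrays of
    shape (n_participants, nx, ny, nz) holding the feature volume the
    map was computed on; ``cluster_sets`` the matching
    :class:`ClusterSet` per map.  For each map and each of its clusters,
    the participant's mean value over the cluster's voxels is one
    feature; features are concatenated in (map, cluster-rank) order.
    """
    volume_sets = list(volume_sets)
    cluster_sets = list(cluster_sets)
    if len(volume_sets) != len(cluster_sets):
        raise ValueError("one ClusterSet per feature-volume array required")
    if sum(len(cs) for cs in cluster_sets) == 0:
        raise ValueError("no features selected: every ClusterSet is empty")
    n_participants = np.asarray(volume_sets[0]).shape[0]
    cols = []
    for vols, cs in zip(volume_sets, cluster_sets):
        vols = np.asarray(vols, dtype=float)
        if vols.shape[0] != n_participants:
            raise ValueError("participant counts differ across volume sets")
        for cl in cs:
            idx = tuple(cl.voxels.T)
            cols.append(vols[(slice(None),) + idx].mean(axis=1))
    return np.column_stack(cols)


class ClusterFeatureExtractor:
    """Group-difference cluster feature selection as a fit/transform step.

    ``fit`` takes per-participant feature volumes ``V`` of shape
    (n_participants, eta, nx, ny, nz) and diagnosis labels, computes the
    eta x n_comparisons two-sample t-maps (patients vs controls and,
    when requested, ADHD-C vs ADHD-I), thresholds them voxelwise and by
    cluster size, optionally applies the robust sub-iteration
    intersection, and extracts mass-ordered clusters.  ``transform``
    returns each participant's cluster-mean feature vector.  Fitting on
    training rows only keeps the selection leakage-free inside
    cross-validation.

    Parameters
    ----------
    spec : ClusterFeatureSpec
        The [theta_t, theta_cs, n_clusters, d_min, v_min] recipe;
        ``spec.n_comparisons == 2`` adds the ADHD-C vs ADHD-I contrast.
    robust : bool
        If true, ``fit`` requires ``sub_folds`` — nine index arrays, each
        the training rows with one further fold removed — and keeps only
        voxels significant in all nine sub-iteration map sets.
    """

    def __init__(self, spec: ClusterFeatureSpec, robust: bool = False,
                 connectivity: int = 26, voxel_mm: float = 3.0):
        self.spec = spec
        self.robust = robust
        self.connectivity = connectivity
        self.voxel_mm = voxel_mm

    @staticmethod
    def _groups(y: np.ndarray, comparison: str) -> tuple[np.ndarray, np.ndarray]:
        y = np.asarray(y)
        if comparison == "patients-vs-controls":
            return np.flatnonzero(y != "control"), np.flatnonzero(y == "control")
        if comparison == "c-vs-i":
            return np.flatnonzero(y == "adhd-c"), np.flatnonzero(y == "adhd-i")
        raise ValueError(f"unknown comparison {comparison!r}")

    def _thresholded_maps(self, V: np.ndarray, y: np.ndarray, mask: Mask,
                          rows: np.ndarray) -> list[StatMap]:
        comparisons = ["patients-vs-controls"]
        if self.spec.n_comparisons == 2:
            comparisons.append("c-vs-i")
        maps = []
        for comparison in comparisons:
            ia, ib = self._groups(y[rows], comparison)
            for k in range(V.shape[1]):
                m = two_sample_tmap(V[rows][ia, k], V[rows][ib, k], mask,
                                    contrast=comparison, voxel_mm=self.voxel_mm)
                maps.append(threshold_and_size_filter(
                    m, self.spec.theta_t, self.spec.theta_cs, self.connectivity))
        return maps

    def fit(self, V: np.ndarray, y, mask: Mask | None = None,
            sub_folds=None) -> "ClusterFeatureExtractor":
        V = np.asarray(V, dtype=float)
        if V.ndim != 5:
            raise ValueError("V must be (participants, eta, nx, ny, nz)")
        y = np.asarray(y)
        if mask is None:
            mask = Mask(np.ones(V.shape[2:], dtype=bool))
        all_rows = np.arange(V.shape[0])
        maps = self._thresholded_maps(V, y, mask, all_rows)
        if self.robust:
            if sub_folds is None or len(sub_folds) != 9:
                raise ValueError("robust selection requires 9 sub-iteration index sets")
            sub_maps = [self._thresholded_maps(V, y, mask, np.asarray(rows))
                        for rows in sub_folds]
            maps = robust_voxel_selection(maps, sub_maps)
        self.stat_maps_ = maps
        self.cluster_sets_ = [
            extract_clusters(m, self.spec.d_min, self.spec.v_min,
                             self.spec.n_clusters, self.connectivity)
            for m in maps]
        self.n_features_ = sum(len(cs) for cs in self.cluster_sets_)
        if self.n_features_ == 0:
            raise ValueError("no features selected: every ClusterSet is empty")
        self.eta_ = V.shape[1]
        return self

    def transform(self, V: np.ndarray) -> np.ndarray:
        if not hasattr(self, "cluster_sets_"):
            raise RuntimeError("ClusterFeatureExtractor is not fitted")
        V = np.asarray(V, dtype=float)
        n_maps_per_cmp = self.eta_
        volume_sets = []
        for m_idx in range(len(self.cluster_sets_)):
            k = m_idx % n_maps_per_cmp
            volume_sets.append(V[:, k])
        return cluster_mean_features(volume_sets, self.cluster_sets_)

    def fit_transform(self, V, y, mask: Mask | None = None, sub_folds=None) -> np.ndarray:
        return self.fit(V, y, mask, sub_folds).transform(V)


def robust_voxel_selection(s_i_maps, subiteration_maps) -> list[StatMap]:
    """Intersect significance across the nine leave-two-folds-out map sets.

    ``s_i_maps`` is the list of thresholded maps computed without fold i;
    ``subiteration_maps`` is a list of nine lists, each holding the
    correspondingly ordered thresholded maps computed without folds i and
    j.  Each map in ``s_i_maps`` is zeroed wherever any of its nine
    counterparts is zero, so only voxels significant in all ten map sets
    survive.
    """
    s_i_maps = list(s_i_maps)
    subs = [list(s) for s in subiteration_maps]
    if len(subs) != 9:
        raise ValueError(f"expected 9 sub-iteration map sets, got {len(subs)}")
    for s in subs:
        if len(s) != len(s_i_maps):
            raise ValueError("sub-iteration set size differs from S_i")
    out = []
    for m_idx, base in enumerate(s_i_maps):
        survive = base.t != 0
        for s in subs:
            survive &= s[m_idx].t != 0
        t = np.where(survive, base.t, 0.0)
        out.append(base.copy_with(t))
    return out
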