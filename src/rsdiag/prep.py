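"""Scan-level preprocessing: temporal standardization, spatial window
averaging, brain masking, and percent-signal-change normalization.

Temporal standardization truncates every scan to its first 185 s and
linearly resamples it to 2 Hz, giving a common grid of 370 volumes at
0.5 s.  Spatial window averaging (SWA) block-averages the grid by an
integer factor r per axis (57x67x50 -> 19x22x16 at r=3, 7x8x6 at r=8),
absorbing the remainder voxels into the final window of each axis so no
data are dropped.  Two intensity normalizations are provided: PSCS-tc
scales each voxel's timecourse to percent signal change about its own
temporal mean (making every voxel mean-zero), and PSCS-s scales the whole
scan by its mean over masked voxels and time (cancelling site-level
multiplicative gain while preserving between-voxel mean differences).
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import interp1d

from .types import GridMismatchError, Mask, Scan4D


class ScanTooShortError(ValueError):
    """Raised when a scan is shorter than the standardization target."""


def standardize_time(scan: Scan4D, target_duration_s: float = 185.0,
                     target_rate_hz: float = 2.0) -> Scan4D:
    """Truncate to the first ``target_duration_s`` seconds and resample.

    The output grid has ``round(target_duration_s * target_rate_hz)``
    volumes at sample times 0, 1/rate, 2/rate, ... anchored at the first
    input volume (taken as time 0).  Values are linear interpolations of
    the input timecourse; extrapolation is refused.
    """
    n_out = int(round(target_duration_s * target_rate_hz))
    out_tr = 1.0 / target_rate_hz
    out_times = np.arange(n_out) * out_tr
    in_times = np.arange(scan.n_timepoints) * scan.tr_s
    if scan.duration_s < target_duration_s - 1e-9 or in_times[-1] < out_times[-1] - 1e-9:
        raise ScanTooShortError(
            f"scan duration {scan.duration_s:.1f}s < target {target_duration_s}s; "
            "refusing to extrapolate")
    if scan.n_timepoints == n_out and abs(scan.tr_s - out_tr) < 1e-12:
        return Scan4D(scan.data.copy(), scan.voxel_mm, out_tr)
    f = interp1d(in_times, scan.data, axis=3, bounds_error=False,
                 fill_value=(scan.data[..., 0], scan.data[..., -1]))
    return Scan4D(f(out_times), scan.voxel_mm, out_tr)


def _swa_axis_edges(dim: int, r: int) -> np.ndarray:
    """Window start indices along one axis; the last window absorbs the remainder."""
    m = dim // r
    return np.arange(m) * r


def swa_array(arr: np.ndarray, r: int) -> np.ndarray:
    """Spatial window averaging of a 3D volume or 4D scan array.

    Output spatial dims are ``floor(dim / r)`` per axis; each output voxel
    is the arithmetic mean of its window, with remainder voxels absorbed
    into the final window of each axis.  Time (axis 3), if present, is
    untouched.
    """
    arr = np.asarray(arr, dtype=float)
    if arr.ndim not in (3, 4):
        raise ValueError("swa expects a 3D volume or 4D scan")
    dims = arr.shape[:3]
    if r < 1:
        raise ValueError("reduction factor r must be >= 1")
    if r > min(dims):
        raise ValueError(f"r={r} exceeds smallest grid dimension {min(dims)}")
    if r == 1:
        return arr.copy()
    out = arr
    counts = np.ones([1] * arr.ndim, dtype=float)
    for axis in range(3):
        edges = _swa_axis_edges(dims[axis], r)
        out = np.add.reduceat(out, edges, axis=axis)
        win_len = np.full(len(edges), r, dtype=float)
        win_len[-1] = dims[axis] - edges[-1]
        shape = [1] * arr.ndim
        shape[axis] = len(edges)
        counts = counts * win_len.reshape(shape)
    return out / counts


def swa(scan: Scan4D, r: int) -> Scan4D:
    """SWA applied independently per time point of a 4D scan."""
    return Scan4D(swa_array(scan.data, r), voxel_mm=scan.voxel_mm * r, tr_s=scan.tr_s)


def build_mask(scans, threshold_frac: float = 0.5) -> Mask:
    """Mean-intensity brain mask over a collection of scans.

    A voxel is included iff its mean intensity across all scans and time
    points is at least ``threshold_frac`` times the global mean of
    nonzero voxels of that mean volume.
    """
    scans = list(scans)
    if not scans:
        raise ValueError("build_mask requires at least one scan")
    grid = scans[0].grid_dims
    mean_vol = np.zeros(grid)
    for s in scans:
        if s.grid_dims != grid:
            raise GridMismatchError("scans passed to build_mask have differing grids")
        mean_vol += s.data.mean(axis=3)
    mean_vol /= len(scans)
    nonzero = mean_vol[mean_vol != 0]
    global_mean = nonzero.mean() if nonzero.size else 0.0
    mask = mean_vol >= threshold_frac * global_mean
    return Mask(mask, provenance={"method": "mean-intensity",
                                  "threshold_frac": threshold_frac,
                                  "n_scans": len(scans)})


def downsample_mask(mask: Mask, r: int) -> Mask:
    """Reduced-resolution mask by majority vote within SWA windows."""
    frac = swa_array(mask.data.astype(float), r)
    prov = dict(mask.provenance)
    prov["swa_r"] = r
    return Mask(frac >= 0.5, provenance=prov)


def mask_and_flatten(volume, mask: Mask) -> np.ndarray:
    """Masked voxels of a 3D volume in x-fastest lexicographic order."""
    from .types import flatten_volume
    return flatten_volume(volume, mask)


def unflatten(vector, mask: Mask) -> np.ndarray:
    """Zero-filling inverse of :func:`mask_and_flatten`."""
    from .types import unflatten_vector
    return unflatten_vector(vector, mask)


def pscs_tc(scan: Scan4D, mask: Mask | None = None) -> Scan4D:
    """Percent-signal-change scaling of each voxel's timecourse.

    Each voxel timecourse x becomes ``100 * (x - mu_v) / mu_v`` where
    ``mu_v`` is that voxel's temporal mean; every output timecourse has
    mean zero.  Outside the mask (if given) voxels are zeroed.  A zero
    temporal mean inside the mask is an error (the scaling is undefined).
    """
    mu = scan.data.mean(axis=3)
    if mask is None:
        sel = np.ones(scan.grid_dims, dtype=bool)
    else:
        if mask.grid_dims != scan.grid_dims:
            raise GridMismatchError("mask grid does not match scan grid")
        sel = mask.data
    zero = sel & (mu == 0)
    if zero.any():
        vox = tuple(int(c) for c in np.argwhere(zero)[0])
        raise ZeroDivisionError(f"zero temporal mean at masked voxel {vox}")
    out = np.zeros_like(scan.data)
    out[sel] = 100.0 * (scan.data[sel] - mu[sel, None]) / mu[sel, None]
    return Scan4D(out, scan.voxel_mm, scan.tr_s)


def pscs_s(scan: Scan4D, mask: Mask) -> Scan4D:
    """Percent-signal-change scaling of the whole scan.

    Every value becomes ``100 * x / mu_scan`` with ``mu_scan`` the mean
    over all masked voxels and time points.  Between-voxel mean
    differences are preserved up to the common scale, and any global
    (site) gain cancels.
    """
    if mask.grid_dims != scan.grid_dims:
        raise GridMismatchError("mask grid does not match scan grid")
    mu = scan.data[mask.data].mean()
    if mu == 0:
        raise ZeroDivisionError("scan mean over mask is zero")
    return Scan4D(100.0 * scan.data / mu, scan.voxel_mm, scan.tr_s)
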