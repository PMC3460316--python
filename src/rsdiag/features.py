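"""Per-voxel temporal reductions: T Avg, timecourse PCA, band-limited
FFT features, and ALFF, plus assembly into participant feature vectors.

All reductions expect scans standardized to the common temporal grid
(370 volumes at 0.5 s).  The FFT convention is the unnormalized forward
DFT; the low-frequency band is the 18 components with frequencies
k / 185 Hz, k = 1..18, which are exactly those in [0.001, 0.1] Hz
(inclusive on both ends).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .types import FeatureVolumeSet, Mask, Scan4D, flatten_volume

STANDARD_N_T = 370
STANDARD_TR_S = 0.5
BAND_LO_HZ = 0.001
BAND_HI_HZ = 0.1


def tavg(scan: Scan4D) -> FeatureVolumeSet:
    """Replace each voxel's timecourse by its temporal mean (eta = 1)."""
    mean_vol = scan.data.mean(axis=3)
    mask = Mask(np.ones(scan.grid_dims, dtype=bool))
    return FeatureVolumeSet(mean_vol[None], mask, names=["tavg"])


def collect_timecourses(scans, mask: Mask) -> np.ndarray:
    """Pool masked voxel timecourses across participants.

    Returns an (n_participants * n_voxels) x n_t observation matrix, the
    input convention for :class:`TimecoursePCA` (each voxel timecourse
    from each participant is one observation).
    """
    rows = []
    for scan in scans:
        if scan.grid_dims != mask.grid_dims:
            raise ValueError("scan grid does not match mask")
        rows.append(scan.data[mask.data])  # (n_vox, n_t)
    return np.concatenate(rows, axis=0)


class TimecoursePCA(BaseEstimator, TransformerMixin):
    """PCA basis over pooled voxel timecourses.

    Observations are voxel timecourses (length 370 on the standard grid)
    pooled across the training participants; the basis is computed from
    centered observations by SVD with a deterministic sign convention
    (each component's largest-magnitude loading is positive).  Fitted on
    training participants only when used inside cross-validation.

    Attributes
    ----------
    components_ : ndarray (n_components, n_t)
        Orthonormal basis vectors.
    mean_ : ndarray (n_t,)
        Per-dimension centering means.
    explained_variance_ratio_ : ndarray (n_components,)
    """

    def __init__(self, n_components: int = 5):
        self.n_components = n_components

    def fit(self, X: np.ndarray, y=None) -> "TimecoursePCA":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need at least 2 timecourse observations")
        pca = PCA(n_components=self.n_components, svd_solver="full")
        pca.fit(X)
        comps = pca.components_
        # deterministic sign: largest-|loading| entry positive
        for i in range(comps.shape[0]):
            j = np.argmax(np.abs(comps[i]))
            if comps[i, j] < 0:
                comps[i] = -comps[i]
        self.components_ = comps
        self.mean_ = pca.mean_
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "components_")
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.components_.T

    def project_scan(self, scan: Scan4D, mask: Mask, k_keep: int) -> FeatureVolumeSet:
        """Per-voxel projection coefficients onto the first ``k_keep`` components."""
        check_is_fitted(self, "components_")
        if k_keep < 1 or k_keep > self.components_.shape[0]:
            raise ValueError(f"k_keep={k_keep} not in [1, {self.components_.shape[0]}]")
        if scan.grid_dims != mask.grid_dims:
            raise ValueError("scan grid does not match mask")
        coeffs = self.transform(scan.data[mask.data])[:, :k_keep]  # (n_vox, k)
        vols = np.zeros((k_keep,) + scan.grid_dims)
        for k in range(k_keep):
            vols[k][mask.data] = coeffs[:, k]
        names = [f"pca{k + 1}" for k in range(k_keep)]
        return FeatureVolumeSet(vols, mask, names=names)


def fit_timecourse_pca(scans, mask: Mask, n_components: int = 5) -> TimecoursePCA:
    """Fit a :class:`TimecoursePCA` on the pooled training timecourses."""
    return TimecoursePCA(n_components).fit(collect_timecourses(scans, mask))


def project_pca(scan: Scan4D, basis: TimecoursePCA, mask: Mask,
                k_keep: int) -> FeatureVolumeSet:
    """Thin wrapper over :meth:`TimecoursePCA.project_scan` (k_keep in {1, 5})."""
    return basis.project_scan(scan, mask, k_keep)


def _check_standard_grid(scan: Scan4D) -> None:
    if scan.n_timepoints != STANDARD_N_T or abs(scan.tr_s - STANDARD_TR_S) > 1e-9:
        raise ValueError(
            f"expected the standardized temporal grid ({STANDARD_N_T} points at "
            f"{STANDARD_TR_S}s), got {scan.n_timepoints} points at {scan.tr_s}s")


def band_component_indices(n_t: int = STANDARD_N_T, tr_s: float = STANDARD_TR_S,
                           lo_hz: float = BAND_LO_HZ, hi_hz: float = BAND_HI_HZ) -> np.ndarray:
    """DFT component indices k whose frequency k/(n_t*tr) lies in [lo, hi]."""
    freqs = np.arange(1, n_t // 2 + 1) / (n_t * tr_s)
    ks = np.flatnonzero((freqs >= lo_hz) & (freqs <= hi_hz)) + 1
    return ks


def fft_band_features(scan: Scan4D) -> FeatureVolumeSet:
    """Modulus and phase of the low-frequency DFT components (eta = 36).

    Unnormalized forward DFT of each voxel's 370-point timecourse; the
    18 band components' moduli come first, then their 18 phase angles
    (radians in (-pi, pi]).
    """
    _check_standard_grid(scan)
    ks = band_component_indices(scan.n_timepoints, scan.tr_s)
    spectrum = np.fft.rfft(scan.data, axis=3)[..., ks]  # (x, y, z, 18)
    moduli = np.abs(spectrum)
    phases = np.angle(spectrum)
    vols = np.concatenate([np.moveaxis(moduli, 3, 0), np.moveaxis(phases, 3, 0)], axis=0)
    mask = Mask(np.ones(scan.grid_dims, dtype=bool))
    names = [f"mod_k{k}" for k in ks] + [f"phase_k{k}" for k in ks]
    return FeatureVolumeSet(vols, mask, names=names)


def alff(scan: Scan4D) -> FeatureVolumeSet:
    """Amplitude of low-frequency fluctuations: mean band modulus (eta = 1)."""
    _check_standard_grid(scan)
    ks = band_component_indices(scan.n_timepoints, scan.tr_s)
    moduli = np.abs(np.fft.rfft(scan.data, axis=3)[..., ks])
    mask = Mask(np.ones(scan.grid_dims, dtype=bool))
    return FeatureVolumeSet(moduli.mean(axis=3)[None], mask, names=["alff"])


def assemble_feature_vector(fvs: FeatureVolumeSet, mask: Mask) -> tuple[np.ndarray, list[str]]:
    """Mask, flatten, and concatenate the eta feature volumes in k order.

    Returns the participant feature vector and its feature names, which
    encode (k, flattened voxel index).
    """
    if fvs.volumes.shape[1:] != mask.grid_dims:
        raise ValueError("feature volume grid does not match mask")
    parts, names = [], []
    base = fvs.names if fvs.names is not None else [f"k{k}" for k in range(fvs.eta)]
    for k in range(fvs.eta):
        flat = flatten_volume(fvs.volumes[k], mask)
        parts.append(flat)
        names.extend(f"{base[k]}_v{i}" for i in range(flat.size))
    return np.concatenate(parts), names
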