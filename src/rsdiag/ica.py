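"""Group spatial ICA with GICA3 back-reconstruction.

The functional-connectivity analysis proceeds in four stages:

1. **Subject PCA** — each participant's masked, PSCS-tc-normalized data
   matrix (time x voxels) is reduced to 25 temporal dimensions by a
   separate spatial PCA.
2. **Group PCA** — the 25-dimensional reductions are concatenated across
   participants and reduced to 20 whitened group dimensions.
3. **FastICA** — symmetric (parallel) FastICA separates the 20 whitened
   spatial dimensions into 20 independent spatial component maps.
4. **GICA3 back-reconstruction** — participant-specific spatial maps are
   reconstructed through the stored linear transforms; by construction
   the across-participant mean of the subject maps equals the group map.

Component sign is fixed so each group map's largest-|value| voxel is
positive (ICA is sign-indeterminate); subject maps and the mixing matrix
are flipped consistently.  The default-mode network is identified among
the 20 components by absolute spatial correlation with a template map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning
from sklearn.utils.validation import check_is_fitted

from .prep import downsample_mask, pscs_tc, swa_array
from .types import Mask, Scan4D, flatten_volume, unflatten_vector

_FUN_ALIASES = {"tanh": "logcosh", "logcosh": "logcosh", "exp": "exp", "cube": "cube"}


class ICAConvergenceError(RuntimeError):
    """FastICA failed to converge within the iteration budget."""

    def __init__(self, max_iter: int, tol: float):
        super().__init__(
            f"FastICA did not converge within {max_iter} iterations at tol={tol}; "
            "increase max_iter or relax tol")
        self.max_iter = max_iter
        self.tol = tol


class NoDMNError(RuntimeError):
    """No component correlates with the DMN template above the floor."""


@dataclass
class ICAConfig:
    """Settings for the two-stage PCA + FastICA decomposition."""

    n_subject_pcs: int = 25
    n_group_pcs: int = 20
    nonlinearity: str = "logcosh"
    max_iter: int = 1000
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group_pcs > self.n_subject_pcs:
            raise ValueError("n_group_pcs must be <= n_subject_pcs")
        if self.nonlinearity not in _FUN_ALIASES:
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")


@dataclass
class SubjectReduction:
    """Output of a per-participant spatial PCA, with its back-transform."""

    reduced: np.ndarray        # (n_components, n_voxels)
    basis: np.ndarray          # (n_timepoints, n_components), orthonormal columns
    row_means: np.ndarray      # (n_timepoints,) centering over voxels
    singular_values: np.ndarray


def subject_pca(data: np.ndarray, n_components: int = 25) -> SubjectReduction:
    """Spatial PCA of one participant's (time x voxels) matrix.

    Voxels are the observations; the temporal dimension is reduced to
    ``n_components``.  Rows are centered across voxels first.  The
    reducing basis is retained so the reduction is invertible up to the
    discarded variance.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("expected a (time x voxels) matrix")
    n_t = data.shape[0]
    if n_t < n_components:
        raise ValueError(f"{n_t} time points < {n_components} requested components")
    m = data.mean(axis=1)
    centered = data - m[:, None]
    U, s, _ = np.linalg.svd(centered, full_matrices=False)
    U = U[:, :n_components]
    return SubjectReduction(U.T @ centered, U, m, s[:n_components])


def scan_to_matrix(scan: Scan4D, mask: Mask, normalize: bool = True) -> np.ndarray:
    """Masked (time x voxels) matrix, PSCS-tc-normalized by default.

    Voxel order is the package-wide x-fastest flattening order.
    """
    s = pscs_tc(scan, mask) if normalize else scan
    n_vox_total = int(np.prod(s.grid_dims))
    two_d = s.data.reshape(n_vox_total, s.n_timepoints, order="F")
    return two_d[np.ravel(mask.data, order="F")].T


class GroupICA(BaseEstimator):
    """Two-stage PCA + FastICA group decomposition with GICA3 maps.

    Parameters mirror :class:`ICAConfig`.  ``fit`` takes a list of
    per-participant (time x voxels) matrices (already masked and
    PSCS-tc-normalized; use :func:`scan_to_matrix`), or use
    :meth:`fit_scans` for :class:`~rsdiag.types.Scan4D` input.

    Attributes
    ----------
    components_ : ndarray (n_group_pcs, n_voxels)
        Group spatial maps, sign-fixed.
    subject_maps_ : ndarray (n_subjects, n_group_pcs, n_voxels)
        GICA3 per-participant spatial maps; their across-subject mean
        equals ``components_`` exactly (up to floating point).
    mixing_ : ndarray (n_group_pcs, n_group_pcs)
    n_iter_ : int
        FastICA iterations used.
    dmn_index_ : int
        Set by :meth:`identify_dmn`.
    """

    def __init__(self, n_subject_pcs: int = 25, n_group_pcs: int = 20,
                 nonlinearity: str = "logcosh", max_iter: int = 1000,
                 tol: float = 1e-6, random_state: int = 0):
        self.n_subject_pcs = n_subject_pcs
        self.n_group_pcs = n_group_pcs
        self.nonlinearity = nonlinearity
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    # -- fitting ----------------------------------------------------------

    def fit(self, subject_matrices, y=None) -> "GroupICA":
        mats = [np.asarray(m, dtype=float) for m in subject_matrices]
        if len(mats) < 1:
            raise ValueError("group ICA needs at least 1 participant")
        n_vox = mats[0].shape[1]
        if any(m.shape[1] != n_vox for m in mats):
            raise ValueError("participants have differing voxel counts")
        cfg = ICAConfig(self.n_subject_pcs, self.n_group_pcs,
                        self.nonlinearity, self.max_iter, self.tol,
                        self.random_state)
        L1, L2 = cfg.n_subject_pcs, cfg.n_group_pcs
        reductions = [subject_pca(m, L1) for m in mats]
        stacked = np.concatenate([r.reduced for r in reductions], axis=0)  # (M*L1, V)
        c = stacked.mean(axis=1)
        centered = stacked - c[:, None]
        U, s, Vt = np.linalg.svd(centered, full_matrices=False)
        if s[L2 - 1] <= 1e-12 * s[0]:
            raise ValueError(
                f"group data rank < {L2}; cannot retain {L2} group components")
        # whitened group data: rows have zero mean and unit variance over voxels
        white = np.sqrt(n_vox) * Vt[:L2]
        group_transform = np.sqrt(n_vox) * (U[:, :L2] / s[:L2]).T  # (L2, M*L1)

        ica = FastICA(n_components=L2, whiten=False, algorithm="parallel",
                      fun=_FUN_ALIASES[self.nonlinearity], max_iter=self.max_iter,
                      tol=self.tol, random_state=self.random_state)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            ica.fit(white.T)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            raise ICAConvergenceError(self.max_iter, self.tol)
        W = ica.components_  # (L2, L2), orthogonal on whitened data
        sources = W @ white  # (L2, V)

        # fix sign: largest-|value| voxel of each group map positive
        flips = np.ones(L2)
        for k in range(L2):
            j = np.argmax(np.abs(sources[k]))
            if sources[k, j] < 0:
                flips[k] = -1.0
        sources *= flips[:, None]
        W = flips[:, None] * W

        M = len(mats)
        subject_maps = np.empty((M, L2, n_vox))
        for i, red in enumerate(reductions):
            block = group_transform[:, i * L1:(i + 1) * L1]  # (L2, L1)
            c_i = c[i * L1:(i + 1) * L1]
            subject_maps[i] = M * (W @ (block @ (red.reduced - c_i[:, None])))

        self.components_ = sources
        self.subject_maps_ = subject_maps
        self.unmixing_ = W
        self.mixing_ = W.T  # W is orthogonal on the whitened space
        self.n_iter_ = int(ica.n_iter_)
        self.subject_reductions_ = reductions
        self.n_subjects_ = M
        return self

    def fit_scans(self, scans, mask: Mask) -> "GroupICA":
        """Mask + PSCS-tc-normalize scans, then :meth:`fit`."""
        self.mask_ = mask
        return self.fit([scan_to_matrix(s, mask) for s in scans])

    # -- derived outputs --------------------------------------------------

    def group_map_volume(self, k: int, mask: Mask) -> np.ndarray:
        """3D group component map, zero-filled outside the mask."""
        check_is_fitted(self, "components_")
        return unflatten_vector(self.components_[k], mask)

    def subject_map_volume(self, i: int, k: int, mask: Mask) -> np.ndarray:
        check_is_fitted(self, "subject_maps_")
        return unflatten_vector(self.subject_maps_[i, k], mask)

    def identify_dmn(self, template: np.ndarray, mask: Mask,
                     floor: float = 0.2) -> tuple[int, float]:
        """Locate the default-mode-like component by template correlation.

        Returns ``(component index, correlation)`` for the component whose
        spatial correlation with the template has the largest magnitude;
        raises :class:`NoDMNError` if every |correlation| is below
        ``floor``.  The match is sign-invariant.
        """
        check_is_fitted(self, "components_")
        tvec = flatten_volume(np.asarray(template, dtype=float), mask)
        corrs = np.array([_pearson(self.components_[k], tvec)
                          for k in range(self.components_.shape[0])])
        best = int(np.argmax(np.abs(corrs)))
        if np.abs(corrs[best]) < floor:
            raise NoDMNError(
                f"max |template correlation| {np.abs(corrs[best]):.3f} < floor {floor}")
        self.dmn_index_ = best
        self.dmn_correlation_ = float(corrs[best])
        return best, float(corrs[best])


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(a @ b / denom)


def group_ica_decompose(subject_matrices, config: ICAConfig) -> GroupICA:
    """Functional wrapper: fit a :class:`GroupICA` from a config."""
    return GroupICA(config.n_subject_pcs, config.n_group_pcs, config.nonlinearity,
                    config.max_iter, config.tol, config.seed).fit(subject_matrices)


def fc_subject_volumes(model: GroupICA, mask: Mask,
                       components: list[int] | None = None) -> np.ndarray:
    """Per-participant 3D FC weighting maps, zero-filled outside the mask.

    Returns an array of shape (n_subjects, n_components, nx, ny, nz).
    """
    check_is_fitted(model, "subject_maps_")
    comps = components if components is not None else list(range(model.subject_maps_.shape[1]))
    M = model.subject_maps_.shape[0]
    out = np.empty((M, len(comps)) + mask.grid_dims)
    for i in range(M):
        for j, k in enumerate(comps):
            out[i, j] = unflatten_vector(model.subject_maps_[i, k], mask)
    return out


def fc_features(model: GroupICA, mask: Mask, mode: str = "fc_1_20",
                swa_r: int = 1, reduced_mask: Mask | None = None) -> np.ndarray:
    """FC feature matrix: SWA + masking + flattening of subject maps.

    ``mode`` is ``"fc_dmn"`` (the identified DMN map only; requires
    :meth:`GroupICA.identify_dmn` to have been called) or ``"fc_1_20"``
    (all components, concatenated in component order).  With ``swa_r > 1``
    the maps are window-averaged and the reduced-resolution mask is used
    (derived by majority vote if not supplied).
    """
    if mode == "fc_dmn":
        if not hasattr(model, "dmn_index_"):
            raise RuntimeError("identify_dmn must be called before FC_DMN extraction")
        comps = [model.dmn_index_]
    elif mode == "fc_1_20":
        comps = None
    else:
        raise ValueError(f"unknown FC feature mode {mode!r}")
    vols = fc_subject_volumes(model, mask, comps)
    if swa_r > 1:
        if reduced_mask is None:
            reduced_mask = downsample_mask(mask, swa_r)
        flat_mask = reduced_mask
    else:
        flat_mask = mask
    M, K = vols.shape[:2]
    rows = []
    for i in range(M):
        parts = []
        for k in range(K):
            v = swa_array(vols[i, k], swa_r) if swa_r > 1 else vols[i, k]
            parts.append(flatten_volume(v, flat_mask))
        rows.append(np.concatenate(parts))
    return np.asarray(rows)


def gica3_backreconstruct(model: GroupICA) -> np.ndarray:
    """Subject spatial maps (n_subjects, n_components, n_voxels).

    The maps are computed during :meth:`GroupICA.fit`; their
    across-subject mean equals the group maps (the GICA3 defining
    property).
    """
    check_is_fitted(model, "subject_maps_")
    return model.subject_maps_
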