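"""Synthetic multi-site cohorts and resting-state scans.

The generators emulate the two inputs the analysis pipeline consumes:

* participant tables with multi-site group structure in age, gender,
  handedness, medication and a site-dependent IQ battery, mirroring the
  published per-group marginal summaries of the 668-participant training
  cohort and the 171-participant holdout cohort; and
* 4D scans built as linear mixtures of spatial source maps (one of them a
  default-mode-like network whose weighting can differ between patients
  and controls in a specified voxel block) plus Gaussian noise and a
  site-specific intensity gain.

Fields are drawn independently given group and site: the published
summaries are marginal, so no joint structure (e.g. age x IQ correlation)
is imposed.  A two-Gaussian group simulation illustrating the gap between
group-level significance and individual-level separability is also
provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .types import Scan4D

DIAGNOSES = ("control", "adhd-c", "adhd-i")
SITES = ("PekingU", "BrownU", "KKI", "NeuroIMAGE", "NYU", "OHSU", "UPitt", "WashU")
IQ_FIELDS = ("verbal_iq", "performance_iq", "full2_iq", "full4_iq")

#: Fixed participant-table header, in writing order.
TABLE_COLUMNS = (
    "participant_id",
    "site",
    "diagnosis",
    "age",
    "gender",
    "handedness",
    "medication",
    "iq_measure",
    "verbal_iq",
    "performance_iq",
    "full2_iq",
    "full4_iq",
)


class CohortSpecError(ValueError):
    """Raised for invalid cohort specifications."""


def _check_prob(p: float, name: str) -> None:
    if not (0.0 <= p <= 1.0):
        raise CohortSpecError(f"{name} = {p} outside [0, 1]")


@dataclass
class CohortSpec:
    """Distributional recipe for a multi-site participant table.

    All per-group dictionaries are keyed by diagnosis (``control``,
    ``adhd-c``, ``adhd-i``).  ``iq_params`` values of ``None`` mean the
    score is never provided for that group; ``missingness`` adds
    per-site, per-field missing probabilities on top.
    """

    n_per_group: Mapping[str, int]
    site_proportions: Mapping[str, Mapping[str, float]]
    age_params: Mapping[str, tuple[float, float]]
    gender_props: Mapping[str, float]  # fraction female
    handedness_props: Mapping[str, Mapping[str, float]]  # left/right/ambidextrous/missing
    iq_params: Mapping[str, Mapping[str, tuple[float, float] | None]]
    medication_props: Mapping[str, Mapping[str, float]]  # none/medicated/missing
    missingness: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    edinburgh_sites: frozenset[str] = frozenset({"NeuroIMAGE"})
    iq_measure_by_site: Mapping[str, str] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            if n < 0:
                raise CohortSpecError(f"negative count for group {g}")
        for g, props in self.site_proportions.items():
            total = float(sum(props.values()))
            if abs(total - 1.0) > 1e-9:
                raise CohortSpecError(f"site proportions for {g} sum to {total}, not 1")
            for s, p in props.items():
                _check_prob(p, f"site_proportions[{g}][{s}]")
        for g, p in self.gender_props.items():
            _check_prob(p, f"gender_props[{g}]")
        for mapping, name in ((self.handedness_props, "handedness"), (self.medication_props, "medication")):
            for g, props in mapping.items():
                for k, p in props.items():
                    _check_prob(p, f"{name}_props[{g}][{k}]")
        for s, fields_ in self.missingness.items():
            for f, p in fields_.items():
                _check_prob(p, f"missingness[{s}][{f}]")

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(self.n_per_group)


def _normalize(d: Mapping[str, float]) -> dict[str, float]:
    total = float(sum(d.values()))
    return {k: v / total for k, v in d.items()}


def training_cohort_spec(seed: int = 0) -> CohortSpec:
    """Cohort spec matching the published training-cohort marginals.

    Group sizes 429/141/98 (majority fraction 429/668 = 64.2%), per-group
    age, gender, handedness, medication and IQ summaries, per-group site
    proportions, and the structural missingness of the IQ battery (no IQ
    at NeuroIMAGE; verbal/performance IQ only at PekingU, KKI, NYU, UPitt;
    Full-2 IQ only at UPitt and only for controls).
    """
    site_props = {
        "control": {"PekingU": 27.0, "KKI": 13.5, "NeuroIMAGE": 5.1, "NYU": 21.2,
                    "OHSU": 8.4, "UPitt": 15.4, "WashU": 9.3},
        "adhd-c": {"PekingU": 20.6, "KKI": 10.6, "NeuroIMAGE": 11.3, "NYU": 45.4,
                   "OHSU": 12.1},
        "adhd-i": {"PekingU": 50.0, "KKI": 5.1, "NYU": 33.7, "OHSU": 11.2},
    }
    iq_measures = {"PekingU": "WISCC-R", "KKI": "WISC-IV", "NYU": "WASI",
                   "OHSU": "WASI", "UPitt": "WASI", "WashU": "WASI-2sub",
                   "NeuroIMAGE": "none", "BrownU": "none"}
    # Sites that never provide a given IQ score.
    missing = {s: {} for s in SITES}
    for s in ("NeuroIMAGE", "BrownU"):
        for f in IQ_FIELDS:
            missing[s][f] = 1.0
    for s in ("OHSU", "WashU"):
        missing[s]["verbal_iq"] = 1.0
        missing[s]["performance_iq"] = 1.0
    for s in SITES:
        if s != "UPitt":
            missing[s].setdefault("full2_iq", 1.0)
    return CohortSpec(
        n_per_group={"control": 429, "adhd-c": 141, "adhd-i": 98},
        site_proportions={g: _normalize(p) for g, p in site_props.items()},
        age_params={"control": (12.4, 3.3), "adhd-c": (11.4, 3.1), "adhd-i": (12.1, 2.5)},
        gender_props={"control": 0.476, "adhd-c": 0.170, "adhd-i": 0.265},
        handedness_props={
            "control": _normalize({"left": 2.6, "right": 96.3, "ambidextrous": 0.2, "missing": 0.9}),
            "adhd-c": _normalize({"left": 3.5, "right": 95.0, "ambidextrous": 0.0, "missing": 1.4}),
            "adhd-i": _normalize({"left": 2.0, "right": 98.0, "ambidextrous": 0.0, "missing": 0.0}),
        },
        iq_params={
            "control": {"verbal_iq": (114.9, 13.6), "performance_iq": (110.7, 13.5),
                        "full2_iq": (112.2, 8.3), "full4_iq": (114.3, 13.3)},
            "adhd-c": {"verbal_iq": (110.2, 16.1), "performance_iq": (103.3, 14.0),
                       "full2_iq": None, "full4_iq": (107.5, 13.9)},
            "adhd-i": {"verbal_iq": (106.9, 15.2), "performance_iq": (100.6, 15.3),
                       "full2_iq": None, "full4_iq": (104.2, 14.1)},
        },
        medication_props={
            "control": _normalize({"none": 67.4, "medicated": 2.1, "missing": 30.5}),
            "adhd-c": _normalize({"none": 34.0, "medicated": 26.2, "missing": 39.7}),
            "adhd-i": _normalize({"none": 60.2, "medicated": 22.5, "missing": 17.4}),
        },
        missingness=missing,
        iq_measure_by_site=iq_measures,
        seed=seed,
    )


def holdout_cohort_spec(seed: int = 0) -> CohortSpec:
    """Cohort spec matching the published holdout-cohort marginals (94/51/26)."""
    base = training_cohort_spec(seed)
    site_props = {
        "control": {"PekingU": 28.7, "KKI": 8.5, "NeuroIMAGE": 14.9, "NYU": 12.8,
                    "OHSU": 29.8, "UPitt": 5.3},
        "adhd-c": {"PekingU": 19.6, "KKI": 5.9, "NeuroIMAGE": 21.6, "NYU": 43.1,
                   "OHSU": 9.8},
        "adhd-i": {"PekingU": 53.8, "NYU": 26.9, "OHSU": 3.8, "UPitt": 15.4},
    }
    return CohortSpec(
        n_per_group={"control": 94, "adhd-c": 51, "adhd-i": 26},
        site_proportions={g: _normalize(p) for g, p in site_props.items()},
        age_params={"control": (12.0, 4.2), "adhd-c": (11.5, 3.5), "adhd-i": (12.1, 2.6)},
        gender_props={"control": 0.511, "adhd-c": 0.157, "adhd-i": 0.346},
        handedness_props={
            "control": _normalize({"left": 5.3, "right": 93.6, "ambidextrous": 0.0, "missing": 1.1}),
            "adhd-c": _normalize({"left": 5.9, "right": 92.2, "ambidextrous": 0.0, "missing": 2.0}),
            "adhd-i": _normalize({"left": 0.0, "right": 100.0, "ambidextrous": 0.0, "missing": 0.0}),
        },
        iq_params={
            "control": {"verbal_iq": (119.2, 12.8), "performance_iq": (108.5, 13.6),
                        "full2_iq": (100.6, 14.4), "full4_iq": (114.6, 12.3)},
            "adhd-c": {"verbal_iq": (109.2, 13.6), "performance_iq": (101.1, 17.0),
                       "full2_iq": (93.3, 16.5), "full4_iq": (107.0, 14.8)},
            "adhd-i": {"verbal_iq": (108.6, 13.1), "performance_iq": (101.5, 11.2),
                       "full2_iq": None, "full4_iq": (106.1, 11.2)},
        },
        medication_props={
            "control": _normalize({"none": 34.0, "medicated": 0.0, "missing": 63.3}),
            "adhd-c": _normalize({"none": 3.9, "medicated": 15.7, "missing": 80.4}),
            "adhd-i": _normalize({"none": 46.2, "medicated": 23.1, "missing": 30.8}),
        },
        missingness=base.missingness,
        iq_measure_by_site=base.iq_measure_by_site,
        seed=seed,
    )


_HAND_CODES = {"left": 0.0, "right": 1.0, "ambidextrous": 2.0, "missing": np.nan}
_MED_CODES = {"none": 0.0, "medicated": 1.0, "missing": np.nan}


def generate_participants(spec: CohortSpec) -> pd.DataFrame:
    """Draw a participant table from a :class:`CohortSpec`.

    One row per participant; missing fields are encoded as NaN (the
    explicit missing marker throughout the package).  Sites flagged in
    ``spec.edinburgh_sites`` emit continuous Edinburgh handedness scores
    uniform on [-100, 100]; all other sites use the 0/1/2 categorical
    code (left/right/ambidextrous).
    """
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    pid = 0
    for group in spec.groups:
        n = int(spec.n_per_group[group])
        if n == 0:
            continue
        sites = list(spec.site_proportions[group])
        site_p = np.array([spec.site_proportions[group][s] for s in sites])
        drawn_sites = rng.choice(sites, size=n, p=site_p)
        mean_age, sd_age = spec.age_params[group]
        ages = rng.normal(mean_age, sd_age, size=n)
        female = rng.random(n) < spec.gender_props[group]
        hand_cats = list(spec.handedness_props[group])
        hand_p = np.array([spec.handedness_props[group][c] for c in hand_cats])
        med_cats = list(spec.medication_props[group])
        med_p = np.array([spec.medication_props[group][c] for c in med_cats])
        for i in range(n):
            site = str(drawn_sites[i])
            if site in spec.edinburgh_sites:
                hand = float(rng.uniform(-100.0, 100.0))
            else:
                hand = _HAND_CODES[str(rng.choice(hand_cats, p=hand_p))]
            med = _MED_CODES[str(rng.choice(med_cats, p=med_p))]
            row = {
                "participant_id": pid,
                "site": site,
                "diagnosis": group,
                "age": float(ages[i]),
                "gender": "F" if female[i] else "M",
                "handedness": hand,
                "medication": med,
                "iq_measure": spec.iq_measure_by_site.get(site, "none"),
            }
            site_missing = spec.missingness.get(site, {})
            for iq in IQ_FIELDS:
                params = spec.iq_params[group].get(iq)
                p_miss = site_missing.get(iq, 0.0)
                if params is None or rng.random() < p_miss:
                    row[iq] = np.nan
                else:
                    row[iq] = float(rng.normal(params[0], params[1]))
            rows.append(row)
            pid += 1
    table = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    return table


def write_participants(table: pd.DataFrame, path) -> None:
    """Write a participant table as CSV with the fixed documented header."""
    table.to_csv(path, index=False, columns=list(TABLE_COLUMNS))


def read_participants(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# 4D scan generation: linear mixing of spatial sources
# ---------------------------------------------------------------------------


@dataclass
class ScanGenSpec:
    """Recipe for linear-mixture 4D scans.

    A scan is ``site_gain * (baseline + sum_k timecourse_k (x)
    weightfield_k * map_k + noise)`` with ``round(duration_s / tr_s)``
    time points.  ``baseline`` is a constant tissue intensity (real BOLD
    signal rides on a large baseline; set it nonzero when the scans will
    be percent-signal-change normalized, which divides by the temporal
    mean).  The weighting of the default-mode-like source can carry an
    additive group difference of size ``dmn_effect`` inside a designated
    voxel block.
    """

    grid_dims: tuple[int, int, int] = (15, 15, 12)
    voxel_mm: float = 3.0
    duration_s: float = 200.0
    tr_s: float = 2.0
    n_sources: int = 4
    dmn_effect: float = 0.0
    noise_sd: float = 1.0
    site_gain: float = 1.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if len(self.grid_dims) != 3 or min(self.grid_dims) < 1:
            raise ValueError("grid_dims must be 3 positive integers")
        if self.n_sources < 2:
            raise ValueError("n_sources must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.duration_s <= 0 or self.tr_s <= 0:
            raise ValueError("duration_s and tr_s must be positive")

    @property
    def n_timepoints(self) -> int:
        return int(round(self.duration_s / self.tr_s))


@dataclass
class GroundTruth:
    """Generator ground truth used as a parameter-recovery oracle."""

    source_maps: np.ndarray  # (n_sources, nx, ny, nz)
    subject_weights: np.ndarray  # (n_subjects, n_sources)
    dmn_index: int
    effect_mask: np.ndarray  # boolean (nx, ny, nz)

    def __post_init__(self) -> None:
        if not (0 <= self.dmn_index < self.source_maps.shape[0]):
            raise ValueError("dmn_index out of range")
        if self.effect_mask.shape != self.source_maps.shape[1:]:
            raise ValueError("effect_mask grid does not match source maps")


def make_ground_truth(spec: ScanGenSpec, n_subjects: int, seed: int = 0,
                      smooth_sigma: float = 0.6) -> GroundTruth:
    """Build sparse, spatially disjoint source maps plus subject weights.

    Each source occupies two rectangular blocks inside its own slab of the
    x-axis (sparse supports make the sources strongly non-Gaussian, which
    spatial ICA needs).  Source 0 is the default-mode-like network; its
    first block is the designated effect region.
    """
    rng = np.random.default_rng(seed)
    nx, ny, nz = spec.grid_dims
    K = spec.n_sources
    maps = np.zeros((K, nx, ny, nz))
    effect_mask = np.zeros(spec.grid_dims, dtype=bool)
    slab = max(nx // K, 1)
    for k in range(K):
        x0 = k * slab
        x1 = nx if k == K - 1 else (k + 1) * slab
        for b in range(2):
            bx = max((x1 - x0) // 2, 1)
            by, bz = max(ny // 3, 1), max(nz // 3, 1)
            ox = x0 + int(rng.integers(0, max(x1 - x0 - bx, 1)))
            oy = int(rng.integers(0, max(ny - by, 1)))
            oz = int(rng.integers(0, max(nz - bz, 1)))
            maps[k, ox:ox + bx, oy:oy + by, oz:oz + bz] = 1.0
            if k == 0 and b == 0:
                effect_mask[ox:ox + bx, oy:oy + by, oz:oz + bz] = True
    if smooth_sigma > 0:
        for k in range(K):
            maps[k] = gaussian_filter(maps[k], smooth_sigma)
    weights = rng.uniform(0.8, 1.2, size=(n_subjects, K))
    return GroundTruth(maps, weights, dmn_index=0, effect_mask=effect_mask)


def _source_timecourses(n_sources: int, n_t: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth, zero-mean, unit-variance random timecourses (sources x time)."""
    tc = rng.standard_normal((n_sources, n_t))
    tc = gaussian_filter1d(tc, sigma=2.0, axis=1)
    tc -= tc.mean(axis=1, keepdims=True)
    sd = tc.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return tc / sd


def generate_scan(subject_weights: Sequence[float], spec: ScanGenSpec,
                  truth: GroundTruth, seed: int, effect_scale: float = 0.0) -> Scan4D:
    """Generate one subject's 4D scan by linear mixing.

    ``effect_scale`` is the additive offset applied to the default-mode
    source's weighting inside ``truth.effect_mask`` (pass
    ``spec.dmn_effect`` for patients, 0 for controls).
    """
    w = np.asarray(subject_weights, dtype=float)
    if w.shape != (spec.n_sources,):
        raise ValueError(f"expected {spec.n_sources} weights, got shape {w.shape}")
    if truth.source_maps.shape[1:] != tuple(spec.grid_dims):
        raise ValueError("ground-truth grid does not match spec grid")
    rng = np.random.default_rng(seed)
    n_t = spec.n_timepoints
    tcs = _source_timecourses(spec.n_sources, n_t, rng)
    data = np.zeros(tuple(spec.grid_dims) + (n_t,))
    for k in range(spec.n_sources):
        weight_field = np.full(spec.grid_dims, w[k])
        if k == truth.dmn_index and effect_scale != 0.0:
            weight_field = weight_field + effect_scale * truth.effect_mask
        data += (weight_field * truth.source_maps[k])[..., None] * tcs[k]
    if spec.noise_sd > 0:
        data += spec.noise_sd * rng.standard_normal(data.shape)
    data += spec.baseline
    data *= spec.site_gain
    return Scan4D(data, voxel_mm=spec.voxel_mm, tr_s=spec.tr_s)


def simulate_cohort_scans(n_controls: int, n_patients: int, spec: ScanGenSpec,
                          seed: int = 0) -> tuple[list[Scan4D], np.ndarray, GroundTruth]:
    """Generate a labelled two-group cohort of scans plus its ground truth.

    Patients receive the ``spec.dmn_effect`` additive weighting offset on
    the default-mode source inside the effect block; controls do not.
    Returns ``(scans, labels, truth)`` with labels in {"control", "adhd"}.
    """
    n = n_controls + n_patients
    truth = make_ground_truth(spec, n, seed=seed)
    labels = np.array(["control"] * n_controls + ["adhd"] * n_patients)
    scans = []
    for i in range(n):
        eff = spec.dmn_effect if labels[i] == "adhd" else 0.0
        scans.append(generate_scan(truth.subject_weights[i], spec, truth,
                                   seed=seed + 1000 + i, effect_scale=eff))
    return scans, labels, truth


# ---------------------------------------------------------------------------
# Two-Gaussian group simulation
# ---------------------------------------------------------------------------


@dataclass
class TwoGaussianResult:
    """Samples and summary statistics of the two-group simulation."""

    group_a: np.ndarray
    group_b: np.ndarray
    t_stat: float
    accuracy: float  # fraction in [0, 1]


def simulate_two_gaussian_groups(n_per_group: int, delta: float,
                                 seed: int = 0) -> TwoGaussianResult:
    """Simulate N(0,1) vs N(delta,1) groups and score a midpoint classifier.

    Each sample is assigned to the group whose estimated mean is nearer
    (equivalently, thresholded at the midpoint of the two sample means).
    The expected accuracy is Phi(delta/2): a mean separation that is
    highly significant at the group level (large two-sample t) can still
    give near-chance individual-level separation.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(n_per_group)
    b = rng.standard_normal(n_per_group) + delta
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt(((n_per_group - 1) * va + (n_per_group - 1) * vb)
                     / (2 * n_per_group - 2))
    t_stat = (mb - ma) / (pooled * np.sqrt(2.0 / n_per_group))
    # nearest estimated group mean
    correct_a = np.abs(a - ma) <= np.abs(a - mb)
    correct_b = np.abs(b - mb) < np.abs(b - ma)
    accuracy = (correct_a.sum() + correct_b.sum()) / (2.0 * n_per_group)
    return TwoGaussianResult(a, b, float(t_stat), float(accuracy))
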