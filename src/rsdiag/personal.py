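"""Personal-characteristic feature matrices (PCs1 / PCs2).

Two fixed feature selections over the participant table:

* **PCs1** — 7 features: site, gender, age, handedness, verbal IQ,
  performance IQ, full-4 IQ.  Handedness is passed through unmodified and
  treated as continuous.
* **PCs2** — 9 features: site, gender, age, handedness, IQ-measure
  indicator, verbal IQ, performance IQ, full-2 IQ, full-4 IQ.  Continuous
  Edinburgh handedness scores (from sites flagged as Edinburgh sites) are
  recoded to the 0/1 right/left categorical scheme, and handedness is
  treated as categorical.

Preprocessing is mean imputation for continuous features, mode imputation
for categorical features, explicit one-hot encoding of categoricals, and
min-max scaling of every resulting column to [0, 1].  All statistics are
fitted on the training rows only (fit/transform split), so the
preprocessor is leakage-safe inside cross-validation.
"""

from __future__ import annotations

import json
import numbers
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

PCS1_FIELDS = ("site", "gender", "age", "handedness",
               "verbal_iq", "performance_iq", "full4_iq")
PCS2_FIELDS = ("site", "gender", "age", "handedness", "iq_measure",
               "verbal_iq", "performance_iq", "full2_iq", "full4_iq")

_CONTINUOUS = {"age", "verbal_iq", "performance_iq", "full2_iq", "full4_iq"}


@dataclass
class FeatureSelectionSpec:
    """Named personal-characteristic selection."""

    name: str
    fields_included: tuple[str, ...]
    handedness_mode: str  # "as-is" | "recode-edinburgh"

    def __post_init__(self) -> None:
        if self.name == "PCs1" and len(self.fields_included) != 7:
            raise ValueError("PCs1 must list exactly 7 fields")
        if self.name == "PCs2" and len(self.fields_included) != 9:
            raise ValueError("PCs2 must list exactly 9 fields")
        if self.handedness_mode not in ("as-is", "recode-edinburgh"):
            raise ValueError(f"unknown handedness_mode {self.handedness_mode!r}")

    @property
    def categorical_fields(self) -> set[str]:
        cats = {"site", "gender", "iq_measure"} & set(self.fields_included)
        if self.handedness_mode == "recode-edinburgh":
            cats.add("handedness")
        return cats


def selection_spec(name: str) -> FeatureSelectionSpec:
    if name == "PCs1":
        return FeatureSelectionSpec("PCs1", PCS1_FIELDS, "as-is")
    if name == "PCs2":
        return FeatureSelectionSpec("PCs2", PCS2_FIELDS, "recode-edinburgh")
    raise ValueError(f"unknown selection {name!r}")


def recode_handedness(score: float) -> int:
    """Collapse a continuous Edinburgh score to 0 (left) / 1 (right).

    Positive scores map to 1, negative to 0.  An exact 0 maps to 1 with a
    warning: the published rule covers only strictly positive/negative
    scores, and right-handed is the overwhelmingly common category.
    """
    if not isinstance(score, numbers.Real) or isinstance(score, bool):
        raise TypeError(f"handedness score must be numeric, got {type(score).__name__}")
    if np.isnan(score):
        raise ValueError("cannot recode a missing handedness score")
    if score == 0:
        warnings.warn("Edinburgh handedness score of exactly 0 mapped to 1 (right-handed)")
        return 1
    return 1 if score > 0 else 0


def select_features(table: pd.DataFrame, spec: FeatureSelectionSpec,
                    edinburgh_sites: tuple[str, ...] = ("NeuroIMAGE",)) -> pd.DataFrame:
    """Project the participant table onto the selection's fields, in order.

    Under ``recode-edinburgh``, handedness values of rows from the listed
    Edinburgh sites are collapsed to 0/1; categorical 0/1/2 codes from
    all other sites pass through unchanged.
    """
    missing = [f for f in spec.fields_included if f not in table.columns]
    if missing:
        raise KeyError(f"participant table lacks columns {missing}")
    out = table.loc[:, list(spec.fields_included)].copy()
    if spec.handedness_mode == "recode-edinburgh" and len(out):
        is_edinburgh = table["site"].isin(edinburgh_sites).to_numpy()
        hand = out["handedness"].to_numpy(dtype=float, copy=True)
        for i in np.flatnonzero(is_edinburgh):
            if not np.isnan(hand[i]):
                hand[i] = recode_handedness(hand[i])
        out["handedness"] = hand
    return out


def impute(matrix: pd.DataFrame, stats: dict) -> pd.DataFrame:
    """Fill missing entries using precomputed per-feature statistics.

    ``stats`` maps feature name to the imputation value (a mean for
    continuous features, a mode for categorical ones).  Non-missing
    entries are never modified.
    """
    out = matrix.copy()
    for col in out.columns:
        if col not in stats:
            raise KeyError(f"no imputation statistic for feature {col!r}")
        out[col] = out[col].fillna(stats[col])
    return out


class PersonalCharacteristicsPreprocessor(BaseEstimator, TransformerMixin):
    """Participant table -> numeric feature matrix in [0, 1].

    Fit learns, from the training rows only: imputation statistics
    (mean/mode), the category inventory for one-hot encoding, and per
    column min-max scaling bounds.  Transform applies them to any rows.
    Constant columns scale to 0.  Categories unseen at fit time encode
    as all-zero indicator blocks.

    Parameters
    ----------
    selection : str
        "PCs1" or "PCs2".
    edinburgh_sites : tuple of str
        Sites whose handedness scores are continuous Edinburgh values.
    """

    def __init__(self, selection: str = "PCs2",
                 edinburgh_sites: tuple[str, ...] = ("NeuroIMAGE",)):
        self.selection = selection
        self.edinburgh_sites = edinburgh_sites

    def fit(self, table: pd.DataFrame, y=None) -> "PersonalCharacteristicsPreprocessor":
        spec = selection_spec(self.selection)
        raw = select_features(table, spec, self.edinburgh_sites)
        cats = spec.categorical_fields
        self.spec_ = spec
        self.imputation_stats_ = {}
        self.categories_ = {}
        for col in raw.columns:
            series = raw[col].dropna()
            if col in cats:
                if len(series):
                    mode = series.mode().sort_values().iloc[0]
                else:
                    mode = 0
                self.imputation_stats_[col] = mode
            else:
                self.imputation_stats_[col] = float(series.mean()) if len(series) else 0.0
        complete = impute(raw, self.imputation_stats_)
        for col in cats:
            self.categories_[col] = sorted(complete[col].unique(), key=str)
        encoded = self._encode(complete)
        self.feature_names_out_ = list(encoded.columns)
        lo = encoded.min(axis=0)
        hi = encoded.max(axis=0)
        if encoded.empty:
            lo = pd.Series(0.0, index=encoded.columns)
            hi = pd.Series(0.0, index=encoded.columns)
        self.scale_bounds_ = {c: (float(lo[c]), float(hi[c])) for c in encoded.columns}
        return self

    def _encode(self, complete: pd.DataFrame) -> pd.DataFrame:
        cols = {}
        for col in complete.columns:
            if col in self.spec_.categorical_fields:
                levels = self.categories_.get(col, sorted(complete[col].unique(), key=str))
                for level in levels:
                    cols[f"{col}={level}"] = (complete[col] == level).astype(float)
            else:
                cols[col] = complete[col].astype(float)
        return pd.DataFrame(cols, index=complete.index)

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "scale_bounds_")
        raw = select_features(table, self.spec_, self.edinburgh_sites)
        complete = impute(raw, self.imputation_stats_)
        encoded = self._encode(complete)
        encoded = encoded.reindex(columns=self.feature_names_out_, fill_value=0.0)
        for c in encoded.columns:
            lo, hi = self.scale_bounds_[c]
            if hi > lo:
                encoded[c] = (encoded[c] - lo) / (hi - lo)
            else:
                encoded[c] = 0.0
        return encoded

    def inverse_scale(self, matrix: pd.DataFrame) -> pd.DataFrame:
        """Undo min-max scaling using the recorded bounds (continuous columns)."""
        check_is_fitted(self, "scale_bounds_")
        out = matrix.copy()
        for c in out.columns:
            lo, hi = self.scale_bounds_[c]
            if hi > lo:
                out[c] = out[c] * (hi - lo) + lo
            else:
                out[c] = lo
        return out

    def stats_dict(self) -> dict:
        """Imputation statistics and scaling bounds, JSON-serializable."""
        check_is_fitted(self, "scale_bounds_")
        return {
            "selection": self.selection,
            "imputation_stats": {k: (v if isinstance(v, str) else float(v))
                                 for k, v in self.imputation_stats_.items()},
            "categories": {k: [str(x) for x in v] for k, v in self.categories_.items()},
            "scale_bounds": {k: list(v) for k, v in self.scale_bounds_.items()},
        }

    def save_stats(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.stats_dict(), fh, indent=2)
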