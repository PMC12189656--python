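"""Rule-based semiquantitative grading of PVR morphology.

Reproduces the four-class visual grading used in vascular laboratories as a
deterministic decision cascade on extracted features:

1. no visible pulsation -> ``non_pulsatile`` (corresponds to CLTI);
2. dicrotic notch present, flat/scooped interbeat interval present and a
   steep upstroke -> ``normal``;
3. prolonged upstroke (upstroke/downslope ratio or upstroke ratio above
   threshold) together with a flattened amplitude -> ``severely_abnormal``;
4. otherwise -> ``mildly_abnormal`` (notch and flat interval lost, upstroke
   still steep).

The numeric thresholds operationalise the qualitative reading criteria; they
are exposed as classifier parameters with fixed defaults.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from pvrkit.errors import ValidationError
from pvrkit.fiducials import PVRFeatures

__all__ = ["MorphologyGrade", "MorphologyClassifier", "classify_morphology", "GRADE_ORDER"]

#: Severity ordering, most severe first.
GRADE_ORDER = ["non_pulsatile", "severely_abnormal", "mildly_abnormal", "normal"]

DEFAULT_UPDOWN_RATIO_THRESHOLD = 0.75
DEFAULT_USR_THRESHOLD = 0.40
DEFAULT_MSA_FLAT_THRESHOLD = 0.35


@dataclass(frozen=True)
class MorphologyGrade:
    """A grade plus the identifiers of the cascade rules that fired."""

    value: str
    rationale: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.value not in GRADE_ORDER:
            raise ValidationError(f"unknown grade {self.value!r}")
        if not self.rationale:
            raise ValidationError("rationale must be non-empty")

    @property
    def severity_rank(self) -> int:
        """0 = normal ... 3 = non_pulsatile."""
        return len(GRADE_ORDER) - 1 - GRADE_ORDER.index(self.value)


class MorphologyClassifier(ClassifierMixin, BaseEstimator):
    """sklearn-style deterministic classifier over PVR feature vectors.

    ``predict`` accepts a sequence of :class:`PVRFeatures` (or a DataFrame in
    the feature-table schema of :class:`~pvrkit.fiducials.PVRFeatureExtractor`)
    and returns the grade labels; ``explain`` returns full
    :class:`MorphologyGrade` objects with rule rationales. Rule-based, so
    ``fit`` only validates thresholds and sets ``classes_``.
    """

    def __init__(
        self,
        updown_ratio_threshold: float = DEFAULT_UPDOWN_RATIO_THRESHOLD,
        usr_threshold: float = DEFAULT_USR_THRESHOLD,
        msa_flat_threshold: float = DEFAULT_MSA_FLAT_THRESHOLD,
    ) -> None:
        self.updown_ratio_threshold = updown_ratio_threshold
        self.usr_threshold = usr_threshold
        self.msa_flat_threshold = msa_flat_threshold

    def fit(self, X=None, y=None) -> "MorphologyClassifier":
        for name in ("updown_ratio_threshold", "usr_threshold", "msa_flat_threshold"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        self.classes_ = np.array(sorted(GRADE_ORDER))
        return self

    def _grade_one(self, f: PVRFeatures) -> MorphologyGrade:
        if not f.pulsatile:
            return MorphologyGrade("non_pulsatile", ("no_visible_pulsation",))
        steep = (
            f.upstroke_downslope_ratio is not None
            and f.upstroke_downslope_ratio < self.updown_ratio_threshold
        )
        if f.notch_present and f.flat_interval_present and steep:
            return MorphologyGrade(
                "normal", ("dicrotic_notch_present", "flat_interval_present", "sharp_upstroke")
            )
        prolonged = (not steep) or (f.usr is not None and f.usr >= self.usr_threshold)
        flattened = f.msa < self.msa_flat_threshold
        if prolonged and flattened:
            return MorphologyGrade(
                "severely_abnormal", ("prolonged_upstroke", "flattened_amplitude")
            )
        return MorphologyGrade("mildly_abnormal", ("notch_or_flat_interval_lost",))

    def explain(self, X) -> list[MorphologyGrade]:
        self.fit()
        return [self._grade_one(f) for f in _as_features(X)]

    def predict(self, X) -> np.ndarray:
        return np.array([g.value for g in self.explain(X)])


def _as_features(X) -> list[PVRFeatures]:
    import pandas as pd

    if isinstance(X, pd.DataFrame):
        out = []
        for _, row in X.iterrows():
            pulsatile = bool(row["pulsatile"])
            out.append(
                PVRFeatures(
                    pulsatile=pulsatile,
                    msa=float(row["msa_mmhg"]) if pulsatile else 0.0,
                    ust=float(row["ust_ms"]) if pulsatile else None,
                    usr=float(row["usr"]) if pulsatile else None,
                    wavelength=float(row["wavelength_ms"]) if pulsatile else None,
                    n_beats_used=int(row.get("n_beats_used", 0)),
                    notch_present=bool(row.get("notch_present", False)),
                    flat_interval_present=bool(row.get("flat_interval_present", False)),
                    upstroke_downslope_ratio=(
                        float(row["upstroke_downslope_ratio"])
                        if pulsatile and row.get("upstroke_downslope_ratio") is not None
                        else None
                    ),
                )
            )
        return out
    return list(X)


def classify_morphology(
    features: PVRFeatures,
    updown_ratio_threshold: float = DEFAULT_UPDOWN_RATIO_THRESHOLD,
    usr_threshold: float = DEFAULT_USR_THRESHOLD,
    msa_flat_threshold: float = DEFAULT_MSA_FLAT_THRESHOLD,
) -> MorphologyGrade:
    """Grade a single feature vector (thin wrapper over MorphologyClassifier)."""
    clf = MorphologyClassifier(
        updown_ratio_threshold=updown_ratio_threshold,
        usr_threshold=usr_threshold,
        msa_flat_threshold=msa_flat_threshold,
    )
    return clf.explain([features])[0]
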