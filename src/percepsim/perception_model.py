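"""Logistic models of expert similarity perception.

A panel of experts votes on whether a molecular pair is "similar"; the
fraction voting yes, pxp, is modeled through its logit

    y = log(pxp / (1 - pxp))

as a linear function of calculated similarity features: a single
feature t_i (either the 2D fingerprint Tanimoto tXT or the 3D
TanimotoCombo tCS),

    y = omega0 + omega1 * t_i

or both features jointly,

    y = omega0 + omega1 * tXT + omega2 * tCS.

The predicted expert fraction is the inverse logit
``p = exp(y) / (1 + exp(y))`` and a pair is labeled *similar* when
p >= 0.5, mirroring the majority-vote ("at least 50% of experts")
labeling convention of the surveys.

Models are fitted as L1-regularized logistic classifiers; a
regularization parameter "lambda = 1" in the survey-calibration
literature corresponds to inverse strength C = 1.0 here, recorded in
the model metadata.  Two fit modes are supported: ``binary_label``
(each pair one observation, label pxp >= 0.5 — the reported workflow)
and ``per_vote`` (each pair's yes/no votes weighted individually).

The bundled default models carry the published coefficients of the
survey-calibrated single- and double-feature equations (e.g. the
single-feature tXT model omega0 = -4.860, omega1 = 8.449).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from sklearn.linear_model import LogisticRegression

from .chem_io import PairFeatureTable
from .exceptions import (
    FeatureError,
    ModelFormatError,
    NoThresholdError,
    PercepsimError,
)

__all__ = [
    "SimilarityFeatures",
    "PerceptionModel",
    "PerceptionPrediction",
    "logit",
    "inverse_logit",
    "predict",
    "fit",
    "threshold_for_probability",
    "load_default_model",
    "DEFAULT_MODELS",
]

MODEL_SCHEMA_VERSION = 1

_FEATURE_DOMAINS = {"tXT": (0.0, 1.0), "tCS": (0.0, 2.0)}

#: names of the bundled, survey-calibrated default models
DEFAULT_MODELS = ("default_tXT", "default_tCS", "default_combo")


@dataclass(frozen=True)
class SimilarityFeatures:
    """Calculated similarity features of one molecular pair."""

    tXT: float | None = None
    tCS: float | None = None

    def __post_init__(self):
        for name, value in (("tXT", self.tXT), ("tCS", self.tCS)):
            if value is None:
                continue
            lo, hi = _FEATURE_DOMAINS[name]
            if not lo <= value <= hi:
                raise FeatureError(f"{name}={value} outside [{lo}, {hi}]")

    def get(self, name: str) -> float:
        value = getattr(self, name)
        if value is None:
            raise FeatureError(f"feature {name} required but missing")
        return value


@dataclass(frozen=True)
class PerceptionPrediction:
    y_hat: float
    p_hat: float
    label: str  # "similar" | "dissimilar"


@dataclass(frozen=True)
class PerceptionModel:
    """Linear-logit model of the expert 'similar' fraction.

    ``feature_spec`` is ("tXT",), ("tCS",) or ("tXT", "tCS");
    ``omega2`` is present exactly when two features are used.
    """

    feature_spec: tuple[str, ...]
    omega0: float
    omega1: float
    omega2: float | None = None
    regularization: dict = field(default_factory=lambda: {"type": "L1", "C": 1.0})
    fit_mode: str = "binary_label"

    def __post_init__(self):
        spec = tuple(self.feature_spec)
        object.__setattr__(self, "feature_spec", spec)
        if spec not in (("tXT",), ("tCS",), ("tXT", "tCS")):
            raise ModelFormatError(f"unsupported feature_spec {spec}")
        if (self.omega2 is not None) != (len(spec) == 2):
            raise ModelFormatError(
                "omega2 must be present exactly for two-feature models"
            )
        for name in ("omega0", "omega1"):
            if getattr(self, name) is None or not math.isfinite(getattr(self, name)):
                raise ModelFormatError(f"{name} must be a finite number")

    @property
    def is_single_feature(self) -> bool:
        return len(self.feature_spec) == 1

    def linear_predictor(self, features: SimilarityFeatures) -> float:
        y = self.omega0 + self.omega1 * features.get(self.feature_spec[0])
        if self.omega2 is not None:
            y += self.omega2 * features.get(self.feature_spec[1])
        return y

    # ---- serialization -------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "schema_version": MODEL_SCHEMA_VERSION,
                "feature_spec": list(self.feature_spec),
                "omega0": self.omega0,
                "omega1": self.omega1,
                "omega2": self.omega2,
                "regularization": self.regularization,
                "fit_mode": self.fit_mode,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PerceptionModel":
        try:
            payload = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ModelFormatError(f"invalid model JSON: {exc}") from exc
        version = payload.get("schema_version")
        if version != MODEL_SCHEMA_VERSION:
            raise ModelFormatError(
                f"unsupported model schema_version {version!r} "
                f"(supported: {MODEL_SCHEMA_VERSION})"
            )
        try:
            return cls(
                feature_spec=tuple(payload["feature_spec"]),
                omega0=payload["omega0"],
                omega1=payload["omega1"],
                omega2=payload.get("omega2"),
                regularization=payload.get("regularization", {}),
                fit_mode=payload.get("fit_mode", "binary_label"),
            )
        except KeyError as exc:
            raise ModelFormatError(f"model file missing field {exc}") from exc


# --------------------------------------------------------------------------
# logit machinery
# --------------------------------------------------------------------------

def logit(p: float, n_total: int | None = None) -> float:
    """log(p / (1-p)).  Boundary values are clamped.

    For an observed expert fraction from ``n_total`` votes, p in {0, 1}
    is clamped to ``1/(2 n_total)`` from the boundary (the usual
    empirical-logit correction); without a vote count a tiny epsilon is
    used.  A warning is emitted either way.
    """
    if not 0.0 <= p <= 1.0:
        raise FeatureError(f"probability {p} outside [0, 1]")
    if p in (0.0, 1.0):
        eps = 1.0 / (2 * n_total) if n_total else 1e-9
        warnings.warn(
            f"logit of boundary probability {p} clamped by {eps}", stacklevel=2
        )
        p = eps if p == 0.0 else 1.0 - eps
    return math.log(p / (1.0 - p))


def inverse_logit(y: float) -> float:
    """exp(y) / (1 + exp(y)), computed stably for large |y|."""
    if y >= 0:
        return 1.0 / (1.0 + math.exp(-y))
    e = math.exp(y)
    return e / (1.0 + e)


# --------------------------------------------------------------------------
# predict / fit / invert
# --------------------------------------------------------------------------

def predict(model: PerceptionModel, features: SimilarityFeatures) -> PerceptionPrediction:
    """Predicted expert fraction and similar/dissimilar label for one pair.

    Ties at p = 0.5 are labeled *similar* (the >= 50% convention).
    """
    y = model.linear_predictor(features)
    p = inverse_logit(y)
    return PerceptionPrediction(
        y_hat=y, p_hat=p, label="similar" if p >= 0.5 else "dissimilar"
    )


def fit(
    table: PairFeatureTable,
    feature_spec: tuple[str, ...] = ("tXT",),
    fit_mode: str = "binary_label",
    C: float = 1.0,
) -> PerceptionModel:
    """Fit an L1-regularized logistic perception model to a vote table.

    ``binary_label`` turns each pair into one observation labeled by the
    expert majority (pxp >= 0.5); ``per_vote`` gives each pair two
    weighted observations (n_similar yes votes, n_total - n_similar no
    votes).  ``C`` is the inverse regularization strength (C = 1.0
    corresponds to the customary default lambda = 1).
    """
    feature_spec = tuple(feature_spec)
    df = table.df
    missing = [f for f in feature_spec if f not in df.columns]
    if missing:
        raise FeatureError(f"table lacks feature columns {missing}")
    if "pxp" not in df.columns:
        raise FeatureError("table lacks vote data (n_similar/n_total)")

    X = df[list(feature_spec)].to_numpy(dtype=float)
    pxp = df["pxp"].to_numpy(dtype=float)

    if fit_mode == "binary_label":
        y = (pxp >= 0.5).astype(int)
        weights = None
    elif fit_mode == "per_vote":
        ns = df["n_similar"].to_numpy(dtype=float)
        nt = df["n_total"].to_numpy(dtype=float)
        X = np.vstack([X, X])
        y = np.concatenate([np.ones(len(df)), np.zeros(len(df))]).astype(int)
        weights = np.concatenate([ns, nt - ns])
        keep = weights > 0
        X, y, weights = X[keep], y[keep], weights[keep]
    else:
        raise PercepsimError(f"unknown fit_mode {fit_mode!r}")

    if len(np.unique(y)) < 2:
        raise PercepsimError(
            "degenerate fit: all pairs carry the same majority label"
        )

    clf = LogisticRegression(
        l1_ratio=1.0, C=C, solver="liblinear", tol=1e-8, max_iter=10_000
    )
    clf.fit(X, y, sample_weight=weights)
    if clf.n_iter_[0] >= 10_000:
        raise PercepsimError(
            f"logistic fit did not converge in {clf.n_iter_[0]} iterations"
        )
    coefs = clf.coef_[0]
    return PerceptionModel(
        feature_spec=feature_spec,
        omega0=float(clf.intercept_[0]),
        omega1=float(coefs[0]),
        omega2=float(coefs[1]) if len(feature_spec) == 2 else None,
        regularization={"type": "L1", "C": C, "lambda": 1.0 / C,
                        "solver": "liblinear", "tol": 1e-8},
        fit_mode=fit_mode,
    )


def threshold_for_probability(model: PerceptionModel, p: float) -> float:
    """Feature value at which a single-feature model predicts p.

    Inverts the linear logit: ``t = (logit(p) - omega0) / omega1``; the
    round trip ``predict(model, t).p_hat == p`` holds to ~1e-9.  Note
    that thresholds published alongside survey models are not always
    plain inversions of the fitted equation; this function implements
    the closed-form inversion only.
    """
    if not model.is_single_feature:
        raise NoThresholdError("threshold inversion requires a single-feature model")
    if model.omega1 == 0:
        raise NoThresholdError("omega1 = 0: model is flat, no threshold exists")
    if not 0.0 < p < 1.0:
        raise FeatureError(f"probability must be in (0, 1), got {p}")
    return (math.log(p / (1.0 - p)) - model.omega0) / model.omega1


def load_default_model(name: str = "default_tXT") -> PerceptionModel:
    """Load one of the bundled survey-calibrated models.

    ``default_tXT`` and ``default_tCS`` are the single-feature models,
    ``default_combo`` the double-feature model.
    """
    if name not in DEFAULT_MODELS:
        raise ModelFormatError(
            f"unknown default model {name!r}; available: {DEFAULT_MODELS}"
        )
    text = (
        resources.files("percepsim").joinpath(f"data/models/{name}.json").read_text()
    )
    return PerceptionModel.from_json(text)
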