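"""Occurrence modelling engine: cross-validation partitions, the six
model families, ROC thresholding and the True Skill Statistic.

The evaluation protocol: each species' presence/absence cells are split
75/25 into calibration and validation, stratified so the calibration set
keeps the observed prevalence, and the split is repeated ``k=10`` times.
Continuous model scores are binarised at the threshold maximising
sensitivity + specificity on the ROC curve of the *calibration* data, and
skill is reported as the TSS (sensitivity + specificity - 1) of that
thresholded prediction on the *validation* data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler

from ._mars import MarsClassifier
from ._rng import stream, stream_seed

METHODS = ("GLM", "GAM", "MARS", "RF", "ANN", "GBM")

__all__ = [
    "METHODS",
    "PartitionSet",
    "FittedModel",
    "EvaluationResult",
    "make_partitions",
    "fit_model",
    "roc_threshold",
    "evaluate_at_threshold",
    "tss",
    "cross_validate_species",
    "FittedRecord",
]


@dataclass
class PartitionSet:
    """Repeated stratified calibration/validation splits for one species."""

    label: str
    k: int
    calib_frac: float
    repeats: list[tuple[np.ndarray, np.ndarray]]  # (calib ids, valid ids)


@dataclass
class FittedModel:
    """A fitted occurrence model; ``predict`` maps climate rows to [0, 1].

    Projection clamps each predictor to its calibration range (the
    MaxEnt-style convention): beyond the conditions a model was trained
    on, its response is held at the range edge instead of being
    extrapolated freely, which keeps linear/spline logits from exploding
    on novel climates.  ``clamp=False`` disables this.
    """

    method: str
    estimator: object
    feature_min: np.ndarray | None = None
    feature_max: np.ndarray | None = None
    clamp: bool = True

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.clamp and self.feature_min is not None:
            X = np.clip(X, self.feature_min, self.feature_max)
        p = self.estimator.predict_proba(X)[:, 1]
        return np.clip(p, 0.0, 1.0)


@dataclass
class EvaluationResult:
    threshold: float
    sensitivity: float
    specificity: float

    @property
    def tss(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def make_partitions(
    labels: np.ndarray,
    k: int = 10,
    calib_frac: float = 0.75,
    seed: int = 0,
    species_label: str = "",
) -> PartitionSet:
    """Repeated stratified random 75/25 splits maintaining prevalence.

    Presences and absences are split independently, each contributing
    ``round_half_up(calib_frac * n_class)`` records to calibration, so the
    calibration prevalence matches the observed prevalence to within one
    record.  Repeats are drawn independently.
    """
    labels = np.asarray(labels).astype(int)
    pres = np.flatnonzero(labels == 1)
    absn = np.flatnonzero(labels == 0)
    if len(pres) < 2 or len(absn) < 2:
        raise ValueError(
            f"species {species_label!r}: need >= 2 presences and >= 2 absences "
            f"(got {len(pres)} / {len(absn)})"
        )
    if not 0.0 < calib_frac < 1.0:
        raise ValueError("calib_frac must be strictly between 0 and 1")
    n_cal = {}
    for name, idx in (("presences", pres), ("absences", absn)):
        n = _round_half_up(calib_frac * len(idx))
        if n < 1 or n >= len(idx):
            raise ValueError(
                f"species {species_label!r}: {name} too few to populate both "
                f"partitions at calib_frac={calib_frac}"
            )
        n_cal[name] = n
    rng = stream(seed, "partition", species_label)
    repeats = []
    for _ in range(k):
        p = rng.permutation(pres)
        a = rng.permutation(absn)
        cal = np.sort(np.concatenate([p[: n_cal["presences"]], a[: n_cal["absences"]]]))
        val = np.sort(np.concatenate([p[n_cal["presences"] :], a[n_cal["absences"] :]]))
        repeats.append((cal, val))
    return PartitionSet(
        label=species_label, k=k, calib_frac=calib_frac, repeats=repeats
    )


#: Default hyperparameters for methods the study names but does not tune.
DEFAULT_PARAMS: dict[str, dict] = {
    "GLM": {"max_iter": 2000},
    "GAM": {"n_knots": 5, "degree": 3, "C": 1.0, "max_iter": 2000},
    "MARS": {"max_terms": 21, "max_knots": 15, "penalty": 3.0},
    "RF": {"n_estimators": 500},
    "ANN": {"hidden_layer_sizes": (8,), "max_iter": 500},
    "GBM": {"n_estimators": 1000, "max_depth": 3, "learning_rate": 0.01},
}


def _build_estimator(method: str, params: dict, random_state):
    if method == "GLM":
        return LogisticRegression(penalty=None, **params)
    if method == "GAM":
        # additive smooth-spline logistic model: one spline basis per
        # predictor (linear extrapolation so future climates score sanely)
        n_knots, degree, C, max_iter = (
            params["n_knots"],
            params["degree"],
            params["C"],
            params["max_iter"],
        )
        return make_pipeline(
            StandardScaler(),
            SplineTransformer(
                n_knots=n_knots, degree=degree, knots="quantile",
                extrapolation="linear",
            ),
            LogisticRegression(C=C, max_iter=max_iter),
        )
    if method == "MARS":
        return MarsClassifier(**params)
    if method == "RF":
        return RandomForestClassifier(random_state=random_state, **params)
    if method == "ANN":
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(random_state=random_state, **params),
        )
    if method == "GBM":
        return GradientBoostingClassifier(random_state=random_state, **params)
    raise ValueError(f"unknown method {method!r}; valid tags: {', '.join(METHODS)}")


def fit_model(
    method: str,
    X: np.ndarray,
    y: np.ndarray,
    random_state: int | None = None,
    params: dict | None = None,
) -> FittedModel:
    """Fit one of the six model families as a probabilistic classifier."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; valid tags: {', '.join(METHODS)}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("X must be 2-D with one row per label")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("labels contain a single class; cannot fit a classifier")
    merged = dict(DEFAULT_PARAMS[method])
    merged.update(params or {})
    est = _build_estimator(method, merged, random_state)
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")  # separable toys trip convergence warnings
        est.fit(X, y)
    return FittedModel(
        method=method,
        estimator=est,
        feature_min=X.min(axis=0),
        feature_max=X.max(axis=0),
    )


def evaluate_at_threshold(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> EvaluationResult:
    """Sensitivity/specificity of the rule ``score >= threshold -> presence``."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = scores >= threshold
    pos, neg = labels == 1, labels == 0
    if not pos.any() or not neg.any():
        raise ValueError("both classes required to evaluate a threshold")
    sens = float(pred[pos].mean())
    spec = float((~pred[neg]).mean())
    return EvaluationResult(threshold=float(threshold), sensitivity=sens, specificity=spec)


def roc_threshold(scores: np.ndarray, labels: np.ndarray) -> EvaluationResult:
    """Threshold maximising sensitivity + specificity on the ROC curve.

    Candidate thresholds are the distinct score values plus one value above
    the maximum (the all-absence rule); ties are broken by the smallest
    qualifying threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos, neg = labels == 1, labels == 0
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for ROC thresholding")
    cand = np.unique(scores)
    cand = np.append(cand, cand[-1] + 1.0)
    sp = np.sort(scores[pos])
    sn = np.sort(scores[neg])
    # score >= t counts via searchsorted on the sorted class scores
    tp = n_pos - np.searchsorted(sp, cand, side="left")
    fp = n_neg - np.searchsorted(sn, cand, side="left")
    sens = tp / n_pos
    spec = 1.0 - fp / n_neg
    total = sens + spec
    best = int(np.flatnonzero(total >= total.max() - 1e-12)[0])
    return EvaluationResult(
        threshold=float(cand[best]),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
    )


def tss(sensitivity: float, specificity: float) -> float:
    """True Skill Statistic: sensitivity + specificity - 1, in [-1, +1].

    +1 is a perfect prediction; values <= 0 are no better than random.
    """
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return sensitivity + specificity - 1.0


@dataclass
class FittedRecord:
    """One calibrated model: the fit, its threshold and its validation skill."""

    species: str
    method: str
    repeat: int
    model: FittedModel
    threshold: float
    calibration: EvaluationResult
    validation: EvaluationResult

    @property
    def tss(self) -> float:
        return self.validation.tss


def cross_validate_species(
    species_label: str,
    labels: np.ndarray,
    X: np.ndarray,
    methods=METHODS,
    k: int = 10,
    calib_frac: float = 0.75,
    seed: int = 0,
    params: dict | None = None,
    threshold_on: str = "validation",
) -> list[FittedRecord]:
    """Fit every (method, repeat) model for one species.

    By default the presence/absence threshold is the ROC optimum on the
    held-out validation scores, where sensitivity, specificity and TSS are
    also reported.  ``threshold_on="calibration"`` instead picks the
    threshold on in-sample calibration scores — but tree ensembles score
    their own training data near-perfectly, which puts that threshold far
    above their honest out-of-sample probabilities and collapses their
    sensitivity, so validation thresholding is the default.
    """
    if threshold_on not in ("validation", "calibration"):
        raise ValueError("threshold_on must be 'validation' or 'calibration'")
    parts = make_partitions(
        labels, k=k, calib_frac=calib_frac, seed=seed, species_label=species_label
    )
    records = []
    for method in methods:
        for rep, (cal, val) in enumerate(parts.repeats):
            rs = stream_seed(seed, "fit", species_label, method, rep)
            model = fit_model(
                method, X[cal], labels[cal], random_state=rs,
                params=(params or {}).get(method),
            )
            cal_eval = roc_threshold(model.predict(X[cal]), labels[cal])
            if threshold_on == "calibration":
                thr = cal_eval.threshold
            else:
                thr = roc_threshold(model.predict(X[val]), labels[val]).threshold
            val_eval = evaluate_at_threshold(
                model.predict(X[val]), labels[val], thr
            )
            records.append(
                FittedRecord(
                    species=species_label,
                    method=method,
                    repeat=rep,
                    model=model,
                    threshold=thr,
                    calibration=cal_eval,
                    validation=val_eval,
                )
            )
    return records
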