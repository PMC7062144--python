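"""BTR model semantics: scoring, decision rule, threshold fit, regression scaling.

A BTR model is a sparse linear decision rule over a features x samples
abundance matrix whose coefficients are restricted to a tiny discrete set:

``bin``
    coefficients in {1}; the score is the cumulative abundance of the
    selected features and is compared to a threshold (the intercept beta0);
``ter``
    coefficients in {-1, 1}; the score is the difference of two cumulative
    abundances;
``terlog``
    a ter model fitted on log-transformed abundances (a multiplicative
    balance);
``ratio``
    each selected feature sits on the numerator (+1) or denominator (-1)
    side; the score is the ratio of the two cumulative abundances and the
    threshold is the ratio factor theta (> 0 at the optimum); the intercept
    is fixed at zero, which makes the rule scale-invariant.

The decision is ``positive_class`` iff score > threshold (direction
``score_greater``; strict comparison, ties go to the non-positive class) or
symmetrically score < threshold (``score_less``).  The direction flag is
learned, not assumed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .data_io import AbundanceMatrix, SampleTarget, ValidationError, log_transform

LANGUAGES = ("bin", "ter", "ratio", "terlog")
CLASSIFICATION_METRICS = ("accuracy", "auc", "f1", "precision", "recall")
REGRESSION_METRICS = ("r2", "spearman_rho", "ser")


class ModelError(ValueError):
    """Invalid model structure or use."""


class DegenerateFitError(ModelError):
    """A fit is undefined (e.g. constant scores in regression scaling)."""


@dataclass(frozen=True)
class BTRModel:
    """One sparse BTR model.

    ``feature_indices`` point into the matrix the model was fit on;
    ``feature_names`` carry the corresponding identifiers so the model can be
    re-applied to any matrix sharing feature names.  ``coefficients`` align
    one-to-one with the indices: +1/-1 signs for ter/terlog, numerator(+1) /
    denominator(-1) side tags for ratio, all +1 for bin.
    """

    language: str
    feature_indices: tuple[int, ...]
    coefficients: tuple[int, ...]
    feature_names: tuple[str, ...] = ()
    threshold: float | None = None
    direction: str = "score_greater"  # or "score_less"
    positive_label: str | None = None
    negative_label: str | None = None
    fitness: float | None = None
    fitness_metric: str | None = None
    data_scale: str = "relative"

    def __post_init__(self):
        if self.language not in LANGUAGES:
            raise ModelError(f"unknown language {self.language!r}")
        k = len(self.feature_indices)
        if k < 1:
            raise ModelError("a model must select at least one feature")
        if len(self.coefficients) != k:
            raise ModelError("coefficients must align one-to-one with features")
        if self.feature_names and len(self.feature_names) != k:
            raise ModelError("feature_names must align one-to-one with features")
        if len(set(self.feature_indices)) != k:
            raise ModelError("duplicate feature in model")
        allowed = {1} if self.language == "bin" else {-1, 1}
        if not set(self.coefficients) <= allowed:
            raise ModelError(
                f"{self.language} coefficients must lie in {sorted(allowed)}"
            )
        if self.language == "ratio" and 1 not in self.coefficients:
            raise ModelError("ratio model needs a non-empty numerator")
        if self.language == "terlog" and self.data_scale != "log":
            raise ModelError("terlog models are defined on log-scale data")
        if self.direction not in ("score_greater", "score_less"):
            raise ModelError(f"unknown direction {self.direction!r}")

    @property
    def k(self) -> int:
        """Model size: number of selected features."""
        return len(self.feature_indices)

    @property
    def class_map(self) -> dict:
        return {"positive": self.positive_label, "negative": self.negative_label}

    def structure_key(self) -> tuple:
        """Dedup key: feature/sign structure, ignoring threshold and fitness."""
        return (self.language, self.feature_indices, self.coefficients)


def make_model(language: str, feature_indices, coefficients,
               m: AbundanceMatrix, **kw) -> BTRModel:
    """Build a model against ``m``, resolving feature names from indices."""
    idx = tuple(int(i) for i in feature_indices)
    names = tuple(m.feature_ids[i] for i in idx)
    return BTRModel(language, idx, tuple(int(c) for c in coefficients),
                    feature_names=names, data_scale=m.scale, **kw)


def canonicalize(model: BTRModel) -> BTRModel:
    """Sort features by index; anchor the first coefficient at +1.

    A ter/terlog model and its global sign flip, or a ratio model with its
    numerator and denominator swapped, encode the same decision rule with the
    comparison direction flipped; storing only the canonical representative
    (first selected feature on the +1 side) halves the search space.  The
    threshold and fitness are cleared: callers refit.
    """
    order = np.argsort(model.feature_indices)
    idx = tuple(model.feature_indices[i] for i in order)
    coefs = tuple(model.coefficients[i] for i in order)
    names = tuple(model.feature_names[i] for i in order) if model.feature_names else ()
    if model.language != "bin" and coefs[0] == -1:
        coefs = tuple(-c for c in coefs)
    return replace(model, feature_indices=idx, coefficients=coefs,
                   feature_names=names, threshold=None, fitness=None)


# -- scoring and prediction -------------------------------------------------


def _resolve_indices(model: BTRModel, m: AbundanceMatrix) -> np.ndarray:
    idx = np.asarray(model.feature_indices, dtype=int)
    if (idx < 0).any() or (idx >= m.n_features).any():
        if model.feature_names:
            return np.asarray([m.feature_index(f) for f in model.feature_names])
        raise ModelError("feature index out of range for this matrix")
    if model.feature_names:
        for i, name in zip(idx, model.feature_names):
            if m.feature_ids[i] != name:
                # matrix with a different feature order: resolve by name
                return np.asarray([m.feature_index(f) for f in model.feature_names])
    return idx


def score_samples(model: BTRModel, m: AbundanceMatrix) -> np.ndarray:
    """One score per sample.

    bin/ter/terlog: signed cumulative abundance over the selected features
    (the threshold is *not* part of the score).  ratio: numerator sum over
    denominator sum, with the sentinels x/0 -> +inf (x > 0) and 0/0 -> 0 so
    predictions stay defined on presence-sparse data.
    """
    if model.data_scale != m.scale:
        raise ModelError(
            f"model fit on {model.data_scale!r} data applied to {m.scale!r} data"
        )
    idx = _resolve_indices(model, m)
    sub = m.values[idx, :]
    coefs = np.asarray(model.coefficients, dtype=float)
    if model.language in ("bin", "ter", "terlog"):
        return coefs @ sub
    num = sub[coefs > 0].sum(axis=0)
    den = sub[coefs < 0].sum(axis=0) if (coefs < 0).any() else np.zeros(m.n_samples)
    out = np.zeros(m.n_samples)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    out[~ok & (num > 0)] = np.inf
    return out


def predict(model: BTRModel, m: AbundanceMatrix) -> np.ndarray:
    """Predicted labels; ties (score == threshold) go to the non-positive class."""
    if model.threshold is None:
        raise ModelError("model threshold is not fitted")
    if model.positive_label is None or model.negative_label is None:
        raise ModelError("class map is unset; fit the model on labelled data first")
    scores = score_samples(model, m)
    if model.direction == "score_greater":
        pos = scores > model.threshold
    else:
        pos = scores < model.threshold
    out = np.empty(m.n_samples, dtype=object)
    out[pos] = model.positive_label
    out[~pos] = model.negative_label
    return out


# -- threshold optimisation -------------------------------------------------


def optimize_threshold(scores, y_positive) -> tuple[float, str, int]:
    """Best decision cut for a score vector against binary labels.

    Sorts the samples by score and sweeps the cumulative misclassification
    count over every cut position (midpoints between consecutive distinct
    scores plus -inf/+inf sentinels) in both comparison directions; the
    result is guaranteed equal to brute force over all (cut, direction)
    pairs.  Ties on error are broken by the widest margin (largest gap
    between neighbouring scores), then the smallest cut value, then
    ``score_greater``.

    Returns ``(threshold, direction, train_error_count)``.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y_positive, dtype=bool)
    n = scores.size
    if n < 2:
        raise ValidationError("threshold optimisation needs at least 2 samples")
    if y.all() or not y.any():
        raise ValidationError("both classes must be present")

    order = np.argsort(scores, kind="stable")
    s = scores[order]
    yp = y[order]
    cum_pos = np.concatenate(([0], np.cumsum(yp)))
    total_neg = n - int(cum_pos[-1])

    change = np.flatnonzero(s[1:] != s[:-1]) + 1
    b = np.concatenate(([0], change, [n]))  # samples with score <= cut
    cb = cum_pos[b]
    # predict positive iff score > cut
    err_greater = 2 * cb - b + total_neg
    err_less = n - err_greater

    cuts = np.empty(b.size)
    gaps = np.empty(b.size)
    cuts[0], gaps[0] = -np.inf, np.inf
    cuts[-1], gaps[-1] = np.inf, np.inf
    if b.size > 2:
        lo = s[b[1:-1] - 1]
        hi = s[b[1:-1]]
        mid = 0.5 * (lo + hi)
        if np.isinf(s[-1]) or np.isinf(s[0]):  # sentinel-score boundaries
            mid = np.where(np.isinf(hi) & ~np.isinf(lo), lo + 1.0, mid)
            mid = np.where(np.isinf(lo) & ~np.isinf(hi), hi - 1.0, mid)
        cuts[1:-1] = mid
        gaps[1:-1] = hi - lo

    best = None
    for pref, (direction, err) in enumerate(
            (("score_greater", err_greater), ("score_less", err_less))):
        i = int(np.lexsort((cuts, -gaps, err))[0])
        key = (int(err[i]), -gaps[i], cuts[i], pref)
        if best is None or key < best[0]:
            best = (key, float(cuts[i]), direction, int(err[i]))
    _, threshold, direction, err = best
    return threshold, direction, err


def fit_model_threshold(model: BTRModel, m: AbundanceMatrix, y: SampleTarget,
                        metric: str = "accuracy") -> BTRModel:
    """Fit the decision cut on training data and record training fitness.

    For bin/ter/terlog the selected cut is the intercept-equivalent beta0;
    for ratio the cut on the ratio scores *is* the ratio factor theta.
    """
    if y.kind != "binary_class":
        raise ValidationError("threshold fitting requires a binary target")
    pos = y.resolved_positive()
    neg = [c for c in y.classes if c != pos][0]
    scores = score_samples(model, m)
    threshold, direction, err = optimize_threshold(scores, y.positive_mask())
    fitted = replace(model, threshold=threshold, direction=direction,
                     positive_label=pos, negative_label=neg,
                     fitness_metric=metric)
    if metric == "accuracy":
        fitness = 1.0 - err / m.n_samples
    else:
        from .evaluation import compute_metric  # lazy: avoids a module cycle
        if metric == "auc":
            oriented = scores if direction == "score_greater" else -scores
            fitness = compute_metric(y.values, oriented, "auc", positive_class=pos)
        else:
            preds = predict(fitted, m)
            fitness = compute_metric(y.values, preds, metric, positive_class=pos)
    return replace(fitted, fitness=float(fitness))


# -- regression scaling -----------------------------------------------------


@dataclass(frozen=True)
class RegressionFit:
    """OLS scaling of a BTR score onto a continuous target: y ~ alpha*score + beta."""

    alpha: float
    beta: float
    metric: str
    value: float


def fit_regression_scaling(scores, y, metric: str = "r2") -> RegressionFit:
    """Scale a raw BTR score into the range of a continuous target by OLS.

    The score of a fitted model reflects cumulative/difference/ratio relative
    abundance and needs a multiplication factor alpha and intercept beta to
    live on the target's scale.  Quality is reported as R^2 (default),
    Spearman rho, or the scaled standard error of regression (residual SD
    over target SD; lower is better).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float)
    if scores.size < 3:
        raise ValidationError("regression scaling needs at least 3 samples")
    if metric not in REGRESSION_METRICS:
        raise ModelError(f"unknown regression metric {metric!r}")
    if np.ptp(scores) == 0:
        raise DegenerateFitError("scores are constant; scaling is undefined")
    res = stats.linregress(scores, y)
    alpha, beta = float(res.slope), float(res.intercept)
    if metric == "r2":
        value = float(res.rvalue ** 2)
    elif metric == "spearman_rho":
        value = float(stats.spearmanr(scores, y).statistic)
    else:
        resid = y - (alpha * scores + beta)
        sd_y = y.std(ddof=1)
        value = float(resid.std(ddof=1) / sd_y) if sd_y > 0 else 0.0
    return RegressionFit(alpha, beta, metric, value)


# -- serialization ----------------------------------------------------------


def model_to_dict(model: BTRModel) -> dict:
    """JSON-ready document keyed by feature names, not indices."""
    if not model.feature_names:
        raise ModelError("cannot serialise a model without feature names")
    side = {1: "numerator", -1: "denominator"}
    features = []
    for name, c in zip(model.feature_names, model.coefficients):
        entry = {"name": name, "coefficient": int(c)}
        if model.language == "ratio":
            entry["side"] = side[c]
        features.append(entry)
    return {
        "language": model.language,
        "features": features,
        "threshold": model.threshold,
        "direction": model.direction,
        "class_map": {"positive": model.positive_label,
                      "negative": model.negative_label},
        "data_scale": model.data_scale,
        "fitness": {"metric": model.fitness_metric, "value": model.fitness},
    }


def model_from_dict(doc: dict, m: AbundanceMatrix | None = None) -> BTRModel:
    """Re-instantiate a model; indices resolve against ``m`` when given."""
    names = tuple(f["name"] for f in doc["features"])
    coefs = tuple(int(f["coefficient"]) for f in doc["features"])
    if m is not None:
        idx = tuple(m.feature_index(f) for f in names)
    else:
        idx = tuple(range(len(names)))
    fit = doc.get("fitness") or {}
    return BTRModel(
        doc["language"], idx, coefs, feature_names=names,
        threshold=doc.get("threshold"), direction=doc.get("direction", "score_greater"),
        positive_label=(doc.get("class_map") or {}).get("positive"),
        negative_label=(doc.get("class_map") or {}).get("negative"),
        fitness=fit.get("value"), fitness_metric=fit.get("metric"),
        data_scale=doc.get("data_scale", "relative"),
    )


def save_model(model: BTRModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=2)


def load_model(path, m: AbundanceMatrix | None = None) -> BTRModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh), m)


def barcode_table(model: BTRModel):
    """Ordered (feature, sign) list for barcode-style rendering, as a DataFrame."""
    import pandas as pd

    return pd.DataFrame({
        "feature": list(model.feature_names or
                        [str(i) for i in model.feature_indices]),
        "sign": [int(c) for c in model.coefficients],
    })


def apply_terlog(m: AbundanceMatrix, pseudocount: float | None = None) -> AbundanceMatrix:
    """Data-side half of the terlog language: log-transform for ter fitting."""
    from .data_io import DEFAULT_PSEUDOCOUNT

    pc = DEFAULT_PSEUDOCOUNT if pseudocount is None else pseudocount
    return log_transform(m, pc)
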