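"""Penalized best-model choice and family-of-best-models (FBM) extraction.

Sparsity is rewarded explicitly: the selected model maximises
``fitness - lambda * k`` with the default lambda of 1%, i.e. a model using
one more feature wins only if it improves accuracy by more than one
percentage point.

The FBM collects every searched model whose training accuracy lies within a
statistically equivalent window of the best accuracy.  The window comes from
the sampling noise of an accuracy estimated on ``n_train`` samples: a
one-sided normal approximation to the binomial,
``window = z_(1-p) * sqrt(a (1 - a) / n_train)`` with ``a`` the best
accuracy (an exact binomial quantile is available behind a flag; it differs
negligibly for n >= 30).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .models import BTRModel, CLASSIFICATION_METRICS, ModelError
from .search import ModelPopulation, _sort_key


class NotSupportedError(ModelError):
    """Operation undefined for this population (e.g. FBM on regression)."""


def penalized_select(pop: ModelPopulation, lam: float = 0.01) -> BTRModel:
    """Argmax of ``fitness - lam * k`` over the population.

    Ties break towards the smaller model, then by feature-name lexicographic
    order, so the result is invariant under population reordering.
    """
    if not pop.models:
        raise ModelError("cannot select from an empty population")
    if lam < 0:
        raise ModelError("lambda must be non-negative")

    def key(mdl: BTRModel) -> tuple:
        return (-(mdl.fitness - lam * mdl.k), mdl.k,
                mdl.feature_names, mdl.coefficients)

    return min(pop.models, key=key)


@dataclass
class FBM:
    """Family of best models: statistically equivalent near-optimal models."""

    models: list[BTRModel]
    best_fitness: float
    window: float
    n_train: int
    p_level: float = 0.05

    def __post_init__(self):
        if not self.models:
            raise ModelError("FBM cannot be empty")

    @property
    def feature_names(self) -> list[str]:
        """Distinct features used by any member, sorted."""
        out = set()
        for mdl in self.models:
            out.update(mdl.feature_names)
        return sorted(out)


def extract_fbm(pop: ModelPopulation, n_train: int, p_level: float = 0.05,
                exact_binomial: bool = False) -> FBM:
    """All models with fitness within the binomial equivalence window.

    Members are deduplicated by (feature set, signs); the same structure
    refit with a different threshold counts once.  Requires a classification
    fitness in [0, 1].
    """
    if not pop.models:
        raise ModelError("cannot extract an FBM from an empty population")
    if n_train < 1:
        raise ModelError("n_train must be >= 1")
    metric = pop.models[0].fitness_metric
    if metric not in CLASSIFICATION_METRICS:
        raise NotSupportedError(
            "the FBM window is defined on classification accuracy, "
            f"not on {metric!r}"
        )
    fits = [mdl.fitness for mdl in pop.models]
    if any(f is None or not (0.0 <= f <= 1.0) for f in fits):
        raise NotSupportedError("FBM requires fitted fitness values in [0, 1]")
    best = max(fits)
    if exact_binomial:
        lower = stats.binom.ppf(p_level, n_train, best) / n_train
        window = float(best - lower)
    else:
        z = stats.norm.ppf(1.0 - p_level)
        window = float(z * np.sqrt(best * (1.0 - best) / n_train))
    cutoff = best - window
    members = [mdl for mdl in pop.models if mdl.fitness >= cutoff]
    members = _dedup_structures(members)
    return FBM(members, best_fitness=float(best), window=window,
               n_train=int(n_train), p_level=float(p_level))


def _dedup_structures(models: list[BTRModel]) -> list[BTRModel]:
    seen = set()
    out = []
    for mdl in sorted(models, key=_sort_key):
        key = (mdl.language, mdl.feature_indices, mdl.coefficients)
        if key not in seen:
            seen.add(key)
            out.append(mdl)
    return out


def fbm_to_dicts(fbm: FBM) -> dict:
    """JSON-ready FBM document: member models plus window metadata."""
    from .models import model_to_dict

    return {
        "best_fitness": fbm.best_fitness,
        "window": fbm.window,
        "n_train": fbm.n_train,
        "p_level": fbm.p_level,
        "models": [model_to_dict(mdl) for mdl in fbm.models],
    }


def fbm_from_dicts(doc: dict, m=None) -> FBM:
    from .models import model_from_dict

    return FBM([model_from_dict(d, m) for d in doc["models"]],
               best_fitness=doc["best_fitness"], window=doc["window"],
               n_train=doc["n_train"], p_level=doc.get("p_level", 0.05))
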