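"""Evolutionary search over the BTR model space.

Learning an optimal BTR model is a discrete subset-selection problem (NP-hard
in general): exhaustive enumeration blows up combinatorially with the number
of features, so the production path is a genetic algorithm — populations of
models per model size k, tournament selection with elitism, feature-swap /
sign-flip mutation and union-of-parents crossover.  An exhaustive enumerator
with a guard bound is provided for small instances; it doubles as the test
oracle for the GA.

The search runs one island per model size k so that the penalized selection
afterwards compares sizes fairly.  Populations store canonical model forms
(features sorted, first coefficient +1) because a ter model and its global
sign flip — or a ratio model with numerator and denominator swapped — encode
the same decision rule with the direction flag flipped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np

from .data_io import (AbundanceMatrix, SampleTarget, ValidationError,
                      log_transform, prepare_for_fitting)
from .models import (BTRModel, CLASSIFICATION_METRICS, ModelError, canonicalize,
                     fit_model_threshold, make_model)

logger = logging.getLogger(__name__)

#: refusal bound for exhaustive enumeration (models evaluated)
EXHAUSTIVE_GUARD = 2_000_000


@dataclass
class SearchConfig:
    """Tunable knobs of the evolutionary search.

    The defaults (population 200 per model size, 100 generations, elite
    fraction 0.1, mutation rate 0.2, crossover rate 0.8, tournament size 2)
    are conventional GA settings; everything is configurable and expressible
    in the YAML run configuration.
    """

    language: str = "bin"
    k_min: int = 1
    k_max: int = 5
    population_size: int = 200
    generations: int = 100
    mutation_rate: float = 0.2
    crossover_rate: float = 0.8
    elite_fraction: float = 0.1
    tournament_size: int = 2
    seeded_fraction: float = 0.5
    seed: int = 0
    fitness_metric: str = "accuracy"

    def __post_init__(self):
        if not (1 <= self.k_min <= self.k_max):
            raise ValidationError("need 1 <= k_min <= k_max")
        if self.population_size < 2:
            raise ValidationError("population_size must be >= 2")
        for name in ("mutation_rate", "crossover_rate", "elite_fraction",
                     "seeded_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")


@dataclass
class ModelPopulation:
    """Models grouped by size k, as evolved or enumerated."""

    models: list[BTRModel]
    language: str
    data_scale: str
    feature_ids: list[str]
    generation: int = 0
    fitness_history: dict = field(default_factory=dict)  # k -> [best per gen]
    n_evaluated: int = 0

    def models_by_k(self) -> dict[int, list[BTRModel]]:
        out: dict[int, list[BTRModel]] = {}
        for mdl in self.models:
            out.setdefault(mdl.k, []).append(mdl)
        return out

    def best(self) -> BTRModel:
        if not self.models:
            raise ModelError("empty population")
        return min(self.models, key=_sort_key)


def _sort_key(mdl: BTRModel) -> tuple:
    return (-(mdl.fitness if mdl.fitness is not None else -np.inf),
            mdl.k, mdl.feature_names, mdl.coefficients)


def prepare_data(m: AbundanceMatrix, language: str) -> AbundanceMatrix:
    """Raw input is closed to relative abundance; terlog adds the log transform."""
    data = prepare_for_fitting(m)
    if language == "terlog" and data.scale != "log":
        data = log_transform(data)
    return data


def _enrichment_signs(data: AbundanceMatrix, y: SampleTarget) -> np.ndarray:
    """+1 where the feature's mean rank is higher in the positive class."""
    from .evaluation import mann_whitney_rank

    tab = mann_whitney_rank(data, y)
    signs = np.ones(data.n_features, dtype=int)
    effects = tab.set_index("feature")["effect"]
    for i, name in enumerate(data.feature_ids):
        signs[i] = 1 if effects[name] >= 0.5 else -1
    return signs


def _mw_order(data: AbundanceMatrix, y: SampleTarget) -> np.ndarray:
    from .evaluation import mann_whitney_rank

    tab = mann_whitney_rank(data, y)
    lookup = {f: i for i, f in enumerate(data.feature_ids)}
    return np.asarray([lookup[f] for f in tab["feature"]], dtype=int)


class _FitContext:
    """Precomputed per-search state for fast model fitting.

    Caches the data array, the positive-class mask and the label pair so the
    inner GA loop builds one model object per candidate instead of threading
    everything through the public fitting API.
    """

    __slots__ = ("data", "values", "ymask", "pos", "neg", "metric",
                 "language", "y", "cache")

    def __init__(self, data: AbundanceMatrix, y: SampleTarget,
                 language: str, metric: str):
        self.data = data
        self.values = data.values
        self.ymask = y.positive_mask()
        self.pos = y.resolved_positive()
        self.neg = [c for c in y.classes if c != self.pos][0]
        self.metric = metric
        self.language = language
        self.y = y
        self.cache: dict[tuple, BTRModel] = {}


def _ctx_build(ctx: _FitContext, feats, coefs) -> BTRModel:
    """Canonicalize, score, fit the threshold and assemble one model.

    Fitting is deterministic given the data, so fitted models are memoized
    by their canonical structure (models are immutable)."""
    from .models import optimize_threshold

    feats = [int(f) for f in feats]
    coefs = [int(c) for c in coefs]
    if len(feats) != len(coefs):
        raise ModelError("coefficients must align one-to-one with features")
    pairs = sorted(zip(feats, coefs))
    if ctx.language != "bin" and pairs[0][1] == -1:
        pairs = [(f, -c) for f, c in pairs]
    idx = tuple(f for f, _ in pairs)
    coef_t = tuple(c for _, c in pairs)
    cached = ctx.cache.get((idx, coef_t))
    if cached is not None:
        return cached
    sub = ctx.values[list(idx), :]
    if ctx.language == "ratio":
        w = np.asarray(coef_t, dtype=float)
        num = sub[w > 0].sum(axis=0)
        if (w < 0).any():
            den = sub[w < 0].sum(axis=0)
            scores = np.zeros(sub.shape[1])
            ok = den > 0
            scores[ok] = num[ok] / den[ok]
            scores[~ok & (num > 0)] = np.inf
        else:
            scores = np.where(num > 0, np.inf, 0.0)
    elif len(idx) == 1:
        scores = coef_t[0] * sub[0]
    else:
        scores = np.asarray(coef_t, dtype=float) @ sub
    threshold, direction, err = optimize_threshold(scores, ctx.ymask)
    names = tuple(ctx.data.feature_ids[i] for i in idx)
    mdl = BTRModel(ctx.language, idx, coef_t, feature_names=names,
                   threshold=threshold, direction=direction,
                   positive_label=ctx.pos, negative_label=ctx.neg,
                   fitness=1.0 - err / scores.size,
                   fitness_metric="accuracy", data_scale=ctx.data.scale)
    if ctx.metric != "accuracy":
        mdl = fit_model_threshold(mdl, ctx.data, ctx.y, metric=ctx.metric)
    ctx.cache[(idx, coef_t)] = mdl
    return mdl


def _build(language, feats, coefs, data, y, metric) -> BTRModel:
    mdl = canonicalize(make_model(language, feats, coefs, data))
    return fit_model_threshold(mdl, data, y, metric=metric)


def _random_coefs(language: str, k: int, rng) -> np.ndarray:
    if language == "bin":
        return np.ones(k, dtype=int)
    return rng.choice((-1, 1), size=k)


def initialize_population(m: AbundanceMatrix, y: SampleTarget, cfg: SearchConfig,
                          rng=None) -> ModelPopulation:
    """Seed one island per model size with ranked and random models.

    A configurable fraction of each island is seeded from the top
    Mann-Whitney-ranked features with signs set by class-wise enrichment
    direction (the first seeded model is exactly the top-k ranked features);
    the remainder are uniform random subsets with random signs.  Thresholds
    are fitted; the result is deterministic given the seed.
    """
    data = prepare_data(m, cfg.language)
    if cfg.k_max > data.n_features:
        raise ValidationError(
            f"k_max={cfg.k_max} exceeds the {data.n_features} available features"
        )
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    order = _mw_order(data, y)
    signs = _enrichment_signs(data, y)
    ctx = _FitContext(data, y, cfg.language, cfg.fitness_metric)
    models: list[BTRModel] = []
    history: dict[int, list[float]] = {}
    for k in range(cfg.k_min, cfg.k_max + 1):
        island = _init_island(ctx, cfg, k, rng, order, signs)
        history[k] = [island[0].fitness]
        models.extend(island)
    return ModelPopulation(models, cfg.language, data.scale,
                           list(data.feature_ids), generation=0,
                           fitness_history=history)


def _init_island(ctx, cfg, k, rng, order, signs) -> list[BTRModel]:
    p = ctx.data.n_features
    pool = order[:min(p, max(10, 3 * cfg.k_max))]
    n_seeded = int(round(cfg.seeded_fraction * cfg.population_size))
    island = []
    for i in range(cfg.population_size):
        if i < n_seeded:
            if i == 0:
                feats = np.sort(order[:k])
            else:
                feats = np.sort(rng.choice(pool, size=k, replace=False))
            coefs = (np.ones(k, dtype=int) if cfg.language == "bin"
                     else signs[feats])
        else:
            feats = np.sort(rng.choice(p, size=k, replace=False))
            coefs = _random_coefs(cfg.language, k, rng)
        island.append(_ctx_build(ctx, feats, coefs))
    island.sort(key=_sort_key)
    return island


# -- variation operators ----------------------------------------------------


def mutate(model: BTRModel, data: AbundanceMatrix, y: SampleTarget,
           rate: float, rng, metric: str = "accuracy",
           _ctx: _FitContext | None = None) -> BTRModel:
    """Per-feature mutation: swap for an unselected feature or flip the sign.

    Each selected position is hit independently with probability ``rate``;
    ter/ratio positions choose between a swap and a sign/side flip with equal
    probability, bin positions always swap.  Model size is preserved and the
    threshold is refitted.  ``rate=0`` returns the model unchanged, threshold
    included.
    """
    idx = list(model.feature_indices)
    coefs = list(model.coefficients)
    p = data.n_features
    current = set(idx)
    changed = False
    for pos in range(len(idx)):
        if rng.random() >= rate:
            continue
        changed = True
        flip = model.language != "bin" and rng.random() < 0.5
        if flip:
            coefs[pos] = -coefs[pos]
        elif p > len(idx):
            new = int(rng.integers(p))
            while new in current:
                new = int(rng.integers(p))
            current.discard(idx[pos])
            current.add(new)
            idx[pos] = new
    if not changed:
        return model
    if _ctx is None:
        _ctx = _FitContext(data, y, model.language, metric)
    return _ctx_build(_ctx, idx, coefs)


def crossover(a: BTRModel, b: BTRModel, data: AbundanceMatrix, y: SampleTarget,
              rng, metric: str = "accuracy",
              _ctx: _FitContext | None = None) -> tuple[BTRModel, BTRModel]:
    """Two children drawn from the union of the parents' (feature, sign) pairs.

    Child sizes are sampled between the parents' k values (inclusive);
    features appearing in both parents with conflicting signs take a side at
    random, per child.  Duplicate features are impossible by construction
    and thresholds are refitted.
    """
    if a.language != b.language or a.data_scale != b.data_scale:
        raise ModelError("crossover requires the same language and data scale")
    union: dict[int, list[int]] = {}
    for parent in (a, b):
        for f, c in zip(parent.feature_indices, parent.coefficients):
            union.setdefault(int(f), []).append(int(c))
    feats_all = np.asarray(sorted(union), dtype=int)
    lo, hi = min(a.k, b.k), max(a.k, b.k)
    if _ctx is None:
        _ctx = _FitContext(data, y, a.language, metric)
    children = []
    for _ in range(2):
        k = int(rng.integers(lo, hi + 1))
        feats = np.sort(rng.choice(feats_all, size=k, replace=False))
        coefs = []
        for f in feats:
            cands = union[int(f)]
            if len(set(cands)) == 1:
                coefs.append(cands[0])
            else:
                coefs.append(int(rng.choice(cands)))
        children.append(_ctx_build(_ctx, feats, coefs))
    return children[0], children[1]


def _tournament(island: list[BTRModel], rng, size: int) -> BTRModel:
    picks = rng.integers(len(island), size=size)
    return min((island[i] for i in picks), key=_sort_key)


# -- the main loop ----------------------------------------------------------


def evolve(m: AbundanceMatrix, y: SampleTarget, cfg: SearchConfig) -> ModelPopulation:
    """Run the full evolutionary search; deterministic given ``cfg.seed``.

    Per generation and per k island: elites are carried over unchanged, the
    remainder is produced by tournament selection followed by crossover (with
    probability ``crossover_rate``) or cloning, then mutation.  Elitism makes
    the best-so-far fitness non-decreasing across generations.  The final
    population is deduplicated by model structure and sorted by fitness
    within each k.
    """
    data = prepare_data(m, cfg.language)
    if cfg.k_max > data.n_features:
        raise ValidationError(
            f"k_max={cfg.k_max} exceeds the {data.n_features} available features"
        )
    master = np.random.SeedSequence(cfg.seed)
    init_rng = np.random.default_rng(master.spawn(1)[0])
    order = _mw_order(data, y)
    signs = _enrichment_signs(data, y)
    ctx = _FitContext(data, y, cfg.language, cfg.fitness_metric)

    ks = list(range(cfg.k_min, cfg.k_max + 1))
    island_seeds = master.spawn(len(ks) + 1)[1:]
    models: list[BTRModel] = []
    history: dict[int, list[float]] = {}
    n_eval = 0
    for k, seed_seq in zip(ks, island_seeds):
        rng = np.random.default_rng(seed_seq)
        island = _init_island(ctx, cfg, k, init_rng, order, signs)
        n_eval += len(island)
        hist = [island[0].fitness]
        n_elite = max(1, int(cfg.elite_fraction * cfg.population_size))
        for gen in range(cfg.generations):
            elites = island[:n_elite]
            children: list[BTRModel] = []
            while len(children) < cfg.population_size - n_elite:
                if rng.random() < cfg.crossover_rate:
                    pa = _tournament(island, rng, cfg.tournament_size)
                    pb = _tournament(island, rng, cfg.tournament_size)
                    c1, c2 = crossover(pa, pb, data, y, rng,
                                       cfg.fitness_metric, _ctx=ctx)
                    children.extend((c1, c2))
                else:
                    children.append(_tournament(island, rng, cfg.tournament_size))
            children = children[:cfg.population_size - n_elite]
            children = [mutate(c, data, y, cfg.mutation_rate, rng,
                               cfg.fitness_metric, _ctx=ctx) for c in children]
            n_eval += len(children)
            island = sorted(elites + children, key=_sort_key)
            hist.append(island[0].fitness)
            logger.info("k=%d gen=%d best %s=%.4f", k, gen + 1,
                        cfg.fitness_metric, island[0].fitness)
        history[k] = hist
        models.extend(island)

    models = _dedup(models)
    models.sort(key=_sort_key)
    return ModelPopulation(models, cfg.language, data.scale,
                           list(data.feature_ids), generation=cfg.generations,
                           fitness_history=history, n_evaluated=n_eval)


def _dedup(models: list[BTRModel]) -> list[BTRModel]:
    seen = set()
    out = []
    for mdl in sorted(models, key=_sort_key):
        key = mdl.structure_key()
        if key not in seen:
            seen.add(key)
            out.append(mdl)
    return out


# -- exhaustive oracle ------------------------------------------------------


def count_models(p: int, k_max: int, language: str) -> int:
    """Closed-form count of canonical models with size <= k_max.

    bin has one sign pattern per subset; ter/terlog and ratio have 2^(k-1)
    canonical patterns (the first selected feature is anchored on the
    +1/numerator side, since the global flip is the same rule with the
    direction reversed).
    """
    total = 0
    for k in range(1, k_max + 1):
        patterns = 1 if language == "bin" else 2 ** (k - 1)
        total += math.comb(p, k) * patterns
    return total


def exhaustive_search(m: AbundanceMatrix, y: SampleTarget, language: str,
                      k_max: int, fitness_metric: str = "accuracy",
                      guard: int = EXHAUSTIVE_GUARD) -> ModelPopulation:
    """Enumerate and fit every canonical model of size <= k_max.

    Used as a certification oracle on small instances, not as the production
    path.  Refuses to run when the enumeration would exceed ``guard``
    evaluated models.
    """
    data = prepare_data(m, language)
    p = data.n_features
    if k_max > p:
        raise ValidationError(f"k_max={k_max} exceeds the {p} available features")
    total = count_models(p, k_max, language)
    if total > guard:
        raise ValidationError(
            f"exhaustive enumeration of {total} models exceeds the guard "
            f"bound of {guard}"
        )
    ctx = _FitContext(data, y, language, fitness_metric)
    models = []
    for k in range(1, k_max + 1):
        sign_tails = ([(1,) * (k - 1)] if language == "bin"
                      else list(product((1, -1), repeat=k - 1)))
        for feats in combinations(range(p), k):
            for tail in sign_tails:
                models.append(_ctx_build(ctx, feats, (1,) + tail))
    models.sort(key=_sort_key)
    return ModelPopulation(models, language, data.scale, list(data.feature_ids),
                           n_evaluated=total)
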