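"""Permutation feature importance (mean decrease accuracy) over the FBM.

A feature's importance is what it costs the family of best models to lose
it: per cross-validation fold, the feature's values are permuted across the
fold's held-out samples (all other features intact), each FBM model's
held-out error is recomputed, and the error increase is averaged over FBM
models and permutations.  The final MDA is the mean of these per-fold values
across folds, reported with the standard error of that mean.  Features
absent from every FBM model have MDA exactly 0; models not containing the
permuted feature contribute exactly 0 to the average.

Error here is always 1 - accuracy, whatever metric drove the search.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_io import AbundanceMatrix, SampleTarget, ValidationError
from .models import ModelError, predict
from .selection import FBM


def _error(model, m: AbundanceMatrix, y: SampleTarget) -> float:
    return float((predict(model, m) != np.asarray(y.values, dtype=object)).mean())


def compute_mda(fbm_per_fold: list[FBM],
                held_out_per_fold: list[tuple[AbundanceMatrix, SampleTarget]],
                n_permutations: int = 10, seed: int = 0,
                reference: tuple[AbundanceMatrix, SampleTarget] | None = None
                ) -> pd.DataFrame:
    """Mean decrease accuracy per feature, aggregated over folds.

    Parameters
    ----------
    fbm_per_fold:
        One family of best models per CV fold (fitted on that fold's
        training data).
    held_out_per_fold:
        The matching held-out (matrix, target) pairs.  Matrices must share
        feature names with the models.
    n_permutations:
        Independent permutations per feature per fold; the default of 10
        balances cost against Monte-Carlo variance.
    reference:
        Optional (matrix, target) on which the class-enrichment direction
        tag is computed (Mann-Whitney mean-rank comparison).

    Returns a DataFrame (feature, mda, sem, direction) sorted by MDA
    descending; deterministic given ``seed``.
    """
    if len(fbm_per_fold) != len(held_out_per_fold):
        raise ValidationError("one held-out split is required per FBM")
    if not fbm_per_fold:
        raise ModelError("no FBMs supplied")
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    for fbm in fbm_per_fold:
        if not fbm.models:
            raise ModelError("empty FBM")

    rngs = [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(len(fbm_per_fold))]
    all_features: set[str] = set()
    for fbm in fbm_per_fold:
        all_features.update(fbm.feature_names)

    n_folds = len(fbm_per_fold)
    per_fold = {f: np.zeros(n_folds) for f in all_features}

    for fold, (fbm, (m_te, y_te), rng) in enumerate(
            zip(fbm_per_fold, held_out_per_fold, rngs)):
        models = fbm.models
        base_err = [_error(mdl, m_te, y_te) for mdl in models]
        containing: dict[str, list[int]] = {}
        for mi, mdl in enumerate(models):
            for f in mdl.feature_names:
                containing.setdefault(f, []).append(mi)
        n_te = m_te.n_samples
        for f in sorted(containing):
            row = m_te.feature_index(f)
            acc = 0.0
            for _ in range(n_permutations):
                perm = rng.permutation(n_te)
                values = m_te.values.copy()
                values[row] = values[row, perm]
                m_perm = AbundanceMatrix(values, list(m_te.feature_ids),
                                         list(m_te.sample_ids), m_te.scale,
                                         validate=False)
                for mi in containing[f]:
                    acc += _error(models[mi], m_perm, y_te) - base_err[mi]
            # models not containing f contribute exactly 0 to the average
            per_fold[f][fold] = acc / (n_permutations * len(models))

    rows = []
    directions = _directions(reference)
    for f in sorted(all_features):
        vals = per_fold[f]
        mda = float(vals.mean())
        sem = float(vals.std(ddof=1) / np.sqrt(n_folds)) if n_folds > 1 else 0.0
        rows.append({"feature": f, "mda": mda, "sem": sem,
                     "direction": directions.get(f, "")})
    out = pd.DataFrame(rows).sort_values(["mda", "feature"],
                                         ascending=[False, True])
    return out.reset_index(drop=True)


def _directions(reference) -> dict[str, str]:
    if reference is None:
        return {}
    from .evaluation import mann_whitney_rank

    m, y = reference
    tab = mann_whitney_rank(m, y)
    return dict(zip(tab["feature"], tab["direction"]))


def write_mda(table: pd.DataFrame, path) -> None:
    """TSV export (feature, mda, sem, direction) for lollipop-style plots."""
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")
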