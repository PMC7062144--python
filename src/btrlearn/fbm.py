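"""Distilling a family of best models: incidence tables, per-feature class
statistics, and a feature co-presence network.

Near-optimal models tend to draw on a small shared pool of features.  The
models x features signed incidence table makes that pool explicit; the phi
coefficient of feature presence across models then separates complementary
features (co-presence, positive weight) from interchangeable ones (mutual
exclusion, negative weight) — redundant features carry the same signal, so
the search uses one or the other but rarely both.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import AbundanceMatrix, SampleTarget, ValidationError
from .models import ModelError
from .selection import FBM


def model_feature_table(fbm: FBM) -> pd.DataFrame:
    """Signed incidence matrix: one row per model, one column per feature.

    Entries are the model coefficients (-1/0/+1; for ratio models +1 marks
    the numerator and -1 the denominator side).
    """
    if not fbm.models:
        raise ModelError("empty FBM")
    features = fbm.feature_names
    col = {f: j for j, f in enumerate(features)}
    table = np.zeros((len(fbm.models), len(features)), dtype=int)
    for i, mdl in enumerate(fbm.models):
        for f, c in zip(mdl.feature_names, mdl.coefficients):
            table[i, col[f]] = int(c)
    index = [f"model_{i}" for i in range(len(fbm.models))]
    return pd.DataFrame(table, index=index, columns=features)


def feature_class_stats(m: AbundanceMatrix, y: SampleTarget,
                        features) -> pd.DataFrame:
    """Prevalence (overall and per class) and abundance-shift test per feature.

    Prevalence is the fraction of samples where the feature is detected
    (abundance > 0); the shift test is a two-sided Mann-Whitney with the
    enrichment direction given by the class with the greater mean rank.
    """
    if y.kind != "binary_class":
        raise ValidationError("class statistics require a binary target")
    mask = y.positive_mask()
    pos_label = y.resolved_positive()
    neg_label = [c for c in y.classes if c != pos_label][0]
    rows = []
    for f in features:
        x = m.values[m.feature_index(f)]
        xa, xb = x[mask], x[~mask]
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.mannwhitneyu(xa, xb, alternative="two-sided",
                                     method="asymptotic")
        p = 1.0 if math.isnan(res.pvalue) else float(res.pvalue)
        effect = float(res.statistic) / (len(xa) * len(xb))
        rows.append({
            "feature": f,
            "prevalence": float((x > 0).mean()),
            f"prevalence_{pos_label}": float((xa > 0).mean()),
            f"prevalence_{neg_label}": float((xb > 0).mean()),
            "mw_p": p,
            "direction": pos_label if effect >= 0.5 else neg_label,
        })
    return pd.DataFrame(rows)


def cooccurrence_network(fbm: FBM, top_fraction: float = 0.05) -> pd.DataFrame:
    """Feature co-presence network over the FBM incidence table.

    Edge weight is the phi coefficient (Pearson correlation of 0/1 presence
    vectors) of the two features across FBM models; positive weight means
    co-presence (complementarity), negative weight mutual exclusion
    (redundancy).  Only the ``top_fraction`` strongest edges by |weight| are
    retained (default 5%, at least one edge), ties broken by the name pair.
    Constant presence columns are excluded with a warning.
    """
    if not 0 < top_fraction <= 1:
        raise ValidationError("top_fraction must lie in (0, 1]")
    table = model_feature_table(fbm)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValidationError("the network needs >= 2 models and >= 2 features")
    presence = (table.to_numpy() != 0).astype(float)
    keep = []
    for j, f in enumerate(table.columns):
        if presence[:, j].std() == 0:
            warnings.warn(f"feature {f!r} has constant presence across models; "
                          "excluded from the network")
        else:
            keep.append(j)
    if len(keep) < 2:
        raise ValidationError("fewer than 2 non-constant features")
    sub = presence[:, keep]
    names = [table.columns[j] for j in keep]
    corr = np.corrcoef(sub, rowvar=False)
    edges = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            w = float(corr[i, j])
            edges.append({"source": names[i], "target": names[j],
                          "weight": w, "sign": 1 if w >= 0 else -1})
    edges.sort(key=lambda e: (-abs(e["weight"]), e["source"], e["target"]))
    n_keep = max(1, math.ceil(top_fraction * len(edges)))
    return pd.DataFrame(edges[:n_keep]).reset_index(drop=True)


def data_vs_model_correlation(m: AbundanceMatrix, fbm: FBM,
                              edges: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per edge: feature correlation in the data vs presence phi in the models.

    The scatter of these pairs shows replacement structure: feature pairs
    highly correlated in the data tend *not* to co-occur in models (one
    stands in for the other).
    """
    if edges is None:
        edges = cooccurrence_network(fbm, top_fraction=1.0)
    table = model_feature_table(fbm)
    presence = (table.to_numpy() != 0).astype(float)
    col = {f: j for j, f in enumerate(table.columns)}
    rows = []
    for _, e in edges.iterrows():
        fa, fb = e["source"], e["target"]
        for f in (fa, fb):
            if f not in col:
                raise ValidationError(f"edge ({fa}, {fb}): feature {f!r} "
                                      "absent from the FBM")
            try:
                m.feature_index(f)
            except KeyError:
                raise ValidationError(f"edge ({fa}, {fb}): feature {f!r} "
                                      "absent from the data matrix") from None
        xa = m.values[m.feature_index(fa)]
        xb = m.values[m.feature_index(fb)]
        data_r = float(np.corrcoef(xa, xb)[0, 1]) if xa.std() > 0 and xb.std() > 0 \
            else 0.0
        pa, pb = presence[:, col[fa]], presence[:, col[fb]]
        model_phi = float(np.corrcoef(pa, pb)[0, 1]) \
            if pa.std() > 0 and pb.std() > 0 else 0.0
        rows.append({"source": fa, "target": fb,
                     "data_correlation": data_r, "model_correlation": model_phi})
    return pd.DataFrame(rows)


def write_edges(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False, float_format="%.10g")


def node_attributes(fbm: FBM, m: AbundanceMatrix, y: SampleTarget,
                    mda: pd.DataFrame | None = None) -> pd.DataFrame:
    """Node table (feature, prevalence, direction, optional MDA) for graph tools."""
    stats_tab = feature_class_stats(m, y, fbm.feature_names)
    if mda is not None:
        stats_tab = stats_tab.merge(mda[["feature", "mda", "sem"]],
                                    on="feature", how="left")
    return stats_tab
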