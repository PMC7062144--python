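"""Synthetic compositional abundance data with planted BTR structure.

The generator emulates the statistical shape of shotgun relative-abundance
tables: per-feature log-normal abundances (heavy tails, orders-of-magnitude
spread between features), zero-inflation from a detection threshold, and
per-sample closure to sum 1.  Log-normal-plus-closure is used rather than a
Dirichlet because it gives independent control of per-feature location and
dispersion while producing the sparse, skewed profiles typical of real
profiles.  It deliberately does not emulate taxonomy, phylogenetic
correlation or batch effects.

Labels are planted by a known BTR model whose decision the learners must
recover, optionally corrupted by independent label flips; continuous targets
are an affine function of the planted model's score plus Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data_io import AbundanceMatrix, SampleTarget, ValidationError
from .models import BTRModel, make_model, optimize_threshold, score_samples


@dataclass
class PlantedModel:
    """Description of the ground-truth model: language, features, signs, cut.

    ``threshold=None`` plants the cut at the median score, which balances the
    classes.
    """

    language: str = "bin"
    feature_indices: tuple[int, ...] = (0, 1, 2)
    coefficients: tuple[int, ...] | None = None  # default: all +1
    threshold: float | None = None

    def resolved_coefficients(self) -> tuple[int, ...]:
        if self.coefficients is not None:
            return tuple(self.coefficients)
        return tuple(1 for _ in self.feature_indices)


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    Defaults describe a mid-sized case/control shotgun cohort: 300 samples,
    100 features, per-feature log-means spread with SD 1.5 (several orders of
    magnitude between rare and dominant features), within-feature log-SD 1.0,
    30% zeros from a detection threshold, a planted 3-feature bin signal and
    5% label noise.
    """

    n_samples: int = 300
    p_features: int = 100
    log_mean_scale: float = 1.5  # SD of per-feature log-means
    log_sd: float = 1.0          # within-feature SD on the log scale
    sparsity: float = 0.3        # fraction of entries zeroed (detection quantile)
    planted_model: PlantedModel = field(default_factory=PlantedModel)
    label_noise: float = 0.05    # independent flip probability
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 2 or self.p_features < 1:
            raise ValidationError("need n_samples >= 2 and p_features >= 1")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValidationError("label_noise must lie in [0, 0.5)")
        if not 0.0 <= self.sparsity < 1.0:
            raise ValidationError("sparsity must lie in [0, 1)")
        bad = [i for i in self.planted_model.feature_indices
               if not 0 <= i < self.p_features]
        if bad:
            raise ValidationError(f"planted features out of range: {bad}")


def _streams(spec: SyntheticSpec) -> list[np.random.Generator]:
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(spec.seed).spawn(3)]


def generate_abundance(spec: SyntheticSpec) -> AbundanceMatrix:
    """Log-normal draw, detection-threshold zeroing, per-sample closure."""
    rng = _streams(spec)[0]
    p, n = spec.p_features, spec.n_samples
    mu = rng.normal(0.0, spec.log_mean_scale, size=p)
    x = np.exp(mu[:, None] + spec.log_sd * rng.standard_normal((p, n)))
    if spec.sparsity > 0:
        cut = np.quantile(x, spec.sparsity)
        zero = x < cut
        # never silence a whole sample: keep each column's largest entry
        zero[np.argmax(x, axis=0), np.arange(n)] = False
        x = np.where(zero, 0.0, x)
    x = x / x.sum(axis=0)
    feature_ids = [f"feat_{i:04d}" for i in range(p)]
    sample_ids = [f"sample_{j:04d}" for j in range(n)]
    return AbundanceMatrix(x, feature_ids, sample_ids, scale="relative")


def planted_btr_model(m: AbundanceMatrix, spec: SyntheticSpec) -> BTRModel:
    """Instantiate the planted model against a generated matrix."""
    pm = spec.planted_model
    mdl = make_model(pm.language, pm.feature_indices,
                     pm.resolved_coefficients(), m,
                     positive_label="pos", negative_label="neg")
    thr = pm.threshold
    if thr is None:
        thr = float(np.median(score_samples(mdl, m)))
    return replace(mdl, threshold=thr, direction="score_greater")


def plant_labels(m: AbundanceMatrix, spec: SyntheticSpec) -> SampleTarget:
    """Labels from the planted model's decision, then independent flips.

    Labels are "pos"/"neg" with positive_class="pos".  If the planted cut
    degenerates (a single predicted class), the threshold is re-drawn at the
    score median with a warning.
    """
    import warnings

    rng = _streams(spec)[1]
    mdl = planted_btr_model(m, spec)
    scores = score_samples(mdl, m)
    pos = scores > mdl.threshold
    if pos.all() or not pos.any():
        warnings.warn("planted threshold predicts a single class; "
                      "re-drawing the cut at the score median")
        mdl = replace(mdl, threshold=float(np.median(scores)))
        pos = scores > mdl.threshold
        if pos.all() or not pos.any():  # all scores identical
            pos = np.zeros(m.n_samples, dtype=bool)
            pos[: m.n_samples // 2] = True
    if spec.label_noise > 0:
        flips = rng.random(m.n_samples) < spec.label_noise
        pos = pos ^ flips
    labels = np.where(pos, "pos", "neg")
    return SampleTarget(list(m.sample_ids), "binary_class", labels,
                        positive_class="pos")


def generate_regression_target(m: AbundanceMatrix, spec: SyntheticSpec,
                               alpha: float = 1.0, beta: float = 0.0,
                               noise_sd: float = 0.0) -> SampleTarget:
    """Continuous target y = alpha * planted score + beta + Gaussian noise."""
    rng = _streams(spec)[2]
    mdl = planted_btr_model(m, spec)
    scores = score_samples(mdl, m)
    y = alpha * scores + beta
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=m.n_samples)
    return SampleTarget(list(m.sample_ids), "continuous", y)


def generate_dataset(spec: SyntheticSpec) -> tuple[AbundanceMatrix, SampleTarget]:
    """Convenience: abundance matrix plus planted binary labels."""
    m = generate_abundance(spec)
    return m, plant_labels(m, spec)
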