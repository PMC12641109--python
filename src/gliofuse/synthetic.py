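"""Synthetic study material: ellipsoid-tumor mpMRI phantoms and
class-conditional Gaussian feature cohorts with known Bayes-optimal AUC.

The phantom emulates a curated, co-registered glioma scan: a homogeneous
brain background of intensity 100 with an ellipsoidal tumor whose
tumor-to-background contrast differs per modality, plus additive Gaussian
noise. The feature generator emulates per-subject 5x400 deep-feature tables:
features are independent unit-variance Gaussians and the methylated class is
shifted on an informative subset so the between-class Mahalanobis distance
per branch is exactly the configured effect size — which pins the
Bayes-optimal AUC at Phi(delta / sqrt(2)) and makes recovery testable
analytically.

Every generator fans one global seed out to per-subject substreams, so
subject i's data does not depend on the cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .features import BRANCHES, N_BRANCHES, Cohort
from .preprocessing import Modality, MRIVolume, SegmentationMask

BACKGROUND_INTENSITY = 100.0

#: modalities of the four acquired phantom channels, in branch order minus delta
PHANTOM_MODALITIES = (Modality.T1, Modality.T1WCE, Modality.T2, Modality.FLAIR)


@dataclass
class PhantomConfig:
    """Geometry and contrast of one synthetic subject.

    ``modality_contrasts`` are tumor-to-background intensity ratios for
    (T1, T1wCE, T2, FLAIR); the T1wCE default exceeds T1 so the delta image
    carries genuine enhancement signal.
    """

    grid_shape: tuple[int, int, int] = (240, 240, 150)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tumor_center: tuple[float, float, float] = (120.0, 120.0, 75.0)
    tumor_radii: tuple[float, float, float] = (20.0, 15.0, 10.0)
    modality_contrasts: tuple[float, float, float, float] = (0.8, 1.6, 1.3, 1.4)
    noise_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if any(int(g) <= 0 for g in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        if any(r <= 0 for r in self.tumor_radii):
            raise ValueError("tumor radii must be positive")
        if len(self.modality_contrasts) != len(PHANTOM_MODALITIES):
            raise ValueError("need one contrast per modality")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def ellipsoid_mask(grid_shape, center, radii) -> np.ndarray:
    """Binary mask of { x : sum_i ((x_i - c_i) / r_i)^2 <= 1 } on the voxel grid."""
    axes = np.ogrid[tuple(slice(0, int(n)) for n in grid_shape)]
    q = sum(((ax - c) / r) ** 2 for ax, c, r in zip(axes, center, radii))
    return (q <= 1.0).astype(np.uint8)


def generate_phantom_subject(config: PhantomConfig):
    """One phantom subject: four modality volumes plus the shared tumor mask.

    Each modality is ``background * contrast`` inside the tumor, background
    outside, plus N(0, noise_sd^2) noise from a modality-specific substream.
    Deterministic given ``config.seed``.
    """
    config.validate()
    mask = ellipsoid_mask(config.grid_shape, config.tumor_center, config.tumor_radii)
    if not mask.any():
        raise ValueError("empty mask: tumor lies entirely outside the grid")
    streams = np.random.SeedSequence(config.seed).spawn(len(PHANTOM_MODALITIES))
    volumes: dict[Modality, MRIVolume] = {}
    for modality, contrast, stream in zip(PHANTOM_MODALITIES,
                                          config.modality_contrasts, streams):
        data = np.full(config.grid_shape, BACKGROUND_INTENSITY, dtype=np.float64)
        data[mask == 1] = BACKGROUND_INTENSITY * contrast
        if config.noise_sd > 0:
            rng = np.random.Generator(np.random.PCG64(stream))
            data += rng.normal(0.0, config.noise_sd, size=config.grid_shape)
        volumes[modality] = MRIVolume(data, config.spacing_mm, modality)
    return volumes, SegmentationMask(mask)


@dataclass
class FeatureCohortConfig:
    """Statistical design of a synthetic deep-feature cohort.

    ``effect_size`` is the per-branch between-class Mahalanobis separation;
    with independent unit-variance features the Bayes-optimal AUC of branch b
    alone is ``Phi(effect_size[b] / sqrt(2))``. ``informative_fraction`` of
    the features per branch carry the shift (spread evenly: each informative
    feature is shifted by effect / sqrt(k) for k informative features).
    ``prevalence_methylated`` defaults to a balanced internal cohort; the
    external cohort in this problem domain runs around 0.75 methylated.
    """

    n_subjects: int = 585
    prevalence_methylated: float = 0.5
    n_features: int = 400
    effect_size: tuple[float, ...] = (0.0,) * N_BRANCHES
    informative_fraction: float = 0.025
    cross_network_ccc: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0.0 < self.prevalence_methylated < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if len(self.effect_size) != N_BRANCHES:
            raise ValueError(f"effect_size needs {N_BRANCHES} entries")
        if any(e < 0 for e in self.effect_size):
            raise ValueError("effect_size must be non-negative")
        if not 0.0 <= self.informative_fraction <= 1.0:
            raise ValueError("informative_fraction must lie in [0, 1]")
        if self.n_informative == 0 and any(e > 0 for e in self.effect_size):
            raise ValueError("unachievable effect: informative_fraction is 0 "
                             "but a nonzero effect size was requested")
        if not -1.0 <= self.cross_network_ccc <= 1.0:
            raise ValueError("cross_network_ccc must lie in [-1, 1]")

    @property
    def n_informative(self) -> int:
        return int(round(self.informative_fraction * self.n_features))


def bayes_auc(effect_size: float) -> float:
    """AUC of the optimal classifier for two unit-variance Gaussians a
    Mahalanobis distance ``effect_size`` apart: Phi(delta / sqrt(2))."""
    return float(norm.cdf(effect_size / np.sqrt(2.0)))


def _subject_shift(config: FeatureCohortConfig) -> np.ndarray:
    """Per-branch additive mean shift applied to methylated subjects."""
    k = config.n_informative
    shift = np.zeros((N_BRANCHES, config.n_features))
    if k > 0:
        for b, eff in enumerate(config.effect_size):
            shift[b, :k] = eff / np.sqrt(k)
    return shift


def generate_feature_cohort(config: FeatureCohortConfig,
                            name: str = "synthetic") -> Cohort:
    """Draw a labeled cohort under the configured class-conditional model.

    Labels are Bernoulli(prevalence); class-0 features are N(0, 1) i.i.d.;
    class-1 features add the informative mean shift. The first
    ``n_informative`` feature columns of every branch are the informative
    ones (a fixed, documented convention).
    """
    config.validate()
    shift = _subject_shift(config)
    streams = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    X = np.empty((config.n_subjects, N_BRANCHES, config.n_features))
    y = np.empty(config.n_subjects, dtype=np.int64)
    for i, stream in enumerate(streams):
        rng = np.random.Generator(np.random.PCG64(stream))
        label = int(rng.random() < config.prevalence_methylated)
        feats = rng.standard_normal((N_BRANCHES, config.n_features))
        if label:
            feats = feats + shift
        X[i] = feats
        y[i] = label
    ids = [f"syn-{i:04d}" for i in range(config.n_subjects)]
    return Cohort(ids, X, y, name=name, extractor_id="synthetic")


def generate_paired_network_tables(config: FeatureCohortConfig):
    """Two feature tables with a controlled per-feature concordance.

    Each feature column of the pair is drawn from a bivariate normal with
    equal means and variances and correlation ``cross_network_ccc``; with
    equal marginal moments Lin's concordance coefficient equals the Pearson
    correlation, so the population CCC is exactly the configured target.

    Returns ``(table_a, table_b)`` of shape (n_subjects, n_features) each.
    """
    config.validate()
    rho = config.cross_network_ccc
    streams = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    a = np.empty((config.n_subjects, config.n_features))
    b = np.empty_like(a)
    scale = np.sqrt(max(0.0, 1.0 - rho * rho))
    for i, stream in enumerate(streams):
        rng = np.random.Generator(np.random.PCG64(stream))
        ai = rng.standard_normal(config.n_features)
        eps = rng.standard_normal(config.n_features)
        a[i] = ai
        b[i] = rho * ai + scale * eps
    return a, b


@dataclass
class _ExternalDefaults:
    """Convenience presets mirroring the study's two cohorts."""

    internal: FeatureCohortConfig = field(
        default_factory=lambda: FeatureCohortConfig(n_subjects=585,
                                                    prevalence_methylated=0.5))
    external: FeatureCohortConfig = field(
        default_factory=lambda: FeatureCohortConfig(n_subjects=81,
                                                    prevalence_methylated=0.75))


COHORT_PRESETS = _ExternalDefaults()
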