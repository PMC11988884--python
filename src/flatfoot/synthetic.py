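"""Synthetic foot-radiograph and feature-table generators.

Real lateral weight-bearing foot radiographs cannot be redistributed, so
tests and examples run on a parametric stand-in: a bright foot-like
silhouette with a heel-to-midfoot band inclined at a controllable "arch
angle". The clinical labeling rule is emulated directly — an angle below
18 degrees means a collapsed arch (``pes_planus``), above it
``not_pes_planus`` — so the label is a deterministic function of the
drawn angle and the image's discriminative signal is exactly the band's
slope. Realism is a non-goal; controllable difficulty (angle separation,
pixel noise) is the point.

Patients are first-class: each patient draws one true angle, every image
of that patient shares it up to a small render jitter, and all of a
patient's images carry the same label. This is what makes patient-grouped
cross-validation meaningful on the synthetic data.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidConfigError, InvalidInputError
from .samples import NOT_PES_PLANUS, PES_PLANUS, ImageSample

__all__ = ["SyntheticConfig", "render_foot", "gen_dataset",
           "gen_feature_clusters"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition knobs of the generator.

    Defaults: 60 patients with 2 images each (a reduced-scale cohort of
    the two-per-patient acquisition pattern), 224px frames, the 18-degree
    diagnostic threshold, class angle means at 10 and 26 degrees with a
    3-degree patient-to-patient spread, 0.5-degree per-image render
    jitter, and mild Gaussian pixel noise.
    """

    n_patients: int = 60
    images_per_patient: int = 2
    image_size: int = 224
    angle_threshold: float = 18.0
    class_angle_means: tuple[float, float] = (10.0, 26.0)  # (pes, not-pes)
    angle_sd: float = 3.0
    jitter_sd: float = 0.5
    noise_sd: float = 0.02
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1 or self.images_per_patient < 1:
            raise InvalidConfigError("counts must be positive")
        if self.image_size < 8:
            raise InvalidConfigError("image_size too small to render")
        if not 0.0 < self.class_balance < 1.0:
            raise InvalidConfigError("class_balance must be in (0, 1)")
        lo, hi = self.class_angle_means
        if not lo < self.angle_threshold < hi:
            raise InvalidConfigError(
                "class angle means must straddle angle_threshold")
        if self.angle_sd < 0 or self.noise_sd < 0:
            raise InvalidConfigError("spreads must be >= 0")


def render_foot(angle: float, config: SyntheticConfig,
                seed: int | None = None) -> np.ndarray:
    """Render one grayscale frame whose arch band is inclined at ``angle``.

    The frame contains a dim elliptical foot silhouette and a bright band
    running from the heel (lower left) toward the midfoot, rising at
    ``angle`` degrees above horizontal, plus clipped Gaussian pixel noise.
    Deterministic given ``(angle, seed)``.
    """
    if not 0.0 < angle < 90.0:
        raise InvalidInputError(f"angle {angle} outside (0, 90) degrees")
    s = config.image_size
    rng = np.random.default_rng(config.seed if seed is None else seed)
    cols, rows = np.meshgrid(np.arange(s), np.arange(s))
    x = cols.astype(np.float64)
    y = (s - 1 - rows).astype(np.float64)          # y axis points up

    img = np.full((s, s), 0.05)

    # foot silhouette: ellipse low in the frame
    ex, ey = 0.50 * s, 0.30 * s
    silhouette = ((x - ex) / (0.42 * s)) ** 2 + ((y - ey) / (0.20 * s)) ** 2 <= 1.0
    img[silhouette] = 0.45

    # arch band: from the heel toward the midfoot at the given inclination
    hx, hy = 0.12 * s, 0.22 * s
    rad = np.deg2rad(angle)
    ux, uy = np.cos(rad), np.sin(rad)
    t = (x - hx) * ux + (y - hy) * uy              # along-band coordinate
    d = np.abs(-(x - hx) * uy + (y - hy) * ux)     # perpendicular distance
    band = (d <= max(1.5, 0.015 * s)) & (t >= 0) & (t <= 0.55 * s)
    img[band] = 0.95

    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def label_for_angle(angle: float, threshold: float = 18.0) -> str:
    """The diagnostic rule: arch angle below the threshold means flat foot."""
    return PES_PLANUS if angle < threshold else NOT_PES_PLANUS


def gen_dataset(config: SyntheticConfig) -> list[ImageSample]:
    """Generate the full labeled cohort.

    Each patient draws a class (Bernoulli ``class_balance``), then a true
    arch angle from that class's Gaussian; the label is re-derived from
    the drawn angle against the threshold, so it is always consistent with
    what the images show. All of a patient's images render that angle with
    independent ``jitter_sd`` perturbations and independent pixel noise.
    """
    root = np.random.SeedSequence(config.seed)
    mean_pes, mean_not = config.class_angle_means
    samples: list[ImageSample] = []
    for p, child in enumerate(root.spawn(config.n_patients)):
        rng = np.random.default_rng(child)
        is_pes = rng.random() < config.class_balance
        mean = mean_pes if is_pes else mean_not
        angle = float(np.clip(rng.normal(mean, config.angle_sd), 1.0, 89.0))
        label = label_for_angle(angle, config.angle_threshold)
        pid = f"P{p:04d}"
        for j in range(config.images_per_patient):
            render_angle = float(np.clip(angle + rng.normal(0, config.jitter_sd),
                                         1.0, 89.0))
            img_seed = int(rng.integers(2 ** 31))
            pixels = render_foot(render_angle, config, seed=img_seed)
            samples.append(ImageSample(
                pixels=pixels, label=label, patient_id=pid,
                meta={"angle": angle, "render_angle": render_angle,
                      "image_index": j}))
    return samples


def gen_feature_clusters(n: int, d: int, separation: float, seed: int = 0):
    """Two unit-noise Gaussian feature clusters, balanced labels.

    Cluster centers sit at ``+/- separation / 2`` along one random unit
    direction, so ``separation`` is the between-center distance in noise
    units (Bayes error ~ Phi(-separation / 2)). Returns
    ``(features, labels, patient_ids)``; each row is its own patient.
    """
    if n % 2:
        raise InvalidInputError("n must be even for balanced classes")
    if d < 1:
        raise InvalidConfigError("d must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.normal(size=d)
    u /= np.linalg.norm(u)
    half = n // 2
    labels = np.array([PES_PLANUS] * half + [NOT_PES_PLANUS] * half)
    signs = np.r_[np.ones(half), -np.ones(half)]
    X = rng.normal(size=(n, d)) + np.outer(signs * separation / 2.0, u)
    order = rng.permutation(n)
    pids = np.array([f"S{i:05d}" for i in range(n)])
    return X[order], list(labels[order]), list(pids[order])
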