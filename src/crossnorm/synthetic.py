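"""Paired two-platform expression generator with known DEG/NDEG ground truth.

The generator emulates the structure of a cross-platform tumor-subtype
cohort: two platforms measure the same samples; a shared class-dependent
signal lives in a planted DEG subset; the remaining genes carry no class
effect (NDEG-like); platform B additionally applies a monotone distortion
(by default a power-law, i.e. a gain factor in log space) and carries a few
platform-exclusive samples; class sizes are severely imbalanced
(default 231:8, ~29:1 largest:smallest, per platform).

Model: per-gene latent log2 expression ~ Normal(8, 2^2); each planted DEG
adds a shift of magnitude effect_size * noise_sd to one carrier class (drawn
among classes with at least ``min_carrier_class_size`` samples, random sign);
each platform observes latent + Normal(0, noise_sd^2) with independent noise
and exponentiates to the linear scale.  A small fraction of entries is set
missing to exercise the cleaning path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from crossnorm.core_io import DataError, ExpressionMatrix, SubtypeLabels

DEFAULT_CLASS_NAMES = ("Basal", "Her2", "LumA", "LumB", "Normal")
DEFAULT_CLASS_SIZES = (96, 58, 231, 127, 8)
DEFAULT_SEED = 20240225


@dataclass
class SyntheticDesign:
    """Knobs of the generator; defaults mirror the benchmark cohort's structure."""

    n_genes: int = 1000
    n_deg: int = 100
    class_sizes: tuple[int, ...] = DEFAULT_CLASS_SIZES
    class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES
    n_extra_b: int = 2          # platform-B-exclusive samples of class_names[0]
    effect_size: float = 2.0    # class-mean shift in within-class-SD units
    platform_distortion: tuple = ("power", 1.3)  # ("power", g) | ("affine", a, b) | ("none",)
    noise_sd: float = 1.0
    dropout_rate: float = 1e-4  # fraction of entries set missing, pre-cleaning
    min_carrier_class_size: int = 20
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_deg > self.n_genes:
            raise DataError("n_deg must not exceed n_genes")
        if len(self.class_sizes) != len(self.class_names):
            raise DataError("class_sizes and class_names lengths differ")
        if any(s < 1 for s in self.class_sizes):
            raise DataError("class_sizes must all be >= 1")
        if not (0 <= self.dropout_rate < 1):
            raise DataError("dropout_rate must be in [0,1)")
        if self.platform_distortion[0] not in ("power", "affine", "none"):
            raise DataError(f"unknown distortion {self.platform_distortion!r}")


@dataclass
class GroundTruth:
    deg_gene_ids: list[str]
    ndeg_gene_ids: list[str]
    labels: dict[str, str]
    shared_sample_ids: list[str] = field(default_factory=list)
    exclusive_b_sample_ids: list[str] = field(default_factory=list)


def _distort_log(log_values: np.ndarray, distortion) -> np.ndarray:
    kind = distortion[0]
    if kind == "none":
        return log_values
    if kind == "power":  # v -> v**g on the linear scale == g*log(v) in log space
        return distortion[1] * log_values
    if kind == "affine":  # a*log(v) + b in log space
        return distortion[1] * log_values + distortion[2]
    raise DataError(f"unknown distortion {distortion!r}")


def generate(design: SyntheticDesign):
    """Draw one paired dataset.

    Returns ``(platform_a, platform_b, labels, truth)``: two linear-scale
    :class:`ExpressionMatrix` objects (platforms tagged ``"microarray"`` and
    ``"rnaseq"``), the labels covering every sample of either platform, and
    the planted ground truth.  Identical design + seed gives bitwise-identical
    output.
    """
    rng = np.random.default_rng(design.seed)
    g, k = design.n_genes, len(design.class_sizes)
    gene_ids = [f"G{i:05d}" for i in range(g)]

    deg_idx = np.sort(rng.choice(g, size=design.n_deg, replace=False))
    eligible = [c for c, s in enumerate(design.class_sizes) if s >= design.min_carrier_class_size]
    if design.n_deg and not eligible:
        raise DataError("no class large enough to carry a planted effect")
    baseline = rng.normal(8.0, 2.0, size=g)
    delta = np.zeros((g, k))
    if design.n_deg:
        carriers = rng.choice(eligible, size=design.n_deg)
        signs = rng.choice([-1.0, 1.0], size=design.n_deg)
        delta[deg_idx, carriers] = signs * design.effect_size * design.noise_sd

    n_shared = int(sum(design.class_sizes))
    shared_ids = [f"S{i:04d}" for i in range(n_shared)]
    class_idx = np.repeat(np.arange(k), design.class_sizes)
    extra_ids = [f"SB{i:04d}" for i in range(design.n_extra_b)]
    labels_map = {s: design.class_names[c] for s, c in zip(shared_ids, class_idx)}
    labels_map.update({s: design.class_names[0] for s in extra_ids})

    latent = baseline[:, None] + delta[:, class_idx]  # g x n_shared
    latent_extra = np.tile((baseline + delta[:, 0])[:, None], (1, design.n_extra_b))

    def _noisy(base: np.ndarray) -> np.ndarray:
        if design.noise_sd == 0:
            return base.copy()
        return base + rng.normal(0.0, design.noise_sd, size=base.shape)

    log_a = _noisy(latent)
    log_b = _distort_log(
        np.concatenate([_noisy(latent), _noisy(latent_extra)], axis=1),
        design.platform_distortion,
    )
    lin_a = np.exp2(log_a)
    lin_b = np.exp2(log_b)

    if design.dropout_rate > 0:
        lin_a[rng.random(lin_a.shape) < design.dropout_rate] = np.nan
        lin_b[rng.random(lin_b.shape) < design.dropout_rate] = np.nan

    platform_a = ExpressionMatrix(
        pd.DataFrame(lin_a, index=gene_ids, columns=shared_ids), platform="microarray"
    )
    platform_b = ExpressionMatrix(
        pd.DataFrame(lin_b, index=gene_ids, columns=shared_ids + extra_ids), platform="rnaseq"
    )
    labels = SubtypeLabels.from_mapping(labels_map, class_order=design.class_names)
    deg_set = set(deg_idx.tolist())
    truth = GroundTruth(
        deg_gene_ids=[gene_ids[i] for i in sorted(deg_set)],
        ndeg_gene_ids=[gid for i, gid in enumerate(gene_ids) if i not in deg_set],
        labels=labels_map,
        shared_sample_ids=shared_ids,
        exclusive_b_sample_ids=extra_ids,
    )
    return platform_a, platform_b, labels, truth
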