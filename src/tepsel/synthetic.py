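"""Synthetic labeled expression matrices with known informative genes.

The generator emulates the statistical shape the downstream pipeline
assumes: a gene-by-sample matrix of non-negative RNA-seq-like counts over
seven classes (six cancer subtypes plus healthy controls by default), a
configurable subset of genes whose class-conditional mean is shifted in
exactly one class, and a subset of near-universally-zero genes that the
low-expression filter must remove.

Counts are negative-binomial, sampled as a gamma-Poisson mixture: each
gene g has a baseline mean mu_g drawn from a broad log-normal, shared
overdispersion ``dispersion`` (variance mu + dispersion * mu^2), and an
informative gene's mean is multiplied by exp(effect_size) in its assigned
class.  Zero-inflated genes have every entry independently zeroed with
probability 0.95, so almost all of them exceed a 90%-zero filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import gse68086_class_sizes
from .mrmr import RankedFeatureList

logger = logging.getLogger(__name__)

# probability that an entry of a zero-inflated gene is forced to zero
_ZERO_INFLATION_P = 0.95
# baseline log-mean distribution of counts: median ~20 reads, broad spread
_LOG_MU_MEAN = 3.0
_LOG_MU_SD = 1.5


class ConfigurationError(ValueError):
    """Raised for an invalid synthetic-data configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic cohort.

    Defaults mirror the published 285-sample platelet cohort shape: its
    seven class sizes and a gene count of order 10^4.
    """

    class_sizes: dict[str, int] = field(default_factory=gse68086_class_sizes)
    n_genes: int = 10_000
    n_informative: int = 100
    effect_size: float = 1.0
    dispersion: float = 0.3
    zero_gene_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if not self.class_sizes or any(s <= 0 for s in self.class_sizes.values()):
            raise ConfigurationError("class_sizes must be positive")
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if not 0 <= self.n_informative <= self.n_genes:
            raise ConfigurationError("need 0 <= n_informative <= n_genes")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be non-negative")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive")
        if not 0 <= self.zero_gene_fraction <= 1:
            raise ConfigurationError("zero_gene_fraction must be in [0, 1]")

    @property
    def n_samples(self) -> int:
        return sum(self.class_sizes.values())


@dataclass(frozen=True)
class GroundTruth:
    """Which genes carry signal, and in which class each is shifted."""

    informative_genes: frozenset[str]
    class_of_effect: dict[str, str]


def generate_expression(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Sample one labeled cohort.

    Returns ``(matrix, labels, truth)``: a genes x samples count DataFrame,
    a sample -> class Series, and the ground truth of planted signal.
    Identical config (including seed) gives bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    gene_ids = np.array([f"G{i:05d}" for i in range(config.n_genes)])
    classes = list(config.class_sizes)
    labels = pd.Series(
        np.repeat(classes, [config.class_sizes[c] for c in classes]),
        index=[f"S{i:04d}" for i in range(config.n_samples)],
        name="class",
    )

    mu = rng.lognormal(_LOG_MU_MEAN, _LOG_MU_SD, size=config.n_genes)
    mean = np.tile(mu[:, None], (1, config.n_samples))

    # informative genes: multiplicative shift exp(effect_size) in one class,
    # assigned round-robin so every class carries signal
    informative = gene_ids[: config.n_informative]
    class_of_effect: dict[str, str] = {}
    for i, g in enumerate(informative):
        cls = classes[i % len(classes)]
        class_of_effect[g] = cls
        mean[i, (labels == cls).to_numpy()] *= np.exp(config.effect_size)

    # gamma-Poisson == negative binomial with var = mu + dispersion * mu^2
    shape = 1.0 / config.dispersion
    lam = rng.gamma(shape, mean / shape)
    counts = rng.poisson(lam).astype(float)

    # zero-inflated block: taken from the tail so it never overlaps the
    # informative block
    n_zero = int(round(config.zero_gene_fraction * config.n_genes))
    if n_zero > config.n_genes - config.n_informative:
        n_zero = config.n_genes - config.n_informative
    if n_zero:
        drop = rng.random((n_zero, config.n_samples)) < _ZERO_INFLATION_P
        counts[config.n_genes - n_zero :][drop] = 0.0

    matrix = pd.DataFrame(counts, index=gene_ids, columns=labels.index)
    truth = GroundTruth(frozenset(informative), class_of_effect)
    logger.info(
        "generated %d genes x %d samples (%d informative, %d zero-inflated)",
        config.n_genes, config.n_samples, config.n_informative, n_zero,
    )
    return matrix, labels, truth


def ground_truth_ranks(truth: GroundTruth, ranked: RankedFeatureList) -> list[int]:
    """1-based positions of the informative genes in a ranked list, ascending.

    Raises ``KeyError`` if an informative gene is missing from the list.
    """
    pos = {g: i + 1 for i, g in enumerate(ranked.features)}
    missing = truth.informative_genes - pos.keys()
    if missing:
        raise KeyError(f"informative genes absent from ranked list: {sorted(missing)[:5]}")
    return sorted(pos[g] for g in truth.informative_genes)


def write_labels_table(labels: pd.Series, path) -> None:
    """Write a two-column TSV (sample ID, class), no header."""
    labels.rename("class").rename_axis("sample").to_csv(path, sep="\t", header=False)
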