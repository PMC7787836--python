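"""Synthetic multi-platform expression data with planted informative gene pairs.

Emulates the statistical structure the gene-pair pipeline assumes: two classes
(malignant = 1, benign = 0) that differ only in the expected *ordering* of a
set of informative gene pairs, samples spread across platforms that each apply
their own strictly increasing transform to a whole sample, additive Gaussian
noise, and a configurable (heavily imbalanced by default) class mix.

For an informative pair (a, b) the latent means satisfy
mean(a) - mean(b) = +delta in class 1 and -delta in class 0; every other gene
has a class-independent mean drawn once per roster.  Observed expression is
the per-sample platform transform (x -> scale*x + shift, then log1p when the
platform is log-scaled) applied uniformly to all genes of the sample,
optionally followed by gene-wise multiplicative jitter — a deliberate
stress-test knob that *breaks* the within-sample monotonicity the pair
features rely on (default 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PlatformSpec",
    "SimConfig",
    "SyntheticTruth",
    "SimConfigError",
    "simulate_dataset",
    "write_fixture",
    "DEFAULT_PLATFORMS",
]

MAX_GENES = 923  # size of the cross-platform immune-gene roster being emulated


class SimConfigError(ValueError):
    """Invalid simulation configuration; the message names the offending field."""


@dataclass(frozen=True)
class PlatformSpec:
    """One platform's sample-uniform transform: x -> scale*x + shift [-> log1p]."""

    name: str
    scale: float = 1.0
    shift: float = 0.0
    log_transform: bool = False

    def apply(self, x: np.ndarray) -> np.ndarray:
        y = self.scale * x + self.shift
        if self.log_transform:
            if (y <= -1.0).any():
                raise SimConfigError(
                    f"platforms: log platform {self.name!r} received values <= -1; "
                    "raise `shift` or reduce `sigma`"
                )
            y = np.log1p(y)
        return y


DEFAULT_PLATFORMS = (
    PlatformSpec("rnaseq", scale=1.0, shift=0.0, log_transform=False),
    PlatformSpec("array_a", scale=2.5, shift=10.0, log_transform=False),
    PlatformSpec("array_log", scale=1.5, shift=20.0, log_transform=True),
)


@dataclass(frozen=True)
class SimConfig:
    n_samples: int
    prevalence: float = 0.858
    n_genes: int = 200
    n_informative_pairs: int = 30
    delta: float = 3.0
    sigma: float = 1.0
    platforms: tuple[PlatformSpec, ...] = DEFAULT_PLATFORMS
    gene_distortion: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise SimConfigError(f"n_samples must be >= 1, got {self.n_samples}")
        if not 0.0 < self.prevalence < 1.0:
            raise SimConfigError(f"prevalence must lie in (0, 1), got {self.prevalence}")
        if not 2 <= self.n_genes <= MAX_GENES:
            raise SimConfigError(f"n_genes must lie in [2, {MAX_GENES}], got {self.n_genes}")
        if not 1 <= self.n_informative_pairs <= self.n_genes // 2:
            raise SimConfigError(
                f"n_informative_pairs must lie in [1, floor(n_genes/2)={self.n_genes // 2}], "
                f"got {self.n_informative_pairs}"
            )
        if self.delta <= 0:
            raise SimConfigError(f"delta must be > 0, got {self.delta}")
        if self.sigma < 0:
            raise SimConfigError(f"sigma must be >= 0, got {self.sigma}")
        if self.gene_distortion < 0:
            raise SimConfigError(f"gene_distortion must be >= 0, got {self.gene_distortion}")
        if not self.platforms:
            raise SimConfigError("platforms must be non-empty")
        for ps in self.platforms:
            if ps.scale <= 0:
                raise SimConfigError(f"platforms: scale must be > 0 for {ps.name!r}, got {ps.scale}")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated dataset, for recovery tests."""

    labels: np.ndarray  # (n_samples,) int, 1 = malignant
    platform_of: pd.Series  # sample id -> platform name
    informative_pairs: list[tuple[str, str]]  # (geneA, geneB): A > B in class 1
    latent: pd.DataFrame = field(repr=False, default=None)  # pre-platform expression


def _gene_names(n: int) -> list[str]:
    return [f"IRG{k:04d}" for k in range(1, n + 1)]


def simulate_dataset(config: SimConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a genes x samples expression DataFrame plus its ground truth.

    Deterministic for a fixed seed; independent substreams are used for
    labels, gene means, pair placement, noise, platform assignment and
    distortion, so e.g. changing sigma does not reshuffle the labels.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_labels, rng_means, rng_pairs, rng_noise, rng_platform, rng_distort = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    n, g = config.n_samples, config.n_genes
    genes = _gene_names(g)
    samples = [f"S{k:05d}" for k in range(1, n + 1)]

    labels = (rng_labels.random(n) < config.prevalence).astype(int)

    # class-independent baseline means, drawn once per roster
    base_means = rng_means.uniform(4.0, 8.0, size=g)

    # plant informative pairs on disjoint genes
    perm = rng_pairs.permutation(g)
    pair_pos = [(perm[2 * k], perm[2 * k + 1]) for k in range(config.n_informative_pairs)]
    informative_pairs = [(genes[a], genes[b]) for a, b in pair_pos]

    means = np.tile(base_means[:, None], (1, n)).astype(float)
    half = config.delta / 2.0
    for a, b in pair_pos:
        center = (base_means[a] + base_means[b]) / 2.0
        sign = np.where(labels == 1, 1.0, -1.0)  # a > b in class 1, a < b in class 0
        means[a, :] = center + sign * half
        means[b, :] = center - sign * half

    latent = means + rng_noise.normal(0.0, config.sigma, size=(g, n))

    platform_names = [ps.name for ps in config.platforms]
    assignment = rng_platform.integers(0, len(config.platforms), size=n)
    observed = np.empty_like(latent)
    for p_idx, ps in enumerate(config.platforms):
        cols = assignment == p_idx
        if cols.any():
            observed[:, cols] = ps.apply(latent[:, cols])

    if config.gene_distortion > 0:
        # gene-by-platform multiplicative jitter: breaks within-sample monotonicity
        mult = np.exp(rng_distort.normal(0.0, config.gene_distortion, size=(g, len(config.platforms))))
        observed = observed * mult[:, assignment]

    expr = pd.DataFrame(observed, index=genes, columns=samples)
    truth = SyntheticTruth(
        labels=labels,
        platform_of=pd.Series([platform_names[k] for k in assignment], index=samples, name="platform"),
        informative_pairs=informative_pairs,
        latent=pd.DataFrame(latent, index=genes, columns=samples),
    )
    return expr, truth


def write_fixture(expr: pd.DataFrame, truth: SyntheticTruth, directory) -> dict[str, Path]:
    """Write expression / labels / platforms / pair-registry TSVs.

    Round-trips exactly through the package's own readers (full float repr).
    """
    if expr.empty:
        raise ValueError("refusing to write an empty expression matrix")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "labels": directory / "labels.tsv",
        "platforms": directory / "platforms.tsv",
        "pairs": directory / "pair_registry.tsv",
        "roster": directory / "roster.txt",
    }
    out = expr.copy()
    out.index.name = "gene"
    out.to_csv(paths["expression"], sep="\t", float_format="%.17g")
    pd.DataFrame({"sample": expr.columns, "label": truth.labels}).to_csv(
        paths["labels"], sep="\t", index=False
    )
    truth.platform_of.rename_axis("sample").to_frame().to_csv(paths["platforms"], sep="\t")
    pd.DataFrame(
        [{"geneA": a, "geneB": b, "class1_orientation": 1} for a, b in truth.informative_pairs]
    ).to_csv(paths["pairs"], sep="\t", index=False)
    paths["roster"].write_text("\n".join(expr.index) + "\n")
    return paths
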