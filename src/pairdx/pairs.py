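"""Within-sample gene-pair binarization and correlation-based pair selection.

The featurization is a top-scoring-pair style rank transform: for every
unordered pair of roster genes (gene I, gene II) with I before II in the
roster, a sample scores 1 iff its expression of gene I strictly exceeds that
of gene II, otherwise 0 (ties score 0).  Because the indicator depends only on
the within-sample ordering of two genes, it is invariant to any strictly
increasing transform applied uniformly to a sample — which is what makes
samples from different expression platforms directly comparable without
normalisation or batch correction.

Pair selection correlates each binary pair feature with the binary
malignant/benign label (the phi coefficient, i.e. Pearson on two binaries) and
retains pairs with |r| above a threshold and a two-sided t-test P value below
a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairIndex",
    "PairFeatureMatrix",
    "FilterResult",
    "make_pair_index",
    "score_pairs",
    "filter_pairs",
    "restrict_to",
]


@dataclass(frozen=True)
class PairIndex:
    """All unordered gene pairs over a roster, lexicographic by roster position."""

    genes: tuple[str, ...]
    pairs: np.ndarray  # (m, 2) int array of roster positions, i < j

    def __len__(self) -> int:
        return len(self.pairs)

    def pair_names(self) -> list[tuple[str, str]]:
        return [(self.genes[i], self.genes[j]) for i, j in self.pairs]

    def subset(self, positions) -> "PairIndex":
        return PairIndex(self.genes, self.pairs[np.asarray(positions)])


@dataclass
class PairFeatureMatrix:
    """Samples x pairs binary indicator matrix with its pair index."""

    samples: tuple[str, ...]
    pair_index: PairIndex
    values: np.ndarray  # (n_samples, n_pairs) uint8 in {0, 1}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.samples), len(self.pair_index)):
            raise ValueError(
                f"feature matrix shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.pair_index)} pairs"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("pair features must be strictly binary")

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{a}>{b}" for a, b in self.pair_index.pair_names()]
        return pd.DataFrame(self.values, index=list(self.samples), columns=cols)


@dataclass
class FilterResult:
    """Correlation filter output over a PairIndex."""

    retained: np.ndarray  # positions into the tested pair index
    r: np.ndarray
    p: np.ndarray
    r_threshold: float = 0.4
    p_threshold: float = 0.05
    n_tested: int = 0

    def retained_pairs(self, idx: PairIndex) -> pd.DataFrame:
        names = idx.pair_names()
        return pd.DataFrame(
            [
                {"geneI": names[k][0], "geneII": names[k][1], "r": self.r[k], "p": self.p[k]}
                for k in self.retained
            ]
        )


def make_pair_index(roster) -> PairIndex:
    """All C(n, 2) unordered pairs in lexicographic roster order."""
    genes = tuple(str(g) for g in roster)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to form pairs")
    if len(set(genes)) != len(genes):
        dupes = sorted({g for g in genes if genes.count(g) > 1})
        raise ValueError(f"duplicate gene symbols in roster: {dupes[:5]}")
    i, j = np.triu_indices(len(genes), k=1)
    return PairIndex(genes, np.column_stack([i, j]))


def score_pairs(expr: pd.DataFrame, idx: PairIndex) -> PairFeatureMatrix:
    """Binarize expression into pair indicators: 1 iff gene I > gene II.

    ``expr`` is genes x samples.  Ties and gene I < gene II both score 0, so
    the output is invariant to strictly increasing within-sample transforms.
    """
    missing = [g for g in idx.genes if g not in expr.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing[:5]}")
    vals = expr.loc[list(idx.genes)].to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("expression matrix contains NaN values")
    scores = (vals[idx.pairs[:, 0], :] > vals[idx.pairs[:, 1], :]).T.astype(np.uint8)
    return PairFeatureMatrix(tuple(expr.columns), idx, scores)


def filter_pairs(
    feat: PairFeatureMatrix,
    labels,
    r_threshold: float = 0.4,
    p_threshold: float = 0.05,
    signed: bool = False,
) -> FilterResult:
    """Retain pairs correlated with the class label.

    r is the Pearson correlation of each binary feature with the binary label
    (the phi coefficient); P comes from the two-sided t test
    t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom.  Zero-variance
    features get r = 0, p = 1 and are never retained.  By default the
    threshold applies to |r| (both pair orientations are informative);
    ``signed=True`` applies it to signed r instead.
    """
    y = np.asarray(labels, dtype=float)
    X = feat.values.astype(float)
    n = len(y)
    if X.shape[0] != n:
        raise ValueError(f"{X.shape[0]} feature rows vs {n} labels")
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class; correlation undefined")

    xm = X.mean(axis=0)
    ym = y.mean()
    cov = (X * y[:, None]).mean(axis=0) - xm * ym
    var_x = xm * (1.0 - xm)  # binary feature variance
    var_y = ym * (1.0 - ym)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / np.sqrt(var_x * var_y)
    degenerate = var_x <= 0
    r = np.where(degenerate, 0.0, r)
    r = np.clip(r, -1.0, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p = np.where(degenerate, 1.0, p)

    # degenerate features carry r=0, p=1 and so fail any useful threshold;
    # they are only retained in the deliberate retain-everything case
    stat = r if signed else np.abs(r)
    retained = np.flatnonzero((stat >= r_threshold) & (p < p_threshold))
    return FilterResult(retained, r, p, r_threshold, p_threshold, n_tested=len(feat.pair_index))


def restrict_to(feat: PairFeatureMatrix, result: FilterResult) -> PairFeatureMatrix:
    """Subset a feature matrix to the retained pairs (training-set vocabulary).

    The selection is positional, so a filter computed on training samples is
    reusable verbatim on held-out samples featurized over the same PairIndex.
    """
    if result.n_tested != len(feat.pair_index):
        raise ValueError(
            f"filter was computed over {result.n_tested} pairs but matrix has {len(feat.pair_index)}"
        )
    if len(result.retained) == 0:
        raise ValueError("empty feature set: no pairs passed the filter")
    return PairFeatureMatrix(
        feat.samples,
        feat.pair_index.subset(result.retained),
        feat.values[:, result.retained],
    )
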