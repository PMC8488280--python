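"""Binary within-sample gene-pair features (relative expression ordering).

A pair (g1, g2) scores 0 for a sample when g1 is expressed more than g2 and 1
otherwise (ties score 1).  Because the score depends only on the within-sample
order of two genes, it is invariant to any strictly increasing transform of a
sample's expression values — the property that makes the features comparable
across platforms without normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io_cohorts import ExpressionMatrix

__all__ = [
    "GenePair",
    "PairMatrix",
    "make_pair",
    "enumerate_pairs",
    "pair_score",
    "build_pair_matrix",
    "filter_informative_pairs",
    "write_pair_matrix",
    "read_pair_matrix",
]


class GenePair(NamedTuple):
    """An unordered gene pair in canonical (lexicographic) order."""

    gene1: str
    gene2: str

    @property
    def label(self) -> str:
        return f"{self.gene1}|{self.gene2}"


def make_pair(a: str, b: str) -> GenePair:
    if a == b:
        raise ValueError(f"a pair needs two distinct genes, got {a!r} twice")
    return GenePair(a, b) if a < b else GenePair(b, a)


def enumerate_pairs(genes) -> list[GenePair]:
    """All unordered pairs of the given genes, canonically ordered.

    The listing order is deterministic: lexicographic over the sorted gene
    list, giving G(G-1)/2 pairs.
    """
    unique = sorted(set(genes))
    if len(unique) < 2:
        raise ValueError(f"need >=2 unique genes, got {len(unique)}")
    return [GenePair(a, b) for a, b in combinations(unique, 2)]


def pair_score(expr1: float, expr2: float) -> int:
    """0 if the first gene is expressed more than the second, else 1."""
    if not (np.isfinite(expr1) and np.isfinite(expr2)):
        raise ValueError(f"non-finite expression values ({expr1}, {expr2})")
    return 0 if expr1 > expr2 else 1


@dataclass
class PairMatrix:
    """0/1 pair scores, pairs in rows, samples in columns."""

    pairs: list[GenePair]
    sample_ids: list[str]
    cohort_labels: np.ndarray  # one label per sample
    scores: np.ndarray  # shape (n_pairs, n_samples), values in {0, 1}

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.uint8)
        if self.scores.shape != (len(self.pairs), len(self.sample_ids)):
            raise ValueError("scores shape does not match pairs x samples")
        if not np.isin(self.scores, (0, 1)).all():
            raise ValueError("pair scores must all be 0 or 1")
        self.cohort_labels = np.asarray(self.cohort_labels, dtype=object)
        if self.cohort_labels.shape != (len(self.sample_ids),):
            raise ValueError("need one cohort label per sample")

    def select(self, pairs: list[GenePair]) -> "PairMatrix":
        index = {p: i for i, p in enumerate(self.pairs)}
        rows = [index[p] for p in pairs]
        return PairMatrix(
            list(pairs), self.sample_ids, self.cohort_labels, self.scores[rows]
        )

    def hstack(self, other: "PairMatrix") -> "PairMatrix":
        if self.pairs != other.pairs:
            raise ValueError("pair lists differ")
        return PairMatrix(
            self.pairs,
            self.sample_ids + other.sample_ids,
            np.concatenate([self.cohort_labels, other.cohort_labels]),
            np.hstack([self.scores, other.scores]),
        )


def build_pair_matrix(
    expr: ExpressionMatrix | pd.DataFrame,
    pairs: list[GenePair],
    cohort_labels=None,
) -> PairMatrix:
    """Score every pair on every sample of an expression matrix.

    ``expr`` may be a single-cohort :class:`ExpressionMatrix` (cohort labels
    are taken from it) or a merged genes x samples frame with explicit
    per-sample ``cohort_labels``.
    """
    if isinstance(expr, ExpressionMatrix):
        data = expr.data
        if cohort_labels is None:
            cohort_labels = [expr.cohort_id] * data.shape[1]
    else:
        data = expr
        if cohort_labels is None:
            raise ValueError("cohort_labels required for a plain DataFrame")
    gene_index = {g: i for i, g in enumerate(data.index)}
    missing = sorted({g for p in pairs for g in p if g not in gene_index})
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing}")
    values = data.to_numpy(dtype=float)
    i1 = np.array([gene_index[p.gene1] for p in pairs])
    i2 = np.array([gene_index[p.gene2] for p in pairs])
    scores = (values[i1] <= values[i2]).astype(np.uint8)
    return PairMatrix(list(pairs), list(data.columns), cohort_labels, scores)


def filter_informative_pairs(
    pm: PairMatrix,
    mode: str = "per_cohort",
    min_minority_freq: float | None = None,
) -> list[GenePair]:
    """Drop pairs with a constant score vector, guarding against platform bias.

    ``mode='per_cohort'`` (default) excludes a pair that is constant within
    any single cohort — the strict reading of the rule, which is what makes
    the surviving features robust across platforms.  ``mode='pooled'``
    excludes only pairs constant across the pooled sample set.  The optional
    ``min_minority_freq`` additionally drops pairs whose rarer score occurs in
    less than that fraction of all samples (off by default).
    """
    if mode not in ("per_cohort", "pooled"):
        raise ValueError(f"unknown mode {mode!r}")
    scores = pm.scores
    if mode == "per_cohort":
        keep = np.ones(len(pm.pairs), dtype=bool)
        for cohort in pd.unique(pm.cohort_labels):
            cols = pm.cohort_labels == cohort
            if cols.sum() < 2:
                raise ValueError(
                    f"cohort {cohort!r} has {int(cols.sum())} sample(s); "
                    "constancy is undefined below 2"
                )
            sub = scores[:, cols]
            keep &= sub.min(axis=1) != sub.max(axis=1)
    else:
        if scores.shape[1] < 2:
            raise ValueError("constancy is undefined below 2 samples")
        keep = scores.min(axis=1) != scores.max(axis=1)
    if min_minority_freq is not None:
        ones = scores.mean(axis=1)
        keep &= np.minimum(ones, 1 - ones) >= min_minority_freq
    return [p for p, k in zip(pm.pairs, keep) if k]


def write_pair_matrix(pm: PairMatrix, path) -> None:
    frame = pd.DataFrame(
        pm.scores, index=[p.label for p in pm.pairs], columns=pm.sample_ids
    )
    frame.to_csv(path, sep="\t", index_label="pair_id")


def read_pair_matrix(path, cohort_labels) -> PairMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    pairs = [make_pair(*label.split("|")) for label in frame.index]
    return PairMatrix(pairs, list(frame.columns), cohort_labels, frame.to_numpy())
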