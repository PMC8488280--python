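"""Cohort I/O: expression matrices, clinical tables, harmonization and splitting.

Expression files are tab-separated text with genes in rows: first column holds
the gene symbol (header ``gene_id``), remaining columns are samples.  Clinical
tables are CSV with the columns ``sample_id,time_days,event,age,stage,sex,
cohort_id``; tumor stage is accepted as ``I``/``II`` or ``1``/``2`` and stored
as the coded integer (I=1, II=2).  No cross-sample normalization is assumed or
performed anywhere: downstream pair features depend only on within-sample gene
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CohortCollection",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "harmonize_genes",
    "merge_split",
    "filter_excluded",
]

CLINICAL_COLUMNS = ("time_days", "event", "age", "stage", "sex", "cohort_id")

_STAGE_CODES = {"I": 1, "II": 2, "1": 1, "2": 2, 1: 1, 2: 2}


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix for one cohort.

    Values are on an arbitrary platform scale (log or linear); only their
    within-sample ordering matters to the pair features built on top.
    """

    cohort_id: str
    data: pd.DataFrame  # index: gene ids, columns: sample ids

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r} in cohort {self.cohort_id!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r} in cohort {self.cohort_id!r}")
        if self.data.shape[0] < 2 or self.data.shape[1] < 1:
            raise ValueError(
                f"cohort {self.cohort_id!r} needs >=2 genes and >=1 sample, "
                f"got shape {self.data.shape}"
            )
        values = self.data.to_numpy(dtype=float, copy=False)
        if not np.all(np.isfinite(values)):
            gi, si = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at gene {self.data.index[gi]!r}, "
                f"sample {self.data.columns[si]!r} in cohort {self.cohort_id!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def restrict_genes(self, genes: list[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes absent from cohort {self.cohort_id!r}: {missing}")
        return ExpressionMatrix(self.cohort_id, self.data.loc[genes])

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.cohort_id, self.data[sample_ids])


@dataclass
class CohortCollection:
    """One or more expression cohorts joined with a clinical table.

    Every expression sample must have exactly one clinical record.  After
    :func:`harmonize_genes` all cohorts share an identical gene list, which is
    required by :meth:`merged_expression`.
    """

    cohorts: list[ExpressionMatrix]
    clinical: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        if not self.cohorts:
            raise ValueError("collection needs at least one cohort")
        seen: set[str] = set()
        for cm in self.cohorts:
            for s in cm.sample_ids:
                if s in seen:
                    raise ValueError(f"sample {s!r} appears in more than one cohort")
                seen.add(s)
        if self.clinical.index.has_duplicates:
            dup = self.clinical.index[self.clinical.index.duplicated()][0]
            raise ValueError(f"duplicate clinical record for sample {dup!r}")
        missing = seen - set(self.clinical.index)
        if missing:
            raise ValueError(
                f"samples without clinical records: {sorted(missing)[:5]}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return [s for cm in self.cohorts for s in cm.sample_ids]

    @property
    def cohort_labels(self) -> np.ndarray:
        return np.array(
            [cm.cohort_id for cm in self.cohorts for _ in cm.sample_ids], dtype=object
        )

    @property
    def n_samples(self) -> int:
        return sum(len(cm.sample_ids) for cm in self.cohorts)

    def merged_expression(self) -> pd.DataFrame:
        """Genes x all-samples matrix; requires harmonized (identical) gene sets."""
        genes = self.cohorts[0].gene_ids
        for cm in self.cohorts[1:]:
            if cm.gene_ids != genes:
                raise ValueError(
                    "cohorts are not harmonized; call harmonize_genes first"
                )
        return pd.concat([cm.data for cm in self.cohorts], axis=1)

    def clinical_in_order(self) -> pd.DataFrame:
        return self.clinical.loc[self.sample_ids]

    def subset(self, sample_ids: set[str]) -> "CohortCollection":
        cohorts = []
        for cm in self.cohorts:
            keep = [s for s in cm.sample_ids if s in sample_ids]
            if keep:
                cohorts.append(cm.subset_samples(keep))
        kept = [s for cm in cohorts for s in cm.sample_ids]
        return CohortCollection(cohorts, self.clinical.loc[kept])


def read_expression(path, cohort_id: str) -> ExpressionMatrix:
    """Parse a tab-separated expression file (genes in rows).

    Duplicate gene symbols are collapsed by arithmetic mean.  Any cell that
    does not parse as a finite number (including ``NA``) is a hard error that
    names the offending gene and sample; no imputation is performed.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        dup = next(s for i, s in enumerate(samples) if s in samples[:i])
        raise ValueError(f"duplicate sample id {dup!r} in {path}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    probe = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = ~np.isfinite(probe.to_numpy(dtype=float))
    if bad.any():
        gi, si = np.argwhere(bad)[0]
        raise ValueError(
            f"non-numeric cell {raw.iloc[gi, si]!r} at gene {raw.index[gi]!r}, "
            f"sample {raw.columns[si]!r} in {path}"
        )
    # numpy's string->float conversion is correctly rounded (pd.to_numeric
    # is not), so parse the validated cells through astype for exact round-trips
    numeric = pd.DataFrame(
        raw.to_numpy().astype(float), index=raw.index, columns=raw.columns
    )
    if numeric.index.has_duplicates:
        first_seen = numeric.index[~numeric.index.duplicated()]
        numeric = numeric.groupby(level=0, sort=False).mean().loc[first_seen]
    return ExpressionMatrix(cohort_id, numeric)


def write_expression(em: ExpressionMatrix, path) -> None:
    # %.17g guarantees read->write->read round-trips to the exact float
    em.data.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical CSV, validate it and code tumor stage as I=1, II=2."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValueError(f"clinical table {path} lacks a sample_id column")
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table {path} lacks columns {missing}")
    df = df.set_index("sample_id")
    return validate_clinical(df)


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    try:
        df["stage"] = [
            _STAGE_CODES[s if not isinstance(s, str) else s.strip()]
            for s in df["stage"]
        ]
    except KeyError as exc:
        raise ValueError(
            f"stage {exc.args[0]!r} not recognised (allowed: I, II, 1, 2); "
            "this pipeline is restricted to early-stage disease"
        ) from None
    if not (df["time_days"] > 0).all():
        raise ValueError("all survival times must be positive")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0 or 1")
    if not df["sex"].isin(["female", "male"]).all():
        raise ValueError("sex must be 'female' or 'male'")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate clinical record for sample {dup!r}")
    return df


def write_clinical(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index_label="sample_id")


def harmonize_genes(cohorts: list[ExpressionMatrix]) -> list[ExpressionMatrix]:
    """Restrict every cohort to the genes detected in all of them.

    The shared gene list keeps the order of the first cohort, so the output is
    deterministic and identical across cohorts.  Idempotent.
    """
    if not cohorts:
        raise ValueError("need at least one cohort")
    common = set(cohorts[0].gene_ids)
    for cm in cohorts[1:]:
        common &= set(cm.gene_ids)
    if len(common) < 2:
        raise ValueError(
            f"gene intersection across cohorts has {len(common)} genes; need >=2"
        )
    ordered = [g for g in cohorts[0].gene_ids if g in common]
    return [cm.restrict_genes(ordered) for cm in cohorts]


def merge_split(
    collection: CohortCollection, ratio: float, seed: int
) -> tuple[CohortCollection, CohortCollection]:
    """Randomly partition the merged samples into training/testing collections.

    The split is plain uniform (no stratification), reproducible for a fixed
    seed, and preserves each sample's cohort label — the cross-cohort
    constancy filter needs it downstream.
    """
    if not 0 < ratio < 1:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    samples = np.array(collection.sample_ids, dtype=object)
    n_train = int(round(ratio * len(samples)))
    n_train = min(max(n_train, 1), len(samples) - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(samples))
    train_ids = set(samples[perm[:n_train]])
    test_ids = set(samples[perm[n_train:]])
    return collection.subset(train_ids), collection.subset(test_ids)


def filter_excluded(
    collection: CohortCollection, column: str = "excluded"
) -> CohortCollection:
    """Drop samples flagged in a boolean clinical metadata column (e.g. patients
    who received neoadjuvant/adjuvant therapy).  No-op if the column is absent."""
    if column not in collection.clinical.columns:
        return collection
    keep = set(collection.clinical.index[~collection.clinical[column].astype(bool)])
    return collection.subset(keep)
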