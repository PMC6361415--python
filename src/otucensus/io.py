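"""Readers and writers for the tabular formats used throughout the census pipeline.

All on-disk tables are UTF-8 TSV with a mandatory header row; lines starting
with ``#`` are treated as comments (and are also used to carry small pieces of
metadata, such as the number of sampling units of a frequency-count table).
Results are serialized as JSON records carrying the method name, parameters,
seed and estimate, so that stochastic runs can be reproduced exactly.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("otucensus")

__all__ = [
    "SampleCountTable",
    "Hit",
    "HitTable",
    "ResultRecord",
    "read_sample_counts",
    "write_sample_counts",
    "write_study_map",
    "read_frequency_counts",
    "write_frequency_counts",
    "read_hit_table",
    "write_result",
]


class TableFormatError(ValueError):
    """Raised when an input table is malformed (never silently coerced)."""


@dataclass
class SampleCountTable:
    """OTU-by-sample read counts plus the sample-to-study assignment.

    ``counts`` is an integer DataFrame indexed by OTU id with one column per
    sample; ``study_of_sample`` maps every sample to exactly one study.
    """

    counts: pd.DataFrame
    study_of_sample: dict[str, str]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dup = c.index[c.index.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate OTU identifiers: {dup[:5]}")
        if c.columns.has_duplicates:
            dup = c.columns[c.columns.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate sample identifiers: {dup[:5]}")
        if not all(np.issubdtype(dt, np.integer) for dt in c.dtypes):
            raise TableFormatError("read counts must be integers")
        if (c.to_numpy() < 0).any():
            r, s = np.argwhere(c.to_numpy() < 0)[0]
            raise TableFormatError(
                f"negative count at OTU {c.index[r]!r}, sample {c.columns[s]!r}"
            )
        missing = [s for s in c.columns if s not in self.study_of_sample]
        if missing:
            raise TableFormatError(f"samples without a study assignment: {missing[:5]}")
        # keep only mapped samples that actually occur in the table
        self.study_of_sample = {s: self.study_of_sample[s] for s in c.columns}

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def study_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.counts.columns:
            seen.setdefault(self.study_of_sample[s], None)
        return list(seen)

    def samples_of_study(self, study: str) -> list[str]:
        return [s for s in self.counts.columns if self.study_of_sample[s] == study]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def n_studies(self) -> int:
        return len(set(self.study_of_sample.values()))

    @property
    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    def subset_otus(self, otus: Sequence[str]) -> "SampleCountTable":
        return SampleCountTable(self.counts.loc[list(otus)], dict(self.study_of_sample))


@dataclass(frozen=True)
class Hit:
    query_id: str
    subject_id: str
    percent_identity: float
    taxonomy: tuple[str, ...]


@dataclass
class HitTable:
    """Alignment hits grouped by query, sorted by descending percent identity."""

    groups: dict[str, list[Hit]]

    @property
    def query_ids(self) -> list[str]:
        return list(self.groups)


@dataclass
class ResultRecord:
    """Serializable record of one analysis result."""

    method: str
    estimate: float | None
    se: float | None = None
    parameters: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.estimate is not None:
            if not math.isfinite(self.estimate) or self.estimate < 0:
                raise ValueError(f"point estimate must be finite and >= 0, got {self.estimate}")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "estimate": self.estimate,
            "se": self.se,
            "parameters": self.parameters,
            "diagnostics": self.diagnostics,
            "seed": self.seed,
        }


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", **kwargs)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise TableFormatError(f"malformed TSV {path}: {exc}") from exc


def read_sample_counts(path: str | Path, study_map_path: str | Path) -> SampleCountTable:
    """Read an OTU-by-sample count TSV plus a two-column sample->study map.

    The count table has a header row of sample ids and OTU ids in the first
    column.  Samples present in the counts but missing from the study map are
    an error; study-map entries for unknown samples are ignored.
    """
    df = _read_tsv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    def _intlike(v) -> bool:
        try:
            return pd.notna(v) and float(v).is_integer()
        except (TypeError, ValueError):
            return False

    for col in df.columns:
        vals = df[col]
        if not np.issubdtype(vals.dtype, np.integer):
            bad = vals[~vals.apply(_intlike)]
            if len(bad):
                raise TableFormatError(
                    f"non-integer count at OTU {bad.index[0]!r}, sample {col!r} in {path}"
                )
            df[col] = vals.astype(np.int64)
    neg = df.lt(0)
    if neg.to_numpy().any():
        r = neg.any(axis=1).idxmax()
        c = neg.loc[r].idxmax()
        raise TableFormatError(f"negative count at OTU {r!r}, sample {c!r} in {path}")

    smap = _read_tsv(study_map_path, dtype=str)
    if smap.shape[1] < 2:
        raise TableFormatError(f"study map {study_map_path} needs >=2 columns")
    study_of_sample = dict(zip(smap.iloc[:, 0], smap.iloc[:, 1]))
    return SampleCountTable(df.astype(np.int64), study_of_sample)


def write_sample_counts(table: SampleCountTable, path: str | Path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="otu_id")


def write_study_map(table: SampleCountTable, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(table.study_of_sample),
         "study_id": list(table.study_of_sample.values())}
    ).to_csv(path, sep="\t", index=False)


def read_frequency_counts(path: str | Path, n_units: int | None = None):
    """Read incidence frequency counts Q_i from TSV.

    Two layouts are accepted:

    * a two-column ``(i, Q_i)`` table with strictly increasing ``i >= 1``; the
      number of sampling units T is taken from a ``# T=<int>`` comment line or
      from *n_units*;
    * a wide binary OTU-by-unit matrix (first column OTU ids), from which the
      counts are tallied directly (T = number of unit columns).

    Missing indices are filled with Q_i = 0.
    """
    from .richness import FrequencyCounts, IncidenceMatrix, frequency_counts

    header_T = None
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip().replace(" ", "")
                if stripped.upper().startswith("T="):
                    header_T = int(stripped[2:])
            elif line.strip():
                ncols = len(line.rstrip("\n").split("\t"))
                break
        else:
            ncols = 2

    if ncols > 2:  # OTU-by-unit incidence matrix layout
        df = _read_tsv(path, index_col=0)
        vals = df.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise TableFormatError(f"incidence matrix {path} must be binary")
        m = IncidenceMatrix(df.astype(np.int8))
        return frequency_counts(m)

    df = _read_tsv(path)
    T = n_units if n_units is not None else header_T
    if T is None:
        raise TableFormatError(f"{path}: number of sampling units T not declared")
    q = np.zeros(T, dtype=np.int64)
    if df.shape[0]:
        idx = df.iloc[:, 0].to_numpy()
        counts = df.iloc[:, 1].to_numpy()
        seen: set[int] = set()
        for i, qi in zip(idx, counts):
            i = int(i)
            if i in seen:
                raise TableFormatError(f"{path}: duplicate frequency index i={i}")
            seen.add(i)
            if i < 1 or i > T:
                raise TableFormatError(f"{path}: frequency index i={i} outside 1..T={T}")
            if qi < 0:
                raise TableFormatError(f"{path}: negative count Q_{i}={qi}")
            q[i - 1] = int(qi)
    return FrequencyCounts(q=q, n_units=T)


def write_frequency_counts(fc, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"# T={fc.n_units}\n")
        fh.write("i\tQ_i\n")
        for i, qi in enumerate(fc.q, start=1):
            if qi:
                fh.write(f"{i}\t{int(qi)}\n")


def read_hit_table(path: str | Path) -> HitTable:
    """Read a BLAST outfmt-6-style hit TSV with an appended taxonomy column.

    Expected columns: query_id, subject_id, percent_identity, taxonomy (a
    semicolon-delimited path, domain first).  Extra columns are ignored.
    Rows are grouped by query and sorted by descending identity.
    """
    df = _read_tsv(path, dtype={0: str, 1: str})
    if df.shape[1] < 4:
        raise TableFormatError(f"hit table {path} needs >=4 columns")
    groups: dict[str, list[Hit]] = {}
    for row in df.itertuples(index=False):
        q, s, ident, tax = str(row[0]), str(row[1]), float(row[2]), str(row[3])
        if not (0.0 <= ident <= 100.0):
            raise TableFormatError(f"identity {ident} outside [0,100] for query {q!r}")
        path_parts = tuple(p.strip() for p in tax.split(";") if p.strip())
        if not path_parts:
            raise TableFormatError(f"empty taxonomy path for query {q!r}")
        groups.setdefault(q, []).append(Hit(q, s, ident, path_parts))
    for q in groups:
        groups[q].sort(key=lambda h: -h.percent_identity)
    return HitTable(groups)


def write_result(record: ResultRecord, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        json.dump(record.to_dict(), fh, indent=2)
        fh.write("\n")


def setup_logging(level: int = logging.INFO) -> None:
    """Configure package logging to standard error."""
    h = logging.StreamHandler()
    h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [h]
    logger.setLevel(level)
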