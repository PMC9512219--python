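"""Reading, validating and aligning count tables and survival metadata.

The raw observable is a sample-by-taxon table of non-negative integer read
counts.  Survival metadata supplies, per sample, the observed follow-up time
``U_i = min(T_i, C_i)``, the event indicator ``Delta_i`` and any confounding
covariates to adjust for.  Everything downstream (transforms, residual
regressions, distance tests) consumes the aligned containers defined here.

Library sizes are the row sums of the *full* table; prevalence filtering
drops columns but deliberately keeps the original library sizes, so that
relative abundances always mean "count divided by total reads sequenced for
that sample".
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "SurvivalOutcome",
    "Covariates",
    "read_count_table",
    "read_biom_table",
    "read_metadata",
    "filter_rare_taxa",
    "write_count_table",
    "write_results",
]


class FormatError(ValueError):
    """Malformed input file (non-integer counts, negative entries, ...)."""


class AlignmentError(ValueError):
    """Sample IDs do not match between the count table and the metadata."""


@dataclass
class CountTable:
    """Integer sample-by-taxon count matrix with IDs and library sizes.

    ``library_sizes`` are the per-sample totals of the table the object was
    *constructed* from; :func:`filter_rare_taxa` keeps them fixed while
    dropping columns.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray  # (n, J) non-negative integers
    library_sizes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.rint(self.counts).astype(np.int64)
            if not np.allclose(self.counts, as_int):
                raise FormatError("counts must be integers")
            self.counts = as_int
        if (self.counts < 0).any():
            raise FormatError("counts must be non-negative")
        n, J = self.counts.shape
        if n < 2 or J < 1:
            raise ValueError(f"need n >= 2 samples and J >= 1 taxa, got {n}x{J}")
        if len(self.sample_ids) != n or len(self.taxon_ids) != J:
            raise ValueError("ID lengths do not match the count matrix")
        for name, ids in (("sample", self.sample_ids), ("taxon", self.taxon_ids)):
            if len(set(ids)) != len(ids):
                raise FormatError(f"duplicate {name} IDs")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=1)
        self.library_sizes = np.asarray(self.library_sizes, dtype=np.int64)
        if (self.library_sizes <= 0).any():
            bad = [self.sample_ids[i] for i in np.where(self.library_sizes <= 0)[0]]
            raise ValueError(f"zero library size for samples {bad}")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)


@dataclass
class SurvivalOutcome:
    """Observed times and event indicators, aligned to a count table."""

    time: np.ndarray  # (n,) positive reals, U_i
    event: np.ndarray  # (n,) in {0, 1}, Delta_i

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        if self.time.shape != self.event.shape or self.time.ndim != 1:
            raise ValueError("time and event must be 1-D and the same length")
        if (self.time <= 0).any():
            raise ValueError("all observed times must be positive")
        ev = np.unique(self.event)
        if not np.isin(ev, [0, 1]).all():
            raise ValueError(f"event indicators must be 0/1, found {ev}")
        self.event = self.event.astype(np.int64)
        if self.event.sum() == 0:
            raise ValueError("no events observed; a Cox fit would be degenerate")

    @property
    def n(self) -> int:
        return self.time.shape[0]


@dataclass
class Covariates:
    """Confounder matrix X (no intercept column), optionally centered."""

    X: np.ndarray  # (n, p), p >= 0
    names: list[str]
    centered: bool = False

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.size == 0:
            self.X = self.X.reshape(self.X.shape[0] if self.X.ndim == 2 else 0, 0)
        if self.X.shape[1] != len(self.names):
            raise ValueError("covariate names do not match the matrix")
        if np.isnan(self.X).any():
            raise ValueError("missing covariate values are not supported")
        if self.centered and self.X.shape[1] and np.abs(self.X.mean(axis=0)).max() > 1e-10:
            raise ValueError("centered flag set but column means are nonzero")

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def center(self) -> "Covariates":
        if self.p == 0:
            return replace(self, centered=True)
        return Covariates(self.X - self.X.mean(axis=0), list(self.names), centered=True)

    @classmethod
    def empty(cls, n: int) -> "Covariates":
        return cls(np.empty((n, 0)), [], centered=True)


def _read_delimited(path, delimiter=None) -> pd.DataFrame:
    if delimiter is None:
        delimiter = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=delimiter, index_col=0)


def read_count_table(path, orientation: str = "samples-in-rows",
                     delimiter: str | None = None) -> CountTable:
    """Read a delimited count table; canonical orientation is samples-in-rows."""
    if orientation not in ("samples-in-rows", "taxa-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_delimited(path, delimiter)
    if orientation == "taxa-in-rows":
        df = df.T
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError(f"non-numeric entries in {path}")
    if (values < 0).any():
        raise FormatError(f"negative counts in {path}")
    return CountTable(
        sample_ids=[str(s) for s in df.index],
        taxon_ids=[str(t) for t in df.columns],
        counts=values,
    )


def read_biom_table(path) -> CountTable:
    """Read a BIOM v1 (JSON) table; BIOM stores observations (taxa) in rows."""
    with open(path) as fh:
        doc = json.load(fh)
    taxa = [row["id"] for row in doc["rows"]]
    samples = [col["id"] for col in doc["columns"]]
    mat = np.zeros((len(taxa), len(samples)))
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    else:
        mat[:] = np.asarray(doc["data"])
    return CountTable(sample_ids=samples, taxon_ids=taxa, counts=mat.T)


_TRUTHY = {"1", "true", "t", "yes", "y"}
_FALSY = {"0", "false", "f", "no", "n", "0.0"}


def _coerce_event(col: pd.Series) -> np.ndarray:
    if np.issubdtype(col.dtype, np.number):
        return col.to_numpy()
    out = []
    for v in col:
        s = str(v).strip().lower()
        if s in _TRUTHY:
            out.append(1)
        elif s in _FALSY:
            out.append(0)
        else:
            raise ValueError(f"cannot coerce event value {v!r} to 0/1")
    return np.asarray(out)


def read_metadata(path, time_col: str, event_col: str,
                  covariate_cols: list[str] | None = None,
                  sample_ids: list[str] | None = None,
                  delimiter: str | None = None) -> tuple[SurvivalOutcome, Covariates]:
    """Read survival metadata, align to ``sample_ids`` and center covariates."""
    covariate_cols = list(covariate_cols or [])
    df = _read_delimited(path, delimiter)
    df.index = df.index.map(str)
    for col in [time_col, event_col, *covariate_cols]:
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    if sample_ids is not None:
        missing = [s for s in sample_ids if s not in df.index]
        if missing:
            raise AlignmentError(f"metadata missing samples: {missing}")
        df = df.loc[sample_ids]
    outcome = SurvivalOutcome(df[time_col].to_numpy(dtype=float),
                              _coerce_event(df[event_col]))
    X = df[covariate_cols].to_numpy(dtype=float) if covariate_cols else np.empty((len(df), 0))
    if np.isnan(X).any():
        raise ValueError("missing covariate values are an error (no imputation)")
    cov = Covariates(X, covariate_cols).center()
    return outcome, cov


def filter_rare_taxa(table: CountTable, min_prevalence: int = 5) -> CountTable:
    """Drop taxa present (count > 0) in fewer than ``min_prevalence`` samples.

    The sample set and the original library sizes are unchanged; only columns
    are removed, so downstream relative abundances keep their denominator.
    """
    if min_prevalence < 0:
        raise ValueError("min_prevalence must be >= 0")
    prevalence = (table.counts > 0).sum(axis=0)
    keep = prevalence >= min_prevalence
    if not keep.any():
        raise ValueError("prevalence filter removed every taxon")
    return CountTable(
        sample_ids=list(table.sample_ids),
        taxon_ids=[t for t, k in zip(table.taxon_ids, keep) if k],
        counts=table.counts[:, keep],
        library_sizes=table.library_sizes.copy(),
    )


def write_count_table(table: CountTable, path, delimiter: str | None = None) -> None:
    sep = delimiter or ("," if str(path).endswith(".csv") else "\t")
    table.to_frame().to_csv(path, sep=sep)


def write_results(taxon_frame: pd.DataFrame, global_summary: dict,
                  out_prefix: str) -> None:
    """Write per-taxon results as TSV and the global summary as JSON."""
    taxon_frame.to_csv(f"{out_prefix}.taxa.tsv", sep="\t")
    with open(f"{out_prefix}.global.json", "w") as fh:
        json.dump(global_summary, fh, indent=2, default=float)
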