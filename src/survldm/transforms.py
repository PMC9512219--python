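"""Analysis scales, rarefaction, distances and Gower-centered kernels.

Counts are analyzed on one of three scales: relative abundance (count over
library size), its arcsin-root transform (variance-stabilizing for
multinomial / Dirichlet-multinomial proportions), or presence-absence.
Distance matrices (Bray-Curtis on relative abundances, Jaccard on
presence-absence, Euclidean on anything) feed the distance-based global
tests after Gower double-centering of the squared distances, which recovers
the inner-product (kernel) matrix: for Euclidean distances of column-centered
data Z, the centered kernel is exactly Z Z'.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import CountTable

__all__ = ["TaxonMatrix", "DistanceMatrix", "KernelMatrix", "transform",
           "rarefy", "distance_matrix", "gower_center",
           "read_distance_matrix", "write_distance_matrix"]

SCALES = ("relabund", "arcsinroot", "presence")
METRICS = ("bray-curtis", "jaccard", "euclidean")


@dataclass
class TaxonMatrix:
    Z: np.ndarray           # (n, J)
    scale: str
    centered: bool = False
    taxon_ids: list[str] | None = None

    def center(self) -> "TaxonMatrix":
        return TaxonMatrix(self.Z - self.Z.mean(axis=0), self.scale, True,
                           self.taxon_ids)


@dataclass
class DistanceMatrix:
    D: np.ndarray           # (n, n)
    metric: str

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(D, D.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if np.abs(np.diag(D)).max() > 1e-10:
            raise ValueError("distance matrix must have a zero diagonal")
        if not np.isfinite(D).all():
            raise ValueError("non-finite distances")
        self.D = D


@dataclass
class KernelMatrix:
    K: np.ndarray           # (n, n), rows sum to ~0


def transform(table: CountTable, scale: str, center: bool = False) -> TaxonMatrix:
    """Counts to an analysis scale; library sizes are the table's originals."""
    if scale not in SCALES:
        raise ValueError(f"unknown scale {scale!r}; choose from {SCALES}")
    if (table.library_sizes <= 0).any():
        raise ValueError("zero library size")
    if scale == "presence":
        Z = (table.counts > 0).astype(float)
    else:
        Z = table.counts / table.library_sizes[:, None]
        if scale == "arcsinroot":
            Z = np.arcsin(np.sqrt(np.clip(Z, 0.0, 1.0)))
    tm = TaxonMatrix(Z, scale, False, list(table.taxon_ids))
    return tm.center() if center else tm


def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample each sample's reads to ``depth`` without replacement.

    Samples whose library size is below ``depth`` are dropped with a warning
    (standard rarefaction behavior).
    """
    import warnings

    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    keep = table.library_sizes >= depth
    if not keep.all():
        dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
        warnings.warn(f"dropping samples below depth {depth}: {dropped}")
    if not keep.any():
        raise ValueError("no samples at or above the rarefaction depth")
    counts = table.counts[keep]
    out = np.empty_like(counts)
    for i, row in enumerate(counts):
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    return CountTable(
        sample_ids=[s for s, k in zip(table.sample_ids, keep) if k],
        taxon_ids=list(table.taxon_ids),
        counts=out,
    )


def distance_matrix(Zm: TaxonMatrix, metric: str) -> DistanceMatrix:
    """Pairwise distances on the appropriate (uncentered) scale."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if Zm.centered and metric != "euclidean":
        raise ValueError(f"{metric} requires uncentered data")
    if metric == "bray-curtis" and Zm.scale != "relabund":
        raise ValueError("bray-curtis requires the relative abundance scale")
    if metric == "jaccard" and Zm.scale != "presence":
        raise ValueError("jaccard requires the presence-absence scale")
    Z = Zm.Z
    if metric == "bray-curtis":
        D = squareform(pdist(Z, "braycurtis"))
    elif metric == "jaccard":
        both_empty = ~Z.any(axis=1)
        with np.errstate(invalid="ignore"):
            D = squareform(pdist(Z.astype(bool), "jaccard"))
        if both_empty.any():  # two all-zero rows are identical by convention
            D[np.ix_(both_empty, both_empty)] = 0.0
        D = np.nan_to_num(D, nan=0.0)
    else:
        D = squareform(pdist(Z, "euclidean"))
    return DistanceMatrix(D, metric)


def gower_center(D: DistanceMatrix) -> KernelMatrix:
    """K = -(1/2) C (D o D) C with C = I - 11'/n; rows sum to zero."""
    D2 = D.D ** 2
    n = D2.shape[0]
    row = D2.mean(axis=1, keepdims=True)
    K = -0.5 * (D2 - row - row.T + D2.mean())
    return KernelMatrix(K)


def read_distance_matrix(path, metric: str = "euclidean") -> DistanceMatrix:
    """Square TSV with sample IDs, e.g. for externally computed distances."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index.map(str)) != [str(c) for c in df.columns]:
        raise ValueError("distance matrix rows/columns do not match")
    return DistanceMatrix(df.to_numpy(dtype=float), metric)


def write_distance_matrix(D: DistanceMatrix, sample_ids, path) -> None:
    pd.DataFrame(D.D, index=sample_ids, columns=sample_ids).to_csv(path, sep="\t")
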