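"""Shared permutation machinery for all tests in the package.

Inference is permutation-based throughout: a single :class:`PermutationPlan`
is drawn per analysis and reused by every component test whose p-values will
later be combined, so that the min-p combination sees component statistics
computed on *identical* relabelings.

p-values use the add-one rank rule ``p = (1 + #{null >= observed}) / (B+1)``,
which can never be zero.  The min-p combination takes the minimum of the
component p-values as its statistic and calibrates it against the minima of
leave-one-out null p-values computed from the same permutation streams.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

__all__ = ["PermutationPlan", "PermStat", "CombinedResult", "make_permutation_plan",
           "orthonormal_basis", "adjust", "adjust_rows", "rank_pvalue",
           "perm_pvalues", "null_pvalue_streams", "minp_combine", "bh_adjust"]


@dataclass
class PermutationPlan:
    n: int
    B: int
    seed: int
    permutations: np.ndarray  # (B, n) index vectors
    exhaustive: bool = False

    def __post_init__(self) -> None:
        if self.permutations.shape != (self.B, self.n):
            raise ValueError("permutation array shape does not match (B, n)")


def make_permutation_plan(n: int, B: int, seed: int, *,
                          exhaustive: bool = False) -> PermutationPlan:
    """B uniform random permutations of 0..n-1, or all n! when exhaustive."""
    if n < 2:
        raise ValueError("need n >= 2")
    if exhaustive:
        perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
        return PermutationPlan(n, perms.shape[0], seed, perms, True)
    if B < 1:
        raise ValueError("need B >= 1")
    rng = np.random.default_rng(seed)
    perms = np.tile(np.arange(n, dtype=np.intp), (B, 1))
    perms = rng.permuted(perms, axis=1)
    return PermutationPlan(n, B, seed, perms)


def orthonormal_basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of centered X (possibly empty).

    Rank-deficient input loses its dependent columns with a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if X.shape[1] == 0:
        return np.empty((n, 0))
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
    if rank < X.shape[1]:
        warnings.warn(f"covariate matrix is rank deficient "
                      f"({rank} < {X.shape[1]}); dropping dependent columns")
    return U[:, :rank]


def adjust(v: np.ndarray, basis: np.ndarray, normalize: bool = False) -> np.ndarray:
    """Project ``v`` onto the orthogonal complement of the basis columns."""
    v = np.asarray(v, dtype=float)
    out = v - basis @ (basis.T @ v) if basis.shape[1] else v.copy()
    if normalize:
        nrm = np.linalg.norm(out)
        if nrm > 1e-12:
            out = out / nrm
    return out


def adjust_rows(R: np.ndarray, basis: np.ndarray, normalize: bool = False) -> np.ndarray:
    """Row-wise :func:`adjust` for a (B, n) matrix of permuted regressors."""
    out = R - (R @ basis) @ basis.T if basis.shape[1] else np.array(R, dtype=float)
    if normalize:
        nrm = np.linalg.norm(out, axis=1, keepdims=True)
        out = out / np.where(nrm > 1e-12, nrm, 1.0)
    return out


def _tie_tol(observed) -> np.ndarray:
    # relative slack so nulls mathematically equal to the observed statistic
    # (e.g. the identity permutation) count as "at least as extreme" despite
    # floating-point jitter between code paths
    return 1e-12 * np.abs(observed) + 1e-300


def rank_pvalue(observed: float, nulls: np.ndarray) -> float:
    """Add-one permutation p-value: (1 + #{null >= observed}) / (B + 1)."""
    nulls = np.asarray(nulls)
    count = (nulls >= observed - _tie_tol(observed)).sum()
    return (1.0 + count) / (nulls.shape[0] + 1.0)


def perm_pvalues(observed: np.ndarray, nulls: np.ndarray) -> np.ndarray:
    """Columnwise rank p-values for (J,) observed against (B, J) nulls."""
    B = nulls.shape[0]
    obs = np.asarray(observed)
    count = (nulls >= (obs - _tie_tol(obs))[None, :]).sum(axis=0)
    return (1.0 + count) / (B + 1.0)


def null_pvalue_streams(nulls: np.ndarray) -> np.ndarray:
    """Leave-one-out null p-values along axis 0.

    For permutation b, ``p_b = (1 + #{b' != b : null_b' >= null_b}) / B``;
    these are the null analogues of the observed rank p-value and calibrate
    the min-p combination.
    """
    nulls = np.asarray(nulls)
    B = nulls.shape[0]
    rank_min = rankdata(nulls, method="min", axis=0)  # 1 + #{ < v_b }
    return (1.0 + B - rank_min) / B


@dataclass
class PermStat:
    """One component's observed statistic and its permutation nulls."""

    label: str
    observed: np.ndarray | float   # scalar or (J,)
    nulls: np.ndarray              # (B,) or (B, J)
    _null_p: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def B(self) -> int:
        return self.nulls.shape[0]

    def pvalue(self):
        if np.ndim(self.observed) == 0:
            return rank_pvalue(float(self.observed), self.nulls)
        return perm_pvalues(self.observed, self.nulls)

    def null_pvalues(self) -> np.ndarray:
        """Leave-one-out null p-values, cached (reused across combinations)."""
        if self._null_p is None:
            self._null_p = null_pvalue_streams(self.nulls)
        return self._null_p


@dataclass
class CombinedResult:
    component_pvalues: dict
    pvalue: np.ndarray | float
    B: int = 0
    null_minp: np.ndarray | None = field(default=None, repr=False)


def minp_combine(components: list[PermStat]) -> CombinedResult:
    """Min-p combination of component tests sharing one permutation plan.

    The observed statistic is ``t = min_c p_c``; each permutation's null
    statistic is the minimum over components of the leave-one-out null
    p-values, and the combined p-value ranks t among those minima (add-one
    rule, with <= since small p is extreme).
    Works elementwise when components carry per-taxon statistics.
    """
    if not components:
        raise ValueError("no components to combine")
    Bs = {c.B for c in components}
    if len(Bs) != 1:
        raise ValueError("components disagree on the number of permutations "
                         "(were they run on the same plan?)")
    B = Bs.pop()
    obs_p = {c.label: c.pvalue() for c in components}
    if len(components) == 1:
        # single component: the min-p rank rule returns its p-value exactly
        only = components[0]
        p = obs_p[only.label]
        return CombinedResult(component_pvalues=obs_p,
                              pvalue=float(p) if np.ndim(p) == 0 else np.asarray(p),
                              B=B)
    t = np.minimum.reduce([np.asarray(obs_p[c.label]) for c in components])
    null_t = np.minimum.reduce([c.null_pvalues() for c in components])
    combined = (1.0 + (null_t <= t).sum(axis=0)) / (B + 1.0)
    if np.ndim(components[0].observed) == 0:
        combined = float(combined)
    return CombinedResult(component_pvalues=obs_p, pvalue=combined, B=B,
                          null_minp=null_t)


def bh_adjust(pvals: np.ndarray, q: float = 0.10) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted p-values and detections at q."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals, np.zeros(0, dtype=bool)
    _, adj, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return adj, adj <= q
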