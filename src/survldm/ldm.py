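"""LDM-style permutation F-tests with a Cox residual as the tested regressor.

The model regressed, taxon by taxon, is

    Z_ij = beta_Xj' X_i + beta_j r_i + e_ij,

where ``r`` is the Martingale (LDM-m) or deviance (LDM-d) residual from a
Cox fit of the survival outcome on the covariates alone.  After projecting
both the taxon data and the regressor off the covariate space, the taxon
statistic is ``U_j = r~' z*_j`` (r~ unit-normalized) and the F-type statistics

    F_j      = U_j^2 / (||z*_j||^2 - U_j^2)
    F_global = sum_j U_j^2 / sum_j (||z*_j||^2 - U_j^2)

are referred to their permutation distributions: the regressor is permuted,
re-orthogonalized against X and re-normalized at every permutation
(Freedman-Lane style), keeping the covariate effect fixed.  With no
covariates, ``sum_j U_j^2`` (unnormalized) is exactly the linear-kernel
variance-component score statistic ``M' Z Z' M`` used by kernel tests.

Tests on the two residual types, or across analysis scales, are combined by
the min-p machinery in :mod:`survldm.inference` on a shared permutation plan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inference import (CombinedResult, PermStat, PermutationPlan, adjust,
                        adjust_rows, bh_adjust, minp_combine, orthonormal_basis,
                        perm_pvalues, rank_pvalue)
from .io import Covariates
from .transforms import TaxonMatrix

__all__ = ["LdmStatistics", "TestResult", "LdmCombined", "ldm_statistics",
           "ldm_test", "ldm_combined", "ldm_omnibus", "combine_tests"]

_NORM_TOL = 1e-12


@dataclass
class LdmStatistics:
    U: np.ndarray                  # (J,) U_j = r~' z*_j
    F_taxon: np.ndarray            # (J,)
    F_global: float
    adjusted_sq_norms: np.ndarray  # (J,) ||z*_j||^2
    degenerate: np.ndarray         # (J,) bool, zero adjusted norm


@dataclass
class TestResult:
    method: str
    residual: str                  # martingale | deviance
    scale: str
    p_global: float
    p_taxon: np.ndarray
    detected: np.ndarray           # bool, BH at q
    p_taxon_adjusted: np.ndarray
    q: float
    B: int
    seed: int
    global_stat: PermStat = field(repr=False)
    taxon_stat: PermStat = field(repr=False)
    taxon_ids: list[str] | None = None
    degenerate: np.ndarray | None = None


def _f_stats(U: np.ndarray, sq_norms: np.ndarray):
    """Taxon and global F from U_j and adjusted squared norms (any leading dims)."""
    U2 = U ** 2
    denom = np.maximum(sq_norms - U2, 0.0)
    zero = sq_norms <= _NORM_TOL
    with np.errstate(divide="ignore", invalid="ignore"):
        F_taxon = np.where(zero, 0.0, U2 / np.maximum(denom, 1e-300))
    denom_g = denom.sum(axis=-1)
    F_global = U2.sum(axis=-1) / np.maximum(denom_g, 1e-300)
    return F_taxon, F_global


def ldm_statistics(Z: np.ndarray, basisX: np.ndarray, r: np.ndarray) -> LdmStatistics:
    """Observed LDM statistics for centered Z, covariate basis and regressor r."""
    Z = np.asarray(Z, dtype=float)
    r_star = adjust(r, basisX)
    nrm = np.linalg.norm(r_star)
    if nrm <= 1e-10:
        raise ValueError("regressor lies in the covariate span; the test is "
                         "degenerate (remove collinear covariates)")
    r_tilde = r_star / nrm
    Z_star = Z - basisX @ (basisX.T @ Z) if basisX.shape[1] else Z
    U = r_tilde @ Z_star
    sq_norms = (Z_star ** 2).sum(axis=0)
    F_taxon, F_global = _f_stats(U, sq_norms)
    return LdmStatistics(U=U, F_taxon=F_taxon, F_global=float(F_global),
                         adjusted_sq_norms=sq_norms,
                         degenerate=sq_norms <= _NORM_TOL)


def ldm_test(Zm: TaxonMatrix, X: Covariates | None, r: np.ndarray,
             plan: PermutationPlan, q: float = 0.10, *,
             residual: str = "martingale") -> TestResult:
    """Per-taxon and global permutation F-test of the residual regressor.

    The regressor is permuted by the plan, re-orthogonalized against X and
    re-normalized for every permutation; per-taxon p-values use each taxon's
    own permutation null.  Degenerate taxa (zero adjusted norm) get p = 1.
    """
    Zc = Zm if Zm.centered else Zm.center()
    Z = Zc.Z
    n = Z.shape[0]
    if plan.n != n:
        raise ValueError("permutation plan size does not match the data")
    r = np.asarray(r, dtype=float)
    r = r - r.mean()
    basis = orthonormal_basis(X.X) if X is not None and X.p else np.empty((n, 0))
    Z_star = Z - basis @ (basis.T @ Z) if basis.shape[1] else Z
    sq_norms = (Z_star ** 2).sum(axis=0)

    obs = ldm_statistics(Z, basis, r)

    R = r[plan.permutations]                       # (B, n)
    R_t = adjust_rows(R, basis, normalize=True)
    U_null = R_t @ Z_star                          # (B, J)
    F_taxon_null, F_global_null = _f_stats(U_null, sq_norms[None, :])

    p_global = rank_pvalue(obs.F_global, F_global_null)
    p_taxon = perm_pvalues(obs.F_taxon, F_taxon_null)
    p_taxon = np.where(obs.degenerate, 1.0, p_taxon)
    adj, det = bh_adjust(p_taxon, q)
    return TestResult(
        method="ldm", residual=residual, scale=Zm.scale,
        p_global=p_global, p_taxon=p_taxon, detected=det,
        p_taxon_adjusted=adj, q=q, B=plan.B, seed=plan.seed,
        global_stat=PermStat(f"{residual}:{Zm.scale}:global", obs.F_global,
                             F_global_null),
        taxon_stat=PermStat(f"{residual}:{Zm.scale}:taxon", obs.F_taxon,
                            F_taxon_null),
        taxon_ids=Zm.taxon_ids, degenerate=obs.degenerate,
    )


@dataclass
class LdmCombined:
    """Min-p combination of component LDM tests (residuals and/or scales)."""

    p_global: float
    p_taxon: np.ndarray
    detected: np.ndarray
    p_taxon_adjusted: np.ndarray
    component_global: dict
    component_taxon: dict
    q: float
    B: int
    global_combined: CombinedResult = field(repr=False)
    taxon_combined: CombinedResult = field(repr=False)
    taxon_ids: list[str] | None = None


def combine_tests(results: list[TestResult], q: float = 0.10, *,
                  taxon: bool = True) -> LdmCombined:
    """Combine component tests that share one permutation plan.

    ``taxon=False`` skips the per-taxon combination (global-only analyses).
    """
    if not results:
        raise ValueError("nothing to combine")
    key = {(t.B, t.seed) for t in results}
    if len(key) != 1:
        raise ValueError("component tests were not run on the same "
                         "permutation plan")
    gc = minp_combine([t.global_stat for t in results])
    if not taxon:
        return LdmCombined(
            p_global=float(gc.pvalue), p_taxon=None, detected=None,
            p_taxon_adjusted=None, component_global=gc.component_pvalues,
            component_taxon={}, q=q, B=results[0].B, global_combined=gc,
            taxon_combined=None, taxon_ids=results[0].taxon_ids)
    tc = minp_combine([t.taxon_stat for t in results])
    p_taxon = np.asarray(tc.pvalue)
    degen = np.logical_and.reduce([t.degenerate for t in results
                                   if t.degenerate is not None]) \
        if any(t.degenerate is not None for t in results) else None
    if degen is not None:
        p_taxon = np.where(degen, 1.0, p_taxon)
    adj, det = bh_adjust(p_taxon, q)
    return LdmCombined(
        p_global=float(gc.pvalue), p_taxon=p_taxon, detected=det,
        p_taxon_adjusted=adj, component_global=gc.component_pvalues,
        component_taxon=tc.component_pvalues, q=q, B=results[0].B,
        global_combined=gc, taxon_combined=tc, taxon_ids=results[0].taxon_ids,
    )


def ldm_combined(Zm: TaxonMatrix, X: Covariates | None, M: np.ndarray,
                 D: np.ndarray, plan: PermutationPlan,
                 q: float = 0.10) -> LdmCombined:
    """LDM-c: combine the Martingale- and deviance-residual tests."""
    res_m = ldm_test(Zm, X, M, plan, q, residual="martingale")
    res_d = ldm_test(Zm, X, D, plan, q, residual="deviance")
    return combine_tests([res_m, res_d], q)


def ldm_omnibus(results: list[TestResult], q: float = 0.10) -> LdmCombined:
    """Omnibus over analysis scales (same machinery as the residual combo)."""
    return combine_tests(results, q)
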