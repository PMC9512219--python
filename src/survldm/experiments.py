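"""Benchmark harness: type-I error, power, and taxon-level FDR/sensitivity.

Each replicate simulates a dataset, applies the prevalence filter, fits the
Cox model once to obtain Martingale/deviance residuals, and runs every
requested method on one shared permutation plan:

* global tests: ldm-m / ldm-d / ldm-c (with the relative-abundance +
  arcsin-root omnibus under abundance-driven scenarios, presence-absence
  under presence-driven ones), permanovafl-m / -d / -c (Bray-Curtis or
  Jaccard), mirkat-s (raw Martingale permutation score test), mirkat-m /
  mirkat-d (covariate-adjusted variants);
* taxon-level tests: the LDM per-taxon tests with BH detection, and the
  ad hoc taxon-by-taxon Cox Wald test fit by a vectorized Newton solver.

Rejection fractions come with binomial Monte-Carlo standard errors
``sqrt(f (1 - f) / R)``.  Reports are reproducible from
(config, seed, R, B).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

from . import cox
from .distance_tests import (dist_combined_omnibus, mirkat_adjusted_test,
                             mirkat_s_test, permanova_fl_test)
from .inference import bh_adjust, make_permutation_plan
from .io import Covariates, CountTable, SurvivalOutcome, filter_rare_taxa
from .ldm import combine_tests, ldm_test
from .simulate import SimConfig, SimDesign, simulate_replicate
from .transforms import TaxonMatrix, distance_matrix, gower_center, transform

__all__ = ["ExperimentReport", "CoxComparatorResult", "taxonwise_cox",
           "run_type1", "run_power", "run_fdr_sensitivity",
           "GLOBAL_METHODS", "TAXON_METHODS"]

GLOBAL_METHODS = ("ldm-m", "ldm-d", "ldm-c", "permanovafl-m", "permanovafl-d",
                  "permanovafl-c", "mirkat-s", "mirkat-m", "mirkat-d")
TAXON_METHODS = ("ldm-m", "ldm-d", "ldm-c", "cox")


@dataclass
class ExperimentReport:
    kind: str                          # type1 | power | fdr
    rejection: dict = field(default_factory=dict)    # method -> fraction
    rejection_se: dict = field(default_factory=dict)
    sensitivity: dict = field(default_factory=dict)  # method -> mean
    sensitivity_se: dict = field(default_factory=dict)
    fdr: dict = field(default_factory=dict)
    fdr_se: dict = field(default_factory=dict)
    R: int = 0
    B: int = 0
    alpha: float = 0.05
    q: float = 0.10
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


@dataclass
class CoxComparatorResult:
    p: np.ndarray              # per-taxon Wald p
    coef: np.ndarray           # taxon coefficient alpha_j
    converged: np.ndarray      # bool per taxon
    p_adjusted: np.ndarray
    detected: np.ndarray


def taxonwise_cox(outcome: SurvivalOutcome, X: Covariates | None,
                  Zm: TaxonMatrix, q: float = 0.10, *, max_iter: int = 30,
                  tol: float = 1e-8) -> CoxComparatorResult:
    """Ad hoc comparator: one Cox fit per taxon, Wald test on its coefficient.

    Every model contains all covariates plus exactly one taxon variable
    (relative abundance or presence, *uncentered*).  All J fits run in one
    vectorized Newton iteration (Breslow ties).  Taxa whose fit fails to
    converge, separates, or is collinear with the covariates are flagged and
    assigned p = 1 (they count as non-detections, never as errors).
    """
    t, d = outcome.time, outcome.event
    n = t.shape[0]
    Xm = X.X if X is not None else np.empty((n, 0))
    p_cov = Xm.shape[1]
    Z = np.asarray(Zm.Z, dtype=float)
    J = Z.shape[1]
    nq = p_cov + 1
    # fit on unit-sd taxon covariates (Wald z is scale-invariant); report the
    # coefficient on the original scale afterwards
    z_sd = Z.std(axis=0, ddof=1)
    z_scale = np.where(z_sd > 0, z_sd, 1.0)
    Z = Z / z_scale

    order = np.argsort(t, kind="stable")
    t_s, d_s = t[order], d[order]
    X_s, Z_s = Xm[order], Z[order]
    # risk-set start index per position (ties share the group start)
    starts = np.searchsorted(t_s, t_s, side="left")
    ev = np.where(d_s == 1)[0]
    ev_start = starts[ev]

    def revcum(a):  # reverse cumulative sum along axis 0
        return np.cumsum(a[::-1], axis=0)[::-1]

    beta = np.zeros((J, nq))
    active = np.ones(J, dtype=bool)
    # flag taxa collinear with covariates (or constant): residual variance ~ 0
    if p_cov:
        Q, _ = np.linalg.qr(np.column_stack([np.ones(n), Xm]))
    else:
        Q, _ = np.linalg.qr(np.ones((n, 1)))
    resid_var = ((Z - Q @ (Q.T @ Z)) ** 2).sum(axis=0)
    active &= resid_var > 1e-10 * np.maximum((Z ** 2).sum(axis=0), 1.0)

    hess = np.zeros((J, nq, nq))
    for _ in range(max_iter):
        eta = X_s @ beta[:, :p_cov].T + Z_s * beta[:, p_cov][None, :]  # (n, J)
        eta = eta - eta.max(axis=0, keepdims=True)
        w = np.exp(eta)
        S0 = revcum(w)[ev_start]                        # (E, J)
        covs = [X_s[:, k][:, None] for k in range(p_cov)] + [Z_s]
        S1 = [revcum(w * c)[ev_start] for c in covs]    # each (E, J)
        score = np.empty((J, nq))
        for a in range(nq):
            ca = covs[a]
            obs = (ca[ev] if ca.shape[1] > 1 else np.repeat(ca[ev], J, axis=1))
            score[:, a] = obs.sum(axis=0) - (S1[a] / S0).sum(axis=0)
            for b in range(a, nq):
                cb = covs[b]
                S2ab = revcum(w * ca * cb)[ev_start]
                h = -(S2ab / S0 - (S1[a] / S0) * (S1[b] / S0)).sum(axis=0)
                hess[:, a, b] = h
                hess[:, b, a] = h
        upd = active.copy()
        if not upd.any():
            break
        with np.errstate(all="ignore"):
            try:
                step = np.linalg.solve(-hess[upd], score[upd][..., None])[..., 0]
            except np.linalg.LinAlgError:
                # singular hessians: solve taxon by taxon, flag failures
                step = np.zeros((upd.sum(), nq))
                for i, j in enumerate(np.where(upd)[0]):
                    try:
                        step[i] = np.linalg.solve(-hess[j], score[j])
                    except np.linalg.LinAlgError:
                        active[j] = False
        step = np.nan_to_num(step, nan=0.0, posinf=0.0, neginf=0.0)
        big = np.abs(step).max(axis=1)
        step[big > 5.0] *= (5.0 / big[big > 5.0])[:, None]
        beta[upd] += step
        blown = np.abs(beta).max(axis=1) > 30
        active &= ~blown
        done = np.linalg.norm(score, axis=1) < tol
        if (done | ~active).all():
            break
    converged = active & (np.linalg.norm(score, axis=1) < 1e-3)

    pvals = np.ones(J)
    coef = beta[:, p_cov] / z_scale
    ok = np.where(converged)[0]
    if ok.size:
        with np.errstate(all="ignore"):
            try:
                cov_inv = np.linalg.inv(-hess[ok])
                var = cov_inv[:, p_cov, p_cov]
            except np.linalg.LinAlgError:
                var = np.full(ok.size, np.nan)
        good = np.isfinite(var) & (var > 0)
        zstat = np.zeros(ok.size)
        zstat[good] = beta[ok, p_cov][good] / np.sqrt(var[good])
        pv = np.ones(ok.size)
        pv[good] = 2.0 * norm.sf(np.abs(zstat[good]))
        pvals[ok] = pv
        converged[ok[~good]] = False
        pvals[ok[~good]] = 1.0
    adj, det = bh_adjust(pvals, q)
    return CoxComparatorResult(p=pvals, coef=coef, converged=converged,
                               p_adjusted=adj, detected=det)


# ---------------------------------------------------------------------------
# per-replicate analysis


def _scenario_scales(config: SimConfig) -> tuple[list[str], str]:
    """Analysis scales + distance for a scenario, following its score scale."""
    presence = (config.score_scale == "presence"
                or (config.score_scale is None and config.model == "M2"))
    if presence:
        return ["presence"], "jaccard"
    return ["relabund", "arcsinroot"], "bray-curtis"


def _analyze_replicate(rep, config: SimConfig, B: int, plan_seed: int,
                       methods, *, adjust_X: bool = True, q: float = 0.10,
                       taxon_level: bool = False, min_prevalence: int = 5):
    """All requested tests on one replicate, sharing a permutation plan."""
    table = filter_rare_taxa(rep.table, min_prevalence)
    n = table.n_samples
    X = rep.covariates() if adjust_X else Covariates.empty(n)
    _, resid = cox.residual_set(rep.outcome, X if X.p else None)
    M, D = resid.martingale, resid.deviance
    plan = make_permutation_plan(n, B, plan_seed)
    scales, metric = _scenario_scales(config)

    gp: dict[str, float] = {}
    taxon: dict[str, object] = {}

    need_ldm = any(m.startswith("ldm") for m in methods)
    if need_ldm:
        comp = {"martingale": [], "deviance": []}
        for scale in scales:
            Zm = transform(table, scale)
            comp["martingale"].append(
                ldm_test(Zm, X, M, plan, q, residual="martingale"))
            comp["deviance"].append(
                ldm_test(Zm, X, D, plan, q, residual="deviance"))
        ldm_m = combine_tests(comp["martingale"], q, taxon=taxon_level)
        ldm_d = combine_tests(comp["deviance"], q, taxon=taxon_level)
        ldm_c = combine_tests(comp["martingale"] + comp["deviance"], q,
                              taxon=taxon_level)
        for name, res in (("ldm-m", ldm_m), ("ldm-d", ldm_d), ("ldm-c", ldm_c)):
            gp[name] = res.p_global
            if taxon_level:
                taxon[name] = res

    need_dist = any(m.startswith(("permanovafl", "mirkat")) for m in methods)
    if need_dist:
        dist_scale = "presence" if metric == "jaccard" else "relabund"
        Dmat = distance_matrix(transform(table, dist_scale), metric)
        if any(m.startswith("permanovafl") for m in methods):
            pfl_m = permanova_fl_test(Dmat, X, M, plan, residual="martingale")
            pfl_d = permanova_fl_test(Dmat, X, D, plan, residual="deviance")
            gp["permanovafl-m"] = pfl_m.p
            gp["permanovafl-d"] = pfl_d.p
            gp["permanovafl-c"] = float(
                dist_combined_omnibus([pfl_m, pfl_d]).pvalue)
        if any(m.startswith("mirkat") for m in methods):
            K = gower_center(Dmat)
            if "mirkat-s" in methods:
                gp["mirkat-s"] = mirkat_s_test(K, M, plan, kernel=metric).p
            if "mirkat-m" in methods:
                gp["mirkat-m"] = mirkat_adjusted_test(
                    K, X, M, plan, residual="martingale", kernel=metric).p
            if "mirkat-d" in methods:
                gp["mirkat-d"] = mirkat_adjusted_test(
                    K, X, D, plan, residual="deviance", kernel=metric).p

    if taxon_level and "cox" in methods:
        cox_scale = "presence" if metric == "jaccard" else "relabund"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            taxon["cox"] = taxonwise_cox(rep.outcome, X,
                                         transform(table, cox_scale), q)
    return gp, taxon, table.taxon_ids


def _plan_seed(seed: int, r: int) -> int:
    return int((seed * 1_000_003 + 7919 * r + 1) % (2 ** 31 - 1))


def _frac_se(f: float, R: int) -> float:
    return float(np.sqrt(f * (1.0 - f) / R))


def _run_global(config: SimConfig, kind: str, methods, alpha: float, R: int,
                B: int, seed: int, adjust_X: bool) -> ExperimentReport:
    design = SimDesign(config)
    methods = tuple(methods)
    hits = {m: 0 for m in methods}
    for r in range(R):
        rep = simulate_replicate(design, r + 1)
        gp, _, _ = _analyze_replicate(rep, config, B, _plan_seed(seed, r),
                                      methods, adjust_X=adjust_X)
        for m in methods:
            hits[m] += gp[m] <= alpha
    rej = {m: hits[m] / R for m in methods}
    return ExperimentReport(
        kind=kind, rejection=rej,
        rejection_se={m: _frac_se(rej[m], R) for m in methods},
        R=R, B=B, alpha=alpha, config=config.__dict__.copy())


def run_type1(config: SimConfig, methods=GLOBAL_METHODS, alpha: float = 0.05,
              R: int = 1000, B: int = 1000, seed: int = 0, *,
              adjust_X: bool = True) -> ExperimentReport:
    """Global type-I error: rejection fraction at alpha under beta = 0."""
    if config.beta != 0:
        config = replace(config, beta=0.0)
    return _run_global(config, "type1", methods, alpha, R, B, seed, adjust_X)


def run_power(config: SimConfig, betas, methods=GLOBAL_METHODS,
              alpha: float = 0.05, R: int = 1000, B: int = 1000,
              seed: int = 0) -> list[ExperimentReport]:
    """Global power over a grid of causal effect sizes beta."""
    return [_run_global(replace(config, beta=float(b)), "power", methods,
                        alpha, R, B, seed, True) for b in betas]


def run_fdr_sensitivity(config: SimConfig, methods=TAXON_METHODS,
                        q: float = 0.10, R: int = 1000, B: int = 1000,
                        seed: int = 0) -> ExperimentReport:
    """Taxon-level sensitivity and empirical FDR at nominal level q.

    sensitivity = |detected & causal| / |causal|, FDR = |detected \\ causal|
    / max(|detected|, 1), each averaged over replicates.
    """
    design = SimDesign(config)
    if design.causal.size == 0:
        raise ValueError("causal set is empty")
    causal_names = {f"taxon{j + 1}" for j in design.causal}
    methods = tuple(methods)
    sens = {m: [] for m in methods}
    fdr = {m: [] for m in methods}
    for r in range(R):
        rep = simulate_replicate(design, r + 1)
        _, taxon, taxon_ids = _analyze_replicate(
            rep, config, B, _plan_seed(seed, r), methods, q=q,
            taxon_level=True)
        names = np.asarray(taxon_ids)
        for m in methods:
            det = taxon[m].detected
            det_names = set(names[det])
            tp = len(det_names & causal_names)
            sens[m].append(tp / len(causal_names))
            fdr[m].append((len(det_names) - tp) / max(len(det_names), 1))
    rep_out = ExperimentReport(kind="fdr", R=R, B=B, q=q,
                               config=config.__dict__.copy())
    for m in methods:
        s, f = np.asarray(sens[m]), np.asarray(fdr[m])
        rep_out.sensitivity[m] = float(s.mean())
        rep_out.sensitivity_se[m] = float(s.std(ddof=1) / np.sqrt(R))
        rep_out.fdr[m] = float(f.mean())
        rep_out.fdr_se[m] = float(f.std(ddof=1) / np.sqrt(R))
    return rep_out
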