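"""REML linear mixed models and the two-stage breeding-value pipeline.

Stage 1 analyzes every trial (environment = location x year x season)
separately: grain yield (or days to flowering) is modelled with a random
genotype effect ``g ~ N(0, I sigma2_g)``, design-specific blocking factors
chosen by BIC, and a heterogeneous residual whose diagonal is driven by the
number of hills harvested per plot.  BLUPs, prediction-error variances and
reliabilities ``r2 = 1 - PEV / sigma2_g`` are extracted per genotype.

Stage 2 de-regresses the stage-1 BLUPs (``y_dr = BLUP / r2``), then fits a
single pedigree model across environments with environment as a fixed
effect, days to flowering as a fixed covariate, genetic effect
``g ~ N(0, A sigma2_g)`` through the sparse A-inverse, and residual diagonal
``1 / r2``.  Breeding values are reported on the trait scale (overall mean
plus genetic effect).

The REML engine profiles the residual variance out of the restricted
likelihood and optimizes variance ratios ``lambda_k = sigma2_k / sigma2_e``
on the log scale over Henderson's mixed-model equations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg as la
import scipy.optimize as opt
import scipy.sparse as sp

from .pedigree import Pedigree, a_inverse_with_logdet

logger = logging.getLogger("ricegain")

DESIGNS = ("rcbd", "augmented_rcbd", "alpha_lattice", "p_rep", "row_column", "augmented")

#: candidate blocking factors per experimental design (column names in plots)
DESIGN_FACTORS: dict[str, tuple[str, ...]] = {
    "row_column": ("row", "col"),
    "p_rep": ("row", "col", "rep", "block"),
    "rcbd": ("rep",),
    "augmented_rcbd": ("rep",),
    "augmented": ("rep",),
    "alpha_lattice": ("rep", "block", "row", "col"),
}

#: blocking factors with more than this many levels enter as random effects
RANDOM_LEVELS_MIN = 5

#: trials with more trait missingness than this are rejected
MISSING_MAX = 0.15


class ConvergenceError(RuntimeError):
    """REML optimization failed; carries the optimizer trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


class ModelSpecificationError(ValueError):
    """Singular fixed part or otherwise unusable model specification."""


class TrialRejectedError(ValueError):
    """Trial fails the data-quality filters (e.g. >15% missing trait data)."""


@dataclass
class TrialTable:
    """Plot-level records of one environment."""

    environment_id: str
    design: str
    plots: pd.DataFrame  # genotype, yield_kg_ha, dtf_days, hills, row, col, rep, block

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}; expected one of {DESIGNS}")
        if "genotype" not in self.plots.columns:
            raise ValueError("plots must contain a 'genotype' column")

    @property
    def h_max(self) -> float:
        return float(np.nanmax(self.plots["hills"])) if "hills" in self.plots else np.nan


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_blocks: dict[str, float]
    sigma2_e: float
    boundary: set[str] = field(default_factory=set)


@dataclass
class BlupResult:
    """Per-genotype BLUPs with PEV and reliability for one fitted model."""

    environment_id: str
    trait: str
    table: pd.DataFrame  # genotype, blup, pev, reliability
    vc: VarianceComponents
    mean: float
    loglik: float
    bic: float
    model_terms: tuple[str, ...] = ()
    n_obs: int = 0
    mean_reps: float = np.nan


# ---------------------------------------------------------------------------
# Core REML engine
# ---------------------------------------------------------------------------


@dataclass
class RandomTerm:
    """One random effect: incidence matrix, level labels, optional G-inverse."""

    name: str
    Z: np.ndarray
    levels: list
    ginv: Optional[sp.spmatrix] = None  # None -> iid (identity covariance)
    logdet_g: float = 0.0  # log|G| (0 for identity)


@dataclass
class LmmFit:
    vc: VarianceComponents
    beta: np.ndarray
    fixed_names: list[str]
    random_effects: dict[str, pd.DataFrame]  # level, blup, pev
    loglik: float  # REML log-likelihood at the optimum
    bic: float
    n_obs: int
    n_fixed: int
    beta_cov: Optional[np.ndarray] = None
    converged: bool = True


def _design_matrix_factor(values: pd.Series) -> tuple[np.ndarray, list]:
    codes, levels = pd.factorize(values.astype(str), sort=True)
    Z = np.zeros((len(values), len(levels)))
    Z[np.arange(len(values)), codes] = 1.0
    return Z, list(levels)


_LAMBDA_LOG_BOUNDS = (np.log(1e-7), np.log(1e7))


def fit_lmm_reml(
    y: np.ndarray,
    X: np.ndarray,
    random_terms: Sequence[RandomTerm],
    residual_weights: Optional[np.ndarray] = None,
    fixed_names: Optional[Sequence[str]] = None,
    tol: float = 1e-8,
) -> LmmFit:
    """REML fit of ``y = X beta + sum Z_k u_k + e``.

    ``u_k ~ N(0, G_k sigma2_k)`` with ``G_k`` identity or supplied through its
    sparse inverse, and ``e ~ N(0, diag(w) sigma2_e)`` for per-observation
    weights ``w`` (``diag(R) = w``; larger w = noisier plot).  Variance ratios
    are optimized by bounded quasi-Newton on the log scale; components whose
    ratio ends at the lower bound are flagged as boundary (zero) estimates.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != n:
        raise ValueError("X and y have incompatible shapes")
    p = X.shape[1]
    if fixed_names is None:
        fixed_names = [f"x{j}" for j in range(p)]
    if np.linalg.matrix_rank(X) < p:
        # name aliased columns: those whose removal does not lower the rank
        r_full = np.linalg.matrix_rank(X)
        aliased = [
            fixed_names[j]
            for j in range(p)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == r_full
        ]
        raise ModelSpecificationError(f"fixed part is singular; aliased terms: {aliased}")
    if residual_weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(residual_weights, dtype=float)
        if np.any(w <= 0) or np.any(~np.isfinite(w)):
            raise ValueError("residual weights must be positive and finite")
    rinv = 1.0 / w

    K = len(random_terms)
    if K == 0:
        raise ValueError("at least one random term is required")
    q = [t.Z.shape[1] for t in random_terms]
    blocks = [sp.csr_matrix(X)] + [sp.csr_matrix(t.Z) for t in random_terms]
    W = sp.hstack(blocks, format="csr")
    # W' R^-1 W and W' R^-1 y assembled once; only the G^-1/lambda block varies
    WtRi = (W.T.multiply(rinv)).tocsr()
    M = np.asarray((WtRi @ W).todense())
    rhs = np.asarray(WtRi @ y).ravel()
    yRy = float(np.sum(y * y * rinv))
    sum_log_w = float(np.sum(np.log(w)))
    # the ln|X'X| constant makes restricted likelihoods comparable across
    # candidate models that differ in their fixed parts (Harville's form)
    logdet_xtx = float(np.linalg.slogdet(X.T @ X)[1])
    offs = np.cumsum([p] + q)

    ginv_dense = [
        None if t.ginv is None else np.asarray(t.ginv.todense(), dtype=float)
        if sp.issparse(t.ginv)
        else np.asarray(t.ginv, dtype=float)
        for t in random_terms
    ]

    def assemble(lam: np.ndarray) -> np.ndarray:
        C = M.copy()
        for k in range(K):
            a, b = offs[k], offs[k + 1]
            if ginv_dense[k] is None:
                C[np.arange(a, b), np.arange(a, b)] += 1.0 / lam[k]
            else:
                C[a:b, a:b] += ginv_dense[k] / lam[k]
        return C

    def minus2_reml(theta: np.ndarray) -> float:
        lam = np.exp(theta)
        C = assemble(lam)
        try:
            cf = la.cho_factor(C, lower=True, check_finite=False)
        except la.LinAlgError:
            return 1e30
        b = la.cho_solve(cf, rhs, check_finite=False)
        ypy = yRy - float(rhs @ b)
        if ypy <= 0:
            return 1e30
        s2e = ypy / (n - p)
        logdet_c = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        val = (
            (n - p) * (1.0 + np.log(2.0 * np.pi * s2e))
            + sum_log_w + logdet_c - logdet_xtx
        )
        for k in range(K):
            val += q[k] * theta[k] + random_terms[k].logdet_g
        return float(val)

    theta0 = np.zeros(K)
    res = opt.minimize(
        minus2_reml,
        theta0,
        method="L-BFGS-B",
        bounds=[_LAMBDA_LOG_BOUNDS] * K,
        options={"ftol": tol, "gtol": 1e-8, "maxiter": 500},
    )
    if not res.success and not np.isfinite(res.fun):
        raise ConvergenceError(f"REML optimization failed: {res.message}", trace=res)
    # derivative-free polish (numerical L-BFGS-B gradients limit precision)
    res2 = opt.minimize(
        minus2_reml, res.x, method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 200 * K},
    )
    if np.isfinite(res2.fun) and res2.fun <= res.fun:
        res = res2
    theta = np.clip(res.x, *_LAMBDA_LOG_BOUNDS)
    lam = np.exp(theta)

    C = assemble(lam)
    cf = la.cho_factor(C, lower=True, check_finite=False)
    b = la.cho_solve(cf, rhs, check_finite=False)
    ypy = yRy - float(rhs @ b)
    s2e = ypy / (n - p)
    Cinv = la.cho_solve(cf, np.eye(C.shape[0]), check_finite=False)

    boundary = {
        random_terms[k].name
        for k in range(K)
        if theta[k] <= _LAMBDA_LOG_BOUNDS[0] + 1e-6
    }
    sigma2 = {random_terms[k].name: float(lam[k] * s2e) for k in range(K)}
    for name in boundary:
        logger.info("variance component %s at zero boundary", name)

    beta = b[:p]
    random_effects: dict[str, pd.DataFrame] = {}
    for k in range(K):
        a0, b0 = offs[k], offs[k + 1]
        pev = np.clip(np.diag(Cinv)[a0:b0] * s2e, 0.0, None)
        random_effects[random_terms[k].name] = pd.DataFrame(
            {
                "level": random_terms[k].levels,
                "blup": b[a0:b0],
                "pev": pev,
            }
        )
    # BIC uses the profile *ML* likelihood at the REML variance estimates:
    # the restricted likelihood's (n - p) prefactor mechanically rewards
    # every extra fixed-effect column by ~ln(sigma2) and would make the
    # lowest-BIC blocking-model rule degenerate across fixed parts.
    logdet_v = sum_log_w
    for k in range(K):
        logdet_v += q[k] * theta[k] + random_terms[k].logdet_g
    Czz = C[p:, p:]
    logdet_v += 2.0 * float(
        np.sum(np.log(np.diag(la.cholesky(Czz, lower=True, check_finite=False))))
    )
    s2e_ml = ypy / n
    minus2l_ml = n * (1.0 + np.log(2.0 * np.pi * s2e_ml)) + logdet_v
    minus2l = float(res.fun)
    n_vpar = K + 1  # one ratio per random term + residual
    bic = minus2l_ml + (n_vpar + p) * np.log(n)
    vc = VarianceComponents(
        sigma2_g=sigma2.get("genotype", np.nan),
        sigma2_blocks={k: v for k, v in sigma2.items() if k != "genotype"},
        sigma2_e=float(s2e),
        boundary=boundary,
    )
    return LmmFit(
        vc=vc,
        beta=beta,
        fixed_names=list(fixed_names),
        random_effects=random_effects,
        loglik=-0.5 * minus2l,
        bic=float(bic),
        n_obs=n,
        n_fixed=p,
        beta_cov=Cinv[:p, :p] * s2e,
    )


# ---------------------------------------------------------------------------
# Stage 1: per-trial analysis
# ---------------------------------------------------------------------------


def _hills_weights(df: pd.DataFrame, invert: bool) -> tuple[np.ndarray, bool]:
    """Residual diagonal from hills harvested.

    Default (the program's convention): ``diag(R) = h / h_max``.  With
    ``invert=True``: ``diag(R) = h_max / h`` (fewer hills = noisier plot).
    Missing hills are mean-imputed and flagged.
    """
    if "hills" not in df.columns or df["hills"].isna().all():
        return np.ones(len(df)), False
    h = df["hills"].astype(float).to_numpy()
    imputed = np.isnan(h)
    if imputed.any():
        h = np.where(imputed, np.nanmean(h), h)
    h_max = float(np.max(h))
    w = (h_max / h) if invert else (h / h_max)
    return np.clip(w, 1e-8, None), bool(imputed.any())


def _candidate_model_fits(
    df: pd.DataFrame,
    trait: str,
    design: str,
    residual_weights: np.ndarray,
    include_hills_covariate: bool = True,
    tol: float = 1e-8,
) -> list[tuple[tuple[str, ...], LmmFit]]:
    """Fit every design-specific candidate blocking model; return (terms, fit)."""
    from itertools import chain, combinations

    factors = [
        f
        for f in DESIGN_FACTORS[design]
        if f in df.columns and df[f].notna().any() and df[f].astype(str).nunique() > 1
    ]
    subsets = list(
        chain.from_iterable(combinations(factors, r) for r in range(len(factors) + 1))
    )
    hills_opts: list[bool] = [False]
    if (
        include_hills_covariate
        and "hills" in df.columns
        and df["hills"].notna().any()
        and df["hills"].nunique() > 1
    ):
        hills_opts.append(True)

    y = df[trait].astype(float).to_numpy()
    Zg, g_levels = _design_matrix_factor(df["genotype"])
    results: list[tuple[tuple[str, ...], LmmFit]] = []
    for subset in subsets:
        for use_hills in hills_opts:
            X_cols = [np.ones((len(df), 1))]
            names = ["intercept"]
            rts = [RandomTerm("genotype", Zg, g_levels)]
            for f in subset:
                Zf, f_levels = _design_matrix_factor(df[f])
                if len(f_levels) > RANDOM_LEVELS_MIN:
                    rts.append(RandomTerm(f, Zf, f_levels))
                else:
                    X_cols.append(Zf[:, 1:])  # drop first level (reference)
                    names += [f"{f}[{lv}]" for lv in f_levels[1:]]
            if use_hills:
                h = df["hills"].astype(float).to_numpy()
                h = np.where(np.isnan(h), np.nanmean(h), h)
                cov = (np.nanmax(h) - h).reshape(-1, 1)
                X_cols.append(cov)
                names.append("missing_hills")
            X = np.hstack(X_cols)
            terms = subset + (("missing_hills",) if use_hills else ())
            try:
                fit = fit_lmm_reml(
                    y, X, rts, residual_weights=residual_weights,
                    fixed_names=names, tol=tol,
                )
            except (ConvergenceError, ModelSpecificationError) as exc:
                logger.debug("candidate %s failed: %s", terms, exc)
                continue
            results.append((terms, fit))
    return results


def select_blocking_model(
    trial: TrialTable,
    trait: str = "yield_kg_ha",
    invert_hills_weight: bool = False,
) -> tuple[tuple[str, ...], LmmFit]:
    """Pick the blocking-factor subset minimizing BIC for one trial.

    Candidate factors depend on the design (row-column: row, column; p-rep:
    row, column, replicate, block; RCBD/augmented: replicate; alpha-lattice:
    replicate, block-in-replicate, row, column), optionally plus a covariate
    for missing hills.  Factors with more than five levels enter as random
    effects, otherwise as fixed.  Falls back to the genotype-only model with
    a warning when no candidate converges.
    """
    df = trial.plots.loc[trial.plots[trait].notna()].reset_index(drop=True)
    w, _ = _hills_weights(df, invert=invert_hills_weight)
    fits = _candidate_model_fits(df, trait, trial.design, w)
    if not fits:
        warnings.warn(
            f"no candidate blocking model converged for {trial.environment_id}; "
            "falling back to genotype-only",
            stacklevel=2,
        )
        y = df[trait].astype(float).to_numpy()
        Zg, g_levels = _design_matrix_factor(df["genotype"])
        fit = fit_lmm_reml(
            y, np.ones((len(df), 1)), [RandomTerm("genotype", Zg, g_levels)],
            residual_weights=w, fixed_names=["intercept"],
        )
        return (), fit
    return min(fits, key=lambda tf: tf[1].bic)


def stage1_analyze_trial(
    trial: TrialTable,
    trait: str = "yield_kg_ha",
    invert_hills_weight: bool = False,
) -> BlupResult:
    """Stage-1 analysis of one trial: BIC model selection, BLUPs, reliabilities."""
    df = trial.plots
    if trait not in df.columns:
        raise ValueError(f"trait column {trait!r} missing from trial")
    miss = float(df[trait].isna().mean())
    if miss > MISSING_MAX:
        raise TrialRejectedError(
            f"trial {trial.environment_id}: {miss:.1%} missing {trait} exceeds "
            f"{MISSING_MAX:.0%}"
        )
    if df["genotype"].nunique() < 2:
        raise ValueError("trial needs at least 2 genotypes")
    terms, fit = select_blocking_model(trial, trait, invert_hills_weight)
    tab = fit.random_effects["genotype"].rename(columns={"level": "genotype"})
    s2g = fit.vc.sigma2_g
    rel = 1.0 - tab["pev"] / s2g if s2g > 0 else pd.Series(0.0, index=tab.index)
    tab = tab.assign(reliability=np.clip(rel, 0.0, 1.0 - 1e-12))
    obs = df.loc[df[trait].notna(), "genotype"]
    mean_reps = float(obs.value_counts().mean())
    return BlupResult(
        environment_id=trial.environment_id,
        trait=trait,
        table=tab,
        vc=fit.vc,
        mean=float(fit.beta[0]),
        loglik=fit.loglik,
        bic=fit.bic,
        model_terms=terms,
        n_obs=fit.n_obs,
        mean_reps=mean_reps,
    )


# ---------------------------------------------------------------------------
# De-regression and stage 2
# ---------------------------------------------------------------------------


def deregress(
    blup: BlupResult, reliability_floor: float = 0.05
) -> pd.DataFrame:
    """De-regress stage-1 BLUPs: ``y_dr = blup / r2``, weight = r2.

    Records with reliability below the floor (or <= 0) are dropped and the
    count logged; division by a non-positive reliability never happens.
    """
    t = blup.table
    keep = t["reliability"] >= max(reliability_floor, 1e-12)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info(
            "deregress: dropped %d/%d genotypes with r2 < %.3g in %s",
            n_drop, len(t), reliability_floor, blup.environment_id,
        )
    t = t.loc[keep]
    # the trial mean is carried along so stage-2 environment effects absorb it
    # and breeding values come out on the trait scale
    return pd.DataFrame(
        {
            "genotype": t["genotype"].to_numpy(),
            "environment_id": blup.environment_id,
            "y_dr": (blup.mean + t["blup"] / t["reliability"]).to_numpy(),
            "weight": t["reliability"].to_numpy(),
        }
    )


@dataclass
class BreedingValueTable:
    """Stage-2 output joined with pedigree metadata."""

    table: pd.DataFrame  # line_id, bv_yield, reliability, eqg, cross_year, ...
    vc: VarianceComponents
    mean: float


def stage2_breeding_values(
    records: pd.DataFrame,
    ped: Pedigree,
    flowering: Optional[pd.DataFrame] = None,
    center_deviations: bool = True,
) -> BreedingValueTable:
    """Pedigree mixed model across environments on de-regressed BLUPs.

    ``records`` has columns genotype, environment_id, y_dr, weight (stage-1
    reliability).  Environment is fixed (full dummy coding, no intercept),
    days-to-flowering — supplied as per genotype x environment stage-1 BLUPs
    in ``flowering`` (genotype, environment_id, blup) — is a fixed covariate,
    centered so the reported overall mean is at the mean flowering.  The
    genetic effect covers every pedigree line with covariance A sigma2_g via
    the sparse A-inverse; the residual diagonal is ``1 / r2``.

    Breeding values are overall mean (average environment effect) + genetic
    effect.  Lines observed in no environment still receive (shrunken)
    values through their relatives; genotypes absent from any relative's
    data are flagged low-information via reliability ~ 0.
    """
    req = {"genotype", "environment_id", "y_dr", "weight"}
    if not req <= set(records.columns):
        raise ValueError(f"records must have columns {sorted(req)}")
    df = records.copy()
    unknown = sorted(set(df["genotype"]) - set(ped.index))
    if unknown:
        raise ValueError(f"genotypes not in pedigree: {unknown[:10]}")
    n_env = df["environment_id"].nunique()
    if n_env < 2:
        raise ValueError("stage 2 requires records from at least 2 environments")

    if flowering is not None:
        flw = flowering.rename(columns={"blup": "covariate_flowering"})
        df = df.merge(
            flw[["genotype", "environment_id", "covariate_flowering"]],
            on=["genotype", "environment_id"],
            how="left",
        )
        n_miss = int(df["covariate_flowering"].isna().sum())
        if n_miss:
            logger.info("stage2: mean-imputed %d missing flowering covariates", n_miss)
            df["covariate_flowering"] = df["covariate_flowering"].fillna(
                df["covariate_flowering"].mean()
            )
        cov = df["covariate_flowering"].to_numpy(dtype=float)
        cov = cov - cov.mean()
    else:
        cov = None

    y = df["y_dr"].to_numpy(dtype=float)
    Xe, env_levels = _design_matrix_factor(df["environment_id"])
    X_cols = [Xe]
    names = [f"env[{e}]" for e in env_levels]
    if cov is not None and np.std(cov) > 0:
        X_cols.append(cov.reshape(-1, 1))
        names.append("flowering")
    X = np.hstack(X_cols)

    # genotype incidence over the whole pedigree (sparse: records x lines)
    all_ids = ped.ids
    idx = {g: i for i, g in enumerate(all_ids)}
    cols = np.array([idx[g] for g in df["genotype"]], dtype=np.int64)
    Zg = sp.csr_matrix(
        (np.ones(len(df)), (np.arange(len(df)), cols)),
        shape=(len(df), len(all_ids)),
    )
    ainv, logdet_a = a_inverse_with_logdet(ped)
    rt = RandomTerm("genotype", Zg, all_ids, ginv=ainv, logdet_g=logdet_a)

    w = 1.0 / df["weight"].to_numpy(dtype=float)  # diag(R) = 1/r2
    fit = fit_lmm_reml(y, X, [rt], residual_weights=w, fixed_names=names)

    mu = float(np.mean(fit.beta[: len(env_levels)]))
    ge = fit.random_effects["genotype"]
    s2g = fit.vc.sigma2_g
    rel = np.clip(1.0 - ge["pev"] / s2g, 0.0, 1.0 - 1e-12) if s2g > 0 else 0.0
    counts = df["genotype"].value_counts()
    out = pd.DataFrame(
        {
            "line_id": ge["level"].to_numpy(),
            "bv_yield": mu + ge["blup"].to_numpy(),
            "reliability": rel,
            "eqg": ped.eqg(),
            "cross_year": [r.cross_year for r in ped.records],
            "entry_type": [r.entry_type.value for r in ped.records],
            "n_env": [int(counts.get(g, 0)) for g in ge["level"]],
        }
    )
    out["low_information"] = (out["n_env"] == 0) & (out["reliability"] < 0.05)
    return BreedingValueTable(table=out, vc=fit.vc, mean=mu)


def trial_repeatability(blup: BlupResult) -> float:
    """Line-mean repeatability ``H2 = s2g / (s2g + s2e / rbar)`` of one trial."""
    s2g, s2e = blup.vc.sigma2_g, blup.vc.sigma2_e
    if s2g + s2e <= 0:
        raise ValueError("repeatability undefined: sigma2_g + sigma2_e = 0")
    rbar = blup.mean_reps if np.isfinite(blup.mean_reps) and blup.mean_reps > 0 else 1.0
    return float(s2g / (s2g + s2e / rbar))
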