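"""Multilevel random-effects meta-analysis with a phylogenetic random effect.

The model for the k study-level effect sizes y (log odds ratios with known
sampling variances v) is

    y = X beta + Z_p u_p + Z_s u_s + e,
    u_p ~ N(0, sigma2_phylo * R),   u_s ~ N(0, sigma2_study * I),
    e_i ~ N(0, v_i),

where R is the species correlation matrix derived from a phylogeny, Z_p maps
effects to species, and Z_s maps effects to studies.  Variance components are
estimated by REML over the non-negative orthant; beta by generalized least
squares at the optimum, with normal-theory Wald tests and 95% CIs.

Two evaluation paths give identical answers: a dense textbook path (builds
the full marginal covariance V), and a low-rank path used when every study
contributes exactly one effect (then Z_s Z_s' = I and only the species block
is non-diagonal), which keeps all factorizations at n_species size.

Alongside the fit live the residual-heterogeneity Q test, Egger's regression
test for funnel asymmetry (standard error appended as a moderator, or the
classical precision regression), leave-one-out influence diagnostics, and
the outlier-excluded refit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg, optimize, stats

from .effect_sizes import EffectSize
from .tree_tools import VCVMatrix

__all__ = [
    "MetaModelSpec",
    "MetaFit",
    "EggerResult",
    "InfluenceReport",
    "MetaModel",
    "fit_meta",
    "q_residual",
    "egger_test",
    "influence_diagnostics",
    "refit_without_outliers",
    "RankError",
]

EGGER_ALPHA = 0.10  # funnel asymmetry called at P < 0.10, two-sided
LOW_POWER_STUDIES = 5  # fits on fewer studies are flagged as low-powered


class RankError(ValueError):
    """The fixed-effect design matrix is rank deficient."""


@dataclass(frozen=True)
class MetaModelSpec:
    """Fixed-effect structure of the meta-regression.

    moderators may contain "period" (reference level: breeding) and
    "detection" (reference level: microscopy); both enter treatment-coded on
    top of an intercept.  Estimation is REML.
    """

    moderators: tuple[str, ...] = ()
    estimation: str = "REML"

    def __post_init__(self):
        for m in self.moderators:
            if m not in ("period", "detection"):
                raise ValueError(f"unknown moderator {m!r}")
        if self.estimation != "REML":
            raise ValueError("only REML estimation is supported")


_PERIOD_LEVELS = ("breeding", "nonbreeding", "year_round")  # ref = breeding
_DETECTION_LEVELS = ("microscopy", "molecular", "both")  # ref = microscopy


@dataclass
class MetaFit:
    """A fitted multilevel meta-analysis."""

    coef_names: list[str]
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    sigma2_phylo: float
    sigma2_study: float
    QE: float
    QE_df: int
    QE_p: float
    k: int
    n_species: int
    n_studies: int
    loglik_reml: float
    low_power_flag: bool
    model: "MetaModel" = field(repr=False)

    @property
    def estimate(self) -> float:
        """Pooled estimate: the intercept at reference moderator levels."""
        return float(self.beta[0])


@dataclass(frozen=True)
class EggerResult:
    estimate: float
    se: float
    p: float
    mode: str

    @property
    def biased(self) -> bool:
        return self.p < EGGER_ALPHA


@dataclass
class InfluenceReport:
    effect_ids: list[tuple[str, str]]  # (study_id, species)
    estimate_shift: np.ndarray  # full-fit intercept minus leave-one-out
    loo_estimate: np.ndarray
    rstudent: np.ndarray
    hat: np.ndarray
    cooks_d: np.ndarray
    flagged: list[int]

    @property
    def flagged_ids(self) -> list[tuple[str, str]]:
        return [self.effect_ids[i] for i in self.flagged]


def _build_design(
    effects: Sequence[EffectSize], spec: MetaModelSpec, extra_se: bool = False
) -> tuple[np.ndarray, list[str]]:
    k = len(effects)
    cols: list[np.ndarray] = [np.ones(k)]
    names = ["intercept"]
    if "period" in spec.moderators:
        present = {e.period for e in effects}
        for level in _PERIOD_LEVELS[1:]:
            if level in present:
                cols.append(np.array([1.0 if e.period == level else 0.0 for e in effects]))
                names.append(f"period[{level}]")
    if "detection" in spec.moderators:
        present = {e.detection for e in effects}
        for level in _DETECTION_LEVELS[1:]:
            if level in present:
                cols.append(
                    np.array([1.0 if e.detection == level else 0.0 for e in effects])
                )
                names.append(f"detection[{level}]")
    if extra_se:
        cols.append(np.array([e.sei for e in effects]))
        names.append("sei")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify the first column aliased with its predecessors
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) <= np.linalg.matrix_rank(X[:, :j]):
                raise RankError(f"design column {names[j]!r} is aliased")
        raise RankError("design matrix is rank deficient")
    return X, names


class MetaModel:
    """Holds the data/design and evaluates the REML objective.

    Parameters
    ----------
    effects : study-level effect sizes with known sampling variances.
    spec : fixed-effect structure.
    phylo : species *correlation* matrix (unit diagonal) covering every
        mapped species.
    mapping : optional explicit (species, study) pair per effect; by default
        taken from each effect's own species key and study id.
    """

    def __init__(
        self,
        effects: Sequence[EffectSize],
        spec: MetaModelSpec = MetaModelSpec(),
        phylo: VCVMatrix | None = None,
        mapping: Sequence[tuple[str, str]] | None = None,
        extra_se_moderator: bool = False,
    ):
        if len(effects) < 2:
            raise ValueError("need at least 2 effect sizes")
        self.effects = list(effects)
        self.spec = spec
        k = len(self.effects)
        self.y = np.array([e.yi for e in self.effects])
        self.v = np.array([e.vi for e in self.effects])
        if np.any(self.v <= 0):
            raise ValueError("all sampling variances must be positive")
        self.X, self.coef_names = _build_design(self.effects, spec, extra_se_moderator)

        if mapping is None:
            mapping = [(e.species_key, e.study_id) for e in self.effects]
        elif len(mapping) != k:
            raise ValueError("mapping length must equal the number of effects")
        self.species = [m[0] for m in mapping]
        self.studies = [m[1] for m in mapping]

        sp_levels = sorted(set(self.species))
        self.species_levels = sp_levels
        self.sp_idx = np.array([sp_levels.index(s) for s in self.species])
        st_levels = sorted(set(self.studies))
        self.study_levels = st_levels
        self.st_idx = np.array([st_levels.index(s) for s in self.studies])

        ns = len(sp_levels)
        if phylo is None:
            self.R = np.eye(ns)
        else:
            aligned = phylo.submatrix(sp_levels)
            self.R = np.asarray(aligned.C, dtype=float)
            if not np.allclose(np.diag(self.R), 1.0, atol=1e-6):
                raise ValueError(
                    "phylo matrix must be a correlation matrix (unit diagonal)"
                )

        # each study contributing exactly one effect makes Z_s Z_s' = I and
        # enables the low-rank path
        self._studies_unique = len(st_levels) == k

        self.Zp = np.zeros((k, ns))
        self.Zp[np.arange(k), self.sp_idx] = 1.0
        self.Zs = np.zeros((k, len(st_levels)))
        self.Zs[np.arange(k), self.st_idx] = 1.0
        self.A = self.Zp @ self.R @ self.Zp.T
        self.B = self.Zs @ self.Zs.T

    # ---- REML objective -------------------------------------------------

    def reml_loglik(self, sigma2_phylo: float, sigma2_study: float) -> float:
        nll, _ = self._nll_grad(np.array([sigma2_phylo, sigma2_study]))
        return -nll

    def _nll_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        if self._studies_unique:
            return self._nll_grad_lowrank(theta)
        return self._nll_grad_dense(theta)

    def _nll_grad_dense(self, theta):
        sp, ss = float(theta[0]), float(theta[1])
        k, p = self.X.shape
        V = sp * self.A + ss * self.B + np.diag(self.v)
        cho = linalg.cho_factor(V, lower=True)
        logdetV = 2.0 * np.sum(np.log(np.diag(cho[0])))
        ViX = linalg.cho_solve(cho, self.X)
        Viy = linalg.cho_solve(cho, self.y)
        XtViX = self.X.T @ ViX
        choX = linalg.cho_factor(XtViX)
        logdetXtViX = 2.0 * np.sum(np.log(np.diag(choX[0])))
        beta = linalg.cho_solve(choX, self.X.T @ Viy)
        r = self.y - self.X @ beta
        Py = linalg.cho_solve(cho, r)
        quad = float(r @ Py)
        ll = -0.5 * ((k - p) * math.log(2 * math.pi) + logdetV + logdetXtViX + quad)

        grad = np.empty(2)
        M = linalg.cho_solve(choX, ViX.T)  # (X'V^-1X)^-1 X'V^-1
        for j, Aj in enumerate((self.A, self.B)):
            ViAj = linalg.cho_solve(cho, Aj)
            tr_P_Aj = np.trace(ViAj) - float(np.sum((ViX @ M) * Aj))
            quad_j = float(Py @ Aj @ Py)
            # derivative of ll; grad of nll is its negative
            grad[j] = 0.5 * (tr_P_Aj - quad_j)
        return -ll, grad

    def _nll_grad_lowrank(self, theta):
        sp, ss = float(theta[0]), float(theta[1])
        k, p = self.X.shape
        ns = self.R.shape[0]
        s = self.v + ss  # Sigma diagonal
        inv_s = 1.0 / s
        Svec = np.bincount(self.sp_idx, weights=inv_s, minlength=ns)
        F = np.eye(ns) + sp * (self.R * Svec[None, :])  # I + sp R S
        lu = linalg.lu_factor(F)
        G = sp * linalg.lu_solve(lu, self.R)
        G = 0.5 * (G + G.T)
        sign, logdetF = np.linalg.slogdet(F)
        if sign <= 0:
            raise linalg.LinAlgError("marginal covariance not positive definite")
        logdetV = float(np.sum(np.log(s)) + logdetF)

        def visolve(Mat):
            u = Mat * inv_s[..., None] if Mat.ndim == 2 else Mat * inv_s
            if Mat.ndim == 2:
                T = np.zeros((ns, Mat.shape[1]))
                np.add.at(T, self.sp_idx, u)
                w = G @ T
                return u - w[self.sp_idx, :] * inv_s[:, None]
            T = np.bincount(self.sp_idx, weights=u, minlength=ns)
            w = G @ T
            return u - w[self.sp_idx] * inv_s

        ViX = visolve(self.X)
        Viy = visolve(self.y)
        XtViX = self.X.T @ ViX
        choX = linalg.cho_factor(XtViX)
        logdetXtViX = 2.0 * np.sum(np.log(np.diag(choX[0])))
        beta = linalg.cho_solve(choX, self.X.T @ Viy)
        r = self.y - self.X @ beta
        Py = visolve(r)
        quad = float(r @ Py)
        ll = -0.5 * ((k - p) * math.log(2 * math.pi) + logdetV + logdetXtViX + quad)

        # K = Zp' V^-1 Zp = S - S G S  (S diagonal)
        K = np.diag(Svec) - (Svec[:, None] * G) * Svec[None, :]
        tr_Vi_A = float(np.sum(self.R * K))
        tr_Vi_B = float(np.sum(inv_s) - np.sum(inv_s**2 * np.diag(G)[self.sp_idx]))

        Minv = linalg.cho_solve(choX, np.eye(p))
        T_X = np.zeros((ns, p))
        np.add.at(T_X, self.sp_idx, ViX)
        corr_A = float(np.sum(Minv * (T_X.T @ self.R @ T_X)))
        corr_B = float(np.sum(Minv * (ViX.T @ ViX)))

        ZtPy = np.bincount(self.sp_idx, weights=Py, minlength=ns)
        quad_A = float(ZtPy @ self.R @ ZtPy)
        quad_B = float(Py @ Py)

        grad = np.array(
            [
                0.5 * ((tr_Vi_A - corr_A) - quad_A),
                0.5 * ((tr_Vi_B - corr_B) - quad_B),
            ]
        )
        return -ll, grad

    # ---- fitting --------------------------------------------------------

    def _starts(self) -> list[tuple[float, float]]:
        vy = float(np.var(self.y, ddof=1)) if len(self.y) > 1 else 0.1
        t0 = max(vy - float(np.mean(self.v)), 1e-3 * vy + 1e-8)
        return [
            (0.5 * t0, 0.5 * t0),
            (t0, 0.1 * t0),
            (0.1 * t0, t0),
            (1e-8, 1e-8),
            (max(vy, 1e-6), max(vy, 1e-6)),
        ]

    def optimize(self) -> tuple[np.ndarray, float]:
        """Maximize the REML log-likelihood over the non-negative orthant.

        Five deterministic starts; stops early once two consecutive extra
        starts fail to improve the best objective (they almost always land on
        the same optimum).
        """
        best = None
        stale = 0
        for start in self._starts():
            res = optimize.minimize(
                self._nll_grad,
                x0=np.asarray(start, dtype=float),
                jac=True,
                method="L-BFGS-B",
                bounds=[(0.0, None), (0.0, None)],
                options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-8},
            )
            if best is None or res.fun < best.fun - 1e-8:
                best = res
                stale = 0
            else:
                stale += 1
                if stale >= 2:
                    break
        if best is None or not np.all(np.isfinite(best.x)):
            raise RuntimeError("REML optimization failed to produce an estimate")
        return np.maximum(best.x, 0.0), -float(best.fun)

    def fit(self) -> MetaFit:
        theta, loglik = self.optimize()
        sp, ss = float(theta[0]), float(theta[1])
        beta, cov_beta = self.gls_beta(sp, ss)
        se = np.sqrt(np.diag(cov_beta))
        z = beta / se
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        qe, qdf, qp = self._q_statistic()
        fit = MetaFit(
            coef_names=list(self.coef_names),
            beta=beta,
            se=se,
            z=z,
            p=pvals,
            ci_low=beta - 1.959963984540054 * se,
            ci_high=beta + 1.959963984540054 * se,
            sigma2_phylo=sp,
            sigma2_study=ss,
            QE=qe,
            QE_df=qdf,
            QE_p=qp,
            k=len(self.y),
            n_species=len(self.species_levels),
            n_studies=len(self.study_levels),
            loglik_reml=loglik,
            low_power_flag=len(self.study_levels) < LOW_POWER_STUDIES,
            model=self,
        )
        return fit

    def gls_beta(self, sp: float, ss: float) -> tuple[np.ndarray, np.ndarray]:
        V = sp * self.A + ss * self.B + np.diag(self.v)
        cho = linalg.cho_factor(V, lower=True)
        ViX = linalg.cho_solve(cho, self.X)
        XtViX = self.X.T @ ViX
        choX = linalg.cho_factor(XtViX)
        beta = linalg.cho_solve(choX, ViX.T @ self.y)
        cov = linalg.cho_solve(choX, np.eye(self.X.shape[1]))
        return beta, cov

    def hat_values(self, sp: float, ss: float) -> np.ndarray:
        """Diagonal of the GLS projection H = X (X'V^-1 X)^-1 X' V^-1."""
        V = sp * self.A + ss * self.B + np.diag(self.v)
        cho = linalg.cho_factor(V, lower=True)
        ViX = linalg.cho_solve(cho, self.X)
        XtViX = self.X.T @ ViX
        Minv = linalg.cho_solve(linalg.cho_factor(XtViX), np.eye(self.X.shape[1]))
        return np.einsum("ij,jk,ik->i", self.X, Minv, ViX)

    def _q_statistic(self) -> tuple[float, int, float]:
        w = 1.0 / self.v
        WX = self.X * w[:, None]
        beta_w = np.linalg.solve(self.X.T @ WX, WX.T @ self.y)
        resid = self.y - self.X @ beta_w
        qe = float(np.sum(w * resid**2))
        df = len(self.y) - self.X.shape[1]
        if df <= 0:
            raise ValueError("Q undefined: no residual degrees of freedom")
        return qe, df, float(stats.chi2.sf(qe, df))


def fit_meta(
    effects: Sequence[EffectSize],
    spec: MetaModelSpec = MetaModelSpec(),
    phylo: VCVMatrix | None = None,
    mapping: Sequence[tuple[str, str]] | None = None,
) -> MetaFit:
    """Fit the multilevel phylogenetic meta-analysis (see module docstring)."""
    return MetaModel(effects, spec, phylo, mapping).fit()


def q_residual(fit: MetaFit) -> tuple[float, int, float]:
    """Residual heterogeneity: Q = sum of 1/v_i-weighted squared residuals
    after removing moderator effects, with df = k - rank(X) and a chi-square
    upper-tail P."""
    return fit.model._q_statistic()


def egger_test(
    effects: Sequence[EffectSize],
    spec: MetaModelSpec = MetaModelSpec(),
    phylo: VCVMatrix | None = None,
    mode: str = "se_moderator",
    mapping: Sequence[tuple[str, str]] | None = None,
) -> EggerResult:
    """Egger's regression test for funnel-plot asymmetry.

    ``se_moderator`` (default) appends each effect's standard error to the
    moderator matrix of the multilevel model and tests that coefficient;
    ``precision_regression`` is the classical Egger test (regress yi/sei on
    1/sei by OLS and test the intercept).  Asymmetry is called at P < 0.10.
    """
    if len(effects) < 3:
        raise ValueError("Egger's test needs at least 3 effect sizes")
    sei = np.array([e.sei for e in effects])
    if np.allclose(sei, sei[0]):
        raise ValueError(
            "all standard errors identical: the Egger term is aliased "
            "with the intercept"
        )
    if mode == "se_moderator":
        model = MetaModel(effects, spec, phylo, mapping, extra_se_moderator=True)
        fit = model.fit()
        j = model.coef_names.index("sei")
        return EggerResult(
            estimate=float(fit.beta[j]), se=float(fit.se[j]), p=float(fit.p[j]),
            mode=mode,
        )
    if mode == "precision_regression":
        y = np.array([e.yi for e in effects]) / sei
        x = 1.0 / sei
        X = np.column_stack([np.ones_like(x), x])
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = len(y) - 2
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(X.T @ X)
        se0 = math.sqrt(cov[0, 0])
        t0 = beta[0] / se0
        p0 = 2.0 * stats.t.sf(abs(t0), dof)
        return EggerResult(estimate=float(beta[0]), se=se0, p=float(p0), mode=mode)
    raise ValueError(f"unknown Egger mode {mode!r}")


def influence_diagnostics(
    fit: MetaFit,
    resid_threshold: float = 2.0,
    hat_factor: float = 2.0,
) -> InfluenceReport:
    """Leave-one-out influence diagnostics for every effect size.

    Each effect is deleted in turn and the model refit (variance components
    re-estimated); reported are the shift in the pooled estimate, the
    studentized deleted residual, the GLS hat value, and a Cook's-distance
    analogue.  An effect is flagged when |studentized deleted residual| >
    ``resid_threshold`` AND hat > ``hat_factor`` x mean(hat).
    """
    model = fit.model
    k = len(model.y)
    if k < 3:
        raise ValueError("influence diagnostics need at least 3 effects")
    # leverage under the known sampling variances (the QE weighting): an
    # extreme, ultra-precise effect inflates the estimated variance
    # components, which would equalize marginal-V hat values and mask it
    hat = model.hat_values(0.0, 0.0)
    shifts = np.empty(k)
    loo_est = np.empty(k)
    rstud = np.empty(k)
    cooks = np.empty(k)
    _, cov_full = model.gls_beta(fit.sigma2_phylo, fit.sigma2_study)
    XtViX_full = np.linalg.inv(cov_full)
    p = model.X.shape[1]
    for i in range(k):
        keep = [j for j in range(k) if j != i]
        sub = MetaModel(
            [model.effects[j] for j in keep],
            model.spec,
            phylo=None,
            mapping=[(model.species[j], model.studies[j]) for j in keep],
        )
        # reuse the already-aligned correlation matrix rather than re-pruning
        sub_levels = sub.species_levels
        idx = [model.species_levels.index(s) for s in sub_levels]
        sub.R = model.R[np.ix_(idx, idx)]
        sub.A = sub.Zp @ sub.R @ sub.Zp.T
        sub_fit = sub.fit()
        loo_est[i] = sub_fit.estimate
        shifts[i] = fit.estimate - sub_fit.estimate
        xi = model.X[i]
        beta_i, cov_i = sub.gls_beta(sub_fit.sigma2_phylo, sub_fit.sigma2_study)
        pred = float(xi @ beta_i)
        sp_i = model.sp_idx[i]
        marg = (
            sub_fit.sigma2_phylo * model.R[sp_i, sp_i]
            + sub_fit.sigma2_study
            + model.v[i]
        )
        var_pred = float(xi @ cov_i @ xi) + marg
        rstud[i] = (model.y[i] - pred) / math.sqrt(var_pred)
        dbeta = fit.beta - beta_i
        cooks[i] = float(dbeta @ XtViX_full @ dbeta) / p
    mean_hat = float(np.mean(hat))
    flagged = [
        i
        for i in range(k)
        if abs(rstud[i]) > resid_threshold and hat[i] > hat_factor * mean_hat
    ]
    return InfluenceReport(
        effect_ids=[(e.study_id, e.species) for e in model.effects],
        estimate_shift=shifts,
        loo_estimate=loo_est,
        rstudent=rstud,
        hat=hat,
        cooks_d=cooks,
        flagged=flagged,
    )


def refit_without_outliers(
    effects: Sequence[EffectSize],
    spec: MetaModelSpec,
    phylo: VCVMatrix | None,
    report: InfluenceReport,
    mapping: Sequence[tuple[str, str]] | None = None,
    original_fit: MetaFit | None = None,
) -> MetaFit:
    """Refit after dropping the flagged effects (no-op when none flagged)."""
    if not report.flagged:
        return original_fit if original_fit is not None else fit_meta(
            effects, spec, phylo, mapping
        )
    keep = [i for i in range(len(effects)) if i not in set(report.flagged)]
    if len(keep) < 2:
        raise ValueError("outlier exclusion leaves fewer than 2 effects")
    sub_effects = [effects[i] for i in keep]
    sub_mapping = [mapping[i] for i in keep] if mapping is not None else None
    return fit_meta(sub_effects, spec, phylo, sub_mapping)
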