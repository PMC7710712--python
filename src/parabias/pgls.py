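"""Phylogenetic generalized least squares with maximum-likelihood Pagel's λ.

The residual covariance is sigma2 * C(lambda), where C(lambda) keeps the
phylogenetic covariance matrix's diagonal and multiplies its off-diagonal
entries by lambda in [0, 1].  For a fixed lambda, beta is the GLS estimate
with sigma2 profiled out; lambda is chosen by maximizing the profile ML
log-likelihood with a bounded scalar search (tolerance 1e-6), with both
interval endpoints checked explicitly so boundary optima (lambda = 0, i.e.
ordinary least squares, or lambda = 1, full Brownian structure) are exact.

t statistics use df = n - p - 1 and the residual-variance estimate
RSS/(n - p - 1) in whitened coordinates; adjusted R^2 compares the whitened
residual sums of squares of the model and of the intercept-only null fitted
under the same lambda-hat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .tree_tools import VCVMatrix, lambda_scale, prune_and_align, vcv_from_tree
from .data_io import canonical_name

__all__ = ["PGLSFit", "ModelSuiteResult", "fit_pgls", "run_model_suite", "MODEL_SUITE"]


@dataclass
class PGLSFit:
    """A fitted PGLS model."""

    coef_names: list[str]
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    lambda_ml: float
    loglik: float
    adj_r2: float
    n: int
    sigma2: float
    df_resid: int
    species: list[str] = field(default_factory=list)
    dropped_species: list[str] = field(default_factory=list)

    def slope(self, name: str) -> float:
        return float(self.beta[self.coef_names.index(name)])

    def pvalue(self, name: str) -> float:
        return float(self.p[self.coef_names.index(name)])


def _gls_profile(y: np.ndarray, X: np.ndarray, C: np.ndarray, lam: float):
    """GLS at fixed lambda; returns (beta, XtViX_inv, rss, logdetV, loglik_ml)."""
    n = len(y)
    V = lambda_scale(C, lam)
    cho = linalg.cho_factor(V, lower=True)
    logdetV = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    ViX = linalg.cho_solve(cho, X)
    Viy = linalg.cho_solve(cho, y)
    XtViX = X.T @ ViX
    choX = linalg.cho_factor(XtViX)
    beta = linalg.cho_solve(choX, X.T @ Viy)
    r = y - X @ beta
    rss = float(r @ linalg.cho_solve(cho, r))
    sigma2_ml = rss / n
    loglik = -0.5 * (n * math.log(2 * math.pi * sigma2_ml) + logdetV + n)
    XtViX_inv = linalg.cho_solve(choX, np.eye(X.shape[1]))
    return beta, XtViX_inv, rss, logdetV, loglik


def fit_pgls(
    y,
    X,
    tree: dendropy.Tree | None = None,
    vcv: VCVMatrix | None = None,
    lam: str | float = "ml",
    lambda_tol: float = 1e-6,
) -> PGLSFit:
    """Fit y ~ X under phylogenetically correlated residuals.

    Parameters
    ----------
    y : pandas Series indexed by species name.
    X : pandas DataFrame of predictors (no intercept column) on the same
        index; an intercept is always added.
    tree : phylogeny covering (at least) the complete-case species; pruned
        internally.  Alternatively pass a precomputed ``vcv``.
    lam : "ml" (default) maximizes the profile likelihood over [0, 1];
        a float fixes lambda.

    Rows with any missing value are dropped (listwise deletion) and recorded
    in ``dropped_species``.
    """
    y = pd.Series(y).astype(float)
    X = pd.DataFrame(X).astype(float)
    data = pd.concat([y.rename("__y__"), X], axis=1)
    complete = data.dropna()
    dropped = [s for s in data.index if s not in complete.index]
    n = len(complete)
    p = X.shape[1]
    if n <= p + 1:
        raise ValueError(
            f"insufficient data: n={n} complete cases for p={p} predictors"
        )
    species = list(complete.index)

    if vcv is None:
        if tree is None:
            raise ValueError("supply a tree or a precomputed VCV matrix")
        pruned, index_map = prune_and_align(tree, species)
        full = vcv_from_tree(pruned, scale="covariance")
        order = [index_map[canonical_name(s).casefold()] for s in species]
        C = full.C[np.ix_(order, order)]
    else:
        C = vcv.submatrix(species).C

    yv = complete["__y__"].to_numpy()
    Xmat = np.column_stack([np.ones(n), complete.drop(columns="__y__").to_numpy()])
    names = ["intercept"] + list(X.columns)

    if lam == "ml":
        def neg_ll(l):
            try:
                return -_gls_profile(yv, Xmat, C, l)[4]
            except linalg.LinAlgError:
                return np.inf  # singular covariance (e.g. duplicate tips at 1)

        res = optimize.minimize_scalar(
            neg_ll, bounds=(0.0, 1.0), method="bounded",
            options={"xatol": lambda_tol},
        )
        candidates = [(res.x, -res.fun), (0.0, -neg_ll(0.0)), (1.0, -neg_ll(1.0))]
        lam_hat, _ = max(candidates, key=lambda c: c[1])
    else:
        lam_hat = float(lam)
        if not 0.0 <= lam_hat <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")

    beta, XtViX_inv, rss, _, loglik = _gls_profile(yv, Xmat, C, lam_hat)
    df_resid = n - p - 1
    sigma2 = rss / df_resid
    se = np.sqrt(sigma2 * np.diag(XtViX_inv))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)

    # null model: intercept only, same lambda
    _, _, rss_null, _, _ = _gls_profile(yv, Xmat[:, :1], C, lam_hat)
    adj_r2 = 1.0 - (rss / df_resid) / (rss_null / (n - 1))

    return PGLSFit(
        coef_names=names,
        beta=beta,
        se=se,
        t=tvals,
        p=pvals,
        lambda_ml=float(lam_hat),
        loglik=float(loglik),
        adj_r2=float(adj_r2),
        n=n,
        sigma2=float(sigma2),
        df_resid=df_resid,
        species=species,
        dropped_species=dropped,
    )


# the six-model suite run per parasite class: response, predictors
MODEL_SUITE: tuple[tuple[str, str, tuple[str, ...]], ...] = (
    ("male_single", "logit_mort_m", ("logit_prev_m",)),
    ("female_single", "logit_mort_f", ("logit_prev_f",)),
    ("bias_single", "mort_bias", ("prev_bias",)),
    ("male_multi", "logit_mort_m", ("logit_prev_m", "log_mass_m", "male_polygamy")),
    ("female_multi", "logit_mort_f", ("logit_prev_f", "log_mass_f", "female_polygamy")),
    ("bias_multi", "mort_bias", ("prev_bias", "ssd", "mating_bias")),
)


@dataclass
class ModelSuiteResult:
    fits: dict[str, PGLSFit]
    skipped: dict[str, str]


def run_model_suite(
    species_table: pd.DataFrame,
    tree: dendropy.Tree,
    models: Sequence[tuple[str, str, tuple[str, ...]]] = MODEL_SUITE,
    lam: str | float = "ml",
) -> ModelSuiteResult:
    """Run the per-class model suite on a species-level table.

    ``species_table`` is indexed by species and must carry the derived
    variables named in ``models`` (missing values allowed; each model applies
    its own listwise deletion).  ``prev_bias`` is the species-level weighted
    average sex-bias log odds ratio.  Models whose complete-case n falls at
    or below the estimability bound are skipped with a reason.
    """
    fits: dict[str, PGLSFit] = {}
    skipped: dict[str, str] = {}
    for name, response, predictors in models:
        missing_cols = [
            c for c in (response, *predictors) if c not in species_table.columns
        ]
        if missing_cols:
            skipped[name] = f"missing columns: {missing_cols}"
            continue
        try:
            fits[name] = fit_pgls(
                species_table[response],
                species_table[list(predictors)],
                tree=tree,
                lam=lam,
            )
        except ValueError as exc:
            skipped[name] = str(exc)
    return ModelSuiteResult(fits=fits, skipped=skipped)
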