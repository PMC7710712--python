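"""Independent brute-force oracles used by the test suite.

These deliberately re-derive everything from textbook formulas with dense
matrices and naive enumeration, sharing no code path with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def reml_loglik_brute(y, X, v, sp_idx, st_idx, R, sigma2_phylo, sigma2_study):
    """Textbook REML log-likelihood via the explicit marginal covariance."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    v = np.asarray(v, float)
    k = len(y)
    p = X.shape[1]
    ns = R.shape[0]
    nst = int(np.max(st_idx)) + 1
    Zp = np.zeros((k, ns))
    Zp[np.arange(k), sp_idx] = 1.0
    Zs = np.zeros((k, nst))
    Zs[np.arange(k), st_idx] = 1.0
    V = sigma2_phylo * Zp @ R @ Zp.T + sigma2_study * Zs @ Zs.T + np.diag(v)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    _, ldV = np.linalg.slogdet(V)
    _, ldX = np.linalg.slogdet(XtViX)
    ll = -0.5 * ((k - p) * math.log(2 * math.pi) + ldV + ldX + r @ Vi @ r)
    return float(ll), beta


def gls_brute(y, X, V):
    """GLS estimate and covariance via explicit matrix inversion."""
    Vi = np.linalg.inv(V)
    XtViX_inv = np.linalg.inv(X.T @ Vi @ X)
    beta = XtViX_inv @ X.T @ Vi @ y
    return beta, XtViX_inv


def clade_frequencies_brute(trees):
    """For every tip subset, the fraction of trees in which it is monophyletic.

    Monophyly is checked from scratch: a subset S is a clade of a rooted tree
    iff some node's descendant-leaf set equals S.  Only feasible for small
    tip counts.
    """
    trees = list(trees)
    tips = sorted(leaf.taxon.label for leaf in trees[0].leaf_node_iter())
    freqs = {}
    for r in range(2, len(tips)):
        for subset in itertools.combinations(tips, r):
            target = frozenset(subset)
            hits = 0
            for tree in trees:
                clades = set()
                for node in tree.preorder_internal_node_iter():
                    clades.add(frozenset(l.taxon.label for l in node.leaf_iter()))
                if target in clades:
                    hits += 1
            freqs[target] = hits / len(trees)
    return freqs


def pgls_ols_brute(y, x):
    """Simple-regression OLS closed form (slope, intercept)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
    return slope, float(np.mean(y) - slope * np.mean(x))
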