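"""Phylogenetic generalized least squares under a Brownian-motion covariance.

Shared ancestry makes species traits correlated: under Brownian trait
evolution the covariance of two tips equals the branch length their
root-to-tip paths share (the depth of their most recent common ancestor).
PGLS is ordinary linear regression with that tip-by-tip matrix V as the
residual covariance structure,

    beta_hat = (X' V^-1 X)^-1 X' V^-1 y ,

estimated here by Cholesky whitening.  Reported per-model statistics follow
the comparative-methods convention: sigma^2 = e' V^-1 e / (n - k), Student-t
tests per coefficient, a generalized R^2 against the GLS intercept-only
null, and F = (R^2/df1) / ((1-R^2)/df2) with df1 = #predictors and
df2 = n - #predictors - 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "RESPONSES",
    "PREDICTORS",
    "ComparativeDataset",
    "PGLSResult",
    "PGLSRegression",
    "brownian_covariance",
    "pgls_fit",
    "standardized_fit",
    "run_full_analysis",
    "results_long_table",
    "model_summary_table",
]

RESPONSES = ("D_hyd", "D_pol", "D_vol", "D_pI")
PREDICTORS = ("gc", "temperature", "nacl", "ph")


def brownian_covariance(
    tree: dendropy.Tree, taxa_order: Sequence[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Tip-by-tip Brownian covariance matrix from a rooted tree.

    V[i, j] is the depth (distance from the root) of the most recent common
    ancestor of tips i and j; V[i, i] is the root-to-tip distance.  The
    root's own edge, if any, is not counted.  Polytomies are fine.
    """
    root = tree.seed_node
    if root is None or len(root.child_nodes()) < 2:
        raise ValueError("tree must be rooted with at least two root children")
    leaves = [lf for lf in tree.leaf_node_iter()]
    if len(leaves) < 3:
        raise ValueError(f"need at least 3 tips, got {len(leaves)}")
    labels = [lf.taxon.label if lf.taxon is not None else "" for lf in leaves]
    if len(set(labels)) != len(labels) or "" in labels:
        raise ValueError("tips must carry unique, non-empty taxon labels")
    if taxa_order is None:
        taxa_order = sorted(labels)
    if set(taxa_order) != set(labels):
        raise ValueError("taxa_order must be a permutation of the tip labels")
    index = {lab: i for i, lab in enumerate(taxa_order)}

    depth: dict[int, float] = {id(root): 0.0}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        bl = node.edge.length
        if bl is None:
            bl = 0.0
        if bl < 0:
            raise ValueError(f"negative branch length {bl} in tree")
        depth[id(node)] = depth[id(node.parent_node)] + bl

    n = len(labels)
    V = np.zeros((n, n))
    tipset: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            tipset[id(node)] = [i]
            V[i, i] = depth[id(node)]
        else:
            h = depth[id(node)]
            groups = [tipset.pop(id(ch)) for ch in node.child_nodes()]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    for i in groups[a]:
                        for j in groups[b]:
                            V[i, j] = V[j, i] = h
            tipset[id(node)] = [i for g in groups for i in g]
    return V, list(taxa_order)


def _cholesky_with_jitter(V: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor; one round of diagonal jitter if V is singular."""
    try:
        return np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        jitter = 1e-10 * np.trace(V) / V.shape[0]
        try:
            return np.linalg.cholesky(V + jitter * np.eye(V.shape[0]))
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "covariance matrix is not positive definite even after jitter; "
                "check for duplicated tips or zero-length terminal branches"
            ) from err


class PGLSRegression(RegressorMixin, BaseEstimator):
    """Generalized least squares regression with a known residual covariance.

    A scikit-learn style estimator: ``fit(X, y, V=...)`` takes the tip-level
    design matrix, response, and the (optional) phylogenetic covariance V.
    With ``V=None`` (or any multiple of the identity, e.g. a star phylogeny)
    the fit reduces exactly to OLS.

    Attributes (after fit)
    ----------------------
    coef_, intercept_ : slope estimates and intercept
    bse_, tvalues_, pvalues_ : per-coefficient inference (intercept first)
    rsquared_ : generalized R^2 against the GLS intercept-only null
    fvalue_, f_pvalue_, df_model_, df_resid_ : whole-model F test
    sigma2_ : residual variance estimate e'V^-1 e / (n - k)
    """

    def __init__(self, fit_intercept: bool = True):
        self.fit_intercept = fit_intercept

    def fit(self, X, y, V: np.ndarray | None = None) -> "PGLSRegression":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        n, p = X.shape
        if y.shape[0] != n:
            raise ValueError("X and y have inconsistent lengths")
        if not self.fit_intercept:
            raise NotImplementedError("PGLS here always includes an intercept")
        k = p + 1
        if n <= k:
            raise ValueError(f"need more than {k} observations, got {n}")

        if V is None:
            L = np.eye(n)
        else:
            V = np.asarray(V, dtype=float)
            if V.shape != (n, n):
                raise ValueError("V must be n x n aligned with rows of X")
            L = _cholesky_with_jitter(V)

        Xd = np.column_stack([np.ones(n), X])
        Xw = solve_triangular(L, Xd, lower=True)
        yw = solve_triangular(L, y, lower=True)

        XtX = Xw.T @ Xw
        if np.linalg.matrix_rank(Xw) < k:
            raise np.linalg.LinAlgError("design matrix is (near-)collinear")
        XtX_inv = np.linalg.inv(XtX)
        beta = XtX_inv @ (Xw.T @ yw)

        resid_w = yw - Xw @ beta
        ssr = float(resid_w @ resid_w)  # e' V^-1 e
        df_resid = n - k
        sigma2 = ssr / df_resid
        bse = np.sqrt(np.clip(sigma2 * np.diag(XtX_inv), 0.0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(bse > 0, beta / bse, np.inf * np.sign(beta))
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)

        # GLS intercept-only null for the generalized R^2
        ones_w = Xw[:, 0]
        mu0 = float(ones_w @ yw) / float(ones_w @ ones_w)
        tss = float(np.sum((yw - ones_w * mu0) ** 2))
        rsq = 1.0 - ssr / tss if tss > 0 else 0.0
        df_model = p
        if rsq < 1.0:
            fval = (rsq / df_model) / ((1.0 - rsq) / df_resid)
        else:
            fval = np.inf
        f_p = float(stats.f.sf(fval, df_model, df_resid)) if np.isfinite(fval) else 0.0

        self.n_features_in_ = p
        self.nobs_ = n
        self.params_ = beta
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:].copy()
        self.bse_ = bse
        self.tvalues_ = tvals
        self.pvalues_ = pvals
        self.sigma2_ = sigma2
        self.ssr_ = ssr
        self.rsquared_ = float(rsq)
        self.fvalue_ = float(fval)
        self.f_pvalue_ = f_p
        self.df_model_ = df_model
        self.df_resid_ = df_resid
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X @ self.coef_


@dataclass
class ComparativeDataset:
    """A rooted tree plus a per-tip trait table, keyed by taxon id.

    ``traits`` must contain a ``taxon_id`` column (or use it as index) in
    bijection with the tree's tip labels, with no missing values among the
    analysis columns.
    """

    tree: dendropy.Tree
    traits: pd.DataFrame
    _cov: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        t = self.traits
        if "taxon_id" in t.columns:
            t = t.set_index("taxon_id")
        t.index = t.index.astype(str)
        tips = {lf.taxon.label for lf in self.tree.leaf_node_iter()}
        ids = set(t.index)
        if tips != ids:
            missing = sorted(ids - tips)
            extra = sorted(tips - ids)
            raise ValueError(
                "tip labels and trait taxon_ids must be in bijection; "
                f"trait rows without a tip: {missing}; tips without a row: {extra}"
            )
        if t.index.has_duplicates:
            raise ValueError("duplicate taxon_id rows in trait table")
        self.traits = t.sort_index()

    @property
    def taxa(self) -> list[str]:
        return list(self.traits.index)

    def covariance(self) -> np.ndarray:
        if self._cov is None:
            V, _ = brownian_covariance(self.tree, self.taxa)
            self._cov = V
        return self._cov


@dataclass(frozen=True)
class PGLSResult:
    """Inference summary for one PGLS model."""

    response_name: str
    terms: tuple[str, ...]  # "intercept" first, then predictors
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    rsquared: float
    fvalue: float
    f_pvalue: float
    df1: int
    df2: int
    n_tips: int
    standardized_betas: Mapping[str, float]

    def coef(self, term: str) -> float:
        return float(self.params[self.terms.index(term)])

    def pvalue(self, term: str) -> float:
        return float(self.pvalues[self.terms.index(term)])


def _design(dataset: ComparativeDataset, response: str, predictors: Sequence[str]):
    cols = [response, *predictors]
    missing = [c for c in cols if c not in dataset.traits.columns]
    if missing:
        raise ValueError(f"trait table lacks columns: {missing}")
    sub = dataset.traits[cols].astype(float)
    if sub.isna().any().any():
        bad = sub.index[sub.isna().any(axis=1)].tolist()
        raise ValueError(f"missing trait values for taxa: {bad}")
    return sub[list(predictors)].to_numpy(), sub[response].to_numpy()


def standardized_fit(
    dataset: ComparativeDataset,
    response_name: str,
    predictor_names: Sequence[str] = PREDICTORS,
) -> dict[str, float]:
    """Slope coefficients after Z-transforming response and predictors.

    The Z-transform (subtract mean, divide by standard deviation, unweighted)
    puts all variables on one scale so slopes are comparable across
    predictors with different units.
    """
    X, y = _design(dataset, response_name, predictor_names)
    sx = X.std(axis=0, ddof=1)
    sy = y.std(ddof=1)
    if sy == 0 or np.any(sx == 0):
        zero = [predictor_names[i] for i in np.where(sx == 0)[0]]
        raise ValueError(f"zero-variance variable(s): {zero or [response_name]}")
    Xz = (X - X.mean(axis=0)) / sx
    yz = (y - y.mean()) / sy
    est = PGLSRegression().fit(Xz, yz, V=dataset.covariance())
    return {name: float(b) for name, b in zip(predictor_names, est.coef_)}


def pgls_fit(
    dataset: ComparativeDataset,
    response_name: str,
    predictor_names: Sequence[str] = PREDICTORS,
) -> PGLSResult:
    """Fit one PGLS model of a distortion response on the predictors."""
    X, y = _design(dataset, response_name, predictor_names)
    est = PGLSRegression().fit(X, y, V=dataset.covariance())
    std = standardized_fit(dataset, response_name, predictor_names)
    return PGLSResult(
        response_name=response_name,
        terms=("intercept", *predictor_names),
        params=est.params_,
        bse=est.bse_,
        tvalues=est.tvalues_,
        pvalues=est.pvalues_,
        rsquared=est.rsquared_,
        fvalue=est.fvalue_,
        f_pvalue=est.f_pvalue_,
        df1=est.df_model_,
        df2=est.df_resid_,
        n_tips=est.nobs_,
        standardized_betas=std,
    )


def run_full_analysis(
    dataset: ComparativeDataset,
    responses: Sequence[str] = RESPONSES,
    predictors: Sequence[str] = PREDICTORS,
) -> dict[str, PGLSResult]:
    """One PGLS model per distortion response, all on the same predictors."""
    return {r: pgls_fit(dataset, r, predictors) for r in responses}


def results_long_table(results: Mapping[str, PGLSResult]) -> pd.DataFrame:
    """Per-term coefficients in long format (response, term, beta, se, t, p, beta_std)."""
    rows = []
    for r in results.values():
        for i, term in enumerate(r.terms):
            rows.append({
                "response": r.response_name,
                "term": term,
                "beta": r.params[i],
                "se": r.bse[i],
                "t": r.tvalues[i],
                "p": r.pvalues[i],
                "beta_std": r.standardized_betas.get(term, np.nan),
            })
    return pd.DataFrame(rows)


def model_summary_table(results: Mapping[str, PGLSResult]) -> pd.DataFrame:
    """Whole-model summaries (response, r2, f, df1, df2, p_model, n)."""
    return pd.DataFrame(
        [{
            "response": r.response_name,
            "r2": r.rsquared,
            "f": r.fvalue,
            "df1": r.df1,
            "df2": r.df2,
            "p_model": r.f_pvalue,
            "n": r.n_tips,
        } for r in results.values()]
    )
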