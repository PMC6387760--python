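"""Phylogenetically informed statistics: Pagel's lambda, PGLS, grade ANCOVA.

Trait covariance between species follows Brownian motion on a time-calibrated
tree: cov(i, j) is the shared root-to-MRCA path length, and Pagel's lambda
multiplies the off-diagonal covariances to measure how much of that structure
the data actually carry (lambda = 0: independent tips; lambda = 1: full
Brownian structure).  PGLS is generalized least squares under that
(lambda-transformed) covariance; the grade ANCOVA compares nested PGLS models
(single grade vs group-specific grades) with an F-test on whitened residual
sums of squares, preserving the whole-sample covariance structure.

Because p-values near 0.05 carry high false-discovery risk, each test is
accompanied by the conditional error probability

    alpha(p) = (1 + [-e p ln p]^(-1))^(-1)

the (Bayesian-calibrated) probability that a rejection at the observed p is
a false positive; alpha(0.05) is about 29%, alpha(0.001) about 1.84%.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DataError",
    "conditional_error_probability",
    "calibrate_tree",
    "tree_from_newick",
    "bm_covariance",
    "LambdaResult",
    "estimate_lambda",
    "PGLS",
    "PGLSResults",
    "GradeComparison",
    "PhylANCOVA",
    "AncovaReport",
    "DEFAULT_COMPARISONS",
    "load_printed_ancova_table",
]

_LAMBDA_TOL = 1e-8


class DataError(ValueError):
    """Raised for unusable inputs (missing dates, constant traits, bad groups)."""


# ---------------------------------------------------------------------------
# conditional error probability

def conditional_error_probability(p: float) -> float:
    """False-discovery probability alpha(p) attached to an observed p-value.

    alpha(p) = 1 / (1 + 1 / (-e p ln p)), defined on 0 < p < 1; monotone
    increasing on (0, 1/e) and exactly 0.5 at p = 1/e.
    """
    p = float(p)
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly between 0 and 1")
    q = -math.e * p * math.log(p)
    return 1.0 / (1.0 + 1.0 / q)


# ---------------------------------------------------------------------------
# trees

def tree_from_newick(newick: str) -> dendropy.Tree:
    # underscores are significant in specimen labels, not quoted spaces
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def calibrate_tree(topology, occurrences, epsilon: float | None = None,
                   padding: float = 1.0) -> dendropy.Tree:
    """Assign branch lengths (Myr) to a topology from tip occurrence dates.

    ``occurrences`` maps tip label -> (FAD, LAD) in Ma (a dict or a frame
    with columns tip, fad_ma, lad_ma).  A simplified calibrator is used:
    tips sit at their first appearance, each internal node at the oldest
    descendant FAD plus ``padding`` Myr, and any non-positive branch this
    leaves (including arbitrarily resolved hard polytomies) is opened up by
    ``epsilon`` (default: 0.001 x tree depth).  Pre-calibrated trees can
    bypass this entirely.
    """
    tree = topology if isinstance(topology, dendropy.Tree) else tree_from_newick(topology)
    tree = tree.clone(depth=1)
    if isinstance(occurrences, pd.DataFrame):
        occurrences = {
            str(r["tip"]): (float(r["fad_ma"]), float(r["lad_ma"]))
            for _, r in occurrences.iterrows()
        }
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    for tip in tips:
        if tip not in occurrences:
            raise DataError(f"tip {tip!r} has no occurrence dates")
        fad, lad = occurrences[tip]
        if fad < lad:
            raise DataError(f"tip {tip!r} has FAD {fad} < LAD {lad}")
    tree.resolve_polytomies(limit=2, update_bipartitions=False)

    # node age = oldest descendant first appearance + padding (NOT compounded
    # per level): nested nodes sharing an oldest descendant collapse to
    # zero-length internal branches, which the epsilon pass then opens up --
    # exactly the near-zero-branch treatment hard polytomies require
    oldest: dict[int, float] = {}
    ages: dict[int, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            oldest[id(node)] = ages[id(node)] = occurrences[node.taxon.label][0]
        else:
            oldest[id(node)] = max(oldest[id(c)] for c in node.child_nodes())
            ages[id(node)] = oldest[id(node)] + padding
    root_age = ages[id(tree.seed_node)]
    depth = root_age - min(occ[0] for occ in occurrences.values())
    if epsilon is None:
        epsilon = max(0.001 * depth, 1e-6)
    # enforce strictly positive branches from the tips upward
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            continue
        min_parent = max(ages[id(c)] for c in node.child_nodes()) + epsilon
        if ages[id(node)] < min_parent:
            ages[id(node)] = min_parent
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node.edge.length = 0.0
        else:
            node.edge.length = ages[id(node.parent_node)] - ages[id(node)]
    return tree


def _tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def bm_covariance(tree: dendropy.Tree, lam: float = 1.0,
                  taxa: list[str] | None = None) -> tuple[list[str], np.ndarray]:
    """Brownian-motion tip covariance matrix under Pagel's lambda transform.

    V[i, j] is the root-to-MRCA path length for tips i and j (the shared
    evolutionary time); the lambda transform multiplies off-diagonal entries
    by ``lam`` and leaves the diagonal untouched.  Returns the tip order and
    the matrix.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    labels = _tip_labels(tree)
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    depth: dict[int, float] = {}
    leafset: dict[int, list[int]] = {}
    V = np.zeros((n, n))
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        d = 0.0 if parent is None else depth[id(parent)] + (node.edge.length or 0.0)
        depth[id(node)] = d
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            leafset[id(node)] = [i]
            V[i, i] = depth[id(node)]
        else:
            children = node.child_nodes()
            sets = [leafset.pop(id(c)) for c in children]
            d = depth[id(node)]
            for a in range(len(sets)):
                for b in range(a + 1, len(sets)):
                    for i in sets[a]:
                        for j in sets[b]:
                            V[i, j] = V[j, i] = d
            leafset[id(node)] = [i for s in sets for i in s]
    if lam != 1.0:
        diag = np.diag(V).copy()
        V = V * lam
        np.fill_diagonal(V, diag)
    if taxa is not None:
        missing = [t for t in taxa if t not in index]
        if missing:
            raise DataError(f"taxa not on the tree: {', '.join(map(str, missing))}")
        order = [index[t] for t in taxa]
        V = V[np.ix_(order, order)]
        labels = list(taxa)
    return labels, V


# ---------------------------------------------------------------------------
# Pagel's lambda (single trait)

@dataclass(frozen=True)
class LambdaResult:
    lambda_: float
    loglik: float
    loglik_lambda0: float
    loglik_lambda1: float


def _chol(V: np.ndarray) -> np.ndarray:
    """Cholesky factor with a tiny relative ridge fallback.

    Near-zero terminal branches (hard polytomies, cherries on deep trees)
    make V numerically semidefinite; a ridge of 1e-10 x mean diagonal is far
    below any biological signal and restores definiteness.
    """
    try:
        return np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        ridge = 1e-10 * float(np.mean(np.diag(V)))
        return np.linalg.cholesky(V + ridge * np.eye(V.shape[0]))


def _bm_loglik(y: np.ndarray, X: np.ndarray, V: np.ndarray) -> tuple[float, np.ndarray, float]:
    """Profile (ML) log-likelihood of a GLS model y ~ X under covariance V.

    Returns (loglik, beta_hat, sigma2_ml); sigma2 is the ML rate, i.e. the
    whitened residual sum of squares divided by n.
    """
    n = y.size
    L = _chol(V)
    yw = np.linalg.solve(L, y)
    Xw = np.linalg.solve(L, X)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    r = yw - Xw @ beta
    rss = float(r @ r)
    sigma2 = rss / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    loglik = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)
    return loglik, beta, sigma2


def estimate_lambda(trait, tree: dendropy.Tree, taxa: list[str] | None = None,
                    tol: float = _LAMBDA_TOL) -> LambdaResult:
    """Maximum-likelihood Pagel's lambda on [0, 1] for a single trait.

    The mean and Brownian rate are profiled out analytically; the bounded
    1-D optimization over lambda uses the stated tolerance.  A constant
    trait has no defined lambda and raises :class:`DataError`.
    """
    if isinstance(trait, pd.Series):
        taxa = list(trait.index) if taxa is None else taxa
        y = trait.to_numpy(float)
    else:
        y = np.asarray(trait, dtype=float)
    if y.size < 4:
        raise DataError("lambda estimation needs at least 4 tips")
    if np.ptp(y) == 0:
        raise DataError("trait is constant: lambda is undefined")
    _, V = bm_covariance(tree, 1.0, taxa)
    X = np.ones((y.size, 1))

    def negll(lam: float) -> float:
        Vl = _lambda_transform(V, lam)
        return -_bm_loglik(y, X, Vl)[0]

    res = optimize.minimize_scalar(negll, bounds=(0.0, 1.0), method="bounded",
                                   options={"xatol": tol})
    ll0, ll1 = -negll(0.0), -negll(1.0)
    lam, ll = float(res.x), -float(res.fun)
    # the bounded optimizer never evaluates the exact endpoints
    if ll0 >= ll and ll0 >= ll1:
        lam, ll = 0.0, ll0
    elif ll1 >= ll:
        lam, ll = 1.0, ll1
    return LambdaResult(lambda_=lam, loglik=ll, loglik_lambda0=ll0, loglik_lambda1=ll1)


def _lambda_transform(V: np.ndarray, lam: float) -> np.ndarray:
    Vl = V * lam
    np.fill_diagonal(Vl, np.diag(V))
    return Vl


# ---------------------------------------------------------------------------
# PGLS

class PGLS:
    """Phylogenetic generalized least squares regression model.

    Parameters
    ----------
    y : array or pandas Series (indexed by taxon)
        Response, one value per tip (complete cases only).
    x : array, DataFrame or Series
        Covariate(s); an intercept column is always prepended.
    tree : dendropy.Tree
        Calibrated phylogeny whose tips cover the observations.
    taxa : list of str, optional
        Tip order of ``y``/``x``; inferred from a Series/DataFrame index.

    ``fit(lambda_="ml")`` maximizes the profile likelihood over Pagel's
    lambda; ``fit(lambda_=0.5)`` fixes it.  Returns :class:`PGLSResults`.
    """

    def __init__(self, y, x, tree: dendropy.Tree, taxa: list[str] | None = None):
        if isinstance(y, pd.Series):
            taxa = list(y.index) if taxa is None else taxa
            y = y.to_numpy(float)
        self.y = np.asarray(y, dtype=float)
        if isinstance(x, (pd.Series, pd.DataFrame)):
            if taxa is None:
                taxa = list(x.index)
            x = x.to_numpy(float)
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        if np.any(~np.isfinite(self.y)) or np.any(~np.isfinite(x)):
            raise DataError("PGLS requires complete, finite cases")
        self.exog_names = ["intercept"] + [f"x{i+1}" for i in range(x.shape[1])]
        self.X = np.column_stack([np.ones(len(self.y)), x])
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise np.linalg.LinAlgError("design matrix is rank deficient")
        self.tree = tree
        self.taxa = taxa
        _, self.V1 = bm_covariance(tree, 1.0, taxa)
        if self.V1.shape[0] != self.y.size:
            raise DataError("y length does not match the number of tips")

    def loglik(self, lam: float) -> float:
        return _bm_loglik(self.y, self.X, _lambda_transform(self.V1, lam))[0]

    def fit(self, lambda_: float | str = "ml") -> "PGLSResults":
        if lambda_ == "ml":
            res = optimize.minimize_scalar(lambda l: -self.loglik(l), bounds=(0.0, 1.0),
                                           method="bounded", options={"xatol": _LAMBDA_TOL})
            lam = float(res.x)
            for bound in (0.0, 1.0):
                if self.loglik(bound) >= -float(res.fun):
                    lam = bound
            lambda_ml = True
        else:
            lam = float(lambda_)
            if not 0.0 <= lam <= 1.0:
                raise ValueError("lambda must lie in [0, 1]")
            lambda_ml = False
        V = _lambda_transform(self.V1, lam)
        return PGLSResults(self, lam, V, lambda_ml)


class PGLSResults:
    """Estimates, uncertainties and diagnostics of a fitted PGLS model."""

    def __init__(self, model: PGLS, lam: float, V: np.ndarray, lambda_ml: bool):
        self.model = model
        self.lambda_ = lam
        self.lambda_ml = lambda_ml
        y, X = model.y, model.X
        n, p = X.shape
        L = _chol(V)
        yw = np.linalg.solve(L, y)
        Xw = np.linalg.solve(L, X)
        XtX = Xw.T @ Xw
        self.params = np.linalg.solve(XtX, Xw.T @ yw)
        resid_w = yw - Xw @ self.params
        self.ssr = float(resid_w @ resid_w)
        self.nobs, self.df_model = n, p - 1
        self.df_resid = n - p
        self.scale = self.ssr / self.df_resid  # sigma^2 relative to V
        self.normalized_cov_params = np.linalg.inv(XtX)
        self.bse = np.sqrt(self.scale * np.diag(self.normalized_cov_params))
        self.tvalues = self.params / self.bse
        self.pvalues = 2 * stats.t.sf(np.abs(self.tvalues), self.df_resid)
        self.fittedvalues = X @ self.params
        self.resid = y - self.fittedvalues
        self.loglik = _bm_loglik(y, X, V)[0]
        # R^2 in the whitened (GLS) space against the whitened intercept model
        ones_w = np.linalg.solve(L, np.ones(n))
        mu_w = float(ones_w @ yw / (ones_w @ ones_w))
        tss_w = float((yw - mu_w * ones_w) @ (yw - mu_w * ones_w))
        self.rsquared = 1.0 - self.ssr / tss_w if tss_w > 0 else np.nan
        # raw-space R^2 (fit quality on the original scale; a different flavour,
        # reported alongside because the two can diverge substantially)
        tss = float(np.sum((y - y.mean()) ** 2))
        self.rsquared_raw = 1.0 - float(self.resid @ self.resid) / tss if tss > 0 else np.nan
        k = self.df_model
        self.rsquared_adj = 1.0 - (1 - self.rsquared) * (n - 1) / (n - p) if n > p else np.nan
        self.fvalue = ((tss_w - self.ssr) / k) / self.scale if k > 0 else np.nan
        self.f_pvalue = float(stats.f.sf(self.fvalue, k, self.df_resid)) if k > 0 else np.nan
        self._V = V
        self._L = L

    @property
    def slope(self) -> float:
        return float(self.params[1])

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        t = stats.t.ppf(1 - alpha / 2, self.df_resid)
        return np.column_stack([self.params - t * self.bse, self.params + t * self.bse])

    def prediction_frame(self, alpha: float = 0.05) -> pd.DataFrame:
        """Per-tip fit with confidence and prediction intervals.

        The prediction variance adds the tip's own phylogenetic variance
        ``scale * V_ii`` to the fit variance, so "at or above the 95% PI"
        flags can be emitted per tip.
        """
        X = self.model.X
        t = stats.t.ppf(1 - alpha / 2, self.df_resid)
        se_fit = np.sqrt(self.scale * np.einsum("ij,jk,ik->i", X,
                                                self.normalized_cov_params, X))
        se_pred = np.sqrt(se_fit**2 + self.scale * np.diag(self._V))
        fit = self.fittedvalues
        frame = pd.DataFrame(
            {
                "observed": self.model.y,
                "fit": fit,
                "ci_low": fit - t * se_fit,
                "ci_high": fit + t * se_fit,
                "pi_low": fit - t * se_pred,
                "pi_high": fit + t * se_pred,
            },
            index=self.model.taxa if self.model.taxa is not None else None,
        )
        frame["at_or_above_pi"] = frame["observed"] >= frame["pi_high"]
        return frame

    def summary(self) -> str:
        lines = [
            "PGLS regression results",
            "=" * 56,
            f"No. observations: {self.nobs:>6d}    df resid: {self.df_resid}",
            f"Pagel's lambda:   {self.lambda_:>8.4f}    ({'ML' if self.lambda_ml else 'fixed'})",
            f"Log-likelihood:   {self.loglik:>10.4f}",
            f"R^2 (GLS):        {self.rsquared:>8.4f}    R^2 (raw): {self.rsquared_raw:.4f}",
            f"F-statistic:      {self.fvalue:>8.4g}    p = {self.f_pvalue:.3g}",
            "-" * 56,
            f"{'':<12}{'coef':>10}{'std err':>10}{'t':>9}{'P>|t|':>10}",
        ]
        for name, b, se, tv, pv in zip(self.model.exog_names, self.params,
                                       self.bse, self.tvalues, self.pvalues):
            lines.append(f"{name:<12}{b:>10.4f}{se:>10.4f}{tv:>9.3f}{pv:>10.3g}")
        lines.append("=" * 56)
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# grade ANCOVA

@dataclass(frozen=True)
class GradeComparison:
    """A nested grade test: ``full`` vs ``reduced`` grade assignments.

    Each mapping sends a group label to a grade label; groups sharing a
    grade share intercept (and slope, if freed).  ``None`` pools everything
    into a single grade.
    """

    name: str
    full: dict[str, str] | None
    reduced: dict[str, str] | None


def default_comparisons(adult: str = "tyrannosaurid_adult",
                        juvenile: str = "tyrannosaurid_juvenile",
                        other: str = "other") -> list[GradeComparison]:
    """The standard three-way design: adults, juveniles, everything else."""
    three = {adult: adult, juvenile: juvenile, other: other}
    two = {adult: "tyrannosaur", juvenile: "tyrannosaur", other: other}
    return [
        GradeComparison("among_groups", three, None),
        GradeComparison("juvenile_vs_adult", three, two),
        GradeComparison("tyrannosaurs_vs_others", two, None),
    ]


DEFAULT_COMPARISONS = default_comparisons()


@dataclass
class AncovaRow:
    comparison: str
    F: float
    df_num: int
    df_den: int
    p: float
    alpha_p: float


@dataclass
class AncovaReport:
    """F-tests for grade structure, with conditional error probabilities."""

    rows: list[AncovaRow] = field(default_factory=list)
    lambda_: float = np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"comparison": r.comparison, "F": r.F, "df_num": r.df_num,
              "df_den": r.df_den, "p": r.p, "alpha_p": r.alpha_p} for r in self.rows]
        )

    def summary(self) -> str:
        lines = [
            "Phylogenetic ANCOVA (nested grade F-tests)",
            f"common lambda = {self.lambda_:.4f}",
            "=" * 64,
            f"{'comparison':<26}{'F':>8}{'df':>9}{'p':>10}{'alpha(p)':>10}",
        ]
        for r in self.rows:
            lines.append(
                f"{r.comparison:<26}{r.F:>8.3f}{f'{r.df_num},{r.df_den}':>9}"
                f"{r.p:>10.4g}{r.alpha_p:>10.4f}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)


class PhylANCOVA:
    """Grade-wise phylogenetic ANCOVA on a common tree.

    Fits nested PGLS models — a reduced (coarser-grade) and a full
    (finer-grade) design — under one shared lambda (estimated by ML on the
    pooled single-grade model so nested models compare like with like), and
    F-tests the improvement on V-whitened residual sums of squares.  By
    default grades free intercepts only; ``slopes=True`` frees slopes too.
    """

    def __init__(self, y, x, tree: dendropy.Tree, groups,
                 taxa: list[str] | None = None):
        if isinstance(y, pd.Series):
            taxa = list(y.index) if taxa is None else taxa
            y = y.to_numpy(float)
        self.y = np.asarray(y, dtype=float)
        if isinstance(x, pd.Series):
            x = x.to_numpy(float)
        self.x = np.asarray(x, dtype=float)
        self.groups = np.asarray(groups, dtype=object)
        if not (self.y.size == self.x.size == self.groups.size):
            raise DataError("y, x and groups must have equal length")
        self.taxa = taxa
        self.tree = tree
        _, self.V1 = bm_covariance(tree, 1.0, taxa)

    def _design(self, grading: dict[str, str] | None, slopes: bool) -> np.ndarray:
        if grading is None:
            return np.column_stack([np.ones(self.y.size), self.x])
        unknown = sorted(set(self.groups) - set(grading))
        if unknown:
            raise DataError(f"group(s) without a grade: {', '.join(map(str, unknown))}")
        grades = np.array([grading[g] for g in self.groups], dtype=object)
        levels = sorted(set(grades))
        for lev in levels:
            if int(np.sum(grades == lev)) < 2:
                raise DataError(f"grade {lev!r} has fewer than 2 tips")
        cols = [np.ones(self.y.size), self.x]
        for lev in levels[1:]:  # first level absorbed by the intercept
            ind = (grades == lev).astype(float)
            cols.append(ind)
            if slopes:
                cols.append(ind * self.x)
        return np.column_stack(cols)

    def _whitened_rss(self, X: np.ndarray, L: np.ndarray) -> tuple[float, int]:
        yw = np.linalg.solve(L, self.y)
        Xw = np.linalg.solve(L, X)
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        r = yw - Xw @ beta
        return float(r @ r), int(np.linalg.matrix_rank(Xw))

    def fit(self, comparisons: list[GradeComparison] | None = None,
            slopes: bool = False, lambda_: float | str = "ml") -> AncovaReport:
        if comparisons is None:
            comparisons = default_comparisons()
        pooled = PGLS(self.y, self.x, self.tree, self.taxa).fit(lambda_=lambda_)
        lam = pooled.lambda_
        V = _lambda_transform(self.V1, lam)
        L = _chol(V)
        n = self.y.size
        report = AncovaReport(lambda_=lam)
        for comp in comparisons:
            rss_f, rank_f = self._whitened_rss(self._design(comp.full, slopes), L)
            rss_r, rank_r = self._whitened_rss(self._design(comp.reduced, slopes), L)
            df_num = rank_f - rank_r
            df_den = n - rank_f
            if df_num <= 0 or df_den <= 0:
                F, p = 0.0, 1.0
                df_num = max(df_num, 0)
            else:
                F = max(rss_r - rss_f, 0.0) / df_num / (rss_f / df_den)
                p = float(stats.f.sf(F, df_num, df_den))
            alpha_p = conditional_error_probability(p) if 0 < p < 1 else np.nan
            report.rows.append(AncovaRow(comp.name, float(F), df_num, df_den, p, alpha_p))
        return report


# ---------------------------------------------------------------------------
# packaged printed test results (statistics-stage fixture)

def load_printed_ancova_table() -> pd.DataFrame:
    """Printed grade-test results (scenario, response, comparison, F, p, alpha)."""
    with importlib.resources.files("frusta.data").joinpath("ancova_pvalues.csv").open() as fh:
        return pd.read_csv(fh)
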