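"""Phylogenetic signal and generalized least squares under tree-structured
residual covariance.

Three covariance structures are supported for a rooted tree with branch
lengths:

* Brownian motion: cov(i, j) = shared root-to-MRCA path length, the variance
  of each tip its root-to-tip depth;
* stationary Ornstein-Uhlenbeck: cov(i, j) proportional to exp(-alpha * d_ij)
  with d_ij the patristic distance, so the diagonal is the (unit) stationary
  variance — this requires an ultrametric tree;
* Pagel's lambda: the Brownian matrix with off-diagonals multiplied by
  lambda in [0, 1] (lambda = 0 is an identity-like star structure, lambda = 1
  is Brownian).

PGLS coefficients come from the whitened least-squares solution; the Gaussian
GLS likelihood profiles out the residual scale analytically. Accuracy
statistics for a PGLS fit are computed by evaluating the fitted line as an
ordinary line (ordinary residuals), which is how PGLS-based prediction
equations are used in practice: PGLS re-weights the fit but carries no
phylogenetic position information for a new observation. Predictions for new
taxa therefore ignore the phylogenetic position of the target — a known
limitation of line-based PGLS prediction, not of this implementation alone.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .allometry import AllometricModelSpec, _design, _gaussian_loglik
from .io import match_species_to_tips

logger = logging.getLogger(__name__)

__all__ = [
    "PhyloCovariance",
    "PGLSFit",
    "LambdaResult",
    "brownian_vcv",
    "ou_vcv",
    "lambda_vcv",
    "estimate_lambda",
    "fit_pgls",
    "pgls_over_trees",
]


@dataclass
class PhyloCovariance:
    """A labeled n x n species covariance structure."""

    kind: str  # brownian / ou / lambda
    matrix: np.ndarray
    labels: list[str]
    parameters: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)

    def reordered(self, labels: list[str]) -> np.ndarray:
        idx = [self.labels.index(l) for l in labels]
        return self.matrix[np.ix_(idx, idx)]


def _leaf_depths_and_mrca(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Labels plus the matrix of shared root-to-MRCA path lengths."""
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label if lf.taxon else str(i) for i, lf in enumerate(leaves)]
    index = {id(lf): i for i, lf in enumerate(leaves)}
    n = len(leaves)

    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            raise ValueError("tree has edges without branch lengths")
        depth[id(node)] = depth[id(node.parent_node)] + float(node.edge.length)

    V = np.zeros((n, n))
    leafsets: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[id(node)]
            leafsets[id(node)] = [i]
            V[i, i] = depth[id(node)]
            continue
        child_sets = [leafsets.pop(id(ch)) for ch in node.child_nodes()]
        d = depth[id(node)]
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                for i in child_sets[a]:
                    for j in child_sets[b]:
                        V[i, j] = V[j, i] = d
        merged: list[int] = []
        for s in child_sets:
            merged.extend(s)
        leafsets[id(node)] = merged
    return labels, V


def brownian_vcv(tree: dendropy.Tree) -> PhyloCovariance:
    """Brownian-motion covariance: shared path length to the MRCA."""
    labels, V = _leaf_depths_and_mrca(tree)
    return PhyloCovariance(kind="brownian", matrix=V, labels=labels)


def _check_ultrametric(V: np.ndarray, rel_tol: float = 1e-6) -> float:
    depths = np.diag(V)
    if np.ptp(depths) > rel_tol * max(depths.max(), 1e-12):
        raise ValueError(
            "tree is not ultrametric (root-to-tip depths differ); the "
            "stationary OU covariance is only defined for ultrametric trees"
        )
    return float(depths.mean())


def ou_vcv(tree: dendropy.Tree, alpha: float) -> PhyloCovariance:
    """Stationary Ornstein-Uhlenbeck covariance exp(-alpha * patristic distance).

    The matrix is scaled so the diagonal is 1 (the stationary variance); the
    GLS residual scale absorbs the overall magnitude.
    """
    if not alpha > 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    labels, V = _leaf_depths_and_mrca(tree)
    _check_ultrametric(V)
    depths = np.diag(V)
    D = depths[:, None] + depths[None, :] - 2.0 * V  # patristic distances
    M = np.exp(-alpha * D)
    return PhyloCovariance(kind="ou", matrix=M, labels=labels, parameters={"alpha": alpha})


def lambda_vcv(tree: dendropy.Tree, lam: float) -> PhyloCovariance:
    """Pagel's lambda covariance: Brownian off-diagonals multiplied by lambda."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    labels, V = _leaf_depths_and_mrca(tree)
    M = lam * V
    np.fill_diagonal(M, np.diag(V))
    return PhyloCovariance(kind="lambda", matrix=M, labels=labels, parameters={"lambda": lam})


def _chol_solve(V: np.ndarray):
    """Cholesky factor with one documented jitter retry for numerically
    non-PSD inputs."""
    try:
        return np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        jitter = 1e-10 * float(np.mean(np.diag(V)))
        logger.warning("covariance not numerically PSD; adding jitter %.3e", jitter)
        try:
            return np.linalg.cholesky(V + jitter * np.eye(len(V)))
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "covariance is singular even after jitter; check the tree for "
                "zero-length terminal branches or duplicated tips"
            ) from exc


def _gls_profile_loglik(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """GLS with the residual scale profiled out.

    Returns (beta, sigma2_hat, loglik, cov_unit) where cov(beta) =
    sigma2_hat * cov_unit and sigma2_hat = r' V^-1 r / n (ML).
    """
    n = len(y)
    L = _chol_solve(V)
    Xw = np.linalg.solve(L, X)
    yw = np.linalg.solve(L, y)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    rw = yw - Xw @ beta
    rss_w = float(rw @ rw)
    sigma2 = rss_w / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    loglik = -0.5 * (n * math.log(2 * math.pi) + n * math.log(sigma2) + n + logdet)
    cov_unit = np.linalg.inv(Xw.T @ Xw)
    return beta, sigma2, loglik, cov_unit, rss_w


@dataclass
class LambdaResult:
    """Maximum-likelihood estimate of Pagel's lambda for a species trait."""

    lam: float
    loglik: float
    loglik0: float  # at lambda = 0
    lr: float
    p: float  # likelihood-ratio p against lambda = 0, chi2(1)
    profile: pd.DataFrame  # columns lambda, loglik


def estimate_lambda(values: pd.Series, tree: dendropy.Tree) -> LambdaResult:
    """ML estimate of Pagel's lambda in [0, 1] for a per-species trait.

    ``values`` is indexed by species name; every species must match exactly
    one tree tip (after underscore/space and case normalization). The mean
    structure is an intercept only — the intended use is residuals of a
    cross-species regression.
    """
    values = values.dropna()
    if len(values) < 10:
        raise ValueError(f"need >= 10 species, got {len(values)}")
    matched, unmatched = match_species_to_tips(values.index, tree)
    if unmatched:
        raise ValueError(f"species not found among tree tips: {unmatched}")
    labels = [matched[s] for s in values.index]
    cov = brownian_vcv(tree)
    V = cov.reordered(labels)
    y = np.asarray(values, dtype=float)
    n = len(y)
    X = np.ones((n, 1))
    offdiag = V - np.diag(np.diag(V))
    diag = np.diag(np.diag(V))

    def negll(lam: float) -> float:
        M = lam * offdiag + diag
        return -_gls_profile_loglik(y, X, M)[2]

    grid = np.linspace(0.0, 1.0, 21)
    ll_grid = np.array([-negll(l) for l in grid])
    l0 = grid[int(np.argmax(ll_grid))]
    res = scipy.optimize.minimize_scalar(
        negll, bounds=(max(0.0, l0 - 0.1), min(1.0, l0 + 0.1)), method="bounded",
        options={"xatol": 1e-6},
    )
    lam_hat = float(res.x)
    ll_hat = float(-res.fun)
    ll_0 = float(-negll(0.0))
    if ll_0 > ll_hat:  # boundary optimum at 0
        lam_hat, ll_hat = 0.0, ll_0
    lr = max(0.0, 2.0 * (ll_hat - ll_0))
    p = float(scipy.stats.chi2.sf(lr, df=1))
    profile = pd.DataFrame({"lambda": grid, "loglik": ll_grid})
    return LambdaResult(lam=lam_hat, loglik=ll_hat, loglik0=ll_0, lr=lr, p=p, profile=profile)


@dataclass
class PGLSFit:
    """GLS fit of an allometric spec under a phylogenetic covariance.

    ``resid`` / ``fitted`` are the *ordinary* residuals and fitted values of
    the GLS line (the convention under which PGLS prediction equations are
    evaluated and their accuracy reported); ``gls_resid`` are the whitened
    residuals. ``s2`` is the ordinary residual mean square, feeding the
    correction factors and %SEE on the same footing as an OLS fit.
    """

    spec: AllometricModelSpec
    kind: str
    params: pd.Series
    bse: pd.Series
    resid: np.ndarray
    fitted: np.ndarray
    observed: np.ndarray
    gls_resid: np.ndarray
    n: int
    df_resid: int
    s2: float
    see: float
    loglik: float
    aic: float
    bic: float
    sigma2_gls: float
    parameters: dict = field(default_factory=dict)


def _covariance_for(tree, kind: str, alpha, lam) -> PhyloCovariance:
    if kind == "brownian":
        return brownian_vcv(tree)
    if kind == "ou":
        if alpha is None:
            raise ValueError("alpha required (or use fit_pgls's profiling)")
        return ou_vcv(tree, alpha)
    if kind == "lambda":
        if lam is None:
            raise ValueError("lambda required for a lambda covariance")
        return lambda_vcv(tree, lam)
    raise ValueError(f"unknown covariance kind {kind!r}")


def fit_pgls(
    data: pd.DataFrame,
    tree: dendropy.Tree,
    spec: AllometricModelSpec | None = None,
    kind: str = "brownian",
    alpha: float | None = None,
    lam: float | None = None,
    species_column: str = "species",
) -> PGLSFit:
    """Fit a PGLS regression of the spec under the chosen covariance.

    For ``kind='ou'`` with ``alpha=None`` the OU rate is estimated by
    profiling the GLS likelihood over a log-spaced alpha grid (1e-3 to 1e3 in
    tree-depth units) with bounded local refinement; for ``kind='lambda'``
    with ``lam=None`` Pagel's lambda is likewise estimated by ML jointly with
    the regression (preferable to estimating lambda from OLS residuals, which
    is attenuated because the fitted intercept absorbs shared root history).
    Extra covariance parameters estimated this way are counted in AIC/BIC.
    """
    if spec is None:
        spec = AllometricModelSpec.power(2 / 3)
    matched, unmatched = match_species_to_tips(data[species_column], tree)
    if unmatched:
        raise ValueError(f"species not found among tree tips: {unmatched}")
    labels = [matched[s] for s in data[species_column]]
    y, X = _design(data, spec)
    Xv = X.values
    n, k = Xv.shape
    n_cov_par = 0

    if kind == "lambda" and lam is None:
        cov0 = brownian_vcv(tree)
        V0 = cov0.reordered(labels)
        off = V0 - np.diag(np.diag(V0))
        dia = np.diag(np.diag(V0))

        def ll_for_lam(l: float) -> float:
            return _gls_profile_loglik(y, Xv, l * off + dia)[2]

        grid = np.linspace(0.0, 1.0, 21)
        lls = np.array([ll_for_lam(l) for l in grid])
        i = int(np.argmax(lls))
        res = scipy.optimize.minimize_scalar(
            lambda l: -ll_for_lam(l),
            bounds=(max(0.0, grid[i] - 0.05), min(1.0, grid[i] + 0.05)),
            method="bounded",
        )
        lam = float(res.x) if -res.fun >= lls[i] else float(grid[i])
        n_cov_par = 1

    if kind == "ou" and alpha is None:
        ou_vcv(tree, 1.0)  # validates ultrametricity up front

        def ll_for_alpha(a: float) -> float:
            M = _covariance_for(tree, "ou", a, None).reordered(labels)
            return _gls_profile_loglik(y, Xv, M)[2]

        grid = np.logspace(-3, 3, 25)
        lls = np.array([ll_for_alpha(a) for a in grid])
        i = int(np.argmax(lls))
        lo = grid[max(0, i - 1)]
        hi = grid[min(len(grid) - 1, i + 1)]
        res = scipy.optimize.minimize_scalar(
            lambda a: -ll_for_alpha(a), bounds=(lo, hi), method="bounded",
        )
        alpha = float(res.x)
        n_cov_par = 1

    cov = _covariance_for(tree, kind, alpha, lam)
    V = cov.reordered(labels)
    beta, sigma2, loglik, cov_unit, _ = _gls_profile_loglik(y, Xv, V)
    fitted = Xv @ beta
    resid = y - fitted
    df_resid = n - k
    rss = float(resid @ resid)
    bse = np.sqrt(sigma2 * n / df_resid * np.diag(cov_unit))  # df-corrected scale
    npar = k + 1 + n_cov_par
    L = _chol_solve(V)
    gls_resid = np.linalg.solve(L, resid)
    params = pd.Series(beta, index=X.columns)
    return PGLSFit(
        spec=spec,
        kind=kind,
        params=params,
        bse=pd.Series(bse, index=X.columns),
        resid=resid,
        fitted=fitted,
        observed=y,
        gls_resid=gls_resid,
        n=n,
        df_resid=df_resid,
        s2=rss / df_resid,
        see=math.sqrt(rss / df_resid),
        loglik=loglik,
        aic=-2 * loglik + 2 * npar,
        bic=-2 * loglik + math.log(n) * npar,
        sigma2_gls=sigma2,
        parameters=dict(cov.parameters),
    )


def pgls_over_trees(
    data: pd.DataFrame,
    trees: list[dendropy.Tree],
    spec: AllometricModelSpec | None = None,
    kind: str = "brownian",
    **kwargs,
) -> pd.DataFrame:
    """Fit the same PGLS across a sample of trees; one row per tree.

    Tree samples summarize phylogenetic uncertainty: coefficients are usually
    stable across reasonable trees while information criteria vary widely, so
    per-tree AIC/BIC distributions (summarize as mean +/- SD) are reported
    rather than a single model-selection verdict.
    """
    rows = []
    for i, tree in enumerate(trees):
        fit = fit_pgls(data, tree, spec=spec, kind=kind, **kwargs)
        row = {"tree": i, "aic": fit.aic, "bic": fit.bic, "loglik": fit.loglik}
        for name, val in fit.params.items():
            row[name] = float(val)
        rows.append(row)
    return pd.DataFrame(rows)
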