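"""Phylogenetic generalized least squares with Pagel's lambda.

Under Brownian-motion trait evolution the regression residuals of related
species covary in proportion to shared evolutionary history: the
covariance of tips i and j is sigma^2 * C[i, j], where C[i, j] is the
branch length shared from the root to their most recent common ancestor.
Pagel's lambda multiplies the off-diagonal of C, interpolating between
star-phylogeny independence (lambda = 0) and pure Brownian motion
(lambda = 1). lambda is estimated by maximising the Gaussian profile
log-likelihood of the residual model over [0, 1].

The GLS solve itself and the profile likelihood are written out here
(Cholesky-whitened normal equations) rather than delegated, because the
lambda transform couples the two and both are needed at many lambda
values during optimisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy import optimize

from .allometry import AllometricFit

__all__ = [
    "PhyloCovariance",
    "PGLSFit",
    "PGLSModel",
    "tree_covariance",
    "apply_lambda",
    "pgls_fit",
    "estimate_lambda_ml",
    "phylo_signal_mass_independent",
]

LN10 = math.log(10.0)


@dataclass(frozen=True)
class PhyloCovariance:
    """Tip-to-tip shared-path-length matrix with an attached Pagel's lambda."""

    labels: tuple[str, ...]
    C: np.ndarray
    lam: float = 1.0

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if C.shape != (len(self.labels), len(self.labels)):
            raise ValueError("C must be square and match the label count")
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("C must be symmetric")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")

    def with_lambda(self, lam: float) -> "PhyloCovariance":
        return PhyloCovariance(self.labels, apply_lambda(self.C, lam), lam)

    def reorder(self, labels: list[str]) -> "PhyloCovariance":
        idx = [self.labels.index(l) for l in labels]
        return PhyloCovariance(tuple(labels), self.C[np.ix_(idx, idx)], self.lam)


def tree_covariance(tree: dendropy.Tree) -> PhyloCovariance:
    """Shared root-to-MRCA path lengths for every tip pair.

    C[i, i] is the root-to-tip depth of tip i; C[i, j] the depth of the
    most recent common ancestor of tips i and j.
    """
    if not tree.is_rooted:
        raise ValueError("tree must be rooted")
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    leaves = list(tree.leaf_node_iter())
    labels = tuple(lf.taxon.label for lf in leaves)
    index = {id(lf): i for i, lf in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))
    for i, lf in enumerate(leaves):
        C[i, i] = lf.root_distance
    # postorder: a node of depth d is the MRCA of every tip pair split
    # across its child subtrees
    tip_sets: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tip_sets[id(node)] = [index[id(node)]]
            continue
        child_tips = [tip_sets.pop(id(ch)) for ch in node.child_nodes()]
        d = node.root_distance
        for a in range(len(child_tips)):
            for b in range(a + 1, len(child_tips)):
                ia, ib = child_tips[a], child_tips[b]
                C[np.ix_(ia, ib)] = d
                C[np.ix_(ib, ia)] = d
        tip_sets[id(node)] = [t for ts in child_tips for t in ts]
    return PhyloCovariance(labels, C)


def apply_lambda(C: np.ndarray, lam: float) -> np.ndarray:
    """Pagel transform: off-diagonal entries scaled by lambda, diagonal kept."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    C = np.asarray(C, dtype=float)
    out = lam * C
    np.fill_diagonal(out, np.diag(C))
    return out


@dataclass(frozen=True)
class PGLSFit(AllometricFit):
    """Allometric fit under phylogenetic covariance, with the ML lambda."""

    lambda_hat: float = 1.0
    loglik_at_lambda: float = float("nan")

    def summary(self) -> str:  # noqa: D102
        base = super().summary()
        return base + (
            f"\n  Pagel's lambda = {self.lambda_hat:.3f}"
            f" (log-likelihood {self.loglik_at_lambda:.3f})"
        )


class PGLSModel:
    """Regression of y on x with phylogenetic error covariance.

    ``fit(lam=...)`` performs GLS at a fixed lambda; ``fit()`` with no
    argument profiles lambda over [0, 1] by ML first.
    """

    def __init__(self, x: np.ndarray, y: np.ndarray, cov: PhyloCovariance):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        n = len(cov.labels)
        if x.shape != (n,) or y.shape != (n,):
            raise ValueError("x, y must align with the covariance labels")
        self.x = x
        self.y = y
        self.cov = cov
        self._X = np.column_stack([np.ones(n), x])

    # -- internals ---------------------------------------------------------
    def _solve(self, V: np.ndarray):
        """Cholesky-whitened GLS solve; returns (beta, XtVi_X_inv, rss_V, logdetV, tss_V)."""
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError as exc:
            cond = np.linalg.cond(V)
            raise np.linalg.LinAlgError(
                f"phylogenetic covariance is singular (cond ~ {cond:.3g})"
            ) from exc
        from scipy.linalg import solve_triangular

        Xw = solve_triangular(L, self._X, lower=True)
        yw = solve_triangular(L, self.y, lower=True)
        XtX = Xw.T @ Xw
        beta = np.linalg.solve(XtX, Xw.T @ yw)
        resid = yw - Xw @ beta
        rss = float(resid @ resid)
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        # V-weighted mean of y: GLS fit of intercept-only model
        onesw = Xw[:, 0]
        ybar_V = float(onesw @ yw / (onesw @ onesw))
        tss = float(np.sum((yw - ybar_V * onesw) ** 2))
        return beta, np.linalg.inv(XtX), rss, logdet, tss

    def _loglik(self, lam: float) -> float:
        V = apply_lambda(self.cov.C, lam)
        _, _, rss, logdet, _ = self._solve(V)
        n = len(self.y)
        sigma2 = rss / n
        if sigma2 <= 0 or not np.isfinite(sigma2):
            raise FloatingPointError("non-finite ML variance in lambda profile")
        return -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)

    # -- API ---------------------------------------------------------------
    def profile_lambda(self, tol: float = 1e-6) -> tuple[float, float]:
        """ML estimate of lambda on [0, 1] by bounded scalar optimisation."""
        res = optimize.minimize_scalar(
            lambda lam: -self._loglik(lam),
            bounds=(0.0, 1.0),
            method="bounded",
            options={"xatol": tol},
        )
        lam_hat = float(np.clip(res.x, 0.0, 1.0))
        ll_hat = -float(res.fun)
        # Brent-on-interior can miss a boundary optimum; check both ends.
        for lam_edge in (0.0, 1.0):
            ll_edge = self._loglik(lam_edge)
            if ll_edge > ll_hat:
                lam_hat, ll_hat = lam_edge, ll_edge
        return lam_hat, ll_hat

    def fit(self, lam: float | None = None) -> PGLSFit:
        if lam is None:
            if len(self.y) < 4:
                raise ValueError("lambda estimation needs n >= 4")
            lam, ll = self.profile_lambda()
        else:
            ll = self._loglik(lam)
        V = apply_lambda(self.cov.C, lam)
        beta, XtXinv, rss, _, tss = self._solve(V)
        n = len(self.y)
        df_resid = n - 2
        s2 = rss / df_resid if df_resid > 0 else float("nan")
        se = np.sqrt(np.diag(XtXinv) * s2) if df_resid > 0 else np.full(2, np.nan)
        x = self.x
        xbar = float(np.mean(x))
        return PGLSFit(
            log10_a=float(beta[0]),
            b=float(beta[1]),
            se_log10_a=float(se[0]),
            se_b=float(se[1]),
            r2=1.0 - rss / tss if tss > 0 else float("nan"),
            n=n,
            residual_sd=math.sqrt(s2) if df_resid > 0 else float("nan"),
            x_mean=xbar,
            ssx=float(np.sum((x - xbar) ** 2)),
            method="PGLS",
            lambda_hat=float(lam),
            loglik_at_lambda=float(ll),
        )


def pgls_fit(x: np.ndarray, y: np.ndarray, cov: PhyloCovariance,
             lam: float | None = None) -> PGLSFit:
    """GLS fit of y on x under covariance ``cov``.

    The matrix in ``cov`` is used as-is when ``lam`` is None (pass a
    matrix already lambda-transformed, e.g. via ``cov.with_lambda``);
    give ``lam`` to apply the Pagel transform here instead.
    """
    model = PGLSModel(x, y, cov)
    return model.fit(lam=1.0 if lam is None else lam)


def estimate_lambda_ml(x: np.ndarray, y: np.ndarray,
                       cov: PhyloCovariance) -> tuple[float, float]:
    """Maximum-likelihood Pagel's lambda for the regression residual model.

    Returns ``(lambda_hat, loglik_at_lambda_hat)``; boundary values 0 and 1
    are legitimate estimates, not errors.
    """
    if len(np.asarray(y)) < 4:
        raise ValueError("lambda estimation needs n >= 4")
    return PGLSModel(x, y, cov).profile_lambda()


def phylo_signal_mass_independent(table, tree) -> float:
    """Pagel's lambda of mass-independent BMR.

    Fits log10 BMR on log10 mass with the lambda-transformed covariance of
    the matched tree; the returned lambda measures phylogenetic signal in
    the residual (mass-corrected) BMR structure.
    """
    from .io import match_tree_to_table

    matched = match_tree_to_table(tree, table)
    cov = tree_covariance(matched.tree)
    df = matched.table.data.set_index("species")
    order = [l for l in cov.labels]
    # tip labels may use underscores for spaces
    idx = {s.replace(" ", "_"): s for s in df.index}
    rows = df.loc[[idx[l.replace(" ", "_")] for l in order]]
    x = np.log10(rows["mass_g"].to_numpy(dtype=float))
    y = np.log10(rows["bmr"].to_numpy(dtype=float))
    lam_hat, _ = estimate_lambda_ml(x, y, cov)
    return lam_hat
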