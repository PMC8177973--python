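"""Multitask sparse regression (MTSR) variable screening.

Solves the l2,1-regularised multitask least-squares problem

    min_W  1/2 ||Y - W^T X||_F^2  +  lambda * sum_i ||w^i||_2

where X (d x n) holds the channel-feature variables, Y (c x n) is a one-hot
class-indicator matrix and W (d x c) is the coefficient matrix.  The l2,1
penalty zeroes whole rows of W, eliminating a (channel, feature) variable
jointly across all class tasks; variables with surviving rows are kept.

Two solvers are provided: iteratively reweighted least squares (IRLS, the
default — each step solves a d x d ridge-like system) and an accelerated
proximal-gradient (FISTA) solver used as an independent numerical
cross-check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .varset import VariableSet

logger = logging.getLogger(__name__)


def one_hot(labels) -> tuple[np.ndarray, tuple]:
    """Encode per-window labels as a c x n {0,1} indicator matrix.

    Classes are ordered by sorted unique label; each column sums to 1.
    """
    labels = np.asarray(labels)
    classes = tuple(np.unique(labels).tolist())
    Y = np.zeros((len(classes), len(labels)))
    for k, cls in enumerate(classes):
        Y[k, labels == cls] = 1.0
    return Y, classes


def mtsr_objective(W: np.ndarray, X: np.ndarray, Y: np.ndarray,
                   lam: float) -> float:
    """1/2 ||Y - W^T X||_F^2 + lambda * l2,1(W)."""
    W, X, Y = (np.asarray(a, dtype=float) for a in (W, X, Y))
    if W.shape[0] != X.shape[0] or W.shape[1] != Y.shape[0] \
            or X.shape[1] != Y.shape[1]:
        raise ValueError("incompatible shapes for W, X, Y")
    resid = Y - W.T @ X
    return 0.5 * float(np.sum(resid * resid)) \
        + lam * float(np.sum(np.linalg.norm(W, axis=1)))


def lambda_max(X: np.ndarray, Y: np.ndarray) -> float:
    """Smallest penalty at which W = 0 is stationary: the largest row
    l2-norm of X Y^T."""
    return float(np.linalg.norm(np.asarray(X) @ np.asarray(Y).T,
                                axis=1).max())


@dataclass
class MTSRResults:
    """Fit results: coefficients, row norms, convergence diagnostics."""

    W: np.ndarray
    lam: float
    objective_trace: np.ndarray
    smoothed_trace: np.ndarray
    converged: bool
    n_iter: int
    classes: tuple
    row_index: tuple | None = None
    zero_floor: float = 0.0

    @property
    def row_norms(self) -> np.ndarray:
        return np.linalg.norm(self.W, axis=1)

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])

    def selected_rows(self, zero_tol: float = 1e-6) -> np.ndarray:
        """Indices of rows treated as nonzero.

        A row survives if its norm exceeds ``zero_tol`` times the largest
        row norm and the absolute floor below which a truly zero row can
        linger due to epsilon smoothing.
        """
        norms = self.row_norms
        mx = norms.max() if len(norms) else 0.0
        thr = max(zero_tol * mx, self.zero_floor)
        return np.flatnonzero(norms > thr)

    def variable_set(self, row_index=None, zero_tol: float = 1e-6) -> VariableSet:
        idx = row_index if row_index is not None else self.row_index
        if idx is None:
            raise ValueError("no row_index available")
        keep = self.selected_rows(zero_tol)
        if len(keep) == 0:
            logger.info("MTSR at lambda=%g selected no variables", self.lam)
        norms = self.row_norms
        order = keep[np.argsort(-norms[keep], kind="stable")]
        return VariableSet(pairs=tuple(idx[i] for i in order),
                           method="mtsr",
                           scores=tuple(float(norms[i]) for i in order))

    def summary(self) -> str:
        norms = self.row_norms
        sel = self.selected_rows()
        lines = [
            "Multitask sparse regression (l2,1) results",
            "=" * 44,
            f"lambda            {self.lam:.6g}",
            f"variables (d)     {self.W.shape[0]}",
            f"tasks (c)         {self.W.shape[1]}",
            f"selected rows     {len(sel)}",
            f"iterations        {self.n_iter}",
            f"converged         {self.converged}",
            f"final objective   {self.objective:.6g}",
            "",
            "top rows by coefficient norm:",
        ]
        top = np.argsort(-norms)[:10]
        for i in top:
            name = (f"{self.row_index[i][0]}:{self.row_index[i][1]}"
                    if self.row_index else f"row {i}")
            lines.append(f"  {name:<24s} {norms[i]:.4g}")
        return "\n".join(lines)


class MTSRModel:
    """Model object for the l2,1-penalised multitask regression.

    Parameters
    ----------
    X : (d, n) array
        Variables x samples (typically a standardized feature matrix).
    y : (n,) labels or (c, n) one-hot matrix
        Gesture class per sample.
    lam : float
        Sparsity weight; larger values zero more rows of W.
    epsilon : float
        Row-norm smoothing constant of the IRLS reweighting.
    tol : float
        Relative objective-change convergence tolerance.
    max_iter : int
        IRLS iteration cap; non-convergence returns the best iterate
        flagged ``converged=False``.
    """

    def __init__(self, X, y, lam: float, *, epsilon: float = 1e-8,
                 tol: float = 1e-7, max_iter: int = 200, row_index=None):
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (d x n)")
        y = np.asarray(y)
        if y.ndim == 1:
            self.Y, self.classes = one_hot(y)
        else:
            self.Y = np.asarray(y, dtype=float)
            self.classes = tuple(range(self.Y.shape[0]))
        if self.Y.shape[1] != self.X.shape[1]:
            raise ValueError("X and Y sample counts differ")
        if lam < 0:
            raise ValueError("lambda must be >= 0")
        self.lam = float(lam)
        self.epsilon = float(epsilon)
        self.tol = float(tol)
        self.max_iter = int(max_iter)
        self.row_index = tuple(row_index) if row_index is not None else None

    # -- solvers ----------------------------------------------------------

    def fit(self, method: str = "irls") -> MTSRResults:
        if method == "irls":
            return self._fit_irls()
        if method == "proxgrad":
            return self._fit_proxgrad()
        raise ValueError("method must be 'irls' or 'proxgrad'")

    def _smoothed_objective(self, W, G, B) -> float:
        resid = self.Y - W.T @ self.X
        pen = np.sum(np.sqrt(np.sum(W * W, axis=1) + self.epsilon ** 2))
        return 0.5 * float(np.sum(resid * resid)) + self.lam * float(pen)

    def _fit_irls(self) -> MTSRResults:
        X, Y, lam, eps = self.X, self.Y, self.lam, self.epsilon
        d = X.shape[0]
        G = X @ X.T
        B = X @ Y.T
        ridge = lam if lam > 0 else 1e-8 * max(1.0, np.trace(G) / d)
        W = np.linalg.solve(G + ridge * np.eye(d), B)
        obj = [mtsr_objective(W, X, Y, lam)]
        sobj = [self._smoothed_objective(W, G, B)]
        converged = False
        it = 0
        if lam == 0:
            converged = True  # ridge/pseudo-inverse solution is the answer
        else:
            for it in range(1, self.max_iter + 1):
                dinv = 1.0 / np.sqrt(np.sum(W * W, axis=1) + eps ** 2)
                W = np.linalg.solve(G + lam * np.diag(dinv), B)
                obj.append(mtsr_objective(W, X, Y, lam))
                sobj.append(self._smoothed_objective(W, G, B))
                rel = abs(sobj[-2] - sobj[-1]) / max(abs(sobj[-2]), 1e-30)
                if rel < self.tol:
                    converged = True
                    break
            if not converged:
                logger.warning("IRLS did not converge in %d iterations",
                               self.max_iter)
        zero_floor = 0.0
        if lam > 0:
            # converged truly-zero rows linger at ~eps*lambda_max/lam;
            # rows still shrinking when the objective test fires are
            # bounded via the per-step objective decrease (~tol * J).
            zero_floor = max(10.0 * eps * lambda_max(X, Y) / lam,
                             30.0 * self.tol * obj[-1] / lam)
        return MTSRResults(W=W, lam=lam,
                           objective_trace=np.asarray(obj),
                           smoothed_trace=np.asarray(sobj),
                           converged=converged, n_iter=it,
                           classes=self.classes, row_index=self.row_index,
                           zero_floor=zero_floor)

    def _fit_proxgrad(self, max_iter: int = 20000,
                      tol: float = 1e-12) -> MTSRResults:
        """FISTA with row-wise group soft-thresholding (reference solver)."""
        X, Y, lam = self.X, self.Y, self.lam
        d, c = X.shape[0], Y.shape[0]
        G = X @ X.T
        B = X @ Y.T
        L = float(np.linalg.eigvalsh(G).max())
        L = max(L, 1e-12)
        step = 1.0 / L
        W = np.zeros((d, c))
        V = W.copy()
        t = 1.0
        obj = [mtsr_objective(W, X, Y, lam)]
        for it in range(1, max_iter + 1):
            grad = G @ V - B
            U = V - step * grad
            norms = np.linalg.norm(U, axis=1)
            shrink = np.maximum(0.0, 1.0 - step * lam /
                                np.maximum(norms, 1e-30))
            W_new = U * shrink[:, None]
            t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
            V = W_new + ((t - 1.0) / t_new) * (W_new - W)
            W, t = W_new, t_new
            obj.append(mtsr_objective(W, X, Y, lam))
            if it > 1 and abs(obj[-2] - obj[-1]) <= tol * max(abs(obj[-2]),
                                                             1e-30):
                break
        trace = np.asarray(obj)
        return MTSRResults(W=W, lam=lam, objective_trace=trace,
                           smoothed_trace=trace, converged=True,
                           n_iter=len(obj) - 1, classes=self.classes,
                           row_index=self.row_index, zero_floor=0.0)


# ---------------------------------------------------------------------------
# functional wrappers


def solve_mtsr(X, y, lam, *, epsilon: float = 1e-8, tol: float = 1e-7,
               max_iter: int = 200, row_index=None,
               method: str = "irls") -> MTSRResults:
    return MTSRModel(X, y, lam, epsilon=epsilon, tol=tol, max_iter=max_iter,
                     row_index=row_index).fit(method=method)


def select_variables_mtsr(results: MTSRResults, row_index=None,
                          zero_tol: float = 1e-6) -> VariableSet:
    return results.variable_set(row_index=row_index, zero_tol=zero_tol)


def lambda_sweep(X, y, grid, *, row_index=None, eval_config=None,
                 zero_tol: float = 1e-6, **solver_kw):
    """Fit MTSR along a penalty grid and tabulate selection size (and,
    optionally, cross-validated accuracy of the selected variables).

    ``eval_config`` is a dict passed to evaluate.crossval_evaluate and must
    include ``feature_matrix`` (the unstandardized FeatureMatrix whose rows
    the indices refer to); accuracy is NaN where the selection is empty.
    """
    import pandas as pd

    grid = list(grid)
    if not grid:
        raise ValueError("empty lambda grid")
    rows = []
    prev = None
    for lam in grid:
        res = solve_mtsr(X, y, lam, row_index=row_index, **solver_kw)
        keep = res.selected_rows(zero_tol)
        n_sel = len(keep)
        if prev is not None and n_sel > prev:
            logger.info("selection size increased at lambda=%g "
                        "(%d -> %d)", lam, prev, n_sel)
        prev = n_sel
        acc = np.nan
        if eval_config is not None and n_sel > 0:
            from .evaluate import crossval_evaluate

            cfg = dict(eval_config)
            fm = cfg.pop("feature_matrix")
            vs = res.variable_set(zero_tol=zero_tol)
            sub = fm.subset(channels=set(vs.channels),
                            features={ft for _, ft in vs.pairs})
            # keep exactly the selected pairs
            keep_rows = [i for i, pr in enumerate(sub.row_index)
                         if pr in vs.as_set()]
            sub = FeatureSubset(sub, keep_rows)
            acc = crossval_evaluate(sub, **cfg).accuracy_mean
        rows.append({"lambda": lam, "n_selected": n_sel,
                     "cv_accuracy": acc})
    return pd.DataFrame(rows)


class FeatureSubset:
    """Row-subset view quacking like a FeatureMatrix for evaluation."""

    def __init__(self, fm, rows):
        self.values = fm.values[rows]
        self.row_index = tuple(fm.row_index[i] for i in rows)
        self.col_labels = fm.col_labels
        self.window_spec = fm.window_spec
        self.standardization = fm.standardization

    def subset(self, channels=None, features=None):
        from .features import FeatureMatrix

        return FeatureMatrix(self.values, self.row_index,
                             self.col_labels).subset(channels, features)


def pick_lambda(sweep_table, margin: float = 0.01) -> float:
    """Pick the penalty giving the smallest selection whose CV accuracy is
    within ``margin`` of the best — the accuracy-versus-size trade-off read
    off a sweep curve, made explicit.  Requires evaluated accuracies.
    """
    tab = sweep_table.dropna(subset=["cv_accuracy"])
    if tab.empty:
        raise ValueError("sweep table has no evaluated accuracies")
    best = tab["cv_accuracy"].max()
    ok = tab[tab["cv_accuracy"] >= best - margin]
    ok = ok.sort_values(["n_selected", "lambda"], ascending=[True, False])
    return float(ok.iloc[0]["lambda"])
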