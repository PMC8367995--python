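"""Entropic optimal-transport couplings between consecutive time points.

Two estimators are provided, both scikit-learn compatible:

* :class:`StateCoupling` — the state-only baseline: entropic OT between
  early and late cell states with quadratic cost ``||x_i - y_j||^2``.
  This is the maximum-likelihood coupling of a pure diffusion when the
  entropy parameter equals the diffusion variance accrued between the two
  sampling times.
* :class:`LineageCoupling` — the lineage-aware coupling: each late cell's
  ancestor state at the early time is first estimated from the lineage
  tree (Gaussian graphical model, see :mod:`treeot.ancestors`), then
  entropic OT couples early cells to those inferred ancestors with cost
  ``||x_i - mu_j||^2 / sigma_j^2``.

The solver is a log-domain Sinkhorn iteration, so small entropy values are
handled without underflow.  Marginals are hard constraints (balanced OT).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .ancestors import AncestorEstimate, DiffusionModel, estimate_ancestors
from .tree import LineageTree

__all__ = [
    "Coupling",
    "quadratic_cost",
    "lineage_cost",
    "entropic_ot",
    "fit_state_coupling",
    "fit_lineage_coupling",
    "compose",
    "independent_coupling",
    "StateCoupling",
    "LineageCoupling",
]


class SinkhornWarning(UserWarning):
    pass


@dataclass
class Coupling:
    """A joint distribution over (early cell, late cell) pairs.

    ``matrix`` is nonnegative, sums to one, and its row/column sums match
    the declared marginals to solver tolerance.
    """

    matrix: np.ndarray
    row_marginal: np.ndarray
    col_marginal: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.row_marginal = np.asarray(self.row_marginal, dtype=float)
        self.col_marginal = np.asarray(self.col_marginal, dtype=float)

    @property
    def shape(self):
        return self.matrix.shape

    def validate(self, atol: float = 1e-6) -> "Coupling":
        if (self.matrix < -1e-12).any():
            raise ValueError("coupling has negative entries")
        if abs(self.matrix.sum() - 1.0) > 1e-8:
            raise ValueError("coupling mass is not 1")
        if np.abs(self.matrix.sum(axis=1) - self.row_marginal).max() > atol:
            raise ValueError("row sums do not match row marginal")
        if np.abs(self.matrix.sum(axis=0) - self.col_marginal).max() > atol:
            raise ValueError("column sums do not match column marginal")
        return self

    # -- serialization ----------------------------------------------------
    def to_tsv(self, path, row_ids=None, col_ids=None) -> None:
        import pandas as pd

        n, m = self.shape
        df = pd.DataFrame(self.matrix,
                          index=row_ids if row_ids is not None else range(n),
                          columns=col_ids if col_ids is not None else range(m))
        df.to_csv(path, sep="\t")
        sidecar = str(path) + ".json"
        with open(sidecar, "w") as fh:
            json.dump({k: v for k, v in self.metadata.items()
                       if isinstance(v, (int, float, str, bool, type(None)))},
                      fh, indent=2)

    @classmethod
    def from_tsv(cls, path) -> "Coupling":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        g = df.to_numpy(dtype=float)
        meta = {}
        try:
            with open(str(path) + ".json") as fh:
                meta = json.load(fh)
        except OSError:
            pass
        return cls(g, g.sum(axis=1), g.sum(axis=0), meta)


# ---------------------------------------------------------------------------
# Costs
# ---------------------------------------------------------------------------

def _states(X) -> np.ndarray:
    X = np.asarray(getattr(X, "X", X), dtype=float)
    return np.atleast_2d(X)


def quadratic_cost(X, Y) -> np.ndarray:
    """Squared-Euclidean cost ``c[i,j] = ||x_i - y_j||^2``."""
    X, Y = _states(X), _states(Y)
    if X.shape[1] != Y.shape[1]:
        raise ValueError(
            f"state dimensions differ: {X.shape[1]} vs {Y.shape[1]}")
    return cdist(X, Y, metric="sqeuclidean")


def lineage_cost(X, est: AncestorEstimate) -> np.ndarray:
    """Cost ``c[i,j] = ||x_i - mu_j||^2 / sigma_j^2`` against inferred ancestors."""
    c = quadratic_cost(X, est.means)
    return c / est.variances[None, :]


# ---------------------------------------------------------------------------
# Sinkhorn
# ---------------------------------------------------------------------------

def entropic_ot(
    cost: np.ndarray,
    row_marginal=None,
    col_marginal=None,
    epsilon: float = 0.05,
    max_iter: int = 100_000,
    tol: float = 1e-9,
) -> Coupling:
    """Entropically regularized optimal transport.

    Minimizes ``sum(gamma*cost) - epsilon*H(gamma)`` subject to the given
    marginals, by log-domain Sinkhorn scaling.  Iterations stop when the
    worst marginal violation drops below ``tol`` (or at ``max_iter``, with
    a warning and the best iterate).
    """
    C = np.asarray(cost, dtype=float)
    if not np.isfinite(C).all():
        raise ValueError("cost matrix must be finite")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    n, m = C.shape
    a = np.full(n, 1.0 / n) if row_marginal is None else np.asarray(row_marginal, float)
    b = np.full(m, 1.0 / m) if col_marginal is None else np.asarray(col_marginal, float)
    for v, name in ((a, "row"), (b, "col")):
        if (v < 0).any():
            raise ValueError(f"{name} marginal has negative entries")
        if abs(v.sum() - 1.0) > 1e-8:
            raise ValueError(f"{name} marginal must sum to 1")

    # zero-mass rows/columns are dropped and reinserted as zero slices
    ri, ci = np.nonzero(a)[0], np.nonzero(b)[0]
    Cs = C[np.ix_(ri, ci)]
    la = np.log(a[ri])
    lb = np.log(b[ci])
    K = -Cs / epsilon  # log kernel
    f = np.zeros(ri.size)
    g = np.zeros(ci.size)
    converged = False
    for it in range(max_iter):
        f = epsilon * (la - logsumexp((g[None, :] - Cs) / epsilon, axis=1))
        g = epsilon * (lb - logsumexp((f[:, None] - Cs) / epsilon, axis=0))
        if it % 10 == 0 or it == max_iter - 1:
            P = np.exp((f[:, None] + g[None, :] - Cs) / epsilon)
            err = max(np.abs(P.sum(axis=1) - a[ri]).max(),
                      np.abs(P.sum(axis=0) - b[ci]).max())
            if err < tol:
                converged = True
                break
    if not converged:
        P = np.exp((f[:, None] + g[None, :] - Cs) / epsilon)
        warnings.warn(
            f"Sinkhorn did not reach tol={tol} in {max_iter} iterations "
            f"(violation {err:.2e}); returning best iterate",
            SinkhornWarning,
        )
    full = np.zeros((n, m))
    full[np.ix_(ri, ci)] = P
    return Coupling(full, a, b, {"epsilon": float(epsilon), "cost": "custom",
                                 "converged": bool(converged)})


def _resolve_epsilon(epsilon, scale, cost):
    if scale == "absolute":
        return float(epsilon)
    if scale == "median":
        med = float(np.median(cost))
        return float(epsilon) * (med if med > 0 else 1.0)
    raise ValueError("epsilon_scale must be 'absolute' or 'median'")


def fit_state_coupling(X, Y, row_marginal=None, col_marginal=None,
                       epsilon=0.05, epsilon_scale="median", **kw) -> Coupling:
    """State-only entropic OT with quadratic cost (diffusion baseline)."""
    C = quadratic_cost(X, Y)
    eps = _resolve_epsilon(epsilon, epsilon_scale, C)
    cpl = entropic_ot(C, row_marginal, col_marginal, eps, **kw)
    cpl.metadata.update(cost="quadratic", epsilon_requested=float(epsilon),
                        epsilon_scale=epsilon_scale)
    return cpl


def fit_lineage_coupling(X, Y, tree: LineageTree, row_marginal=None,
                         col_marginal=None, epsilon=0.05,
                         epsilon_scale="median",
                         model: DiffusionModel | None = None,
                         cell_ids=None, **kw) -> Coupling:
    """Lineage-aware entropic OT.

    Chains the four steps: insert the t1 slice into the tree, estimate each
    late cell's ancestor state, form the variance-scaled quadratic cost to
    the early cells, and solve entropic OT.  The returned coupling carries
    the :class:`AncestorEstimate` in ``metadata['ancestors']``.
    """
    if model is None:
        raise ValueError("a DiffusionModel (with t1, t2) is required")
    est = estimate_ancestors(tree, _states(Y), model, cell_ids=cell_ids)
    C = lineage_cost(X, est)
    eps = _resolve_epsilon(epsilon, epsilon_scale, C)
    cpl = entropic_ot(C, row_marginal, col_marginal, eps, **kw)
    cpl.metadata.update(cost="lineage", epsilon_requested=float(epsilon),
                        epsilon_scale=epsilon_scale, ancestors=est)
    return cpl


# ---------------------------------------------------------------------------
# Algebra on couplings
# ---------------------------------------------------------------------------

def _rowcond(M: np.ndarray) -> np.ndarray:
    s = M.sum(axis=1, keepdims=True)
    out = np.divide(M, s, out=np.zeros_like(M), where=s > 0)
    return out


def compose(g12: Coupling, g23: Coupling, atol: float = 1e-6) -> Coupling:
    """Concatenate couplings across time points by conditional composition.

    ``P(3|1) = sum_2 P(3|2) P(2|1)``; the composed joint keeps g12's row
    marginal.  Requires g12's column marginal to match g23's row marginal.
    """
    mid1 = g12.matrix.sum(axis=0)
    mid2 = g23.matrix.sum(axis=1)
    if np.abs(mid1 - mid2).max() > atol:
        raise ValueError("intermediate marginals do not match")
    row = g12.matrix.sum(axis=1)
    composed = np.diag(row) @ _rowcond(g12.matrix) @ _rowcond(g23.matrix)
    return Coupling(composed, row, composed.sum(axis=0),
                    {"composed": True})


def independent_coupling(row_marginal, col_marginal) -> Coupling:
    """The noninformative product coupling (outer product of marginals)."""
    a = np.asarray(row_marginal, float)
    b = np.asarray(col_marginal, float)
    return Coupling(np.outer(a, b), a, b, {"cost": "independent"})


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

class StateCoupling(BaseEstimator):
    """Entropic OT between early and late cell states (no lineage).

    Parameters
    ----------
    epsilon : float
        Entropy parameter.  Interpreted on the scale given by
        ``epsilon_scale``: "median" multiplies by the median entry of the
        cost matrix (unit-free), "absolute" uses cost units directly.
    epsilon_scale : {"median", "absolute"}
    max_iter, tol
        Sinkhorn stopping controls.

    Attributes
    ----------
    coupling_ : Coupling
    cost_matrix_ : ndarray
    epsilon_ : float
        The absolute entropy value actually used.
    """

    def __init__(self, epsilon=0.05, epsilon_scale="median",
                 max_iter=100_000, tol=1e-9):
        self.epsilon = epsilon
        self.epsilon_scale = epsilon_scale
        self.max_iter = max_iter
        self.tol = tol

    def _marginals(self, n, m, row_marginal, col_marginal):
        a = np.full(n, 1.0 / n) if row_marginal is None else np.asarray(row_marginal, float)
        b = np.full(m, 1.0 / m) if col_marginal is None else np.asarray(col_marginal, float)
        return a, b

    def fit(self, X, Y, row_marginal=None, col_marginal=None):
        X, Y = _states(X), _states(Y)
        C = quadratic_cost(X, Y)
        a, b = self._marginals(C.shape[0], C.shape[1], row_marginal, col_marginal)
        self.epsilon_ = _resolve_epsilon(self.epsilon, self.epsilon_scale, C)
        self.cost_matrix_ = C
        self.coupling_ = entropic_ot(C, a, b, self.epsilon_,
                                     max_iter=self.max_iter, tol=self.tol)
        self.coupling_.metadata.update(cost="quadratic")
        return self

    def predict_descendants(self, weights_on_early: np.ndarray) -> np.ndarray:
        """Push a distribution over early cells forward to late cells."""
        cond = _rowcond(self.coupling_.matrix)
        return np.asarray(weights_on_early, float) @ cond

    def predict_ancestors(self, weights_on_late: np.ndarray) -> np.ndarray:
        """Pull a distribution over late cells back to early cells."""
        cond = _rowcond(self.coupling_.matrix.T)
        return np.asarray(weights_on_late, float) @ cond


class LineageCoupling(StateCoupling):
    """Lineage-aware entropic OT using a lineage tree for the late cells.

    In addition to :class:`StateCoupling`'s parameters:

    Parameters
    ----------
    t1, t2 : float
        Early and late sampling times on the tree's clock.
    diffusion : float
        Diffusion constant D of the Gaussian tree model.  Only rescales
        the cost; absorbed by ``epsilon`` in practice.

    Attributes
    ----------
    ancestors_ : AncestorEstimate
        Inferred ancestor means/variances used to build the cost.
    """

    def __init__(self, epsilon=0.05, epsilon_scale="median", t1=None, t2=None,
                 diffusion=1.0, max_iter=100_000, tol=1e-9):
        super().__init__(epsilon=epsilon, epsilon_scale=epsilon_scale,
                         max_iter=max_iter, tol=tol)
        self.t1 = t1
        self.t2 = t2
        self.diffusion = diffusion

    def fit(self, X, Y, tree: LineageTree = None, row_marginal=None,
            col_marginal=None, cell_ids=None):
        if tree is None:
            raise ValueError("LineageCoupling.fit requires tree=")
        if self.t1 is None:
            raise ValueError("t1 must be set")
        X, Y = _states(X), _states(Y)
        t2 = self.t2 if self.t2 is not None else min(
            tree.time(v) for v in tree.leaves())
        model = DiffusionModel(D=self.diffusion, t1=self.t1, t2=t2)
        self.ancestors_ = estimate_ancestors(tree, Y, model, cell_ids=cell_ids)
        C = lineage_cost(X, self.ancestors_)
        a, b = self._marginals(C.shape[0], C.shape[1], row_marginal, col_marginal)
        self.epsilon_ = _resolve_epsilon(self.epsilon, self.epsilon_scale, C)
        self.cost_matrix_ = C
        self.coupling_ = entropic_ot(C, a, b, self.epsilon_,
                                     max_iter=self.max_iter, tol=self.tol)
        self.coupling_.metadata.update(cost="lineage", ancestors=self.ancestors_)
        return self
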