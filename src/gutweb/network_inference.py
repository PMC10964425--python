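"""Sparse signed co-occurrence network inference from compositional counts.

The pipeline is the latent Gaussian graphical model route: centered
log-ratio (clr) transform to lift counts out of the simplex, per-node
L1-penalized neighborhood regressions to estimate the conditional-dependence
graph, and StARS (Stability Approach to Regularization Selection) over
subsamples to pick the sparsest penalty whose edge set is stable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path

from gutweb.tabular_io import FeatureTable

logger = logging.getLogger(__name__)


@dataclass
class CompositionMatrix:
    """clr-transformed abundances; every row sums to zero."""

    values: pd.DataFrame  # samples × features
    pseudocount: float

    def __post_init__(self) -> None:
        row_sums = self.values.sum(axis=1).to_numpy()
        if np.any(np.abs(row_sums) > 1e-9 * max(1, self.values.shape[1])):
            raise ValueError("clr rows must sum to zero")

    @property
    def feature_ids(self) -> list:
        return list(self.values.columns)


@dataclass
class AssociationNetwork:
    """Signed, weighted, undirected association graph with provenance."""

    nodes: list
    edges: list  # (u, v, weight) with u < v, weight != 0
    node_domain: dict = field(default_factory=dict)
    lambda_path: np.ndarray | None = None
    selected_lambda: float | None = None
    instability_per_lambda: np.ndarray | None = None
    subsample_count: int | None = None
    seed: int | None = None
    sign_conflicts: int = 0

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for u, v, w in self.edges:
            if u == v:
                raise ValueError(f"self-edge on node {u!r}")
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge endpoint not among nodes: ({u!r}, {v!r})")
            if w == 0:
                raise ValueError(f"zero-weight edge ({u!r}, {v!r})")
        if self.instability_per_lambda is not None:
            inst = np.asarray(self.instability_per_lambda)
            if np.any((inst < 0) | (inst > 0.5)):
                raise ValueError("instability values must lie in [0, 0.5]")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_id_set(self) -> set:
        return {frozenset((u, v)) for u, v, _ in self.edges}

    def to_networkx(self, signed: bool = True):
        import networkx as nx

        g = nx.Graph()
        for n in self.nodes:
            g.add_node(n, domain=self.node_domain.get(n, "unknown"))
        for u, v, w in self.edges:
            g.add_edge(u, v, weight=w if signed else abs(w),
                       sign="positive" if w > 0 else "negative")
        return g


# ---------------------------------------------------------------------------
# clr
# ---------------------------------------------------------------------------

def clr_transform(table: FeatureTable, pseudocount: float = 1.0) -> CompositionMatrix:
    """Centered log-ratio transform of each sample row.

    y_j = log(x_j + pseudocount) - mean_k log(x_k + pseudocount).
    ``pseudocount=0`` is allowed only on strictly positive tables, where clr
    is exactly scale-invariant.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    x = table.counts.to_numpy(float)
    if pseudocount == 0 and np.any(x <= 0):
        raise ValueError("pseudocount=0 requires strictly positive counts")
    logx = np.log(x + pseudocount)
    y = logx - logx.mean(axis=1, keepdims=True)
    return CompositionMatrix(
        pd.DataFrame(y, index=table.counts.index, columns=table.counts.columns),
        pseudocount=pseudocount,
    )


# ---------------------------------------------------------------------------
# neighborhood selection
# ---------------------------------------------------------------------------

def _as_values(comp) -> tuple[np.ndarray, list]:
    """Accept a CompositionMatrix, DataFrame or ndarray as estimator input."""
    if isinstance(comp, CompositionMatrix):
        return comp.values.to_numpy(float), comp.feature_ids
    if isinstance(comp, pd.DataFrame):
        return comp.to_numpy(float), list(comp.columns)
    x = np.asarray(comp, float)
    return x, [f"F{j}" for j in range(x.shape[1])]


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def _directed_coefs(x_std: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Directed lasso coefficients for every node and penalty.

    Returns an array B of shape (n_lambda, p, p) with B[l, j, i] the
    coefficient of predictor i in the penalized regression of column j at
    lambdas[l]; the diagonal is zero.
    """
    n, p = x_std.shape
    n_lam = len(lambdas)
    out = np.zeros((n_lam, p, p))
    order = np.argsort(lambdas)[::-1]  # lasso_path wants decreasing alphas
    lam_sorted = lambdas[order]
    for j in range(p):
        mask = np.arange(p) != j
        _, coefs, _ = lasso_path(x_std[:, mask], x_std[:, j], alphas=lam_sorted,
                                 max_iter=5000)
        # coefs: (p-1, n_lambda) aligned with lam_sorted
        for pos, l_idx in enumerate(order):
            out[l_idx, j, mask] = coefs[:, pos]
    return out


def _symmetrize(b: np.ndarray) -> tuple[np.ndarray, int]:
    """OR-symmetrized signed weights from a directed coefficient matrix.

    Edge (i, j) exists when either directed coefficient is nonzero; the
    weight is the mean of the nonzero coefficients, except that two nonzero
    coefficients of opposite sign resolve to the one of larger magnitude
    (counted as a conflict).
    """
    p = b.shape[0]
    w = np.zeros((p, p))
    conflicts = 0
    ij = np.transpose(np.nonzero(np.triu((b != 0) | (b.T != 0), k=1)))
    for i, j in ij:
        a, c = b[j, i], b[i, j]
        if a != 0 and c != 0:
            if np.sign(a) != np.sign(c):
                conflicts += 1
                val = a if abs(a) >= abs(c) else c
            else:
                val = 0.5 * (a + c)
        else:
            val = a if a != 0 else c
        w[i, j] = w[j, i] = val
    return w, conflicts


def mb_neighborhood(comp: CompositionMatrix, lam: float
                    ) -> tuple[pd.DataFrame, int]:
    """Meinshausen–Bühlmann neighborhood selection at a single penalty.

    Columns are standardized internally, each column is lasso-regressed on
    all the others with penalty ``lam`` on the standardized coefficients, and
    the directed supports are OR-combined into a signed symmetric weight
    matrix. Returns (weights, sign_conflict_count).
    """
    if lam <= 0:
        raise ValueError("lambda must be > 0 (the dense solution is not meaningful)")
    x, ids = _as_values(comp)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 features")
    b = _directed_coefs(_standardize(x), np.array([lam]))[0]
    w, conflicts = _symmetrize(b)
    if conflicts:
        logger.info("mb_neighborhood: %d opposite-sign coefficient conflicts", conflicts)
    return pd.DataFrame(w, index=ids, columns=ids), conflicts


def default_lambda_path(comp: CompositionMatrix, n_lambda: int = 30,
                        ratio: float = 0.01) -> np.ndarray:
    """Log-spaced path from lambda_max (max |off-diagonal correlation|) down."""
    x, _ = _as_values(comp)
    x = _standardize(x)
    n = x.shape[0]
    corr = (x.T @ x) / n
    np.fill_diagonal(corr, 0.0)
    lam_max = float(np.abs(corr).max())
    if lam_max <= 0:
        lam_max = 1.0
    return np.logspace(np.log10(lam_max), np.log10(lam_max * ratio), n_lambda)


def stars_select(comp: CompositionMatrix, lambda_path: np.ndarray | None = None,
                 beta_target: float = 0.05, n_subsamples: int = 20,
                 seed: int = 0, n_lambda: int = 30,
                 node_domain: dict | None = None) -> AssociationNetwork:
    """StARS model selection over subsampled neighborhood regressions.

    Draws ``n_subsamples`` subsamples of size b = min(floor(10 sqrt(n)),
    floor(0.8 n)) without replacement, estimates the edge set at every
    penalty on each, and measures per-penalty instability as the mean over
    all feature pairs of 2 theta (1 - theta), where theta is the edge's
    selection frequency. The largest penalty whose running-supremum
    instability stays at or below ``beta_target`` is selected and refit on
    the full data.
    """
    if n_subsamples < 2:
        raise ValueError("n_subsamples must be >= 2")
    x, ids = _as_values(comp)
    n, p = x.shape
    if lambda_path is None:
        lambda_path = default_lambda_path(comp, n_lambda=n_lambda)
    lambda_path = np.asarray(lambda_path, float)
    if np.any(np.diff(lambda_path) >= 0):
        raise ValueError("lambda_path must be strictly decreasing")

    rng = np.random.default_rng(seed)
    b = min(int(np.floor(10 * np.sqrt(n))), int(np.floor(0.8 * n)))
    b = max(b, 2)
    n_lam = len(lambda_path)
    freq = np.zeros((n_lam, p, p))
    for _ in range(n_subsamples):
        idx = rng.choice(n, size=b, replace=False)
        coefs = _directed_coefs(_standardize(x[idx]), lambda_path)
        support = (coefs != 0) | np.transpose(coefs != 0, (0, 2, 1))
        freq += support
    freq /= n_subsamples

    iu = np.triu_indices(p, k=1)
    theta = freq[:, iu[0], iu[1]]
    instability = (2 * theta * (1 - theta)).mean(axis=1)
    sup_instability = np.maximum.accumulate(instability)

    ok = np.nonzero(sup_instability <= beta_target)[0]
    if len(ok) > 0:
        # the densest model (smallest penalty) whose edge set is still stable
        sel_idx = int(ok[-1])
    else:
        sel_idx = int(np.argmin(np.abs(sup_instability - beta_target)))
        warnings.warn(
            f"no penalty reached instability <= {beta_target}; selected the "
            f"closest (instability {sup_instability[sel_idx]:.4f})",
            stacklevel=2,
        )
    selected_lambda = float(lambda_path[sel_idx])

    weights, conflicts = mb_neighborhood(comp, selected_lambda)
    wv = weights.to_numpy()
    edges = [
        (ids[i], ids[j], float(wv[i, j]))
        for i, j in zip(*np.nonzero(np.triu(wv, k=1) != 0))
    ]
    return AssociationNetwork(
        nodes=list(ids), edges=sorted(edges),
        node_domain=dict(node_domain or {}),
        lambda_path=lambda_path, selected_lambda=selected_lambda,
        instability_per_lambda=sup_instability,
        subsample_count=n_subsamples, seed=seed,
        sign_conflicts=conflicts,
    )
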