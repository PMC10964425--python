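"""Distance-based community statistics.

Bray-Curtis dissimilarity, principal coordinate analysis, a
dispersion-homogeneity test in the style of vegan's betadisper, PERMANOVA
with crossed factors and interaction using sequential (type I) sums of
squares in the style of vegan's adonis, and patristic distance matrices
from trees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from gutweb.tabular_io import FeatureTable, PhyloTree


@dataclass
class DistanceMatrix:
    labels: list
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.labels) != v.shape[0]:
            raise ValueError("label count does not match matrix size")
        if np.any(np.abs(v - v.T) > 1e-12):
            raise ValueError("distance matrix must be symmetric to 1e-12")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be exactly 0")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame        # samples × retained axes
    eigenvalues: np.ndarray          # all eigenvalues, descending
    negative_eigenvalues: np.ndarray


@dataclass
class DispersionResult:
    distances: pd.Series             # per-sample distance to its group center
    groups: pd.Series
    f_statistic: float
    p_value: float
    center: str
    n_permutations: int
    seed: int


@dataclass
class PermanovaResult:
    table: pd.DataFrame              # index: terms + Residual + Total
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        r2 = self.table.loc[self.table.index != "Total", "R2"].sum()
        if abs(r2 - 1.0) > 1e-9:
            raise ValueError(f"R2 components sum to {r2}, expected 1")


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def bray_curtis(table: FeatureTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between sample rows: sum|x-y| / sum(x+y)."""
    x = table.counts.to_numpy(float)
    if np.any(x.sum(axis=1) <= 0):
        bad = [s for s, t in zip(table.sample_ids, x.sum(axis=1)) if t <= 0]
        raise ValueError(f"zero-total samples have undefined dissimilarity: {bad[:5]}")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(labels=table.sample_ids, values=d)


def patristic_matrix(tree: PhyloTree) -> DistanceMatrix:
    """Sum of branch lengths along the path between every pair of tips."""
    pdm = tree.tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix(labels=labels, values=d)


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ (d ** 2) @ j


def pcoa(d: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Principal coordinate analysis by eigendecomposition of the Gower matrix.

    Returns up to ``k`` coordinate axes scaled by sqrt(eigenvalue) for the
    positive eigenvalues; negative eigenvalues are reported but their axes
    omitted (fewer axes with a warning when k exceeds the positive count).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    g = _gower_center(d.values)
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = 1e-8 * max(1.0, abs(eigvals[0]))
    positive = eigvals > tol
    n_pos = int(positive.sum())
    if k > n_pos:
        warnings.warn(f"only {n_pos} positive eigenvalues; returning {n_pos} axes",
                      stacklevel=2)
    n_axes = min(k, n_pos)
    coords = eigvecs[:, :n_axes] * np.sqrt(eigvals[:n_axes])
    return OrdinationResult(
        coordinates=pd.DataFrame(
            coords, index=d.labels,
            columns=[f"PCo{a + 1}" for a in range(n_axes)],
        ),
        eigenvalues=eigvals,
        negative_eigenvalues=eigvals[eigvals < -tol],
    )


# ---------------------------------------------------------------------------
# dispersion homogeneity
# ---------------------------------------------------------------------------

def _spatial_median(x: np.ndarray, tol: float = 1e-10,
                    max_iter: int = 1000) -> np.ndarray:
    """Geometric (spatial) median by Weiszfeld iteration."""
    c = x.mean(axis=0)
    for _ in range(max_iter):
        dist = np.linalg.norm(x - c, axis=1)
        if np.any(dist < 1e-12):  # median coincides with a point
            return x[np.argmin(dist)].copy()
        w = 1.0 / dist
        c_new = (x * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(c_new - c) < tol:
            return c_new
        c = c_new
    return c


def _anova_f(z: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = len(z)
    grand = z.mean()
    ssb = 0.0
    ssw = 0.0
    for g in range(n_groups):
        zg = z[codes == g]
        ssb += len(zg) * (zg.mean() - grand) ** 2
        ssw += ((zg - zg.mean()) ** 2).sum()
    # guard against pure floating-point residue when all distances coincide
    eps = 1e-12 * max(1.0, float((z ** 2).sum()))
    if ssw <= eps:
        return 0.0 if ssb <= eps else np.inf
    return (ssb / (n_groups - 1)) / (ssw / (n - n_groups))


def betadisper(d: DistanceMatrix, groups, center: str = "median",
               n_perm: int = 999, seed: int = 0) -> DispersionResult:
    """Homogeneity of multivariate dispersions across groups.

    Samples are embedded by PCoA keeping both positive- and
    negative-eigenvalue axes; each sample's distance to its group center
    (spatial median by default, centroid optionally) is computed as the real
    part squared minus the imaginary part squared, floored at zero. A
    one-way ANOVA F on those distances is referenced to a permutation
    distribution obtained by shuffling group labels.
    """
    if center not in ("median", "centroid"):
        raise ValueError("center must be 'median' or 'centroid'")
    groups = pd.Series(groups)
    if len(groups) != d.n:
        raise ValueError("groups length does not match distance matrix")
    codes, levels = pd.factorize(groups, sort=True)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        small = [levels[g] for g in np.nonzero(counts < 2)[0]]
        raise ValueError(f"groups of size 1 are not allowed: {small}")

    g = _gower_center(d.values)
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = 1e-8 * max(1.0, float(np.abs(eigvals).max()))
    pos = eigvals > tol
    neg = eigvals < -tol
    real_axes = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    imag_axes = eigvecs[:, neg] * np.sqrt(-eigvals[neg])

    z2 = np.zeros(d.n)
    for gid in range(len(levels)):
        members = codes == gid
        xr = real_axes[members]
        xi = imag_axes[members]
        if center == "median":
            cr = _spatial_median(xr)
            ci = _spatial_median(xi) if xi.shape[1] else np.zeros(0)
        else:
            cr = xr.mean(axis=0)
            ci = xi.mean(axis=0) if xi.shape[1] else np.zeros(0)
        dr2 = ((xr - cr) ** 2).sum(axis=1)
        di2 = ((xi - ci) ** 2).sum(axis=1) if xi.shape[1] else 0.0
        z2[members] = np.maximum(dr2 - di2, 0.0)
    z = np.sqrt(z2)

    f_obs = _anova_f(z, codes, len(levels))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        f_perm = _anova_f(z, rng.permutation(codes), len(levels))
        if f_perm >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return DispersionResult(
        distances=pd.Series(z, index=d.labels),
        groups=pd.Series(groups.to_numpy(), index=d.labels),
        f_statistic=float(f_obs), p_value=float(p),
        center=center, n_permutations=n_perm, seed=seed,
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _term_design(factors: pd.DataFrame, term: str) -> np.ndarray:
    """One-hot design block for a main factor or an a:b interaction."""
    if ":" in term:
        parts = term.split(":")
        combined = factors[parts[0]].astype(str)
        for p_ in parts[1:]:
            combined = combined + "\x1f" + factors[p_].astype(str)
        codes, _ = pd.factorize(combined)
    else:
        codes, _ = pd.factorize(factors[term])
    return np.eye(codes.max() + 1)[codes]


def _hat(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Projection matrix onto the column space of x, and its rank."""
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if len(s) else 0
    u = u[:, :rank]
    return u @ u.T, rank


def permanova(d: DistanceMatrix, factors: pd.DataFrame,
              terms: list[str] | None = None, n_perm: int = 999,
              seed: int = 0) -> PermanovaResult:
    """Permutational multivariate ANOVA with sequential (type I) terms.

    Partitions the Gower-centered matrix of ``d`` by the hat matrices of the
    sequential model; each term's pseudo-F is (SS_term/df_term) /
    (SS_resid/df_resid), with significance from free permutation of sample
    labels and the add-one estimator p = (1 + #{F* >= F}) / (1 + n_perm).
    Interactions are written "a:b"; empty cells of unbalanced designs are
    dropped implicitly through the rank of the design.
    """
    factors = factors.loc[d.labels]
    if terms is None:
        terms = list(factors.columns)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = d.n
    g = _gower_center(d.values)
    ss_total = float(np.trace(g))

    hats = []
    dfs = []
    x = np.ones((n, 1))
    prev_hat, prev_rank = _hat(x)
    for term in terms:
        x = np.hstack([x, _term_design(factors, term)])
        h, rank = _hat(x)
        df = rank - prev_rank
        if df == 0:
            raise ValueError(f"term {term!r} is confounded with earlier terms")
        hats.append(h)
        dfs.append(df)
        prev_hat, prev_rank = h, rank
    df_resid = n - prev_rank
    if df_resid == 0:
        raise ValueError("zero residual degrees of freedom; model is saturated")

    def term_stats(gmat: np.ndarray) -> tuple[np.ndarray, float]:
        traces = np.array([np.sum(h * gmat) for h in hats])
        ss = np.diff(np.concatenate([[0.0], traces]))
        ss_resid = np.trace(gmat) - traces[-1]
        return ss, ss_resid

    ss_terms, ss_resid = term_stats(g)
    ms_resid = ss_resid / df_resid
    f_obs = (ss_terms / np.array(dfs)) / ms_resid

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    f_tol = 1e-9 * np.maximum(1.0, np.abs(f_obs))  # ties count as exceedances
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ss_p, ss_resid_p = term_stats(gp)
        f_p = (ss_p / np.array(dfs)) / (ss_resid_p / df_resid)
        exceed += f_p >= f_obs - f_tol
    p_values = (1 + exceed) / (1 + n_perm)

    rows = []
    for term, df, ss, f, p in zip(terms, dfs, ss_terms, f_obs, p_values):
        rows.append({"term": term, "df": df, "SS": ss, "F": f,
                     "R2": ss / ss_total, "p": p})
    rows.append({"term": "Residual", "df": df_resid, "SS": ss_resid,
                 "F": np.nan, "R2": ss_resid / ss_total, "p": np.nan})
    rows.append({"term": "Total", "df": n - 1, "SS": ss_total,
                 "F": np.nan, "R2": 1.0, "p": np.nan})
    table = pd.DataFrame(rows).set_index("term")
    return PermanovaResult(table=table, n_permutations=n_perm, seed=seed)
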