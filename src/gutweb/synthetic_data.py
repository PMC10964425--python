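"""Synthetic amplicon datasets with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume, so each stage has a recoverable target:

* multi-kingdom (16S + ITS) count tables whose dependence structure comes
  from a known sparse interaction graph, via a Gaussian copula
  (normal-to-anything) with zero-inflated negative binomial margins;
* planted reagent contaminants whose relative abundance varies inversely
  with sample DNA concentration, plus no-template-control (NTC) libraries;
* planted multiplicative host-group effects on composition;
* random binary trees with exponential branch lengths for patristic tests.

Everything is fully deterministic under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from gutweb.tabular_io import FeatureTable, PhyloTree, SampleMetadata, tree_from_newick

HOST_GROUPS = ("frog", "lizard", "salamander")
#: sampling proportions mirroring a broad herptile survey (16:35:90)
HOST_WEIGHTS = (16 / 141, 35 / 141, 90 / 141)
STATES = ("AL", "AR", "AZ", "GA", "LA", "NC", "OH", "TN")
GENERA = {
    "frog": ("Lithobates", "Hyla"),
    "lizard": ("Sceloporus", "Anolis"),
    "salamander": ("Plethodon", "Desmognathus", "Eurycea"),
}


@dataclass
class InteractionGraph:
    """A signed sparse graph over feature indices plus its precision matrix."""

    edges: list  # (i, j, sign) with i < j; sign is the association sign
    precision: np.ndarray
    partial_correlations: dict  # (i, j) -> signed partial correlation
    module_of: np.ndarray | None = None  # module id per feature (modular topology)

    @property
    def n_features(self) -> int:
        return self.precision.shape[0]

    def edge_set(self) -> set:
        return {(i, j) for i, j, _ in self.edges}


@dataclass
class ZINBParams:
    """Zero-inflated negative binomial margins.

    ``dispersion`` is the overdispersion coefficient alpha in
    Var = mu (1 + alpha mu); ``zero_inflation`` is the structural-zero
    probability.
    """

    mean: np.ndarray
    dispersion: np.ndarray
    zero_inflation: np.ndarray

    @classmethod
    def default(cls, p: int, rng: np.random.Generator,
                mean_log_mu: float = np.log(50.0), mean_log_sigma: float = 1.0,
                dispersion: float = 0.5, zero_inflation: float = 0.3):
        mu = rng.lognormal(mean_log_mu, mean_log_sigma, size=p)
        return cls(mean=mu,
                   dispersion=np.full(p, float(dispersion)),
                   zero_inflation=np.full(p, float(zero_inflation)))


@dataclass
class SyntheticTruth:
    """The planted structure a simulation run must recover."""

    graph: InteractionGraph
    feature_ids: list
    contaminant_ids: list
    group_effect_features: dict  # host_group -> list of feature ids
    group_effect_multiplier: float
    seed: int

    def __post_init__(self) -> None:
        effect = {f for ids in self.group_effect_features.values() for f in ids}
        overlap = set(self.contaminant_ids) & effect
        if overlap:
            raise ValueError(
                f"contaminant ids must be disjoint from group-effect features: "
                f"{sorted(overlap)[:5]}"
            )

    def edge_id_set(self) -> set:
        """Planted edges as unordered feature-id pairs."""
        fid = self.feature_ids
        return {frozenset((fid[i], fid[j])) for i, j, _ in self.graph.edges}


# ---------------------------------------------------------------------------
# interaction graph
# ---------------------------------------------------------------------------

def make_interaction_graph(p: int, topology: str = "modular", n_modules: int = 6,
                           density: float = 0.05, seed: int = 0,
                           partial_corr: float = 0.3,
                           positive_fraction: float = 0.8) -> InteractionGraph:
    """Sample a sparse signed graph and a matching positive-definite precision.

    The precision matrix Omega has off-diagonal support exactly on the graph
    edges, with entry -sign * partial_corr for an edge of the given
    association sign; the diagonal is boosted until the minimum eigenvalue is
    strictly positive.

    Parameters
    ----------
    p : int
        Number of features (>= 4).
    topology : {"band", "modular", "scale_free"}
    n_modules : int
        Number of equal-size modules (modular topology only).
    density : float
        Target edge density in (0, 0.5): m = round(density * p(p-1)/2).
    """
    if p < 4:
        raise ValueError("p must be >= 4")
    if not 0 < density < 0.5:
        raise ValueError("density must be in (0, 0.5)")
    rng = np.random.default_rng(seed)
    n_pairs = p * (p - 1) // 2
    m_target = max(1, round(density * n_pairs))
    module_of = None

    if topology == "band":
        pairs = []
        bandwidth = 1
        while len(pairs) < m_target:
            new = [(i, i + bandwidth) for i in range(p - bandwidth)]
            if not new:
                raise ValueError(
                    f"density {density} infeasible for band topology at p={p}"
                )
            pairs.extend(new)
            bandwidth += 1
        pairs = pairs[:m_target]
    elif topology == "modular":
        module_of = np.repeat(np.arange(n_modules), int(np.ceil(p / n_modules)))[:p]
        within = [(i, j) for i in range(p) for j in range(i + 1, p)
                  if module_of[i] == module_of[j]]
        if m_target > len(within):
            raise ValueError(
                f"density {density} infeasible: only {len(within)} within-module "
                f"pairs for p={p}, n_modules={n_modules}"
            )
        idx = rng.choice(len(within), size=m_target, replace=False)
        pairs = [within[k] for k in sorted(idx)]
    elif topology == "scale_free":
        import networkx as nx

        m_attach = max(1, round(m_target / p))
        g = nx.barabasi_albert_graph(p, m_attach, seed=int(rng.integers(2**31)))
        pairs = sorted(tuple(sorted(e)) for e in g.edges())
    else:
        raise ValueError(f"unknown topology {topology!r}")

    signs = np.where(rng.random(len(pairs)) < positive_fraction, 1, -1)
    omega = np.eye(p)
    for (i, j), s in zip(pairs, signs):
        omega[i, j] = omega[j, i] = -s * partial_corr
    # diagonal boosting to enforce positive definiteness
    eigmin = np.linalg.eigvalsh(omega).min()
    if eigmin < 0.05:
        omega += (0.05 - eigmin) * np.eye(p)
    d = np.sqrt(np.diag(omega))
    pcorr = {
        (i, j): float(-omega[i, j] / (d[i] * d[j])) for (i, j) in pairs
    }
    edges = [(i, j, int(s)) for (i, j), s in zip(pairs, signs)]
    return InteractionGraph(edges=edges, precision=omega,
                            partial_correlations=pcorr, module_of=module_of)


def make_truth(p: int = 60, topology: str = "modular", n_modules: int = 6,
               density: float = 0.05, n_contaminants: int = 0,
               group_effect_fraction: float = 0.10,
               group_effect_multiplier: float = 3.0,
               seed: int = 0, **graph_kwargs) -> SyntheticTruth:
    """Assemble a full :class:`SyntheticTruth` for a simulation run."""
    if group_effect_multiplier < 1:
        raise ValueError("group_effect_multiplier must be >= 1")
    graph = make_interaction_graph(p, topology=topology, n_modules=n_modules,
                                   density=density, seed=seed, **graph_kwargs)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    feature_ids = [f"F{k:04d}" for k in range(p)]
    n_effect = round(group_effect_fraction * p)
    perm = rng.permutation(p)
    effect_features: dict[str, list[str]] = {}
    used = 0
    if group_effect_multiplier > 1 and n_effect > 0:
        for group in HOST_GROUPS:
            block = perm[used:used + n_effect]
            effect_features[group] = [feature_ids[k] for k in block]
            used += n_effect
    remaining = [feature_ids[k] for k in perm[used:]]
    if n_contaminants > len(remaining):
        raise ValueError("not enough features left to plant contaminants")
    contaminant_ids = sorted(remaining[:n_contaminants])
    return SyntheticTruth(graph=graph, feature_ids=feature_ids,
                          contaminant_ids=contaminant_ids,
                          group_effect_features=effect_features,
                          group_effect_multiplier=group_effect_multiplier,
                          seed=seed)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _zinb_ppf(u: np.ndarray, mu: float, alpha: float, pi0: float) -> np.ndarray:
    """Quantile function of a zero-inflated negative binomial."""
    out = np.zeros_like(u, dtype=np.int64)
    body = u >= pi0
    if body.any():
        r = 1.0 / alpha
        pr = r / (r + mu)
        out[body] = stats.nbinom.ppf((u[body] - pi0) / (1.0 - pi0), r, pr)
    return out


def simulate_counts(truth: SyntheticTruth, n_samples: int,
                    depth_mean: int = 10_000, zinb: ZINBParams | None = None,
                    its_fraction: float = 0.375, balanced_groups: bool = False,
                    seed: int | None = None) -> tuple[FeatureTable, SampleMetadata]:
    """Draw a count table + metadata from the planted model.

    A latent multivariate normal with covariance inverse to the planted
    precision is mapped margin-by-margin through the normal CDF to ZINB
    quantile functions (normal-to-anything). Host-group effects multiply the
    ZINB mean of that group's effect features. Rows are then resampled to
    stochastic library depths around ``depth_mean``.
    """
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    p = truth.graph.n_features
    rng = np.random.default_rng(
        np.random.SeedSequence([truth.seed if seed is None else seed, 29])
    )
    if zinb is None:
        zinb = ZINBParams.default(p, rng)

    omega = truth.graph.precision
    try:
        np.linalg.cholesky(omega)
    except np.linalg.LinAlgError as exc:
        raise ValueError("precision matrix is not positive definite") from exc
    sigma = np.linalg.inv(omega)
    dsd = np.sqrt(np.diag(sigma))
    corr = sigma / np.outer(dsd, dsd)
    chol = np.linalg.cholesky(corr)

    sample_ids = [f"S{k:03d}" for k in range(n_samples)]
    if balanced_groups:  # equal group sizes, e.g. for power studies
        reps = int(np.ceil(n_samples / len(HOST_GROUPS)))
        groups = rng.permutation(np.repeat(HOST_GROUPS, reps)[:n_samples])
    else:
        groups = rng.choice(HOST_GROUPS, size=n_samples, p=HOST_WEIGHTS)
    genera = [rng.choice(GENERA[g]) for g in groups]
    states = rng.choice(STATES, size=n_samples)
    ecoregions = [f"eco{STATES.index(s) % 4}" for s in states]
    conc = rng.lognormal(np.log(10.0), 0.6, size=n_samples)

    z = rng.standard_normal((n_samples, p)) @ chol.T
    u = stats.norm.cdf(z)

    fid_index = {f: k for k, f in enumerate(truth.feature_ids)}
    mult = np.ones((n_samples, p))
    for group, fids in truth.group_effect_features.items():
        rows = groups == group
        cols = [fid_index[f] for f in fids]
        mult[np.ix_(rows, cols)] = truth.group_effect_multiplier

    raw = np.zeros((n_samples, p), dtype=np.int64)
    for j in range(p):
        mu_col = zinb.mean[j] * mult[:, j]
        r = 1.0 / zinb.dispersion[j]
        pr = r / (r + mu_col)
        body = u[:, j] >= zinb.zero_inflation[j]
        q = np.zeros(n_samples)
        q[body] = stats.nbinom.ppf(
            (u[body, j] - zinb.zero_inflation[j]) / (1 - zinb.zero_inflation[j]),
            r, pr[body],
        )
        raw[:, j] = q.astype(np.int64)

    depths = np.maximum(
        1, rng.lognormal(np.log(depth_mean) - 0.02, 0.2, size=n_samples)
    ).astype(np.int64)
    counts = np.zeros_like(raw)
    for i in range(n_samples):
        total = raw[i].sum()
        if total == 0:
            continue
        counts[i] = rng.multinomial(depths[i], raw[i] / total)

    n_its = round(its_fraction * p)
    marker = np.array(["16S"] * p, dtype=object)
    its_idx = rng.choice(p, size=n_its, replace=False)
    marker[its_idx] = "ITS"
    domain = np.where(marker == "ITS", "Fungi", "Bacteria")

    table = FeatureTable(
        pd.DataFrame(counts, index=sample_ids, columns=truth.feature_ids),
        pd.Series(marker, index=truth.feature_ids),
        pd.Series(domain, index=truth.feature_ids),
    )
    meta = SampleMetadata(pd.DataFrame(
        {
            "host_group": groups,
            "host_genus": genera,
            "state": states,
            "ecoregion3": ecoregions,
            "dna_concentration": conc,
            "is_ntc": False,
        },
        index=sample_ids,
    ))
    return table, meta


# ---------------------------------------------------------------------------
# contamination
# ---------------------------------------------------------------------------

#: scale constant in the contaminant model E[count] = strength * depth / (conc * C)
_CONTAM_SCALE = 50.0
#: nominal DNA concentration assigned to NTC libraries (ng/uL)
NTC_CONCENTRATION = 0.1


def add_contamination(table: FeatureTable, metadata: SampleMetadata,
                      truth: SyntheticTruth, contam_strength: float = 1.0,
                      n_ntc: int = 3,
                      seed: int | None = None) -> tuple[FeatureTable, SampleMetadata]:
    """Plant the reagent-contamination signature and append NTC libraries.

    Each contaminant feature's counts are replaced by Poisson draws with
    expectation ``contam_strength * depth / (dna_concentration * 50)`` — the
    inverse frequency/concentration signature the screen looks for. Appended
    NTC libraries carry only contaminants plus low-rate noise.
    """
    if contam_strength <= 0:
        raise ValueError("contam_strength must be > 0")
    if not truth.contaminant_ids:
        raise ValueError("truth has no planted contaminants")
    rng = np.random.default_rng(
        np.random.SeedSequence([truth.seed if seed is None else seed, 43])
    )
    counts = table.counts.copy()
    meta = metadata.data.copy()
    depths = counts.sum(axis=1).to_numpy()
    conc = meta.loc[counts.index, "dna_concentration"].to_numpy(float)
    for f in truth.contaminant_ids:
        lam = contam_strength * depths / (conc * _CONTAM_SCALE)
        counts[f] = rng.poisson(lam)

    depth_mean = max(1.0, float(depths.mean()))
    ntc_rows = []
    ntc_meta = []
    for k in range(n_ntc):
        row = np.zeros(counts.shape[1], dtype=np.int64)
        lam_ntc = contam_strength * depth_mean / (NTC_CONCENTRATION * _CONTAM_SCALE)
        for f in truth.contaminant_ids:
            row[counts.columns.get_loc(f)] = rng.poisson(lam_ntc)
        row += rng.poisson(0.2, size=len(row))  # low-rate carry-over noise
        ntc_rows.append(row)
        ntc_meta.append({
            "host_group": "control", "host_genus": "none", "state": "none",
            "ecoregion3": "none", "dna_concentration": NTC_CONCENTRATION,
            "is_ntc": True,
        })
    ntc_ids = [f"NTC{k:02d}" for k in range(n_ntc)]
    counts = pd.concat(
        [counts, pd.DataFrame(ntc_rows, index=ntc_ids, columns=counts.columns)]
    )
    meta = pd.concat([meta, pd.DataFrame(ntc_meta, index=ntc_ids)])
    out_table = FeatureTable(counts, table.feature_marker.copy(),
                             table.feature_domain.copy())
    return out_table, SampleMetadata(meta)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def simulate_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0) -> PhyloTree:
    """A Yule pure-birth topology with iid exponential branch lengths.

    Branch lengths are exponential with rate ``birth_rate``; the tree is
    binary but not ultrametric.
    """
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = np.random.default_rng(seed)

    # pure-birth topology: repeatedly split a uniformly chosen extant lineage;
    # every edge gets an iid exponential(birth_rate) length at creation
    leaves: list[list] = []  # [label, length, children]

    def new_leaf(label: str) -> list:
        return [label, rng.exponential(1.0 / birth_rate), []]

    root = ["", None, [new_leaf("T000"), new_leaf("T001")]]
    leaves = list(root[2])
    next_tip = 2
    while next_tip < n_tips:
        k = int(rng.integers(len(leaves)))
        node = leaves[k]
        left = new_leaf(node[0])
        right = new_leaf(f"T{next_tip:03d}")
        node[0] = ""
        node[2] = [left, right]
        leaves[k] = left
        leaves.append(right)
        next_tip += 1

    def to_newick(node: list) -> str:
        if not node[2]:
            return f"{node[0]}:{node[1]:.6f}"
        inner = ",".join(to_newick(c) for c in node[2])
        suffix = "" if node[1] is None else f":{node[1]:.6f}"
        return f"({inner}){suffix}"

    return tree_from_newick(to_newick(root) + ";")
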