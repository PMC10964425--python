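"""Readers, writers and validated domain types for every external artifact.

All tabular files are UTF-8, tab-separated, "." decimal separator. Count
tables are stored samples-as-rows; the transpose is accepted via
``orient="features"``. Feature and sample ids are opaque strings — no
taxonomy is ever parsed out of an id.
"""

from __future__ import annotations


from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
import yaml

VALID_MARKERS = frozenset({"16S", "ITS"})
VALID_DOMAINS = frozenset({"Bacteria", "Archaea", "Fungi", "unknown"})
VALID_HOST_GROUPS = frozenset({"frog", "lizard", "salamander", "control"})

#: fixed rank order for taxonomy tables
TAXONOMY_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


class ValidationError(ValueError):
    """An object violates one of its declared invariants."""


class ParseError(ValueError):
    """A file could not be parsed into a valid object."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Integer count matrix (samples × features) with per-feature labels.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer counts, rows indexed by sample id, columns by
        feature id.
    feature_marker : pandas.Series
        Per-feature amplicon marker, one of ``{"16S", "ITS"}``.
    feature_domain : pandas.Series
        Per-feature taxonomic domain, one of
        ``{"Bacteria", "Archaea", "Fungi", "unknown"}``.
    """

    counts: pd.DataFrame
    feature_marker: pd.Series
    feature_domain: pd.Series

    def __post_init__(self) -> None:
        self.validate()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    def validate(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups}")
        values = c.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                bad = np.argwhere(~np.isfinite(values) | (values != np.floor(values)))
                r, col = bad[0]
                raise ValidationError(
                    f"non-integer count at sample {c.index[r]!r}, "
                    f"feature {c.columns[col]!r}: {values[r, col]!r}"
                )
            self.counts = c = c.astype(np.int64)
            values = c.to_numpy()
        if np.any(values < 0):
            r, col = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at sample {c.index[r]!r}, "
                f"feature {c.columns[col]!r}: {values[r, col]}"
            )
        for name, series, valid in (
            ("feature_marker", self.feature_marker, VALID_MARKERS),
            ("feature_domain", self.feature_domain, VALID_DOMAINS),
        ):
            series = series.reindex(c.columns)
            if series.isna().any():
                missing = series.index[series.isna()].tolist()
                raise ValidationError(f"{name} missing for features: {missing[:5]}")
            bad = set(series.unique()) - valid
            if bad:
                raise ValidationError(f"invalid {name} labels: {sorted(bad)}")
            setattr(self, name, series)

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.counts.copy(), self.feature_marker.copy(), self.feature_domain.copy()
        )

    def select_features(self, feature_ids) -> "FeatureTable":
        """Restrict to ``feature_ids``, preserving the input column order."""
        keep = [f for f in self.feature_ids if f in set(feature_ids)]
        return FeatureTable(
            self.counts[keep].copy(),
            self.feature_marker[keep].copy(),
            self.feature_domain[keep].copy(),
        )

    def select_samples(self, sample_ids) -> "FeatureTable":
        keep = [s for s in self.sample_ids if s in set(sample_ids)]
        return FeatureTable(
            self.counts.loc[keep].copy(),
            self.feature_marker.copy(),
            self.feature_domain.copy(),
        )


@dataclass
class SampleMetadata:
    """Per-sample covariates: host, geography, DNA concentration, NTC flag."""

    data: pd.DataFrame

    REQUIRED = ("host_group", "host_genus", "state", "ecoregion3",
                "dna_concentration", "is_ntc")

    def __post_init__(self) -> None:
        self.validate()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def validate(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise ValidationError("duplicate sample ids in metadata")
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        bad_groups = set(df["host_group"].unique()) - VALID_HOST_GROUPS
        if bad_groups:
            raise ValidationError(f"invalid host_group values: {sorted(bad_groups)}")
        is_ntc = df["is_ntc"].astype(bool)
        conc = df["dna_concentration"].astype(float)
        if (conc[~is_ntc] <= 0).any() or conc[~is_ntc].isna().any():
            bad = df.index[~is_ntc & ~(conc > 0)].tolist()
            raise ValidationError(
                f"non-NTC samples need dna_concentration > 0: {bad[:5]}"
            )
        if (df.loc[is_ntc, "host_group"] != "control").any():
            bad = df.index[is_ntc & (df["host_group"] != "control")].tolist()
            raise ValidationError(f"NTC samples must have host_group=control: {bad}")
        self.data = df.assign(is_ntc=is_ntc, dna_concentration=conc)

    def non_ntc_ids(self) -> list[str]:
        return list(self.data.index[~self.data["is_ntc"]])

    def ntc_ids(self) -> list[str]:
        return list(self.data.index[self.data["is_ntc"]])


@dataclass
class TaxonomyTable:
    """Per-feature lineage at the fixed rank order; missing ranks allowed."""

    data: pd.DataFrame  # indexed by feature id, columns = TAXONOMY_RANKS

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate feature ids in taxonomy")
        for rank in TAXONOMY_RANKS:
            if rank not in self.data.columns:
                self.data[rank] = pd.NA
        self.data = self.data[list(TAXONOMY_RANKS)]

    def rank(self, rank: str) -> pd.Series:
        if rank not in TAXONOMY_RANKS:
            raise KeyError(f"unknown rank {rank!r}; expected one of {TAXONOMY_RANKS}")
        return self.data[rank]


@dataclass
class PhyloTree:
    """A rooted or unrooted tree with unique tip labels and branch lengths.

    Branch lengths are in substitutions/site and must be present and
    non-negative on every edge except the root edge — patristic distances
    are undefined otherwise.
    """

    tree: dendropy.Tree = field(repr=False)

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            raise ValidationError("duplicate tip labels in tree")
        for edge in self.tree.preorder_edge_iter():
            if edge.tail_node is None:  # root edge carries no length
                continue
            if edge.length is None:
                raise ValidationError(
                    "tree has an edge with no branch length; patristic "
                    "distances would be undefined"
                )
            if edge.length < 0:
                raise ValidationError(f"negative branch length {edge.length}")

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


# ---------------------------------------------------------------------------
# feature table I/O
# ---------------------------------------------------------------------------

def read_feature_table(path, marker_map=None, domain_map=None,
                       orient: str = "samples") -> FeatureTable:
    """Read a tab-separated count table.

    Parameters
    ----------
    path : str or Path
        TSV file; first column holds sample ids (``orient="samples"``,
        default) or feature ids (``orient="features"``).
    marker_map, domain_map : mapping, optional
        Per-feature marker/domain labels. Unlisted features default to
        "16S" / "unknown".
    """
    if orient not in ("samples", "features"):
        raise ValueError("orient must be 'samples' or 'features'")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot read {path}: {exc}") from exc
    if orient == "features":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=np.int64)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any():
            bad_row = df.index[converted.isna()][0]
            raise ParseError(
                f"non-numeric count at sample {bad_row!r}, feature {col!r}: "
                f"{df.loc[bad_row, col]!r}"
            )
        if (converted < 0).any():
            bad_row = df.index[converted < 0][0]
            raise ParseError(
                f"negative count at sample {bad_row!r}, feature {col!r}: "
                f"{df.loc[bad_row, col]!r}"
            )
        if (converted != np.floor(converted)).any():
            bad_row = df.index[converted != np.floor(converted)][0]
            raise ParseError(
                f"non-integer count at sample {bad_row!r}, feature {col!r}: "
                f"{df.loc[bad_row, col]!r}"
            )
        numeric[col] = converted.astype(np.int64)
    features = numeric.columns
    marker = pd.Series(
        [(marker_map or {}).get(f, "16S") for f in features], index=features
    )
    domain = pd.Series(
        [(domain_map or {}).get(f, "unknown") for f in features], index=features
    )
    return FeatureTable(numeric, marker, domain)


def write_feature_table(table: FeatureTable, path, orient: str = "samples") -> None:
    df = table.counts if orient == "samples" else table.counts.T
    df.to_csv(path, sep="\t", index_label="id")


def read_feature_metadata(path) -> tuple[dict, dict]:
    """Read a feature-id → (marker, domain) sidecar TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return df["marker"].to_dict(), df["domain"].to_dict()


def write_feature_metadata(table: FeatureTable, path) -> None:
    pd.DataFrame(
        {"marker": table.feature_marker, "domain": table.feature_domain}
    ).to_csv(path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# metadata / taxonomy I/O
# ---------------------------------------------------------------------------

def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if "is_ntc" in df.columns and df["is_ntc"].dtype == object:
        df["is_ntc"] = df["is_ntc"].map(
            {"True": True, "False": False, "true": True, "false": False}
        )
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.data.to_csv(path, sep="\t", index_label="sample_id")


def read_taxonomy(path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    return TaxonomyTable(df)


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    tax.data.to_csv(path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def tree_from_newick(newick: str) -> PhyloTree:
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:
        raise ParseError(f"invalid newick: {exc}") from exc
    return PhyloTree(tree)


def read_tree(path) -> PhyloTree:
    with open(path, encoding="utf-8") as fh:
        return tree_from_newick(fh.read())


def write_tree(tree: PhyloTree, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(tree.as_newick() + "\n")


# ---------------------------------------------------------------------------
# networks (Cytoscape-importable edge lists)
# ---------------------------------------------------------------------------

def write_network(net, path) -> None:
    """Write a signed edge list: source, target, weight, sign (one header)."""
    rows = [
        {"source": u, "target": v, "weight": w,
         "sign": "positive" if w > 0 else "negative"}
        for u, v, w in net.edges
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight", "sign"]).to_csv(
        path, sep="\t", index=False
    )


def read_network(path, nodes=None, node_domain=None):
    """Re-import an edge list written by :func:`write_network`."""
    from gutweb.network_inference import AssociationNetwork

    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    edges = [
        (r.source, r.target, float(r.weight)) for r in df.itertuples(index=False)
    ]
    if nodes is None:
        seen: dict[str, None] = {}
        for u, v, _ in edges:
            seen.setdefault(u)
            seen.setdefault(v)
        nodes = list(seen)
    return AssociationNetwork(nodes=list(nodes), edges=edges,
                              node_domain=dict(node_domain or {}))


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

def read_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError(f"config {path} must be a YAML mapping")
    return cfg


def write_config(cfg: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
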