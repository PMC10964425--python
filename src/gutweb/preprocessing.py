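"""Rarefaction and count-table filtering, with full per-rule reporting.

The canonical order for the network stage is decontaminate → rarefy →
prevalence filter; the keystone role analysis additionally applies the
abundance filter. Filters never reorder features: output feature order is
input order restricted to the kept set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gutweb.tabular_io import FeatureTable


@dataclass
class FilterReport:
    rule: str
    features_before: int
    features_after: int
    samples_before: int
    samples_after: int
    parameters: dict = field(default_factory=dict)
    dropped_samples: list = field(default_factory=list)
    dropped_features: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.features_after > self.features_before:
            raise ValueError("features_after exceeds features_before")
        if self.samples_after > self.samples_before:
            raise ValueError("samples_after exceeds samples_before")


def rarefy(table: FeatureTable, depth: int,
           seed: int = 0) -> tuple[FeatureTable, FilterReport]:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples whose total is below ``depth`` are dropped and reported. A
    sample's counts are drawn from the multivariate hypergeometric
    distribution over its reads, so zero cells stay zero and a sample whose
    total equals ``depth`` is returned unchanged.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=1)
    keep = totals.index[totals >= depth].tolist()
    dropped = totals.index[totals < depth].tolist()
    if not keep:
        raise ValueError(f"all samples are below rarefaction depth {depth}")
    rows = []
    for sid in keep:
        row = table.counts.loc[sid].to_numpy()
        if row.sum() == depth:
            rows.append(row)
        else:
            rows.append(rng.multivariate_hypergeometric(row, depth))
    out = FeatureTable(
        pd.DataFrame(rows, index=keep, columns=table.feature_ids, dtype=np.int64),
        table.feature_marker.copy(),
        table.feature_domain.copy(),
    )
    report = FilterReport(
        rule="rarefy",
        features_before=table.n_features, features_after=out.n_features,
        samples_before=table.n_samples, samples_after=out.n_samples,
        parameters={"depth": depth, "seed": seed},
        dropped_samples=dropped,
    )
    return out, report


def prevalence_filter(table: FeatureTable, min_prevalence: float = 0.20,
                      strict: bool = True) -> tuple[FeatureTable, FilterReport]:
    """Keep features present (count > 0) in more than ``min_prevalence`` of samples.

    The boundary is a strict inequality by default: a feature present in
    exactly 20% of samples is dropped at ``min_prevalence=0.20``.
    """
    if not 0 < min_prevalence < 1:
        raise ValueError("min_prevalence must be in (0, 1)")
    prevalence = (table.counts > 0).mean(axis=0)
    if strict:
        kept = prevalence.index[prevalence > min_prevalence].tolist()
    else:
        kept = prevalence.index[prevalence >= min_prevalence].tolist()
    if not kept:
        raise ValueError(
            f"prevalence filter at {min_prevalence} removed every feature; "
            "lower the threshold"
        )
    out = table.select_features(kept)
    report = FilterReport(
        rule="prevalence_filter",
        features_before=table.n_features, features_after=out.n_features,
        samples_before=table.n_samples, samples_after=out.n_samples,
        parameters={"min_prevalence": min_prevalence, "strict": strict},
        dropped_features=[f for f in table.feature_ids if f not in set(kept)],
    )
    return out, report


def abundance_filter(table: FeatureTable, min_reads: int = 10,
                     min_rel_abundance: float = 0.005
                     ) -> tuple[FeatureTable, FilterReport]:
    """Keep features with dataset-total reads >= ``min_reads`` AND overall
    relative abundance >= ``min_rel_abundance``.

    Both thresholds are dataset-wide (totals over all samples), not
    per-sample.
    """
    if min_reads < 0 or min_rel_abundance < 0:
        raise ValueError("thresholds must be >= 0")
    totals = table.counts.sum(axis=0)
    grand = float(totals.sum())
    rel = totals / grand if grand > 0 else totals.astype(float)
    kept = totals.index[(totals >= min_reads) & (rel >= min_rel_abundance)].tolist()
    out = table.select_features(kept)
    report = FilterReport(
        rule="abundance_filter",
        features_before=table.n_features, features_after=out.n_features,
        samples_before=table.n_samples, samples_after=out.n_samples,
        parameters={"min_reads": min_reads, "min_rel_abundance": min_rel_abundance},
        dropped_features=[f for f in table.feature_ids if f not in set(kept)],
    )
    return out, report


def top_n_by_abundance(table: FeatureTable, n: int,
                       restrict_to_domain: str | None = None) -> FeatureTable:
    """The ``n`` features of highest dataset-total reads.

    Ties are broken by lexicographically smaller feature id. Optionally
    restrict the candidate set to one taxonomic domain first. Returns all
    candidates with a warning when fewer than ``n`` exist.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    candidates = table
    if restrict_to_domain is not None:
        keep = table.feature_domain.index[
            table.feature_domain == restrict_to_domain
        ].tolist()
        candidates = table.select_features(keep)
    totals = candidates.counts.sum(axis=0)
    ranked = sorted(totals.index, key=lambda f: (-totals[f], f))
    if len(ranked) < n:
        warnings.warn(
            f"only {len(ranked)} features available for top_n_by_abundance(n={n})",
            stacklevel=2,
        )
    return candidates.select_features(ranked[:n])
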