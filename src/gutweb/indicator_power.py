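"""Indicator power of bacterial features for target fungal features.

Indicator power (IP) of an indicator for a target is the geometric mean of
positive and negative predictive power estimated from the 2x2
presence/absence contingency: with a = P(target present | indicator present)
and b = P(target absent | indicator absent), IP = sqrt(a*b). IP is undefined
when the indicator is present in every sample or absent from all of them
(one conditional has an empty denominator); undefined values are excluded
from all means, never imputed as zero. Total indicator power (TIP) for a
target is the mean IP over the indicator assemblage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from gutweb.preprocessing import top_n_by_abundance
from gutweb.tabular_io import FeatureTable, TaxonomyTable


@dataclass
class IndicatorResult:
    ip: pd.DataFrame                     # indicators × targets, NaN = undefined
    mean_ip_per_indicator: pd.Series
    mean_ip_per_class: pd.DataFrame      # columns: mean_ip, n_indicators
    tip_per_target: pd.Series
    correlation: pd.DataFrame            # indicators × targets, Pearson
    row_order: list                      # indicator ids, clustered order
    col_order: list                      # target ids, clustered order
    n_undefined: int = 0


def indicator_power(indicator_pa, target_pa) -> float:
    """IP of one presence/absence indicator vector for one target vector.

    Returns NaN when undefined (indicator constant across samples).
    """
    ind = np.asarray(indicator_pa).astype(bool)
    tgt = np.asarray(target_pa).astype(bool)
    if ind.shape != tgt.shape or ind.ndim != 1 or len(ind) < 1:
        raise ValueError("vectors must be 1-D and of identical length >= 1")
    n_pres = ind.sum()
    n_abs = (~ind).sum()
    if n_pres == 0 or n_abs == 0:
        return float("nan")
    a = (ind & tgt).sum() / n_pres          # P(target | indicator)
    b = (~ind & ~tgt).sum() / n_abs         # P(no target | no indicator)
    return float(np.sqrt(a * b))


def indicator_power_matrix(indicators_pa: np.ndarray,
                           targets_pa: np.ndarray) -> np.ndarray:
    """Vectorized IP for every indicator (column) x target (column) pair.

    Inputs are samples x indicators and samples x targets boolean matrices;
    the result is indicators x targets with NaN where undefined.
    """
    ind = np.asarray(indicators_pa).astype(bool)
    tgt = np.asarray(targets_pa).astype(bool)
    if ind.shape[0] != tgt.shape[0]:
        raise ValueError("sample dimensions differ")
    n = ind.shape[0]
    n_pres = ind.sum(axis=0).astype(float)           # per indicator
    n11 = ind.T.astype(float) @ tgt.astype(float)    # both present
    n00 = (~ind).T.astype(float) @ (~tgt).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = n11 / n_pres[:, None]
        b = n00 / (n - n_pres)[:, None]
        ip = np.sqrt(a * b)
    ip[(n_pres == 0) | (n_pres == n), :] = np.nan
    return ip


def indicator_analysis(bact_table: FeatureTable, fungi_table: FeatureTable,
                       taxonomy: TaxonomyTable, top_n: int = 100,
                       target_min_reads: int = 10,
                       min_observations: int = 10,
                       target_ids=None) -> IndicatorResult:
    """IP matrix, per-class mean IP, and TIP per target.

    Indicators are the ``top_n`` most abundant bacterial features (after
    dropping features with dataset-total reads below ``min_observations``);
    targets are the fungal features with total reads >= ``target_min_reads``
    (optionally restricted to ``target_ids``, e.g. one genus). Vectors are
    binarized as count > 0.
    """
    shared = [s for s in bact_table.sample_ids if s in set(fungi_table.sample_ids)]
    if not shared:
        raise ValueError("tables share no sample ids")
    bact = bact_table.select_samples(shared)
    fungi = fungi_table.select_samples(shared)

    bact_tot = bact.counts.sum(axis=0)
    bact = bact.select_features(bact_tot.index[bact_tot >= min_observations])
    indicators = top_n_by_abundance(bact, top_n)

    fungi_tot = fungi.counts.sum(axis=0)
    keep = fungi_tot.index[fungi_tot >= target_min_reads]
    if target_ids is not None:
        keep = [f for f in keep if f in set(target_ids)]
    targets = fungi.select_features(keep)
    if targets.n_features == 0:
        raise ValueError("no target features left after filtering")

    ind_pa = indicators.counts.to_numpy() > 0
    tgt_pa = targets.counts.to_numpy() > 0
    ip = pd.DataFrame(indicator_power_matrix(ind_pa, tgt_pa),
                      index=indicators.feature_ids,
                      columns=targets.feature_ids)
    n_undefined = int(ip.isna().sum().sum())

    mean_per_indicator = ip.mean(axis=1, skipna=True)
    classes = taxonomy.rank("class").reindex(ip.index)
    per_class = (
        pd.DataFrame({"mean_ip": mean_per_indicator, "class": classes})
        .dropna(subset=["mean_ip"])
        .groupby("class", dropna=False)
        .agg(mean_ip=("mean_ip", "mean"), n_indicators=("mean_ip", "size"))
    )
    tip = ip.mean(axis=0, skipna=True)

    if indicators.n_features >= 2 and targets.n_features >= 2:
        corr, row_order, col_order = heatmap_order(indicators, targets)
    else:  # too small to cluster: report correlations in input order
        xi = indicators.counts.to_numpy(float)
        yt = targets.counts.to_numpy(float)
        corr = pd.DataFrame(
            [[float(np.corrcoef(xi[:, i], yt[:, j])[0, 1])
              for j in range(yt.shape[1])] for i in range(xi.shape[1])],
            index=indicators.feature_ids, columns=targets.feature_ids)
        row_order = list(corr.index)
        col_order = list(corr.columns)
    return IndicatorResult(
        ip=ip,
        mean_ip_per_indicator=mean_per_indicator,
        mean_ip_per_class=per_class,
        tip_per_target=tip,
        correlation=corr,
        row_order=row_order,
        col_order=col_order,
        n_undefined=n_undefined,
    )


def heatmap_order(indicator_table: FeatureTable, target_table: FeatureTable
                  ) -> tuple[pd.DataFrame, list, list]:
    """Pearson correlations plus complete-linkage leaf orders.

    Correlations are computed on abundance vectors across samples for every
    indicator-target pair; rows (indicators) and columns (targets) are each
    clustered by complete linkage on Euclidean distances between their
    correlation-profile vectors.
    """
    if indicator_table.n_features < 2 or target_table.n_features < 2:
        raise ValueError("need at least 2 indicators and 2 targets")
    x = indicator_table.counts.to_numpy(float)
    y = target_table.counts.to_numpy(float)
    xs = x.std(axis=0)
    ys = y.std(axis=0)
    if np.any(xs == 0) or np.any(ys == 0):
        warnings.warn("zero-variance vectors: correlations set missing for "
                      "their pairs; clustering uses available values",
                      stacklevel=2)
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (xc.T @ yc) / (len(x) * np.outer(xs, ys))
    corr[xs == 0, :] = np.nan
    corr[:, ys == 0] = np.nan
    corr_df = pd.DataFrame(corr, index=indicator_table.feature_ids,
                           columns=target_table.feature_ids)

    def leaf_order(profile: np.ndarray, labels) -> list:
        filled = np.nan_to_num(profile, nan=0.0)
        link = hierarchy.linkage(pdist(filled, metric="euclidean"),
                                 method="complete")
        return [labels[k] for k in hierarchy.leaves_list(link)]

    row_order = leaf_order(corr, list(corr_df.index))
    col_order = leaf_order(corr.T, list(corr_df.columns))
    return corr_df, row_order, col_order
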