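"""Reagent-contaminant screening from the frequency/concentration signature.

Reagent contaminants arrive at a roughly fixed number of molecules per
library, so their *relative* abundance varies inversely with the amount of
true template DNA. Each feature is scored by comparing, over the samples
where it occurs, a contaminant model (log-frequency on log-concentration
with slope fixed at -1) against a non-contaminant model (slope 0); small
scores are contaminant-like. The flagging threshold is then chosen by
sweeping a probability grid and asking at which value the marginal removal
still takes more sequence from no-template-control (NTC) libraries than
from real samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from gutweb.tabular_io import FeatureTable, SampleMetadata

DEFAULT_GRID = np.round(np.arange(0.05, 0.96, 0.10), 2)  # 0.05, 0.15, ..., 0.95
FALLBACK_THRESHOLD = 0.1


@dataclass
class ContaminantScreenResult:
    """Scores, removal curves and the selected flagging threshold."""

    scores: pd.Series
    threshold_grid: np.ndarray = field(default_factory=lambda: DEFAULT_GRID.copy())
    ntc_removed_pct: np.ndarray | None = None
    sample_removed_pct: np.ndarray | None = None
    selected_threshold: float | None = None
    flagged_ids: list = field(default_factory=list)
    fallback_used: bool = False

    def flagged_at(self, threshold: float) -> list:
        s = self.scores
        return list(s.index[(s < threshold).fillna(False)])

    def apply(self, table: FeatureTable) -> FeatureTable:
        """Drop the flagged features from ``table``."""
        if self.selected_threshold is None:
            raise ValueError("run select_threshold first")
        keep = [f for f in table.feature_ids if f not in set(self.flagged_ids)]
        return table.select_features(keep)


def frequency_score(table: FeatureTable, metadata: SampleMetadata,
                    min_occurrences: int = 5) -> pd.Series:
    """Per-feature contaminant score in [0, 1]; low = contaminant-like.

    For each feature, over the non-NTC samples where it occurs, fit by least
    squares (i) a contaminant model with the slope of log-frequency on
    log-concentration fixed at -1 and (ii) a non-contaminant model with slope
    fixed at 0. The score is the left-tail probability of an F comparison of
    the two residual sums of squares (each model spends one parameter, so the
    degrees of freedom are k-1, k-1 over k occupied samples). Features
    occurring in fewer than ``min_occurrences`` samples are left unscored
    (NaN) and are never flagged.
    """
    ids = [s for s in metadata.non_ntc_ids() if s in set(table.sample_ids)]
    counts = table.counts.loc[ids]
    totals = counts.sum(axis=1).to_numpy(float)
    if (totals <= 0).any():
        raise ValueError("samples with zero total counts cannot be scored")
    conc = metadata.data.loc[ids, "dna_concentration"].to_numpy(float)
    log_conc = np.log(conc)
    freq = counts.to_numpy(float) / totals[:, None]

    scores = pd.Series(np.nan, index=table.feature_ids, dtype=float)
    for j, fid in enumerate(table.feature_ids):
        occ = freq[:, j] > 0
        k = int(occ.sum())
        if k < min_occurrences:
            continue
        x = log_conc[occ]
        if np.ptp(x) == 0:
            warnings.warn(
                f"feature {fid!r}: all DNA concentrations equal; score undefined",
                stacklevel=2,
            )
            continue
        y = np.log(freq[occ, j])
        rss_contam = np.sum((y + x - np.mean(y + x)) ** 2)
        rss_flat = np.sum((y - np.mean(y)) ** 2)
        if rss_flat == 0 and rss_contam == 0:
            continue  # degenerate: both models perfect
        if rss_flat == 0:
            scores[fid] = 1.0
        elif rss_contam == 0:
            scores[fid] = 0.0
        else:
            scores[fid] = stats.f.cdf(rss_contam / rss_flat, k - 1, k - 1)
    return scores


def threshold_sweep(scores: pd.Series, table: FeatureTable,
                    metadata: SampleMetadata,
                    grid: np.ndarray | None = None) -> ContaminantScreenResult:
    """Removal-percentage curves over the probability-threshold grid.

    For each grid threshold t, features with score < t are flagged;
    ``ntc_removed_pct(t)`` (resp. ``sample_removed_pct(t)``) is the share of
    total NTC (resp. sample) sequences carried by flagged features, in
    percent.
    """
    grid = DEFAULT_GRID.copy() if grid is None else np.asarray(grid, float)
    ntc_ids = [s for s in metadata.ntc_ids() if s in set(table.sample_ids)]
    if not ntc_ids:
        raise ValueError("threshold selection is NTC-defined: no NTC samples found")
    sample_ids = [s for s in metadata.non_ntc_ids() if s in set(table.sample_ids)]
    ntc_by_feature = table.counts.loc[ntc_ids].sum(axis=0)
    smp_by_feature = table.counts.loc[sample_ids].sum(axis=0)
    ntc_total = float(ntc_by_feature.sum())
    smp_total = float(smp_by_feature.sum())

    ntc_pct = np.zeros(len(grid))
    smp_pct = np.zeros(len(grid))
    flagged_mask = scores.reindex(table.feature_ids)
    for k, t in enumerate(grid):
        flagged = (flagged_mask < t).fillna(False)
        ntc_pct[k] = 100.0 * ntc_by_feature[flagged].sum() / ntc_total if ntc_total else 0.0
        smp_pct[k] = 100.0 * smp_by_feature[flagged].sum() / smp_total if smp_total else 0.0
    return ContaminantScreenResult(
        scores=scores, threshold_grid=grid,
        ntc_removed_pct=ntc_pct, sample_removed_pct=smp_pct,
    )


def select_threshold(result: ContaminantScreenResult,
                     sweep_mode: str = "marginal",
                     min_ntc_removal: float = 10.0,
                     fallback: float = FALLBACK_THRESHOLD) -> float:
    """Apply the NTC-based selection rule and fill in the flagged set.

    Marginal mode (default): a grid value t_i is eligible when at least
    ``min_ntc_removal`` percent of total NTC sequences are removed at t_i and
    the marginal removal on the step to the next grid value still takes more
    from NTC than from sample libraries; the last grid value inherits the
    final step's comparison. The largest eligible value is selected.

    Cumulative mode: t_i is eligible when its cumulative NTC removal both
    meets the floor and exceeds the cumulative sample removal.

    Falls back to 0.1 with a warning when no grid value qualifies.
    """
    if result.ntc_removed_pct is None:
        raise ValueError("run threshold_sweep first")
    grid = result.threshold_grid
    ntc = result.ntc_removed_pct
    smp = result.sample_removed_pct
    g = len(grid)
    eligible = np.zeros(g, dtype=bool)
    if sweep_mode == "marginal":
        adv = (np.diff(ntc) > np.diff(smp))
        for i in range(g):
            step_ok = adv[i] if i < g - 1 else adv[g - 2]
            eligible[i] = step_ok and ntc[i] >= min_ntc_removal
    elif sweep_mode == "cumulative":
        eligible = (ntc > smp) & (ntc >= min_ntc_removal)
    else:
        raise ValueError("sweep_mode must be 'marginal' or 'cumulative'")

    if eligible.any():
        selected = float(grid[np.nonzero(eligible)[0][-1]])
        result.fallback_used = False
    else:
        warnings.warn(
            f"no grid threshold met the NTC rule; falling back to {fallback}",
            stacklevel=2,
        )
        selected = float(fallback)
        result.fallback_used = True
    result.selected_threshold = selected
    result.flagged_ids = result.flagged_at(selected)
    return selected


def screen_contaminants(table: FeatureTable, metadata: SampleMetadata,
                        sweep_mode: str = "marginal",
                        min_occurrences: int = 5,
                        grid: np.ndarray | None = None) -> ContaminantScreenResult:
    """Score, sweep and select in one call."""
    scores = frequency_score(table, metadata, min_occurrences=min_occurrences)
    result = threshold_sweep(scores, table, metadata, grid=grid)
    select_threshold(result, sweep_mode=sweep_mode)
    return result
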