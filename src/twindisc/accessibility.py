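"""Accessibility quantification, normalization, and within-pair discordance.

The accessibility of meta-peak j in sample i is the tag enrichment relative
to genome background::

    A[j, i] = (c[j, i] / L_j) / (R_i / G)

with c the read count, L the peak length, R the sample's total mapped reads
and G the genome size.  Within a twin pair with sibling accessibilities X1
and X2, discordance is reported both as |X1 - X2| and as the normalized
difference |X1 - X2| / (X1 + X2), which is bounded in [0, 1] and removes the
bias toward highly accessible sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from twindisc.cohort import TwinCohort
from twindisc.errors import InputError, ParameterError, SampleError
from twindisc.intervals import merge_intervals, overlap_pairs, peak_ids, validate_intervals


@dataclass
class AccessibilityMatrix:
    """Meta-peak x sample accessibility with its normalization context."""

    values: pd.DataFrame  # peaks x samples, non-negative reals
    sample_totals: pd.Series  # R_i, reads per sample
    genome_size: float  # G, bp

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise InputError("accessibility values must be finite")
        if (self.values.to_numpy() < 0).any():
            raise InputError("accessibility values must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def merge_peaks(peak_sets: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Merge per-sample peak sets into disjoint meta-peaks (union; book-ended merged)."""
    merged = merge_intervals(peak_sets)
    merged.index = peak_ids(merged)
    return merged


def normalize_accessibility(
    counts: pd.DataFrame, peaks: pd.DataFrame, genome_size: float
) -> AccessibilityMatrix:
    """Depth- and length-normalize a peak x sample count matrix.

    Invariant to scaling any sample's column (its R_i scales with it).
    """
    peaks = validate_intervals(peaks, "peaks") if peaks.index.name != "peak_id" else peaks
    if len(counts) != len(peaks):
        raise InputError(
            f"counts has {len(counts)} rows but {len(peaks)} peaks were supplied"
        )
    if genome_size <= 0:
        raise ParameterError("genome_size must be positive")
    lengths = (peaks["end"] - peaks["start"]).to_numpy(dtype=float)
    totals = counts.sum(axis=0).astype(float)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise SampleError(f"samples with zero total reads: {bad}")
    # (c/L)/(R/G) computed as (c/R) * (G/L): the count/total quotient is a
    # correctly-rounded division of exact integers, so scaling a sample's
    # column (and hence its total) by any constant cancels exactly
    values = (counts.to_numpy(dtype=float) / totals.to_numpy()[None, :]) * (
        float(genome_size) / lengths
    )[:, None]
    df = pd.DataFrame(values, index=counts.index, columns=counts.columns)
    return AccessibilityMatrix(values=df, sample_totals=totals, genome_size=float(genome_size))


def quantile_normalize_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Quantile-quantile normalization of columns.

    Every column is mapped onto the reference distribution (the row-wise mean
    of the sorted columns); tied values within a column receive the average
    of the reference values at their tied ranks.
    """
    if df.shape[1] < 2:
        warnings.warn("quantile normalization needs >= 2 samples; returning input unchanged")
        return df.copy()
    x = df.to_numpy(dtype=float)
    n, k = x.shape
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(k):
        order = np.argsort(x[:, j], kind="mergesort")
        col_sorted = x[order, j]
        _, inv, counts = np.unique(col_sorted, return_inverse=True, return_counts=True)
        group_mean = np.bincount(inv, weights=ref) / counts
        out[order, j] = group_mean[inv]
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def quantile_normalize(matrix: AccessibilityMatrix) -> AccessibilityMatrix:
    return AccessibilityMatrix(
        values=quantile_normalize_frame(matrix.values),
        sample_totals=matrix.sample_totals,
        genome_size=matrix.genome_size,
    )


def pair_discordance(matrix: AccessibilityMatrix, pairing: TwinCohort) -> pd.DataFrame:
    """Per (meta-peak, pair) discordance table.

    Columns: peak_id, pair_id, x1, x2, d_abs, d_norm.  d_norm is NaN
    (undefined-as-missing) where X1 + X2 = 0.
    """
    missing = set(pairing.sample_ids) - set(matrix.values.columns)
    if missing:
        raise InputError(f"samples missing from matrix: {sorted(missing)}")
    frames = []
    for _, row in pairing.pair_table().iterrows():
        x1 = matrix.values[row["sample1"]].to_numpy()
        x2 = matrix.values[row["sample2"]].to_numpy()
        s = x1 + x2
        d_abs = np.abs(x1 - x2)
        with np.errstate(invalid="ignore", divide="ignore"):
            d_norm = np.where(s > 0, d_abs / s, np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "peak_id": matrix.values.index,
                    "pair_id": row["pair_id"],
                    "x1": x1,
                    "x2": x2,
                    "d_abs": d_abs,
                    "d_norm": d_norm,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def call_discordant_sites(
    disc: pd.DataFrame,
    rule: str = "fold_change",
    pseudocount: float = 1.0,
    fc_threshold: float = 4.0,
) -> pd.DataFrame:
    """Flag discordant chromatin sites.

    ``fold_change``: per (peak, pair), flagged when
    (max(X1,X2)+c) / (min(X1,X2)+c) > fc_threshold; the pseudocount c bounds
    the ratio at zero-accessibility sites.

    ``variance``: per peak, flagged when the within-pair variance
    (mean over pairs of (X1-X2)^2 / 2) exceeds the between-pair variance
    (variance of the pair means (X1+X2)/2).
    """
    if rule == "fold_change":
        hi = np.maximum(disc["x1"], disc["x2"]) + pseudocount
        lo = np.minimum(disc["x1"], disc["x2"]) + pseudocount
        out = disc[["peak_id", "pair_id"]].copy()
        out["fold_change"] = hi / lo
        out["discordant"] = out["fold_change"] > fc_threshold
        return out
    if rule == "variance":
        rows = []
        for peak_id, grp in disc.groupby("peak_id", sort=False):
            within = np.mean((grp["x1"] - grp["x2"]) ** 2 / 2.0)
            means = (grp["x1"] + grp["x2"]) / 2.0
            between = float(np.var(means, ddof=1)) if len(means) > 1 else 0.0
            rows.append((peak_id, within, between, within > between))
        return pd.DataFrame(
            rows, columns=["peak_id", "within_var", "between_var", "discordant"]
        )
    raise ParameterError(f"unknown rule {rule!r}; expected 'fold_change' or 'variance'")


def summarize_by_state(
    peak_values: pd.Series,
    peaks: pd.DataFrame,
    states: pd.DataFrame,
    flagged: pd.Series | None = None,
) -> pd.DataFrame:
    """Summarize a per-peak quantity by regulatory-state domain.

    A peak overlapping several state domains contributes to each.  Per state:
    number of domains containing any analyzed peak, mean and median of the
    value over contributing peaks, and — when ``flagged`` is given — the
    fraction of those domains holding at least one flagged peak.
    """
    if "name" not in states.columns:
        raise InputError("states need a 'name' column with the state label")
    peaks = peaks.reset_index(drop=True)
    states = states.reset_index(drop=True)
    hits = overlap_pairs(peaks, states)
    if hits.empty:
        warnings.warn("no peak overlaps any state domain; empty summary")
        return pd.DataFrame(
            columns=["state", "n_domains", "n_peaks", "mean", "median", "flagged_fraction"]
        )
    vals = peak_values.to_numpy()
    flg = flagged.to_numpy() if flagged is not None else None
    rows = []
    hits["state"] = states.loc[hits["index_b"], "name"].to_numpy()
    for state, grp in hits.groupby("state"):
        v = vals[grp["index_a"].to_numpy()]
        domains = grp["index_b"].unique()
        frac = np.nan
        if flg is not None:
            flagged_domains = grp.loc[flg[grp["index_a"].to_numpy()], "index_b"].unique()
            frac = len(flagged_domains) / len(domains)
        rows.append(
            (state, len(domains), len(grp), float(np.nanmean(v)), float(np.nanmedian(v)), frac)
        )
    return pd.DataFrame(
        rows, columns=["state", "n_domains", "n_peaks", "mean", "median", "flagged_fraction"]
    )


def compare_discordance_by_group(
    values: pd.Series, groups: pd.Series
) -> tuple[pd.DataFrame, float]:
    """Group means of a discordance measure plus a rank-based test p-value.

    Two groups: two-sided Wilcoxon rank-sum.  More: Kruskal-Wallis.
    Empty groups are dropped with a warning; at least two must remain.
    """
    df = pd.DataFrame({"value": values, "group": groups}).dropna(subset=["value"])
    arrays, labels = [], []
    for g, grp in df.groupby("group", sort=False):
        if grp.empty:
            warnings.warn(f"group {g!r} empty; skipped")
            continue
        labels.append(g)
        arrays.append(grp["value"].to_numpy())
    if len(arrays) < 2:
        raise InputError("need >= 2 non-empty groups to compare")
    means = pd.DataFrame(
        {
            "group": labels,
            "n": [len(a) for a in arrays],
            "mean": [float(np.mean(a)) for a in arrays],
            "median": [float(np.median(a)) for a in arrays],
        }
    )
    if len(arrays) == 2:
        p = float(stats.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided").pvalue)
    else:
        p = float(stats.kruskal(*arrays).pvalue)
    return means, p
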