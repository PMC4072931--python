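"""Coupling chromatin discordance to expression and methylation.

Within-pair differential expression (|Δlog2| between siblings) is compared
against the discordance of the gene's promoter peak; the coupling is tested
by a rank correlation between discordance tertiles (high/medium/low) and
differential expression, with significance from permutations of the
differential-expression values across genes.  For TFBS CpGs, the magnitude
of lymphocyte-versus-other-cell-type methylation differences is compared
between substituted (mutated/polymorphic) and non-substituted CpGs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from twindisc.cohort import TwinCohort
from twindisc.errors import InputError
from twindisc.intervals import point_to_interval_distance

CELL_TYPES = ["ESC", "HPC", "neutrophil"]  # compared against lymphocyte


def within_pair_expression_diff(expr: pd.DataFrame, pairing: TwinCohort) -> pd.DataFrame:
    """Gene x pair |Δlog2 expression|; missing values propagate as missing."""
    cols = {}
    for _, row in pairing.pair_table().iterrows():
        if row["sample1"] not in expr.columns or row["sample2"] not in expr.columns:
            warnings.warn(f"pair {row['pair_id']} incomplete in expression matrix; skipped")
            continue
        cols[row["pair_id"]] = (expr[row["sample1"]] - expr[row["sample2"]]).abs()
    return pd.DataFrame(cols)


def link_genes_to_peaks(
    tss: pd.DataFrame, peaks: pd.DataFrame, window: int = 2000
) -> pd.DataFrame:
    """Link each gene to the nearest peak within ``window`` bp of its TSS.

    At most one link per gene; equidistant ties go to the lower-coordinate
    peak.  Columns: gene, peak_id, distance.
    """
    rows = []
    by_chrom = {c: g.sort_values("start") for c, g in peaks.groupby("chrom")}
    for _, g in tss.iterrows():
        cand = by_chrom.get(g["chrom"])
        if cand is None:
            continue
        dists = np.array(
            [
                point_to_interval_distance(int(g["pos"]), int(s), int(e))
                for s, e in zip(cand["start"], cand["end"])
            ]
        )
        best = int(np.argmin(dists))  # first-on-ties = lower coordinate
        if dists[best] <= window:
            rows.append((g["gene"], cand.index[best], int(dists[best])))
    return pd.DataFrame(rows, columns=["gene", "peak_id", "distance"])


def tertile_permutation_test(
    discordance, diff_expr, n_perm: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """Rank correlation of discordance tertile (low/medium/high) with
    differential expression, with an empirical permutation p-value.

    The statistic is the Spearman correlation between each gene's tertile
    index (1/2/3 by discordance rank) and its differential expression; the
    null is built by permuting the differential-expression values across
    genes; p = (b + 1) / (n_perm + 1) with b the number of permutations whose
    |statistic| reaches the observed one.
    """
    disc = np.asarray(discordance, dtype=float)
    de = np.asarray(diff_expr, dtype=float)
    if len(disc) != len(de):
        raise InputError("discordance and diff_expr must align")
    ok = ~(np.isnan(disc) | np.isnan(de))
    disc, de = disc[ok], de[ok]
    n = len(disc)
    if n < 30:
        raise InputError("need >= 30 genes for the tertile test")
    if np.ptp(disc) == 0:
        raise InputError("constant discordance: tertiles undefined")
    order = np.argsort(disc, kind="mergesort")
    tertile = np.empty(n, dtype=float)
    for t, chunk in enumerate(np.array_split(order, 3)):
        tertile[chunk] = t + 1
    de_rank = stats.rankdata(de)
    # spearman(tertile, de) = pearson(tertile, rank(de)); under permutation of
    # de only the cross term t . r changes, so permutations reduce to dot products
    t_c = tertile - tertile.mean()
    r_c = de_rank - de_rank.mean()
    denom = np.sqrt((t_c @ t_c) * (r_c @ r_c))
    if denom == 0:
        raise InputError("degenerate ranks")
    observed = float(t_c @ r_c) / denom
    rng = np.random.default_rng(seed)
    b = 0
    block = 2000  # permute in blocks to bound memory
    done = 0
    while done < n_perm:
        k = min(block, n_perm - done)
        perm = rng.permuted(np.tile(r_c, (k, 1)), axis=1)
        s = (perm @ t_c) / denom
        b += int(np.sum(np.abs(s) >= abs(observed) - 1e-12))
        done += k
    p = (b + 1) / (n_perm + 1)
    return observed, p


def cpg_differential_methylation_compare(
    meth: pd.DataFrame,
    reference_cell: str = "lymphocyte",
    mode: str = "cpg",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Differential methylation |reference_cell - other| by CpG substitution status.

    ``meth`` columns: the four cell types, a ``status`` column in
    {mutated, polymorphic, non_substituted}, and (for ``mode='tfbs'``) a
    ``tfbs_peak`` column; in TFBS mode Δ values are first averaged per TFBS
    (a TFBS counts as substituted when any of its CpGs is).  Returns a
    per-(status, cell) summary and rank-sum p-values of non-substituted
    versus each substituted class.
    """
    if "status" not in meth.columns:
        raise InputError("methylation table needs a 'status' column")
    others = [c for c in CELL_TYPES if c in meth.columns]
    if not others:
        raise InputError("no comparison cell types present")
    deltas = meth[["status"]].copy()
    for ct in others:
        deltas[ct] = (meth[reference_cell] - meth[ct]).abs()
    if mode == "tfbs":
        if "tfbs_peak" not in meth.columns:
            raise InputError("tfbs mode needs a 'tfbs_peak' column")
        deltas["tfbs_peak"] = meth["tfbs_peak"]
        rank = {"mutated": 2, "polymorphic": 1, "non_substituted": 0}
        agg = deltas.groupby("tfbs_peak").agg(
            {**{ct: "mean" for ct in others}, "status": lambda s: max(s, key=lambda v: rank[v])}
        )
        deltas = agg.reset_index(drop=True)
    elif mode != "cpg":
        raise InputError(f"unknown mode {mode!r}")

    summary_rows, test_rows = [], []
    for ct in others:
        groups = {s: g[ct].dropna().to_numpy() for s, g in deltas.groupby("status")}
        for s, v in groups.items():
            if len(v):
                summary_rows.append((ct, s, len(v), float(np.mean(v)), float(np.median(v))))
        base = groups.get("non_substituted", np.array([]))
        for s in ("mutated", "polymorphic"):
            v = groups.get(s, np.array([]))
            if len(base) == 0 or len(v) == 0:
                warnings.warn(f"empty group for {s} vs non_substituted ({ct}); skipped")
                continue
            p = float(stats.mannwhitneyu(base, v, alternative="two-sided").pvalue)
            test_rows.append((ct, s, p))
    summary = pd.DataFrame(
        summary_rows, columns=["cell_type", "status", "n", "mean_delta", "median_delta"]
    )
    tests = pd.DataFrame(test_rows, columns=["cell_type", "versus", "p"])
    return summary, tests
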