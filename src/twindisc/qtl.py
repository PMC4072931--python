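"""Variability-QTL mapping.

The trait is the pair-level normalized chromatin difference
y = |X1 - X2| / (X1 + X2): a genotype shared by both siblings of a pair is
associated with how *different* the siblings are at a locus, not with the
locus's accessibility level.  Because most within-pair differences are tiny,
only the peaks with the highest between-pair variance of y (top 1% by
default) enter the mapping; every (SNP, peak) pair within 1 Mb is tested by
ordinary least squares of y on dosage across pairs, with step-up FDR over
all tested cis pairs.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from twindisc.errors import InputError, ParameterError


def fdr_adjust(p_values) -> np.ndarray:
    """Step-up FDR-adjusted q-values (monotone, order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pair_trait_matrix(disc: pd.DataFrame) -> pd.DataFrame:
    """Pivot a discordance table to a peak x pair matrix of d_norm."""
    return disc.pivot(index="peak_id", columns="pair_id", values="d_norm")


def select_top_variance_loci(traits: pd.DataFrame, fraction: float = 0.01) -> list:
    """The ceil(fraction * m) peaks with the largest between-pair variance of y.

    Boundary ties break by peak order (stable).  With fewer peaks than
    1/fraction, at least one peak is still returned (with a warning).
    """
    if not (0 < fraction <= 1):
        raise ParameterError("fraction must be in (0, 1]")
    m = len(traits)
    if m == 0:
        raise InputError("empty trait matrix")
    k = math.ceil(fraction * m)
    if m < 1 / fraction:
        warnings.warn(
            f"only {m} peaks for top-{fraction:.0%} selection; returning {k}"
        )
    variances = traits.var(axis=1, ddof=1).to_numpy()
    order = np.argsort(-variances, kind="stable")  # stable: ties keep peak order
    return list(traits.index[order[:k]])


def _vectorized_ols(y: np.ndarray, d: np.ndarray) -> tuple[float, float, float]:
    """Slope, t, and two-sided p of simple OLS y ~ d (complete data)."""
    n = len(y)
    dx = d - d.mean()
    sxx = float(dx @ dx)
    if sxx == 0 or n < 3:
        return np.nan, np.nan, np.nan
    slope = float(dx @ (y - y.mean())) / sxx
    resid = (y - y.mean()) - slope * dx
    s2 = float(resid @ resid) / (n - 2)
    if s2 == 0:
        return slope, np.inf, 0.0
    se = math.sqrt(s2 / sxx)
    t = slope / se
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return slope, t, float(p)


def map_variability_qtl(
    traits: pd.DataFrame,
    peaks: pd.DataFrame,
    genotypes: pd.DataFrame,
    snp_positions: pd.DataFrame,
    cis_window: float = 1e6,
    fdr: float = 0.01,
    maf_min: float = 0.01,
) -> pd.DataFrame:
    """Map cis variability-QTLs on the selected peaks.

    ``traits``: peak x pair matrix of y (restrict to the selected loci before
    calling, see :func:`select_top_variance_loci`).  ``genotypes``: SNP x pair
    dosages (identical within a pair — MZ twins share genotype).  SNPs are
    filtered at minor allele frequency ``maf_min``; a (SNP, peak) pair is
    tested iff the gap between the SNP and the peak interval is below
    ``cis_window``.  Pairs with a missing trait are dropped listwise per test.
    """
    pairs = [c for c in traits.columns if c in genotypes.columns]
    if len(pairs) < 3:
        raise InputError("need >= 3 pairs shared between traits and genotypes")
    geno = genotypes[pairs]
    G = geno.to_numpy(dtype=float)
    snp_pos = snp_positions.set_index("snp_id").reindex(geno.index)
    snp_chroms = snp_pos["chrom"].to_numpy()
    snp_positions_arr = snp_pos["pos"].to_numpy()
    Y = traits[pairs].to_numpy(dtype=float)
    peak_ids_list = list(traits.index)
    p_chrom = peaks.loc[peak_ids_list, "chrom"].to_numpy()
    p_start = peaks.loc[peak_ids_list, "start"].to_numpy(dtype=int)
    p_end = peaks.loc[peak_ids_list, "end"].to_numpy(dtype=int)
    rows = []
    for si, snp_id in enumerate(geno.index):
        if pd.isna(snp_positions_arr[si]):
            continue
        d_full = G[si]
        maf = min(d_full.mean() / 2.0, 1.0 - d_full.mean() / 2.0)
        if maf < maf_min or np.var(d_full) == 0:
            continue
        chrom, pos = snp_chroms[si], int(snp_positions_arr[si])
        dist = np.where(
            pos < p_start, p_start - pos, np.where(pos >= p_end, pos - p_end + 1, 0)
        )
        cis_idx = np.flatnonzero((p_chrom == chrom) & (dist < cis_window))
        for j in cis_idx:
            y = Y[j]
            ok = ~np.isnan(y)
            slope, t, p = _vectorized_ols(y[ok], d_full[ok])
            if np.isnan(p):
                continue
            rows.append(
                (snp_id, chrom, pos, peak_ids_list[j], int(dist[j]), slope, t, p, True)
            )
    out = pd.DataFrame(
        rows, columns=["snp_id", "chrom", "pos", "peak_id", "distance", "slope", "t", "p", "cis"]
    )
    # deterministic output order regardless of input SNP/peak order
    out = out.sort_values(["chrom", "pos", "snp_id", "peak_id"]).reset_index(drop=True)
    if len(out):
        out["q"] = fdr_adjust(out["p"].to_numpy())
        out["significant"] = out["q"] < fdr
    else:
        out["q"] = []
        out["significant"] = []
    return out


def simulate_pair_traits(
    n_pairs: int = 36,
    n_peaks: int = 500,
    n_qtls: int = 1,
    n_snps_per_peak: int = 1,
    beta: float = 0.2,
    maf: float = 0.3,
    residual_sd: float = 0.05,
    baseline: float = 0.05,
    cis_window: float = 1e6,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Trait-level simulator for power/null studies of the QTL mapper.

    Builds a peak x pair matrix of y = baseline + beta * dosage + noise
    (clipped to [0, 1]) for the first ``n_qtls`` peaks, pure noise elsewhere,
    plus ``n_snps_per_peak`` genotyped SNPs inside each peak (the first SNP
    of a QTL peak carries the effect).  Peaks are spaced beyond 2x the cis
    window so each SNP is cis to exactly one peak.  Returns
    (traits, peaks, genotypes, snp_positions).
    """
    rng = np.random.default_rng(seed)
    pair_ids = [f"pair{i + 1:02d}" for i in range(n_pairs)]
    peak_len = 200
    spacing = int(2 * cis_window) + 1000
    starts = np.arange(n_peaks, dtype=np.int64) * spacing
    peaks = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + peak_len})
    peaks.index = pd.Index(
        [f"chr1:{s}-{s + peak_len}" for s in peaks["start"]], name="peak_id"
    )
    geno = rng.binomial(2, maf, size=(n_peaks * n_snps_per_peak, n_pairs)).astype(float)
    noise = rng.normal(0.0, residual_sd, size=(n_peaks, n_pairs))
    y = baseline + noise
    y[:n_qtls] += beta * geno[np.arange(n_qtls) * n_snps_per_peak]
    y = np.clip(y, 0.0, 1.0)
    snp_ids = [
        f"snp{j + 1:04d}_{k + 1}" for j in range(n_peaks) for k in range(n_snps_per_peak)
    ]
    traits = pd.DataFrame(y, index=peaks.index, columns=pair_ids)
    genotypes = pd.DataFrame(geno, index=pd.Index(snp_ids, name="snp_id"), columns=pair_ids)
    snp_positions = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": "chr1",
            "pos": np.repeat(starts + peak_len // 2, n_snps_per_peak)
            + np.tile(np.arange(n_snps_per_peak), n_peaks),
        }
    )
    return traits, peaks, genotypes, snp_positions
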