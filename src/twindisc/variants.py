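"""Somatic mutation and polymorphism calling from strand-resolved allele counts.

A somatic mutation is a within-pair difference: at one position, Fisher's
exact test on the siblings' ref/alt read counts ``[[ref1, alt1], [ref2, alt2]]``
with p < 1e-3, both siblings covered by >= 10 high-quality reads on each
strand, and the variant seen on both strands of the carrier.  A polymorphism
is a cohort-level variant: covered in every sample, not somatic in any pair,
pooled alternate-read fraction >= 1%, and not supported by a single strand
only in every carrier.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from twindisc.accessibility import AccessibilityMatrix
from twindisc.cohort import TwinCohort
from twindisc.errors import InputError

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

CALL_COLUMNS = [
    "chrom", "pos", "ref", "alt", "class", "pair_id", "carrier_sample",
    "p_value", "pooled_maf", "direction", "base_change",
]


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table of non-negative integers.

    Minimum-likelihood definition: the sum of hypergeometric probabilities of
    all tables with the observed margins whose probability does not exceed
    that of the observed table.  Degenerate margins give p = 1.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise InputError("Fisher test needs a 2x2 table")
    if (arr < 0).any():
        raise InputError("Fisher table entries must be non-negative")
    if arr.sum() == 0:
        return 1.0
    # the two-sided p is invariant to row/column swaps; canonicalize so
    # callers get bit-identical results under relabeling (sibling symmetry)
    if tuple(arr[1]) < tuple(arr[0]):
        arr = arr[::-1]
    if tuple(arr[:, 1]) < tuple(arr[:, 0]):
        arr = arr[:, ::-1]
    p = float(stats.fisher_exact(arr, alternative="two-sided")[1])
    return min(max(p, np.nextafter(0, 1)), 1.0)


def base_change_class(ref: str, alt: str) -> str:
    """Strand-collapsed substitution class, anchored on the C/A strand.

    C>A and G>T are one event seen from the two strands: both are C:G>A:T.
    """
    if ref not in COMPLEMENT or alt not in COMPLEMENT or ref == alt:
        raise InputError(f"invalid base change {ref}>{alt}")
    if ref in ("G", "T"):
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return f"{ref}:{COMPLEMENT[ref]}>{alt}:{COMPLEMENT[alt]}"


def classify_base_change(ref: str, alt: str, reference_homozygous: bool) -> str | None:
    """Type a change *from the reference*; None when neither configuration
    is reference-homozygous (kept but direction-unclassified)."""
    if not reference_homozygous:
        return None
    return base_change_class(ref, alt)


def _with_pairing(alleles: pd.DataFrame, pairing: TwinCohort) -> pd.DataFrame:
    df = alleles.merge(
        pairing.pairs, left_on="sample", right_on="sample_id", how="inner", validate="m:1"
    )
    df["ref_n"] = df["fwd_ref"] + df["rev_ref"]
    df["alt_n"] = df["fwd_alt"] + df["rev_alt"]
    df["n"] = df["ref_n"] + df["alt_n"]
    return df


def call_somatic_mutations(
    alleles: pd.DataFrame,
    pairing: TwinCohort,
    p_threshold: float = 1e-3,
    min_hq_per_strand: int = 10,
    min_alt_per_strand: int = 2,
    hom_ref_max_fraction: float = 0.15,
) -> pd.DataFrame:
    """Call within-pair somatic mutations.

    Emitted iff, per (position, pair): Fisher p on [[ref1,alt1],[ref2,alt2]]
    is below ``p_threshold``; both siblings have >= ``min_hq_per_strand``
    high-quality reads on each strand; and the carrier sibling shows the
    variant on both strands (>= ``min_alt_per_strand`` reads each).
    The base change is typed only when the co-twin is reference-homozygous
    (alt fraction <= ``hom_ref_max_fraction``).
    """
    df = _with_pairing(alleles, pairing)
    key = ["chrom", "pos", "ref", "alt", "pair_id"]
    cols = ["ref_n", "alt_n", "n", "fwd_alt", "rev_alt", "hq_fwd", "hq_rev", "sample"]
    wide = df.set_index(key + ["sibling"])[cols].unstack("sibling")
    wide = wide.reindex(columns=pd.MultiIndex.from_product([cols, [1, 2]]))
    incomplete = wide.isna().any(axis=1)
    if incomplete.any():
        logger.info("skipped %d (position, pair) records missing one sibling", int(incomplete.sum()))
        wide = wide[~incomplete]
    if wide.empty:
        return pd.DataFrame(columns=CALL_COLUMNS)

    num = {
        (c, s): wide[(c, s)].to_numpy(dtype=float)
        for c in ["ref_n", "alt_n", "n", "fwd_alt", "rev_alt", "hq_fwd", "hq_rev"]
        for s in (1, 2)
    }
    hq_ok = (
        (num[("hq_fwd", 1)] >= min_hq_per_strand)
        & (num[("hq_rev", 1)] >= min_hq_per_strand)
        & (num[("hq_fwd", 2)] >= min_hq_per_strand)
        & (num[("hq_rev", 2)] >= min_hq_per_strand)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(num[("n", 1)] > 0, num[("alt_n", 1)] / num[("n", 1)], 0.0)
        f2 = np.where(num[("n", 2)] > 0, num[("alt_n", 2)] / num[("n", 2)], 0.0)
    carrier = np.where(f1 >= f2, 1, 2)
    c_fwd = np.where(carrier == 1, num[("fwd_alt", 1)], num[("fwd_alt", 2)])
    c_rev = np.where(carrier == 1, num[("rev_alt", 1)], num[("rev_alt", 2)])
    both_strands = (c_fwd >= min_alt_per_strand) & (c_rev >= min_alt_per_strand)
    candidate = hq_ok & both_strands & (num[("alt_n", 1)] != num[("alt_n", 2)])

    rows = []
    idx = np.flatnonzero(candidate)
    keys = wide.index.to_frame(index=False)
    for i in idx:
        table = [
            [int(num[("ref_n", 1)][i]), int(num[("alt_n", 1)][i])],
            [int(num[("ref_n", 2)][i]), int(num[("alt_n", 2)][i])],
        ]
        p = fisher_exact_two_sided(table)
        if p >= p_threshold:
            continue
        k = keys.iloc[i]
        carrier_sib = int(carrier[i])
        noncarrier_f = f2[i] if carrier_sib == 1 else f1[i]
        bcc = classify_base_change(k["ref"], k["alt"], noncarrier_f <= hom_ref_max_fraction)
        rows.append(
            {
                "chrom": k["chrom"],
                "pos": int(k["pos"]),
                "ref": k["ref"],
                "alt": k["alt"],
                "class": "somatic_mutation",
                "pair_id": k["pair_id"],
                "carrier_sample": wide[("sample", carrier_sib)].iloc[i],
                "p_value": p,
                "pooled_maf": np.nan,
                "direction": "unclassified",
                "base_change": bcc,
            }
        )
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return calls.sort_values(["chrom", "pos", "pair_id"]).reset_index(drop=True)


def call_polymorphisms(
    alleles: pd.DataFrame,
    pairing: TwinCohort,
    somatic_calls: pd.DataFrame | None = None,
    maf_threshold: float = 0.01,
    strand_frac: float = 0.90,
    contigs: list[str] | None = None,
) -> pd.DataFrame:
    """Call cohort-level polymorphisms.

    Candidates: autosomal positions (``contigs`` allow-list) covered by at
    least one read in all samples, not somatic in any pair, with pooled
    alternate-read fraction >= ``maf_threshold``; removed when in *every*
    carrier sample more than ``strand_frac`` of the variant-supporting reads
    come from one strand (alignment-artifact filter).
    """
    df = _with_pairing(alleles, pairing)
    if contigs is not None:
        df = df[df["chrom"].isin(contigs)]
    somatic_pos = set()
    if somatic_calls is not None and len(somatic_calls):
        somatic_pos = set(zip(somatic_calls["chrom"], somatic_calls["pos"]))
    n_samples = len(pairing.sample_ids)
    rows = []
    for (chrom, pos, ref, alt), grp in df.groupby(["chrom", "pos", "ref", "alt"], sort=True):
        if (chrom, pos) in somatic_pos:
            continue
        if len(grp) < n_samples or (grp["n"] < 1).any():
            continue  # must be covered by >= 1 read in every sample
        total = int(grp["n"].sum())
        alt_total = int(grp["alt_n"].sum())
        frac = alt_total / total
        if frac < maf_threshold:
            continue
        carriers = grp[grp["alt_n"] > 0]
        if len(carriers):
            one_strand = (
                np.maximum(carriers["fwd_alt"], carriers["rev_alt"])
                > strand_frac * carriers["alt_n"]
            )
            if one_strand.all():
                continue
        bcc = classify_base_change(ref, alt, reference_homozygous=frac <= 0.5)
        rows.append(
            {
                "chrom": chrom,
                "pos": int(pos),
                "ref": ref,
                "alt": alt,
                "class": "polymorphism",
                "pair_id": None,
                "carrier_sample": None,
                "p_value": np.nan,
                "pooled_maf": min(frac, 1.0 - frac),
                "direction": "unclassified",
                "base_change": bcc,
            }
        )
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return calls.sort_values(["chrom", "pos"]).reset_index(drop=True)


def annotate_direction(
    calls: pd.DataFrame,
    matrix: AccessibilityMatrix,
    pairing: TwinCohort,
    peaks: pd.DataFrame,
) -> pd.DataFrame:
    """Direction of accessibility change for somatic calls.

    'increase' when the carrier sibling's host-peak accessibility exceeds the
    co-twin's, 'decrease' when lower, 'unclassified' outside any peak or on a
    tie.
    """
    out = calls.copy()
    for i, row in out.iterrows():
        if row["class"] != "somatic_mutation":
            continue
        host = peaks[
            (peaks["chrom"] == row["chrom"])
            & (peaks["start"] <= row["pos"])
            & (peaks["end"] > row["pos"])
        ]
        if host.empty:
            continue
        peak_id = host.index[0]
        carrier = row["carrier_sample"]
        cotwin = pairing.sibling_of(carrier)
        a_c = matrix.values.loc[peak_id, carrier]
        a_o = matrix.values.loc[peak_id, cotwin]
        if a_c > a_o:
            out.loc[i, "direction"] = "increase"
        elif a_c < a_o:
            out.loc[i, "direction"] = "decrease"
    return out


def annotate_mutation_peak_context(calls: pd.DataFrame, peaks: pd.DataFrame) -> pd.DataFrame:
    """Distance to host-peak center and per-peak mutation density.

    distance = |pos - floor((start+end)/2)|; density = mutations in the peak
    divided by its length.  Calls outside all peaks are flagged.
    """
    out = calls.copy()
    out["peak_id"] = None
    out["distance_to_center"] = np.nan
    out["in_peak"] = False
    for i, row in out.iterrows():
        host = peaks[
            (peaks["chrom"] == row["chrom"])
            & (peaks["start"] <= row["pos"])
            & (peaks["end"] > row["pos"])
        ]
        if host.empty:
            logger.info("call at %s:%d outside all peaks", row["chrom"], row["pos"])
            continue
        h = host.iloc[0]
        center = (int(h["start"]) + int(h["end"])) // 2
        out.loc[i, "peak_id"] = host.index[0]
        out.loc[i, "distance_to_center"] = abs(int(row["pos"]) - center)
        out.loc[i, "in_peak"] = True
    density = (
        out[out["in_peak"]]
        .groupby("peak_id")
        .size()
        .rename("n_mutations")
        .to_frame()
        .join((peaks["end"] - peaks["start"]).rename("length"))
    )
    density["mutations_per_bp"] = density["n_mutations"] / density["length"]
    out = out.merge(
        density[["mutations_per_bp"]], left_on="peak_id", right_index=True, how="left"
    )
    return out


def associate_snp_accessibility(
    polymorphisms: pd.DataFrame,
    alleles: pd.DataFrame,
    matrix: AccessibilityMatrix,
    peaks: pd.DataFrame,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Simple linear regression of host-peak accessibility on SNP dosage.

    Dosage per sample is encoded 0/1/2 from the alternate-read fraction
    (< 0.25 -> 0, < 0.75 -> 1, else 2).  q-values are step-up FDR over all
    tested SNPs; significant iff q < ``fdr``.
    """
    from twindisc.qtl import fdr_adjust

    df = alleles.copy()
    df["alt_n"] = df["fwd_alt"] + df["rev_alt"]
    df["n"] = df["alt_n"] + df["fwd_ref"] + df["rev_ref"]
    rows = []
    for _, snp in polymorphisms.iterrows():
        at = df[(df["chrom"] == snp["chrom"]) & (df["pos"] == snp["pos"])]
        if at.empty:
            continue
        host = peaks[
            (peaks["chrom"] == snp["chrom"])
            & (peaks["start"] <= snp["pos"])
            & (peaks["end"] > snp["pos"])
        ]
        if host.empty:
            continue
        peak_id = host.index[0]
        at = at.set_index("sample").reindex(matrix.samples)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = at["alt_n"] / at["n"]
        dosage = np.select([frac < 0.25, frac < 0.75], [0, 1], default=2).astype(float)
        dosage[frac.isna().to_numpy()] = np.nan
        y = matrix.values.loc[peak_id].to_numpy(dtype=float)
        ok = ~np.isnan(dosage)
        if ok.sum() < 3 or np.var(dosage[ok]) == 0:
            warnings.warn(f"SNP {snp['chrom']}:{snp['pos']}: constant dosage, skipped")
            continue
        res = stats.linregress(dosage[ok], y[ok])
        rows.append(
            {
                "chrom": snp["chrom"],
                "pos": int(snp["pos"]),
                "peak_id": peak_id,
                "slope": res.slope,
                "t": res.slope / res.stderr if res.stderr > 0 else np.inf,
                "p": res.pvalue if res.stderr > 0 else 0.0,
            }
        )
    out = pd.DataFrame(rows, columns=["chrom", "pos", "peak_id", "slope", "t", "p"])
    if len(out):
        out["q"] = fdr_adjust(out["p"].to_numpy())
        out["significant"] = out["q"] < fdr
    else:
        out["q"] = []
        out["significant"] = []
    return out
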