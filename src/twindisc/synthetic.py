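"""Synthetic twin cohort with known ground truth.

Emulates the structure of a FAIRE-seq MZ twin study: a small genome with
open-chromatin peaks covering ~2% of it, TFBSs nested inside peaks and
enriched for CpG dinucleotides, pair-correlated negative-binomial peak read
counts for 36 twin pairs, planted somatic mutations with allele-specific
accessibility effects, planted cis variability-QTLs acting on the normalized
within-pair difference, expression coupled to promoter accessibility, and
bimodal CpG methylation profiles across four cell types.

All randomness flows from one explicit seed through a single
``numpy.random.Generator``; identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from twindisc import _io
from twindisc.accessibility import normalize_accessibility, quantile_normalize
from twindisc.cohort import TwinCohort
from twindisc.errors import InputError, ParameterError
from twindisc.intervals import peak_ids

STATE_LABELS = [
    "active_promoter",
    "poised_promoter",
    "strong_enhancer",
    "weak_enhancer",
    "insulator",
    "transcribed",
]
STATE_PROBS = [0.20, 0.10, 0.25, 0.25, 0.10, 0.10]

CELL_TYPES = ["ESC", "HPC", "neutrophil", "lymphocyte"]

BASES = np.array(list("ACGT"))


@dataclass
class GenomeAssets:
    """Synthetic genome plus its annotation layers."""

    sequences: dict[str, str]
    peaks: pd.DataFrame  # chrom, start, end; index = peak_id
    tfbs: pd.DataFrame  # chrom, start, end, name (host peak_id)
    states: pd.DataFrame  # chrom, start, end, name (state label)
    cpg_positions: pd.DataFrame  # chrom, pos
    tss: pd.DataFrame  # gene, chrom, pos, strand

    @property
    def genome_size(self) -> int:
        return sum(len(s) for s in self.sequences.values())


@dataclass
class SimTruth:
    """Ground truth of every planted signal, recoverable from emitted files."""

    mutations: pd.DataFrame = field(default_factory=pd.DataFrame)
    qtls: pd.DataFrame = field(default_factory=pd.DataFrame)
    expression_coupling: pd.DataFrame = field(default_factory=pd.DataFrame)
    methylation_regulated: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class SyntheticCohort:
    """Everything :func:`generate_twin_cohort` emits, plus the pairing."""

    assets: GenomeAssets
    pairing: TwinCohort
    counts: pd.DataFrame  # peak_id x sample
    alleles: pd.DataFrame  # long allele count table
    genotypes: pd.DataFrame  # snp_id x pair dosage (0/1/2)
    snp_positions: pd.DataFrame  # snp_id, chrom, pos
    truth: SimTruth


# ------------------------------------------------------------------- genome


def _suppressed_background(rng: np.random.Generator, length: int, keep_cpg: float = 0.25) -> np.ndarray:
    """Random sequence with CpG depletion (real genomes are CpG-poor)."""
    seq = rng.integers(0, 4, size=length)
    for _ in range(2):  # two passes; replacements can create a few new CpGs
        is_cg = (seq[:-1] == 1) & (seq[1:] == 2)
        idx = np.flatnonzero(is_cg)
        broken = idx[rng.random(len(idx)) > keep_cpg]
        # replace the G with a random non-G base
        seq[broken + 1] = rng.choice([0, 1, 3], size=len(broken))
    return seq


def _cpg_rich_block(rng: np.random.Generator, length: int, cg_prob: float) -> np.ndarray:
    """Sequence built from 'CG' blocks (prob cg_prob) and single random bases."""
    out = np.empty(length + 1, dtype=np.int64)
    i = 0
    while i < length:
        if rng.random() < cg_prob:
            out[i] = 1  # C
            out[i + 1] = 2  # G
            i += 2
        else:
            out[i] = rng.integers(0, 4)
            i += 1
    return out[:length]


def _scan_cpg(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    return np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))


def generate_genome(
    n_contigs: int = 1,
    contig_length: int = 1_000_000,
    peak_density: float = 0.02,
    tfbs_cpg_boost: float = 4.0,
    seed: int = 0,
    peak_length_range: tuple[int, int] = (50, 90),
    tfbs_length_range: tuple[int, int] = (14, 26),
    gene_fraction: float = 0.6,
) -> GenomeAssets:
    """Synthesize a genome with open peaks, nested TFBSs, states, CpGs, TSSs.

    ``peak_density`` is the fraction of the genome covered by open peaks
    (the study scale is ~2%); ``tfbs_cpg_boost`` the minimum ratio of CpG
    start frequency inside TFBSs to the surrounding (non-TFBS) open chromatin.
    """
    if contig_length < 10_000:
        raise ParameterError("contig_length must be >= 10000")
    if not (0 < peak_density <= 0.05):
        raise ParameterError("peak_density must be in (0, 0.05]")
    if tfbs_cpg_boost < 1:
        raise ParameterError("tfbs_cpg_boost must be >= 1")
    if n_contigs < 1:
        raise ParameterError("n_contigs must be >= 1")
    rng = np.random.default_rng(seed)
    mean_len = float(np.mean(peak_length_range))
    # background CpG start frequency after suppression is ~0.018; a 2.5x
    # margin over the requested boost absorbs sampling noise
    target_freq = min(0.45, 2.5 * tfbs_cpg_boost * 0.018)
    cg_prob = target_freq / (1.0 - target_freq)

    sequences: dict[str, str] = {}
    peak_rows, tfbs_rows, state_rows, tss_rows = [], [], [], []
    gene_no = 0
    for ci in range(n_contigs):
        chrom = f"chr{ci + 1}"
        seq = _suppressed_background(rng, contig_length)
        n_peaks = int(round(peak_density * contig_length / mean_len))
        slot = contig_length // n_peaks
        for k in range(n_peaks):
            plen = int(rng.integers(peak_length_range[0], peak_length_range[1] + 1))
            lo = k * slot + 50
            hi = min((k + 1) * slot, contig_length) - plen - 50
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            end = start + plen
            peak_rows.append((chrom, start, end))
            tlen = int(rng.integers(tfbs_length_range[0], tfbs_length_range[1] + 1))
            tlen = min(tlen, plen - 4)
            toff = int(rng.integers(2, plen - tlen - 1))
            ts, te = start + toff, start + toff + tlen
            tfbs_rows.append((chrom, ts, te, f"{chrom}:{start}-{end}"))
            seq[ts:te] = _cpg_rich_block(rng, te - ts, cg_prob)
            pad = 100
            label = STATE_LABELS[rng.choice(len(STATE_LABELS), p=STATE_PROBS)]
            state_rows.append((chrom, max(0, start - pad), min(contig_length, end + pad), label))
            if rng.random() < gene_fraction:
                gene_no += 1
                strand = "+" if rng.random() < 0.5 else "-"
                pos = int(np.clip(start + int(rng.integers(-500, plen + 500)), 0, contig_length - 1))
                tss_rows.append((f"gene{gene_no:04d}", chrom, pos, strand))
        sequences[chrom] = "".join(BASES[seq])

    peaks = pd.DataFrame(peak_rows, columns=["chrom", "start", "end"])
    peaks.index = peak_ids(peaks)
    tfbs = pd.DataFrame(tfbs_rows, columns=["chrom", "start", "end", "name"])
    states = pd.DataFrame(state_rows, columns=["chrom", "start", "end", "name"])
    cpg = pd.concat(
        [
            pd.DataFrame({"chrom": c, "pos": _scan_cpg(s)})
            for c, s in sequences.items()
        ],
        ignore_index=True,
    )
    tss = pd.DataFrame(tss_rows, columns=["gene", "chrom", "pos", "strand"])
    return GenomeAssets(
        sequences=sequences, peaks=peaks, tfbs=tfbs, states=states, cpg_positions=cpg, tss=tss
    )


# -------------------------------------------------------------------- cohort


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = m + dispersion * m^2 (gamma-Poisson)."""
    mean = np.maximum(mean, 1e-9)
    if dispersion <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def _positions_in(intervals: pd.DataFrame) -> np.ndarray:
    """Row indices expanded: total bp available across intervals."""
    return (intervals["end"] - intervals["start"]).to_numpy()


def generate_twin_cohort(
    assets: GenomeAssets,
    n_pairs: int = 36,
    depth: float = 300.0,
    dispersion: float = 0.005,
    n_mutations: int = 30,
    n_qtls: int = 3,
    qtl_beta: float = 0.4,
    seed: int = 0,
    allele_depth: float = 60.0,
    vaf: float = 0.5,
    error_rate: float = 0.002,
    hq_fraction: float = 0.92,
    n_polymorphisms: int = 24,
    n_background_positions: int = 150,
    n_null_snps: int = 20,
    disc_noise_range: tuple[float, float] = (0.01, 0.08),
    mutation_effect: float = 0.6,
    pair_effect_sd: float = 0.3,
) -> SyntheticCohort:
    """Simulate peak counts, allele counts, genotypes and ground truth.

    ``depth`` is the mean reads per meta-peak per sample, ``dispersion`` the
    negative-binomial overdispersion, ``qtl_beta`` the shift of the
    normalized within-pair difference per dosage unit at planted QTL loci,
    ``vaf`` the variant allele fraction in the carrier sibling, and
    ``allele_depth`` the mean read depth at tracked single positions.
    """
    if n_pairs < 2:
        raise ParameterError("n_pairs must be >= 2")
    if depth <= 0:
        raise ParameterError("depth must be positive")
    rng = np.random.default_rng(seed)
    peaks = assets.peaks
    m = len(peaks)
    samples = [f"twin{p + 1:02d}{s}" for p in range(n_pairs) for s in ("a", "b")]
    pairing = TwinCohort(
        pd.DataFrame(
            {
                "sample_id": samples,
                "pair_id": [f"pair{p + 1:02d}" for p in range(n_pairs) for _ in range(2)],
                "sibling": [s for _ in range(n_pairs) for s in (1, 2)],
            }
        )
    )
    pair_ids = pairing.pair_ids

    # ---- planted somatic mutations: one position inside a TFBS each
    tfbs_bp = _positions_in(assets.tfbs)
    if n_mutations > int(tfbs_bp.sum()):
        raise ParameterError("n_mutations exceeds available TFBS positions")
    mut_tfbs = rng.choice(len(assets.tfbs), size=min(n_mutations, len(assets.tfbs)), replace=False)
    mut_rows = []
    for t_idx in mut_tfbs[:n_mutations]:
        trow = assets.tfbs.iloc[t_idx]
        pos = int(rng.integers(trow["start"], trow["end"]))
        ref = assets.sequences[trow["chrom"]][pos]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        pid = pair_ids[int(rng.integers(n_pairs))]
        carrier_sib = int(rng.integers(1, 3))
        sign = -1 if rng.random() < 0.7 else 1  # losses of accessibility dominate
        mut_rows.append((pid, carrier_sib, trow["chrom"], pos, ref, alt, sign, trow["name"]))
    mutations = pd.DataFrame(
        mut_rows,
        columns=["pair_id", "carrier_sibling", "chrom", "pos", "ref", "alt", "effect_sign", "peak_id"],
    )

    # ---- planted variability QTLs + null genotyped SNPs
    qtl_peak_idx = rng.choice(m, size=n_qtls, replace=False)
    qtl_rows, snp_rows, geno_rows = [], [], []
    for qi, pk in enumerate(qtl_peak_idx):
        prow = peaks.iloc[pk]
        pos = int(
            np.clip(
                prow["start"] + int(rng.integers(-50_000, 50_000)),
                0,
                len(assets.sequences[prow["chrom"]]) - 1,
            )
        )
        snp_id = f"qsnp{qi + 1:03d}"
        maf = float(rng.uniform(0.1, 0.5))
        dosage = rng.binomial(2, maf, size=n_pairs)
        while dosage.var() == 0:  # MAF in [0.1,0.5] at >=2 pairs: retry degenerate draws
            dosage = rng.binomial(2, maf, size=n_pairs)
        snp_rows.append((snp_id, prow["chrom"], pos))
        geno_rows.append(dosage)
        qtl_rows.append((snp_id, prow["chrom"], pos, peaks.index[pk], qtl_beta, maf))
    for ni in range(n_null_snps):
        pk = int(rng.integers(m))
        prow = peaks.iloc[pk]
        pos = int(
            np.clip(
                prow["start"] + int(rng.integers(-50_000, 50_000)),
                0,
                len(assets.sequences[prow["chrom"]]) - 1,
            )
        )
        maf = float(rng.uniform(0.1, 0.5))
        snp_rows.append((f"nsnp{ni + 1:03d}", prow["chrom"], pos))
        geno_rows.append(rng.binomial(2, maf, size=n_pairs))
    snp_positions = pd.DataFrame(snp_rows, columns=["snp_id", "chrom", "pos"])
    genotypes = pd.DataFrame(
        np.array(geno_rows), index=snp_positions["snp_id"], columns=pair_ids
    )
    genotypes.index.name = "snp_id"
    qtls = pd.DataFrame(
        qtl_rows, columns=["snp_id", "chrom", "pos", "peak_id", "beta", "maf"]
    )

    # ---- peak x sample counts: NB with shared pair effect + planted asymmetries
    base_mu = depth * rng.lognormal(mean=-0.125, sigma=0.5, size=m)  # mean ~ depth
    # per-peak discordance scale: loci differ in how labile they are
    peak_disc_sd = rng.uniform(disc_noise_range[0], disc_noise_range[1], size=m)
    counts = np.zeros((m, 2 * n_pairs), dtype=np.int64)
    qtl_peak_pos = {pk: qi for qi, pk in enumerate(qtl_peak_idx)}
    mut_by_pair_peak: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for _, mr in mutations.iterrows():
        mut_by_pair_peak.setdefault((mr["pair_id"], mr["peak_id"]), []).append(
            (mr["carrier_sibling"], mr["effect_sign"])
        )
    peak_index_by_id = {pid: i for i, pid in enumerate(peaks.index)}
    for p, pid in enumerate(pair_ids):
        u = rng.lognormal(mean=0.0, sigma=pair_effect_sd, size=m)
        a = rng.normal(0.0, 1.0, size=m) * peak_disc_sd
        for pk, qi in qtl_peak_pos.items():
            a[pk] += qtl_beta * genotypes.iloc[qi, p]
        a = np.clip(a, -0.9, 0.9)
        m1 = base_mu * u * (1.0 + a)
        m2 = base_mu * u * (1.0 - a)
        for (pair_id, peak_id), effs in mut_by_pair_peak.items():
            if pair_id != pid:
                continue
            j = peak_index_by_id[peak_id]
            for sib, sign in effs:
                factor = 1.0 + sign * mutation_effect
                if sib == 1:
                    m1[j] *= factor
                else:
                    m2[j] *= factor
        counts[:, 2 * p] = _nb_draw(rng, m1, dispersion)
        counts[:, 2 * p + 1] = _nb_draw(rng, m2, dispersion)
    counts_df = pd.DataFrame(counts, index=peaks.index, columns=samples)

    # ---- planted polymorphisms (cohort-level variants, shared within pair)
    poly_rows = []
    n_poly_tfbs = int(round(0.5 * n_polymorphisms))
    poly_tfbs = [i for i in range(len(assets.tfbs)) if i not in set(mut_tfbs[:n_mutations])]
    chosen_tfbs = rng.choice(poly_tfbs, size=min(n_poly_tfbs, len(poly_tfbs)), replace=False)
    for t_idx in chosen_tfbs:
        trow = assets.tfbs.iloc[t_idx]
        poly_rows.append((trow["chrom"], int(rng.integers(trow["start"], trow["end"]))))
    poly_taken = {(c, p) for c, p in poly_rows} | {
        (r["chrom"], r["pos"]) for _, r in mutations.iterrows()
    }
    while len(poly_rows) < n_polymorphisms:
        pk = int(rng.integers(m))
        prow = peaks.iloc[pk]
        pos = int(rng.integers(prow["start"], prow["end"]))
        trow = assets.tfbs.loc[assets.tfbs["name"] == peaks.index[pk]]
        # keep non-TFBS polymorphisms outside TFBS intervals
        if len(trow) and trow["start"].iloc[0] <= pos < trow["end"].iloc[0]:
            continue
        if (prow["chrom"], pos) in poly_taken:
            continue
        poly_taken.add((prow["chrom"], pos))
        poly_rows.append((prow["chrom"], pos))
    poly_meta = []
    for chrom, pos in poly_rows:
        ref = assets.sequences[chrom][pos]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        maf = float(rng.uniform(0.05, 0.4))
        dosage = rng.binomial(2, maf, size=n_pairs)
        poly_meta.append((chrom, pos, ref, alt, maf, dosage))

    # ---- allele count table at tracked positions
    tracked: list[dict] = []
    for _, mr in mutations.iterrows():
        tracked.append(
            {
                "chrom": mr["chrom"],
                "pos": mr["pos"],
                "ref": mr["ref"],
                "alt": mr["alt"],
                "kind": "mutation",
                "pair_id": mr["pair_id"],
                "carrier_sibling": mr["carrier_sibling"],
            }
        )
    for chrom, pos, ref, alt, maf, dosage in poly_meta:
        tracked.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "kind": "polymorphism",
                "dosage": dosage,
            }
        )
    taken = {(t["chrom"], t["pos"]) for t in tracked}
    for _ in range(n_background_positions):
        pk = int(rng.integers(m))
        prow = peaks.iloc[pk]
        pos = int(rng.integers(prow["start"], prow["end"]))
        if (prow["chrom"], pos) in taken:
            continue
        taken.add((prow["chrom"], pos))
        ref = assets.sequences[prow["chrom"]][pos]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        tracked.append({"chrom": prow["chrom"], "pos": pos, "ref": ref, "alt": alt, "kind": "background"})

    allele_rows = []
    for rec in tracked:
        for si, sample in enumerate(samples):
            p, sib = si // 2, si % 2 + 1
            if rec["kind"] == "mutation":
                carrier = rec["pair_id"] == pair_ids[p] and rec["carrier_sibling"] == sib
                alt_p = vaf if carrier else error_rate
            elif rec["kind"] == "polymorphism":
                alt_p = max(rec["dosage"][p] / 2.0 * vaf * 2.0, error_rate)
            else:
                alt_p = error_rate
            n = int(rng.poisson(allele_depth))
            alt_n = int(rng.binomial(n, min(alt_p, 1.0)))
            ref_n = n - alt_n
            fwd_ref = int(rng.binomial(ref_n, 0.5))
            fwd_alt = int(rng.binomial(alt_n, 0.5))
            rev_ref, rev_alt = ref_n - fwd_ref, alt_n - fwd_alt
            hq_fwd = int(rng.binomial(fwd_ref + fwd_alt, hq_fraction))
            hq_rev = int(rng.binomial(rev_ref + rev_alt, hq_fraction))
            allele_rows.append(
                (
                    rec["chrom"], rec["pos"], rec["ref"], rec["alt"], sample,
                    fwd_ref, rev_ref, fwd_alt, rev_alt, hq_fwd, hq_rev,
                )
            )
    alleles = pd.DataFrame(
        allele_rows,
        columns=[
            "chrom", "pos", "ref", "alt", "sample",
            "fwd_ref", "rev_ref", "fwd_alt", "rev_alt", "hq_fwd", "hq_rev",
        ],
    )

    mutations["sample_id"] = [
        pairing.pairs.loc[
            (pairing.pairs["pair_id"] == r["pair_id"])
            & (pairing.pairs["sibling"] == r["carrier_sibling"]),
            "sample_id",
        ].iloc[0]
        for _, r in mutations.iterrows()
    ]
    truth = SimTruth(mutations=mutations, qtls=qtls)
    _check_truth(assets, truth)
    return SyntheticCohort(
        assets=assets,
        pairing=pairing,
        counts=counts_df,
        alleles=alleles,
        genotypes=genotypes,
        snp_positions=snp_positions,
        truth=truth,
    )


def _check_truth(assets: GenomeAssets, truth: SimTruth) -> None:
    """Every truth record must refer to an existing position/peak/gene."""
    for _, r in truth.mutations.iterrows():
        if r["peak_id"] not in assets.peaks.index:
            raise InputError(f"truth mutation refers to unknown peak {r['peak_id']}")
        if not (0 <= r["pos"] < len(assets.sequences[r["chrom"]])):
            raise InputError("truth mutation outside contig bounds")
    for _, r in truth.qtls.iterrows():
        if r["peak_id"] not in assets.peaks.index:
            raise InputError(f"truth QTL refers to unknown peak {r['peak_id']}")


def generate_allele_table(
    n_positions: int,
    n_pairs: int,
    depth: float = 60.0,
    n_mutations: int = 0,
    vaf: float = 0.5,
    error_rate: float = 0.002,
    hq_fraction: float = 0.92,
    fixed_depth: bool = False,
    seed: int = 0,
) -> tuple[pd.DataFrame, TwinCohort, pd.DataFrame]:
    """Vectorized position-level allele-count simulator for calibration studies.

    Positions sit on one contig at 1 bp spacing; the first ``n_mutations``
    positions carry a VAF-``vaf`` somatic variant in one random sibling of
    one random pair, all others are reference-homozygous with sequencing
    error ``error_rate``.  Returns (alleles, pairing, truth) where truth
    lists (pos, pair_id, sample_id) of the planted mutations.
    """
    rng = np.random.default_rng(seed)
    n_samp = 2 * n_pairs
    samples = [f"twin{p + 1:02d}{s}" for p in range(n_pairs) for s in ("a", "b")]
    pair_ids = [f"pair{p + 1:02d}" for p in range(n_pairs)]
    pairing = TwinCohort(
        pd.DataFrame(
            {
                "sample_id": samples,
                "pair_id": [pid for pid in pair_ids for _ in range(2)],
                "sibling": [s for _ in range(n_pairs) for s in (1, 2)],
            }
        )
    )
    total = (
        np.full((n_positions, n_samp), int(depth))
        if fixed_depth
        else rng.poisson(depth, size=(n_positions, n_samp))
    )
    alt_p = np.full((n_positions, n_samp), error_rate)
    mut_pair = rng.integers(0, n_pairs, size=n_mutations)
    mut_sib = rng.integers(0, 2, size=n_mutations)
    for i in range(n_mutations):
        alt_p[i, 2 * mut_pair[i] + mut_sib[i]] = vaf
    alt = rng.binomial(total, alt_p)
    ref = total - alt
    fwd_ref = rng.binomial(ref, 0.5)
    fwd_alt = rng.binomial(alt, 0.5)
    rev_ref, rev_alt = ref - fwd_ref, alt - fwd_alt
    hq_fwd = rng.binomial(fwd_ref + fwd_alt, hq_fraction)
    hq_rev = rng.binomial(rev_ref + rev_alt, hq_fraction)
    alleles = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.repeat(np.arange(n_positions), n_samp),
            "ref": "A",
            "alt": "C",
            "sample": np.tile(samples, n_positions),
            "fwd_ref": fwd_ref.ravel(),
            "rev_ref": rev_ref.ravel(),
            "fwd_alt": fwd_alt.ravel(),
            "rev_alt": rev_alt.ravel(),
            "hq_fwd": hq_fwd.ravel(),
            "hq_rev": hq_rev.ravel(),
        }
    )
    truth = pd.DataFrame(
        {
            "pos": np.arange(n_mutations),
            "pair_id": [pair_ids[p] for p in mut_pair],
            "sample_id": [samples[2 * p + s] for p, s in zip(mut_pair, mut_sib)],
        }
    )
    return alleles, pairing, truth


# ---------------------------------------------------------------- expression


def generate_expression(
    cohort: SyntheticCohort,
    coupling_strength: float = 0.1,
    noise_sd: float = 0.3,
    seed: int = 0,
    coupled_fraction: float = 0.5,
    window: int = 2000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x sample log2 expression coupled to promoter accessibility.

    For a coupled gene, each sibling's expression tracks the quantile-
    normalized accessibility of its promoter peak with slope
    ``coupling_strength``, so the within-pair |Δexpression| scales with the
    pair's accessibility discordance at that peak.
    """
    from twindisc.integrate import link_genes_to_peaks

    rng = np.random.default_rng(seed)
    assets = cohort.assets
    mat = quantile_normalize(
        normalize_accessibility(cohort.counts, assets.peaks, assets.genome_size)
    )
    links = link_genes_to_peaks(assets.tss, assets.peaks, window=window)
    samples = cohort.pairing.sample_ids
    genes = list(assets.tss["gene"])
    base = rng.normal(8.0, 1.5, size=len(genes))
    expr = np.tile(base[:, None], (1, len(samples)))
    link_map = dict(zip(links["gene"], links["peak_id"]))
    coupling_rows = []
    for gi, gene in enumerate(genes):
        peak = link_map.get(gene)
        coupled = peak is not None and rng.random() < coupled_fraction
        slope = coupling_strength if coupled else 0.0
        if coupled:
            expr[gi, :] += slope * mat.values.loc[peak, samples].to_numpy()
        coupling_rows.append((gene, peak if peak is not None else "", slope))
    if noise_sd > 0:
        expr += rng.normal(0.0, noise_sd, size=expr.shape)
    expr_df = pd.DataFrame(expr, index=pd.Index(genes, name="gene"), columns=samples)
    coupling = pd.DataFrame(coupling_rows, columns=["gene", "peak_id", "slope"])
    cohort.truth.expression_coupling = coupling
    return expr_df, coupling


# --------------------------------------------------------------- methylation


def generate_methylation(
    assets: GenomeAssets,
    regulated_fraction: float = 0.3,
    delta: float = 0.5,
    seed: int = 0,
    noise_sd: float = 0.03,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """CpG x cell-type methylation in [0, 1] for TFBS CpGs.

    Differentiation-regulated CpGs shift their lymphocyte methylation by
    ``delta`` (toward the side with more head-room) relative to the ESC/HPC/
    neutrophil baseline; unregulated CpGs keep the baseline in all cell
    types.  Baselines are Beta(0.5, 0.5): methylation is bimodal.
    """
    if not (0.0 <= delta <= 1.0):
        raise ParameterError("delta must be in [0, 1]")
    if not (0.0 <= regulated_fraction <= 1.0):
        raise ParameterError("regulated_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    cpgs = []
    for _, t in assets.tfbs.iterrows():
        sub = assets.cpg_positions[
            (assets.cpg_positions["chrom"] == t["chrom"])
            & (assets.cpg_positions["pos"] >= t["start"])
            & (assets.cpg_positions["pos"] < t["end"] - 1)
        ]
        for pos in sub["pos"]:
            cpgs.append((t["chrom"], int(pos), t["name"]))
    cpg_df = pd.DataFrame(cpgs, columns=["chrom", "pos", "tfbs_peak"]).drop_duplicates(
        subset=["chrom", "pos"], ignore_index=True
    )
    n = len(cpg_df)
    base = rng.beta(0.5, 0.5, size=n)
    regulated = rng.random(n) < regulated_fraction
    lymph = base.copy()
    up = base <= 0.5  # shift toward the side with more head-room
    lymph[regulated & up] = base[regulated & up] + delta
    lymph[regulated & ~up] = base[regulated & ~up] - delta
    meth = pd.DataFrame(
        {
            "chrom": cpg_df["chrom"],
            "pos": cpg_df["pos"],
            "tfbs_peak": cpg_df["tfbs_peak"],
            "ESC": base,
            "HPC": base,
            "neutrophil": base,
            "lymphocyte": lymph,
        }
    )
    if noise_sd > 0:
        for ct in CELL_TYPES:
            meth[ct] = meth[ct] + rng.normal(0.0, noise_sd, size=n)
    for ct in CELL_TYPES:
        meth[ct] = np.clip(meth[ct], 0.0, 1.0)
    flags = cpg_df.loc[regulated, ["chrom", "pos"]].reset_index(drop=True)
    return meth, flags


# ------------------------------------------------------------------- writing


def write_cohort(
    cohort: SyntheticCohort,
    out_dir: str | Path,
    expression: pd.DataFrame | None = None,
    methylation: pd.DataFrame | None = None,
) -> None:
    """Write every emitted file of the synthetic study to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    assets = cohort.assets
    _io.write_fasta(assets.sequences, out / "genome.fa")
    _io.write_bed(assets.peaks, out / "peaks.bed")
    _io.write_bed(assets.tfbs, out / "tfbs.bed")
    _io.write_bed(assets.states, out / "states.bed")
    tss_bed = assets.tss.assign(start=assets.tss["pos"], end=assets.tss["pos"] + 1)
    _io.write_bed(
        tss_bed[["chrom", "start", "end", "gene", "strand"]].rename(columns={"gene": "name"}).assign(score=0)[
            ["chrom", "start", "end", "name", "score", "strand"]
        ],
        out / "tss.bed",
    )
    _io.write_matrix(cohort.counts, out / "counts.tsv", index_label="peak_id")
    cohort.alleles.to_csv(out / "alleles.tsv", sep="\t", index=False)
    cohort.pairing.to_tsv(out / "pairs.tsv")
    _io.write_matrix(cohort.genotypes, out / "genotypes.tsv", index_label="snp_id")
    cohort.snp_positions.to_csv(out / "snps.tsv", sep="\t", index=False)
    if expression is not None:
        _io.write_matrix(expression, out / "expression.tsv", index_label="gene")
    if methylation is not None:
        methylation.to_csv(out / "methylation.tsv", sep="\t", index=False)
    tdir = out / "truth"
    tdir.mkdir(exist_ok=True)
    cohort.truth.mutations.to_csv(tdir / "mutations.tsv", sep="\t", index=False)
    cohort.truth.qtls.to_csv(tdir / "qtls.tsv", sep="\t", index=False)
    if len(cohort.truth.expression_coupling):
        cohort.truth.expression_coupling.to_csv(tdir / "expression_coupling.tsv", sep="\t", index=False)
    if len(cohort.truth.methylation_regulated):
        cohort.truth.methylation_regulated.to_csv(
            tdir / "methylation_regulated.tsv", sep="\t", index=False
        )


def simulate_cohort(
    out_dir: str | Path,
    seed: int = 0,
    n_pairs: int = 36,
    contig_length: int = 1_000_000,
    n_contigs: int = 1,
    **kwargs,
) -> SyntheticCohort:
    """One-call simulation of the full study (genome, cohort, expression, methylation)."""
    rng = np.random.default_rng(seed)
    s_genome, s_cohort, s_expr, s_meth = rng.integers(0, 2**31 - 1, size=4)
    assets = generate_genome(
        n_contigs=n_contigs, contig_length=contig_length, seed=int(s_genome)
    )
    cohort = generate_twin_cohort(assets, n_pairs=n_pairs, seed=int(s_cohort), **kwargs)
    expression, _ = generate_expression(cohort, seed=int(s_expr))
    methylation, flags = generate_methylation(assets, seed=int(s_meth))
    cohort.truth.methylation_regulated = flags
    write_cohort(cohort, out_dir, expression=expression, methylation=methylation)
    return cohort
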