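"""End-to-end orchestration: simulate -> quantify -> call -> spectrum -> qtl -> integrate.

Stages are coupled only through their declared files in the run directory;
the manifest records the config hash, the seed, and per-stage row counts.
Re-running with an identical config reproduces identical outputs.
"""

from __future__ import annotations

import json
import logging
import sys
import warnings
from pathlib import Path

import pandas as pd

from twindisc import _io, accessibility, integrate, qtl, spectrum, variants
from twindisc.cohort import TwinCohort
from twindisc.config import RunConfig
from twindisc.errors import StageError, TwindiscError
from twindisc.intervals import peak_ids, positions_in_intervals, subtract_intervals

logger = logging.getLogger("twindisc")


def _setup_logging(verbose: bool) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("twindisc")
    root.handlers[:] = [handler]
    root.setLevel(logging.DEBUG if verbose else logging.INFO)


def _read_peaks(path: Path) -> pd.DataFrame:
    peaks = _io.read_bed(path)
    peaks.index = peak_ids(peaks)
    return peaks


def stage_quantify(data: Path, out: Path, config: RunConfig) -> dict:
    peaks = _read_peaks(data / "peaks.bed")
    counts = _io.read_matrix(data / "counts.tsv")
    pairing = TwinCohort.from_tsv(data / "pairs.tsv")
    genome_size = sum(len(s) for s in _io.read_fasta(data / "genome.fa").values())
    mat = accessibility.normalize_accessibility(counts, peaks, genome_size)
    mat = accessibility.quantile_normalize(mat)
    _io.write_matrix(mat.values, out / "accessibility.tsv", index_label="peak_id")
    disc = accessibility.pair_discordance(mat, pairing)
    disc.to_csv(out / "discordance.tsv", sep="\t", index=False)
    flags = accessibility.call_discordant_sites(
        disc, rule="fold_change", pseudocount=config.pseudocount, fc_threshold=config.fc
    )
    flags.to_csv(out / "discordant_sites.tsv", sep="\t", index=False)
    states_path = data / "states.bed"
    if states_path.exists():
        states = _io.read_bed(states_path)
        per_peak = disc.groupby("peak_id", sort=False)["d_norm"].mean().reindex(peaks.index)
        summary = accessibility.summarize_by_state(per_peak, peaks, states)
        summary.to_csv(out / "state_summary.tsv", sep="\t", index=False)
    return {"peaks": len(peaks), "discordance_rows": len(disc)}


def stage_callmut(data: Path, out: Path, config: RunConfig) -> dict:
    alleles = pd.read_csv(data / "alleles.tsv", sep="\t")
    pairing = TwinCohort.from_tsv(data / "pairs.tsv")
    calls = variants.call_somatic_mutations(
        alleles,
        pairing,
        p_threshold=config.p_threshold,
        min_hq_per_strand=config.min_hq_per_strand,
    )
    peaks = _read_peaks(data / "peaks.bed")
    acc_path = out / "accessibility.tsv"
    if acc_path.exists():
        values = _io.read_matrix(acc_path)
        mat = accessibility.AccessibilityMatrix(
            values=values, sample_totals=values.sum(axis=0), genome_size=1.0
        )
        calls = variants.annotate_direction(calls, mat, pairing, peaks)
    _io.write_vcf(calls, out / "mutations.vcf")
    context = variants.annotate_mutation_peak_context(calls, peaks)
    context.to_csv(out / "context.tsv", sep="\t", index=False)
    return {"mutations": len(calls)}


def stage_callsnp(data: Path, out: Path, config: RunConfig) -> dict:
    alleles = pd.read_csv(data / "alleles.tsv", sep="\t")
    pairing = TwinCohort.from_tsv(data / "pairs.tsv")
    somatic = _io.read_vcf(out / "mutations.vcf") if (out / "mutations.vcf").exists() else None
    calls = variants.call_polymorphisms(
        alleles,
        pairing,
        somatic_calls=somatic,
        maf_threshold=config.maf,
        strand_frac=config.strand_frac,
    )
    _io.write_vcf(calls, out / "polymorphisms.vcf")
    return {"polymorphisms": len(calls)}


def stage_spectrum(data: Path, out: Path, config: RunConfig) -> dict:
    genome = _io.read_fasta(data / "genome.fa")
    peaks = _read_peaks(data / "peaks.bed")
    tfbs = _io.read_bed(data / "tfbs.bed", names=["chrom", "start", "end", "name"])
    open_bg = subtract_intervals(peaks, tfbs)  # host peaks minus their TFBSs
    muts = _io.read_vcf(out / "mutations.vcf")
    polys = _io.read_vcf(out / "polymorphisms.vcf")
    calls = pd.concat([muts, polys], ignore_index=True)
    in_tfbs = positions_in_intervals(calls["chrom"], calls["pos"], tfbs)
    in_peak = positions_in_intervals(calls["chrom"], calls["pos"], peaks)
    calls_tfbs = calls[in_tfbs]
    calls_open = calls[in_peak & ~in_tfbs]

    seq_tfbs = spectrum.count_sequence_dinucleotides(genome, tfbs)
    seq_open = spectrum.count_sequence_dinucleotides(genome, open_bg)
    seq_genome = spectrum.count_sequence_dinucleotides(genome)
    spec_frames = {
        "seq_tfbs": seq_tfbs,
        "seq_open_chromatin": seq_open,
        "seq_genome": seq_genome,
        "variants_tfbs": spectrum.count_variant_dinucleotides(calls_tfbs, genome),
        "variants_open_chromatin": spectrum.count_variant_dinucleotides(calls_open, genome),
    }
    pd.DataFrame(spec_frames).to_csv(out / "spectrum.tsv", sep="\t", index_label="dinuc_class")

    frames = []
    enr_open = spectrum.dinuc_relative_enrichment(seq_tfbs, seq_open)
    enr_open["mode"] = "dinuc_enrichment_open_bg"
    enr_genome = spectrum.dinuc_relative_enrichment(seq_tfbs, seq_genome)
    enr_genome["mode"] = "dinuc_enrichment_genome_bg"
    frames += [enr_open.reset_index(), enr_genome.reset_index()]
    if len(calls_tfbs) and len(calls_open):
        sub = spectrum.substituted_dinuc_oe(
            spec_frames["variants_tfbs"], spec_frames["variants_open_chromatin"], seq_tfbs, seq_open
        )
        sub["mode"] = "substituted_dinuc_oe"
        frames.append(sub.reset_index().rename(columns={"index": "dinuc_class"}))
        try:
            bc = spectrum.base_change_oe(calls_tfbs, calls_open)
            bc["mode"] = "base_change_oe"
            frames.append(bc.reset_index().rename(columns={"index": "dinuc_class"}))
        except TwindiscError as exc:
            warnings.warn(f"base-change O/E skipped: {exc}")
        try:
            cpg = spectrum.cpg_substitution_oe(calls_tfbs, calls_open, genome)
            cpg["mode"] = "cpg_substitution_oe"
            frames.append(cpg.reset_index().rename(columns={"index": "dinuc_class"}))
        except TwindiscError as exc:
            warnings.warn(f"CpG substitution O/E skipped: {exc}")
    oe = pd.concat(frames, ignore_index=True)
    oe.to_csv(out / "oe_ratios.tsv", sep="\t", index=False)
    return {"tfbs_calls": int(len(calls_tfbs)), "open_calls": int(len(calls_open)), "oe_rows": len(oe)}


def stage_qtl(data: Path, out: Path, config: RunConfig) -> dict:
    disc = pd.read_csv(out / "discordance.tsv", sep="\t")
    peaks = _read_peaks(data / "peaks.bed")
    genotypes = _io.read_matrix(data / "genotypes.tsv")
    snp_positions = pd.read_csv(data / "snps.tsv", sep="\t")
    traits = qtl.pair_trait_matrix(disc)
    top = qtl.select_top_variance_loci(traits, fraction=config.top_frac)
    assoc = qtl.map_variability_qtl(
        traits.loc[top],
        peaks,
        genotypes,
        snp_positions,
        cis_window=config.cis_window,
        fdr=config.fdr_qtl,
        maf_min=config.maf,
    )
    assoc.to_csv(out / "qtl_associations.tsv", sep="\t", index=False)
    return {"selected_peaks": len(top), "tests": len(assoc), "significant": int(assoc["significant"].sum())}


def stage_integrate(data: Path, out: Path, config: RunConfig) -> dict:
    pairing = TwinCohort.from_tsv(data / "pairs.tsv")
    peaks = _read_peaks(data / "peaks.bed")
    result: dict = {}
    expr_path = data / "expression.tsv"
    if expr_path.exists():
        expr = _io.read_matrix(expr_path)
        tss = _io.read_bed(data / "tss.bed").rename(columns={"name": "gene"})
        tss["pos"] = tss["start"]
        diff = integrate.within_pair_expression_diff(expr, pairing)
        links = integrate.link_genes_to_peaks(tss, peaks, window=config.window)
        disc = pd.read_csv(out / "discordance.tsv", sep="\t")
        disc_wide = disc.pivot(index="peak_id", columns="pair_id", values="d_norm")
        linked = links[links["peak_id"].isin(disc_wide.index)]
        # pooled (gene, pair) observations: promoter discordance vs |dlog2 expr|
        pair_cols = [c for c in disc_wide.columns if c in diff.columns]
        obs_disc = disc_wide.loc[linked["peak_id"], pair_cols].to_numpy().ravel()
        obs_de = diff.loc[linked["gene"], pair_cols].to_numpy().ravel()
        rho, p = integrate.tertile_permutation_test(
            obs_disc, obs_de, n_perm=config.n_perm, seed=config.seed
        )
        pd.DataFrame(
            [{"statistic": rho, "p": p, "n_genes": len(linked), "n_perm": config.n_perm}]
        ).to_csv(out / "expression_coupling_test.tsv", sep="\t", index=False)
        result.update({"linked_genes": len(linked), "coupling_p": p})
    meth_path = data / "methylation.tsv"
    if meth_path.exists():
        meth = pd.read_csv(meth_path, sep="\t")
        muts = _io.read_vcf(out / "mutations.vcf")
        polys = _io.read_vcf(out / "polymorphisms.vcf")

        def status_of(chrom: str, pos: int) -> str:
            # a CpG at pos spans [pos, pos+2); either base may be substituted
            m = ((muts["chrom"] == chrom) & muts["pos"].isin([pos, pos + 1])).any()
            if m:
                return "mutated"
            s = ((polys["chrom"] == chrom) & polys["pos"].isin([pos, pos + 1])).any()
            return "polymorphic" if s else "non_substituted"

        meth["status"] = [status_of(c, p) for c, p in zip(meth["chrom"], meth["pos"])]
        summary, tests = integrate.cpg_differential_methylation_compare(meth)
        summary.to_csv(out / "methylation_by_status.tsv", sep="\t", index=False)
        tests.to_csv(out / "methylation_tests.tsv", sep="\t", index=False)
        result["methylation_cpgs"] = len(meth)
    return result


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    data_dir: str | Path | None = None,
    simulate: bool = True,
    stages: list[str] | None = None,
    verbose: bool = False,
) -> dict:
    """Run the pipeline; returns (and writes) the manifest.

    ``data_dir`` holds the inputs; with ``simulate`` it is populated by the
    synthetic-cohort generator first.  Any stage failure halts the run with a
    stage-labeled error.
    """
    _setup_logging(verbose)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = Path(data_dir) if data_dir is not None else out / "data"
    manifest: dict = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stages": [],
    }
    plan = stages or ["simulate", "quantify", "callmut", "callsnp", "spectrum", "qtl", "integrate"]
    if not simulate and "simulate" in plan:
        plan = [s for s in plan if s != "simulate"]

    def run_stage(name: str, fn) -> None:
        logger.info("stage %s: start", name)
        try:
            info = fn()
        except TwindiscError as exc:
            raise StageError(name, str(exc)) from exc
        except FileNotFoundError as exc:
            raise StageError(name, f"missing input: {exc.filename}") from exc
        manifest["stages"].append({"name": name, **(info or {})})
        logger.info("stage %s: done %s", name, info)

    for name in plan:
        if name == "simulate":
            def do_sim():
                from twindisc.synthetic import simulate_cohort

                cohort = simulate_cohort(
                    data,
                    seed=config.seed,
                    n_pairs=config.n_pairs,
                    contig_length=config.contig_length,
                    n_contigs=config.n_contigs,
                )
                return {"samples": len(cohort.pairing.sample_ids), "peaks": len(cohort.assets.peaks)}

            run_stage("simulate", do_sim)
        elif name == "quantify":
            run_stage("quantify", lambda: stage_quantify(data, out, config))
        elif name == "callmut":
            run_stage("callmut", lambda: stage_callmut(data, out, config))
        elif name == "callsnp":
            run_stage("callsnp", lambda: stage_callsnp(data, out, config))
        elif name == "spectrum":
            run_stage("spectrum", lambda: stage_spectrum(data, out, config))
        elif name == "qtl":
            run_stage("qtl", lambda: stage_qtl(data, out, config))
        elif name == "integrate":
            run_stage("integrate", lambda: stage_integrate(data, out, config))
        else:
            raise StageError(name, "unknown stage")
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
    return manifest
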