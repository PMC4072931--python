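"""Run configuration: every numeric threshold of the pipeline, with the
study defaults, plus YAML round-tripping and a content hash."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from twindisc.errors import ParameterError

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """All tunables of a pipeline run.

    Defaults are the study's stated thresholds: mutation Fisher p < 1e-3 with
    >= 10 high-quality reads per strand per sibling; polymorphism pooled MAF
    >= 1% with a 90% one-strand artifact filter; fold change > 4 for
    discordant sites; top 1% of peaks by between-pair variance, cis window
    1 Mb and FDR 0.01 for QTL mapping; FDR 0.05 for SNP-accessibility
    associations; +/-2 kb promoter window; 10,000 permutations.
    """

    seed: int = 0
    # variant calling
    p_threshold: float = 1e-3
    min_hq_per_strand: int = 10
    maf: float = 0.01
    strand_frac: float = 0.90
    # discordance
    fc: float = 4.0
    pseudocount: float = 1.0
    # QTL mapping
    top_frac: float = 0.01
    cis_window: float = 1e6
    fdr_qtl: float = 0.01
    fdr_snp: float = 0.05
    # integration
    window: int = 2000
    n_perm: int = 10_000
    # simulation
    n_pairs: int = 36
    contig_length: int = 1_000_000
    n_contigs: int = 1
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        checks = [
            (0 < self.p_threshold <= 1, "p_threshold in (0, 1]"),
            (self.min_hq_per_strand >= 0, "min_hq_per_strand >= 0"),
            (0 <= self.maf <= 0.5, "maf in [0, 0.5]"),
            (0.5 <= self.strand_frac <= 1, "strand_frac in [0.5, 1]"),
            (self.fc > 1, "fc > 1"),
            (self.pseudocount >= 0, "pseudocount >= 0"),
            (0 < self.top_frac <= 1, "top_frac in (0, 1]"),
            (self.cis_window > 0, "cis_window > 0"),
            (0 < self.fdr_qtl < 1, "fdr_qtl in (0, 1)"),
            (0 < self.fdr_snp < 1, "fdr_snp in (0, 1)"),
            (self.window >= 0, "window >= 0"),
            (self.n_perm >= 1, "n_perm >= 1"),
            (self.n_pairs >= 2, "n_pairs >= 2"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ParameterError(f"config: {msg}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        version = data.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ParameterError(f"unsupported config schema version {version}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
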