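"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA reading goes through pyfaidx; BED and the TSV matrices through pandas.
VCF output is the minimal 8-column VCF 4.2 the variant callers emit
(INFO keys: SOMATIC, FETP, PAIR, DIR, BCC, MAF).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from pyfaidx import Fasta

from twindisc.errors import InputError
from twindisc.intervals import validate_intervals

# ---------------------------------------------------------------- FASTA / BED


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["chrom", "start", "end"]
    for extra in ("name", "score", "strand"):
        if extra in df.columns:
            cols.append(extra)
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path, names: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    base = ["chrom", "start", "end", "name", "score", "strand"]
    df.columns = (names or base)[: df.shape[1]]
    return validate_intervals(df, name=str(path))


# --------------------------------------------------------------- TSV matrices


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str) -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# ----------------------------------------------------------------------- VCF

VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=SOMATIC,Number=0,Type=Flag,Description="Within-pair somatic mutation">
##INFO=<ID=FETP,Number=1,Type=Float,Description="Fisher exact test p-value">
##INFO=<ID=PAIR,Number=1,Type=String,Description="Twin pair carrying the mutation">
##INFO=<ID=DIR,Number=1,Type=String,Description="Direction of accessibility change">
##INFO=<ID=BCC,Number=1,Type=String,Description="Strand-collapsed base-change class">
##INFO=<ID=MAF,Number=1,Type=Float,Description="Pooled minor allele frequency">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(calls: pd.DataFrame, path: str | Path) -> None:
    """Write variant calls as minimal VCF 4.2 (POS is 1-based in VCF)."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for _, row in calls.iterrows():
            info = []
            if row.get("class") == "somatic_mutation":
                info.append("SOMATIC")
                info.append(f"FETP={row['p_value']:.6g}")
                info.append(f"PAIR={row['pair_id']}")
            if pd.notna(row.get("pooled_maf", None)):
                info.append(f"MAF={row['pooled_maf']:.6g}")
            if pd.notna(row.get("direction", None)):
                info.append(f"DIR={row['direction']}")
            if pd.notna(row.get("base_change", None)):
                info.append(f"BCC={row['base_change']}")
            fh.write(
                f"{row['chrom']}\t{int(row['pos']) + 1}\t.\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t{';'.join(info) if info else '.'}\n"
            )


def read_vcf(path: str | Path) -> pd.DataFrame:
    """Read a minimal VCF back into the 0-based call table."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 8:
                raise InputError(f"{path}: short VCF line")
            info = dict(
                kv.split("=", 1) if "=" in kv else (kv, True) for kv in f[7].split(";") if kv != "."
            )
            rows.append(
                {
                    "chrom": f[0],
                    "pos": int(f[1]) - 1,
                    "ref": f[3],
                    "alt": f[4],
                    "class": "somatic_mutation" if "SOMATIC" in info else "polymorphism",
                    "p_value": float(info["FETP"]) if "FETP" in info else float("nan"),
                    "pair_id": info.get("PAIR"),
                    "pooled_maf": float(info["MAF"]) if "MAF" in info else float("nan"),
                    "direction": info.get("DIR"),
                    "base_change": info.get("BCC"),
                }
            )
    cols = [
        "chrom", "pos", "ref", "alt", "class", "p_value",
        "pair_id", "pooled_maf", "direction", "base_change",
    ]
    return pd.DataFrame(rows, columns=cols)
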