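"""Dinucleotide-context typing of variants and observed/expected enrichment.

Complementary strands are treated as one: the 16 dinucleotides collapse onto
10 strand-symmetric classes, and the four palindromic dinucleotides (ApT,
CpG, GpC, TpA) — which are their own reverse complement and would otherwise
be counted once where two-member classes are counted twice — are
double-counted for fair comparison.  Each variant contributes its two
reference-context dinucleotides: the -1 base with the variant position
(-1pV) and the variant position with the +1 base (Vp+1).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from twindisc.errors import InputError

logger = logging.getLogger(__name__)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


def _label(dinuc: str) -> str:
    rc = _revcomp(dinuc)
    lo, hi = sorted([dinuc, rc])
    p = lambda d: f"{d[0]}p{d[1]}"
    return p(lo) if lo == hi else f"{p(lo)}:{p(hi)}"


#: canonical class label for each of the 16 dinucleotides
DINUC_CLASS = {a + b: _label(a + b) for a in "ACGT" for b in "ACGT"}
#: the 10 strand-collapsed classes, in label order
DINUC_CLASSES = sorted(set(DINUC_CLASS.values()))
#: classes whose single member equals its own reverse complement
PALINDROMIC_CLASSES = [_label(d) for d in ("AT", "CG", "GC", "TA")]

BASE_CHANGE_CLASSES = [
    "C:G>T:A", "C:G>A:T", "C:G>G:C", "A:T>G:C", "A:T>C:G", "A:T>T:A",
]

CPG_CHANGE_CLASSES = ["CpG>TpG", "CpG>ApG", "CpG>GpG"]


def collapse_dinucleotide(dinuc: str) -> str:
    """Class label for a 2-mer; the label is the lexicographically smaller of
    the dinucleotide and its reverse complement."""
    dinuc = dinuc.upper()
    if len(dinuc) != 2 or any(b not in _COMP for b in dinuc):
        raise InputError(f"not an ACGT dinucleotide: {dinuc!r}")
    return DINUC_CLASS[dinuc]


def _empty_spectrum() -> pd.Series:
    return pd.Series(0, index=pd.Index(DINUC_CLASSES, name="dinuc_class"), dtype=int)


def _apply_palindrome_doubling(spec: pd.Series) -> pd.Series:
    out = spec.copy()
    out[PALINDROMIC_CLASSES] = out[PALINDROMIC_CLASSES] * 2
    return out


def count_sequence_dinucleotides(
    genome: dict[str, str] | str, regions: pd.DataFrame | None = None
) -> pd.Series:
    """Spectrum of all dinucleotide windows inside ``regions``.

    ``genome`` may be a plain sequence (regions optional) or a contig dict.
    Palindromic class totals are doubled.
    """
    if isinstance(genome, str):
        genome = {"seq": genome}
        if regions is None:
            regions = pd.DataFrame(
                [{"chrom": "seq", "start": 0, "end": len(genome["seq"])}]
            )
    elif regions is None:
        regions = pd.DataFrame(
            [{"chrom": c, "start": 0, "end": len(s)} for c, s in genome.items()]
        )
    spec = _empty_spectrum()
    counts: dict[str, int] = {}
    for _, r in regions.iterrows():
        seq = genome[r["chrom"]][int(r["start"]) : int(r["end"])].upper()
        for i in range(len(seq) - 1):
            d = seq[i : i + 2]
            if d in DINUC_CLASS:
                counts[DINUC_CLASS[d]] = counts.get(DINUC_CLASS[d], 0) + 1
    for k, v in counts.items():
        spec[k] = v
    return _apply_palindrome_doubling(spec)


def count_variant_dinucleotides(calls: pd.DataFrame, genome: dict[str, str]) -> pd.Series:
    """Spectrum of the reference-context dinucleotides of variant calls.

    Per variant, the -1pV and Vp+1 dinucleotides of the *reference* sequence
    contribute one count each; palindromic class totals are doubled.
    Variants at contig edges contribute only the available side.
    """
    spec = _empty_spectrum()
    for _, row in calls.iterrows():
        seq = genome[row["chrom"]]
        pos = int(row["pos"])
        if not (0 <= pos < len(seq)):
            raise InputError(f"variant {row['chrom']}:{pos} outside contig")
        if pos >= 1:
            spec[DINUC_CLASS[seq[pos - 1 : pos + 1].upper()]] += 1
        else:
            logger.info("variant at contig start: only Vp+1 counted")
        if pos + 2 <= len(seq):
            spec[DINUC_CLASS[seq[pos : pos + 2].upper()]] += 1
        else:
            logger.info("variant at contig end: only -1pV counted")
    return _apply_palindrome_doubling(spec)


def _frequencies(labels: pd.Series, classes: list[str]) -> pd.Series:
    counts = labels.value_counts().reindex(classes).fillna(0)
    total = counts.sum()
    if total == 0:
        raise InputError("no classified calls to compute frequencies")
    return counts / total


def base_change_oe(calls_tfbs: pd.DataFrame, calls_open: pd.DataFrame) -> pd.DataFrame:
    """Observed/expected per base-change class.

    Observed: class frequency among TFBS calls.  Expected: the overall class
    frequency among open-chromatin calls.  Direction-unclassified calls
    (no reference-homozygote configuration) are excluded.
    """
    if not len(calls_tfbs):
        raise InputError("empty TFBS call set")
    obs = _frequencies(calls_tfbs["base_change"].dropna(), BASE_CHANGE_CLASSES)
    exp = _frequencies(calls_open["base_change"].dropna(), BASE_CHANGE_CLASSES)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = obs / exp.replace(0, np.nan)
    return pd.DataFrame({"observed": obs, "expected": exp, "ratio": ratio})


def dinuc_relative_enrichment(
    spectrum_tfbs: pd.Series, spectrum_background: pd.Series
) -> pd.DataFrame:
    """Relative enrichment of each dinucleotide class in TFBSs.

    ratio_d = (n_d^TFBS / n_d^bg) / (N^TFBS / N^bg); the all-class ratio in
    the denominator controls for the different region sizes.  Classes absent
    from the background are flagged missing (NaN).
    """
    nt, nb = spectrum_tfbs.astype(float), spectrum_background.astype(float)
    size_ratio = nt.sum() / nb.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = (nt / nb.replace(0, np.nan)) / size_ratio
    return pd.DataFrame({"n_tfbs": spectrum_tfbs, "n_background": spectrum_background, "ratio": ratio})


def substituted_dinuc_oe(
    variant_spectrum_tfbs: pd.Series,
    variant_spectrum_open: pd.Series,
    seq_spectrum_tfbs: pd.Series,
    seq_spectrum_open: pd.Series,
) -> pd.DataFrame:
    """O/E of substituted dinucleotides in TFBSs.

    The relative enrichment of substituted dinucleotides in TFBSs (vs open
    chromatin) divided by the relative enrichment of the dinucleotides
    themselves.  All four spectra must use identical region definitions.
    """
    sub = dinuc_relative_enrichment(variant_spectrum_tfbs, variant_spectrum_open)["ratio"]
    seq = dinuc_relative_enrichment(seq_spectrum_tfbs, seq_spectrum_open)["ratio"]
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = sub / seq.replace(0, np.nan)
    return pd.DataFrame(
        {
            "sub_enrichment": sub,
            "seq_enrichment": seq,
            "ratio": ratio,
        }
    )


def cpg_substitution_oe(
    calls_tfbs: pd.DataFrame, calls_open: pd.DataFrame, genome: dict[str, str]
) -> pd.DataFrame:
    """O/E of the three CpG change classes (CpG>TpG, CpG>ApG, CpG>GpG).

    Restricted to calls whose reference context contains the CpG
    dinucleotide at the variant position; strand-collapsed (a G>A change at
    the G of a CpG is the CpG>TpG event seen from the other strand).
    """

    def cpg_classes(calls: pd.DataFrame) -> pd.Series:
        labels = []
        for _, row in calls.iterrows():
            seq = genome[row["chrom"]]
            pos = int(row["pos"])
            ref, alt = row["ref"].upper(), row["alt"].upper()
            if ref == "C" and pos + 1 < len(seq) and seq[pos + 1].upper() == "G":
                labels.append(f"CpG>{alt}pG")
            elif ref == "G" and pos >= 1 and seq[pos - 1].upper() == "C":
                labels.append(f"CpG>{_COMP[alt]}pG")
        return pd.Series(labels, dtype=object)

    obs_labels = cpg_classes(calls_tfbs)
    exp_labels = cpg_classes(calls_open)
    if not len(obs_labels) or not len(exp_labels):
        raise InputError("no CpG-context calls in one of the sets")
    obs = _frequencies(obs_labels, CPG_CHANGE_CLASSES)
    exp = _frequencies(exp_labels, CPG_CHANGE_CLASSES)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = obs / exp.replace(0, np.nan)
    return pd.DataFrame({"observed": obs, "expected": exp, "ratio": ratio})


def filter_chip_peaks_by_summit(peaks: list[dict], min_tag_fraction: float = 0.80):
    """Summit-focus filter for ChIP peaks.

    Each peak dict carries ``chrom``, ``start``, ``end`` and ``tags`` (a list
    of (start, end) tag intervals).  The summit is the position of maximal
    tag depth (leftmost on ties); a peak is retained iff at least
    ``min_tag_fraction`` of its tags overlap the summit.  Returns
    (retained peaks with a 'summit' key, discarded peaks).
    """
    retained, discarded = [], []
    for peak in peaks:
        tags = peak.get("tags", [])
        if not tags:
            logger.info("peak %s:%s-%s has no tags; discarded", peak.get("chrom"), peak.get("start"), peak.get("end"))
            discarded.append(peak)
            continue
        start, end = int(peak["start"]), int(peak["end"])
        depth = np.zeros(end - start, dtype=int)
        for ts, te in tags:
            lo, hi = max(ts, start) - start, min(te, end) - start
            if hi > lo:
                depth[lo:hi] += 1
        summit = start + int(np.argmax(depth))  # argmax is leftmost on ties
        covering = sum(1 for ts, te in tags if ts <= summit < te)
        if covering / len(tags) >= min_tag_fraction:
            retained.append({**peak, "summit": summit})
        else:
            discarded.append(peak)
    return retained, discarded
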