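import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import brute_force_dinuc_windows
from twindisc.errors import InputError
from twindisc.spectrum import (
    DINUC_CLASS,
    DINUC_CLASSES,
    PALINDROMIC_CLASSES,
    base_change_oe,
    collapse_dinucleotide,
    count_sequence_dinucleotides,
    count_variant_dinucleotides,
    cpg_substitution_oe,
    dinuc_relative_enrichment,
    filter_chip_peaks_by_summit,
    substituted_dinuc_oe,
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(s):
    return "".join(_COMP[b] for b in reversed(s))


class TestCollapse:
    def test_class_structure(self):
        assert len(DINUC_CLASSES) == 10
        assert set(PALINDROMIC_CLASSES) == {"ApT", "CpG", "GpC", "TpA"}

    @pytest.mark.parametrize(
        "dinuc,label",
        [("CG", "CpG"), ("CT", "ApG:CpT"), ("TT", "ApA:TpT"), ("CA", "CpA:TpG")],
    )
    def test_examples(self, dinuc, label):
        assert collapse_dinucleotide(dinuc) == label

    def test_revcomp_maps_to_same_class(self):
        for d in DINUC_CLASS:
            assert DINUC_CLASS[d] == DINUC_CLASS[_revcomp(d)]

    def test_non_acgt_rejected(self):
        with pytest.raises(InputError):
            collapse_dinucleotide("CN")


class TestSequenceCounting:
    def test_cgcg(self):
        spec = count_sequence_dinucleotides("CGCG")
        # windows CG, GC, CG; palindromes doubled
        assert spec["CpG"] == 4
        assert spec["GpC"] == 2
        assert spec.sum() == 6

    def test_aaaa(self):
        spec = count_sequence_dinucleotides("AAAA")
        assert spec["ApA:TpT"] == 3
        assert spec.sum() == 3

    def test_single_base_region(self):
        spec = count_sequence_dinucleotides("ACGTACGT", pd.DataFrame(
            [{"chrom": "seq", "start": 3, "end": 4}]))
        assert spec.sum() == 0

    @settings(max_examples=60, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=2, max_size=1000))
    def test_conservation_and_strand_symmetry(self, seq):
        spec = count_sequence_dinucleotides(seq)
        windows = brute_force_dinuc_windows(seq)
        n_palin = sum(v for d, v in windows.items() if d == _revcomp(d))
        n_other = sum(v for d, v in windows.items() if d != _revcomp(d))
        assert spec.sum() == n_other + 2 * n_palin
        assert spec.equals(count_sequence_dinucleotides(_revcomp(seq)))


class TestVariantCounting:
    def _calls(self, positions, chrom="c"):
        return pd.DataFrame([{"chrom": chrom, "pos": p} for p in positions])

    def test_middle_of_gaa(self):
        # GAA with middle A substituted: contexts GpA and ApA
        spec = count_variant_dinucleotides(self._calls([1]), {"c": "GAA"})
        assert spec["GpA:TpC"] == 1
        assert spec["ApA:TpT"] == 1
        assert spec.sum() == 2

    def test_palindromic_context_doubled(self):
        # ACG with middle C substituted: contexts ApC and CpG (doubled)
        spec = count_variant_dinucleotides(self._calls([1]), {"c": "ACG"})
        assert spec["ApC:GpT"] == 1
        assert spec["CpG"] == 2

    def test_contig_start_only_right_context(self):
        spec = count_variant_dinucleotides(self._calls([0]), {"c": "ACG"})
        assert spec["ApC:GpT"] == 1
        assert spec.sum() == 1


class TestEnrichmentRatios:
    def test_identical_spectra_all_one(self):
        calls = pd.DataFrame({"base_change": ["C:G>A:T"] * 5 + ["A:T>G:C"] * 5})
        out = base_change_oe(calls, calls.copy())
        present = out.dropna(subset=["ratio"])
        assert np.allclose(present["ratio"], 1.0)

    def test_twofold_enrichment(self):
        tfbs = pd.DataFrame({"base_change": ["C:G>A:T"] * 10 + ["C:G>T:A"] * 90})
        open_ = pd.DataFrame({"base_change": ["C:G>A:T"] * 5 + ["C:G>T:A"] * 95})
        out = base_change_oe(tfbs, open_)
        assert out.loc["C:G>A:T", "ratio"] == pytest.approx(2.0)

    def test_empty_tfbs_rejected(self):
        with pytest.raises(InputError):
            base_change_oe(pd.DataFrame({"base_change": []}), pd.DataFrame({"base_change": ["C:G>A:T"]}))

    def test_uniform_subsample_ratio_one(self):
        spec = count_sequence_dinucleotides("ACGTTGCA" * 50)
        out = dinuc_relative_enrichment(spec, spec * 3)
        assert np.allclose(out["ratio"].dropna(), 1.0)

    def test_missing_background_class_flagged(self):
        spec = count_sequence_dinucleotides("ACGT")
        bg = spec.copy()
        bg["CpG"] = 0
        out = dinuc_relative_enrichment(spec, bg)
        assert np.isnan(out.loc["CpG", "ratio"])

    def test_palindrome_doubling_cancels_in_ratio(self):
        seq_t, seq_b = "CGCGAATT" * 20, "CGAATTCG" * 40
        out = dinuc_relative_enrichment(
            count_sequence_dinucleotides(seq_t), count_sequence_dinucleotides(seq_b)
        )

        def raw_ratio(d):
            wt = brute_force_dinuc_windows(seq_t)
            wb = brute_force_dinuc_windows(seq_b)
            cls_t = sum(v for k, v in wt.items() if k in (d, _revcomp(d)) or (d == _revcomp(d) and k == d))
            cls_b = sum(v for k, v in wb.items() if k in (d, _revcomp(d)) or (d == _revcomp(d) and k == d))
            n_t = sum(2 * v if k == _revcomp(k) else v for k, v in wt.items())
            n_b = sum(2 * v if k == _revcomp(k) else v for k, v in wb.items())
            scale_t = 2 if d == _revcomp(d) else 1
            return (scale_t * cls_t / (scale_t * cls_b)) / (n_t / n_b)

        # doubling scales numerator and denominator counts identically
        assert out.loc["CpG", "ratio"] == pytest.approx(raw_ratio("CG"))

    def test_substituted_oe_single_class_fixture(self):
        one = pd.Series(0, index=pd.Index(DINUC_CLASSES))
        one["CpG"] = 10
        seq = one.copy()
        seq["CpG"] = 100
        out = substituted_dinuc_oe(one, one * 3, seq, seq * 5)
        assert out.loc["CpG", "ratio"] == pytest.approx(1.0)

    def test_substituted_oe_depletion(self):
        # CpG substitutions depleted 5x in TFBS relative to sequence enrichment
        sub_t = pd.Series([10, 40], index=["CpG", "ApA:TpT"]).reindex(DINUC_CLASSES).fillna(0)
        sub_o = pd.Series([50, 40], index=["CpG", "ApA:TpT"]).reindex(DINUC_CLASSES).fillna(0)
        seq = pd.Series([100, 100], index=["CpG", "ApA:TpT"]).reindex(DINUC_CLASSES).fillna(0)
        out = substituted_dinuc_oe(sub_t, sub_o, seq, seq)
        # sub enrichment of CpG = (10/50)/(50/90); seq enrichment = 1
        assert out.loc["CpG", "ratio"] == pytest.approx((10 / 50) / (50 / 90))
        assert out.loc["ApA:TpT", "ratio"] == pytest.approx((40 / 40) / (50 / 90))

    def test_random_substitution_placement_near_one(self):
        # substitutions placed uniformly over dinucleotide occurrences -> ratios ~ 1
        rng = np.random.default_rng(21)
        ratios = []
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=4000))
            genome = {"c": seq}
            cut = 2000
            tfbs = pd.DataFrame([{"chrom": "c", "start": 0, "end": cut}])
            open_ = pd.DataFrame([{"chrom": "c", "start": cut, "end": 4000}])
            pos = rng.choice(np.arange(1, 3999), size=800, replace=False)
            calls = pd.DataFrame({"chrom": "c", "pos": pos})
            vt = count_variant_dinucleotides(calls[calls["pos"] < cut], genome)
            vo = count_variant_dinucleotides(calls[calls["pos"] >= cut], genome)
            st_ = count_sequence_dinucleotides(genome, tfbs)
            so = count_sequence_dinucleotides(genome, open_)
            ratios.append(substituted_dinuc_oe(vt, vo, st_, so)["ratio"])
        mean_ratio = pd.concat(ratios, axis=1).mean(axis=1)
        assert (np.abs(mean_ratio.dropna() - 1.0) < 0.1).all()


class TestCpGChangeOE:
    def test_strand_collapsed_classes(self):
        genome = {"c": "ACGTCGA"}
        # C>T at pos 1 (CpG context) and G>A at pos 5 (preceded by C)
        tfbs_calls = pd.DataFrame(
            [
                {"chrom": "c", "pos": 1, "ref": "C", "alt": "T"},
                {"chrom": "c", "pos": 5, "ref": "G", "alt": "A"},
            ]
        )
        open_calls = pd.DataFrame(
            [
                {"chrom": "c", "pos": 1, "ref": "C", "alt": "T"},
                {"chrom": "c", "pos": 4, "ref": "C", "alt": "A"},
            ]
        )
        out = cpg_substitution_oe(tfbs_calls, open_calls, genome)
        # both TFBS calls are CpG>TpG (G>A on the minus strand is C>T)
        assert out.loc["CpG>TpG", "observed"] == pytest.approx(1.0)
        assert out.loc["CpG>TpG", "expected"] == pytest.approx(0.5)
        assert out.loc["CpG>TpG", "ratio"] == pytest.approx(2.0)


class TestSummitFilter:
    def _peak(self, tags):
        return {"chrom": "c", "start": 0, "end": 100, "tags": tags}

    def test_all_tags_at_summit_retained(self):
        retained, discarded = filter_chip_peaks_by_summit([self._peak([(10, 50)] * 5)])
        assert len(retained) == 1 and not discarded
        assert retained[0]["summit"] == 10  # leftmost maximal position

    def test_seven_of_ten_discarded(self):
        tags = [(10, 50)] * 7 + [(60, 90)] * 3
        retained, discarded = filter_chip_peaks_by_summit([self._peak(tags)])
        assert not retained and len(discarded) == 1

    def test_exactly_eighty_percent_retained(self):
        tags = [(10, 50)] * 8 + [(60, 90)] * 2
        retained, _ = filter_chip_peaks_by_summit([self._peak(tags)])
        assert len(retained) == 1

    def test_zero_tags_discarded(self):
        retained, discarded = filter_chip_peaks_by_summit([self._peak([])])
        assert not retained and len(discarded) == 1
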