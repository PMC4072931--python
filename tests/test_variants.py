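import numpy as np
import pandas as pd
import pytest

from _oracles import fisher_oracle
from twindisc.accessibility import AccessibilityMatrix
from twindisc.cohort import TwinCohort
from twindisc.errors import InputError
from twindisc.synthetic import generate_allele_table
from twindisc.variants import (
    annotate_mutation_peak_context,
    associate_snp_accessibility,
    base_change_class,
    call_polymorphisms,
    call_somatic_mutations,
    classify_base_change,
    fisher_exact_two_sided,
)


def _pairing(n_pairs=1):
    samples = [f"s{p}{s}" for p in range(n_pairs) for s in "ab"]
    return TwinCohort(
        pd.DataFrame(
            {
                "sample_id": samples,
                "pair_id": [f"p{p}" for p in range(n_pairs) for _ in "ab"],
                "sibling": [s for _ in range(n_pairs) for s in (1, 2)],
            }
        )
    )


def _allele_row(sample, pos=100, ref="A", alt="C", fwd_ref=0, rev_ref=0, fwd_alt=0,
                rev_alt=0, hq_fwd=None, hq_rev=None):
    hq_fwd = fwd_ref + fwd_alt if hq_fwd is None else hq_fwd
    hq_rev = rev_ref + rev_alt if hq_rev is None else hq_rev
    return {
        "chrom": "chr1", "pos": pos, "ref": ref, "alt": alt, "sample": sample,
        "fwd_ref": fwd_ref, "rev_ref": rev_ref, "fwd_alt": fwd_alt, "rev_alt": rev_alt,
        "hq_fwd": hq_fwd, "hq_rev": hq_rev,
    }


class TestFisher:
    def test_symmetric_table(self):
        assert fisher_exact_two_sided([[5, 5], [5, 5]]) == 1.0

    def test_diagonal_table_matches_enumeration(self):
        # 2 / C(20,10) = 1.0825e-5, frozen from the enumeration oracle
        p = fisher_exact_two_sided([[10, 0], [0, 10]])
        assert p == pytest.approx(1.0825088224469003e-05, abs=1e-12)
        assert p == pytest.approx(fisher_oracle(10, 0, 0, 10), abs=1e-12)

    def test_degenerate_margins(self):
        assert fisher_exact_two_sided([[0, 0], [0, 0]]) == 1.0

    def test_negative_entry_rejected(self):
        with pytest.raises(InputError):
            fisher_exact_two_sided([[1, -1], [0, 0]])

    def test_matches_oracle_on_random_tables(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 13, size=4)
            assert fisher_exact_two_sided([[a, b], [c, d]]) == pytest.approx(
                fisher_oracle(a, b, c, d), abs=1e-12
            )


class TestBaseChangeClass:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            ("C", "A", "C:G>A:T"),
            ("G", "T", "C:G>A:T"),
            ("G", "A", "C:G>T:A"),
            ("C", "T", "C:G>T:A"),
            ("A", "G", "A:T>G:C"),
            ("T", "G", "A:T>C:G"),
            ("A", "T", "A:T>T:A"),
        ],
    )
    def test_strand_collapse(self, ref, alt, expected):
        assert base_change_class(ref, alt) == expected

    def test_unclassified_when_no_reference_homozygote(self):
        assert classify_base_change("C", "A", reference_homozygous=False) is None


class TestSomaticCaller:
    def test_clear_mutation_called(self):
        rows = [
            _allele_row("s0a", fwd_ref=10, rev_ref=10),
            _allele_row("s0b", fwd_ref=1, rev_ref=1, fwd_alt=9, rev_alt=9),
        ]
        calls = call_somatic_mutations(pd.DataFrame(rows), _pairing())
        assert len(calls) == 1
        row = calls.iloc[0]
        assert row["pair_id"] == "p0"
        assert row["carrier_sample"] == "s0b"
        # Fisher on [[20,0],[2,18]] from the enumeration oracle
        assert row["p_value"] == pytest.approx(fisher_oracle(20, 0, 2, 18), rel=1e-9)
        assert row["base_change"] == "A:T>C:G"  # co-twin is reference homozygote

    def test_nine_hq_reads_on_one_strand_rejected(self):
        rows = [
            _allele_row("s0a", fwd_ref=10, rev_ref=10, hq_fwd=9),  # below threshold
            _allele_row("s0b", fwd_ref=1, rev_ref=1, fwd_alt=9, rev_alt=9),
        ]
        assert call_somatic_mutations(pd.DataFrame(rows), _pairing()).empty

    def test_identical_siblings_not_called(self):
        rows = [
            _allele_row("s0a", fwd_ref=10, rev_ref=10, fwd_alt=5, rev_alt=5),
            _allele_row("s0b", fwd_ref=10, rev_ref=10, fwd_alt=5, rev_alt=5),
        ]
        assert call_somatic_mutations(pd.DataFrame(rows), _pairing()).empty

    def test_variant_on_single_strand_of_carrier_rejected(self):
        rows = [
            _allele_row("s0a", fwd_ref=15, rev_ref=15),
            _allele_row("s0b", fwd_ref=2, rev_ref=15, fwd_alt=13, rev_alt=0),
        ]
        assert call_somatic_mutations(pd.DataFrame(rows), _pairing()).empty

    def test_sibling_swap_symmetry(self):
        alleles, pairing, _ = generate_allele_table(
            n_positions=60, n_pairs=4, depth=60, n_mutations=15, seed=9
        )
        calls = call_somatic_mutations(alleles, pairing)
        swapped = pairing.pairs.copy()
        swapped["sibling"] = 3 - swapped["sibling"]
        calls_swapped = call_somatic_mutations(alleles, TwinCohort(swapped))
        key = ["chrom", "pos", "pair_id", "p_value", "carrier_sample"]
        assert calls[key].equals(calls_swapped[key])
        assert len(calls) > 0

    def test_position_missing_one_sibling_skipped(self):
        rows = [_allele_row("s0a", fwd_ref=10, rev_ref=10)]
        assert call_somatic_mutations(pd.DataFrame(rows), _pairing()).empty


class TestPolymorphismCaller:
    def _cohort_rows(self, alt_reads_by_sample, depth=50):
        """One position; alt_reads_by_sample maps sample -> (fwd_alt, rev_alt)."""
        rows = []
        for s in ["s0a", "s0b", "s1a", "s1b"]:
            fa, ra = alt_reads_by_sample.get(s, (0, 0))
            n_ref = depth - fa - ra
            rows.append(
                _allele_row(s, fwd_ref=n_ref // 2, rev_ref=n_ref - n_ref // 2,
                            fwd_alt=fa, rev_alt=ra)
            )
        return pd.DataFrame(rows)

    def test_maf_boundary(self):
        # total reads 200; 2 alt reads = exactly 1% -> retained
        at = call_polymorphisms(self._cohort_rows({"s0a": (1, 1)}), _pairing(2))
        assert len(at) == 1
        assert at["pooled_maf"].iloc[0] == pytest.approx(0.01)

    def test_below_maf_rejected(self):
        # 2 alt of 222 reads = 0.9% -> rejected
        rows = self._cohort_rows({"s0a": (1, 1)})
        extra = rows.index[rows["sample"] == "s0b"]
        rows.loc[extra, "fwd_ref"] += 22
        assert call_polymorphisms(rows, _pairing(2)).empty

    def test_one_strand_carriers_filtered(self):
        # all variant reads forward-strand in every carrier -> artifact
        rows = self._cohort_rows({"s0a": (6, 0), "s1b": (4, 0)})
        assert call_polymorphisms(rows, _pairing(2)).empty

    def test_zero_coverage_sample_excludes_position(self):
        rows = self._cohort_rows({"s0a": (5, 5)})
        i = rows.index[rows["sample"] == "s1b"]
        for c in ["fwd_ref", "rev_ref", "fwd_alt", "rev_alt", "hq_fwd", "hq_rev"]:
            rows.loc[i, c] = 0
        assert call_polymorphisms(rows, _pairing(2)).empty

    def test_somatic_positions_excluded(self):
        rows = self._cohort_rows({"s0a": (10, 10)})
        somatic = pd.DataFrame([{"chrom": "chr1", "pos": 100}])
        assert call_polymorphisms(rows, _pairing(2), somatic_calls=somatic).empty

    def test_contig_allowlist(self):
        rows = self._cohort_rows({"s0a": (5, 5), "s0b": (5, 5)})
        assert call_polymorphisms(rows, _pairing(2), contigs=["chr2"]).empty


class TestMutationContext:
    def test_distance_and_density(self):
        peaks = pd.DataFrame(
            {"chrom": ["chr1"], "start": [100], "end": [300]}, index=["chr1:100-300"]
        )
        calls = pd.DataFrame(
            [
                {"chrom": "chr1", "pos": 200, "class": "somatic_mutation"},
                {"chrom": "chr1", "pos": 150, "class": "somatic_mutation"},
                {"chrom": "chr1", "pos": 250, "class": "somatic_mutation"},
                {"chrom": "chr1", "pos": 999, "class": "somatic_mutation"},
            ]
        )
        out = annotate_mutation_peak_context(calls, peaks)
        assert out.loc[0, "distance_to_center"] == 0  # at the center
        assert out.loc[1, "distance_to_center"] == 50
        assert out.loc[0, "mutations_per_bp"] == pytest.approx(3 / 200)
        assert not out.loc[3, "in_peak"]  # outside all peaks, flagged


class TestSnpAccessibilityAssociation:
    def _setup(self, dosages, y, depth=40):
        samples = [f"s{p}{s}" for p in range(len(dosages) // 2) for s in "ab"]
        rows = []
        for s, d in zip(samples, dosages):
            fa = int(d / 2 * depth / 2)
            ra = int(d / 2 * depth) - fa
            nr = depth - fa - ra
            rows.append(_allele_row(s, pos=150, fwd_ref=nr // 2, rev_ref=nr - nr // 2,
                                    fwd_alt=fa, rev_alt=ra))
        alleles = pd.DataFrame(rows)
        peaks = pd.DataFrame(
            {"chrom": ["chr1"], "start": [100], "end": [200]}, index=["chr1:100-200"]
        )
        values = pd.DataFrame([y], index=["chr1:100-200"], columns=samples)
        mat = AccessibilityMatrix(values=values, sample_totals=values.sum(axis=0), genome_size=1.0)
        snps = pd.DataFrame([{"chrom": "chr1", "pos": 150}])
        return snps, alleles, mat, peaks

    def test_perfect_linear_fit_significant(self):
        dosages = [0, 0, 1, 1, 2, 2, 0, 1]
        y = [1.0 + 2.0 * d for d in dosages]
        out = associate_snp_accessibility(*self._setup(dosages, y))
        assert out["significant"].iloc[0]
        assert out["slope"].iloc[0] == pytest.approx(2.0)

    def test_constant_dosage_skipped(self):
        dosages = [1, 1, 1, 1, 1, 1, 1, 1]
        with pytest.warns(UserWarning):
            out = associate_snp_accessibility(*self._setup(dosages, list(range(8))))
        assert out.empty

    def test_null_calibration(self):
        # permuted genotypes: fraction with p < 0.05 should be ~5%
        rng = np.random.default_rng(12)
        n_samples, n_snps = 60, 1000
        from scipy import stats

        hits = 0
        for _ in range(n_snps):
            d = rng.binomial(2, 0.3, n_samples).astype(float)
            y = rng.normal(size=n_samples)
            if d.var() == 0:
                continue
            hits += stats.linregress(d, y).pvalue < 0.05
        assert 0.03 <= hits / n_snps <= 0.07
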