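"""Genetic code structure, codon counting, RSCU and the start/stop census."""

from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocub.codon import (
    INVERTEBRATE_MITO,
    CodonCounts,
    GeneticCode,
    classify_rscu,
    compute_rscu,
    count_codons,
    mean_rscu,
    start_stop_census,
)
from mitocub.errors import ConfigError, MitocubError
from mitocub.io import CodingSeq


def make_cds(trimmed: str, stop_kind: str = "complete", stop: str = "TAA") -> CodingSeq:
    nt = trimmed + (stop if stop_kind == "complete"
                    else "TA" if stop_kind == "incomplete_TA" else "T")
    return CodingSeq(gene="X", nt=nt, start_codon=trimmed[:3],
                     stop_kind=stop_kind, stop_codon=stop if stop_kind == "complete"
                     else nt[len(trimmed):], trimmed_nt=trimmed)


class TestGeneticCodeStructure:
    """The invertebrate mitochondrial code (table 5)."""

    def test_exactly_62_sense_codons(self):
        assert len(INVERTEBRATE_MITO.sense_codons) == 62

    def test_stop_set(self):
        assert INVERTEBRATE_MITO.stop_codons == {"TAA", "TAG"}

    def test_family_size_multiset(self):
        sizes = Counter(len(f) for f in INVERTEBRATE_MITO.families().values())
        assert sizes == {2: 12, 4: 6, 6: 1, 8: 1}

    def test_families_partition_sense_codons(self):
        seen = [c for fam in INVERTEBRATE_MITO.families().values() for c in fam]
        assert sorted(seen) == sorted(INVERTEBRATE_MITO.sense_codons)
        assert len(seen) == len(set(seen))

    def test_table5_reassignments(self):
        code = INVERTEBRATE_MITO.codon_to_aa
        assert code["TGA"] == "W"
        assert code["ATA"] == "M"
        assert code["AGA"] == "S" and code["AGG"] == "S"


class TestCountCodons:
    def test_simple_gene(self):
        counts = count_codons([make_cds("ATGAAA")])
        assert counts.counts == {"ATG": 1, "AAA": 1}
        assert counts.n_sense == 2

    def test_additivity_doubling(self):
        one = count_codons([make_cds("ATGAAATTT")])
        two = count_codons([make_cds("ATGAAATTT")] * 2)
        assert two.counts == Counter(
            {k: 2 * v for k, v in one.counts.items()}
        )

    def test_stop_and_incomplete_tail_excluded(self):
        counts = count_codons([make_cds("ATGAAA", stop_kind="incomplete_T")])
        assert counts.n_sense == 2

    def test_synthetic_pcgs_total(self):
        from mitocub.synth import simulate_codingseqs

        freqs = {c: 1 / 62 for c in INVERTEBRATE_MITO.sense_codons}
        cds, _ = simulate_codingseqs(freqs, n_genes=13, codons_per_gene=100, seed=5)
        assert count_codons(cds).n_sense == 1300

    def test_frame_violation_detected(self):
        bad = CodingSeq(gene="X", nt="ATGAA", start_codon="ATG",
                        stop_kind="complete", stop_codon="TAA", trimmed_nt="ATGA")
        with pytest.raises(MitocubError):
            count_codons([bad])


class TestRscu:
    def test_lys_family_three_to_one(self):
        counts = CodonCounts("t", Counter({"AAA": 3, "AAG": 1}))
        by_codon = {e.codon: e.rscu for e in compute_rscu(counts)}
        assert by_codon["AAA"] == pytest.approx(1.5)
        assert by_codon["AAG"] == pytest.approx(0.5)

    def test_uniform_within_families_gives_all_ones(self):
        counts = CodonCounts("t", Counter({c: 4 for c in INVERTEBRATE_MITO.sense_codons}))
        for e in compute_rscu(counts):
            assert e.rscu == pytest.approx(1.0)
            assert e.bias_class == "unbiased"

    def test_unobserved_family_is_undefined(self):
        counts = CodonCounts("t", Counter({"AAA": 3}))
        entries = {e.codon: e for e in compute_rscu(counts)}
        assert entries["TTT"].rscu is None
        assert entries["TTT"].bias_class == "undefined"

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=50), min_size=62, max_size=62))
    def test_family_sums_equal_family_size(self, raw):
        counts = CodonCounts(
            "t", Counter(dict(zip(INVERTEBRATE_MITO.sense_codons, raw)))
        )
        if counts.n_sense == 0:
            return
        entries = {e.codon: e for e in compute_rscu(counts)}
        for fam in INVERTEBRATE_MITO.families().values():
            vals = [entries[c].rscu for c in fam]
            if any(v is not None for v in vals):
                assert sum(vals) == pytest.approx(len(fam))

    def test_scale_invariance(self):
        base = Counter({"AAA": 3, "AAG": 1, "TTT": 7, "TTC": 2})
        r1 = {e.codon: e.rscu for e in compute_rscu(CodonCounts("a", base))}
        scaled = Counter({k: 5 * v for k, v in base.items()})
        r2 = {e.codon: e.rscu for e in compute_rscu(CodonCounts("b", scaled))}
        for c in base:
            assert r1[c] == pytest.approx(r2[c])


class TestClassifyRscu:
    @pytest.mark.parametrize(
        "rscu,expected",
        [
            (1.7, "overrepresented"),
            (0.5, "underrepresented"),
            (1.6, "unbiased"),  # strict >
            (0.6, "unbiased"),  # strict <
            (1.0, "unbiased"),
        ],
    )
    def test_thresholds(self, rscu, expected):
        counts = CodonCounts("t", Counter({"AAA": 1}))
        entries = compute_rscu(counts)
        from mitocub.codon import RscuEntry

        entry = RscuEntry("AAA", "K", 1, rscu, "unbiased")
        (out,) = classify_rscu([entry])
        assert out.bias_class == expected

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ConfigError):
            classify_rscu([], hi=0.5, lo=0.6)
        with pytest.raises(ConfigError):
            classify_rscu([], hi=1.6, lo=0.0)


class TestPooling:
    def test_mean_rscu_is_mean_of_vectors_not_rscu_of_sums(self):
        a = CodonCounts("a", Counter({"AAA": 30, "AAG": 10}))  # rscu 1.5/0.5
        b = CodonCounts("b", Counter({"AAA": 1, "AAG": 1}))  # rscu 1.0/1.0
        pooled = mean_rscu([compute_rscu(a), compute_rscu(b)]).set_index("codon")
        assert pooled.loc["AAA", "mean_rscu"] == pytest.approx(1.25)
        # rscu of summed counts differs: 31/16 vs 11/16 scaled -> 1.9375
        summed = {e.codon: e.rscu for e in compute_rscu(a + b)}
        assert summed["AAA"] == pytest.approx(2 * 31 / 42)
        assert pooled.loc["AAA", "mean_rscu"] != pytest.approx(summed["AAA"])


class TestCensus:
    def test_start_binning(self):
        genes = [make_cds(s + "AAA") for s in ("ATG", "ATA", "TTG")]
        starts, _ = start_stop_census(genes)
        assert starts == {"ATG": 1, "ATA": 1, "TTG": 1}

    def test_incomplete_stop_bins(self):
        genes = [
            make_cds("ATGAAA", stop_kind="incomplete_T"),
            make_cds("ATGAAA", stop_kind="incomplete_TA"),
            make_cds("ATGAAA", stop="TAG"),
        ]
        _, stops = start_stop_census(genes)
        assert stops == {"T-": 1, "TA-": 1, "TAG": 1}

    def test_start_counts_conserved(self, default_synth):
        genome, truth = default_synth
        from mitocub.io import coding_seqs

        starts, stops = start_stop_census(coding_seqs(genome))
        assert sum(starts.values()) == 13
        assert sum(stops.values()) == 13
        assert dict(starts) == truth.start_census
        assert dict(stops) == truth.stop_census

    def test_empty_list_error(self):
        with pytest.raises(MitocubError):
            start_stop_census([])
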