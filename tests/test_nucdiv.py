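"""Nucleotide diversity: global, windowed, per-partition, deletion modes."""

import itertools
import warnings

import numpy as np
import pytest

from mitocub.errors import InsufficientDataError, UndefinedStatisticError
from mitocub.nucdiv import (
    MultiAlignment,
    nucleotide_diversity,
    per_partition_pi,
    pi_with_sites,
    read_alignment,
    sliding_window_pi,
)


def brute_force_pi(rows: list[str]) -> float:
    """Direct enumeration over all unordered pairs with pairwise deletion."""
    ratios = []
    for a, b in itertools.combinations(rows, 2):
        diffs = compared = 0
        for x, y in zip(a, b):
            if x in "ACGT" and y in "ACGT":
                compared += 1
                diffs += x != y
        if compared:
            ratios.append(diffs / compared)
    return sum(ratios) / len(ratios)


def aln_of(rows, partitions=None):
    return MultiAlignment(
        taxa=[f"t{i}" for i in range(len(rows))], rows=rows,
        partitions=partitions or {},
    )


class TestGlobalPi:
    def test_two_rows_one_difference(self):
        assert nucleotide_diversity(aln_of(["AAAAAAAAAA", "AAAAAAAAAC"])) == pytest.approx(0.1)

    def test_identical_rows(self):
        assert nucleotide_diversity(aln_of(["ACGT" * 5] * 4)) == 0.0

    @pytest.mark.parametrize("n_rows", [3, 4, 6])
    def test_matches_brute_force_enumeration(self, n_rows):
        rng = np.random.default_rng(n_rows)
        alphabet = np.array(list("ACGTN-"))
        rows = [
            "".join(rng.choice(alphabet, p=[0.22, 0.22, 0.22, 0.22, 0.06, 0.06],
                               size=50))
            for _ in range(n_rows)
        ]
        assert nucleotide_diversity(aln_of(rows)) == pytest.approx(brute_force_pi(rows))

    def test_pairwise_vs_complete_deletion(self):
        # column 2 has a gap in row c only: pairwise keeps it for pair (a,b)
        rows = ["AACA", "AAGA", "AA-A"]
        pairwise = nucleotide_diversity(aln_of(rows), deletion="pairwise")
        complete = nucleotide_diversity(aln_of(rows), deletion="complete")
        # pairwise: (a,b): 1/4; (a,c): 0/3; (b,c): 0/3 -> mean = 1/12
        assert pairwise == pytest.approx(1 / 12)
        # complete drops column 2 entirely: all pairs identical on AAA
        assert complete == 0.0

    def test_undefined_when_no_comparable_pair(self):
        with pytest.raises(UndefinedStatisticError):
            nucleotide_diversity(aln_of(["N-", "-N"]))

    def test_invariant_to_row_and_column_order(self):
        rng = np.random.default_rng(9)
        rows = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(5)]
        base = nucleotide_diversity(aln_of(rows))
        assert nucleotide_diversity(aln_of(rows[::-1])) == pytest.approx(base)
        perm = rng.permutation(40)
        shuffled = ["".join(r[i] for i in perm) for r in rows]
        assert nucleotide_diversity(aln_of(shuffled)) == pytest.approx(base)

    def test_duplicating_a_row_cannot_increase_pi(self):
        rows = ["AAAA", "AACA", "TACA"]
        base = nucleotide_diversity(aln_of(rows))
        dup = nucleotide_diversity(aln_of(rows + [rows[0]]))
        assert dup <= base + 1e-12

    def test_fewer_than_two_rows_rejected(self):
        with pytest.raises(InsufficientDataError):
            aln_of(["ACGT"])


class TestSlidingWindow:
    def test_window_equal_to_length_gives_global_pi(self):
        rows = ["AAAAAAAAAC", "AAAAAAAAAA"]
        (w,) = sliding_window_pi(aln_of(rows), window=10, step=10)
        assert w.pi == pytest.approx(nucleotide_diversity(aln_of(rows)))
        assert (w.start, w.end) == (0, 10)

    def test_400_columns_window_200_step_20(self):
        rng = np.random.default_rng(1)
        rows = ["".join(rng.choice(list("ACGT"), size=400)) for _ in range(3)]
        windows = sliding_window_pi(aln_of(rows), window=200, step=20)
        assert len(windows) == 11
        assert (windows[0].start, windows[0].end) == (0, 200)
        assert (windows[-1].start, windows[-1].end) == (200, 400)

    def test_all_identical_alignment_every_window_zero(self):
        rows = ["ACGT" * 100] * 3
        assert all(w.pi == 0.0 for w in sliding_window_pi(aln_of(rows)))

    def test_window_longer_than_alignment_truncates_with_warning(self):
        rows = ["AAAAAAAAAC", "AAAAAAAAAA"]
        with pytest.warns(UserWarning, match="truncated"):
            windows = sliding_window_pi(aln_of(rows), window=50, step=20)
        assert len(windows) == 1
        assert windows[0].end == 10

    def test_window_pi_bounded_by_column_extremes(self):
        rng = np.random.default_rng(4)
        rows = ["".join(rng.choice(list("ACGT"), size=300)) for _ in range(4)]
        aln = aln_of(rows)
        col_pis = [nucleotide_diversity(aln, [i]) for i in range(300)]
        for w in sliding_window_pi(aln, window=100, step=50):
            window_cols = col_pis[w.start:w.end]
            assert min(window_cols) - 1e-12 <= w.pi <= max(window_cols) + 1e-12

    def test_bad_window_step_rejected(self):
        with pytest.raises(ValueError):
            sliding_window_pi(aln_of(["AC", "AG"]), window=2, step=3)


class TestPerPartition:
    def test_invariant_gene_is_argmin(self):
        rows = ["AAAA" + "ACGT", "AAAA" + "TGCA"]
        parts = {"geneA": [(0, 4)], "geneB": [(4, 8)]}
        by_gene, hi, lo = per_partition_pi(aln_of(rows, parts))
        assert by_gene["geneA"] == 0.0
        assert (hi, lo) == ("geneB", "geneA")

    def test_rate_order_matches_rank_order(self):
        from mitocub.synth import simulate_alignment

        parts = {"slow": [(0, 2000)], "mid": [(2000, 4000)], "fast": [(4000, 6000)]}
        aln, truth = simulate_alignment(
            10, 6000, [0.02, 0.10, 0.30], seed=17, partitions=parts
        )
        by_gene, hi, lo = per_partition_pi(aln)
        assert by_gene["slow"] < by_gene["mid"] < by_gene["fast"]
        assert (hi, lo) == ("fast", "slow")

    def test_single_partition_spanning_everything_equals_global(self):
        rng = np.random.default_rng(8)
        rows = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(4)]
        aln = aln_of(rows, {"all": [(0, 60)]})
        by_gene, _, _ = per_partition_pi(aln)
        assert by_gene["all"] == pytest.approx(nucleotide_diversity(aln))

    def test_empty_partition_skipped_with_warning(self):
        rows = ["ACGTAC", "TGCAAC"]
        aln = aln_of(rows, {"good": [(0, 4)]})
        aln.partitions["bad"] = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            by_gene, _, _ = per_partition_pi(aln)
        assert "bad" not in by_gene

    def test_no_partitions_error(self):
        with pytest.raises(InsufficientDataError):
            per_partition_pi(aln_of(["AC", "AG"]))


class TestFileBoundary:
    def test_read_alignment_converts_1_based_inclusive(self, tmp_path):
        fasta = tmp_path / "aln.fasta"
        fasta.write_text(">a\nACGTACGT\n>b\nACGTTCGT\n")
        parts = tmp_path / "parts.tsv"
        parts.write_text("gene\tstart\tend\ngene1\t1\t4\ngene2\t5\t8\n")
        aln = read_alignment(str(fasta), str(parts))
        assert aln.partitions == {"gene1": [(0, 4)], "gene2": [(4, 8)]}
        assert aln.n_columns == 8

    def test_n_sites_used_with_missing_data(self):
        rows = ["ACGTNN", "ACCT--"]
        pi, used = pi_with_sites(aln_of(rows))
        assert used == 4
        assert pi == pytest.approx(1 / 4)
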