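"""Representative fragments, canonical k-mer counting, fCGR grids."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import extremosig as es
from extremosig.signatures import revcomp, _pixel

from conftest import random_dna


def naive_signature(s: str, k: int) -> list[int]:
    """Independent oracle: enumerate every window of s and of revcomp(s)."""
    counts = Counter()
    for seq in (s.upper(), revcomp(s.upper())):
        for i in range(len(seq) - k + 1):
            w = seq[i:i + k]
            if "N" in w:
                continue
            counts[min(w, revcomp(w))] += 1
    return [counts.get(w, 0) for w in es.canonical_kmer_list(k)]


class TestFragmentSelection:
    def test_window_from_long_contig(self):
        rng = np.random.default_rng(1)
        contig = random_dna(rng, 600_000)
        cs = es.ContigSet("a1", [contig])
        frag = es.select_fragment(cs, target_len=500_000, seed=7)
        assert frag.effective_length == 500_000
        assert frag.selection_mode == "single-contig-window"
        assert len(frag.sequence) == 500_000
        assert frag.sequence in contig

    def test_concatenation_with_separator(self):
        rng = np.random.default_rng(2)
        long, short = random_dna(rng, 300_000), random_dna(rng, 250_000)
        cs = es.ContigSet("a2", [short, long])  # unsorted on purpose
        frag = es.select_fragment(cs, target_len=500_000, seed=0)
        assert frag.selection_mode == "concatenation"
        assert frag.sequence == long + "N" + short[:200_000]
        assert frag.effective_length == 500_000
        assert frag.sequence.count("N") == 1

    def test_insufficient_sequence(self):
        rng = np.random.default_rng(3)
        cs = es.ContigSet("a3", [random_dna(rng, 400_000)])
        with pytest.raises(es.InsufficientSequence):
            es.select_fragment(cs, target_len=500_000, seed=0)

    def test_empty_assembly(self):
        with pytest.raises(es.EmptyAssembly):
            es.ContigSet("a4", [])

    def test_window_offset_deterministic_and_seed_dependent(self):
        rng = np.random.default_rng(4)
        contig = random_dna(rng, 60_000)
        cs = es.ContigSet("a5", [contig])
        f1 = es.select_fragment(cs, target_len=50_000, seed=11)
        f2 = es.select_fragment(cs, target_len=50_000, seed=11)
        f3 = es.select_fragment(cs, target_len=50_000, seed=12)
        assert f1.sequence == f2.sequence
        assert f1.window_offset != f3.window_offset

    def test_in_contig_ns_do_not_count_toward_length(self):
        rng = np.random.default_rng(5)
        contig = random_dna(rng, 1_000) + "N" * 50 + random_dna(rng, 1_000)
        cs = es.ContigSet("a6", [contig])
        frag = es.select_fragment(cs, target_len=1_500, seed=0)
        non_n = len(frag.sequence) - frag.sequence.count("N")
        assert non_n == 1_500 == frag.effective_length

    def test_separator_count_matches_pieces(self):
        rng = np.random.default_rng(6)
        contigs = [random_dna(rng, n) for n in (40_000, 30_000, 20_000, 10_000)]
        cs = es.ContigSet("a7", contigs)
        frag = es.select_fragment(cs, target_len=85_000, seed=0)
        # 40+30+20 = 90 > 85, so three pieces and two separators
        assert frag.sequence.count("N") == 2

    def test_ambiguity_codes_mapped_to_n(self):
        cs = es.ContigSet("a8", ["ACGRYacgt"])
        assert cs.contigs[0] == "ACGNNACGT"


class TestCanonicalKmers:
    def test_k1_is_a_and_c(self):
        assert list(es.canonical_kmer_list(1)) == ["A", "C"]

    @pytest.mark.parametrize("k", range(1, 7))
    def test_dimension_formula(self, k):
        n = len(es.canonical_kmer_list(k))
        expected = 4 ** k // 2 if k % 2 else (4 ** k + 4 ** (k // 2)) // 2
        assert n == expected
        # exhaustive: each member is the smaller of its pair, all pairs covered
        members = set(es.canonical_kmer_list(k))
        assert all(w <= revcomp(w) for w in members)
        assert len({min(w, revcomp(w)) for w in members}) == n

    def test_out_of_range_k(self):
        for bad in (0, 7):
            with pytest.raises(ValueError):
                es.canonical_kmer_list(bad)

    def test_acg_example(self):
        sig = es.count_canonical_kmers("ACG", 1)
        assert list(sig.counts) == [2, 4]
        assert np.allclose(sig.freqs, [1 / 3, 2 / 3])

    def test_all_n_is_degenerate(self):
        sig = es.count_canonical_kmers("NNNNN", 3)
        assert sig.counts.sum() == 0
        assert sig.degenerate and sig.freqs is None

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(250):
            k = int(rng.integers(1, 7))
            s = random_dna(rng, int(rng.integers(k, 200)), with_n=True)
            sig = es.count_canonical_kmers(s, k)
            assert list(sig.counts) == naive_signature(s, k)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(43)
        for _ in range(200):
            k = int(rng.integers(1, 7))
            s = random_dna(rng, int(rng.integers(k, 120)), with_n=True)
            assert es.count_canonical_kmers(s, k) == \
                es.count_canonical_kmers(revcomp(s), k)

    def test_k1_freq_is_gc_content(self):
        rng = np.random.default_rng(44)
        for _ in range(20):
            s = random_dna(rng, 500, with_n=True)
            sig = es.count_canonical_kmers(s, 1)
            non_n = [c for c in s if c != "N"]
            gc = sum(c in "GC" for c in non_n) / len(non_n)
            assert sig.freqs[1] == pytest.approx(gc)

    def test_count_total_is_twice_window_count(self):
        rng = np.random.default_rng(45)
        s = random_dna(rng, 5_000)
        for k in (1, 3, 6):
            sig = es.count_canonical_kmers(s, k)
            assert sig.counts.sum() == 2 * (len(s) - k + 1)


@given(st.text(alphabet="ACGTN", min_size=1, max_size=60),
       st.integers(min_value=1, max_value=6))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_counting_properties_hold_for_arbitrary_sequences(s, k):
    """For any DNA-with-N string: oracle agreement, strand symmetry, and the
    2x-window count total."""
    sig = es.count_canonical_kmers(s, k)
    assert list(sig.counts) == naive_signature(s, k)
    assert sig == es.count_canonical_kmers(revcomp(s), k)
    if not sig.degenerate:
        assert np.isclose(sig.freqs.sum(), 1.0)


class TestFCGR:
    def test_k1_example(self):
        g = es.fcgr_map({"A": 2, "C": 4}, 1)
        # row 0 is top: C, G; row 1 bottom: A, T
        assert g.grid.tolist() == [[4, 4], [2, 2]]

    def test_revcomp_pixel_involution(self):
        rng = np.random.default_rng(46)
        for k in (2, 3, 6):
            kmers = ["".join(rng.choice(list("ACGT"), size=k)) for _ in range(40)]
            for w in kmers:
                x1, y1 = _pixel(w)
                x2, y2 = _pixel(revcomp(w))
                assert _pixel(revcomp(revcomp(w))) == (x1, y1)
                # and the canonical grid carries equal values at both pixels
            sig = es.count_canonical_kmers(random_dna(rng, 2000), k)
            g = es.fcgr_map(sig.counts, k)
            for w in kmers:
                x1, y1 = _pixel(w)
                x2, y2 = _pixel(revcomp(w))
                side = 2 ** k
                assert g.grid[side - 1 - y1, x1] == g.grid[side - 1 - y2, x2]

    def test_full_vector_grid_sums_to_twice_windows(self):
        rng = np.random.default_rng(47)
        s = random_dna(rng, 10_000)
        for k in (3, 6):
            sig = es.count_canonical_kmers(s, k)
            g = es.fcgr_map(sig.full_symmetrized(), k)
            assert g.grid.sum() == 2 * (len(s) - k + 1)

    def test_uniform_values_give_constant_grid(self):
        n = len(es.canonical_kmer_list(4))
        g = es.fcgr_map(np.ones(n), 4)
        assert np.all(g.grid == 1.0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            es.fcgr_map(np.ones(5), 3)


class TestIO:
    def test_fasta_and_matrix_roundtrip(self, tmp_path):
        rng = np.random.default_rng(48)
        cs = es.ContigSet("asm1", [random_dna(rng, 3_000), random_dna(rng, 2_000)])
        from extremosig.synthetic import write_dataset
        from extremosig.folds import SampleMeta
        meta = [SampleMeta("asm1", "s", "g", "Bacteria", "mesophile")]
        truth = es.GroundTruth(samples=meta, domain_sets={}, category_sets={})
        write_dataset([cs], meta, truth, tmp_path)
        back = es.read_assembly_fasta(tmp_path / "genomes" / "asm1.fasta", "asm1")
        assert back.contigs == cs.contigs
        df = es.signatures_from_contigsets([back], k=3, target_len=2_000, seed=0)
        es.write_signature_matrix(df, tmp_path / "sig.tsv")
        df2 = es.read_signature_matrix(tmp_path / "sig.tsv")
        assert np.allclose(df.to_numpy(), df2.to_numpy())
        assert list(df2.columns) == list(es.canonical_kmer_list(3))
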