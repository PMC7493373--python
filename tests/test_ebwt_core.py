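import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ebwtax.ebwt_core import (ALPHABET, IUPAC_BASES, IUPAC_COMPLEMENT,
                              CollectionError, IndexFormatError, build_index,
                              count_occurrences, load_collection,
                              make_collection, read_index, reverse_complement,
                              write_index)
from oracle import brute_substring_count, naive_index, random_collection

iupac_strings = st.text(alphabet=sorted(ALPHABET), min_size=1, max_size=40)


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ACGT", "ACGT"), ("GGCGTACCA", "TGGTACGCC"), ("AR", "YT"), ("acgt", "ACGT")],
    )
    def test_examples(self, seq, expected):
        assert reverse_complement(seq) == expected

    @given(iupac_strings)
    @settings(deadline=None)
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq

    def test_complement_is_setwise(self):
        # bases(complement(c)) must equal the complemented base set of c
        for code, bases in IUPAC_BASES.items():
            comp = IUPAC_COMPLEMENT[code]
            assert IUPAC_BASES[comp] == {IUPAC_COMPLEMENT[b] for b in bases}
            assert IUPAC_COMPLEMENT[comp] == code

    def test_unknown_symbol_rejected(self):
        with pytest.raises(CollectionError, match="no complement"):
            reverse_complement("AXG")


class TestLoadCollection:
    def test_fasta_plus_fasta(self, tmp_path):
        (tmp_path / "reads.fa").write_text(">r1\nGGCG\nTACCA\n")
        (tmp_path / "gen.fa").write_text(">g1\nGGGGCGTAT\n>g2\nACGARTACGAC\n")
        coll = load_collection(tmp_path / "reads.fa", tmp_path / "gen.fa")
        assert (coll.r, coll.g, coll.m) == (1, 2, 3)
        assert coll.records[0].seq == "GGCGTACCA"  # multi-line FASTA joined
        assert [rec.role for rec in coll.records] == ["read", "genome", "genome"]

    def test_fastq_lowercase_and_quality_discarded(self, tmp_path):
        (tmp_path / "reads.fq").write_text("@r1\nacgt\n+\n!!!!\n")
        (tmp_path / "gen.fa").write_text(">g1\nAAAA\n")
        coll = load_collection(tmp_path / "reads.fq", tmp_path / "gen.fa")
        assert coll.records[0].seq == "ACGT"

    def test_invalid_character_names_record_and_position(self, tmp_path):
        (tmp_path / "reads.fa").write_text(">bad\nACXGT\n")
        (tmp_path / "gen.fa").write_text(">g1\nAAAA\n")
        with pytest.raises(CollectionError, match="'bad'.*'X' at position 3"):
            load_collection(tmp_path / "reads.fa", tmp_path / "gen.fa")

    def test_empty_file_rejected(self, tmp_path):
        (tmp_path / "reads.fa").write_text("")
        (tmp_path / "gen.fa").write_text(">g1\nAAAA\n")
        with pytest.raises(CollectionError, match="empty"):
            load_collection(tmp_path / "reads.fa", tmp_path / "gen.fa")

    def test_genome_before_read_rejected(self):
        from ebwtax.ebwt_core import Collection, SequenceRecord
        with pytest.raises(CollectionError, match="reads must precede"):
            Collection((SequenceRecord("g", "ACGT", "genome"),
                        SequenceRecord("r", "ACGT", "read")))


class TestBuildIndex:
    def test_single_sequence(self):
        idx = build_index(make_collection([("r", "A")], []))
        assert idx.ebwt == "A#"
        assert idx.da.tolist() == [1, 1]
        assert idx.lcp.tolist() == [0, 0, 0]

    def test_worked_example_size_and_lcp(self, worked_example):
        _, expected, idx = worked_example
        assert idx.N == expected["N"]
        assert idx.lcp_at(17) == expected["lcp_17"]
        assert idx.lcp_at(1) == 0 and idx.lcp_at(idx.N + 1) == 0

    def test_matches_naive_oracle_on_random_collections(self, rng):
        for _ in range(40):
            seqs, r = random_collection(rng)
            coll = make_collection(
                [(f"r{i}", s) for i, s in enumerate(seqs[:r])],
                [(f"g{i}", s) for i, s in enumerate(seqs[r:])],
            )
            idx = build_index(coll)
            ebwt, da, lcp, _ = naive_index(seqs, r)
            assert idx.ebwt == ebwt
            assert idx.da.tolist() == da
            assert idx.lcp.tolist() == lcp
            assert idx.N == sum(map(len, seqs)) + len(seqs)
            counts = np.bincount(idx.da, minlength=len(seqs) + 1)
            assert all(counts[j + 1] == len(seqs[j]) + 1 for j in range(len(seqs)))

    def test_substring_right_extension_property(self, rng):
        # if u of length k occurs l times, every proper suffix of u occurs >= l times
        seqs, _ = random_collection(rng, max_seqs=3, max_len=20, iupac_rate=0.0)
        for s in seqs:
            for k in (2, 3):
                for p in range(len(s) - k + 1):
                    u = s[p:p + k]
                    occ = brute_substring_count(seqs, u)
                    for cut in range(1, k):
                        assert brute_substring_count(seqs, u[cut:]) >= occ


class TestCountOccurrences:
    def test_worked_example_counts(self, worked_example):
        _, expected, idx = worked_example
        for pattern, n in expected["substring_counts"].items():
            assert count_occurrences(idx, pattern) == n

    def test_matches_direct_count(self, rng):
        for _ in range(20):
            seqs, r = random_collection(rng, iupac_rate=0.0)
            idx = build_index(make_collection(
                [(f"r{i}", s) for i, s in enumerate(seqs[:r])],
                [(f"g{i}", s) for i, s in enumerate(seqs[r:])],
            ))
            for pattern in ("A", "GT", "ACG", "TTTTTTTT"):
                assert count_occurrences(idx, pattern) == brute_substring_count(seqs, pattern)


class TestIndexSerialization:
    def test_round_trip(self, tmp_path, worked_example):
        _, _, idx = worked_example
        write_index(idx, tmp_path / "ex")
        loaded = read_index(tmp_path / "ex")
        assert loaded.ebwt == idx.ebwt
        assert loaded.da.tolist() == idx.da.tolist()
        assert loaded.lcp.tolist() == idx.lcp.tolist()
        assert (loaded.r, loaded.g, loaded.ids, loaded.lengths) == (
            idx.r, idx.g, idx.ids, idx.lengths)

    def test_missing_component(self, tmp_path, worked_example):
        _, _, idx = worked_example
        write_index(idx, tmp_path / "ex")
        (tmp_path / "ex.lcp").unlink()
        with pytest.raises(IndexFormatError, match=r"ex\.lcp"):
            read_index(tmp_path / "ex")

    def test_tampered_meta(self, tmp_path, worked_example):
        _, _, idx = worked_example
        write_index(idx, tmp_path / "ex")
        meta = json.loads((tmp_path / "ex.meta.json").read_text())
        meta["N"] -= 1
        (tmp_path / "ex.meta.json").write_text(json.dumps(meta))
        with pytest.raises(IndexFormatError, match="inconsistent"):
            read_index(tmp_path / "ex")
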