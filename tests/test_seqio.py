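"""ORF enumeration, FASTA ingestion, and main-ORF selection."""

import numpy as np
import pytest

from anrfscan import (
    SeqioError,
    Transcript,
    enumerate_orfs,
    find_main_orf,
    nested_sorfs,
    read_fasta,
    upstream_uorfs,
)

STOPS = {"TAA", "TAG", "TGA"}


def orf_oracle(seq, min_aa, max_aa):
    """Brute force: scan every position for ATG and walk codons to the first stop."""
    hits = []
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        j = i + 3
        while j + 3 <= len(seq):
            if seq[j : j + 3] in STOPS:
                aa = (j - i) // 3
                if min_aa <= aa <= max_aa:
                    hits.append((i + 1, j + 3))
                break
            j += 3
    return hits


class TestReadFasta:
    def test_normalizes_rna_and_case(self, tmp_path):
        p = tmp_path / "in.fa"
        p.write_text(">t1\nAUGcau\n")
        (t,) = read_fasta(p)
        assert t.id == "t1" and t.seq == "ATGCAT"

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text("")
        with pytest.raises(SeqioError, match="empty FASTA"):
            read_fasta(p)

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "dup.fa"
        p.write_text(">a\nACGT\n>a\nACGT\n")
        with pytest.raises(SeqioError, match="duplicate id"):
            read_fasta(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(SeqioError, match="no such file"):
            read_fasta(tmp_path / "nope.fa")

    def test_ambiguity_codes_become_n(self, tmp_path, caplog):
        p = tmp_path / "amb.fa"
        p.write_text(">t\nACGRYT\n")
        with caplog.at_level("WARNING"):
            (t,) = read_fasta(p)
        assert t.seq == "ACGNNT"
        assert "mapped to N" in caplog.text

    def test_illegal_characters_rejected(self):
        with pytest.raises(SeqioError, match="non-nucleotide"):
            Transcript(id="t", seq="ACGJ")


class TestEnumerateOrfs:
    def test_start_stop_uorf(self):
        t = Transcript(id="t", seq="ATGCATTAA")
        (orf,) = enumerate_orfs(t, 1, 100)
        assert (orf.start, orf.end, orf.peptide, orf.length_aa) == (1, 9, "MH", 2)

    def test_no_atg_gives_empty(self):
        assert enumerate_orfs(Transcript(id="t", seq="CCCCCCTAA"), 0, 100) == []

    def test_atg_without_stop_yields_nothing(self):
        assert enumerate_orfs(Transcript(id="t", seq="ATGAAAAAA"), 0, 100) == []

    def test_n_codons_never_start_or_stop(self):
        # ATN is not a start; TNA is not a stop, the walk continues past it
        t = Transcript(id="t", seq="ATNCATTAA" + "ATGTNATAA")
        orfs = enumerate_orfs(t, 0, 100)
        assert [(o.start, o.end) for o in orfs] == [(10, 18)]

    def test_matches_brute_force_oracle_on_random_sequences(self):
        rng = np.random.default_rng(42)
        for _ in range(120):
            seq = "".join("ACGTN"[i] for i in rng.choice(5, 300, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            t = Transcript(id="r", seq=seq)
            got = [(o.start, o.end) for o in enumerate_orfs(t, 0, 100)]
            assert got == orf_oracle(seq, 0, 100)

    def test_records_satisfy_type_invariants(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
            t = Transcript(id="r", seq=seq)
            for o in enumerate_orfs(t, 0, 200):
                assert (o.end - o.start + 1) % 3 == 0
                assert o.length_aa == (o.end - o.start + 1) // 3 - 1
                o.validate(t)


class TestFindMainOrf:
    def test_longest_wins(self):
        # 3-aa ORF vs 1-aa ORF
        t = Transcript(id="t", seq="ATGTAACC" + "ATGAAAGCTGCTTAG")
        main = find_main_orf(t)
        assert (main.start, main.length_aa, main.kind, main.frame_offset) == (9, 4, "main", 0)

    def test_tie_broken_by_smaller_start(self):
        t = Transcript(id="t", seq="ATGAAATAACC" + "ATGAAATAA")
        assert find_main_orf(t).start == 1

    def test_hint_returned_verbatim(self):
        seq = "CCATGAAATAACC"
        t = Transcript(id="t", seq=seq, main_orf_hint=(3, 11))
        main = find_main_orf(t)
        assert (main.start, main.end, main.peptide) == (3, 11, "MK")

    def test_bad_hint_rejected(self):
        t = Transcript(id="t", seq="CCATGAAATAACC", main_orf_hint=(2, 10))
        with pytest.raises(SeqioError):
            find_main_orf(t)

    def test_no_orf_error_names_transcript(self):
        with pytest.raises(SeqioError, match="myid"):
            find_main_orf(Transcript(id="myid", seq="CCCCCC"))

    def test_606_nt_orf_encodes_201_aa(self, kpilp_like):
        t, entry = kpilp_like
        main = find_main_orf(t)
        assert main.end - main.start + 1 == 606
        assert main.length_aa == 201


class TestNestedSorfs:
    def test_planted_candidate_found_exactly(self, kpilp_like):
        t, entry = kpilp_like
        main = find_main_orf(t)
        hits = [
            o for o in nested_sorfs(t, main)
            if (o.start, o.end) == (entry.anrf_start, entry.anrf_end)
        ]
        assert len(hits) == 1
        orf = hits[0]
        assert orf.kind == "nested" and orf.frame_offset in (1, 2)
        assert orf.length_aa == 53

    def test_in_frame_internal_aug_excluded(self):
        # internal in-frame ATG (same frame as main) must not be a nested sORF
        inner = "ATG" + "GCT" * 12 + "TAA"
        seq = "ATG" + "GCA" * 3 + inner + "GCA" * 3 + "TAA"
        t = Transcript(id="t", seq=seq)
        main = find_main_orf(t)
        assert main.start == 1
        assert nested_sorfs(t, main, min_aa=1, max_aa=100) == []

    def test_length_band_boundaries(self):
        def planted(n_aa):
            # alt-frame nested ORF encoding n_aa residues (Met included) at offset 1
            nested = "ATG" + "GCC" * (n_aa - 1) + "TAA"
            body = "A" + nested + "GC"  # shift by 1 => frame offset 1
            assert len(body) % 3 == 0
            return Transcript(id="t", seq="ATG" + "GGC" * 2 + body + "GGC" * 2 + "TAA")

        for n_aa, expected in [(9, 0), (10, 1)]:
            t = planted(n_aa)
            main = find_main_orf(t)
            got = [o for o in nested_sorfs(t, main, 10, 100) if o.length_aa == n_aa]
            assert len(got) == expected

    def test_subset_of_enumerate_within_main(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            seq = "ATG" + "".join("ACGT"[i] for i in rng.integers(0, 4, 300)) + "TAA"
            t = Transcript(id="r", seq=seq)
            try:
                main = find_main_orf(t)
            except SeqioError:
                continue
            all_orfs = {(o.start, o.end) for o in enumerate_orfs(t, 1, 100)}
            for o in nested_sorfs(t, main, 1, 100):
                assert (o.start, o.end) in all_orfs
                assert o.start > main.start and o.end <= main.end
                assert (o.start - main.start) % 3 == o.frame_offset in (1, 2)


def test_uorfs_lie_strictly_upstream(kpilp_like):
    t, entry = kpilp_like
    main = find_main_orf(t)
    uorfs = upstream_uorfs(t, main)
    assert [(u.start, u.end, u.peptide) for u in uorfs] == [(1, 9, "MH")]
    assert all(u.end < main.start for u in uorfs)
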