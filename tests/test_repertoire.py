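import numpy as np
import pytest

from cdrnet.repertoire import (
    CloneRecord,
    CloneTableFormatError,
    CloneValidationError,
    Repertoire,
    filter_repertoire,
    find_public_clones,
    read_clone_table,
    write_clone_csv,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadCloneTable:
    def test_identity_collapse_sums_counts(self, tmp_path):
        p = _write(tmp_path, "a.csv", "cdr3_aa,count\nCARDY,3\nCARDY,2\nCARWW,1\n")
        rep = read_clone_table(p, format="csv")
        assert len(rep) == 2
        assert dict(zip(rep.sequences, rep.counts)) == {"CARDY": 5, "CARWW": 1}

    def test_row_order_invariance(self, tmp_path):
        rows = ["CARDY,3", "CARWW,1", "CARDY,2"]
        a = read_clone_table(_write(tmp_path, "a.csv", "cdr3_aa,count\n" + "\n".join(rows)))
        b = read_clone_table(
            _write(tmp_path, "b.csv", "cdr3_aa,count\n" + "\n".join(rows[::-1]))
        )
        assert dict(zip(a.sequences, a.counts)) == dict(zip(b.sequences, b.counts))

    def test_empty_file_with_header(self, tmp_path):
        rep = read_clone_table(_write(tmp_path, "e.csv", "cdr3_aa,count\n"))
        assert len(rep) == 0

    def test_collapse_idempotent(self, tmp_path):
        p = _write(tmp_path, "a.csv", "cdr3_aa,count\nCARDY,3\nCARDY,2\n")
        rep = read_clone_table(p)
        write_clone_csv(rep, tmp_path / "round.csv")
        again = read_clone_table(tmp_path / "round.csv")
        assert again.sequences == rep.sequences
        assert list(again.counts) == list(rep.counts)

    @pytest.mark.parametrize(
        "fmt,header,row",
        [
            ("airr", "junction_aa\tduplicate_count", "CARDY\t4"),
            ("mixcr", "aaSeqCDR3\tcloneCount", "CARDY\t4"),
        ],
    )
    def test_dialects(self, tmp_path, fmt, header, row):
        p = _write(tmp_path, "t.tsv", f"{header}\n{row}\n")
        rep = read_clone_table(p, format=fmt)
        assert rep.sequences == ["CARDY"] and rep.counts[0] == 4

    def test_missing_column_names_column(self, tmp_path):
        p = _write(tmp_path, "bad.csv", "sequence,count\nCARDY,1\n")
        with pytest.raises(CloneTableFormatError, match="cdr3_aa"):
            read_clone_table(p, format="csv")

    @pytest.mark.parametrize("seq", ["CARXDY", "CAR*Y", "CA_DY", "CARdBZ"])
    def test_ambiguous_residues_rejected(self, tmp_path, seq):
        p = _write(tmp_path, "amb.csv", f"cdr3_aa,count\n{seq},2\n")
        with pytest.raises(CloneValidationError):
            read_clone_table(p, format="csv")


class TestFilterRepertoire:
    def make(self, items):
        return Repertoire("s", [CloneRecord(s, c) for s, c in items])

    def test_default_filters_match_clone_definition(self):
        rep = self.make([("CAR", 9), ("CARD", 1), ("CARDY", 2)])
        out, report = filter_repertoire(rep)
        assert out.sequences == ["CARDY"]
        assert report.n_removed_short == 1 and report.n_removed_rare == 1

    def test_vacuous_filter_keeps_input(self):
        rep = self.make([("CAR", 1), ("CARDY", 2)])
        out, _ = filter_repertoire(rep, min_len=1, min_count=1)
        assert out.sequences == rep.sequences

    def test_all_singletons_empty(self):
        rep = self.make([("CARD", 1), ("CARDY", 1)])
        out, _ = filter_repertoire(rep)
        assert len(out) == 0

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(0)
        from cdrnet.simulate import synthetic_repertoire

        rep = synthetic_repertoire(60, seed=rng)
        sizes = [
            len(filter_repertoire(rep, min_len=l, min_count=c)[0])
            for l, c in [(1, 1), (4, 2), (6, 3), (8, 5)]
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_frequencies_computed_after_filtering(self):
        rep = self.make([("CARDY", 6), ("CARDW", 2)])
        assert np.allclose(rep.frequencies, [0.75, 0.25])
        assert rep.frequencies.sum() <= 1 + 1e-9


class TestPublicClones:
    def make(self, sid, seqs):
        return Repertoire(sid, [CloneRecord(s, 2) for s in seqs])

    def test_shared_clone_detected(self):
        a = self.make("A", ["CARDY", "CARWW"])
        b = self.make("B", ["CARDY", "CAAAA"])
        pub = find_public_clones([a, b])
        assert set(pub.clones) == {"CARDY"}
        assert pub.per_clone_sharing["CARDY"] == 2

    def test_disjoint_repertoires_empty(self):
        pub = find_public_clones([self.make("A", ["CARDY"]), self.make("B", ["CAAAA"])])
        assert len(pub) == 0

    def test_sharing_counts_subjects_not_reads(self):
        reps = [self.make(s, ["CARDY"]) for s in "ABC"]
        pub = find_public_clones(reps)
        assert pub.per_clone_sharing["CARDY"] == 3

    def test_requires_two_repertoires(self):
        with pytest.raises(ValueError):
            find_public_clones([self.make("A", ["CARDY"])])

    def test_public_private_partition(self):
        a = self.make("A", ["CARDY", "CARWW", "CAFFF"])
        b = self.make("B", ["CARDY", "CAAAA"])
        pub = find_public_clones([a, b])
        for rep in (a, b):
            seqs = rep.sequence_set()
            public = seqs & pub.clones
            private = seqs - pub.clones
            assert public | private == seqs and not public & private


class TestCloneRecord:
    def test_rejects_zero_count(self):
        with pytest.raises(CloneValidationError):
            CloneRecord("CARDY", 0)

    def test_uppercases(self):
        assert CloneRecord("cardy", 1).cdr3_aa == "CARDY"

    def test_duplicate_clones_rejected_in_repertoire(self):
        with pytest.raises(CloneValidationError):
            Repertoire("s", [CloneRecord("CARDY", 1), CloneRecord("CARDY", 2)])
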