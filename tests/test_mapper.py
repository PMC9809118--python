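"""Seed-and-extend alignment, pairing and SAM output."""

import pysam

from dinomfrs.mapper import (
    DISCOVERY,
    VERIFY,
    ReadPair,
    align_read,
    map_pair,
    score_from_cigar,
    write_sam,
)
from dinomfrs.refdb import AlleleSequence, ReferenceDB, revcomp

from conftest import mutate, random_seq


class TestAlignRead:
    def test_perfect_substring(self, allele):
        read = allele.seq[123:223]
        rec = align_read(read, allele, DISCOVERY)
        assert rec.score == 100
        assert rec.edit_distance == 0
        assert rec.cigar == (("M", 100),)
        assert rec.ref_start == 123
        assert rec.strand == "+"

    def test_one_substitution(self, allele, rng):
        read = mutate(allele.seq[123:223], [50], rng)
        rec = align_read(read, allele, DISCOVERY)
        assert rec.score == 95  # 99 matches - 1 mismatch * 4
        assert rec.edit_distance == 1

    def test_unrelated_read_unmapped(self, allele, rng):
        read = random_seq(rng, 100)
        assert align_read(read, allele, DISCOVERY) is None

    def test_reverse_strand(self, allele):
        read = revcomp(allele.seq[200:300])
        rec = align_read(read, allele, DISCOVERY)
        assert rec.score == 100
        assert rec.strand == "-"
        assert rec.ref_start == 200
        assert rec.aligned_seq == allele.seq[200:300]

    def test_deletion_read(self, allele):
        read = allele.seq[100:150] + allele.seq[151:201]
        rec = align_read(read, allele, DISCOVERY)
        # 100 matches minus one 1-bp gap (open 6 + extend 1)
        assert rec.score == 93
        assert ("D", 1) in rec.cigar

    def test_score_consistent_with_cigar(self, allele, rng):
        for _ in range(20):
            s = int(rng.integers(0, 440))
            read = mutate(allele.seq[s : s + 100],
                          rng.integers(0, 100, size=3), rng)
            rec = align_read(read, allele, DISCOVERY)
            assert rec is not None
            assert score_from_cigar(rec, allele.seq, DISCOVERY) == rec.score

    def test_strand_symmetry(self, allele, rng):
        """Reverse-complementing both read and allele keeps the score."""
        read = mutate(allele.seq[50:150], [10, 70], rng)
        rc_allele = AlleleSequence("rc", revcomp(allele.seq))
        r1 = align_read(read, allele, DISCOVERY)
        r2 = align_read(revcomp(read), rc_allele, DISCOVERY)
        assert r1.score == r2.score

    def test_verify_stringency_subset(self, allele, rng):
        """Edit-distance-0 VERIFY hits also map under DISCOVERY at the
        same locus."""
        for _ in range(20):
            s = int(rng.integers(0, 440))
            read = allele.seq[s : s + 100]
            v = align_read(read, allele, VERIFY)
            if v is not None and v.edit_distance == 0:
                d = align_read(read, allele, DISCOVERY)
                assert d is not None and d.ref_start == v.ref_start


class TestMapPair:
    def _pair_from(self, seq, start, frag=300, rl=100, pid="p1"):
        return ReadPair(pid, seq[start : start + rl],
                        revcomp(seq[start + frag - rl : start + frag]))

    def test_proper_pair(self, small_db):
        x = small_db.alleles[0]
        pair = self._pair_from(x.seq, 40)
        recs = map_pair(pair, small_db, DISCOVERY)
        assert {r.allele_id for r in recs} == {"A1"}
        assert all(r.proper_pair for r in recs)
        assert {r.mate for r in recs} == {1, 2}

    def test_conserved_block_maps_to_both(self, rng):
        """A pair drawn from a 300 bp block shared by two alleles is
        reported on both (co-mapping ties)."""
        block = random_seq(rng, 300)
        x = AlleleSequence("X", random_seq(rng, 120) + block + random_seq(rng, 129))
        y = AlleleSequence("Y", random_seq(rng, 60) + block + random_seq(rng, 189))
        db = ReferenceDB(alleles=[x, y])
        pair = ReadPair("c1", block[:100], revcomp(block[200:300]))
        recs = map_pair(pair, db, DISCOVERY)
        assert {r.allele_id for r in recs} == {"X", "Y"}

    def test_chimeric_pair_not_proper(self, rng):
        # mates drawn from two unrelated alleles: no reference carries
        # both, the pair score is charged the unpaired penalty
        x = AlleleSequence("X", random_seq(rng, 549))
        y = AlleleSequence("Y", random_seq(rng, 549))
        db = ReferenceDB(alleles=[x, y])
        pair = ReadPair("chi", x.seq[0:100], revcomp(y.seq[200:300]))
        recs = map_pair(pair, db, DISCOVERY)
        assert recs and not any(r.proper_pair for r in recs)
        assert {r.allele_id for r in recs} == {"X", "Y"}  # tie at 100 - 17

    def test_unmappable_pair_empty(self, small_db, rng):
        pair = ReadPair("junk", random_seq(rng, 100), random_seq(rng, 100))
        assert map_pair(pair, small_db, DISCOVERY) == []


class TestWriteSam:
    def test_header_only(self, tmp_path, small_db):
        path = tmp_path / "empty.sam"
        write_sam([], small_db, path)
        with pysam.AlignmentFile(str(path), "r") as sam:
            assert list(sam) == []
            assert set(sam.references) == set(small_db.ids)

    def test_proper_pair_flags(self, tmp_path, small_db):
        x = small_db.alleles[0]
        pair = ReadPair("p1", x.seq[10:110], revcomp(x.seq[210:310]))
        recs = map_pair(pair, small_db, DISCOVERY)
        path = tmp_path / "pair.sam"
        write_sam(recs, small_db, path)
        with pysam.AlignmentFile(str(path), "r") as sam:
            flags = sorted(r.flag for r in sam)
        assert flags in ([99, 147], [83, 163])

    def test_reverse_strand_seq(self, tmp_path, small_db):
        x = small_db.alleles[0]
        read = revcomp(x.seq[100:200])
        rec = align_read(read, x, DISCOVERY)
        rec.read_id = "r1"
        rec.mate = 1
        path = tmp_path / "rev.sam"
        write_sam([rec], small_db, path)
        with pysam.AlignmentFile(str(path), "r") as sam:
            aln = next(iter(sam))
        assert aln.is_reverse
        assert aln.query_sequence == x.seq[100:200]  # reverse-complemented
        assert aln.get_tag("NM") == 0
        assert aln.get_tag("AS") == rec.score


def test_small_oracle_sample(allele, rng):
    """align_read scores match a full unbanded clip-aware DP on a small
    random sample (the large-scale check lives in the acceptance suite)."""
    from test_acceptance import full_dp_score

    from dinomfrs._align import encode

    for _ in range(40):
        s = int(rng.integers(0, 400))
        read = mutate(allele.seq[s : s + 120],
                      rng.integers(0, 120, size=int(rng.integers(0, 6))), rng)
        rec = align_read(read, allele, DISCOVERY)
        oracle = full_dp_score(
            encode(read), encode(allele.seq),
            DISCOVERY.match, DISCOVERY.mismatch,
            DISCOVERY.gap_open, DISCOVERY.gap_extend, DISCOVERY.clip,
        )
        rc_oracle = full_dp_score(
            encode(revcomp(read)), encode(allele.seq),
            DISCOVERY.match, DISCOVERY.mismatch,
            DISCOVERY.gap_open, DISCOVERY.gap_extend, DISCOVERY.clip,
        )
        assert rec is not None
        assert rec.score == max(oracle, rc_oracle)
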