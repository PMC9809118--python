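"""Pileups, known-allele calls, candidate rule and expression binning."""

import pytest

from dinomfrs.allele_caller import (
    CandidateRegion,
    bin_expression,
    call_known,
    compute_pileup,
    consensus_sequence,
    find_candidates,
)
from dinomfrs.mapper import AlignmentRecord, DISCOVERY, map_pair
from dinomfrs.refdb import AlleleSequence, ReferenceDB

from conftest import mutate, perfect_pairs_from, random_seq


def _records_for(allele, pairs, db=None):
    db = db or ReferenceDB(alleles=[allele])
    recs = []
    for p in pairs:
        recs.extend(r for r in map_pair(p, db, DISCOVERY)
                    if r.allele_id == allele.id)
    return recs


def _simple_record(allele_id, seq, ref_start, proper=True, read_id="r1",
                   cigar=None):
    return AlignmentRecord(
        read_id=read_id, mate=1, allele_id=allele_id, ref_start=ref_start,
        cigar=cigar or (("M", len(seq)),), score=len(seq), strand="+",
        proper_pair=proper, edit_distance=0, seq=seq,
    )


class TestComputePileup:
    def test_empty(self, allele):
        p = compute_pileup([], allele)
        assert not p.complete
        assert p.covered_span == 0
        assert int(p.depth.sum()) == 0

    def test_uniform_error_free_coverage(self, allele):
        pairs = perfect_pairs_from(allele.seq, allele.id, step=3)
        # add terminal-covering single reads so every column is deep
        recs = _records_for(allele, pairs)
        recs.append(_simple_record(allele.id, allele.seq[-100:], 449,
                                   read_id="tail"))
        for k in range(6):
            recs.append(_simple_record(allele.id, allele.seq[-100:], 449,
                                       read_id=f"t{k}"))
            recs.append(_simple_record(allele.id, allele.seq[:100], 0,
                                       read_id=f"h{k}"))
        p = compute_pileup(recs, allele)
        assert p.complete
        assert p.covered_span == len(allele.seq)
        assert p.mismatch_positions == []
        assert p.het_positions == []
        assert call_known(p)

    def test_variant_site_becomes_mismatch(self, allele, rng):
        variant = mutate(allele.seq, [250], rng)
        recs = [
            _simple_record(allele.id, variant[200:300], 200, read_id=f"v{k}")
            for k in range(50)
        ]
        p = compute_pileup(recs, allele)
        assert p.mismatch_positions == [250]
        assert p.het_positions == []
        assert not call_known(p)

    def test_mixture_flags_het(self, allele, rng):
        variant = mutate(allele.seq, [250], rng)
        recs = [
            _simple_record(allele.id, allele.seq[200:300], 200, read_id=f"a{k}")
            for k in range(30)
        ] + [
            _simple_record(allele.id, variant[200:300], 200, read_id=f"b{k}")
            for k in range(20)
        ]
        p = compute_pileup(recs, allele)
        assert p.het_positions == [250]
        assert p.mismatch_positions == []  # majority still the reference

    def test_base_count_conservation(self, allele, rng):
        """Tallied bases equal aligned (non-clipped, non-inserted) bases."""
        recs = []
        total = 0
        for k in range(30):
            s = int(rng.integers(0, 440))
            seq = allele.seq[s : s + 100]
            cig = (("S", 5), ("M", 90), ("S", 5))
            recs.append(_simple_record(allele.id, seq, s + 5, read_id=f"r{k}",
                                       cigar=cig))
            total += 90
        p = compute_pileup(recs, allele)
        assert int(p.base_counts[:4].sum()) == total

    def test_wrong_allele_rejected(self, allele):
        rec = _simple_record("other", allele.seq[:100], 0)
        with pytest.raises(ValueError):
            compute_pileup([rec], allele)

    def test_monotone_presence(self, allele):
        """Adding error-free reads never turns a present call absent."""
        pairs = perfect_pairs_from(allele.seq, allele.id, step=2)
        recs = _records_for(allele, pairs)
        for k in range(8):
            recs.append(_simple_record(allele.id, allele.seq[:100], 0,
                                       read_id=f"h{k}"))
            recs.append(_simple_record(allele.id, allele.seq[-100:], 449,
                                       read_id=f"t{k}"))
        p1 = compute_pileup(recs, allele)
        assert call_known(p1)
        more = recs + [
            _simple_record(allele.id, allele.seq[100:200], 100, read_id=f"m{k}")
            for k in range(25)
        ]
        assert call_known(compute_pileup(more, allele))


class TestCandidateRule:
    def _pileup_like(self, allele, n_reads, span, het=True):
        """Engineer a pileup with the requested read count and span."""
        read_len = 100
        recs = []
        step = max(1, (span - read_len) // max(1, n_reads - 1)) if span > read_len else 1
        k = 0
        while len(recs) < n_reads:
            s = (k * step) % max(1, span - read_len + 1)
            recs.append(_simple_record(allele.id, allele.seq[s : s + read_len],
                                       s, read_id=f"e{k}"))
            k += 1
        p = compute_pileup(recs, allele)
        if het:
            p.het_positions = [span // 2]
        return p

    @pytest.mark.parametrize(
        "n_reads,span,expected",
        [
            (501, 450, True),  # both thresholds strictly exceeded
            (500, 450, False),  # not more than 500 reads
            (2000, 380, False),  # span not longer than 400 bp
        ],
    )
    def test_boundaries(self, rng, n_reads, span, expected):
        allele = AlleleSequence("C1", random_seq(rng, 549))
        p = self._pileup_like(allele, n_reads, span)
        cands = find_candidates([p])
        assert bool(cands) == expected
        if cands:
            assert isinstance(cands[0], CandidateRegion)

    def test_clean_pileup_not_candidate(self, rng):
        allele = AlleleSequence("C2", random_seq(rng, 549))
        p = self._pileup_like(allele, 800, 549, het=False)
        # no mismatch or heterogeneous column -> not a candidate
        p.mismatch_positions = []
        p.het_positions = []
        assert find_candidates([p]) == []


class TestConsensus:
    def test_exact_substring(self, allele):
        recs = [_simple_record(allele.id, allele.seq[100:200], 100,
                               read_id=f"r{k}") for k in range(10)]
        p = compute_pileup(recs, allele)
        assert consensus_sequence(p) == allele.seq[100:200]

    def test_mixed_site_masked(self, allele, rng):
        variant = mutate(allele.seq, [150], rng)
        recs = [_simple_record(allele.id, allele.seq[100:200], 100,
                               read_id=f"a{k}") for k in range(30)]
        recs += [_simple_record(allele.id, variant[100:200], 100,
                                read_id=f"b{k}") for k in range(20)]
        p = compute_pileup(recs, allele)
        cons = consensus_sequence(p)
        assert cons[50] == "N"
        assert cons[:50] == allele.seq[100:150]

    def test_gap_restricts_to_longest_run(self, allele):
        recs = [_simple_record(allele.id, allele.seq[0:100], 0,
                               read_id=f"a{k}") for k in range(8)]
        recs += [_simple_record(allele.id, allele.seq[250:500], 250,
                                read_id=f"b{k}") for k in range(8)]
        p = compute_pileup(recs, allele)
        assert consensus_sequence(p) == allele.seq[250:500]


class TestBinExpression:
    def _marker_records(self, allele, n, covers=True):
        s = 150 if covers else 300
        return [_simple_record(allele.id, allele.seq[s : s + 100], s,
                               read_id=f"m{k}") for k in range(n)]

    @pytest.mark.parametrize(
        "n,expected",
        [(999, "low"), (1000, "middle"), (5000, "middle"), (5001, "high")],
    )
    def test_bin_boundaries(self, allele, n, expected):
        recs = self._marker_records(allele, n)
        bin_, count = bin_expression(recs, marker_pos=260, allele_offset=73,
                                     allele_length=len(allele.seq))
        assert bin_ == expected
        assert count == n

    def test_only_covering_reads_counted(self, allele):
        recs = self._marker_records(allele, 10) + self._marker_records(
            allele, 500, covers=False)
        _, count = bin_expression(recs, 260, 73, len(allele.seq))
        assert count == 10

    def test_marker_outside_allele(self, allele):
        with pytest.raises(ValueError):
            bin_expression([], marker_pos=700, allele_offset=0,
                           allele_length=549)


def test_pileup_table_report(allele):
    from dinomfrs.allele_caller import pileups_to_table

    recs = [_simple_record(allele.id, allele.seq[:100], 0, read_id=f"r{k}")
            for k in range(8)]
    df = pileups_to_table([compute_pileup(recs, allele)])
    assert list(df.columns) == ["allele_id", "n_reads", "span_len",
                                "complete", "n_mismatch", "n_het", "decision"]
    assert df.iloc[0]["decision"] == "absent"  # incomplete coverage
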