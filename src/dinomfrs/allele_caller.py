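"""Pileups, known-allele calls, candidate detection and expression binning.

A known allele carried by an individual shows complete, mismatch-free
coverage by the aligned reads.  Alignments that instead show mismatched or
heterogeneous columns -- reads from one or more alleles missing from the
reference -- become novel-allele candidates when they stack more than 500
aligned reads over a contiguous span longer than 400 bp.  Per-allele
transcription is binned from the read count at one marker column (CDS
position 260, a position that differs between most alleles, so counts
there are allele specific).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mapper import AlignmentRecord
from .refdb import AlleleSequence
from ._align import encode

#: coverage floor defining "complete coverage" of an allele
DEFAULT_MIN_DEPTH = 5
#: a column is heterogeneous when the runner-up base reaches both of
#: these.  The frequency floor sits far above the sequencing-error
#: expectation (~0.1% per alternative base) yet below the smallest
#: minority an allele in the lowest expression tier contributes when its
#: reads stack on a reference shared with the highest tier (~9%) --
#: a 20% floor would hide exactly those low-expressed novel alleles.
DEFAULT_HET_MIN_COUNT = 10
DEFAULT_HET_MIN_FRAC = 0.05

MIN_CANDIDATE_READS = 500  # candidacy requires strictly more than this
MIN_CANDIDATE_SPAN = 400  # and a covered span strictly longer than this

_BASES = "ACGT"


@dataclass
class PileupSummary:
    """Per-position tally of aligned bases on one allele."""

    allele_id: str
    ref: str
    depth: np.ndarray  # reads whose alignment spans the position (M or D)
    base_counts: np.ndarray  # 5 x L: A, C, G, T, deletion
    n_reads: int
    min_depth: int
    covered_span: int
    span_start: int  # 0-based start of the longest covered run
    complete: bool
    mismatch_positions: list[int]
    het_positions: list[int]
    proper_read_ids: set[str] = field(default_factory=set)
    insertions: int = 0


def compute_pileup(
    records: list[AlignmentRecord],
    allele: AlleleSequence,
    min_depth: int = DEFAULT_MIN_DEPTH,
    het_min_count: int = DEFAULT_HET_MIN_COUNT,
    het_min_frac: float = DEFAULT_HET_MIN_FRAC,
) -> PileupSummary:
    """Tally per-position depth and base counts from cigar walks.

    Soft-clipped bases are excluded; deletions are tallied in their own
    row; insertions are counted but not positionally tallied.  The
    consensus base of a column is the majority base (ties resolved toward
    the reference base); a column is heterogeneous when the second most
    common base has count >= het_min_count and frequency >= het_min_frac.
    """
    L = len(allele.seq)
    counts = np.zeros((5, L), dtype=np.int32)
    depth = np.zeros(L, dtype=np.int32)
    insertions = 0
    proper_ids: set[str] = set()
    for rec in records:
        if rec.allele_id != allele.id:
            raise ValueError(
                f"record for {rec.allele_id} in pileup of {allele.id}"
            )
        read = encode(rec.aligned_seq)
        i = 0
        j = rec.ref_start
        for op, n in rec.cigar:
            if op == "S":
                i += n
            elif op == "M":
                seg = read[i : i + n]
                depth[j : j + n] += 1
                cols = np.arange(j, j + n)
                ok = seg < 4  # ambiguous read bases are not tallied
                np.add.at(counts, (seg[ok], cols[ok]), 1)
                i += n
                j += n
            elif op == "I":
                insertions += n
                i += n
            elif op == "D":
                depth[j : j + n] += 1
                counts[4, j : j + n] += 1
                j += n
        if rec.proper_pair:
            proper_ids.add(rec.read_id)

    covered = depth >= min_depth
    span_start, span_len = _longest_run(covered)
    complete = bool(covered.all()) and L > 0

    ref_codes = encode(allele.seq)
    mismatch_positions: list[int] = []
    het_positions: list[int] = []
    base4 = counts[:4]
    order = np.argsort(base4, axis=0, kind="stable")
    top = order[3]
    second = order[2]
    top_cnt = base4[top, np.arange(L)]
    sec_cnt = base4[second, np.arange(L)]
    for pos in np.nonzero(covered)[0]:
        t = int(top[pos])
        consensus = t
        # tie toward the reference base
        if top_cnt[pos] == base4[ref_codes[pos], pos]:
            consensus = int(ref_codes[pos])
        if consensus != int(ref_codes[pos]):
            mismatch_positions.append(int(pos))
        d = depth[pos]
        if (
            sec_cnt[pos] >= het_min_count
            and d > 0
            and sec_cnt[pos] / d >= het_min_frac
        ):
            het_positions.append(int(pos))

    return PileupSummary(
        allele_id=allele.id,
        ref=allele.seq,
        depth=depth,
        base_counts=counts,
        n_reads=len(records),
        min_depth=min_depth,
        covered_span=span_len,
        span_start=span_start,
        complete=complete,
        mismatch_positions=mismatch_positions,
        het_positions=het_positions,
        proper_read_ids=proper_ids,
        insertions=insertions,
    )


def _longest_run(mask: np.ndarray) -> tuple[int, int]:
    """(start, length) of the longest True run; (0, 0) when all False."""
    best_start = best_len = 0
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if i - start > best_len:
                best_start, best_len = start, i - start
            start = None
    if start is not None and len(mask) - start > best_len:
        best_start, best_len = start, len(mask) - start
    return best_start, best_len


def call_known(pileup: PileupSummary) -> bool:
    """Present iff coverage is complete with no mismatched or
    heterogeneous columns."""
    return (
        pileup.complete
        and not pileup.mismatch_positions
        and not pileup.het_positions
    )


@dataclass(frozen=True)
class CandidateRegion:
    """A pileup worth de novo reassembly: possibly a novel allele."""

    allele_id: str
    read_ids: frozenset[str]
    span_len: int
    n_reads: int


def find_candidates(
    pileups: list[PileupSummary],
    min_reads: int = MIN_CANDIDATE_READS,
    min_span: int = MIN_CANDIDATE_SPAN,
) -> list[CandidateRegion]:
    """Apply the candidate rule to one round of discovery pileups.

    A pileup is a candidate when it is NOT a present known allele, has
    strictly more than ``min_reads`` aligned reads over a covered span
    strictly longer than ``min_span``, and shows at least one mismatched
    or heterogeneous column.  Contributing reads are collected from proper
    pairs only.
    """
    out = []
    for p in pileups:
        if call_known(p):
            continue
        if p.n_reads <= min_reads or p.covered_span <= min_span:
            continue
        if not p.mismatch_positions and not p.het_positions:
            continue
        out.append(
            CandidateRegion(
                allele_id=p.allele_id,
                read_ids=frozenset(p.proper_read_ids),
                span_len=p.covered_span,
                n_reads=p.n_reads,
            )
        )
    return out


def consensus_sequence(pileup: PileupSummary) -> str:
    """Majority-base string over the longest covered run.

    Heterogeneous columns are masked as N; positions outside the covered
    run are omitted.
    """
    if pileup.covered_span == 0:
        raise ValueError("no covered span")
    start = pileup.span_start
    end = start + pileup.covered_span
    het = set(pileup.het_positions)
    base4 = pileup.base_counts[:4, start:end]
    ref_codes = encode(pileup.ref[start:end])
    top = np.argmax(base4, axis=0)
    top_cnt = base4[top, np.arange(end - start)]
    ref_cnt = base4[ref_codes, np.arange(end - start)]
    chars = []
    for k in range(end - start):
        if start + k in het:
            chars.append("N")
        elif top_cnt[k] == ref_cnt[k]:
            chars.append(pileup.ref[start + k])
        else:
            chars.append(_BASES[int(top[k])])
    return "".join(chars)


def pileups_to_table(pileups: list[PileupSummary]):
    """Tabular pileup/candidate report (one row per allele)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "allele_id": p.allele_id,
                "n_reads": p.n_reads,
                "span_len": p.covered_span,
                "complete": p.complete,
                "n_mismatch": len(p.mismatch_positions),
                "n_het": len(p.het_positions),
                "decision": "present" if call_known(p) else "absent",
            }
            for p in pileups
        ]
    )


EXPRESSION_BINS = ("low", "middle", "high")


def bin_expression(
    records: list[AlignmentRecord],
    marker_pos: int,
    allele_offset: int,
    allele_length: int,
) -> tuple[str, int]:
    """Bin transcription level from read counts at the marker column.

    ``marker_pos`` is a 1-based full-CDS coordinate; ``allele_offset`` is
    the number of CDS bases preceding the trimmed region, so the local
    1-based column is ``marker_pos - allele_offset``.  Counts reads whose
    reference-consuming span covers that column.  Bins: < 1000 low,
    1000-5000 middle (boundaries inclusive), > 5000 high.

    Returns (bin, count).
    """
    local = marker_pos - allele_offset  # 1-based
    if local < 1 or local > allele_length:
        raise ValueError(
            f"marker position {marker_pos} (local {local}) outside allele"
        )
    pos0 = local - 1
    n = sum(1 for rec in records if rec.covers(pos0))
    if n < 1000:
        return "low", n
    if n <= 5000:
        return "middle", n
    return "high", n
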