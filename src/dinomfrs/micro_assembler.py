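"""Stringent greedy overlap-layout-consensus micro-assembly.

Candidate read subsets extracted from mismatched alignments are reassembled
de novo under stringent overlap conditions (>= 40 bp overlap at >= 99%
identity): reads from two alleles that differ anywhere inside the overlap
refuse to merge, so a mixture of divergent alleles separates into one
contig per allele instead of collapsing onto an ambiguous consensus.

The assembler is deterministic: reads are strand-normalized, identical
reads are collapsed with multiplicity, all qualifying pairwise overlaps
are computed, and merges proceed best-score-first (ties: longer overlap,
then smallest member read id).  Consensus is a per-column majority vote
over the stacked reads.
"""

from __future__ import annotations

import heapq
import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, replace

import numpy as np

from . import _align
from .refdb import AlleleSequence, ReferenceDB, revcomp

log = logging.getLogger(__name__)

_KMER = 16
_STRIDE = 8
_BASES = "ACGT"

#: fixed overlap-score weights (reward per matching base, penalty per
#: mismatching base inside the overlap)
SCORE_MATCH = 3
SCORE_MISMATCH = 5


@dataclass(frozen=True)
class AssemblyParams:
    """Stringency gates for overlap acceptance.

    An overlap qualifies when its length is >= ``min_overlap_len``, its
    identity is >= ``min_overlap_identity`` and its score
    (3*matches - 5*mismatches) is >= ``min_overlap_score``.  Contigs
    supported by fewer than ``min_reads_per_contig`` reads are discarded.
    """

    min_overlap_len: int = 40
    min_overlap_identity: float = 0.99
    min_overlap_score: int = 120
    min_reads_per_contig: int = 20

    def __post_init__(self) -> None:
        if not (0.0 < self.min_overlap_identity <= 1.0):
            raise ValueError("identity must be in (0, 1]")
        if self.min_overlap_len < 16:
            raise ValueError("min_overlap_len must be >= 16")


@dataclass(frozen=True)
class Contig:
    """An assembled consensus with its supporting-read layout."""

    seq: str
    n_reads: int
    read_layout: tuple[tuple[str, int, str], ...]  # (read_id, offset, strand)
    full_length: bool = False


class _Working:
    """Mutable contig under assembly: consensus + column counts.

    Contigs are extended in place; ``left`` tracks how many columns have
    been prepended since creation so that edge offsets recorded in the
    contig's anchor frame stay valid as it grows.
    """

    __slots__ = ("cid", "key", "seq", "arr", "counts", "members",
                 "confirmed", "left")

    def __init__(self, cid, key, seq, counts, members):
        self.cid = cid
        self.key = key  # smallest member read id, for tie-breaking
        self.counts = counts  # 4 x L weighted base counts
        self.members = members  # list of (read_id, offset, strand)
        self.left = 0
        self.seq = seq
        self.arr = _align.encode(seq)
        self.confirmed = self._confirm()

    def _confirm(self) -> np.ndarray:
        # In a deep contig (>= 5 reads) a column is confirmed when >= 2
        # reads vouch for it AND the majority base holds a clear (>= 70%)
        # majority: the single-read growth frontier and tied columns are
        # provisional, so one error base cannot wall off a junction.  In
        # a shallow contig a single-read column carries the same trust as
        # a singleton read and everything is confirmed.
        if len(self.members) < 5:
            return np.ones(len(self.seq), dtype=bool)
        depth = self.counts.sum(axis=0)
        top = self.counts.max(axis=0)
        return (depth >= 2) & (top * 10 >= depth * 7)

    def absorb(self, other: "_Working", off: int) -> None:
        """Merge ``other`` into this contig at current-frame offset
        ``off`` (position of other's array start)."""
        shift = -min(0, off)
        L = max(len(self.seq) + shift, off + shift + len(other.seq))
        counts = np.zeros((4, L), dtype=np.int32)
        counts[:, shift : shift + len(self.seq)] += self.counts
        counts[:, off + shift : off + shift + len(other.seq)] += other.counts
        self.counts = counts
        self.left += shift
        if shift:
            self.members = [(rid, o + shift, s) for rid, o, s in self.members]
        self.members.extend(
            (rid, o + off + shift, s) for rid, o, s in other.members
        )
        cons = counts.argmax(axis=0)  # ties resolve to the smaller base code
        self.seq = "".join(_BASES[c] for c in cons)
        self.arr = _align.encode(self.seq)
        self.confirmed = self._confirm()
        self.key = min(self.key, other.key)


def _normalize_strands(reads: list[tuple[str, str]]) -> list[tuple[str, str, str]]:
    """Assign a consistent strand to every read via shared k-mers.

    Returns (read_id, oriented_seq, strand) with strand recording whether
    the read was flipped.  Reads already orientation-normalized come out
    unchanged.
    """
    idx: dict[str, list[tuple[int, str]]] = {}
    for n, (_rid, seq) in enumerate(reads):
        for p in range(0, max(1, len(seq) - _KMER + 1), _STRIDE):
            idx.setdefault(seq[p : p + _KMER], []).append((n, "f"))
        rc = revcomp(seq)
        for p in range(0, max(1, len(rc) - _KMER + 1), _STRIDE):
            idx.setdefault(rc[p : p + _KMER], []).append((n, "r"))
    strand: dict[int, str] = {}
    for n in range(len(reads)):
        if n in strand:
            continue
        strand[n] = "+"
        stack = [n]
        while stack:
            cur = stack.pop()
            seq = reads[cur][1] if strand[cur] == "+" else revcomp(reads[cur][1])
            # query every position against the stride-8 index so any
            # clean shared run >= 24 bp links the reads
            for p in range(max(1, len(seq) - _KMER + 1)):
                for m, tag in idx.get(seq[p : p + _KMER], ()):
                    if m in strand:
                        continue
                    strand[m] = "+" if tag == "f" else "-"
                    stack.append(m)
    out = []
    for n, (rid, seq) in enumerate(reads):
        s = strand.get(n, "+")
        out.append((rid, seq if s == "+" else revcomp(seq), s))
    return out


def _overlap_stats(a: _Working, b: _Working, off: int) -> tuple[int, int] | None:
    """(overlap length, mismatches) of b placed at ``off`` in a's frame.

    Mismatches are counted over mutually confirmed columns only: a
    disagreement against a single-read growth frontier is as likely a
    sequencing error as real divergence, so it neither counts against the
    overlap nor permanently walls off a junction.  At least half of the
    overlap must be mutually confirmed, which defers frontier-only
    overlaps until the frontier has consolidated.
    """
    ov, n_conf, mm = _align.masked_overlap(
        a.arr, a.confirmed, b.arr, b.confirmed, off
    )
    if ov <= 0 or n_conf * 2 < ov:
        return None
    return ov, mm


def _edge_ok(ov: int, mm: int, p: AssemblyParams) -> int | None:
    """Overlap score if the overlap passes all gates, else None."""
    if ov < p.min_overlap_len:
        return None
    matches = ov - mm
    if matches / ov < p.min_overlap_identity:
        return None
    score = SCORE_MATCH * matches - SCORE_MISMATCH * mm
    if score < p.min_overlap_score:
        return None
    return score


def assemble(
    reads: Mapping[str, str] | Iterable[tuple[str, str]],
    params: AssemblyParams = AssemblyParams(),
) -> list[Contig]:
    """Greedy OLC assembly of a read collection.

    Returns contigs with at least ``min_reads_per_contig`` supporting
    reads, sorted by read support (descending, then by sequence).  An
    all-singleton outcome yields an empty list.
    """
    items = list(reads.items()) if isinstance(reads, Mapping) else list(reads)
    if len(items) < 2:
        raise ValueError("need at least 2 reads")
    items.sort(key=lambda t: t[0])
    oriented = _normalize_strands(items)

    # collapse identical oriented sequences, keeping multiplicity
    by_seq: dict[str, list[tuple[str, str]]] = {}
    for rid, seq, strand in oriented:
        by_seq.setdefault(seq, []).append((rid, strand))

    contigs: dict[int, _Working] = {}
    for cid, (seq, members) in enumerate(sorted(by_seq.items())):
        counts = np.zeros((4, len(seq)), dtype=np.int32)
        arr = _align.encode(seq)
        ok = arr < 4
        counts[arr[ok], np.nonzero(ok)[0]] = len(members)
        mem = [(rid, 0, strand) for rid, strand in sorted(members)]
        contigs[cid] = _Working(cid, mem[0][0], seq, counts, mem)

    # Edge offsets are stored in "anchor" frames (the frame each contig
    # was created in); ostar = position of b's anchor origin in a's
    # anchor frame = off_current - a.left + b.left.  They stay valid as
    # contigs are extended in place.
    # edges[c][other] = set of ostar values already recorded
    edges: dict[int, dict[int, set[int]]] = {c: {} for c in contigs}
    heap: list[tuple] = []
    min_ov = params.min_overlap_len
    min_id = params.min_overlap_identity
    min_score = params.min_overlap_score

    def check(a: _Working, b: _Working, ostar: int) -> tuple[int, int] | None:
        """(score, overlap) at the anchor-frame offset, or None."""
        off = ostar - b.left + a.left
        if min(len(a.seq), off + len(b.seq)) - max(0, off) < min_ov:
            return None
        ov, n_conf, mm = _align.masked_overlap(
            a.arr, a.confirmed, b.arr, b.confirmed, off
        )
        if ov < min_ov or n_conf * 2 < ov:
            return None
        matches = ov - mm
        if matches / ov < min_id:
            return None
        score = SCORE_MATCH * matches - SCORE_MISMATCH * mm
        if score < min_score:
            return None
        return score, ov

    def try_edge(a: _Working, b: _Working, ostar: int, force: bool = False) -> None:
        if a.cid == b.cid:
            return
        known = edges[a.cid].setdefault(b.cid, set())
        if ostar in known:
            if not force:
                return
        else:
            known.add(ostar)
            edges[b.cid].setdefault(a.cid, set()).add(-ostar)
        res = check(a, b, ostar)
        if res is None:
            return
        heapq.heappush(
            heap,
            (-res[0], -res[1], min(a.key, b.key), max(a.key, b.key),
             a.cid, b.cid, ostar),
        )

    # initial candidate edges via stride-indexed shared k-mers; querying
    # every position against the stride-8 index detects every clean
    # shared run >= 24 bp, under the 40 bp overlap floor
    kidx: dict[str, list[tuple[int, int]]] = {}
    for cid, w in contigs.items():
        for p in range(0, max(1, len(w.seq) - _KMER + 1), _STRIDE):
            kidx.setdefault(w.seq[p : p + _KMER], []).append((cid, p))
    cand_set: set[tuple[int, int, int]] = set()
    for cid, w in contigs.items():
        seq = w.seq
        get = kidx.get
        add = cand_set.add
        for p in range(len(seq) - _KMER + 1):
            hits = get(seq[p : p + _KMER])
            if hits:
                for ocid, op in hits:
                    if ocid > cid:
                        add((cid, ocid, p - op))
                    elif ocid < cid:
                        add((ocid, cid, op - p))
    for ca, cb, off in sorted(cand_set):
        try_edge(contigs[ca], contigs[cb], off)  # left=0: off == ostar
    del cand_set

    # dead cid -> (absorber cid, anchor-frame position of the dead
    # contig's anchor origin within the absorber's anchor frame)
    redirect: dict[int, tuple[int, int]] = {}

    def resolve(cid: int) -> tuple[int, int]:
        orig = cid
        acc = 0
        while cid in redirect:
            cid, sh = redirect[cid][0], redirect[cid][1]
            acc += sh
        if orig != cid:
            redirect[orig] = (cid, acc)  # path compression
        return cid, acc

    while heap:
        negs, negov, _ka, _kb, ca, cb, ostar = heapq.heappop(heap)
        a = contigs.get(ca)
        b = contigs.get(cb)
        if a is None or b is None:
            continue
        # re-verify against current consensi (contigs may have grown)
        res = check(a, b, ostar)
        if res is None:
            continue
        if -negs != res[0] or -negov != res[1]:
            # stale score: re-queue with the fresh one
            heapq.heappush(
                heap, (-res[0], -res[1], min(a.key, b.key),
                       max(a.key, b.key), ca, cb, ostar))
            continue
        # absorb the smaller contig into the larger (stable identity for
        # the big one keeps its heap entries and edge map valid)
        if len(b.members) > len(a.members) or (
            len(b.members) == len(a.members) and b.cid < a.cid
        ):
            a, b = b, a
            ostar = -ostar
        off = ostar - b.left + a.left
        # anchor of b inside a's anchor frame, before a.left changes
        delta = off + b.left - a.left
        a.absorb(b, off)
        del contigs[b.cid]
        redirect[b.cid] = (a.cid, delta)
        for pc, ostars in edges.pop(b.cid, {}).items():
            live, acc = resolve(pc)
            if live == a.cid:
                continue
            other = contigs.get(live)
            if other is None:
                continue
            for o in ostars:
                # pc anchor at (delta + o) in a's anchor frame; live
                # anchor sits acc before pc's anchor.  Force a re-check:
                # a previously rejected offset may qualify now that the
                # absorbing contig has grown.
                try_edge(a, other, delta + o - acc, force=True)

    out = []
    for w in contigs.values():
        n = len(w.members)
        if n < params.min_reads_per_contig:
            continue
        # trim short provisional terminal overhangs next to deep columns:
        # in a deep assembly a 1-2 bp single-read overhang is a clipped
        # or error base hanging past the true end, not real sequence.
        # Long or shallow single-read ends are legitimate and kept.
        conf = np.nonzero(w.confirmed)[0]
        depth = w.counts.sum(axis=0)
        lo, hi = 0, len(w.seq)
        if conf.size:
            first, last = int(conf[0]), int(conf[-1])
            if 0 < first <= 5 and depth[first] >= 5:
                lo = first
            if 0 < len(w.seq) - 1 - last <= 5 and depth[last] >= 5:
                hi = last + 1
        out.append(
            Contig(
                seq=w.seq[lo:hi],
                n_reads=n,
                read_layout=tuple(
                    sorted((rid, o - lo, s) for rid, o, s in w.members)
                ),
            )
        )
    if not out:
        log.info("assembly yielded no contig above the read-support floor")
    out.sort(key=lambda c: (-c.n_reads, c.seq))
    return out




def write_contigs(contigs: list[Contig], fasta_path, layout_path) -> None:
    """Contig FASTA plus a layout TSV (read_id, contig_id, offset, strand)."""
    from Bio.Seq import Seq
    from Bio.SeqIO.FastaIO import FastaWriter
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(c.seq), id=f"contig{i + 1}",
                  description=f"n_reads={c.n_reads}")
        for i, c in enumerate(contigs)
    ]
    with open(fasta_path, "w") as fh:
        FastaWriter(fh, wrap=70).write_file(records)
    with open(layout_path, "w") as fh:
        fh.write("read_id\tcontig_id\toffset\tstrand\n")
        for i, c in enumerate(contigs):
            for rid, off, strand in c.read_layout:
                fh.write(f"{rid}\tcontig{i + 1}\t{off}\t{strand}\n")


def mark_full_length(
    contig: Contig, db: ReferenceDB, min_frac: float = 0.95
) -> Contig:
    """Set ``full_length`` from the contig's best coverage of any allele.

    True iff the contig's best local alignment to some database allele
    covers at least ``min_frac`` of that allele's length.
    """
    if len(db) == 0:
        raise ValueError("empty reference database")
    best = 0.0
    for allele in db.alleles:
        best = max(best, _coverage(contig.seq, allele))
        if best >= min_frac:
            break
    return replace(contig, full_length=best >= min_frac)


def _coverage(contig_seq: str, allele: AlleleSequence) -> float:
    """Fraction of the allele spanned by its best local alignment inside
    the contig (both orientations).

    Scoring is deliberately soft (+1/-1): this is a span question -- does
    the contig run the full length of an allele-like region -- so the
    alignment must extend through divergent but homologous stretches
    (novel alleles run up to ~20% local divergence), while unrelated
    sequence (~75% mismatches) still cannot extend.
    """
    q = _align.encode(allele.seq)
    cov = 0.0
    for target in (contig_seq, revcomp(contig_seq)):
        t = _align.encode(target)
        res = _align.banded_sw(
            q, t, -(len(allele.seq) - 1), len(target) - 1,
            1, 1, 2, 1, 0,
        )
        score, rs, re_ = res[0], res[1], res[2]
        if score > 0:
            cov = max(cov, (re_ - rs) / len(allele.seq))
    return cov
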