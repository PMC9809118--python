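"""Seed-and-extend read mapping against an allele reference database.

Reads are aligned to every allele with exact k-mer seeding followed by
banded, clip-aware, affine-gap local extension.  Two scoring regimes are
used by the discovery loop: a permissive DISCOVERY preset (match 1,
mismatch 4, band 100, clip 5) that lets reads from divergent, unknown
alleles align to their closest known relative, and a stringent VERIFY
preset (match 2, mismatch 5, band 30, clip 2) for the final confirmation
run, which avoids mapping of dissimilar fragments.

Multi-allele co-mapping is deliberate: a read pair is reported on *every*
allele that ties the best pair score, so reads from conserved segments
count toward the per-allele pileup of each tied allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pysam

from . import _align
from .refdb import AlleleSequence, ReferenceDB, revcomp

log = logging.getLogger(__name__)

_OPCHAR = {0: "M", 1: "I", 2: "D", 4: "S"}

Cigar = tuple[tuple[str, int], ...]


@dataclass(frozen=True)
class MapperParams:
    """Scoring regime for seed-and-extend alignment.

    ``band`` is the half-width of the diagonal band explored around seed
    diagonals; ``clip`` is charged once per soft-clipped read end;
    ``unpaired_penalty`` is subtracted from the pair score when the two
    mates of a fragment do not form a proper pair.
    """

    match: int
    mismatch: int
    band: int
    clip: int
    gap_open: int = 6
    gap_extend: int = 1
    unpaired_penalty: int = 17
    seed_len: int = 19
    min_score: int = 30


DISCOVERY = MapperParams(match=1, mismatch=4, band=100, clip=5, min_score=30)
VERIFY = MapperParams(match=2, mismatch=5, band=30, clip=2, min_score=40)


@dataclass(frozen=True)
class ReadPair:
    id: str
    seq1: str
    seq2: str
    qual1: str = ""
    qual2: str = ""

    def __post_init__(self) -> None:
        if not self.seq1 or not self.seq2:
            raise ValueError(f"read pair {self.id}: empty mate sequence")
        for q, s in ((self.qual1, self.seq1), (self.qual2, self.seq2)):
            if q and len(q) != len(s):
                raise ValueError(f"read pair {self.id}: quality length mismatch")


@dataclass
class AlignmentRecord:
    """One read's placement on one allele.

    ``cigar`` consumes exactly the read length (soft clips included) and is
    expressed in reference-forward orientation; for reverse-strand hits it
    therefore describes the reverse complement of ``seq``.
    """

    read_id: str
    mate: int
    allele_id: str
    ref_start: int  # 0-based
    cigar: Cigar
    score: int
    strand: str  # '+' or '-'
    proper_pair: bool
    edit_distance: int
    seq: str = ""
    qual: str = ""

    @property
    def ref_end(self) -> int:
        """0-based exclusive end on the reference."""
        return self.ref_start + sum(n for op, n in self.cigar if op in "MD")

    @property
    def aligned_seq(self) -> str:
        """Read sequence in reference-forward orientation."""
        return self.seq if self.strand == "+" else revcomp(self.seq)

    def covers(self, pos0: int) -> bool:
        """Whether the reference-consuming span covers 0-based ``pos0``."""
        return self.ref_start <= pos0 < self.ref_end


def score_from_cigar(
    rec: AlignmentRecord, allele_seq: str, params: MapperParams
) -> int:
    """Recompute the alignment score implied by a record's cigar."""
    read = rec.aligned_seq
    score = 0
    i = 0
    j = rec.ref_start
    clipped_ends = 0
    for idx, (op, n) in enumerate(rec.cigar):
        if op == "S":
            clipped_ends += 1
            i += n
        elif op == "M":
            for _ in range(n):
                score += params.match if read[i] == allele_seq[j] else -params.mismatch
                i += 1
                j += 1
        elif op == "I":
            score -= params.gap_open + n * params.gap_extend
            i += n
        elif op == "D":
            score -= params.gap_open + n * params.gap_extend
            j += n
    return score - clipped_ends * params.clip


# ---------------------------------------------------------------------------
# seed index + extension


class ReferenceIndex:
    """Exact k-mer index over both strands of every allele in a database."""

    def __init__(self, alleles: list[AlleleSequence], params: MapperParams):
        self.params = params
        self.alleles = alleles
        self.targets: list[tuple[int, str, str, np.ndarray]] = []
        k = params.seed_len
        for ai, allele in enumerate(alleles):
            if len(allele.seq) < k:
                log.warning("allele %s shorter than seed length", allele.id)
            for strand, seq in (("+", allele.seq), ("-", revcomp(allele.seq))):
                self.targets.append((ai, strand, seq, _align.encode(seq)))
        cat = np.concatenate([t[3] for t in self.targets])
        starts = np.zeros(len(self.targets) + 1, dtype=np.int64)
        np.cumsum([len(t[2]) for t in self.targets], out=starts[1:])
        self.lut, self.entries = _align.build_seed_index(cat, starts, k)

    def seed_diagonals(self, seq: str) -> dict[int, list[int]]:
        """target_idx -> sorted seed diagonals (ref_pos - read_pos)."""
        return self._seed_diagonals(_align.encode(seq))

    def _seed_diagonals(self, read_b: np.ndarray) -> dict[int, list[int]]:
        tis, diags = _align.seed_lookup(
            read_b, self.lut, self.entries, self.params.seed_len
        )
        out: dict[int, list[int]] = {}
        for n in range(tis.shape[0]):
            out.setdefault(int(tis[n]), []).append(int(diags[n]))
        return out

    def best_hits(self, seq: str) -> dict[int, tuple]:
        """Best alignment per allele for one read (forward as given).

        Returns allele_idx -> (score, strand, ref_start, read_start,
        read_end, cigar, nm); entries below min_score are omitted.
        """
        p = self.params
        if len(seq) < p.seed_len:
            return {}
        read_b = _align.encode(seq)
        cands = self._seed_diagonals(read_b)
        L = len(seq)
        gap_ceiling = L * p.match - p.gap_open - p.gap_extend
        # gapless pass first: when one target already scores above what
        # any gapped alignment can reach (gap_ceiling), the dynamic
        # program is provably unnecessary on every other target
        prelim: dict[int, tuple] = {}
        best_seen = -(2 ** 30)
        for ti in sorted(cands):
            g = _gapless_eval(read_b, self.targets[ti][3], sorted(cands[ti]), p)
            if g is not None:
                prelim[ti] = g
                best_seen = max(best_seen, g[0])
        best: dict[int, tuple] = {}
        for ti, g in sorted(
            prelim.items(), key=lambda kv: (-kv[1][0], kv[0])
        ):
            ai, strand, tseq, tb = self.targets[ti]
            if g[0] >= gap_ceiling or gap_ceiling < best_seen:
                res = g
            else:
                res = _dp_eval(read_b, tb, sorted(cands[ti]), p, g)
                best_seen = max(best_seen, res[0])
            if res[0] < p.min_score:
                continue
            hit = _orient_hit(res, strand, L, len(tseq))
            prev = best.get(ai)
            if prev is None or _hit_key(hit) < _hit_key(prev):
                best[ai] = hit
        return best


def _hit_key(hit: tuple) -> tuple:
    score, strand, ref_start = hit[0], hit[1], hit[2]
    return (-score, ref_start, 0 if strand == "+" else 1)


def _orient_hit(res: tuple, strand: str, read_len: int, tlen: int) -> tuple:
    """Convert a target-frame result to allele-forward coordinates."""
    score, rs, re_, ts, te, cigar, nm = res
    if strand == "+":
        return (score, "+", ts, rs, re_, cigar, nm)
    # mirror: target was the reverse complement of the allele
    a_start = tlen - te
    r_start = read_len - re_
    r_end = read_len - rs
    rev = tuple(reversed(cigar))
    return (score, "-", a_start, r_start, r_end, rev, nm)


def _gapless_eval(
    read_b: np.ndarray, ref_b: np.ndarray, diagonals: list[int], p: MapperParams
) -> tuple | None:
    """Best gapless segment over the seed diagonals, as a result tuple
    (score, read_start, read_end, ref_start, ref_end, cigar, nm)."""
    L = read_b.shape[0]
    best = None  # (score, ref_start, read_start, read_end, nm, diag)
    for d in diagonals:
        sc, rs, re_, nm = _align.gapless_scan(
            read_b, ref_b, d, p.match, p.mismatch, p.clip
        )
        if sc <= -(2 ** 29):
            continue
        key = (-sc, d + rs)
        if best is None or key < (-best[0], best[1]):
            best = (sc, d + rs, rs, re_, nm, d)
    if best is None:
        return None
    sc, ref_start, rs, re_, nm, d = best
    return (sc, rs, re_, ref_start, d + re_, _gapless_cigar(rs, re_, L), nm)


def _dp_eval(
    read_b: np.ndarray,
    ref_b: np.ndarray,
    diagonals: list[int],
    p: MapperParams,
    gapless: tuple | None,
) -> tuple:
    """Banded affine DP around the seed diagonals.

    A diagonal deviation of d from the seeds implies >= d gapped bases,
    so alignments beyond d_max = (L*match - gap_open - best_gapless) /
    gap_extend cannot beat the gapless score; the explored band shrinks
    accordingly.  Returns the better of the DP and gapless results.
    """
    L = read_b.shape[0]
    if gapless is not None:
        d_max = (L * p.match - p.gap_open - gapless[0]) // p.gap_extend + 1
        reach = min(p.band, max(1, d_max))
    else:
        reach = p.band
    result = gapless
    for d_lo, d_hi in _cluster(diagonals, p.band):
        lo = max(d_lo - reach, -(L - 1))
        hi = min(d_hi + reach, ref_b.shape[0] - 1)
        sc, rs, re_, ts, te, ops, lens, n_ops, nm = _align.banded_sw(
            read_b, ref_b, lo, hi, p.match, p.mismatch,
            p.gap_open, p.gap_extend, p.clip,
        )
        if sc <= -(2 ** 27):
            continue
        cand = (sc, rs, re_, ts, te, _dp_cigar(ops, lens, n_ops, rs, re_, L), nm)
        if result is None or (-cand[0], cand[3]) < (-result[0], result[3]):
            result = cand
    return result


def _evaluate_target(
    read_b: np.ndarray, ref_b: np.ndarray, diagonals: list[int], p: MapperParams
) -> tuple | None:
    """Best clip-aware local alignment of a read against one target.

    Gapless scan per seed diagonal first; the banded affine DP only runs
    when a gapped alignment could still beat the best gapless segment.
    Returns (score, read_start, read_end, ref_start, ref_end, cigar, nm)
    in target coordinates, or None.
    """
    L = read_b.shape[0]
    g = _gapless_eval(read_b, ref_b, diagonals, p)
    if g is not None and g[0] >= L * p.match - p.gap_open - p.gap_extend:
        return g
    return _dp_eval(read_b, ref_b, diagonals, p, g)


def _cluster(diagonals: list[int], band: int) -> list[tuple[int, int]]:
    """Group sorted diagonals whose windows would overlap."""
    groups = []
    lo = hi = diagonals[0]
    for d in diagonals[1:]:
        if d - hi <= 2 * band:
            hi = d
        else:
            groups.append((lo, hi))
            lo = hi = d
    groups.append((lo, hi))
    return groups


def _gapless_cigar(rs: int, re_: int, L: int) -> Cigar:
    parts = []
    if rs > 0:
        parts.append(("S", rs))
    parts.append(("M", re_ - rs))
    if re_ < L:
        parts.append(("S", L - re_))
    return tuple(parts)


def _dp_cigar(ops, lens, n_ops: int, rs: int, re_: int, L: int) -> Cigar:
    parts = []
    if rs > 0:
        parts.append(("S", rs))
    for t in range(n_ops):
        parts.append((_OPCHAR[int(ops[t])], int(lens[t])))
    if re_ < L:
        parts.append(("S", L - re_))
    return tuple(parts)


def _index_for(db: ReferenceDB, params: MapperParams) -> ReferenceIndex:
    cache = getattr(db, "_seed_index_cache", None)
    if cache is None:
        cache = {}
        db._seed_index_cache = cache  # type: ignore[attr-defined]
    idx = cache.get(params)
    if idx is None:
        idx = ReferenceIndex(db.alleles, params)
        cache[params] = idx
    return idx


# ---------------------------------------------------------------------------
# public alignment API


def align_read(
    seq: str, allele: AlleleSequence, params: MapperParams
) -> AlignmentRecord | None:
    """Best-scoring placement of a single read on a single allele.

    Both strands are tried; ties are broken by smaller reference start,
    then by forward strand.  Returns None when the best score falls below
    ``params.min_score`` (or the allele is shorter than the seed length).
    """
    if len(seq) < params.seed_len:
        raise ValueError("read shorter than seed length")
    if len(allele.seq) < params.seed_len:
        log.warning("allele %s shorter than seed length; skipped", allele.id)
        return None
    idx = ReferenceIndex([allele], params)
    hits = idx.best_hits(seq)
    if not hits:
        return None
    return _record_from_hit(hits[0], "", 0, allele.id, seq, "")


def _record_from_hit(
    hit: tuple, read_id: str, mate: int, allele_id: str, seq: str, qual: str
) -> AlignmentRecord:
    score, strand, ref_start, rs, re_, cigar, nm = hit
    return AlignmentRecord(
        read_id=read_id,
        mate=mate,
        allele_id=allele_id,
        ref_start=ref_start,
        cigar=cigar,
        score=score,
        strand=strand,
        proper_pair=False,
        edit_distance=nm,
        seq=seq,
        qual=qual,
    )


def pair_hits(
    h1: dict[int, tuple],
    h2: dict[int, tuple],
    read_len: int,
    params: MapperParams,
    max_fragment: int = 1000,
) -> tuple[list[int], int, dict[int, bool]]:
    """Combine per-allele mate hits into pair scores.

    Returns (tied allele indices, best pair score, proper flags).  A pair
    is proper on an allele when both mates align there on opposite strands
    with an implied fragment length within [read length, max_fragment];
    otherwise the pair score is charged the unpaired penalty.
    """
    scores: dict[int, int] = {}
    proper: dict[int, bool] = {}
    for ai in set(h1) | set(h2):
        a = h1.get(ai)
        b = h2.get(ai)
        if a is not None and b is not None:
            frag = max(a[2] + _ref_span(a), b[2] + _ref_span(b)) - min(a[2], b[2])
            is_proper = a[1] != b[1] and read_len <= frag <= max_fragment
            s = a[0] + b[0] - (0 if is_proper else params.unpaired_penalty)
        else:
            one = a if a is not None else b
            s = one[0] - params.unpaired_penalty
            is_proper = False
        scores[ai] = s
        proper[ai] = is_proper
    if not scores:
        return [], 0, {}
    top = max(scores.values())
    tied = sorted(ai for ai, s in scores.items() if s == top)
    return tied, top, proper


def _ref_span(hit: tuple) -> int:
    return sum(n for op, n in hit[5] if op in "MD")


#: a rescued mate must overlap the reference by at least this many bases
MIN_RESCUE_OVERLAP = 40
#: and match it at no less than this identity (random sequence peaks
#: around 0.39 over all diagonals of a ~550 bp reference)
MIN_RESCUE_IDENTITY = 0.65


def rescue_mate(
    seq: str, allele: AlleleSequence, strand: str, params: MapperParams
) -> tuple | None:
    """Mate rescue: place a mate near its aligned partner without seeding.

    The partner's strand dictates the expected orientation (``strand`` is
    the orientation to try).  The mate is placed full-length and gapless
    at the diagonal minimizing its mismatch fraction and accepted on
    identity rather than score: a mate sitting in a highly divergent
    stretch of a novel allele scores below any seeded-alignment floor yet
    its bases are exactly what the candidate pileup and the extraction
    step need.  This mirrors the emulated tool's mate rescue, which keeps
    both mates of an anchored fragment in the alignment.
    """
    read = seq if strand == "+" else revcomp(seq)
    read_b = _align.encode(read)
    ref_b = _align.encode(allele.seq)
    L = len(read)
    diag, ov, mm = _align.best_gapless_placement(
        read_b, ref_b, MIN_RESCUE_OVERLAP
    )
    if ov < MIN_RESCUE_OVERLAP or (ov - mm) / ov < MIN_RESCUE_IDENTITY:
        return None
    i0 = 0 if diag >= 0 else -diag
    i1 = i0 + ov
    score = (ov - mm) * params.match - mm * params.mismatch
    if i0 > 0:
        score -= params.clip
    if i1 < L:
        score -= params.clip
    cigar = _gapless_cigar(i0, i1, L)
    return (score, strand, diag + i0, i0, i1, cigar, mm)


def map_pair(
    pair: ReadPair, db: ReferenceDB, params: MapperParams
) -> list[AlignmentRecord]:
    """Align both mates against every allele; emit records for every
    allele tying the best pair score."""
    if len(db) == 0:
        raise ValueError("empty reference database")
    idx = _index_for(db, params)
    h1 = idx.best_hits(pair.seq1)
    h2 = idx.best_hits(pair.seq2)
    return pair_records(pair, h1, h2, db.alleles, params)


def pair_records(
    pair: ReadPair,
    h1: dict[int, tuple],
    h2: dict[int, tuple],
    alleles: list[AlleleSequence],
    params: MapperParams,
    rescue_cache: dict | None = None,
) -> list[AlignmentRecord]:
    """Resolve ties, rescue missing mates on tied alleles, build records."""
    read_len = max(len(pair.seq1), len(pair.seq2))
    tied, _, proper = pair_hits(h1, h2, read_len, params)
    records: list[AlignmentRecord] = []
    for ai in tied:
        aid = alleles[ai].id
        a, b = h1.get(ai), h2.get(ai)
        if (a is None) != (b is None):
            anchored = a if a is not None else b
            missing_mate = 2 if a is not None else 1
            mseq = pair.seq2 if missing_mate == 2 else pair.seq1
            want = "-" if anchored[1] == "+" else "+"
            key = (id(pair), ai, missing_mate)
            if rescue_cache is not None and key in rescue_cache:
                rescued = rescue_cache[key]
            else:
                rescued = rescue_mate(mseq, alleles[ai], want, params)
                if rescue_cache is not None:
                    rescue_cache[key] = rescued
            if rescued is not None:
                if missing_mate == 1:
                    a = rescued
                else:
                    b = rescued
        is_proper = proper[ai]
        if a is not None and b is not None and not is_proper:
            frag = max(a[2] + _ref_span(a), b[2] + _ref_span(b)) - min(a[2], b[2])
            is_proper = a[1] != b[1] and read_len <= frag <= 1000
        for mate, hit, seq, qual in (
            (1, a, pair.seq1, pair.qual1),
            (2, b, pair.seq2, pair.qual2),
        ):
            if hit is None:
                continue
            rec = _record_from_hit(hit, pair.id, mate, aid, seq, qual)
            rec.proper_pair = is_proper
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# I/O


def read_fastq_pairs(r1_path, r2_path) -> list[ReadPair]:
    """Read paired FASTQ files (plain or gzipped); ids must match in order."""
    pairs = []
    with pysam.FastxFile(str(r1_path)) as f1, pysam.FastxFile(str(r2_path)) as f2:
        for e1, e2 in zip(f1, f2, strict=True):
            n1 = e1.name.removesuffix("/1")
            n2 = e2.name.removesuffix("/2")
            if n1 != n2:
                raise ValueError(f"read id mismatch: {e1.name} vs {e2.name}")
            pairs.append(
                ReadPair(
                    id=n1,
                    seq1=e1.sequence,
                    seq2=e2.sequence,
                    qual1=e1.quality or "",
                    qual2=e2.quality or "",
                )
            )
    if not pairs:
        raise ValueError("no reads found")
    return pairs


def cigar_string(cigar: Cigar) -> str:
    return "".join(f"{n}{op}" for op, n in cigar)


def write_sam(records: list[AlignmentRecord], db: ReferenceDB, path) -> None:
    """Write records as a valid SAM file with @SQ lines per allele."""
    ids = {a.id for a in db.alleles}
    for rec in records:
        if rec.allele_id not in ids:
            raise ValueError(f"record references unknown allele {rec.allele_id}")
    mate_of = {}
    for rec in records:
        mate_of[(rec.read_id, rec.allele_id, rec.mate)] = rec
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for a in db.alleles:
            fh.write(f"@SQ\tSN:{a.id}\tLN:{len(a.seq)}\n")
        fh.write("@PG\tID:dinomfrs\tPN:dinomfrs\n")
        for rec in records:
            other = mate_of.get((rec.read_id, rec.allele_id, 3 - rec.mate))
            flag = 0x1
            flag |= 0x40 if rec.mate == 1 else 0x80
            if rec.strand == "-":
                flag |= 0x10
            if rec.proper_pair:
                flag |= 0x2
            if other is None:
                flag |= 0x8
                rnext, pnext, tlen = "*", 0, 0
            else:
                if other.strand == "-":
                    flag |= 0x20
                rnext = "="
                pnext = other.ref_start + 1
                lo = min(rec.ref_start, other.ref_start)
                hi = max(rec.ref_end, other.ref_end)
                tlen = hi - lo
                if rec.ref_start > other.ref_start or (
                    rec.ref_start == other.ref_start and rec.mate == 2
                ):
                    tlen = -tlen
            seq = rec.aligned_seq
            qual = rec.qual if rec.strand == "+" else rec.qual[::-1]
            fh.write(
                "\t".join(
                    [
                        rec.read_id,
                        str(flag),
                        rec.allele_id,
                        str(rec.ref_start + 1),
                        "60",
                        cigar_string(rec.cigar),
                        rnext,
                        str(pnext),
                        str(tlen),
                        seq,
                        qual or "*",
                        f"NM:i:{rec.edit_distance}",
                        f"AS:i:{rec.score}",
                    ]
                )
                + "\n"
            )
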