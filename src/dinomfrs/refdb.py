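"""Allele reference database: build, filter, version and persist.

The mapper aligns RNA-Seq reads against a curated library of MHC class I
allele sequences trimmed to the exon 2 - exon 3 region (the ~549 bp stretch
encoding the alpha-1/alpha-2 domains).  This module owns that library: it
validates sequences, removes near-duplicate alleles (fewer than ``min_diff``
edit-distance differences), and supports the iterative augmentation with
newly assembled alleles that drives the discovery loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import edlib
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

_VALID = frozenset("ACGT")

#: allowed trimmed-sequence lengths (nominal full region is 549 bp)
MIN_LEN = 400
MAX_LEN = 700

PROVENANCES = ("curated", "external", "novel")


class SequenceValidationError(ValueError):
    """Raised when a nucleotide sequence contains an invalid character."""


def clean_sequence(seq: str) -> str:
    """Uppercase, map U->T, and reject non-ACGT characters.

    Raises :class:`SequenceValidationError` naming the first offending
    (0-based) position.
    """
    s = seq.upper().replace("U", "T")
    for i, c in enumerate(s):
        if c not in _VALID:
            raise SequenceValidationError(
                f"invalid nucleotide {c!r} at position {i}"
            )
    return s


@dataclass(frozen=True)
class AlleleSequence:
    """A named exon2-exon3 nucleotide sequence with provenance.

    Parameters
    ----------
    id : str
        Allele label, e.g. ``"N*11:01"``, ``"LfL2003"`` or an accession.
    seq : str
        Uppercase nucleotide sequence over A/C/G/T.
    provenance : str
        One of ``curated`` (IPD-style reference), ``external`` (other
        database entry) or ``novel`` (assembled in-run).
    source : str
        Free-text accession or sample id.
    """

    id: str
    seq: str
    provenance: str = "curated"
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", clean_sequence(self.seq))
        if not self.seq:
            raise ValueError("empty sequence")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")

    def __len__(self) -> int:
        return len(self.seq)


def pairwise_differences(a: str, b: str) -> int:
    """Edit distance (substitutions + indels) between two sequences.

    This is the distance underlying the redundancy filter: alleles closer
    than ``min_diff`` are collapsed.  Symmetric; 0 iff identical.
    """
    a = clean_sequence(a)
    b = clean_sequence(b)
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if a == b:
        return 0
    return edlib.align(a, b, task="distance")["editDistance"]


@dataclass
class ReferenceDB:
    """An ordered, versioned collection of allele sequences.

    Invariant: after :func:`build_reference`, every retained pair differs in
    at least ``min_diff`` positions.  ``version`` increases by exactly one
    per augmentation.
    """

    alleles: list[AlleleSequence] = field(default_factory=list)
    version: int = 0
    min_diff: int = 5

    def __post_init__(self) -> None:
        ids = [a.id for a in self.alleles]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate allele ids in database")

    def __len__(self) -> int:
        return len(self.alleles)

    def __iter__(self):
        return iter(self.alleles)

    def __contains__(self, allele_id: str) -> bool:
        return any(a.id == allele_id for a in self.alleles)

    def get(self, allele_id: str) -> AlleleSequence:
        for a in self.alleles:
            if a.id == allele_id:
                return a
        raise KeyError(allele_id)

    @property
    def ids(self) -> list[str]:
        return [a.id for a in self.alleles]


def build_reference(
    candidates: list[AlleleSequence], min_diff: int = 5
) -> tuple[ReferenceDB, list[tuple[str, str]]]:
    """Greedy redundancy filter preserving input order.

    Retains a maximal subset, in input order, such that every retained pair
    differs in at least ``min_diff`` positions.  When a pair violates the
    threshold the later-listed member is dropped (curated entries are
    conventionally listed first and therefore win ties).

    Returns
    -------
    (db, drops)
        The filtered database (version 0) and a list of
        ``(dropped_id, kept_id)`` pairs for reporting.
    """
    if not candidates:
        raise ValueError("no candidate sequences supplied")
    ids = [a.id for a in candidates]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate allele ids: {dup}")
    kept: list[AlleleSequence] = []
    drops: list[tuple[str, str]] = []
    for cand in candidates:
        clash = None
        for prev in kept:
            if pairwise_differences(cand.seq, prev.seq) < min_diff:
                clash = prev
                break
        if clash is None:
            kept.append(cand)
        else:
            drops.append((cand.id, clash.id))
            log.info("dropping %s: <%d differences from %s",
                     cand.id, min_diff, clash.id)
    return ReferenceDB(alleles=kept, version=0, min_diff=min_diff), drops


def augment(
    db: ReferenceDB, novel: list[AlleleSequence]
) -> tuple[ReferenceDB, dict[str, str]]:
    """Append novel alleles, absorbing exact duplicates.

    Novel sequences identical to an existing allele (or to an earlier
    member of the same batch) are discarded and the existing id reported.
    All others are appended regardless of ``min_diff`` -- genuinely novel
    alleles may legitimately sit fewer than five differences from a known
    one.  The version counter is incremented once per call.

    Returns
    -------
    (new_db, identical)
        ``identical`` maps each discarded novel id to the id it matched.
    """
    existing = {a.id for a in db.alleles}
    for n in novel:
        if n.id in existing:
            raise ValueError(f"id collision: {n.id}")
    by_seq = {a.seq: a.id for a in db.alleles}
    added: list[AlleleSequence] = []
    identical: dict[str, str] = {}
    for n in novel:
        match = by_seq.get(n.seq)
        if match is not None:
            identical[n.id] = match
            log.info("novel %s identical to %s", n.id, match)
        else:
            added.append(n)
            by_seq[n.seq] = n.id
    return (
        ReferenceDB(
            alleles=db.alleles + added,
            version=db.version + 1,
            min_diff=db.min_diff,
        ),
        identical,
    )


def trim_to_anchor(
    seq: str, anchor: str, max_divergence: float = 0.35
) -> str | None:
    """Cut ``seq`` to the region matching a designated anchor allele.

    The anchor (a trimmed exon2-exon3 sequence) is located inside ``seq``
    by infix alignment on both strands; the matching span of ``seq`` is
    returned, or ``None`` when the best hit diverges more than
    ``max_divergence`` from the anchor.  This replaces multiple-alignment
    based trimming with a coordinate/anchor-driven cut.
    """
    seq = clean_sequence(seq)
    anchor = clean_sequence(anchor)
    best = None
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        res = edlib.align(anchor, s, mode="HW", task="locations")
        d = res["editDistance"]
        if d < 0:
            continue
        if best is None or d < best[0]:
            start, end = res["locations"][0]
            best = (d, s[start : end + 1])
    if best is None or best[0] > max_divergence * len(anchor):
        return None
    return best[1]


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement."""
    return seq.translate(_COMP)[::-1]


def read_fasta(path, provenance: str = "curated") -> list[AlleleSequence]:
    """Read alleles from FASTA; description after the id is kept as source."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(
            AlleleSequence(
                id=rec.id,
                seq=str(rec.seq),
                provenance=provenance,
                source=rec.description[len(rec.id) :].strip(),
            )
        )
    return out


def write_fasta(db: ReferenceDB | list[AlleleSequence], path) -> None:
    """Write alleles as FASTA wrapped at 70 columns."""
    alleles = db.alleles if isinstance(db, ReferenceDB) else db
    records = [
        SeqRecord(Seq(a.seq), id=a.id, description=a.source)
        for a in alleles
    ]
    with open(path, "w") as fh:
        FastaWriter(fh, wrap=70).write_file(records)


def with_provenance(a: AlleleSequence, provenance: str) -> AlleleSequence:
    return replace(a, provenance=provenance)
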