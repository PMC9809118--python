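"""Characterization of confirmed alleles.

Closest-known-allele identity (as printed in genotype tables), translation
and IPD-style amino-acid numbering, classical vs putative non-classical
grouping from the 31 antigen-contact positions, gene-conversion screening
(identical flanks around a divergent core), and window diversity
statistics.

Amino-acid numbering: the trimmed nucleotide region starts at full-CDS
position ``cds_offset + 1`` (default 74); the first complete codon then
begins at local position 3 (frame offset 2) and corresponds to amino acid
26.  This frame is validated against the anchor that CDS positions
256-264 encode residues 86-88.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .refdb import AlleleSequence, ReferenceDB, clean_sequence

#: defaults tying the trimmed region to IPD full-CDS numbering
DEFAULT_CDS_OFFSET = 73
DEFAULT_FRAME_OFFSET = 2
DEFAULT_AA_START = 26

#: residues occurring exclusively in the putative non-classical groups
#: (contact positions only), keyed by group
GROUP_MARKERS = {
    "group1": {62: "H", 65: "L", 69: "T", 91: "I", 122: "G",
               161: "R", 170: "L", 180: "F", 186: "N"},
    "group2": {88: "N", 181: "V"},
}


@dataclass(frozen=True)
class ContactPositionSet:
    """The 31 antigen-contact amino-acid positions (IPD numbering)."""

    positions: tuple[int, ...]
    pocket_labels: dict[int, str] | None = None

    def __post_init__(self) -> None:
        if len(self.positions) != 31:
            raise ValueError("contact set must contain exactly 31 positions")
        if list(self.positions) != sorted(set(self.positions)):
            raise ValueError("positions must be strictly increasing")


def load_contact_positions() -> ContactPositionSet:
    """Load the packaged contact-position curation."""
    text = (
        resources.files("dinomfrs.data")
        .joinpath("contact_positions_synthetic.tsv")
        .read_text()
    )
    positions = []
    pockets = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("position"):
            continue
        pos, pocket = line.split("\t")
        positions.append(int(pos))
        pockets[int(pos)] = pocket
    return ContactPositionSet(tuple(positions), pockets)


# ---------------------------------------------------------------------------
# identity


def _global_aligner() -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -1
    a.extend_gap_score = -1
    return a


def percent_identity(a: str, b: str) -> float:
    """Identity over a global alignment, percent to one decimal.

    Scoring +1 match / -1 mismatch / -1 gap; identity is matches divided
    by alignment columns.
    """
    a = clean_sequence(a)
    b = clean_sequence(b)
    if a == b:
        return 100.0
    aln = _global_aligner().align(a, b)[0]
    counts = aln.counts()
    return round(counts.identities / aln.length * 100.0, 1)


def closest_allele(
    query: str | AlleleSequence, db: ReferenceDB
) -> tuple[str, float]:
    """Database allele maximizing percent identity (ties: earlier-listed)."""
    if len(db) == 0:
        raise ValueError("empty reference database")
    qseq = query.seq if isinstance(query, AlleleSequence) else query
    best_id = None
    best_pct = -1.0
    for allele in db.alleles:
        pct = percent_identity(qseq, allele.seq)
        if pct > best_pct:
            best_id, best_pct = allele.id, pct
    return best_id, best_pct


# ---------------------------------------------------------------------------
# coordinates & translation


def cds_to_aa(nt_pos: int) -> int:
    """One-based amino-acid index of the codon containing CDS position
    ``nt_pos`` (one-based from the first base of the start codon)."""
    if nt_pos < 1:
        raise ValueError("CDS position must be >= 1")
    return (nt_pos + 2) // 3


def translate(nt: str, frame_offset: int = 0) -> str:
    """Standard-code translation; stops as '*', ambiguous codons as 'X'.

    The trailing partial codon is dropped.
    """
    if len(nt) - frame_offset < 3:
        raise ValueError("fewer than one codon after the frame offset")
    s = nt.upper().replace("U", "T")[frame_offset:]
    s = s[: len(s) - len(s) % 3]
    return str(Seq(s).translate())


def translate_allele(
    seq: str,
    frame_offset: int = DEFAULT_FRAME_OFFSET,
    aa_start: int = DEFAULT_AA_START,
) -> tuple[str, int]:
    """(amino-acid sequence, IPD number of its first residue)."""
    return translate(seq, frame_offset), aa_start


# ---------------------------------------------------------------------------
# classification


def contact_residues(
    aa_seq: str, contacts: ContactPositionSet, aa_start: int = DEFAULT_AA_START
) -> str | None:
    """Extract the residues at the 31 contact positions, or None when the
    sequence does not span them all."""
    out = []
    for pos in contacts.positions:
        idx = pos - aa_start
        if idx < 0 or idx >= len(aa_seq):
            return None
        out.append(aa_seq[idx])
    return "".join(out)


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def classify_alleles(
    aa_records: dict[str, str],
    contacts: ContactPositionSet | None = None,
    max_diff: int = 3,
    klow: int = 3,
    aa_start: int = DEFAULT_AA_START,
) -> dict[str, tuple[str, list[str]]]:
    """Group alleles by their antigen-contact residues.

    Single-linkage clustering by Hamming distance restricted to the 31
    contact positions with linkage threshold ``max_diff``; clusters of at
    least ``klow`` alleles whose within-cluster contact diversity stays
    within ``max_diff`` are labeled "putative non-classical" (low contact
    diversity is the hallmark of non-classical class I genes), the rest
    "classical".  Sequences not spanning all contact positions are
    "unclassified".

    Returns allele_id -> (class_call, matched group-marker residues like
    ``["62H", "65L"]``).
    """
    if contacts is None:
        contacts = load_contact_positions()
    ids = sorted(aa_records)
    profile = {
        i: contact_residues(aa_records[i], contacts, aa_start) for i in ids
    }
    valid = [i for i in ids if profile[i] is not None]
    # single linkage via union-find with deterministic order
    parent = {i: i for i in valid}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for n, i in enumerate(valid):
        for j in valid[n + 1 :]:
            if _hamming(profile[i], profile[j]) <= max_diff:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    clusters: dict[str, list[str]] = {}
    for i in valid:
        clusters.setdefault(find(i), []).append(i)

    out: dict[str, tuple[str, list[str]]] = {}
    for i in ids:
        if profile[i] is None:
            out[i] = ("unclassified", [])
            continue
        members = clusters[find(i)]
        diverse = max(
            (_hamming(profile[a], profile[b])
             for n, a in enumerate(members) for b in members[n + 1 :]),
            default=0,
        )
        call = (
            "putative non-classical"
            if len(members) >= klow and diverse <= max_diff
            else "classical"
        )
        hits = []
        for group in sorted(GROUP_MARKERS):
            for pos, res in sorted(GROUP_MARKERS[group].items()):
                idx = pos - aa_start
                if 0 <= idx < len(aa_records[i]) and aa_records[i][idx] == res:
                    hits.append(f"{pos}{res}")
        out[i] = (call, hits)
    return out


@dataclass(frozen=True)
class AnnotationRecord:
    allele_id: str
    closest_id: str
    closest_identity: float
    aa_seq: str
    class_call: str
    marker_hits: tuple[str, ...]


def annotate_alleles(
    alleles: list[AlleleSequence],
    db: ReferenceDB,
    contacts: ContactPositionSet | None = None,
    frame_offset: int = DEFAULT_FRAME_OFFSET,
    aa_start: int = DEFAULT_AA_START,
) -> list[AnnotationRecord]:
    """Closest-reference identity, translation and class call per allele."""
    aa = {a.id: translate(a.seq, frame_offset) for a in alleles}
    calls = classify_alleles(aa, contacts, aa_start=aa_start)
    out = []
    for a in alleles:
        cid, pct = closest_allele(a, db)
        call, hits = calls[a.id]
        out.append(
            AnnotationRecord(a.id, cid, pct, aa[a.id], call, tuple(hits))
        )
    return out


def annotations_to_table(records: list[AnnotationRecord]):
    """Tabular annotation report (allele, closest match, identity, class)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "allele": r.allele_id,
                "closest": r.closest_id,
                "identity_pct": r.closest_identity,
                "class": r.class_call,
                "marker_hits": ",".join(r.marker_hits),
            }
            for r in records
        ]
    )


# ---------------------------------------------------------------------------
# gene conversion & diversity


@dataclass(frozen=True)
class GeneConversionReport:
    """Identical flanks around a divergent core between two alleles."""

    flank5_len: int
    core_start: int  # 1-based inclusive on the trimmed region
    core_end: int
    core_divergence: float
    flank3_len: int


def detect_gene_conversion(
    a: str,
    b: str,
    min_flank: int = 200,
    min_core_div: float = 0.10,
    min_core_len: int = 50,
) -> GeneConversionReport | None:
    """Screen an equal-length aligned pair for a gene-conversion signature.

    Reports when the maximal identical prefix and suffix each reach
    ``min_flank`` and the intervening core (>= ``min_core_len``) diverges
    by >= ``min_core_div``.
    """
    a = clean_sequence(a)
    b = clean_sequence(b)
    if len(a) != len(b):
        raise ValueError("pair must be equal-length (aligned)")
    L = len(a)
    p = 0
    while p < L and a[p] == b[p]:
        p += 1
    if p == L:
        return None  # identical pair
    s = 0
    while s < L - p and a[L - 1 - s] == b[L - 1 - s]:
        s += 1
    core_len = L - p - s
    if p < min_flank or s < min_flank or core_len < min_core_len:
        return None
    div = _hamming(a[p : L - s], b[p : L - s]) / core_len
    if div < min_core_div:
        return None
    return GeneConversionReport(
        flank5_len=p,
        core_start=p + 1,
        core_end=L - s,
        core_divergence=div,
        flank3_len=s,
    )


def diversity_stats(
    alleles: list[AlleleSequence] | list[str],
    window_start: int,
    window_end: int,
    cds_offset: int = DEFAULT_CDS_OFFSET,
) -> tuple[float, int, int]:
    """(mean, max pairwise substitution count, window length) over a
    full-CDS coordinate window.

    Alleles not spanning the window are excluded with a warning.
    """
    import logging

    if window_end < window_start:
        raise ValueError("empty window")
    lo = window_start - cds_offset - 1  # 0-based local
    hi = window_end - cds_offset  # exclusive
    win_len = window_end - window_start + 1
    seqs = []
    for a in alleles:
        seq = a.seq if isinstance(a, AlleleSequence) else clean_sequence(a)
        if lo < 0 or hi > len(seq):
            logging.getLogger(__name__).warning(
                "allele does not span the window; excluded"
            )
            continue
        seqs.append(seq[lo:hi])
    if len(seqs) < 2:
        raise ValueError("need at least two alleles spanning the window")
    diffs = [
        _hamming(seqs[i], seqs[j])
        for i in range(len(seqs))
        for j in range(i + 1, len(seqs))
    ]
    return round(sum(diffs) / len(diffs), 1), max(diffs), win_len
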