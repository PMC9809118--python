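"""Locating RNA-derived alleles in genomic contigs.

A transcribed exon2-exon3 allele maps to the genome as two exon hits
separated by an intron.  Each exon is aligned separately (both strands)
against every contig; colinear hit pairs on one strand with an intron-
sized gap are reported with per-exon identities and coordinates in the
contig's forward-strand numbering -- for reverse-orientation matches the
per-exon start is greater than the end, matching the usual reporting
convention for minus-strand BLAST-style hits.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

from .refdb import AlleleSequence, clean_sequence, revcomp

#: nominal exon2 length within the trimmed region
DEFAULT_BOUNDARY = 272
#: plausible intron-size window for pairing exon hits
INTRON_RANGE = (50, 5000)

_CIG = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class ExonHit:
    start: int  # 1-based inclusive, forward-strand numbering
    end: int
    identity: float  # percent


@dataclass(frozen=True)
class GenomicMatch:
    allele_id: str
    contig_id: str
    orientation: str  # "forward" | "reverse"
    exon2: ExonHit
    exon3: ExonHit
    intron_len: int


def split_exons(allele: AlleleSequence, boundary: int) -> tuple[str, str]:
    """Cut the trimmed region at the exon2/exon3 boundary."""
    if not (0 < boundary < len(allele.seq)):
        raise ValueError(
            f"boundary {boundary} out of range for {len(allele.seq)} bp allele"
        )
    return allele.seq[:boundary], allele.seq[boundary:]


def _best_infix(query: str, target: str) -> tuple[int, int, float] | None:
    """Best infix placement of query in target: (start0, end0_excl,
    identity%)."""
    res = edlib.align(query, target, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    start, end = res["locations"][0]
    matches = 0
    cols = 0
    for n, op in _CIG.findall(res["cigar"]):
        n = int(n)
        cols += n
        if op == "=":
            matches += n
    return start, end + 1, round(matches / cols * 100.0, 1)


def match_to_genome(
    allele: AlleleSequence,
    contigs: dict[str, str] | list[tuple[str, str]],
    boundary: int = DEFAULT_BOUNDARY,
    min_identity: float = 80.0,
    intron_range: tuple[int, int] = INTRON_RANGE,
) -> list[GenomicMatch]:
    """Best exon2+intron+exon3 placement of an allele per contig.

    Hit pairs are kept when both exons land on the same contig and strand,
    colinear in transcript orientation, with an intron gap inside
    ``intron_range`` and both identities >= ``min_identity``.
    """
    exon2, exon3 = split_exons(allele, boundary)
    items = contigs.items() if isinstance(contigs, dict) else contigs
    out: list[GenomicMatch] = []
    for contig_id, seq in items:
        seq = clean_sequence(seq)
        L = len(seq)
        best: GenomicMatch | None = None
        for orientation in ("forward", "reverse"):
            t = seq if orientation == "forward" else revcomp(seq)
            h2 = _best_infix(exon2, t)
            h3 = _best_infix(exon3, t)
            if h2 is None or h3 is None:
                continue
            if h2[2] < min_identity or h3[2] < min_identity:
                continue
            gap = h3[0] - h2[1]
            if not (intron_range[0] <= gap <= intron_range[1]):
                continue
            if orientation == "forward":
                e2 = ExonHit(h2[0] + 1, h2[1], h2[2])
                e3 = ExonHit(h3[0] + 1, h3[1], h3[2])
            else:
                # reflect oriented coordinates back to the forward strand;
                # start > end marks the reverse orientation
                e2 = ExonHit(L - h2[0], L - h2[1] + 1, h2[2])
                e3 = ExonHit(L - h3[0], L - h3[1] + 1, h3[2])
            cand = GenomicMatch(
                allele_id=allele.id,
                contig_id=contig_id,
                orientation=orientation,
                exon2=e2,
                exon3=e3,
                intron_len=gap,
            )
            if best is None or (e2.identity + e3.identity) > (
                best.exon2.identity + best.exon3.identity
            ):
                best = cand
        if best is not None:
            out.append(best)
    return out


def matches_to_table(matches: list[GenomicMatch]):
    """Tabular report mirroring the per-allele genomic-alignment layout."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "allele": m.allele_id,
                "contig": m.contig_id,
                "orientation": m.orientation,
                "exon2_start": m.exon2.start,
                "exon2_end": m.exon2.end,
                "exon2_identity": m.exon2.identity,
                "intron_len": m.intron_len,
                "exon3_start": m.exon3.start,
                "exon3_end": m.exon3.end,
                "exon3_identity": m.exon3.identity,
            }
            for m in matches
        ]
    )
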