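"""The discovery loop: map, call, extract, reassemble, augment, verify.

Per individual: reads are mapped to the current reference database under
the permissive DISCOVERY regime; alleles with complete mismatch-free
coverage are called as known; mismatched pileups stacking >500 reads over
>400 bp become candidates; the proper-pair reads of all candidates are
pooled and reassembled under stringent overlap conditions; full-length
contigs are named (LfL####), added to the database, and the loop repeats
until a round adds nothing.  A final stringent VERIFY mapping against the
individual-complete database confirms each allele: complete mismatch-free
coverage plus paired-read support at both sequence ends.
"""

from __future__ import annotations

import json
import logging
from zlib import crc32
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import allele_caller as ac
from . import mapper as mp
from . import micro_assembler as asm
from . import refdb as rd

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of the discovery loop, nested from the other modules."""

    max_rounds: int = 5
    novel_prefix: str = "LfL"
    novel_counter_start: int = 2001
    min_depth: int = ac.DEFAULT_MIN_DEPTH
    het_min_count: int = ac.DEFAULT_HET_MIN_COUNT
    het_min_frac: float = ac.DEFAULT_HET_MIN_FRAC
    candidate_min_reads: int = ac.MIN_CANDIDATE_READS
    candidate_min_span: int = ac.MIN_CANDIDATE_SPAN
    assembly: asm.AssemblyParams = field(default_factory=asm.AssemblyParams)
    discovery: mp.MapperParams = mp.DISCOVERY
    verify: mp.MapperParams = mp.VERIFY
    marker_pos: int = 260  # full-CDS coordinate of the expression marker
    cds_offset: int = 73
    end_window: int = 30
    full_length_frac: float = 0.95
    extraction_pos_cap: int = 1  # pairs kept per (ref start, mate) bucket
    extraction_end_cap: int = 3  # deeper cap near the reference ends
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, sub in (
            ("assembly", asm.AssemblyParams),
            ("discovery", mp.MapperParams),
            ("verify", mp.MapperParams),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class GenotypeAllele:
    allele_id: str
    status: str  # "known" | "novel"
    expression: str  # "low" | "middle" | "high"
    n_reads_marker: int


@dataclass
class Genotype:
    """Verified per-individual allele set."""

    individual_id: str
    alleles: list[GenotypeAllele]
    db_version_final: int
    rounds: int

    @property
    def allele_ids(self) -> list[str]:
        return [a.allele_id for a in self.alleles]


class NovelNamer:
    """Hands out provisional LfL#### names; one name per distinct contig."""

    def __init__(self, prefix: str = "LfL", start: int = 2001):
        self.prefix = prefix
        self.counter = start
        self._by_seq: dict[str, str] = {}

    def name(self, seq: str) -> str:
        known = self._by_seq.get(seq)
        if known is not None:
            return known
        if self.counter > 9999:
            raise OverflowError("novel-allele counter exhausted")
        name = f"{self.prefix}{self.counter:04d}"
        self.counter += 1
        self._by_seq[seq] = name
        return name


def name_novel(namer: NovelNamer, contig: asm.Contig) -> str:
    """Provisional name for a contig (identical contigs share one name)."""
    return namer.name(contig.seq)


def verify_allele(
    records: list[mp.AlignmentRecord],
    allele: rd.AlleleSequence,
    min_depth: int = ac.DEFAULT_MIN_DEPTH,
    end_window: int = 30,
    het_min_count: int = ac.DEFAULT_HET_MIN_COUNT,
    het_min_frac: float = ac.DEFAULT_HET_MIN_FRAC,
) -> bool:
    """Final confirmation of one allele from stringent-regime alignments.

    Pass iff coverage is complete and mismatch-free AND each terminal
    window (first and last ``end_window`` bases) is covered by at least
    one read belonging to a proper pair -- reads without an anchored mate
    do not count toward the sequence ends, which guards against
    recombination/misalignment artifacts there.
    """
    if not records:
        return False
    pileup = ac.compute_pileup(
        records, allele, min_depth, het_min_count, het_min_frac
    )
    if not ac.call_known(pileup):
        return False
    L = len(allele.seq)
    head = False
    tail = False
    for rec in records:
        if not rec.proper_pair:
            continue
        if rec.ref_start < end_window:
            head = True
        if rec.ref_end > L - end_window:
            tail = True
        if head and tail:
            return True
    return False


# ---------------------------------------------------------------------------
# cached multi-round mapping


class _IterativeMapper:
    """Maps a fixed read set against a growing allele list, aligning each
    pair only against alleles added since its last pass."""

    def __init__(self, pairs: list[mp.ReadPair], params: mp.MapperParams):
        self.pairs = pairs
        self.params = params
        self.hits1: list[dict[int, tuple]] = [dict() for _ in pairs]
        self.hits2: list[dict[int, tuple]] = [dict() for _ in pairs]
        self.rescue_cache: dict = {}
        self.n_indexed = 0

    def extend(self, alleles: list[rd.AlleleSequence]) -> None:
        new = alleles[self.n_indexed :]
        if not new:
            return
        idx = mp.ReferenceIndex(new, self.params)
        base = self.n_indexed
        for n, pair in enumerate(self.pairs):
            for store, seq in ((self.hits1, pair.seq1), (self.hits2, pair.seq2)):
                for ai, hit in idx.best_hits(seq).items():
                    store[n][base + ai] = hit
        self.n_indexed = len(alleles)

    def records_by_allele(
        self, alleles: list[rd.AlleleSequence]
    ) -> dict[str, list[mp.AlignmentRecord]]:
        """Tie-resolved records grouped per allele id."""
        out: dict[str, list[mp.AlignmentRecord]] = {}
        for n, pair in enumerate(self.pairs):
            h1 = self.hits1[n]
            h2 = self.hits2[n]
            if not h1 and not h2:
                continue
            recs = mp.pair_records(
                pair, h1, h2, alleles, self.params, self.rescue_cache
            )
            for rec in recs:
                out.setdefault(rec.allele_id, []).append(rec)
        return out


def _extract_candidate_reads(
    candidates: list[ac.CandidateRegion],
    records_by_allele: dict[str, list[mp.AlignmentRecord]],
    pos_cap: int,
    end_cap: int | None = None,
) -> dict[str, str]:
    """Pool proper-pair reads from all candidates of one round.

    Reads are orientation-normalized to the forward strand of the
    reference they aligned to, and the pool is positionally subsampled
    (at most ``pos_cap`` pairs per (reference start, mate, edit-distance
    class) bucket) so coverage stays bounded while every start position
    -- including the terminal ones -- remains represented.  Bucketing by
    edit-distance class (reference-like, <= 2, vs divergent, >= 3) keeps
    the mismatching reads of a weakly expressed hidden allele from
    competing for cap slots with the reads of a strongly expressed
    reference.  Mates whose
    alignment contains an indel (a sequencing-error artifact between
    substitution-only alleles) are excluded: out of register with the
    gapless read stack, they would corrupt consensus extensions.
    """
    if end_cap is None:
        end_cap = max(pos_cap, 3)
    pool: dict[str, str] = {}
    for cand in candidates:
        buckets: dict[tuple[int, int], int] = {}
        recs = records_by_allele.get(cand.allele_id, [])
        if not recs:
            continue
        max_end = max(r.ref_end for r in recs)
        chosen: set[str] = set()
        # within-bucket order via a deterministic hash so co-mapping
        # alleles share the cap slots evenly regardless of id order
        for rec in sorted(
            recs,
            key=lambda r: (r.ref_start, r.mate, crc32(r.read_id.encode())),
        ):
            if rec.read_id not in cand.read_ids or not rec.proper_pair:
                continue
            if any(op in "ID" for op, _ in rec.cigar):
                continue
            key = (rec.ref_start, rec.mate, rec.edit_distance >= 3)
            cap = (
                end_cap
                if rec.ref_start <= 5 or rec.ref_end >= max_end - 5
                else pos_cap
            )
            if buckets.get(key, 0) >= cap:
                continue
            buckets[key] = buckets.get(key, 0) + 1
            chosen.add(rec.read_id)
        for rec in recs:
            if rec.read_id in chosen and not any(
                op in "ID" for op, _ in rec.cigar
            ):
                pool.setdefault(f"{rec.read_id}/{rec.mate}", rec.aligned_seq)
    return pool


def run_individual(
    r1,
    r2,
    db: rd.ReferenceDB,
    cfg: RunConfig,
    individual_id: str = "",
    namer: NovelNamer | None = None,
) -> tuple[Genotype, rd.ReferenceDB]:
    """Genotype one individual and return the augmented shared database.

    The returned database is the input database plus every *verified*
    novel allele; provisional contigs that fail the final verification are
    not propagated.
    """
    pairs = mp.read_fastq_pairs(r1, r2)
    return run_pairs(pairs, db, cfg, individual_id, namer)


def run_pairs(
    pairs: list[mp.ReadPair],
    db: rd.ReferenceDB,
    cfg: RunConfig,
    individual_id: str = "",
    namer: NovelNamer | None = None,
) -> tuple[Genotype, rd.ReferenceDB]:
    """As :func:`run_individual`, from in-memory read pairs."""
    if not pairs:
        raise ValueError("zero reads")
    if namer is None:
        namer = NovelNamer(cfg.novel_prefix, cfg.novel_counter_start)

    working = list(db.alleles)
    original_ids = {a.id for a in db.alleles}
    imap = _IterativeMapper(pairs, cfg.discovery)
    rounds = 0
    round_log: list[dict] = []
    while rounds < cfg.max_rounds:
        rounds += 1
        imap.extend(working)
        by_allele = imap.records_by_allele(working)
        pileups = []
        for allele in working:
            recs = by_allele.get(allele.id)
            if recs:
                pileups.append(
                    ac.compute_pileup(
                        recs, allele, cfg.min_depth,
                        cfg.het_min_count, cfg.het_min_frac,
                    )
                )
        candidates = ac.find_candidates(
            pileups, cfg.candidate_min_reads, cfg.candidate_min_span
        )
        entry = {
            "round": rounds,
            "n_alleles": len(working),
            "present_known": [
                p.allele_id for p in pileups if ac.call_known(p)
            ],
            "candidates": [c.allele_id for c in candidates],
            "added": [],
        }
        round_log.append(entry)
        if not candidates:
            break
        pool = _extract_candidate_reads(
            candidates, by_allele, cfg.extraction_pos_cap,
            cfg.extraction_end_cap,
        )
        if len(pool) < 2:
            break
        contigs = asm.assemble(pool, cfg.assembly)
        snapshot = rd.ReferenceDB(
            alleles=list(working), version=0, min_diff=db.min_diff
        )
        added = 0
        existing_seqs = {a.seq for a in working}
        for contig in contigs:
            contig = asm.mark_full_length(
                contig, snapshot, cfg.full_length_frac
            )
            if not contig.full_length or contig.seq in existing_seqs:
                continue
            name = name_novel(namer, contig)
            working.append(
                rd.AlleleSequence(
                    id=name, seq=contig.seq,
                    provenance="novel", source=individual_id,
                )
            )
            existing_seqs.add(contig.seq)
            entry["added"].append(name)
            added += 1
        if added == 0:
            break

    # final stringent verification against the individual-complete set
    vmap = _IterativeMapper(pairs, cfg.verify)
    vmap.extend(working)
    by_allele = vmap.records_by_allele(working)
    genotype_entries: list[GenotypeAllele] = []
    confirmed_novel: list[rd.AlleleSequence] = []
    for allele in working:
        recs = by_allele.get(allele.id)
        if not recs:
            continue
        if not verify_allele(
            recs, allele, cfg.min_depth, cfg.end_window,
            cfg.het_min_count, cfg.het_min_frac,
        ):
            log.info("%s: insufficient evidence, excluded", allele.id)
            continue
        status = "known" if allele.id in original_ids else "novel"
        expression, n_marker = ac.bin_expression(
            recs, cfg.marker_pos, cfg.cds_offset, len(allele.seq)
        )
        genotype_entries.append(
            GenotypeAllele(allele.id, status, expression, n_marker)
        )
        if status == "novel":
            confirmed_novel.append(allele)

    if confirmed_novel:
        final_db, _ = rd.augment(db, confirmed_novel)
    else:
        final_db = db
    genotype = Genotype(
        individual_id=individual_id,
        alleles=genotype_entries,
        db_version_final=final_db.version,
        rounds=rounds,
    )
    genotype._round_log = round_log  # type: ignore[attr-defined]
    genotype._verify_records = by_allele  # type: ignore[attr-defined]
    return genotype, final_db


def write_outputs(
    genotype: Genotype,
    db: rd.ReferenceDB,
    outdir,
    cfg: RunConfig | None = None,
) -> None:
    """Genotype TSV, updated reference FASTA, final SAM and round log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "genotype.tsv", "w") as fh:
        fh.write("allele_id\tstatus\texpression_bin\tn_reads_marker\n")
        for a in genotype.alleles:
            fh.write(
                f"{a.allele_id}\t{a.status}\t{a.expression}\t{a.n_reads_marker}\n"
            )
    rd.write_fasta(db, outdir / "reference.fasta")
    log_payload = {
        "individual": genotype.individual_id,
        "rounds": genotype.rounds,
        "db_version_final": genotype.db_version_final,
        "round_log": getattr(genotype, "_round_log", []),
    }
    if cfg is not None:
        log_payload["config"] = cfg.to_dict()
    (outdir / "rounds.json").write_text(json.dumps(log_payload, indent=2))
    by_allele = getattr(genotype, "_verify_records", None)
    if by_allele:
        records = [
            r
            for aid in genotype.allele_ids
            for r in by_allele.get(aid, [])
        ]
        mp.write_sam(records, db, outdir / "final.sam")
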