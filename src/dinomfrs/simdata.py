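"""Seeded synthetic data: allele sets, genotypes, reads and genomic contigs.

The generator emulates the study system: a multigene MHC class I family
where an individual expresses 2-6 alleles of a ~549 bp exon2-exon3 region,
pairwise divergence is 5-15% and concentrates in hypervariable windows
(the antigen-contact region), expression spans three tiers (fewer than
1000, 1000-5000, more than 5000 reads at the marker column), and reads
are proper 2x100-150 bp pairs with a small per-base error rate.

Every simulated allele pair is guaranteed to differ at >= 4 positions in
every 100 bp (read-sized) window, with no identical run longer than 60
bp, and every novel allele stays locally closer to its parent lineage
than to any other allele.  This mirrors the observed density of MHC
class I polymorphism (an average of 18.5 differences per 120 bp window
in real allele sets); it is what makes single reads allele-informative
and lets stringent overlap assembly separate read mixtures without
chimeras.

All randomness flows from one integer seed through numpy's PCG64
generator; identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .refdb import AlleleSequence, ReferenceDB, build_reference, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: default marker-read targets per expression tier; chosen to sit well
#: inside the three bins (< 1000 / 1000-5000 / > 5000)
TIER_TARGETS = {"low": 650, "middle": 2600, "high": 6200}

#: minimum pairwise differences per sliding window, mirroring the observed
#: polymorphism density of the gene family; the window matches the read
#: length so that every read carries allele-distinguishing positions
WINDOW_LEN = 100
WINDOW_MIN_DIFF = 4

#: maximum identical run length between two distinct alleles; mirrors the
#: dense spread of class I polymorphism (~15% average divergence in any
#: read-sized window of real allele sets)
MAX_IDENTICAL_RUN = 60


@dataclass
class SimConfig:
    """Study conditions for one simulated individual."""

    rng_seed: int
    n_known: int = 6  # reference-database alleles (carried + background)
    n_novel: int = 2
    n_carried_known: int = 2
    divergence_range: tuple[float, float] = (0.05, 0.15)  # pairwise
    hypervariable_windows: tuple[tuple[int, int], ...] = ((150, 280), (380, 480))
    allele_len: int = 549
    read_len: int = 100
    fragment_mean: int = 300
    fragment_sd: int = 50
    error_rate: float = 0.003
    indel_rate: float | None = None  # defaults to error_rate / 10
    cds_offset: int = 73  # trimmed region starts at CDS position 74
    marker_pos: int = 260  # full-CDS coordinate of the expression marker
    motif: str = "CAGATACAA"
    motif_cds_start: int = 256
    plant_motif: bool = True
    depth_tiers: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.indel_rate is None:
            self.indel_rate = self.error_rate / 10.0
        if self.read_len not in (100, 125, 150):
            raise ValueError("read_len must be one of 100, 125, 150")
        if not (0.0 <= self.error_rate <= 1.0):
            raise ValueError("error_rate must be a probability")
        if self.n_known < 1:
            raise ValueError("need at least one known allele")

    @property
    def marker_local0(self) -> int:
        """0-based marker column on the trimmed allele."""
        return self.marker_pos - self.cds_offset - 1


def _decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def _mutation_weights(cfg: SimConfig) -> np.ndarray:
    """Per-position substitution weight (hypervariable windows doubled)."""
    w = np.ones(cfg.allele_len)
    for a, b in cfg.hypervariable_windows:
        w[a - 1 : b] = 2.0
    return w / w.sum()


def _substitute(arr: np.ndarray, positions: np.ndarray, rng) -> None:
    for p in positions:
        cur = arr[p]
        choices = _BASES[_BASES != cur]
        arr[p] = choices[rng.integers(0, 3)]


def _window_deficits(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Start indices of length-WINDOW_LEN windows with too few differences."""
    diff = (a != b).astype(np.int32)
    c = np.concatenate(([0], np.cumsum(diff)))
    L = a.shape[0]
    if L <= WINDOW_LEN:
        return np.array([0]) if c[-1] < WINDOW_MIN_DIFF else np.array([], dtype=int)
    sums = c[WINDOW_LEN:] - c[:-WINDOW_LEN]
    return np.nonzero(sums < WINDOW_MIN_DIFF)[0]


def simulate_allele_set(
    cfg: SimConfig,
) -> tuple[ReferenceDB, list[AlleleSequence], dict]:
    """Generate a known-allele database plus novel alleles.

    A random ancestral sequence is diversified by seeded substitutions,
    denser inside the hypervariable windows.  Novel alleles are derived
    from a randomly chosen known parent at a pairwise divergence drawn
    from ``divergence_range``.  When ``plant_motif`` is set, the first
    novel allele carries the 9 bp marker motif at CDS 256-264 and is
    checked to differ there in >= 4 of 9 positions from every other
    allele.  Every allele pair is repaired to satisfy the per-window
    divergence floor (which also guarantees >= 5 global differences).
    """
    rng = np.random.default_rng(cfg.rng_seed)
    L = cfg.allele_len
    weights = _mutation_weights(cfg)
    ancestral = _BASES[rng.integers(0, 4, size=L)]
    motif_arr = np.frombuffer(cfg.motif.encode(), dtype=np.uint8)
    m0 = cfg.motif_cds_start - cfg.cds_offset - 1  # 0-based local
    if cfg.plant_motif:
        # anchor the ancestral motif window maximally far from the motif
        comp = np.frombuffer(
            revcomp(cfg.motif).encode()[::-1], dtype=np.uint8
        )  # plain complement
        ancestral[m0 : m0 + len(motif_arr)] = comp

    lo, hi = cfg.divergence_range
    seqs: list[np.ndarray] = []
    names: list[str] = []
    for i in range(cfg.n_known):
        arr = ancestral.copy()
        rate = rng.uniform(lo, hi) / 2.0
        n_sub = max(1, round(rate * L))
        pos = rng.choice(L, size=n_sub, replace=False, p=weights)
        _substitute(arr, pos, rng)
        seqs.append(arr)
        names.append(f"K{i + 1:02d}")
    parent_of: dict[int, int] = {}
    for i in range(cfg.n_novel):
        pi = int(rng.integers(0, cfg.n_known))
        parent_of[cfg.n_known + i] = pi
        arr = seqs[pi].copy()
        d = rng.uniform(lo, hi)
        n_sub = max(1, round(d * L))
        pos = rng.choice(L, size=n_sub, replace=False, p=weights)
        _substitute(arr, pos, rng)
        if cfg.plant_motif and i == 0:
            arr[m0 : m0 + len(motif_arr)] = motif_arr
        seqs.append(arr)
        names.append(f"NOV{i + 1:02d}")

    motif_idx = cfg.n_known if cfg.plant_motif and cfg.n_novel else None
    mlen = len(motif_arr)
    for _ in range(400):
        dirty = _window_floor_pass(seqs, cfg, rng, motif_idx, m0, mlen)
        dirty |= _coherence_pass(seqs, parent_of, rng, motif_idx, m0, mlen)
        if not dirty:
            break
    else:
        raise RuntimeError(
            "could not satisfy the divergence-spread and parental-"
            "coherence floors; too many alleles for the divergence range"
        )

    if cfg.plant_motif and cfg.n_novel:
        motif_seq = seqs[cfg.n_known]
        for k, other in enumerate(seqs):
            if k == cfg.n_known:
                continue
            d = int((other[m0 : m0 + len(motif_arr)] != motif_arr).sum())
            if d < 4:
                # re-randomize the other allele's motif window from ancestry
                other[m0 : m0 + len(motif_arr)] = ancestral[m0 : m0 + len(motif_arr)]

    known = [
        AlleleSequence(id=names[i], seq=_decode(seqs[i]), provenance="curated")
        for i in range(cfg.n_known)
    ]
    novel = [
        AlleleSequence(
            id=names[cfg.n_known + i],
            seq=_decode(seqs[cfg.n_known + i]),
            provenance="novel",
        )
        for i in range(cfg.n_novel)
    ]
    db, drops = build_reference(known, min_diff=5)
    if drops:
        raise RuntimeError("window-floor repair failed to separate alleles")
    truth = {
        "ancestral": _decode(ancestral),
        "names": names,
        "motif_allele": names[cfg.n_known] if cfg.plant_motif and cfg.n_novel else None,
        "marker_local0": cfg.marker_local0,
    }
    return db, novel, truth


def _window_floor_pass(seqs, cfg, rng, motif_idx, m0, mlen) -> bool:
    """One repair pass of the divergence-spread floor; True if dirty."""
    L = cfg.allele_len
    dirty = False
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            target = None
            starts = _window_deficits(seqs[i], seqs[j])
            if starts.size:
                s = int(starts[0])
                target = slice(s, min(s + WINDOW_LEN, L))
            else:
                run = _longest_identical_run(seqs[i], seqs[j])
                if run is not None:
                    a, b = run
                    # break the run near its middle
                    mid = (a + b) // 2
                    target = slice(max(a, mid - 10), min(b, mid + 10))
            if target is None:
                continue
            dirty = True
            equal = np.nonzero(seqs[i][target] == seqs[j][target])[0]
            equal = equal + target.start
            if motif_idx is not None and j == motif_idx:
                equal = equal[(equal < m0) | (equal >= m0 + mlen)]
            if equal.size == 0:
                continue
            p = int(equal[rng.integers(0, equal.size)])
            _substitute(seqs[j], np.array([p]), rng)
    return dirty


#: a novel allele must stay closer to its parent than to any competitor
#: by at least this many differences in every sliding window
COHERENCE_MARGIN = 2


def _coherence_pass(seqs, parent_of, rng, motif_idx, m0, mlen) -> bool:
    """One repair pass of local parental coherence; True if dirty.

    For every novel allele and every length-WINDOW_LEN window, the novel
    must differ from its parent by at least COHERENCE_MARGIN fewer
    positions than from any other allele.  Novel alleles arise by point
    mutation within one allelic lineage; this guarantee is what makes
    their reads stack coherently on a single closest reference.
    Violations are repaired by reverting one of the novel's own window
    mutations toward the parent (preferring positions that currently
    match the competitor).
    """
    L = seqs[0].shape[0]
    dirty = False
    for ni, pi in parent_of.items():
        nov = seqs[ni]
        par = seqs[pi]
        dp = (nov != par).astype(np.int32)
        cdp = np.concatenate(([0], np.cumsum(dp)))
        wp = (
            cdp[WINDOW_LEN:] - cdp[:-WINDOW_LEN]
            if L > WINDOW_LEN
            else np.array([int(dp.sum())])
        )
        for ci in range(len(seqs)):
            if ci == ni or ci == pi:
                continue
            dc = (nov != seqs[ci]).astype(np.int32)
            cdc = np.concatenate(([0], np.cumsum(dc)))
            wc = (
                cdc[WINDOW_LEN:] - cdc[:-WINDOW_LEN]
                if L > WINDOW_LEN
                else np.array([int(dc.sum())])
            )
            bad = np.nonzero(wp + COHERENCE_MARGIN > wc)[0]
            if bad.size == 0:
                continue
            s = int(bad[0])
            win = slice(s, min(s + WINDOW_LEN, L))
            # candidate positions: novel mutations where parent and the
            # competitor disagree (reverting gains margin)
            idx = np.arange(win.start, win.stop)
            novw, parw, cw = nov[win], par[win], seqs[ci][win]
            mut = (novw != parw) & (parw != cw)
            if motif_idx is not None and ni == motif_idx:
                inmotif = (idx >= m0) & (idx < m0 + mlen)
                mut &= ~inmotif
            if not mut.any():
                continue
            prefer = mut & (novw == cw)
            pool = idx[prefer] if prefer.any() else idx[mut]
            p = int(pool[rng.integers(0, pool.size)])
            nov[p] = par[p]
            dirty = True
    return dirty


def _longest_identical_run(a: np.ndarray, b: np.ndarray) -> tuple[int, int] | None:
    """[start, end) of the longest identical run if it exceeds
    MAX_IDENTICAL_RUN, else None."""
    diff = np.nonzero(a != b)[0]
    bounds = np.concatenate(([-1], diff, [a.shape[0]]))
    gaps = np.diff(bounds) - 1
    k = int(np.argmax(gaps))
    if gaps[k] <= MAX_IDENTICAL_RUN:
        return None
    return int(bounds[k] + 1), int(bounds[k + 1])


# ---------------------------------------------------------------------------
# read simulation


def simulate_reads(
    genotype: list[tuple[AlleleSequence, int]],
    cfg: SimConfig,
    outdir,
    sample_id: str = "sim",
) -> tuple[Path, Path, pd.DataFrame]:
    """Simulate expression-stratified paired-end reads.

    For each (allele, marker target) pair, fragments are drawn until the
    number of reads covering the marker column reaches the target.
    Fragment lengths are normal(mean, sd) truncated to [read_len,
    min(2*mean, allele length)]; mate 1 is the fragment 5' end, mate 2 the
    reverse complement of its 3' end.  Per-base substitution errors occur
    at ``error_rate`` and single-base indels at ``indel_rate``.

    Writes ``<sample>_R1.fastq`` / ``<sample>_R2.fastq`` under ``outdir``
    and returns their paths plus a truth table with one row per pair.
    """
    if not genotype:
        raise ValueError("empty genotype")
    rng = np.random.default_rng(cfg.rng_seed + 0x5EED)
    R = cfg.read_len
    m = cfg.marker_local0
    # fragments may overhang the trimmed region: the flanking transcript
    # continues on both sides, so coverage of the region is uniform up to
    # its very ends.  Only the in-region part of each mate is emitted
    # (the flanks are outside the modeled sequence), so edge mates are
    # truncated; the overhang is capped so both mates keep >= 40 bp.
    overhang = R - 40
    rows = []
    reads: list[tuple[str, str, str]] = []  # id, seq1, seq2
    serial = 0
    for allele, target in genotype:
        if len(allele.seq) < R:
            raise ValueError(f"allele {allele.id} shorter than read length")
        arr = np.frombuffer(allele.seq.encode(), dtype=np.uint8)
        L = arr.shape[0]
        max_len = min(2 * cfg.fragment_mean, L)
        marker_reads = 0
        while marker_reads < target:
            flen = int(np.clip(
                round(rng.normal(cfg.fragment_mean, cfg.fragment_sd)), R, max_len
            ))
            start = int(rng.integers(-overhang, L - flen + overhang + 1))
            end = start + flen
            m1_lo, m1_hi = max(start, 0), min(start + R, L)
            m2_lo, m2_hi = max(end - R, 0), min(end, L)
            m1_cov = m1_lo <= m < m1_hi
            m2_cov = m2_lo <= m < m2_hi
            s1, e1 = _make_read(arr[m1_lo:m2_hi], True, m1_hi - m1_lo, cfg, rng)
            s2, e2 = _make_read(arr[m1_lo:m2_hi], False, m2_hi - m2_lo, cfg, rng)
            rid = f"{sample_id}_{serial:06d}"
            serial += 1
            reads.append((rid, s1, s2))
            rows.append(
                (rid, allele.id, start, flen, m1_cov, m2_cov, e1, e2)
            )
            marker_reads += int(m1_cov) + int(m2_cov)

    order = rng.permutation(len(reads))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    r1 = outdir / f"{sample_id}_R1.fastq"
    r2 = outdir / f"{sample_id}_R2.fastq"
    q = chr(35 + 33)  # constant Q35
    with open(r1, "w") as f1, open(r2, "w") as f2:
        for k in order:
            rid, s1, s2 = reads[k]
            f1.write(f"@{rid}/1\n{s1}\n+\n{q * len(s1)}\n")
            f2.write(f"@{rid}/2\n{s2}\n+\n{q * len(s2)}\n")
    truth = pd.DataFrame(
        rows,
        columns=[
            "read_id", "allele_id", "frag_start", "frag_len",
            "mate1_covers_marker", "mate2_covers_marker",
            "n_errors_1", "n_errors_2",
        ],
    ).iloc[order].reset_index(drop=True)
    return r1, r2, truth


def _make_read(
    frag: np.ndarray, forward: bool, R: int, cfg: SimConfig, rng
) -> tuple[str, int]:
    """One mate with substitution and rare single-base indel errors."""
    flen = frag.shape[0]
    take = min(flen, R + 1)  # one base of slack for deletions
    raw = frag[:take].copy() if forward else frag[flen - take :].copy()
    if not forward:
        raw = _rc_arr(raw)
    n_err = 0
    hit = np.nonzero(rng.random(R) < cfg.error_rate)[0]
    for p in hit:
        _substitute(raw, np.array([p]), rng)
    n_err += hit.size
    if flen > R and rng.random() < cfg.indel_rate * R:
        p = int(rng.integers(1, R - 1))
        if rng.random() < 0.5:
            raw = np.delete(raw, p)
        else:
            raw = np.insert(raw, p, _BASES[rng.integers(0, 4)])
        n_err += 1
    return _decode(raw[:R]), int(n_err)


_RC = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGT", b"TGCA"):
    _RC[_a] = _b


def _rc_arr(arr: np.ndarray) -> np.ndarray:
    return _RC[arr][::-1]


# ---------------------------------------------------------------------------
# individual-level scenario


@dataclass
class SimulatedIndividual:
    """A complete scenario: database, fastq pair and truth."""

    sample_id: str
    db: ReferenceDB  # known alleles (carried subset + background)
    carried: list[AlleleSequence]  # every expressed allele, known and novel
    novel: list[AlleleSequence]  # the subset of carried absent from db
    tiers: dict[str, str]  # allele_id -> expression tier name
    marker_targets: dict[str, int]  # allele_id -> simulated marker reads
    r1: Path
    r2: Path
    truth: pd.DataFrame


def simulate_individual(
    cfg: SimConfig, outdir, sample_id: str = "sim"
) -> SimulatedIndividual:
    """Build one individual: allele set, carried genotype, tiered reads.

    The first three carried alleles span the three expression bins;
    extras alternate the lower tiers.
    """
    db, novel, _truth = simulate_allele_set(cfg)
    rng = np.random.default_rng(cfg.rng_seed + 0xCA55)
    n_carry = min(cfg.n_carried_known, cfg.n_known)
    carry_idx = sorted(rng.choice(cfg.n_known, size=n_carry, replace=False))
    carried = [db.alleles[int(i)] for i in carry_idx] + list(novel)
    tiers = {}
    targets = {}
    order = rng.permutation(len(carried))
    for rank, k in enumerate(order):
        # first three alleles span the three bins; extras alternate the
        # lower tiers (individuals typically express one allele highly)
        if rank < 3:
            tier = ("low", "middle", "high")[rank]
        else:
            tier = ("low", "middle")[(rank - 3) % 2]
        tiers[carried[int(k)].id] = tier
        targets[carried[int(k)].id] = (
            cfg.depth_tiers.get(carried[int(k)].id) or TIER_TARGETS[tier]
        )
    genotype = [(a, targets[a.id]) for a in carried]
    r1, r2, truth = simulate_reads(genotype, cfg, outdir, sample_id)
    return SimulatedIndividual(
        sample_id=sample_id,
        db=db,
        carried=carried,
        novel=list(novel),
        tiers=tiers,
        marker_targets=targets,
        r1=r1,
        r2=r2,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# genomic contigs


def simulate_genomic_contig(
    allele: AlleleSequence,
    intron_len: int,
    flank_len: int,
    rng_seed: int,
    boundary: int = 272,
    reverse: bool = False,
) -> tuple[str, dict]:
    """A genomic contig embedding the allele as exon2 + intron + exon3.

    The intron starts with GT and ends with AG.  Returns the contig
    sequence and the planted 1-based forward-strand coordinates (with
    start > end per exon when ``reverse`` is set, matching the reporting
    convention for reverse-orientation hits).
    """
    if intron_len < 50:
        raise ValueError("intron_len must be >= 50")
    rng = np.random.default_rng(rng_seed)
    exon2, exon3 = allele.seq[:boundary], allele.seq[boundary:]
    intron = (
        "GT" + _decode(_BASES[rng.integers(0, 4, size=intron_len - 4)]) + "AG"
    )
    flank5 = _decode(_BASES[rng.integers(0, 4, size=flank_len)])
    flank3 = _decode(_BASES[rng.integers(0, 4, size=flank_len)])
    contig = flank5 + exon2 + intron + exon3 + flank3
    e2s = flank_len + 1
    e2e = flank_len + len(exon2)
    e3s = e2e + intron_len + 1
    e3e = e3s + len(exon3) - 1
    coords = {
        "exon2": (e2s, e2e),
        "exon3": (e3s, e3e),
        "intron_len": intron_len,
        "orientation": "forward",
    }
    if reverse:
        L = len(contig)
        contig = revcomp(contig)
        refl = lambda p: L - p + 1  # noqa: E731
        coords = {
            "exon2": (refl(e2s), refl(e2e)),
            "exon3": (refl(e3s), refl(e3e)),
            "intron_len": intron_len,
            "orientation": "reverse",
        }
    return contig, coords
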