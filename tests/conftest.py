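"""Shared fixtures: small deterministic sequences and simulated scenes."""

import numpy as np
import pytest

from dinomfrs.refdb import AlleleSequence, ReferenceDB

BASES = "ACGT"


def random_seq(rng, n: int) -> str:
    return "".join(rng.choice(list(BASES), n))


def mutate(seq: str, positions, rng) -> str:
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([b for b in BASES if b != out[p]])
    return "".join(out)


def spread_mutate(seq: str, n_diff: int, rng, max_gap: int = 30) -> str:
    """Mutate with diffs spread so every window stays divergent."""
    L = len(seq)
    step = max(1, min(max_gap, L // max(1, n_diff)))
    positions = [(i * step + int(rng.integers(0, max(1, step // 2)))) % L
                 for i in range(n_diff)]
    return mutate(seq, sorted(set(positions)), rng)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def allele(rng):
    return AlleleSequence("A1", random_seq(rng, 549))


@pytest.fixture()
def small_db(rng):
    """Three mutually divergent 549 bp alleles."""
    base = random_seq(rng, 549)
    seqs = [base]
    for k in (1, 2):
        seqs.append(spread_mutate(base, 50 + 10 * k, np.random.default_rng(k)))
    alleles = [AlleleSequence(f"A{i+1}", s) for i, s in enumerate(seqs)]
    return ReferenceDB(alleles=alleles)


def perfect_pairs_from(seq: str, allele_id: str, frag: int = 300,
                       read_len: int = 100, step: int = 3, prefix: str = "p"):
    """Error-free proper read pairs tiling one allele."""
    from dinomfrs.mapper import ReadPair
    from dinomfrs.refdb import revcomp

    pairs = []
    L = len(seq)
    n = 0
    for start in range(0, L - frag + 1, step):
        s1 = seq[start : start + read_len]
        s2 = revcomp(seq[start + frag - read_len : start + frag])
        pairs.append(ReadPair(id=f"{prefix}{n:05d}", seq1=s1, seq2=s2))
        n += 1
    return pairs
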