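"""Low-level local-alignment kernels (numba-compiled).

Scoring model shared by all kernels: +match per identical base, -mismatch
per substitution, affine gaps (-gap_open - k*gap_extend for a k-base gap),
and a flat -clip penalty per read end that is not included in the alignment
(reference ends are always free, as in local alignment).  An alignment may
start at read position i > 0 (paying one clip) and end before the last read
base (paying another).

Two kernels are provided: a gapless diagonal scan used as a fast path when
no gap can improve the score, and a banded affine dynamic program with full
traceback for everything else.  Calling ``banded_sw`` with the full
diagonal range [-(L-1), R-1] gives an unbanded alignment.
"""

from __future__ import annotations

import numpy as np
from numba import njit, types
from numba.typed import Dict as NumbaDict

# cigar op codes (SAM numeric): 0=M 1=I 2=D 4=S
OP_M = 0
OP_I = 1
OP_D = 2
OP_S = 4

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 array (A=0 C=1 G=2 T=3)."""
    return _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)].copy()


@njit(cache=True)
def build_seed_index(cat, starts, k):
    """Exact k-mer index over concatenated targets (2-bit rolling hash).

    ``cat`` is the concatenation of all encoded target sequences,
    ``starts`` their start offsets (with a final sentinel).  Returns
    (lut, entries): ``lut`` maps each hash to (bucket start << 32 |
    bucket size - 1) and ``entries`` holds the (target_idx << 32 | pos)
    hits sorted by hash.
    """
    n_t = starts.shape[0] - 1
    total = 0
    for t in range(n_t):
        L = starts[t + 1] - starts[t]
        if L >= k:
            total += L - k + 1
    hashes = np.empty(total, dtype=np.int64)
    entries = np.empty(total, dtype=np.int64)
    m = 0
    for t in range(n_t):
        s = starts[t]
        L = starts[t + 1] - s
        if L < k:
            continue
        h = np.int64(0)
        valid = 0
        mask = (np.int64(1) << (2 * k)) - 1
        for i in range(L):
            c = cat[s + i]
            if c > 3:
                valid = 0
                h = np.int64(0)
                continue
            h = ((h << 2) | np.int64(c)) & mask
            valid += 1
            if valid >= k:
                hashes[m] = h
                entries[m] = (np.int64(t) << 32) | np.int64(i - k + 1)
                m += 1
    hashes = hashes[:m]
    entries = entries[:m]
    order_idx = np.argsort(hashes, kind="mergesort")
    sorted_h = hashes[order_idx]
    sorted_e = entries[order_idx]
    lut = NumbaDict.empty(types.int64, types.int64)
    for i in range(m):
        if i == 0 or sorted_h[i] != sorted_h[i - 1]:
            lut[sorted_h[i]] = np.int64(i) << 32
        else:
            lut[sorted_h[i]] = lut[sorted_h[i]] + 1
    return lut, sorted_e


@njit(cache=True)
def seed_lookup(read, lut, sorted_e, k):
    """Unique (target_idx, diagonal) seed hits for one read.

    Returns parallel int64 arrays (tis, diags), deduplicated.
    """
    L = read.shape[0]
    cap = 4096
    raw = np.empty(cap, dtype=np.int64)
    m = 0
    h = np.int64(0)
    valid = 0
    mask = (np.int64(1) << (2 * k)) - 1
    for i in range(L):
        c = read[i]
        if c > 3:
            valid = 0
            h = np.int64(0)
            continue
        h = ((h << 2) | np.int64(c)) & mask
        valid += 1
        if valid >= k:
            if h in lut:
                v = lut[h]
                start = v >> 32
                end = start + (v & 0xFFFFFFFF) + 1
                qpos = i - k + 1
                for e in range(start, end):
                    if m >= cap:
                        break
                    ent = sorted_e[e]
                    ti = ent >> 32
                    pos = ent & 0xFFFFFFFF
                    # diag offset by 1<<20 keeps the packed key positive
                    raw[m] = (ti << 32) | (pos - qpos + (1 << 20))
                    m += 1
    if m == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    raw = np.sort(raw[:m])
    tis = np.empty(m, dtype=np.int64)
    diags = np.empty(m, dtype=np.int64)
    n = 0
    prev = np.int64(-1)
    for i in range(m):
        if raw[i] != prev:
            prev = raw[i]
            tis[n] = raw[i] >> 32
            diags[n] = (raw[i] & 0xFFFFFFFF) - (1 << 20)
            n += 1
    return tis[:n], diags[:n]


@njit(cache=True)
def gapless_scan(read, ref, diag, match, mismatch, clip):
    """Best gapless segment on one diagonal with end-clip charges.

    ``diag`` is ref_pos - read_pos.  Returns (score, read_start, read_end
    exclusive, n_mismatch); score is -2**30 if the diagonal has no overlap.
    """
    L = read.shape[0]
    R = ref.shape[0]
    i0 = 0 if diag >= 0 else -diag
    i1 = min(L, R - diag)
    if i1 <= i0:
        return -(2 ** 30), 0, 0, 0
    NEG = -(2 ** 30)
    best = NEG
    best_s = 0
    best_e = 0
    best_m = 0
    cur = NEG
    cur_s = 0
    cur_m = 0
    for i in range(i0, i1):
        s = match if read[i] == ref[i + diag] else -mismatch
        mm = 0 if read[i] == ref[i + diag] else 1
        fresh = s - (clip if i > 0 else 0)
        if cur == NEG or cur + s < fresh:
            cur = fresh
            cur_s = i
            cur_m = mm
        else:
            cur = cur + s
            cur_m += mm
        total = cur - (clip if i < L - 1 else 0)
        if total > best:
            best = total
            best_s = cur_s
            best_e = i + 1
            best_m = cur_m
    return best, best_s, best_e, best_m


@njit(cache=True)
def banded_sw(read, ref, d_lo, d_hi, match, mismatch,
              gap_open, gap_extend, clip):
    """Banded affine local alignment with traceback.

    The band is the diagonal window [d_lo, d_hi] (diag = ref_pos - read_pos).
    Returns (score, read_start, read_end_excl, ref_start, ref_end_excl,
    ops, lens, n_ops, n_edits) where ops/lens describe the aligned part of
    the read (soft clips are added by the caller) and n_edits counts
    substitutions plus inserted and deleted bases.
    """
    L = read.shape[0]
    R = ref.shape[0]
    W = d_hi - d_lo + 1
    NEG = -(2 ** 28)
    M = np.full(W, NEG, dtype=np.int32)
    X = np.full(W, NEG, dtype=np.int32)
    Y = np.full(W, NEG, dtype=np.int32)
    Mp = np.full(W, NEG, dtype=np.int32)
    Xp = np.full(W, NEG, dtype=np.int32)
    Yp = np.full(W, NEG, dtype=np.int32)
    # traceback: originating state per cell; 0=start, 1=M, 2=X, 3=Y
    tbM = np.zeros((L, W), dtype=np.uint8)
    tbX = np.zeros((L, W), dtype=np.uint8)
    tbY = np.zeros((L, W), dtype=np.uint8)
    best = NEG
    bi = -1
    bk = -1
    for i in range(L):
        for k in range(W):
            j = i + d_lo + k
            if j < 0 or j >= R:
                M[k] = NEG
                X[k] = NEG
                Y[k] = NEG
                continue
            sub = match if read[i] == ref[j] else -mismatch
            # M: diagonal predecessors at (i-1, j-1) = previous row, same k
            bestprev = -clip if i > 0 else 0
            code = 0
            if i > 0:
                if Mp[k] > bestprev:
                    bestprev = Mp[k]
                    code = 1
                if Xp[k] > bestprev:
                    bestprev = Xp[k]
                    code = 2
                if Yp[k] > bestprev:
                    bestprev = Yp[k]
                    code = 3
            M[k] = bestprev + sub
            tbM[i, k] = code
            # X: gap in ref (read insertion), from (i-1, j) = prev row, k+1
            xv = NEG
            xc = 1
            if i > 0 and k + 1 < W:
                a = Mp[k + 1] - gap_open - gap_extend
                b = Xp[k + 1] - gap_extend
                if a >= b:
                    xv = a
                else:
                    xv = b
                    xc = 2
            X[k] = xv
            tbX[i, k] = xc
            # Y: gap in read (deletion), from (i, j-1) = same row, k-1
            yv = NEG
            yc = 1
            if k - 1 >= 0:
                a = M[k - 1] - gap_open - gap_extend
                b = Y[k - 1] - gap_extend
                if a >= b:
                    yv = a
                else:
                    yv = b
                    yc = 3
            Y[k] = yv
            tbY[i, k] = yc
            end = M[k] - (clip if i < L - 1 else 0)
            if end > best:
                best = end
                bi = i
                bk = k
        for k in range(W):
            Mp[k] = M[k]
            Xp[k] = X[k]
            Yp[k] = Y[k]
    ops = np.zeros(2 * L + 4, dtype=np.int32)
    lens = np.zeros(2 * L + 4, dtype=np.int32)
    if bi < 0:
        return NEG, 0, 0, 0, 0, ops, lens, 0, 0
    i = bi
    k = bk
    state = 1
    nm = 0
    read_end = bi + 1
    ref_end = bi + d_lo + bk + 1
    rops = np.zeros(2 * L + 4, dtype=np.int32)
    nr = 0
    while True:
        if state == 1:
            j = i + d_lo + k
            rops[nr] = OP_M
            nr += 1
            if read[i] != ref[j]:
                nm += 1
            code = tbM[i, k]
            if code == 0:
                break
            state = code
            i -= 1
        elif state == 2:
            rops[nr] = OP_I
            nr += 1
            nm += 1
            state = tbX[i, k]
            i -= 1
            k += 1
        else:
            rops[nr] = OP_D
            nr += 1
            nm += 1
            state = tbY[i, k]
            k -= 1
    read_start = i
    ref_start = i + d_lo + k
    # run-length encode (rops is reversed, so walk it backwards)
    n_ops = 0
    idx = nr - 1
    while idx >= 0:
        op = rops[idx]
        run = 1
        idx -= 1
        while idx >= 0 and rops[idx] == op:
            run += 1
            idx -= 1
        ops[n_ops] = op
        lens[n_ops] = run
        n_ops += 1
    return best, read_start, read_end, ref_start, ref_end, ops, lens, n_ops, nm


@njit(cache=True)
def best_gapless_placement(read, ref, min_overlap):
    """Full-length gapless placement minimizing mismatch fraction.

    Scans every diagonal; the read may overhang the reference ends (the
    overhang is excluded from the comparison).  Returns (diag, overlap,
    n_mismatch) of the best placement with overlap >= min_overlap, or
    (0, 0, 0) when none exists.  Ties prefer the smaller diagonal.
    """
    L = read.shape[0]
    R = ref.shape[0]
    best_diag = 0
    best_ov = 0
    best_mm = 0
    best_frac = 2.0
    for diag in range(-L + min_overlap, R - min_overlap + 1):
        i0 = 0 if diag >= 0 else -diag
        i1 = min(L, R - diag)
        ov = i1 - i0
        if ov < min_overlap:
            continue
        mm = 0
        for i in range(i0, i1):
            if read[i] != ref[i + diag]:
                mm += 1
        frac = mm / ov
        if frac < best_frac:
            best_frac = frac
            best_diag = diag
            best_ov = ov
            best_mm = mm
    return best_diag, best_ov, best_mm


@njit(cache=True)
def count_mismatches(a, b):
    """Hamming distance between two equal-length encoded sequences."""
    n = 0
    for i in range(a.shape[0]):
        if a[i] != b[i]:
            n += 1
    return n


@njit(cache=True)
def masked_overlap(arr_a, conf_a, arr_b, conf_b, off):
    """Overlap stats of sequence b placed at ``off`` in a's frame.

    Returns (overlap length, mutually-confirmed columns, mismatches over
    confirmed columns); (0, 0, 0) when there is no overlap.
    """
    la = arr_a.shape[0]
    lb = arr_b.shape[0]
    s = off if off > 0 else 0
    e = min(la, off + lb)
    if e <= s:
        return 0, 0, 0
    n_conf = 0
    mm = 0
    for i in range(s, e):
        j = i - off
        if conf_a[i] and conf_b[j]:
            n_conf += 1
            if arr_a[i] != arr_b[j]:
                mm += 1
    return e - s, n_conf, mm
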