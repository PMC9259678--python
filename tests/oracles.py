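"""Independent brute-force oracles used by the test suite.

These deliberately re-derive every quantity from first principles (naive
counting, full dynamic programming, exhaustive enumeration) without calling
the package's own implementation paths.
"""

from __future__ import annotations

import numpy as np

_RC = str.maketrans("ACGTN", "TGCAN")
_STOPS = {"TAA", "TAG", "TGA"}


def rc(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def n50_oracle(lengths) -> int:
    """Descending cumulative sums; first length where the sum reaches half."""
    total = sum(lengths)
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if acc >= total / 2:
            return length
    raise AssertionError


def stats_oracle(seqs) -> dict:
    """Naive per-character counting and sorting."""
    lengths = sorted(len(s) for s in seqs)
    counts = {b: 0 for b in "ACGTN"}
    for s in seqs:
        for ch in s:
            counts[ch] += 1
    acgt = counts["A"] + counts["C"] + counts["G"] + counts["T"]
    n = len(lengths)
    median = (
        lengths[n // 2] if n % 2 else (lengths[n // 2 - 1] + lengths[n // 2]) / 2
    )
    return {
        "n_transcripts": n,
        "gc_percent": 100.0 * (counts["G"] + counts["C"]) / acgt,
        "median_length": float(median),
        "n50": n50_oracle(lengths),
        "total_bases": sum(lengths),
    }


def semiglobal_distance_oracle(query: str, target: str) -> int:
    """Unit-cost edit distance, query global, free end gaps on target.

    Row-wise DP; the in-row (insertion) dependency is resolved with the
    minimum-accumulate trick: cur[j] = min_k<=j (m[k] + (j - k)).
    """
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    m = t.size
    prev = np.zeros(m + 1, dtype=np.int32)  # free leading gap in target
    idx = np.arange(m + 1, dtype=np.int32)
    for i in range(q.size):
        sub = prev[:-1] + (t != q[i])
        cand = np.minimum(prev[1:] + 1, sub)
        cur = np.empty(m + 1, dtype=np.int32)
        cur[0] = prev[0] + 1
        best = np.minimum(np.concatenate(([cur[0]], cand)), 2**30)
        cur = np.minimum.accumulate(best - idx) + idx
        prev = cur
    return int(prev.min())  # free trailing gap in target


def identity_oracle(a: str, b: str, both_strands: bool = False) -> float:
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    ident = 1.0 - semiglobal_distance_oracle(short, long_) / len(short)
    if both_strands:
        ident = max(ident, 1.0 - semiglobal_distance_oracle(rc(short), long_) / len(short))
    return max(0.0, ident)


def smith_waterman_intervals(s: str, t: str, block_identity_min: float,
                             min_score: int = 20,
                             match: int = 1, mismatch: int = -2,
                             gap: int = -10**6) -> list[tuple[int, int]]:
    """Iterated local alignment: best local block, mask it on s, repeat.

    Gaps are prohibitively penalised by default because the block model
    under test is ungapped (substitution-only); the DP is still exhaustive
    over all diagonals and positions.  Each accepted block must reach
    ``block_identity_min`` (matches over aligned columns).  Returns the
    matched intervals on s.
    """
    sa = np.frombuffer(s.encode(), dtype=np.uint8)
    ta = np.frombuffer(t.encode(), dtype=np.uint8)
    masked = np.zeros(sa.size, dtype=bool)
    intervals: list[tuple[int, int]] = []
    while True:
        n, m = sa.size, ta.size
        H = np.zeros((n + 1, m + 1), dtype=np.int32)
        for i in range(1, n + 1):
            if masked[i - 1]:
                continue  # masked rows contribute nothing
            score = np.where(ta == sa[i - 1], match, mismatch)
            diag = H[i - 1, :-1] + score
            up = H[i - 1, 1:] + gap
            cand = np.maximum(np.maximum(diag, up), 0)
            row = np.empty(m + 1, dtype=np.int32)
            row[0] = 0
            idx = np.arange(m + 1, dtype=np.int32) * (-gap)
            best = np.concatenate(([0], cand))
            row = np.maximum.accumulate(best + idx) - idx
            H[i] = np.maximum(row, 0)
        peak = int(H.max())
        if peak < min_score:
            break
        i, j = np.unravel_index(int(H.argmax()), H.shape)
        # traceback
        matches = cols = 0
        lo = hi = i
        while i > 0 and j > 0 and H[i, j] > 0:
            hi = max(hi, i)
            if not masked[i - 1] and H[i, j] == H[i - 1, j - 1] + (
                match if ta[j - 1] == sa[i - 1] else mismatch
            ):
                matches += int(ta[j - 1] == sa[i - 1])
                cols += 1
                i, j = i - 1, j - 1
                lo = i
            elif H[i, j] == H[i - 1, j] + gap:
                cols += 1
                i -= 1
                lo = i
            elif j > 0 and H[i, j] == H[i, j - 1] + gap:
                cols += 1
                j -= 1
            else:
                break
        if cols and matches / cols >= block_identity_min:
            intervals.append((lo, hi))
        masked[lo:hi] = True
        if masked.all():
            break
    merged: list[list[int]] = []
    for a, b in sorted(intervals):
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def coverage_oracle(s: str, t: str, block_identity_min: float = 0.95,
                    both_strands: bool = True) -> float:
    """Covered fraction of s by accepted local blocks of t (best strand)."""
    def one(tt: str) -> float:
        iv = smith_waterman_intervals(s, tt, block_identity_min)
        return sum(b - a for a, b in iv) / len(s)
    cov = one(t)
    if both_strands:
        cov = max(cov, one(rc(t)))
    return cov


def orf_oracle(seq: str, min_cds: int):
    """Exhaustive 6-frame enumeration of ATG-initiated ORFs.

    Returns (length, strand_index, frame_offset, start_on_scanned_strand)
    of the winning ORF, or None; ties broken exactly as documented
    (longest, forward strand first, smaller frame, earlier start).
    """
    candidates = []
    for strand_idx, s in enumerate((seq, rc(seq))):
        for off in range(3):
            codons = [s[p:p + 3] for p in range(off, len(s) - 2, 3)]
            for ci, codon in enumerate(codons):
                if codon != "ATG":
                    continue
                end = None
                has_stop = False
                for cj in range(ci, len(codons)):
                    if codons[cj] in _STOPS:
                        if cj > ci or codons[ci] in _STOPS:
                            end = cj
                            has_stop = True
                        break
                if has_stop:
                    length = (end - ci + 1) * 3
                else:
                    length = (len(codons) - ci) * 3
                if length >= min_cds:
                    candidates.append((length, strand_idx, off, off + 3 * ci, has_stop))
    if not candidates:
        return None
    # keep, per (strand, frame), only maximal ORFs (an ATG inside another
    # ORF of the same frame yields a shorter nested call; the scanner
    # reports the outermost) — for the tie rule, pick max length with
    # preference order strand asc, frame asc, start asc
    candidates.sort(key=lambda c: (-c[0], c[1], c[2], c[3]))
    return candidates[0]


def hamming_matches_oracle(transcript: str, mature: str, max_mismatch: int):
    """All full-length ungapped placements on both strands.

    Returns a set of (start_on_forward, strand, mismatches).
    """
    out = set()
    m = len(mature)
    n = len(transcript)
    for start in range(n - m + 1):
        window = transcript[start:start + m]
        d = sum(1 for x, y in zip(window, mature) if x != y)
        if d <= max_mismatch:
            out.add((start, "forward", d))
        d_rc = sum(1 for x, y in zip(window, rc(mature)) if x != y)
        if d_rc <= max_mismatch:
            out.add((start, "reverse", d_rc))
    return out
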