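"""Shared low-level sequence helpers: reverse complement, semi-global
identity, k-mer extraction.

Identity convention used throughout the toolkit: for sequences a, b with
s = the shorter and l = the longer,

    identity(a, b) = max(0, 1 - d(s, l) / |s|)

where d is the unit-cost edit distance of a semi-global alignment (s aligned
globally, free end gaps on l).  This is 1.0 whenever s is an exact substring
of l, and approximately 1 - mu for a copy mutated at per-base rate mu.  The
value is unique (it does not depend on which optimal traceback an aligner
happens to report).  Computed with edlib in infix (HW) mode.
"""

from __future__ import annotations

import edlib

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def semiglobal_distance(query: str, target: str) -> int:
    """Unit-cost edit distance of query aligned globally within target."""
    return edlib.align(query, target, mode="HW", task="distance")["editDistance"]


def identity(a: str, b: str) -> float:
    """Semi-global identity on the shorter sequence (see module docstring)."""
    if not a or not b:
        raise ValueError("identity of an empty sequence is undefined")
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    d = semiglobal_distance(short, long_)
    return max(0.0, 1.0 - d / len(short))


def kmer_positions(seq: str, k: int) -> list[str]:
    """All k-mers of seq in position order (length len(seq)-k+1, or empty)."""
    return [seq[i:i + k] for i in range(len(seq) - k + 1)]


def max_edits(length: int, identity_min: float) -> int:
    """Largest edit count compatible with identity >= identity_min on a
    shorter-sequence length of ``length``."""
    return int((1.0 - identity_min) * length + 1e-9)


def min_shared_kmers(length: int, k: int, identity_min: float) -> int:
    """Provable lower bound on the number of k-mer positions of the shorter
    sequence whose k-mer must occur exactly in the longer one, given
    identity >= identity_min.

    Each of the at most E = max_edits(length) edit operations destroys at
    most k of the length-k windows of the shorter sequence; every untouched
    window aligns match-only and therefore occurs verbatim in the longer
    sequence.  A bound <= 0 is vacuous (no comparison may be skipped).
    """
    positions = length - k + 1
    return positions - k * max_edits(length, identity_min)
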