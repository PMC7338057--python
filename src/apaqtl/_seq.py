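"""Small strand-aware sequence helpers shared across modules.

Coordinates are 0-based half-open genomic; "transcript sense" means the
strand the mRNA is read from, so for a minus-strand gene the upstream
direction is toward larger genomic coordinates and windows are
reverse-complemented before inspection.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# uint8 base codes used by the simulator: 0=A 1=C 2=G 3=T (complement = 3 - code)
BASE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)
A, C, G, T = 0, 1, 2, 3


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def downstream_window(genome, chrom: str, pos: int, strand: str, n: int) -> str:
    """Transcript-sense sequence of the ``n`` bases immediately 3' of ``pos``.

    The window excludes ``pos`` itself.  Truncated at chromosome ends.
    """
    seq = genome[chrom]
    if strand == "+":
        return seq[pos + 1 : pos + 1 + n]
    return revcomp(seq[max(0, pos - n) : pos])


def upstream_window(genome, chrom: str, pos: int, strand: str, n: int) -> str:
    """Transcript-sense sequence of the ``n`` bases immediately 5' of ``pos``.

    The returned string reads 5'->3' in transcript orientation and its last
    character is the base adjacent to ``pos``.
    """
    seq = genome[chrom]
    if strand == "+":
        return seq[max(0, pos - n) : pos]
    return revcomp(seq[pos + 1 : pos + 1 + n])


def max_run(seq: str, base: str = "A") -> int:
    best = run = 0
    for ch in seq:
        if ch == base:
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


def codes_to_str(codes: np.ndarray) -> str:
    return BASE_LUT[codes].tobytes().decode("ascii")


def str_to_codes(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.zeros(raw.size, dtype=np.uint8)
    out[raw == ord("C")] = C
    out[raw == ord("G")] = G
    out[raw == ord("T")] = T
    return out
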