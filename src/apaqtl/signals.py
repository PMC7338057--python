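"""Polyadenylation signal-site scanning and enrichment statistics.

The polyadenylation machinery is recruited by a hexamer signal (canonically
AATAAA) located roughly 10-50 bases upstream of the cleavage site.  This
module scans the 100 transcript-sense bases upstream of each PAS for the 12
single-hexamer signal variants, exactly and strand-aware, and compares
presence rates between PAS categories and against randomly drawn intronic
background windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportions_ztest

from ._seq import upstream_window
from .simulate import SIGNAL_MOTIFS


@dataclass
class SignalScan:
    pas_id: str
    hits: list[tuple[str, int]]  # (motif, start offset upstream of pas_pos)
    has_signal_10_50: bool


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def scan_signals(
    chrom: str, pas_pos: int, strand: str, genome, window_up: int = 100,
    pas_id: str | None = None,
) -> SignalScan:
    """Exact motif scan of the ``window_up`` bases upstream of a cleavage site.

    A hit's offset is the distance from the motif's transcript-sense start to
    the cleavage base; ``has_signal_10_50`` is true iff any hit starts 10-50
    bases upstream (both ends inclusive).  Windows are truncated at chromosome
    starts.
    """
    w = upstream_window(genome, chrom, pas_pos, strand, window_up)
    n = len(w)
    hits = []
    for motif in SIGNAL_MOTIFS:
        for i in _find_all(w, motif):
            hits.append((motif, n - i))
    hits.sort(key=lambda h: (h[1], h[0]))
    flag = any(10 <= off <= 50 for _, off in hits)
    return SignalScan(pas_id or f"{chrom}:{pas_pos}:{strand}", hits, flag)


def scan_catalog(catalog: pd.DataFrame, genome, window_up: int = 100) -> pd.DataFrame:
    """Per-PAS signal presence for a catalog; one row per PAS."""
    rows = []
    for row in catalog.itertuples():
        scan = scan_signals(
            row.chrom, int(row.pas_pos), row.strand, genome, window_up, pas_id=row.pas_id
        )
        rows.append(
            dict(
                pas_id=row.pas_id,
                category=row.category,
                n_hits=len(scan.hits),
                first_motif=scan.hits[0][0] if scan.hits else None,
                first_offset=scan.hits[0][1] if scan.hits else None,
                has_signal_10_50=scan.has_signal_10_50,
            )
        )
    return pd.DataFrame(rows)


def background_signal_rate(
    introns: pd.DataFrame, genome, width: int = 40, n_draws: int = 1000, seed: int = 0
) -> float:
    """Fraction of random intronic windows containing any signal hexamer.

    Windows of ``width`` bases are drawn uniformly (intron chosen uniformly
    among those long enough, then a uniform start within it) and scanned on
    the intron's transcript sense.
    """
    rng = np.random.default_rng(seed)
    ok = introns[(introns.end - introns.start) >= width].reset_index(drop=True)
    if ok.empty:
        raise ValueError("no intron is long enough for the requested window width")
    n_hit = 0
    idx = rng.integers(0, len(ok), size=n_draws)
    for i in idx:
        row = ok.iloc[int(i)]
        start = int(rng.integers(row.start, row.end - width + 1))
        seq = genome[row.chrom][start : start + width]
        if row.strand == "-":
            from ._seq import revcomp

            seq = revcomp(seq)
        if any(m in seq for m in SIGNAL_MOTIFS):
            n_hit += 1
    return n_hit / n_draws


def proportion_diff_test(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Two-sample pooled-variance proportion z-test, two-sided.

    Returns ``(z, p)``; the statistic is positive when group 1's rate is the
    larger one.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if k1 > n1 or k2 > n2:
        raise ValueError("successes cannot exceed trials")
    if k1 * n2 == k2 * n1:
        return 0.0, 1.0
    stat, p = proportions_ztest([k1, k2], [n1, n2], alternative="two-sided")
    return float(stat), float(p)
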