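"""Peak calling, gene assignment, site filter and usage quantification."""

import math

import numpy as np
import pandas as pd
import pytest

from apaqtl import peaks as pk
from apaqtl.reads import READ_COLUMNS, MappedReadSet


def read_set_from_matrix(counts, chrom="chr1", strand="+", start=0):
    """Dense (bases x libraries) count matrix -> MappedReadSet."""
    libs = [f"lib{j}" for j in range(counts.shape[1])]
    rows = []
    for i, j in zip(*np.nonzero(counts)):
        rows.append((chrom, start + i, strand, libs[j], int(counts[i, j])))
    return MappedReadSet(pd.DataFrame(rows, columns=READ_COLUMNS), libs)


def brute_force_peaks(counts, min_nonzero_frac=0.9, min_mean_count=2.0,
                      chrom="chr1", strand="+", start=0):
    """Independent per-base scan + run merge over a dense coverage matrix."""
    n_bases, n_lib = counts.shape
    need = math.ceil(min_nonzero_frac * n_lib - 1e-9)
    qual = [
        (counts[i] > 0).sum() >= need and counts[i].sum() / n_lib > min_mean_count
        for i in range(n_bases)
    ]
    peaks, i = [], 0
    while i < n_bases:
        if not qual[i]:
            i += 1
            continue
        j = i
        while j + 1 < n_bases and qual[j + 1]:
            j += 1
        span = counts[i : j + 1].sum(axis=0)
        per_lib = {f"lib{l}": int(span[l]) for l in range(n_lib) if span[l] > 0}
        pas = start + (j if strand == "+" else i)
        peaks.append((chrom, start + i, start + j + 1, strand, per_lib, pas))
        i = j + 1
    return peaks


def as_tuples(peaks):
    return [
        (p.chrom, p.start, p.end, p.strand, dict(p.per_library_counts), p.pas_pos)
        for p in peaks
    ]


def test_boundary_ninety_percent_and_mean():
    """9/10 nonzero libraries with mean 2.7 qualifies; mean exactly 2 does not."""
    m = np.zeros((1, 10), dtype=int)
    m[0, :9] = 3
    assert len(pk.call_peaks(read_set_from_matrix(m))) == 1
    m2 = np.full((1, 10), 2, dtype=int)
    assert len(pk.call_peaks(read_set_from_matrix(m2))) == 0


def test_gap_splits_peaks():
    m = np.zeros((4, 4), dtype=int)
    m[0] = m[1] = m[3] = 5
    m[2] = 0
    peaks = pk.call_peaks(read_set_from_matrix(m))
    assert [(p.start, p.end) for p in peaks] == [(0, 2), (3, 4)]


def test_pas_pos_is_transcript_sense_three_prime_end():
    m = np.full((3, 4), 5, dtype=int)
    plus = pk.call_peaks(read_set_from_matrix(m, strand="+", start=10))[0]
    minus = pk.call_peaks(read_set_from_matrix(m, strand="-", start=10))[0]
    assert plus.pas_pos == 12 and minus.pas_pos == 10


def test_peak_caller_matches_bruteforce_on_random_matrices():
    rng = np.random.default_rng(5)
    for _ in range(100):
        n_bases = int(rng.integers(1, 60))
        n_lib = int(rng.integers(2, 12))
        m = rng.poisson(rng.uniform(0.5, 4.0), size=(n_bases, n_lib))
        m[rng.random(size=m.shape) < 0.3] = 0
        strand = rng.choice(["+", "-"])
        got = as_tuples(pk.call_peaks(read_set_from_matrix(m, strand=strand)))
        want = brute_force_peaks(m, strand=strand)
        assert got == want


def _annotation(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene_id", "feature"])


def _peak(start, end, strand="+", chrom="chr1"):
    return pk.Peak(chrom, start, end, strand, {"lib0": 5}, start if strand == "-" else end - 1)


def test_assignment_hierarchy():
    ann = _annotation([
        ("chr1", 0, 100, "+", "geneA", "utr3"),
        ("chr1", 0, 100, "+", "geneB", "intron"),
        ("chr1", 200, 300, "+", "geneC", "intron"),
        ("chr1", 400, 500, "+", "geneD", "exon"),
        ("chr1", 400, 500, "+", "geneD", "utr5"),
    ])
    assert pk.assign_gene(_peak(10, 20), ann) == ("geneA", "utr3")
    assert pk.assign_gene(_peak(210, 220), ann) == ("geneC", "intron")
    assert pk.assign_gene(_peak(410, 420), ann) == ("geneD", "exon")
    assert pk.assign_gene(_peak(600, 610), ann) is None


def test_assignment_requires_matching_strand():
    ann = _annotation([("chr1", 0, 100, "-", "geneA", "utr3")])
    assert pk.assign_gene(_peak(10, 20, strand="+"), ann) is None


def test_assignment_tie_breaks_and_order_independence():
    rows = [
        ("chr1", 0, 15, "+", "geneB", "intron"),
        ("chr1", 0, 30, "+", "geneA", "intron"),
        ("chr1", 5, 30, "+", "geneC", "intron"),
    ]
    ann = _annotation(rows)
    shuffled = _annotation([rows[2], rows[0], rows[1]])
    # overlap with [0, 30): geneA 30, geneC 25, geneB 15
    assert pk.assign_gene(_peak(0, 30), ann) == ("geneA", "intron")
    assert pk.assign_gene(_peak(0, 30), shuffled) == ("geneA", "intron")


@pytest.mark.parametrize(
    "window,removed",
    [
        ("AAAAAACGTACGTAC", True),              # six consecutive A
        ("AAGAAGAAGAAGAAA", True),              # 11 of 15 A, no 6-run
        ("ACGTACGTACGTACG", False),
        ("AAGAAGAAGAAGACA", False),             # 10 of 15 A: below 70%
    ],
)
def test_pas_level_mispriming_filter(window, removed):
    genome = {"chr1": "ACGTACGTAC" + window + "GGGG"}
    catalog = pd.DataFrame(
        [dict(pas_id="p1", gene_id="g", category="utr3", chrom="chr1",
              strand="+", pas_pos=9, start=8, end=10)]
    )
    out = pk.filter_misprimed_pas(catalog, genome)
    assert out.empty == removed


def _usage_fixture(counts_by_pas):
    """Two-PAS single-gene catalog plus reads producing the given counts."""
    catalog = pd.DataFrame(
        [
            dict(pas_id="pA", gene_id="g1", category="utr3", chrom="chr1",
                 strand="+", pas_pos=10, start=10, end=11),
            dict(pas_id="pB", gene_id="g1", category="intron", chrom="chr1",
                 strand="+", pas_pos=50, start=50, end=51),
        ]
    )
    rows = []
    for lib, (a, b) in counts_by_pas.items():
        if a:
            rows.append(("chr1", 10, "+", lib, a))
        if b:
            rows.append(("chr1", 50, "+", lib, b))
    sheet = pd.DataFrame(
        [dict(library_id=l, individual=l, fraction="nuclear", batch="b0")
         for l in counts_by_pas]
    )
    rs = MappedReadSet(pd.DataFrame(rows, columns=READ_COLUMNS), list(counts_by_pas))
    return catalog, rs, sheet


def test_usage_normalization_and_missingness():
    catalog, rs, sheet = _usage_fixture({"l1": (30, 70), "l2": (0, 0)})
    m = pk.quantify_usage(catalog, rs, sheet)
    assert m.usage.loc["pA", "l1"] == pytest.approx(0.3)
    assert m.usage.loc["pB", "l1"] == pytest.approx(0.7)
    assert np.isnan(m.usage.loc["pA", "l2"]) and np.isnan(m.usage.loc["pB", "l2"])


def test_single_pas_gene_usage_is_one():
    catalog, rs, sheet = _usage_fixture({"l1": (12, 0)})
    catalog = catalog.iloc[:1]
    m = pk.quantify_usage(catalog, rs, sheet)
    assert m.usage.loc["pA", "l1"] == pytest.approx(1.0)


def test_unknown_library_rejected():
    catalog, rs, sheet = _usage_fixture({"l1": (3, 4)})
    with pytest.raises(KeyError):
        pk.quantify_usage(catalog, rs, sheet.iloc[:0])


def _matrix_with_means(nuc_mean, tot_mean):
    counts = pd.DataFrame({"n1": [10, 10], "t1": [10, 10]},
                          index=pd.Index(["pA", "pB"], name="pas_id")).astype(float)
    usage = pd.DataFrame({"n1": [nuc_mean, 1 - nuc_mean], "t1": [tot_mean, 1 - tot_mean]},
                         index=counts.index)
    meta = pd.DataFrame(
        dict(gene_id=["g1", "g1"], category=["utr3", "utr3"], chrom="chr1",
             strand="+", pas_pos=[5, 50], start=[5, 50], end=[6, 51]),
        index=counts.index,
    )
    sheet = pd.DataFrame(
        [dict(individual="i1", fraction="nuclear", batch="b"),
         dict(individual="i1", fraction="total", batch="b")],
        index=pd.Index(["n1", "t1"], name="library_id"),
    )
    return pk.UsageMatrix(counts, usage, meta, sheet)


@pytest.mark.parametrize(
    "nuc,tot,kept",
    [
        (0.06, 0.01, True),    # passes in nuclear only
        (0.02, 0.03, False),   # fails in both
        (0.05, 0.05, True),    # boundary: 'less than 5%' is strict
    ],
)
def test_low_usage_filter_requires_failure_in_both_fractions(nuc, tot, kept):
    m = _matrix_with_means(nuc, tot)
    out = pk.filter_low_usage(m)
    assert ("pA" in out.counts.index) == kept
    assert "pB" in out.counts.index  # complement is always high-usage


def test_usage_columns_sum_to_one_on_full_run(small_discovery):
    m = small_discovery.matrix
    gene_sums = m.usage.groupby(m.pas_meta.gene_id).sum(min_count=1)
    defined = gene_sums.notna()
    assert defined.any().any()
    assert np.allclose(gene_sums.to_numpy()[defined.to_numpy()], 1.0, atol=1e-9)
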