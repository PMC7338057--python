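"""End-to-end discovery driver: reads -> filtered, quantified PAS catalog."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import fractions as fr
from . import peaks as pk
from . import reads as rd


@dataclass
class DiscoveryResult:
    catalog: pd.DataFrame
    matrix: pk.UsageMatrix
    n_peaks: int
    n_removed_misprimed_pas: int


def run_pas_discovery(
    read_set: rd.MappedReadSet,
    genome,
    annotation: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    min_nonzero_frac: float = 0.9,
    min_mean_count: float = 2.0,
    min_mean_usage: float = 0.05,
) -> DiscoveryResult:
    """Filter misprimed reads, call peaks, assign, screen and quantify PAS."""
    filtered = rd.filter_misprimed_reads(read_set, genome)
    peaks = pk.call_peaks(filtered, min_nonzero_frac, min_mean_count)
    catalog = pk.build_catalog(peaks, annotation)
    kept = pk.filter_misprimed_pas(catalog, genome)
    n_removed = len(catalog) - len(kept)
    matrix = pk.quantify_usage(kept, filtered, sample_sheet)
    matrix = pk.filter_low_usage(matrix, min_mean_usage)
    catalog_final = kept[kept.pas_id.isin(matrix.counts.index)].reset_index(drop=True)
    return DiscoveryResult(catalog_final, matrix, len(peaks), n_removed)


def run_fraction_comparison(matrix: pk.UsageMatrix, fdr: float = 0.1, dpau_cut: float = 0.2):
    """Gene-level DM test plus dPAU labelling and nuclear-enriched calls."""
    gene_table, pas_table = fr.fraction_differential_table(matrix)
    gene_table, pas_table = fr.classify_differential(gene_table, pas_table, fdr, dpau_cut)
    enriched = fr.nuclear_enriched_pas(matrix, gene_table, pas_table, dpau_cut)
    return gene_table, pas_table, enriched
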