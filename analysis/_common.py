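"""Shared state for the numbered analysis scripts.

The study is deterministic in the seed, so scripts can either rebuild it or
reuse the pickle cached under scratch/ by an earlier script in the sequence.
"""

from __future__ import annotations

import pickle
from pathlib import Path

from apaqtl import pipeline as pl
from apaqtl import simulate as sim

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
SEED = 1


def get_study(seed: int = SEED):
    """Synthetic study + discovery result, cached in scratch/ between scripts."""
    SCRATCH.mkdir(exist_ok=True)
    cache = SCRATCH / f"study_seed{seed}.pkl"
    if cache.exists():
        with open(cache, "rb") as fh:
            return pickle.load(fh)
    cfg = sim.SyntheticConfig(seed=seed)  # 300 genes, 52 individuals, 2 fractions
    truth = sim.generate_truth(cfg)
    geno = sim.generate_genotypes(truth, cfg)
    read_set, sheet = sim.simulate_dataset(truth, geno, cfg)
    disc = pl.run_pas_discovery(read_set, truth.genome, truth.annotation_frame(), sheet)
    study = dict(config=cfg, truth=truth, genotypes=geno, read_set=read_set,
                 sample_sheet=sheet, discovery=disc)
    with open(cache, "wb") as fh:
        pickle.dump(study, fh)
    return study


def get_qtl_tables(study, seed: int = SEED, n_permutations: int = 200):
    """Per-fraction apaQTL tables (all tested PAS), cached in scratch/."""
    from apaqtl import qtl

    SCRATCH.mkdir(exist_ok=True)
    cache = SCRATCH / f"apaqtl_seed{seed}.pkl"
    if cache.exists():
        with open(cache, "rb") as fh:
            return pickle.load(fh)
    tables = {
        fraction: qtl.map_apaqtls(study["discovery"].matrix, study["genotypes"],
                                  fraction, n_permutations=n_permutations, seed=seed)
        for fraction in ("nuclear", "total")
    }
    with open(cache, "wb") as fh:
        pickle.dump(tables, fh)
    return tables
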