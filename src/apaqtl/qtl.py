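"""cis-apaQTL mapping: phenotype normalization, covariates, permutation scan.

Phenotypes are per-PAS usage ratios across individuals within one fraction.
Each row is mean-imputed, centered/scaled, then rank inverse-normal
transformed with offset (rank - 0.5)/n, which makes every retained phenotype
standard-normal-like and the scan robust to the ratio scale.  Covariates are
the top phenotype principal components (default 4) plus one-hot library batch.

For every PAS, variants within a symmetric cis window (default +/- 25 kb,
inclusive) are tested by OLS of the phenotype on dosage after residualizing
both on the covariates.  Site-level significance uses an empirical
permutation scheme: the phenotype vector is permuted across individuals
(covariates stay attached to the genotypes), the minimum nominal p in the
window is recorded each round, and the permutation p-value is
``(1 + #{perm min-p <= observed}) / (B + 1)``.  Benjamini-Hochberg across all
PAS within a fraction at 10% FDR yields the apaQTL calls; interpretable
effect sizes are re-estimated as OLS slopes on the pre-normalized usage
ratios (delta usage per alternate allele).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .peaks import UsageMatrix
from .simulate import GenotypeMatrix


@dataclass
class PhenotypeMatrix:
    values: pd.DataFrame     # rows pas_id, columns individuals (normalized)
    raw: pd.DataFrame        # pre-normalization usage ratios, same shape
    meta: pd.DataFrame       # pas metadata aligned to rows
    fraction: str


def inverse_normal_transform(x: np.ndarray) -> np.ndarray:
    """Rank-based INT with offset (rank - 0.5)/n; ties share average ranks."""
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.5) / len(x))


def normalize_phenotypes(
    matrix: UsageMatrix, fraction: str, min_present: int = 5
) -> PhenotypeMatrix:
    """Usage ratios -> QTL-ready phenotypes for one fraction.

    Missing entries are imputed to the row mean (keeping one design matrix
    across PAS), rows are centered, scaled and inverse-normal transformed;
    rows that are constant or observed in fewer than ``min_present``
    individuals are dropped.
    """
    libs = matrix.libraries_for(fraction)
    individuals = matrix.sample_sheet.loc[libs, "individual"].tolist()
    if len(set(individuals)) != len(individuals):
        raise ValueError("expected one library per individual per fraction")
    raw = matrix.usage[libs].copy()
    raw.columns = individuals

    rows, raw_rows, kept = [], [], []
    for pas_id, row in raw.iterrows():
        x = row.to_numpy(dtype=float)
        present = np.isfinite(x)
        if present.sum() < min_present:
            continue
        x = np.where(present, x, np.nanmean(x))
        if np.nanstd(x) == 0:
            continue
        x = (x - x.mean()) / x.std()
        rows.append(inverse_normal_transform(x))
        raw_rows.append(np.where(present, row.to_numpy(dtype=float), np.nanmean(row)))
        kept.append(pas_id)

    values = pd.DataFrame(rows, index=pd.Index(kept, name="pas_id"), columns=individuals)
    rawf = pd.DataFrame(raw_rows, index=values.index, columns=individuals)
    return PhenotypeMatrix(values, rawf, matrix.pas_meta.loc[kept], fraction)


def build_covariates(
    phenotypes: PhenotypeMatrix, n_pcs: int = 4, batch: pd.Series | None = None
) -> pd.DataFrame:
    """Top phenotype PCs plus one-hot batch (reference level dropped).

    PCA treats individuals as observations and PAS phenotypes as features;
    the intercept is added by the regression, not here.
    """
    individuals = list(phenotypes.values.columns)
    n = len(individuals)
    if n_pcs >= n:
        raise ValueError("n_pcs must be smaller than the number of individuals")
    cols = {}
    if n_pcs > 0:
        x = phenotypes.values.to_numpy().T  # individuals x pas
        pcs = PCA(n_components=n_pcs, svd_solver="full").fit_transform(x)
        for j in range(n_pcs):
            cols[f"PC{j + 1}"] = pcs[:, j]
    cov = pd.DataFrame(cols, index=individuals)
    if batch is not None:
        b = batch.reindex(individuals)
        dummies = pd.get_dummies(b, prefix="batch", drop_first=True, dtype=float)
        cov = pd.concat([cov, dummies], axis=1)
    return cov


def _residualize(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Residuals of y (vector or columns of a matrix) on a design with intercept."""
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def _design(cov: pd.DataFrame | None, n: int) -> np.ndarray:
    if cov is None or cov.shape[1] == 0:
        return np.ones((n, 1))
    return np.column_stack([np.ones(n), cov.to_numpy(dtype=float)])


def cis_variants(
    genotypes: GenotypeMatrix, chrom: str, pas_pos: int, window: int = 25000
) -> np.ndarray:
    v = genotypes.variants
    mask = (v.chrom == chrom) & ((v.pos - pas_pos).abs() <= window)
    return np.flatnonzero(mask.to_numpy())


def cis_scan(
    phenotype: np.ndarray,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame | None,
    chrom: str,
    pas_pos: int,
    window: int = 25000,
    individuals: list[str] | None = None,
) -> pd.DataFrame:
    """Nominal OLS associations for every variant within the cis window."""
    idx = cis_variants(genotypes, chrom, pas_pos, window)
    if idx.size == 0:
        return pd.DataFrame(columns=["snp_id", "pos", "slope", "se", "nominal_p"])
    cols = (
        [genotypes.individuals.index(i) for i in individuals]
        if individuals is not None
        else list(range(len(genotypes.individuals)))
    )
    g = genotypes.dosages[np.ix_(idx, cols)].astype(float)
    y = np.asarray(phenotype, dtype=float)
    design = _design(covariates, len(y))
    q = design.shape[1]
    yr = _residualize(y, design)
    gr = _residualize(g.T, design).T  # variants x n

    gg = (gr * gr).sum(axis=1)
    valid = gg > 1e-12
    slope = np.full(len(idx), np.nan)
    se = np.full(len(idx), np.nan)
    pval = np.full(len(idx), np.nan)
    df = len(y) - q - 1
    if df > 0 and valid.any():
        b = (gr[valid] @ yr) / gg[valid]
        rss = (yr * yr).sum() - b**2 * gg[valid]
        sigma2 = np.maximum(rss, 0.0) / df
        s = np.sqrt(sigma2 / gg[valid])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(s > 0, b / s, np.inf * np.sign(b))
        slope[valid] = b
        se[valid] = s
        pval[valid] = 2 * stats.t.sf(np.abs(t), df)
    sub = genotypes.variants.iloc[idx]
    return pd.DataFrame(
        dict(snp_id=sub.snp_id.to_numpy(), pos=sub.pos.to_numpy(),
             slope=slope, se=se, nominal_p=pval)
    )


def permutation_pass(
    phenotype: np.ndarray,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame | None,
    chrom: str,
    pas_pos: int,
    window: int = 25000,
    n_permutations: int = 1000,
    seed: int = 0,
    individuals: list[str] | None = None,
):
    """Empirical permutation p-value for the best cis association of one PAS.

    Returns ``(lead_snp_id, permutation_p, lead_nominal_p, lead_slope)`` or
    ``None`` when the window holds no variant.
    """
    nominal = cis_scan(phenotype, genotypes, covariates, chrom, pas_pos, window, individuals)
    nominal = nominal.dropna(subset=["nominal_p"])
    if nominal.empty:
        return None
    best = nominal.nominal_p.idxmin()
    obs_p = float(nominal.nominal_p.loc[best])

    idx = cis_variants(genotypes, chrom, pas_pos, window)
    cols = (
        [genotypes.individuals.index(i) for i in individuals]
        if individuals is not None
        else list(range(len(genotypes.individuals)))
    )
    g = genotypes.dosages[np.ix_(idx, cols)].astype(float)
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    design = _design(covariates, n)
    q = design.shape[1]
    df = n - q - 1

    gr = _residualize(g.T, design).T
    gnorm = np.linalg.norm(gr, axis=1)
    ok = gnorm > 1e-12
    gu = gr[ok] / gnorm[ok][:, None]

    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(y) for _ in range(n_permutations)], axis=1)
    pr = _residualize(perms, design)  # n x B
    pnorm = np.linalg.norm(pr, axis=0)
    pnorm[pnorm == 0] = 1.0
    r = gu @ (pr / pnorm)  # variants x B correlations
    r2max = np.clip((r**2).max(axis=0), 0.0, 1.0 - 1e-12)
    tmax2 = r2max * df / (1.0 - r2max)
    perm_min_p = 2 * stats.t.sf(np.sqrt(tmax2), df)
    perm_p = (1.0 + np.sum(perm_min_p <= obs_p + 1e-15)) / (n_permutations + 1.0)
    return (
        str(nominal.snp_id.loc[best]),
        float(perm_p),
        obs_p,
        float(nominal.slope.loc[best]),
    )


def call_qtls(perm_table: pd.DataFrame, fdr: float = 0.1) -> pd.DataFrame:
    """BH over PAS-level permutation p-values; flags significant rows."""
    out = perm_table.copy()
    if len(out):
        rej, q, _, _ = multipletests(out.permutation_p, alpha=fdr, method="fdr_bh")
    else:
        rej, q = np.array([], bool), np.array([])
    out["q_value"] = q
    out["significant"] = rej
    return out


def effect_size_raw(
    raw_usage: np.ndarray, dosage: np.ndarray, covariates: pd.DataFrame | None = None
) -> float:
    """Covariate-adjusted OLS slope of raw usage on dosage (delta usage/allele)."""
    y = np.asarray(raw_usage, dtype=float)
    g = np.asarray(dosage, dtype=float)
    if np.std(g) == 0:
        return float("nan")
    design = _design(covariates, len(y))
    yr = _residualize(y, design)
    gr = _residualize(g, design)
    denom = float(gr @ gr)
    if denom <= 1e-12:
        return float("nan")
    return float((gr @ yr) / denom)


def map_apaqtls(
    matrix: UsageMatrix,
    genotypes: GenotypeMatrix,
    fraction: str,
    window: int = 25000,
    n_permutations: int = 1000,
    n_pcs: int = 4,
    fdr: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Full per-fraction scan: normalize, covariates, permutations, BH calls.

    One row per tested PAS: lead variant, nominal/permutation p, BH q,
    significance flag, and the raw-scale slope for the lead variant.
    """
    phen = normalize_phenotypes(matrix, fraction)
    libs = matrix.libraries_for(fraction)
    batch = matrix.sample_sheet.loc[libs].set_index("individual")["batch"]
    batch = batch if batch.nunique() > 1 else None
    cov = build_covariates(phen, n_pcs=min(n_pcs, len(phen.values.columns) - 1), batch=batch)
    individuals = list(phen.values.columns)

    rows = []
    for i, (pas_id, meta) in enumerate(phen.meta.iterrows()):
        res = permutation_pass(
            phen.values.loc[pas_id].to_numpy(),
            genotypes,
            cov,
            meta.chrom,
            int(meta.pas_pos),
            window=window,
            n_permutations=n_permutations,
            seed=seed * 1_000_003 % (2**31) + i,
            individuals=individuals,
        )
        if res is None:
            continue
        lead, perm_p, nom_p, _ = res
        slope_raw = effect_size_raw(
            phen.raw.loc[pas_id].to_numpy(),
            genotypes.dosages[
                genotypes.variants.index[genotypes.variants.snp_id == lead][0],
                [genotypes.individuals.index(i2) for i2 in individuals],
            ],
            cov,
        )
        rows.append(
            dict(
                pas_id=pas_id, gene_id=meta.gene_id, chrom=meta.chrom,
                pas_pos=int(meta.pas_pos), lead_snp=lead, nominal_p=nom_p,
                slope_raw=slope_raw, permutation_p=perm_p,
            )
        )
    table = pd.DataFrame(
        rows,
        columns=["pas_id", "gene_id", "chrom", "pas_pos", "lead_snp",
                 "nominal_p", "slope_raw", "permutation_p"],
    )
    return call_qtls(table, fdr=fdr)
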