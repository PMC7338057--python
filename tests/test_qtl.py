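"""Phenotype normalization, covariates, cis scan and permutation scheme."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from apaqtl import peaks as pk
from apaqtl import qtl
from apaqtl.simulate import GenotypeMatrix


def _usage_matrix(usage_rows, individuals, fraction="nuclear", pos=None):
    libs = [f"{i}_{fraction}" for i in individuals]
    index = pd.Index([f"pas{i}" for i in range(len(usage_rows))], name="pas_id")
    usage = pd.DataFrame(usage_rows, index=index, columns=libs, dtype=float)
    counts = usage.fillna(0.0) * 100
    meta = pd.DataFrame(
        dict(gene_id="g1", category="utr3", chrom="chr1",
             pas_pos=pos if pos is not None else np.arange(len(usage_rows)) * 100 + 1000,
             strand="+",
             start=0, end=1),
        index=index,
    )
    sheet = pd.DataFrame(
        [dict(individual=i, fraction=fraction, batch="b0") for i in individuals],
        index=pd.Index(libs, name="library_id"),
    )
    return pk.UsageMatrix(counts, usage, meta, sheet)


def _genotypes(dosage_rows, positions, individuals):
    variants = pd.DataFrame(
        [dict(snp_id=f"chr1:{p}", chrom="chr1", pos=p, maf=0.3, sample_maf=0.3)
         for p in positions]
    )
    return GenotypeMatrix(variants, np.array(dosage_rows, dtype=np.int8), list(individuals))


def test_inverse_normal_transform_offset_and_symmetry():
    got = qtl.inverse_normal_transform(np.array([0.1, 0.5, 0.9]))
    want = sps.norm.ppf((np.array([1, 2, 3]) - 0.5) / 3)
    assert np.allclose(got, want)
    assert got[1] == pytest.approx(0.0, abs=1e-12)
    assert got[0] == pytest.approx(-got[2])


def test_normalization_rank_invariance_and_dropping():
    inds = [f"i{k}" for k in range(8)]
    base = np.linspace(0.1, 0.8, 8)
    m = _usage_matrix([base, base**3, np.full(8, 0.5)], inds)
    phen = qtl.normalize_phenotypes(m, "nuclear")
    assert list(phen.values.index) == ["pas0", "pas1"]  # constant row dropped
    # monotone transform of a row gives identical normalized values
    assert np.allclose(phen.values.loc["pas0"], phen.values.loc["pas1"])
    assert phen.values.loc["pas0"].mean() == pytest.approx(0.0, abs=1e-9)


def test_rows_with_few_observations_dropped():
    inds = [f"i{k}" for k in range(8)]
    sparse = [0.1, 0.4, np.nan, np.nan, np.nan, np.nan, 0.3, np.nan]
    m = _usage_matrix([sparse, np.linspace(0, 1, 8)], inds)
    phen = qtl.normalize_phenotypes(m, "nuclear")
    assert list(phen.values.index) == ["pas1"]


def test_covariates_intercept_only_and_pc_orthogonality():
    inds = [f"i{k}" for k in range(10)]
    rng = np.random.default_rng(1)
    m = _usage_matrix(list(rng.uniform(0.1, 0.9, size=(6, 10))), inds)
    phen = qtl.normalize_phenotypes(m, "nuclear")
    empty = qtl.build_covariates(phen, n_pcs=0)
    assert empty.shape == (10, 0)
    cov = qtl.build_covariates(phen, n_pcs=3)
    gram = cov.to_numpy().T @ cov.to_numpy()
    off = gram - np.diag(np.diag(gram))
    assert np.all(np.abs(off) < 1e-8)
    with pytest.raises(ValueError):
        qtl.build_covariates(phen, n_pcs=10)


def test_planted_batch_shift_recovered_by_pc1():
    from apaqtl import pipeline as pl
    from apaqtl import simulate as sim

    cfg = sim.SyntheticConfig(n_genes=40, n_individuals=20, n_batches=2,
                              batch_effect=2.0, qtl_fraction=0.0, seed=21)
    truth = sim.generate_truth(cfg)
    geno = sim.generate_genotypes(truth, cfg)
    rs, sheet = sim.simulate_dataset(truth, geno, cfg)
    disc = pl.run_pas_discovery(rs, truth.genome, truth.annotation_frame(), sheet)
    phen = qtl.normalize_phenotypes(disc.matrix, "nuclear")
    cov = qtl.build_covariates(phen, n_pcs=4)
    batch = sheet[sheet.fraction == "nuclear"].set_index("individual").batch
    b = (batch.reindex(phen.values.columns) == "batch1").astype(float)
    r = np.corrcoef(cov["PC1"], b)[0, 1]
    assert abs(r) > 0.5


def test_cis_scan_perfect_association_and_window_bounds():
    inds = [f"i{k}" for k in range(12)]
    dosage = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, 0, 1, 2])
    geno = _genotypes(
        [dosage, dosage[::-1]], positions=[26000, 51001], individuals=inds
    )
    y = dosage.astype(float)
    res = qtl.cis_scan(y, geno, None, "chr1", 1000, window=25000)
    assert list(res.snp_id) == ["chr1:26000"]  # 51001 is outside +/-25 kb
    assert res.slope.iloc[0] == pytest.approx(1.0, abs=1e-12)
    assert res.nominal_p.iloc[0] < 1e-20


def test_cis_window_inclusive_at_exact_boundary():
    inds = [f"i{k}" for k in range(6)]
    geno = _genotypes(
        [[0, 1, 2, 0, 1, 2]], positions=[26000], individuals=inds
    )
    hit = qtl.cis_variants(geno, "chr1", 1000, window=25000)
    assert hit.size == 1
    miss = qtl.cis_variants(geno, "chr1", 999, window=25000)
    assert miss.size == 0


def test_cis_scan_matches_normal_equations_oracle():
    rng = np.random.default_rng(3)
    inds = [f"i{k}" for k in range(6)]
    g = rng.integers(0, 3, size=(1, 6))
    geno = _genotypes(list(g), positions=[1000], individuals=inds)
    y = rng.normal(size=6)
    cov = pd.DataFrame({"c1": rng.normal(size=6)}, index=inds)
    res = qtl.cis_scan(y, geno, cov, "chr1", 1000)
    # explicit OLS with intercept + covariate + dosage
    x = np.column_stack([np.ones(6), cov.c1.to_numpy(), g[0]])
    beta = np.linalg.solve(x.T @ x, x.T @ y)
    resid = y - x @ beta
    sigma2 = resid @ resid / (6 - 3)
    se = np.sqrt(sigma2 * np.linalg.inv(x.T @ x)[2, 2])
    t = beta[2] / se
    p = 2 * sps.t.sf(abs(t), 6 - 3)
    assert res.slope.iloc[0] == pytest.approx(beta[2], abs=1e-10)
    assert res.se.iloc[0] == pytest.approx(se, abs=1e-10)
    assert res.nominal_p.iloc[0] == pytest.approx(p, abs=1e-10)


def test_permutation_p_lower_bound_and_seed_determinism():
    rng = np.random.default_rng(4)
    inds = [f"i{k}" for k in range(20)]
    g = rng.integers(0, 3, size=(5, 20))
    geno = _genotypes(list(g), positions=[1000, 2000, 3000, 4000, 5000], individuals=inds)
    y = g[2] + rng.normal(0, 0.1, size=20)
    out1 = qtl.permutation_pass(y, geno, None, "chr1", 2500, n_permutations=100, seed=9)
    out2 = qtl.permutation_pass(y, geno, None, "chr1", 2500, n_permutations=100, seed=9)
    assert out1 == out2
    assert out1[1] >= 1 / 101
    assert out1[0] == "chr1:3000"


def test_permutation_p_matches_bruteforce_single_variant():
    rng = np.random.default_rng(5)
    n, B = 15, 100
    inds = [f"i{k}" for k in range(n)]
    g = rng.integers(0, 3, size=(1, n)).astype(float)
    geno = _genotypes(list(g.astype(np.int8)), positions=[1000], individuals=inds)
    y = rng.normal(size=n)
    lead, perm_p, obs_p, _ = qtl.permutation_pass(
        y, geno, None, "chr1", 1000, n_permutations=B, seed=17
    )
    # brute force: same permutation stream, explicit per-permutation OLS p
    rng2 = np.random.default_rng(17)
    count = 0
    for _ in range(B):
        yp = rng2.permutation(y)
        res = sps.linregress(g[0], yp)
        if res.pvalue <= obs_p + 1e-15:
            count += 1
    assert perm_p == pytest.approx((1 + count) / (B + 1), abs=1e-12)


def test_bh_fixture_and_bruteforce_equivalence():
    table = pd.DataFrame(
        dict(pas_id=list("abcd"), permutation_p=[0.001, 0.02, 0.04, 0.8])
    )
    out = qtl.call_qtls(table, fdr=0.1)
    assert out.significant.tolist() == [True, True, True, False]

    def bh_bruteforce(p, alpha):
        p = np.asarray(p)
        order = np.argsort(p, kind="mergesort")
        m = len(p)
        passed = [i for i, idx in enumerate(order) if p[idx] <= alpha * (i + 1) / m]
        rej = np.zeros(m, bool)
        if passed:
            rej[order[: passed[-1] + 1]] = True
        return rej

    rng = np.random.default_rng(6)
    for _ in range(100):
        p = rng.uniform(size=rng.integers(1, 40)) ** rng.uniform(0.3, 3)
        got = qtl.call_qtls(pd.DataFrame(dict(permutation_p=p)), fdr=0.1).significant.to_numpy()
        assert np.array_equal(got, bh_bruteforce(p, 0.1))


def test_bh_scale_invariance_under_duplication():
    p = [0.002, 0.03, 0.2, 0.6]
    single = qtl.call_qtls(pd.DataFrame(dict(permutation_p=p)), fdr=0.1)
    double = qtl.call_qtls(pd.DataFrame(dict(permutation_p=p + p)), fdr=0.1)
    assert single.significant.mean() == double.significant.mean()
    assert qtl.call_qtls(pd.DataFrame(dict(permutation_p=[1.0, 1.0])), fdr=0.1).significant.sum() == 0


def test_raw_effect_size_fixture_and_allele_flip():
    usage = np.array([0.2, 0.2, 0.4, 0.4, 0.6, 0.6])
    dosage = np.array([0, 0, 1, 1, 2, 2])
    assert qtl.effect_size_raw(usage, dosage) == pytest.approx(0.2, abs=1e-12)
    assert qtl.effect_size_raw(usage, 2 - dosage) == pytest.approx(-0.2, abs=1e-12)
    assert np.isnan(qtl.effect_size_raw(usage, np.zeros(6)))
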