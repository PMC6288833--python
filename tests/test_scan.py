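"""Genome-scan semantics: nulls, LODs, degrees of freedom, invariants."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mvqtlmap import (
    DesignPair,
    ModelSpec,
    ScanResult,
    calc_genoprob,
    fit_dglm,
    qtl_dosages,
    scanonevar,
    simulate_cross,
    summary_scan,
)
from mvqtlmap.scan import ScanEngine
from mvqtlmap.simulate import PhenotypeSpec, SimSpec


def test_qtl_dosage_coding(bench_probs):
    add, dom = qtl_dosages(bench_probs, "D1M1")
    g = np.argmax(bench_probs.probs[:, bench_probs.locus_index("D1M1"), :], axis=1)
    # near-certain genotypes at a typed marker map to the corner codings
    certain = bench_probs.probs[:, bench_probs.locus_index("D1M1"), :].max(axis=1) > 0.999
    expected_add = {0: -1.0, 1: 0.0, 2: 1.0}
    expected_dom = {0: 0.0, 1: 1.0, 2: 0.0}
    assert np.allclose(add[certain], [expected_add[k] for k in g[certain]], atol=2e-3)
    assert np.allclose(dom[certain], [expected_dom[k] for k in g[certain]], atol=2e-3)
    assert np.all((add >= -1) & (add <= 1))
    assert np.all((dom >= 0) & (dom <= 1))


def test_average_additive_dosage_near_zero(big_cross, big_probs):
    add, _ = qtl_dosages(big_probs, "D2M6")
    se = np.sqrt(0.5 / big_cross.n_individuals)  # Var(d) = 1/2 in an F2
    assert abs(add.mean()) < 3 * se


def test_uniform_uncertainty_dosage():
    from mvqtlmap.genoprob import GenotypeProbabilities, LocusGrid

    grid = LocusGrid(("1",), {"1": (("m", 0.0, False),)})
    probs = GenotypeProbabilities(
        grid=grid, probs=np.full((1, 1, 3), 1 / 3), cross_type="f2", error_rate=0.0
    )
    add, dom = qtl_dosages(probs, "m")
    assert add[0] == pytest.approx(0.0) and dom[0] == pytest.approx(1 / 3)


def test_degrees_of_freedom_per_test(bench_cross, bench_probs, sex_spec):
    res = scanonevar(bench_cross, sex_spec, bench_probs)
    df = res.table.groupby("test")["df"].unique()
    assert df["mQTL"].tolist() == [2]
    assert df["vQTL"].tolist() == [2]
    assert df["mvQTL"].tolist() == [4]
    assert df["traditional"].tolist() == [2]


def test_lod_p_chi2_identity(bench_cross, bench_probs, sex_spec):
    """p = chi2 survival of 2 ln(10) LOD at the stated df, every row."""
    res = scanonevar(bench_cross, sex_spec, bench_probs)
    t = res.table
    recomputed = stats.chi2.sf(2 * np.log(10) * t["lod"], t["df"])
    assert np.allclose(recomputed, t["p"], atol=1e-12)
    assert (t["lod"] >= 0).all()
    assert ((t["p"] > 0) & (t["p"] <= 1)).all()
    # LOD = 1 at df 2 corresponds to p = 0.1 exactly
    assert stats.chi2.sf(2 * np.log(10) * 1.0, 2) == pytest.approx(0.1, abs=1e-12)


def test_alternative_fit_shared_across_tests(bench_cross, bench_probs, sex_spec):
    eng = ScanEngine(bench_cross, sex_spec, bench_probs)
    # one alternative likelihood serves mQTL, vQTL and mvQTL
    lods = eng.lods()
    ll_alt = eng.ll_alt
    for t in ("mQTL", "vQTL", "mvQTL"):
        back = lods[t] * np.log(10) + eng.ll_null[t]
        assert np.allclose(back, ll_alt, atol=1e-6)


def test_traditional_equals_mqtl_without_variance_predictors(bench_cross, bench_probs):
    spec = ModelSpec(
        phenotype="phenotype2",
        var_qtl_add=False,
        var_qtl_dom=False,
    )
    res = scanonevar(bench_cross, spec, bench_probs, tests=("mQTL", "traditional"))
    wide = res.table.pivot(index="locus", columns="test", values="lod")
    assert np.allclose(wide["mQTL"], wide["traditional"], atol=1e-6)


def test_monomorphic_locus_yields_zero_lod(bench_cross, sex_spec):
    from mvqtlmap.genoprob import calc_genoprob as cg

    probs = cg(bench_cross, step=2.0)
    probs.probs[:, 0, :] = [0.25, 0.5, 0.25]  # flatten one locus to a constant
    res = scanonevar(bench_cross, sex_spec, probs)
    first = res.table[res.table["locus"] == probs.grid.locus_names[0]]
    assert np.allclose(first["lod"], 0.0, atol=1e-9)
    assert np.allclose(first["p"], 1.0, atol=1e-9)


def test_dominance_recoding_leaves_lr_unchanged(bench_cross, bench_probs):
    """P(AB) vs P(AB) - 1/2 dominance coding: same likelihood ratio."""
    y = bench_cross.phenotypes["phenotype2"].to_numpy()
    add, dom = qtl_dosages(bench_probs, "D1M6")
    n = len(y)
    ones = np.ones((n, 1))
    for shift in (0.0, -0.5):
        X = np.column_stack([np.ones(n), add, dom + shift])
        fit = fit_dglm(DesignPair(X, X, y))
        null = fit_dglm(DesignPair(ones, X, y))
        lod = (fit.loglik - null.loglik) / np.log(10)
        if shift == 0.0:
            ref = lod
    assert lod == pytest.approx(ref, abs=1e-6)


def test_null_cache_equals_uncached(bench_cross, bench_probs, sex_spec):
    cached = scanonevar(bench_cross, sex_spec, bench_probs, cache_nulls=True)
    fresh = scanonevar(bench_cross, sex_spec, bench_probs, cache_nulls=False)
    pd.testing.assert_frame_equal(cached.table, fresh.table, atol=1e-7, rtol=0)


def test_phenotype2_peak_on_chromosome_one(bench_cross, bench_probs, sex_spec):
    res = scanonevar(bench_cross, sex_spec, bench_probs)
    sub = res.table[res.table["test"] == "mQTL"]
    peak = sub.loc[sub["lod"].idxmax()]
    assert str(peak["chromosome"]) == "1"


def test_all_missing_phenotype_raises(bench_cross, bench_probs):
    cross = bench_cross
    cross2 = type(cross)(
        cross_type=cross.cross_type,
        map=cross.map,
        genotypes=cross.genotypes,
        phenotypes=cross.phenotypes.assign(empty=np.nan),
        covariates=cross.covariates,
    )
    with pytest.raises(ValueError, match="no observed values"):
        scanonevar(cross2, ModelSpec(phenotype="empty"), bench_probs)


def test_missing_rows_dropped_consistently(bench_probs, bench_cross):
    pheno = bench_cross.phenotypes.copy()
    pheno.loc[:9, "phenotype1"] = np.nan
    cross2 = type(bench_cross)(
        cross_type=bench_cross.cross_type,
        map=bench_cross.map,
        genotypes=bench_cross.genotypes,
        phenotypes=pheno,
        covariates=bench_cross.covariates,
    )
    res = scanonevar(cross2, ModelSpec(phenotype="phenotype1"), bench_probs)
    assert res.meta["n_individuals"] == 390
    assert res.meta["n_dropped"] == 10


def test_nominal_p_uniform_under_null():
    """Nominal mQTL p at a single fixed marker over many null crosses is
    approximately uniform (scaled-down)."""
    pvals = []
    for seed in range(400):
        spec = SimSpec(
            n_males=60, n_females=60, chromosomes=((20.0, 3),), seed=seed,
            phenotypes=(PhenotypeSpec(name="noise"),),
        )
        cross = simulate_cross(spec)
        probs = calc_genoprob(cross, step=50.0)
        res = scanonevar(cross, ModelSpec(phenotype="noise"), probs, tests=("mQTL",))
        row = res.table[res.table["locus"] == "D1M2"].iloc[0]
        pvals.append(row["p"])
    ks = stats.kstest(pvals, "uniform")
    # critical value at alpha=0.001 for n=400 is ~1.95/sqrt(n)
    assert ks.statistic < 1.95 / np.sqrt(len(pvals))


def test_summary_roundtrip(tmp_path, bench_cross, bench_probs, sex_spec):
    res = scanonevar(bench_cross, sex_spec, bench_probs)
    text = summary_scan(res)
    assert "phenotype2" in text and "max LOD" in text
    # every reported max-LOD locus is on the grid
    for t in res.tests:
        locus, _ = res.max_lod(t)
        assert locus in set(res.table["locus"])
    path = tmp_path / "scan.csv"
    res.to_csv(path)
    back = ScanResult.from_csv(path)
    assert summary_scan(back) == text


def test_backcross_scan_uses_additive_dosage_only():
    """Backcross: two genotype classes, additive coding only, df=1 tests."""
    rng = np.random.default_rng(0)
    from mvqtlmap import CrossData, GeneticMap

    gmap = GeneticMap(
        ("1",), {"1": tuple((f"b{j}", 10.0 * j) for j in range(6))}
    )
    n = 150
    geno = (rng.random((n, 6)) < 0.5).astype(np.int8)  # AA/AB only
    y = 0.6 * geno[:, 3] + rng.normal(size=n)
    cross = CrossData(
        cross_type="backcross", map=gmap, genotypes=geno,
        phenotypes=pd.DataFrame({"y": y}),
    )
    probs = calc_genoprob(cross, step=5.0)
    assert probs.n_classes == 2
    res = scanonevar(cross, ModelSpec(phenotype="y"), probs)
    assert set(res.table["df"].unique()) == {1, 2}  # 1 per submodel, 2 for mvQTL
    sub = res.table[res.table["test"] == "mQTL"]
    assert str(sub.loc[sub["lod"].idxmax(), "locus"]) == "b3"
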