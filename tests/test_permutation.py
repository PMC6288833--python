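"""Permutation scans, GEV fitting, and FWER-adjusted p-values."""

import numpy as np
import pytest
from scipy import stats

from mvqtlmap import (
    GevParams,
    ModelSpec,
    calc_genoprob,
    combine_permutations,
    empirical_p,
    fit_gev,
    permuted_scan,
    run_permutations,
    scanonevar,
)
from mvqtlmap.permutation import MIN_PERMS_FOR_GEV, PermutationMaxima, _attach_empirical_p
from mvqtlmap.scan import ScanEngine


@pytest.fixture(scope="module")
def small_setup(request):
    """Single-chromosome cross and model for quick permutation runs."""
    from mvqtlmap.simulate import PhenotypeSpec, SimSpec, simulate_cross

    spec = SimSpec(
        n_males=75, n_females=75, chromosomes=((60.0, 7),), seed=21,
        phenotypes=(
            PhenotypeSpec(name="noise"),
            PhenotypeSpec(name="mq", qtl_chromosome="1", qtl_position_cM=30.0,
                          mean_effect=0.08),
        ),
    )
    cross = simulate_cross(spec)
    probs = calc_genoprob(cross, step=5.0)
    return cross, probs


def test_identity_permutation_reproduces_observed_maxima(small_setup):
    cross, probs = small_setup
    spec = ModelSpec(phenotype="mq")
    observed = scanonevar(cross, spec, probs)
    ident = permuted_scan(
        cross, spec, probs, perm_seed=0, perm=np.arange(cross.n_individuals)
    )
    for t in observed.tests:
        _, max_lod = observed.max_lod(t)
        assert ident[t] == pytest.approx(max_lod, abs=1e-6)


def test_permuted_scan_deterministic_in_seed(small_setup):
    cross, probs = small_setup
    spec = ModelSpec(phenotype="noise")
    a = permuted_scan(cross, spec, probs, perm_seed=33)
    b = permuted_scan(cross, spec, probs, perm_seed=33)
    assert a == b


def test_null_observed_max_within_permutation_range(small_setup):
    """On pure noise the observed maximum is just another permutation draw."""
    cross, probs = small_setup
    spec = ModelSpec(phenotype="noise")
    res = run_permutations(cross, spec, probs, n_perms=60, n_cores=1,
                           base_seed=5, tests=("mQTL",))
    _, obs_max = res.scan.max_lod("mQTL")
    v = res.maxima.maxima["mQTL"]
    assert v.min() < obs_max < v.max() + 1.0
    assert res.min_empirical_p("mQTL") > 0.05


def test_gev_parameter_recovery():
    """MLE recovers (loc, scale, shape) within 3 asymptotic SEs."""
    rng = np.random.default_rng(8)
    true = GevParams(loc=3.0, scale=0.5, shape=0.1)
    x = stats.genextreme.rvs(c=-true.shape, loc=true.loc, scale=true.scale,
                             size=10_000, random_state=rng)
    est = fit_gev(x)

    def nll(params):
        loc, scale, shape = params
        return -np.sum(stats.genextreme.logpdf(x, c=-shape, loc=loc, scale=scale))

    # asymptotic SEs from a finite-difference Hessian at the MLE
    p0 = np.array([est.loc, est.scale, est.shape])
    h = 1e-4 * np.maximum(np.abs(p0), 0.1)
    H = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            pp = p0.copy(); pp[i] += h[i]; pp[j] += h[j]; fpp = nll(pp)
            pm = p0.copy(); pm[i] += h[i]; pm[j] -= h[j]; fpm = nll(pm)
            mp = p0.copy(); mp[i] -= h[i]; mp[j] += h[j]; fmp = nll(mp)
            mm = p0.copy(); mm[i] -= h[i]; mm[j] -= h[j]; fmm = nll(mm)
            H[i, j] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    se = np.sqrt(np.diag(np.linalg.inv(H)))
    for got, want, s in zip(p0, (true.loc, true.scale, true.shape), se):
        assert abs(got - want) < 3 * s


def test_gumbel_shape_recovered_near_zero():
    rng = np.random.default_rng(9)
    x = stats.gumbel_r.rvs(loc=2.0, scale=0.7, size=10_000, random_state=rng)
    est = fit_gev(x)
    assert abs(est.shape) < 0.1


def test_gev_refuses_degenerate_input():
    with pytest.raises(ValueError, match="constant"):
        fit_gev(np.full(100, 2.0))
    with pytest.raises(ValueError, match="at least"):
        fit_gev(np.arange(MIN_PERMS_FOR_GEV - 1, dtype=float))


def test_empirical_p_properties():
    params = GevParams(loc=2.0, scale=0.5, shape=0.05)
    # far-left LOD -> p -> 1; at the fitted median -> 0.5
    assert empirical_p(-5.0, params) == pytest.approx(1.0, abs=1e-6)
    assert empirical_p(params.median(), params) == pytest.approx(0.5, abs=1e-9)
    lods = np.linspace(0, 8, 100)
    p = empirical_p(lods, params, n_perms=100)
    assert np.all(np.diff(p) <= 0)  # monotone non-increasing in LOD
    assert p.min() >= 1 / 101 and p.max() <= 1.0


def test_gev_p_close_to_quantile_p_at_05():
    """GEV-smoothed and raw-quantile p agree near the 0.05 level."""
    rng = np.random.default_rng(10)
    x = stats.genextreme.rvs(c=-0.05, loc=1.5, scale=0.4, size=1000,
                             random_state=rng)
    est = fit_gev(x)
    q95 = np.quantile(x, 0.95)
    assert empirical_p(q95, est) == pytest.approx(0.05, abs=0.02)


def test_run_permutations_independent_of_worker_count(small_setup):
    cross, probs = small_setup
    spec = ModelSpec(phenotype="mq")
    a = run_permutations(cross, spec, probs, n_perms=30, n_cores=1,
                         base_seed=17, tests=("mQTL",))
    b = run_permutations(cross, spec, probs, n_perms=30, n_cores=4,
                         base_seed=17, tests=("mQTL",))
    assert np.array_equal(a.maxima.maxima["mQTL"], b.maxima.maxima["mQTL"])
    assert np.allclose(a.table["emp_p"].dropna(), b.table["emp_p"].dropna())


def test_combine_batches(small_setup):
    cross, probs = small_setup
    spec = ModelSpec(phenotype="mq")
    a = run_permutations(cross, spec, probs, n_perms=30, n_cores=1,
                         base_seed=1, tests=("mQTL",))
    b = run_permutations(cross, spec, probs, n_perms=30, n_cores=1,
                         base_seed=2, tests=("mQTL",))
    solo = combine_permutations([a])
    assert np.array_equal(solo.maxima.maxima["mQTL"], a.maxima.maxima["mQTL"])
    both = combine_permutations([a, b])
    assert both.maxima.n_perms == 60
    assert sorted(both.maxima.maxima["mQTL"]) == sorted(
        np.concatenate([a.maxima.maxima["mQTL"], b.maxima.maxima["mQTL"]])
    )
    # pooled result == refit on the pooled maxima, by construction
    pooled = PermutationMaxima(
        maxima={"mQTL": np.concatenate([a.maxima.maxima["mQTL"],
                                        b.maxima.maxima["mQTL"]])},
        seeds=np.concatenate([a.maxima.seeds, b.maxima.seeds]),
        meta=dict(a.maxima.meta),
    )
    pooled.fit_gevs()
    fresh = _attach_empirical_p(
        scanonevar(cross, spec, probs, tests=("mQTL",)), pooled
    )
    assert np.allclose(
        both.table["emp_p"].dropna(), fresh.table["emp_p"].dropna(), atol=1e-9
    )


def test_combine_refuses_mismatched_metadata(small_setup):
    cross, probs = small_setup
    a = run_permutations(cross, ModelSpec(phenotype="mq"), probs, n_perms=30,
                         n_cores=1, base_seed=1, tests=("mQTL",))
    c = run_permutations(cross, ModelSpec(phenotype="noise"), probs, n_perms=30,
                         n_cores=1, base_seed=1, tests=("mQTL",))
    with pytest.raises(ValueError, match="metadata"):
        combine_permutations([a, c])


def test_maxima_roundtrip(tmp_path, small_setup):
    cross, probs = small_setup
    a = run_permutations(cross, ModelSpec(phenotype="mq"), probs, n_perms=30,
                         n_cores=1, base_seed=1, tests=("mQTL", "vQTL"))
    path = tmp_path / "perms.csv"
    a.maxima.to_csv(path)
    back = PermutationMaxima.from_csv(path)
    for t in ("mQTL", "vQTL"):
        assert np.allclose(back.maxima[t], a.maxima.maxima[t])
        assert back.gev[t].loc == pytest.approx(a.maxima.gev[t].loc)


def test_same_permutation_shared_across_tests(small_setup):
    """One individual-level permutation drives all four tests at an index."""
    cross, probs = small_setup
    spec = ModelSpec(phenotype="mq")
    eng = ScanEngine(cross, spec, probs)
    rng = np.random.default_rng(0)
    perm = rng.permutation(eng.n)
    m1 = eng.permuted_maxima(perm[None, :])
    m2 = eng.permuted_maxima(perm[None, :])
    assert {t: v[0] for t, v in m1.items()} == {t: v[0] for t, v in m2.items()}
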