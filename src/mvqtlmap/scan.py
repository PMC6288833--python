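"""Genome scan for mean, variance and mean-variance QTL.

At every locus of the evaluation grid the scan fits one alternative DGLM

    mean          = covariates + locus dosage terms
    log(variance) = covariates + locus dosage terms

and compares it against three nulls obtained by column deletion:

* **mQTL** — null omits the locus terms from the mean submodel only
  (the variance-side locus terms are retained, so the test is specifically
  about mean effects);
* **vQTL** — null omits the locus terms from the variance submodel only;
* **mvQTL** — null omits the locus terms from both submodels.

A fourth, **traditional** test is the classic homoscedastic interval-mapping
comparison: mean-submodel locus terms against none, with an intercept-only
variance submodel in *both* models.

Each comparison is reported as a LOD score, the base-10 log likelihood
ratio, and a nominal p-value from the chi-square distribution of
2 ln(10) LOD with degrees of freedom equal to the difference in parameter
count.  Nominal p-values ignore multiple testing across the genome; the
permutation module attaches genome-wide FWER-adjusted p-values.

Locus genotypes enter as expected dosages computed from the HMM genotype
probabilities (Haley-Knott style regression): additive = P(BB) - P(AA),
dominance = P(AB).  Any full-rank linear recoding of these columns leaves
the likelihood ratios unchanged.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cross_io import CrossData
from .dglm import fit_dglm_batch
from .genoprob import GenotypeProbabilities

__all__ = ["TESTS", "ModelSpec", "ScanResult", "qtl_dosages", "scanonevar", "summary_scan"]

TESTS = ("mQTL", "vQTL", "mvQTL", "traditional")
_LN10 = float(np.log(10.0))
_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ModelSpec:
    """What to scan: the phenotype, the covariates in each submodel, and
    which QTL dosage terms enter each submodel."""

    phenotype: str
    mean_covariates: tuple[str, ...] = ()
    var_covariates: tuple[str, ...] = ()
    mean_qtl_add: bool = True
    mean_qtl_dom: bool = True
    var_qtl_add: bool = True
    var_qtl_dom: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean_covariates", tuple(self.mean_covariates))
        object.__setattr__(self, "var_covariates", tuple(self.var_covariates))

    def to_dict(self) -> dict:
        return {
            "phenotype": self.phenotype,
            "mean_covariates": list(self.mean_covariates),
            "var_covariates": list(self.var_covariates),
            "mean_qtl_add": self.mean_qtl_add,
            "mean_qtl_dom": self.mean_qtl_dom,
            "var_qtl_add": self.var_qtl_add,
            "var_qtl_dom": self.var_qtl_dom,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            phenotype=d["phenotype"],
            mean_covariates=tuple(d["mean_covariates"]),
            var_covariates=tuple(d["var_covariates"]),
            mean_qtl_add=d["mean_qtl_add"],
            mean_qtl_dom=d["mean_qtl_dom"],
            var_qtl_add=d["var_qtl_add"],
            var_qtl_dom=d["var_qtl_dom"],
        )


@dataclass
class ScanResult:
    """Tidy per-locus, per-test scan output plus run metadata.

    ``table`` columns: locus, chromosome, position, test, lod, df, p and —
    once permutations have been attached — ``emp_p``.
    """

    table: pd.DataFrame
    spec: ModelSpec
    meta: dict = field(default_factory=dict)

    @property
    def tests(self) -> list[str]:
        return [t for t in TESTS if t in set(self.table["test"])]

    @property
    def has_empirical_p(self) -> bool:
        return "emp_p" in self.table.columns

    def max_lod(self, test: str) -> tuple[str, float]:
        sub = self.table[self.table["test"] == test]
        i = sub["lod"].idxmax()
        return str(sub.loc[i, "locus"]), float(sub.loc[i, "lod"])

    def to_csv(self, path) -> None:
        """Write the tidy table as CSV plus a JSON metadata sidecar."""
        self.table.to_csv(path, index=False)
        side = {"spec": self.spec.to_dict(), "meta": self.meta}
        with open(str(path) + ".json", "w", encoding="utf-8") as fh:
            json.dump(side, fh, indent=1, default=str)

    @classmethod
    def from_csv(cls, path) -> "ScanResult":
        table = pd.read_csv(path)
        with open(str(path) + ".json", encoding="utf-8") as fh:
            side = json.load(fh)
        return cls(table=table, spec=ModelSpec.from_dict(side["spec"]), meta=side["meta"])


def qtl_dosages(probs: GenotypeProbabilities, locus: str) -> tuple[np.ndarray, np.ndarray | None]:
    """Expected dosage coding of one locus: additive = P(BB) - P(AA) in
    [-1, 1] and dominance = P(AB) in [0, 1] (None for a backcross)."""
    j = probs.locus_index(locus)
    p = probs.probs[:, j, :]
    if probs.cross_type == "backcross":
        return p[:, 1] - p[:, 0], None
    return p[:, 2] - p[:, 0], p[:, 1]


def _ols_loglik_batch(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """ML normal log-likelihood of OLS fits, batched over (B, n, p)."""
    B, n, _ = X.shape
    y = np.broadcast_to(y, (B, n))
    Xt = X.transpose(0, 2, 1)
    try:
        beta = np.linalg.solve(Xt @ X, np.einsum("bpn,bn->bp", Xt, y)[..., None])[..., 0]
    except np.linalg.LinAlgError:
        beta = np.stack(
            [np.linalg.lstsq(X[i], y[i], rcond=None)[0] for i in range(B)]
        )
    resid = y - np.einsum("bnp,bp->bn", X, beta)
    rss = np.einsum("bn,bn->b", resid, resid)
    return -0.5 * n * (_LOG_2PI + np.log(rss / n) + 1.0)


class ScanEngine:
    """Precomputed designs and cached null likelihoods for one scan.

    Holds everything needed to evaluate observed and permuted scans
    cheaply: the base covariate designs, per-locus dosage blocks, and the
    null log-likelihoods (which never involve permuted columns and are
    therefore shared across permutations).
    """

    def __init__(
        self,
        cross: CrossData,
        spec: ModelSpec,
        probs: GenotypeProbabilities,
        tests: tuple[str, ...] = TESTS,
        chromosomes=None,
        cache_nulls: bool = True,
        tol: float = 1e-8,
        max_iter: int = 50,
    ):
        self.spec = spec
        self.tests = tuple(tests)
        self.tol = tol
        self.max_iter = max_iter
        if spec.phenotype not in cross.phenotypes.columns:
            raise KeyError(f"phenotype {spec.phenotype!r} not in the cross")
        if probs.cross_type != cross.cross_type:
            raise ValueError("genotype probabilities computed for a different cross type")

        chroms = tuple(chromosomes) if chromosomes is not None else probs.grid.chromosomes
        entries = [
            (name, c, pos)
            for c in chroms
            for name, pos, _ in probs.grid.loci[c]
        ]
        self.loci = [e[0] for e in entries]
        self.locus_chrom = [e[1] for e in entries]
        self.locus_pos = [e[2] for e in entries]
        idx = [probs.locus_index(name) for name in self.loci]

        y_all = cross.phenotypes[spec.phenotype].to_numpy(float)
        if np.all(np.isnan(y_all)):
            raise ValueError(f"phenotype {spec.phenotype!r} has no observed values")

        def covar(name: str) -> np.ndarray:
            if name in cross.covariates.columns:
                return cross.covariates[name].to_numpy(float)
            if name in cross.phenotypes.columns:
                return cross.phenotypes[name].to_numpy(float)
            raise KeyError(f"covariate {name!r} not in the cross")

        used = sorted(set(spec.mean_covariates) | set(spec.var_covariates))
        cov_cols = {name: covar(name) for name in used}
        keep = ~np.isnan(y_all)
        for v in cov_cols.values():
            keep &= ~np.isnan(v)
        self.rows = np.nonzero(keep)[0]
        self.n_dropped = int(len(y_all) - keep.sum())
        self.y = y_all[keep]
        self.n = len(self.y)

        ones = np.ones((self.n, 1))
        self.base_mean = np.hstack(
            [ones] + [cov_cols[c][keep][:, None] for c in spec.mean_covariates]
        )
        self.base_var = np.hstack(
            [ones] + [cov_cols[c][keep][:, None] for c in spec.var_covariates]
        )

        # per-locus dosage blocks (L, n, k)
        p = probs.probs[keep][:, idx, :]  # (n, L, classes)
        if cross.cross_type == "backcross":
            add = (p[:, :, 1] - p[:, :, 0]).T
            dom = None
        else:
            add = (p[:, :, 2] - p[:, :, 0]).T
            dom = p[:, :, 1].T
        mean_cols, var_cols = [], []
        if spec.mean_qtl_add:
            mean_cols.append(add)
        if spec.mean_qtl_dom and dom is not None:
            mean_cols.append(dom)
        if spec.var_qtl_add:
            var_cols.append(add)
        if spec.var_qtl_dom and dom is not None:
            var_cols.append(dom)
        L = add.shape[0]
        n = add.shape[1]
        if ("mQTL" in self.tests or "traditional" in self.tests) and not mean_cols:
            raise ValueError("the mQTL/traditional tests need a mean-submodel QTL term")
        if "vQTL" in self.tests and not var_cols:
            raise ValueError("the vQTL test needs a variance-submodel QTL term")
        if "mvQTL" in self.tests and not (mean_cols and var_cols):
            raise ValueError("the mvQTL test needs QTL terms in both submodels")
        self.Dm = np.stack(mean_cols, axis=2) if mean_cols else np.empty((L, n, 0))
        self.Dv = np.stack(var_cols, axis=2) if var_cols else np.empty((L, n, 0))
        self.L = L
        self.km = self.Dm.shape[2]
        self.kv = self.Dv.shape[2]

        # loci whose dosage block is constant carry no information
        def _flat(D):
            return (
                np.ptp(D, axis=1).max(axis=1) < 1e-10
                if D.shape[2]
                else np.ones(L, dtype=bool)
            )

        self.degenerate = _flat(self.Dm) & _flat(self.Dv)

        # null log-likelihoods (shared by observed and permuted scans)
        self._fit_nulls(cache_nulls)
        # observed alternative (shared by the mQTL, vQTL and mvQTL tests)
        self.ll_alt = None
        self.alt_converged = np.ones(self.L, dtype=bool)
        if any(t in self.tests for t in ("mQTL", "vQTL", "mvQTL")):
            alt = self._fit(self._mean_design(self.Dm), self._var_design(self.Dv))
            self.ll_alt = alt["loglik"]
            self.alt_converged = alt["converged"]
        if "traditional" in self.tests:
            self.ll_trad_alt = _ols_loglik_batch(self._mean_design(self.Dm), self.y)

    # -- design assembly ----------------------------------------------------
    def _mean_design(self, D: np.ndarray) -> np.ndarray:
        B = D.shape[0]
        base = np.broadcast_to(self.base_mean, (B,) + self.base_mean.shape)
        return np.concatenate([base, D], axis=2)

    def _var_design(self, D: np.ndarray) -> np.ndarray:
        B = D.shape[0]
        base = np.broadcast_to(self.base_var, (B,) + self.base_var.shape)
        return np.concatenate([base, D], axis=2)

    def _fit(self, Xm, Xv) -> dict:
        return fit_dglm_batch(Xm, Xv, self.y, tol=self.tol, max_iter=self.max_iter)

    def _fit_nulls(self, cache: bool) -> None:
        self.ll_null = {}
        if "mQTL" in self.tests:
            res = self._fit(
                np.broadcast_to(
                    self.base_mean, (self.L,) + self.base_mean.shape
                ).copy(),
                self._var_design(self.Dv),
            )
            self.ll_null["mQTL"] = res["loglik"]
        if "vQTL" in self.tests:
            res = self._fit(
                self._mean_design(self.Dm),
                np.broadcast_to(self.base_var, (self.L,) + self.base_var.shape).copy(),
            )
            self.ll_null["vQTL"] = res["loglik"]
        if "mvQTL" in self.tests:
            if cache:
                res = self._fit(self.base_mean[None], self.base_var[None])
                self.ll_null["mvQTL"] = np.full(self.L, res["loglik"][0])
            else:
                res = self._fit(
                    np.broadcast_to(self.base_mean, (self.L,) + self.base_mean.shape).copy(),
                    np.broadcast_to(self.base_var, (self.L,) + self.base_var.shape).copy(),
                )
                self.ll_null["mvQTL"] = res["loglik"]
        if "traditional" in self.tests:
            ll0 = _ols_loglik_batch(self.base_mean[None], self.y)[0]
            self.ll_null["traditional"] = np.full(self.L, ll0)

    @property
    def df(self) -> dict:
        return {
            "mQTL": self.km,
            "vQTL": self.kv,
            "mvQTL": self.km + self.kv,
            "traditional": self.km,
        }

    # -- observed scan ------------------------------------------------------
    def lods(self) -> dict:
        """Per-test (L,) LOD vectors for the observed data."""
        out = {}
        for t in self.tests:
            if t == "traditional":
                lod = (self.ll_trad_alt - self.ll_null[t]) / _LN10
            else:
                lod = (self.ll_alt - self.ll_null[t]) / _LN10
                bad = ~self.alt_converged
                if bad.any():
                    warnings.warn(
                        f"{bad.sum()} locus fits did not converge; LODs recorded "
                        "as missing"
                    )
                    lod = lod.copy()
                    lod[bad] = np.nan
            lod = np.where(self.degenerate, 0.0, lod)
            out[t] = np.maximum(lod, 0.0)  # floor numerical noise
        return out

    # -- bootstrap resamples ------------------------------------------------
    def bootstrap_peaks(self, rows: np.ndarray, test: str, chunk: int = 8) -> np.ndarray:
        """Peak position (cM) of ``test`` for each row-resample in ``rows``
        (R, n), batching the per-locus fits across resamples.

        Ties in the maximum LOD break toward the smallest position (the
        locus list is sorted by position).
        """
        R = rows.shape[0]
        pos = np.asarray(self.locus_pos, float)
        peaks = np.empty(R)
        for start in range(0, R, chunk):
            rr = rows[start : start + chunk]
            c = rr.shape[0]
            y_c = self.y[rr]  # (c, n)
            y_rep = np.repeat(y_c, self.L, axis=0)
            bm = np.repeat(self.base_mean[rr], self.L, axis=0)  # (c*L, n, pm)
            bv = np.repeat(self.base_var[rr], self.L, axis=0)

            def resampled(D):
                if D.shape[2] == 0:
                    return np.empty((c * self.L, self.n, 0))
                DT = D.transpose(1, 0, 2)  # (n, L, k)
                return (
                    DT[rr].transpose(0, 2, 1, 3).reshape(c * self.L, self.n, D.shape[2])
                )

            Dm_c, Dv_c = resampled(self.Dm), resampled(self.Dv)
            if test == "traditional":
                ll_alt = _ols_loglik_batch(np.concatenate([bm, Dm_c], axis=2), y_rep)
                ll_null = np.repeat(
                    _ols_loglik_batch(self.base_mean[rr], y_c), self.L
                )
            else:
                Xm_alt = np.concatenate([bm, Dm_c], axis=2)
                Xv_alt = np.concatenate([bv, Dv_c], axis=2)
                ll_alt = fit_dglm_batch(Xm_alt, Xv_alt, y_rep,
                                        tol=self.tol, max_iter=self.max_iter)["loglik"]
                if test == "mQTL":
                    ll_null = fit_dglm_batch(bm, Xv_alt, y_rep,
                                             tol=self.tol, max_iter=self.max_iter)["loglik"]
                elif test == "vQTL":
                    ll_null = fit_dglm_batch(Xm_alt, bv, y_rep,
                                             tol=self.tol, max_iter=self.max_iter)["loglik"]
                else:  # mvQTL: null is locus-independent within a resample
                    ll0 = fit_dglm_batch(self.base_mean[rr], self.base_var[rr], y_c,
                                         tol=self.tol, max_iter=self.max_iter)["loglik"]
                    ll_null = np.repeat(ll0, self.L)
            lod = np.maximum((ll_alt - ll_null) / _LN10, 0.0).reshape(c, self.L)
            best = np.nanmax(lod, axis=1, keepdims=True)
            first = np.argmax(lod >= best - 1e-12, axis=1)
            peaks[start : start + c] = pos[first]
        return peaks

    # -- permuted scans -----------------------------------------------------
    def permuted_maxima(self, perms: np.ndarray, chunk: int = 16) -> dict:
        """Genome-wide maximum LOD per permutation for each test.

        ``perms`` is a (P, n) array of row permutations applied to the
        dosage columns of the *alternative* models only: the mean-side
        block for the mQTL (and traditional) test, the variance-side block
        for the vQTL test, and both blocks for the mvQTL test.  Phenotype,
        covariates and all null models stay unpermuted.
        """
        P = perms.shape[0]
        maxima = {t: np.empty(P) for t in self.tests}
        for start in range(0, P, chunk):
            pp = perms[start : start + chunk]
            c = pp.shape[0]
            # (c*L, n, k) permuted dosage blocks
            Dm_p = np.empty((c, self.L, self.n, self.km))
            Dv_p = np.empty((c, self.L, self.n, self.kv))
            for i in range(c):
                Dm_p[i] = self.Dm[:, pp[i], :]
                Dv_p[i] = self.Dv[:, pp[i], :]
            Dm_p = Dm_p.reshape(c * self.L, self.n, self.km)
            Dv_p = Dv_p.reshape(c * self.L, self.n, self.kv)
            Dm_o = np.broadcast_to(self.Dm, (c,) + self.Dm.shape).reshape(
                c * self.L, self.n, self.km
            )
            Dv_o = np.broadcast_to(self.Dv, (c,) + self.Dv.shape).reshape(
                c * self.L, self.n, self.kv
            )
            for t in self.tests:
                if t == "mQTL":
                    ll = self._fit(self._mean_design(Dm_p), self._var_design(Dv_o))["loglik"]
                    null = self.ll_null[t]
                elif t == "vQTL":
                    ll = self._fit(self._mean_design(Dm_o), self._var_design(Dv_p))["loglik"]
                    null = self.ll_null[t]
                elif t == "mvQTL":
                    ll = self._fit(self._mean_design(Dm_p), self._var_design(Dv_p))["loglik"]
                    null = self.ll_null[t]
                else:
                    ll = _ols_loglik_batch(self._mean_design(Dm_p), self.y)
                    null = self.ll_null[t]
                lod = (ll.reshape(c, self.L) - null[None, :]) / _LN10
                lod = np.where(self.degenerate[None, :], 0.0, lod)
                maxima[t][start : start + c] = np.maximum(lod, 0.0).max(axis=1)
        return maxima


def scanonevar(
    cross: CrossData,
    spec: ModelSpec,
    probs: GenotypeProbabilities,
    tests: tuple[str, ...] = TESTS,
    chromosomes=None,
    cache_nulls: bool = True,
) -> ScanResult:
    """Run the genome scan and return per-locus LODs and nominal p-values."""
    eng = ScanEngine(
        cross, spec, probs, tests=tests, chromosomes=chromosomes, cache_nulls=cache_nulls
    )
    return result_from_engine(eng, cross, probs, chromosomes)


def result_from_engine(
    eng: "ScanEngine", cross: CrossData, probs: GenotypeProbabilities, chromosomes=None
) -> ScanResult:
    """Assemble the tidy ScanResult from an already-fitted engine."""
    spec = eng.spec
    lods = eng.lods()
    dfs = eng.df
    records = []
    for t in eng.tests:
        lod = lods[t]
        df = dfs[t]
        with np.errstate(invalid="ignore"):
            pvals = stats.chi2.sf(2.0 * _LN10 * lod, df)
        for j in range(eng.L):
            records.append(
                (eng.loci[j], eng.locus_chrom[j], eng.locus_pos[j], t,
                 lod[j], df, pvals[j])
            )
    table = pd.DataFrame(
        records, columns=["locus", "chromosome", "position", "test", "lod", "df", "p"]
    )
    meta = {
        "cross_hash": cross.content_hash(),
        "cross_type": cross.cross_type,
        "n_individuals": int(eng.n),
        "n_dropped": eng.n_dropped,
        "step": probs.step,
        "tests": list(eng.tests),
        "chromosomes": list(chromosomes) if chromosomes is not None else list(probs.grid.chromosomes),
    }
    return ScanResult(table=table, spec=spec, meta=meta)


def summary_scan(result: ScanResult) -> str:
    """Human-readable account of how the scan was run and what it found."""
    lines = [
        "Mean-variance QTL genome scan",
        f"  phenotype:        {result.spec.phenotype}",
        f"  mean covariates:  {', '.join(result.spec.mean_covariates) or '(none)'}",
        f"  var covariates:   {', '.join(result.spec.var_covariates) or '(none)'}",
        f"  individuals:      {result.meta.get('n_individuals', '?')}"
        f" ({result.meta.get('n_dropped', 0)} dropped for missing data)",
        f"  grid loci:        {result.table['locus'].nunique()}",
        "",
    ]
    for t in result.tests:
        locus, lod = result.max_lod(t)
        sub = result.table[result.table["test"] == t]
        row = sub.loc[sub["lod"].idxmax()]
        line = (
            f"  {t:<12} max LOD {lod:7.3f} at {locus} "
            f"(chr {row['chromosome']}, {row['position']:.1f} cM)"
        )
        if result.has_empirical_p:
            line += f", min FWER p = {sub['emp_p'].min():.4g}"
        lines.append(line)
    return "\n".join(lines)
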