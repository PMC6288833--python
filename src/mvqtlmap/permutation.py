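"""Genome-wide significance by permutation with a GEV tail model.

Nominal per-locus p-values ignore the multiple testing inherent in a
genome scan.  The family-wise error rate (FWER) is controlled empirically:
many permutation scans are run on pseudo-null data, the genome-wide
maximum LOD is extracted from each, a generalized extreme value (GEV)
distribution is fitted to those maxima by maximum likelihood, and every
observed LOD is transformed through the fitted survival function.  An
adjusted p of 0.05 at a locus then means: in 5% of comparable experiments
with no true genotype-phenotype association anywhere, some locus would
show this much or more evidence.

The permutation deliberately preserves as much of the data's structure as
possible: one permutation of individuals per scan is applied to the QTL
dosage columns of the *alternative* models only — the mean-side block for
the mQTL test, the variance-side block for the vQTL test, both blocks for
the mvQTL test — while phenotype, covariates and all null models stay
fixed.  The same permutation is reused across the four tests within one
permutation index so their maxima are comparable and computation is
shared.

Per-permutation seeds are derived deterministically from a base seed, so
results are identical regardless of how many worker processes are used,
and permutation batches run on different machines can be pooled
(`combine_permutations`), which refits the GEV on the pooled maxima and
re-evaluates the observed scan.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cross_io import CrossData
from .genoprob import GenotypeProbabilities
from .scan import TESTS, ModelSpec, ScanEngine, ScanResult, result_from_engine

__all__ = [
    "GevParams",
    "PermutationMaxima",
    "EmpiricalScanResult",
    "permuted_scan",
    "fit_gev",
    "empirical_p",
    "run_permutations",
    "combine_permutations",
]

MIN_PERMS_FOR_GEV = 25


@dataclass(frozen=True)
class GevParams:
    """GEV parameters in the standard parameterization: CDF
    F(x) = exp(-[1 + shape (x - loc)/scale]^(-1/shape)), Gumbel at
    shape = 0."""

    loc: float
    scale: float
    shape: float

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("GEV scale must be positive")

    def cdf(self, x) -> np.ndarray:
        # scipy's genextreme uses c = -shape
        return stats.genextreme.cdf(x, c=-self.shape, loc=self.loc, scale=self.scale)

    def sf(self, x) -> np.ndarray:
        return stats.genextreme.sf(x, c=-self.shape, loc=self.loc, scale=self.scale)

    def median(self) -> float:
        return float(
            stats.genextreme.median(c=-self.shape, loc=self.loc, scale=self.scale)
        )


@dataclass
class PermutationMaxima:
    """Per-test genome-wide maximum LODs across permutation scans."""

    maxima: dict[str, np.ndarray]
    seeds: np.ndarray
    gev: dict[str, GevParams | None] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def n_perms(self) -> int:
        return len(self.seeds)

    def __post_init__(self) -> None:
        for t, v in self.maxima.items():
            if len(v) != self.n_perms:
                raise ValueError(f"maxima vector for {t} has wrong length")

    def fit_gevs(self) -> None:
        for t, v in self.maxima.items():
            if self.n_perms >= MIN_PERMS_FOR_GEV:
                try:
                    self.gev[t] = fit_gev(v)
                    continue
                except ValueError as exc:
                    warnings.warn(f"GEV fit failed for {t} ({exc}); "
                                  "falling back to empirical quantiles")
            else:
                warnings.warn(
                    f"only {self.n_perms} permutations (< {MIN_PERMS_FOR_GEV}); "
                    f"using empirical quantile p-values for {t}"
                )
            self.gev[t] = None

    def empirical_p(self, test: str, lod) -> np.ndarray:
        """FWER-adjusted p for observed LOD(s) under this test's maxima."""
        lod = np.asarray(lod, float)
        params = self.gev.get(test)
        if params is not None:
            p = params.sf(lod)
        else:  # quantile fallback
            v = self.maxima[test]
            p = (1.0 + (v[None, :] >= lod.reshape(-1, 1)).sum(axis=1)) / (
                self.n_perms + 1.0
            )
            p = p.reshape(lod.shape)
        return np.clip(p, 1.0 / (self.n_perms + 1.0), 1.0)

    def to_csv(self, path) -> None:
        rows = []
        for t in self.maxima:
            for i, (s, m) in enumerate(zip(self.seeds, self.maxima[t])):
                rows.append((t, i, int(s), m))
        pd.DataFrame(rows, columns=["test", "perm_index", "seed", "max_lod"]).to_csv(
            path, index=False
        )
        side = {
            "meta": self.meta,
            "gev": {
                t: (None if g is None else
                    {"loc": g.loc, "scale": g.scale, "shape": g.shape})
                for t, g in self.gev.items()
            },
        }
        with open(str(path) + ".json", "w", encoding="utf-8") as fh:
            json.dump(side, fh, indent=1, default=str)

    @classmethod
    def from_csv(cls, path) -> "PermutationMaxima":
        df = pd.read_csv(path)
        with open(str(path) + ".json", encoding="utf-8") as fh:
            side = json.load(fh)
        tests = list(dict.fromkeys(df["test"]))
        maxima = {
            t: df[df["test"] == t].sort_values("perm_index")["max_lod"].to_numpy()
            for t in tests
        }
        seeds = df[df["test"] == tests[0]].sort_values("perm_index")["seed"].to_numpy()
        gev = {
            t: (None if g is None else GevParams(**g))
            for t, g in side.get("gev", {}).items()
        }
        return cls(maxima=maxima, seeds=seeds, gev=gev, meta=side.get("meta", {}))


@dataclass
class EmpiricalScanResult:
    """A scan with FWER-adjusted p-values and the maxima that produced them."""

    scan: ScanResult
    maxima: PermutationMaxima

    @property
    def table(self) -> pd.DataFrame:
        return self.scan.table

    def min_empirical_p(self, test: str) -> float:
        sub = self.table[self.table["test"] == test]
        return float(sub["emp_p"].min())


def _derive_seeds(base_seed: int, n_perms: int) -> np.ndarray:
    return np.random.default_rng(base_seed).integers(0, 2**31 - 1, size=n_perms)


def _perm_from_seed(seed: int, n: int, retry: int = 0) -> np.ndarray:
    rng = np.random.default_rng((int(seed), retry) if retry else int(seed))
    return rng.permutation(n)


def permuted_scan(
    cross: CrossData,
    spec: ModelSpec,
    probs: GenotypeProbabilities,
    perm_seed: int,
    tests: tuple[str, ...] = TESTS,
    perm: np.ndarray | None = None,
) -> dict[str, float]:
    """Run one permutation scan and return the genome-wide max LOD per test.

    ``perm`` overrides the seed-derived permutation (e.g. the identity, for
    which the maxima equal the observed scan's maxima).
    """
    eng = ScanEngine(cross, spec, probs, tests=tests)
    if perm is None:
        perm = _perm_from_seed(perm_seed, eng.n)
    maxima = eng.permuted_maxima(np.asarray(perm, int)[None, :])
    return {t: float(v[0]) for t, v in maxima.items()}


def fit_gev(maxima: np.ndarray) -> GevParams:
    """Maximum-likelihood GEV fit to a vector of per-scan maxima.

    Requires at least ``MIN_PERMS_FOR_GEV`` values (with fewer, callers
    fall back to empirical quantiles); refuses a (near-)constant vector,
    whose ML scale would be zero.
    """
    x = np.asarray(maxima, float)
    if len(x) < MIN_PERMS_FOR_GEV:
        raise ValueError(
            f"need at least {MIN_PERMS_FOR_GEV} maxima for a stable GEV fit"
        )
    if np.ptp(x) < 1e-10:
        raise ValueError("maxima are constant; GEV scale would be zero")
    # Gumbel-motivated start via the method of moments
    scale0 = np.sqrt(6.0) * np.std(x) / np.pi
    loc0 = np.mean(x) - 0.5772156649 * scale0
    c, loc, scale = stats.genextreme.fit(x, 0.0, loc=loc0, scale=scale0)
    if not (np.isfinite(c) and np.isfinite(loc) and scale > 0):
        raise ValueError("GEV maximum-likelihood fit did not converge")
    shape = -float(c)
    if abs(shape) > 1:
        warnings.warn(
            f"fitted GEV shape {shape:.2f} has |shape| > 1 (heavy-tail "
            "instability); consider the quantile-based p-values as well"
        )
    return GevParams(loc=float(loc), scale=float(scale), shape=shape)


def empirical_p(observed_lod, gev_params: GevParams, n_perms: int | None = None):
    """FWER-adjusted p = 1 - F_GEV(LOD), clamped to [1/(n_perms+1), 1]."""
    p = gev_params.sf(observed_lod)
    floor = 1.0 / (n_perms + 1.0) if n_perms else 0.0
    return np.clip(p, floor, 1.0)


def _maxima_for_indices(eng: ScanEngine, seeds: np.ndarray, idx: np.ndarray, chunk: int):
    perms = np.empty((len(idx), eng.n), dtype=int)
    for k, i in enumerate(idx):
        perms[k] = _perm_from_seed(int(seeds[i]), eng.n)
    try:
        return eng.permuted_maxima(perms, chunk=chunk)
    except Exception:
        # retry failed permutations one at a time with a fresh derived seed
        out = {t: np.empty(len(idx)) for t in eng.tests}
        for k, i in enumerate(idx):
            try:
                m = eng.permuted_maxima(perms[k][None, :])
            except Exception:
                retry = _perm_from_seed(int(seeds[i]), eng.n, retry=1)
                try:
                    m = eng.permuted_maxima(retry[None, :])
                except Exception as exc:
                    raise RuntimeError(f"permutation {i} failed twice: {exc}") from exc
            for t in eng.tests:
                out[t][k] = m[t][0]
        return out


def run_permutations(
    cross: CrossData,
    spec: ModelSpec,
    probs: GenotypeProbabilities,
    n_perms: int,
    n_cores: int | None = None,
    base_seed: int = 0,
    tests: tuple[str, ...] = TESTS,
    chunk: int = 16,
) -> EmpiricalScanResult:
    """Observed scan plus ``n_perms`` permutation scans and FWER p-values.

    Per-permutation seeds are pre-derived from ``base_seed`` so the result
    is independent of ``n_cores`` (default: all available cores minus 2)
    and scheduling.
    """
    if n_perms < 1:
        raise ValueError("n_perms must be at least 1")
    eng = ScanEngine(cross, spec, probs, tests=tests)
    observed = result_from_engine(eng, cross, probs)
    seeds = _derive_seeds(base_seed, n_perms)

    if n_cores is None:
        import os

        n_cores = max(1, (os.cpu_count() or 1) - 2)
    n_jobs = min(n_cores, n_perms)
    if n_jobs > 1:
        from joblib import Parallel, delayed

        splits = np.array_split(np.arange(n_perms), n_jobs)
        parts = Parallel(n_jobs=n_jobs)(
            delayed(_maxima_for_indices)(eng, seeds, idx, chunk) for idx in splits
        )
        maxima = {
            t: np.concatenate([p[t] for p in parts]) for t in eng.tests
        }
    else:
        maxima = _maxima_for_indices(eng, seeds, np.arange(n_perms), chunk)

    pm = PermutationMaxima(
        maxima=maxima,
        seeds=seeds,
        meta={
            "cross_hash": observed.meta["cross_hash"],
            "spec": spec.to_dict(),
            "loci": list(observed.table["locus"].unique()),
            "base_seed": int(base_seed),
        },
    )
    pm.fit_gevs()
    return _attach_empirical_p(observed, pm)


def _attach_empirical_p(observed: ScanResult, pm: PermutationMaxima) -> EmpiricalScanResult:
    table = observed.table.copy()
    table["emp_p"] = np.nan
    for t in pm.maxima:
        mask = table["test"] == t
        table.loc[mask, "emp_p"] = pm.empirical_p(t, table.loc[mask, "lod"].to_numpy())
        # adjusted p must be monotone non-increasing in LOD within a test
        sub = table.loc[mask].dropna(subset=["lod"]).sort_values("lod")
        assert np.all(np.diff(sub["emp_p"].to_numpy()) <= 1e-12), (
            f"empirical p not monotone in LOD for {t}"
        )
    scan = ScanResult(table=table, spec=observed.spec, meta=dict(observed.meta))
    return EmpiricalScanResult(scan=scan, maxima=pm)


def combine_permutations(batches: list[EmpiricalScanResult]) -> EmpiricalScanResult:
    """Pool permutation batches: concatenate maxima, refit the GEV, and
    re-evaluate the observed LODs.  Combining a single batch is the
    identity (up to the refitted GEV)."""
    if not batches:
        raise ValueError("no batches to combine")
    ref = batches[0]
    ref_meta = {k: ref.maxima.meta.get(k) for k in ("cross_hash", "spec", "loci")}
    for b in batches[1:]:
        b_meta = {k: b.maxima.meta.get(k) for k in ("cross_hash", "spec", "loci")}
        if b_meta != ref_meta:
            diff = {
                k: (ref_meta[k], b_meta[k])
                for k in ref_meta
                if ref_meta[k] != b_meta[k]
            }
            raise ValueError(f"permutation batches disagree on metadata: {diff}")
    tests = list(ref.maxima.maxima)
    pooled = PermutationMaxima(
        maxima={
            t: np.concatenate([b.maxima.maxima[t] for b in batches]) for t in tests
        },
        seeds=np.concatenate([b.maxima.seeds for b in batches]),
        meta=dict(ref.maxima.meta),
    )
    pooled.fit_gevs()
    observed = ScanResult(
        table=ref.scan.table.drop(columns=["emp_p"]),
        spec=ref.scan.spec,
        meta=dict(ref.scan.meta),
    )
    return _attach_empirical_p(observed, pooled)
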