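"""Synthetic F2 intercrosses and benchmark phenotypes.

The generator emulates a classic small mapping experiment: an F2
population from two inbred founders, a few chromosomes of equally spaced
markers, and phenotypes carrying a single QTL that acts on the mean, the
residual variance, or both.  Each parental gamete is simulated as a
two-state Markov chain along the marker grid with Haldane recombination
fractions between adjacent markers; the offspring genotype at a marker is
the union of its two gamete alleles, giving the familiar 1:2:1 AA/AB/BB
segregation.

The shipped benchmark phenotypes (see :func:`default_sim_spec`):

* ``phenotype1`` — pure noise, the negative control;
* ``phenotype2`` — an mQTL at the center of chromosome 1 explaining 4% of
  phenotype variance;
* ``phenotype3`` — a vQTL at the center of chromosome 2, additive on the
  log-SD scale, residual SDs (0.8, 1, 1.25) for (AA, AB, BB);
* ``phenotype4`` — an mvQTL at the center of chromosome 3: a mean effect
  explaining 2.7% of variance plus residual SDs (0.85, 1, 1.17).

``phenotype1x`` .. ``phenotype4x`` add sex-specific residual variance
(females noisier than males by a configurable SD ratio, default 1.5).

The additive coefficient is derived from the target variance-explained
fraction f: for an F2 the +/-1/0 additive dosage has variance 1/2, so
``a = sqrt(2 f sigma2_bar / (1 - f))`` where ``sigma2_bar`` is the
genotype-frequency-weighted mean residual variance.  Dominance mean
effects are zero in the shipped specs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cross_io import CrossData, GeneticMap
from .genoprob import haldane_recomb_fraction

__all__ = [
    "SimSpec",
    "PhenotypeSpec",
    "simulate_cross",
    "simulate_phenotype",
    "simulate_gametes",
    "default_sim_spec",
    "simulate_study",
]


@dataclass(frozen=True)
class PhenotypeSpec:
    """One simulated phenotype.

    ``mean_effect`` is the fraction of phenotype variance explained by the
    additive mean effect at the QTL (0 for no mQTL); ``sd_by_genotype``
    gives residual SDs for (AA, AB, BB); ``sex_variance_ratio`` is the
    multiplicative female/male residual-SD ratio (1 = homoscedastic
    across sex).
    """

    name: str
    qtl_chromosome: str | None = None
    qtl_position_cM: float = 50.0
    mean_effect: float = 0.0
    sd_by_genotype: tuple[float, float, float] = (1.0, 1.0, 1.0)
    sex_variance_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_effect < 1.0:
            raise ValueError("mean_effect must lie in [0, 1)")
        if any(s <= 0 for s in self.sd_by_genotype):
            raise ValueError("residual SDs must be positive")
        if self.sex_variance_ratio <= 0:
            raise ValueError("sex_variance_ratio must be positive")


@dataclass(frozen=True)
class SimSpec:
    """Cross-level simulation parameters."""

    n_males: int = 200
    n_females: int = 200
    chromosomes: tuple[tuple[float, int], ...] = ((100.0, 11),) * 3
    seed: int = 0
    phenotypes: tuple[PhenotypeSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.n_males <= 0 or self.n_females <= 0:
            raise ValueError("individual counts must be positive")
        for length, n_markers in self.chromosomes:
            if n_markers < 2:
                raise ValueError("each chromosome needs at least 2 markers")
            if length <= 0:
                raise ValueError("chromosome length must be positive")

    @property
    def n_individuals(self) -> int:
        return self.n_males + self.n_females


def _build_map(spec: SimSpec) -> GeneticMap:
    chroms = tuple(str(i + 1) for i in range(len(spec.chromosomes)))
    markers = {}
    for c, (length, n_markers) in zip(chroms, spec.chromosomes):
        pos = np.linspace(0.0, length, n_markers)
        markers[c] = tuple((f"D{c}M{j + 1}", float(p)) for j, p in enumerate(pos))
    return GeneticMap(chroms, markers)


def simulate_gametes(rng: np.random.Generator, positions: np.ndarray, n: int) -> np.ndarray:
    """Simulate ``n`` gametes (0/1 founder-allele vectors) along a marker
    grid at the given cM positions, recombining between adjacent markers
    with Haldane probabilities."""
    m = len(positions)
    alleles = np.empty((n, m), dtype=np.int8)
    alleles[:, 0] = rng.random(n) < 0.5
    for j in range(1, m):
        r = haldane_recomb_fraction(positions[j] - positions[j - 1])
        flip = rng.random(n) < r
        alleles[:, j] = np.where(flip, 1 - alleles[:, j - 1], alleles[:, j - 1])
    return alleles


def simulate_cross(spec: SimSpec) -> CrossData:
    """Simulate the F2 genotypes, sex covariate and all phenotypes in
    ``spec``; deterministic given ``spec.seed``.

    RNG consumption order: chromosome by chromosome, maternal gametes then
    paternal gametes; then one child seed per phenotype in spec order.
    """
    rng = np.random.default_rng(spec.seed)
    gmap = _build_map(spec)
    n = spec.n_individuals
    cols = []
    for c, (length, n_markers) in zip(gmap.chromosomes, spec.chromosomes):
        positions = np.array([p for _, p in gmap.markers[c]])
        g1 = simulate_gametes(rng, positions, n)
        g2 = simulate_gametes(rng, positions, n)
        cols.append((g1 + g2).astype(np.int8))
    genotypes = np.concatenate(cols, axis=1)
    sex = np.concatenate([np.zeros(spec.n_males), np.ones(spec.n_females)])
    cross = CrossData(
        cross_type="f2",
        map=gmap,
        genotypes=genotypes,
        phenotypes=pd.DataFrame(index=range(n)),
        covariates=pd.DataFrame({"sex": sex}),
    )
    pheno_seeds = rng.integers(0, 2**31 - 1, size=len(spec.phenotypes))
    for pspec, s in zip(spec.phenotypes, pheno_seeds):
        cross.phenotypes[pspec.name] = simulate_phenotype(cross, pspec, int(s))
    return cross


def qtl_marker_name(cross: CrossData, chromosome: str, position_cM: float) -> str:
    """Name of the marker at (or nearest to) the requested position."""
    entries = cross.map.markers[chromosome]
    dists = [abs(p - position_cM) for _, p in entries]
    return entries[int(np.argmin(dists))][0]


def simulate_phenotype(cross: CrossData, pspec: PhenotypeSpec, seed: int) -> np.ndarray:
    """Draw one phenotype column for ``cross`` under ``pspec``.

    y_i = a d_i + eps_i, with d the -1/0/+1 additive code at the QTL
    marker and eps_i ~ Normal(0, sd[g_i]^2 * svr^(2 sex_i)).
    """
    rng = np.random.default_rng(seed)
    n = cross.n_individuals
    sds = np.asarray(pspec.sd_by_genotype, dtype=float)
    # genotype-frequency-weighted mean residual variance (expected F2 freqs)
    sigma2_bar = 0.25 * sds[0] ** 2 + 0.5 * sds[1] ** 2 + 0.25 * sds[2] ** 2

    if pspec.qtl_chromosome is not None:
        marker = qtl_marker_name(cross, pspec.qtl_chromosome, pspec.qtl_position_cM)
        g = cross.genotypes[:, cross.marker_index(marker)].astype(int)
        if np.any(g < 0):
            raise ValueError("QTL marker has missing genotypes")
    else:
        g = np.ones(n, dtype=int)  # all-AB: no genetic signal

    f = pspec.mean_effect
    a = np.sqrt(2.0 * f * sigma2_bar / (1.0 - f)) if f > 0 else 0.0
    d = g - 1

    sd_i = sds[g]
    if pspec.sex_variance_ratio != 1.0:
        sex = cross.covariates["sex"].to_numpy(float)
        sd_i = sd_i * pspec.sex_variance_ratio**sex
    return a * d + rng.standard_normal(n) * sd_i


def default_sim_spec(
    n_males: int = 200,
    n_females: int = 200,
    seed: int = 0,
    sex_effects: bool = False,
    sex_variance_ratio: float = 1.5,
) -> SimSpec:
    """The benchmark study design: 400 F2s (half each sex), 3 chromosomes
    of 100 cM with 11 equally spaced markers, and the four benchmark
    phenotypes (with optional sex-specific residual variance)."""
    svr = sex_variance_ratio if sex_effects else 1.0
    suffix = "x" if sex_effects else ""
    phenotypes = (
        PhenotypeSpec(name=f"phenotype1{suffix}", sex_variance_ratio=svr),
        PhenotypeSpec(
            name=f"phenotype2{suffix}",
            qtl_chromosome="1",
            qtl_position_cM=50.0,
            mean_effect=0.04,
            sex_variance_ratio=svr,
        ),
        PhenotypeSpec(
            name=f"phenotype3{suffix}",
            qtl_chromosome="2",
            qtl_position_cM=50.0,
            sd_by_genotype=(0.8, 1.0, 1.25),
            sex_variance_ratio=svr,
        ),
        PhenotypeSpec(
            name=f"phenotype4{suffix}",
            qtl_chromosome="3",
            qtl_position_cM=50.0,
            mean_effect=0.027,
            sd_by_genotype=(0.85, 1.0, 1.17),
            sex_variance_ratio=svr,
        ),
    )
    return SimSpec(
        n_males=n_males, n_females=n_females, seed=seed, phenotypes=phenotypes
    )


def simulate_study(seed: int = 0, n_males: int = 200, n_females: int = 200) -> CrossData:
    """Convenience wrapper: simulate the full benchmark cross."""
    return simulate_cross(default_sim_spec(n_males=n_males, n_females=n_females, seed=seed))
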