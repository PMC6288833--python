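"""Genotype-class probabilities at markers and pseudomarkers.

A hidden Markov model along each chromosome converts observed marker
genotypes (with a small genotyping-error allowance) into posterior
probabilities of the true genotype class at every point of an evaluation
grid.  The grid is the union of the genotyped markers and pseudomarkers
placed at exact multiples of ``step`` cM from the chromosome start, so a
2 cM step reproduces the usual "probabilities every 2 cM" evaluation grid.

Genetic distance is converted to recombination fraction with the Haldane
map function (no crossover interference); for an F2 intercross the hidden
chain has three states (AA, AB, BB) with stationary distribution
(1/4, 1/2, 1/4), for a backcross two states with stationary (1/2, 1/2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cross_io import CrossData

__all__ = [
    "LocusGrid",
    "GenotypeProbabilities",
    "haldane_recomb_fraction",
    "f2_transition_matrix",
    "bc_transition_matrix",
    "calc_genoprob",
]

_F2_STATIONARY = np.array([0.25, 0.5, 0.25])
_BC_STATIONARY = np.array([0.5, 0.5])


def haldane_recomb_fraction(d) -> np.ndarray | float:
    """Recombination fraction for a genetic distance ``d`` in cM.

    r = (1 - exp(-2 d / 100)) / 2, monotone in d, saturating at 1/2.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("genetic distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return r if r.ndim else float(r)


def f2_transition_matrix(r: float) -> np.ndarray:
    """3x3 transition kernel between F2 genotype classes across one
    interval with recombination fraction ``r`` (both gametes recombine
    independently)."""
    if not 0.0 <= r <= 0.5:
        raise ValueError("recombination fraction must lie in [0, 0.5]")
    s = 1.0 - r
    return np.array(
        [
            [s * s, 2 * r * s, r * r],
            [r * s, s * s + r * r, r * s],
            [r * r, 2 * r * s, s * s],
        ]
    )


def bc_transition_matrix(r: float) -> np.ndarray:
    """2-state backcross analogue (single segregating gamete)."""
    if not 0.0 <= r <= 0.5:
        raise ValueError("recombination fraction must lie in [0, 0.5]")
    return np.array([[1.0 - r, r], [r, 1.0 - r]])


@dataclass(frozen=True)
class LocusGrid:
    """Evaluation grid: per chromosome an ordered list of
    (locus name, position cM, is_pseudomarker)."""

    chromosomes: tuple[str, ...]
    loci: dict[str, tuple[tuple[str, float, bool], ...]]

    @property
    def locus_names(self) -> list[str]:
        return [name for c in self.chromosomes for name, _, _ in self.loci[c]]

    @property
    def n_loci(self) -> int:
        return sum(len(self.loci[c]) for c in self.chromosomes)

    def table(self):
        """Flat (locus, chromosome, position, is_pseudomarker) records."""
        return [
            (name, c, pos, pseudo)
            for c in self.chromosomes
            for name, pos, pseudo in self.loci[c]
        ]

    def index_of(self, locus: str) -> int:
        for i, name in enumerate(self.locus_names):
            if name == locus:
                return i
        raise KeyError(f"locus {locus!r} not on the evaluation grid")


def _build_grid(cross: CrossData, step: float, chromosomes=None) -> LocusGrid:
    chroms = tuple(chromosomes) if chromosomes is not None else cross.map.chromosomes
    loci: dict[str, tuple[tuple[str, float, bool], ...]] = {}
    for chrom in chroms:
        markers = cross.map.markers[chrom]
        start, end = markers[0][1], markers[-1][1]
        marker_pos = {round(p, 9) for _, p in markers}
        entries = [(name, p, False) for name, p in markers]
        k = int(np.ceil(start / step))
        pos = k * step
        while pos <= end + 1e-9:
            if round(pos, 9) not in marker_pos:
                entries.append((f"c{chrom}.loc{pos:g}", float(pos), True))
            pos += step
        entries.sort(key=lambda t: t[1])
        loci[chrom] = tuple(entries)
    return LocusGrid(chroms, loci)


@dataclass
class GenotypeProbabilities:
    """Posterior genotype-class probabilities on an evaluation grid.

    ``probs`` has shape (individuals, grid loci, classes) with classes
    (AA, AB, BB) for an F2 and (AA, AB) for a backcross; each probability
    vector sums to one.
    """

    grid: LocusGrid
    probs: np.ndarray
    cross_type: str
    error_rate: float
    map_function: str = "haldane"
    step: float = 2.0

    def __post_init__(self) -> None:
        self._index = {name: i for i, name in enumerate(self.grid.locus_names)}
        self._chrom_of = {
            name: c for c in self.grid.chromosomes for name, _, _ in self.grid.loci[c]
        }
        self._pos_of = {
            name: p for c in self.grid.chromosomes for name, p, _ in self.grid.loci[c]
        }

    @property
    def n_classes(self) -> int:
        return self.probs.shape[2]

    def locus_index(self, locus: str) -> int:
        try:
            return self._index[locus]
        except KeyError:
            raise KeyError(f"locus {locus!r} not on the evaluation grid") from None

    def chromosome_of(self, locus: str) -> str:
        return self._chrom_of[locus]

    def position_of(self, locus: str) -> float:
        return self._pos_of[locus]

    def subset_individuals(self, rows: np.ndarray) -> "GenotypeProbabilities":
        """Probabilities are per-individual, so resampling rows is exact."""
        out = GenotypeProbabilities(
            grid=self.grid,
            probs=self.probs[rows],
            cross_type=self.cross_type,
            error_rate=self.error_rate,
            map_function=self.map_function,
            step=self.step,
        )
        return out

    def to_table(self):
        """Flat table (locus, individual, class, probability)."""
        import pandas as pd

        classes = ["AA", "AB", "BB"][: self.n_classes]
        records = []
        for j, name in enumerate(self.grid.locus_names):
            for i in range(self.probs.shape[0]):
                for k, cls in enumerate(classes):
                    records.append((name, i, cls, self.probs[i, j, k]))
        return pd.DataFrame(
            records, columns=["locus", "individual", "class", "probability"]
        )


def _emission(obs: np.ndarray, n_states: int, error_rate: float) -> np.ndarray:
    """(individuals, states) emission probabilities for one marker's
    observed codes; missing (-1) is uninformative."""
    n = obs.shape[0]
    e = np.ones((n, n_states))
    typed = obs >= 0
    if error_rate == 0.0:
        e[typed] = 0.0
    else:
        e[typed] = error_rate / (n_states - 1)
    e[typed, obs[typed]] = 1.0 - error_rate
    return e


def calc_genoprob(
    cross: CrossData,
    step: float = 2.0,
    error_rate: float = 1e-4,
    map_function: str = "haldane",
    chromosomes=None,
) -> GenotypeProbabilities:
    """Forward-backward posterior genotype probabilities on the grid.

    Emission at a typed marker gives the observed class probability
    ``1 - error_rate`` and splits ``error_rate`` over the other classes;
    missing markers are uninformative.  Pseudomarker loci carry no data,
    only the chain smoothing between flanking markers.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must lie in [0, 0.5)")
    if map_function != "haldane":
        raise ValueError("only the Haldane map function is supported")

    n_states = 3 if cross.cross_type == "f2" else 2
    stationary = _F2_STATIONARY if n_states == 3 else _BC_STATIONARY
    trans = f2_transition_matrix if n_states == 3 else bc_transition_matrix

    grid = _build_grid(cross, step, chromosomes)
    n = cross.n_individuals
    probs = np.empty((n, grid.n_loci, n_states))

    marker_names = cross.map.marker_names
    marker_col = {m: j for j, m in enumerate(marker_names)}

    offset = 0
    for chrom in grid.chromosomes:
        entries = grid.loci[chrom]
        L = len(entries)
        positions = np.array([p for _, p, _ in entries])
        # per-locus emissions: uninformative at pseudomarkers
        emis = np.ones((L, n, n_states))
        for j, (name, _, pseudo) in enumerate(entries):
            if not pseudo:
                emis[j] = _emission(
                    cross.genotypes[:, marker_col[name]], n_states, error_rate
                )
        kernels = np.empty((L - 1, n_states, n_states))
        for j in range(L - 1):
            r = haldane_recomb_fraction(positions[j + 1] - positions[j])
            kernels[j] = trans(r)

        # vectorized forward-backward over individuals, scaled
        alpha = np.empty((L, n, n_states))
        scale = np.empty((L, n))
        a = stationary[None, :] * emis[0]
        scale[0] = a.sum(axis=1)
        alpha[0] = a / scale[0][:, None]
        for j in range(1, L):
            a = (alpha[j - 1] @ kernels[j - 1]) * emis[j]
            scale[j] = a.sum(axis=1)
            alpha[j] = a / scale[j][:, None]
        beta = np.ones((n, n_states))
        post = np.empty((L, n, n_states))
        post[L - 1] = alpha[L - 1]
        for j in range(L - 2, -1, -1):
            beta = (beta * emis[j + 1]) @ kernels[j].T
            beta /= beta.sum(axis=1, keepdims=True)
            p = alpha[j] * beta
            post[j] = p / p.sum(axis=1, keepdims=True)

        probs[:, offset : offset + L, :] = np.transpose(post, (1, 0, 2))
        offset += L

    return GenotypeProbabilities(
        grid=grid,
        probs=probs,
        cross_type=cross.cross_type,
        error_rate=error_rate,
        map_function=map_function,
        step=step,
    )
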