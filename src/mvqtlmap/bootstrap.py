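"""Nonparametric bootstrap confidence interval for QTL location.

Once a QTL has been declared on a chromosome, the precision of its
estimated position is assessed by resampling individuals with replacement,
rescanning only that chromosome, and recording the position of the
maximum LOD of the chosen test in each resample.  Percentile intervals of
the resampled peak positions give the confidence interval: the 10th-90th
percentiles for 80% coverage and the 5th-95th for 90%.  1000 resamples is
the recommended default for stable 80% and 90% intervals.

Genotype probabilities are per-individual, so a resample is obtained
exactly by row-subsetting the precomputed probability array — no HMM
recomputation is needed.  Ties in the maximum LOD are broken toward the
smallest cM position, deterministically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cross_io import CrossData
from .genoprob import GenotypeProbabilities
from .scan import ModelSpec, ScanEngine

__all__ = ["BootstrapResult", "bootstrap_ci"]

DEFAULT_RESAMPLES = 1000


@dataclass
class BootstrapResult:
    """Resampled peak positions and the percentile CIs derived from them."""

    test: str
    chromosome: str
    peak_positions: np.ndarray
    ci80: tuple[float, float]
    ci90: tuple[float, float]
    seeds: np.ndarray
    n_skipped: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_resamples(self) -> int:
        return len(self.peak_positions)

    def covers(self, position_cM: float, level: int = 90) -> bool:
        lo, hi = self.ci90 if level == 90 else self.ci80
        return lo <= position_cM <= hi

    def to_csv(self, path) -> None:
        import json

        import pandas as pd

        pd.DataFrame(
            {
                "resample_index": np.arange(self.n_resamples),
                "seed": self.seeds,
                "peak_cM": self.peak_positions,
            }
        ).to_csv(path, index=False)
        side = {
            "test": self.test,
            "chromosome": self.chromosome,
            "ci80": list(self.ci80),
            "ci90": list(self.ci90),
            "n_skipped": self.n_skipped,
            "meta": self.meta,
        }
        with open(str(path) + ".json", "w", encoding="utf-8") as fh:
            json.dump(side, fh, indent=1, default=str)


def _peak_position(eng: ScanEngine, test: str) -> float:
    lod = eng.lods()[test]
    pos = np.asarray(eng.locus_pos, float)
    best = np.nanmax(lod)
    # ties broken toward the smallest position; grid is sorted by position
    return float(pos[np.nonzero(lod >= best - 1e-12)[0][0]])


def bootstrap_ci(
    cross: CrossData,
    spec: ModelSpec,
    probs: GenotypeProbabilities,
    test: str,
    chromosome: str,
    n_resamples: int = DEFAULT_RESAMPLES,
    n_cores: int | None = None,
    seed: int = 0,
) -> BootstrapResult:
    """Bootstrap the peak position of ``test`` on ``chromosome``.

    Each resample draws n individuals with replacement (per-resample seeds
    pre-derived from ``seed``, so results are independent of ``n_cores``);
    degenerate resamples (e.g. monomorphic after resampling) are skipped,
    redrawn with a fresh derived seed, and counted.
    """
    if test not in ("mQTL", "vQTL", "mvQTL", "traditional"):
        raise ValueError(f"unknown test {test!r}")
    if chromosome not in probs.grid.chromosomes:
        raise ValueError(f"chromosome {chromosome!r} not in the evaluation grid")
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_resamples)

    eng = ScanEngine(cross, spec, probs, tests=(test,), chromosomes=(chromosome,))
    n = eng.n
    rows = np.empty((n_resamples, n), dtype=int)
    for i in range(n_resamples):
        rows[i] = np.random.default_rng(int(seeds[i])).integers(0, n, size=n)

    def one(i: int) -> tuple[float, int]:
        """Per-resample fallback: full engine rebuild with redraw on a
        degenerate design."""
        skipped = 0
        for retry in range(5):
            rng = np.random.default_rng(
                (int(seeds[i]), retry) if retry else int(seeds[i])
            )
            rr = rng.integers(0, cross.n_individuals, size=cross.n_individuals)
            try:
                e = ScanEngine(
                    cross.subset(rr), spec, probs.subset_individuals(rr),
                    tests=(test,), chromosomes=(chromosome,),
                )
                return _peak_position(e, test), skipped
            except (ValueError, np.linalg.LinAlgError):
                skipped += 1
        raise RuntimeError(f"resample {i} degenerate after {skipped} redraws")

    if n_cores is None:
        import os

        n_cores = max(1, (os.cpu_count() or 1) - 2)
    n_skipped = 0
    try:
        if min(n_cores, n_resamples) > 1:
            from joblib import Parallel, delayed

            splits = np.array_split(np.arange(n_resamples), min(n_cores, n_resamples))
            parts = Parallel(n_jobs=min(n_cores, n_resamples))(
                delayed(eng.bootstrap_peaks)(rows[idx], test) for idx in splits
            )
            peaks = np.concatenate(parts)
        else:
            peaks = eng.bootstrap_peaks(rows, test)
    except (ValueError, np.linalg.LinAlgError):
        results = [one(i) for i in range(n_resamples)]
        peaks = np.array([r[0] for r in results])
        n_skipped = int(sum(r[1] for r in results))
        if n_skipped:
            warnings.warn(f"{n_skipped} degenerate resamples were redrawn")

    ci80 = tuple(np.percentile(peaks, [10.0, 90.0]))
    ci90 = tuple(np.percentile(peaks, [5.0, 95.0]))
    return BootstrapResult(
        test=test,
        chromosome=chromosome,
        peak_positions=peaks,
        ci80=(float(ci80[0]), float(ci80[1])),
        ci90=(float(ci90[0]), float(ci90[1])),
        seeds=seeds,
        n_skipped=n_skipped,
        meta={
            "cross_hash": cross.content_hash(),
            "spec": spec.to_dict(),
            "seed": int(seed),
            "n_resamples": int(n_resamples),
        },
    )
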