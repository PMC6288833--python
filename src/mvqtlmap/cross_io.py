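"""Reading, writing and validation of experimental-cross data.

The on-disk format is the r/qtl comma-separated ("csv") cross layout:

* row 1 — phenotype column names followed by marker names;
* row 2 — blank cells under the phenotypes, chromosome id under each marker;
* row 3 — blank cells under the phenotypes, centimorgan position under each
  marker;
* rows 4+ — one individual per row: phenotype values, then genotype codes.

Genotypes use the single-letter dialect ``A`` (homozygous AA), ``H``
(heterozygous AB), ``B`` (homozygous BB), with ``-`` or an empty cell for
missing.  Other r/qtl dialects (two-letter codes, rotated "csvr") are
rejected rather than guessed: bit-exact interoperability on one dialect
beats silent misparsing.

Positions are genetic (cM) only; there are no physical coordinates anywhere
in the package.  The canonical covariate is a column named ``sex`` coded
0 = male, 1 = female.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "CrossData",
    "CrossFormatError",
    "CrossValidationError",
    "read_cross",
    "write_cross",
    "GENO_CODES",
]

#: integer genotype codes used throughout the package
GENO_CODES = {"AA": 0, "AB": 1, "BB": 2, "missing": -1}
_SYMBOL_TO_CODE = {"A": 0, "H": 1, "B": 2, "-": -1, "": -1}
_CODE_TO_SYMBOL = {0: "A", 1: "H", 2: "B", -1: "-"}


class CrossFormatError(ValueError):
    """The file does not follow the expected csv cross layout."""


class CrossValidationError(ValueError):
    """In-memory cross data violates a structural invariant."""


@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker map: chromosome -> [(marker name, position in cM)].

    Positions must be strictly increasing within each chromosome and marker
    names globally unique.
    """

    chromosomes: tuple[str, ...]
    markers: dict[str, tuple[tuple[str, float], ...]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for chrom in self.chromosomes:
            entries = self.markers.get(chrom, ())
            if len(entries) == 0:
                raise CrossValidationError(f"chromosome {chrom!r} has no markers")
            pos = np.array([p for _, p in entries], dtype=float)
            if np.any(pos < 0):
                raise CrossValidationError(
                    f"chromosome {chrom!r} has a negative cM position"
                )
            if np.any(np.diff(pos) <= 0):
                raise CrossValidationError(
                    f"positions not strictly increasing on chromosome {chrom!r}"
                )
            for name, _ in entries:
                if name in seen:
                    raise CrossValidationError(f"duplicate marker name {name!r}")
                seen.add(name)

    @property
    def marker_names(self) -> list[str]:
        return [m for c in self.chromosomes for m, _ in self.markers[c]]

    @property
    def n_markers(self) -> int:
        return len(self.marker_names)

    def chromosome_of(self, marker: str) -> str:
        for chrom in self.chromosomes:
            if any(m == marker for m, _ in self.markers[chrom]):
                return chrom
        raise KeyError(marker)

    def position_of(self, marker: str) -> float:
        for chrom in self.chromosomes:
            for m, p in self.markers[chrom]:
                if m == marker:
                    return p
        raise KeyError(marker)


@dataclass
class CrossData:
    """One mapping population: genotypes, phenotypes, covariates and the map.

    ``genotypes`` is an individuals x markers int8 matrix over
    ``GENO_CODES`` values; column order follows the map's marker order.
    ``cross_type`` is ``"f2"`` (codes AA/AB/BB) or ``"backcross"``
    (AA/AB only).
    """

    cross_type: str
    map: GeneticMap
    genotypes: np.ndarray
    phenotypes: pd.DataFrame
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.cross_type not in ("f2", "backcross"):
            raise CrossValidationError(f"unknown cross type {self.cross_type!r}")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n, m = self.genotypes.shape
        if m != self.map.n_markers:
            raise CrossValidationError(
                f"genotype matrix has {m} columns but the map has "
                f"{self.map.n_markers} markers"
            )
        valid = {-1, 0, 1, 2} if self.cross_type == "f2" else {-1, 0, 1}
        bad = set(np.unique(self.genotypes)) - valid
        if bad:
            raise CrossValidationError(
                f"invalid genotype codes {sorted(bad)} for cross type "
                f"{self.cross_type!r}"
            )
        if len(self.phenotypes) not in (0, n):
            raise CrossValidationError("phenotype table row count mismatch")
        if len(self.covariates) not in (0, n):
            raise CrossValidationError("covariate table row count mismatch")
        if len(self.phenotypes) == 0:
            self.phenotypes = pd.DataFrame(index=range(n))
        if len(self.covariates) == 0:
            self.covariates = pd.DataFrame(index=range(n))
        self.phenotypes = self.phenotypes.reset_index(drop=True)
        self.covariates = self.covariates.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    def marker_index(self, marker: str) -> int:
        return self.map.marker_names.index(marker)

    def subset(self, rows: np.ndarray) -> "CrossData":
        """Row-subset (e.g. a bootstrap resample); preserves column order."""
        return CrossData(
            cross_type=self.cross_type,
            map=self.map,
            genotypes=self.genotypes[rows],
            phenotypes=self.phenotypes.iloc[rows].reset_index(drop=True),
            covariates=self.covariates.iloc[rows].reset_index(drop=True),
        )

    def content_hash(self) -> str:
        """Stable hash of the numeric content, used to match permutation
        batches to the cross they were computed on."""
        import hashlib

        h = hashlib.sha256()
        h.update(self.cross_type.encode())
        for chrom in self.map.chromosomes:
            h.update(chrom.encode())
            for m, p in self.map.markers[chrom]:
                h.update(f"{m}:{p:.6f}".encode())
        h.update(self.genotypes.tobytes())
        for df in (self.phenotypes, self.covariates):
            for col in df.columns:
                h.update(str(col).encode())
                h.update(np.ascontiguousarray(df[col].to_numpy(float)).tobytes())
        return h.hexdigest()[:16]


def _parse_float(cell: str, where: str) -> float:
    try:
        return float(cell)
    except ValueError as exc:
        raise CrossFormatError(f"cannot parse {cell!r} as a number in {where}") from exc


def read_cross(
    path,
    cross_type: str = "f2",
    covariate_names: Sequence[str] = ("sex",),
) -> CrossData:
    """Read an r/qtl csv cross file into a validated :class:`CrossData`.

    Columns whose header appears in ``covariate_names`` are routed to
    ``CrossData.covariates``; all other non-marker columns become phenotypes.
    """
    raw = pd.read_csv(path, header=None, dtype=str, keep_default_na=False)
    if raw.shape[0] < 3:
        raise CrossFormatError(
            "file has fewer than 3 rows; expected name/chromosome/position "
            "header rows"
        )
    header = [str(c).strip() for c in raw.iloc[0]]
    chrom_row = [str(c).strip() for c in raw.iloc[1]]
    pos_row = [str(c).strip() for c in raw.iloc[2]]

    # phenotype columns are those with a blank chromosome cell (row 2)
    is_marker = [c != "" for c in chrom_row]
    if any(m1 and not m2 for m1, m2 in zip(is_marker, is_marker[1:])):
        raise CrossFormatError(
            "marker columns must follow all phenotype columns (row 2 has a "
            "blank chromosome cell after a filled one)"
        )
    if not any(is_marker):
        raise CrossFormatError("no marker columns found (row 2 is entirely blank)")
    for j, m in enumerate(is_marker):
        if m and pos_row[j] == "":
            raise CrossFormatError(
                f"marker column {header[j]!r} is missing its cM position (row 3)"
            )

    pheno_cols = [j for j, m in enumerate(is_marker) if not m]
    marker_cols = [j for j, m in enumerate(is_marker) if m]

    # build the map, preserving chromosome order of first appearance
    chrom_order: list[str] = []
    markers: dict[str, list[tuple[str, float]]] = {}
    for j in marker_cols:
        chrom = chrom_row[j]
        if chrom not in markers:
            chrom_order.append(chrom)
            markers[chrom] = []
        markers[chrom].append(
            (header[j], _parse_float(pos_row[j], f"position row, column {header[j]!r}"))
        )
    gmap = GeneticMap(tuple(chrom_order), {c: tuple(v) for c, v in markers.items()})

    body = raw.iloc[3:].reset_index(drop=True)
    n = len(body)
    geno = np.empty((n, len(marker_cols)), dtype=np.int8)
    for k, j in enumerate(marker_cols):
        col = body.iloc[:, j].str.strip()
        for i, sym in enumerate(col):
            try:
                geno[i, k] = _SYMBOL_TO_CODE[sym]
            except KeyError:
                raise CrossFormatError(
                    f"unknown genotype symbol {sym!r} at individual {i + 1}, "
                    f"marker {header[j]!r}"
                ) from None

    pheno = pd.DataFrame(index=range(n))
    for j in pheno_cols:
        vals = body.iloc[:, j].str.strip().replace({"": np.nan, "NA": np.nan, "-": np.nan})
        pheno[header[j]] = pd.to_numeric(vals, errors="raise").astype(float)

    covar_cols = [c for c in pheno.columns if c in set(covariate_names)]
    covariates = pheno[covar_cols].copy()
    phenotypes = pheno.drop(columns=covar_cols)
    return CrossData(
        cross_type=cross_type,
        map=gmap,
        genotypes=geno,
        phenotypes=phenotypes,
        covariates=covariates,
    )


def _format_number(x: float) -> str:
    if np.isnan(x):
        return ""
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))


def write_cross(cross: CrossData, path) -> None:
    """Write ``cross`` in the csv layout read by :func:`read_cross`.

    Covariate columns are written among the phenotype columns (the format
    has no covariate marker); ``read_cross`` re-separates them by name.
    """
    non_marker = list(cross.phenotypes.columns) + list(cross.covariates.columns)
    marker_names = cross.map.marker_names
    chrom_of = {
        m: chrom for chrom in cross.map.chromosomes for m, _ in cross.map.markers[chrom]
    }
    pos_of = {
        m: p for chrom in cross.map.chromosomes for m, p in cross.map.markers[chrom]
    }

    buf = io.StringIO()
    buf.write(",".join(list(map(str, non_marker)) + marker_names) + "\n")
    buf.write(",".join([""] * len(non_marker) + [str(chrom_of[m]) for m in marker_names]) + "\n")
    buf.write(
        ",".join([""] * len(non_marker) + [_format_number(pos_of[m]) for m in marker_names])
        + "\n"
    )
    both = pd.concat([cross.phenotypes, cross.covariates], axis=1)
    for i in range(cross.n_individuals):
        cells = [_format_number(both[c].iloc[i]) for c in non_marker] if non_marker else []
        cells += [_CODE_TO_SYMBOL[int(g)] for g in cross.genotypes[i]]
        buf.write(",".join(cells) + "\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())
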