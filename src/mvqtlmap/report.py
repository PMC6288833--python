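"""Publication-style outputs: genome-scan plots and locus effect summaries.

Two views matter after a scan.  The genome-wide view plots each test's
statistic along the genome — in LOD units, nominal p-value units, or
(recommended) FWER-adjusted p-value units, the last two drawn as
-log10(p) so that genome-wide significance is directly readable.  The
locus view (`mean-variance plot`) summarizes *why* a locus was detected:
one point per genotype group at (estimated mean, estimated residual SD),
with standard-error bars in each direction.  Horizontal separation of the
groups indicates a mean effect, vertical separation a variance effect.

Grouping factors are either *focal* (modeled, and one prediction plotted
per group) or *nuisance* (modeled, then averaged over on the linear
predictor scale before plotting).  Plotting functions return the numbers
they drew, so downstream checks never parse images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .cross_io import CrossData
from .dglm import DesignPair, fit_dglm
from .genoprob import GenotypeProbabilities
from .scan import ModelSpec, ScanResult

__all__ = [
    "EffectsSummary",
    "effects_at_locus",
    "effects_at_locus_model_free",
    "plot_scan",
    "plot_mean_var",
]

TEST_COLORS = {
    "mQTL": "tab:blue",
    "vQTL": "tab:red",
    "mvQTL": "black",
    "traditional": "tab:green",
}

_F2_GENO_CODING = {"AA": (-1.0, 0.0), "AB": (0.0, 1.0), "BB": (1.0, 0.0)}
_BC_GENO_CODING = {"AA": (-1.0,), "AB": (1.0,)}


@dataclass
class EffectsSummary:
    """Per-group mean/SD estimates with standard errors at one locus."""

    table: pd.DataFrame  # columns: group, mean, se_mean, sd, se_sd
    locus: str
    focal_groups: tuple[str, ...]
    nuisance_groups: tuple[str, ...] = ()
    model_based: bool = True
    meta: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _group_columns(name: str, cross: CrossData, probs, locus, rows):
    """Design columns and per-level values for one grouping factor."""
    if name == "genotype":
        j = probs.locus_index(locus)
        p = probs.probs[rows, j, :]
        if probs.cross_type == "backcross":
            cols = [("qtl_add", p[:, 1] - p[:, 0])]
            coding = _BC_GENO_CODING
        else:
            cols = [("qtl_add", p[:, 2] - p[:, 0]), ("qtl_dom", p[:, 1])]
            coding = _F2_GENO_CODING
        levels = {lvl: np.array(v) for lvl, v in coding.items()}
        return cols, levels
    if name in cross.covariates.columns:
        v = cross.covariates[name].to_numpy(float)[rows]
    elif name in cross.phenotypes.columns:
        v = cross.phenotypes[name].to_numpy(float)[rows]
    else:
        raise KeyError(f"grouping factor {name!r} not found")
    levels = {f"{name}={lvl:g}": np.array([lvl]) for lvl in np.unique(v)}
    return [(name, v)], levels


def effects_at_locus(
    cross: CrossData,
    spec: ModelSpec,
    probs: GenotypeProbabilities,
    locus: str,
    focal_groups: tuple[str, ...] = ("genotype",),
    nuisance_groups: tuple[str, ...] = (),
    nuisance_weights: str = "equal",
) -> EffectsSummary:
    """Fit the locus DGLM with focal and nuisance terms in both submodels
    and predict each focal group's mean and residual SD.

    SE(mean) comes from the mean-submodel coefficient covariance;
    SD = exp(eta/2) with SE by the delta method, SE(SD) = SD * SE(eta)/2.
    Nuisance factors are averaged on the linear predictor scale, with
    equal weight per observed level (or observation-frequency weights if
    ``nuisance_weights="observed"``).
    """
    y_all = cross.phenotypes[spec.phenotype].to_numpy(float)
    rows = ~np.isnan(y_all)
    factors = list(focal_groups) + list(nuisance_groups)
    cols_by_factor, levels_by_factor = {}, {}
    for f in factors:
        cols, levels = _group_columns(f, cross, probs, locus, rows)
        for _, v in cols:
            if v.ndim == 1:
                rows_ok = ~np.isnan(v)
                if not rows_ok.all():
                    raise ValueError(f"missing values in grouping factor {f!r}")
        cols_by_factor[f] = cols
        levels_by_factor[f] = levels

    y = y_all[rows]
    n = len(y)
    names = ["intercept"]
    design_cols = [np.ones(n)]
    for f in factors:
        for cname, v in cols_by_factor[f]:
            names.append(cname)
            design_cols.append(v)
    X = np.column_stack(design_cols)
    fit = fit_dglm(DesignPair(X, X, y, tuple(names), tuple(names)))

    # nuisance factors contribute their averaged column values
    nuisance_vals: dict[str, float] = {}
    for f in nuisance_groups:
        lvl_vecs = list(levels_by_factor[f].values())
        if nuisance_weights == "observed":
            col = cols_by_factor[f][0][1]
            w = np.array([np.mean(np.isclose(col, v[0])) for v in lvl_vecs])
            w = w / w.sum()
        else:
            w = np.full(len(lvl_vecs), 1.0 / len(lvl_vecs))
        avg = sum(wi * v for wi, v in zip(w, lvl_vecs))
        for (cname, _), val in zip(cols_by_factor[f], np.atleast_1d(avg)):
            nuisance_vals[cname] = float(val)

    focal_levels = [list(levels_by_factor[f].items()) for f in focal_groups]
    records = []
    for combo in product(*focal_levels):
        x = np.zeros(len(names))
        x[0] = 1.0
        label_parts = []
        vals: dict[str, float] = dict(nuisance_vals)
        for (lvl_name, lvl_vec), f in zip(combo, focal_groups):
            label_parts.append(lvl_name)
            for (cname, _), v in zip(cols_by_factor[f], np.atleast_1d(lvl_vec)):
                vals[cname] = float(v)
        for j, cname in enumerate(names[1:], start=1):
            x[j] = vals[cname]
        mean = float(x @ fit.beta)
        se_mean = float(np.sqrt(x @ fit.cov_beta @ x))
        eta = float(x @ fit.theta)
        se_eta = float(np.sqrt(x @ fit.cov_theta @ x))
        sd = float(np.exp(eta / 2.0))
        records.append((":".join(label_parts), mean, se_mean, sd, sd * se_eta / 2.0))

    if not records:
        raise ValueError("no focal groups to summarize")
    table = pd.DataFrame(records, columns=["group", "mean", "se_mean", "sd", "se_sd"])
    return EffectsSummary(
        table=table,
        locus=locus,
        focal_groups=tuple(focal_groups),
        nuisance_groups=tuple(nuisance_groups),
        meta={"n": n, "loglik": fit.loglik, "converged": fit.converged},
    )


def effects_at_locus_model_free(
    cross: CrossData,
    phenotype: str,
    probs: GenotypeProbabilities,
    locus: str,
) -> EffectsSummary:
    """Raw per-genotype-group sample means and SDs (no model): individuals
    hard-assigned to their most probable genotype class at the locus, with
    textbook SEs (SE(mean) = s/sqrt(n), SE(SD) ~ s/sqrt(2(n-1))).

    A convenience companion to the model-based summary for eyeballing
    whether the model is being led by a few points.
    """
    y_all = cross.phenotypes[phenotype].to_numpy(float)
    rows = ~np.isnan(y_all)
    y = y_all[rows]
    j = probs.locus_index(locus)
    assigned = np.argmax(probs.probs[rows, j, :], axis=1)
    classes = ["AA", "AB", "BB"][: probs.n_classes]
    records = []
    for k, cls in enumerate(classes):
        yk = y[assigned == k]
        if len(yk) < 2:
            raise ValueError(f"group {cls} has fewer than 2 observations")
        s = float(np.std(yk, ddof=1))
        records.append(
            (cls, float(np.mean(yk)), s / np.sqrt(len(yk)), s, s / np.sqrt(2.0 * (len(yk) - 1)))
        )
    table = pd.DataFrame(records, columns=["group", "mean", "se_mean", "sd", "se_sd"])
    return EffectsSummary(
        table=table,
        locus=locus,
        focal_groups=("genotype",),
        model_based=False,
        meta={"n": int(rows.sum())},
    )


def plot_scan(result: ScanResult, units: str = "lod", out=None, ax=None) -> pd.DataFrame:
    """Genome-scan plot: one series per test along the concatenated genome.

    ``units`` is ``"lod"``, ``"nominal_p"`` or ``"fwer_p"``; p-value units
    are drawn as -log10(p).  Returns the plotted (locus, test, x, y) table
    and writes ``out`` if given.
    """
    if units not in ("lod", "nominal_p", "fwer_p"):
        raise ValueError(f"unknown plotting units {units!r}")
    if units == "fwer_p" and "emp_p" not in result.table.columns:
        raise ValueError(
            "fwer_p units require permutations: run run_permutations() first"
        )
    table = result.table.copy()
    if len(table) == 0:
        raise ValueError("scan result is empty; nothing to plot")

    # genome coordinate: concatenate chromosomes with a small gap
    chroms = list(dict.fromkeys(table["chromosome"].astype(str)))
    offset, gap, offsets = 0.0, 10.0, {}
    for c in chroms:
        offsets[c] = offset
        offset += float(table.loc[table["chromosome"].astype(str) == c, "position"].max()) + gap
    table["x"] = [
        offsets[str(c)] + p for c, p in zip(table["chromosome"], table["position"])
    ]
    if units == "lod":
        table["y"] = table["lod"]
        ylabel = "LOD"
    elif units == "nominal_p":
        table["y"] = -np.log10(table["p"])
        ylabel = "-log10 nominal p"
    else:
        table["y"] = -np.log10(table["emp_p"])
        ylabel = "-log10 FWER-adjusted p"

    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    own_fig = ax is None
    if own_fig:
        fig, ax = plt.subplots(figsize=(8, 3))
    for t in result.tests:
        sub = table[table["test"] == t].sort_values("x")
        ax.plot(sub["x"], sub["y"], color=TEST_COLORS.get(t, "gray"), label=t, lw=1.2)
    if units == "fwer_p":
        ax.axhline(-np.log10(0.05), color="gray", ls=":", lw=0.8)
    ax.set_xlabel("genome position (chromosomes concatenated, cM)")
    ax.set_ylabel(ylabel)
    ax.set_title(result.spec.phenotype)
    ax.legend(fontsize=8)
    if own_fig:
        fig.tight_layout()
        if out is not None:
            fig.savefig(out, dpi=150)
        plt.close(fig)
    return table[["locus", "chromosome", "position", "test", "x", "y"]]


def plot_mean_var(summary: EffectsSummary, out=None, ax=None) -> pd.DataFrame:
    """Mean-variance plot: one dot per group at (mean, SD) with SE bars.

    Returns the coordinate table (exactly the EffectsSummary numbers —
    plotting adds no computation) and writes ``out`` if given.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    t = summary.table
    own_fig = ax is None
    if own_fig:
        fig, ax = plt.subplots(figsize=(4, 4))
    colors = plt.rcParams["axes.prop_cycle"].by_key()["color"]
    for i, row in t.iterrows():
        c = colors[i % len(colors)]
        ax.errorbar(
            row["mean"], row["sd"],
            xerr=row["se_mean"], yerr=row["se_sd"],
            fmt="o", color=c, label=row["group"], capsize=3,
        )
    ax.set_xlabel("phenotype mean")
    ax.set_ylabel("residual SD")
    ax.set_title(summary.locus)
    ax.legend(fontsize=8)
    if own_fig:
        fig.tight_layout()
        if out is not None:
            fig.savefig(out, dpi=150)
        plt.close(fig)
    return t.copy()
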