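"""Genome scan for a mean QTL.

At every 2 cM grid position a double generalized linear model with
additive+dominance dosage terms in both the mean and log-variance
submodels is compared against three nulls, yielding the mQTL, vQTL and
mvQTL LOD scores, plus the traditional homoscedastic test.
"""

from mvqtlmap import ModelSpec, calc_genoprob, scanonevar, simulate_study, summary_scan

cross = simulate_study(seed=1)
probs = calc_genoprob(cross, step=2.0)

spec = ModelSpec(
    phenotype="phenotype2",
    mean_covariates=("sex",),
    var_covariates=("sex",),
)
result = scanonevar(cross, spec, probs)
print(summary_scan(result))
print(
    "\n-> phenotype2 carries a 4% mean QTL at 50 cM on chromosome 1: the\n"
    "   mQTL and traditional tests peak there, while the vQTL LOD stays low."
)
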