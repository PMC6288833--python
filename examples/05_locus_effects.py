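"""Why was this locus detected?  Mean-variance effect plots.

For each genotype group the fitted DGLM gives an estimated phenotype mean
and residual SD with standard errors.  A mean QTL separates the groups
horizontally (means differ), a variance QTL vertically (SDs differ).
"""

from mvqtlmap import (
    ModelSpec,
    calc_genoprob,
    effects_at_locus,
    plot_mean_var,
    simulate_study,
)

cross = simulate_study(seed=1)
probs = calc_genoprob(cross, step=2.0)

for pheno, locus, kind in (
    ("phenotype2", "D1M6", "mean QTL: groups separate in the mean column"),
    ("phenotype3", "D2M6", "variance QTL: groups separate in the sd column"),
):
    summ = effects_at_locus(cross, ModelSpec(phenotype=pheno), probs, locus)
    print(f"\n{pheno} at {locus} ({kind}):")
    print(summ.table.round(3).to_string(index=False))
    plot_mean_var(summ, out=f"mean_var_{pheno}.png")
    print(f"wrote mean_var_{pheno}.png")
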