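"""Full run: seed-paired cohorts for three conditions, morphometry, statistics.

Generates normoxia day 1 (ND1), normoxia day 5 (ND5) and hypoxia day 5
(HD5) cohorts from one seed (so islet sizes pair across groups), runs the
whole pipeline, and prints the group summaries and tests.  Expected
pattern: hypoxic islets have fewer laminin nodes, larger E-cadherin holes,
brighter E-cadherin and a CA9-positive core rim, while islet volume does
not differ between groups.
"""

from islet3d import StackInput, generate_cohort, get_profile, run_pipeline
from islet3d.phantom import analysis_config

SCALE = dict(voxel_size=(3.0, 3.0, 3.0), radius_range_um=(30.0, 55.0))  # desk scale

inputs = []
for prof in ("ND1", "ND5", "HD5"):
    for i, (grid, _) in enumerate(generate_cohort(get_profile(prof, **SCALE), 6, seed=3)):
        inputs.append(StackInput(grid=grid, condition=prof, name=f"{prof}_{i:03d}"))

report = run_pipeline(analysis_config(min_islet_volume_um3=3000.0), inputs)
df = report.records

print("group means (one row per islet x marker):")
for marker, col, unit in (
    ("laminin", "node_count", "nodes"),
    ("ecadherin", "hole_fraction_pct", "% holes"),
    ("ecadherin", "mean_intensity_au", "AU"),
    ("ca9", "volume_fraction_pct", "% CA9"),
):
    sub = df[df.marker == marker].groupby("condition")[col].agg(["mean", "std"])
    line = "  ".join(f"{c}: {m:8.2f} ± {s:6.2f}" for c, (m, s) in sub.iterrows())
    print(f"  {marker:10s} {col:20s} {line} ({unit})")

print("\nhypoxia vs normoxia day 5 (Welch t on working values):")
for label, cmp_res in zip(report.comparison_labels, report.comparisons):
    if label.endswith("ND5_vs_HD5") and any(
        k in label for k in ("node_count", "hole_fraction", "mean_intensity_au.")
    ):
        print(f"  {label:45s} p = {cmp_res.p_value:.2e}  transform={cmp_res.transform}")

print(f"\nANOVA on islet volume across groups: p = {report.anova_volume.p_value:.3f} "
      "(volumes are identically distributed by design)")
for corr in report.correlations:
    print(f"Pearson {corr.variables[0]} vs {corr.variables[1]}: r = {corr.r:.3f}, "
          f"p = {corr.p_value:.3g} (n = {corr.n})")
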