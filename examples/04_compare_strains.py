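"""Cross-strain comparison of effector responsiveness.

Runs noise-free linkage fits for the three Prochlorococcus strains and prints
fold differences of the intrinsic Kd against the MIT9313 reference."""

import pandas as pd

from itclink import compare_variants, fit_linkage, get_preset, simulate_linkage_dataset

fits = {
    name: fit_linkage(simulate_linkage_dataset(get_preset(name)))
    for name in ("MIT9313", "SS120", "MED4")
}
df = compare_variants(fits, reference="MIT9313")

with pd.option_context("display.float_format", "{:.3g}".format):
    print(df[["kd_intrinsic_uM", "kd_oxo_mM", "alpha",
              "kd_eff_uM", "kd_oxo_eff_mM", "kd_fold_vs_ref"]])

print("\nSS120 binds the glnA promoter "
      f"{df.loc['SS120', 'kd_fold_vs_ref']:.1f}x more weakly than MIT9313; "
      f"MED4 {df.loc['MED4', 'kd_fold_vs_ref']:.1f}x.")
# Higher Kd and lower alpha in SS120/MED4 mean those strains need more
# 2-oxoglutarate to reach the same promoter occupancy as MIT9313.
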