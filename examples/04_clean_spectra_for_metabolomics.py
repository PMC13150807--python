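"""Remove EDTA signals with baseline reconstruction and compare by PCA.

Three matched cohorts: serum-EDTA, the same samples without EDTA, and
the EDTA cohort after automated cleanup (plus a zero-filled "manual
chop" comparator). Binned PCA shows automated removal preserves the
metabolic covariance structure better than chopping.
"""

from edtaqc.studies import cleaning_fidelity_study, mass_balance_study

res = cleaning_fidelity_study(seed=7, n=20)
cv = res["cumvar2_pct"]
print("PC1+PC2 cumulative explained variance (0.02 ppm bins, mean-centred):")
print(f"  EDTA-free cohort      : {cv['edta_free']:.2f} %")
print(f"  automated EDTA removal: {cv['cleaned']:.2f} %")
print(f"  region chopping       : {cv['chopped']:.2f} %")
print(f"automated removal closer to the EDTA-free reference: "
      f"{res['cleaned_closer']}")
print(f"largest non-EDTA metabolite integral change: "
      f"{res['max_non_edta_integral_change'] * 100:.3f} %")

mb = mass_balance_study(seed=7)
print("\nEDTA mass balance on one sample (mM):")
for pool, c in mb["pools_mM"].items():
    print(f"  {pool:10s} {c:.4f}")
print(f"  expected in-tube total: {mb['true_total_mM']:.4f}")
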