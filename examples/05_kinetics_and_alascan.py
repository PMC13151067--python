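"""1:1 binding kinetics: global fitting and alanine-scan triage.

Synthetic sensorgrams (5 min baseline, 210 s association, 5 min
dissociation) at five analyte concentrations are fitted globally to a
single (k_on, k_off, R_max); variants are classified by K_D fold change
over the parent macrocycle.
"""

from macropan import (
    classify_alascan,
    fit_global_1to1,
    fold_selectivity,
    simulate_sensorgrams,
)

# a Z1-like binder: K_D = k_off / k_on = 135 nM
KON, KOFF = 2.0e5, 0.027
concs = [25e-9, 50e-9, 100e-9, 200e-9, 400e-9]
grams = simulate_sensorgrams(KON, KOFF, 1.0, concs, noise_sd=0.02, seed=1)
fit = fit_global_1to1(grams)
print("global 1:1 fit of 5 noisy traces:")
print(f"  k_on  = {fit.k_on:.3g} 1/(M s)   (true {KON:.3g})")
print(f"  k_off = {fit.k_off:.3g} 1/s       (true {KOFF:.3g})")
print(f"  K_D   = {fit.k_d * 1e9:.1f} nM          (true {KOFF / KON * 1e9:.1f} nM)")
print(f"  RMSE  = {fit.rmse:.3g} nm, converged = {fit.converged}")

wild_type = 4.7 * fit.k_d
print(f"\nselectivity over a wild-type-like off-target at "
      f"{wild_type * 1e9:.0f} nM: {fold_selectivity(wild_type, fit.k_d):.1f}-fold")

variants = {
    "W3A": fit.k_d * 12.0,   # aromatic anchor: large affinity loss
    "E8A": fit.k_d * 10.5,
    "T9A": fit.k_d * 3.0,    # polar position: mild
    "S2A": fit.k_d * 1.2,
}
table = classify_alascan(fit.k_d, variants)
print("\nalanine-scan triage (>9 essential, 4-9 intermediate, 2-4 mild):")
for row in table.itertuples():
    print(f"  {row.variant}: {row.fold_change:5.1f}-fold -> {row._4}")
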