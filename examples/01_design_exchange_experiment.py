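"""Plan an HDX-MS ligand-mapping experiment: dilutions, ratios, regimes.

Before labeling, one checks that the ligand concentration keeps the target
protein essentially fully bound AND that reassociation outcompetes intrinsic
exchange (k_on*[L] >> k_ex), so protection at the binding site is observable.
"""

from hdx_allomap import (
    BindingKinetics,
    MixComponent,
    MixDesign,
    fractional_occupancy,
    ligand_protein_ratio,
    mix_concentrations,
    saturation_check,
)
from hdx_allomap.units import format_ratio

# The exchange reaction: 1 uL of 100 uM protein stock diluted into 27 uL of
# 99.9% D2O buffer plus 2 uL of ligand in DMSO.
design = MixDesign([
    MixComponent(volume_ul=1.0, conc=100e-6),
    MixComponent(volume_ul=27.0, d2o_fraction=0.999),
    MixComponent(volume_ul=2.0),
])
concs, d2o = mix_concentrations(design)
protein = concs[0]
print(f"exchange conditions: {protein * 1e6:.1f} uM protein, {d2o:.0%} D2O")

# A tight inhibitor (K_D = 19 nM) used at 20 uM, and a weak fragment
# (K_D = 570 uM) pushed to 5 mM to stay near-saturating.
for name, K_D, lig in [("inhibitor", 19e-9, 20e-6), ("fragment", 570e-6, 5e-3)]:
    ratio = format_ratio(ligand_protein_ratio(lig, protein))
    occ = fractional_occupancy(K_D, protein, lig)
    print(f"{name}: {ratio} ligand:protein, occupancy {occ:.2%}")

# Which kinetic regime applies? With k_on*[L]/k_ex >= 10 the saturating
# limit k_obs = K_D*k_ex/[L] is valid; a k_off below 0.01/min means the
# complex never dissociates during the minutes-long time course.
kin = BindingKinetics(K_D=19e-9, k_on=1e7, ligand_conc=20e-6,
                      protein_conc=protein)
verdict = saturation_check(kin, k_ex=1.0)
print(f"regime: {verdict.scenario} (k_on[L]/k_ex = {verdict.kinetic_ratio:.0f})")
print(f"  -> {verdict.note}")
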