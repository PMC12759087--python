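"""Dose-response of a selective SERCA2 blocker in both species.

A virtual pump inhibitor (pIC50 = 5.5, i.e. IC50 ~ 3.2 uM) is applied at
four concentrations.  Printed per concentration: the scaling factor s that
multiplies the pump rate, and the percentage change of percentage
sarcomere shortening (Short, inotropy) and of the Ca2+ transient amplitude
(CaAmp).  Blocking SR reuptake depletes the SR and depresses contraction
in both species; the IC50-Short fit summarises the human inotropic potency.
"""

from cardiotrans.calibration import ic50_short
from cardiotrans.drugs import DrugSpec
from cardiotrans.models import DrugStudy

drug = DrugSpec("serca-blocker", {"SERCA2": 5.5})
concs = [0.1, 1.0, 10.0, 30.0]
study = DrugStudy.desk()

for species in ("rat", "human"):
    effects, abnormal = study.drug_effects(species, drug, concs)
    print(f"\n=== {species}: SERCA2 blocker (pIC50 5.5) ===")
    short = []
    for c in concs:
        s = drug.scaling_at(c)["SERCA2"]
        eff = effects[c]
        short.append(eff["Short"])
        print(f"  C = {c:5.1f} uM  s = {s:5.3f}   "
              f"Short {eff['Short']:+7.2f} %   CaAmp {eff['CaAmp']:+7.2f} %")
    if species == "human":
        fit = ic50_short(short, concs)
        print(f"  IC50-Short: {fit}")
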