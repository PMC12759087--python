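"""The three-step rat-to-human drug-effect translation on one virtual drug.

A virtual drug with known potencies on RyR2, SERCA2 and NCX1 generates a
synthetic rat dataset at four concentrations (step 1 stand-in); the
potencies are re-inferred from the rat biomarker effects by penalised
differential evolution (step 2); the human model then predicts the human
drug effects (step 3) which are compared to the human model's own
synthetic response to the true drug.  With noiseless self-generated data
the inferred potencies should match the truth to ~1e-3 and the predicted
human Short effects should match the synthetic human ones almost exactly.
"""

from cardiotrans.drugs import DrugSpec
from cardiotrans.models import DrugStudy
from cardiotrans.synthetic import generate_drug_effect_dataset
from cardiotrans.translation import InferenceSpec, RatEffectDataset, translate

truth = DrugSpec("virtual-drug", {"RyR2": 5.3, "SERCA2": 5.8, "NCX1": 5.6})
concs = [0.01, 0.1, 1.0, 10.0]
study = DrugStudy.desk()

dataset = generate_drug_effect_dataset(truth, concs, study)
rat = RatEffectDataset.from_table(dataset["rat"])
print("rat median drug effects (Short row, %):")
print(" ", rat.effects.loc["Short"].round(2).to_dict())

spec = InferenceSpec(targets=("RyR2", "SERCA2", "NCX1"),
                     restarts=2, maxiter=12, popsize=3)
result = translate(rat, spec, study, seed=1)
print("\ninferred blocking potencies (pIC50):")
for t, truth_v in truth.potencies.items():
    print(f"  {t:7s} inferred {result.potencies.potencies[t]:.4f}  "
          f"truth {truth_v:.4f}")
print(f"  objective {result.objective:.3f}  "
      f"(restarts: {[round(o, 3) for o in result.restart_objectives]})")

pred = RatEffectDataset.from_table(result.predicted_human)
human_truth = RatEffectDataset.from_table(dataset["human"])
print("\npredicted vs synthetic human Short effects (%):")
for c in concs:
    print(f"  C = {c:5.2f} uM  predicted {pred.effects.loc['Short', c]:+7.2f}  "
          f"synthetic {human_truth.effects.loc['Short', c]:+7.2f}")
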