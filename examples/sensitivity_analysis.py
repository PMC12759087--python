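"""Small Sobol' sensitivity analysis of rat biomarkers to drug block.

Scaling factors of the 8 shared drug targets are sampled in [0.6, 1.0]
(Saltelli scheme, small base sample for speed) and the normalised
total-effect indices of Short (inotropy) and SLTR50 (lusitropy) are
printed: 1 marks the most influential target per biomarker, values below
0.1 mark insensitivity.  Expect the Ca2+ handling proteins (RyR2, SERCA2,
NCX1) and Kv4.3 to dominate, with the late Na+ current and the Na+/K+
pump insensitive.
"""

import numpy as np

from cardiotrans.models import DrugStudy
from cardiotrans.sensitivity import (
    drug_response_problem,
    evaluate_batch,
    impute_missing,
    saltelli_sample,
    total_effect_indices,
)
from cardiotrans.transients import ALL_BIOMARKERS, drug_effect

study = DrugStudy.desk()
base_sl, base_ca = study.baseline_biomarkers("rat")
targets = study.params_for("rat").targets
problem = drug_response_problem(targets, n=16)
samples = saltelli_sample(problem)
print(f"{samples.shape[0]} model evaluations ...")


def runner(row):
    res = study.drugged_run("rat", dict(zip(targets, row)))
    if res.abnormal():
        return None
    slb, cab = res.biomarkers()
    eff = drug_effect(base_sl, slb)
    eff.update(drug_effect(base_ca, cab))
    return [eff.get(b, float("nan")) for b in ALL_BIOMARKERS]


outputs, mask = evaluate_batch(samples, runner, len(ALL_BIOMARKERS))
excluded = 100.0 * float(np.mean(mask.any(axis=1)))
result = total_effect_indices(problem, impute_missing(outputs, mask), excluded)

print(f"excluded samples: {excluded:.1f} %")
for bm in ("Short", "SLTR50"):
    j = ALL_BIOMARKERS.index(bm)
    print(f"\nnormalised total-effect indices for {bm}:")
    order = np.argsort(-result.stn[:, j])
    for i in order:
        flag = "  (insensitive)" if result.stn[i, j] < 0.1 else ""
        print(f"  {problem.names[i]:12s} {result.stn[i, j]:6.3f}{flag}")
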