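"""Ca2+ sensitivity of the contraction component and a mini recalibration.

First the steady-state isometric force-pCa relation of each species is
fitted with a Hill curve to report pCa50 / Ca50 (the Ca2+ concentration
producing half-maximal active stress).  Then one contraction parameter of
the rat model is perturbed and re-fitted against biomarker targets
generated by the unperturbed model, demonstrating the penalised
differential-evolution recalibration recovering the reference value.
"""

from cardiotrans.calibration import CalibrationTargets, ca_sensitivity, recalibrate
from cardiotrans.models import StimulusProtocol, human_params, rat_params, run_paced

for species, make in (("rat", rat_params), ("human", human_params)):
    fit = ca_sensitivity(make())
    print(f"{species:5s}: pCa50 = {fit.pca50:.3f}  Ca50 = {fit.ca50_um:.3f} uM  "
          f"hill = {fit.hill:.2f}")

proto = StimulusProtocol(n_beats=40, dt_solver=0.05)
truth = rat_params()
res = run_paced(truth, None, proto)
sl_t, ca_t = res.biomarkers()
targets = CalibrationTargets(
    sl_targets={k: sl_t[k] for k in ("SLRes", "Short", "SLTP", "SLTR50",
                                     "SLTR90", "dSLMaxC", "dSLMaxR")},
    ca_targets={k: (0.97 * ca_t[k], 1.03 * ca_t[k]) for k in
                ("CaRes", "CaPeak", "CaTP", "CaTR50")},
)
fit = recalibrate(truth, ["c_a"], targets, proto, seed=2, maxiter=12, popsize=8)
print(f"\nrecalibration of the active-tension gain c_a:")
print(f"  reference {truth['c_a']:.4f}  fitted {fit.fitted_values['c_a']:.4f}  "
      f"cost {fit.cost:.2e}  ({fit.n_evaluations} evaluations)")
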