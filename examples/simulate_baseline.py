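"""Paced baseline runs of the rat and human cardiomyocyte models.

Simulates 100 beats at 1 Hz per species and prints the final-beat
sarcomere-length and Ca2+ biomarkers next to the experimental reference
ranges the models are calibrated against, plus the action-potential
durations.  All printed SL and APD values should fall inside their ranges.
"""

from cardiotrans.calibration import (
    HUMAN_APD_RANGES,
    HUMAN_SL_RANGES,
    RAT_APD_RANGES,
    RAT_SL_RANGES,
)
from cardiotrans.models import StimulusProtocol, apd, human_params, rat_params, run_paced

for species, make, sl_ranges, apd_ranges in (
    ("rat", rat_params, RAT_SL_RANGES, RAT_APD_RANGES),
    ("human", human_params, HUMAN_SL_RANGES, HUMAN_APD_RANGES),
):
    result = run_paced(make(), None, StimulusProtocol(n_beats=100))
    sl, ca = result.biomarkers()
    print(f"\n=== {species} baseline (1 Hz, 100 beats, last beat) ===")
    for name, (lo, hi) in sl_ranges.items():
        print(f"  {name:8s} {sl[name]:10.4g}   experimental range [{lo:g}, {hi:g}]")
    for name in ca.names:
        print(f"  {name:8s} {ca[name]:10.4g}")
    for frac, name in ((0.5, "APD50"), (0.9, "APD90")):
        lo, hi = apd_ranges[name]
        print(f"  {name:8s} {apd(result, frac):10.4g}   experimental range [{lo:g}, {hi:g}]")
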