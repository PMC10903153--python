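"""Simulate SMX degradation curves and quantify removal per dosing phase.

Five sediment-microcosm treatments receive 10 mg/L sulfamethoxazole at days
0, 8 and 10 (phases I/II/III).  The sterilized control loses SMX only
abiotically, the non-inoculated sediment degrades it slowly, and the two
bioaugmented treatments remove it fast — the classic pattern this package's
kinetics stage quantifies as removal efficiencies and first-order rates.
"""

import warnings

from sipaug import ExperimentDesign, KineticsParams, kinetics_report, simulate_degradation

warnings.filterwarnings("ignore")

design = ExperimentDesign(seed=1)
params = KineticsParams()  # calibrated defaults: see docs/methods.md
series = simulate_degradation(design, params)

report = kinetics_report(series, reference_treatment="non-Inoc")
cols = ["treatment", "phase", "removal_pct", "removal_sd", "k_per_day",
        "half_life_days", "removal_vs_ref_abs_pts"]
print(report[cols].round(3).to_string(index=False))

print(
    "\nremoval_pct is the percent SMX lost across each phase (mean over 3\n"
    "replicates); k_per_day is the first-order rate from the ln C ~ t fit.\n"
    "The sterilized control stays below 3.5 % in phase I (abiotic loss only),\n"
    "the non-inoculated sediment removes ~10 %, and the inoculated\n"
    "treatments approach 100 % — the Pseudomonas-type system about 70\n"
    "percentage points above the non-inoculated control by day 8\n"
    "(removal_vs_ref_abs_pts)."
)
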