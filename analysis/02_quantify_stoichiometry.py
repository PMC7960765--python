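"""Stoichiometry recovery on simulated hinge-peptide runs.

Replays the published hydroxyproline distributions of the in-planta
experiments as simulation ground truth, quantifies each run by four-peak
EIC summation, and tabulates the recovered distributions with average Hyp
counts and percent change versus the control. A second experiment turns on
20% ammonium-adduct signal and compares four-peak quantification with the
monoisotopic-only fallback. Writes results/table2_recovery.tsv and
results/adduct_comparison.json.
"""

import json
from pathlib import Path

import numpy as np

from hypquant import (
    GroundTruth,
    quantify_stoichiometry,
    quantify_stoichiometry_monoiso,
    simulate_lcms_run,
)
from hypquant.peptides import HINGE_PEPTIDE
from hypquant.pipeline import QuantCondition, RunConfig, run_quantification_workflow

out_dir = Path(__file__).resolve().parents[1] / "results"
out_dir.mkdir(exist_ok=True)

# published hydroxyproline distributions (percent, 0..6 Hyp) used as truth
CONDITIONS = [
    QuantCondition("pPT2M control", (32.2, 30.7, 18.8, 11.4, 5.2, 1.5, 0.3), is_control=True),
    QuantCondition("P4H1 silenced", (23.1, 30.5, 23.6, 14.4, 6.1, 1.9, 0.4)),
    QuantCondition("P4H10 silenced", (36.9, 31.5, 17.1, 8.9, 4.1, 1.3, 0.2)),
    QuantCondition("P4H1+P4H10 silenced", (50.5, 27.0, 13.7, 6.0, 2.5, 0.4, 0.0)),
]

config = RunConfig(peptide=HINGE_PEPTIDE, conditions=tuple(CONDITIONS), seed=20)
result = run_quantification_workflow(config)
table = result["table"]
table.to_csv(out_dir / "table2_recovery.tsv", sep="\t", index=False)
print(f"quantification workflow (config {result['config_hash']}):")
print(table.round(2).to_string(index=False))

# ammonium-adduct interference: four-peak vs monoisotopic-only
f = np.array(CONDITIONS[0].fractions_percent)
f = f / f.sum()
errors = {"four_peak": [], "monoiso": []}
for seed in range(1, 11):
    truth = GroundTruth(
        peptide=HINGE_PEPTIDE, stoichiometry=tuple(f), adduct_fraction=0.2,
        noise_cv=0.02, seed=seed,
    )
    scans = simulate_lcms_run(truth)
    for mode, fn in (
        ("four_peak", lambda s: quantify_stoichiometry(s, HINGE_PEPTIDE, 6)),
        ("monoiso", lambda s: quantify_stoichiometry_monoiso(s, HINGE_PEPTIDE, 6)),
    ):
        rec = np.array(fn(scans).fractions_percent) / 100
        errors[mode].append(float(np.abs(rec - f).max()))

summary = {
    "adduct_fraction": 0.2,
    "noise_cv": 0.02,
    "seeds": 10,
    "max_abs_error_four_peak": max(errors["four_peak"]),
    "max_abs_error_monoiso": max(errors["monoiso"]),
}
(out_dir / "adduct_comparison.json").write_text(json.dumps(summary, indent=1))
print(
    "\nwith 20% ammonium adduct: four-peak max error "
    f"{summary['max_abs_error_four_peak']:.3f}, monoisotopic-only "
    f"{summary['max_abs_error_monoiso']:.3f} (unit fractions)"
)
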