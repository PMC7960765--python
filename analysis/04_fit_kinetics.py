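"""Michaelis–Menten parameter recovery for the four enzymes.

Simulates endpoint internal-standard assays using the published (Km, vmax)
pairs as ground truth — noiselessly for an exact-refit check, then with 2%
multiplicative noise over 100 seeds to measure the median recovered Km for
the two high-affinity enzymes. Writes results/table1_recovery.tsv and
results/km_medians.json.
"""

import json
from pathlib import Path

import numpy as np

from hypquant import KineticParameters, fit_assay, simulate_kinetics
from hypquant.pipeline import KineticScenario, RunConfig, run_kinetics_workflow

out_dir = Path(__file__).resolve().parents[1] / "results"
out_dir.mkdir(exist_ok=True)

SCENARIOS = (
    KineticScenario("Nb-P4H1", km_um=8, vmax_um_min=0.03, reaction_time_min=30),
    KineticScenario("Nb-P4H4", km_um=1900, vmax_um_min=0.1, reaction_time_min=30),
    KineticScenario("Nb-P4H9", km_um=72, vmax_um_min=0.4, reaction_time_min=20),
    KineticScenario("Nb-P4H10", km_um=66, vmax_um_min=0.02, reaction_time_min=20),
)

config = RunConfig(peptide="VTVPVPSTPPTPSPSTPPTPSPS", kinetics=SCENARIOS, noise_cv=0.0, seed=0)
result = run_kinetics_workflow(config)
table = result["table"]
table.to_csv(out_dir / "table1_recovery.tsv", sep="\t", index=False)
print(f"noiseless refit (config {result['config_hash']}):")
print(table.round(4).to_string(index=False))

medians = {}
for scenario in (SCENARIOS[0], SCENARIOS[3]):
    kms = []
    for seed in range(1, 101):
        assay = simulate_kinetics(
            KineticParameters(km=scenario.km_um, vmax=scenario.vmax_um_min),
            reaction_time=scenario.reaction_time_min,
            noise_cv=0.02,
            seed=seed,
        )
        kms.append(fit_assay(assay).km)
    medians[scenario.name] = {
        "true_km_um": scenario.km_um,
        "median_km_um": float(np.median(kms)),
        "seeds": len(kms),
    }
    print(
        f"{scenario.name}: median recovered Km over 100 noisy assays = "
        f"{np.median(kms):.2f} μM (truth {scenario.km_um} μM)"
    )

(out_dir / "km_medians.json").write_text(json.dumps(medians, indent=1))
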