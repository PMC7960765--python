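"""Mass arithmetic checks on the study's peptides.

Computes the protonated monoisotopic mass of the carbamidomethylated IgA1
hinge-region tryptic peptide, the per-charge m/z increment of a single
proline oxidation, and the IgA1 proline site census (how many prolines are
realistic hydroxylation targets). Writes results/peptide_checks.json.
"""

import json
from pathlib import Path

from hypquant import Peptidoform, OXIDATION, monoisotopic_mass, mz, proline_sites
from hypquant.peptides import HINGE_PEPTIDE, IGA1, IGA1_TARGET_SITES, INTERNAL_STANDARD

out_dir = Path(__file__).resolve().parents[1] / "results"
out_dir.mkdir(exist_ok=True)

hinge = Peptidoform.with_fixed_cam(HINGE_PEPTIDE)
hinge_mh = mz(monoisotopic_mass(hinge), 1)

shifts = {z: OXIDATION.mass_shift / z for z in (1, 2, 3)}
n_prolines = len(proline_sites(IGA1))
n_targets = len(IGA1_TARGET_SITES)

results = {
    "hinge_peptide": HINGE_PEPTIDE,
    "hinge_protonated_mass_da": round(hinge_mh, 4),
    "internal_standard_mass_da": round(monoisotopic_mass(INTERNAL_STANDARD), 4),
    "oxidation_mz_shift_z1": round(shifts[1], 1),
    "oxidation_mz_shift_z2": round(shifts[2], 1),
    "oxidation_mz_shift_z3": round(shifts[3], 1),
    "iga1_prolines": n_prolines,
    "iga1_target_sites": n_targets,
    "iga1_target_percent": round(100 * n_targets / n_prolines),
}
(out_dir / "peptide_checks.json").write_text(json.dumps(results, indent=1))

print(f"hinge peptide [M+H]+ = {hinge_mh:.4f} Da")
print(f"one oxidation shifts m/z by {shifts[1]:.0f} / {shifts[2]:.0f} / {shifts[3]:.1f} at z=1/2/3")
print(
    f"IgA1 peptide: {n_prolines} prolines, {n_targets} observed target sites "
    f"({100 * n_targets // n_prolines}%)"
)
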