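"""Site-localization round-trips on the four substrate peptides.

For every proline of each substrate, simulates a noiseless MS/MS spectrum
of the singly oxidized positional isomer and re-localizes the site from the
b/y fragment pattern. Writes results/site_localization.tsv.
"""

from pathlib import Path

import pandas as pd

from hypquant import Peptidoform, localize, proline_sites, simulate_msms
from hypquant.peptides import SUBSTRATES

out_dir = Path(__file__).resolve().parents[1] / "results"
out_dir.mkdir(exist_ok=True)

rows = []
for name, seq in SUBSTRATES.items():
    for site in proline_sites(seq):
        pf = Peptidoform.with_fixed_cam(seq, (site,))
        mzs, _ = simulate_msms(pf, noise_cv=0.0, seed=0)
        assignment = localize(mzs, seq, n_ox=1)
        rows.append(
            {
                "substrate": name,
                "true_site": site,
                "assigned_sites": ",".join(map(str, sorted(assignment.sites))),
                "score": assignment.score,
                "ambiguous": assignment.is_ambiguous,
                "recovered": assignment.sites == frozenset({site}),
            }
        )

table = pd.DataFrame(rows)
table.to_csv(out_dir / "site_localization.tsv", sep="\t", index=False)
n_ok = int(table["recovered"].sum())
print(table.to_string(index=False))
print(f"\n{n_ok}/{len(table)} single-site placements recovered exactly")
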