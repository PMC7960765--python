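"""The peptide sequences of the hydroxylation study, as package constants.

Four synthetic substrate peptides cover the O-glycosylated regions of two
human proteins (IgA1 hinge, erythropoietin) and two plant proteins (the
mugwort allergen Art v 1 and Arabidopsis STRUBBELIG). The tryptic
hinge-region peptide is the species quantified in the in-planta experiments;
the threonine-rich peptide serves as internal standard in kinetics assays.
"""

from .peptide_chem import proline_sites

IGA1 = "VTVPVPSTPPTPSPSTPPTPSPS"
EPO = "AQKEAISPPDAASAA"
ARTV1 = "AAGGSPSPPADGGSPPPPADG"
STRUBBELIG = "DGTPFNTSIITPPPPPCCDPPPATHR"

SUBSTRATES = {"IgA1": IGA1, "EPO": EPO, "Art v 1": ARTV1, "STRUBBELIG": STRUBBELIG}

#: tryptic peptide of the IgA1 hinge region (three Cys, carbamidomethylated)
HINGE_PEPTIDE = "HYTNPSQDVTVPCPVPSTPPTPSPSTPPTPSPSCCHPR"

INTERNAL_STANDARD = "PTTTPITTTTTVTPTPTPTGTQTK"

#: IgA1 prolines never found oxidized by any of the four enzymes
IGA1_UNTOUCHED_SITES = (4, 6, 22)

#: IgA1 prolines identified as hydroxylation targets
IGA1_TARGET_SITES = tuple(
    p for p in proline_sites(IGA1) if p not in IGA1_UNTOUCHED_SITES
)
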