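"""Published A1-LCD fit results used as inputs to the residue-energy analysis.

The prion-like low-complexity domain of hnRNPA1 (A1-LCD, 137 residues) and a
panel of composition variants have measured coexistence curves; fitting them
with a shared effective chain length yields per-variant protein-protein
contact energies E = -N * delta_eps and deviations from wild type
dE_variant = E_variant - E_WT.  The values below are the published fit
results for that panel; variant labels follow the +/- nX convention (n
residues of type X added to or removed from WT).

They are *data* for the residue-decomposition workflow in
:mod:`floryfit.fitting`, which re-derives per-residue sticker energies from
them; re-running the underlying global fit itself requires the experimental
measurement tables (see the measurement CSV schema in :mod:`floryfit.io`).
"""

from __future__ import annotations

#: Shared effective chain length from the global fit.
A1_LCD_N = 158.6

#: Wild-type protein-protein contact energy E_WT = -N * delta_eps, kJ/mol.
A1_LCD_E_WT = -251.9

#: Number of amino acid residues in A1-LCD.
A1_LCD_RESIDUES = 137

#: Average molecular weight used for concentration conversion, kDa.
A1_LCD_MW_KDA = 13.1

#: Protein mass density used for concentration conversion, g/cm^3.
PROTEIN_DENSITY_G_CM3 = 1.35

#: dE_variant = E_variant - E_WT in kJ/mol, grouped by variant series.
A1_LCD_DELTA_E = {
    "aromatic": {
        "-12F+12Y": -5.5,
        "-7F-7Y": 7.4,
        "-4F-2Y": 22.0,
    },
    "polar": {
        "+23G-23S": -5.8,
        "-10G+10S": 5.4,
        "-20G+20S": 10.0,
        "-30G+30S": 13.0,
    },
    "ionic": {
        "+7R+12D": -15.5,
        "+7K+12D": 8.0,
        "+12D": 13.0,
    },
}

#: Published per-residue difference dE_Phe - dE_Tyr (kJ/mol) inferred from the
#: first two aromatic-series variants.  Direct algebra on the tabulated dE
#: values gives a different number (see docs/methods.md); the printed value
#: is kept as the input to the downstream Tyr/Phe solve.
ARO_PHE_MINUS_TYR = 0.8
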