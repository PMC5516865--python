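# Default network topology

Independent enumeration of the species and reactions generated by
`build_erbb_network()` with default flags (BTC-bound EGFR routed to ErbB3
only; no BTC:EGFR homodimer or BTC:EGFR:HER2 pairing).

## Species (44)

| class | members | count |
|---|---|---|
| extracellular ligands | HRG, BTC | 2 |
| membrane receptor monomers | EGFR, HER2, ErbB3 | 3 |
| ligand-bound monomers | HRG:ErbB3, BTC:EGFR | 2 |
| cytosolic pools | PI3K, Akt, pAkt | 3 |
| dimers, unphosphorylated | EGFR:EGFR, EGFR:HER2, EGFR:ErbB3, HER2:HER2, HER2:ErbB3, HRG:ErbB3:EGFR, HRG:ErbB3:HER2, BTC:EGFR:ErbB3 | 8 |
| dimers, phosphorylated (`p:` prefix) | one per dimer | 8 |
| endosomal phospho dimers (`@endo`) | one per dimer | 8 |
| PI3K complexes (`:PI3K`) | one per ErbB3-containing phospho dimer (5 of the 8 dimers carry ErbB3) | 5 |
| Akt ternary complexes (`:PI3K:Akt`) | one per PI3K complex | 5 |

ErbB3:ErbB3 homodimers are deliberately absent (kinase-dead pairing); the
constitutive dimer set is exactly {EGFR:EGFR, EGFR:HER2, EGFR:ErbB3,
HER2:HER2, HER2:ErbB3}.

## Reactions (86)

| class | count |
|---|---|
| ligand capture (HRG+ErbB3, BTC+EGFR; reversible) | 2 |
| constitutive dimerization (5 pairs; reversible) | 5 |
| ligand-induced dimerization (HRG:ErbB3 + EGFR/HER2, BTC:EGFR + ErbB3; reversible) | 3 |
| per dimer (x8): phosphorylation, dephosphorylation, internalization, recycling, degradation | 40 |
| per ErbB3-containing phospho dimer (x5): PI3K binding (reversible), Akt binding (reversible), Akt phosphorylation turnover, dephosphorylation of `:PI3K`, dephosphorylation of `:PI3K:Akt`, internalization of `:PI3K`, internalization of `:PI3K:Akt` | 35 |
| p-Akt dephosphorylation | 1 |

Totals: species 2+3+2+3+8+8+8+5+5 = 44; reactions 2+5+3+40+35+1 = 86.

Optional build flags add, per extra BTC dimer (BTC:EGFR:EGFR and/or
BTC:EGFR:HER2): 3 species, 1 dimerization and 5 per-dimer reactions
(these dimers carry no ErbB3, so no adaptor reactions).
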