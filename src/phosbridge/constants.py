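"""Monoisotopic mass constants (Da) used throughout the package.

Atomic masses follow CODATA/IUPAC monoisotopic values; derived group
masses are exact sums, not rounded literature figures.
"""

#: Mass of a proton (charge carrier in positive-mode ESI).
PROTON = 1.00727646688

#: Monoisotopic mass of a hydrogen atom.
H = 1.00782503207

_C = 12.0
_N = 14.0030740048
_O = 15.9949146196
_P = 30.97376163

#: Ammonia, the N-terminal fragment shift c = b + NH3.
NH3 = _N + 3 * H

#: Water, added to residue-mass sums to obtain the neutral peptide mass.
H2O = 2 * H + _O

#: NH2 group; z• = y − NH2 (loss of backbone amide NH plus H transfer).
NH2 = _N + 2 * H

#: CO group; a = b − CO.
CO = _C + _O

#: Phosphorylation delta (HPO3): +79.966331 Da on Ser/Thr/Tyr.
PHOSPHO = H + _P + 3 * _O

#: N-terminal acetylation delta (C2H2O): +42.010565 Da.
ACETYL = 2 * _C + 2 * H + _O

#: Phosphoric acid, the characteristic neutral loss of phosphopeptides.
H3PO4 = 3 * H + _P + 4 * _O

#: Molecular mass of the nitrogen drift gas used in TWIMS.
N2_MASS = 28.00615
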