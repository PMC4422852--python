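"""Salt-bridge vs ionic-hydrogen-bond distance analysis of model structures.

Builds three conformers of APLpSFRGSLPKSYVK with different planted
phosphate contacts and classifies every phosphate/basic-site pair under
the two competing protonation hypotheses: phosphate deprotonated
(salt bridges possible) vs phosphate neutral (ionic hydrogen bonds).
A 'Y' cell means the minimum charged-heavy-atom distance is < 4 A.
"""

import phosbridge as pb
from phosbridge import reference as ref

seq = ref.SEQUENCES["R6pS4"]
planted = [
    ("pS4-K11 bound", [pb.ContactSpec((4, 11), 3.5)]),
    ("no contacts", []),
    ("pS4-R6 and pS4-K15", [pb.ContactSpec((4, 6), 3.2), pb.ContactSpec((4, 15), 3.8)]),
]
structures = []
for i, (name, contacts) in enumerate(planted):
    (s,) = pb.gen_conformers(seq, 1, contacts, seed=100 + i)
    s.label = name
    structures.append(s)

for state in ("deprotonated", "neutral"):
    pattern = ref.protonation_pattern("R6pS4", state)
    mat = pb.interaction_table(structures, pattern)
    print(f"\nhypothesis {pattern.name} (total charge +{pattern.total_charge}):")
    print(mat.to_text())
    kinds = {r.classification for r in mat.records if r.contact}
    print(f"  contact classifications: {sorted(kinds) or ['none']}")
print("\n-> with the phosphate deprotonated, sub-4 A contacts to protonated")
print("   side chains are salt bridges; with it neutral they are ionic")
print("   hydrogen bonds (or plain hydrogen bonds to uncharged partners).")
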