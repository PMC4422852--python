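"""End-to-end: score protonation hypotheses against observed ECD coverage.

Reconstructs the observed fragmentation coverage of APLpSFRGSLPKSYVK
from its published abundances, builds a synthetic conformer ensemble
with a planted pS4-K11 salt bridge and one with no contacts, converts
each ensemble's interaction matrix into predicted suppressed cleavage
sites, and ranks the hypotheses by per-site agreement with experiment.
"""

import phosbridge as pb
from phosbridge import reference as ref
from phosbridge.constants import H3PO4
from phosbridge.fragments import ION_TYPES

pep = pb.build_peptide(ref.SEQUENCES["R6pS4"])
peaks = pb.gen_peaklist(pep, ref.TABLE2_ABUNDANCE["R6pS4"], seed=0)
ions = pb.theoretical_ions(pep, ION_TYPES, (1,), (0.0, H3PO4))
cov = pb.coverage_map(pb.assign_peaks(peaks, ions, 3.0), pep)
observed = sorted(s for s in range(1, pep.length) if cov.count_at(s) > 0)
print(f"observed fragment coverage at sites: {observed}")

pattern = ref.protonation_pattern("R6pS4", "deprotonated")
ensembles = {
    "pS4-K11 salt bridge": pb.gen_conformers(
        ref.SEQUENCES["R6pS4"], 12, [pb.ContactSpec((4, 11), 3.5)], seed=1
    ),
    "no interactions": pb.gen_conformers(ref.SEQUENCES["R6pS4"], 12, seed=2),
}
scores = []
for name, ensemble in ensembles.items():
    mat = pb.interaction_table(ensemble, pattern)
    pred = pb.predict(mat, pep.length, rule="union")
    sc = pb.score(pred, cov)
    sc.hypothesis = name
    print(
        f"\n{name}: suppressed sites {sorted(pred.suppressed) or 'none'}; "
        f"agreement {sc.matches}/{sc.n_sites} = {sc.score:.3f}"
    )
    scores.append(sc)

print("\nranking:")
for s, tied in pb.rank_hypotheses(scores):
    flag = " (tie)" if tied else ""
    print(f"  {s.score:.3f}  {s.hypothesis}{flag}")
print("-> the salt-bridge hypothesis explains the coverage gap; a model")
print("   without the contact predicts fragments that were never observed.")
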