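"""Annotate ECD fragments of a phosphopeptide and locate the coverage gap.

Builds the doubly protonated phosphopeptide APLpSFRGSLPKSYVK, synthesizes
a peak list realizing its published fragment abundances (plus decoy
peaks), assigns peaks to theoretical c/z ions at 3 ppm, and reports the
cleavage-site coverage between the phosphoserine (residue 4) and Lys11.
A fragment count of zero there is the signature of a noncovalent contact
holding the two fragments together through electron capture.
"""

import phosbridge as pb
from phosbridge import reference as ref
from phosbridge.constants import H3PO4
from phosbridge.fragments import ION_TYPES

pep = pb.build_peptide(ref.SEQUENCES["R6pS4"])
print(f"peptide: {ref.SEQUENCES['R6pS4']}  N={pep.length}  M={pep.mass:.4f} Da")

peaks = pb.gen_peaklist(pep, ref.TABLE2_ABUNDANCE["R6pS4"], n_decoys=40, seed=11)
ions = pb.theoretical_ions(pep, ION_TYPES, (1,), (0.0, H3PO4))
assignments = pb.relative_abundance(pb.assign_peaks(peaks, ions, tol_ppm=3.0))

print(f"\n{len(peaks)} peaks, {len(assignments)} assigned:")
for a in sorted(assignments, key=lambda a: a.observed_mz):
    print(
        f"  {a.ion.label:22s} m/z {a.observed_mz:9.4f}  "
        f"{a.relative_abundance:5.2f}%"
    )

cov = pb.coverage_map(assignments, pep)
print(f"\nsite coverage (sites 1..{pep.length - 1}):", [int(c) for c in cov.site_cover])
print("gaps (maximal uncovered runs):", cov.gaps)

rep = pb.gap_between(cov, 4, 11)
print(
    f"\nfragments separating pS4 from K11 (sites {rep.sites[0]}..{rep.sites[-1]}): "
    f"{rep.n_fragments}"
)
print("-> zero means every cleavage between them is suppressed, as expected")
print("   for a contact bridging the phosphate and the Lys11 side chain.")
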