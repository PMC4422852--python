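"""Filter a conformer ensemble to the experimental CCS window and cluster.

Generates a spread-out synthetic ensemble, computes PA CCS for each
member, filters to +/-3% of a target CCS (the median, standing in for
the measured conformer), clusters the survivors by k-means on superposed
coordinates, and reports cluster populations and representatives.
"""

import numpy as np

import phosbridge as pb
from phosbridge import reference as ref

confs = pb.gen_conformers(ref.SEQUENCES["R6pS4"], 30, seed=17, spread=0.2)
ccs_results = pb.batch_ccs(confs, n_orientations=100, seed=2)
ccs = [r.ccs for r in ccs_results]
target = float(np.median(ccs))
print(f"ensemble of {len(confs)}; CCS range {min(ccs):.0f}-{max(ccs):.0f} A^2; "
      f"target {target:.0f} A^2")

cset = pb.ConformerSet(list(zip(confs, ccs)), target_ccs=target, window=0.03)
kept = pb.filter_by_ccs(cset)
print(f"retained within +/-3%: {len(kept)} structures")

clustering = pb.cluster(kept, k=3, seed=0)
print("\ncluster populations (% of filtered structures):")
for cid in pb.top_clusters(clustering, 3):
    print(
        f"  cluster {cid}: {clustering.populations[cid]:5.1f}%  "
        f"representative = {clustering.representatives[cid]}"
    )
print("-> distance analysis runs on the representatives of the most")
print("   populated clusters, as proxies for the conformer families.")
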