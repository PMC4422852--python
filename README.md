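# phosbridge

Tools for rationalizing the electron capture dissociation (ECD) behavior
of doubly protonated phosphopeptides from ion-mobility-filtered
conformer ensembles.

## The problem

ECD of an [M + 2H]²⁺ peptide ion cleaves N–Cα bonds along the backbone,
producing *c*- and *z*-type fragments while leaving labile phosphate
groups in place. For some phosphopeptides, however, whole stretches of
the sequence yield **no** fragments: a noncovalent contact between the
phosphate and a protonated side chain (Arg guanidinium, Lys ammonium)
can hold the two halves together even after the backbone is cleaved, so
no fragment at those sites is ever separated and detected. Whether that
contact is a **salt bridge** (deprotonated phosphate, POₓ⁻, paired with
a protonated side chain) or an **ionic hydrogen bond** (neutral
phosphate, POₓ⁰) cannot be read off the spectrum alone.

phosbridge implements the combined mass-spectrometry / ion-mobility /
structure-modeling workflow that settles the question:

1. **fragments** — theoretical c/c•/z•/z′ ladders, peak assignment at
   ppm tolerance, the relative-abundance statistic
   (100·Iᵢ/ΣI, charge-reduced species included), cleavage-site coverage
   maps and gap reports.
2. **calibration** — traveling-wave ion mobility CCS calibration:
   t′ = t_d − c·√(m/z)/1000, Ω′ = Ω/(z·√(1/m + 1/m_gas)), power-law fit
   ln Ω′ = ln A + X·ln t′; random-coil trendline regression of ln Ω on
   ln M and the percent deviations ΔCCS→RC and ΔCCS→unmod; arrival-time
   peak detection.
3. **ccs** — orientation-averaged projection-approximation CCS of
   atomic structures (seeded Monte Carlo over uniform rotations and
   dart-throwing projected areas), with Monte-Carlo standard errors.
4. **ensemble** — ±3% CCS filtering, Kabsch superposition, seeded
   k-means clustering with populations and centroid representatives.
5. **interactions** — charged heavy-atom identification under a
   protonation hypothesis and the < 4 Å salt-bridge / ionic-H-bond /
   H-bond classification, emitted as Y/N distance matrices.
6. **correlate** — contacts → predicted suppressed cleavage sites
   (a contact between residues a < b suppresses sites a..b−1) →
   per-site agreement score against the observed coverage → hypothesis
   ranking.
7. **synthetic** — seeded generators for every input: coarse-grained
   conformers with planted sub-4 Å contacts, calibrant tables from known
   power laws, peak lists realizing specified abundance tables, and
   Gaussian arrival-time profiles.

The `phosbridge.reference` module carries the published study inputs as
plain data: the six peptide sequences (APLSFRGSLPKSYVK and its Arg6→Leu
analogue, unmodified or phosphorylated at Ser4/Ser12), their fragment
abundance tables, CCS values with trendline deviations, and the
published contact matrices.

## Worked example

`python examples/hypothesis_ranking.py` reconstructs the observed
coverage of APL**pS**FRGSLPK**S**YVK from its published fragment
abundances, builds a synthetic ensemble with a planted pS4–K11 salt
bridge and one without, and scores both against experiment:

```
observed fragment coverage at sites: [2, 3, 11, 12, 13, 14]

pS4-K11 salt bridge: suppressed sites [4, 5, 6, 7, 8, 9, 10]; agreement 13/14 = 0.929

no interactions: suppressed sites none; agreement 6/14 = 0.429

ranking:
  0.929  pS4-K11 salt bridge
  0.429  no interactions
```

The salt-bridge model predicts exactly the observed dead zone between
the phosphoserine and Lys11 (sites 4–10) and agrees at 13 of 14
cleavage sites; a contact-free model cannot explain the gap. The other
examples (`examples/*.py`) walk through fragment annotation, CCS
calibration and trendline deviations, projection CCS, ensemble
filtering/clustering, and the distance analysis one capability at a
time, each printing the numbers it computes.

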