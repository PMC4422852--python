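# Methods

## Scientific model

A doubly protonated phosphopeptide ion that captures a low-energy
electron cleaves an N–Cα backbone bond, giving an N-terminal c (or
radical c•) fragment and a C-terminal z• (or hydrogen-attached z′)
fragment. Noncovalent electrostatic contacts survive the capture event;
if the phosphate group is bound to a basic side chain, every cleavage
*between* the two partners produces pieces that remain tethered and are
detected only as the charge-reduced precursor. The observable
consequence is a contiguous run of cleavage sites with no assigned
fragments. The package's core inference inverts this: candidate 3D
structures, filtered to the experimentally measured collision cross
section and examined for sub-4 Å phosphate contacts under a given
protonation hypothesis, predict a suppressed-site set; the hypothesis
whose prediction best matches the observed coverage is preferred.

Two hypotheses per peptide are modeled, both at net charge +2: a
deprotonated phosphate with three protonated basic sites (salt bridges
possible) and a neutral phosphate with two (ionic hydrogen bonds).
For the Arg-containing peptides the N-terminus is never protonated
(N-acetylated controls behave identically); for the Leu analogues the
N-terminus takes the third proton in the deprotonated pattern.

## Fragment masses and assignment

Residue monoisotopic masses come from pyteomics; ion-species deltas are
the standard ECD conventions, b = Σresidues(1..site),
c = b + NH₃ (17.026549), c• = c − H, y = Σresidues(site+1..N) + H₂O,
z• = y − NH₂ (16.018724), z′ = z• + H, with
m/z = (neutral + z·1.0072765 − loss)/z and H₃PO₄ (97.976896) the only
built-in neutral loss. The complementary-pair identity
c_i + z•_{N−i} = M + NH₃ − NH₂ = M + 1.007825 Da holds for every site
and is checked numerically. The charge-reduced species [M + 2H]⁺• is
treated as M plus two proton masses at charge 1 (the electron mass,
0.00055 Da, is below every tolerance used). Peaks are greedily matched
to the nearest theoretical ion within a ppm tolerance (default 5 ppm,
FT-ICR-appropriate; 3 ppm in the bundled analyses), ties broken by
smallest |ppm| then by ion-type precedence c > c• > z• > z′ > y > b > a.
One peak yields at most one assignment. Relative abundances are percents
of the summed assigned intensity including the charge-reduced species,
so they always total 100.

Cleavage sites are 1-based: site s separates residues s and s+1, an
N-terminal fragment at site s covers site s, a C-terminal fragment of
length j covers site N−j, and a contact between residues a < b
suppresses exactly the sites a..b−1. In printed-table notation the
plain zN rows are read as the even-electron z′ species and zN• as the
radical.

## Reference-table transcription

The bundled abundance tables list only the major fragments, so columns
total 45–72% rather than 100%. Where the flattened source table left
row-to-column membership ambiguous, membership was fixed by the stated
coverage gaps (the pS4 Arg-peptide has no fragments at sites 4–10, the
pS12 Arg-peptide none at sites 6–11) and by the accompanying
observations (the Leu/pS4 peptide shows only z10/z11 in the gap region;
its Arg counterpart's mid-sequence c6–c10 ions reflect the tendency of
Arg-containing fragments to dominate; the Leu/pS12 peptide's c12/c12•
exceed the unmodified analogue's). When a peak list is synthesized from
a table, the unprinted remainder is assigned to the charge-reduced
species; the printed values therefore round-trip exactly through
assignment and the relative-abundance statistic, at the cost of an
inflated charge-reduced abundance that no bundled analysis reads.

## TW-IMS calibration

The standard protocol: EDC flight-time correction
t′ = t_d − c·√(m/z)/1000 (the coefficient c is an instrument constant
and a required input), charge/reduced-mass normalization
Ω′ = Ω/(z·√(1/m + 1/m_gas)) with nitrogen (28.00615 Da) as default
drift gas, and an ordinary least-squares fit of ln Ω′ on ln t′ giving
the power law Ω′ = A·t′^X. The fit is exact on noiseless synthetic
calibrants (round-trip to 1e-9 relative) and, with 1% multiplicative
log-normal drift-time noise at n = 20, recovers the exponent to within
±0.0055 across a 1000-seed sweep (the test suite asserts the
conservative ±0.05 bound). The random-coil trendline is a log-log
regression of CCS on molecular mass — the source describes only "a
regression line", and the power-law form is the field's standard choice.
Deviation percentages are 100·(Ω − Ω_rc(M))/Ω_rc(M); the deviation
relative to the unmodified peptide is the *difference of the two
trendline deviations*, the only reading that reproduces all four
published values (−7.6, −3.8, −6.4, +1.4) from the published trendline
deviations. Which calibrant subset produced the original trendline is
not recorded, so absolute trendline reproduction is out of scope.

Arrival-time profiles are reduced to conformer CCS values with local
maxima detection (scipy `find_peaks`): peaks above 10% of the global
maximum by default, merged below a configurable minimum spacing,
returned in decreasing intensity order.

## Projection-approximation CCS

Trajectory-method CCS requires force-field parameters and long
integrations; this package uses the projection approximation: the CCS
is the orientation-averaged area of the union of atomic disks of radius
(element radius + probe radius). Orientations are seeded uniform random
rotations (normalized quaternions); each projected union area is
estimated by uniform dart throwing over the projected bounding box
(defaults 300 orientations × 512 darts), giving a standard error across
orientations. Atomic radii default to Bondi van-der-Waals values
(H 1.20, C 1.70, N 1.55, O 1.52, P/S 1.80 Å) with a helium probe
(1.0 Å; a nitrogen probe of 1.8 Å is selectable), and an optional
multiplicative scale (default 1.0) accommodates the known PA-vs-TM
offset. Absolute comparability to any published trajectory-method CCS
is *not* claimed — experimental CCS values enter the pipeline as
inputs, never as predictions. Verification uses two independent
references: the analytic single-sphere projection πr², and a two-sphere
dumbbell oracle built from the closed-form two-disk union area
integrated over view angles by adaptive quadrature.

## Ensemble filtering and clustering

Structures are retained when |Ω − Ω_target|/Ω_target ≤ 0.03 (inclusive
bounds, window configurable). Retained structures are rigid-body
superposed (Kabsch/SVD, proper rotation enforced) onto the first
retained structure — a documented, configurable convention — and
clustered by k-means on the flattened coordinates (scikit-learn, seeded
initialization, up to 500 iterations). The original clustering method's
exact variant and its k are not recorded, so k is a parameter.
Populations are percentages of the *filtered* ensemble and each
cluster's representative is the member nearest its coordinate mean.
Because each structure is aligned to the reference independently,
inter-structure distances (and hence representatives) are exactly
invariant only to rigid motion of the whole input, not to the choice of
reference; partitions on well-separated ensembles are stable.

## Distance analysis

"Charged atoms" are resolved to heavy atoms — the ammonium NZ, the
three guanidinium nitrogens NE/NH1/NH2, the backbone N of residue 1,
and the terminal phosphate oxygens (O1P/O2P/O3P or OP1/OP2/OP3) whether
the phosphate is charged or neutral — avoiding any dependence on
hydrogen placement. The group-to-group distance is the minimum over all
cross pairs. Classification uses a strict < 4.0 Å cutoff for every
category (the same cutoff is deliberately kept for ionic and neutral
hydrogen bonds): deprotonated phosphate + charged partner → salt
bridge; neutral phosphate + charged partner → ionic hydrogen bond;
uncharged partner → plain hydrogen bond, reported but by default *not*
counted as suppressing, since such contacts are unlikely to survive
electron capture.

## Hypothesis scoring

The published model-vs-experiment comparison is narrative; this package
formalizes it. Suppressing contacts (salt bridges and ionic hydrogen
bonds by default; the set is configurable) are aggregated over an
ensemble by union (default) or majority rule, and a hypothesis' score
is the fraction of cleavage sites where predicted observability matches
the data (site predicted observable and covered, or predicted
suppressed and empty). Observed coverage counts assigned site-bearing
fragments only. Conformers are weighted equally; intensity-weighted
combination across mobility peaks is left to the caller.

## Synthetic generators

The conformer generator emits a persistent Cα random walk (3.8 Å steps)
carrying the charged pseudo-atom groups, then translates partner groups
so every planted contact's minimum distance is met to ±0.1 Å while all
unplanted phosphate/basic pairs are pushed beyond 6 Å — a clear margin
on both sides of the 4 Å criterion, mirroring the published contact
matrices where Y and N cells are unambiguous. A per-structure chain
scale drawn from 1 ± spread varies the ensemble's CCS. Structures are
written as standard PDB text and re-read with Bio.PDB; generation is
byte-deterministic per seed. What the generator does *not* emulate:
force-field energetics, realistic side-chain geometry, solvent history,
or the tens-of-thousands-of-structures annealing campaigns behind the
published cluster populations (~16/13/10%), which is why those
populations, the absolute experimental CCS values (336–372 Å²) and
replicate t-tests are not reproduction targets — the property suites
cover the corresponding machinery instead. Passing tests therefore
demonstrate the correctness of the measurement, filtering,
classification and scoring logic on structures with known ground truth,
not the realism of any conformational model.

Calibrant sets sample 600–2500 Da, charge 1–3, with CCS on a
literature-style mass power law plus 2% scatter; drift times invert the
calibration relation with optional multiplicative log-normal noise
applied to the corrected drift time. Peak lists place ions at exact
theoretical m/z; decoy peaks are kept ≥ 5 ppm from every theoretical
ion so they can never be assigned at the tolerances in use.

## Numerical choices and problem sizes

Inclusive bounds on the CCS window (|Δ|/target ≤ 0.03 retains the
boundary); strict inequality at the 4 Å contact cutoff (3.99 Å is a
contact, 4.00 Å is not); assignment ties broken by |ppm| then ion-type
precedence; degenerate inputs (empty peak lists, empty filtered sets)
pass through as empty results, while empty structures, all-zero
intensities and sub-minimum calibrant counts raise errors. The bundled
analyses use ensembles of 1–30 structures, 20 calibrants, and
300–1000 Monte-Carlo orientations; these sizes were chosen so that
every statistical margin in the test suite is several times its Monte
Carlo error while the full suite runs in seconds.

## Known limitations

- The projection approximation underestimates large-ion CCS relative to
  trajectory methods; use the scale factor for absolute work.
- The coarse-grained conformer generator is a geometry fixture, not a
  conformational sampler.
- The agreement score treats all cleavage sites and conformers equally;
  no intensity modeling, hydrogen migration, or proton-affinity
  arguments are implemented.
- Calibrant literature CCS values must be supplied by the user; no
  database is bundled.
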