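# Methods

This note documents the models, conventions and numerical choices behind
`loopscan`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Containers and units

Trajectories are ordered frames of a fixed atom table. Coordinates are
stored in nanometres (PDB ångström values are divided by 10 on read) and
times in picoseconds; the default frame spacing is 10 ps. Residue
numbering is the 1-based author numbering of the input and is never
remapped — for the bovine carrier this is the conventional AAC1
numbering (P27 kink, R30 capping arginine, E264 of the domain-3 [DE]G
motif, and so on).

Multi-model PDB is the interchange format: it is plain text, carries
atom identities and per-model coordinates, and round-trips through the
package at PDB precision (0.001 Å, i.e. 10⁻⁴ nm). The reader enforces a
constant atom table across models and reports malformed records with
their line number. Binary trajectory formats are deliberately out of
contract; they can be converted externally.

## Contact occupancy

A residue-pair interaction is specified by two atom groups (backbone
carbonyl `(O)`, backbone amide `(NH)`, or side-chain polar set) and is
in contact in a frame when the minimum Euclidean distance over the
Cartesian product of the groups is **≤ 0.33 nm** (inclusive at the
boundary). Occupancy is the percentage of in-contact frames over the
analysis window; with several parallel trajectories the per-trajectory
occupancies are averaged arithmetically. Interactions with average
occupancy **strictly above 25%** are retained.

Choices worth noting:

* The hydrogen-bond criterion is distance-only between donor and
  acceptor heavy atoms (N/O). No angle term is applied: the analysis is
  defined by a single distance cutoff, and adding a geometric angle
  criterion would change retained sets in ways the cutoff alone does not
  capture. Donors must bear a hydrogen in the residue template table
  (e.g. the proline backbone N is not a donor).
* Salt bridges pair basic side-chain nitrogens (Arg NE/NH1/NH2, Lys NZ)
  with acidic carboxylate oxygens (Asp OD1/OD2, Glu OE1/OE2). Histidine
  is excluded by default.
* The analysis window defaults to the trailing 2 µs of each trajectory
  (the equilibrated part of a multi-microsecond run). For inputs shorter
  than 2 µs the window degrades to the trailing ⅔ of frames, and the
  substitution is logged; desk-scale fixtures in the test suite use this
  fallback.
* Occupancies are reported as integers via round-half-up, matching the
  usual table formatting; full precision is kept internally.
* Pair enumeration screens the regions of interest — pairs within a
  matrix loop, between a loop and its own domain's matrix helix, and
  across domain–domain interfaces — prefiltered by requiring the heavy-
  atom minimum distance to come within 0.6 nm in at least one frame.
  Self-pairs and backbone–backbone pairs of sequence neighbours (i, i+1)
  are excluded as trivial. Classification is a partition: every retained
  record gets exactly one category, and residues not covered by the
  element map fall into `other` with a warning.

## Triplet mapping

The three ~100-residue domains of the carrier fold are aligned in three
rows; a **triplet** is one alignment column, indexed by the residue
number of its domain-1 member. Columns where domain 1 is gapped receive
fractional labels between the neighbouring integer triplets ("between t
and t+1") and are excluded from symmetry summaries, since triplets are
indexed strictly by domain-1 numbering. The alignment is an input, not
hard-coded; `validate_anchors` checks any supplied alignment against
the known anchor columns (27: kink prolines; 30: capping arginines
R30/R139/R236; 37: hydrophobic plug V37/A142/M239; 38: loop N-ends
Q38/D143/Q240; 50: β-turn aromatics Y50/F153/Y250; 65: the [DE]G
glycines G65/G168/G265).

One inconsistency in the published description of the capping arginines
(once given as "R30, R139 and R264", elsewhere consistently R236) is
resolved in favour of R236, which is the residue the alignment anchors
and every other passage support.

`build_triplet_map` needs the first residue number of each domain; these
are taken from a 3-tuple argument or parsed from `>id/start-end` FASTA
headers.

## Motif grammar and element derivation

Patterns are token lists over literals, the wildcard `x`, bracketed
classes, and `π` ("small residue"). The membership of `π` defaults to
{G, A, S, C, T} and is configurable, since "small" has no universally
fixed definition. Scanning reports **all** (possibly overlapping)
matches in ascending order, equivalent to exhaustive per-position
matching; the scanner is validated against an independent
regular-expression oracle. Disambiguation — choosing one instance of
each motif per domain — happens only in `annotate_mcf`, which picks the
hit nearest the motif's expected anchor triplet and warns (never
silently resolves) on ties or missing candidates.

Structural elements are derived per domain as:

* matrix loop = (residue of the plug triplet + 1) … (residue before the
  [YF]xG aromatic),
* matrix helix = [YF]xG aromatic … G of the [DE]G motif.

The plug triplet defaults to 37, the carrier convention. The loop N-end
is taken from the triplet map rather than from a sequence hit of the
full `Px[DE]xx[KR]xRxQxQ` motif, because that motif carries indels in
real carrier domains (the alignment, not the linear sequence, is what
anchors it); the relaxed prefix `Px[DE]xx[KR]` is used to sanity-check
the region, and a missing [YF]xG or [DE]G anchor in any domain is a
hard derivation error listing the missing anchors.

## Geometry

* **θ angle**: the angle at a vertex atom between rays to two reference
  atoms, degrees in [0, 180]; the default spec is Cζ(R236)–Cα(R236)–
  Cα(T232), the orientation of the domain-3 capping-arginine side chain.
  Computed as the arccos of the clipped normalized dot product; invariant
  under rigid transforms.
* **RMSF**: every frame is least-squares superposed (Kabsch, via
  `scipy.spatial.transform.Rotation.align_vectors`) onto a reference
  over a fit group (all Cα by default), then
  RMSF_i = √(mean_t ‖x_i(t) − x̄_i‖²) per selected Cα. The reference is
  the first frame by default, or a two-pass time-mean structure
  (`reference="mean"`). With isotropic per-axis jitter σ on one atom and
  a static fit core, the estimator recovers σ√3; fitting *on* the mobile
  atom absorbs ~1/N of the fluctuation, which is why calibration tests
  superpose on the static core.
* **Minimum-distance series**: per-frame minimum over all heavy atoms or
  side-chain heavy atoms of two residues (or residue groups).

## Family survey

`locate_deg` scans each of three domain windows (normally the matrix-
helix ranges) for `[DE]G`; the instance nearest the window's C-end wins,
and the call is the residue preceding the G (D, E, or `other` with a
warning when the G is anchored by something else or absent). The
exclusion lists default to the four carriers outside the inner
mitochondrial membrane (MTCH1, MTCH2, SLC25A46, PM34) and the three with
a charged residue in the motif's second position (SLC25A47, SLC25A51,
SLC25A52); applying them to a 53-member family retains 46. An entry on
both lists is excluded once with both flags recorded, and no entry is
ever lost (retained + excluded = input). E frequencies are direct
per-domain counts over retained members, optionally stratified by
user-supplied group labels — the grouping of carriers into functional
classes is user input, since no canonical machine-readable grouping
ships with the package.

Position frequency matrices count residues (and gaps separately) per
column; information content is log₂20 − H in bits, with gaps excluded
from the frequency normalisation. The small-sample correction
e(n) = (s−1)/(2·ln2·n) is off by default and available as a flag.

## Synthetic data

The generators define the conditions under which the pipeline is
tested:

* **Contact trajectories.** Each pair's bound/unbound state is a
  stationary two-state Markov (telegraph) process with P(bound) = p and
  lag-1 autocorrelation φ; φ = 0 recovers i.i.d. frames. The telegraph
  model was chosen over i.i.d. frames so that windowing and threshold
  behaviour under temporal correlation is testable; the effective sample
  size n_eff = n(1−φ)/(1+φ) gives the binomial error band
  σ = √(p(1−p)/n_eff) used in calibration tests. Residues are real
  amino-acid types with standard atom names (schematic internal
  geometry), so selection and donor/acceptor logic is exercised
  unchanged. The anchored residue of each pair is static; the partner is
  rigidly placed at the bound (0.25 nm) or unbound (0.45 nm) tip
  distance and displaced by one isotropic Gaussian (σ = 0.02 nm per
  axis) per frame, so the stated separability margin
  (bound + 3σ < 0.33 < unbound − 3σ) is the actual misclassification
  margin. Pairs are spaced 10 nm apart so they cannot cross-contact.
  Generation is fully deterministic from an integer seed (NumPy PCG64,
  no parallelism).
* **Tripartite sequences.** Three gap-free domains (default 60 residues)
  with the canonical motif layout planted at fixed offsets and filler
  drawn from residues that cannot complete any planted motif; the [DE]G
  first residue is set per domain. Families draw each member's [DE]G
  letters as independent Bernoulli(E; p_d) choices. Gapped alignments
  are exercised by the carrier-like fixture below rather than by a
  generator option.
* **Carrier-like fixture** (`synthetic.aac_like`). A synthetic stand-in
  for the bovine carrier: filler is arbitrary, but every residue
  identity and alignment relationship the analyses rely on is honoured,
  including the indel structure the triplet anchors imply (domains 2/3
  carry a four-residue insertion between the kink proline and capping
  arginine; domain 1 is four residues longer between the capping
  arginine and the plug and two longer inside the matrix loop).

What passing these tests shows: the estimators are unbiased and
correctly calibrated on processes with known statistics, the grammar
and mapping machinery is exact, and the pipeline is deterministic. What
they do not show: behaviour on real force-field trajectories (periodic
boundaries, correlated multi-residue motions, protonation effects) or
real carrier sequences with noisy domain boundaries — the fixtures are
whole, imaged, and cleanly separable by construction.

## Problem sizes and determinism

Calibration tests use 10,000-frame trajectories, 20 replicas per
(p, φ) cell on a 5 × 3 grid, 1,000 random 200-mers for the scanner
oracle, and a 500-member family for frequency recovery; these sizes make
the statistical bands tight (sub-percentage-point) while keeping the
whole suite and the acceptance script fast on a single CPU. All
randomness flows from explicit integer seeds; pipeline manifests embed
the full parameterisation plus SHA-256 checksums of every output, and
reruns with the same config are byte-identical.

## Known limitations

* No angle term in the H-bond criterion (by design, see above); no
  water-mediated bridges; no SH–π or π-stacking detection — the SH–π
  stacking between the DCxx[RK] cysteine and the [YF]xG aromatic is a
  structural observation without a published geometric criterion, so the
  package does not invent one.
* The occupancy table printed by one published source contains a row
  (Q38(O):S41(NH), per-trajectory 21/30/13 with "average" 12) whose
  average is arithmetically inconsistent with its entries (mean ≈ 21);
  the package's averaging cannot and does not reproduce that cell.
* Element derivation assumes each domain has exactly one [YF]xG and one
  [DE]G near the expected anchors; heavily diverged family members may
  need explicit element ranges in the run config instead.
* The PDB writer emits a minimal dialect (ATOM/MODEL/ENDMDL/TER-less);
  occupancy/B-factor columns are fixed at 1.00/0.00.
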