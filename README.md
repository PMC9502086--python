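# loopscan

Contact-occupancy and sequence-motif analysis for the tripartite
mitochondrial carrier (SLC25) fold.

Mitochondrial carriers such as the ADP/ATP carrier (AAC) are built from
three homologous ~100-residue domains, each contributing two
transmembrane helices joined by a matrix loop and a short matrix helix.
The matrix side carries a conserved signature,
`Px[DE]xx[KR]xRxQxQ-(loop-helix)-[DE]Gxxxx[YWF][KR]G`, with
`[YF]xGxxDCxx[RK]` on the matrix helix. How symmetric the three copies
of this machinery actually behave — which loop contacts persist, whether
the acidic residue of the [DE]G motif is D or E in each domain, how the
capping arginine orients — is the scientific question this package's
analyses quantify.

`loopscan` is aimed at people analysing molecular-dynamics trajectories
and sequence sets of carrier proteins. It provides:

* **Trajectory analysis** — multi-model PDB input, a selection
  mini-language, per-frame minimum distances, and *contact occupancy*:
  the percentage of analysed frames in which a residue pair's minimum
  donor/acceptor heavy-atom distance is ≤ 0.33 nm (inclusive), measured
  over the trailing window of each trajectory and averaged over parallel
  runs. Interactions with average occupancy strictly above 25% are
  retained and classified as intra-loop, loop–matrix-helix, or
  inter-domain (1–2, 2–3, 3–1).
* **Triplet mapping** — a bidirectional residue ↔ (domain, triplet)
  mapping built from a three-row domain alignment, where a "triplet" is
  an alignment column indexed by its domain-1 residue number (e.g.
  triplet 30 = the capping arginines R30/R139/R236).
* **Motif grammar** — compile/scan patterns made of literals, the
  wildcard `x`, classes `[YF]`, and the small-residue class `π`;
  per-domain annotation by anchor proximity; structural-element
  derivation (matrix loop and matrix helix ranges) from motif anchors.
* **Geometry** — the side-chain orientation angle θ (by default
  Cζ(R236)–Cα(R236)–Cα(T232)), per-residue Cα RMSF after Kabsch
  superposition, and minimum-distance time series.
* **Family survey** — locate the [DE]G motif per domain across a carrier
  family, apply the standard exclusions (carriers outside the inner
  mitochondrial membrane; carriers with a charged residue in the motif's
  second position), and compute per-domain E frequencies; position
  frequency matrices with per-column information content for logos.
* **Synthetic data** — generators for all of the above with known ground
  truth: contact trajectories whose bound/unbound state follows a
  two-state Markov (telegraph) process with prescribed occupancy and
  autocorrelation, and tripartite sequences/families with planted motifs
  and controlled D/E choices.

## Worked example

```python
from loopscan import occupancy
from loopscan.synthetic import (
    ContactPairScenario, ContactScenario, gen_contact_trajectory,
)

scenario = ContactScenario(
    pairs=(ContactPairScenario(p=0.67, phi=0.5),), n_frames=5000, seed=42,
)
traj, truth = gen_contact_trajectory(scenario)
spec = truth.specs[0]
print(spec.label, occupancy(traj, spec, cutoff=0.33))
```

prints

```
R1:E2 67.46
```

i.e. the Arg–Glu salt bridge planted with a 67% duty cycle is measured
at 67.5% occupancy by frame counting at the 0.33 nm cutoff (the realized
duty cycle of this particular seed is 67.5%; the ±1.8 percentage-point
band is the binomial error at the autocorrelation-corrected effective
sample size). The scripts in `examples/` walk through each capability
the same way — triplet mapping, motif annotation and element derivation,
geometry metrics, and the family survey — printing the numbers they
compute and what they mean.

A command-line layer mirrors the library:

```sh
loopscan simulate contacts --pairs 0.67:0.5 --frames 5000 --seed 42 --out traj.pdb
loopscan occupancy traj.pdb --cutoff 0.33 --threshold 25
loopscan theta traj.pdb --atoms 1:NH1,1:CA,2:OE1
loopscan run config.json
```

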