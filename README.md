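# thermofluct

Comparative molecular-dynamics flexibility analysis for homologous proteins
that differ in thermostability — for structural bioinformaticians asking *why*
a hyperthermophilic enzyme stays folded where its mesophilic counterpart
unravels. The motivating system is methylglyoxal synthase (MGS, EC 4.2.3.3):
a hyperthermophilic homolog (*Oceanithermus profundus*), a moderate
thermophile (*Thermus* sp.) and a mesophile (*Clostridioides difficile*)
compared over high-temperature MD trajectories.

The package implements the full comparison as a tested, reusable pipeline:

- **Superposition & drift** — least-squares rigid (Kabsch) superposition and
  per-frame RMSD(t) = √(1/N Σᵢ |R xᵢ(t) + t − xᵢ(ref)|²), the global
  rigidity measure.
- **Per-residue flexibility** — RMSFᵢ = √(⟨|rᵢ − ⟨rᵢ⟩|²⟩) about an iterated
  mean structure after superposing every frame.
- **Common residue numbering** — global multiple alignment (Gotoh affine-gap
  dynamic programming, BLOSUM62, progressive profile merge) assigns each
  homolog's residues to shared alignment columns so per-residue quantities
  are comparable across proteins of different lengths.
- **Fluctuation regions** — the per-column difference
  Δᵢ = RMSFᵢ(mesophile) − mean over thermophiles of RMSFᵢ is thresholded at
  its own average; contiguous above-average runs become Regions I, II, ….
- **Interactions** — salt bridges (Lys/Arg/His vs Asp/Glu side-chain heavy
  atoms ≤ 4.0 Å) and hydrogen bonds (N/O donor–acceptor heavy atoms ≤ 3.5 Å),
  with per-frame distance traces, occupancy (fraction of frames in contact)
  and an SB / HB / NI classification per homolog on the common numbering.

Because real production trajectories are rarely shareable, the package ships
a first-class synthetic generator: coarse two-atoms-per-residue structures,
trajectories with planted per-residue fluctuation amplitudes, global
rigid-body frame noise and planted two-state contacts with known occupancy —
ground truth for every downstream stage.

## Worked example

Generate the default synthetic study set (three homologs, 1,000 frames at
400 ps ≙ 400 ns, 358 K metadata) and run the full analysis:

```sh
thermofluct generate --out demo --seed 1
thermofluct analyze --config demo/analysis_config.yaml
thermofluct report --run demo/analysis
```

prints

```text
pairwise identity (%): {"hyperMGS|thermoMGS": 81.6, "hyperMGS|mesoMGS": 50.4, "thermoMGS|mesoMGS": 42.4}
mean RMSD (A): {"hyperMGS": 0.429, "thermoMGS": 0.6022, "mesoMGS": 1.1861}
mean RMSF (A): {"hyperMGS": 0.4291, "thermoMGS": 0.6022, "mesoMGS": 1.1243}
mean RMSF difference (A): 0.5806
region I: columns 10-27 (mean delta 1.0243 A)
region II: columns 34-41 (mean delta 1.0257 A)
region III: columns 78-91 (mean delta 1.031 A)
region IV: columns 103-112 (mean delta 1.0188 A)
interaction rows: 341
```

Reading this: the hyperthermophile is the most rigid (lowest mean RMSD), the
mesophile the floppiest, and the four planted high-fluctuation regions of the
mesophile are recovered as Regions I–IV on the common numbering. The
interaction table (`demo/analysis/interaction_comparison.csv`) shows rows
such as

```text
common_pair,kind,...           hyper            thermo           meso
12-82,SB,  K12-D82 0.906 SB   K12-D82 0.616 SB   M12-D82  NI
81-90,SB,  R81-E90 0.855 SB   R81-E90   NI       R81-E90 0.612 SB
```

i.e. the K12–D82 salt bridge is occupied in both thermophiles but impossible
in the mesophile (lysine replaced by methionine → NI), while the R81–E90
bridge is missing in the middle thermophile only. All stage outputs are
plain CSV / FASTA / interval text under the run's output directory, plus a
`report.json` with provenance (config echo, seeds, versions).

The same functionality is available as a library; see
`thermofluct.superpose`, `thermofluct.mapping`, `thermofluct.regions`,
`thermofluct.interactions`, `thermofluct.synthetic` and
`thermofluct.pipeline`. Model details, parameter defaults and estimator
caveats are documented in [docs/methods.md](docs/methods.md).

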