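# allores

Per-amino-acid-residue identification of allosteric-site-forming residues
(AFRs) from holo/apo protein structure pairs.

The pipeline:

1. **Label** — residues within 5 Å (heavy-atom minimum distance) of a bound
   modulator are AFRs; everything else is a free residue (FR). The loss of
   accessible surface area on complex formation (LASA = ASA_apo −
   ASA_complex, deterministic golden-spiral Shrake–Rupley) is computed and
   stored per residue. When no apo structure exists, one is derived by
   stripping the modulator group.
2. **Describe** — a per-residue internal-nanoenvironment descriptor panel:
   relative accessibility, distance to the chain's centre of geometry, void
   ("sponge") fraction, neighbourhood hydrophobicity, Coulomb electrostatic
   potential, Kabsch–Sander backbone H-bond donor/acceptor energies, and
   contact-graph eccentricity and betweenness ("bottleneck").
3. **Select** — greedy Pearson-correlation pruning (|ρ| ≤ 0.7) followed by a
   two-sample Kolmogorov–Smirnov filter comparing AFR vs FR distributions.
4. **Train** — one weighted gradient-boosted classifier per canonical
   residue type, with the positive class up-weighted by the FR/AFR ratio.
5. **Evaluate** — chain-centric train/validation/test splitting, site-level
   DCC (distance between predicted- and true-site centroids, success at
   ≤ 4 Å) with explicit N/A policies, residue-level confusion-matrix
   metrics, and pocket-coverage auditing against externally supplied
   pocket residue lists.

A synthetic-data module generates ideal α-helix fixtures with a planted
rigid modulator at a controlled gap (exact ground truth by construction)
and Gaussian descriptor tables with configurable shift/imbalance, so the
entire pipeline is testable offline.

## CLI

```sh
allores simulate fixtures/ --n-fixtures 15 --seed 0   # synthetic holo PDBs + labels
allores label holo.pdb --out labels.tsv               # AFR/FR + LASA per residue
allores describe labels.tsv apo.pdb --out desc.tsv    # descriptor table
allores select desc.tsv --rho-max 0.7 --alpha 0.05    # feature manifest
allores split labels.tsv --fractions 0.5,0.25,0.25    # chain-centric split
allores train config.yaml --seed 1                    # full training workflow
allores predict run/ensemble desc.tsv                 # per-residue probabilities
allores evaluate config.yaml run/ensemble             # DCC + metrics report
allores pockets-coverage labels.tsv pockets.tsv       # AFR-in-pocket audit
```

`train`/`evaluate` read a YAML run configuration, e.g.

```yaml
structures:
  - {holo: fixtures/HX024S0000.pdb}        # apo/modulator optional per entry
split_fractions: [0.5, 0.25, 0.25]
split_seed: 0
selection: {rho_max: 0.7, alpha: 0.05}
model: {scale_pos_weight: auto, seed: 0}
nanoenv: {n_points: 960}
output_dir: run
```

Exit code 2 signals a contract violation (bad input, unmet precondition).

## Layout

```
src/allores/
  structures.py   PDB/mmCIF I/O (biotite), geometry primitives
  sasa.py         Shrake–Rupley accessible surface area
  labeling.py     LASA + AFR/FR labeling, dataset assembly
  nanoenv.py      descriptor panel + descriptor table
  selection.py    correlation pruning, KS filter, Q-Q export
  models.py       per-residue-type weighted boosted classifiers
  evaluation.py   splits, DCC, metrics, pocket coverage
  synthetic.py    helix fixtures, modulator planting, synthetic tables
  pipeline.py     orchestration, provenance, config
  cli.py          typer CLI
```
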