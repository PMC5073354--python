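# allopath

Structural-dynamics toolkit for dissecting direct (active-site) and indirect
(metal-exosite, allosteric) protease inhibition, built around the KLK4 /
SFTI-1 case study:

- **`structio`** — PDB structure/ensemble I/O (multi-model files as
  conformational ensembles), altloc policies, atom selections, Kabsch
  superposition, RMSD, average/normalized B-factors.
- **`interface`** — Shrake–Rupley solvent-accessible surface area (1.4 Å
  probe by default), per-residue buried area and percent burial across a
  chain partition, geometric hydrogen-bond (≤ 3.5 Å, antecedent angle ≥ 90°)
  and salt-bridge (≤ 4.0 Å) detection. All criteria are config-exposed and
  echoed with every count.
- **`ensemble_compare`** — ligand-induced conformational-change detection:
  per-residue Cα deviation profiles after global backbone alignment, maximal
  segments of ≥ 3 consecutive residues deviating > 0.5 Å, and a two-tailed
  Welch t-test against a third (unliganded-active-site) structure to call
  segments ligand-associated / shared / indeterminate. Also per-residue
  ensemble RMSF.
- **`modes`** — Cα anisotropic elastic-network normal modes (15 Å cutoff),
  atomic fluctuations, inverse-eigenvalue variance fractions, projection of
  ensembles onto low-frequency modes (numbering includes the six rigid-body
  modes, so the first internal mode is mode 7), per-mode population-shift
  statistics, and mode-reconstructed dynamical cross-correlation matrices.
- **`frustration`** — decoy-based mutational local frustration: per-contact
  z-scores against randomized residue identities, minimal / neutral / high
  classification (+0.78 / −1.0 thresholds), and shortest-path search through
  the graph of highly frustrated contacts between two sites (e.g. exosite →
  catalytic triad). Ships a simple deterministic 20×20 pair potential; larger
  index = more favorable native pair than decoys.
- **`clash`** — grafting of a reference-complex ligand onto every frame of a
  receptor ensemble by receptor superposition, van-der-Waals overlap
  screening (≥ 0.4 Å) with a native-contact whitelist, and clash
  timecourses.
- **`synthetic_data`** — seed-deterministic fixture generators (ideal
  helices, planted deviation triples, mode-displaced ensembles, interface
  complexes with known bonds, frustration toys, clash trajectories), each
  emitting a machine-readable planted-truth record.
- **`pipeline`** — declarative YAML config with validated defaults, staged
  orchestration with partial-failure reporting, and site-to-site distances.
- **`klk4`** — the case-study measurements (interface RMSDs, bond counts,
  burial shares, exosite distance, residue displacements, B-factor and
  mode-variance summaries) used by the acceptance report.

## CLI

```bash
allopath rmsd --mobile a.pdb --target b.pdb --select backbone
allopath interface --pdb complex.pdb --side-a "chain A" --side-b "chain I" --probe 1.4
allopath compare --query holo.pdb --ref reference.pdb --third apo.pdb
allopath modes --pdb apo.pdb --cutoff 15 --n-modes 100
allopath project --ensemble traj.pdb --pdb apo.pdb --modes 7-11
allopath dcc --pdb apo.pdb --n-modes 100
allopath frustration --pdb apo.pdb --site-a "25,77" --site-b "57,102,195" --seed 1
allopath clash --ensemble traj.pdb --complex complex.pdb --overlap 0.4
allopath fixtures --kind mode_ensemble --seed 1 --out fixtures/
allopath run --config run.yaml
```

Ensembles are exchanged as multi-model PDB files. All outputs are
tab-separated tables suitable for plotting or molecular-graphics coloring.

## Notes on model substitutions

- Normal modes use a Cα elastic network (ANM) instead of all-atom
  force-field modes; variance fractions are therefore approximate targets.
- The frustration energy is a shipped simplified statistical potential
  (additive hydropathy + charge product with a smooth distance switch), not
  a transferable force field; the decoy/z-score machinery and the
  classification logic are the point, and they are exact.
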