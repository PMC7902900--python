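# mdpost

Post-simulation analysis of molecular-dynamics trajectories, built for
studies of small GTPase systems (Ras–GAP/SOS/Raf-style complexes) but
applicable to any protein trajectory. One package covers the four analysis
families such studies chain together:

* **Geometry & statistics** — Kabsch superposition and RMSD/RMSF,
  distance/angle series with histograms, SASA (Shrake–Rupley), residue-pair
  contact and salt-bridge persistence, Welch's t-test.
* **Free-energy landscapes** — 2D potential of mean force over collective
  variables, G = −k_B T ln(n/n_max), with basin segmentation and
  average-linkage conformational clustering with medoid representatives.
* **MM/PBSA energetics** — single-trajectory binding free energies
  ΔG_bind = ΔE_vdW + ΔE_ele + ΔE_PB + ΔE_nonpolar (entropy omitted), with a
  finite-difference Poisson–Boltzmann solver, the γ·SASA + b nonpolar model
  (γ = 0.00542 kcal·mol⁻¹·Å⁻², b = 0.92 kcal/mol), and per-residue
  decomposition whose rows sum exactly to the totals.
* **Allosteric networks** — dynamic cross-correlation matrices
  C_ij = ⟨Δr_i·Δr_j⟩/√(⟨Δr_i²⟩⟨Δr_j²⟩), residue networks gated by the
  4.5 Å / 75% contact-persistence rule with edge weights d_ij = −ln|C_ij|,
  Girvan–Newman communities with intercommunity connectivity, and
  optimal/suboptimal path enumeration (Floyd–Warshall + pruned DFS).

Because microsecond MD is not reproducible on a desktop, the package ships
a first-class synthetic-data module: Gaussian trajectories with prescribed
correlation structure, multi-basin collective-variable series with
prescribed occupancies, contact schedules with *exact* per-pair contact
fractions, and parameterised toy complexes. Every analysis stage is tested
against these known-truth generators or against closed-form/brute-force
oracles.

## Worked example: binding energetics of a toy complex

```python
import numpy as np
import mdpost as mp

spec = mp.SyntheticSpec(
    chain_layout=[("A", 2), ("B", 1)], n_residues=3,
    charges=np.array([0.5, -0.5, 0.3]), seed=0,
)
top = mp.build_toy_system(spec)
traj = mp.Trajectory(top, np.array([[[0.0, 0, 0], [4.0, 0, 0], [2.0, 4.0, 0]]]))

report = mp.mmpbsa_binding(
    traj,
    receptor_sel=top.select("chain A"),
    ligand_sel=top.select("chain B"),
    grid=mp.PBGridSpec(spacing=0.5, padding=8.0),
    frame_stride=1,
)
print(report.summary().to_string(index=False))
```

```
  component      mean  std
     dE_vdw -0.124650  0.0
     dE_ele  0.000000  0.0
      dE_PB  0.013057  0.0
dE_nonpolar -1.284677  0.0
      dE_MM -0.124650  0.0
    dG_solv -1.271620  0.0
 dG_binding -1.396270  0.0
```

Reading the table (all kcal/mol): the receptor–ligand van der Waals
attraction is −0.125; the electrostatic cross term cancels because the
receptor charges are ±0.5 at equal distance from the ligand; desolvation
(ΔE_PB) mildly opposes binding; the nonpolar term is dominated by the
buried surface area plus the model's constant offset. ΔG_binding is the
exact sum ΔE_MM + ΔG_solv — an identity the test suite checks to 1e−10 —
and ΔE_int is structurally zero because receptor and ligand conformations
are cut from the complex frames.

A network example with programmed ground truth — a residue pair in contact
in exactly 750 of 1000 frames sits right on the persistence threshold and
receives an edge of weight −ln 0.5 ≈ 0.693:

```python
top = mp.build_toy_system(mp.SyntheticSpec(n_residues=4, seed=0))
traj, truth = mp.sample_contact_schedule(
    top, {(("A", 1), ("A", 3)): 0.75}, contact_distance=4.4,
    n_frames=1000, seed=1)
c = np.full((4, 4), 0.5); np.fill_diagonal(c, 1.0)
net = mp.build_network(traj, mp.CorrelationMatrix(c, [("A", i) for i in range(1, 5)]))
print(list(net.graph.edges(data="weight")))   # [(0, 2, 0.6931471805599453)]
```

## Pipeline

Multi-stage, multi-system runs are driven by one YAML config:

```bash
mdpost run --config config.yaml --seed 7 --outdir out
```

with paired "unmodified"/"modified" systems, per-stage parameter blocks,
deterministic per-stage seeds, and a machine-readable `summary.json`
enumerating every artifact. See `mdpost.pipeline.PipelineConfig`.

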