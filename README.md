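# e2dyn — conformational-ensemble analysis of Cdc34-like E2 enzymes

Cdc34-like E2 ubiquitin-conjugating enzymes carry a 12-residue acidic
insertion (residues 103–114 of yeast Cdc34) in the β4α2 loop next to the
catalytic cysteine C95.  The loop acts as a lid: in its **closed**
conformations it occludes the catalytic cleft, in **open** conformations
the cysteine becomes solvent-accessible and competent for ubiquitin
charging; CK2 phosphorylation of S130/S167 shifts the balance toward
open.  `e2dyn` implements the complete analysis pipeline used to
characterise this switch from conformational ensembles, plus the
sequence-level co-conservation scan of the phospho-sites and the loop —
driven by a synthetic-ensemble generator so every stage is testable
without access to the original µs-scale trajectories.

The pipeline stages, each an importable module under `src/e2dyn/` and a
numbered driver under `analysis/`:

1. **Convergence** (`convergence`) — RMSD series vs. the starting
   structure, plateau-based equilibration cuts, macro-trajectory
   assembly, per-residue Cα RMSF
   (rmsf_i = √⟨|r_i − ⟨r_i⟩|²⟩), and cross-replica consistency
   (pairwise Pearson r > 0.6).
2. **Essential dynamics** (`essential_dynamics`) — PCA of the Cα
   covariance matrix C = ⟨Δx Δxᵀ⟩, explained-variance fractions,
   cosine-content sampling diagnostics, and the free-energy landscape
   ΔG(PC1, PC2) = −kT ln(n/n_max) in kJ/mol.
3. **Ensembles** (`ensembles`) — RMSD-cutoff (GROMOS-style
   neighbor-count) clustering, free-energy basin extraction by
   watershed, and their integration into labeled conformational
   ensembles (A, B, C, …).
4. **Cleft geometry** (`cleft_geometry`) — Shrake–Rupley SASA of the
   catalytic cysteine side chain, loop–cysteine center-of-mass distance,
   open/closed classification and the joint d–SAS profile.
5. **Conservation** (`conservation`) — phospho-site S/T and CK2
   acidic-consensus D/E conservation at mapped alignment columns,
   acidic-insertion detection, global pairwise identity.

`structio` provides the ensemble container, multi-model PDB I/O and
Kabsch superposition; `synthetic` generates study-condition ensembles
(five metastable loop states, phospho-like and Δ-loop variants);
`pipeline` orchestrates everything from a TOML config into a validated
JSON report.  Scientific background, defaults and design choices are in
[docs/methods.md](docs/methods.md).

## Worked example

Four seeded replicas of the wild-type-like system, equilibration cuts,
macro-trajectory PCA, and ensemble integration:

```python
from e2dyn.structio import select_atoms
from e2dyn.synthetic import preset_spec, preset_region, generate_replicas
from e2dyn.convergence import (rmsd_series, detect_equilibration,
                               build_macrotrajectory, rmsf_profile, rmsf_consistency)
from e2dyn.essential_dynamics import fit_pca, project, explained_fraction, build_fel
from e2dyn.ensembles import gromos_cluster, find_basins, integrate_ensembles

spec, region = preset_spec("cdc34_like"), preset_region("cdc34_like")
replicas = generate_replicas(spec, 4, base_seed=0)          # seeds 1-4
fit = select_atoms(replicas[0], residues=region.fit_ranges(), atom_names={"CA"})
cuts = [detect_equilibration(rmsd_series(r, 0, fit, fit)).cut for r in replicas]
macro = build_macrotrajectory(replicas, cuts)

ca = select_atoms(macro, atom_names={"CA"})
model = fit_pca(macro, ca)
print(f"first 3 PCs: {100 * explained_fraction(model, 3):.1f}% of total motion")

p2 = project(macro, model, 2)
fel = build_fel(p2)
basins = find_basins(fel, depth_cut=2 * fel.kT)
sub = macro.subset_frames(slice(None, None, macro.n_frames // 300))
clusters = gromos_cluster(sub, selection=ca, cutoff=1.0)
labels = integrate_ensembles(clusters, basins, p2[::macro.n_frames // 300], fel)
print(f"{labels.n_labels} ensembles, congruence {labels.congruence:.3f}")
```

Output:

```
first 3 PCs: 84.0% of total motion
5 ensembles, congruence 0.984
```

84 % of the Cα positional variance in three components reflects the
dominance of the designed loop motions (the bound of interest is 60 %);
the five ensembles A–E are the five metastable loop states, recovered
congruently by clustering and by the free-energy basins.  Running the
numbered drivers (`python analysis/01_generate_ensembles.py` … `06`)
reproduces the full narrative: equilibration at ~1.7 ns of each 20 ns
replica, RMSF consistency r ≈ 1.0 with the loop at ~5 Å RMSF vs. ~0.5 Å
elsewhere, ensembles A–E spanning loop–cysteine distances 5.0→17.9 Å,
accessibility rising with loop distance (d–SAS r ≈ 0.87), the
phospho-like variant open-shifted (open fraction 0.92 vs. 0.46) and more
exposed (avSAS 64.5 % vs. 53.4 %), and the toy family scan showing
phospho-site/insertion co-occurrence.  Tables land under `results/`.

The full pipeline can also run from a config:

```sh
python -m e2dyn config.toml --seed 1 --out results/run
```

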