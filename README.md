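# structscope

Geometric analysis of protein–protein complexes, built around the kind of
question raised by disease variants such as the Gβ₁ L95P substitution in
GNB1 encephalopathy: *is a residue part of a complex interface, what does it
touch, what happens to those contacts when it is mutated, which docked poses
of a membrane-protein complex are geometrically plausible, and is a
predicted ΔΔG large enough to matter?*

The package provides five analysis stages behind one importable API and a
thin `structscope` CLI:

1. **Interface & contact environments** — a residue pair is in contact when
   its minimum heavy-atom distance is ≤ 5.5 Å (the PRODIGY-style interface
   convention). `interface()` lists interface residues between two chain
   groups; `residue_environment()` lists everything within the cutoff of a
   focal residue, sorted by distance.
2. **Residue interaction networks** — `build_network()` classifies every
   environment pair into one non-covalent kind by precedence
   (`ionic > hbond > hydrophobic > vdw > generic`) with user-editable
   geometric thresholds.
3. **Point mutants** — `substitute_residue()` performs a rigid-template
   substitution: backbone (and shared CB) coordinates are kept bit-exactly,
   the new side chain is grown from ideal internal coordinates. There is
   deliberately *no* rotamer search or energy minimisation; WT/mutant
   contact comparisons are rigid-template estimates.
4. **Docked-pose triage** — after Kabsch superposition onto a
   membrane-embedded reference (leaflets as z-planes, OPM convention,
   inferable from DUM pseudo-atoms), a pose is excluded if any ligand atom
   lies above the lower leaflet, or if the γ-chain C-terminal Cα is more
   than 30 Å below it (the geranylgeranyl-anchor argument).
   `select_models()` picks the largest-cluster and best-score centroids.
5. **ΔΔG classification** — `classify()` labels |ΔΔG| against a
   1.0 kcal/mol significance threshold and a 0.6 kcal/mol noise threshold
   (≈ RT at 25 °C); `kd_fold_change()` converts a binding ΔΔG to the implied
   dissociation-constant fold change, exp(|ΔΔG|/RT).

A seeded synthetic-fixture generator (`make_complex`, `make_pose_ensemble`,
`make_ddg_table`) plants known contacts, verdicts and classes alongside its
outputs, so the whole pipeline is testable offline against ground truth.

## Worked example

```sh
python examples/03_point_mutation_delta.py
```

```
wild-type environment of A:5: 7 residues
mutant (Leu->Pro) environment:   3 residues
retained: 3, lost: 4, gained: 0
lost residues: B:4, B:5, B:6, B:7
```

The fixture plants seven cross-chain contacts around a focal leucine, four
of them anchored on the side-chain tip. After the rigid Leu→Pro
substitution the tip atoms are gone, those four partners fall outside the
5.5 Å environment, and the three backbone-anchored contacts survive
unchanged — the contact-loss signature expected when a leucine in a packed
environment is replaced by proline.

Other examples: `01_interface_contacts.py`, `02_interaction_network.py`,
`04_pose_triage.py` (40-pose triage: 20 retained, 12 excluded above the
leaflet, 8 with the γ anchor too deep), `05_ddg_classification.py`
(RT = 0.5925 kcal/mol, 1 kcal/mol ≈ 5.4-fold Kd change).

The same stages are scriptable from the shell:

```sh
structscope simulate complex --seed 11 --out fixture/
structscope environment --model fixture/complex.pdb --focal A:5 --out env.tsv
structscope mutate --model fixture/complex.pdb --mut A:5:LEU>PRO --out mutant.pdb
structscope ddg-report --in ddg.tsv --out classified.tsv
```

## Scope

Docking itself, ΔΔG prediction, homology modelling, membrane embedding and
conservation scoring are out of scope: poses, ΔΔG tables and membrane
frames are consumed as inputs in documented TSV/PDB formats. See
`docs/methods.md` for the model, parameter and design details.
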