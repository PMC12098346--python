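# Methods

## Contact model

All distance criteria operate on heavy atoms (hydrogens and waters are
parsed and flagged, but excluded by default; non-water hetero groups are
also excluded because the analyses count amino acids). The distance between
two residues is the minimum Euclidean distance over their heavy-atom pairs.
A pair is a *contact* when that minimum is **≤ 5.5 Å** — the comparison is
inclusive, matching the "5.5 Å and below" interface convention popularised
by PRODIGY, and roughly the upper length of a non-covalent interaction.

An *interface residue* of partition (A, B) is any residue of A with at
least one contact to B (and vice versa); a *residue environment* is the
list of all residues in contact with a focal residue, reported with exact
minimum distances and sorted by (distance, residue key) so reports are
reproducible. Sequence neighbours (i±1) are included in environments by
default — nothing in the contact definition excludes them — with a flag to
drop them. Residues are addressed by author numbering
(chain : number : insertion code), because that is how positions like
"Gβ L95" are named in practice; mmCIF label numbering is mapped on read.

Neighbour search uses a k-d tree (`scipy.spatial.cKDTree`) over atom
coordinates with the cutoff as query radius. Its output is held equal to an
all-pairs brute-force oracle in the test suite and the acceptance script
(100 seeded fixtures, zero tolerated mismatches).

### Parsing choices

* Altloc resolution: one conformer per atom name — highest occupancy, ties
  broken by the lexicographically smallest altloc letter. Resolution never
  changes the residue count, only the atom set.
* Multi-model files: first model only, with a warning.
* Writing is fixed-column PDB (3-decimal coordinates); round-trips preserve
  residue keys exactly and coordinates to 10⁻³ Å. Residue numbers outside
  [-999, 9999] are refused rather than silently truncated.

## Interaction network

Within a focal environment, every residue pair is classified into at most
one interaction kind by fixed precedence — **ionic > hbond > hydrophobic >
vdw > generic** — using geometric rules only:

| kind | rule | default cutoff |
|---|---|---|
| ionic | side-chain charged N/O of (Arg, Lys, His) vs (Asp, Glu) | 4.0 Å |
| hbond | donor-capable N/O vs acceptor-capable N/O | 3.5 Å |
| hydrophobic | side-chain carbons of two apolar residues | 5.0 Å |
| vdw | any heavy-atom pair | Σ vdW radii + 0.5 Å |
| generic | any heavy-atom pair | 5.5 Å |

His is treated as chargeable by default (flag to disable). Because the
pipeline runs on heavy atoms, the default hbond rule has no angle term;
distance-only donor/acceptor capability tables stand in for explicit
hydrogen geometry. The thresholds are conventional values, editable through
a YAML rule table that is echoed into run metadata — reproducibility of
*this* pipeline's edges is the goal, not byte-matching any particular
external network server, whose exact thresholds are not published alongside
their figures. π-stacking and cation-π detection are not implemented
(they need ring-geometry machinery; the rule table is the extension point).

Classification is symmetric and deterministic; edge endpoints are reported
in canonical key order. Every edge is also a ≤ 5.5 Å contact pair, and
per-kind counts are invariant under rigid transformation of the structure
(both properties are tested).

## Rigid-template mutagenesis

`substitute_residue` replaces one residue in place:

* N, CA, C, O (and OXT) keep their original coordinates **bit-exactly**;
  CB is inherited when both source and target have one, rebuilt from the
  template when the source is Gly, and dropped for Gly targets.
* The remaining side chain is grown atom-by-atom from ideal internal
  coordinates (bond length, bond angle, torsion — NeRF construction) in the
  local backbone frame. Chains are extended (χ = 180°) with ±60° branches;
  rings are planar idealisations. The CB torsion (+122.686° over C–N–CA)
  fixes L-chirality.
* The proline ring's two free torsions were solved once for ring closure
  (CD–N = 1.474 Å) and frozen into the template (χ₁ = −0.894°,
  χ₂ = +15.552°); the backbone φ is not adjusted.

There is **no rotamer search, repacking or minimisation** — the builder is
a declared simplified stand-in for an energy-minimising mutation protocol.
Consequences: mutant side-chain coordinates are not predictions of the
relaxed structure, and WT/mutant contact deltas are rigid-template
estimates (stated in run reports). `clash_report` (heavy-atom pairs under
2.5 Å, peptide-bond partners excepted) is the sanity check that replaces an
energy term. The wild type and mutant pass through the identical
interface/environment/network code path, so any difference in the report is
purely a data difference.

## Membrane-geometry pose triage

The membrane is a pair of z-planes with +z toward the extracellular side
(OPM convention). The frame is either given explicitly or inferred from
DUM pseudo-atom layers in the reference file (each leaflet = mean z of its
layer, layers split at the overall midpoint). Each pose is first rigidly
superposed onto the reference by matched receptor Cα atoms (Kabsch via
SVD; fewer than 3 pairs or a collinear selection is an error). The RMSD is
recomputed from residuals rather than the closed-form rssd, which cancels
catastrophically for near-perfect alignments of large coordinates.

Two conjunctive exclusion rules follow, both strict at the boundary,
mirroring the wording they encode ("above", "more than 30 Å"):

1. any ligand heavy atom with z > z_lower → `atom_above_lower_leaflet`;
2. z_lower − z(γ C-terminal Cα) > 30 Å → `gamma_cterm_too_far`.

"Above the lower leaflet" is read as *toward the membrane interior from the
cytoplasmic side*, consistent with a cytosolic ligand whose γ-subunit lipid
anchor must reach the inner leaflet; the convention is recorded in run
metadata and the frame can be mirrored (`MembraneFrame.flipped()`) for
structures embedded the other way. Distances to leaflets are signed plane
distances along z, not 3-D slab distances, because the leaflets are defined
as planes. The γ C-terminus is the Cα of the highest-(number, icode)
residue of the γ chain.

Both metrics are always reported for every pose; unreadable pose files
become error verdicts and the run continues. The retained set does not
depend on rule order (the rules are conjunctive); reason reporting uses the
fixed order above. From the retained centroids, the largest-cluster and
best-(lowest)-score models are selected; ties break toward lower score,
then lower cluster id, and the selection is input-order invariant.
Filtering whatever set it is given (all models vs centroids only) is the
caller's choice and is documented per run. Cluster assignments and scores
are inputs (documented TSV; a lenient ClusPro-style `cluster.scores` reader
is provided as an adapter) — no docking or clustering is performed here.

## ΔΔG classification

ΔΔG values are inputs (e.g. from a structure-based predictor); the module
classifies magnitudes and converts units:

* RT = R·T with R = 1.9872042586×10⁻³ kcal/(mol·K); 25 °C is mapped to
  298.15 K exactly, giving RT ≈ 0.5925 kcal/mol (the conventional
  0.6 kcal/mol noise threshold).
* |ΔΔG| > 1.0 kcal/mol → `significant` (strict: exactly 1.0 is not);
  0.6 < |ΔΔG| ≤ 1.0 → `above_noise`; |ΔΔG| ≤ 0.6 → `within_noise`.
* Kd fold change = exp(|ΔΔG|/RT) ≥ 1, multiplicative in ΔΔG;
  1 kcal/mol ↦ ≈ 5.41 (the usual "~5-fold" statement).

Classification uses the magnitude; the sign (destabilising vs stabilising)
is carried in a separate column. Non-numeric rows become row-level errors
without stopping the batch, and output ordering is deterministic.

## Synthetic fixtures

The generator builds what the analyses need, with truth planted by
construction rather than measured after the fact:

* **Complex** (`make_complex`): chain A is a widely spaced (18 Å rise)
  poly-Ala arc with a fully built focal leucine at its centre; chain B
  residues are slid along chosen directions until their minimum distance to
  the focal residue equals the planted contact distance (default 5.0 Å) to
  within 10⁻⁶, while all other cross-chain pairs stay beyond 8 Å. Contacts
  that should *survive* a Leu→Pro approach from the backbone side; contacts
  that should *vanish* extend past the side-chain tip, directly away from
  CB. Because the mutant builder is deterministic, the generator verifies
  the post-mutation geometry exactly (against the ideal proline ring) and
  raises on any violated margin instead of emitting a wrong truth. The wide
  inter-residue spacing is what makes planted distances controllable with
  multi-atom residues; the price is that chain A is not a realistic fold.
  Defaults (7 contacts, 3 surviving mutation) mirror the contact-loss
  pattern the pipeline is designed to quantify.
* **Pose ensemble** (`make_pose_ensemble`): a membrane-spanning receptor
  plus a rigid two-chain ligand placed per planted label (pass /
  above-leaflet / far-C-terminus, default mix 50/30/20 over 40 poses), then
  scrambled by a random rigid transform so triage must superpose first.
  Margins of ≥ 0.3–0.5 Å (and 2 Å on the C-terminus rule) keep planted
  verdicts unambiguous. Every pose is its own cluster centroid with
  distinct sizes and scores, so the expected selection is a simple
  argmax/argmin the generator records.
* **ΔΔG table** (`make_ddg_table`): magnitudes sampled inside
  class-specific intervals (significant (1.05, 3.0], above-noise
  (0.65, 0.95], within-noise [0, 0.55]) with random signs; the gaps around
  0.6 and 1.0 keep planted classes robust to rounding.

All fixtures are seeded (`numpy.random.default_rng`), ≤ 500 atoms, and
written as fixed-format text, so the same seed reproduces byte-identical
files on any platform. What passing these tests shows is that the
*geometry and bookkeeping* of every stage are correct; it does not show
performance on real folds — real interfaces have packed, irregular contact
geometry, crystallographic artefacts (altlocs, gaps, waters) beyond the
flagged cases, and mutations relax, which the rigid-template builder
deliberately ignores.

## Problem sizes and numerics

Defaults throughout are desk scale: fixtures of a few hundred atoms,
ensembles of tens of poses, tables of tens of rows — sizes at which the
brute-force oracles that guarantee correctness run in milliseconds while
the k-d tree path scales to complex-sized structures. Planted-distance
tolerance is 0.01 Å (construction solves to 10⁻⁶); superposition identity
is exact to ~10⁻¹³ Å RMSD; fold-change multiplicativity holds to 10⁻⁹
relative. Degenerate inputs (empty models, empty groups, missing chains or
focal residues, < 3 or collinear superposition atoms, non-numeric ΔΔG)
raise typed errors naming the offending input, except where the contract is
to continue (per-pose and per-row errors in batch runs).

## Known limitations

* The mutant builder's fixed ideal torsions can produce side-chain clashes
  that a repacking protocol would relieve; `clash_report` surfaces them but
  nothing resolves them.
* Interaction typing is distance-only; donor/acceptor geometry (angles,
  protonation states) is not modelled.
* The membrane is two infinite planes; curvature, tilt and thickness
  variation are out of scope.
* Pose clustering, docking scores, ΔΔG values, homology models and
  membrane embeddings are consumed, never computed.
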