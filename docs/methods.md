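# Methods

This note records what the toolkit actually computes, the defaults and
why, the numerical choices, and what the synthetic-data generators do and
do not emulate.

## Structures and annotation

Structures are flat atom lists plus a `(n_models, n_atoms, 3)` coordinate
array; all models of a multi-model file must share atom identities.
Residue numbering is taken verbatim from the input file — every hotspot
convention in this workflow is tied to the construct's own sequential
numbering (hinge cysteines at 130/136/139), so renumbering would be
destructive.  Default domain boundaries are VHH 1–129, hinge 130–142,
Fc 143–end, overridable per call or via config; the VHH/hinge split at
129/130 matches the Ser–Cys junction where hinge cleavage is observed.

Kabat CDR identification is implemented as anchor-pattern heuristics
(first framework Cys + 9 → CDR1 start, conserved Trp closes it; CDR2
opens 15 after CDR1 and is closed by the first `[KR][LIVFTA][TSIA]`
framework-3 motif; second Cys + 3 → CDR3 start, closed by `W-G-x-G`).
Anchor rules on unusual frameworks can fail or drift; an explicit
override is therefore accepted everywhere and is authoritative.  Any
serious reproduction should supply its own ranges.

Van der Waals radii: Bondi-style per-element table (C 1.70, N 1.55,
O 1.52, S 1.80, H 1.20 Å); geometry operations work on heavy atoms by
default, hydrogens are carried through when present.

## SASA

Shrake–Rupley quadrature on a deterministic Fibonacci sphere (default
960 points, probe 1.4 Å).  Two numerical choices deserve note:

* **Canonical frame.**  With a fixed quadrature grid, per-atom SASA of a
  rigidly rotated molecule differs by O(1/n_points).  The engine first
  rotates coordinates into a principal-axes frame whose axis signs are
  fixed by the third moment (skewness) of the projections — a property of
  the point cloud, not the input basis — so rigid motions reproduce SASA
  to floating-point precision.  Exactly symmetric or
  principal-degenerate point clouds remain ambiguous; disable with
  `canonical_frame=False` (which also restores strict monotonicity of
  occlusion when atoms are added, since then the grid never moves).
* **Accuracy.**  Per-atom error vs a 10 000-point brute-force quadrature
  is ≈4 % at 960 points and <1 % at 3840 on a dipeptide fixture; nearly
  buried atoms (a few Å² left) carry the largest relative error.  The
  default favors speed; pass `n_points` explicitly where per-atom
  precision matters.

Relative SASA divides by a fully exposed per-residue-type reference
(theoretical maxima); values above 100 % occur for terminal or fragment
residues and are reported as computed.  The Met entry can be overridden
to 231.7 Å² where consistency with absolute/percent value pairs computed
against that reference is needed.

Surface patches: atoms with SASA > 0.1 Å² and positive atomic
hydrophobicity (per-element logP-like table: C positive, S weakly
positive, N/O negative) are clustered by single-linkage with a 4.5 Å
center-to-center cutoff; patch area is the summed member SASA, with
conventional significance floors of 50 Å² (hydrophobic) and 40 Å²
(ionic), strict inequalities.  Ionic patches place formal charges on
side-chain terminal heavy atoms (Asp/Glu carboxylate oxygens −0.5 each,
Lys NZ +1, Arg NH1/NH2 +0.5 each, His ND1/NE2 +0.5 each only when the
charge model protonates His).  This is a simplification of force-field
charge mapping; it preserves which residues can seed a patch, not exact
electrostatics.  The 4.5 Å cutoff and 0.1 Å² surface floor were chosen
to separate opposite faces of a helix and are recorded in config.

## Charge and pI

Henderson–Hasselbalch sums over side chains (D, E, C, Y, K, R, H) and
per-chain termini with intrinsic pKa sets (EMBOSS-style default,
Lehninger alternative, or any user mapping).  No structure-aware pKa
shifts: the upstream alternative (PROPKA-class methods) needs the full
structure context and is out of scope; calibrated per-residue pKas can
be passed as a custom set.  pI is found by bisection on pH 0–14 to
|q| < 1e−4 (reproducible to 0.01 pH units); it requires ionizable groups
of both signs.  The working pH for net charge in DI defaults to 6.0, a
typical formulation pH for this antibody class.

## SAP and DI

Per atom *i*: for each residue with ≥1 atom within 5.0 Å (inclusive) of
*i*, the solvent-accessible area of that residue's side-chain atoms
inside the sphere is divided by the fully exposed side-chain area of the
residue type and weighted by residue hydrophobicity; contributions sum
over neighbor residues.  Multi-model inputs average per-model SAP values
(a single static structure is the one-model case).  Choices:

* Hydrophobicity: Black & Mould (1991) scale normalized so Gly = 0 — the
  scale of the original SAP formulation; shipped as data, overridable.
* Fully exposed side-chain reference: computed on extended Gly-X-Gly
  tripeptides with this package's own SASA engine (heavy atoms, probe
  1.4 Å), so numerator and denominator are self-consistent; the table is
  frozen in `data_sidechain.py` and regenerated by
  `scripts/regenerate_sidechain_reference.py` (RDKit embedding, fixed
  seed).  Because tripeptide conformers are embedded rather than
  idealized, ratios slightly above 1 can occur for extreme exposures.

SAP score = Σ positive atomic SAP over CDR atoms (an empty CDR set is an
error, not zero).  DI = SAP score − β q² with β = 0.0498, the regression
coefficient of the published DI formulation; q is the molecule's net
charge at the working pH.

## Disulfide redox

E = −ΔG/(nF) with F = 96.485 kJ mol⁻¹ V⁻¹ and n = 2 by default;
E_corr = 1.5 E_cal − 43 (mV, exact affine transform); classification:
E_corr < −330 mV stabilizing, otherwise reduction-prone, with values
above −89 mV additionally flagged highly labile.  The boundary −330 mV
goes to the risk class (conservative for flagging).  Published
calculated potentials for this system embed a protocol offset of ≈4–6 %
relative to the plain Nernst conversion of their ΔG values (free-energy
reference-state details not recoverable from ΔG alone), so `E_cal` can
be supplied directly and takes precedence over the ΔG route.

## Interfaces

Contacts are cross-partner heavy-atom pairs within 5.0 Å (inclusive).
Binding-mode assignment: per partner, the domain owning the most
interface contacts; ties resolve by the fixed priority VHH > hinge > Fc
(the designable antigen-binding domain is flagged preferentially).  Pose
energies are optional metadata only — no energy-weighted assignment.
PPIP pools raw counts over poses, over both partner roles (homodimer
chains share one numbering), and over all supplied ensembles before one
global normalization by the maximum; per-ensemble maps can be obtained
by calling per ensemble.  Aggregation interface: preference strictly
greater than 0.5.

## Hotspot rules

Oxidation: Met flagged at relative SASA > 20 %, Trp at > 30 % (strict).
Histidine catalysis generalizes the observed buried-Met mechanism: a Met
is catalysis-flagged when an imidazole heavy atom lies within 10 Å of
its sulfur and either the Met itself is exposure-flagged or an
exposure-flagged Met sulfur sits within 6 Å (an oxidized exposed
neighbor can relay the reaction to a buried one).  Both radii are
configurable; the 6 Å pair radius is the minimal generalization of a
5.2 Å observed sulfur–sulfur distance.  Flagged residues are reported
regardless of CDR distance, with `in_cdr`/`near_cdr` annotations;
platform-process arguments for conserved positions are captured by the
conserved input list, not by geometry.

STAP filter: {score > 1.0} ∩ interface ∖ conserved, strict threshold.
Binding-critical: alanine-scan ΔΔG > 1.0 kcal/mol, strict.  The merged
report marks a residue mutable iff it has ≥1 reason and is neither
conserved nor binding-critical; binding-critical hotspots are listed but
never mutable.  Conservation is always an input (external database
lookups are out of scope) and defaults to empty.

## Variant design

Per-site options: Cys→S, Trp→F, hydrophobic (A/V/L/I/F/M/Y)→{K, D}.
Enumeration takes all combinations up to `max_substitutions` sites that
include every always-on site (default: the mutable cysteines — the
reduction-prone hinge Cys in the intended use), deterministically named
M1..Mn.  The published panel for this antibody class is a curated subset
of this rule-complete enumeration; the enumeration is asserted to
contain the printed compositions rather than to match the curated
numbering.  Structure-level mutation renames the residue and truncates
the side chain beyond Cβ — no rotamer building — so variant SAP uses the
mutant hydrophobicity with approximately wild-type exposure geometry; a
documented approximation, adequate for ranking hydrophobicity-removal
designs, not for packing effects.

## Stability statistics

Rates are (day-28 − day-0)/weeks with a 4-week default window;
appearance maps clear/slight-opalescent/opalescent/turbid/particles onto
9/7/5/3/1; fold improvement is parent/variant to one decimal with a
`None` sentinel for zero variant rates.  The screen computes Pearson r
and the two-sided p from t with n−2 dof over pairwise complete cases
(pairs with <3 shared samples are skipped).  Significance uses
**|r| > 0.5** and p < 0.1: the absolute-value reading keeps strong
negative correlations significant, which matches how such screens treat
protective features; no multiple-testing correction enters the flag (a
Benjamini–Hochberg column is emitted for reference).

## Synthetic data

The generators plant ground truth by construction:

* Toy structures place coarse residues (canonical single-orientation
  side chains, ~9 Å spacing) on a line; "buried" residues sit inside a
  350-point occluding carbon shell at 6 Å radius (optionally with a
  directional opening), giving <5 % relative SASA; key-atom distances
  (Met SD, His NE2, Trp NE1) are planted exactly.
* Pose ensembles park the ligand copy 200 Å away and move selected
  single-atom residues to 3 Å above chosen receptor residues, so each
  planted pair contributes exactly one contact and the planted mode is
  the exact majority on both partners.
* Stability tables draw features as ρ·z + √(1−ρ²)·noise against the
  attribute's latent z, per planted pair, plus independent null columns.

These fixtures validate bookkeeping, thresholds, clustering, and
statistics exactly; they do not emulate realistic protein packing,
side-chain rotamers, docking physics, or measurement noise models.
Passing tests therefore demonstrate correctness of the rules and
engines, not predictive accuracy on real antibodies.

## Problem sizes and determinism

Test and acceptance runs use dipeptide-to-tripeptide SASA/SAP fixtures,
100 random pose ensembles (≤ 12 poses each), and 1000-replicate
correlation calibrations at n = 12 — sizes at which every oracle is
exact or Monte-Carlo error is well below the asserted bands.  All
randomness flows from explicit seeds; the acceptance script derives all
of its streams from `--seed`.

## Known limitations

Single static structures (no trajectory averaging beyond multi-model
means); intrinsic pKas only; no rotamer building on mutation; anchor
heuristics rather than full Kabat insertion-code numbering; patch
detection approximates, and does not reproduce, commercial
surface-property implementations; mmCIF is not parsed.
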