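# vhhfc

Structure-based stability assessment and variant design for VHH-Fc
heavy-chain antibodies.

VHH (nanobody) domains fused to an Fc fragment are a major therapeutic
format, but hinge-linked VHH-Fc homodimers aggregate and degrade through a
handful of recurring mechanisms: reduction-labile hinge disulfides that
seed intermolecular crosslinks, hydrophobic patches at self-association
interfaces, and solvent-exposed Met/Trp oxidation sites.  `vhhfc`
implements the in silico side of that developability workflow for people
doing early-stage antibody engineering: it consumes structures (PDB),
docked pose ensembles, and score tables from upstream tools, and turns
them into residue-level risk flags, a ranked hotspot report, and an
enumerated panel of candidate variants.

## What it computes

* **Surface**: Shrake-Rupley SASA per atom/residue, relative SASA
  (percent of the fully exposed reference), hydrophobic patches
  (> 50 A^2) and ionic patches (> 40 A^2) by distance clustering of
  exposed atoms.
* **Charge**: Henderson-Hasselbalch net charge *q*(pH) and isoelectric
  point by bisection, with configurable pKa sets.
* **Aggregation propensity**: spatial aggregation propensity per atom,

      SAP(i) = sum over residues R with an atom within 5 A of i of
               [SAA of R's side-chain atoms within 5 A
                / SAA of the fully exposed side chain of R's type]
               * phi(R),

  with phi the Black & Mould hydrophobicity normalized to Gly = 0; the
  SAP score sums positive values over CDR atoms, and the developability
  index is DI = SAP_score − 0.0498 q².
* **Disulfide redox**: E = −ΔG/(nF) (Nernst, n = 2), the empirical
  correction E_corr = 1.5 E_cal − 43 mV, and classification
  (stabilizing below −330 mV, reduction-prone in the −330 to −89 mV
  band, highly labile above).
* **Interfaces**: contact counting (5 A heavy-atom cutoff) over docked
  dimer ensembles, six domain-pair binding modes (Fc-Fc ... VHH-VHH),
  per-residue interface preference (PPIP, normalized to [0,1]), and the
  aggregation interface (PPIP > 0.5).
* **Hotspots**: oxidation rules (Met SASA% > 20, Trp SASA% > 30,
  histidine-catalysis within 10 A), the STAP filter
  (aggregation score > 1 ∩ interface ∖ conserved), binding-critical
  exclusions (alanine-scan ΔΔG > 1 kcal/mol), merged into one report.
* **Variants**: rule-based enumeration (Cys→S always on, Trp→F,
  hydrophobics→K/D, ≤ 3 substitutions), applied to sequences and
  structures with recomputed charge/pI/SAP/DI deltas.
* **Statistics**: per-week stress rates, appearance grading (9/7/5/3/1),
  fold improvements, and the feature-vs-attribute Pearson screen with
  the |r| > 0.5 & p < 0.1 significance rule.

A `fixtures` module generates synthetic structures, pose ensembles, and
stability tables with planted ground truth, so the whole pipeline is
testable without downloads.

## Worked example

```sh
python examples/redox_classification.py
```

```
bond_label  E_cal_mV  E_corr_mV  classification
 C130-C130    -137.1    -248.65 reduction-prone
 C136-C136    -261.2    -434.80     stabilizing
 C139-C139    -270.4    -448.60     stabilizing
```

The three interchain hinge disulfides of a VHH-Fc homodimer, given their
calculated reduction potentials: after the empirical correction, the first
cysteine pair lands in the −330 to −89 mV band, meaning it is susceptible
to enzymatic reduction during production — the free thiols it leaves
behind can crosslink two molecules into oligomers.  The other two bonds
sit below −330 mV and stabilize the fold.  This is the flag that makes the
first hinge cysteine an always-on Cys→Ser site in variant design:

```sh
python examples/hotspots_and_variants.py
```

```
hotspots: [57, 105, 106, 111, 120, 130]
mutable : [57, 111, 120, 130]   (Y105/Y106 stay: binding-critical)

14 rule-compliant variants:
  M1   C130S                  dq=+0.00
  M2   F57K/C130S             dq=+1.00
  ...
  M12  F57D/L120D/C130S       dq=-1.98  [colloidal-risk: >= 2 Asp ...]
```

Each line is one candidate: its substitutions and the net-charge change
they bring at pH 6.  The other scripts in `examples/` walk through the
surface, SAP/DI, interface-preference, and correlation-screen capabilities
the same way.

There is also a thin CLI (`vhhfc annotate|surface|charge|sap|redox|
interfaces|hotspots|design|correlate|fixtures`) over the same functions.

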