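"""Spatial aggregation propensity and the developability index.

SAP weighs each atom's local side-chain exposure by residue hydrophobicity
inside a 5 A sphere; the SAP score sums positive atomic values over the CDR
atoms.  The developability index then penalizes low net charge:

    DI = SAP_score - 0.0498 * q^2

Lower DI predicts lower aggregation risk: hydrophobic CDR surface is bad,
net charge of either sign protects.
"""

from vhhfc.charge import net_charge
from vhhfc.fixtures import make_toy_structure
from vhhfc.sap import developability_index, sap_per_atom, sap_score
from vhhfc.sasa import shrake_rupley

structure, _ = make_toy_structure([("PHE", True), ("TRP", True), ("SER", True)])
profile = shrake_rupley(structure)
values = sap_per_atom(structure, profile)

score = sap_score(structure, values, cdr_ranges=[(1, 2)])
sequence = structure.sequence()
q = net_charge(sequence, pH=6.0)
di = developability_index(score, q)

print(f"per-atom SAP range : {values.min():+.3f} .. {values.max():+.3f}")
print(f"CDR SAP score      : {score:.3f}")
print(f"net charge (pH 6)  : {q:+.2f}")
print(f"developability index: {di:.3f}")
print()
print("The exposed Phe/Trp pair drives the positive SAP score; with almost")
print("no net charge the DI stays close to the raw SAP score.")
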