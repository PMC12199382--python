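"""From rule outputs to a hotspot report to an enumerated variant panel.

Combines the four evidence streams (labile disulfide, interface aggregation
scores, oxidation liability, binding-critical alanine-scan exclusions) into
one report, then enumerates every rule-compliant variant: the labile Cys is
always replaced by Ser, Trp by Phe, and hydrophobic interface residues by
Lys or Asp, up to three substitutions.
"""

from vhhfc.hotspots import (
    OxidationFlag,
    binding_critical,
    hotspot_report,
    stap_filter,
)
from vhhfc.variants import enumerate_variants, evaluate_variant

# inputs as they would come from the upstream tools
a3d_scores = {5: 1.2, 11: 1.1, 57: 1.8, 58: 1.3, 59: 1.5, 103: 1.05,
              105: 1.6, 106: 1.7, 120: 1.2}
interface = {57, 58, 59, 105, 106, 120}
conserved = {58, 59, 115}
ddg = {55: 1.4, 59: 2.1, 62: 1.2, 105: 3.0, 106: 2.7, 107: 1.1}
oxidation = [OxidationFlag(111, "TRP", 69.2, True),
             OxidationFlag(115, "TRP", 28.0, False)]

report = hotspot_report(
    redox_cys={130},
    oxidation_flags=oxidation,
    stap_hotspots=stap_filter(a3d_scores, interface, conserved),
    binding_critical_set=binding_critical(ddg),
    conserved=conserved,
)
print(f"hotspots: {sorted(report.hotspots())}")
print(f"mutable : {sorted(report.mutable())}   "
      "(Y105/Y106 stay: binding-critical)")

parent = {57: "F", 105: "Y", 106: "Y", 111: "W", 120: "L", 130: "C"}
variants = enumerate_variants(report, parent, max_substitutions=3)
print(f"\n{len(variants)} rule-compliant variants:")
for v in variants:
    delta = evaluate_variant(parent, v, pH=6.0)
    note = f"  [{'; '.join(delta.warnings)}]" if delta.warnings else ""
    print(f"  {v.name:<4} {v.label:<22} dq={delta.delta_net_charge:+.2f}{note}")
print()
print("Every variant carries C130S; charge deltas preview the pI shift each")
print("K/D substitution brings.")
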