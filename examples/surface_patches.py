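"""Solvent accessibility and surface patches on a synthetic structure.

Builds a small exposed Phe-Ser fragment, computes per-residue SASA (absolute
and relative to the fully exposed reference of each residue type), and
clusters exposed hydrophobic atoms into patches.  Large hydrophobic patches
(> 50 A^2 on a real antibody surface) mark aggregation-competent regions.
"""

from vhhfc.fixtures import make_toy_structure
from vhhfc.sasa import hydrophobic_patches, relative_sasa, shrake_rupley

structure, _ = make_toy_structure([("PHE", True), ("SER", True)])
profile = shrake_rupley(structure)
rel = relative_sasa(structure, profile)

print("residue   SASA[A^2]   SASA[%]")
for chain, num, name in structure.residues():
    print(f"{name}{num:<6} {profile.residue_sasa[(chain, num)]:9.1f}"
          f" {rel[(chain, num)]:9.1f}")

patches = hydrophobic_patches(structure, profile, min_area=10.0)
print()
for p in patches:
    residues = sorted(f"{c}{n}" for c, n in p.residues(structure))
    print(f"hydrophobic patch: {p.area:.1f} A^2 over {residues}")
print()
print("The phenylalanine ring forms the dominant hydrophobic patch; the")
print("serine adds only a small backbone-carbon cluster.  Relative SASA")
print("exceeds 100 % here because an isolated fragment is more exposed than")
print("the folded-protein reference state.")
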