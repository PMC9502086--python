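"""Triplet mapping across the three homologous domains.

Builds the triplet map from the carrier-like three-domain alignment and
queries a few symmetry-related positions.
"""

from loopscan.synthetic import aac_like
from loopscan.tripartite import validate_anchors

fixture = aac_like()
tmap = fixture.triplet_map()
validate_anchors(tmap)  # raises if any anchor column is wrong

for triplet in (30, 37, 38, 50, 65):
    print(f"triplet {triplet}: residues {tmap.triplet_partners(triplet)}")
for residue in (236, 167, 143):
    domain, triplet = tmap.map_residue(residue)
    print(f"residue {residue}: domain {domain}, triplet {triplet}")
print()
print("A 'triplet' is one alignment column of the three ~100-residue")
print("domains, indexed by the domain-1 residue number: e.g. the capping")
print("arginines R30/R139/R236 are the three members of triplet 30.")
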