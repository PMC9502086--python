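"""Scan and annotate the matrix-side motif grammar, derive elements.

Annotates one instance of each conserved motif per domain on the
carrier-like sequence, then derives the matrix-loop and matrix-helix
ranges from the motif anchors.
"""

import warnings

from loopscan.motifs import annotate_mcf
from loopscan.synthetic import aac_like
from loopscan.tripartite import derive_elements

fixture = aac_like()
tmap = fixture.triplet_map()
with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # the degenerate matrix-gate motif warns
    hits = annotate_mcf(fixture.sequence, tmap)

for hit in hits:
    print(f"domain {hit.domain}  {hit.pattern_name:<12s} at {hit.start:>3d}  {hit.match}")

elements = derive_elements(tmap, hits)
print()
for d in (1, 2, 3):
    loop = elements.range(d, "matrix_loop")
    helix = elements.range(d, "matrix_helix")
    print(f"domain {d}: matrix loop {loop[0]}-{loop[1]}, matrix helix {helix[0]}-{helix[1]}")
print()
print("Each matrix loop runs from the residue after the hydrophobic plug")
print("(triplet 37) to the residue before the [YF]xG beta-turn aromatic;")
print("the short matrix helix ends at the G of the [DE]G motif.")
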