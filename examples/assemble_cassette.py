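"""Assemble circular guide RNA cassettes and derive the ligated circle.

Builds the classic variant panel for one spacer — mature U6+27 guide,
unprocessed Pre guide, and the circular C-L7 precursor — then predicts
the circle the ribozyme/RtcB pathway produces from the precursor.
"""

from circguide import LinkerPair, SpacerSet, assemble_construct, predict_circle
from circguide.fixtures import default_registry

parts = default_registry(seed=0)
spacer = SpacerSet.single("IL1RN-like", "ACCACAACCAAACCACCAACCAC")
linkers = LinkerPair(ext5="ACACA", ext3="CACAC")

for variant in ("U6+27", "Pre", "C-L7"):
    c = assemble_construct(spacer, variant, parts,
                           linkers=linkers if variant == "C-L7" else None)
    order = " ".join(f.role for f in c.features)
    print(f"{variant:7s} {len(c):4d} nt  [{order}]")

precursor = assemble_construct(spacer, "C-L7", parts, linkers=linkers)
circle = predict_circle(precursor, parts)
print(f"\ncircle: {len(circle)} nt, starts at {circle.features[0].part} "
      f"(the 5' ligation junction)")
# The circle is the precursor minus promoter and both ribozymes: the
# ribozymes cleave themselves off and RtcB seals the remaining ends.
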