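"""Predict guide RNA secondary structure with the builtin engines.

Folds a toy hairpin linearly and circularly, showing that circular
folding recovers a stem split across the sequence origin, and compares
the bundled MFE model with the maximum-pair confirmation engine.
"""

from circguide import fold, fold_maxpair

hairpin = "GGGAAAACCC"
s = fold(hairpin)
print(f"{hairpin}\n{s.dotbracket} ({s.dG:.2f} kcal/mol, {s.engine_id})")

# rotate the hairpin so its two arms flank the origin
rotated = hairpin[5:] + hairpin[:5]
linear = fold_maxpair(rotated)
circular = fold_maxpair(rotated, circular=True)
print(f"\nrotated {rotated}")
print(f"linear   : {linear.n_pairs} pairs")
print(f"circular : {circular.n_pairs} pairs "
      f"(stem rejoined across the origin; frame offset {circular.origin})")
# A circular RNA has no free ends, so the stem the rotation broke is
# intact on the circle — exactly why cgRNA design folds circles as circles.
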