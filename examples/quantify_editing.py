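"""Editing-outcome statistics on synthetic count tables.

Computes the off-target specificity index, FACS cleavage efficiency and
guide half-life from generated tables shaped like the real assays.
"""

from circguide import cleavage_efficiency, decay_half_life, specificity_index
from circguide.fixtures import toy_decay_series, toy_facs_counts, toy_site_reads

reads = toy_site_reads(seed=1)
for condition in ("U6+27", "C-Sp1", "C-L7"):
    si = specificity_index(reads, condition=condition)
    print(f"specificity index {condition:7s}: {si:.3f}")
# SI = on-target reads / (on-target + off-target reads); 1.0 = no
# detectable off-target cleavage.

facs = toy_facs_counts(seed=1)
print()
for _, row in facs.iterrows():
    e = cleavage_efficiency(row["mneon_neg_mcherry_pos"], row["mcherry_pos"],
                            row["total"])
    print(f"cleavage efficiency {row['sample']:6s}: {e:.3f}")
# E = mNeonGreen-negative fraction of transfected (mCherry+) cells.

decay = toy_decay_series(seed=1)
print()
for species, grp in decay.groupby("species"):
    fit = decay_half_life(grp["time_h"], grp["abundance"])
    print(f"half-life {species:14s}: {fit.t_half:6.2f} h  "
          f"(k={fit.k:.3f}/h, r2={fit.r_squared:.3f})")
# The circular guide decays far more slowly than its linear counterpart —
# the stability gain that motivates circularisation.
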