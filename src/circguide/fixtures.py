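"""Synthetic fixtures: parts registries, toy spacers and count tables.

The real cassette parts (Twister P3 U2A / P1 ribozymes, Tornado ligation
stems, per-nuclease direct repeats, the Sp1 linkers) are user-supplied
config.  The fixtures here are *synthetic stand-ins* with the documented
lengths and coarse architecture: structured parts are designed hairpins
(homopolymer G/C stem arms around A loops) whose reference motifs are
verified self-consistent against the builtin folding engines at
creation time; unstructured fillers are AC-rich, like the flexible
linkers the design uses.

``discrimination_registry``/``discrimination_linkers`` build the
engineered screen fixture: an alphabet-restricted cassette plus one
motif-preserving and one scaffold-invading linker pair (the invader's
extensions are reverse-complement constructions against the scaffold
stem), giving a screen whose right answer is known by construction.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .constructs import LinkerPair, SpacerSet
from .errors import PartError
from .folding import fold
from .parts import Part, PartRegistry


def _ac_filler(rng: np.random.Generator, n: int) -> str:
    """AC-rich unstructured filler (no G/U, so it cannot form pairs with
    itself or with other fillers)."""
    return "".join(rng.choice(["A", "C"], size=n, p=[0.6, 0.4]))


def _hairpin(stem: int, loop: int = 4) -> tuple[str, str]:
    seq = "G" * stem + "A" * loop + "C" * stem
    motif = "(" * stem + "." * loop + ")" * stem
    return seq, motif


def default_registry(seed: int = 0) -> PartRegistry:
    """Synthetic parts registry with the documented part lengths.

    Structured parts (ribozymes, scaffold, F30) are designed hairpins
    with reference motifs; fillers, ligation sequences and the 42/41-nt
    Sp1 spacer regions are AC-rich; linker cores default to the 10-nt
    polyAC elsewhere.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    rz5_seq, rz5_motif = _hairpin(8)
    rz3_seq, rz3_motif = _hairpin(7)
    sc_seq, sc_motif = _hairpin(5)
    f30_seq, f30_motif = _hairpin(4)
    reg = PartRegistry(
        [
            Part("U6prom", "promoter", _ac_filler(rng, 20)),
            Part("leader27", "extension_5p", _ac_filler(rng, 27)),
            Part("twister_p3_u2a", "ribozyme_5p", rz5_seq, motif=rz5_motif),
            Part("twister_p1", "ribozyme_3p", rz3_seq, motif=rz3_motif),
            Part("lig5", "ligation_5p", _ac_filler(rng, 8)),
            Part("lig3", "ligation_3p", _ac_filler(rng, 8)),
            Part("sp1_5p", "spacer_region_5p", _ac_filler(rng, 42)),
            Part("sp1_3p", "spacer_region_3p", _ac_filler(rng, 41)),
            Part("f30", "f30_junction", f30_seq, motif=f30_motif),
            Part("broccoli", "broccoli", _ac_filler(rng, 16)),
            Part("dr_scaffold", "scaffold", sc_seq, motif=sc_motif),
            Part("ext9", "extension_5p", _ac_filler(rng, 9)),
            Part("ext59", "extension_5p", _ac_filler(rng, 59)),
            Part("ext_t4at4", "extension_3p", "TTTTATTTT"),
        ]
    )
    verify_motifs(reg)
    return reg


def verify_motifs(reg: PartRegistry) -> None:
    """Check each declared motif is what the part folds to in isolation."""
    for part in reg:
        if part.motif is None:
            continue
        s = fold(part.sequence.replace("T", "U"))
        if s.dotbracket != part.motif:
            raise PartError(
                f"fixture motif for {part.name!r} is not self-consistent: "
                f"folds to {s.dotbracket}, template {part.motif}"
            )


def toy_spacers(seed: int = 0, n: int = 5) -> SpacerSet:
    """Toy spacer set (AC-rich, 23 nt) named after the multiplexed
    target panel CD47/VEGFA/DNMT1/EMX1/RUNX1."""
    rng = np.random.default_rng(seed + 1)
    names = ["CD47-S3", "VEGFA-S1", "DNMT1-S3", "EMX1", "RUNX1"][:n]
    return SpacerSet(
        spacers=tuple((name, _ac_filler(rng, 23)) for name in names)
    )


# ---------------------------------------------------------------------
# the engineered discrimination fixture
# ---------------------------------------------------------------------

def discrimination_registry() -> PartRegistry:
    """Alphabet-restricted registry for the preserve-vs-invade screen.

    Every nucleotide outside the designed stems is A, and stem arms are
    homopolymer G/C blocks, so both builtin engines have a unique optimal
    structure for the intact cassette (the designed stems) and the
    invading linker's effect is analytically predictable.
    """
    rz5_seq, rz5_motif = _hairpin(8)
    rz3_seq, rz3_motif = _hairpin(7)
    sc_seq, sc_motif = _hairpin(5)
    reg = PartRegistry(
        [
            Part("U6prom", "promoter", "A" * 20),
            Part("leader27", "extension_5p", "A" * 27),
            Part("twister_p3_u2a", "ribozyme_5p", rz5_seq, motif=rz5_motif),
            Part("twister_p1", "ribozyme_3p", rz3_seq, motif=rz3_motif),
            Part("lig5", "ligation_5p", "A" * 8),
            Part("lig3", "ligation_3p", "A" * 8),
            Part("dr_scaffold", "scaffold", sc_seq, motif=sc_motif),
        ]
    )
    verify_motifs(reg)
    return reg


def discrimination_linkers() -> tuple[LinkerPair, LinkerPair]:
    """(preserving, invading) linker pairs for the discrimination screen.

    The preserving pair is inert (poly-A core and extensions).  The
    invading pair attacks the scaffold stem from both sides by
    reverse-complement construction: its 5' extension (C7) competes for
    the scaffold's G arm, and its 3' extension (revcomp of the scaffold
    loop end + C arm) forms a longer, more stable helix with the
    scaffold's 3' arm than the designed stem itself.
    """
    core = "A" * 10
    preserving = LinkerPair(ext5="AAAAA", ext3="AAAAA", core=core)
    # scaffold is GGGGG AAAA CCCCC; target the last two loop A's + C arm:
    # revcomp("AACCCCC") == "GGGGGTT"
    invading = LinkerPair(ext5="CCCCCCC", ext3="GGGGGTT", core=core)
    return preserving, invading


def discrimination_spacer() -> SpacerSet:
    return SpacerSet.single("toy-target", "A" * 23)


# ---------------------------------------------------------------------
# toy count tables for the quantification module
# ---------------------------------------------------------------------

def toy_site_reads(seed: int = 0) -> pd.DataFrame:
    """Synthetic cleavage-site read table: 14 on-target sites per guide
    condition plus a few off-target sites, TSV-ready."""
    rng = np.random.default_rng(seed + 2)
    rows = []
    for condition, n_off, off_scale in (
        ("U6+27", 3, 0.02),
        ("C-Sp1", 5, 0.05),
        ("C-L7", 4, 0.06),
    ):
        for s in range(1, 15):
            rows.append(
                {
                    "condition": condition,
                    "site": f"site{s:02d}",
                    "kind": "on_target",
                    "reads": int(rng.integers(200, 2000)),
                }
            )
        for o in range(1, n_off + 1):
            rows.append(
                {
                    "condition": condition,
                    "site": f"off{o:02d}",
                    "kind": "off_target",
                    "reads": int(max(1, rng.poisson(off_scale * 1000))),
                }
            )
    return pd.DataFrame(rows)


def toy_facs_counts(seed: int = 0) -> pd.DataFrame:
    """Synthetic FACS table for the fluorescent-reporter cleavage assay."""
    rng = np.random.default_rng(seed + 3)
    rows = []
    for sample, eff in (("NT", 0.02), ("U6+27", 0.28), ("Pre", 0.26),
                        ("C-L7", 0.40)):
        total = int(rng.integers(8000, 12000))
        mcherry = int(total * rng.uniform(0.4, 0.6))
        neg = int(np.clip(rng.normal(eff, 0.02), 0, 1) * mcherry)
        rows.append(
            {
                "sample": sample,
                "total": total,
                "mcherry_pos": mcherry,
                "mneon_neg_mcherry_pos": neg,
            }
        )
    return pd.DataFrame(rows)


def toy_decay_series(seed: int = 0) -> pd.DataFrame:
    """Synthetic transcription-shutoff time course (1, 3, 6, 9, 18 h):
    a fast-decaying linear guide and a slow-decaying circular guide."""
    rng = np.random.default_rng(seed + 4)
    t = np.array([1.0, 3.0, 6.0, 9.0, 18.0])
    rows = []
    for species, t_half in (("linear_gRNA", 2.0), ("circular_gRNA", 24.0)):
        k = np.log(2) / t_half
        noise = rng.normal(1.0, 0.05, size=t.size)
        for ti, ai in zip(t, np.exp(-k * t) * noise):
            rows.append(
                {"species": species, "time_h": ti, "abundance": float(ai)}
            )
    return pd.DataFrame(rows)


def make_fixtures(seed: int = 0) -> dict:
    """Everything at once: parts registry, toy spacers, toy count tables."""
    return {
        "parts": default_registry(seed),
        "spacers": toy_spacers(seed),
        "site_reads": toy_site_reads(seed),
        "facs": toy_facs_counts(seed),
        "decay": toy_decay_series(seed),
    }


def write_fixtures(directory: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the fixture set to a directory; returns the path map."""
    from .io import write_fasta, write_table

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fx = make_fixtures(seed)
    paths = {
        "parts": directory / "parts.yaml",
        "spacers": directory / "spacers.fasta",
        "site_reads": directory / "site_reads.tsv",
        "facs": directory / "facs.tsv",
        "decay": directory / "decay.tsv",
    }
    fx["parts"].save(paths["parts"])
    write_fasta(list(fx["spacers"].spacers), paths["spacers"])
    write_table(fx["site_reads"], paths["site_reads"])
    write_table(fx["facs"], paths["facs"])
    write_table(fx["decay"], paths["decay"])
    return paths
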