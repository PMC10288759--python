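"""Digital linker-library screening.

The screened object is a circular precursor cassette whose 5' and 3'
linkers carry a fixed polyAC core plus 5-7 random bases.  The pipeline
mirrors the published design procedure: enumerate or sample a linker
library, fold each precursor transcript with the primary engine, keep
candidates whose ribozyme and scaffold structure motifs are intact, rank
them by ΔG (most stable first), take the top 10-20, group by structural
similarity, re-check the group members with a confirmation engine, and
select per group the most stable doubly-correct candidate.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constructs import (
    Construct,
    LinkerPair,
    SpacerSet,
    assemble_construct,
    transcript_construct,
)
from .errors import ScreenError
from .folding import SecondaryStructure, dotbracket_to_pairs, get_engine
from .parts import PartRegistry

DNA = "ACGT"


# ---------------------------------------------------------------------
# motifs and correctness
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class StructureMotif:
    """A reference sub-structure that must be preserved in the full fold.

    ``template`` is the dot-bracket over the anchored part's footprint.
    A candidate passes if at least ``min_pair_recovery`` of the template
    pairs are present in the prediction (mapped through the feature
    offset) and at most ``max_cross_pairs`` predicted pairs have exactly
    one end inside the footprint.
    """

    part_name: str
    template: str
    min_pair_recovery: float = 1.0
    max_cross_pairs: int = 0

    def __post_init__(self) -> None:
        dotbracket_to_pairs(self.template)  # raises if unbalanced
        if not (0.0 <= self.min_pair_recovery <= 1.0):
            raise ScreenError("min_pair_recovery must be in [0, 1]")
        if self.max_cross_pairs < 0:
            raise ScreenError("max_cross_pairs must be >= 0")


def motifs_from_parts(parts: PartRegistry, **thresholds) -> list[StructureMotif]:
    """One motif per registry part that declares a reference structure."""
    return [
        StructureMotif(part_name=p.name, template=p.motif, **thresholds)
        for p in sorted(parts, key=lambda p: p.name)
        if p.motif is not None
    ]


def check_correctness(
    structure: SecondaryStructure,
    construct: Construct,
    motifs: list[StructureMotif],
) -> tuple[list[dict], bool]:
    """Per-motif recovery/cross-pair report and the overall verdict.

    A motif anchored to a part that occurs several times in the cassette
    (e.g. the two scaffold copies) is checked at every occurrence.
    """
    if len(structure.sequence) != len(construct.sequence):
        raise ScreenError(
            f"structure length {len(structure.sequence)} != construct length "
            f"{len(construct.sequence)}"
        )
    predicted = set(structure.pairs)
    report: list[dict] = []
    for motif in motifs:
        feats = construct.features_named(motif.part_name)
        if not feats:
            raise ScreenError(
                f"motif part {motif.part_name!r} not among construct features"
            )
        template = dotbracket_to_pairs(motif.template)
        for occ, feat in enumerate(feats):
            if len(feat) != len(motif.template):
                raise ScreenError(
                    f"motif template length {len(motif.template)} != footprint "
                    f"of {motif.part_name!r} ({len(feat)})"
                )
            tpl_global = {(i + feat.start, j + feat.start) for i, j in template}
            recovered = (
                len(predicted & tpl_global) / len(tpl_global)
                if tpl_global
                else 1.0
            )
            span = range(feat.start, feat.end)
            cross = sum(
                1 for i, j in predicted if (i in span) != (j in span)
            )
            report.append(
                {
                    "part": motif.part_name,
                    "occurrence": occ,
                    "recovery": recovered,
                    "cross_pairs": cross,
                    "pass": recovered >= motif.min_pair_recovery - 1e-12
                    and cross <= motif.max_cross_pairs,
                }
            )
    return report, all(r["pass"] for r in report)


# ---------------------------------------------------------------------
# library generation
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenConfig:
    """Settings for one library screen."""

    core: str = "ACACACACAC"
    ext_lengths: tuple[int, ...] = (5, 6, 7)
    library_size: int | str = 512  # int = sampled, "exhaustive" = all pairs
    seed: int = 0
    top_n: int = 20
    primary_engine: str = "builtin-mfe"
    confirm_engine: str = "builtin-maxpair"
    distance_mode: str = "shape"  # shape | base-pair
    distance_threshold: float = 0.3
    min_pair_recovery: float = 1.0
    max_cross_pairs: int = 0
    max_exhaustive_pairs: int = 1_000_000

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ScreenError("top_n must be >= 1")
        if not self.ext_lengths:
            raise ScreenError("at least one extension length is required")
        if self.distance_mode not in {"shape", "base-pair"}:
            raise ScreenError(f"unknown distance mode {self.distance_mode!r}")

    def to_dict(self) -> dict:
        return {
            "core": self.core,
            "ext_lengths": list(self.ext_lengths),
            "library_size": self.library_size,
            "seed": self.seed,
            "top_n": self.top_n,
            "primary_engine": self.primary_engine,
            "confirm_engine": self.confirm_engine,
            "distance_mode": self.distance_mode,
            "distance_threshold": self.distance_threshold,
            "min_pair_recovery": self.min_pair_recovery,
            "max_cross_pairs": self.max_cross_pairs,
        }

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def enumerate_extensions(lengths) -> list[str]:
    """All extension strings of the given lengths, in deterministic order."""
    out: list[str] = []
    for ln in sorted(lengths):
        out.extend("".join(t) for t in itertools.product(DNA, repeat=ln))
    return out


def _ext_space(lengths) -> int:
    return sum(4 ** ln for ln in sorted(lengths))


def _ext_by_index(lengths, idx: int) -> str:
    for ln in sorted(lengths):
        block = 4 ** ln
        if idx < block:
            digits = []
            for _ in range(ln):
                digits.append(DNA[idx % 4])
                idx //= 4
            return "".join(reversed(digits))
        idx -= block
    raise IndexError(idx)


def generate_linker_library(config: ScreenConfig) -> list[LinkerPair]:
    """Enumerate (exhaustive) or sample (unique, seeded) linker pairs."""
    space = _ext_space(config.ext_lengths)
    if config.library_size == "exhaustive":
        if space * space > config.max_exhaustive_pairs:
            raise ScreenError(
                f"exhaustive pair space {space}^2 exceeds the "
                f"{config.max_exhaustive_pairs} guard; sample instead"
            )
        exts = enumerate_extensions(config.ext_lengths)
        lo, hi = min(config.ext_lengths), max(config.ext_lengths)
        return [
            LinkerPair(ext5=a, ext3=b, core=config.core, min_ext=lo, max_ext=hi)
            for a in exts
            for b in exts
        ]
    n = int(config.library_size)
    if n < 1:
        raise ScreenError("library_size must be >= 1")
    if n > space * space:
        raise ScreenError(
            f"library_size {n} exceeds enumerable space {space}^2"
        )
    rng = np.random.default_rng(config.seed)
    seen: set[tuple[int, int]] = set()
    out: list[LinkerPair] = []
    while len(out) < n:
        a = int(rng.integers(space))
        b = int(rng.integers(space))
        if (a, b) in seen:
            continue
        seen.add((a, b))
        out.append(
            LinkerPair(
                ext5=_ext_by_index(config.ext_lengths, a),
                ext3=_ext_by_index(config.ext_lengths, b),
                core=config.core,
                min_ext=min(config.ext_lengths),
                max_ext=max(config.ext_lengths),
            )
        )
    return out


# ---------------------------------------------------------------------
# per-candidate record, ranking, grouping, selection
# ---------------------------------------------------------------------

@dataclass
class ScreenResult:
    """One screened linker pair with everything the report needs."""

    linkers: LinkerPair
    construct_name: str
    transcript: Construct
    structure_primary: SecondaryStructure
    dG_primary: float
    correct_primary: bool
    motif_report: list[dict] = field(default_factory=list)
    structure_confirm: SecondaryStructure | None = None
    dG_confirm: float | None = None
    correct_confirm: bool | None = None
    rank: int | None = None
    group_id: str | None = None
    selected: bool = False

    @property
    def key(self) -> tuple[str, str]:
        return (self.linkers.linker5, self.linkers.linker3)


def rank_by_dG(results: list[ScreenResult]) -> list[ScreenResult]:
    """Correct candidates sorted by ΔG ascending; ties by linker sequence.

    Assigns ``rank`` 1..N on the returned (correct-only) list; incorrect
    candidates are excluded and keep ``rank=None``.
    """
    correct = [r for r in results if r.correct_primary]
    correct.sort(key=lambda r: (r.dG_primary, r.key))
    for pos, r in enumerate(correct, start=1):
        r.rank = pos
    return correct


def shape_string(dotbracket: str) -> str:
    """Coarse shape abstraction: helices -> ``[]``, loops collapsed.

    ``"((..))"`` and ``"(((...)))"`` both map to ``"[]"``; the open chain
    maps to ``"_"``.
    """
    pairs = dotbracket_to_pairs(dotbracket)
    if not pairs:
        return "_"
    children: dict[tuple | None, list[tuple]] = {None: []}
    stack: list[tuple] = []
    for p in sorted(pairs):
        while stack and not (stack[-1][0] < p[0] and p[1] < stack[-1][1]):
            stack.pop()
        parent = stack[-1] if stack else None
        children.setdefault(parent, []).append(p)
        children.setdefault(p, [])
        stack.append(p)

    def render(p) -> str:
        while len(children[p]) == 1:
            p = children[p][0]
        kids = children[p]
        if not kids:
            return "[]"
        return "[" + "".join(render(k) for k in kids) + "]"

    return "".join(render(k) for k in children[None])


def _invariant_pair_keys(result: ScreenResult) -> set:
    """Base pairs keyed by (part occurrence, offset) coordinates.

    Makes pair sets comparable across candidates whose linker extensions
    differ in length.
    """
    feats = sorted(result.transcript.features, key=lambda f: f.start)
    keys = set()
    lookup: list[tuple[range, str]] = []
    occ_count: dict[str, int] = {}
    for f in feats:
        occ = occ_count.get(f.part, 0)
        occ_count[f.part] = occ + 1
        lookup.append((range(f.start, f.end), f"{f.part}#{occ}"))

    def key_of(pos: int):
        for rng, label in lookup:
            if pos in rng:
                return (label, pos - rng.start)
        return ("?", pos)

    for i, j in result.structure_primary.pairs:
        keys.add((key_of(i), key_of(j)))
    return keys


def base_pair_distance(pairs1, pairs2, normalize: bool = False) -> float:
    """Symmetric-difference distance between two base-pair sets."""
    s1, s2 = set(pairs1), set(pairs2)
    d = len(s1 ^ s2)
    if normalize:
        return d / max(1, len(s1 | s2))
    return float(d)


def group_by_similarity(
    top: list[ScreenResult],
    mode: str = "shape",
    threshold: float = 0.3,
) -> list[list[ScreenResult]]:
    """Partition the top candidates into structural-similarity groups.

    ``shape`` groups candidates whose coarse shape strings are identical;
    ``base-pair`` single-links candidates whose normalized base-pair
    distance (over part-anchored coordinates) is <= threshold.  Groups
    and their members are returned in a canonical deterministic order.
    """
    if mode == "shape":
        buckets: dict[str, list[ScreenResult]] = {}
        for r in top:
            buckets.setdefault(
                shape_string(r.structure_primary.dotbracket), []
            ).append(r)
        groups = list(buckets.values())
    elif mode == "base-pair":
        keys = [_invariant_pair_keys(r) for r in top]
        parent = list(range(len(top)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a in range(len(top)):
            for b in range(a + 1, len(top)):
                if base_pair_distance(keys[a], keys[b], normalize=True) <= threshold:
                    parent[find(a)] = find(b)
        buckets = {}
        for idx, r in enumerate(top):
            buckets.setdefault(find(idx), []).append(r)
        groups = list(buckets.values())
    else:
        raise ScreenError(f"unknown grouping mode {mode!r}")

    for g in groups:
        g.sort(key=lambda r: (r.dG_primary, r.key))
    groups.sort(key=lambda g: (g[0].dG_primary, g[0].key))
    for gid, g in enumerate(groups, start=1):
        for r in g:
            r.group_id = f"G{gid}"
    return groups


def select_representatives(
    groups: list[list[ScreenResult]],
) -> tuple[list[ScreenResult], list[str]]:
    """Pick per group the most stable doubly-correct candidate.

    Returns the selected results and the ids of groups with no candidate
    passing the confirmation-engine correctness check.
    """
    selected: list[ScreenResult] = []
    empty: list[str] = []
    for g in groups:
        for r in g:  # already sorted by (dG_primary, linkers)
            if r.correct_confirm:
                r.selected = True
                selected.append(r)
                break
        else:
            empty.append(g[0].group_id or "?")
    return selected, empty


# ---------------------------------------------------------------------
# the end-to-end screen
# ---------------------------------------------------------------------

@dataclass
class ScreenReport:
    """Full screen output: per-candidate table plus run provenance."""

    results: list[ScreenResult]
    groups: list[list[ScreenResult]]
    selected: list[ScreenResult]
    unconfirmed_groups: list[str]
    manifest: dict

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append(
                {
                    "linker5": r.linkers.linker5,
                    "linker3": r.linkers.linker3,
                    "dG_primary": r.dG_primary,
                    "dG_confirm": r.dG_confirm,
                    "correct_primary": r.correct_primary,
                    "correct_confirm": r.correct_confirm,
                    "rank": r.rank,
                    "group_id": r.group_id,
                    "selected": r.selected,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "linker5", "linker3", "dG_primary", "dG_confirm",
                "correct_primary", "correct_confirm", "rank", "group_id",
                "selected",
            ],
        )

    def to_tsv(self) -> str:
        return self.to_dataframe().to_csv(sep="\t", index=False, float_format="%.6g")


def run_screen(
    spacers: SpacerSet,
    variant: str,
    parts: PartRegistry,
    config: ScreenConfig,
    motifs: list[StructureMotif] | None = None,
    library: list[LinkerPair] | None = None,
) -> ScreenReport:
    """Generate → assemble → fold → filter → rank → group → confirm → select.

    ``library`` may inject a pre-built linker list (the generator is used
    otherwise); candidates are canonically sorted on ingest so the
    outcome is independent of library order.
    """
    if library is None:
        library = generate_linker_library(config)
    library = sorted(library, key=lambda lp: (lp.linker5, lp.linker3))

    if motifs is None:
        motifs = motifs_from_parts(
            parts,
            min_pair_recovery=config.min_pair_recovery,
            max_cross_pairs=config.max_cross_pairs,
        )
        if library:
            # registry-derived motifs are kept only for parts this variant uses
            probe = assemble_construct(spacers, variant, parts,
                                       linkers=library[0])
            present = {f.part for f in probe.features}
            motifs = [m for m in motifs if m.part_name in present]

    primary = get_engine(config.primary_engine)
    confirm = get_engine(config.confirm_engine)

    results: list[ScreenResult] = []
    for lp in library:
        cassette = assemble_construct(spacers, variant, parts, linkers=lp)
        rna = transcript_construct(cassette)
        s1 = primary.fold(rna.sequence, circular=False)
        report, ok = check_correctness(s1, rna, motifs)
        results.append(
            ScreenResult(
                linkers=lp,
                construct_name=cassette.name,
                transcript=rna,
                structure_primary=s1,
                dG_primary=s1.dG,
                correct_primary=ok,
                motif_report=report,
            )
        )

    ranked = rank_by_dG(results)
    top = ranked[: config.top_n]

    for r in top:
        s2 = confirm.fold(r.transcript.sequence, circular=False)
        _, ok2 = check_correctness(s2, r.transcript, motifs)
        r.structure_confirm = s2
        r.dG_confirm = s2.dG
        r.correct_confirm = ok2

    groups = group_by_similarity(
        top, mode=config.distance_mode, threshold=config.distance_threshold
    )
    selected, empty = select_representatives(groups)

    manifest = {
        "tool": "circguide.screen",
        "variant": variant,
        "spacers": [name for name, _ in spacers.spacers],
        "cas_system": spacers.cas_system,
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "seed": config.seed,
        "library_size": len(library),
        "engines": {"primary": primary.engine_id, "confirm": confirm.engine_id},
        "n_correct_primary": len(ranked),
        "n_selected": len(selected),
    }
    return ScreenReport(
        results=results,
        groups=groups,
        selected=selected,
        unconfirmed_groups=empty,
        manifest=manifest,
    )
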