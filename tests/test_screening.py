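"""Linker-library generation, correctness filter, ranking, grouping."""

import numpy as np
import pytest

from circguide.constructs import LinkerPair, assemble_construct, transcript_construct
from circguide.errors import ScreenError
from circguide.folding import fold, fold_maxpair, open_chain
from circguide.screening import (
    ScreenConfig,
    ScreenResult,
    StructureMotif,
    base_pair_distance,
    check_correctness,
    enumerate_extensions,
    generate_linker_library,
    group_by_similarity,
    motifs_from_parts,
    rank_by_dG,
    run_screen,
    select_representatives,
    shape_string,
)


class TestLibrary:
    def test_one_side_enumeration_counts(self):
        assert len(enumerate_extensions([5])) == 4**5 == 1024
        assert len(enumerate_extensions([5, 6, 7])) == 1024 + 4096 + 16384

    def test_sampled_library_is_seed_reproducible_and_unique(self):
        cfg = ScreenConfig(library_size=100, seed=17)
        a = generate_linker_library(cfg)
        b = generate_linker_library(cfg)
        assert [(x.ext5, x.ext3) for x in a] == [(x.ext5, x.ext3) for x in b]
        assert len({(x.ext5, x.ext3) for x in a}) == 100

    def test_every_linker_is_core_plus_extension(self):
        cfg = ScreenConfig(library_size=50, seed=1)
        for lp in generate_linker_library(cfg):
            assert lp.linker5.startswith("ACACACACAC")
            assert 5 <= len(lp.ext5) <= 7 and 5 <= len(lp.ext3) <= 7

    def test_exhaustive_pairs_small_space(self):
        cfg = ScreenConfig(ext_lengths=(1,), library_size="exhaustive")
        lib = generate_linker_library(cfg)
        assert len(lib) == 16  # 4 x 4 extension pairs
        assert len({(x.ext5, x.ext3) for x in lib}) == 16

    def test_oversized_requests_rejected(self):
        with pytest.raises(ScreenError):
            generate_linker_library(
                ScreenConfig(ext_lengths=(1,), library_size=17)
            )
        with pytest.raises(ScreenError):
            generate_linker_library(ScreenConfig(library_size="exhaustive"))


class TestCorrectness:
    def _folded(self, disc, lp, engine=fold):
        c = assemble_construct(disc["spacers"], "C-L7", disc["parts"], linkers=lp)
        rna = transcript_construct(c)
        return engine(rna.sequence), rna

    def test_identity_case_full_recovery(self, disc):
        s, rna = self._folded(disc, disc["preserving"])
        motifs = motifs_from_parts(disc["parts"])
        report, ok = check_correctness(s, rna, motifs)
        assert ok and all(r["recovery"] == 1.0 and r["cross_pairs"] == 0
                          for r in report)

    def test_zero_recovery_fails(self, disc):
        _, rna = self._folded(disc, disc["preserving"])
        motifs = motifs_from_parts(disc["parts"])
        report, ok = check_correctness(open_chain(rna.sequence), rna, motifs)
        assert not ok and all(r["recovery"] == 0.0 for r in report)

    def test_invading_linker_counts_cross_pairs(self, disc):
        s, rna = self._folded(disc, disc["invading"])
        motifs = motifs_from_parts(disc["parts"])
        report, ok = check_correctness(s, rna, motifs)
        assert not ok
        scaffold = [r for r in report if r["part"] == "dr_scaffold"]
        assert any(r["cross_pairs"] >= 1 for r in scaffold)
        assert any(r["recovery"] < 1.0 for r in scaffold)

    def test_template_footprint_mismatch_rejected(self, disc):
        s, rna = self._folded(disc, disc["preserving"])
        bad = [StructureMotif(part_name="dr_scaffold", template="(...)")]
        with pytest.raises(ScreenError):
            check_correctness(s, rna, bad)


def _fake(ext5, ext3, dg, correct=True, db=None, seq=None):
    seq = seq or "GGGAAAACCC"
    db = db or "(((....)))"
    s = open_chain(seq) if db == "open" else None
    from circguide.folding.structure import SecondaryStructure

    if s is None:
        s = SecondaryStructure(sequence=seq, dotbracket=db, dG=dg)
    lp = LinkerPair(ext5=ext5, ext3=ext3)
    from circguide.constructs import Construct, Feature

    c = Construct(name="fake", topology="linear_gRNA", sequence=seq,
                  features=(Feature("body", "scaffold", 0, len(seq)),),
                  is_rna=True)
    return ScreenResult(
        linkers=lp, construct_name="fake", transcript=c,
        structure_primary=s, dG_primary=dg, correct_primary=correct,
    )


class TestRanking:
    def test_ascending_dg_order(self):
        rs = [_fake("AAAAA", "AAAAA", -28.1), _fake("CCCCC", "AAAAA", -30.2)]
        ranked = rank_by_dG(rs)
        assert [r.dG_primary for r in ranked] == [-30.2, -28.1]
        assert [r.rank for r in ranked] == [1, 2]

    def test_incorrect_candidates_excluded(self):
        rs = [_fake("AAAAA", "AAAAA", -50.0, correct=False),
              _fake("CCCCC", "AAAAA", -10.0)]
        ranked = rank_by_dG(rs)
        assert len(ranked) == 1 and ranked[0].dG_primary == -10.0
        assert ranked[0].rank == 1 and rs[0].rank is None

    def test_ties_broken_by_linker_sequence(self):
        rs = [_fake("GGGGG", "AAAAA", -5.0), _fake("AAAAA", "AAAAA", -5.0)]
        ranked = rank_by_dG(rs)
        assert ranked[0].linkers.ext5 == "AAAAA"

    def test_top_n_truncation(self):
        rs = [_fake(f"AA{bases}", "AAAAA", -float(i))
              for i, bases in enumerate(
                  ("AAA", "AAC", "AAG", "AAT", "ACA", "ACC", "ACG", "ACT",
                   "AGA", "AGC", "AGG", "AGT", "ATA", "ATC", "ATG", "ATT",
                   "CAA", "CAC", "CAG", "CAT", "CCA", "CCC", "CCG", "CCT",
                   "CGA", "CGC", "CGG", "CGT", "CTA", "CTC"))]
        ranked = rank_by_dG(rs)
        assert len(ranked) == 30
        assert len(ranked[:20]) == 20  # "top 10-20" retention


class TestGrouping:
    def test_single_stem_shapes_collapse(self):
        assert shape_string("((..))") == shape_string("(((...)))") == "[]"

    def test_two_stems_differ_from_one(self):
        assert shape_string("((..))..((..))") == "[][]"
        assert shape_string("((..))..((..))") != shape_string("((..))")

    def test_multiloop_shape(self):
        assert shape_string("((((...))((...))))") == "[[][]]"
        assert shape_string("") == "_" == shape_string("...")

    def test_shape_grouping_is_an_equivalence_relation(self):
        rng = np.random.default_rng(31)
        from conftest import random_rna

        results = []
        for i in range(24):
            seq = random_rna(rng, 30)
            s = fold(seq)
            r = _fake("AAAAA", "AAAAA", s.dG, db=s.dotbracket, seq=seq)
            results.append(r)
        groups = group_by_similarity(results, mode="shape")
        # partition: every result in exactly one group
        seen = [id(r) for g in groups for r in g]
        assert sorted(seen) == sorted(id(r) for r in results)
        for g in groups:
            shapes = {shape_string(r.structure_primary.dotbracket) for r in g}
            assert len(shapes) == 1

    def test_base_pair_distance_metric_properties(self):
        rng = np.random.default_rng(37)
        from conftest import random_rna

        sets = []
        for _ in range(9):
            s = fold_maxpair(random_rna(rng, 20))
            sets.append(set(s.pairs))
        for s in sets:
            assert base_pair_distance(s, s) == 0
            assert base_pair_distance(s, set()) == len(s)
        for a in sets:
            for b in sets:
                for c in sets:
                    assert base_pair_distance(a, c) <= \
                        base_pair_distance(a, b) + base_pair_distance(b, c)

    def test_base_pair_mode_groups_identical_structures(self):
        rs = [_fake("AAAAA", "AAAAA", -3.0), _fake("CCCCC", "GGGGG", -2.0),
              _fake("GGGGG", "TTTTT", -1.0, db="open")]
        groups = group_by_similarity(rs, mode="base-pair", threshold=0.1)
        sizes = sorted(len(g) for g in groups)
        assert sizes == [1, 2]


class TestSelection:
    def test_confirmation_failure_falls_back_to_next_best(self):
        a = _fake("AAAAA", "AAAAA", -30.0)
        b = _fake("CCCCC", "AAAAA", -32.0)
        a.correct_confirm, b.correct_confirm = True, False
        groups = [[b, a]]  # b more stable but fails confirmation
        for g in groups:
            g.sort(key=lambda r: (r.dG_primary, r.key))
        selected, empty = select_representatives(groups)
        assert selected == [a] and a.selected and not b.selected
        assert empty == []

    def test_group_with_no_confirmed_member_is_flagged(self):
        a = _fake("AAAAA", "AAAAA", -30.0)
        a.correct_confirm = False
        a.group_id = "G1"
        selected, empty = select_representatives([[a]])
        assert selected == [] and empty == ["G1"]

    def test_single_member_doubly_correct_selected(self):
        a = _fake("AAAAA", "AAAAA", -30.0)
        a.correct_confirm = True
        selected, _ = select_representatives([[a]])
        assert selected == [a]


class TestEndToEnd:
    def test_discrimination_screen(self, disc):
        cfg = ScreenConfig(core="A" * 10, library_size=2, seed=7)
        rep = run_screen(disc["spacers"], "C-L7", disc["parts"], cfg,
                         library=[disc["invading"], disc["preserving"]])
        sel = {(r.linkers.ext5, r.linkers.ext3) for r in rep.selected}
        assert sel == {("AAAAA", "AAAAA")}
        invader = next(r for r in rep.results if r.linkers.ext5 == "CCCCCCC")
        assert not invader.correct_primary and not invader.selected

    def test_seeded_screen_is_byte_deterministic(self, disc):
        cfg = ScreenConfig(core="A" * 10, library_size=6, seed=3, top_n=6)
        a = run_screen(disc["spacers"], "C-L7", disc["parts"], cfg)
        b = run_screen(disc["spacers"], "C-L7", disc["parts"], cfg)
        assert a.to_tsv() == b.to_tsv()
        assert a.manifest["config_digest"] == b.manifest["config_digest"]

    def test_report_order_independent_of_library_order(self, disc):
        cfg = ScreenConfig(core="A" * 10, library_size=6, seed=3, top_n=6)
        lib = generate_linker_library(cfg)
        fwd = run_screen(disc["spacers"], "C-L7", disc["parts"], cfg, library=lib)
        rev = run_screen(disc["spacers"], "C-L7", disc["parts"], cfg,
                         library=list(reversed(lib)))
        assert fwd.to_tsv() == rev.to_tsv()

    def test_selection_invariant_to_adding_incorrect_candidates(self, disc):
        cfg = ScreenConfig(core="A" * 10, library_size=2, seed=7)
        small = run_screen(disc["spacers"], "C-L7", disc["parts"], cfg,
                           library=[disc["preserving"]])
        padded = run_screen(disc["spacers"], "C-L7", disc["parts"], cfg,
                            library=[disc["preserving"], disc["invading"]])
        assert {r.key for r in small.selected} == {r.key for r in padded.selected}

    def test_structural_bounds(self, disc):
        cfg = ScreenConfig(core="A" * 10, library_size=8, seed=2, top_n=5)
        rep = run_screen(disc["spacers"], "C-L7", disc["parts"], cfg)
        assert len(rep.selected) <= len(rep.groups) <= 5

    def test_filter_monotonicity_under_threshold_tightening(self, disc):
        cfg = ScreenConfig(core="A" * 10, library_size=12, seed=5)
        lib = generate_linker_library(cfg)
        structures = []
        for lp in lib:
            c = assemble_construct(disc["spacers"], "C-L7", disc["parts"],
                                   linkers=lp)
            rna = transcript_construct(c)
            structures.append((fold(rna.sequence), rna))
        counts = []
        for rec, cross in ((0.5, 3), (0.8, 1), (1.0, 0)):
            motifs = motifs_from_parts(disc["parts"], min_pair_recovery=rec,
                                       max_cross_pairs=cross)
            counts.append(sum(
                check_correctness(s, rna, motifs)[1] for s, rna in structures
            ))
        assert counts[0] >= counts[1] >= counts[2]
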