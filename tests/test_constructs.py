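"""Cassette grammar, coordinate bookkeeping and circularisation."""

import numpy as np
import pytest

from circguide.constructs import (
    LinkerPair,
    SpacerSet,
    assemble_array,
    assemble_construct,
    canonical_rotation,
    predict_circle,
    transcribe,
    transcript_construct,
)
from circguide.errors import GrammarError, PartError
from circguide.fixtures import default_registry
from circguide.parts import Part, PartRegistry

LP = LinkerPair(ext5="ACACA", ext3="CACAC")


def roles_of(construct):
    return [f.role for f in construct.features]


class TestGrammars:
    def test_pre_is_spacer_flanked_by_two_scaffolds(self, parts, spacer_one):
        c = assemble_construct(spacer_one, "Pre", parts)
        assert roles_of(c) == ["promoter", "scaffold", "spacer", "scaffold"]
        assert c.topology == "pre_gRNA"

    def test_u6_27_mature_guide(self, parts, spacer_one):
        c = assemble_construct(spacer_one, "U6+27", parts)
        assert roles_of(c) == ["promoter", "scaffold", "spacer"]
        assert c.leader is not None and len(c.leader) == 27

    def test_circular_variants_carry_ribozymes_and_ligation(self, parts, spacer_one):
        for variant in ("C-Sp1", "C-Sp1-F30"):
            c = assemble_construct(spacer_one, variant, parts)
            r = roles_of(c)
            for needed in ("ribozyme_5p", "ribozyme_3p", "ligation_5p",
                           "ligation_3p"):
                assert needed in r, (variant, needed)
            assert c.topology == "circular_precursor"

    def test_t4at4_extension_ends_cassette(self, parts, spacer_one):
        c = assemble_construct(spacer_one, "gRNA+T4AT4", parts)
        assert c.sequence.endswith("TTTTATTTT")

    def test_linker_variant_aliases(self, parts, spacer_one):
        c7 = assemble_construct(spacer_one, "C-L7", parts, linkers=LP)
        generic = assemble_construct(spacer_one, "C-linker", parts, linkers=LP)
        assert c7.sequence == generic.sequence

    def test_d27_differs_only_by_leader(self, parts, spacer_one):
        full = assemble_construct(spacer_one, "C-L7", parts, linkers=LP)
        d27 = assemble_construct(spacer_one, "C-L7-d27", parts, linkers=LP)
        assert full.sequence == d27.sequence  # cassette body identical
        t_full = transcribe(full)
        t_d27 = transcribe(d27)
        assert t_full == transcribe("".join(
            p.sequence for p in [parts["leader27"]]
        )) + t_d27

    def test_csp1_length_is_sum_of_part_lengths(self, parts, spacer_one):
        c = assemble_construct(spacer_one, "C-Sp1", parts)
        expected = sum(
            len(parts[n]) for n in
            ("U6prom", "twister_p3_u2a", "lig5", "sp1_5p", "dr_scaffold",
             "dr_scaffold", "sp1_3p", "lig3", "twister_p1")
        ) + len(spacer_one.spacers[0][1])
        assert len(c) == expected

    def test_coordinates_match_independent_substring_scan(self, parts, spacer_one):
        # recompute each feature's start by scanning the concatenation
        c = assemble_construct(spacer_one, "C-Sp1", parts)
        pos = 0
        for f in c.features:
            sub = c.feature_seq(f)
            assert c.sequence[pos : pos + len(sub)] == sub
            assert f.start == pos
            pos += len(sub)
        assert pos == len(c)


class TestErrors:
    def test_empty_spacer_set_rejected(self):
        with pytest.raises(GrammarError):
            SpacerSet(spacers=())

    def test_spacer_length_bounds(self):
        with pytest.raises(GrammarError):
            SpacerSet.single("short", "ACGT")

    def test_unknown_variant(self, parts, spacer_one):
        with pytest.raises(GrammarError):
            assemble_construct(spacer_one, "C-X99-nope", parts)

    def test_missing_part(self, spacer_one):
        empty = PartRegistry([Part("U6prom", "promoter", "AAAA")])
        with pytest.raises(PartError):
            assemble_construct(spacer_one, "U6", empty)

    def test_linkers_required_for_linker_variants(self, parts, spacer_one):
        with pytest.raises(GrammarError):
            assemble_construct(spacer_one, "C-L7", parts, linkers=None)

    def test_single_spacer_rejected_for_arrays(self, parts, spacer_one):
        with pytest.raises(GrammarError):
            assemble_array(spacer_one, "multiplex-circular", parts, linkers=LP)


class TestMultiplex:
    def test_circular_array_feature_counts(self, parts, spacer_panel):
        three = SpacerSet(spacers=spacer_panel.spacers[:3])
        c = assemble_array(three, "multiplex-circular", parts, linkers=LP)
        assert len(c.features_with_role("spacer")) == 3
        assert len(c.features_with_role("scaffold")) >= 3

    def test_five_spacer_order_preserved(self, parts, spacer_panel):
        c = assemble_array(spacer_panel, "multiplex-circular", parts, linkers=LP)
        got = [f.part.split(":", 1)[1] for f in c.features_with_role("spacer")]
        assert got == [n for n, _ in spacer_panel.spacers]

    def test_linear_array_trailing_scaffold(self, parts, spacer_panel):
        c = assemble_array(spacer_panel, "multiplex-linear", parts)
        roles = roles_of(c)
        assert roles[-1] == "scaffold"
        assert roles.count("scaffold") == len(spacer_panel) + 1


class TestTilingProperty:
    @pytest.mark.parametrize("variant", ["U6+27", "Pre", "L-Sp1", "C-Sp1",
                                         "C-Sp1-F30", "C-L7", "gRNA+9",
                                         "gRNA+59", "gRNA+T4AT4"])
    def test_random_assemblies_tile_and_reassemble_identically(self, variant):
        rng = np.random.default_rng(17)
        for trial in range(25):
            reg = default_registry(seed=int(rng.integers(1000)))
            sp = SpacerSet.single(
                "t", "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 24))))
            )
            lp = LinkerPair(
                ext5="".join(rng.choice(list("ACGT"), 5)),
                ext3="".join(rng.choice(list("ACGT"), 7)),
            )
            a = assemble_construct(sp, variant, reg, linkers=lp)
            b = assemble_construct(sp, variant, reg, linkers=lp)
            # idempotence: byte-identical sequence and coordinates
            assert a.sequence == b.sequence and a.features == b.features
            # gap-free, overlap-free tiling reconstructs the sequence
            assert "".join(a.feature_seq(f) for f in a.features) == a.sequence


class TestCircularisation:
    def test_circle_length_is_between_cleavage_points(self, parts, spacer_one):
        pre = assemble_construct(spacer_one, "C-Sp1", parts)
        circ = predict_circle(pre, parts)
        rz5 = pre.features_with_role("ribozyme_5p")[0]
        rz3 = pre.features_with_role("ribozyme_3p")[0]
        assert len(circ) == rz3.start - rz5.end
        assert circ.topology == "circular_rna"

    def test_circle_contains_no_ribozyme_residues(self, parts, spacer_one):
        pre = assemble_construct(spacer_one, "C-Sp1", parts)
        circ = predict_circle(pre, parts)
        assert not [f for f in circ.features if f.role.startswith("ribozyme")]

    def test_circle_preserves_retained_nucleotides_in_order(self, parts, spacer_one):
        pre = assemble_construct(spacer_one, "C-Sp1", parts)
        circ = predict_circle(pre, parts)
        rz5 = pre.features_with_role("ribozyme_5p")[0]
        assert circ.sequence in pre.sequence[rz5.end:] + pre.sequence[rz5.end:]

    def test_canonical_start_at_ligation_junction(self, parts, spacer_one):
        pre = assemble_construct(spacer_one, "C-Sp1", parts)
        circ = predict_circle(pre, parts)
        assert circ.features[0].role == "ligation_5p"
        assert circ.sequence.startswith(parts["lig5"].sequence)

    def test_nonzero_offsets_wrap_ribozyme_residues_to_end(self, spacer_one):
        reg = default_registry(seed=0)
        parts2 = PartRegistry(
            [p if p.role != "ribozyme_5p"
             else Part(p.name, p.role, p.sequence, motif=p.motif,
                       cleavage_offset=len(p) - 2)
             for p in reg]
        )
        pre = assemble_construct(spacer_one, "C-Sp1", parts2)
        circ = predict_circle(pre, parts2)
        base = predict_circle(pre, default_registry(seed=0))
        assert len(circ) == len(base) + 2
        # equivalent up to rotation with the 2 retained residues appended
        assert circ.sequence.startswith(parts2["lig5"].sequence)
        assert canonical_rotation(circ.sequence) == canonical_rotation(
            circ.sequence[-2:] + circ.sequence[:-2]
        )

    def test_rejects_non_precursor(self, parts, spacer_one):
        lin = assemble_construct(spacer_one, "Pre", parts)
        with pytest.raises(GrammarError):
            predict_circle(lin, parts)


class TestTranscription:
    def test_t_to_u_mapping(self):
        assert transcribe("TTTTATTTT") == "UUUUAUUUU"
        assert transcribe("") == ""

    def test_random_sequence_length_preserved_no_t(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=100))
        rna = transcribe(seq)
        assert len(rna) == 100 and "T" not in rna

    def test_promoter_excluded_leader_prepended(self, parts, spacer_one):
        c = assemble_construct(spacer_one, "U6+27", parts)
        rna = transcript_construct(c)
        assert rna.features[0].part == "leader27"
        assert len(rna) == len(c) - len(parts["U6prom"]) + 27
        assert rna.sequence == transcribe(
            parts["leader27"].sequence
            + parts["dr_scaffold"].sequence
            + spacer_one.spacers[0][1]
        )

    def test_u6_variant_has_no_leader(self, parts, spacer_one):
        c = assemble_construct(spacer_one, "U6", parts)
        rna = transcript_construct(c)
        assert rna.features[0].role == "scaffold"
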