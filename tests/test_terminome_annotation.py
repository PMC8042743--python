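import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ntermflow.io_formats import AnalysisConfig, Compartment, ProteinEntry
from ntermflow.terminome_annotation import (
    MODIFICATIONS,
    MONOISOTOPIC_MASS,
    Category,
    ModificationSpec,
    NTermMod,
    NTermPeptide,
    WindowKind,
    annotate_peptides,
    classify_terminus,
    detect_precursors,
    map_peptide,
    mass_shift,
    offset_histogram,
    tally_categories,
)


class TestMassShift:
    # Independent oracle: hand-computed dot products with IUPAC monoisotopic
    # atomic masses (H 1.0078250, D 2.0141018, C 12, 13C 13.0033548,
    # N 14.0030740, O 15.9949146).
    ORACLE = {
        "dimethyl_light": 2 * 12.0 + 4 * 1.00782503207,
        "dimethyl_heavy": 2 * 13.00335483507 + 6 * 2.01410177785 - 2 * 1.00782503207,
        "acetyl": 2 * 12.0 + 2 * 1.00782503207 + 15.99491461957,
        "pyroglu_E": -(2 * 1.00782503207 + 15.99491461957),
        "pyroglu_Q": -(14.00307400443 + 3 * 1.00782503207),
    }

    @pytest.mark.parametrize("name", list(ORACLE))
    def test_agrees_with_elemental_oracle(self, name):
        assert mass_shift(MODIFICATIONS[name]) == pytest.approx(self.ORACLE[name], abs=1e-6)

    def test_empty_delta_is_zero(self):
        assert mass_shift(ModificationSpec("noop", {})) == 0.0

    def test_unknown_element_raises(self):
        with pytest.raises(KeyError, match="Xx"):
            mass_shift(ModificationSpec("bad", {"Xx": 1}))

    def test_heavy_minus_light_is_the_channel_spacing(self):
        # the 8.044 Da per-label spacing separating heavy from light channels
        delta = mass_shift(MODIFICATIONS["dimethyl_heavy"]) - mass_shift(
            MODIFICATIONS["dimethyl_light"]
        )
        assert delta == pytest.approx(8.04437, abs=1e-5)


class TestMapPeptide:
    def test_direct_match(self):
        assert map_peptide("AST", {"P1": "MASTK"}) == [("P1", 2)]

    def test_overlapping_hits_all_reported(self):
        assert map_peptide("AA", {"P1": "AAAA"}) == [("P1", 1), ("P1", 2), ("P1", 3)]

    def test_no_match_is_empty(self):
        assert map_peptide("XYZ", {"P1": "MASTK"}) == []

    def test_sorted_by_accession_then_position(self):
        hits = map_peptide("MK", {"B": "MKMK", "A": "AMK"})
        assert hits == [("A", 2), ("B", 1), ("B", 3)]


class TestClassifyTerminus:
    def test_position_1_is_start_site(self, plastid_protein, cfg):
        ann = classify_terminus(1, plastid_protein, cfg)
        assert ann.category is Category.POS1
        assert ann.expected

    def test_position_2_requires_initiator_met(self, cfg):
        no_met = ProteinEntry("P", "ASTKLMNPQ")
        ann = classify_terminus(2, no_met, cfg)
        assert ann.category is Category.UNANNOTATED

    def test_mature_terminus_at_predicted_cleavage(self, plastid_protein, cfg):
        # e.g. the protease's own mature N-terminus right after TP cleavage
        ann = classify_terminus(51, plastid_protein, cfg)
        assert ann.category is Category.CLEAVAGE_WINDOW
        assert ann.window_kind is WindowKind.TP_PLASTID
        assert ann.offset == 0

    def test_one_past_window_is_unannotated(self, plastid_protein, cfg):
        ann = classify_terminus(57, plastid_protein, cfg)
        assert ann.category is Category.UNANNOTATED
        assert ann.offset == 6
        assert not ann.expected

    def test_pos2_precedence_over_cleavage_window(self, cfg):
        protein = ProteinEntry("P", "MASTKLMNPQW", Compartment.PLASTID, cleavage_pos=3)
        ann = classify_terminus(2, protein, cfg)
        assert ann.category is Category.POS2
        assert ann.offset == -2  # still reported

    def test_precedence_order_by_enumeration(self, cfg):
        """Brute-force check of POS1 > POS2 > window > unannotated over all
        starts of a protein whose window overlaps the start site."""
        protein = ProteinEntry("P", "M" + "A" * 29, Compartment.SECRETORY, cleavage_pos=4)
        for start in range(1, 31):
            ann = classify_terminus(start, protein, cfg)
            if start == 1:
                expect = Category.POS1
            elif start == 2:
                expect = Category.POS2
            elif abs(start - 5) <= cfg.window_W:
                expect = Category.CLEAVAGE_WINDOW
            else:
                expect = Category.UNANNOTATED
            assert ann.category is expect, start

    def test_propeptide_sites_use_same_window_rule(self, cfg):
        protein = ProteinEntry("P", "M" + "A" * 99)  # no presequence
        without = classify_terminus(32, protein, cfg)
        assert without.category is Category.UNANNOTATED
        with_site = classify_terminus(32, protein, cfg, propeptide_sites=[30])
        assert with_site.category is Category.CLEAVAGE_WINDOW
        assert with_site.window_kind is WindowKind.PROPEPTIDE
        too_far = classify_terminus(40, protein, cfg, propeptide_sites=[30])
        assert too_far.category is Category.UNANNOTATED

    def test_out_of_range_start_raises(self, plastid_protein, cfg):
        with pytest.raises(ValueError):
            classify_terminus(0, plastid_protein, cfg)
        with pytest.raises(ValueError):
            classify_terminus(101, plastid_protein, cfg)

    @given(d=st.integers(min_value=0, max_value=5))
    @settings(deadline=None)
    def test_window_is_symmetric(self, d):
        cfg = AnalysisConfig()
        protein = ProteinEntry("P", "X" + "A" * 99, Compartment.PLASTID, cleavage_pos=50)
        left = classify_terminus(51 - d, protein, cfg)
        right = classify_terminus(51 + d, protein, cfg)
        assert (left.category is Category.CLEAVAGE_WINDOW) == (
            right.category is Category.CLEAVAGE_WINDOW
        )

    @given(start=st.integers(min_value=1, max_value=100))
    @settings(deadline=None)
    def test_every_start_gets_exactly_one_category(self, start):
        cfg = AnalysisConfig()
        protein = ProteinEntry("P", "M" + "A" * 99, Compartment.MITOCHONDRION, cleavage_pos=40)
        ann = classify_terminus(start, protein, cfg)
        assert ann.category in Category
        assert ann.expected == (ann.category is not Category.UNANNOTATED)


class TestNTermPeptide:
    def test_pyroglu_consistency_enforced(self):
        with pytest.raises(ValueError):
            NTermPeptide("ASTK", "P1", 2, NTermMod.PYROGLU_E)
        pep = NTermPeptide("QSTK", "P1", 2, NTermMod.PYROGLU_Q)
        assert pep.terminus_id == "P1@2"

    def test_validate_against_protein(self, tiny_proteome):
        pep = NTermPeptide("AST", "P1", 2, NTermMod.FREE_DIMETHYLATED)
        pep.validate_against(tiny_proteome["P1"])
        bad = NTermPeptide("TSA", "P1", 2, NTermMod.FREE_DIMETHYLATED)
        with pytest.raises(ValueError):
            bad.validate_against(tiny_proteome["P1"])


class TestAnnotatePeptides:
    def test_ambiguous_peptides_flagged_and_excluded_from_tally(self, cfg):
        proteome = {
            "A": ProteinEntry("A", "MSHARED"),
            "B": ProteinEntry("B", "MSHAREDK"),
        }
        pep = NTermPeptide("SHARED", "?", 0, NTermMod.FREE_DIMETHYLATED, terminus_id="amb")
        pep.accession = "?"  # force re-mapping
        ann = annotate_peptides([pep], proteome, cfg)
        assert ann.loc["amb", "accession"] == "A"  # lexicographically smallest
        assert bool(ann.loc["amb", "ambiguous"])
        assert tally_categories(ann)["total"].sum() == 0
        assert tally_categories(ann, include_ambiguous=True)["total"].sum() == 1

    def test_tally_is_exhaustive_and_disjoint(self, tiny_proteome, cfg):
        peps = [
            NTermPeptide("MASTK", "P1", 1, NTermMod.ACETYLATED),
            NTermPeptide("ASTKL", "P1", 2, NTermMod.FREE_DIMETHYLATED),
            NTermPeptide("SERLK", "P2", 61, NTermMod.FREE_DIMETHYLATED),
            NTermPeptide("QEGR", "P1", 8, NTermMod.PYROGLU_Q),
        ]
        ann = annotate_peptides(peps, tiny_proteome, cfg)
        tally = tally_categories(ann)
        assert tally["total"].sum() == len(peps)
        assert (tally["acetylated"] + tally["dimethylated"]).equals(tally["total"])
        assert tally.loc["POS1", "acetylated"] == 1
        assert tally.loc["CLEAVAGE_WINDOW", "total"] == 1

    def test_empty_input_tallies_to_zero(self, cfg):
        ann = annotate_peptides([], {}, cfg)
        assert tally_categories(ann)["total"].sum() == 0


class TestOffsetHistogram:
    def test_all_zero_offsets_single_bar(self):
        ann = pd.DataFrame({"offset": [0, 0, 0], "ambiguous": False})
        h = offset_histogram(ann)
        assert len(h) == 1
        assert h.iloc[0]["count"] == 3 and h.iloc[0]["in_window"]

    def test_counts_sum_to_defined_offsets(self):
        ann = pd.DataFrame({"offset": [0, 1, -2, np.nan, 7], "ambiguous": False})
        h = offset_histogram(ann, window_W=5)
        assert h["count"].sum() == 4
        assert not h.loc[h["offset"] == 7, "in_window"].iloc[0]

    def test_no_cleavage_proteins_empty(self):
        ann = pd.DataFrame({"offset": [np.nan, np.nan], "ambiguous": False})
        assert offset_histogram(ann).empty


class TestDetectPrecursors:
    def test_pos2_far_upstream_is_candidate(self, cfg):
        protein = ProteinEntry("P", "M" + "A" * 9 + "K" + "A" * 89, Compartment.PLASTID, cleavage_pos=60)
        proteome = {"P": protein}
        peps = [NTermPeptide("A" * 9 + "K", "P", 2, NTermMod.ACETYLATED)]
        ann = annotate_peptides(peps, proteome, cfg)
        cand = detect_precursors(ann, proteome, cfg)
        assert list(cand["start"]) == [2]
        assert bool(cand["quantifiable_via_lys"].iloc[0])

    def test_mature_terminus_is_not_candidate(self, plastid_protein, cfg):
        proteome = {"PLAST1": plastid_protein}
        seq = plastid_protein.sequence[50:58]
        peps = [NTermPeptide(seq, "PLAST1", 51, NTermMod.FREE_DIMETHYLATED)]
        ann = annotate_peptides(peps, proteome, cfg)
        assert detect_precursors(ann, proteome, cfg).empty

    def test_candidate_count_matches_brute_force(self, cfg):
        rng = np.random.default_rng(11)
        protein = ProteinEntry("P", "M" + "A" * 199, Compartment.PLASTID, cleavage_pos=60)
        proteome = {"P": protein}
        starts = rng.integers(1, 150, size=10)
        peps = [
            NTermPeptide(protein.sequence[s - 1 : s + 7], "P", int(s),
                         NTermMod.FREE_DIMETHYLATED, terminus_id=f"t{i}")
            for i, s in enumerate(starts)
        ]
        ann = annotate_peptides(peps, proteome, cfg)
        cand = detect_precursors(ann, proteome, cfg)
        expected = sum(1 for s in starts if s <= 60 - cfg.window_W)
        assert len(cand) == expected
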