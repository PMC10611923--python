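"""SLiM construction, scanning (vs a regex oracle) and the tiered screen."""
import re

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from h3k9net import (
    InteractomeCollection,
    PRESETS,
    SlimMotif,
    build_motif,
    evidence_crosscheck,
    motif_to_pattern,
    parse_pattern,
    scan_proteome,
    scan_sequence,
    tier_screen,
)
from h3k9net.mimicry import phase_split

FINAL = PRESETS["results_final"]
METHODS = PRESETS["methods_scansite"]


def regex_oracle(sequence: str, motif: SlimMotif) -> list[tuple[int, int]]:
    """Independent overlapping-window scan via regex lookahead."""
    pattern = "(?=(" + "".join("[" + re.escape("".join(sorted(c))) + "]" for c in motif.positions) + "))"
    return [
        (m.start() + 1, m.start() + motif.k_index)
        for m in re.finditer(pattern, sequence.upper())
    ]


class TestMotifConstruction:
    def test_union_by_position(self):
        motif = build_motif(["ARKS", "GRKT"])
        assert [set(c) for c in motif.positions] == [{"A", "G"}, {"R"}, {"K"}, {"S", "T"}]

    def test_single_residue_column(self):
        motif = build_motif(["ARKS", "ARKT"])
        assert motif.positions[0] == frozenset("A")
        assert motif.positions[1] == frozenset("R")

    def test_constructing_peptides_match_their_motif(self):
        rng = np.random.default_rng(0)
        alphabet = list("ACDEFGHILMNPQRSTVWY")
        for _ in range(20):
            peptides = [
                "".join(rng.choice(alphabet, 2)) + "K" + "".join(rng.choice(alphabet, 2))
                for _ in range(4)
            ]
            motif = build_motif(peptides, k_offset=3)
            for p in peptides:
                assert motif.matches(p)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            build_motif(["ARKS"])  # fewer than two peptides
        with pytest.raises(ValueError):
            build_motif(["ARKS", "GRKTT"])  # unequal lengths
        with pytest.raises(ValueError):
            build_motif(["ARAS", "GRKT"])  # missing K at target position


class TestPatternRoundTrip:
    def test_final_preset_canonical_form(self):
        assert motif_to_pattern(FINAL) == "[ACEGKLNS][R][K][AEGKLMNQRSTV]"

    def test_methods_preset_canonical_form(self):
        assert motif_to_pattern(METHODS) == "[ACGKLNS][R][K][AEGKLMNQRSTV]"

    def test_singletons_keep_brackets(self):
        assert motif_to_pattern(build_motif(["ARKS", "ARKS"])) == "[A][R][K][S]"

    @pytest.mark.parametrize("preset", sorted(PRESETS))
    def test_parse_print_identity(self, preset):
        motif = PRESETS[preset]
        assert parse_pattern(motif_to_pattern(motif)).positions == motif.positions

    def test_malformed_pattern_rejected(self):
        with pytest.raises(ValueError):
            parse_pattern("[AR]K[S]")


class TestScanner:
    @pytest.mark.parametrize("preset", sorted(PRESETS))
    def test_both_presets_accept_arks(self, preset):
        """The canonical histone H3 tail context is matched by both motif versions."""
        hits = scan_sequence("ARKS", PRESETS[preset])
        assert len(hits) == 1 and hits[0].k_position == 3

    def test_lysine_required(self):
        assert scan_sequence("ARAS", FINAL) == []

    def test_h3_tail_single_hit(self):
        # H3 N-terminal tail around K9: one motif window starting at A7
        hits = scan_sequence("QTARKSTGGKAPRKQ", FINAL)
        assert len(hits) == 1
        assert hits[0].start == 3 and hits[0].k_position == 5

    def test_nonstandard_letters_never_match(self):
        assert scan_sequence("XRKS", FINAL) == []
        assert scan_sequence("ARKX", FINAL) == []

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=100, deadline=None)
    def test_matches_regex_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWYX"), size=rng.integers(0, 200)))
        got = [(h.start, h.k_position) for h in scan_sequence(seq, FINAL)]
        assert got == regex_oracle(seq, FINAL)

    def test_proteome_scan_round_trips_planted_registry(self, bundle):
        table, hit_proteins = scan_proteome(bundle["sequences"], FINAL)
        registry = bundle["truth"].planted_motifs
        got = {
            p: sorted(g["k_position"].tolist()) for p, g in table.groupby("protein")
        }
        assert got == {p: sorted(v) for p, v in registry.items()}
        assert hit_proteins == set(registry)

    def test_empty_proteome(self):
        table, proteins = scan_proteome({}, FINAL)
        assert table.empty and proteins == set()

    def test_hit_set_invariant_to_ordering(self, bundle):
        seqs = bundle["sequences"]
        reordered = dict(reversed(list(seqs.items())))
        _, a = scan_proteome(seqs, FINAL)
        _, b = scan_proteome(reordered, FINAL)
        assert a == b


class TestTierScreen:
    def hits_frame(self, entries):
        return pd.DataFrame(entries, columns=["protein", "start", "k_position"])

    def test_toy_enumeration(self):
        hits = self.hits_frame([("P1", 1, 3), ("P2", 5, 7)])
        writers = InteractomeCollection({("EHMT1", "G1S"): {"P1", "P2"}})
        readers = InteractomeCollection({("CBX3", "G2M"): {"P2"}})
        table = tier_screen(hits, writers, readers)
        tier1 = set(table.loc[table["tier1"], "protein"])
        tier2 = set(table.loc[table["tier2"], "protein"])
        assert tier1 == {"P1", "P2"} and tier2 == {"P2"}
        p2 = table[table["protein"] == "P2"].iloc[0]
        assert p2["phases"] == "G1S,G2M"

    def test_absent_protein_gets_no_tier(self):
        hits = self.hits_frame([("LONER", 1, 3)])
        writers = InteractomeCollection({("EHMT1", "G1S"): {"P1"}})
        readers = InteractomeCollection({("CBX5", "G1S"): {"P1"}})
        table = tier_screen(hits, writers, readers)
        row = table.iloc[0]
        assert not row["tier1"] and not row["tier2"] and row["phases"] == ""

    def test_tier_nesting_invariant(self, bundle):
        table, motif_proteins = scan_proteome(bundle["sequences"], FINAL)
        truth = bundle["truth"]
        writers = InteractomeCollection(
            {k: v for k, v in truth.true_interactors.items() if k[0] in ("EHMT1", "EHMT2")}
        )
        readers = InteractomeCollection(
            {k: v for k, v in truth.true_interactors.items() if k[0] in ("CBX3", "CBX5")}
        )
        screened = tier_screen(table, writers, readers)
        tier1 = set(screened.loc[screened["tier1"], "protein"])
        tier2 = set(screened.loc[screened["tier2"], "protein"])
        assert tier2 <= tier1 <= motif_proteins
        assert (screened.loc[screened["tier1"], "phases"] != "").all()

    def test_intersection_mode_is_stricter(self):
        hits = self.hits_frame([("P1", 1, 3), ("P2", 1, 3)])
        writers = InteractomeCollection(
            {("EHMT1", "G1S"): {"P1", "P2"}, ("EHMT2", "G1S"): {"P1"}}
        )
        readers = InteractomeCollection({("CBX3", "G1S"): {"P1", "P2"}})
        union = tier_screen(hits, writers, readers, writer_mode="union")
        inter = tier_screen(hits, writers, readers, writer_mode="intersection")
        assert set(union.loc[union["tier1"], "protein"]) == {"P1", "P2"}
        assert set(inter.loc[inter["tier1"], "protein"]) == {"P1"}

    def test_phase_split_partitions_candidates(self):
        table = pd.DataFrame(
            {
                "protein": ["A", "B", "C"],
                "k_position": [3, 3, 3],
                "tier1": True,
                "tier2": True,
                "phases": ["G1S,G2M", "G1S", "G2M"],
                "evidence": False,
            }
        )
        split = phase_split(table)
        assert split == {"both": 1, "only_G1S": 1, "only_G2M": 1, "total": 3}


class TestEvidenceCrosscheck:
    def table(self):
        return pd.DataFrame(
            {
                "protein": ["P1", "P2"],
                "k_position": [9, 9],
                "tier1": True,
                "tier2": True,
                "phases": "G1S",
                "evidence": False,
            }
        )

    def test_empty_evidence_all_false(self):
        sites = pd.DataFrame(columns=["protein", "position", "modification"])
        assert not evidence_crosscheck(self.table(), sites)["evidence"].any()

    def test_exact_position_flagged_adjacent_not(self):
        sites = pd.DataFrame(
            {"protein": ["P2", "P1"], "position": [9, 10], "modification": ["me2", "me2"]}
        )
        out = evidence_crosscheck(self.table(), sites)
        flags = dict(zip(out["protein"], out["evidence"]))
        assert flags == {"P1": False, "P2": True}
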