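"""Spectral-count filtering: boundaries, reason attribution, oracle equivalence."""
import math

import numpy as np
import pandas as pd
import pytest

from h3k9net import (
    FilterConfig,
    SampleInfo,
    SpectralCountTable,
    classify_hits,
    flag_contaminants,
    flag_low_enrichment,
    log2_enrichment,
    qc_enrichment_ratio,
)
from h3k9net.config import ConfigurationError
from h3k9net.ipms import reason_tallies

from conftest import make_table


class TestLowEnrichment:
    @pytest.mark.parametrize(
        "count,min_peptides,flagged",
        [(3, 4, True), (4, 4, False), (0, 4, True), (3, 0, False)],
    )
    def test_strict_less_than_boundary(self, count, min_peptides, flagged):
        """'Fewer than four peptides' is a strict inequality: 4 passes."""
        table = make_table(
            {"B_G1S": {"P1": count}, "IgG_G1S": {"P1": 0}},
            {"B_G1S": ("B", "G1S"), "IgG_G1S": ("IgG", "G1S")},
        )
        result = flag_low_enrichment(table, "B", "G1S", min_peptides)
        assert ("P1" in result) is flagged

    def test_unknown_bait_raises(self, toy_counts):
        with pytest.raises(KeyError):
            flag_low_enrichment(toy_counts, "NOPE", "G1S")


class TestLog2Enrichment:
    @pytest.mark.parametrize(
        "bait,igg,pc,expected",
        [
            (0, 0, 1.0, 0.0),
            (16, 2, 1.0, math.log2(17 / 3)),  # 2.5025
            (8, 0, 1.0, math.log2(9)),  # 3.1699
            (10, 10, 1.0, 0.0),
        ],
    )
    def test_values(self, bait, igg, pc, expected):
        assert log2_enrichment(bait, igg, pc) == pytest.approx(expected, abs=1e-4)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            log2_enrichment(-1, 0)
        with pytest.raises(ValueError):
            log2_enrichment(1, 2, pseudocount=0)


class TestContaminantFlagging:
    def test_family_prefixes(self):
        proteins = ["KRT18", "EHMT2", "ACTB", "TUBB4A", "HIST1H1C", "KRAS"]
        flagged = flag_contaminants(proteins, ("ACT", "KRT", "TUB", "HIST"))
        assert flagged == {"KRT18", "ACTB", "TUBB4A", "HIST1H1C"}

    def test_empty_family_list(self):
        assert flag_contaminants(["KRT18"], ()) == set()


def brute_force_classify(table: SpectralCountTable, cfg: FilterConfig) -> set[tuple]:
    """Literal reimplementation of the three rules, for oracle comparison."""
    out = set()
    for sid, info in table.samples.items():
        if info.is_control or sid not in table.counts.columns:
            continue
        igg_sid = next(
            s
            for s, i in table.samples.items()
            if i.is_control and i.phase == info.phase and s in table.counts.columns
        )
        for protein in table.counts.index:
            c = int(table.counts.loc[protein, sid])
            if c == 0:
                continue
            g = int(table.counts.loc[protein, igg_sid])
            if c < cfg.min_peptides:
                reason = "low_enrichment"
            elif math.log2((c + cfg.pseudocount) / (g + cfg.pseudocount)) < cfg.log2fc_threshold:
                reason = "low_fold_change"
            elif str(protein).upper().startswith(tuple(f.upper() for f in cfg.contaminant_families)):
                reason = "contaminant"
            else:
                reason = "hit"
            out.add((protein, info.bait, info.phase, reason))
    return out


def random_table(rng: np.random.Generator) -> SpectralCountTable:
    proteins = [f"P{i}" for i in range(8)] + ["KRT1", "ACTB"]
    cols, samples = {}, {}
    for phase in ("G1S", "G2M"):
        for bait in ("EHMT1", "CBX5", "IgG"):
            sid = f"{bait}_{phase}"
            cols[sid] = {p: int(rng.integers(0, 30)) for p in proteins}
            samples[sid] = (bait, phase)
    return make_table(cols, samples)


class TestClassifyHits:
    def test_matches_brute_force_on_random_tables(self):
        cfg = FilterConfig()
        rng = np.random.default_rng(42)
        for _ in range(50):
            table = random_table(rng)
            hits = classify_hits(table, cfg)
            got = set(zip(hits["protein"], hits["bait"], hits["phase"], hits["reason"]))
            assert got == brute_force_classify(table, cfg)

    def test_enriched_contaminant_gets_contaminant_reason(self, toy_counts):
        hits = classify_hits(toy_counts)
        row = hits[(hits["protein"] == "KRT18") & (hits["bait"] == "EHMT1")].iloc[0]
        assert not row["status"] and row["reason"] == "contaminant"

    def test_first_failing_filter_wins(self, toy_counts):
        hits = classify_hits(toy_counts)
        by = {(r.protein, r.bait): r.reason for r in hits.itertuples(index=False)}
        assert by[("AAA1", "EHMT1")] == "hit"
        assert by[("BBB2", "EHMT1")] == "low_enrichment"
        assert by[("CCC3", "EHMT1")] == "low_fold_change"

    def test_reason_partition(self, toy_counts):
        hits = classify_hits(toy_counts)
        assert sum(reason_tallies(hits).values()) == len(hits)
        assert (hits["status"] == (hits["reason"] == "hit")).all()
        assert not hits.duplicated(["protein", "bait", "phase"]).any()

    def test_empty_table_gives_empty_hits(self):
        table = make_table(
            {"B_G1S": {}, "IgG_G1S": {}}, {"B_G1S": ("B", "G1S"), "IgG_G1S": ("IgG", "G1S")}
        )
        assert classify_hits(table).empty

    def test_missing_igg_is_configuration_error(self):
        table = make_table({"B_G1S": {"P1": 10}}, {"B_G1S": ("B", "G1S")})
        with pytest.raises(ConfigurationError):
            classify_hits(table)

    @pytest.mark.parametrize("param,loose,strict", [
        ("log2fc_threshold", 0.5, 2.0),
        ("min_peptides", 2, 8),
    ])
    def test_monotone_in_thresholds(self, param, loose, strict):
        """Raising either threshold never adds True hits."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            table = random_table(rng)
            sets = []
            for value in (loose, strict):
                hits = classify_hits(table, FilterConfig(**{param: value}))
                sets.append(
                    set(map(tuple, hits.loc[hits["status"], ["protein", "bait", "phase"]].values))
                )
            assert sets[1] <= sets[0]


class TestRecovery:
    def test_true_hits_equal_ground_truth(self, bundle):
        """With an 8x+ bait/IgG separation and sub-threshold noise the filter
        recovers the planted interactor sets exactly (precision = recall = 1)."""
        hits = classify_hits(bundle["counts"])
        truth = bundle["truth"]
        for (bait, phase), expected in truth.true_interactors.items():
            sel = hits[(hits["bait"] == bait) & (hits["phase"] == phase) & hits["status"]]
            assert set(sel["protein"]) == set(expected)


class TestQcRatio:
    def test_toy_arithmetic(self):
        table = make_table(
            {"B_G1S": {"A": 10, "B": 10}, "IgG_G1S": {"A": 10, "B": 0}},
            {"B_G1S": ("B", "G1S"), "IgG_G1S": ("IgG", "G1S")},
        )
        hits = pd.DataFrame(
            {
                "protein": ["A", "B"],
                "bait": "B",
                "phase": "G1S",
                "status": [False, True],
                "reason": ["low_fold_change", "hit"],
            }
        )
        before, after = qc_enrichment_ratio(table, hits, "B", "G1S", pseudocount=1.0)
        assert before == pytest.approx(2.0)
        assert after == pytest.approx(10.0)

    def test_filtration_increases_ratio_on_synthetic_data(self, bundle):
        counts = bundle["counts"]
        hits = classify_hits(counts)
        for bait in counts.baits:
            before, after = qc_enrichment_ratio(counts, hits, bait, "G1S")
            assert after > before
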