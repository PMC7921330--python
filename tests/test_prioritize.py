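import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirlens.core import DifferentialRecord, LensEnrichmentRecord
from mirlens.pairing import MiRnaMrnaPair
from mirlens.prioritize import (
    EVIDENCE_FLAGS,
    CorrelationResult,
    TierRuleSet,
    assign_tiers,
    enrichment_filter,
    inverse_correlation,
    pair_flags,
    set_p30_directions,
    tier_counts,
)


def make_pair(mirna="mirA", mrna="geneX", mirna_dir="up", p4=None, p30="missing", score=70.0):
    p4 = p4 or ("down" if mirna_dir == "up" else "up")
    return MiRnaMrnaPair(mirna, mrna, mirna_dir, p4, mrna_direction_p30=p30, prediction_score=score)


def enr(gene, fc, intensity, stage="p4"):
    return LensEnrichmentRecord(gene, stage, fc, intensity)


class TestTierRules:
    def test_default_truth_table(self):
        """Exhaustively check the default rules on all 16 flag combinations."""
        rules = TierRuleSet.default()
        for bits in itertools.product([False, True], repeat=4):
            flags = dict(zip(EVIDENCE_FLAGS, bits))
            de4, de30, e4, e30 = bits
            if de4 and de30 and e4 and e30:
                expected = "top"
            elif de4 and de30 and (e4 or e30):
                expected = "high"
            elif de4 and (e4 or e30):
                expected = "promising"
            else:
                expected = "unranked"
            assert rules.classify(flags) == expected, flags

    def test_custom_rules_parse_and_apply(self):
        rules = TierRuleSet.from_text(
            "top: de_p4 AND de_p30\n"
            "high: de_p4 OR de_p30\n"
            "promising: enriched_p4 AND (enriched_p30 OR de_p4)\n"
        )
        assert rules.classify({"de_p4": True, "de_p30": True, "enriched_p4": False, "enriched_p30": False}) == "top"
        assert rules.classify({"de_p4": False, "de_p30": True, "enriched_p4": False, "enriched_p30": False}) == "high"
        assert rules.classify({"de_p4": False, "de_p30": False, "enriched_p4": True, "enriched_p30": True}) == "promising"
        assert rules.classify({"de_p4": False, "de_p30": False, "enriched_p4": False, "enriched_p30": True}) == "unranked"

    @pytest.mark.parametrize(
        "text",
        [
            "top: de_p4\nhigh: de_p4\n",  # missing promising
            "top: de_p4\ntop: de_p30\nhigh: de_p4\npromising: de_p4\n",  # duplicate
            "top: de_p4 AND\nhigh: de_p4\npromising: de_p4\n",  # dangling AND
            "top: nonsense_flag\nhigh: de_p4\npromising: de_p4\n",  # unknown flag
            "top: (de_p4 AND de_p30\nhigh: de_p4\npromising: de_p4\n",  # unbalanced
            "legend: de_p4\nhigh: de_p4\npromising: de_p4\n",  # unknown tier
        ],
    )
    def test_malformed_rules_rejected(self, text):
        with pytest.raises(ValueError):
            TierRuleSet.from_text(text)

    def test_comments_and_blank_lines_ignored(self):
        rules = TierRuleSet.from_text(
            "# default-style rules\n\n"
            "top: de_p4 AND de_p30 AND enriched_p4 AND enriched_p30\n"
            "high: de_p4 AND de_p30 AND (enriched_p4 OR enriched_p30)\n"
            "promising: de_p4 AND (enriched_p4 OR enriched_p30)\n"
        )
        default = TierRuleSet.default()
        for bits in itertools.product([False, True], repeat=4):
            flags = dict(zip(EVIDENCE_FLAGS, bits))
            assert rules.classify(flags) == default.classify(flags)


class TestEnrichmentFilter:
    def test_floor_inclusive_and_fc_strict(self):
        pairs = [make_pair(mrna=g) for g in ("g1", "g2", "g3", "g4")]
        table = {
            "g1": enr("g1", 2.0, 100.0),  # at floor, fc > 1 -> enriched
            "g2": enr("g2", 2.0, 99.9),  # below floor
            "g3": enr("g3", 1.0, 500.0),  # fc not > 1
            # g4 absent from table
        }
        enrichment_filter(pairs, table, "p4")
        assert [p.enrichment_p4 is not None for p in pairs] == [True, False, False, False]

    def test_stage_validation(self):
        with pytest.raises(ValueError):
            enrichment_filter([], {}, "p7")

    def test_stages_independent(self):
        pair = make_pair(mrna="g1")
        enrichment_filter([pair], {"g1": enr("g1", 3.0, 200.0)}, "p4")
        enrichment_filter([pair], {}, "p30")
        assert pair.enrichment_p4 is not None and pair.enrichment_p30 is None


class TestFlagsAndTiers:
    def test_p30_direction_fill(self):
        pairs = [make_pair(mrna="g1"), make_pair(mrna="g2")]
        set_p30_directions(pairs, [DifferentialRecord("G1", 5.0, 10.0, -2.0, 0.01, direction="down")])
        assert pairs[0].mrna_direction_p30 == "down"
        assert pairs[1].mrna_direction_p30 == "missing"

    def test_pair_flags_opposite_logic(self):
        pair = make_pair(mirna_dir="down", p4="up", p30="up")
        flags = pair_flags(pair)
        assert flags["de_p4"] and flags["de_p30"]
        pair2 = make_pair(mirna_dir="down", p4="up", p30="down")
        assert not pair_flags(pair2)["de_p30"]

    def test_assign_tiers_end_to_end(self):
        pair = make_pair(mrna="g1", p30="down")
        enrichment_filter([pair], {"g1": enr("g1", 2.0, 150.0)}, "p4")
        enrichment_filter([pair], {"g1": enr("g1", 2.0, 150.0, stage="p30")}, "p30")
        assign_tiers([pair])
        assert pair.tier == "top"

    def test_tier_counts_best_tier_per_gene(self):
        # g1 reached "high" via mirB even though mirA only made "promising"
        a = make_pair(mirna="mirA", mrna="g1")
        b = make_pair(mirna="mirB", mrna="g1", p30="down")
        c = make_pair(mirna="mirC", mrna="g2")
        for p in (a, b, c):
            enrichment_filter([p], {p.mrna_id: enr(p.mrna_id, 2.0, 150.0)}, "p4")
        assign_tiers([a, b, c])
        counts = tier_counts([a, b, c], "up")
        assert counts == {"top": 0, "high": 1, "promising": 1, "unranked": 0}
        assert tier_counts([a, b, c], "down") == {"top": 0, "high": 0, "promising": 0, "unranked": 0}


def de_rec(fid, fc):
    d = "up" if fc > 1 else ("down" if fc < -1 else "unchanged")
    return DifferentialRecord(fid, 10.0, 10.0, fc, 0.01, direction=d)


class TestInverseCorrelation:
    def test_exact_inverse_gives_minus_one(self):
        mirna = [de_rec(f"m{i}", fc) for i, fc in enumerate([1.5, 2.0, 3.0, -1.5, -2.5])]
        mrna = [de_rec(f"g{i}", -fc if fc > 0 else -fc) for i, fc in enumerate([1.5, 2.0, 3.0, -1.5, -2.5])]
        pairs = [make_pair(mirna=f"m{i}", mrna=f"g{i}", mirna_dir="up" if i < 3 else "down", p4="down" if i < 3 else "up") for i in range(5)]
        result = inverse_correlation(pairs, mirna, mrna)
        assert result.r == pytest.approx(-1.0)
        assert result.n_pairs == 5

    def test_four_pair_covariance_oracle(self):
        """r recomputed from the covariance formula on signed log2 values."""
        import math

        mirna_fcs = [1.5, 2.0, -1.2, -3.0]
        mrna_fcs = [-1.3, -2.5, 1.4, 2.0]
        mirna = [de_rec(f"m{i}", fc) for i, fc in enumerate(mirna_fcs)]
        mrna = [de_rec(f"g{i}", fc) for i, fc in enumerate(mrna_fcs)]
        pairs = [
            make_pair(
                mirna=f"m{i}",
                mrna=f"g{i}",
                mirna_dir="up" if mirna_fcs[i] > 0 else "down",
                p4="down" if mirna_fcs[i] > 0 else "up",
            )
            for i in range(4)
        ]
        xs = [math.copysign(math.log2(abs(f)), f) for f in mirna_fcs]
        ys = [math.copysign(math.log2(abs(f)), f) for f in mrna_fcs]
        mx, my = sum(xs) / 4, sum(ys) / 4
        cov = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
        sx = math.sqrt(sum((x - mx) ** 2 for x in xs))
        sy = math.sqrt(sum((y - my) ** 2 for y in ys))
        result = inverse_correlation(pairs, mirna, mrna)
        assert result.r == pytest.approx(cov / (sx * sy))

    def test_too_few_pairs_rejected(self):
        mirna = [de_rec("m0", 2.0)]
        mrna = [de_rec("g0", -2.0)]
        with pytest.raises(ValueError, match=">= 3"):
            inverse_correlation([make_pair(mirna="m0", mrna="g0")], mirna, mrna)

    def test_zero_variance_rejected(self):
        mirna = [de_rec(f"m{i}", 2.0) for i in range(3)]
        mrna = [de_rec(f"g{i}", -fc) for i, fc in enumerate([1.5, 2.0, 3.0])]
        pairs = [make_pair(mirna=f"m{i}", mrna=f"g{i}") for i in range(3)]
        with pytest.raises(ValueError, match="variance"):
            inverse_correlation(pairs, mirna, mrna)

    def test_result_bounds_validated(self):
        with pytest.raises(ValueError):
            CorrelationResult(r=1.5, p=0.1, n_pairs=3)

    @given(
        fcs=st.lists(
            st.floats(min_value=1.05, max_value=16.0, allow_nan=False), min_size=3, max_size=12
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_perfectly_inverse_pairs_correlate_negatively(self, fcs):
        mirna = [de_rec(f"m{i}", fc) for i, fc in enumerate(fcs)]
        mrna = [de_rec(f"g{i}", -fc) for i, fc in enumerate(fcs)]
        pairs = [make_pair(mirna=f"m{i}", mrna=f"g{i}") for i in range(len(fcs))]
        try:
            result = inverse_correlation(pairs, mirna, mrna)
        except ValueError:
            # all fold changes identical -> zero variance, correctly rejected
            assert len(set(fcs)) == 1
            return
        assert result.r == pytest.approx(-1.0)
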