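"""Overlap arithmetic, concordance, mutation frequencies, amplification."""

import numpy as np
import pandas as pd
import pytest

from thyrosig import (
    DataError,
    amplification_stat,
    direction_concordance,
    mutation_frequencies,
    overlap_summary,
)
from thyrosig.cohort_stats import round_half_away
from thyrosig.consensus import ConsensusList


def _clist(group, up, down):
    probes = list(up) + list(down)
    return ConsensusList(
        group=group,
        threshold_fold=2.0,
        up=list(up),
        down=list(down),
        min_abs_ratio=pd.Series(1.0, index=probes),
    )


def synthetic_lists(ptc_up, ptc_down, shared_up, shared_down,
                    atc_up=1051, atc_down=1113):
    """Construct consensus lists realizing the given Venn counts."""
    pu = [f"u{i}" for i in range(ptc_up)]
    pdn = [f"d{i}" for i in range(ptc_down)]
    au = pu[:shared_up] + [f"au{i}" for i in range(atc_up - shared_up)]
    adn = pdn[:shared_down] + [f"ad{i}" for i in range(atc_down - shared_down)]
    return _clist("PTC", pu, pdn), _clist("ATC", au, adn)


class TestOverlapSummary:
    def test_published_counts_give_43_percent(self):
        ptc, atc = synthetic_lists(337, 173, 104, 114)
        ov = overlap_summary(ptc, atc)
        assert (ov.ptc_up, ov.ptc_down) == (337, 173)
        assert (ov.shared_up, ov.shared_down) == (104, 114)
        assert ov.pct_ptc_shared == 43  # 218/510 = 42.75 -> 43
        assert ov.opposite == 0

    def test_identical_lists_give_100_percent(self):
        a = _clist("PTC", ["p1", "p2"], ["p3"])
        b = _clist("ATC", ["p1", "p2"], ["p3"])
        ov = overlap_summary(a, b)
        assert ov.pct_ptc_shared == 100
        assert ov.opposite == 0

    def test_disjoint_lists_give_0_percent(self):
        a = _clist("PTC", ["p1"], ["p2"])
        b = _clist("ATC", ["q1"], ["q2"])
        assert overlap_summary(a, b).pct_ptc_shared == 0

    def test_opposite_direction_counted_separately(self):
        a = _clist("PTC", ["p1"], ["p2"])
        b = _clist("ATC", ["p2"], ["p1"])
        ov = overlap_summary(a, b)
        assert ov.opposite == 2
        assert ov.pct_ptc_shared == 0

    def test_invariant_to_probe_relabeling(self):
        ptc, atc = synthetic_lists(30, 20, 10, 5, atc_up=40, atc_down=25)
        relabel = {p: f"X_{p}" for p in
                   set(ptc.up + ptc.down + atc.up + atc.down)}
        ptc2 = _clist("PTC", [relabel[p] for p in ptc.up],
                      [relabel[p] for p in ptc.down])
        atc2 = _clist("ATC", [relabel[p] for p in atc.up],
                      [relabel[p] for p in atc.down])
        assert overlap_summary(ptc, atc) == overlap_summary(ptc2, atc2)


def test_round_half_away_from_zero():
    assert round_half_away(42.75) == 43
    assert round_half_away(36.36) == 36
    assert round_half_away(0.5) == 1
    assert round_half_away(-0.5) == -1
    assert round_half_away(9.0909) == 9


class TestDirectionConcordance:
    def test_perfect_and_inverted_agreement(self):
        a = pd.Series({"g1": 1.0, "g2": -2.0, "g3": 0.5})
        assert direction_concordance(a, a).fraction == 1.0
        assert direction_concordance(a, -a).fraction == 0.0

    def test_one_discordant_of_nine(self):
        a = pd.Series({f"g{i}": 1.0 for i in range(9)})
        b = a.copy()
        b["g0"] = -1.0
        out = direction_concordance(a, b)
        assert out.fraction == pytest.approx(8 / 9)
        assert out.n_compared == 9

    def test_symmetric_in_arguments(self):
        a = pd.Series({"g1": 1.0, "g2": -1.0, "g3": 2.0})
        b = pd.Series({"g1": 0.5, "g2": 1.5, "g3": -0.1})
        assert (direction_concordance(a, b).fraction
                == direction_concordance(b, a).fraction)

    def test_zeros_excluded_as_ties(self):
        a = pd.Series({"g1": 1.0, "g2": 0.0, "g3": -1.0})
        b = pd.Series({"g1": 2.0, "g2": 1.0, "g3": -0.5})
        out = direction_concordance(a, b)
        assert out.ties == ["g2"]
        assert out.n_compared == 2
        assert out.fraction == 1.0

    def test_empty_gene_set_is_data_error(self):
        with pytest.raises(DataError):
            direction_concordance(pd.Series(dtype=float), pd.Series(dtype=float))


def mutation_table(n_samples, mutated):
    """Long-format table; ``mutated`` maps gene -> sample indices carrying it."""
    genes = list(mutated)
    rows = []
    for i in range(1, n_samples + 1):
        for g in genes:
            rows.append([f"ATC{i}", g, int(i in mutated[g])])
    return pd.DataFrame(rows, columns=["sample_id", "gene", "status"])


class TestMutationFrequencies:
    def test_published_atc_frequencies(self):
        # 4/11 TP53 -> 36%, 2/11 BRAF -> 18%, 1/11 PIK3CA -> 9%
        table = mutation_table(
            11, {"TP53": {1, 2, 3, 4}, "BRAF": {1, 5}, "PIK3CA": {6},
                 "HRAS": set()}
        )
        out = mutation_frequencies(table)
        assert out.counts == {"TP53": 4, "BRAF": 2, "PIK3CA": 1, "HRAS": 0}
        assert out.percents["TP53"] == 36
        assert out.percents["BRAF"] == 18
        assert out.percents["PIK3CA"] == 9
        assert out.percents["HRAS"] == 0

    def test_co_occurrence_reported_per_sample(self):
        table = mutation_table(3, {"TP53": {1}, "BRAF": {1, 2}})
        out = mutation_frequencies(table)
        assert out.co_mutated_samples == {"ATC1": ["BRAF", "TP53"]}

    def test_empty_table_is_data_error(self):
        empty = pd.DataFrame(columns=["sample_id", "gene", "status"])
        with pytest.raises(DataError):
            mutation_frequencies(empty)


class TestAmplificationStat:
    def test_zero_noise_recovers_generator_factor_exactly(self, zero_noise_cohort):
        _, ratios, sheet, truth = zero_noise_cohort
        shared = truth.probes("SHARED_UP", "SHARED_DOWN")
        out = amplification_stat(ratios, sheet, shared)
        assert np.allclose(out.per_probe.to_numpy(), 2.0, atol=1e-12)
        assert out.median == pytest.approx(2.0, abs=1e-12)
        assert out.excluded == []

    def test_identical_effects_give_unit_statistic(self):
        cols = ["a1", "a2", "p1", "p2"]
        m = pd.DataFrame([[1.4, 1.4, 1.4, 1.4]], index=["pr1"], columns=cols)
        sheet = pd.Series(["ATC", "ATC", "PTC", "PTC"], index=cols)
        out = amplification_stat(m, sheet, ["pr1"])
        assert out.median == pytest.approx(1.0)

    def test_noisy_default_scenario_median_near_two(self, default_cohort):
        _, ratios, sheet, truth = default_cohort
        shared = truth.probes("SHARED_UP", "SHARED_DOWN")
        out = amplification_stat(ratios, sheet, shared)
        assert 1.8 <= out.median <= 2.2

    def test_zero_denominator_probe_flagged_and_excluded(self):
        cols = ["a1", "p1", "p2"]
        m = pd.DataFrame(
            [[2.0, 0.0, 0.0], [2.0, 1.0, 1.0]], index=["z", "ok"], columns=cols
        )
        sheet = pd.Series(["ATC", "PTC", "PTC"], index=cols)
        out = amplification_stat(m, sheet, ["z", "ok"])
        assert out.excluded == ["z"]
        assert out.median == pytest.approx(2.0)

    def test_empty_shared_set_is_data_error(self, default_cohort):
        _, ratios, sheet, _ = default_cohort
        with pytest.raises(DataError):
            amplification_stat(ratios, sheet, [])
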