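"""Movement classification, fate rules, truncation, pooling, covariates."""

import numpy as np
import pytest

from wintercmr.histories import (
    EncounterHistory,
    FishRecord,
    ReachTable,
    TrackingRecord,
    build_history,
    classify_fate,
    default_reach_table,
    discernible_moves,
    fish_covariates,
    fulton_condition,
    pool_occasions,
    return_rate,
    truncate_mortality,
)


def fish(group="adult_trout", spring=False, **kw):
    defaults = dict(fish_id="F1", group=group, length_mm=180.0, weight_g=60.0, subreach_id=2)
    defaults.update(kw)
    return FishRecord(spring_recaptured=spring, **defaults)


def recs(positions, start=1, lateral=None):
    lateral = lateral or [False] * len(positions)
    return [
        TrackingRecord(fish_id="F1", occasion=start + i, detected=True, position_m=p, lateral=l)
        for i, (p, l) in enumerate(zip(positions, lateral))
    ]


class TestDiscernibleMoves:
    def test_below_accuracy_is_none(self):
        assert discernible_moves(recs([100.0, 100.4])) == ["none"]

    def test_sign_gives_direction(self):
        assert discernible_moves(recs([100.0, 103.0])) == ["upstream"]
        assert discernible_moves(recs([103.0, 100.0])) == ["downstream"]

    def test_single_detection_empty(self):
        assert discernible_moves(recs([100.0])) == []

    def test_random_walk_matches_pairwise_oracle(self):
        rng = np.random.default_rng(3)
        pos = np.cumsum(rng.normal(0, 2, 30)) + 100
        got = discernible_moves(recs(list(pos)))
        expect = []
        for a, b in zip(pos[:-1], pos[1:]):
            d = b - a
            expect.append("none" if abs(d) <= 0.5 else ("upstream" if d > 0 else "downstream"))
        assert got == expect


class TestClassifyFate:
    def test_never_detected_is_transient(self):
        assert classify_fate(fish(), []) == "transient"

    def test_downstream_only_not_recaptured_is_transient(self):
        assert classify_fate(fish(spring=False), recs([100, 95, 90])) == "transient"

    def test_downstream_only_but_recaptured_is_resident(self):
        assert classify_fate(fish(spring=True), recs([100, 95, 90])) == "resident"

    def test_one_upstream_move_is_resident(self):
        assert classify_fate(fish(), recs([100.0, 103.0])) == "resident"

    def test_stationary_tag_is_transient(self):
        assert classify_fate(fish(), recs([100.0, 100.2, 99.9, 100.1])) == "transient"

    def test_lateral_activity_qualifies_residency(self):
        r = recs([100.0, 100.0], lateral=[False, True])
        assert classify_fate(fish(), r) == "resident"


class TestTruncateMortality:
    def test_not_dead_identity(self):
        h = build_history("F1", recs([100, 103, 99]), n_occasions=10)
        assert np.array_equal(truncate_mortality(h, recs([100, 103, 99]), False).bits, h.bits)

    def test_zeroed_after_last_upstream_move(self):
        # upstream move completed at occasion 10; stray detections at 12-14
        r = recs([100.0, 105.0], start=9) + recs([105.2, 105.1, 104.9], start=12)
        h = build_history("F1", r, n_occasions=26)
        out = truncate_mortality(h, r, True)
        assert out.bits[9] == 1 and out.bits[10] == 1
        assert np.all(out.bits[11:] == 0)

    def test_upstream_at_final_occasion_no_change(self):
        r = recs([100.0, 105.0], start=25)
        h = build_history("F1", r, n_occasions=26)
        assert np.array_equal(truncate_mortality(h, r, True).bits, h.bits)

    def test_no_upstream_move_zeroes_after_marking_with_warning(self):
        r = recs([100.0, 99.0], start=3)
        h = build_history("F1", r, n_occasions=10)
        with pytest.warns(UserWarning, match="no upstream move"):
            out = truncate_mortality(h, r, True)
        assert out.bits[0] == 1 and np.all(out.bits[1:] == 0)


class TestPooling:
    def test_or_rule(self):
        h = EncounterHistory("F1", [1, 1, 0, 0, 0, 0, 1, 1, 1])
        pooled = pool_occasions(h)
        assert list(pooled.bits) == [1, 1, 0, 1, 1]
        assert pooled.pooled

    def test_all_ones_keeps_all_ones(self):
        h = EncounterHistory("F1", [1] + [1] * 26)
        pooled = pool_occasions(h)
        assert len(pooled.bits) == 14 and np.all(pooled.bits == 1)

    def test_pooled_one_wherever_either_source_week_detected(self):
        rng = np.random.default_rng(5)
        weekly = rng.integers(0, 2, 26)
        pooled = pool_occasions(EncounterHistory("F1", [1, *weekly]))
        assert np.array_equal(pooled.bits[1:], weekly.reshape(13, 2).max(axis=1))

    def test_odd_structure_errors(self):
        with pytest.raises(ValueError):
            pool_occasions(EncounterHistory("F1", [1, 1, 0, 1]), width=2)


class TestReturnRate:
    def test_always_detected(self):
        hs = [EncounterHistory(f"F{i}", [1] * 9) for i in range(5)]
        out = return_rate(hs)
        assert np.all(out["rates"] == 1.0)
        assert out["cv"] == 0.0 and out["factor"] == 1.0

    def test_factor_and_cv_against_direct_oracle(self):
        rng = np.random.default_rng(9)
        mat = rng.integers(0, 2, (40, 12))
        hs = [EncounterHistory(f"F{i}", [1, *row]) for i, row in enumerate(mat)]
        out = return_rate(hs)
        rates = mat.mean(axis=0)
        assert np.allclose(out["rates"], rates)
        assert out["cv"] == pytest.approx(rates.std(ddof=1) / rates.mean())
        if rates.min() > 0:
            assert out["factor"] == pytest.approx(rates.max() / rates.min())

    def test_two_rate_factor(self):
        hs = [
            EncounterHistory("a", [1, 1, 1]),
            EncounterHistory("b", [1, 0, 1]),
            EncounterHistory("c", [1, 0, 0]),
            EncounterHistory("d", [1, 0, 1]),
            EncounterHistory("e", [1, 0, 1]),
        ]
        out = return_rate(hs)  # rates 0.2 and 0.8
        assert out["factor"] == pytest.approx(4.0)


class TestFultonCondition:
    @pytest.mark.parametrize(
        "length_mm,weight_g,expected",
        [(100.0, 10.0, 1.0), (150.0, 33.75, 1.0), (150.0, 40.0, 1.1852)],
    )
    def test_values(self, length_mm, weight_g, expected):
        assert fulton_condition(length_mm, weight_g) == pytest.approx(expected, abs=1e-4)

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            fulton_condition(0, 10)


class TestFishCovariates:
    def test_midreach_distance(self):
        reach = ReachTable(
            subreach_id=[1, 2],
            length_m=[275, 275],
            mean_depth_cm=[20, 20],
            complexity=[30, 30],
        )
        out = fish_covariates(fish(subreach_id=1), recs([275.0]), reach)
        assert out["distance"] == pytest.approx(275.0)

    def test_tag_burden_adult(self):
        f = fish(weight_g=46.0)  # 23-mm tag weighs 0.6 g
        out = fish_covariates(f, recs([100.0]), default_reach_table())
        assert out["tag_burden"] == pytest.approx(0.013, abs=5e-4)

    def test_complexity_from_single_subreach(self, reach):
        # positions inside subreach 2 (42..91 m from the downstream end)
        out = fish_covariates(fish(subreach_id=2), recs([50.0, 60.0]), reach)
        assert out["complex"] == pytest.approx(46.1)

    def test_condition_recovered_exactly(self, reach):
        f = fish(length_mm=150.0, weight_g=33.75)
        out = fish_covariates(f, recs([50.0]), reach)
        assert out["cond"] == pytest.approx(1.0)

    def test_no_detections_falls_back_to_tagging_subreach(self, reach):
        with pytest.warns(UserWarning, match="no detections"):
            out = fish_covariates(fish(subreach_id=2), [], reach)
        assert out["complex"] == pytest.approx(46.1)


def test_fate_partition_is_exhaustive(sim_dataset):
    """Every tagged fish ends up resident or transient; counts sum to total."""
    by_fish = {f.fish_id: [] for f in sim_dataset.registry}
    for r in sim_dataset.tracking:
        by_fish[r.fish_id].append(r)
    fates = [classify_fate(f, by_fish[f.fish_id]) for f in sim_dataset.registry]
    assert set(fates) <= {"resident", "transient"}
    assert len(fates) == len(sim_dataset.registry)
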