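"""Trial orchestration: randomization, candidate sets, selection, variants."""

from dataclasses import replace

import numpy as np
import pytest

from greatwall import (
    DesignConfig,
    DoseCombo,
    candidate_set_C2,
    go_nogo,
    randomize_equal,
    run_trial,
    select_odc,
)


def doses(*pairs):
    return [DoseCombo(*p) for p in pairs]


class TestRandomizeEqual:
    def test_divisible_allocation(self):
        alloc = randomize_equal(36, doses((1, 1), (1, 2), (1, 3), (2, 1), (2, 2), (2, 3)),
                                np.random.default_rng(0))
        assert all(v == 6 for v in alloc.values())

    def test_remainder_spread_over_distinct_doses(self):
        alloc = randomize_equal(20, doses((1, 1), (1, 2), (1, 3)), np.random.default_rng(1))
        assert sorted(alloc.values(), reverse=True) == [7, 7, 6]

    def test_zero_patients(self):
        alloc = randomize_equal(0, doses((1, 1), (2, 1)), np.random.default_rng(0))
        assert sum(alloc.values()) == 0

    def test_empty_dose_set_rejected(self):
        with pytest.raises(ValueError):
            randomize_equal(5, [], np.random.default_rng(0))

    @pytest.mark.parametrize("n,m", [(17, 5), (3, 7), (50, 6)])
    def test_sum_and_balance_invariants(self, n, m):
        ds = doses(*[(1, k) for k in range(1, m + 1)])
        alloc = randomize_equal(n, ds, np.random.default_rng(n * m))
        assert sum(alloc.values()) == n
        assert max(alloc.values()) - min(alloc.values()) <= 1


class TestCandidateSets:
    def test_gamma_threshold(self):
        u = dict(zip(doses((1, 1), (1, 2), (1, 3)), [0.70, 0.50, 0.48]))
        c2 = candidate_set_C2(u, list(u), 0.7)
        assert c2 == doses((1, 1), (1, 2))

    def test_gamma_one_keeps_argmax_only(self):
        u = dict(zip(doses((1, 1), (1, 2)), [0.7, 0.5]))
        assert candidate_set_C2(u, list(u), 1.0) == doses((1, 1))

    def test_empty_a2_gives_empty_c2(self):
        assert candidate_set_C2({}, [], 0.7) == []


class TestSelectOdc:
    def test_strict_argmax(self):
        km = dict(zip(doses((1, 1), (1, 2)), [0.55, 0.35]))
        assert select_odc(list(km), km, {}) == DoseCombo(1, 1)

    def test_tie_broken_by_utility_then_total_dose(self):
        ds = doses((1, 2), (2, 1), (1, 1))
        km = {d: 0.5 for d in ds}
        util = {DoseCombo(1, 2): 0.8, DoseCombo(2, 1): 0.6, DoseCombo(1, 1): 0.6}
        assert select_odc(ds, km, util) == DoseCombo(1, 2)
        util = {d: 0.6 for d in ds}
        assert select_odc(ds, km, util) == DoseCombo(1, 1)

    def test_empty_candidate_set(self):
        assert select_odc([], {}, {}) is None


class TestGoNogo:
    @pytest.mark.parametrize("km,expected", [(0.55, "Go"), (0.30, "NoGo"), (0.10, "NoGo")])
    def test_strict_inequality_at_floor(self, km, expected):
        assert go_nogo(km, 0.3) == expected


class TestRunTrial:
    def test_all_safe_all_efficacious_uses_full_budget(self, config, stub_source):
        result = run_trial(stub_source(2, 3), config, seed=0)
        assert result.selected is not None
        assert result.go
        assert result.n_total == config.n1 + config.n2 + config.n3 == 74
        assert result.terminal_stage == 3

    def test_first_cohort_wall_terminates_with_three_patients(self, config, stub_source):
        result = run_trial(stub_source(2, 3, dlt={(1, 1): 3}), config, seed=0)
        assert result.selected is None
        assert not result.go
        assert result.n_total == 3
        assert result.terminal_stage == 1

    def test_low_survival_triggers_nogo(self, config, stub_source):
        result = run_trial(stub_source(2, 3, time=1.0), config, seed=0)
        assert result.selected is None
        assert result.no_selection_reason == "no-go"
        assert result.odc_candidate is not None

    def test_candidate_sets_nested_and_selection_inside(self, library, config):
        for seed in range(25):
            r = run_trial(library[4], config, seed)
            if "C3" in r.sets:
                assert set(r.sets["C3"]) <= set(r.sets["C2"])
                assert set(r.sets["C2"]) <= set(r.sets["A2"])
            if r.selected is not None:
                assert r.selected in r.sets["C3"]

    def test_sample_size_accounting_exact(self, library, config):
        for seed in range(25):
            r = run_trial(library[6], config, seed)
            assert r.n_total == int(r.n_by_dose.sum())
            assert r.n_total == int(r.n_by_stage_dose.sum())
            assert r.n_total <= config.n1 + config.n2 + config.n3

    def test_no_patient_at_excluded_dose(self, library, config):
        """Patients are never treated above a wall or at an excluded dose."""
        for seed in range(25):
            r = run_trial(library[1], config, seed)
            treated = {
                DoseCombo(j + 1, k + 1)
                for j, k in zip(*np.nonzero(r.n_by_dose))
            }
            admissible_after_stage1 = set(r.sets["AT1"]) | set()
            for stage in (2, 3):
                stage_doses = {
                    DoseCombo(j + 1, k + 1)
                    for j, k in zip(*np.nonzero(r.n_by_stage_dose[stage - 1]))
                }
                assert stage_doses <= set(r.sets["A1"]) | set(r.sets.get("C2", []))

    def test_seeded_reproducibility_bitwise(self, library, config):
        a = run_trial(library[5], config, 123)
        b = run_trial(library[5], config, 123)
        assert a.to_json() == b.to_json()

    def test_conv1_and_greatwall_share_stage1_trajectory(self, library, config):
        for seed in range(20):
            gw = run_trial(library[3], config, seed)
            cv = run_trial(library[3], config.with_variant("conv1"), seed)
            np.testing.assert_array_equal(gw.n_by_stage_dose[0], cv.n_by_stage_dose[0])
            assert gw.sets["A1"] == cv.sets["A1"]

    def test_conv1_total_budget_matches_greatwall_maximum(self, config, stub_source):
        r = run_trial(stub_source(2, 3), config.with_variant("conv1"), 0)
        assert r.n_total == 74
        assert r.terminal_stage == 2
        assert r.selected is not None

    def test_greatwall_m_skips_stage2_candidate_refinement(self, config, stub_source):
        r = run_trial(stub_source(2, 3), config.with_variant("greatwall-m"), 0)
        assert r.n_total == 74
        assert "C2" not in r.sets
        assert r.selected is not None

    def test_invalid_config_rejected_before_treatment(self, library):
        bad = DesignConfig(gamma=0.0)
        with pytest.raises(ValueError):
            run_trial(library[1], bad, 0)

    def test_result_json_round_trip(self, library, config):
        import json

        r = run_trial(library[7], config, 5)
        payload = json.loads(r.to_json())
        assert payload["n_total"] == r.n_total
        assert payload["variant"] == "greatwall"
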