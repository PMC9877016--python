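import json

import numpy as np
import pytest

from spinedyn.annotations import PRESENT, read_annotations, validate
from spinedyn.simulate import (
    GroupParams,
    SimulationConfig,
    TreatmentModifier,
    default_scenarios,
    null_scenarios,
    recover_loss_modifier,
    simulate_roi,
    simulate_study,
    write_study,
)

SHORT_DAYS = (1, 4, 7, 10, 13)


def one_group_config(**overrides):
    base = dict(
        n_mice=2,
        n_rois=4,
        baseline_density=0.3,
        gain_rate=0.02,
        survival_persistent=0.95,
        survival_nascent=0.7,
    )
    base.update(overrides)
    return SimulationConfig(
        session_days=SHORT_DAYS,
        groups={"young_vehicle": GroupParams(**base)},
        missing_session_prob=0.0,
    )


class TestSimulateRoi:
    def test_frozen_dynamics(self):
        cfg = one_group_config(
            gain_rate=0.0, survival_persistent=1.0, survival_nascent=1.0
        )
        rng = np.random.default_rng(0)
        s = simulate_roi(cfg, "young", "vehicle", "r1", "m1", rng)
        first = s.present_mask(SHORT_DAYS[0])
        for d in SHORT_DAYS[1:]:
            assert (s.present_mask(d) == first).all()

    def test_total_extinction(self):
        cfg = one_group_config(
            gain_rate=0.0, survival_persistent=0.0, survival_nascent=0.0
        )
        rng = np.random.default_rng(1)
        s = simulate_roi(cfg, "young", "vehicle", "r1", "m1", rng)
        assert s.n_present(SHORT_DAYS[0]) > 0
        for d in SHORT_DAYS[1:]:
            assert s.n_present(d) == 0

    def test_unknown_group_rejected(self):
        cfg = one_group_config()
        with pytest.raises(ValueError):
            simulate_roi(cfg, "old", "THC", "r1", "m1", np.random.default_rng(0))

    def test_initial_count_matches_poisson_mean(self):
        cfg = one_group_config(baseline_density=0.4)
        counts, mus = [], []
        for seed in range(150):
            rng = np.random.default_rng(seed)
            s = simulate_roi(cfg, "young", "vehicle", "r1", "m1", rng)
            counts.append(s.n_present(SHORT_DAYS[0]))
            mus.append(0.4 * s.total_dendrite_length_um)
        total, mu = np.sum(counts), np.sum(mus)
        # Poisson total: observed within 3 SD of the analytic mean
        assert abs(total - mu) < 3 * np.sqrt(mu)

    def test_doubling_density_doubles_initial_density(self):
        dens = {}
        for d0 in (0.2, 0.4):
            cfg = one_group_config(baseline_density=d0)
            vals = []
            for seed in range(100):
                rng = np.random.default_rng(seed)
                s = simulate_roi(cfg, "young", "vehicle", "r1", "m1", rng)
                vals.append(s.n_present(SHORT_DAYS[0]) / s.total_dendrite_length_um)
            dens[d0] = np.mean(vals)
        assert dens[0.4] / dens[0.2] == pytest.approx(2.0, rel=0.1)


class TestSimulateStudy:
    def test_fixed_seed_is_bit_identical(self, tmp_path):
        cfg = default_scenarios()
        a = simulate_study(cfg, seed=11)
        b = simulate_study(cfg, seed=11)
        assert len(a) == len(b)
        assert all(x.equals(y) for x, y in zip(a, b))
        p1, _ = write_study(cfg, tmp_path / "run1", seed=11)
        p2, _ = write_study(cfg, tmp_path / "run2", seed=11)
        assert p1.read_bytes() == p2.read_bytes()

    def test_group_sizes_match_configuration(self):
        cfg = default_scenarios()
        series = simulate_study(cfg, seed=2)
        counts = {}
        mice = {}
        for s in series:
            counts[s.group] = counts.get(s.group, 0) + 1
            mice.setdefault(s.group, set()).add(s.mouse_id)
        assert counts[("old", "THC")] == 22 and len(mice[("old", "THC")]) == 10
        assert counts[("old", "vehicle")] == 17 and len(mice[("old", "vehicle")]) == 8
        assert counts[("young", "THC")] == 12 and len(mice[("young", "THC")]) == 4
        assert counts[("young", "vehicle")] == 10 and len(mice[("young", "vehicle")]) == 4

    def test_default_study_validates_and_roundtrips(self, tmp_path):
        cfg = default_scenarios()
        series = simulate_study(cfg, seed=5)
        assert validate(series).ok
        csv_path, meta_path = write_study(cfg, tmp_path, seed=5)
        back = read_annotations(csv_path, cfg.schedule)
        by_id = {s.roi_id: s for s in back}
        assert len(back) == len(series)
        for s in series:
            assert by_id[s.roi_id].equals(s)
        meta = json.loads(meta_path.read_text())
        assert meta["seed"] == 5 and meta["n_rois"] == len(series)

    def test_stationary_balance_keeps_density_flat(self):
        # gains == expected losses per interval for a persistent-only
        # population: mean density should drift < 2% across the schedule
        density, gain = 0.3, 0.3 * (1 - 0.95)
        cfg = SimulationConfig(
            session_days=tuple(range(0, 43, 3)),
            groups={
                "young_vehicle": GroupParams(
                    n_mice=2,
                    n_rois=4,
                    baseline_density=density,
                    gain_rate=gain,
                    survival_persistent=0.95,
                    survival_nascent=0.95,
                    nascent_threshold=0,
                )
            },
            missing_session_prob=0.0,
        )
        days = cfg.session_days
        first, last = [], []
        for seed in range(200):
            for s in simulate_study(cfg, seed=seed):
                first.append(s.n_present(days[0]) / s.total_dendrite_length_um)
                last.append(s.n_present(days[-1]) / s.total_dendrite_length_um)
        drift = abs(np.mean(last) - np.mean(first)) / np.mean(first)
        assert drift < 0.02

    def test_modifier_window_affects_only_window(self):
        base = dict(
            n_mice=1,
            n_rois=1,
            baseline_density=0.5,
            gain_rate=0.0,
            survival_persistent=0.9,
            survival_nascent=0.9,
        )
        mod = TreatmentModifier(
            metric="loss_hazard_persistent", multiplier=0.0001, window=(4, 13)
        )
        cfg = SimulationConfig(
            session_days=SHORT_DAYS,
            groups={"young_THC": GroupParams(modifiers=[mod], **base)},
            missing_session_prob=0.0,
        )
        # with a near-zero loss hazard inside the window, presence is frozen
        # from day 4 onward
        survived = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            s = simulate_roi(cfg, "young", "THC", "r1", "m1", rng)
            survived.append(s.n_present(13) / max(s.n_present(4), 1))
        assert np.mean(survived) > 0.999


class TestRecoverLossModifier:
    def _simulate_old_pair(self, multiplier, seed):
        cfg = default_scenarios()
        groups = {
            k: v for k, v in cfg.groups.items() if k.startswith("old")
        }
        if multiplier is None:
            groups["old_THC"] = groups["old_THC"].model_copy(
                update={"modifiers": []}
            )
        cfg = cfg.model_copy(update={"groups": groups})
        return simulate_study(cfg, seed=seed)

    def test_null_multiplier_ci_covers_one(self):
        covered = 0
        n_seeds = 20
        for seed in range(n_seeds):
            series = self._simulate_old_pair(None, seed)
            res = recover_loss_modifier(series, n_boot=100, seed=seed)
            covered += res.ci_low <= 1.0 <= res.ci_high
        assert covered >= int(0.7 * n_seeds)

    def test_empty_window_raises(self):
        series = self._simulate_old_pair(0.6, 0)
        with pytest.raises(ValueError):
            recover_loss_modifier(series, window=(57, 99))

    def test_larger_n_shrinks_ci(self):
        widths = {}
        for factor in (1, 4):
            cfg = default_scenarios()
            groups = {
                k: v.model_copy(
                    update={"n_rois": v.n_rois * factor, "n_mice": v.n_mice * factor}
                )
                for k, v in cfg.groups.items()
                if k.startswith("old")
            }
            cfg = cfg.model_copy(update={"groups": groups})
            w = []
            for seed in range(8):
                series = simulate_study(cfg, seed=seed)
                res = recover_loss_modifier(series, n_boot=100, seed=seed)
                w.append(res.ci_high - res.ci_low)
            widths[factor] = np.mean(w)
        assert widths[4] < widths[1]


class TestScenarioConfigs:
    def test_null_scenario_groups_are_identical(self):
        cfg = null_scenarios()
        params = [
            p.model_dump(exclude={"n_mice", "n_rois"})
            for p in cfg.groups.values()
        ]
        assert all(p == params[0] for p in params)
        assert all(not p["modifiers"] for p in params)

    def test_yaml_roundtrip(self, tmp_path):
        import yaml

        cfg = default_scenarios()
        path = tmp_path / "scenario.yaml"
        path.write_text(yaml.safe_dump(cfg.model_dump(), default_flow_style=False))
        back = SimulationConfig.from_yaml(path)
        assert back == cfg
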