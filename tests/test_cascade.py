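import numpy as np
import pytest

import jhtriage as j
from jhtriage.hts_stats import InhibitionResult, ReplicateSummary


CFG = j.CascadeConfig()


def res(cid, values, conc=5e-6):
    return InhibitionResult(cid, conc, "fluc", tuple(float(v) for v in values))


class TestStage1:
    @pytest.mark.parametrize("inh,expected", [(26.0, True), (25.99, False), (80.0, True)])
    def test_inclusive_boundary(self, inh, expected):
        hits = j.stage1_select([res("C1", [inh])], CFG)
        assert ("C1" in hits) == expected


class TestStage2:
    def test_below_threshold_excluded(self):
        hits, reasons = j.stage2_confirm([res("C1", [19.5] * 4)], CFG)
        assert hits == [] and "C1" in reasons

    def test_exact_twenty_retained(self):
        hits, _ = j.stage2_confirm([res("C1", [20.0] * 4)], CFG)
        assert hits == ["C1"]

    def test_adherence_flag_excludes_despite_activity(self):
        hits, reasons = j.stage2_confirm(
            [res("C1", [35.0] * 4)], CFG, adherence={"C1": True}
        )
        assert hits == [] and reasons["C1"] == "adherence"

    def test_replicate_shortfall_warns(self):
        with pytest.warns(UserWarning, match="replicates"):
            hits, _ = j.stage2_confirm([res("C1", [30.0, 31.0])], CFG)
        assert hits == ["C1"]


class TestStage3:
    @pytest.mark.parametrize(
        "means,expected_hit,reason_part",
        [
            ((12, 40, 75), True, None),
            ((5, 40, 75), False, "lowest dose"),
            ((60, 20, 5), False, "non-monotone"),
        ],
    )
    def test_selection(self, means, expected_hit, reason_part):
        curves = {"C1": list(zip((0.05e-6, 0.5e-6, 5e-6), means))}
        hits, reasons = j.stage3_dose_select(curves, CFG)
        assert ("C1" in hits) == expected_hit
        if reason_part:
            assert reason_part in reasons["C1"]

    def test_monotone_check_can_be_disabled(self):
        cfg = j.CascadeConfig(stage3_check_monotone=False)
        curves = {"C1": [(0.05e-6, 60.0), (0.5e-6, 20.0), (5e-6, 5.0)]}
        hits, _ = j.stage3_dose_select(curves, cfg)
        assert hits == ["C1"]

    def test_too_few_concentrations_error(self):
        with pytest.raises(ValueError, match=">=3 concentrations"):
            j.stage3_dose_select({"C1": [(0.05e-6, 12.0), (5e-6, 75.0)]}, CFG)


def table(low, mid, high=90.0):
    mk = lambda v: ReplicateSummary(mean=float(v), sd=0.0, n=3, shortfall=False)
    return {0.05e-6: mk(low), 0.5e-6: mk(mid), 5e-6: mk(high)}


class TestStage4:
    @pytest.mark.parametrize(
        "low,mid,expected",
        [(-9, 16, True), (0, 14, False), (-12, 40, False)],
    )
    def test_selection(self, low, mid, expected):
        hits, _ = j.stage4_analog_select({"C1": table(low, mid)}, CFG)
        assert ("C1" in hits) == expected

    def test_missing_concentration_error(self):
        t = table(-9, 16)
        del t[0.5e-6]
        with pytest.raises(ValueError, match="missing"):
            j.stage4_analog_select({"C1": t}, CFG)


class TestCounterscreen:
    @pytest.mark.parametrize(
        "rluc_inh,retained", [(42.0, True), (50.0, True), (75.0, False)]
    )
    def test_strict_boundary(self, rluc_inh, retained):
        kept, reasons = j.counterscreen_cytotox(
            [InhibitionResult("C1", 5e-6, "rluc", (rluc_inh,))], CFG
        )
        assert ("C1" in kept) == retained
        if not retained:
            assert reasons["C1"] == "cytotoxic"


@pytest.fixture(scope="module")
def campaign():
    """Seeded 320-compound campaign with known truth."""
    props = {
        "inactive": 0.92,
        "competitive_inhibitor": 0.04,
        "noncompetitive_inhibitor": 0.01,
        "cytotoxic": 0.02,
        "agonist": 0.01,
    }
    lib, truth = j.simulate_library(320, class_proportions=props, seed=31)
    config = j.SimulationConfig(seed=31)
    plates, layouts = j.simulate_screen(lib, config)
    result = j.run_cascade(plates, layouts)
    return truth.set_index("compound_id"), plates, layouts, result


def test_cascade_recovers_inhibitors_and_excludes_cytotoxics(campaign):
    truth, _, _, result = campaign
    status = {r.compound_id: r.status for r in result.records}
    competitive = truth.index[truth.latent_class == "competitive_inhibitor"]
    recovered = sum(status[c] == "active" for c in competitive)
    assert recovered / len(competitive) >= 0.9
    for c in truth.index[truth.latent_class == "cytotoxic"]:
        assert status[c] == "excluded_cytotoxic"


def test_counterscreen_soundness(campaign):
    """No final active may exceed the Rluc viability-loss threshold."""
    _, _, _, result = campaign
    for rec in result.records:
        if rec.status == "active":
            assert rec.rluc_inh is not None and rec.rluc_inh <= 50.0


def test_lineage_conservation(campaign):
    """Every final active carries recorded results for all four stages."""
    _, _, _, result = campaign
    for rec in result.records:
        if rec.status == "active":
            assert rec.stage1 and rec.stage2 and rec.stage3 and rec.stage4
            assert all(rec.passed.get(s) for s in (1, 2, 3, 4))


@pytest.mark.parametrize(
    "override",
    [
        {"stage1_min_inh": 40.0},
        {"stage2_min_inh": 35.0},
        {"stage3_min_inh": 25.0},
        {"stage4_min_inh_mid": 40.0},
        {"cytotox_max_rluc_inh": 20.0},
    ],
)
def test_threshold_monotonicity(campaign, override):
    """Tightening any selection threshold never increases final hit count."""
    _, plates, layouts, baseline = campaign
    stricter = j.run_cascade(plates, layouts, j.CascadeConfig(**override))
    assert stricter.counts["final_active"] <= baseline.counts["final_active"]


def test_strong_inhibitors_survive_confirmation():
    """Over 20 seeded campaigns, >=90% of planted inhibitors whose true
    noiseless InH at 5 uM is >=60% reach the stage-3 pool."""
    survived = total = 0
    cfg_cascade = j.CascadeConfig()
    for seed in range(20):
        props = {"inactive": 0.9, "competitive_inhibitor": 0.1}
        lib, truth = j.simulate_library(80, class_proportions=props, seed=100 + seed)
        config = j.SimulationConfig(seed=200 + seed)
        plates, layouts = j.simulate_screen(lib, config)
        result = j.run_cascade({1: plates[1], 2: plates[2]}, layouts, cfg_cascade)
        passed2 = {r.compound_id for r in result.records if r.passed.get(2)}
        f_p, _ = j.expected_signal(None, 0.0, 0.0, config)
        f_n, _ = j.expected_signal(None, 1e-9, 0.0, config)
        for m in lib:
            if m.latent_class != "competitive_inhibitor":
                continue
            f_i, _ = j.expected_signal(m, 1e-9, 5e-6, config)
            true_inh = 100.0 * (1.0 - (f_i - f_p) / (f_n - f_p))
            if true_inh >= 60.0:
                total += 1
                survived += m.compound_id in passed2
    assert total > 50
    assert survived / total >= 0.9


def test_config_from_yaml(tmp_path):
    path = tmp_path / "cfg.yaml"
    path.write_text("stage1_min_inh: 30\nstage4_concs: [1e-7, 1e-6, 1e-5]\n")
    cfg = j.CascadeConfig.from_yaml(path)
    assert cfg.stage1_min_inh == 30 and cfg.stage4_concs == (1e-7, 1e-6, 1e-5)
    (tmp_path / "bad.yaml").write_text("not_a_key: 1\n")
    with pytest.raises(ValueError, match="unknown cascade config key"):
        j.CascadeConfig.from_yaml(tmp_path / "bad.yaml")
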