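"""Unit and property tests for the 14-item scoring rubric."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from simplepda.scoring import (
    ITEM_MAXIMA,
    ITEM_NAMES,
    MAX_TOTAL,
    AdmissionBaseline,
    ScoreInputError,
    VentMode,
    compute_simple,
    score_birth_weight,
    score_cord_gas,
    score_fio2_admission,
    score_max_pip,
    score_metabolic_acidosis,
    score_reduction,
    score_respiratory_acidosis,
    score_surfactant,
    score_tachycardia,
    score_trajectory,
    score_ventilation,
)
from conftest import make_obs


class TestItemScorers:
    @pytest.mark.parametrize("bw,expected", [
        (720, 3), (1000, 1), (1300, 0), (749.9, 3), (750, 2),
        (999.9, 2), (1250, 1), (1250.1, 0),
    ])
    def test_birth_weight_bins(self, bw, expected):
        assert score_birth_weight(bw) == expected

    @pytest.mark.parametrize("bd,expected", [
        (5, 0), (14, 1), (20, 2), (11.9, 0), (12, 1), (16, 1), (16.1, 2),
    ])
    def test_cord_gas_bins(self, bd, expected):
        assert score_cord_gas(bd) == expected

    @pytest.mark.parametrize("ph,bd,expected", [
        (7.20, 8, 2),    # pH ladder 2 beats BD ladder 1
        (7.40, 2, 0),
        (7.30, 17, 3),   # BD > 16 dominates pH score 1
        (7.25, 0, 1), (7.35, 0, 1), (7.36, 0, 0), (7.10, 0, 2), (7.09, 0, 3),
        (7.40, 4, 1), (7.40, 10, 1), (7.40, 10.1, 2), (7.40, 16, 2),
    ])
    def test_metabolic_acidosis_two_ladders(self, ph, bd, expected):
        assert score_metabolic_acidosis(ph, bd) == expected

    @pytest.mark.parametrize("pco2,expected", [
        (40, 0), (70, 3), (30, 0), (45, 0), (45.1, 1), (55, 1), (65, 2), (65.1, 3),
    ])
    def test_respiratory_acidosis_bins(self, pco2, expected):
        assert score_respiratory_acidosis(pco2) == expected

    @pytest.mark.parametrize("mode,expected", [
        (VentMode.NONE, 0), (VentMode.CONVENTIONAL, 1), (VentMode.HFOV, 3),
        ("none", 0), ("hfov", 3),
    ])
    def test_ventilation_no_score_two(self, mode, expected):
        assert score_ventilation(mode) == expected

    @pytest.mark.parametrize("hr,expected", [
        (150, 0), (170, 1), (190, 2), (160, 1), (180, 1), (180.5, 2),
    ])
    def test_tachycardia_bins(self, hr, expected):
        assert score_tachycardia(hr) == expected

    @pytest.mark.parametrize("pip,expected", [
        (22, 1), (25, 2), (None, 0), (17.9, 0), (18, 1), (23, 1), (23.1, 2),
    ])
    def test_max_pip_bins(self, pip, expected):
        assert score_max_pip(pip) == expected

    @pytest.mark.parametrize("prior,current,expected", [
        (20, 15, 0),   # 25% reduction
        (20, 18, 1),   # exactly 10%
        (20, 22, 2),   # increase
        (20, 16, 1),   # exactly 20%
        (20, 15.9, 0),
        (100, 89, 1), (100, 91, 2),
    ])
    def test_reduction_bins(self, prior, current, expected):
        assert score_reduction(prior, current) == expected

    @pytest.mark.parametrize("fio2,expected", [
        (30, 0), (50, 1), (80, 2), (40, 1), (60, 1), (60.5, 2),
    ])
    def test_fio2_admission_bins(self, fio2, expected):
        assert score_fio2_admission(fio2) == expected

    @pytest.mark.parametrize("doses,expected", [(0, 0), (1, 1), (2, 2), (3, 2)])
    def test_surfactant_bins(self, doses, expected):
        assert score_surfactant(doses) == expected

    @pytest.mark.parametrize("fn,args", [
        (score_birth_weight, (0,)),
        (score_birth_weight, (-100,)),
        (score_cord_gas, (-1,)),
        (score_metabolic_acidosis, (6.2, 3)),
        (score_respiratory_acidosis, (0,)),
        (score_tachycardia, (-5,)),
        (score_max_pip, (-1,)),
        (score_reduction, (0, 10)),
        (score_reduction, (10, 0)),
        (score_fio2_admission, (150,)),
        (score_surfactant, (-1,)),
        (score_surfactant, (1.5,)),
        (score_ventilation, ("jet",)),
    ])
    def test_invalid_inputs_raise(self, fn, args):
        with pytest.raises(ScoreInputError):
            fn(*args)


def _worst_obs(hour=6):
    return make_obs(
        hour=hour, heart_rate=190, hypotension_inotropes=True,
        vent_mode=VentMode.HFOV, pip=26, fio2=85.0, ph=7.05,
        base_deficit=20.0, pco2=70.0, surfactant_doses=2,
    )


class TestComputeSimple:
    def test_item_maxima_sum_to_29(self):
        assert sum(ITEM_MAXIMA) == MAX_TOTAL == 29

    def test_all_best_profile_scores_zero(self, benign_record):
        obs = make_obs(fio2=25.0)
        bd = compute_simple(benign_record, obs, AdmissionBaseline(fio2=40.0))
        assert bd.total == 0

    def test_all_worst_profile_scores_29(self, severe_record):
        # PIP and FiO2 both increased vs prior; every item at its maximum
        bd = compute_simple(severe_record, _worst_obs(),
                            AdmissionBaseline(fio2=80.0, pip=24))
        assert bd.total == MAX_TOTAL == 29
        assert all(bd.item_points[n] == m for n, m in zip(ITEM_NAMES, ITEM_MAXIMA))

    def test_total_equals_sum_of_item_scorers(self, severe_record):
        """Mid-severity profile: breakdown total matches a hand-summed ledger."""
        obs = make_obs(
            hour=24, heart_rate=172, hypotension_inotropes=True,
            vent_mode=VentMode.CONVENTIONAL, pip=20, fio2=45.0,
            ph=7.28, base_deficit=6.0, pco2=58.0, surfactant_doses=1,
        )
        prior = make_obs(hour=18, fio2=48.0, vent_mode=VentMode.CONVENTIONAL, pip=21)
        bd = compute_simple(severe_record, obs, prior)
        ledger = (
            1                                      # chorioamnionitis
            + 1                                    # no completed steroids
            + score_birth_weight(600)
            + score_cord_gas(20)
            + 1                                    # hypotension on inotropes
            + score_tachycardia(172)
            + score_ventilation(VentMode.CONVENTIONAL)
            + score_metabolic_acidosis(7.28, 6.0)
            + score_respiratory_acidosis(58.0)
            + score_max_pip(20)
            + score_reduction(21, 20)
            + score_fio2_admission(80.0)
            + score_reduction(48.0, 45.0)
            + score_surfactant(1)
        )
        assert bd.total == ledger == sum(bd.item_points.values())

    def test_mismatched_infant_raises(self, benign_record):
        obs = make_obs(infant_id="B")
        with pytest.raises(ScoreInputError, match="does not match"):
            compute_simple(benign_record, obs, AdmissionBaseline(fio2=25.0))

    def test_missing_values_score_zero_and_flag(self, benign_record):
        obs = make_obs(heart_rate=None, pco2=None)
        bd = compute_simple(benign_record, obs, AdmissionBaseline(fio2=25.0))
        assert bd.item_points["tachycardia"] == 0
        assert bd.item_points["respiratory_acidosis"] == 0
        assert "tachycardia:missing" in bd.flags
        assert "respiratory_acidosis:missing" in bd.flags

    def test_not_ventilated_pip_items_zero_flagged(self, benign_record):
        bd = compute_simple(benign_record, make_obs(), AdmissionBaseline(fio2=25.0))
        assert bd.item_points["max_pip"] == 0
        assert bd.item_points["pip_reduction"] == 0
        assert "max_pip:not_ventilated" in bd.flags

    def test_room_air_fio2_reduction_inapplicable(self, benign_record):
        bd = compute_simple(benign_record, make_obs(fio2=21.0),
                            AdmissionBaseline(fio2=21.0))
        assert bd.item_points["fio2_reduction"] == 0
        assert "fio2_reduction:room_air" in bd.flags


class TestTrajectory:
    def test_single_observation_uses_admission_baseline(self, benign_record):
        # admission FiO2 25 -> 6 h FiO2 25: <10% reduction scores 2
        out = score_trajectory(benign_record, [make_obs(fio2=25.0)])
        assert len(out) == 1
        assert out[0].item_points["fio2_reduction"] == 2

    def test_constant_settings_reduction_scores_two_later(self, benign_record):
        obs = [make_obs(hour=h, fio2=40.0, vent_mode=VentMode.CONVENTIONAL, pip=20)
               for h in (6, 12, 18, 24, 48, 72)]
        out = score_trajectory(benign_record, obs)
        for bd in out[1:]:
            assert bd.item_points["fio2_reduction"] == 2
            assert bd.item_points["pip_reduction"] == 2

    def test_trajectory_matches_per_hour_compute(self, severe_record):
        obs = [make_obs(hour=h, fio2=40.0 + h / 10, heart_rate=150 + h,
                        surfactant_doses=min(h // 12, 2))
               for h in (6, 12, 18, 24, 48, 72)]
        out = score_trajectory(severe_record, obs)
        prior = AdmissionBaseline(fio2=severe_record.fio2_admission)
        for o, bd in zip(obs, out):
            expected = compute_simple(severe_record, o, prior)
            assert bd.item_points == expected.item_points
            prior = o

    def test_duplicate_hours_rejected(self, benign_record):
        with pytest.raises(ScoreInputError, match="duplicate"):
            score_trajectory(benign_record, [make_obs(hour=6), make_obs(hour=6)])

    def test_decreasing_surfactant_rejected(self, benign_record):
        obs = [make_obs(hour=6, surfactant_doses=2), make_obs(hour=12, surfactant_doses=1)]
        with pytest.raises(ScoreInputError, match="non-decreasing"):
            score_trajectory(benign_record, obs)

    def test_carry_forward_flags(self, benign_record):
        obs = [make_obs(hour=6, pco2=60.0), make_obs(hour=12, pco2=None)]
        out = score_trajectory(benign_record, obs)
        assert out[1].item_points["respiratory_acidosis"] == 2  # carried 60 mmHg
        assert "pco2:carried_forward" in out[1].flags

    def test_admission_pip_baseline(self, benign_record):
        obs = [make_obs(hour=6, vent_mode=VentMode.CONVENTIONAL, pip=20)]
        with_prior = score_trajectory(benign_record, obs, admission_pip=26)[0]
        assert with_prior.item_points["pip_reduction"] == 0  # 23% reduction
        without = score_trajectory(benign_record, obs)[0]
        assert without.item_points["pip_reduction"] == 0
        assert "pip_reduction:no_prior" in without.flags


# --- property tests ---------------------------------------------------------

WORSENINGS = [
    ("birth_weight", [1300, 1200, 900, 700]),
    ("cord", [5, 14, 20]),
    ("hr", [150, 170, 190]),
    ("pco2", [40, 50, 60, 70]),
    ("pip", [16, 20, 25]),
    ("fio2_admission", [30, 50, 80]),
    ("surfactant", [0, 1, 2]),
    ("vent", [VentMode.NONE, VentMode.CONVENTIONAL, VentMode.HFOV]),
]


@pytest.mark.parametrize("name,ladder", WORSENINGS)
def test_single_item_worsening_never_decreases_total(name, ladder, severe_record):
    """Severity monotonicity item by item, all else held fixed."""
    totals = []
    for val in ladder:
        kw = dict(hour=24, heart_rate=150, pco2=40.0, surfactant_doses=0,
                  vent_mode=VentMode.CONVENTIONAL, pip=20)
        rec = severe_record
        if name == "birth_weight":
            rec = InfantRecordWith(severe_record, birth_weight=val)
        elif name == "cord":
            rec = InfantRecordWith(severe_record, cord_base_deficit=val)
        elif name == "fio2_admission":
            rec = InfantRecordWith(severe_record, fio2_admission=val)
        elif name == "hr":
            kw["heart_rate"] = val
        elif name == "pco2":
            kw["pco2"] = val
        elif name == "pip":
            kw["pip"] = val
        elif name == "surfactant":
            kw["surfactant_doses"] = val
        elif name == "vent":
            kw["vent_mode"] = val
            if val is VentMode.NONE:
                kw["pip"] = None
        obs = make_obs(**kw)
        totals.append(compute_simple(rec, obs, AdmissionBaseline(fio2=40.0)).total)
    assert totals == sorted(totals)


def InfantRecordWith(rec, **kw):
    from dataclasses import replace
    return replace(rec, **kw)


@settings(max_examples=200, deadline=None)
@given(
    bw=st.floats(200, 2000),
    cord=st.floats(0, 25),
    hr=st.floats(100, 220),
    ph=st.floats(6.9, 7.6),
    bd=st.floats(0, 25),
    pco2=st.floats(20, 90),
    fio2=st.floats(21, 100),
    fio2_prior=st.floats(21, 100),
    pip=st.one_of(st.none(), st.floats(10, 35)),
    doses=st.integers(0, 4),
    chorio=st.booleans(),
    steroid=st.booleans(),
    hypo=st.booleans(),
    vent=st.sampled_from(list(VentMode)),
)
def test_total_is_integer_in_range_and_deterministic(
        bw, cord, hr, ph, bd, pco2, fio2, fio2_prior, pip, doses,
        chorio, steroid, hypo, vent):
    from simplepda.scoring import InfantRecord

    rec = InfantRecord("X", 25.0, bw, chorio, steroid, cord, min(fio2, 100))
    obs = make_obs(
        infant_id="X", hour=12, heart_rate=hr, hypotension_inotropes=hypo,
        vent_mode=vent, pip=pip if vent is not VentMode.NONE else None,
        fio2=fio2, ph=ph, base_deficit=bd, pco2=pco2, surfactant_doses=doses,
    )
    prior = AdmissionBaseline(fio2=fio2_prior, pip=20.0)
    b1 = compute_simple(rec, obs, prior)
    b2 = compute_simple(rec, obs, prior)
    assert b1.item_points == b2.item_points
    assert isinstance(b1.total, int) and 0 <= b1.total <= 29
    for pts, mx in zip(b1.item_points.values(), ITEM_MAXIMA):
        assert 0 <= pts <= mx


def test_no_attainable_total_strictly_between_8_and_9():
    """Classification rules 'score > 8.5' and 'score > 8' coincide.

    Reachable totals are sums over the items' attainable point sets
    (invasive MV can only contribute {0, 1, 3}); dynamic programming over
    those sets shows every attainable total is an integer, so none lies in
    (8, 9).
    """
    attainable_sets = [
        {0, 1}, {0, 1}, {0, 1, 2, 3}, {0, 1, 2}, {0, 1}, {0, 1, 2},
        {0, 1, 3},                       # invasive MV: 2 unattainable
        {0, 1, 2, 3}, {0, 1, 2, 3}, {0, 1, 2}, {0, 1, 2}, {0, 1, 2},
        {0, 1, 2}, {0, 1, 2},
    ]
    reachable = {0}
    for s in attainable_sets:
        reachable = {r + v for r in reachable for v in s}
    assert reachable == set(range(30))
    assert not any(8 < t < 9 for t in reachable)
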