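"""Allometry fitting and the modified Fry back-calculation model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from otolithbc import (
    AnalysisConfig,
    SimConfig,
    back_calculate_all,
    compute_anchors,
    fit,
    fit_allometry,
    mfbc_length,
    simulate_population,
)
from otolithbc.backcalc import (
    BackCalcParams,
    DegenerateAnchorError,
    DegenerateDesignError,
)
from conftest import make_fish


def records_on_curve(a, b, c, radii_cpt):
    """Fish whose capture points lie exactly on L = a + b * R**c."""
    return [
        make_fish(
            fish_id=f"C{i}", radius=r, length=a + b * r ** c,
            age=1, radii=(0.5 * r,),
        )
        for i, r in enumerate(radii_cpt)
    ]


class TestFitAllometry:
    def test_recovers_power_law_exactly(self):
        recs = records_on_curve(10.0, 20.0, 2.0, np.linspace(0.5, 3.0, 50))
        p = fit_allometry(recs)
        assert p.a == pytest.approx(10.0, rel=1e-6)
        assert p.b == pytest.approx(20.0, rel=1e-6)
        assert p.c == pytest.approx(2.0, rel=1e-6)

    def test_recovers_straight_line(self):
        recs = records_on_curve(5.0, 3.0, 1.0, np.linspace(0.5, 3.0, 50))
        p = fit_allometry(recs)
        assert p.a == pytest.approx(5.0, abs=1e-4)
        assert p.b == pytest.approx(3.0, abs=1e-4)
        assert p.c == pytest.approx(1.0, abs=1e-4)

    def test_constant_radius_is_degenerate(self):
        recs = records_on_curve(10.0, 20.0, 2.0, [1.5] * 10)
        with pytest.raises(DegenerateDesignError):
            fit_allometry(recs)

    def test_too_few_fish_rejected(self):
        recs = records_on_curve(10.0, 20.0, 2.0, [1.0, 1.5, 2.0])
        with pytest.raises(DegenerateDesignError, match="5"):
            fit_allometry(recs)

    def test_a_override_is_respected(self):
        recs = records_on_curve(10.0, 20.0, 2.0, np.linspace(0.5, 3.0, 50))
        p = fit_allometry(recs, a_override=8.0)
        assert p.a == 8.0
        assert p.fitted["a"] is False


class TestAnchors:
    def test_r0p_is_mean_first_annulus(self):
        recs = [
            make_fish(fish_id="A", age=1, radii=(0.2,), radius=0.3, length=40),
            make_fish(fish_id="B", age=1, radii=(0.4,), radius=0.5, length=50),
        ]
        params = BackCalcParams(a=10, b=20, c=2)
        r0p, _ = compute_anchors(recs, params)
        assert r0p == pytest.approx(0.3)

    def test_l0p_is_allometric_prediction(self):
        recs = [make_fish(fish_id="A", age=1, radii=(1.0,), radius=1.2, length=60)]
        params = BackCalcParams(a=10, b=20, c=2)
        _, l0p = compute_anchors(recs, params)
        assert l0p == pytest.approx(30.0)

    def test_overrides_win(self):
        recs = [make_fish(fish_id="A", age=1, radii=(1.0,), radius=1.2, length=60)]
        params = BackCalcParams(a=10, b=20, c=2)
        cfg = AnalysisConfig(L0p_override=17.5, R0p_override=0.9)
        r0p, l0p = compute_anchors(recs, params, cfg)
        assert (r0p, l0p) == (0.9, 17.5)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_anchors([], BackCalcParams(a=1, b=1, c=1))


class TestMfbcLength:
    HAND = dict(l_cpt=100.0, r_cpt=10.0, a=10.0, l0p=20.0, r0p=1.0)

    def test_log_midpoint_hand_case(self):
        # ln Ri midway between ln R0p and ln R_cpt -> geometric mean of the
        # anchor offsets: 10 + sqrt(10 * 90) = 40
        assert mfbc_length(np.sqrt(10.0), **self.HAND) == pytest.approx(40.0)

    def test_endpoints(self):
        assert mfbc_length(10.0, **self.HAND) == pytest.approx(100.0)
        assert mfbc_length(1.0, **self.HAND) == pytest.approx(20.0)

    def test_monotone_in_radius(self):
        ri = np.linspace(0.5, 12.0, 200)
        li = mfbc_length(ri, **self.HAND)
        assert np.all(np.diff(li) > 0)

    def test_interior_radii_stay_between_anchor_lengths(self):
        ri = np.linspace(1.0, 10.0, 50)
        li = mfbc_length(ri, **self.HAND)
        assert np.all(li >= 20.0 - 1e-9) and np.all(li <= 100.0 + 1e-9)

    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(l_cpt=5.0), "L_cpt"),
            (dict(l0p=9.0), "L0p"),
            (dict(r0p=-1.0), "R0p"),
        ],
    )
    def test_domain_errors_name_offending_quantity(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            mfbc_length(2.0, **{**self.HAND, **kwargs})

    def test_equal_anchor_radii_degenerate(self):
        with pytest.raises(DegenerateAnchorError):
            mfbc_length(2.0, **{**self.HAND, "r0p": 10.0})

    @settings(max_examples=300, derandomize=True)
    @given(st.data())
    def test_endpoint_identities_hold_generally(self, data):
        a = data.draw(st.floats(0.0, 50.0), label="a")
        l0p = a + data.draw(st.floats(0.1, 50.0), label="dL0")
        l_cpt = l0p + data.draw(st.floats(0.1, 300.0), label="dLc")
        r0p = data.draw(st.floats(1e-3, 5.0), label="r0p")
        r_cpt = r0p * (1 + data.draw(st.floats(0.05, 20.0), label="dR"))
        assert mfbc_length(r_cpt, l_cpt, r_cpt, a, l0p, r0p) == pytest.approx(l_cpt, rel=1e-9)
        assert mfbc_length(r0p, l_cpt, r_cpt, a, l0p, r0p) == pytest.approx(l0p, rel=1e-9)


class TestBackCalculateAll:
    def test_generative_exactness(self, noise_free_sim):
        """On fish grown exactly on the allometry, back-calculation recovers
        every true annulus length (log-linear interpolation is exact)."""
        _, records, truth = noise_free_sim
        params = fit(records)
        obs = back_calculate_all(records, params)
        merged = obs.merge(
            truth, left_on=["fish_id", "age"], right_on=["fish_id", "annulus"]
        )
        assert len(merged) == len(obs)
        rel = np.abs(merged["length"] / merged["true_length"] - 1.0)
        assert rel.max() < 1e-6

    def test_pooled_counts_are_cumulative_tails(self, default_sim):
        records, _ = default_sim
        params = fit(records)
        obs = back_calculate_all(records, params)
        counts = obs.groupby(["status", "age"]).size().unstack(fill_value=0)
        assert tuple(counts.loc["MR"]) == (111, 81, 57, 46, 36, 27, 18, 13, 10, 6, 3, 2)
        assert tuple(counts.loc["FR"]) == (159, 128, 103, 75, 54, 34, 16, 11, 10, 9, 3, 1)
        # non-increasing in age, by construction of pooling
        for status in ("MR", "FR"):
            assert np.all(np.diff(counts.loc[status]) <= 0)

    def test_each_fish_yields_age_observations(self, analyzed):
        per_fish = analyzed["obs"].groupby("fish_id").size()
        ages = {r.fish_id: r.age for r in analyzed["records"]}
        assert all(per_fish[fid] == a for fid, a in ages.items())

    def test_single_age1_fish_yields_one_observation(self):
        rec = make_fish(age=1, radii=(0.3,), radius=0.35, length=40.0)
        params = BackCalcParams(a=5.0, b=50.0, c=1.2, R0p=0.3, L0p=20.0)
        obs = back_calculate_all([rec], params)
        assert len(obs) == 1 and obs.loc[0, "age"] == 1

    def test_capture_radius_mode_returns_capture_length(self):
        rec = make_fish(age=2, radii=(0.2, 0.4), radius=0.5, length=80.0)
        params = BackCalcParams(a=5.0, b=50.0, c=1.2, R0p=0.2, L0p=20.0)
        cfg = AnalysisConfig(use_capture_radius_at_final_age=True)
        obs = back_calculate_all([rec], params, cfg)
        assert obs.loc[obs["age"] == 2, "length"].iloc[0] == pytest.approx(80.0)

    def test_per_fish_anchor_mode_pins_first_annulus(self, noise_free_sim):
        cfg_sim, records, _ = noise_free_sim
        params = fit(records)
        obs = back_calculate_all(records, params, AnalysisConfig(r0p_mode="per_fish"))
        # age-1 observation of each fish equals its own allometric L(r1)
        age1 = obs[obs["age"] == 1].set_index("fish_id")["length"]
        for rec in records[:20]:
            expect = params.a + params.b * rec.radii[0] ** params.c
            assert age1[rec.fish_id] == pytest.approx(expect, rel=1e-9)

    def test_invalid_record_skipped_with_reason(self, caplog):
        good = make_fish(fish_id="G", age=1, radii=(0.3,), radius=0.35, length=40.0)
        bad = make_fish(fish_id="B", age=1, radii=(0.3,), radius=0.35, length=4.0)
        params = BackCalcParams(a=5.0, b=50.0, c=1.2, R0p=0.3, L0p=20.0)
        with caplog.at_level("WARNING", logger="otolithbc"):
            obs = back_calculate_all([good, bad], params)
        assert set(obs["fish_id"]) == {"G"}
        assert obs.attrs["skipped"][0][0] == "B"
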