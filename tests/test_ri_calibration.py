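"""Ladder detection and RT -> RI mapping."""

import numpy as np
import pandas as pd
import pytest

from cilffa.ri_calibration import (LADDER_CARBONS, RICalibration, calibrate_run,
                                   detect_ladder, ladder_mz, rt_to_ri)


def make_ladder_run(carbons=LADDER_CARBONS, rt_of=lambda n: 2.0 + 2.0 * n,
                    intensity=5e6, extra_rows=()):
    rows = [{"mz": ladder_mz(n), "rt": rt_of(n), "intensity": intensity,
             "sample_id": "s1"} for n in carbons]
    rows.extend(extra_rows)
    return pd.DataFrame(rows)


class TestDetectLadder:
    def test_full_ladder(self):
        cal = detect_ladder(make_ladder_run())
        assert cal.n_matched == 20 and cal.completeness == 1.0
        assert np.all(np.diff(cal.anchor_rt) > 0)
        assert list(cal.anchor_ri) == [100.0 * n for n in LADDER_CARBONS]

    def test_missing_standards_counted(self):
        cal = detect_ladder(make_ladder_run(carbons=range(7, 25)))
        assert cal.n_matched == 18
        assert cal.completeness == pytest.approx(18 / 20)
        assert cal.missing_carbons == (5, 6)

    def test_most_intense_in_tolerance_wins(self):
        # a second, weaker feature inside the window must not displace the anchor
        extra = [{"mz": ladder_mz(8) + 0.003, "rt": 99.0, "intensity": 1e3,
                  "sample_id": "s1"}]
        cal = detect_ladder(make_ladder_run(extra_rows=extra))
        i = list(cal.anchor_carbon).index(8)
        assert cal.anchor_rt[i] == pytest.approx(2.0 + 2.0 * 8)

    def test_peak_assigned_to_closer_expected_mass(self):
        # one lone peak halfway-ish between C8 and C9 expected masses goes to
        # the closer one; the other standard is reported missing
        mz_8, mz_9 = ladder_mz(8), ladder_mz(9)
        lone = mz_8 + 0.6 * (mz_9 - mz_8)
        df = make_ladder_run(carbons=[n for n in LADDER_CARBONS if n not in (8, 9)])
        df = pd.concat([df, pd.DataFrame([{"mz": lone, "rt": 17.0, "intensity": 5e6,
                                           "sample_id": "s1"}])], ignore_index=True)
        cal = detect_ladder(df, mz_tolerance_mda=1e4)  # huge window to force overlap
        assert 9 in cal.anchor_carbon and 8 in cal.missing_carbons

    def test_coeluting_ladder_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            detect_ladder(make_ladder_run(rt_of=lambda n: 10.0))

    def test_too_few_anchors(self):
        with pytest.raises(ValueError, match="ladder"):
            detect_ladder(make_ladder_run(carbons=[8]))


class TestRtToRi:
    @pytest.fixture()
    def cal(self):
        return detect_ladder(make_ladder_run())

    def test_exact_at_anchors(self, cal):
        for rt, ri in zip(cal.anchor_rt, cal.anchor_ri):
            assert rt_to_ri(cal, rt) == pytest.approx(ri, abs=1e-12)

    def test_halfway_interpolation(self, cal):
        rt_mid = (2.0 + 2.0 * 10 + 2.0 + 2.0 * 11) / 2
        assert rt_to_ri(cal, rt_mid) == pytest.approx(1050.0)

    def test_extrapolation_uses_end_slopes(self, cal):
        # anchors are affine in rt here, so extrapolation continues the line
        assert rt_to_ri(cal, 0.0) == pytest.approx(-100.0)
        assert rt_to_ri(cal, 60.0) == pytest.approx(2900.0)

    def test_monotone_against_brute_force(self):
        rng = np.random.default_rng(0)
        # non-affine but increasing ladder
        rts = np.cumsum(rng.uniform(0.5, 3.0, 20)) + 2.0
        cal = RICalibration(anchor_rt=rts, anchor_ri=[100.0 * n for n in LADDER_CARBONS],
                            anchor_intensity=np.full(20, 1e6),
                            anchor_carbon=list(LADDER_CARBONS))
        q = np.sort(rng.uniform(0.0, 60.0, 1000))
        ri = rt_to_ri(cal, q)
        assert np.all(np.diff(ri) >= 0)

        def brute(rt):  # independent piecewise evaluation
            x, y = cal.anchor_rt, cal.anchor_ri
            if rt <= x[0]:
                seg = 0
            elif rt >= x[-1]:
                seg = len(x) - 2
            else:
                seg = int(np.searchsorted(x, rt) - 1)
            s = (y[seg + 1] - y[seg]) / (x[seg + 1] - x[seg])
            return y[seg] + s * (rt - x[seg])

        for rt in q[::100]:
            assert rt_to_ri(cal, float(rt)) == pytest.approx(brute(float(rt)), abs=1e-9)

    def test_needs_two_anchors(self):
        cal = RICalibration(anchor_rt=[1.0], anchor_ri=[500.0],
                            anchor_intensity=[1e6], anchor_carbon=[5])
        with pytest.raises(ValueError, match="anchors"):
            rt_to_ri(cal, 1.5)


class TestDriftInvariance:
    def test_affine_warp_leaves_ri_unchanged(self):
        rng = np.random.default_rng(3)
        base = make_ladder_run()
        peaks = pd.DataFrame({
            "mz": rng.uniform(200, 600, 50),
            "rt": rng.uniform(10.0, 50.0, 50),
            "intensity": np.full(50, 1e5),
            "sample_id": "s1",
        })
        run = pd.concat([base, peaks], ignore_index=True)
        warped = run.assign(rt=1.7 + 1.23 * run["rt"])

        ri0 = calibrate_run(run, detect_ladder(run))["ri"]
        ri1 = calibrate_run(warped, detect_ladder(warped))["ri"]
        np.testing.assert_allclose(ri1, ri0, atol=1e-9)

    def test_locally_smooth_warp_within_one_ri_unit(self):
        # a mildly nonlinear monotone warp: RI error stays < 1 unit between anchors
        base = make_ladder_run()
        rng = np.random.default_rng(4)
        peaks = pd.DataFrame({
            "mz": rng.uniform(200, 600, 200),
            "rt": rng.uniform(12.0, 50.0, 200),
            "intensity": np.full(200, 1e5),
            "sample_id": "s1",
        })
        run = pd.concat([base, peaks], ignore_index=True)

        def warp(rt):
            return 0.5 + rt * (1.0 + 0.002 * np.sin(rt / 6.0))

        warped = run.assign(rt=warp(run["rt"].to_numpy()))
        ri0 = calibrate_run(run, detect_ladder(run))["ri"]
        ri1 = calibrate_run(warped, detect_ladder(warped))["ri"]
        assert np.max(np.abs(ri1 - ri0)) < 1.0
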