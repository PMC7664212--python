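"""Light/heavy pairing rules, greedy assignment, cross-sample merging."""

import numpy as np
import pandas as pd
import pytest

from cilffa.chem import pair_mass_delta
from cilffa.pair_extraction import (PairingParams, extract_pairs,
                                    merge_pairs_across_samples)

DELTA = pair_mass_delta()


def peaks(rows):
    df = pd.DataFrame(rows, columns=["mz", "ri", "intensity"])
    df["rt"] = 2.0 + 0.02 * df["ri"]
    df["sample_id"] = "s1"
    df["region"] = "OB"
    return df


class TestParams:
    def test_invalid_tolerances_rejected(self):
        with pytest.raises(ValueError):
            PairingParams(mass_delta_tolerance_mda=0.0)
        with pytest.raises(ValueError):
            PairingParams(max_intensity_fold=0.5)


class TestExtractPairs:
    def test_caprylic_pair_recovered(self):
        df = peaks([(215.2118, 800.0, 1.0e6), (219.2369, 800.0, 1.1e6)])
        out = extract_pairs(df)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["light_mz"] == pytest.approx(215.2118)
        assert row["heavy_mz"] == pytest.approx(219.2369)
        assert abs(row["mass_error_mda"]) < 0.1

    def test_intensity_fold_filter(self):
        df = peaks([(215.2118, 800.0, 1.0e6), (219.2369, 800.0, 2.0e7)])
        assert extract_pairs(df).empty

    def test_ri_filter(self):
        df = peaks([(215.2118, 800.0, 1.0e6), (219.2369, 900.0, 1.1e6)])
        assert extract_pairs(df).empty

    def test_closer_mass_error_wins_tie(self):
        df = peaks([
            (215.2118, 800.0, 1.0e6),
            (215.2118 + DELTA, 800.0, 1.0e6),           # exact split
            (215.2118 + DELTA + 0.0039, 800.0, 1.0e6),  # in tolerance, worse
        ])
        out = extract_pairs(df)
        assert len(out) == 1
        assert out.iloc[0]["heavy_mz"] == pytest.approx(215.2118 + DELTA)

    def test_uncalibrated_peaks_rejected(self):
        df = peaks([(215.2118, 800.0, 1e6)]).drop(columns="ri")
        with pytest.raises(ValueError, match="ri"):
            extract_pairs(df)

    def test_no_peak_reuse(self):
        rng = np.random.default_rng(5)
        # dense random field plus planted pairs: assignment stays one-to-one
        rows = [(mz, ri, 10.0 ** rng.normal(6, 0.3))
                for mz, ri in zip(rng.uniform(200, 210, 150), rng.uniform(790, 810, 150))]
        df = peaks(rows)
        out = extract_pairs(df)
        used = list(zip(out["light_mz"], out["light_ri"])) + \
            list(zip(out["heavy_mz"], out["heavy_ri"]))
        assert len(used) == len(set(used))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(6)
        rows = [(mz, ri, 10.0 ** rng.normal(6, 0.3))
                for mz, ri in zip(rng.uniform(200, 212, 120), rng.uniform(780, 820, 120))]
        df = peaks(rows)
        out1 = extract_pairs(df)
        out2 = extract_pairs(df.sample(frac=1.0, random_state=1).reset_index(drop=True))
        pd.testing.assert_frame_equal(
            out1.sort_values("light_mz").reset_index(drop=True),
            out2.sort_values("light_mz").reset_index(drop=True))


class TestMerge:
    def _pair_row(self, mz, ri, sample, region, intensity=1e6):
        return {"light_mz": mz, "heavy_mz": mz + DELTA, "mass_error_mda": 0.0,
                "light_ri": ri, "heavy_ri": ri, "ri_gap": 0.0,
                "light_rt": 10.0, "heavy_rt": 10.0,
                "light_intensity": intensity, "heavy_intensity": intensity,
                "intensity_ratio": 1.0, "sample_id": sample, "region": region}

    def test_same_ffa_three_runs_merges_to_one(self):
        rows = [self._pair_row(300.2000 + d, 1000.0, s, "OB")
                for d, s in zip((0.0, 0.001, -0.001), ("s1", "s2", "s3"))]
        out = merge_pairs_across_samples(pd.DataFrame(rows))
        assert len(out) == 1
        assert out.iloc[0]["n_pairs"] == 3
        assert out.iloc[0]["samples"] == "s1;s2;s3"

    def test_distinct_masses_stay_separate(self):
        rows = [self._pair_row(300.2, 1000.0, "s1", "OB"),
                self._pair_row(300.7, 1000.0, "s1", "OB")]
        out = merge_pairs_across_samples(pd.DataFrame(rows))
        assert len(out) == 2

    def test_same_mass_distant_ri_stays_separate(self):
        rows = [self._pair_row(300.2, 1000.0, "s1", "OB"),
                self._pair_row(300.2, 1100.0, "s1", "OB")]
        assert len(merge_pairs_across_samples(pd.DataFrame(rows))) == 2

    def test_region_presence_recorded(self):
        rows = [self._pair_row(300.2, 1000.0, "a", "OB"),
                self._pair_row(300.2, 1000.0, "b", "CE"),
                self._pair_row(310.2, 1050.0, "b", "CE")]
        out = merge_pairs_across_samples(pd.DataFrame(rows))
        regions = dict(zip(out["mz"].round(1), out["regions"]))
        assert regions[300.2] == "CE;OB" and regions[310.2] == "CE"

    def test_consensus_is_intensity_weighted(self):
        rows = [self._pair_row(300.2000, 1000.0, "s1", "OB", intensity=3e6),
                self._pair_row(300.2030, 1000.0, "s2", "OB", intensity=1e6)]
        out = merge_pairs_across_samples(pd.DataFrame(rows))
        assert out.iloc[0]["mz"] == pytest.approx(300.20075, abs=1e-6)

    def test_empty_input(self):
        assert merge_pairs_across_samples(pd.DataFrame(columns=["light_mz"])).empty


class TestNoiselessRecovery:
    def test_planted_ffas_exactly_recovered(self):
        # 10 planted pairs and 200 isolated decoys with zero noise: the merged
        # potential-FFA list is exactly the planted panel
        from cilffa.pipeline import _strip_ladder
        from cilffa.simulate import SimulationConfig, random_panel, simulate_qualitative_run
        from cilffa.ri_calibration import calibrate_run, detect_ladder

        cfg = SimulationConfig(seed=42, n_decoys=200, mz_noise_sd_mda=0.0,
                               ri_jitter_sd=0.0, intensity_cv=0.0,
                               presence_prob=1.0, **random_panel(10, seed=42))
        df, man = simulate_qualitative_run(cfg)
        cal = detect_ladder(df)
        pairs = extract_pairs(_strip_ladder(calibrate_run(df, cal)))
        merged = merge_pairs_across_samples(pairs)
        assert len(merged) == 10
        got = np.sort(merged["mz"].to_numpy())
        want = np.sort(man["pairs"]["light_mz"].to_numpy())
        np.testing.assert_allclose(got, want, atol=1e-9)
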