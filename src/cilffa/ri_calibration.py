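"""Retention-index calibration from the d4-labeled alkanoic-acid ladder.

Every run is spiked with heavy-labeled straight-chain acids C5:0..C24:0.  Their
heavy-derivative m/z values are known exactly, so the 20 standards can be
located in each run and used as anchors of a retention-time -> retention-index
mapping (Kovats-style convention RI(Cn:0) = 100 x n).  Interpolation is
piecewise linear between anchors with end-segment linear extrapolation, which
makes the index exact at anchors and invariant under affine RT drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import Formula, LabelTag, derivative_mz

__all__ = [
    "LADDER_CARBONS",
    "ladder_mz",
    "RICalibration",
    "detect_ladder",
    "rt_to_ri",
    "calibrate_run",
    "calibration_report",
]

#: Carbon numbers of the internal-standard ladder (C5:0 .. C24:0).
LADDER_CARBONS: tuple[int, ...] = tuple(range(5, 25))

N_EXPECTED = len(LADDER_CARBONS)


def ladder_mz(n_carbons: int, tag: LabelTag = LabelTag.HEAVY) -> float:
    """Expected [M+H]+ m/z of the labeled Cn:0 straight-chain acid CnH2nO2."""
    return derivative_mz(Formula({"C": n_carbons, "H": 2 * n_carbons, "O": 2}), tag)


@dataclass
class RICalibration:
    """Per-run RT -> RI mapping anchored on detected ladder standards.

    ``anchor_rt``/``anchor_ri`` are strictly increasing; ``anchor_intensity``
    and ``anchor_carbon`` are kept because the same ladder peaks later serve as
    normalization references for quantitation.
    """

    anchor_rt: np.ndarray
    anchor_ri: np.ndarray
    anchor_intensity: np.ndarray
    anchor_carbon: np.ndarray
    missing_carbons: tuple[int, ...] = ()
    n_expected: int = N_EXPECTED

    def __post_init__(self):
        self.anchor_rt = np.asarray(self.anchor_rt, dtype=float)
        self.anchor_ri = np.asarray(self.anchor_ri, dtype=float)
        self.anchor_intensity = np.asarray(self.anchor_intensity, dtype=float)
        self.anchor_carbon = np.asarray(self.anchor_carbon, dtype=int)
        if np.any(np.diff(self.anchor_rt) <= 0):
            raise ValueError("anchor RTs must be strictly increasing (co-eluting ladder)")
        if np.any(np.diff(self.anchor_ri) <= 0):
            raise ValueError("anchor RIs must be strictly increasing")

    @property
    def n_matched(self) -> int:
        return len(self.anchor_rt)

    @property
    def completeness(self) -> float:
        return self.n_matched / self.n_expected


def detect_ladder(peaks: pd.DataFrame, mz_tolerance_mda: float = 5.0,
                  tag: LabelTag = LabelTag.HEAVY) -> RICalibration:
    """Locate the ladder standards in one run and build the calibration.

    For each expected m/z the most intense in-tolerance peak is taken as the
    anchor; a peak in tolerance of two expected masses is assigned to the
    closer one (the other standard counts as missing if nothing else matches).
    Anchors get RI = 100 x carbon number.
    """
    tol = mz_tolerance_mda / 1000.0
    mz = peaks["mz"].to_numpy(dtype=float)
    rt = peaks["rt"].to_numpy(dtype=float)
    intensity = peaks["intensity"].to_numpy(dtype=float)

    expected = np.array([ladder_mz(n, tag) for n in LADDER_CARBONS])
    # nearest expected standard for every peak
    idx = np.clip(np.searchsorted(expected, mz), 0, len(expected) - 1)
    idx_lo = np.clip(idx - 1, 0, len(expected) - 1)
    nearest = np.where(
        np.abs(expected[idx] - mz) <= np.abs(expected[idx_lo] - mz), idx, idx_lo
    )
    in_tol = np.abs(expected[nearest] - mz) <= tol

    anchors: list[tuple[float, float, float, int]] = []
    missing: list[int] = []
    for j, n in enumerate(LADDER_CARBONS):
        cand = np.flatnonzero(in_tol & (nearest == j))
        if cand.size == 0:
            missing.append(n)
            continue
        best = cand[np.argmax(intensity[cand])]
        anchors.append((rt[best], 100.0 * n, intensity[best], n))

    if len(anchors) < 2:
        raise ValueError(
            f"only {len(anchors)} ladder standards detected; >=2 anchors required"
        )
    anchors.sort(key=lambda a: a[1])  # by RI == carbon order
    arr = np.array([a[:3] for a in anchors], dtype=float)
    return RICalibration(
        anchor_rt=arr[:, 0],
        anchor_ri=arr[:, 1],
        anchor_intensity=arr[:, 2],
        anchor_carbon=np.array([a[3] for a in anchors]),
        missing_carbons=tuple(missing),
    )


def rt_to_ri(cal: RICalibration, rt: float | np.ndarray) -> float | np.ndarray:
    """Map retention time(s) to retention index.

    Piecewise-linear between bracketing anchors; outside the anchor range the
    first/last segment slope is extended (linear extrapolation), so the map is
    strictly increasing everywhere.
    """
    if cal.n_matched < 2:
        raise ValueError("calibration needs >= 2 anchors")
    x, y = cal.anchor_rt, cal.anchor_ri
    rt_arr = np.asarray(rt, dtype=float)
    ri = np.interp(rt_arr, x, y)
    s0 = (y[1] - y[0]) / (x[1] - x[0])
    s1 = (y[-1] - y[-2]) / (x[-1] - x[-2])
    ri = np.where(rt_arr < x[0], y[0] + s0 * (rt_arr - x[0]), ri)
    ri = np.where(rt_arr > x[-1], y[-1] + s1 * (rt_arr - x[-1]), ri)
    return float(ri) if np.isscalar(rt) else ri


def calibrate_run(peaks: pd.DataFrame, cal: RICalibration) -> pd.DataFrame:
    """Return a copy of the run's feature table with the ``ri`` column set."""
    out = peaks.copy()
    out["ri"] = rt_to_ri(cal, out["rt"].to_numpy(dtype=float))
    return out


def calibration_report(cal: RICalibration, tag: LabelTag = LabelTag.HEAVY) -> pd.DataFrame:
    """Per-standard detection report for one run (QC artifact)."""
    rows = []
    detected = {int(c): i for i, c in enumerate(cal.anchor_carbon)}
    for n in LADDER_CARBONS:
        if n in detected:
            i = detected[n]
            rows.append((n, ladder_mz(n, tag), cal.anchor_rt[i], cal.anchor_intensity[i],
                         cal.anchor_ri[i], True))
        else:
            rows.append((n, ladder_mz(n, tag), np.nan, np.nan, 100.0 * n, False))
    df = pd.DataFrame(rows, columns=["carbons", "expected_mz", "rt", "intensity",
                                     "ri", "detected"])
    df.attrs["completeness"] = cal.completeness
    return df
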