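"""Light/heavy peak-pair extraction and cross-sample merging.

A potential free fatty acid shows up as two co-eluting features whose m/z
values differ by the exact label split (4.0251068 Da), whose retention indices
coincide, and whose intensities are similar (the two channels are mixed 1:1).
Pairing is a greedy one-to-one assignment ordered by mass-error quality, so
each feature supports at most one pair and the output is independent of the
input row order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem import pair_mass_delta
from .feature_io import PAIR_COLUMNS

__all__ = ["PairingParams", "extract_pairs", "merge_pairs_across_samples"]


@dataclass(frozen=True)
class PairingParams:
    """Tolerances of the pairing and cross-sample merge steps.

    mass_delta_tolerance_mda
        Window around the exact 4.0251068 Da split (instrument mass accuracy).
    ri_tolerance
        Max |RI(light) - RI(heavy)| for "same retention index"; 5 RI units is
        1/20 of one CH2 step of the ladder.
    max_intensity_fold
        Max fold difference between channels for "similar intensities"; the
        1:1 mixing design implies a near-unity ratio, 5 is a generous bound
        for deuterium ionization effects.
    dedup_mz_tolerance_mda / dedup_ri_tolerance
        Windows used when merging per-run pairs into consensus potential FFAs.
    """

    mass_delta_tolerance_mda: float = 5.0
    ri_tolerance: float = 5.0
    max_intensity_fold: float = 5.0
    dedup_mz_tolerance_mda: float = 5.0
    dedup_ri_tolerance: float = 5.0

    def __post_init__(self):
        if min(self.mass_delta_tolerance_mda, self.ri_tolerance,
               self.dedup_mz_tolerance_mda, self.dedup_ri_tolerance) <= 0:
            raise ValueError("all tolerances must be > 0")
        if self.max_intensity_fold < 1:
            raise ValueError("max_intensity_fold must be >= 1")


def extract_pairs(peaks: pd.DataFrame, params: PairingParams = PairingParams()) -> pd.DataFrame:
    """Extract light/heavy pairs from one RI-calibrated run.

    A candidate (light, heavy) passes when the observed m/z difference is
    within ``mass_delta_tolerance_mda`` of the exact label split, the RI gap is
    within ``ri_tolerance``, and the intensity fold difference is at most
    ``max_intensity_fold``.  Candidates are then assigned greedily in ascending
    |mass error| (ties: ascending RI gap, then light m/z), each peak joining at
    most one pair.
    """
    if "ri" not in peaks.columns or peaks["ri"].isna().any():
        raise ValueError("peaks must be RI-calibrated before pairing (missing 'ri')")

    delta = pair_mass_delta()
    tol = params.mass_delta_tolerance_mda / 1000.0

    # canonical internal order: by m/z, tie-broken on ri/intensity, so the
    # result is invariant under permutation of the input rows
    df = peaks.reset_index(drop=True).sort_values(
        ["mz", "ri", "intensity"], kind="mergesort").reset_index(drop=True)
    mz = df["mz"].to_numpy(dtype=float)
    ri = df["ri"].to_numpy(dtype=float)
    inten = df["intensity"].to_numpy(dtype=float)

    cands: list[tuple[float, float, float, int, int]] = []
    lo = np.searchsorted(mz, mz + delta - tol, side="left")
    hi = np.searchsorted(mz, mz + delta + tol, side="right")
    for i in range(len(mz)):
        for j in range(lo[i], hi[i]):
            gap = abs(ri[j] - ri[i])
            if gap > params.ri_tolerance:
                continue
            r = inten[i] / inten[j]
            if max(r, 1.0 / r) > params.max_intensity_fold:
                continue
            err = mz[j] - mz[i] - delta
            cands.append((abs(err), gap, mz[i], i, j))

    cands.sort()
    used: set[int] = set()
    rows = []
    for _aerr, gap, _lmz, i, j in cands:
        if i in used or j in used:
            continue
        used.add(i)
        used.add(j)
        rows.append({
            "light_mz": mz[i], "heavy_mz": mz[j],
            "mass_error_mda": (mz[j] - mz[i] - delta) * 1000.0,
            "light_ri": ri[i], "heavy_ri": ri[j], "ri_gap": gap,
            "light_rt": df["rt"].iat[i], "heavy_rt": df["rt"].iat[j],
            "light_intensity": inten[i], "heavy_intensity": inten[j],
            "intensity_ratio": inten[i] / inten[j],
            "sample_id": df["sample_id"].iat[i] if "sample_id" in df else "",
            "region": df["region"].iat[i] if "region" in df else "",
        })
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def merge_pairs_across_samples(pairs: pd.DataFrame,
                               params: PairingParams = PairingParams()) -> pd.DataFrame:
    """Merge per-run pairs into consensus potential FFAs.

    Pairs whose light m/z agree within ``dedup_mz_tolerance_mda`` and RI within
    ``dedup_ri_tolerance`` collapse into one potential FFA whose consensus m/z
    and RI are intensity-weighted means.  The output records, per FFA, the
    samples and regions it was seen in.

    Returns a table with columns ``ffa_id, mz, ri, mean_intensity, n_pairs,
    samples, regions`` (samples/regions are ';'-joined sorted unique labels).
    """
    if pairs.empty:
        return pd.DataFrame(columns=["ffa_id", "mz", "ri", "mean_intensity",
                                     "n_pairs", "samples", "regions"])
    mz_tol = params.dedup_mz_tolerance_mda / 1000.0

    df = pairs.sort_values(["light_mz", "light_ri"], kind="mergesort").reset_index(drop=True)
    # consensus accumulators
    cons_mz: list[float] = []
    cons_ri: list[float] = []
    cons_w: list[float] = []
    members: list[list[int]] = []

    for k, row in enumerate(df.itertuples(index=False)):
        w = row.light_intensity
        assigned = False
        # pairs arrive in ascending m/z: only recent consensus clusters can match
        for ci in range(len(cons_mz) - 1, -1, -1):
            if row.light_mz - cons_mz[ci] > mz_tol:
                break
            if (abs(row.light_mz - cons_mz[ci]) <= mz_tol
                    and abs(row.light_ri - cons_ri[ci]) <= params.dedup_ri_tolerance):
                tot = cons_w[ci] + w
                cons_mz[ci] = (cons_mz[ci] * cons_w[ci] + row.light_mz * w) / tot
                cons_ri[ci] = (cons_ri[ci] * cons_w[ci] + row.light_ri * w) / tot
                cons_w[ci] = tot
                members[ci].append(k)
                assigned = True
                break
        if not assigned:
            cons_mz.append(row.light_mz)
            cons_ri.append(row.light_ri)
            cons_w.append(w)
            members.append([k])

    out_rows = []
    order = np.argsort(cons_mz, kind="stable")
    for new_id, ci in enumerate(order):
        sub = df.iloc[members[ci]]
        samples = sorted(set(sub["sample_id"].astype(str)))
        regions = sorted(set(sub["region"].astype(str)) - {"", "nan"})
        out_rows.append({
            "ffa_id": f"FFA{new_id + 1:05d}",
            "mz": cons_mz[ci],
            "ri": cons_ri[ci],
            "mean_intensity": float(sub["light_intensity"].mean()),
            "n_pairs": len(sub),
            "samples": ";".join(samples),
            "regions": ";".join(regions),
        })
    return pd.DataFrame(out_rows)
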