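"""Internal-standard relative quantitation for the multi-region study.

Quantitative runs contain light-labeled analytes plus the heavy-labeled
C5:0..C24:0 ladder.  The ladder plays two roles: its completeness is the
sample-QC gate (a run missing any standard is dropped by default, matching the
all-or-nothing rule used on the rat data), and its peak intensities are the
normalization references — each analyte is divided by the intensity of the
ladder standard nearest in retention index, which cancels per-run global
intensity drift exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pair_extraction import PairingParams
from .ri_calibration import RICalibration

__all__ = ["QCResult", "qc_samples", "normalize_run", "build_abundance_table"]


@dataclass
class QCResult:
    kept: list[str]
    excluded: list[str]
    report: pd.DataFrame  # sample_id, n_matched, n_expected, missing_carbons, kept


def qc_samples(calibrations: dict[str, RICalibration],
               required_fraction: float = 1.0) -> QCResult:
    """Apply the ladder-completeness QC rule to a set of runs.

    A sample is kept iff it detected at least ``required_fraction`` of the
    expected standards (default 1.0: every standard, the rule under which the
    original study dropped one hippocampus and two cerebellum samples).
    Raises if no sample survives.
    """
    rows, kept, excluded = [], [], []
    for sample_id in sorted(calibrations):
        cal = calibrations[sample_id]
        ok = cal.n_matched >= required_fraction * cal.n_expected
        (kept if ok else excluded).append(sample_id)
        rows.append({
            "sample_id": sample_id,
            "n_matched": cal.n_matched,
            "n_expected": cal.n_expected,
            "missing_carbons": ";".join(str(c) for c in cal.missing_carbons),
            "kept": ok,
        })
    if not kept:
        raise ValueError("all samples failed ladder-completeness QC")
    return QCResult(kept=kept, excluded=excluded, report=pd.DataFrame(rows))


def normalize_run(analytes: pd.DataFrame, cal: RICalibration) -> pd.DataFrame:
    """Normalize one run's light analyte peaks by the nearest-RI ladder standard.

    Adds columns ``norm_intensity`` (analyte / standard intensity) and
    ``norm_standard`` (carbon number of the reference).  Ties in RI distance go
    to the lower carbon number.  Per-run scaling of all intensities cancels.
    """
    if cal.n_matched == 0:
        raise ValueError("no ladder anchors available for normalization")
    if "ri" not in analytes.columns or analytes["ri"].isna().any():
        raise ValueError("analytes must be RI-calibrated before normalization")
    ri = analytes["ri"].to_numpy(dtype=float)
    # anchors sorted by RI; nearest with ties to the lower carbon
    dist = np.abs(ri[:, None] - cal.anchor_ri[None, :])
    choice = np.argmin(dist, axis=1)  # argmin returns first (= lower carbon) on ties
    out = analytes.copy()
    out["norm_intensity"] = out["intensity"].to_numpy() / cal.anchor_intensity[choice]
    out["norm_standard"] = cal.anchor_carbon[choice]
    return out


def build_abundance_table(runs: dict[str, pd.DataFrame],
                          calibrations: dict[str, RICalibration],
                          regions: dict[str, str],
                          params: PairingParams = PairingParams()) -> pd.DataFrame:
    """Assemble the samples x FFAs matrix of normalized relative concentrations.

    ``runs`` maps sample_id to its RI-calibrated light-analyte feature table
    (ladder peaks already removed).  Analyte features are grouped across
    samples into consensus FFAs with the same m/z/RI windows used for pair
    merging; missing values stay NaN (never zero-filled).  The result has one
    row per sample, one ``FFAxxxxx`` column per consensus feature, plus a
    ``region`` column; per-feature consensus m/z and RI are stored in
    ``df.attrs["features"]``.
    """
    normed = []
    for sample_id, df in runs.items():
        nd = normalize_run(df, calibrations[sample_id])
        nd = nd.assign(sample_id=sample_id)
        normed.append(nd[["mz", "ri", "norm_intensity", "sample_id"]])
    allpk = pd.concat(normed, ignore_index=True).sort_values(
        ["mz", "ri"], kind="mergesort").reset_index(drop=True)

    mz_tol = params.dedup_mz_tolerance_mda / 1000.0
    cons_mz: list[float] = []
    cons_ri: list[float] = []
    cons_n: list[int] = []
    assign = np.empty(len(allpk), dtype=int)
    for k, row in enumerate(allpk.itertuples(index=False)):
        hit = -1
        for ci in range(len(cons_mz) - 1, -1, -1):
            if row.mz - cons_mz[ci] > mz_tol:
                break
            if (abs(row.mz - cons_mz[ci]) <= mz_tol
                    and abs(row.ri - cons_ri[ci]) <= params.dedup_ri_tolerance):
                hit = ci
                break
        if hit < 0:
            cons_mz.append(row.mz)
            cons_ri.append(row.ri)
            cons_n.append(1)
            hit = len(cons_mz) - 1
        else:
            n = cons_n[hit]
            cons_mz[hit] = (cons_mz[hit] * n + row.mz) / (n + 1)
            cons_ri[hit] = (cons_ri[hit] * n + row.ri) / (n + 1)
            cons_n[hit] = n + 1
        assign[k] = hit

    ids = [f"FFA{i + 1:05d}" for i in range(len(cons_mz))]
    allpk["ffa_id"] = [ids[a] for a in assign]
    # a sample may contribute several features to one consensus id; keep the max
    table = (allpk.pivot_table(index="sample_id", columns="ffa_id",
                               values="norm_intensity", aggfunc="max")
             .reindex(sorted(runs)))
    table.insert(0, "region", [regions[s] for s in table.index])
    table.attrs["features"] = pd.DataFrame(
        {"ffa_id": ids, "mz": cons_mz, "ri": cons_ri, "n_obs": cons_n})
    return table
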