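"""End-to-end orchestration of the qualitative and quantitative workflows.

``run_qualitative``: ladder detection -> RI calibration -> pair extraction ->
cross-sample merge -> annotation -> region set algebra.

``run_quantitative``: ladder detection -> sample QC -> RI calibration ->
internal-standard normalization -> per-FFA transform gating + one-way ANOVA ->
PCA and OPLS-DA -> joint VIP/p selection.

Both return plain dicts of DataFrames/objects so the CLI stays a thin
serialization layer and tests can assert on in-memory results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import annotation as ann
from . import quantitation as quant
from . import region_analysis as regions_mod
from . import ri_calibration as ri_mod
from . import stats_models as stats_mod
from .feature_io import LibraryEntry
from .pair_extraction import PairingParams, extract_pairs, merge_pairs_across_samples

logger = logging.getLogger(__name__)

__all__ = ["StageError", "run_qualitative", "run_quantitative"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise StageError(name, exc) from exc
        return wrapper
    return deco


def _calibrate_all(runs: dict[str, pd.DataFrame], mz_tolerance_mda: float):
    cals, calibrated = {}, {}
    for sample_id, df in runs.items():
        cal = ri_mod.detect_ladder(df, mz_tolerance_mda=mz_tolerance_mda)
        cals[sample_id] = cal
        calibrated[sample_id] = ri_mod.calibrate_run(df, cal)
        logger.info("calibrated %s: %d/%d ladder standards", sample_id,
                    cal.n_matched, cal.n_expected)
    return cals, calibrated


def _strip_ladder(df: pd.DataFrame, exclusion_mda: float = 10.0) -> pd.DataFrame:
    """Drop features within ``exclusion_mda`` of any heavy ladder m/z."""
    ladder = np.array([ri_mod.ladder_mz(c) for c in ri_mod.LADDER_CARBONS])
    mz = df["mz"].to_numpy(dtype=float)
    near = np.min(np.abs(mz[:, None] - ladder[None, :]), axis=1) <= exclusion_mda / 1000.0
    return df.loc[~near].reset_index(drop=True)


def run_qualitative(runs: dict[str, pd.DataFrame], library: list[LibraryEntry],
                    params: PairingParams = PairingParams(),
                    region_vocab=None) -> dict:
    """Qualitative workflow over one run per (pooled) region.

    Returns ``pairs`` (per-run concatenated pair table), ``ffas`` (merged
    potential-FFA table), ``annotation``, ``presence`` (region -> id set),
    ``counts`` (per-region series), ``common`` and ``ratio`` matrices, and
    the per-run calibrations.
    """
    cals, calibrated = _stage("ri_calibration")(_calibrate_all)(runs, params.mass_delta_tolerance_mda)

    @_stage("pair_extraction")
    def _pairs():
        # the ladder compounds are genuine fatty acids: their light partners
        # (endogenous Cn:0) may legitimately pair with them, so the qualitative
        # path pairs over the full table; spiked heavy anchors without a light
        # partner simply stay unpaired
        per_run = [extract_pairs(df, params) for df in calibrated.values()]
        out = pd.concat(per_run, ignore_index=True) if per_run else pd.DataFrame()
        logger.info("extracted %d pairs across %d runs", len(out), len(per_run))
        return out

    pairs = _pairs()

    merged = _stage("merge")(merge_pairs_across_samples)(pairs, params)
    logger.info("merged into %d potential FFAs", len(merged))

    annot = _stage("annotation")(ann.annotate)(merged, library)

    @_stage("region_matrices")
    def _matrices():
        sets = regions_mod.presence_sets(merged, region_vocab)
        sets = {r: s for r, s in sets.items() if s}
        counts = pd.Series({r: len(s) for r, s in sets.items()}, name="n_ffas")
        common = regions_mod.common_matrix(sets) if len(sets) >= 2 else None
        ratio = regions_mod.ratio_matrix(common) if common is not None else None
        return sets, counts, common, ratio

    sets, counts, common, ratio = _matrices()
    return {"pairs": pairs, "ffas": merged, "annotation": annot,
            "presence": sets, "counts": counts, "common": common, "ratio": ratio,
            "calibrations": cals}


@dataclass
class _AnovaTables:
    table: pd.DataFrame   # ffa_id, f, p, transform, forced, degenerate
    groups_used: dict[str, list[np.ndarray]]


def _anova_per_ffa(abundance: pd.DataFrame, alpha: float = 0.05) -> _AnovaTables:
    region = abundance["region"]
    rows, used = [], {}
    for col in abundance.columns.drop("region"):
        vals = abundance[col]
        groups = [vals[region == r].dropna().to_numpy(dtype=float)
                  for r in region.unique()]
        if len([g for g in groups if len(g) >= 2]) < len(groups):
            rows.append({"ffa_id": col, "f": np.nan, "p": np.nan,
                         "transform": "", "forced": False, "degenerate": False})
            continue
        if all(len(g) >= 3 for g in groups) and all(g.min() > 0 for g in groups):
            res = stats_mod.anova_with_gating(groups, alpha=alpha)
        else:  # too few values to gate: raw ANOVA, transform recorded as none
            res = stats_mod.one_way_anova(groups)
        used[col] = groups
        rows.append({"ffa_id": col, "f": res.f, "p": res.p,
                     "transform": res.transform, "forced": res.forced_transform,
                     "degenerate": res.degenerate})
    return _AnovaTables(pd.DataFrame(rows).set_index("ffa_id"), used)


def _multivariate_matrix(abundance: pd.DataFrame,
                         max_missing_frac: float = 0.5) -> pd.DataFrame:
    """Complete-data matrix for PCA/OPLS-DA: drop FFAs with > 50 % missing in
    any region, impute the rest with the region-wise median."""
    region = abundance["region"]
    X = abundance.drop(columns="region")
    keep = []
    for col in X.columns:
        frac = X[col].isna().groupby(region).mean()
        if (frac <= max_missing_frac).all():
            keep.append(col)
    X = X[keep].copy()
    for r in region.unique():
        idx = region == r
        med = X.loc[idx].median()
        X.loc[idx] = X.loc[idx].fillna(med)
    return X.dropna(axis=1)


def run_quantitative(runs: dict[str, pd.DataFrame], regions: dict[str, str],
                     params: PairingParams = PairingParams(),
                     required_fraction: float = 1.0,
                     p_threshold: float = 0.05, vip_threshold: float = 1.0,
                     n_orthogonal: int | None = None) -> dict:
    """Quantitative workflow: QC, normalization, ANOVA + PCA + OPLS-DA, selection.

    ``regions`` maps sample_id -> region label.  Returns the QC result, the
    abundance table, the ANOVA table, both latent models, the VIP series and
    the selected FFA list (VIP > 1 and p < 0.05 by default).
    """
    cals, calibrated = _stage("ri_calibration")(_calibrate_all)(runs, params.mass_delta_tolerance_mda)

    qc = _stage("qc")(quant.qc_samples)(cals, required_fraction=required_fraction)
    logger.info("QC kept %d samples, excluded %s", len(qc.kept), qc.excluded or "none")

    @_stage("normalization")
    def _abundance():
        kept_runs = {s: _strip_ladder(calibrated[s]) for s in qc.kept}
        return quant.build_abundance_table(kept_runs, cals, regions, params)

    abundance = _abundance()

    anova = _stage("anova")(_anova_per_ffa)(abundance)

    @_stage("multivariate")
    def _models():
        X = _multivariate_matrix(abundance)
        y = abundance["region"].to_numpy()
        logX = np.log10(X.to_numpy(dtype=float))
        pca_model = stats_mod.pca(logX, n_components=2)
        opls = stats_mod.oplsda(logX, y, n_orthogonal=n_orthogonal)
        vip = pd.Series(opls.vip, index=X.columns, name="vip")
        return pca_model, opls, vip

    pca_model, opls, vip = _models()

    @_stage("selection")
    def _select():
        p = anova.table.loc[vip.index, "p"]
        ok = p.notna()
        return stats_mod.select_significant(p[ok], vip[ok],
                                            p_threshold=p_threshold,
                                            vip_threshold=vip_threshold)

    selected = _select()
    logger.info("selected %d significant FFAs", len(selected))
    return {"qc": qc, "abundance": abundance, "anova": anova.table,
            "pca": pca_model, "oplsda": opls, "vip": vip,
            "selected": selected, "calibrations": cals}
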