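"""Synthetic labeled LC-MS feature tables with ground-truth manifests.

Two designs are emulated at the feature level (no peak shapes or isotope
envelopes):

* **qualitative**: every present FFA contributes a light and a heavy peak
  split by exactly 4.0251068 Da (m/z noise on top), co-eluting up to RI
  jitter, with near-1:1 intensities; plus the heavy ladder anchors and
  isolated decoy singleton features.
* **quantitative**: light-only analyte peaks with region-specific fold
  effects and multiplicative noise, plus the heavy C5:0..C24:0 ladder with
  optional planted dropout to exercise the QC rule.

Defaults encode the study conditions the pipeline is validated under:
m/z noise sigma 1.0 mDa, RI jitter sigma 1.0, intensity CV 20 %, decoys
uniform over the instrument scan range m/z 180-650 with +/-10 mDa isolation
zones, 12 samples per region in the quantitative design.  Every draw is fixed
by ``seed``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .chem import pair_mass_delta
from .feature_io import DEFAULT_REGIONS, read_library
from .ri_calibration import LADDER_CARBONS, ladder_mz

__all__ = [
    "SimulationConfig",
    "library_panel",
    "random_panel",
    "simulate_qualitative_run",
    "simulate_quantitative_study",
]

_DELTA = pair_mass_delta()

#: Baseline RT model: monotone map from retention index to minutes, spanning
#: the gradient (RI 500 -> 12 min, RI 2400 -> 50 min).
def _base_rt(ri: np.ndarray | float) -> np.ndarray | float:
    return 2.0 + 0.02 * np.asarray(ri, dtype=float)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of both simulators; the defaults are the validated study conditions."""

    seed: int = 0
    regions: tuple[str, ...] = DEFAULT_REGIONS
    #: panel of true analytes: parallel tuples (name, light m/z, true RI)
    panel_names: tuple[str, ...] = ()
    panel_mz: tuple[float, ...] = ()
    panel_ri: tuple[float, ...] = ()
    presence_prob: float = 0.8
    intensity_log10_mean: float = 6.0
    intensity_log10_sd: float = 0.5
    intensity_cv: float = 0.2
    mz_noise_sd_mda: float = 1.0
    ri_jitter_sd: float = 1.0
    n_decoys: int = 2000
    mz_range: tuple[float, float] = (180.0, 650.0)
    decoy_isolation_mda: float = 10.0
    decoy_ri_guard: float = 15.0
    rt_drift: tuple[float, float] = (0.0, 1.0)   # rt' = a + b * rt
    rt_drift_sd: tuple[float, float] = (0.2, 0.02)  # per-run draw around rt_drift
    ladder_intensity: float = 5.0e6
    ladder_cv: float = 0.05
    ladder_dropout: tuple[tuple[str, tuple[int, ...]], ...] = ()
    samples_per_region: int = 12
    #: planted effects: ((ffa name, ((region, fold), ...)), ...)
    region_effects: tuple[tuple[str, tuple[tuple[str, float], ...]], ...] = ()

    def __post_init__(self):
        if self.intensity_cv < 0 or self.mz_noise_sd_mda < 0 or self.ri_jitter_sd < 0:
            raise ValueError("noise parameters must be >= 0")
        if not (len(self.panel_names) == len(self.panel_mz) == len(self.panel_ri)):
            raise ValueError("panel_names/panel_mz/panel_ri must be parallel")
        if not 0 <= self.presence_prob <= 1:
            raise ValueError("presence_prob must be in [0, 1]")
        for _, folds in self.region_effects:
            for _, f in folds:
                if f <= 0:
                    raise ValueError("fold changes must be > 0")

    # -- convenience constructors -----------------------------------------
    @classmethod
    def qualitative_default(cls, **kw) -> "SimulationConfig":
        cfg = cls(**kw)
        if not cfg.panel_names:
            cfg = replace(cfg, **library_panel())
        return cfg

    @classmethod
    def quantitative_default(cls, **kw) -> "SimulationConfig":
        kw.setdefault("regions", ("OB", "OC", "HP", "CE"))
        kw.setdefault("presence_prob", 1.0)
        kw.setdefault("n_decoys", 0)
        cfg = cls(**kw)
        if not cfg.panel_names:
            cfg = replace(cfg, **library_panel())
        return cfg

    def effects_map(self) -> dict[str, dict[str, float]]:
        return {name: dict(folds) for name, folds in self.region_effects}

    def dropout_map(self) -> dict[str, set[int]]:
        return {s: set(c) for s, c in self.ladder_dropout}

    def config_hash(self) -> str:
        return hashlib.sha256(repr(self).encode()).hexdigest()[:12]


def library_panel(path=None) -> dict:
    """Panel fields (name, light m/z, reference RI) from a standards library."""
    entries = read_library(path)
    return {
        "panel_names": tuple(e.name for e in entries),
        "panel_mz": tuple(e.light_mz for e in entries),
        "panel_ri": tuple(e.reference_ri for e in entries),
    }


def random_panel(n: int, seed: int, mz_range=(185.0, 640.0),
                 ri_range=(480.0, 2420.0), min_spacing_mda: float = 25.0) -> dict:
    """A synthetic panel of n well-separated analytes for stress tests.

    Light m/z values are drawn uniformly but rejected when within
    ``min_spacing_mda`` of an existing panel mass, of an existing mass +/- the
    label split, or of a ladder mass +/- the label split, so every planted pair
    is unambiguous and no accidental cross-pair can arise.
    """
    rng = np.random.default_rng(seed)
    guard = min_spacing_mda / 1000.0
    ladder = np.array([ladder_mz(c) for c in LADDER_CARBONS])
    avoid = np.concatenate([ladder, ladder - _DELTA, ladder + _DELTA])
    mzs: list[float] = []
    lo, hi = mz_range[0], mz_range[1] - _DELTA - guard
    while len(mzs) < n:
        cand = float(rng.uniform(lo, hi))
        taken = np.concatenate([np.array(mzs), np.array(mzs) - _DELTA,
                                np.array(mzs) + _DELTA, avoid]) if mzs else avoid
        if np.min(np.abs(taken - cand)) > guard:
            mzs.append(cand)
    ris = np.sort(rng.uniform(*ri_range, size=n))
    order = np.argsort(mzs)
    return {
        "panel_names": tuple(f"SYN{i + 1:04d}" for i in range(n)),
        "panel_mz": tuple(np.asarray(mzs)[order]),
        "panel_ri": tuple(ris),
    }


# ---------------------------------------------------------------------------
# Qualitative design: light+heavy pairs, ladder, decoys
# ---------------------------------------------------------------------------

def _ladder_rows(cfg: SimulationConfig, rng: np.random.Generator,
                 drift_a: float, drift_b: float,
                 dropout: set[int]) -> list[dict]:
    rows = []
    for c in LADDER_CARBONS:
        if c in dropout:
            continue
        rt = drift_a + drift_b * float(_base_rt(100.0 * c))
        inten = cfg.ladder_intensity * float(np.exp(rng.normal(0.0, cfg.ladder_cv)))
        rows.append({"mz": ladder_mz(c) + rng.normal(0.0, cfg.mz_noise_sd_mda / 1000.0),
                     "rt": rt, "intensity": inten})
    return rows


def _decoy_rows(cfg: SimulationConfig, rng: np.random.Generator,
                drift_a: float, drift_b: float,
                taken_mz: np.ndarray, taken_ri: np.ndarray) -> tuple[list[dict], pd.DataFrame]:
    """Isolated singleton decoys: never within the isolation zone of any
    existing peak (or its +/- label-split image) at a nearby retention index,
    nor of a previously placed decoy."""
    zone = cfg.decoy_isolation_mda / 1000.0
    mz_list = list(taken_mz)
    ri_list = list(taken_ri)
    rows, man = [], []
    lo, hi = cfg.mz_range
    while len(rows) < cfg.n_decoys:
        mz = float(rng.uniform(lo, hi))
        ri = float(rng.uniform(450.0, 2450.0))
        near = np.abs(np.asarray(ri_list) - ri) <= cfg.decoy_ri_guard
        if near.any():
            m = np.asarray(mz_list)[near]
            d = np.abs(np.concatenate([m - mz, m - _DELTA - mz, m + _DELTA - mz]))
            if d.min() <= zone:
                continue
        inten = 10.0 ** rng.normal(cfg.intensity_log10_mean - 1.0, cfg.intensity_log10_sd)
        rt = drift_a + drift_b * float(_base_rt(ri))
        rows.append({"mz": mz, "rt": rt, "intensity": inten})
        man.append({"mz": mz, "ri": ri, "intensity": inten})
        mz_list.append(mz)
        ri_list.append(ri)
    return rows, pd.DataFrame(man, columns=["mz", "ri", "intensity"])


def simulate_qualitative_run(cfg: SimulationConfig, sample_id: str = "QUAL_01",
                             region: str = "OB") -> tuple[pd.DataFrame, dict]:
    """One 1:1 light/heavy mixed run plus its ground-truth manifest.

    Returns ``(feature_table, manifest)`` where the manifest holds the planted
    pair table (``pairs``), the decoy singleton table (``decoys``), the drift
    coefficients and the present-FFA names.  Same config (incl. seed) gives a
    byte-identical table.
    """
    rng = np.random.default_rng(cfg.seed)
    if not cfg.panel_names:
        raise ValueError("config has an empty FFA panel")
    drift_a = cfg.rt_drift[0] + rng.normal(0.0, cfg.rt_drift_sd[0])
    drift_b = cfg.rt_drift[1] * float(np.exp(rng.normal(0.0, cfg.rt_drift_sd[1])))

    present = rng.random(len(cfg.panel_names)) < cfg.presence_prob
    sigma = np.sqrt(np.log1p(cfg.intensity_cv ** 2))  # lognormal with given CV

    rows: list[dict] = []
    man_rows: list[dict] = []
    for i in np.flatnonzero(present):
        mz_l = cfg.panel_mz[i]
        ri_true = cfg.panel_ri[i]
        base = 10.0 ** rng.normal(cfg.intensity_log10_mean, cfg.intensity_log10_sd)
        int_l = base * float(np.exp(rng.normal(0.0, sigma)))
        int_h = base * float(np.exp(rng.normal(0.0, sigma)))
        obs_l = mz_l + rng.normal(0.0, cfg.mz_noise_sd_mda / 1000.0)
        obs_h = mz_l + _DELTA + rng.normal(0.0, cfg.mz_noise_sd_mda / 1000.0)
        ri_l = ri_true + rng.normal(0.0, cfg.ri_jitter_sd)
        ri_h = ri_true + rng.normal(0.0, cfg.ri_jitter_sd)
        rows.append({"mz": obs_l, "rt": drift_a + drift_b * float(_base_rt(ri_l)),
                     "intensity": int_l})
        rows.append({"mz": obs_h, "rt": drift_a + drift_b * float(_base_rt(ri_h)),
                     "intensity": int_h})
        man_rows.append({"name": cfg.panel_names[i], "light_mz": mz_l,
                         "heavy_mz": mz_l + _DELTA, "ri": ri_true,
                         "light_intensity": int_l, "heavy_intensity": int_h})

    rows.extend(_ladder_rows(cfg, rng, drift_a, drift_b, dropout=set()))
    pairs_man = pd.DataFrame(
        man_rows, columns=["name", "light_mz", "heavy_mz", "ri",
                           "light_intensity", "heavy_intensity"])
    taken_mz = np.concatenate([
        pairs_man["light_mz"].to_numpy(float), pairs_man["heavy_mz"].to_numpy(float),
        [ladder_mz(c) for c in LADDER_CARBONS]]) if len(pairs_man) else np.array(
        [ladder_mz(c) for c in LADDER_CARBONS])
    taken_ri = np.concatenate([
        pairs_man["ri"].to_numpy(float), pairs_man["ri"].to_numpy(float),
        [100.0 * c for c in LADDER_CARBONS]]) if len(pairs_man) else np.array(
        [100.0 * c for c in LADDER_CARBONS])
    decoy_rows, decoys_man = _decoy_rows(cfg, rng, drift_a, drift_b, taken_mz, taken_ri)
    rows.extend(decoy_rows)

    df = pd.DataFrame(rows, columns=["mz", "rt", "intensity"])
    df["sample_id"] = sample_id
    df["region"] = region
    manifest = {
        "pairs": pairs_man,
        "decoys": decoys_man,
        "drift": (drift_a, drift_b),
        "present": [cfg.panel_names[i] for i in np.flatnonzero(present)],
        "config_hash": cfg.config_hash(),
    }
    return df, manifest


def simulate_qualitative_study(cfg: SimulationConfig) -> tuple[dict[str, pd.DataFrame], dict]:
    """One qualitative run per region (pooled-sample design).

    Region-specific presence is redrawn per region from ``presence_prob``;
    the manifest maps each region to its planted-pair table.
    """
    runs: dict[str, pd.DataFrame] = {}
    manifest: dict = {"regions": {}, "config_hash": cfg.config_hash()}
    for k, region in enumerate(cfg.regions):
        sub = replace(cfg, seed=cfg.seed + 1000 + k)
        sample_id = f"{region}_pool"
        df, man = simulate_qualitative_run(sub, sample_id=sample_id, region=region)
        runs[sample_id] = df
        manifest["regions"][region] = man
    return runs, manifest


# ---------------------------------------------------------------------------
# Quantitative design: light analytes + heavy ladder per sample
# ---------------------------------------------------------------------------

def simulate_quantitative_study(cfg: SimulationConfig) -> tuple[dict[str, pd.DataFrame], dict]:
    """Per-sample feature tables for the multi-region quantitative design.

    Every sample carries light-labeled analyte peaks (base level x regional
    fold x multiplicative noise) and the heavy ladder; ``cfg.ladder_dropout``
    plants missing standards in named samples to exercise the QC rule.  The
    manifest records true relative levels, the differential FFA names, and the
    intended QC exclusions.
    """
    if len(cfg.regions) < 2:
        raise ValueError("quantitative design needs >= 2 regions")
    if not cfg.panel_names:
        raise ValueError("config has an empty FFA panel")
    rng = np.random.default_rng(cfg.seed)
    effects = cfg.effects_map()
    dropout = cfg.dropout_map()
    sigma = np.sqrt(np.log1p(cfg.intensity_cv ** 2))

    base = 10.0 ** rng.normal(cfg.intensity_log10_mean, cfg.intensity_log10_sd,
                              size=len(cfg.panel_names))
    runs: dict[str, pd.DataFrame] = {}
    region_of: dict[str, str] = {}
    truth_rows = []
    for region in cfg.regions:
        for s in range(cfg.samples_per_region):
            sample_id = f"{region}_{s + 1:02d}"
            region_of[sample_id] = region
            drift_a = cfg.rt_drift[0] + rng.normal(0.0, cfg.rt_drift_sd[0])
            drift_b = cfg.rt_drift[1] * float(np.exp(rng.normal(0.0, cfg.rt_drift_sd[1])))
            rows = []
            for i, name in enumerate(cfg.panel_names):
                if rng.random() >= cfg.presence_prob:
                    continue
                fold = effects.get(name, {}).get(region, 1.0)
                level = base[i] * fold
                inten = level * float(np.exp(rng.normal(0.0, sigma)))
                ri = cfg.panel_ri[i] + rng.normal(0.0, cfg.ri_jitter_sd)
                rows.append({
                    "mz": cfg.panel_mz[i] + rng.normal(0.0, cfg.mz_noise_sd_mda / 1000.0),
                    "rt": drift_a + drift_b * float(_base_rt(ri)),
                    "intensity": inten,
                })
                truth_rows.append({"sample_id": sample_id, "region": region,
                                   "name": name, "true_level": level})
            rows.extend(_ladder_rows(cfg, rng, drift_a, drift_b,
                                     dropout.get(sample_id, set())))
            df = pd.DataFrame(rows, columns=["mz", "rt", "intensity"])
            df["sample_id"] = sample_id
            df["region"] = region
            runs[sample_id] = df

    manifest = {
        "truth": pd.DataFrame(truth_rows),
        "differential": sorted(effects),
        "qc_exclusions": sorted(dropout),
        "regions": region_of,
        "config_hash": cfg.config_hash(),
    }
    return runs, manifest

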