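"""Identity assignment for potential FFAs.

Matching order mirrors the study workflow: first the packaged standards
library (accurate m/z of the light derivative + retention index), then de-novo
molecular-formula generation over C/H/N/O for whatever the library misses.
Unassigned pairs are legitimate output — most potential FFAs in a brain run
match no known compound.

Classification is formula-level only: carbon-chain length bins
(short 2-5 C, medium 6-12 C, long 13-22 C, very long >22 C) and saturation
(0 / 1 / >1 C=C double bonds), where the double-bond count of a CnH(2n+2-2d)O2
acid is RDBE - 1 (one equivalent is the carboxyl C=O).
"""

from __future__ import annotations

import math

import pandas as pd

from .chem import (DEFAULT_BOUNDS, ElementBounds, Formula, LabelTag,
                   PROTON_MASS, generate_formulas)
from .feature_io import LibraryEntry

__all__ = ["match_library", "annotate_formula", "classify", "annotate"]

# net atoms added by light amidation: + C4H12N2 - H2O
_LABEL_NET_ADD = {"C": 4, "H": 10, "N": 2, "O": -1}


def match_library(ffas: pd.DataFrame, library: list[LibraryEntry],
                  mz_tolerance_mda: float = 5.0, ri_tolerance: float = 10.0) -> pd.DataFrame:
    """Match consensus potential FFAs (columns ``ffa_id, mz, ri``) to the library.

    An FFA matches the entry whose light-derivative m/z lies within
    ``mz_tolerance_mda`` and whose reference RI lies within ``ri_tolerance``;
    among several candidates the closest m/z wins, ties broken by closest RI.
    Unmatched FFAs are flagged for formula generation (``status='unmatched'``).
    """
    mz_tol = mz_tolerance_mda / 1000.0
    rows = []
    for row in ffas.itertuples(index=False):
        best = None
        for e in library:
            dmz = abs(row.mz - e.light_mz)
            dri = abs(row.ri - e.reference_ri)
            if dmz <= mz_tol and dri <= ri_tolerance:
                key = (dmz, dri, e.name)
                if best is None or key < best[0]:
                    best = (key, e)
        if best is None:
            rows.append({"ffa_id": row.ffa_id, "status": "unmatched", "name": "",
                         "formula": "", "compound_class": "",
                         "mass_error_mda": math.nan, "ri_error": math.nan})
        else:
            (dmz, dri, _), e = best
            rows.append({"ffa_id": row.ffa_id, "status": "library", "name": e.name,
                         "formula": str(e.neutral_formula),
                         "compound_class": e.compound_class,
                         "mass_error_mda": (row.mz - e.light_mz) * 1000.0,
                         "ri_error": row.ri - e.reference_ri})
    return pd.DataFrame(rows)


def annotate_formula(light_mz: float, tolerance_mda: float = 5.0,
                     bounds: ElementBounds = DEFAULT_BOUNDS) -> list[Formula]:
    """Candidate neutral *acid* formulas for an unmatched FFA's light m/z.

    The neutral labeled mass is ``light_mz - proton``; candidate labeled
    formulas within tolerance are back-transformed (- DMED + H2O) to the parent
    acid, dropping any candidate whose back-transformation would need negative
    element counts.  An empty list is a valid result.
    """
    neutral_labeled = light_mz - PROTON_MASS
    candidates = generate_formulas(neutral_labeled, tolerance_mda, bounds)
    acids = []
    for f in candidates:
        counts = {s: f[s] - _LABEL_NET_ADD.get(s, 0) for s in ("C", "H", "N", "O")}
        if min(counts.values()) < 0:
            continue
        acids.append(Formula(counts))
    return acids


_SATURATION = {0: "saturated", 1: "monounsaturated"}


def classify(formula: Formula) -> tuple[str, str]:
    """(saturation class, chain-length class) of a candidate acid formula.

    Only plain CnHmO2 compositions are classed; anything else (extra oxygens,
    nitrogen — e.g. oxo-, hydroxy- or bile acids) is ('other', 'other') since
    saturation cannot be read off the formula.
    """
    if formula["O"] != 2 or formula["N"] != 0 or formula["C"] == 0:
        return ("other", "other")
    dbe = formula.rdbe
    double_bonds = dbe - 1  # carboxyl C=O uses one equivalent
    if double_bonds < 0 or double_bonds != int(double_bonds):
        return ("other", "other")
    sat = _SATURATION.get(int(double_bonds), "polyunsaturated")
    c = formula["C"]
    if c > 22:
        chain = "very long chain"
    elif c >= 13:
        chain = "long chain"
    elif c >= 6:
        chain = "medium chain"
    else:
        chain = "short chain"
    return (sat, chain)


def annotate(ffas: pd.DataFrame, library: list[LibraryEntry],
             mz_tolerance_mda: float = 5.0, ri_tolerance: float = 10.0,
             formula_tolerance_mda: float = 5.0,
             bounds: ElementBounds = DEFAULT_BOUNDS,
             max_candidates: int = 5) -> pd.DataFrame:
    """Full annotation: library match, then formula generation for the rest.

    Returns one row per FFA with ``status`` in {library, formula, unassigned};
    ``formula`` holds the matched entry's formula or up to ``max_candidates``
    ';'-joined de-novo candidates (best mass error first).
    """
    out = match_library(ffas, library, mz_tolerance_mda, ri_tolerance)
    mz_by_id = dict(zip(ffas["ffa_id"], ffas["mz"]))
    for i, row in out.iterrows():
        if row["status"] != "unmatched":
            cls = classify(Formula.parse(row["formula"]))
            # keep the curated library class; add formula-level saturation only
            # when the library class is generic
            if row["compound_class"] in ("", "other"):
                out.at[i, "compound_class"] = cls[0]
            continue
        cands = annotate_formula(mz_by_id[row["ffa_id"]], formula_tolerance_mda, bounds)
        if not cands:
            out.at[i, "status"] = "unassigned"
            continue
        out.at[i, "status"] = "formula"
        out.at[i, "formula"] = ";".join(str(f) for f in cands[:max_candidates])
        out.at[i, "compound_class"] = classify(cands[0])[0]
    return out
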