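"""Exact monoisotopic mass arithmetic for isotope-labeled fatty-acid derivatives.

Free carboxylic acids are amidated with 2-dimethylaminoethylamine (DMED) or its
four-deuterium analogue (d4-DMED) before LC-MS.  The derivative of a neutral
acid ``F`` is ``F + C4H12N2 - H2O`` (light) with four H->D substitutions for the
heavy tag, detected as ``[M+H]+``.  The light/heavy mass split of one labeled
analyte is therefore exactly ``4 x (m(2H) - m(1H)) = 4.0251068 Da``, the
signature used downstream to extract peak pairs.

This module also generates candidate molecular formulas over C/H/N/O from an
accurate neutral mass, with a ring-plus-double-bond-equivalents (RDBE)
plausibility filter.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from typing import Iterator, Mapping

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "Formula",
    "LabelTag",
    "ElementBounds",
    "DEFAULT_BOUNDS",
    "monoisotopic_mass",
    "derivative_mz",
    "pair_mass_delta",
    "generate_formulas",
]

# Standard monoisotopic atomic masses (Da), >=7 decimal places.
# "D" denotes deuterium (2H), tracked separately from 1H for labeled species.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "D": 2.0141017781,
    "N": 14.0030740052,
    "O": 15.9949146221,
}

#: Mass of a proton (Da); added for the [M+H]+ adduct.
PROTON_MASS = 1.0072764669

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Formula:
    """Element-count vector over C/H/N/O (plus deuterium ``D`` for labels).

    Counts are non-negative integers.  Hill-order string syntax is supported
    both ways: ``Formula.parse("C12H26N2O")`` and ``str(f)``.
    """

    counts: tuple[tuple[str, int], ...]

    def __init__(self, counts: Mapping[str, int] | None = None, **kw: int):
        merged: dict[str, int] = dict(counts or {})
        merged.update(kw)
        for sym, n in merged.items():
            if sym not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element symbol: {sym!r}")
            if not isinstance(n, (int,)) or n < 0:
                raise ValueError(f"element count must be a non-negative integer: {sym}={n}")
        clean = tuple(sorted((s, n) for s, n in merged.items() if n > 0))
        object.__setattr__(self, "counts", clean)

    # -- construction -----------------------------------------------------
    @classmethod
    def parse(cls, text: str) -> "Formula":
        """Parse a Hill-order element-count string; omitted count means 1."""
        text = text.strip()
        if not text:
            return cls({})
        pos = 0
        counts: dict[str, int] = {}
        for m in _FORMULA_TOKEN.finditer(text):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula string {text!r}")
            sym, num = m.group(1), m.group(2)
            if sym not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element symbol: {sym!r} in {text!r}")
            counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
            pos = m.end()
        if pos != len(text):
            raise ValueError(f"cannot parse formula string {text!r}")
        return cls(counts)

    # -- mapping-ish accessors --------------------------------------------
    def __getitem__(self, sym: str) -> int:
        return dict(self.counts).get(sym, 0)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.counts)

    def __bool__(self) -> bool:
        return bool(self.counts)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other: "Formula") -> "Formula":
        d = dict(self.counts)
        for s, n in other.counts:
            d[s] = d.get(s, 0) + n
        return Formula(d)

    def __sub__(self, other: "Formula") -> "Formula":
        d = dict(self.counts)
        for s, n in other.counts:
            d[s] = d.get(s, 0) - n
            if d[s] < 0:
                raise ValueError(
                    f"subtraction yields negative {s} count: {self} - {other}"
                )
        return Formula(d)

    # -- derived quantities --------------------------------------------------
    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    @property
    def rdbe(self) -> float:
        """Ring-plus-double-bond equivalents, C - H/2 + N/2 + 1 (D counts as H)."""
        return self["C"] - (self["H"] + self["D"]) / 2 + self["N"] / 2 + 1

    @property
    def n_atoms(self) -> int:
        return sum(n for _, n in self.counts)

    @property
    def n_heteroatoms(self) -> int:
        return sum(n for s, n in self.counts if s not in ("C", "H", "D"))

    def __str__(self) -> str:
        # Hill order: C, H (D after H), then other elements alphabetically.
        d = dict(self.counts)
        order = [s for s in ("C", "H", "D") if s in d]
        order += sorted(s for s in d if s not in ("C", "H", "D"))
        return "".join(f"{s}{d[s]}" if d[s] != 1 else s for s in order)

    def __repr__(self) -> str:
        return f"Formula({str(self)!r})"


def monoisotopic_mass(formula: Formula) -> float:
    """Sum of standard monoisotopic atomic masses of ``formula`` in Da."""
    return sum(MONOISOTOPIC_MASS[s] * n for s, n in formula)


_DMED = Formula.parse("C4H12N2")
_WATER = Formula.parse("H2O")

#: Neutral mass added by light (DMED) amidation: + C4H12N2 - H2O.
LIGHT_DELTA_MASS = monoisotopic_mass(_DMED) - monoisotopic_mass(_WATER)

#: Light-to-heavy split: four H -> D substitutions.
_PAIR_DELTA = 4 * (MONOISOTOPIC_MASS["D"] - MONOISOTOPIC_MASS["H"])


class LabelTag(enum.Enum):
    """Isotopic derivatization tag: light DMED or heavy d4-DMED."""

    LIGHT = "light"
    HEAVY = "heavy"

    @property
    def delta_mass(self) -> float:
        """Neutral mass added to the free acid by this tag's amidation."""
        if self is LabelTag.LIGHT:
            return LIGHT_DELTA_MASS
        return LIGHT_DELTA_MASS + _PAIR_DELTA

    def derivative_formula(self, neutral_fa: Formula) -> Formula:
        """Molecular formula of the (neutral) labeled amide."""
        f = neutral_fa + _DMED - _WATER
        if self is LabelTag.HEAVY:
            d = dict(f.counts)
            if d.get("H", 0) < 4:
                raise ValueError("derivative has fewer than 4 hydrogens to substitute")
            d["H"] -= 4
            d["D"] = d.get("D", 0) + 4
            f = Formula(d)
        return f


def pair_mass_delta() -> float:
    """Exact m/z split between heavy- and light-labeled forms of one analyte.

    ``4 x (m(2H) - m(1H)) = 4.0251068 Da``; the pipeline matches pairs around
    this exact value (the value is 4.025 when rounded to 3 decimals).
    """
    return _PAIR_DELTA


def derivative_mz(neutral_fa: Formula, tag: LabelTag) -> float:
    """Protonated ([M+H]+) m/z of the labeled amide of a neutral fatty acid.

    The caller is responsible for ``neutral_fa`` actually carrying a carboxylic
    acid group; no structural validation is done at the formula level.
    """
    return monoisotopic_mass(neutral_fa) + tag.delta_mass + PROTON_MASS


# ---------------------------------------------------------------------------
# Formula generation from accurate mass
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElementBounds:
    """Inclusive per-element count ranges for formula generation."""

    c: tuple[int, int] = (0, 50)
    h: tuple[int, int] = (0, 100)
    n: tuple[int, int] = (0, 6)
    o: tuple[int, int] = (0, 10)

    def __post_init__(self):
        for lo, hi in (self.c, self.h, self.n, self.o):
            if lo < 0 or hi < lo:
                raise ValueError("element bounds must satisfy 0 <= lo <= hi")


#: Default bounds: covers very-long-chain FFAs and the 2-nitrogen label
#: within the instrument scan range.
DEFAULT_BOUNDS = ElementBounds()


def generate_formulas(
    neutral_mass: float,
    tolerance_mda: float = 5.0,
    bounds: ElementBounds = DEFAULT_BOUNDS,
    rdbe_filter: bool = True,
) -> list[Formula]:
    """All C/H/N/O formulas within ``tolerance_mda`` of ``neutral_mass``.

    Candidates must additionally have RDBE >= 0 and integer-valued (the
    even-electron neutral-molecule plausibility filter) unless
    ``rdbe_filter=False``.  Results are sorted by absolute mass error, ties
    broken by fewer heteroatoms, then fewer atoms, then formula string.
    """
    if neutral_mass <= 0:
        raise ValueError(f"neutral_mass must be positive, got {neutral_mass}")
    if tolerance_mda <= 0:
        raise ValueError(f"tolerance must be positive, got {tolerance_mda}")
    tol = tolerance_mda / 1000.0
    m_c, m_h, m_n, m_o = (MONOISOTOPIC_MASS[s] for s in "CHNO")

    out: list[tuple[float, Formula]] = []
    for c in range(bounds.c[0], bounds.c[1] + 1):
        rem_c = neutral_mass - m_c * c
        if rem_c + tol < m_h * bounds.h[0]:
            break  # heavier C only makes it worse
        for n in range(bounds.n[0], bounds.n[1] + 1):
            rem_cn = rem_c - m_n * n
            if rem_cn + tol < 0:
                break
            for o in range(bounds.o[0], bounds.o[1] + 1):
                rem = rem_cn - m_o * o
                if rem + tol < m_h * bounds.h[0]:
                    break
                # H count window solving |rem - h*m_h| <= tol
                h_lo = max(bounds.h[0], int((rem - tol) / m_h))
                h_hi = min(bounds.h[1], int((rem + tol) / m_h) + 1)
                for h in range(h_lo, h_hi + 1):
                    if h < bounds.h[0] or h > bounds.h[1]:
                        continue
                    err = (m_c * c + m_h * h + m_n * n + m_o * o) - neutral_mass
                    if abs(err) > tol:
                        continue
                    if c == 0 and h == 0 and n == 0 and o == 0:
                        continue
                    rdbe = c - h / 2 + n / 2 + 1
                    if rdbe_filter and (rdbe < 0 or (h + n) % 2 != 0):
                        continue
                    out.append((err, Formula({"C": c, "H": h, "N": n, "O": o})))

    out.sort(key=lambda ef: (abs(ef[0]), ef[1].n_heteroatoms, ef[1].n_atoms, str(ef[1])))
    return [f for _, f in out]
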