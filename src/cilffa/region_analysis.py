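"""Presence/absence set algebra across brain regions.

From the merged potential-FFA table, build per-region FFA id sets, the
symmetric pairwise common-species counts matrix, and the asymmetric ratio
matrix R[a][b] = |A ∩ B| / |A| (the share of region a's FFAs also seen in b;
the denominator is the *row* region).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .feature_io import DEFAULT_REGIONS

__all__ = ["presence_sets", "common_matrix", "ratio_matrix", "plot_heatmap"]


def presence_sets(merged: pd.DataFrame,
                  regions: Sequence[str] | None = None) -> dict[str, set[str]]:
    """Map region -> set of FFA ids present there.

    ``merged`` is the output of ``merge_pairs_across_samples`` (columns
    ``ffa_id`` and ';'-joined ``regions``).  When ``regions`` is given, any
    label outside it raises; otherwise labels are taken as found.
    """
    known = set(regions) if regions is not None else None
    sets: dict[str, set[str]] = {r: set() for r in (regions or ())}
    if merged.empty:
        return sets
    for row in merged.itertuples(index=False):
        for region in str(row.regions).split(";"):
            if not region:
                continue
            if known is not None and region not in known:
                raise ValueError(f"unknown region label: {region!r}")
            sets.setdefault(region, set()).add(row.ffa_id)
    return sets


def _ordered(sets: Mapping[str, set[str]]) -> list[str]:
    default_order = {r: i for i, r in enumerate(DEFAULT_REGIONS)}
    return sorted(sets, key=lambda r: (default_order.get(r, len(default_order)), r))


def common_matrix(sets: Mapping[str, set[str]]) -> pd.DataFrame:
    """Symmetric matrix of pairwise common-FFA counts; diagonal = set sizes."""
    if len(sets) < 2:
        raise ValueError("need >= 2 regions for a common-species matrix")
    order = _ordered(sets)
    m = pd.DataFrame(0, index=order, columns=order, dtype=int)
    for a in order:
        for b in order:
            m.loc[a, b] = len(sets[a] & sets[b])
    return m


def ratio_matrix(common: pd.DataFrame, sizes: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Asymmetric ratio matrix R[row a][col b] = common(a,b) / size(a).

    The denominator is the row region, so R[FC][OB] answers "what share of
    FC's FFAs are also in OB".  Diagonal is 1; reciprocity
    R[a][b]*size(a) = R[b][a]*size(b) holds exactly.
    """
    if sizes is None:
        sizes = {r: int(common.loc[r, r]) for r in common.index}
    if any(sizes[r] == 0 for r in common.index):
        empty = [r for r in common.index if sizes[r] == 0]
        raise ValueError(f"empty region set(s): {empty}")
    r = common.astype(float).copy()
    for a in common.index:
        r.loc[a, :] = common.loc[a, :] / sizes[a]
    return r


def plot_heatmap(matrix: pd.DataFrame, path: str, title: str = "",
                 fmt: str = "{:.0f}") -> None:
    """Render a labeled heat map of a counts/ratio matrix (optional QC figure)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(0.6 * len(matrix.columns) + 2,
                                    0.6 * len(matrix.index) + 2))
    im = ax.imshow(matrix.to_numpy(dtype=float), cmap="viridis")
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=90)
    ax.set_yticks(range(len(matrix.index)), matrix.index)
    for i in range(len(matrix.index)):
        for j in range(len(matrix.columns)):
            ax.text(j, i, fmt.format(matrix.iat[i, j]), ha="center", va="center",
                    fontsize=7, color="w")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
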