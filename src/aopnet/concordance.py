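"""Pairwise assay-call concordance: phi (Matthews) correlation matrices
with similarity- and call-conditioning of the compound set.

"Correlation" of binary assay calls is computed as the phi coefficient of
the 2x2 Positive/Negative table, which equals the Pearson correlation of
the 0/1-coded calls on the same support.  Conflicted and missing calls
are non-informative and excluded pairwise.  Cells are Masked — rather
than set to an invented number — when too few paired calls exist or when
a margin of the table is zero (no variance to correlate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .similarity import Compound, neighbors

__all__ = [
    "ConcordanceCell",
    "phi",
    "phi_from_table",
    "concordance_matrix",
    "condition_subset",
    "similarity_subset",
    "matrix_to_frames",
]

_INFORMATIVE = ("Positive", "Negative")


@dataclass(frozen=True)
class ConcordanceCell:
    """phi is None iff the cell is Masked; n is always reported."""

    phi: float | None
    n: int

    @property
    def masked(self) -> bool:
        return self.phi is None


def phi_from_table(a: int, b: int, c: int, d: int) -> ConcordanceCell:
    """phi of the 2x2 table [[a, b], [c, d]] = (ad-bc)/sqrt of the margin
    product; Masked when any margin is zero."""
    n = a + b + c + d
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        return ConcordanceCell(None, n)
    return ConcordanceCell((a * d - b * c) / math.sqrt(margins), n)


def phi(calls_a: pd.Series, calls_b: pd.Series) -> ConcordanceCell:
    """phi over compounds with a Positive-or-Negative call in both series
    (aligned on their index)."""
    df = pd.concat({"a": calls_a, "b": calls_b}, axis=1)
    df = df[df["a"].isin(_INFORMATIVE) & df["b"].isin(_INFORMATIVE)]
    a = int(((df["a"] == "Positive") & (df["b"] == "Positive")).sum())
    b = int(((df["a"] == "Positive") & (df["b"] == "Negative")).sum())
    c = int(((df["a"] == "Negative") & (df["b"] == "Positive")).sum())
    d = int(((df["a"] == "Negative") & (df["b"] == "Negative")).sum())
    return phi_from_table(a, b, c, d)


def concordance_matrix(
    calls_wide: pd.DataFrame,
    assays: list[str] | None = None,
    min_n: int = 5,
) -> dict[tuple[str, str], ConcordanceCell]:
    """Symmetric phi matrix over assay pairs; additionally Masked where
    n < min_n.  The diagonal is 1 with n = the assay's informative-call
    count."""
    if min_n < 2:
        raise ValueError("min_n must be >= 2")
    assays = list(assays) if assays is not None else list(calls_wide.columns)
    out: dict[tuple[str, str], ConcordanceCell] = {}
    for i, ai in enumerate(assays):
        col_i = calls_wide[ai] if ai in calls_wide.columns else pd.Series(dtype=object)
        n_info = int(col_i.isin(_INFORMATIVE).sum())
        out[(ai, ai)] = ConcordanceCell(1.0 if n_info else None, n_info)
        for aj in assays[i + 1 :]:
            col_j = calls_wide[aj] if aj in calls_wide.columns else pd.Series(dtype=object)
            cell = phi(col_i, col_j)
            if cell.n < min_n:
                cell = ConcordanceCell(None, cell.n)
            out[(ai, aj)] = cell
            out[(aj, ai)] = cell
    return out


def condition_subset(calls_wide: pd.DataFrame, by_assay: str, call: str) -> pd.DataFrame:
    """Restrict to compounds with the given call in the given assay.  The
    conditioning assay loses its informative variance, so its row/column
    will be Masked in any subsequent matrix."""
    if by_assay not in calls_wide.columns:
        raise KeyError(f"unknown assay {by_assay!r}")
    return calls_wide[calls_wide[by_assay] == call]


def similarity_subset(
    calls_wide: pd.DataFrame,
    compounds: list[Compound],
    query: Compound,
    scheme: str = "path_default",
    cutoff: float = 0.5,
    alerts: dict[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Restrict to compounds similar to the query (Tanimoto >= cutoff
    under the chosen fingerprint scheme)."""
    near = {c.id for c, _ in neighbors(query, compounds, scheme, cutoff, alerts=alerts)}
    return calls_wide[calls_wide.index.isin(near)]


def matrix_to_frames(
    matrix: dict[tuple[str, str], ConcordanceCell],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a concordance matrix into a phi layer (NaN where Masked) and
    an n layer, both assay x assay, for CSV/heat-map output."""
    assays = sorted({a for a, _ in matrix})
    phi_df = pd.DataFrame(index=assays, columns=assays, dtype=float)
    n_df = pd.DataFrame(0, index=assays, columns=assays, dtype=int)
    for (ai, aj), cell in matrix.items():
        phi_df.loc[ai, aj] = float("nan") if cell.masked else cell.phi
        n_df.loc[ai, aj] = cell.n
    return phi_df, n_df
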