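"""Descriptive surfaces: code-count distribution, frequencies, practice ICC.

The intraclass correlation coefficient (ICC) quantifies how much of the
variation in use of a code is between family practices rather than between
patients.  It is computed with the one-way random-effects ANOVA
(method-of-moments) estimator applied directly to the 0/1 endorsement
indicator, the standard choice for clustered binary utilisation data:

    ICC = (MSB - MSW) / (MSB + (n0 - 1) MSW)

with MSB/MSW the between/within-practice mean squares and ``n0`` the
adjusted mean practice size for unbalanced groups,
``n0 = (N - sum n_j^2 / N) / (J - 1)``.  Negative estimates are truncated
to 0.  Practices contributing fewer than 2 cohort patients are excluded.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .records import ResponseMatrix

__all__ = [
    "code_count_distribution",
    "distribution_from_counts",
    "relative_frequency",
    "practice_icc",
    "icc_table",
    "IccEntry",
]


def distribution_from_counts(counts: Mapping[int, int]) -> pd.DataFrame:
    """Tabulate a distinct-code-count distribution from raw category counts.

    ``counts`` maps number-of-distinct-codes -> number of patients.  Exact
    percentages are retained alongside integer-rounded display values.
    """
    items = sorted(counts.items())
    n = np.array([v for _, v in items], dtype=np.int64)
    total = int(n.sum())
    if total == 0:
        raise ValueError("empty distribution")
    pct = 100.0 * n / total
    return pd.DataFrame(
        {
            "distinct_codes": [k for k, _ in items],
            "n_patients": n,
            "percentage": pct,
            "display_percentage": np.rint(pct).astype(int),
        }
    )


def code_count_distribution(matrix: ResponseMatrix) -> pd.DataFrame:
    """Distribution of patients by number of *distinct* codes endorsed."""
    if matrix.n_patients == 0:
        raise ValueError("empty response matrix")
    row_sums = matrix.X.sum(axis=1)
    values, freq = np.unique(row_sums, return_counts=True)
    return distribution_from_counts(dict(zip(values.tolist(), freq.tolist())))


def relative_frequency(events: pd.DataFrame, scope: list | None = None) -> pd.Series:
    """Share of (deduplicated) occurrences per code, over the given scope.

    The denominator is the total number of occurrences across the scoped
    codes; shares therefore sum to 1.
    """
    counts = events["code"].value_counts()
    if scope is not None:
        scope = list(scope)
        if len(scope) == 0:
            raise ValueError("empty code scope")
        counts = counts.reindex(scope, fill_value=0)
    total = counts.sum()
    if total == 0:
        raise ValueError("no occurrences in scope")
    return (counts / total).rename("relative_frequency")


@dataclasses.dataclass(frozen=True)
class IccEntry:
    code: str
    icc: float
    relative_frequency: float
    n_practices_used: int


def _anova_icc(y: np.ndarray, groups: np.ndarray) -> tuple[float, int]:
    """One-way random-effects ANOVA ICC on ``y`` grouped by ``groups``.

    Groups of size < 2 are excluded.  Returns (icc truncated to [0, 1],
    number of groups used).
    """
    labels, inverse = np.unique(groups, return_inverse=True)
    sizes = np.bincount(inverse)
    usable = sizes >= 2
    if usable.sum() < 2:
        raise ValueError("need at least 2 practices with at least 2 patients each")
    keep = usable[inverse]
    y = np.asarray(y, dtype=float)[keep]
    inverse = inverse[keep]
    labels_kept, inverse = np.unique(inverse, return_inverse=True)
    J = len(labels_kept)
    N = len(y)
    n_j = np.bincount(inverse).astype(float)
    sum_j = np.bincount(inverse, weights=y)
    mean_j = sum_j / n_j
    grand = y.mean()
    ssb = float(np.sum(n_j * (mean_j - grand) ** 2))
    ssw = float(np.sum((y - mean_j[inverse]) ** 2))
    msb = ssb / (J - 1)
    msw = ssw / (N - J)
    n0 = (N - np.sum(n_j**2) / N) / (J - 1)
    denom = msb + (n0 - 1.0) * msw
    if denom <= 0:
        return 0.0, J
    icc = (msb - msw) / denom
    return float(min(max(icc, 0.0), 1.0)), J


def practice_icc(matrix: ResponseMatrix, code: str) -> IccEntry:
    """Between-practice ICC for one code's endorsement indicator."""
    code_index = pd.Index(matrix.code_ids)
    i = code_index.get_loc(code)
    y = matrix.X[:, i].astype(float)
    icc, n_used = _anova_icc(y, matrix.practice)
    total = matrix.X.sum()
    rel = float(matrix.X[:, i].sum() / total) if total else 0.0
    return IccEntry(code=str(code), icc=icc, relative_frequency=rel, n_practices_used=n_used)


def icc_table(matrix: ResponseMatrix, codes: list | None = None, top: int | None = None) -> pd.DataFrame:
    """ICC and relative frequency per code, most frequent first.

    ``top`` limits the table to the most frequently endorsed codes, the
    usual reporting choice since rare codes carry little between-practice
    information.
    """
    counts = matrix.endorsement_counts().sort_values(ascending=False, kind="mergesort")
    if codes is None:
        codes = counts.index.tolist()
        if top is not None:
            codes = codes[:top]
    rows = []
    for code in codes:
        entry = practice_icc(matrix, code)
        term = (matrix.terms or {}).get(code, "")
        rows.append(
            {
                "code": entry.code,
                "term": term,
                "icc": entry.icc,
                "relative_frequency": entry.relative_frequency,
                "n_practices_used": entry.n_practices_used,
                "estimator": "one-way ANOVA (method of moments)",
            }
        )
    return pd.DataFrame(rows)
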