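"""Recognition-memory scoring.

Two primitives: the arcsine parametric modulator that converts a 5-point
recognition-confidence rating into a weight in [-1, +1], and the
area-under-the-ROC-curve memory-performance measure built from cumulative
hit / false-alarm proportions across the confidence criteria.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["parametric_modulator", "roc_points", "compute_auc", "validate_ratings"]

RATING_MIN, RATING_MAX = 1, 5


def parametric_modulator(rating):
    """Arcsine-transformed confidence rating.

    PM = arcsin((x - 3) / 2) * 2 / pi  for x in {1, ..., 5}, so that
    PM(1) = -1, PM(3) = 0 and PM(5) = +1.  High-confidence responses get
    disproportionately large weight relative to uncertain ones.

    Accepts a scalar or array; returns the same shape.
    """
    x = np.asarray(rating)
    if not np.all(np.isin(x, np.arange(RATING_MIN, RATING_MAX + 1))):
        raise ValueError(f"ratings must be integers in [{RATING_MIN}, {RATING_MAX}]")
    pm = np.arcsin((x - 3) / 2.0) * 2.0 / np.pi
    if np.isscalar(rating):
        return float(pm)
    return pm


def validate_ratings(table: pd.DataFrame) -> pd.DataFrame:
    """Check a rating table (columns ``status`` in {old,new}, ``rating`` 1-5)."""
    if not {"status", "rating"}.issubset(table.columns):
        raise ValueError("rating table needs 'status' and 'rating' columns")
    if not set(table["status"]) <= {"old", "new"}:
        raise ValueError("status must be 'old' or 'new'")
    r = table["rating"].to_numpy()
    if not np.all(np.isin(r, np.arange(RATING_MIN, RATING_MAX + 1))):
        raise ValueError("ratings must be integers in [1, 5]")
    return table


def roc_points(old_ratings, new_ratings):
    """Cumulative (false-alarm, hit) proportions at criteria >=5, >=4, >=3, >=2.

    Returns arrays ``fa`` and ``hits`` of length 6 including the (0, 0) and
    (1, 1) endpoints, ordered by increasing false-alarm rate.
    """
    old = np.asarray(old_ratings, dtype=float)
    new = np.asarray(new_ratings, dtype=float)
    if old.size == 0 or new.size == 0:
        raise ValueError("need at least one old and one new item")
    fa = [0.0]
    hits = [0.0]
    for c in (5, 4, 3, 2):
        hits.append(np.mean(old >= c))
        fa.append(np.mean(new >= c))
    fa.append(1.0)
    hits.append(1.0)
    return np.array(fa), np.array(hits)


def compute_auc(table: pd.DataFrame) -> float:
    """Area under the confidence-rating ROC curve (trapezoidal rule).

    0.5 indicates chance discrimination, 1.0 perfect old/new separation.
    Equivalent to the tie-corrected Mann-Whitney statistic U / (n_old *
    n_new) on the same ratings.
    """
    validate_ratings(table)
    old = table.loc[table["status"] == "old", "rating"]
    new = table.loc[table["status"] == "new", "rating"]
    fa, hits = roc_points(old, new)
    return float(np.trapezoid(hits, fa))
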