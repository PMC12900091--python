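"""Two-group MANOVA via Wilks' Lambda.

Healthy vs diseased feature distributions are compared with a multivariate
analysis of variance.  Wilks' Λ = det(W) / det(W + B), where W and B are the
within- and between-group sums-of-squares-and-cross-products matrices, is
the ratio of within-group to total generalized variance; Λ near 1 means no
separation, Λ near 0 strong separation.  For exactly two groups the F
approximation is exact through the Hotelling T² identity:

    F = (1 − Λ) / Λ · (n − d − 1) / d   on  (d, n − d − 1)  df.

Only the two-group case is implemented — Rao's general approximation is
unnecessary when the identity is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import FeatureTable

__all__ = ["ManovaResult", "manova_wilks", "manova_suite"]

#: Conventional significance threshold reported (never enforced) alongside p.
ALPHA = 0.05


@dataclass
class ManovaResult:
    wilks_lambda: float
    F: float
    df1: int
    df2: int
    p: float

    def display_value(self) -> str:
        """'Value [F-Value]' formatting used in the comparison tables."""
        return f"{self.wilks_lambda:.3f} [{self.F:.2f}]"


def manova_wilks(X: np.ndarray, y: np.ndarray) -> ManovaResult:
    """Wilks' Lambda MANOVA for two groups.

    Parameters
    ----------
    X : (n, d) array
        Per-case feature vectors (dependent variables).
    y : (n,) array
        Binary group labels.

    Scatter matrices are raw sums of squares/cross-products about the group
    and grand means (no df scaling — Λ is invariant to that choice).
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y)
    n, d = X.shape
    if d == 0:
        raise ValueError("need at least one dependent variable")
    groups = np.unique(y)
    if groups.size != 2:
        raise ValueError("exactly two groups required")
    if any(np.sum(y == g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 cases")
    if n < d + 2:
        raise ValueError(f"need n ≥ d + 2 (n={n}, d={d})")

    grand = X.mean(axis=0)
    W = np.zeros((d, d))
    B = np.zeros((d, d))
    for g in groups:
        Xg = X[y == g]
        mg = Xg.mean(axis=0)
        C = Xg - mg
        W += C.T @ C
        diff = (mg - grand)[:, None]
        B += Xg.shape[0] * (diff @ diff.T)

    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(W + B)
    if sign_w <= 0 or not np.isfinite(logdet_w):
        raise np.linalg.LinAlgError(
            "within-group scatter matrix is singular; reduce the number of "
            "features or add cases")
    lam = float(np.exp(logdet_w - logdet_t)) if sign_t > 0 else 0.0
    lam = min(lam, 1.0)

    df1, df2 = d, n - d - 1
    if lam == 0.0:
        F = np.inf
    else:
        F = (1.0 - lam) / lam * df2 / df1
    p = float(sps.f.sf(F, df1, df2))
    return ManovaResult(lam, float(F), df1, df2, p)


def manova_suite(tables: dict[str, FeatureTable]) -> pd.DataFrame:
    """Run the two-group MANOVA for several feature representations.

    ``tables`` maps a representation name (e.g. ``Avg-RGB``, ``Avg-MSI``,
    ``Phasor-RGB``, ``Phasor-MSI``) to its feature table; phasor tables must
    carry exactly the two dependent variables (g_avg, s_avg) — never STD.
    All tables must share the same cases and labels.
    """
    items = list(tables.items())
    if not items:
        raise ValueError("no tables given")
    ref = items[0][1]
    rows = []
    for name, table in items:
        if table.case_ids != ref.case_ids or not np.array_equal(table.y, ref.y):
            raise ValueError(f"table '{name}' does not share the reference case set")
        res = manova_wilks(table.X, table.y)
        rows.append({
            "analysis": name, "d": table.d, "wilks_lambda": res.wilks_lambda,
            "F": res.F, "df1": res.df1, "df2": res.df2, "p": res.p,
            "Value [F-Value]": res.display_value(),
            "significant": res.p < ALPHA,
        })
    return pd.DataFrame(rows).set_index("analysis")
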