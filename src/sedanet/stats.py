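"""Repeated-measures statistics for condition comparisons.

One-way repeated-measures ANOVA with the Greenhouse-Geisser sphericity
correction, Bonferroni-adjusted paired post-hoc t-tests, and Pearson
correlations with one- or two-tailed p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import linalg, stats as sps

__all__ = [
    "AnovaResult",
    "PairedTestResult",
    "CorrResult",
    "rm_anova_gg",
    "paired_posthoc_bonferroni",
    "pearson",
]


@dataclass
class AnovaResult:
    """GG-corrected one-way repeated-measures ANOVA."""

    f: float
    df1: float
    df2: float
    epsilon: float
    p: float
    degenerate: bool = False


@dataclass
class PairedTestResult:
    pair: tuple[str, str]
    t: float
    p: float
    p_adj: float
    degenerate: bool = False


@dataclass
class CorrResult:
    r: float
    n: int
    t: float
    p: float
    tails: str
    exact_fit: bool = False


def _validate_table(data) -> np.ndarray:
    x = np.asarray(
        data.to_numpy() if isinstance(data, pd.DataFrame) else data, dtype=float
    )
    if x.ndim != 2:
        raise ValueError("data must be subjects x conditions")
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if k < 2:
        raise ValueError("need at least 2 conditions")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing cells are not allowed")
    return x


def rm_anova_gg(data) -> AnovaResult:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction.

    The sphericity estimate is the Box epsilon of the covariance of the
    condition columns in an orthonormal contrast basis,
    ``eps = tr(V)^2 / ((k-1) tr(V^2))`` with ``V = C S C'``; the F statistic
    is referred to an F distribution with epsilon-scaled degrees of freedom
    ``(eps(k-1), eps(n-1)(k-1))``.

    A zero error sum of squares is flagged degenerate (infinite F, p = 0)
    rather than raising.
    """
    x = _validate_table(data)
    n, k = x.shape
    grand = x.mean()
    mj = x.mean(axis=0)
    ms = x.mean(axis=1)
    ss_cond = n * ((mj - grand) ** 2).sum()
    ss_subj = k * ((ms - grand) ** 2).sum()
    ss_tot = ((x - grand) ** 2).sum()
    ss_err = max(ss_tot - ss_cond - ss_subj, 0.0)
    df1, df2 = k - 1.0, (n - 1.0) * (k - 1.0)

    s = np.cov(x, rowvar=False)
    c = linalg.helmert(k, full=False)  # (k-1) x k orthonormal, rows _|_ ones
    v = c @ s @ c.T
    tr_v = np.trace(v)
    tr_v2 = np.trace(v @ v)
    eps = 1.0 if tr_v2 <= 0 else float(tr_v**2 / ((k - 1) * tr_v2))
    eps = float(np.clip(eps, 1.0 / (k - 1), 1.0))

    if ss_err <= 0:
        if ss_cond == 0:
            return AnovaResult(0.0, eps * df1, eps * df2, eps, 1.0, degenerate=True)
        return AnovaResult(np.inf, eps * df1, eps * df2, eps, 0.0, degenerate=True)
    f = (ss_cond / df1) / (ss_err / df2)
    p = float(sps.f.sf(f, eps * df1, eps * df2))
    return AnovaResult(float(f), eps * df1, eps * df2, eps, p)


def paired_posthoc_bonferroni(
    data, labels: list[str] | None = None
) -> list[PairedTestResult]:
    """Paired t-tests for every unordered condition pair, Bonferroni-adjusted.

    Adjusted p = min(1, p * number_of_pairs).  Zero-variance difference
    scores are flagged degenerate: t = 0, p = 1 if the means are equal, else
    an infinite t with p capped at 0.
    """
    x = _validate_table(data)
    k = x.shape[1]
    if labels is None:
        labels = (
            list(data.columns)
            if isinstance(data, pd.DataFrame)
            else [f"c{j}" for j in range(k)]
        )
    pairs = list(combinations(range(k), 2))
    out = []
    for i, j in pairs:
        d = x[:, i] - x[:, j]
        if d.std(ddof=1) == 0:
            if d.mean() == 0:
                res = PairedTestResult(
                    (labels[i], labels[j]), 0.0, 1.0, 1.0, degenerate=True
                )
            else:
                res = PairedTestResult(
                    (labels[i], labels[j]),
                    np.inf if d.mean() > 0 else -np.inf,
                    0.0,
                    0.0,
                    degenerate=True,
                )
        else:
            t, p = sps.ttest_rel(x[:, i], x[:, j])
            res = PairedTestResult(
                (labels[i], labels[j]),
                float(t),
                float(p),
                min(1.0, float(p) * len(pairs)),
            )
        out.append(res)
    return out


def pearson(x, y, tails: str = "two") -> CorrResult:
    """Pearson correlation with a t-based p-value.

    ``t = r sqrt((n-2) / (1-r^2))``; the one-tailed p is taken in the
    direction of the observed sign of r.  |r| = 1 returns p = 0 with an
    exact-fit flag.
    """
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("both variables need positive variance")
    r = float(np.corrcoef(x, y)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0 - 1e-14:  # exact linear dependence up to roundoff
        r = 1.0 if r > 0 else -1.0
        t = np.inf if r > 0 else -np.inf
        return CorrResult(r, n, t, 0.0, tails, exact_fit=True)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    if tails == "two":
        p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    else:
        p = float(sps.t.sf(abs(t), n - 2))
    return CorrResult(r, n, float(t), p, tails)
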