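"""Nodal strength and the hub disruption index (kappa).

The hub disruption index of a condition pair is the ordinary-least-squares
slope of per-node strength change (target minus reference condition) against
reference strength: a negative kappa means high-strength hubs lose
connectivity while low-strength nodes gain it -- a reorganisation of the hub
hierarchy rather than a uniform shift.

Strengths are computed on the full signed correlation matrices (no
threshold), i.e. the sum of Pearson correlation values per node.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graphs import ConnectivityMatrix

__all__ = [
    "KappaResult",
    "nodal_strength",
    "ols_slope",
    "strength_table",
    "hub_disruption",
]


@dataclass
class KappaResult:
    """Hub disruption slope for one condition pair at one level."""

    kappa: float
    intercept: float
    pair: tuple[str, str]
    level: str  # subject id or "group"
    points: pd.DataFrame  # columns: node, x, y
    r_squared: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.kappa):
            raise ValueError("kappa must be finite")


def nodal_strength(w: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Signed sum of each node's weights to all other nodes."""
    if isinstance(w, ConnectivityMatrix):
        w = w.weights
    w = np.asarray(w, dtype=float)
    return w.sum(axis=1) - np.diag(w)


def ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Ordinary least squares fit y = slope * x + intercept.

    Returns (slope, intercept, r_squared).  Requires >= 3 points and
    non-constant x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    vx = x.var()
    if vx == 0:
        raise ValueError("x is constant; slope undefined")
    slope = float(np.cov(x, y, bias=True)[0, 1] / vx)
    intercept = float(y.mean() - slope * x.mean())
    vy = y.var()
    r2 = 0.0 if vy == 0 else float((np.cov(x, y, bias=True)[0, 1] ** 2) / (vx * vy))
    return slope, intercept, r2


def strength_table(
    matrices: dict[tuple[str, str], ConnectivityMatrix]
) -> pd.DataFrame:
    """Stack per-(subject, condition) nodal strengths into a table.

    Rows are a (subject, condition) MultiIndex; columns are node labels.
    """
    rows = {}
    labels = None
    for (subj, cond), c in matrices.items():
        if labels is None:
            labels = list(c.node_labels)
        elif list(c.node_labels) != labels:
            raise ValueError(f"node labels differ for ({subj}, {cond})")
        rows[(subj, cond)] = nodal_strength(c)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = labels
    df.index = pd.MultiIndex.from_tuples(df.index, names=["subject", "condition"])
    return df


def hub_disruption(
    strengths: pd.DataFrame,
    reference: str,
    target: str,
    level: str = "group",
    x_axis: str = "reference",
) -> KappaResult | list[KappaResult]:
    """Hub disruption index for a condition pair.

    Parameters
    ----------
    strengths : DataFrame
        (subject, condition) MultiIndex rows x node columns, as produced by
        :func:`strength_table`.
    reference, target : str
        Condition labels; y is strength(target) - strength(reference).
    level : {"group", "subject"}
        Group level regresses the across-subject mean change on the
        across-subject mean reference strength (one result); subject level
        regresses each subject's change on that subject's own reference
        strengths (one result per subject).
    x_axis : {"reference", "target"}
        Which condition supplies the x axis.  ``"reference"`` follows the
        original hub-disruption formulation; ``"target"`` is the alternative
        reading in which x is the sedation-condition strength.
    """
    if x_axis not in ("reference", "target"):
        raise ValueError("x_axis must be 'reference' or 'target'")
    subjects = strengths.index.get_level_values("subject").unique()
    for cond in (reference, target):
        for s in subjects:
            if (s, cond) not in strengths.index:
                raise ValueError(f"missing strength row for ({s}, {cond})")
    ref = strengths.xs(reference, level="condition").loc[subjects]
    tgt = strengths.xs(target, level="condition").loc[subjects]
    diff = tgt.to_numpy() - ref.to_numpy()
    xcond = ref if x_axis == "reference" else tgt
    nodes = list(strengths.columns)

    def _fit(x, y, lev):
        slope, intercept, r2 = ols_slope(x, y)
        pts = pd.DataFrame({"node": nodes, "x": x, "y": y})
        return KappaResult(slope, intercept, (reference, target), lev, pts, r2)

    if level == "group":
        return _fit(xcond.to_numpy().mean(axis=0), diff.mean(axis=0), "group")
    if level == "subject":
        return [
            _fit(xcond.to_numpy()[i], diff[i], str(s))
            for i, s in enumerate(subjects)
        ]
    raise ValueError("level must be 'group' or 'subject'")
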