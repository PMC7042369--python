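"""Synthetic multi-subject, multi-condition connectome studies.

Every downstream stage (graph construction, community detection, hub
disruption, rich-club tracking, statistics) is testable without any imaging
data because the generator plants known structure:

* a block-modular correlation matrix (3-4 communities) with unit diagonal,
  repaired to the nearest positive-semidefinite correlation matrix;
* high-strength hub nodes (top decile of each block by construction) whose
  off-block correlations are boosted, and boosted twice between two hubs so
  that the hubs interconnect beyond what their strength alone implies (a
  planted rich-club);
* a condition effect that rescales the matrix so nodal strengths follow
  ``s'_i = s_i + kappa (s_i - mean(s))`` -- a planted hub disruption slope;
* behavioural error counts whose change across the two sedation conditions
  correlates with each subject's planted rich-club strength change at a
  target Pearson r.

Time series are zero-mean multivariate normal draws from the per-subject
covariance; subjects differ by small random perturbations of the
off-diagonal entries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graphs import TimeSeriesPanel

__all__ = [
    "CovarianceModel",
    "StudyDesign",
    "SyntheticStudy",
    "nearest_psd_correlation",
    "generate_covariance",
    "apply_condition_effect",
    "attenuate_club",
    "generate_timeseries",
    "generate_study",
    "power_like_parcellation",
    "write_study",
]

#: Network names of the 14-network cortical/subcortical parcellation scheme
#: the synthetic label table emulates.
NETWORK_NAMES = [
    "DMN", "VN", "SMN", "FPN", "SAN", "CON", "DAN", "VAN",
    "AN", "SCN", "MEM", "CER", "UNC", "SMN-mouth",
]


def _offdiag_strength(cov: np.ndarray) -> np.ndarray:
    return cov.sum(axis=1) - np.diag(cov)


def nearest_psd_correlation(a: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues to zero and renormalise to unit diagonal."""
    a = (a + a.T) / 2.0
    w, v = np.linalg.eigh(a)
    if w[0] >= 0 and np.allclose(np.diag(a), 1.0, atol=1e-12):
        np.fill_diagonal(a, 1.0)
        return a  # already a valid correlation matrix; keep entries exact
    w = np.clip(w, 0.0, None)
    a = (v * w) @ v.T
    d = np.clip(np.diag(a), 1e-12, None)
    a = a / np.sqrt(np.outer(d, d))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return a


@dataclass
class CovarianceModel:
    """A correlation-scale covariance with planted structure.

    ``planted_kappa`` records the hub-disruption slope planted relative to the
    model this one was derived from (0 for a freshly generated baseline);
    ``achieved_kappa`` is the slope actually realised after PSD repair.
    """

    cov: np.ndarray
    partition: np.ndarray
    hub_nodes: np.ndarray
    r_within: float
    r_between: float
    planted_kappa: float = 0.0
    achieved_kappa: float = 0.0
    clip_warnings: int = 0
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        c = np.asarray(self.cov, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("cov must be square")
        if not np.allclose(c, c.T, atol=1e-10):
            raise ValueError("cov must be symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-10):
            raise ValueError("cov must have unit diagonal")
        if np.linalg.eigvalsh(c).min() < -1e-8:
            raise ValueError("cov must be positive semidefinite")
        if abs(self.planted_kappa) >= 1:
            raise ValueError("|planted_kappa| must be < 1")
        self.cov = c
        self.partition = np.asarray(self.partition, dtype=int)
        self.hub_nodes = np.asarray(self.hub_nodes, dtype=int)
        if self.hub_nodes.size and (
            self.hub_nodes.min() < 0 or self.hub_nodes.max() >= c.shape[0]
        ):
            raise ValueError("hub_nodes outside node range")
        if not self.node_labels:
            self.node_labels = [f"roi{i:03d}" for i in range(c.shape[0])]

    @property
    def n_nodes(self) -> int:
        return self.cov.shape[0]

    def strengths(self) -> np.ndarray:
        """Off-diagonal row sums (model-level nodal strengths)."""
        return _offdiag_strength(self.cov)


@dataclass
class StudyDesign:
    """Subjects x conditions design with drug concentration and task errors."""

    subjects: list[str]
    conditions: list[str]
    plasma: pd.DataFrame  # subjects x conditions, ug/mL
    errors: pd.DataFrame  # subjects x conditions, integer counts

    def __post_init__(self) -> None:
        for df, name in ((self.plasma, "plasma"), (self.errors, "errors")):
            if list(df.index) != list(self.subjects) or list(df.columns) != list(
                self.conditions
            ):
                raise ValueError(f"{name} table does not match design")
        if (self.plasma.to_numpy() < 0).any():
            raise ValueError("concentrations must be >= 0")
        e = self.errors.to_numpy()
        if (e < 0).any() or not np.array_equal(e, e.astype(int)):
            raise ValueError("errors must be non-negative integers")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject": s,
                "condition": c,
                "plasma_ugml": float(self.plasma.loc[s, c]),
                "errors": int(self.errors.loc[s, c]),
            }
            for s in self.subjects
            for c in self.conditions
        ]
        return pd.DataFrame(rows)


@dataclass
class SyntheticStudy:
    """Panels keyed by (subject, condition) plus design and ground truth."""

    panels: dict[tuple[str, str], TimeSeriesPanel]
    design: StudyDesign
    ground_truth: dict

    def __post_init__(self) -> None:
        expected = {
            (s, c) for s in self.design.subjects for c in self.design.conditions
        }
        if set(self.panels) != expected:
            raise ValueError("panels do not cover every (subject, condition) once")
        shapes = {p.signals.shape for p in self.panels.values()}
        if len(shapes) != 1:
            raise ValueError("panels differ in node count or length")


def generate_covariance(
    n_nodes: int,
    module_sizes: tuple[int, ...],
    r_within: float,
    r_between: float,
    hub_boost: float = 0.0,
    seed: int = 0,
) -> CovarianceModel:
    """Block-modular correlation matrix with planted hubs.

    Blocks get ``r_within`` inside and ``r_between`` outside; the last
    ``ceil(10%)`` nodes of each block are hubs whose off-block entries are
    raised by ``hub_boost`` per hub endpoint (so hub-hub off-block entries
    gain ``2 * hub_boost``).  The result is repaired to the nearest PSD
    correlation matrix.  Deterministic per seed (the construction itself is
    deterministic; the seed is accepted for interface symmetry).
    """
    del seed  # construction is fully deterministic
    if sum(module_sizes) != n_nodes:
        raise ValueError("module_sizes must sum to n_nodes")
    if not (0 <= r_between <= r_within < 1):
        raise ValueError("need 0 <= r_between <= r_within < 1")
    partition = np.repeat(np.arange(len(module_sizes)), module_sizes)
    cov = np.full((n_nodes, n_nodes), float(r_between))
    start = 0
    hubs = []
    for size in module_sizes:
        block = slice(start, start + size)
        cov[block, block] = r_within
        n_hub = int(np.ceil(0.1 * size))
        hubs.extend(range(start + size - n_hub, start + size))
        start += size
    hubs = np.asarray(hubs, dtype=int)
    if hub_boost > 0:
        is_hub = np.zeros(n_nodes, dtype=bool)
        is_hub[hubs] = True
        off_block = partition[:, None] != partition[None, :]
        n_hub_ends = is_hub[:, None].astype(int) + is_hub[None, :].astype(int)
        cov = cov + hub_boost * n_hub_ends * off_block
    cov = np.clip(cov, -0.99, 0.99)
    np.fill_diagonal(cov, 1.0)
    cov = nearest_psd_correlation(cov)
    return CovarianceModel(
        cov=cov,
        partition=partition,
        hub_nodes=hubs,
        r_within=float(r_within),
        r_between=float(r_between),
    )


def apply_condition_effect(
    model: CovarianceModel, planted_kappa: float, seed: int = 0
) -> CovarianceModel:
    """Rescale the covariance so nodal strengths follow the planted slope.

    Target strengths are ``s_i + kappa (s_i - mean(s))``; the matrix is
    brought to them by iterative symmetric row/column rescaling
    (``w_ij <- w_ij sqrt(f_i f_j)``), entries clipped to [-1, 1] (counted as
    warnings), then repaired to the nearest PSD correlation matrix.  The OLS
    slope of the realised strength change on the original strengths is stored
    as ``achieved_kappa`` and lands within about +-0.05 of the request.
    """
    del seed  # the rescaling is deterministic
    if abs(planted_kappa) >= 1:
        raise ValueError("|planted_kappa| must be < 1")
    s0 = model.strengths()
    target = s0 + planted_kappa * (s0 - s0.mean())
    cov = model.cov.copy()
    np.fill_diagonal(cov, 0.0)
    clipped = 0
    for _ in range(60):
        s = cov.sum(axis=1)
        ratio = np.clip(target / np.where(np.abs(s) < 1e-9, 1e-9, s), 0.05, 20.0)
        cov = cov * np.sqrt(np.outer(ratio, ratio))
        over = np.abs(cov) > 1.0
        clipped += int(over.sum())
        cov = np.clip(cov, -1.0, 1.0)
    np.fill_diagonal(cov, 1.0)
    cov = nearest_psd_correlation(cov)
    s1 = _offdiag_strength(cov)
    dx = s0 - s0.mean()
    achieved = float(dx @ (s1 - s0) / (dx @ dx)) if dx @ dx > 0 else 0.0
    return CovarianceModel(
        cov=cov,
        partition=model.partition.copy(),
        hub_nodes=model.hub_nodes.copy(),
        r_within=model.r_within,
        r_between=model.r_between,
        planted_kappa=float(planted_kappa),
        achieved_kappa=achieved,
        clip_warnings=clipped // 2,
        node_labels=list(model.node_labels),
    )


def attenuate_club(model: CovarianceModel, factor: float) -> CovarianceModel:
    """Scale hub-hub entries by ``1 - factor`` (planted club weakening)."""
    if not 0 <= factor < 1:
        raise ValueError("factor must be in [0, 1)")
    cov = model.cov.copy()
    h = model.hub_nodes
    if h.size >= 2 and factor > 0:
        sub = cov[np.ix_(h, h)] * (1.0 - factor)
        cov[np.ix_(h, h)] = sub
        np.fill_diagonal(cov, 1.0)
        cov = nearest_psd_correlation(cov)
    return CovarianceModel(
        cov=cov,
        partition=model.partition.copy(),
        hub_nodes=h.copy(),
        r_within=model.r_within,
        r_between=model.r_between,
        planted_kappa=model.planted_kappa,
        achieved_kappa=model.achieved_kappa,
        clip_warnings=model.clip_warnings,
        node_labels=list(model.node_labels),
    )


def _mvn_factor(cov: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(cov)
    if w.min() < -1e-8:
        raise ValueError("covariance is not positive semidefinite")
    return v * np.sqrt(np.clip(w, 0.0, None))


def generate_timeseries(
    model: CovarianceModel,
    n_timepoints: int,
    seed: int,
    subject: str = "sim",
    condition: str = "B",
) -> TimeSeriesPanel:
    """Zero-mean multivariate normal draw with the model covariance."""
    rng = np.random.default_rng(seed)
    factor = _mvn_factor(model.cov)
    z = rng.standard_normal((n_timepoints, model.n_nodes))
    signals = (z @ factor.T).T
    return TimeSeriesPanel(
        subject=subject,
        condition=condition,
        signals=signals,
        node_labels=list(model.node_labels),
    )


def _jitter_model(model: CovarianceModel, sd: float, rng: np.random.Generator):
    """Subject-level perturbation: N(0, sd^2) on off-diagonals, PSD repair."""
    n = model.n_nodes
    noise = rng.normal(0.0, sd, size=(n, n))
    noise = (noise + noise.T) / 2.0
    np.fill_diagonal(noise, 0.0)
    cov = nearest_psd_correlation(np.clip(model.cov + noise, -1.0, 1.0))
    out = CovarianceModel(
        cov=cov,
        partition=model.partition.copy(),
        hub_nodes=model.hub_nodes.copy(),
        r_within=model.r_within,
        r_between=model.r_between,
        planted_kappa=model.planted_kappa,
        achieved_kappa=model.achieved_kappa,
        node_labels=list(model.node_labels),
    )
    return out


def _club_cov_strength(model: CovarianceModel) -> float:
    h = model.hub_nodes
    sub = model.cov[np.ix_(h, h)]
    n = len(h)
    return float((sub.sum() - n) / (n * (n - 1)))


def generate_study(
    n_subjects: int,
    conditions: list[str],
    model_per_condition: list[CovarianceModel],
    n_timepoints: int,
    behaviour_target_r: float,
    seed: int,
    subject_jitter_sd: float = 0.02,
    base_error_mean: float = 5.0,
    base_error_sd: float = 1.5,
    delta_error_mean: float = 3.0,
    delta_error_sd: float = 3.0,
    plasma_targets: dict[str, float] | None = None,
    plasma_jitter_sd: float = 0.1,
) -> SyntheticStudy:
    """Full synthetic study with recorded ground truth.

    Per subject, each condition model is perturbed (off-diagonal N(0,
    ``subject_jitter_sd``^2), PSD-repaired) and a time-series panel sampled.
    The error-count change between the last two conditions is
    ``round(a z_s + b eta_s + c)`` where ``z_s`` is the subject's
    standardised planted rich-club-strength change, ``a / sqrt(a^2 + b^2) =
    behaviour_target_r``, and ``eta_s`` is standard normal; plasma
    concentrations are drawn around 0 / 0.6 / 1.2 ug/mL (N(., 0.1^2),
    floored at 0).
    """
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    if len(conditions) != len(model_per_condition):
        raise ValueError("one model per condition required")
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions")
    if not -1 <= behaviour_target_r <= 1:
        raise ValueError("|behaviour_target_r| must be <= 1")
    if plasma_targets is None:
        defaults = {0: 0.0, 1: 0.6, 2: 1.2}
        plasma_targets = {
            c: defaults.get(i, 1.2) for i, c in enumerate(conditions)
        }
    rng = np.random.default_rng(seed)
    subjects = [f"sub{i + 1:02d}" for i in range(n_subjects)]

    panels: dict[tuple[str, str], TimeSeriesPanel] = {}
    club_change = np.empty(n_subjects)
    per_subject_kappa: dict[str, dict[str, float]] = {}
    for si, subj in enumerate(subjects):
        per_subject_kappa[subj] = {}
        subj_models = {}
        for cond, base_model in zip(conditions, model_per_condition):
            m = _jitter_model(base_model, subject_jitter_sd, rng)
            subj_models[cond] = m
            panel_seed = int(rng.integers(0, 2**31 - 1))
            panels[(subj, cond)] = generate_timeseries(
                m, n_timepoints, panel_seed, subject=subj, condition=cond
            )
        c_last, c_prev = conditions[-1], conditions[-2]
        club_change[si] = _club_cov_strength(subj_models[c_last]) - _club_cov_strength(
            subj_models[c_prev]
        )

    # behavioural errors: z = standardised planted club-strength change
    z = (club_change - club_change.mean()) / (
        club_change.std() if club_change.std() > 0 else 1.0
    )
    a = behaviour_target_r * delta_error_sd
    b = float(np.sqrt(max(delta_error_sd**2 - a**2, 0.0)))
    eta = rng.standard_normal(n_subjects)
    delta = np.round(a * z + b * eta + delta_error_mean)

    base = np.maximum(
        np.round(rng.normal(base_error_mean, base_error_sd, size=(n_subjects, 2))), 0
    )
    errors = np.zeros((n_subjects, len(conditions)))
    errors[:, 0] = base[:, 0]
    if len(conditions) >= 3:
        errors[:, 1:-1] = base[:, 1:2]
    errors[:, -1] = np.maximum(errors[:, -2] + delta, 0)

    plasma = np.zeros((n_subjects, len(conditions)))
    for ci, cond in enumerate(conditions):
        mu = plasma_targets[cond]
        if mu == 0:
            continue
        plasma[:, ci] = np.maximum(
            rng.normal(mu, plasma_jitter_sd, size=n_subjects), 0.0
        )

    design = StudyDesign(
        subjects=subjects,
        conditions=list(conditions),
        plasma=pd.DataFrame(plasma, index=subjects, columns=conditions),
        errors=pd.DataFrame(errors.astype(int), index=subjects, columns=conditions),
    )
    ground_truth = {
        "conditions": list(conditions),
        "planted_kappa": {
            c: m.planted_kappa for c, m in zip(conditions, model_per_condition)
        },
        "achieved_kappa": {
            c: m.achieved_kappa for c, m in zip(conditions, model_per_condition)
        },
        "hub_nodes": model_per_condition[0].hub_nodes.tolist(),
        "partition": model_per_condition[0].partition.tolist(),
        "behaviour_target_r": float(behaviour_target_r),
        "club_strength_change": club_change.tolist(),
        "club_change_z": z.tolist(),
        "delta_errors": delta.tolist(),
        "seed": int(seed),
    }
    return SyntheticStudy(panels=panels, design=design, ground_truth=ground_truth)


def power_like_parcellation(
    n_rois_initial: int = 264, n_removed: int = 6, n_networks: int = 14
) -> pd.DataFrame:
    """Synthetic ROI label table emulating a 264-ROI/14-network scheme.

    Returns the retained table (``n_rois_initial - n_removed`` rows) with
    columns ``roi``, ``network``; ROIs are spread across the 14 network names
    roughly proportionally, and the removed ROIs (incomplete coverage in the
    emulated scheme: one attention, five somatomotor) are dropped.
    """
    if n_networks > len(NETWORK_NAMES):
        raise ValueError("at most 14 networks supported")
    n_final = n_rois_initial - n_removed
    nets = [NETWORK_NAMES[i % n_networks] for i in range(n_final)]
    nets.sort(key=NETWORK_NAMES.index)
    return pd.DataFrame(
        {"roi": [f"roi{i:03d}" for i in range(n_final)], "network": nets}
    )


def write_study(study: SyntheticStudy, out_dir, sep: str = "\t") -> None:
    """Write panels (one delimited file per subject-condition), the design
    table (CSV) and the ground truth (JSON)."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (subj, cond), panel in study.panels.items():
        df = pd.DataFrame(panel.signals, index=panel.node_labels)
        df.to_csv(out / f"timeseries_{subj}_{cond}.tsv", sep=sep, header=False)
    study.design.to_frame().to_csv(out / "design.csv", index=False)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(study.ground_truth, fh, indent=1)
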