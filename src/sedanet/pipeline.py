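"""End-to-end study analysis: simulate or load, build graphs, detect
communities, quantify hub disruption and rich-club changes, run the
condition-level statistics, and emit a reproducible report.

The stage order mirrors the analysis protocol: correlation matrices per
subject-condition; percolation threshold across *all* matrices; a 2%-step
density grid from there to 50%; best-of-n Louvain per matrix per density with
grid-averaged Q and participation; consensus partitions per condition; nodal
strengths and the hub disruption index for every condition pair; rich-club
detection at the percolation density (group and per subject) with club
strength per condition; repeated-measures ANOVAs, Bonferroni post-hocs and
the drug/behaviour correlations.  A single master seed fans out
deterministically to every stochastic stage.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community as comm_mod
from . import hubs as hub_mod
from . import richclub as rc_mod
from . import stats as stats_mod
from . import synthdata
from .graphs import (
    ConnectivityMatrix,
    DensityGrid,
    TimeSeriesPanel,
    binarize,
    correlation_matrix,
    percolation_threshold,
    proportional_threshold,
    read_matrix,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StudyReport", "load_study", "simulate_study", "run"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return int(
        np.random.SeedSequence(
            [int(master_seed), zlib.crc32(stage.encode())]
        ).generate_state(1)[0]
        % (2**31 - 1)
    )


@dataclass
class RunConfig:
    """Run configuration; defaults follow the analysis protocol
    (gamma = 1, 10 Louvain restarts, 100 surrogates, 2%-step grid to 50%)."""

    mode: str = "simulate"  # simulate | load
    input_format: str = "timeseries"  # timeseries | matrix
    in_dir: str | None = None
    seed: int = 0
    # synthetic-study block
    n_subjects: int = 19
    conditions: tuple[str, ...] = ("B", "L", "M")
    n_nodes: int = 120
    n_modules: int = 4
    n_timepoints: int = 140
    r_within: float = 0.5
    r_between: float = 0.1
    hub_boost: float = 0.25
    kappa_light: float = -0.2
    kappa_moderate: float = -0.4
    club_attenuation: float = 0.2
    behaviour_target_r: float = -0.7
    subject_jitter_sd: float = 0.02
    # analysis block
    gamma: float = 1.0
    n_restarts: int = 10
    n_surrogates: int = 100
    swaps_per_edge: int = 10
    alpha: float = 0.05
    tails: str = "one"
    consensus_tau: float = 0.5
    grid_step: float = 0.02
    grid_max: float = 0.5
    percolation_step: float = 0.01
    rank: str = "signed"  # documented alternative: absolute
    kappa_x_axis: str = "reference"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if cfg.rank not in ("signed", "absolute"):
            raise ValueError("rank must be 'signed' or 'absolute'")
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conditions"] = list(self.conditions)
        return d


@dataclass
class StudyReport:
    """Everything the analysis computed, JSON-serialisable."""

    percolation_density: float
    density_grid: list[float]
    q_table: pd.DataFrame  # subjects x conditions (grid-averaged)
    p_table: pd.DataFrame
    q_at_percolation: pd.DataFrame
    p_at_percolation: pd.DataFrame
    consensus_partitions: dict
    consensus_flow: dict
    kappa: dict
    richclub: dict
    club_strength: pd.DataFrame  # subjects x conditions
    stats: dict
    provenance: dict
    per_density: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        def df_dict(df):
            return {
                "index": [str(i) for i in df.index],
                "columns": [str(c) for c in df.columns],
                "values": np.asarray(df).round(10).tolist(),
            }

        return {
            "percolation_density": self.percolation_density,
            "density_grid": self.density_grid,
            "q_table": df_dict(self.q_table),
            "p_table": df_dict(self.p_table),
            "q_at_percolation": df_dict(self.q_at_percolation),
            "p_at_percolation": df_dict(self.p_at_percolation),
            "consensus_partitions": self.consensus_partitions,
            "consensus_flow": self.consensus_flow,
            "kappa": self.kappa,
            "richclub": self.richclub,
            "club_strength": df_dict(self.club_strength),
            "stats": self.stats,
            "per_density": self.per_density,
            "provenance": self.provenance,
        }


def simulate_study(config: RunConfig) -> synthdata.SyntheticStudy:
    """Build the condition covariance models and sample a study."""
    sizes = [config.n_nodes // config.n_modules] * config.n_modules
    sizes[-1] += config.n_nodes - sum(sizes)
    base = synthdata.generate_covariance(
        config.n_nodes,
        tuple(sizes),
        config.r_within,
        config.r_between,
        hub_boost=config.hub_boost,
        seed=stage_seed(config.seed, "covariance"),
    )
    kappas = {"B": 0.0, "L": config.kappa_light, "M": config.kappa_moderate}
    models = []
    for i, cond in enumerate(config.conditions):
        kappa = kappas.get(cond, 0.0)
        m = base
        if kappa != 0.0:
            m = synthdata.apply_condition_effect(m, kappa)
        if i > 0 and config.club_attenuation > 0:
            m = synthdata.attenuate_club(m, config.club_attenuation)
        models.append(m)
    return synthdata.generate_study(
        config.n_subjects,
        list(config.conditions),
        models,
        config.n_timepoints,
        config.behaviour_target_r,
        seed=stage_seed(config.seed, "study"),
        subject_jitter_sd=config.subject_jitter_sd,
    )


def load_study(config: RunConfig):
    """Load panels (or matrices) and the design table from ``in_dir``.

    Returns ``(panels_or_matrices, design)``; with ``input_format='matrix'``
    the first element maps (subject, condition) to
    :class:`~sedanet.graphs.ConnectivityMatrix` and the correlation step is
    skipped downstream.
    """
    if config.in_dir is None:
        raise ValueError("load mode requires in_dir")
    in_dir = Path(config.in_dir)
    design_df = pd.read_csv(in_dir / "design.csv")
    required = {"subject", "condition", "plasma_ugml", "errors"}
    if not required.issubset(design_df.columns):
        raise ValueError(f"design.csv must have columns {sorted(required)}")
    subjects = list(dict.fromkeys(design_df["subject"].astype(str)))
    conditions = list(dict.fromkeys(design_df["condition"].astype(str)))
    cells = set(zip(design_df["subject"].astype(str), design_df["condition"].astype(str)))
    for s in subjects:
        for c in conditions:
            if (s, c) not in cells:
                raise ValueError(f"design.csv missing row for ({s}, {c})")
    plasma = design_df.pivot(index="subject", columns="condition", values="plasma_ugml")
    errors = design_df.pivot(index="subject", columns="condition", values="errors")
    design = synthdata.StudyDesign(
        subjects=subjects,
        conditions=conditions,
        plasma=plasma.loc[subjects, conditions],
        errors=errors.loc[subjects, conditions].astype(int),
    )
    data: dict[tuple[str, str], object] = {}
    for s in subjects:
        for c in conditions:
            if config.input_format == "matrix":
                path = in_dir / f"matrix_{s}_{c}.tsv"
                if not path.exists():
                    raise ValueError(f"missing matrix file {path}")
                data[(s, c)] = read_matrix(path)
            else:
                path = in_dir / f"timeseries_{s}_{c}.tsv"
                if not path.exists():
                    raise ValueError(f"missing time-series file {path}")
                df = pd.read_csv(path, sep="\t", header=None, index_col=0)
                data[(s, c)] = TimeSeriesPanel(
                    subject=s,
                    condition=c,
                    signals=df.to_numpy(dtype=float),
                    node_labels=[str(x) for x in df.index],
                )
    logger.info(
        "loaded study: %d subjects x %d conditions", len(subjects), len(conditions)
    )
    return data, design


def _threshold(c: ConnectivityMatrix, d: float, rank: str) -> ConnectivityMatrix:
    if rank == "absolute":
        absc = ConnectivityMatrix(np.abs(c.weights), node_labels=list(c.node_labels))
        thr = proportional_threshold(absc, d)
        kept = thr.weights != 0
        return ConnectivityMatrix(
            np.where(kept, c.weights, 0.0), node_labels=list(c.node_labels), density=d
        )
    return proportional_threshold(c, d)


def _flow_table(p_a: np.ndarray, p_b: np.ndarray) -> list[dict]:
    out = []
    for ca in np.unique(p_a):
        for cb in np.unique(p_b):
            n = int(np.sum((p_a == ca) & (p_b == cb)))
            if n:
                out.append({"from": int(ca), "to": int(cb), "n_nodes": n})
    return out


def run(config: RunConfig, study=None, out_dir=None) -> StudyReport:
    """Execute the full analysis and return (and optionally write) the report."""
    t0 = time.time()
    conditions = list(config.conditions)
    ground_truth = None
    if study is not None:
        panels_or_mats = study.panels
        design = study.design
        ground_truth = study.ground_truth
    elif config.mode == "simulate":
        study = simulate_study(config)
        panels_or_mats = study.panels
        design = study.design
        ground_truth = study.ground_truth
    else:
        panels_or_mats, design = load_study(config)
        conditions = design.conditions
    subjects = design.subjects
    logger.info("stage=input subjects=%d conditions=%s", len(subjects), conditions)

    # --- correlation matrices -------------------------------------------------
    matrices: dict[tuple[str, str], ConnectivityMatrix] = {}
    for key, obj in panels_or_mats.items():
        matrices[key] = (
            obj if isinstance(obj, ConnectivityMatrix) else correlation_matrix(obj)
        )
    n_nodes = next(iter(matrices.values())).n_nodes

    # --- percolation threshold and analysis grid ------------------------------
    perc_grid = DensityGrid(
        list(np.round(np.arange(config.percolation_step, 0.501, config.percolation_step), 6))
    )
    perc = percolation_threshold(list(matrices.values()), perc_grid)
    step = config.grid_step
    start = float(np.round(np.ceil(perc / step - 1e-9) * step, 6))
    grid = [float(np.round(d, 6)) for d in np.arange(start, config.grid_max + 1e-9, step)]
    logger.info("stage=percolation density=%.3f grid=%d levels", perc, len(grid))

    # --- modularity / participation over the grid -----------------------------
    louvain_seed = stage_seed(config.seed, "louvain")
    q_grid = {}
    p_grid = {}
    partitions_by_cond: dict[str, list[comm_mod.Partition]] = {c: [] for c in conditions}
    for (subj, cond), mat in matrices.items():
        for di, d in enumerate(grid):
            thr = _threshold(mat, d, config.rank)
            part = comm_mod.best_partition(
                thr,
                gamma=config.gamma,
                n_restarts=config.n_restarts,
                seed=louvain_seed
                + 1000 * di
                + 100000 * (subjects.index(subj) * len(conditions) + conditions.index(cond)),
            )
            q_grid[(subj, cond, d)] = part.q_value
            p_grid[(subj, cond, d)] = float(comm_mod.participation(thr, part).mean())
            partitions_by_cond[cond].append(part)
    q_df = pd.Series(q_grid).unstack(level=2)
    p_df = pd.Series(p_grid).unstack(level=2)
    q_table = q_df.mean(axis=1).unstack(level=1).loc[subjects, conditions]
    p_table = p_df.mean(axis=1).unstack(level=1).loc[subjects, conditions]
    q_at_perc = q_df[grid[0]].unstack(level=1).loc[subjects, conditions]
    p_at_perc = p_df[grid[0]].unstack(level=1).loc[subjects, conditions]
    logger.info("stage=modularity done (%d partitions)", len(q_grid))

    # --- consensus per condition ----------------------------------------------
    cons_seed = stage_seed(config.seed, "consensus")
    consensus_partitions = {}
    cons_assign = {}
    for cond in conditions:
        part, converged = comm_mod.consensus(
            partitions_by_cond[cond],
            tau=config.consensus_tau,
            seed=cons_seed,
            n_restarts=config.n_restarts,
        )
        cons_assign[cond] = part.assignment
        consensus_partitions[cond] = {
            "assignment": part.assignment.tolist(),
            "n_communities": part.n_communities,
            "converged": bool(converged),
        }
        if not converged:
            logger.warning("consensus for condition %s did not converge", cond)
    consensus_flow = {
        f"{a}->{b}": _flow_table(cons_assign[a], cons_assign[b])
        for a, b in zip(conditions, conditions[1:])
    }

    # --- hub disruption --------------------------------------------------------
    strengths = hub_mod.strength_table(matrices)
    pairs = [(conditions[i], conditions[j]) for i in range(len(conditions))
             for j in range(i + 1, len(conditions))]
    kappa_report = {}
    for ref, tgt in pairs:
        group = hub_mod.hub_disruption(
            strengths, ref, tgt, level="group", x_axis=config.kappa_x_axis
        )
        subj_level = hub_mod.hub_disruption(
            strengths, ref, tgt, level="subject", x_axis=config.kappa_x_axis
        )
        kappa_report[f"{ref}->{tgt}"] = {
            "group": {
                "kappa": group.kappa,
                "intercept": group.intercept,
                "r_squared": group.r_squared,
            },
            "subjects": {
                k.level: {"kappa": k.kappa, "r_squared": k.r_squared}
                for k in subj_level
            },
        }
    logger.info("stage=hub_disruption pairs=%s", [f"{a}->{b}" for a, b in pairs])

    # --- rich-club -------------------------------------------------------------
    rc_seed = stage_seed(config.seed, "richclub")
    baseline = conditions[0]
    group_avg = np.mean(
        [matrices[(s, baseline)].weights for s in subjects], axis=0
    )
    group_mat = ConnectivityMatrix(
        group_avg, node_labels=list(next(iter(matrices.values())).node_labels)
    )
    group_bin = binarize(_threshold(group_mat, perc, config.rank))
    group_curve = rc_mod.normalized_phi(
        group_bin,
        n_surrogates=config.n_surrogates,
        swaps_per_edge=config.swaps_per_edge,
        alpha=config.alpha,
        seed=rc_seed,
    )
    group_club = rc_mod.detect_club(group_bin, group_curve, source="group")
    member_counts = dict.fromkeys(group_mat.node_labels, 0)
    subject_clubs = {}
    for i, subj in enumerate(subjects):
        g = binarize(_threshold(matrices[(subj, baseline)], perc, config.rank))
        curve = rc_mod.normalized_phi(
            g,
            n_surrogates=config.n_surrogates,
            swaps_per_edge=config.swaps_per_edge,
            alpha=config.alpha,
            seed=rc_seed + 1 + i,
        )
        club = rc_mod.detect_club(g, curve, source=subj)
        if not club.detected or len(club.members) < 2:
            logger.warning(
                "no rich-club detected for subject %s; using group club", subj
            )
            club = group_club
        subject_clubs[subj] = club
        for m in club.members:
            member_counts[m] += 1
    club_strength_tab = pd.DataFrame(index=subjects, columns=conditions, dtype=float)
    for subj in subjects:
        for cond in conditions:
            club_strength_tab.loc[subj, cond] = rc_mod.club_strength(
                matrices[(subj, cond)], subject_clubs[subj]
            )
    richclub_report = {
        "group": {
            "k_star": group_club.k_star,
            "detected": group_club.detected,
            "members": group_club.members,
            "significant_k": group_curve.significant_k.tolist(),
            "curve": {
                "k": group_curve.k_levels.tolist(),
                "phi": np.nan_to_num(group_curve.phi, nan=-1.0).tolist(),
                "phi_norm": np.nan_to_num(group_curve.phi_norm, nan=-1.0).tolist(),
                "p": np.nan_to_num(group_curve.p_value, nan=-1.0).tolist(),
            },
        },
        "member_counts": member_counts,
        "subject_k_star": {
            s: subject_clubs[s].k_star for s in subjects
        },
    }
    logger.info(
        "stage=richclub group_k_star=%s club_size=%d",
        group_club.k_star,
        len(group_club.members),
    )

    # --- statistics ------------------------------------------------------------
    def anova_block(tab: pd.DataFrame) -> dict:
        res = stats_mod.rm_anova_gg(tab)
        post = stats_mod.paired_posthoc_bonferroni(tab, labels=conditions)
        return {
            "F": res.f,
            "df1": res.df1,
            "df2": res.df2,
            "epsilon": res.epsilon,
            "p": res.p,
            "degenerate": res.degenerate,
            "posthoc": [
                {
                    "pair": list(r.pair),
                    "t": r.t,
                    "p": r.p,
                    "p_adj": r.p_adj,
                    "degenerate": r.degenerate,
                }
                for r in post
            ],
        }

    stats_report = {
        "anova": {
            "Q": anova_block(q_table),
            "P": anova_block(p_table),
            "club_strength": anova_block(club_strength_tab),
        },
        "correlations": [],
    }
    if len(conditions) >= 3:
        c_l, c_m = conditions[-2], conditions[-1]
        d_plasma = (design.plasma[c_m] - design.plasma[c_l]).to_numpy(dtype=float)
        d_errors = (design.errors[c_m] - design.errors[c_l]).to_numpy(dtype=float)
        corr_specs = [
            ("delta_plasma", "delta_Q_at_percolation",
             d_plasma, (q_at_perc[c_m] - q_at_perc[c_l]).to_numpy()),
            ("delta_plasma", "delta_P_at_percolation",
             d_plasma, (p_at_perc[c_m] - p_at_perc[c_l]).to_numpy()),
            ("delta_club_strength", "delta_errors",
             (club_strength_tab[c_m] - club_strength_tab[c_l]).to_numpy(), d_errors),
        ]
        for xname, yname, xv, yv in corr_specs:
            try:
                c = stats_mod.pearson(xv, yv, tails=config.tails)
            except ValueError as exc:
                logger.warning("correlation %s vs %s skipped: %s", xname, yname, exc)
                continue
            stats_report["correlations"].append(
                {"x": xname, "y": yname, "r": c.r, "n": c.n, "t": c.t,
                 "p": c.p, "tails": c.tails}
            )

    provenance = {
        "config": config.to_dict(),
        "master_seed": config.seed,
        "elapsed_s": round(time.time() - t0, 3),
    }
    if ground_truth is not None:
        provenance["ground_truth"] = ground_truth
    report = StudyReport(
        percolation_density=float(perc),
        density_grid=grid,
        q_table=q_table,
        p_table=p_table,
        q_at_percolation=q_at_perc,
        p_at_percolation=p_at_perc,
        consensus_partitions=consensus_partitions,
        consensus_flow=consensus_flow,
        kappa=kappa_report,
        richclub=richclub_report,
        club_strength=club_strength_tab,
        stats=stats_report,
        provenance=provenance,
        per_density={
            "Q": {f"{s}|{c}|{d}": q_grid[(s, c, d)] for (s, c, d) in q_grid},
            "P": {f"{s}|{c}|{d}": p_grid[(s, c, d)] for (s, c, d) in p_grid},
        },
    )
    if out_dir is not None:
        write_report(report, out_dir)
    logger.info("stage=done elapsed=%.1fs", time.time() - t0)
    return report


def write_report(report: StudyReport, out_dir) -> None:
    """Write the JSON report plus the main CSV tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # drop elapsed time from the JSON so identical seeds give identical bytes
    payload = report.to_json_dict()
    payload["provenance"] = {
        k: v for k, v in payload["provenance"].items() if k != "elapsed_s"
    }
    with open(out / "report.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    report.q_table.to_csv(out / "q_table.csv")
    report.p_table.to_csv(out / "p_table.csv")
    report.club_strength.to_csv(out / "club_strength.csv")
    rows = []
    for pair, block in report.kappa.items():
        rows.append(
            {"pair": pair, "level": "group", "subject": "",
             "kappa": block["group"]["kappa"],
             "r_squared": block["group"]["r_squared"]}
        )
        for subj, vals in block["subjects"].items():
            rows.append(
                {"pair": pair, "level": "subject", "subject": subj,
                 "kappa": vals["kappa"], "r_squared": vals["r_squared"]}
            )
    pd.DataFrame(rows).to_csv(out / "kappa.csv", index=False)


def render_markdown(report_json: dict) -> str:
    """Render a report JSON dictionary as human-readable Markdown tables."""
    lines = ["# Study report", ""]
    lines.append(f"Percolation density: {report_json['percolation_density']:.2f}")
    lines.append(
        f"Density grid: {report_json['density_grid'][0]:.2f}-"
        f"{report_json['density_grid'][-1]:.2f} "
        f"({len(report_json['density_grid'])} levels)"
    )
    lines.append("")
    lines.append("## Hub disruption index")
    lines.append("")
    lines.append("| pair | group kappa | r^2 |")
    lines.append("|---|---|---|")
    for pair, block in report_json["kappa"].items():
        g = block["group"]
        lines.append(f"| {pair} | {g['kappa']:.3f} | {g['r_squared']:.3f} |")
    lines.append("")
    lines.append("## Condition-level statistics")
    lines.append("")
    lines.append("| metric | F | df1 | df2 | epsilon | p |")
    lines.append("|---|---|---|---|---|---|")
    for metric, a in report_json["stats"]["anova"].items():
        lines.append(
            f"| {metric} | {a['F']:.3g} | {a['df1']:.2f} | {a['df2']:.2f} "
            f"| {a['epsilon']:.3f} | {a['p']:.2g} |"
        )
    lines.append("")
    lines.append("| correlation | r | n | p |")
    lines.append("|---|---|---|---|")
    for c in report_json["stats"]["correlations"]:
        lines.append(f"| {c['x']} vs {c['y']} | {c['r']:.3f} | {c['n']} | {c['p']:.2g} |")
    lines.append("")
    rc = report_json["richclub"]["group"]
    lines.append(
        f"Group rich-club: detected={rc['detected']}, k*={rc['k_star']}, "
        f"{len(rc['members'])} members"
    )
    lines.append("")
    return "\n".join(lines)
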