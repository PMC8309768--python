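"""End-to-end study runs: data (real or synthetic) -> endpoints ->
statistics -> report.

A run is driven by a single :class:`RunConfig` (loadable from YAML or
JSON).  ``run_behavior`` produces the seven behavioral endpoints per
fish, collapses them to tank means, and Welch-tests each endpoint
between the two sites; ``run_morphometrics`` runs the landmark branch
(standard length, region areas, GPA + PCA, per-group consensus, MANOVA,
two-way ANOVA + Tukey, paired Wilcoxon, Kruskal-Wallis);
``run_full`` does both and emits one combined JSON report with
provenance (config hash, seed, package version).

Tanks failing the tracking-accuracy gate are excluded with a logged
reason.  All tables are written as tidy delimited text; plots (consensus
overlays, endpoint boxplots) are side artifacts only — no number is ever
read back from an image.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
import yaml

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__
from .activity_metrics import ActivityConfig, activity_endpoints
from .core_io import (
    CalibrationInfo,
    ConfigError,
    DataError,
    EndpointTable,
    GroupRecording,
    LandmarkSet,
    qc_tracking_accuracy,
    read_tps,
    read_trajectory_table,
    write_endpoint_table,
)
from .group_stats import (
    TestResult,
    kruskal_wallis,
    paired_wilcoxon,
    ratio_anova_tukey,
    shape_manova,
    summarize,
    welch_t,
)
from .morphometrics import (
    consensus_by_group,
    gpa_align,
    region_areas,
    shape_pca,
    standard_length,
)
from .social_metrics import ProximityConfig, collapse_to_tank_means, social_endpoints
from .synthetic_data import (
    paper_like_landmark_config,
    paper_like_trajectory_config,
    simulate_landmarks,
    simulate_site,
    trajectory_config_from_dict,
    landmark_config_from_dict,
    config_to_dict,
)

logger = logging.getLogger(__name__)

BEHAVIOR_ENDPOINTS = [
    "interindividual_distance_mm",
    "time_in_proximity_s",
    "nearest_neighbor_distance_mm",
    "distance_traveled_mm",
    "swim_speed_mm_s",
    "time_in_motion_s",
    "exploration_pct",
]


@dataclass
class RunConfig:
    """Resolved run configuration (validated before any computation)."""

    mode: str = "synthetic"               # "synthetic" | "real"
    seed: int = 0
    out_dir: str = "zfsentinel_out"
    log_level: str = "INFO"
    qc_threshold: float = 0.80
    manova_variance_retained: float = 0.99
    proximity: ProximityConfig = field(default_factory=ProximityConfig)
    activity: ActivityConfig = field(default_factory=ActivityConfig)
    # synthetic mode: optional config dicts (presets used when None)
    trajectory_sim: dict | None = None
    landmark_sim: dict | None = None
    # real mode: input paths
    trajectory_files: list[dict] = field(default_factory=list)  # {path, dialect, site, tank_id}
    tps_file: str | None = None
    tps_metadata: str | None = None       # sidecar table: fish_id/site/sex
    calibration: CalibrationInfo | None = None
    make_plots: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ConfigError(f"mode must be 'synthetic' or 'real', got {self.mode!r}")
        if not 0.0 <= self.qc_threshold <= 1.0:
            raise ConfigError("qc_threshold must be in [0, 1]")
        if not 0.0 < self.manova_variance_retained <= 1.0:
            raise ConfigError("manova_variance_retained must be in (0, 1]")
        if self.mode == "real" and not self.trajectory_files and not self.tps_file:
            raise ConfigError("real mode needs trajectory_files and/or tps_file")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "proximity" in raw and isinstance(raw["proximity"], dict):
            raw["proximity"] = ProximityConfig(**raw["proximity"])
        if "activity" in raw and isinstance(raw["activity"], dict):
            raw["activity"] = ActivityConfig(**raw["activity"])
        if "calibration" in raw and isinstance(raw["calibration"], dict):
            raw["calibration"] = CalibrationInfo(**raw["calibration"])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = {
            "mode": self.mode,
            "seed": self.seed,
            "out_dir": str(self.out_dir),
            "log_level": self.log_level,
            "qc_threshold": self.qc_threshold,
            "manova_variance_retained": self.manova_variance_retained,
            "proximity": {
                "threshold_px": self.proximity.threshold_px,
                "use_mm": self.proximity.use_mm,
                "threshold_mm": self.proximity.threshold_mm,
            },
            "activity": {
                "motion_speed_threshold_mm_s": self.activity.motion_speed_threshold_mm_s,
                "exploration_cell_mm": self.activity.exploration_cell_mm,
            },
            "trajectory_sim": self.trajectory_sim,
            "landmark_sim": self.landmark_sim,
            "trajectory_files": self.trajectory_files,
            "tps_file": self.tps_file,
            "tps_metadata": self.tps_metadata,
            "calibration": None
            if self.calibration is None
            else {
                "px_per_mm": self.calibration.px_per_mm,
                "frame_rate": self.calibration.frame_rate,
                "arena_width_mm": self.calibration.arena_width_mm,
                "arena_height_mm": self.calibration.arena_height_mm,
            },
            "make_plots": self.make_plots,
        }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# data acquisition


def _get_recordings(cfg: RunConfig) -> list[GroupRecording]:
    if cfg.mode == "synthetic":
        sim = (
            trajectory_config_from_dict(cfg.trajectory_sim)
            if cfg.trajectory_sim
            else paper_like_trajectory_config(cfg.seed)
        )
        groups: list[GroupRecording] = []
        for site in sorted(sim.sites):
            groups.extend(simulate_site(sim, site))
        return groups
    if cfg.calibration is None:
        raise ConfigError("real mode requires a calibration block")
    groups = []
    for entry in cfg.trajectory_files:
        groups.append(
            read_trajectory_table(
                entry["path"],
                entry.get("dialect", "generic-csv"),
                cfg.calibration,
                site=entry.get("site", ""),
                tank_id=entry.get("tank_id"),
            )
        )
    return groups


def _get_landmarks(cfg: RunConfig) -> list[LandmarkSet]:
    if cfg.mode == "synthetic":
        sim = (
            landmark_config_from_dict(cfg.landmark_sim)
            if cfg.landmark_sim
            else paper_like_landmark_config(cfg.seed)
        )
        lms: list[LandmarkSet] = []
        for site, sex in sim.groups:
            lms.extend(simulate_landmarks(sim, site, sex))
        return lms
    if not cfg.tps_file:
        raise ConfigError("real mode morphometrics requires tps_file")
    meta = None
    if cfg.tps_metadata:
        meta = pd.read_csv(cfg.tps_metadata, sep=None, engine="python")
        required = {"fish_id", "site", "sex"}
        if not required.issubset(meta.columns):
            raise ConfigError(f"tps_metadata must have columns {sorted(required)}")
        meta = meta.set_index("fish_id")
    lms = read_tps(cfg.tps_file, metadata=meta)
    missing = [lm.fish_id for lm in lms if not lm.site]
    if missing:
        raise ConfigError(f"landmark specimens without site metadata: {missing[:5]} ...")
    return lms


# ---------------------------------------------------------------------------
# behavioral branch


def behavior_tables(
    groups: list[GroupRecording],
    proximity: ProximityConfig | None = None,
    activity: ActivityConfig | None = None,
    qc_threshold: float = 0.80,
) -> tuple[EndpointTable, EndpointTable, list[dict]]:
    """Fish- and tank-level endpoint tables for QC-passing tanks, plus
    the per-tank QC reports."""
    qc_reports = []
    tables = []
    for g in groups:
        qc = qc_tracking_accuracy(g, qc_threshold)
        qc_reports.append(qc)
        if not qc["tank_pass"]:
            logger.warning(
                "tank %s excluded by tracking-accuracy gate (failing fish: %s)",
                g.tank_id,
                qc["failing_fish"],
            )
            continue
        s = social_endpoints(g, proximity)
        a = activity_endpoints(g, activity)
        merged = s.data.merge(a.data, on=["site", "tank_id", "fish_id"])
        units = {**s.units, **a.units}
        tables.append((merged, units))
    if not tables:
        raise DataError("no tanks passed the tracking-accuracy gate")
    data = pd.concat([t for t, _ in tables], ignore_index=True)
    units = tables[0][1]
    fish_table = EndpointTable(data=data, units=units, level="fish")
    tank_table = collapse_to_tank_means(fish_table)
    return fish_table, tank_table, qc_reports


def behavior_site_tests(tank_table: EndpointTable) -> dict[str, TestResult]:
    """Welch t per behavioral endpoint between the two sites, on tank
    means."""
    sites = sorted(tank_table.data["site"].unique())
    if len(sites) != 2:
        raise DataError(f"behavioral comparison needs exactly 2 sites, got {sites}")
    a = tank_table.data[tank_table.data.site == sites[0]]
    b = tank_table.data[tank_table.data.site == sites[1]]
    out = {}
    for col in BEHAVIOR_ENDPOINTS:
        if col not in tank_table.data.columns:
            continue
        out[col] = welch_t(a[col].values, b[col].values, labels=(sites[0], sites[1]), name=col)
    return out


def run_behavior(cfg: RunConfig) -> dict:
    """Run the behavioral branch; writes tables and a JSON report into
    ``cfg.out_dir`` and returns the report dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    groups = _get_recordings(cfg)
    fish_table, tank_table, qc_reports = behavior_tables(
        groups, cfg.proximity, cfg.activity, cfg.qc_threshold
    )
    tests = behavior_site_tests(tank_table)
    write_endpoint_table(fish_table, out / "behavior_fish.tsv")
    write_endpoint_table(tank_table, out / "behavior_tank.tsv")
    with open(out / "qc_report.json", "w") as fh:
        json.dump(qc_reports, fh, indent=2, sort_keys=True)
    sites = sorted(tank_table.data["site"].unique())
    summaries = {
        col: {
            site: summarize(
                tank_table.data.loc[tank_table.data.site == site, col].values
            ).__dict__
            for site in sites
        }
        for col in tests
    }
    report = {
        "branch": "behavior",
        "n_tanks": {s: int((tank_table.data.site == s).sum()) for s in sites},
        "endpoints_tested": list(tests),
        "tests": {k: r.to_dict() for k, r in tests.items()},
        "tank_summaries": summaries,
        "settings": {
            "proximity_threshold_px": cfg.proximity.threshold_px,
            "proximity_use_mm": cfg.proximity.use_mm,
            "motion_speed_threshold_mm_s": cfg.activity.motion_speed_threshold_mm_s,
            "exploration_cell_mm": cfg.activity.exploration_cell_mm,
            "qc_threshold": cfg.qc_threshold,
        },
    }
    with open(out / "behavior_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    if cfg.make_plots:
        _plot_endpoints(tank_table, out / "behavior_boxplots.png")
    return report


def _plot_endpoints(tank_table: EndpointTable, path: Path) -> None:
    cols = [c for c in BEHAVIOR_ENDPOINTS if c in tank_table.data.columns]
    fig, axes = plt.subplots(2, 4, figsize=(16, 7))
    for ax, col in zip(axes.ravel(), cols):
        tank_table.data.boxplot(column=col, by="site", ax=ax)
        ax.set_title(col, fontsize=8)
        ax.set_xlabel("")
    for ax in axes.ravel()[len(cols):]:
        ax.axis("off")
    fig.suptitle("tank-mean endpoints by site")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


# ---------------------------------------------------------------------------
# morphometric branch


def run_morphometrics(cfg: RunConfig) -> dict:
    """Run the landmark branch; writes tables, plots, and a JSON report
    into ``cfg.out_dir`` and returns the report dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lms = _get_landmarks(cfg)
    if len(lms) < 3:
        raise DataError(f"morphometric branch needs at least 3 specimens, got {len(lms)}")

    rows = []
    for lm in lms:
        ra = region_areas(lm)
        rows.append(
            {
                "fish_id": lm.fish_id,
                "site": lm.site,
                "sex": lm.sex,
                "standard_length_mm": standard_length(lm),
                "anterior_mm2": ra.anterior_mm2,
                "posterior_mm2": ra.posterior_mm2,
                "ratio": ra.ratio,
            }
        )
    morpho = pd.DataFrame(rows)

    analysis = shape_pca(gpa_align(lms))
    cum = np.cumsum(analysis.variance_explained)
    k = int(np.searchsorted(cum, cfg.manova_variance_retained) + 1)
    k = min(k, analysis.pc_scores.shape[1])

    manova = shape_manova(analysis.pc_scores[:, :k], morpho.site.values, morpho.sex.values)
    anova, tukey = ratio_anova_tukey(morpho.ratio.values, morpho.site.values, morpho.sex.values)
    wilcoxon = paired_wilcoxon(morpho.posterior_mm2.values, morpho.anterior_mm2.values)
    kw = kruskal_wallis(
        morpho.standard_length_mm.values,
        (morpho.site + ":" + morpho.sex).values,
        name="kruskal_wallis_standard_length",
    )

    morpho.to_csv(out / "morphometrics_fish.tsv", sep="\t", index=False)
    tukey.to_csv(out / "tukey_ratio.tsv", sep="\t", index=False)
    aligned_df = pd.DataFrame(
        analysis.aligned.reshape(analysis.n_specimens, -1),
        columns=[f"lm{i}_{ax}" for i in range(1, 8) for ax in ("x", "y")],
    )
    aligned_df.insert(0, "fish_id", analysis.fish_ids)
    aligned_df.to_csv(out / "aligned_coordinates.tsv", sep="\t", index=False)
    scores_df = pd.DataFrame(
        analysis.pc_scores, columns=[f"PC{i + 1}" for i in range(analysis.pc_scores.shape[1])]
    )
    scores_df.insert(0, "fish_id", analysis.fish_ids)
    scores_df.to_csv(out / "pc_scores.tsv", sep="\t", index=False)

    groups_consensus = consensus_by_group(analysis)
    with open(out / "group_consensus.tsv", "w") as fh:
        fh.write("site\tsex\tlandmark\tx\ty\n")
        for (site, sex), shape in groups_consensus.items():
            for i, (x, y) in enumerate(shape, start=1):
                fh.write(f"{site}\t{sex}\t{i}\t{x!r}\t{y!r}\n")

    report = {
        "branch": "morphometrics",
        "n_specimens": len(lms),
        "n_pc_retained": k,
        "variance_explained": [float(v) for v in analysis.variance_explained],
        "pc12_variance_pct": float(100 * analysis.variance_explained[:2].sum()),
        "tests": {
            **{f"manova_{t}": r.to_dict() for t, r in manova.items()},
            **{f"anova_{t}": r.to_dict() for t, r in anova.items()},
            "wilcoxon_posterior_vs_anterior": wilcoxon.to_dict(),
            "kruskal_wallis_standard_length": kw.to_dict(),
        },
        "group_means": {
            f"{site}:{sex}": {
                "ratio": float(sub.ratio.mean()),
                "standard_length_mm": float(sub.standard_length_mm.mean()),
                "n": int(len(sub)),
            }
            for (site, sex), sub in morpho.groupby(["site", "sex"])
        },
        "tukey_significant": [
            f"{r.group1} vs {r.group2}" for r in tukey.itertuples() if r.reject
        ],
    }
    with open(out / "morphometrics_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)

    if cfg.make_plots:
        _plot_consensus(groups_consensus, out / "consensus_shapes.png")
        _plot_morpho_boxes(morpho, out / "morpho_boxplots.png")
    return report


def _plot_consensus(groups: dict, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    for (site, sex), shape in groups.items():
        closed = np.vstack([shape, shape[:1]])
        ax.plot(closed[:, 0], closed[:, 1], marker="o", label=f"{site} {sex}")
    ax.set_aspect("equal")
    ax.legend(fontsize=8)
    ax.set_title("per-group consensus shapes (aligned coordinates)")
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _plot_morpho_boxes(morpho: pd.DataFrame, path: Path) -> None:
    fig, axes = plt.subplots(1, 2, figsize=(11, 4))
    morpho["group"] = morpho.site + "\n" + morpho.sex
    morpho.boxplot(column="ratio", by="group", ax=axes[0])
    axes[0].set_title("posterior/anterior area ratio")
    morpho.boxplot(column="standard_length_mm", by="group", ax=axes[1])
    axes[1].set_title("standard length (mm)")
    for ax in axes:
        ax.set_xlabel("")
    fig.suptitle("")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


# ---------------------------------------------------------------------------
# combined run


def run_full(cfg: RunConfig) -> dict:
    """Both branches plus one combined report with provenance."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "resolved_config.json", "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=2, sort_keys=True)
    behavior = run_behavior(cfg)
    morpho = run_morphometrics(cfg)
    report = {
        "provenance": {
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "version": __version__,
            "mode": cfg.mode,
        },
        "defaults_used": {
            "qc_threshold": cfg.qc_threshold,
            "proximity_threshold_px": cfg.proximity.threshold_px,
            "motion_speed_threshold_mm_s": cfg.activity.motion_speed_threshold_mm_s,
            "exploration_cell_mm": cfg.activity.exploration_cell_mm,
            "manova_variance_retained": cfg.manova_variance_retained,
            "anova_ss_type": "II",
        },
        "behavior": behavior,
        "morphometrics": morpho,
    }
    with open(out / "study_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
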