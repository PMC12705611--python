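"""Two-round closed-loop orchestration.

Wires the stages into the study's sequential design: simulate round 1
(7 doses x 6 replicates), fit a GP dose-response model to root fresh
weight, propose 5 new doses by variance acquisition, simulate round 2
(proposals plus the 0 and 500 uM anchors), evaluate round-1 / round-2 /
combined model variants per target with the CV protocol, compare them, and
run the trajectory pipeline (daily series, per-day screens, clustering) on
the combined observations.  All stage seeds derive deterministically from
one master seed, and every artifact records the seeds and a config digest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation as ev
from .design import AcquisitionRequest, propose_doses
from .gp import GPConfig, fit_gp
from .synthetic import DoseDesign, SimParams, SyntheticStudy, default_params, simulate_experiment
from . import trajectory as tj

__all__ = ["RunConfig", "LoopArtifacts", "run_loop", "harvest_table"]

logger = logging.getLogger("phenoloop")

DEFAULT_TARGETS = ("fw_root", "fw_shoot", "root_px", "shoot_px")


@dataclass
class RunConfig:
    """Everything one closed-loop run needs; YAML-serializable."""

    params: SimParams = field(default_factory=default_params)
    round1: DoseDesign = field(default_factory=DoseDesign.round1)
    acquisition: AcquisitionRequest = field(default_factory=AcquisitionRequest)
    gp: GPConfig = field(default_factory=GPConfig)
    cv: ev.CVScheme = field(default_factory=ev.CVScheme)
    targets: tuple[str, ...] = DEFAULT_TARGETS
    round2_replicates: int = 6
    anchors: tuple[float, ...] = (0.0, 500.0)
    dropout_rate: float = 0.0
    day_window: tuple[int, int] = (11, 25)
    n_boot_daily: int = 2000
    master_seed: int = 7

    def digest(self) -> str:
        blob = json.dumps(_to_jsonable(dataclasses.asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _stage_seeds(master_seed: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


def harvest_table(study: SyntheticStudy) -> pd.DataFrame:
    """Per-plant endpoint table: dose, fresh weights, final-day pixel sizes."""
    plants = study.plants.loc[~study.plants.excluded].copy()
    obs = study.observations
    final_day = obs.day.max()
    rows = []
    for _, p in plants.iterrows():
        sub = obs[(obs.plant_id == p.plant_id) & (obs.day == final_day)]
        root = float(sub.loc[sub.modality == "root_scan", "pixel_count"].iloc[0])
        shoots = sub.loc[sub.modality != "root_scan", "pixel_count"].to_numpy(dtype=float)
        rows.append(dict(plant_id=p.plant_id, round_id=p.round_id, dose_uM=p.dose_uM,
                         fw_root=p.fw_root_g, fw_shoot=p.fw_shoot_g, root_px=root,
                         shoot_px=float(np.sqrt(np.sum(shoots ** 2)))))
    return pd.DataFrame(rows)


@dataclass
class LoopArtifacts:
    """Everything a closed-loop run produced."""

    config_digest: str
    seeds: dict
    round1: SyntheticStudy
    round2: SyntheticStudy
    harvest: pd.DataFrame            # combined endpoint table (scaled px columns added)
    proposals: list[float]
    reports: dict                    # (target, variant) -> EvaluationReport
    comparisons: dict                # target -> ComparisonResult (3 variants)
    improvements: pd.DataFrame       # target, round1_nrmse, combined_nrmse, pct_improvement
    batch_effect: dict               # control-arm t-tests between rounds
    daily_panel: pd.DataFrame
    daily_correlations: dict         # feature -> DataFrame
    daily_tests: dict                # feature -> DataFrame
    cluster_report: tj.ClusterReport
    cluster_stats: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = dict(config_digest=self.config_digest, seeds=self.seeds)
        (outdir / "run.json").write_text(json.dumps(header, indent=1))
        self.round1.to_csv(outdir / "round1")
        self.round2.to_csv(outdir / "round2")
        self.harvest.to_csv(outdir / "harvest.csv", index=False)
        (outdir / "proposals.json").write_text(json.dumps(self.proposals))
        report_rows = [r.to_json_dict() for r in self.reports.values()]
        (outdir / "evaluation.json").write_text(json.dumps(report_rows, indent=1))
        self.improvements.to_csv(outdir / "improvements.csv", index=False)
        if not self.daily_panel.empty:
            self.daily_panel.to_csv(outdir / "daily_panel.csv", index=False)
        for feature, df in self.daily_correlations.items():
            df.to_csv(outdir / f"daily_correlation_{feature}.csv", index=False)
        for feature, df in self.daily_tests.items():
            df.to_csv(outdir / f"daily_tests_{feature}.csv", index=False)
        if self.cluster_report is not None:
            self.cluster_report.embedding.to_csv(outdir / "embedding.csv", index=False)
            self.cluster_report.cluster_summary.to_csv(outdir / "clusters.csv", index=False)


def run_loop(config: RunConfig | None = None, outdir: str | Path | None = None,
             run_trajectories: bool = True) -> LoopArtifacts:
    """Execute the full two-round closed loop; see module docstring."""
    config = config or RunConfig()
    seeds = _stage_seeds(config.master_seed)
    seed_names = ["round1", "ask", "round2", "cv", "gp", "cluster", "boot", "spare"]
    sd = dict(zip(seed_names, seeds))
    digest = config.digest()
    t_start = time.time()

    def _log(stage: str) -> None:
        logger.info("stage=%s seed_digest=%s elapsed=%.1fs", stage, digest,
                    time.time() - t_start)

    stage = "simulate-round1"
    try:
        _log(stage)
        round1 = simulate_experiment(config.round1, config.params, seed=sd["round1"],
                                     dropout_rate=config.dropout_rate)
        h1 = harvest_table(round1)

        stage = "fit-and-ask"
        _log(stage)
        gp_ask = dataclasses.replace(config.gp, seed=sd["gp"])
        root_model = fit_gp(h1.dose_uM.to_numpy(), h1.fw_root.to_numpy(), gp_ask)
        proposals = propose_doses(root_model, config.acquisition)

        stage = "simulate-round2"
        _log(stage)
        round2_doses = sorted(set(config.anchors) | set(proposals))
        design2 = DoseDesign(round_id=2, arms=tuple(
            (d, config.round2_replicates) for d in round2_doses))
        round2 = simulate_experiment(design2, config.params, seed=sd["round2"],
                                     dropout_rate=config.dropout_rate)
        h2 = harvest_table(round2)
        combined = pd.concat([h1, h2], ignore_index=True)
        # scaled pixel targets: MinMax over the course of both experiments
        for col in ("root_px", "shoot_px"):
            combined[f"scaled_{col}"] = ev.minmax_scale(combined[col].to_numpy())

        stage = "evaluate"
        _log(stage)
        datasets = {"round1": combined[combined.round_id == 1],
                    "round2": combined[combined.round_id == 2],
                    "combined": combined}
        reports: dict = {}
        comparisons: dict = {}
        imp_rows = []
        for target in config.targets:
            col = f"scaled_{target}" if target in ("root_px", "shoot_px") else target
            per_variant = {}
            for variant, df in datasets.items():
                scheme = dataclasses.replace(config.cv, seed=sd["cv"])
                gp_cfg = dataclasses.replace(config.gp, seed=sd["gp"])
                rep = ev.evaluate_model(df.dose_uM.to_numpy(), df[col].to_numpy(),
                                        scheme, gp_cfg, target=target, variant=variant)
                reports[(target, variant)] = rep
                per_variant[variant] = rep
            comparisons[target] = ev.compare_models(per_variant)
            r1, comb = per_variant["round1"].mean_nrmse, per_variant["combined"].mean_nrmse
            imp_rows.append(dict(target=target, round1_nrmse=r1, combined_nrmse=comb,
                                 pct_improvement=(r1 - comb) / r1 * 100.0))
        improvements = pd.DataFrame(imp_rows)

        stage = "batch-effect"
        _log(stage)
        ctrl1 = h1[h1.dose_uM == 0]
        ctrl2 = h2[h2.dose_uM == 0]
        batch = {}
        if len(ctrl1) >= 2 and len(ctrl2) >= 2:
            from scipy import stats as _st

            for col in ("fw_root", "fw_shoot"):
                t, p = _st.ttest_ind(ctrl1[col], ctrl2[col])
                batch[col] = dict(t=float(t), p=float(p))

        daily_panel = pd.DataFrame()
        daily_corr: dict = {}
        daily_tests: dict = {}
        cluster_report = None
        cluster_stats: dict = {}
        if run_trajectories:
            stage = "trajectories"
            _log(stage)
            obs = pd.concat([round1.observations, round2.observations],
                            ignore_index=True)
            keep = set(combined.plant_id)
            obs = obs[obs.plant_id.isin(keep)]
            daily_panel = tj.build_daily_panel(obs)
            doses = combined.set_index("plant_id").dose_uM
            for feature in ("root_px", "shoot_px", "health"):
                mat = daily_panel[daily_panel.feature == feature].pivot(
                    index="plant_id", columns="day", values="value")
                post = mat.loc[:, [c for c in mat.columns
                                   if config.day_window[0] <= c <= config.day_window[1]]]
                daily_corr[feature] = tj.daily_correlation(
                    doses, mat, n_boot=config.n_boot_daily, seed=sd["boot"])
                daily_tests[feature] = tj.daily_dose_tests(post, doses)
            matrix = tj.build_trajectory_matrix(daily_panel, config.day_window)
            final_day = daily_panel.day.max()
            final_feats = daily_panel[daily_panel.day == final_day].pivot(
                index="plant_id", columns="feature", values="value")
            cluster_report = tj.embed_cluster(matrix, doses=doses,
                                              final_day_features=final_feats,
                                              seed=sd["cluster"])
            if cluster_report.n_clusters >= 2:
                cluster_stats = tj.cluster_statistics(cluster_report, doses, final_feats)
    except Exception as exc:
        raise RuntimeError(f"closed-loop stage {stage!r} failed: {exc}") from exc

    artifacts = LoopArtifacts(
        config_digest=digest, seeds=sd, round1=round1, round2=round2,
        harvest=combined, proposals=list(map(float, proposals)), reports=reports,
        comparisons=comparisons, improvements=improvements, batch_effect=batch,
        daily_panel=daily_panel, daily_correlations=daily_corr,
        daily_tests=daily_tests, cluster_report=cluster_report,
        cluster_stats=cluster_stats,
    )
    if outdir is not None:
        artifacts.write(outdir)
    return artifacts
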