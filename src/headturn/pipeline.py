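"""Simulate → analyze → report orchestration.

Reproduces the structure of the original analysis on a synthetic cohort:
benefit maps for the four target locations, per-word orientation summaries and
optimal-region occupancy, final-word circular statistics with Kuiper tests,
RAU-transformed per-word intelligibility with model predictions from the
fitted psychometric function, repeated-measures ANOVAs, and the model-vs-data
signed error with the motion-gated deficit estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortConfig, TrialRecord, _word_motion_gate, gen_cohort
from .intelligibility import BenefitMap, benefit_map, optimal_region, trajectory_benefit
from .psychometrics import PsychFit, fit_glre, predict_score, rau, rau_error_to_db
from .room import paper_scene
from .stats import rm_anova
from .trajectory import circ_median, circ_variance, kuiper_two_sample, per_word_orientation

__all__ = [
    "RunConfig",
    "compute_paper_maps",
    "run_simulate",
    "run_analyze",
    "static_predictions_from_maps",
]

TARGET_GROUPS = {0.0: "front", 90.0: "lateral", -90.0: "lateral", 180.0: "rear"}


@dataclass
class RunConfig:
    out_dir: str = "headturn_out"
    seed: int = 0
    grid_step_deg: float = 1.0
    time_limit_s: float = 0.3
    n_permutations: int = 2000
    room_method: str = "calibrated"
    cohort: CohortConfig = field(default_factory=CohortConfig)


def compute_paper_maps(
    targets=(0.0, -90.0, 90.0, 180.0),
    grid_step_deg: float = 1.0,
    time_limit_s: float = 0.3,
    method: str = "calibrated",
) -> dict[float, BenefitMap]:
    """Benefit maps of the four experiment scenes (interferer fixed at 0 deg)."""
    maps = {}
    for tgt in targets:
        scene = paper_scene(tgt, 0.0, method=method)
        maps[tgt] = benefit_map(
            scene, target_index=1, interferer_index=0,
            grid_step_deg=grid_step_deg, time_limit_s=time_limit_s,
            scene_id=f"target_{tgt:+.0f}",
        )
    return maps


def static_predictions_from_maps(maps: dict[float, BenefitMap]) -> dict[float, float]:
    """Model-predicted unmasking per target location at yaw 0 (Static)."""
    return {tgt: float(m.unmasking_at(0.0)) for tgt, m in maps.items()}


def _map_frame(bmap: BenefitMap, margin_db: float = 1.0) -> pd.DataFrame:
    region = optimal_region(bmap, margin_db)
    in_region = np.isin(bmap.yaw_deg, region.yaw_deg)
    return pd.DataFrame({
        "yaw_deg": bmap.yaw_deg,
        "benefit_db": bmap.benefit_db,
        "unmasking_db": bmap.unmasking_db,
        "in_optimal_region": in_region.astype(int),
    })


def run_simulate(config: RunConfig, maps: dict[float, BenefitMap] | None = None) -> dict:
    """Generate benefit maps and a synthetic cohort; write all artifacts.

    Returns a dict with the in-memory objects (maps, trials, paths).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if maps is None:
        maps = compute_paper_maps(
            grid_step_deg=config.grid_step_deg,
            time_limit_s=config.time_limit_s,
            method=config.room_method,
        )
    cohort_cfg = config.cohort
    cohort_cfg.seed = config.seed
    cohort_cfg.static_benefit_db = static_predictions_from_maps(maps)
    trials = gen_cohort(cohort_cfg, benefit_maps=maps)

    from .cohort import cohort_to_frames

    trials_df, traj_df = cohort_to_frames(trials)
    trials_df.to_csv(out / "trials.tsv", sep="\t", index=False)
    traj_df.to_csv(out / "trajectories.csv", index=False)
    for tgt, m in maps.items():
        _map_frame(m).to_csv(out / f"benefit_map_{int(tgt):+d}.tsv", sep="\t", index=False)
    meta = {
        "package_version": __version__,
        "seed": config.seed,
        "room_method": config.room_method,
        "grid_step_deg": config.grid_step_deg,
        "time_limit_s": config.time_limit_s,
        "static_predictions_db": cohort_cfg.static_benefit_db,
    }
    (out / "run_config.json").write_text(json.dumps(meta, indent=2))
    return {"maps": maps, "trials": trials, "out_dir": str(out)}


def _score_table(trials: list[TrialRecord]) -> pd.DataFrame:
    """Per participant x condition x target x word-position counts (out of 24)."""
    rows = []
    for tr in trials:
        for wi in range(5):
            rows.append({
                "participant": tr.participant, "condition": tr.condition,
                "target_deg": tr.target_deg, "word_position": wi + 1,
                "correct": int(tr.correct[wi]),
            })
    df = pd.DataFrame(rows)
    cells = (
        df.groupby(["participant", "condition", "target_deg", "word_position"])
        .agg(n_correct=("correct", "sum"), n_total=("correct", "size"))
        .reset_index()
    )
    cells["percent"] = 100.0 * cells.n_correct / cells.n_total
    cells["rau"] = rau(cells.n_correct.to_numpy(), cells.n_total.to_numpy())
    return cells


def _orientation_summaries(
    trials: list[TrialRecord], maps: dict[float, BenefitMap], margin_db: float = 1.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-word unsigned orientations and final-word circular summaries."""
    regions = {tgt: optimal_region(m, margin_db) for tgt, m in maps.items()}
    word_rows, final_rows = [], []
    for tr in trials:
        med = per_word_orientation(tr.trajectory, tr.windows)
        for wi in range(5):
            word_rows.append({
                "participant": tr.participant, "condition": tr.condition,
                "target_deg": tr.target_deg, "word_position": wi + 1,
                "abs_yaw_deg": abs(med[wi]),
            })
        final_rows.append({
            "participant": tr.participant, "condition": tr.condition,
            "target_deg": tr.target_deg, "final_yaw_deg": med[-1],
            "in_optimal_region": bool(regions[tr.target_deg].contains(med[-1])[()])
            if tr.target_deg != 0.0 else False,
        })
    word_df = (
        pd.DataFrame(word_rows)
        .groupby(["condition", "target_deg", "word_position"], as_index=False)
        .abs_yaw_deg.mean()
    )
    return word_df, pd.DataFrame(final_rows)


def _table1_analogue(final_df: pd.DataFrame, n_permutations: int, seed: int) -> pd.DataFrame:
    """Final-word circular statistics and AV vs A-only Kuiper tests."""
    rows = []
    for tgt, sub in final_df.groupby("target_deg"):
        av = sub.loc[sub.condition == "AV", "final_yaw_deg"].to_numpy()
        ao = sub.loc[sub.condition == "A-only", "final_yaw_deg"].to_numpy()
        if av.size < 5 or ao.size < 5:
            continue
        v, p = kuiper_two_sample(av, ao, n_permutations=n_permutations, rng=seed)
        rows.append({
            "target_deg": tgt, "kuiper_v": v, "kuiper_p": p,
            "median_av_deg": circ_median(av), "median_aonly_deg": circ_median(ao),
            "nvar_av": circ_variance(av), "nvar_aonly": circ_variance(ao),
            "occupancy_av": sub.loc[sub.condition == "AV", "in_optimal_region"].mean(),
            "occupancy_aonly": sub.loc[sub.condition == "A-only", "in_optimal_region"].mean(),
        })
    return pd.DataFrame(rows)


def _model_prediction_cells(
    trials: list[TrialRecord], maps: dict[float, BenefitMap],
    fit: PsychFit, config: CohortConfig,
) -> pd.DataFrame:
    """Per trial-word model predictions (proportion) and motion gating."""
    rows = []
    for tr in trials:
        if tr.condition == "Static":
            benefits = np.full(5, float(maps[tr.target_deg].unmasking_at(0.0)))
            gates = np.zeros(5, dtype=bool)
        else:
            benefits = trajectory_benefit(
                maps[tr.target_deg], tr.trajectory, tr.windows, scale="unmasking"
            )
            gates = _word_motion_gate(tr.trajectory, tr.windows, config.motion_gate_deg_s)
        for wi in range(5):
            p, _ = predict_score(fit, float(benefits[wi]), participant=tr.participant)
            rows.append({
                "participant": tr.participant, "condition": tr.condition,
                "target_deg": tr.target_deg, "word_position": wi + 1,
                "pred_p": p, "benefit_db": float(benefits[wi]),
                "motion_gated": bool(gates[wi]), "observed": int(tr.correct[wi]),
            })
    return pd.DataFrame(rows)


def _signed_error(pred_df: pd.DataFrame, gated_only: bool | None = None) -> float:
    """Mean signed model-minus-data error in RAU over per-cell aggregates."""
    d = pred_df[pred_df.condition != "Static"]
    if gated_only is not None:
        d = d[d.motion_gated == gated_only]
    if d.empty:
        return np.nan
    g = d.groupby(["participant", "condition", "target_deg", "word_position"]).agg(
        pred_p=("pred_p", "mean"), obs=("observed", "sum"), n=("observed", "size")
    )
    pred_rau = rau((g.pred_p * g.n).to_numpy(), g.n.to_numpy())
    obs_rau = rau(g.obs.to_numpy(), g.n.to_numpy())
    return float(np.mean(pred_rau - obs_rau))


def _deficit_db(pred_df: pd.DataFrame, fit: PsychFit) -> float:
    """Motion-related deficit (dB) by inverting the psychometric function.

    For each motion-gated cell of the moving conditions, the observed
    proportion implies an effective benefit x_eff = (logit(p) - b0 - u_j)/b1;
    the deficit is the mean of (model benefit - x_eff).  Unlike a RAU-error /
    max-slope conversion this is unbiased away from the midpoint.
    """
    d = pred_df[(pred_df.condition != "Static") & pred_df.motion_gated]
    if d.empty:
        return np.nan
    g = d.groupby(["participant", "condition", "target_deg", "word_position"]).agg(
        benefit=("benefit_db", "mean"), obs=("observed", "sum"), n=("observed", "size")
    ).reset_index()
    p_emp = (g.obs + 0.5) / (g.n + 1.0)
    u = g.participant.map(lambda j: fit.ranef.get(j, 0.0))
    x_eff = (np.log(p_emp / (1 - p_emp)) - fit.beta0 - u) / fit.beta1
    return float(np.mean(g.benefit - x_eff))


def _anova_tables(cells: pd.DataFrame) -> dict[str, object]:
    """Full three-factor model and the four planned two-factor contrasts."""
    cells = cells.copy()
    cells["target_group"] = cells.target_deg.map(TARGET_GROUPS)
    # average left/right before analysis
    avg = (
        cells.groupby(["participant", "condition", "target_group", "word_position"],
                      as_index=False)
        .rau.mean()
    )
    out: dict[str, object] = {}
    out["full"] = rm_anova(avg, "rau", ["condition", "target_group", "word_position"],
                           "participant")
    for grp in ("lateral", "rear"):
        sub = avg[avg.target_group == grp]
        for pair, name in ((("Static", "A-only"), "static_vs_aonly"),
                           (("AV", "A-only"), "av_vs_aonly")):
            s2 = sub[sub.condition.isin(pair)]
            out[f"{grp}_{name}"] = rm_anova(
                s2, "rau", ["condition", "word_position"], "participant"
            )
    return out


def run_analyze(
    trials: list[TrialRecord],
    maps: dict[float, BenefitMap],
    config: RunConfig,
    out_dir: str | Path | None = None,
) -> dict:
    """Full analysis bundle on a cohort; optionally writes TSV/JSON artifacts."""
    cells = _score_table(trials)
    word_df, final_df = _orientation_summaries(trials, maps)
    table1 = _table1_analogue(final_df, config.n_permutations, config.seed)

    static_pred = static_predictions_from_maps(maps)
    static_cells = cells[cells.condition == "Static"]
    fit = fit_glre(static_cells, static_pred)

    pred_df = _model_prediction_cells(trials, maps, fit, config.cohort)
    err_all = _signed_error(pred_df)
    err_gated = _signed_error(pred_df, gated_only=True)
    deficit_db = _deficit_db(pred_df, fit)
    slope = fit.slope_per_db
    anovas = _anova_tables(cells)

    # model-vs-data single-factor ANOVA (AV + A-only pooled)
    moving = pred_df[pred_df.condition != "Static"]
    g = moving.groupby("participant").agg(model=("pred_p", "mean"), data=("observed", "mean"))
    md = g.reset_index().melt(id_vars="participant", var_name="datatype", value_name="p")
    md["rau"] = rau((md.p * 120).to_numpy(), np.full(len(md), 120.0))
    anova_md = rm_anova(md, "rau", ["datatype"], "participant")

    report = {
        "fit": fit,
        "slope_per_db": slope,
        "mean_signed_error_rau": err_all,
        "mean_signed_error_db": rau_error_to_db(err_all, slope) if np.isfinite(err_all) else np.nan,
        "deficit_estimate_rau": err_gated,
        "deficit_estimate_db": deficit_db,
        "scores": cells,
        "word_orientations": word_df,
        "final_orientations": final_df,
        "table1": table1,
        "predictions": pred_df,
        "anovas": anovas,
        "anova_model_vs_data": anova_md,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cells.to_csv(out / "scores.tsv", sep="\t", index=False)
        word_df.to_csv(out / "word_orientations.tsv", sep="\t", index=False)
        final_df.to_csv(out / "final_orientations.tsv", sep="\t", index=False)
        table1.to_csv(out / "circular_summary.tsv", sep="\t", index=False)
        pred_df.to_csv(out / "model_predictions.tsv", sep="\t", index=False)
        for name, res in anovas.items():
            res.table.to_csv(out / f"anova_{name}.tsv", sep="\t", index=False)
        anova_md.table.to_csv(out / "anova_model_vs_data.tsv", sep="\t", index=False)
        summary = {
            "seed": config.seed,
            "package_version": __version__,
            "slope_per_db": slope,
            "beta0": fit.beta0, "beta1": fit.beta1, "sigma_u": fit.sigma_u,
            "mean_signed_error_rau": err_all,
            "mean_signed_error_db": report["mean_signed_error_db"],
            "deficit_estimate_db": report["deficit_estimate_db"],
            "static_predictions_db": static_pred,
            "map_peaks_db": {str(t): m.peak_unmasking_db for t, m in maps.items()},
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return report
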