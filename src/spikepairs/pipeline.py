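"""End-to-end orchestration: records -> pair distributions -> clusters ->
angles -> adaptation control -> state model -> pooled state analyses.

Every stage can also be run on its own through the library functions (or
the CLI subcommands); ``run_pipeline`` chains them and assembles a
manifest of per-stage counts plus tidy output tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import PairDistribution, NeuronMeta, WINDOW_MS, ONSET_SHIFT_MS
from .clustering import ExtractionResult, extract_clusters
from .geometry import (bootstrap_angle, linear_correlation, angle_significance,
                       angle_significance_two_sided, henze_zirkler,
                       trial_regressions)
from .state import (PooledExample, fit_single_factor, pool_examples,
                    predict_state, rdr_summary, state_correlation, HeywoodError)
from .stationarity import PairProcessing, control_adaptation

log = logging.getLogger(__name__)


def build_distributions(records: pd.DataFrame,
                        stimulus_referenced: bool = False,
                        min_conjunctive: int = 1) -> list[PairDistribution]:
    """Pair distributions (one per ordered neuron pair and condition) from a
    record table.

    Conjunctive trials are those on which both neurons spiked; the neuron
    with the lower id sits on the x axis. If the input latencies are
    referenced to stimulus onset instead of cortical activation onset, the
    5.4 ms onset shift is subtracted and the [0, 50) ms window re-applied.
    """
    if records.empty:
        return []
    df = records.copy()
    if stimulus_referenced:
        df["first_spike_ms"] = df.first_spike_ms - ONSET_SHIFT_MS
    lo, hi = WINDOW_MS
    df = df[(df.first_spike_ms >= lo) & (df.first_spike_ms < hi)]
    # at most one record per (condition, trial, neuron): keep the first spike
    df = (df.sort_values("first_spike_ms")
            .groupby(["session", "whisker", "frequency_hz", "trial", "neuron_id"],
                     as_index=False).first())
    dists: list[PairDistribution] = []
    for (session, whisker, freq), cond in df.groupby(["session", "whisker", "frequency_hz"]):
        neurons = sorted(cond.neuron_id.unique())
        by_neuron = {nid: g.set_index("trial") for nid, g in cond.groupby("neuron_id")}
        for nx, ny in combinations(neurons, 2):
            gx, gy = by_neuron[nx], by_neuron[ny]
            common = gx.index.intersection(gy.index).sort_values()
            if len(common) < min_conjunctive:
                continue
            meta_x = _meta_from_row(gx.iloc[0], nx)
            meta_y = _meta_from_row(gy.iloc[0], ny)
            dists.append(PairDistribution(
                dist_id=f"{session}|{whisker}|{freq:g}|{nx}|{ny}",
                neuron_x=nx, neuron_y=ny, whisker=whisker, frequency_hz=freq,
                trials=common.to_numpy(),
                x=gx.loc[common, "first_spike_ms"].to_numpy(),
                y=gy.loc[common, "first_spike_ms"].to_numpy(),
                meta_x=meta_x, meta_y=meta_y))
    return dists


def _meta_from_row(row, nid: str) -> NeuronMeta | None:
    try:
        return NeuronMeta(neuron_id=nid, ei_type=row["ei_type"], layer=row["layer"],
                          column=str(row["column"]), septum=bool(row["septum"]))
    except (KeyError, ValueError):
        return None


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config_hash: str
    seed: int
    version: str
    counts: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


@dataclass
class PipelineResult:
    manifest: RunManifest
    distributions: list[PairDistribution]
    extractions: dict[str, ExtractionResult]
    processing: dict[str, PairProcessing]
    tables: dict[str, pd.DataFrame]


def _records_hash(records: pd.DataFrame) -> str:
    payload = pd.util.hash_pandas_object(records, index=False).to_numpy().tobytes()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(records: pd.DataFrame, seed: int,
                 out_dir: str | Path | None = None,
                 epsilons: np.ndarray | None = None,
                 min_cluster_size: int = 30,
                 n_boot: int = 10_000,
                 min_state_trials: int = 15) -> PipelineResult:
    """Run the whole analysis on a record table.

    Stages: distributions -> two-stage cluster extraction -> correlation /
    angle estimation (clusters and unclustered distributions) -> adaptation
    control -> single-factor state model and RDR spreads for
    criteria-fulfilling examples -> pooled cross-cluster state correlations.
    Deterministic given ``seed``; per-distribution failures are logged and
    skipped without aborting the run.
    """
    rng = np.random.default_rng(seed)
    dists = build_distributions(records)
    extractions: dict[str, ExtractionResult] = {}
    processing: dict[str, PairProcessing] = {}
    cluster_rows, angle_rows, stat_rows, factor_rows, rdr_rows = [], [], [], [], []
    series_rows: list[dict] = []
    examples: list[PooledExample] = []
    unclustered_examples: list[PooledExample] = []
    counts = {"distributions": len(dists), "stage1": 0, "stage1_correlated": 0,
              "stage2": 0, "unclustered_correlated": 0, "stationary": 0,
              "differenced": 0, "arima": 0, "criteria_fulfilling": 0, "pooled": 0}

    for dist in dists:
        dist_seed = rng.integers(0, 2**31 - 1)
        if dist.n >= min_cluster_size:
            try:
                ext = extract_clusters(dist, epsilons=epsilons,
                                       min_cluster_size=min_cluster_size,
                                       n_boot=n_boot, seed=int(dist_seed))
            except ValueError as exc:
                log.warning("extraction failed for %s: %s", dist.dist_id, exc)
                ext = ExtractionResult([], [], [], None)
            extractions[dist.dist_id] = ext
            counts["stage1"] += len(ext.stage1)
            counts["stage1_correlated"] += len(ext.stage1_correlated)
            for s1 in ext.stage1:
                cluster_rows.append({
                    "dist_id": dist.dist_id, "stage": 1, "epsilon": s1.epsilon,
                    "n_members": s1.n, "centre_x": s1.ellipse.centre[0],
                    "centre_y": s1.ellipse.centre[1],
                    "semi_axis_x": s1.ellipse.semi_axes[0],
                    "semi_axis_y": s1.ellipse.semi_axes[1], "rotation": 0.0,
                    "member_trials": " ".join(map(str, dist.trials[s1.members]))})
            if ext.stage2 is not None:
                counts["stage2"] += 1
                s2 = ext.stage2
                cluster_rows.append({
                    "dist_id": dist.dist_id, "stage": 2, "epsilon": s2.epsilon,
                    "n_members": s2.n, "centre_x": s2.ellipse.centre[0],
                    "centre_y": s2.ellipse.centre[1],
                    "semi_axis_x": s2.ellipse.semi_axes[0],
                    "semi_axis_y": s2.ellipse.semi_axes[1],
                    "rotation": s2.ellipse.rotation,
                    "member_trials": " ".join(map(str, dist.trials[s2.members]))})
                _analyse_example(dist, s2.members, "cluster", seed=int(dist_seed),
                                 angle_rows=angle_rows, stat_rows=stat_rows,
                                 factor_rows=factor_rows, rdr_rows=rdr_rows,
                                 series_rows=series_rows,
                                 examples=examples, counts=counts,
                                 precomputed_angle=s2.angle)
        # unclustered case: the same analyses with membership = all points
        if dist.n >= 10:
            try:
                if linear_correlation(dist.points).p < 0.005:
                    counts["unclustered_correlated"] += 1
                    _analyse_example(dist, np.arange(dist.n), "unclustered",
                                     seed=int(rng.integers(0, 2**31 - 1)),
                                     angle_rows=angle_rows, stat_rows=stat_rows,
                                     factor_rows=factor_rows, rdr_rows=rdr_rows,
                                     series_rows=series_rows,
                                     examples=unclustered_examples, counts=counts,
                                     n_boot=n_boot)
            except ValueError:
                pass

    pooled = pool_examples(examples, unclustered_examples)
    counts["pooled"] = len(pooled)

    edge_rows = []
    preds = []
    for ex in pooled:
        try:
            preds.append((ex, predict_state(ex.points, ex.trials, ex.dist_id,
                                            ex.neuron_ids)))
        except ValueError:
            continue
    for (ex_a, pa), (ex_b, pb) in combinations(preds, 2):
        if set(pa.neuron_ids) & set(pb.neuron_ids):
            continue
        # same stimulus condition required for trial alignment
        if ex_a.dist_id.split("|")[:3] != ex_b.dist_id.split("|")[:3]:
            continue
        try:
            res = state_correlation(pa, pb, min_conjunctive=min_state_trials)
        except ValueError:
            continue
        edge_rows.append({"cluster_a": pa.cluster_id, "cluster_b": pb.cluster_id,
                          "n_common": res.n, "r": res.r, "p": res.p})

    tables = {
        "clusters": pd.DataFrame(cluster_rows),
        "angles": pd.DataFrame(angle_rows),
        "stationarity": pd.DataFrame(stat_rows),
        "processed_series": pd.DataFrame(series_rows),
        "factors": pd.DataFrame(factor_rows),
        "rdr": pd.DataFrame(rdr_rows),
        "state_edges": pd.DataFrame(edge_rows),
    }
    manifest = RunManifest(config_hash=_records_hash(records), seed=seed,
                           version=__version__, counts=counts)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            path = out / f"{name}.csv"
            df.to_csv(path, index=False)
            manifest.outputs[name] = str(path)
        (out / "manifest.json").write_text(manifest.to_json(), encoding="utf-8")
    return PipelineResult(manifest=manifest, distributions=dists,
                          extractions=extractions, processing=processing,
                          tables=tables)


def _analyse_example(dist: PairDistribution, members: np.ndarray, kind: str,
                     seed: int, angle_rows, stat_rows, factor_rows, rdr_rows,
                     series_rows, examples, counts, precomputed_angle=None,
                     n_boot: int = 10_000) -> None:
    """Angles, adaptation control, factor model and RDRs for one example
    (a Stage 2 cluster or a correlated unclustered distribution)."""
    pts = dist.points[members]
    trials = dist.trials[members]
    label = f"{dist.dist_id}:{kind}"
    try:
        est = precomputed_angle or bootstrap_angle(pts, n_boot=n_boot, seed=seed)
    except ValueError as exc:
        log.warning("angle estimation failed for %s: %s", label, exc)
        return
    row = {"dist_id": dist.dist_id, "kind": kind, "n": len(pts),
           "theta": est.theta, "theta45": est.theta45,
           "ci_low": est.ci_low, "ci_high": est.ci_high}
    try:
        corr = linear_correlation(pts)
        row.update(r=corr.r, p=corr.p)
        if 0.0 < est.theta < 90.0:
            row["p_vs_0"] = angle_significance(est, 0.0)
            row["p_vs_45"] = angle_significance(est, 45.0)
            row["p_vs_45_two_sided"] = angle_significance_two_sided(est)
    except ValueError:
        pass
    try:
        row["hz_p"] = henze_zirkler(pts)
    except ValueError:
        row["hz_p"] = float("nan")
    try:
        _, row["trial_r2"] = trial_regressions(pts, trials)
    except ValueError:
        row["trial_r2"] = float("nan")
    angle_rows.append(row)

    if len(pts) < 10:
        return
    proc = control_adaptation(pts, trials, neuron_ids=(dist.neuron_x, dist.neuron_y))
    if kind == "cluster":
        # counts track the clustered case, mirroring the pipeline stages
        if proc.raw_report.stationary:
            counts["stationary"] += 1
        if any(proc.differenced_neurons):
            counts["differenced"] += 1
        if proc.arima_report is not None and proc.arima_report.criteria_fulfilling:
            counts["arima"] += 1
    for report in (proc.raw_report, proc.differenced_report, proc.arima_report):
        if report is None:
            continue
        stat_rows.append({
            "dist_id": dist.dist_id, "kind": kind, "mode": report.mode,
            "stationary": report.stationary,
            "criteria_fulfilling": report.criteria_fulfilling,
            "r": report.r, "p_corr": report.p_corr,
            "trial_r2": report.trial_r2,
            "kpss_p0": report.kpss_p[0], "kpss_p1": report.kpss_p[1],
            "lag1_p0": report.lag1_p[0], "lag1_p1": report.lag1_p[1],
            "bartlett_p": report.bartlett_p,
            "eig1": report.eigenvalues[0], "eig2": report.eigenvalues[1]})

    for mode_name, pair in (("differenced", proc.differenced),
                            ("arima", proc.arima)):
        if pair is None:
            continue
        for s in pair:
            for t, v in zip(s.trials, s.values):
                series_rows.append({
                    "dist_id": dist.dist_id, "kind": kind, "mode": mode_name,
                    "neuron_id": s.neuron_id, "trial": int(t),
                    "value_ms": float(v), "differenced": s.differenced,
                    "rescale": s.rescale, "ar_order": s.ar_order,
                    "ma_order": s.ma_order})

    mode = proc.final_mode
    if mode is None:
        return
    if kind == "cluster":
        counts["criteria_fulfilling"] += 1
    if mode == "raw":
        use_pts, use_trials = pts, trials
    else:
        pair = proc.arima if mode == "arima" else proc.differenced
        use_pts = np.column_stack([pair[0].values, pair[1].values])
        use_trials = pair[0].trials
    try:
        model = fit_single_factor(use_pts)
    except (HeywoodError, ValueError) as exc:
        log.warning("factor fit rejected for %s: %s", label, exc)
        return
    factor_rows.append({"dist_id": dist.dist_id, "kind": kind, "mode": mode,
                        "lambda0": model.lambda0, "lambda1": model.lambda1,
                        "sigma0": model.sigma0, "sigma1": model.sigma1,
                        "sigma_diff": model.sigma_diff})
    rdr = rdr_summary(dist, use_pts, model)
    rdr_rows.append({"dist_id": dist.dist_id, "kind": kind, "mode": mode,
                     "rdr1": rdr.rdr1_sigma_diff, "rdr2": rdr.rdr2_sigma_diff,
                     "rdr3": rdr.rdr3_sigma_diff})
    examples.append(PooledExample(dist_id=dist.dist_id, kind=kind,
                                  points=use_pts, trials=use_trials,
                                  neuron_ids=(dist.neuron_x, dist.neuron_y)))
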