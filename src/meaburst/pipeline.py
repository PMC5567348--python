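"""End-to-end orchestration of the analysis chain.

Stage order: spontaneous event detection -> stimulus-response analysis
-> pattern distances -> clustering -> evaluation.  Every stochastic step
draws a named substream of the configured master seed, so reruns with
the same inputs and seed produce byte-identical outputs.  Results are
written as JSON (events, leadership, splits, clusters, evaluation) and
CSV (distance matrices, MDS coordinates), with a manifest recording
which stages completed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, distance, evaluate, events, psth
from .config import AnalysisConfig
from .io import SpikeTrainSet, StimulationLog
from .layout import MEALayout, mcs_8x8

log = logging.getLogger("meaburst.pipeline")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (frozenset, set)):
        return sorted(obj)
    return obj


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(_jsonable(obj), indent=1, sort_keys=True))


def analyze_spontaneous(spont: SpikeTrainSet, config: AnalysisConfig) -> dict:
    """Bursts, active set, NBs, activation patterns and leadership."""
    thresholds = events.channel_isi_thresholds(spont, config)
    bursts = events.detect_channel_bursts(spont, config, thresholds)
    stats, active = events.channel_activity_stats(spont, bursts, config)
    active_bursts = {e: bursts[e] for e in active}
    nbs = events.detect_network_bursts(active_bursts, len(active), config)
    patterns = {f"s{nb.id:05d}": events.extract_activation_pattern(nb)
                for nb in nbs}
    leadership = events.leadership_scores(nbs, config) if nbs else None
    if leadership is not None:
        leadership.activity = stats
    return {
        "thresholds": thresholds,
        "bursts": bursts,
        "activity": stats,
        "active": active,
        "nbs": nbs,
        "patterns": patterns,
        "leadership": leadership,
    }


def analyze_stimulated(stim: SpikeTrainSet, slog: StimulationLog,
                       active: list[str], config: AnalysisConfig) -> dict:
    """PSTHs, early/late splits and evoked patterns for every session."""
    thresholds = events.channel_isi_thresholds(stim, config)
    sessions = {}
    for session in slog.sessions:
        psths = psth.compute_psth(stim, session, config)
        responding = psth.select_responding_channels(psths, config)
        entry = {
            "session": session,
            "psths": psths,
            "responding": responding,
            "split": None,
            "patterns": [],
            "reliability": 0.0,
            "kept": False,
        }
        if responding:
            split = psth.split_early_late(psths, responding, config)
            entry["split"] = split
            if split.accepted:
                patterns = psth.extract_evoked_patterns(
                    stim, session, split, active, thresholds, config)
                frac, kept = psth.response_reliability(
                    len(patterns), session.n_pulses, config)
                entry.update(patterns=patterns, reliability=frac, kept=kept)
        sessions[session.electrode] = entry
    return {"thresholds": thresholds, "sessions": sessions}


def run_pipeline(config: AnalysisConfig,
                 spont: SpikeTrainSet,
                 stim: SpikeTrainSet | None = None,
                 slog: StimulationLog | None = None,
                 layout: MEALayout | None = None,
                 out_dir: str | Path | None = None) -> dict:
    """Run the full analysis; returns the report bundle as a dict.

    When ``out_dir`` is given, machine-readable outputs are written
    there (JSON/CSV) together with a manifest; a stage failure persists
    the partial manifest and raises :class:`PipelineError` naming the
    stage.
    """
    layout = layout or mcs_8x8()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "seed": config.rng_seed}
    report: dict = {}

    def stage(name: str, fn):
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - report the failing stage
            manifest["stages"][name] = f"failed: {exc}"
            if out is not None:
                _write_json(out / "manifest.json", manifest)
            raise PipelineError(name, exc) from exc
        manifest["stages"][name] = "ok"
        return result

    # ----- network events -------------------------------------------------
    spont_res = stage("network_events", lambda: analyze_spontaneous(spont, config))
    report["spontaneous"] = spont_res
    if out is not None and spont_res["leadership"] is not None:
        lt = spont_res["leadership"]
        _write_json(out / "leadership.json", {
            "n_nbs": lt.n_nbs, "led": lt.led, "score": lt.score,
            "major_leaders": lt.major_leaders, "activity": lt.activity,
        })
        _write_json(out / "network_bursts.json", [
            {"id": nb.id, "onset_ms": nb.onset_ms, "offset_ms": nb.offset_ms,
             "leader": nb.leader, "order": nb.order, "delays": nb.delays}
            for nb in spont_res["nbs"]
        ])

    # ----- stimulus response ----------------------------------------------
    evoked_res = None
    if stim is not None and slog is not None:
        evoked_res = stage("stimulus_response",
                           lambda: analyze_stimulated(stim, slog,
                                                      spont_res["active"], config))
        report["evoked"] = evoked_res
        if out is not None:
            _write_json(out / "splits.json", {
                e: None if s["split"] is None else {
                    "x_peak1_ms": s["split"].x_peak1_ms,
                    "x_peak2_ms": s["split"].x_peak2_ms,
                    "x_min_ms": s["split"].x_min_ms,
                    "s": s["split"].s,
                    "accepted": s["split"].accepted,
                    "reliability": s["reliability"],
                    "kept": s["kept"],
                }
                for e, s in evoked_res["sessions"].items()
            })
            _write_json(out / "evoked_patterns.json", {
                e: [{"trial": p.trial, "order": p.order, "delays": p.delays}
                    for p in s["patterns"]]
                for e, s in evoked_res["sessions"].items()
            })
    else:
        manifest["stages"]["stimulus_response"] = "absent (spontaneous-only input)"
        report["evoked"] = None

    # ----- pattern distances ----------------------------------------------
    spont_patterns = distance.truncate_spontaneous(spont_res["patterns"],
                                                   config.max_spont_nbs)

    def _distances():
        res = {}
        if len(spont_patterns) >= 2:
            res["spont_dm"] = distance.distance_matrix(
                spont_patterns, config, seed=config.rng_seed,
                meta={pid: {"leader": nb.leader}
                      for pid, nb in zip(spont_patterns,
                                         spont_res["nbs"][:len(spont_patterns)])})
        else:
            res["spont_dm"] = None
        if evoked_res is not None:
            evoked_patterns = {}
            for e, s in evoked_res["sessions"].items():
                if s["kept"]:
                    for p in s["patterns"]:
                        evoked_patterns[f"e-{e}-{p.trial:03d}"] = p.order
            res["evoked_patterns"] = evoked_patterns
            res["evoked_dm"] = distance.distance_matrix(
                evoked_patterns, config, seed=config.rng_seed) \
                if len(evoked_patterns) >= 2 else None
        else:
            res["evoked_patterns"] = {}
            res["evoked_dm"] = None
        return res

    dist_res = stage("pattern_similarity", _distances)
    report["distances"] = dist_res
    if out is not None:
        for key, fname in (("spont_dm", "spont_distances.csv"),
                           ("evoked_dm", "evoked_distances.csv")):
            dm = dist_res[key]
            if dm is not None:
                pd.DataFrame(dm.values, index=dm.ids, columns=dm.ids) \
                    .to_csv(out / fname, float_format="%.6g")

    # ----- clustering ------------------------------------------------------
    def _cluster():
        res = {"spont": None, "evoked_by_stim": {}}
        if dist_res["spont_dm"] is not None:
            res["spont"] = clustering.cluster_patterns(dist_res["spont_dm"], config)
        if evoked_res is not None and dist_res["evoked_dm"] is not None:
            # cluster each stimulation site's responses separately
            for e, s in evoked_res["sessions"].items():
                ids = [f"e-{e}-{p.trial:03d}" for p in s["patterns"]] if s["kept"] else []
                if len(ids) < 2:
                    continue
                sub = {i: dist_res["evoked_patterns"][i] for i in ids}
                dm = distance.distance_matrix(sub, config, seed=config.rng_seed)
                cs = clustering.find_cluster_cores(dm, config)
                if cs.cores:
                    cs = clustering.assign_by_template_matching(cs, dm, config)
                res["evoked_by_stim"][e] = {"dm": dm, "clusters": cs}
        return res

    clust_res = stage("pattern_clustering", _cluster)
    report["clusters"] = clust_res
    if out is not None and clust_res["spont"] is not None:
        cs = clust_res["spont"]
        nb_delays = {f"s{nb.id:05d}": nb.delays for nb in spont_res["nbs"]}
        delay_maps = {
            c: clustering.cluster_delay_map(
                [nb_delays[i] for i in ids if i in nb_delays], config)
            for c, ids in cs.members.items()
        }
        _write_json(out / "spont_clusters.json", {
            "labels": cs.labels, "cores": cs.cores, "members": cs.members,
            "delay_maps": delay_maps,
        })

    # ----- evaluation -------------------------------------------------------
    def _evaluate():
        res: dict = {}
        dm = dist_res["spont_dm"]
        cs = clust_res["spont"]
        alpha = config.distance_alpha
        if dm is not None:
            by_leader: dict[str, list[str]] = {}
            for pid in dm.ids:
                leader = dm.meta.get(pid, {}).get("leader")
                if leader:
                    by_leader.setdefault(leader, []).append(pid)
            res["same_ml_ratio"] = _pooled_within(dm, by_leader, alpha)
            res["diff_ml_ratio"] = _pooled_between(dm, by_leader, alpha)
            if cs is not None and cs.cores:
                res["same_cluster_ratio"] = _pooled_within(dm, cs.members, alpha)
                res["diff_cluster_ratio"] = _pooled_between(dm, cs.members, alpha)
        if evoked_res is not None and dm is not None and cs is not None and cs.cores:
            per_stim = {}
            for e, entry in clust_res["evoked_by_stim"].items():
                ecs = entry["clusters"]
                ids = ecs.classified_ids() or list(entry["dm"].ids)
                epat = {i: dist_res["evoked_patterns"][i] for i in ids}
                sim = evaluate.spont_evoked_similarity(
                    spont_patterns, cs, epat, e, config, seed=config.rng_seed)
                ctrl = evaluate.shuffle_control_cross(
                    {i: spont_patterns[i] for i in cs.classified_ids()},
                    epat, config, seed=config.rng_seed)
                entry_res = {
                    "similarity": sim,
                    "shuffle_p95": ctrl["p95"],
                    "above_chance": sim.max_ratio > ctrl["p95"],
                }
                if sim.matched_cluster is not None:
                    within_spont = evaluate.similar_pair_ratio(
                        dm, cs.members[sim.matched_cluster], alpha=alpha)
                    within_evoked = evaluate.similar_pair_ratio(
                        entry["dm"], ids, alpha=alpha) if len(ids) >= 2 else np.nan
                    entry_res["mean_within_ratio"] = float(
                        np.nanmean([within_spont, within_evoked]))
                per_stim[e] = entry_res
            res["per_stim"] = per_stim
            pairs = [(v["similarity"].max_ratio, v.get("mean_within_ratio"))
                     for v in per_stim.values() if v.get("mean_within_ratio") is not None]
            if len(pairs) >= 3:
                res["reliability_correlation"] = evaluate.reliability_correlation(
                    [p[0] for p in pairs], [p[1] for p in pairs])
        if dm is not None and len(dm.ids) >= 3:
            res["mds"] = evaluate.mds_embedding(dm, dims=2)
        return res

    eval_res = stage("evaluation", _evaluate)
    report["evaluation"] = eval_res
    if out is not None:
        summary = {k: v for k, v in eval_res.items() if k not in {"mds", "per_stim"}}
        if "per_stim" in eval_res:
            summary["per_stim"] = {
                e: {"max_ratio": v["similarity"].max_ratio,
                    "classification": v["similarity"].classification,
                    "matched_cluster": v["similarity"].matched_cluster,
                    "shuffle_p95": v["shuffle_p95"],
                    "above_chance": v["above_chance"],
                    "mean_within_ratio": v.get("mean_within_ratio")}
                for e, v in eval_res["per_stim"].items()
            }
        _write_json(out / "evaluation.json", summary)
        if "mds" in eval_res:
            pd.DataFrame(eval_res["mds"]["coordinates"],
                         index=eval_res["mds"]["ids"],
                         columns=["x", "y"]).to_csv(out / "mds_coordinates.csv",
                                                    float_format="%.6g")
        _write_json(out / "manifest.json", manifest)
    report["manifest"] = manifest
    return report


def _pooled_within(dm, groups: dict[str, list[str]], alpha: float) -> float | None:
    vals = []
    for ids in groups.values():
        if len(ids) < 2:
            continue
        sub = dm.submatrix(ids, ids)
        vals.append(sub[np.triu_indices(len(ids), k=1)])
    if not vals:
        return None
    v = np.concatenate(vals)
    return float(np.mean(v < alpha))


def _pooled_between(dm, groups: dict[str, list[str]], alpha: float) -> float | None:
    names = list(groups)
    vals = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = groups[names[i]], groups[names[j]]
            if a and b:
                vals.append(dm.submatrix(a, b).ravel())
    if not vals:
        return None
    v = np.concatenate(vals)
    return float(np.mean(v < alpha))
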