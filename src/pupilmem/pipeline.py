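"""End-to-end orchestration: read, preprocess, decompose, score, link, write."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, dataio, decompose, evoked, linkage
from .config import AnalysisConfig
from .preprocess import preprocess_recordings

log = logging.getLogger("pupilmem")

__all__ = ["JoinError", "analyze", "run_pipeline", "solution_scores_frame"]


class JoinError(ValueError):
    """Input files disagree on participant/block keys."""


def _check_keys(recordings, events: pd.DataFrame, pairs: pd.DataFrame,
                items: pd.DataFrame) -> None:
    rec_keys = {(r.participant_id, int(r.block_id)) for r in recordings}
    ev_keys = set(map(tuple, events[["participant", "block"]].drop_duplicates()
                      .itertuples(index=False)))
    if rec_keys != ev_keys:
        raise JoinError(
            f"samples and events disagree on (participant, block) keys: "
            f"{len(rec_keys ^ ev_keys)} mismatched key(s)")
    for name, df in (("pairs", pairs), ("items", items)):
        extra = set(map(tuple, df[["participant", "block"]].drop_duplicates()
                        .itertuples(index=False))) - ev_keys
        if extra:
            raise JoinError(f"{name} table has keys absent from events: "
                            f"{sorted(extra)[:5]}")


def solution_scores_frame(solution: decompose.ComponentSolution) -> pd.DataFrame:
    """Component scores as a tidy frame: participant, condition, score_1..k."""
    out = solution.keys[["participant", "tone_condition"]].copy()
    for j in range(solution.k):
        out[f"score_{j + 1}"] = solution.scores[:, j]
    return out


def analyze(recordings, events: pd.DataFrame, pairs: pd.DataFrame,
            items: pd.DataFrame, cfg: AnalysisConfig) -> dict:
    """Run every analysis stage on in-memory inputs; returns a result bundle."""
    _check_keys(recordings, events, pairs, items)
    epochs, exclusions = preprocess_recordings(recordings, events, cfg)
    log.info("epoched %d trials x %d timepoints", *epochs.data.shape)

    ev = evoked.evoked_dilation(epochs, cfg)
    b, s, _ = ev.condition_vectors()
    evoked_stats = {
        "boundary_vs_same_context": evoked.paired_contrast(b, s),
        "boundary_vs_baseline": evoked.against_baseline(b),
        "same_context_vs_baseline": evoked.against_baseline(s),
    }

    matrix = decompose.build_waveform_matrix(
        epochs, window_ms=cfg.pca_window_ms, min_trials=cfg.min_trials_per_cell)
    solution = decompose.run_pca(matrix, cfg)
    splits = {cond: decompose.condition_split_pca(epochs, cond, cfg)
              for cond in ("boundary", "same_context")}

    scores_frame = solution_scores_frame(solution)
    score_tests = {}
    wide = scores_frame.pivot(index="participant", columns="tone_condition")
    for j in range(solution.k):
        col = f"score_{j + 1}"
        score_tests[col] = evoked.paired_contrast(
            wide[(col, "boundary")].to_numpy(), wide[(col, "same_context")].to_numpy())

    order_scores = behavior.score_order(pairs)
    distance_scores = behavior.score_distance(pairs)
    source_scores = behavior.score_source(items)
    memory_stats = behavior.condition_tests(order_scores, distance_scores,
                                            source_scores)

    subtractions = linkage.subtraction_scores(scores_frame, order_scores,
                                              distance_scores, source_scores)
    correlations = linkage.pupil_memory_correlations(subtractions)

    trials = linkage.trial_measures(ev.trials, events)
    trial_models = linkage.trial_level_models(trials, pairs, items)
    pitch = linkage.pitch_change_analysis(trials, items)
    # stability uses the repaired traces, so re-run the repair on kept blocks
    from .preprocess import detect_artifacts, interpolate
    kept_keys = set(map(tuple, exclusions.loc[~exclusions["dropped"],
                                              ["participant", "block"]]
                        .itertuples(index=False)))
    repaired = [interpolate(r, detect_artifacts(
        r, velocity_mad_threshold=cfg.velocity_mad_threshold,
        pad_ms=cfg.artifact_pad_ms))
        for r in recordings if (r.participant_id, int(r.block_id)) in kept_keys]
    stability = linkage.stability_analysis(repaired, pairs, events)

    return dict(
        epochs=epochs, exclusions=exclusions, evoked=ev,
        evoked_stats=evoked_stats, matrix=matrix, solution=solution,
        splits=splits, scores_frame=scores_frame, score_tests=score_tests,
        order_scores=order_scores, distance_scores=distance_scores,
        source_scores=source_scores, memory_stats=memory_stats,
        subtractions=subtractions, correlations=correlations,
        trials=trials, trial_models=trial_models, pitch=pitch,
        stability=stability,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def _write_json(data, path: Path) -> None:
    path.write_text(json.dumps(_jsonable(data), indent=2, sort_keys=True))


FLOAT_FMT = "%.10g"


def run_pipeline(cfg: AnalysisConfig, samples_path, events_path, pairs_path,
                 items_path, out_dir) -> dict:
    """File-level entry point; deterministic given the inputs and config.

    Writes component waveforms, per-participant scores, behavioral
    summaries, contrast statistics, and linkage correlations to ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    recordings = dataio.read_samples(samples_path)
    events = dataio.read_events(events_path)
    pairs = dataio.read_pairs(pairs_path)
    items = dataio.read_items(items_path)
    res = analyze(recordings, events, pairs, items, cfg)

    sol = res["solution"]
    loadings = pd.DataFrame(sol.loadings,
                            columns=[f"c{j + 1}" for j in range(sol.k)])
    loadings.insert(0, "time_ms", sol.times_ms)
    loadings.to_csv(out / "loadings.tsv", sep="\t", index=False,
                    float_format=FLOAT_FMT)
    res["scores_frame"].to_csv(out / "scores.tsv", sep="\t", index=False,
                               float_format=FLOAT_FMT)
    res["exclusions"].to_csv(out / "exclusions.tsv", sep="\t", index=False,
                             float_format=FLOAT_FMT)
    res["evoked"].participant_means.to_csv(out / "evoked_means.tsv", sep="\t",
                                           index=False, float_format=FLOAT_FMT)
    for name in ("order_scores", "distance_scores", "source_scores"):
        res[name].to_csv(out / f"{name}.tsv", sep="\t", index=False,
                         float_format=FLOAT_FMT)
    res["subtractions"].to_csv(out / "subtractions.tsv", sep="\t", index=False,
                               float_format=FLOAT_FMT)
    res["correlations"].to_csv(out / "correlations.tsv", sep="\t", index=False,
                               float_format=FLOAT_FMT)
    res["stability"]["pair_sd"].to_csv(out / "pair_pupil_sd.tsv", sep="\t",
                                       index=False, float_format=FLOAT_FMT)
    _write_json(res["evoked_stats"], out / "evoked_stats.json")
    _write_json(res["score_tests"], out / "score_tests.json")
    _write_json(res["memory_stats"], out / "memory_stats.json")
    _write_json(decompose.summarize(sol), out / "pca_summary.json")
    _write_json({cond: decompose.summarize(s) for cond, s in res["splits"].items()},
                out / "pca_splits.json")
    _write_json(res["trial_models"], out / "trial_models.json")
    _write_json(res["pitch"], out / "pitch_change.json")
    _write_json({k: v for k, v in res["stability"].items() if k != "pair_sd"},
                out / "stability.json")
    _write_json(cfg.to_dict(), out / "analysis_config.json")
    log.info("wrote results to %s", out)
    return res
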