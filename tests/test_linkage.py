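import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from pupilmem import behavior, linkage, synth
from pupilmem.config import SimulationConfig
from pupilmem.linkage import (spearman, subtraction_scores,
                              pupil_memory_correlations, mixed_model,
                              trial_measures, stability_analysis,
                              pitch_change_analysis)

from tests.conftest import make_recording


class TestSpearman:
    def test_monotone_is_one(self):
        x = np.array([1.0, 2, 5, 9, 11, 20])
        assert spearman(x, np.exp(x))["rho"] == pytest.approx(1.0)

    def test_hand_rank_formula(self):
        # d = x_rank - y_rank = (-2, 1, -1, 2, 0), sum d^2 = 10,
        # rho = 1 - 6*10/(5*24) = 0.5
        x, y = [1, 2, 3, 4, 5], [3, 1, 4, 2, 5]
        d2 = sum((xi - yi) ** 2 for xi, yi in zip(x, y))
        assert d2 == 10
        res = spearman(x, y, method="t")
        assert res["rho"] == pytest.approx(1 - 6 * d2 / (5 * 24), abs=1e-12)
        from scipy.stats import spearmanr
        assert res["rho"] == pytest.approx(spearmanr(x, y).statistic)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(0, 1, 30)
        base = spearman(x, y, method="t")["rho"]
        assert spearman(np.exp(x), y, method="t")["rho"] == pytest.approx(base)
        assert spearman(x, y ** 3 + 5 * y, method="t")["rho"] == pytest.approx(base)

    def test_exact_permutation_small_n(self):
        res = spearman([1, 2, 3, 4, 5], [1, 2, 3, 4, 5], method="exact")
        # only identity and reversal reach |rho| = 1 among 120 permutations
        assert res["p"] == pytest.approx(2 / 120)

    def test_exact_matches_enumeration_null(self):
        res = spearman([1, 2, 3, 4, 5], [3, 1, 4, 2, 5], method="exact")
        assert 0 < res["p"] <= 1
        # oracle: direct enumeration with scipy rankdata
        from itertools import permutations
        from scipy.stats import rankdata
        rx = rankdata([1, 2, 3, 4, 5])
        ry = rankdata([3, 1, 4, 2, 5])
        obs = np.corrcoef(rx, ry)[0, 1]
        count = sum(abs(np.corrcoef(rx, np.array(p))[0, 1]) >= abs(obs) - 1e-12
                    for p in permutations(ry))
        assert res["p"] == pytest.approx(count / 120)

    def test_zero_variance_flagged(self):
        res = spearman([1.0] * 6, [1, 2, 3, 4, 5, 6])
        assert res["zero_variance"]

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2, 3])


def _component_scores_frame(n=10, k=2, rng=None):
    rng = rng or np.random.default_rng(0)
    rows = []
    for i in range(n):
        for cond in ("boundary", "same_context"):
            row = {"participant": f"P{i:03d}", "tone_condition": cond}
            for j in range(k):
                row[f"score_{j + 1}"] = rng.normal()
            rows.append(row)
    return pd.DataFrame(rows)


def _memory_scores(n=10, rng=None):
    rng = rng or np.random.default_rng(1)
    order, distance, source = [], [], []
    for i in range(n):
        p = f"P{i:03d}"
        for cond in ("boundary_span", "same_context"):
            order.append((p, cond, rng.uniform(0.4, 0.9)))
            distance.append((p, cond, rng.uniform(1.5, 3.5)))
        for t in ("boundary", "same_context", "first", "last"):
            source.append((p, t, rng.uniform(0.5, 1.0)))
    cols_pair = ["participant", "pair_condition", "score"]
    cols_item = ["participant", "item_type", "score"]
    return (pd.DataFrame(order, columns=cols_pair),
            pd.DataFrame(distance, columns=cols_pair),
            pd.DataFrame(source, columns=cols_item))


class TestSubtractionScores:
    def test_shape_and_columns(self):
        subs = subtraction_scores(_component_scores_frame(), *_memory_scores())
        assert len(subs) == 10
        assert {"dscore_1", "dscore_2", "dorder", "ddistance", "dsource"} <= set(subs.columns)

    def test_duplicate_rows_rejected(self):
        frame = _component_scores_frame()
        dup = pd.concat([frame, frame.iloc[:2]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            subtraction_scores(dup, *_memory_scores())

    def test_delta_arithmetic(self):
        frame = _component_scores_frame(n=6)
        order, distance, source = _memory_scores(n=6)
        subs = subtraction_scores(frame, order, distance, source)
        wide = frame.pivot(index="participant", columns="tone_condition",
                           values="score_1")
        np.testing.assert_allclose(
            subs.set_index("participant")["dscore_1"],
            wide["boundary"] - wide["same_context"])


class TestCorrelationMatrix:
    def test_all_cells_present(self):
        subs = subtraction_scores(_component_scores_frame(), *_memory_scores())
        corr = pupil_memory_correlations(subs)
        assert len(corr) == 2 * 3
        assert (corr["multiple_comparison_correction"] == "none").all()

    def test_planted_cell_dominates(self):
        rng = np.random.default_rng(3)
        n = 60
        frame = _component_scores_frame(n=n, k=4, rng=rng)
        order, distance, source = _memory_scores(n=n, rng=rng)
        wide = frame.pivot(index="participant", columns="tone_condition",
                           values="score_4")
        d4 = (wide["boundary"] - wide["same_context"]).sort_index()
        distance = distance.set_index(["participant", "pair_condition"])
        for i, p in enumerate(sorted(d4.index)):
            distance.loc[(p, "boundary_span"), "score"] = 2.0 + 0.8 * d4[p] \
                + 0.1 * rng.normal()
            distance.loc[(p, "same_context"), "score"] = 2.0
        subs = subtraction_scores(frame, order, distance.reset_index(), source)
        corr = pupil_memory_correlations(subs)
        top = corr.loc[corr["rho"].abs().idxmax()]
        assert top["component"] == 4 and top["memory_measure"] == "distance"


class TestMixedModel:
    def test_forced_separation_binary(self, rng):
        n = 400
        df = pd.DataFrame({
            "participant": np.repeat([f"P{i}" for i in range(20)], n // 20),
            "phasic": rng.normal(0, 1, n),
        })
        df["y"] = (df["phasic"] > df["phasic"].median()).astype(int)
        res = mixed_model(df, "y", ["phasic"], binary=True)
        assert res["coefficients"]["phasic"]["estimate"] > 2.0

    def test_degenerate_outcome_flagged(self):
        df = pd.DataFrame({"participant": ["P1"] * 10, "y": 1,
                           "phasic": np.arange(10.0)})
        res = mixed_model(df, "y", ["phasic"], binary=True)
        assert res.get("degenerate_outcome")

    def test_zero_variance_predictor_flagged(self):
        df = pd.DataFrame({"participant": ["P1", "P2"] * 5,
                           "y": [0, 1] * 5, "phasic": 1.0})
        res = mixed_model(df, "y", ["phasic"], binary=True)
        assert res.get("zero_variance_predictor") == "phasic"

    def test_linear_recovers_slope(self, rng):
        n = 600
        g = np.repeat(np.arange(30), 20)
        u = rng.normal(0, 1.0, 30)
        x = rng.normal(0, 2.0, n)
        y = 1.0 + 0.5 * x + u[g] + rng.normal(0, 0.5, n)
        df = pd.DataFrame({"participant": g, "x": x, "y": y})
        res = mixed_model(df, "y", ["x"], binary=False)
        est = res["coefficients"]["x"]["estimate"]
        assert est == pytest.approx(0.5 * 2.0, rel=0.15)  # standardized scale

    def test_binary_null_calibration(self, rng):
        rejections = 0
        n_sims = 20
        for s in range(n_sims):
            r = np.random.default_rng(s)
            n = 300
            g = np.repeat(np.arange(15), 20)
            u = r.normal(0, 0.5, 15)
            x = r.normal(0, 1, n)
            y = (r.random(n) < 1 / (1 + np.exp(-(0.3 + u[g])))).astype(int)
            df = pd.DataFrame({"participant": g, "x": x, "y": y})
            res = mixed_model(df, "x" and "y", ["x"], binary=True)
            rejections += res["coefficients"]["x"]["p"] < 0.05
        assert rejections <= 4  # nominal-ish rate at alpha = .05


class TestTrialLevel:
    @pytest.fixture(scope="class")
    def small_run(self):
        cfg = SimulationConfig(n_participants=10, n_blocks=4, rng_seed=3)
        events, recordings, pairs, items, gt = synth.simulate(cfg, seed=3)
        from pupilmem.config import AnalysisConfig
        from pupilmem.preprocess import preprocess_recordings
        from pupilmem.evoked import evoked_dilation
        acfg = AnalysisConfig()
        epochs, _ = preprocess_recordings(recordings, events, acfg)
        ev = evoked_dilation(epochs, acfg)
        trials = trial_measures(ev.trials, events)
        return dict(cfg=cfg, events=events, recordings=recordings,
                    pairs=pairs, items=items, trials=trials)

    def test_trial_measures_columns(self, small_run):
        t = small_run["trials"]
        assert {"phasic", "tonic", "item_id", "pitch_change_hz"} <= set(t.columns)
        b = t[t["tone_condition"] == "boundary"]
        assert b["pitch_change_hz"].notna().all()
        assert b["pitch_change_hz"].isin([100, 200, 300, 400, 500]).all()
        assert t[t["tone_condition"] != "boundary"]["pitch_change_hz"].isna().all()

    def test_trial_level_models_run(self, small_run):
        res = linkage.trial_level_models(small_run["trials"],
                                         small_run["pairs"], small_run["items"])
        for key in ("order", "distance", "source"):
            assert "coefficients" in res[key] or "degenerate_outcome" in res[key]

    def test_pitch_change_analysis_runs(self, small_run):
        res = pitch_change_analysis(small_run["trials"], small_run["items"])
        assert "pupil" in res and "source" in res

    def test_pitch_constant_flagged(self, small_run):
        trials = small_run["trials"].copy()
        trials.loc[trials["pitch_change_hz"].notna(), "pitch_change_hz"] = 200.0
        res = pitch_change_analysis(trials, small_run["items"])
        assert res["pupil"].get("zero_variance_predictor") == "pitch_change_hz"


class TestDirectionPattern:
    """Reduced-scale direction-pattern checks for the paper-like preset.

    The component-coupling signs and the stability finding are exercised in
    separate generator regimes: the stability signal requires the tonic
    process to dominate the trace sd, which at the same time inflates the
    retained component count, so a single dataset cannot carry both planted
    structures cleanly.
    """

    def test_component_coupling_signs(self):
        from scipy.optimize import linear_sum_assignment
        from pupilmem.config import AnalysisConfig
        from pupilmem.preprocess import preprocess_recordings
        from pupilmem.decompose import build_waveform_matrix, run_pca
        from pupilmem.pipeline import solution_scores_frame

        cfg = synth.paper_like_config(n_participants=30, n_blocks=8)
        acfg = AnalysisConfig()
        kernels = np.vstack([synth.pupil_kernel(l, w) for l, w in
                             zip(cfg.component_latencies_ms,
                                 cfg.component_widths_ms)])
        hits = 0
        n_seeds = 5
        for seed in range(n_seeds):
            events, recordings, pairs, items, gt = synth.simulate(cfg, seed=seed)
            epochs, _ = preprocess_recordings(recordings, events, acfg)
            sol = run_pca(build_waveform_matrix(epochs), acfg)
            if sol.k != 4:
                continue
            cors = np.abs(np.array(
                [[np.corrcoef(sol.loadings[:, j], kernels[i])[0, 1]
                  for i in range(4)] for j in range(4)]))
            rows, cols = linear_sum_assignment(-cors)
            col_of = {planted: f"score_{j + 1}" for j, planted in zip(rows, cols)}
            subs = subtraction_scores(solution_scores_frame(sol),
                                      behavior.score_order(pairs),
                                      behavior.score_distance(pairs),
                                      behavior.score_source(items))
            rho_dist = spearman(subs["d" + col_of[3]], subs["ddistance"],
                                method="t")["rho"]
            rho_order = spearman(subs["d" + col_of[2]], subs["dorder"],
                                 method="t")["rho"]
            hits += bool(rho_dist > 0 and rho_order < 0)
        assert hits >= n_seeds - 1

    def test_stability_direction(self):
        cfg = SimulationConfig(n_participants=30, n_blocks=8,
                               tonic_sd=250.0, tonic_cv=1.0,
                               stability_coupling={"order": -1.0,
                                                   "distance": 0.8})
        hits = 0
        n_seeds = 3
        for seed in range(n_seeds):
            events, recordings, pairs, items, gt = synth.simulate(cfg, seed=seed)
            stab = stability_analysis(recordings, pairs, events)
            c_order = stab["order"]["coefficients"]["pair_pupil_sd"]["estimate"]
            sd = stab["pair_sd"].groupby("participant")["pair_pupil_sd"].mean()
            dist = pairs.groupby("participant")["distance_rating"].mean()
            rho_sd = spearman(sd.sort_index(), dist.sort_index(),
                              method="t")["rho"]
            hits += bool(c_order < 0 and rho_sd > 0)
        assert hits >= n_seeds - 1


class TestStability:
    def test_constant_trace_zero_sd(self, small_pairs_events=None):
        cfg = SimulationConfig(n_participants=2, n_blocks=1, tonic_sd=0.0,
                               noise_sd=0.0, blink_rate_per_min=0.0,
                               amplitude_sds=(0.0,) * 4,
                               amplitude_delta_sds=(0.0,) * 4,
                               amplitude_means=((0.0, 0.0),) * 4,
                               image_amplitude=0.0, participant_mean_sd=0.0)
        events, recordings, pairs, items, gt = synth.simulate(cfg, seed=0)
        res = stability_analysis(recordings, pairs, events)
        assert (res["pair_sd"]["pair_pupil_sd"] == 0).all()

    def test_boundary_bump_raises_boundary_pair_sd(self):
        cfg = SimulationConfig(n_participants=8, n_blocks=2, tonic_sd=0.0,
                               noise_sd=1.0, blink_rate_per_min=0.0,
                               amplitude_sds=(0.0,) * 4,
                               amplitude_delta_sds=(0.0,) * 4,
                               amplitude_means=((200.0, 0.0),) * 4,
                               image_amplitude=0.0, participant_mean_sd=0.0)
        events, recordings, pairs, items, gt = synth.simulate(cfg, seed=1)
        res = stability_analysis(recordings, pairs, events)
        m = res["pair_sd"].groupby("pair_condition")["pair_pupil_sd"].mean()
        assert m["boundary_span"] > m["same_context"]

    def test_stability_coupling_sign_recovered(self):
        # planted: lower tonic variability -> better order memory (negative
        # logistic coefficient) and more compressed distance (positive
        # participant-level association of pair sd with mean rating); tonic
        # must dominate the trace sd for the measured sd to carry the signal
        cfg = SimulationConfig(n_participants=30, n_blocks=8,
                               tonic_sd=250.0, tonic_cv=1.0,
                               stability_coupling={"order": -1.0,
                                                   "distance": 0.8})
        events, recordings, pairs, items, gt = synth.simulate(cfg, seed=0)
        res = stability_analysis(recordings, pairs, events)
        assert res["order"]["coefficients"]["pair_pupil_sd"]["estimate"] < 0
        sd = res["pair_sd"].groupby("participant")["pair_pupil_sd"].mean()
        dist = pairs.groupby("participant")["distance_rating"].mean()
        rho = spearman(sd.sort_index(), dist.sort_index(), method="t")["rho"]
        assert rho > 0.3

    def test_span_outside_recording_dropped(self, tiny_sim, caplog):
        pairs = tiny_sim["pairs"].copy()
        events = tiny_sim["events"].copy()
        first = pairs.iloc[[0]].copy()
        mask = (events["item_id"] == first["item_b"].iloc[0]) \
            & (events["event_type"] == "image")
        events.loc[mask, "onset_ms"] = 10_000_000
        with caplog.at_level("WARNING", logger="pupilmem"):
            res = stability_analysis(tiny_sim["recordings"], pairs, events)
        total = len(pairs)
        assert len(res["pair_sd"]) == total - 1
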