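"""Validation experiments: parameter-recovery, calibration and robustness
studies run against the synthetic generator's ground truth.

Every function here recomputes its quantity from scratch — generating
trials, running the pipeline, fitting models — so the same code backs both
the test suite and the reproducibility script.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import clusterpipe as cp
from . import groupstats as gs
from . import metrics as mx
from . import pipeline, synthgait

METRICS = ("sla", "dlsta", "slsta", "knee_flex_deg", "tla_deg", "circumduction_m", "hip_hike_deg")


# ---------------------------------------------------------------------------
# event detection


def event_detection_accuracy(
    n_trials: int = 100, seed: int = 0, n_strides: int = 8
) -> dict:
    """Fraction of ground-truth gait events detected within one frame on
    noiseless trials spanning the 0.2-1.4 m/s belt-speed range."""
    from . import events as ev

    rng = np.random.default_rng(seed)
    hits = total = 0
    errors = []
    for i in range(n_trials):
        speed = 0.2 + 1.2 * i / max(1, n_trials - 1)  # sweep the belt range
        params = synthgait.sample_params(rng, belt_speed=speed, noise_sd=0.0, n_strides=n_strides)
        trial, truth = synthgait.generate_trial(params)
        for limb in ("left", "right"):
            det_fs, det_to = ev.detect_events(trial, limb)
            for kind, detected in (("foot_strike", det_fs), ("toe_off", det_to)):
                for tf in truth.event_frames(limb, kind, trial.sampling_rate):
                    err = int(np.min(np.abs(detected - tf)))
                    errors.append(err)
                    hits += err <= 1
                    total += 1
    return {
        "fraction_within_1_frame": hits / total,
        "n_events": total,
        "median_abs_error_frames": float(np.median(errors)),
    }


# ---------------------------------------------------------------------------
# metric recovery


def metric_recovery_sweep(
    n_draws: int = 50, seed: int = 0, noise_sd: float = 0.0, n_strides: int = 12
) -> pd.DataFrame:
    """Measured-vs-true regression across random parameter draws.

    Returns one row per metric: slope and R^2 of the regression of measured
    on true values, plus the maximum absolute error.  The low-pass filter is
    applied only when the draws carry marker noise (it exists to reject
    noise; on noiseless data it only rounds the stance-swing corners).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_draws):
        params = synthgait.sample_params(
            rng, noise_sd=noise_sd, n_strides=n_strides, grid_aligned=True
        )
        trial, truth = synthgait.generate_trial(params)
        rec = pipeline.process_trial(trial, apply_filter=noise_sd > 0)
        row = {f"true_{k}": truth.true_metrics[k] for k in METRICS}
        row.update({f"meas_{k}": getattr(rec, k) for k in METRICS})
        rows.append(row)
    df = pd.DataFrame(rows)
    out = []
    for k in METRICS:
        t, m = df[f"true_{k}"].to_numpy(), df[f"meas_{k}"].to_numpy(float)
        slope, intercept = np.polyfit(t, m, 1)
        resid = m - (slope * t + intercept)
        r2 = 1.0 - resid.var() / m.var()
        out.append(
            dict(metric=k, slope=slope, r2=r2, max_abs_error=float(np.max(np.abs(m - t))))
        )
    return pd.DataFrame(out).set_index("metric")


# ---------------------------------------------------------------------------
# mixed-model calibration


def simulate_lmm_table(
    seed,
    n_participants=50,
    n_speeds=4,
    beta=(0.1, 0.08, -0.08, -0.05),
    tau=0.05,
    sigma=0.03,
    metric="sla",
) -> pd.DataFrame:
    """Observations drawn exactly from the random-intercept model."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_participants):
        g = 1.0 if i < n_participants // 2 else 0.0
        u = rng.normal(0, tau)
        base = rng.uniform(0.4, 1.0)
        for k in range(n_speeds):
            s = base + 0.15 * k
            y = beta[0] + beta[1] * g + beta[2] * s + beta[3] * g * s + u + rng.normal(0, sigma)
            rows.append(
                dict(
                    participant_id=f"P{i:03d}",
                    group="stroke" if g else "neurotypical",
                    speed_mps=s,
                    **{metric: y},
                )
            )
    return pd.DataFrame(rows)


def lmm_coverage(
    n_reps: int = 100,
    seed: int = 0,
    beta: tuple = (0.1, 0.08, -0.08, -0.05),
    estimator: str = "classical",
) -> dict:
    """Fraction of replicates in which each coefficient lies within 2
    estimated SEs of its true value (speed grand-mean-centered truth)."""
    root = np.random.SeedSequence(seed)
    hits = np.zeros(4)
    for rep, child in enumerate(root.spawn(n_reps)):
        table = simulate_lmm_table(child)
        sbar = table.speed_mps.mean()
        truth = np.array(
            [beta[0] + beta[2] * sbar, beta[1] + beta[3] * sbar, beta[2], beta[3]]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = gs.fit_metric_model(table, "sla", estimator=estimator)
        hits += np.abs(fit.coef - truth) <= 2 * fit.se
    return {
        "per_coefficient": dict(zip(gs.TERMS, (hits / n_reps).tolist())),
        "pooled_rate": float(hits.sum() / (4 * n_reps)),
        "n_reps": n_reps,
    }


def lmm_type1_error(n_reps: int = 160, seed: int = 0) -> dict:
    """Rejection rate at alpha = 0.05 for the group and interaction
    coefficients under a null with no group effect."""
    root = np.random.SeedSequence(seed + 1)
    rejections = total = 0
    for child in root.spawn(n_reps):
        table = simulate_lmm_table(child, beta=(0.1, 0.0, -0.08, 0.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = gs.fit_metric_model(table, "sla", estimator="classical")
        for term in ("group", "group_x_speed"):
            rejections += fit.p_values[fit.terms.index(term)] < gs.ALPHA
            total += 1
    return {"type1_rate": rejections / total, "n_tests": total}


def robust_outlier_displacement(n_reps: int = 24, seed: int = 0) -> dict:
    """Systematic displacement of the robust fit caused by one 10-sigma
    outlier, as a fraction of the classical fit's displacement.

    Per replicate, the displacement vectors (with vs without the outlier)
    are compared by projecting the robust displacement onto the classical
    displacement direction; the replicate average estimates the estimator's
    systematic influence (single replicates carry configuration-specific
    weight-churn noise of either sign — canonical Huber M-regression shows
    the same spread).
    """
    root = np.random.SeedSequence(seed + 2)
    ratios = []
    for rep, child in enumerate(root.spawn(n_reps)):
        rng = np.random.default_rng(child.spawn(1)[0])
        table = simulate_lmm_table(child)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            c0 = gs.fit_metric_model(table, "sla", estimator="classical")
            r0 = gs.fit_metric_model(table, "sla", estimator="robust")
            spiked = table.copy()
            idx = spiked.index[rng.integers(len(spiked))]
            spiked.loc[idx, "sla"] += 10 * np.sqrt(c0.sigma2)
            c1 = gs.fit_metric_model(spiked, "sla", estimator="classical")
            r1 = gs.fit_metric_model(spiked, "sla", estimator="robust")
        dc, dr = c1.coef - c0.coef, r1.coef - r0.coef
        ratios.append(float(dr @ dc / (dc @ dc)))
    return {
        "mean_displacement_ratio": float(np.mean(ratios)),
        "ratios": ratios,
        "n_reps": n_reps,
    }


def robust_limit_matches_classical(seed: int = 0) -> float:
    """Max coefficient difference between the robust fit with infinite
    tuning constant and the classical fit (should vanish)."""
    table = simulate_lmm_table(np.random.SeedSequence(seed + 3))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        classical = gs.fit_metric_model(table, "sla", estimator="classical")
        robust = gs.fit_metric_model(table, "sla", estimator="robust", tuning_constant=np.inf)
    return float(np.max(np.abs(robust.coef - classical.coef)))


# ---------------------------------------------------------------------------
# clustering pipeline


def cluster_ari_sweep(
    n_seeds: int = 20,
    seed: int = 0,
    n_per_group: int = 10,
    separation_sd: float = 3.0,
    n_strides: int = 8,
) -> dict:
    """Cluster recovery over replicate cohorts at >= ``separation_sd``
    pooled-SD group separation: fraction of cohorts where the silhouette
    method selects k = 2, ARI against the true groups, and the WSS+BSS = TSS
    decomposition residual (self-selected condition, full marker pipeline)."""
    profiles = synthgait.well_separated_profiles(separation_sd)
    aris, k_is_2, tss_resid = [], 0, []
    for s in range(n_seeds):
        cohort = synthgait.generate_cohort(
            n_per_group, profiles, seed=seed * 10_000 + s, n_strides=n_strides, n_speeds=2
        )
        table, _ = pipeline.cohort_metrics_table(cohort)
        wide = pipeline.condition_table(table, "self_selected")
        complete = wide[list(cp.METRIC_COLUMNS)].dropna()
        scaled, _, _ = cp.zscore_scale(complete)
        chosen_k, _ = cp.select_k_silhouette(scaled, seed=seed + s)
        labels, _ = cp.kmeans_fit(scaled, chosen_k, seed=seed + s)
        _, wss, bss = cp.cluster_ss(scaled, labels)
        tss = float(((scaled - scaled.mean()) ** 2).sum().sum())
        tss_resid.append(abs(wss + bss - tss))
        truth = wide.loc[complete.index, "group"].eq("stroke").astype(int)
        k_is_2 += chosen_k == 2
        aris.append(float(adjusted_rand_score(truth, labels)))
    return {
        "mean_ari": float(np.mean(aris)),
        "min_ari": float(np.min(aris)),
        "fraction_k_equals_2": k_is_2 / n_seeds,
        "max_tss_residual": float(np.max(tss_resid)),
        "n_seeds": n_seeds,
    }


def condition_separation_experiment(
    seed: int = 0,
    n_per_group: int = 14,
    separation_sd: float = 3.0,
    n_trees: int = 300,
    n_strides: int = 12,
) -> dict:
    """Full two-condition analysis on a cohort whose group separation grows
    with belt speed: per-condition k, cluster distance (BSS), the WSS+BSS
    decomposition, variable importance, and the cross-condition report."""
    profiles = synthgait.well_separated_profiles(separation_sd, divergent_speed=True)
    cohort = synthgait.generate_cohort(n_per_group, profiles, seed=seed, n_strides=n_strides)
    table, metas = pipeline.cohort_metrics_table(cohort)
    out: dict = {"conditions": {}}
    results = {}
    for cond in ("self_selected", "fast"):
        wide = pipeline.condition_table(table, cond)
        res = cp.cluster_condition(wide, cond, seed=seed, n_trees=n_trees)
        truth = wide.loc[res.participant_ids, "group"].eq("stroke").astype(int)
        tss = float(((res.scaled - res.scaled.mean()) ** 2).sum().sum())
        out["conditions"][cond] = {
            "chosen_k": res.chosen_k,
            "ari": float(adjusted_rand_score(truth, res.labels)),
            "tss_residual": abs(res.total_wss + res.bss - tss),
            "bss": res.bss,
            "total_wss": res.total_wss,
            "top_metric": res.importance.index[0],
        }
        results[cond] = res
    report = cp.compare_conditions(results["self_selected"], results["fast"])
    out["n_switchers"] = report["n_switchers"]
    out["bss_change"] = report["bss_change"]
    return out


def importance_probe(n_seeds: int = 20, seed: int = 0, n: int = 120, n_trees: int = 500) -> dict:
    """Single informative feature vs six pure-noise features: the informative
    one must rank first and the noise importances stay near zero."""
    root = np.random.SeedSequence(seed + 4)
    first, noise_max = 0, []
    for child in root.spawn(n_seeds):
        rng = np.random.default_rng(child)
        X = rng.normal(size=(n, 7))
        labels = (X[:, 0] > 0).astype(int)
        imp = cp.rf_importance(
            pd.DataFrame(X, columns=[f"m{j}" for j in range(7)]),
            labels,
            n_trees=n_trees,
            seed=int(rng.integers(2**31 - 1)),
        )
        first += imp.index[0] == "m0"
        noise_max.append(float(np.max(np.abs(imp.drop("m0")))))
    return {
        "informative_ranked_first_fraction": first / n_seeds,
        "max_abs_noise_importance": float(np.max(noise_max)),
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# inclusion filter


def inclusion_filter_check() -> dict:
    """The bundled 28-row post-stroke demographics table passes the
    slowest-speed > 0.20 m/s filter in full; a constructed participant at
    exactly 0.20 m/s is excluded (strict inequality)."""
    from . import markerio as mio

    metas = mio.read_metadata(mio.stroke_table_path())
    included, excluded = mx.apply_inclusion_filter(metas)
    boundary = mio.ParticipantMeta(
        "BOUNDARY", "stroke", "left", 60.0, [0.20, 0.30, 0.40], le_fugl_meyer=20
    )
    inc2, exc2 = mx.apply_inclusion_filter(metas + [boundary])
    return {
        "n_listed": len(metas),
        "n_included": len(included),
        "n_excluded": len(excluded),
        "boundary_participant_excluded": any(m.participant_id == "BOUNDARY" for m, _ in exc2),
    }
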