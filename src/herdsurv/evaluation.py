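"""Accuracy protocol: repeated 3-fold CV, time-dependent AUC, prediction
error, significance against the random-guessing nulls, and Levene's test.

Six scenarios are evaluated: observation windows v in {60, 150, 240} DIM
crossed with the two horizons t1 (second calving) and t2 (third calving).
Cows are randomly partitioned into 3 near-equal folds; the model is fitted
on two folds and predicts the third; the 3-fold rotation is repeated 3
times, giving 9 metric values per scenario.  Only test cows that survived
at least 240 DIM (the longest observation window) enter the test sets.

Metrics, with pi_i = pi_i(t_j | v):

* PE — censoring-weighted expected squared prediction error.  Cows known
  alive at t_j contribute (1 - pi_i)^2; cows culled in the window
  contribute pi_i^2; a cow censored at T_i inside the window contributes
  the mixture  pi_i(t_j|T_i) (1 - pi_i)^2 + (1 - pi_i(t_j|T_i)) pi_i^2,
  weighting the two outcomes by the model's own conditional survival
  probability beyond the censoring time.  With no censoring in the window
  this reduces to the ordinary Brier score, so a constant prediction of
  0.5 scores exactly 0.25 (the random-guessing null).
* AUC — concordance over comparable pairs: cow i with an observed event in
  (v, t_j] versus cow j known alive at t_j, counting pairs with
  pi_i < pi_j (ties 1/2).  Cows censored inside the window join no pair.
  Independent scores give 0.5 in expectation; no events in the window
  makes the metric non-estimable (returned missing, not zero).
* Significance — mean over the m <= 9 non-missing CV values against the
  null (0.50 for AUC, above; 0.25 for PE, below) with a t-based CI,
  mean +/- t_{0.975, m-1} * SD / sqrt(m).
* Levene's W across herds per scenario (classic form, absolute deviations
  from group means) checks variance homogeneity of the CV metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import OUTCOME_KINDS, HerdDataset, MCMCConfig, PipelineConfig, logger
from .joint_model import build_design, fit_mcmc
from .prediction import predict_survival
from .preprocessing import categorize_afc, compute_herd_stats
from .splines import make_knots

__all__ = [
    "FoldMetrics",
    "EvaluationResult",
    "prediction_error",
    "time_dependent_auc",
    "repeated_kfold_cv",
    "summarize_metrics",
    "significance_ci",
    "levene_test",
]


@dataclass
class FoldMetrics:
    """Metrics for one (scenario, fold, repeat)."""

    v: int
    horizon: str                       # "t1" or "t2"
    fold: int
    repeat: int
    auc: float | None
    pe: float | None
    n_test: int
    n_events_in_horizon: int

    def __post_init__(self):
        no_controls = self.n_test > 0 and self.n_test == self.n_events_in_horizon
        if self.auc is None and self.n_events_in_horizon > 0 and not no_controls:
            raise ValueError("AUC may be missing only when the window has no events")


@dataclass
class EvaluationResult:
    """Per-scenario aggregation over the 9 CV runs."""

    summary: pd.DataFrame              # one row per (v, horizon)
    fold_metrics: pd.DataFrame         # raw per-fold values


def prediction_error(df: pd.DataFrame, t_j: float) -> float:
    """Censoring-weighted expected squared prediction error at horizon t_j.

    ``df`` needs columns T, event, pi (= pi(t_j|v)) and, for cows censored
    inside the window, pi_cond (= pi(t_j|T_i)).
    """
    if len(df) == 0:
        raise ValueError("empty test set")
    T = df["T"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=int)
    pi = df["pi"].to_numpy(dtype=float)
    # a cow censored exactly at t_j is known alive at t_j
    alive = (T > t_j) | ((event == 0) & (T >= t_j))
    culled = (event == 1) & (T <= t_j)
    censored = (event == 0) & (T < t_j)
    contrib = np.where(alive, (1.0 - pi) ** 2, 0.0)
    contrib = np.where(culled, pi**2, contrib)
    if censored.any():
        pc = df["pi_cond"].to_numpy(dtype=float)
        if np.isnan(pc[censored]).any():
            raise ValueError("censored-in-window cows need pi_cond = pi(t_j | T_i)")
        mix = pc * (1.0 - pi) ** 2 + (1.0 - pc) * pi**2
        contrib = np.where(censored, mix, contrib)
    return float(contrib.mean())


def time_dependent_auc(df: pd.DataFrame, v: float, t_j: float) -> float | None:
    """Comparable-pairs concordance at horizon t_j; None when non-estimable.

    Events: observed cullings in (v, t_j].  Survivors: cows known alive at
    t_j (T > t_j, censored or not).  Censored inside the window: excluded.
    """
    T = df["T"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=int)
    pi = df["pi"].to_numpy(dtype=float)
    cases = (event == 1) & (T > v) & (T <= t_j)
    controls = (T > t_j) | ((event == 0) & (T >= t_j))
    if cases.sum() == 0 or controls.sum() == 0:
        return None
    pe_, ps = pi[cases][:, None], pi[controls][None, :]
    conc = (pe_ < ps).sum() + 0.5 * (pe_ == ps).sum()
    return float(conc / (cases.sum() * controls.sum()))


def significance_ci(values, null: float, direction: str):
    """t-based 95% CI over the non-missing CV values and a one-sided
    significance flag: 'above' tests metric > null, 'below' metric < null.

    Returns (ci_low, ci_high, significant); significant is None when fewer
    than two values are available (undetermined).
    """
    vals = np.array([v for v in values if v is not None and np.isfinite(v)], dtype=float)
    m = vals.size
    if m < 2:
        return (np.nan, np.nan, None)
    mean = vals.mean()
    se = vals.std(ddof=1) / np.sqrt(m)
    tq = stats.t.ppf(0.975, df=m - 1)
    lo, hi = mean - tq * se, mean + tq * se
    significant = lo > null if direction == "above" else hi < null
    return (float(lo), float(hi), bool(significant))


def levene_test(groups: dict):
    """Classic Levene W (absolute deviations from group means) across herds.

    ``groups`` maps herd label -> iterable of metric values; requires at
    least two groups with >= 2 values each.
    """
    arrays = []
    for label, vals in groups.items():
        arr = np.array([v for v in vals if v is not None and np.isfinite(v)], dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {label!r} has fewer than 2 values")
        arrays.append(arr)
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if all(np.all(a == a.mean()) for a in arrays):
        return 0.0, 1.0  # no within-group dispersion anywhere
    W, p = stats.levene(*arrays, center="mean")
    return float(W), float(p)


# ----------------------------------------------------------------------
# cross-validation
# ----------------------------------------------------------------------

def _partition(cow_ids, folds, rng) -> list[np.ndarray]:
    ids = np.array(cow_ids)
    perm = rng.permutation(ids.size)
    return [np.sort(perm[f::folds]) for f in range(folds)]


def _prepare_fold_training(dataset: HerdDataset, train_ids):
    """Training-fold dataset with AFC categories and spline knots recomputed
    on the training cows only (test cows never influence either)."""
    tr = dataset.copy()
    keep = tr.cows["cow_id"].isin(train_ids)
    tr.cows = tr.cows.loc[keep].reset_index(drop=True)
    tr.sensor = tr.sensor.loc[tr.sensor["cow_id"].isin(train_ids)].reset_index(drop=True)
    tr.survival = tr.survival.loc[tr.survival["cow_id"].isin(train_ids)].reset_index(drop=True)
    quart = compute_herd_stats(tr)
    tr.cows["afc_cat"] = [categorize_afc(a, quart) for a in tr.cows["afc_days"]]
    specs = {k: make_knots(tr.sensor["dim"].to_numpy(), k) for k in OUTCOME_KINDS}
    return tr, specs, quart


def repeated_kfold_cv(
    dataset: HerdDataset,
    config: PipelineConfig | None = None,
) -> EvaluationResult:
    """Repeated k-fold cross-validation of the full pipeline on one herd.

    ``dataset`` must be preprocessed (survival attached).  Horizons come
    from the dataset (or config override).  Returns per-fold metrics for
    every scenario and the per-scenario summary with significance flags.
    """
    config = config or PipelineConfig()
    if dataset.survival is None:
        raise ValueError("dataset must be preprocessed before cross-validation")
    if dataset.n_cows < 30:
        raise ValueError("need at least 30 cows for repeated k-fold CV")
    t1 = config.t1 if config.t1 is not None else dataset.t1
    t2 = config.t2 if config.t2 is not None else dataset.t2
    if t1 is None or t2 is None:
        raise ValueError("prediction horizons t1/t2 are not set")
    horizons = {"t1": float(t1), "t2": float(t2)}

    surv_all = dataset.survival.set_index("cow_id")
    part_rng = np.random.default_rng(config.partition_seed)
    mcmc_seed_rng = np.random.default_rng(config.mcmc_seed)
    rows = []
    for rep in range(config.repeats):
        folds = _partition(list(dataset.cows["cow_id"]), config.folds, part_rng)
        for fi in range(config.folds):
            test_ids = np.array(dataset.cows["cow_id"])[folds[fi]]
            train_ids = np.array(dataset.cows["cow_id"])[
                np.concatenate([folds[j] for j in range(config.folds) if j != fi])
            ]
            tr, specs, quart = _prepare_fold_training(dataset, set(train_ids))
            tr.t1, tr.t2 = int(t1), int(t2)
            design = build_design(
                tr, specs, association=config.association,
                n_baseline_intervals=config.mcmc.baseline_intervals,
                obs_thin=config.obs_thin, afc_quartiles=quart,
            )
            fit = fit_mcmc(
                design, config.mcmc, seed=int(mcmc_seed_rng.integers(2**31 - 1))
            )
            # test cows must have survived the longest observation window
            elig = [
                c for c in test_ids if surv_all.loc[c, "T"] >= config.min_test_dim
            ]
            preds = _predict_fold(dataset, fit, elig, config, horizons)
            for v in config.v_list:
                for hname, t_j in horizons.items():
                    dfp = preds[v]
                    n_ev = int(
                        ((dfp["event"] == 1) & (dfp["T"] > v) & (dfp["T"] <= t_j)).sum()
                    )
                    sub = dfp.assign(pi=dfp[f"pi_{hname}"], pi_cond=dfp[f"pi_cond_{hname}"])
                    auc = time_dependent_auc(sub, v, t_j) if len(sub) else None
                    pe = prediction_error(sub, t_j) if len(sub) else None
                    rows.append(
                        FoldMetrics(
                            v=v, horizon=hname, fold=fi, repeat=rep, auc=auc, pe=pe,
                            n_test=len(sub), n_events_in_horizon=n_ev,
                        )
                    )
            logger.info("CV repeat %d fold %d done (%d test cows)", rep, fi, len(elig))
    fm = pd.DataFrame([vars(r) for r in rows])
    return EvaluationResult(summary=summarize_metrics(fm), fold_metrics=fm)


def _predict_fold(dataset, fit, test_ids, config, horizons) -> dict:
    """Per-window prediction table for the test cows of one fold."""
    surv = dataset.survival.set_index("cow_id")
    sensor_by_cow = dict(tuple(dataset.sensor.groupby("cow_id")))
    cows = dataset.cows.set_index("cow_id")
    out = {}
    for v in config.v_list:
        recs = []
        for c in test_ids:
            T, event = float(surv.loc[c, "T"]), int(surv.loc[c, "event"])
            u_extra = [T] if (event == 0 and T <= max(horizons.values())) else []
            u_grid = np.unique([float(v)] + list(horizons.values()) + u_extra)
            row = cows.loc[c]
            row = pd.concat([row, pd.Series({"cow_id": c})])
            pred = predict_survival(
                fit, sensor_by_cow[c], row, v=float(v), u_grid=u_grid,
                n_draws=config.n_draws, seed=config.partition_seed, keep_draws=True,
            )
            rec = {"cow_id": c, "T": T, "event": event}
            for hname, t_j in horizons.items():
                rec[f"pi_{hname}"] = pred.at(t_j)
                if u_extra and T < t_j:
                    # conditional survival beyond the censoring time,
                    # averaged over draws: E[exp(-(H(t_j) - H(T_i)))]
                    jT = int(np.flatnonzero(np.isclose(pred.u_grid, T))[0])
                    jU = int(np.flatnonzero(np.isclose(pred.u_grid, t_j))[0])
                    with np.errstate(divide="ignore", invalid="ignore"):
                        ratio = pred.draws[:, jU] / pred.draws[:, jT]
                    rec[f"pi_cond_{hname}"] = float(np.nanmean(np.clip(ratio, 0, 1)))
                else:
                    rec[f"pi_cond_{hname}"] = np.nan
            recs.append(rec)
        out[v] = pd.DataFrame(
            recs,
            columns=["cow_id", "T", "event"]
            + [f"pi_{h}" for h in horizons]
            + [f"pi_cond_{h}" for h in horizons],
        )
    return out


def summarize_metrics(fold_metrics: pd.DataFrame) -> pd.DataFrame:
    """Scenario-level means/SDs, 95% CIs and significance flags
    (AUC above 0.50, PE below 0.25)."""
    rows = []
    for (v, hname), g in fold_metrics.groupby(["v", "horizon"]):
        rec = {"v": v, "horizon": hname, "n_runs": len(g)}
        for metric, null, direction in (("auc", 0.5, "above"), ("pe", 0.25, "below")):
            vals = g[metric].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            rec[f"{metric}_n"] = vals.size
            rec[f"{metric}_mean"] = vals.mean() if vals.size else np.nan
            rec[f"{metric}_sd"] = vals.std(ddof=1) if vals.size > 1 else np.nan
            lo, hi, sig = significance_ci(vals, null, direction)
            rec[f"{metric}_ci_lo"], rec[f"{metric}_ci_hi"] = lo, hi
            rec[f"{metric}_significant"] = sig
        rows.append(rec)
    return pd.DataFrame(rows).sort_values(["v", "horizon"]).reset_index(drop=True)
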