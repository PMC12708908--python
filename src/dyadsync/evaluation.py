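"""Crossvalidation goals, error metrics, secondary analyses and reports.

Protocol:

* Goal 1 (dyad-specific, self ratings): per participant, 10 folds over the
  conversation intervals with an 8:1:1 training/validation/test split; the
  partner's individual features are never used.
* Goal 2 (dyad-nonspecific, self ratings): one fold per dyad with a
  39:1:1 dyad split (780 training rows for a 41-dyad cohort).
* Goal 3 (dyad-nonspecific, observer ratings): one fold per dyad, 33:1:1
  under the study's 35-dyad observer cohort.

Within each fold, every candidate (selector, k, hyper-parameter variant)
of a method is fitted on the training rows only, the candidate with the
lowest validation RMS is applied to the test rows (ties break toward fewer
selected features, then candidate order).  The median-based estimator
(MBE) uses its goal-specific definition.  Per unit (participant or dyad)
the mean-absolute and root-mean-square errors over its 10 test intervals
are reported; RMS >= MA always holds (power-mean inequality) and is
asserted on every summary.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DataError
from .feature_table import FeatureTable, GoalSpec, build_design
from .regression import (ModelConfig, SelectorConfig, fit, mbe_dyad_nonspecific,
                         mbe_dyad_specific)

METHOD_ORDER = ("mbe", "linear", "svm", "mlp")
DEFAULT_KS = (5, 6, 7, 8, 9, 10)
DEFAULT_SELECTORS = ("mrmr", "laplacian")
PENALTY_GRID = (1e-3, 1e-2, 1e-1, 1.0, 10.0)


def interval_error(estimate: float, reference: float) -> float:
    """Signed per-interval estimation error on the 1-9 scale."""
    return float(estimate) - float(reference)


def ma_error(errors: np.ndarray) -> float:
    return float(np.mean(np.abs(errors)))


def rms_error(errors: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.asarray(errors, dtype=float) ** 2)))


# ---------------------------------------------------------------------------
# fold plans

@dataclass(frozen=True)
class Fold:
    train: tuple
    validation: tuple
    test: tuple


@dataclass(frozen=True)
class FoldPlan:
    goal: int
    unit: str  # "interval" (goal 1, within one participant) or "dyad"
    folds: tuple[Fold, ...]

    def __post_init__(self) -> None:
        for f in self.folds:
            overlap = (set(f.test) & set(f.train)) | (set(f.test) & set(f.validation))
            if overlap:
                raise ConfigurationError(f"test units {overlap} leak into "
                                         "training/validation")
            if set(f.train) & set(f.validation):
                raise ConfigurationError("training and validation units overlap")


def plan_intervals(intervals: list[int]) -> FoldPlan:
    """Goal-1 plan: each conversation interval is the test once, the next
    (cyclically) is the validation, the remaining 8 train."""
    n = len(intervals)
    folds = []
    for i, test in enumerate(intervals):
        val = intervals[(i + 1) % n]
        train = tuple(x for x in intervals if x not in (test, val))
        folds.append(Fold(train=train, validation=(val,), test=(test,)))
    return FoldPlan(goal=1, unit="interval", folds=tuple(folds))


def plan_dyads(dyad_ids: list[int], goal: int) -> FoldPlan:
    """Goal-2/3 plan: each dyad is the test once, the next (cyclically) the
    validation, all others train (39:1:1 at 41 dyads, 33:1:1 at 35)."""
    n = len(dyad_ids)
    if n < 3:
        raise ConfigurationError("dyad-nonspecific crossvalidation needs >= 3 dyads")
    folds = []
    for i, test in enumerate(dyad_ids):
        val = dyad_ids[(i + 1) % n]
        train = tuple(d for d in dyad_ids if d not in (test, val))
        folds.append(Fold(train=train, validation=(val,), test=(test,)))
    return FoldPlan(goal=goal, unit="dyad", folds=tuple(folds))


# ---------------------------------------------------------------------------
# candidate grids

def default_candidates(method: str, selectors=DEFAULT_SELECTORS, ks=DEFAULT_KS,
                       linear_penalty_grid=PENALTY_GRID, svm_c_grid=(1.0, 10.0),
                       ) -> list[tuple[ModelConfig, SelectorConfig]]:
    """The validation-selected candidate grid for one method."""
    sel = [SelectorConfig(s, k) for s, k in itertools.product(selectors, ks)]
    if method == "mlp":
        variants = [ModelConfig("mlp")]
    elif method == "linear":
        variants = [ModelConfig("linear", penalty="none")]
        variants += [ModelConfig("linear", penalty=p, alpha=a)
                     for p in ("lasso", "ridge") for a in linear_penalty_grid]
    elif method == "svm":
        variants = [ModelConfig("svm", svm_c=c) for c in svm_c_grid]
    else:
        raise ConfigurationError(f"no candidate grid for method {method!r}")
    return [(m, s) for s in sel for m in variants]


def _seeded(config: ModelConfig, master_seed: int, goal: int, fold: int,
            index: int) -> ModelConfig:
    seed = (master_seed * 1000003 + goal * 10007 + fold * 101 + index) % (2**31)
    return replace(config, seed=seed)


# ---------------------------------------------------------------------------
# summaries

@dataclass
class EvaluationSummary:
    goal: int
    target: str
    estimates: pd.DataFrame  # method, unit, interval_index, estimate, reference
    per_unit: pd.DataFrame  # method, unit, ma, rms, train_ma, train_rms
    fold_choices: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        bad = self.per_unit[self.per_unit.rms < self.per_unit.ma - 1e-9]
        assert bad.empty, "RMS >= MA violated (power-mean inequality)"

    def aggregate(self) -> pd.DataFrame:
        """Mean/median MA and RMS per method."""
        return (self.per_unit.groupby("method")[["ma", "rms", "train_ma",
                                                 "train_rms"]]
                .agg(["mean", "median"]))

    def mean_rms(self, method: str) -> float:
        return float(self.per_unit.loc[self.per_unit.method == method, "rms"].mean())

    def mean_ma(self, method: str) -> float:
        return float(self.per_unit.loc[self.per_unit.method == method, "ma"].mean())


def _per_unit_errors(estimates: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (method, unit), g in estimates.groupby(["method", "unit"]):
        err = g.estimate.to_numpy() - g.reference.to_numpy()
        rows.append({"method": method, "unit": unit, "ma": ma_error(err),
                     "rms": rms_error(err),
                     "train_ma": float(g.train_ma.mean()),
                     "train_rms": float(g.train_rms.mean())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# goal runners

def _fit_candidates(candidates, X_tr, y_tr, X_val, y_val, master_seed, goal,
                    fold_index):
    """Fit every candidate, return the validation-RMS winner.

    Tie-break: lower validation RMS, then fewer selected features, then
    candidate order.
    """
    best = None
    for idx, (mconf, sconf) in enumerate(candidates):
        mconf = _seeded(mconf, master_seed, goal, fold_index, idx)
        fitted = fit(mconf, sconf, X_tr, y_tr)
        val_rms = rms_error(fitted.predict(X_val) - np.asarray(y_val))
        key = (round(val_rms, 12), len(fitted.selected_features), idx)
        if best is None or key < best[0]:
            best = (key, fitted, val_rms)
    return best[1], best[0][0], best[2]


def run_goal(table: FeatureTable, goal: GoalSpec, target: str,
             methods=METHOD_ORDER, candidates: dict | None = None,
             selectors=DEFAULT_SELECTORS, ks=DEFAULT_KS, master_seed: int = 0,
             dyad_ids: list[int] | None = None,
             drop_features: list[str] | None = None) -> EvaluationSummary:
    """Run one goal's full crossvalidation for one target.

    ``candidates`` optionally maps method name -> list of
    (ModelConfig, SelectorConfig) pairs, overriding the default grid.
    ``dyad_ids`` restricts the cohort (e.g. the 35-dyad observer subset);
    ``drop_features`` removes named columns from the design (ablations).
    """
    X, y, units = build_design(table, goal, target)
    if drop_features:
        X = X.drop(columns=[c for c in drop_features if c in X.columns])
    if dyad_ids is not None:
        keep = units.dyad_id.isin(dyad_ids).to_numpy()
        X, y, units = X[keep].reset_index(drop=True), \
            y[keep].reset_index(drop=True), units[keep].reset_index(drop=True)
    ml_methods = [m for m in methods if m != "mbe"]
    cand = {m: (candidates or {}).get(m) or default_candidates(m, selectors, ks)
            for m in ml_methods}
    est_rows, choice_rows = [], []

    if goal.goal == 1:
        for (dyad, part), g in units.groupby(["dyad_id", "participant"]):
            unit_key = f"d{dyad}p{part}"
            idx = g.index.to_numpy()
            intervals = units.loc[idx, "interval_index"].tolist()
            plan = plan_intervals(intervals)
            y_unit = y.loc[idx].to_numpy()
            by_interval = dict(zip(intervals, idx))
            for fi, fold in enumerate(plan.folds):
                tr = [by_interval[i] for i in fold.train]
                va = [by_interval[i] for i in fold.validation]
                te = [by_interval[i] for i in fold.test]
                for method in ml_methods:
                    fitted, _, _ = _fit_candidates(
                        cand[method], X.loc[tr], y.loc[tr], X.loc[va], y.loc[va],
                        master_seed, 1, fi)
                    pred = fitted.predict(X.loc[te])
                    for j, row in enumerate(te):
                        est_rows.append({
                            "method": method, "unit": unit_key, "dyad_id": dyad,
                            "interval_index": int(units.loc[row, "interval_index"]),
                            "estimate": float(pred[j]),
                            "reference": float(y.loc[row]),
                            "train_ma": fitted.train_ma,
                            "train_rms": fitted.train_rms})
                    choice_rows.append({"unit": unit_key, "fold": fi,
                                        "method": method,
                                        "selected": fitted.selected_features})
                if "mbe" in methods:
                    pos = intervals.index(fold.test[0])
                    est = mbe_dyad_specific(y_unit, pos)
                    rest = np.delete(y_unit, pos)
                    tr_err = rest - float(np.median(rest))
                    est_rows.append({
                        "method": "mbe", "unit": unit_key, "dyad_id": dyad,
                        "interval_index": fold.test[0], "estimate": est,
                        "reference": float(y_unit[pos]),
                        "train_ma": ma_error(tr_err),
                        "train_rms": rms_error(tr_err)})
    else:
        ids = dyad_ids if dyad_ids is not None else sorted(units.dyad_id.unique())
        plan = plan_dyads(list(ids), goal.goal)
        for fi, fold in enumerate(plan.folds):
            tr = units.dyad_id.isin(fold.train).to_numpy()
            va = units.dyad_id.isin(fold.validation).to_numpy()
            te = units.dyad_id.isin(fold.test).to_numpy()
            for method in ml_methods:
                fitted, _, _ = _fit_candidates(
                    cand[method], X[tr], y[tr].to_numpy(), X[va], y[va].to_numpy(),
                    master_seed, goal.goal, fi)
                pred = fitted.predict(X[te])
                for j, (_, urow) in enumerate(units[te].iterrows()):
                    unit_key = (f"d{urow.dyad_id}p{urow.participant}"
                                if goal.goal == 2 else f"d{urow.dyad_id}")
                    est_rows.append({
                        "method": method, "unit": unit_key,
                        "dyad_id": int(urow.dyad_id),
                        "interval_index": int(urow.interval_index),
                        "estimate": float(pred[j]),
                        "reference": float(y[te].to_numpy()[j]),
                        "train_ma": fitted.train_ma, "train_rms": fitted.train_rms})
                choice_rows.append({"unit": f"d{fold.test[0]}", "fold": fi,
                                    "method": method,
                                    "selected": fitted.selected_features})
            if "mbe" in methods:
                # pooled per-interval ratings of all other dyads
                pool = y[~te].to_numpy()
                est = mbe_dyad_nonspecific(pool)
                tr_err = pool - est
                for j, (_, urow) in enumerate(units[te].iterrows()):
                    unit_key = (f"d{urow.dyad_id}p{urow.participant}"
                                if goal.goal == 2 else f"d{urow.dyad_id}")
                    est_rows.append({
                        "method": "mbe", "unit": unit_key,
                        "dyad_id": int(urow.dyad_id),
                        "interval_index": int(urow.interval_index),
                        "estimate": est, "reference": float(y[te].to_numpy()[j]),
                        "train_ma": ma_error(tr_err),
                        "train_rms": rms_error(tr_err)})

    estimates = pd.DataFrame(est_rows)
    return EvaluationSummary(goal=goal.goal, target=target, estimates=estimates,
                             per_unit=_per_unit_errors(estimates),
                             fold_choices=pd.DataFrame(choice_rows))


# ---------------------------------------------------------------------------
# statistical comparisons

def _paired_test(a: np.ndarray, b: np.ndarray, alpha: float = 0.05,
                 ) -> tuple[str, float]:
    """Paired t-test when Shapiro-Wilk accepts normality of the differences
    at alpha, Wilcoxon signed-rank otherwise."""
    diff = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if np.allclose(diff, 0):
        return "t", 1.0
    if np.ptp(diff) == 0:  # constant non-zero difference: deterministic effect
        return "t", 0.0
    normal = stats.shapiro(diff).pvalue >= alpha
    if normal:
        return "t", float(stats.ttest_rel(a, b).pvalue)
    return "wilcoxon", float(stats.wilcoxon(a, b).pvalue)


def compare_methods(per_unit: pd.DataFrame, metric: str = "rms") -> dict:
    """Repeated-measures ANOVA across methods plus Holm-Sidak-adjusted
    pairwise paired comparisons, with effect directions."""
    wide = per_unit.pivot(index="unit", columns="method", values=metric)
    if wide.isna().any().any():
        raise DataError("unmatched units across methods")
    methods = [m for m in METHOD_ORDER if m in wide.columns] + \
              [m for m in wide.columns if m not in METHOD_ORDER]
    if len(methods) < 2:
        raise DataError("need at least 2 methods to compare")
    long = wide[methods].reset_index().melt(id_vars="unit", var_name="method",
                                            value_name=metric)
    if np.allclose(long.groupby("unit")[metric].std(ddof=0), 0):
        omnibus_p = 1.0  # identical error vectors: nothing to distinguish
    else:
        aov = AnovaRM(long, depvar=metric, subject="unit",
                      within=["method"]).fit()
        omnibus_p = float(aov.anova_table["Pr > F"].iloc[0])
    pairs, raw_p, kinds = [], [], []
    for m1, m2 in itertools.combinations(methods, 2):
        kind, p = _paired_test(wide[m1].to_numpy(), wide[m2].to_numpy())
        pairs.append((m1, m2))
        raw_p.append(p)
        kinds.append(kind)
    adj = multipletests(raw_p, method="holm-sidak")[1]
    pairwise = pd.DataFrame({
        "method_a": [p[0] for p in pairs], "method_b": [p[1] for p in pairs],
        "test": kinds, "p_raw": raw_p, "p_adj": adj,
        "direction": [f"{a} {'<' if wide[a].mean() < wide[b].mean() else '>='} {b}"
                      for a, b in pairs]})
    return {"metric": metric, "omnibus_p": omnibus_p, "pairwise": pairwise}


# ---------------------------------------------------------------------------
# secondary analyses

def _paired_summary(with_df: pd.DataFrame, without_df: pd.DataFrame,
                    metric: str) -> dict:
    merged = with_df.merge(without_df, on="unit", suffixes=("_with", "_without"))
    kind, p = _paired_test(merged[f"{metric}_with"].to_numpy(),
                           merged[f"{metric}_without"].to_numpy())
    return {"metric": metric, "test": kind, "p": p,
            "mean_with": float(merged[f"{metric}_with"].mean()),
            "mean_without": float(merged[f"{metric}_without"].mean()),
            "per_unit": merged}


def ablate_synchrony(table: FeatureTable, goal: GoalSpec, target: str,
                     master_seed: int = 0, **run_kwargs) -> dict:
    """MLP with vs. without the 36 synchrony features; paired comparison."""
    sync_cols = [n for n, role in table.feature_roles.items() if role == "sync"]
    with_sync = run_goal(table, goal, target, methods=("mlp",),
                         master_seed=master_seed, **run_kwargs)
    without = run_goal(table, goal, target, methods=("mlp",),
                       master_seed=master_seed, drop_features=sync_cols,
                       **run_kwargs)
    out = {"with": with_sync, "without": without, "removed": sync_cols}
    for metric in ("ma", "rms"):
        out[metric] = _paired_summary(with_sync.per_unit, without.per_unit, metric)
    return out


def augment_characteristics(table: FeatureTable, goal: GoalSpec, target: str,
                            master_seed: int = 0, **run_kwargs) -> dict:
    """Dyad-nonspecific runs with vs. without participant characteristics."""
    if goal.goal == 1:
        raise ConfigurationError(
            "characteristics augmentation applies to dyad-nonspecific goals only")
    base = run_goal(table, goal, target, methods=("mlp",),
                    master_seed=master_seed, **run_kwargs)
    aug_goal = GoalSpec(goal.goal, goal.rater, include_characteristics=True)
    augmented = run_goal(table, aug_goal, target, methods=("mlp",),
                         master_seed=master_seed, **run_kwargs)
    out = {"with": augmented, "without": base}
    for metric in ("ma", "rms"):
        out[metric] = _paired_summary(augmented.per_unit, base.per_unit, metric)
    return out


def top_features(table: FeatureTable, goal: GoalSpec, target: str,
                 k: int = 5) -> list[str]:
    """Top-k features by Laplacian score on the full (unsplit) design."""
    from .regression import laplacian_rank

    X, _, _ = build_design(table, goal, target)
    X = X.fillna(X.median(numeric_only=True))
    return laplacian_rank(X, k)


# ---------------------------------------------------------------------------
# descriptive rating statistics

def describe_ratings(table: FeatureTable) -> dict:
    """Descriptive statistics of the rating streams.

    Per target: pooled mean +- SD of self ratings over all collected
    conversation intervals; mean +- SD of each participant's max-minus-min
    rating; mean +- SD of the per-interval inter-partner absolute
    difference; an extreme-value audit (any 1s/9s, counts of intervals both
    partners rated 9 or both rated 1); observer pooled stats if present.
    """
    conv = list(table.conversation_intervals)
    labels = table.labels[table.labels.interval_index.isin(conv)]
    self_l = labels[labels.rater == "self"]
    obs_l = labels[labels.rater == "observer"]
    out: dict = {"n_dyads": int(labels.dyad_id.nunique()),
                 "n_self_intervals": int(len(self_l) // 2)}
    for target in ("valence", "arousal"):
        vals = self_l[target].to_numpy(dtype=float)
        per_part = self_l.groupby(["dyad_id", "participant"])[target] \
            .agg(lambda v: v.max() - v.min())
        wide = self_l.pivot_table(index=["dyad_id", "interval_index"],
                                  columns="participant", values=target)
        diff = (wide[1] - wide[2]).abs().to_numpy(dtype=float)
        both9 = int(((wide[1] == 9) & (wide[2] == 9)).sum())
        both1 = int(((wide[1] == 1) & (wide[2] == 1)).sum())
        out[target] = {
            "mean": float(vals.mean()), "sd": float(np.std(vals, ddof=1)),
            "range_mean": float(per_part.mean()),
            "range_sd": float(np.std(per_part, ddof=1)),
            "partner_diff_mean": float(diff.mean()),
            "partner_diff_sd": float(np.std(diff, ddof=1)),
            "has_1": bool((vals == 1).any()), "has_9": bool((vals == 9).any()),
            "mutual_9_intervals": both9, "mutual_1_intervals": both1,
        }
        if len(obs_l):
            ov = obs_l[target].to_numpy(dtype=float)
            out[target]["observer_mean"] = float(ov.mean())
            out[target]["observer_sd"] = float(np.std(ov, ddof=1))
    return out
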