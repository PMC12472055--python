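"""Model validation and the univariate screen.

Implements the replicated validation scheme: ten stratified random 70:30
train/test splits; within each training split a leave-one-out
cross-validation (LOOCV) picks the number of PLS components by minimum
balanced error rate (BER, the mean of per-class error rates); test-set
metrics are aggregated as mean +/- SD across replicates, with VIP scores
recorded per replicate. Pareto centering/scaling statistics are always
learned on the training portion only and applied to held-out samples, so
no information leaks across the split.

The univariate screen runs Student's t-test (two groups) or one-way ANOVA
with Tukey HSD post hoc comparisons (more than two groups) per variable,
reports Shapiro-Wilk normality per variable and group, and controls the
false discovery rate across variables with Benjamini-Hochberg step-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import InvariantError
from .features import pareto_apply, pareto_fit, ta_normalise
from .io import FeatureTable
from .models import fit_plsda, predict_plsda, vip_scores

METRIC_NAMES = (
    "accuracy",
    "balanced_accuracy",
    "sensitivity",
    "specificity",
    "precision",
    "f1",
    "ber",
)


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------


@dataclass
class Metrics:
    accuracy: float
    balanced_accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    ber: float

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _binary_metrics(y_true, y_pred, positive) -> Metrics:
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == positive and p == positive)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == positive and p != positive)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t != positive and p == positive)
    tn = sum(1 for t, p in zip(y_true, y_pred) if t != positive and p != positive)
    n = tp + fn + fp + tn
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens > 0 else 0.0
    balanced = (sens + spec) / 2.0
    return Metrics(
        accuracy=(tp + tn) / n,
        balanced_accuracy=balanced,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        f1=f1,
        ber=1.0 - balanced,
    )


def compute_metrics(y_true: Sequence, y_pred: Sequence, positive_class=None) -> Metrics:
    """Confusion-matrix metrics.

    Two classes: ``positive_class`` orients sensitivity/precision
    (defaults to the lexicographically last label, mirroring the usual
    case/control ordering). More than two classes: macro averages of the
    one-vs-rest metrics; BER is the mean per-class error rate.
    """
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise InvariantError("y_true and y_pred must be equal-length and non-empty")
    classes = sorted(set(y_true) | set(y_pred), key=str)
    if len(classes) < 2:
        classes = sorted(set(y_true) | set(y_pred) | {positive_class}, key=str)
    if len(classes) == 2:
        positive = positive_class if positive_class is not None else classes[-1]
        if positive not in classes:
            raise InvariantError(f"positive_class {positive!r} not among labels")
        return _binary_metrics(y_true, y_pred, positive)
    # macro-average over one-vs-rest
    per = [_binary_metrics(y_true, y_pred, c) for c in classes]
    acc = sum(1 for t, p in zip(y_true, y_pred) if t == p) / len(y_true)
    recalls = [m.sensitivity for m in per]
    balanced = float(np.mean(recalls))
    return Metrics(
        accuracy=acc,
        balanced_accuracy=balanced,
        sensitivity=balanced,
        specificity=float(np.mean([m.specificity for m in per])),
        precision=float(np.mean([m.precision for m in per])),
        f1=float(np.mean([m.f1 for m in per])),
        ber=1.0 - balanced,
    )


# --------------------------------------------------------------------------
# LOOCV component selection
# --------------------------------------------------------------------------


def loocv_ber_curve(
    X: np.ndarray,
    y: Sequence,
    max_components: int,
    *,
    scale: str = "pareto",
) -> np.ndarray:
    """Leave-one-out BER for every component count 1..max_components.

    Each fold refits the model (and, with ``scale='pareto'``, relearns the
    centering/scaling statistics) on the remaining samples. Every class
    needs >= 3 samples so each fold retains >= 2 per class, the minimum
    the PLS-DA fit accepts.
    """
    X = np.asarray(X, dtype=float)
    y = list(y)
    n = len(y)
    classes = sorted(set(y), key=str)
    counts = {c: y.count(c) for c in classes}
    too_small = [c for c, k in counts.items() if k < 3]
    if too_small:
        raise InvariantError(
            f"LOOCV needs >= 3 samples per class (folds must keep >= 2); "
            f"too small: {too_small}"
        )
    kmax = min(max_components, n - 2, X.shape[1])
    if kmax < 1:
        raise InvariantError("max_components leaves no valid component count")
    # per-class error counts, per component
    errors = {c: np.zeros(kmax) for c in classes}
    for i in range(n):
        train = [j for j in range(n) if j != i]
        X_tr, y_tr = X[train], [y[j] for j in train]
        if scale == "pareto":
            mean, div = pareto_fit(X_tr)
            X_tr = pareto_apply(X_tr, mean, div)
            x_te = pareto_apply(X[i : i + 1], mean, div)
        else:
            x_te = X[i : i + 1]
        model = fit_plsda(X_tr, y_tr, kmax)
        for k in range(1, kmax + 1):
            sub = _truncate(model, k)
            pred, _ = predict_plsda(sub, x_te)
            if pred[0] != y[i]:
                errors[y[i]][k - 1] += 1
    ber = np.zeros(kmax)
    for k in range(kmax):
        ber[k] = float(np.mean([errors[c][k] / counts[c] for c in classes]))
    return ber


def _truncate(model, k: int):
    """K-truncated view of a fitted PLS-DA model (recomputing the class
    score statistics on the first k components)."""
    from dataclasses import replace as _replace

    T = model.scores[:, :k]
    means = {c: model.class_score_means[c][:k] for c in model.class_labels}
    cov = model.score_covariance[:k, :k]
    return _replace(
        model,
        n_components=k,
        weights=model.weights[:, :k],
        x_loadings=model.x_loadings[:, :k],
        y_loadings=model.y_loadings[:, :k],
        scores=T,
        class_score_means=means,
        score_covariance=cov,
    )


# --------------------------------------------------------------------------
# replicated 70:30 evaluation
# --------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Per-replicate and aggregated classification results."""

    replicates: pd.DataFrame  # one row per replicate: metrics + n_components
    aggregate: pd.DataFrame  # index metric, columns mean/sd
    ber_by_component: np.ndarray  # mean LOOCV BER per candidate K (over replicates)
    vip_by_replicate: np.ndarray  # n_replicates x p
    variable_ids: list
    n_vip_gt_1: list
    seeds: list

    def vip_table(self) -> pd.DataFrame:
        """Mean VIP per variable, sorted descending, flagged at VIP > 1."""
        mean_vip = self.vip_by_replicate.mean(axis=0)
        sd_vip = self.vip_by_replicate.std(axis=0, ddof=1) if len(self.vip_by_replicate) > 1 \
            else np.zeros_like(mean_vip)
        frame = pd.DataFrame(
            {"variable": self.variable_ids, "vip_mean": mean_vip, "vip_sd": sd_vip}
        ).sort_values("vip_mean", ascending=False, kind="mergesort")
        frame["vip_gt_1"] = frame["vip_mean"] > 1.0
        return frame.reset_index(drop=True)


def _stratified_split(y: Sequence, train_fraction: float, rng) -> tuple:
    """Per-class split: ceil-rounded train size, capped so every class
    keeps at least one test sample."""
    train_idx, test_idx = [], []
    classes = sorted(set(y), key=str)
    for c in classes:
        idx = np.asarray([i for i, label in enumerate(y) if label == c])
        perm = rng.permutation(idx)
        n_train = min(len(idx) - 1, max(1, math.ceil(train_fraction * len(idx))))
        train_idx.extend(perm[:n_train].tolist())
        test_idx.extend(perm[n_train:].tolist())
    return sorted(train_idx), sorted(test_idx)


def replicated_evaluation(
    t,
    labels: Sequence,
    n_replicates: int = 10,
    train_fraction: float = 0.7,
    max_components: int = 5,
    seed: int = 0,
    positive_class=None,
) -> ValidationReport:
    """The replicated 70:30 validation scheme.

    ``t`` is a :class:`FeatureTable` in raw or normalised state (raw is
    total-area normalised first; per-sample, so no leakage) or a plain
    matrix on the normalised scale. Per replicate: stratified 70:30
    split, LOOCV on the training split chooses the component count
    (argmin BER, ties to the smaller K), the model is refitted on the
    full training split and scored on the test split. Pareto statistics
    come from the training split only.
    """
    if not 0 < train_fraction < 1:
        raise InvariantError("train_fraction must be in (0, 1)")
    if n_replicates < 1:
        raise InvariantError("n_replicates must be positive")
    if isinstance(t, FeatureTable):
        if t.state == "raw":
            t = ta_normalise(t)
        elif t.state == "scaled":
            raise InvariantError(
                "pass a raw or normalised table; scaling is learned per split"
            )
        X = t.values
        variable_ids = t.bin_ids
    else:
        X = np.asarray(t, dtype=float)
        variable_ids = [f"v{j}" for j in range(X.shape[1])]
    y = list(labels)
    if len(y) != X.shape[0]:
        raise InvariantError("labels length does not match table rows")
    counts = {c: y.count(c) for c in sorted(set(y), key=str)}
    too_small = [c for c, k in counts.items() if k < 4]
    if too_small:
        raise InvariantError(f"classes need >= 4 samples for a 70:30 split: {too_small}")

    ss = np.random.SeedSequence(int(seed))
    child_seeds = (ss.generate_state(n_replicates, dtype=np.uint64) % (2**31)).astype(int)
    rows, vips, curves, n_gt1 = [], [], [], []
    for rep, rep_seed in enumerate(child_seeds):
        rng = np.random.default_rng(int(rep_seed))
        train_idx, test_idx = _stratified_split(y, train_fraction, rng)
        X_tr, y_tr = X[train_idx], [y[i] for i in train_idx]
        X_te, y_te = X[test_idx], [y[i] for i in test_idx]
        kmax = min(max_components, len(train_idx) - 2, X.shape[1])
        ber = loocv_ber_curve(X_tr, y_tr, kmax, scale="pareto")
        k_best = int(np.argmin(ber)) + 1  # argmin takes the first (smallest K) on ties
        mean, div = pareto_fit(X_tr)
        model = fit_plsda(pareto_apply(X_tr, mean, div), y_tr, k_best)
        pred, _ = predict_plsda(model, pareto_apply(X_te, mean, div))
        m = compute_metrics(y_te, pred, positive_class)
        vip = vip_scores(model)
        rows.append({"replicate": rep, "n_components": k_best, **m.as_dict()})
        vips.append(vip)
        padded = np.full(max_components, np.nan)
        padded[: ber.size] = ber
        curves.append(padded)
        n_gt1.append(int(np.sum(vip > 1.0)))
    replicates = pd.DataFrame(rows)
    aggregate = pd.DataFrame(
        {
            "mean": replicates[list(METRIC_NAMES)].mean(),
            "sd": replicates[list(METRIC_NAMES)].std(ddof=1)
            if n_replicates > 1
            else 0.0,
        }
    )
    stacked = np.vstack(curves)
    any_value = ~np.all(np.isnan(stacked), axis=0)
    ber_curve = np.full(max_components, np.nan)
    ber_curve[any_value] = np.nanmean(stacked[:, any_value], axis=0)
    return ValidationReport(
        replicates=replicates,
        aggregate=aggregate,
        ber_by_component=ber_curve,
        vip_by_replicate=np.vstack(vips),
        variable_ids=list(variable_ids),
        n_vip_gt_1=n_gt1,
        seeds=[int(s) for s in child_seeds],
    )


# --------------------------------------------------------------------------
# univariate screen
# --------------------------------------------------------------------------


@dataclass
class UnivariateResult:
    table: pd.DataFrame  # one row per variable
    pairwise: Optional[pd.DataFrame]  # Tukey HSD rows (>2 groups) or None
    alpha: float

    @property
    def significant(self) -> pd.Series:
        return self.table["significant"]


def univariate_screen(t, labels: Sequence, alpha: float = 0.05) -> UnivariateResult:
    """Per-variable group comparison with BH FDR control across variables.

    Two groups: Student's t-test (equal variances). More than two: one-way
    ANOVA, with Tukey HSD pairwise comparisons reported per variable.
    Shapiro-Wilk W and p are reported per variable and group but do not
    gate the parametric tests. ``significant`` means BH-adjusted p < alpha.
    """
    if isinstance(t, FeatureTable):
        if t.state != "normalised":
            raise InvariantError(
                f"univariate_screen expects a normalised table, got {t.state!r}"
            )
        X = t.values
        variable_ids = t.bin_ids
    else:
        X = np.asarray(t, dtype=float)
        variable_ids = [f"v{j}" for j in range(X.shape[1])]
    y = list(labels)
    if len(y) != X.shape[0]:
        raise InvariantError("labels length does not match table rows")
    classes = sorted(set(y), key=str)
    if len(classes) < 2:
        raise InvariantError("need at least 2 groups")
    group_idx = {c: [i for i, label in enumerate(y) if label == c] for c in classes}
    small = [c for c in classes if len(group_idx[c]) < 3]
    if small:
        raise InvariantError(f"groups need >= 3 samples: {small}")

    test_used = "t_test" if len(classes) == 2 else "anova_tukey"
    raw_p, rows, pair_rows = [], [], []
    for j, var in enumerate(variable_ids):
        samples = [X[group_idx[c], j] for c in classes]
        if test_used == "t_test":
            stat, p = stats.ttest_ind(samples[0], samples[1], equal_var=True)
        else:
            stat, p = stats.f_oneway(*samples)
            tukey = stats.tukey_hsd(*samples)
            for a in range(len(classes)):
                for b in range(a + 1, len(classes)):
                    pair_rows.append(
                        {
                            "variable": var,
                            "group_a": classes[a],
                            "group_b": classes[b],
                            "tukey_p": float(tukey.pvalue[a, b]),
                        }
                    )
        p = float(p) if np.isfinite(p) else 1.0
        raw_p.append(p)
        row = {"variable": var, "test_used": test_used, "raw_p": p, "statistic": float(stat)}
        for c in classes:
            vals = X[group_idx[c], j]
            if np.ptp(vals) > 0:
                w, wp = stats.shapiro(vals)
            else:
                w, wp = float("nan"), float("nan")
            row[f"shapiro_W_{c}"] = float(w)
            row[f"shapiro_p_{c}"] = float(wp)
        rows.append(row)

    rejected, adj_p, *_ = multipletests(raw_p, alpha=alpha, method="fdr_bh")
    table = pd.DataFrame(rows)
    table["adjusted_p"] = adj_p
    table["significant"] = table["adjusted_p"] < alpha
    pairwise = pd.DataFrame(pair_rows) if pair_rows else None
    return UnivariateResult(table=table, pairwise=pairwise, alpha=alpha)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_p_(i) = min over j >= i of p_(j) * m / j, capped at 1; exposed for
    audit and as a direct hook for the hand-checkable example.
    """
    _, adj, *_ = multipletests(list(p_values), method="fdr_bh")
    return adj
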