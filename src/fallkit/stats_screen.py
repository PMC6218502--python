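"""Univariate measure screening: two-sample t-tests, ROC analysis and
random-forest permutation-importance ranking."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .core_io import FallStatus, ValidationError

__all__ = [
    "GroupSummary",
    "ScreeningResult",
    "ImportanceRanking",
    "ttest_from_summary",
    "ttest_from_samples",
    "roc_auc",
    "screen",
    "rank_measures",
]


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float

    def validate(self) -> None:
        if self.n < 2:
            raise ValidationError("group summary needs n >= 2")
        if self.sd < 0:
            raise ValidationError("sd must be >= 0")


@dataclass
class ScreeningResult:
    measure_id: str
    t: float
    df: int
    p: float
    auc: float
    auc_se: float
    auc_ci95: tuple[float, float]
    auc_direction: int  # +1: fallers score higher; -1: lower
    significant_t: bool
    marginal: bool
    significant_roc: bool
    selected: bool


@dataclass
class ImportanceRanking:
    """Measures ordered by mean decrease accuracy (ties: AUC, then p-value)."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: measure_id, mda, mda_sd, auc, p, rank

    @property
    def order(self) -> list[str]:
        return list(self.table["measure_id"])


def ttest_from_summary(a: GroupSummary, b: GroupSummary) -> tuple[float, int, float]:
    """Pooled-variance (Student) two-sample t-test from group summaries.

    Returns (t, df, two-sided p); df = n1 + n2 - 2.
    """
    a.validate()
    b.validate()
    df = a.n + b.n - 2
    pooled_var = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    se = np.sqrt(pooled_var * (1.0 / a.n + 1.0 / b.n))
    if se == 0:
        if a.mean == b.mean:
            return 0.0, df, 1.0
        return float(np.inf) if a.mean > b.mean else float(-np.inf), df, 0.0
    t = (a.mean - b.mean) / se
    p = 2.0 * sp_stats.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def ttest_from_samples(x, y) -> tuple[float, int, float]:
    """Pooled two-sample t-test on raw samples; exactly equals the summary
    route applied to the samples' own (n, mean, sd)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("each group needs at least 2 values")
    return ttest_from_summary(
        GroupSummary(x.size, float(x.mean()), float(x.std(ddof=1))),
        GroupSummary(y.size, float(y.mean()), float(y.std(ddof=1))),
    )


def _labels_to_bool(labels) -> np.ndarray:
    """True for fallers."""
    out = []
    for v in labels:
        if isinstance(v, FallStatus):
            out.append(v is FallStatus.FALLER)
        elif isinstance(v, str):
            out.append(v == FallStatus.FALLER.value)
        else:
            out.append(bool(v))
    return np.asarray(out, dtype=bool)


def roc_auc(scores, labels) -> tuple[float, float, tuple[float, float]]:
    """Empirical AUC with Hanley-McNeil standard error and 95% CI.

    AUC is the fraction of (faller, non-faller) pairs ordered correctly, ties
    counted one half, oriented so auc >= 0.5 (the direction is recoverable
    from the unoriented value; :func:`screen` records it).
    """
    scores = np.asarray(scores, dtype=float)
    is_faller = _labels_to_bool(labels)
    n1 = int(is_faller.sum())
    n0 = int((~is_faller).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("roc_auc needs both classes present")
    ranks = sp_stats.rankdata(scores)  # midranks handle ties
    auc = (ranks[is_faller].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    auc = float(auc)
    if auc < 0.5:
        auc = 1.0 - auc
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)) / (n1 * n0)
    se = float(np.sqrt(max(var, 0.0)))
    ci = (auc - 1.959963984540054 * se, auc + 1.959963984540054 * se)
    return auc, se, ci


def _split_features(features: pd.DataFrame, measure_ids: Optional[Sequence[str]] = None):
    if "fall_status" not in features.columns:
        raise ValidationError("feature table needs a fall_status column")
    is_faller = _labels_to_bool(features["fall_status"])
    if is_faller.sum() < 2 or (~is_faller).sum() < 2:
        raise ValidationError("need at least 2 subjects per class")
    cols = [c for c in features.columns if c not in ("fall_status", "subject_id")]
    if measure_ids is not None:
        cols = [c for c in cols if c in set(measure_ids)]
    return cols, is_faller


def screen(features: pd.DataFrame, alpha: float = 0.05,
           marginal_alpha: float = 0.10) -> list[ScreeningResult]:
    """Screen every measure column of a labelled feature table.

    A measure is selected when its two-sample t-test is significant at
    ``alpha`` AND its AUC 95% CI excludes 0.5.
    """
    cols, is_faller = _split_features(features)
    results = []
    for measure_id in cols:
        x = features.loc[is_faller, measure_id].to_numpy(float)
        y = features.loc[~is_faller, measure_id].to_numpy(float)
        x, y = x[np.isfinite(x)], y[np.isfinite(y)]
        if x.size < 2 or y.size < 2:
            continue
        t, df, p = ttest_from_samples(x, y)
        raw = np.concatenate([x, y])
        lab = np.concatenate([np.ones(x.size, bool), np.zeros(y.size, bool)])
        auc, se, ci = roc_auc(raw, lab)
        direction = 1 if np.mean(x) >= np.mean(y) else -1
        sig_t = p < alpha
        sig_roc = ci[0] > 0.5
        results.append(ScreeningResult(
            measure_id=measure_id, t=t, df=df, p=p,
            auc=auc, auc_se=se, auc_ci95=ci, auc_direction=direction,
            significant_t=sig_t, marginal=alpha <= p < marginal_alpha,
            significant_roc=sig_roc, selected=sig_t and sig_roc,
        ))
    return results


def screening_table(results: list[ScreeningResult]) -> pd.DataFrame:
    return pd.DataFrame([
        dict(measure_id=r.measure_id, t=r.t, df=r.df, p=r.p, auc=r.auc,
             auc_se=r.auc_se, ci_lo=r.auc_ci95[0], ci_hi=r.auc_ci95[1],
             significant_t=r.significant_t, marginal=r.marginal,
             significant_roc=r.significant_roc, selected=r.selected)
        for r in results
    ])


def rank_measures(features: pd.DataFrame, selected: Sequence[str], seed: int = 0,
                  n_trees: int = 300) -> ImportanceRanking:
    """Rank measures by random-forest mean decrease accuracy.

    A bespoke bagged forest is grown (one decision tree per bootstrap sample);
    each measure's MDA is the drop in out-of-bag accuracy when its column is
    permuted, averaged over trees.  Ties are broken by AUC, then by t-test
    p-value.
    """
    from sklearn.tree import DecisionTreeClassifier

    selected = list(selected)
    if not selected:
        raise ValidationError("rank_measures needs a non-empty selected set")
    cols, is_faller = _split_features(features, selected)
    missing = sorted(set(selected) - set(cols))
    if missing:
        raise ValidationError(f"selected measures absent from table: {missing}")
    cols = [c for c in selected if c in cols]

    X = features[cols].to_numpy(float)
    # mean-impute for the forest (training-time convention)
    col_means = np.nanmean(X, axis=0)
    nan_mask = ~np.isfinite(X)
    X[nan_mask] = np.take(col_means, np.nonzero(nan_mask)[1])
    y = is_faller.astype(int)
    n, d = X.shape

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xDA]))
    drops = np.zeros((n_trees, d))
    valid = np.zeros((n_trees, d), dtype=bool)
    for b in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        if oob.size < 2 or len(np.unique(y[boot])) < 2:
            continue
        tree = DecisionTreeClassifier(
            max_features="sqrt", random_state=int(rng.integers(2**31 - 1))
        ).fit(X[boot], y[boot])
        base = (tree.predict(X[oob]) == y[oob]).mean()
        for j in range(d):
            Xp = X[oob].copy()
            Xp[:, j] = Xp[rng.permutation(oob.size), j]
            perm = (tree.predict(Xp) == y[oob]).mean()
            drops[b, j] = base - perm
            valid[b, j] = True

    with np.errstate(invalid="ignore"):
        mda = np.where(valid.any(axis=0), drops.sum(axis=0) / np.maximum(valid.sum(axis=0), 1), np.nan)
        mda_sd = np.array([
            drops[valid[:, j], j].std(ddof=1) if valid[:, j].sum() > 1 else np.nan
            for j in range(d)
        ])

    aucs, ps = [], []
    for c in cols:
        x = features.loc[is_faller, c].to_numpy(float)
        yv = features.loc[~is_faller, c].to_numpy(float)
        x, yv = x[np.isfinite(x)], yv[np.isfinite(yv)]
        auc, _, _ = roc_auc(np.concatenate([x, yv]),
                            np.concatenate([np.ones(x.size, bool), np.zeros(yv.size, bool)]))
        _, _, p = ttest_from_samples(x, yv)
        aucs.append(auc)
        ps.append(p)

    table = pd.DataFrame({
        "measure_id": cols, "mda": mda, "mda_sd": mda_sd, "auc": aucs, "p": ps,
    })
    table = table.sort_values(
        by=["mda", "auc", "p"], ascending=[False, False, True], kind="mergesort"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return ImportanceRanking(table=table)
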