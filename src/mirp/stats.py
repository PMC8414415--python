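"""Group contrasts and factor-performance correlations.

Subjects are split by mean three-class accuracy into high- and
low-performance groups (top/bottom 8 of 20, middle excluded).  Electrode-
wise group differences use Welch's t-test with Benjamini-Hochberg FDR over
the electrode family.  Factor-performance association is assessed two
ways: Spearman rank correlation across subjects (one point per subject,
session means) and repeated-measures correlation (rmcorr; common
within-subject slope via ANCOVA, df = n_obs - n_subjects - 1) across
sessions, each with BH-FDR over its family of tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

#: All 11 task combinations: 6 binary, 4 three-class, 1 four-class.
TASK_SETS: tuple[tuple[str, ...], ...] = tuple(
    combo
    for k in (2, 3, 4)
    for combo in itertools.combinations(("left", "right", "feet", "idle"), k)
)

_SHORT = {"left": "L", "right": "R", "feet": "F", "idle": "I"}


def task_set_name(tasks: tuple[str, ...]) -> str:
    """Compact name like ``L-R-F`` for a task combination."""
    return "-".join(_SHORT[t] for t in tasks)


@dataclass
class CorrelationResult:
    method: str                # "spearman" or "rmcorr"
    r: float
    p: float
    n: int
    dof: int
    p_fdr: float | None = None


@dataclass
class GroupAssignment:
    performance: pd.DataFrame  # subject, mean, sd — sorted descending by mean
    hp: list[int]
    lp: list[int]
    excluded: list[int]


def subject_performance(metrics: pd.DataFrame,
                        value_col: str = "accuracy") -> pd.DataFrame:
    """Per-subject (and task-set, if present) mean and SD over sessions."""
    if metrics.empty:
        raise ValueError("empty metrics table")
    keys = ["subject"] + (["task_set"] if "task_set" in metrics.columns else [])
    out = (metrics.groupby(keys)[value_col]
           .agg(mean="mean", sd=lambda s: s.std(ddof=0))
           .reset_index())
    return out


def assign_groups(perf: pd.DataFrame, group_size: int = 8) -> GroupAssignment:
    """Sort by mean accuracy; top -> HP, bottom -> LP, middle excluded.

    Boundary ties are broken deterministically by ascending subject id.
    """
    if len(perf) < 2 * group_size:
        raise ValueError(
            f"need >= {2 * group_size} subjects for two groups of {group_size}")
    ordered = perf.sort_values(["mean", "subject"],
                               ascending=[False, True]).reset_index(drop=True)
    hp = ordered["subject"].iloc[:group_size].tolist()
    lp = ordered["subject"].iloc[-group_size:].tolist()
    excluded = ordered["subject"].iloc[group_size:len(ordered) - group_size].tolist()
    return GroupAssignment(performance=ordered, hp=hp, lp=lp, excluded=excluded)


def group_tmap(table: pd.DataFrame, groups: GroupAssignment, band: str,
               alpha: float = 0.05, value_col: str | None = None,
               equal_var: bool = False) -> pd.DataFrame:
    """Electrode-wise HP-vs-LP t-test with BH-FDR over electrodes.

    ``table`` is a tidy per-electrode frame (subject, session, band,
    electrode, value); values are first averaged over sessions per subject.
    Welch's unequal-variance test is the default.
    """
    if value_col is None:
        value_col = "delta_rp" if "delta_rp" in table.columns else "rp"
    sub = table[table["band"] == band]
    if sub.empty:
        raise ValueError(f"no rows for band {band!r}")
    per_subject = (sub.groupby(["subject", "electrode"], as_index=False)
                   [value_col].mean())
    rows = []
    for electrode, grp in per_subject.groupby("electrode"):
        hp_vals = grp[grp["subject"].isin(groups.hp)][value_col].to_numpy()
        lp_vals = grp[grp["subject"].isin(groups.lp)][value_col].to_numpy()
        if len(hp_vals) < 2 or len(lp_vals) < 2:
            raise ValueError(f"fewer than 2 subjects per group at {electrode!r}")
        t, p = sstats.ttest_ind(hp_vals, lp_vals, equal_var=equal_var)
        rows.append((electrode, float(t), float(p)))
    out = pd.DataFrame(rows, columns=["electrode", "t", "p"])
    reject, p_adj = bh_fdr(out["p"].to_numpy(), alpha)
    out["p_fdr"] = p_adj
    out["significant"] = reject
    out["band"] = band
    return out


def bh_fdr(pvals: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject mask, adjusted p-values)."""
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return reject, p_adj


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with two-sided t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input: ranks have zero dispersion")
    r, p = sstats.spearmanr(x, y)
    return CorrelationResult(method="spearman", r=float(r), p=float(p),
                             n=len(x), dof=len(x) - 2)


def rmcorr(subjects, x, y) -> CorrelationResult:
    """Repeated-measures correlation (common within-subject association).

    ANCOVA with subject as a factor and a common slope for x:
    ``r_rm = sign(slope) * sqrt(SS_x / (SS_x + SS_error))`` where SS_x is
    the sum of squares explained by x beyond the subject means and SS_error
    the residual; ``df = n_obs - n_subjects - 1``; two-sided p from the
    t-distribution equivalence.
    """
    subjects = np.asarray(subjects)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ids, idx = np.unique(subjects, return_inverse=True)
    counts = np.bincount(idx)
    if len(ids) < 2 or (counts < 2).any():
        raise ValueError("rmcorr needs >= 2 subjects with >= 2 observations each")
    n_obs, k = len(x), len(ids)
    dummies = np.eye(k)[idx]
    design = np.column_stack([dummies, x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    ss_err = float(resid @ resid)
    resid0 = y - dummies @ np.linalg.lstsq(dummies, y, rcond=None)[0]
    ss_x = float(resid0 @ resid0) - ss_err
    denom = ss_x + ss_err
    if denom <= 0:
        raise ValueError("no within-subject variation in x or y")
    r = float(np.sign(beta[-1]) * np.sqrt(max(ss_x, 0.0) / denom))
    dof = n_obs - k - 1
    if dof <= 0:
        raise ValueError("non-positive degrees of freedom")
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(dof / (1.0 - r ** 2))
        p = float(2 * sstats.t.sf(abs(t), dof))
    return CorrelationResult(method="rmcorr", r=r, p=p, n=n_obs, dof=dof)


def correlation_grid(factors: pd.DataFrame, metrics: pd.DataFrame,
                     task_sets: tuple[tuple[str, ...], ...] = TASK_SETS,
                     bands: tuple[str, ...] = ("theta", "alpha", "gamma"),
                     alpha: float = 0.05,
                     value_col: str = "delta_rp") -> pd.DataFrame:
    """Factor-performance correlations over task sets x bands x aspects.

    ``factors``: (subject, session, band, value) — e.g. region-averaged
    delta-RP; ``metrics``: (subject, session, task_set, accuracy).
    Across-subject cells use Spearman on subject means; across-session
    cells use rmcorr on (subject, session) pairs.  BH-FDR is applied
    separately within each aspect family.
    """
    names = {task_set_name(t) for t in task_sets}
    missing = names - set(metrics["task_set"].unique())
    if missing:
        raise ValueError(f"metrics table missing task sets: {sorted(missing)}")
    missing_b = set(bands) - set(factors["band"].unique())
    if missing_b:
        raise ValueError(f"factor table missing bands: {sorted(missing_b)}")
    rows = []
    for tasks in task_sets:
        tname = task_set_name(tasks)
        acc = metrics[metrics["task_set"] == tname]
        for band in bands:
            fac = factors[factors["band"] == band]
            merged = acc.merge(fac, on=["subject", "session"])
            # across subjects: one point per subject (session means)
            means = merged.groupby("subject")[["accuracy", value_col]].mean()
            cs = spearman(means[value_col], means["accuracy"])
            rows.append((tname, band, "across_subjects", cs.r, cs.p, cs.n, cs.dof))
            # across sessions: repeated-measures correlation
            cr = rmcorr(merged["subject"], merged[value_col], merged["accuracy"])
            rows.append((tname, band, "across_sessions", cr.r, cr.p, cr.n, cr.dof))
    out = pd.DataFrame(rows, columns=["task_set", "band", "aspect", "r", "p",
                                      "n", "dof"])
    out["p_fdr"] = np.nan
    out["significant"] = False
    for aspect, idx in out.groupby("aspect").groups.items():
        reject, p_adj = bh_fdr(out.loc[idx, "p"].to_numpy(), alpha)
        out.loc[idx, "p_fdr"] = p_adj
        out.loc[idx, "significant"] = reject
    return out
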