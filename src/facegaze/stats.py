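"""By-items ANOVAs, Bonferroni post-hoc contrasts and letter displays.

One-way and split-plot (mixed between x within) analyses with partial
eta-squared effect sizes, pairwise t contrasts pooled on the ANOVA
error term with single-step Bonferroni adjustment, and compact letter
displays in which two groups share a letter iff their contrast is not
significant.  Sum-of-squares decompositions are computed explicitly so
the error terms feeding the post-hoc contrasts are available.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "PairwiseContrasts",
    "oneway_anova",
    "mixed_anova",
    "bonferroni_pairwise",
    "compact_letter_display",
]


@dataclass(frozen=True)
class AnovaResult:
    """One F test: effect name, statistic, dfs, p and partial eta^2.

    ``ms_error``/``df_error`` expose the effect's own error term for
    pooled post-hoc contrasts.
    """

    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta_sq: float
    ms_error: float
    df_error: int

    def __str__(self) -> str:  # Results-section style rendering
        return (f"{self.effect}: F({self.df_num}, {self.df_den}) = {self.F:.2f}, "
                f"p = {self.p:.3g}, eta_p^2 = {self.partial_eta_sq:.2f}")


@dataclass(frozen=True)
class PairwiseContrasts:
    """All pairwise group contrasts with raw and adjusted p values."""

    labels: tuple[str, ...]
    t: np.ndarray
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    alpha: float

    def significant(self, a: str, b: str) -> bool:
        i, j = self.labels.index(a), self.labels.index(b)
        return bool(self.p_adjusted[i, j] < self.alpha)


def _f_and_eta(ss_effect: float, df_effect: int, ss_error: float,
               df_error: int) -> tuple[float, float, float]:
    ms_error = ss_error / df_error if df_error else np.nan
    if ss_effect + ss_error <= 0:
        # no variance anywhere: define F = 0 rather than 0/0
        return 0.0, 1.0, 0.0
    ms_effect = ss_effect / df_effect
    if ms_error == 0:
        f = np.inf if ms_effect > 0 else 0.0
    else:
        f = ms_effect / ms_error
    p = float(sps.f.sf(f, df_effect, df_error)) if np.isfinite(f) else 0.0
    eta = ss_effect / (ss_effect + ss_error)
    return float(f), p, float(eta)


def oneway_anova(groups: Mapping[str, Sequence[float]],
                 effect: str = "group") -> AnovaResult:
    """Between-groups one-way ANOVA with partial eta-squared.

    ``groups`` maps each level to its observations (here: item scores).
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    data = [np.asarray(groups[k], dtype=float) for k in labels]
    if any(len(d) < 2 for d in data):
        raise ValueError("need at least two observations per group")
    alln = np.concatenate(data)
    grand = alln.mean()
    ss_between = sum(len(d) * (d.mean() - grand) ** 2 for d in data)
    ss_within = sum(((d - d.mean()) ** 2).sum() for d in data)
    df_b = len(labels) - 1
    df_w = len(alln) - len(labels)
    f, p, eta = _f_and_eta(ss_between, df_b, ss_within, df_w)
    return AnovaResult(effect, f, df_b, df_w, p, eta,
                       ss_within / df_w if df_w else np.nan, df_w)


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    between: str,
    within: str,
    subject: str,
) -> list[AnovaResult]:
    """Split-plot ANOVA: one between-units factor, one within factor.

    Units (``subject``; here stimuli in a by-items analysis) are nested
    in the ``between`` factor and crossed with the ``within`` factor.
    The between effect is tested against units-within-groups, the
    within and interaction effects against the unit-by-within residual;
    each effect's partial eta-squared uses its own error term.  The
    design must be complete (every unit measured at every within
    level); group sizes may differ.
    """
    d = data[[subject, between, within, dv]].dropna()
    b_levels = list(pd.unique(d[between]))
    w_levels = list(pd.unique(d[within]))
    a, b = len(b_levels), len(w_levels)
    cell = d.pivot_table(index=subject, columns=within, values=dv,
                         aggfunc="mean")
    if cell.isna().any().any():
        bad = cell.index[cell.isna().any(axis=1)].tolist()
        raise ValueError(f"incomplete within-factor data for units: {bad}")
    subj_group = d.groupby(subject)[between].first()
    n_units = len(cell)
    y = cell.to_numpy(dtype=float)          # units x within levels
    grand = y.mean()

    group_of = subj_group.reindex(cell.index).to_numpy()
    subj_mean = y.mean(axis=1)
    group_mean = {g: subj_mean[group_of == g].mean() for g in b_levels}
    n_g = {g: int((group_of == g).sum()) for g in b_levels}

    ss_subjects = b * ((subj_mean - grand) ** 2).sum()
    ss_between = b * sum(n_g[g] * (group_mean[g] - grand) ** 2 for g in b_levels)
    ss_err_between = ss_subjects - ss_between
    df_between = a - 1
    df_err_between = n_units - a

    ss_total = ((y - grand) ** 2).sum()
    ss_within_units = ss_total - ss_subjects
    w_mean = y.mean(axis=0)
    ss_w = n_units * ((w_mean - grand) ** 2).sum()
    # group x within cell means carry between + within + interaction SS
    ss_cells = 0.0
    for g in b_levels:
        cell_means = y[group_of == g].mean(axis=0)
        ss_cells += n_g[g] * ((cell_means - grand) ** 2).sum()
    ss_inter = ss_cells - ss_w - ss_between
    ss_err_within = ss_within_units - ss_w - ss_inter
    df_w = b - 1
    df_inter = (a - 1) * (b - 1)
    df_err_within = (n_units - a) * (b - 1)

    out = []
    for name, ss_e, df_e, ss_r, df_r in (
        (between, ss_between, df_between, ss_err_between, df_err_between),
        (within, ss_w, df_w, ss_err_within, df_err_within),
        (f"{between}*{within}", ss_inter, df_inter, ss_err_within, df_err_within),
    ):
        ss_e = max(float(ss_e), 0.0)
        ss_r = max(float(ss_r), 0.0)
        f, p, eta = _f_and_eta(ss_e, df_e, ss_r, df_r)
        out.append(AnovaResult(name, f, df_e, df_r, p, eta,
                               ss_r / df_r if df_r else np.nan, df_r))
    return out


def bonferroni_pairwise(
    groups: Mapping[str, Sequence[float]],
    ms_error: float | None = None,
    df_error: int | None = None,
    alpha: float = 0.05,
) -> PairwiseContrasts:
    """Pairwise t contrasts with single-step Bonferroni adjustment.

    The t statistic pools the omnibus ANOVA mean-square error
    (``ms_error`` with ``df_error``); when not supplied both are
    computed from the groups as in :func:`oneway_anova`.  The adjusted
    p is ``min(1, raw * m)`` with ``m`` the number of pairs, the
    "equivalent adjustment to each p value" form of the correction.
    """
    labels = tuple(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if ms_error is None or df_error is None:
        res = oneway_anova(groups)
        ms_error, df_error = res.ms_error, res.df_error
    data = {k: np.asarray(groups[k], dtype=float) for k in labels}
    k = len(labels)
    m = k * (k - 1) // 2
    t = np.zeros((k, k))
    p_raw = np.ones((k, k))
    for i, j in itertools.combinations(range(k), 2):
        di, dj = data[labels[i]], data[labels[j]]
        se = np.sqrt(ms_error * (1.0 / len(di) + 1.0 / len(dj)))
        tij = (di.mean() - dj.mean()) / se if se > 0 else (
            0.0 if di.mean() == dj.mean() else np.inf)
        t[i, j] = t[j, i] = tij
        p_raw[i, j] = p_raw[j, i] = (2.0 * sps.t.sf(abs(tij), df_error)
                                     if np.isfinite(tij) else 0.0)
    p_adj = np.minimum(p_raw * m, 1.0)
    np.fill_diagonal(p_adj, 1.0)
    return PairwiseContrasts(labels, t, p_raw, p_adj, alpha)


def compact_letter_display(
    contrasts: PairwiseContrasts,
    means: Mapping[str, float],
) -> dict[str, str]:
    """Letter codes summarising the pairwise contrasts.

    Insert-and-absorb assignment: two groups share at least one letter
    iff their contrast is not significant.  Letters are ordered so that
    ``"a"`` attaches to the highest mean, matching the convention of
    norm tables where the largest score carries the first letter.
    """
    labels = list(contrasts.labels)
    sets: list[set[str]] = [set(labels)]
    for a, b in itertools.combinations(labels, 2):
        if not contrasts.significant(a, b):
            continue
        for s in [s for s in sets if a in s and b in s]:
            sets.remove(s)
            sa, sb = s - {a}, s - {b}
            for cand in (sa, sb):
                if not any(cand <= other for other in sets):
                    sets.append(cand)
        sets = [s for s in sets
                if not any(s < other for other in sets)]
    order = sorted(labels, key=lambda g: -float(means[g]))
    # order letter sets by the rank of their best (highest-mean) member
    rank = {g: i for i, g in enumerate(order)}
    sets.sort(key=lambda s: min(rank[g] for g in s) if s else len(order))
    letters = {g: "" for g in labels}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for letter, s in zip(alphabet, sets):
        for g in s:
            letters[g] += letter
    return {g: letters[g] for g in order}
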