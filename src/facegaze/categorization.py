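"""Expression-categorization performance: hits, RTs and confusions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import EXPRESSIONS

__all__ = ["ConfusionMatrix", "confusion_matrix", "hits_and_rts",
           "modal_confusion"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Stimulus-by-response proportion table.

    ``proportions[i, j]`` is the probability that stimulus ``labels[i]``
    was categorized as ``labels[j]``; rows sum to 1 and the diagonal
    holds the hit proportions.  ``row_n`` counts the aggregated units
    per row (trials, or stimuli for the by-items variant).
    """

    labels: tuple[str, ...]
    proportions: np.ndarray
    row_n: tuple[int, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("confusion rows must sum to 1")
        object.__setattr__(self, "proportions", p)

    def to_frame(self, percent: bool = False) -> pd.DataFrame:
        scale = 100.0 if percent else 1.0
        return pd.DataFrame(self.proportions * scale, index=list(self.labels),
                            columns=list(self.labels))

    @property
    def hits(self) -> dict[str, float]:
        return dict(zip(self.labels, np.diag(self.proportions)))


def _check_labels(responses: pd.DataFrame, labels: tuple[str, ...]) -> None:
    for col in ("stimulus_expression", "response"):
        bad = ~responses[col].isin(labels)
        if bad.any():
            row = responses.index[bad][0]
            raise ValueError(f"unknown {col} label {responses.loc[row, col]!r} "
                             f"in trial row {row}")


def confusion_matrix(
    responses: pd.DataFrame,
    labels: tuple[str, ...] = EXPRESSIONS,
    by_items: bool = False,
) -> ConfusionMatrix:
    """Row-normalised stimulus-by-response proportions.

    ``responses`` needs columns ``stimulus_expression`` and ``response``
    (and ``stimulus_id`` for the by-items variant, which first computes
    per-stimulus proportions and then averages them, weighting every
    stimulus equally as in a by-items analysis).
    """
    _check_labels(responses, labels)
    k = len(labels)
    if by_items:
        props = np.zeros((k, k))
        row_n = []
        for i, stim_expr in enumerate(labels):
            sub = responses[responses["stimulus_expression"] == stim_expr]
            per_item = []
            for _, grp in sub.groupby("stimulus_id"):
                counts = grp["response"].value_counts()
                per_item.append([counts.get(r, 0) / len(grp) for r in labels])
            if not per_item:
                raise ValueError(f"no trials for expression {stim_expr!r}")
            props[i] = np.mean(per_item, axis=0)
            row_n.append(len(per_item))
        return ConfusionMatrix(labels, props, tuple(row_n))
    counts = np.zeros((k, k))
    idx = {lab: i for i, lab in enumerate(labels)}
    for stim, resp in zip(responses["stimulus_expression"], responses["response"]):
        counts[idx[stim], idx[resp]] += 1
    n = counts.sum(axis=1)
    if np.any(n == 0):
        missing = [labels[i] for i in np.flatnonzero(n == 0)]
        raise ValueError(f"no trials for expressions: {missing}")
    return ConfusionMatrix(labels, counts / n[:, None], tuple(int(v) for v in n))


def hits_and_rts(
    responses: pd.DataFrame,
    labels: tuple[str, ...] = EXPRESSIONS,
) -> pd.DataFrame:
    """Per-expression hit proportion and correct-response RT stats.

    RT means/SDs are computed over correct trials only (``rt_ms``
    measured from clip offset); they are NaN for an expression without
    any correct trial.  The hit column equals the diagonal of
    :func:`confusion_matrix` on the same input exactly.
    """
    _check_labels(responses, labels)
    rows = []
    for lab in labels:
        sub = responses[responses["stimulus_expression"] == lab]
        if not len(sub):
            raise ValueError(f"no trials for expression {lab!r}")
        correct = sub[sub["response"] == lab]
        rts = correct["rt_ms"].to_numpy(dtype=float)
        rows.append({
            "expression": lab,
            "n_trials": len(sub),
            "hit": len(correct) / len(sub),
            "rt_mean_ms": float(rts.mean()) if len(rts) else np.nan,
            "rt_sd_ms": float(rts.std(ddof=1)) if len(rts) > 1 else np.nan,
        })
    return pd.DataFrame(rows)


def modal_confusion(
    matrix: ConfusionMatrix,
    expression: str,
) -> tuple[tuple[str, ...], float]:
    """Most frequent incorrect response for a stimulus expression.

    Returns the tied set of modal off-diagonal labels (usually a single
    one) and their shared proportion; an expression never confused
    returns an empty label tuple with proportion 0.
    """
    i = matrix.labels.index(expression)
    row = matrix.proportions[i].copy()
    row[i] = -1.0
    best = row.max()
    if best <= 0:
        return (), 0.0
    tied = tuple(matrix.labels[j] for j in np.flatnonzero(row == best))
    return tied, float(best)
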