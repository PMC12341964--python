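"""Per-(tissue, mediator) comparisons across experimental arms.

Two instruments: one-way ANOVA with Tukey's HSD across conditions (the
screening statistic for differential mediator expression), and the Welch
two-sample t-test against baseline that gates which mediators enter a
dynamic correlation network. Welch is used because group sizes are very
unequal (baseline n=5 vs surgery arms n~28) and variances differ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .core_data import MissingGroupError


class InsufficientDataError(ValueError):
    """A group is too small or too degenerate for the requested statistic."""


@dataclass
class TukeyPair:
    condition_a: str
    condition_b: str
    mean_diff: float
    p_adj: float
    significant: bool


@dataclass
class GroupComparison:
    """One-way ANOVA + Tukey HSD for one mediator in one tissue."""

    tissue: str
    mediator: str
    anova_F: float
    anova_p: float
    tukey_pairs: list[TukeyPair]
    alpha: float = 0.05


@dataclass
class ChangeGate:
    """Welch t-test vs baseline; ``passes`` admits the mediator into DyNA."""

    tissue: str
    mediator: str
    condition: str
    t_p: float
    passes: bool


def _group_values(df, tissue, mediator, condition) -> np.ndarray:
    sub = df[
        (df["tissue"] == tissue)
        & (df["mediator"] == mediator)
        & (df["condition"] == condition)
    ]
    return sub["concentration"].to_numpy(dtype=float)


def anova_tukey(
    df: pd.DataFrame,
    tissue: str,
    mediator: str,
    conditions,
    alpha: float = 0.05,
) -> GroupComparison:
    """One-way ANOVA over ``conditions`` with Tukey HSD on all pairs.

    Raises :class:`InsufficientDataError` if fewer than two conditions have
    data or any present group has fewer than two values; callers batching
    over the mediator grid should catch it and record the skip.
    """
    groups, labels = [], []
    for cond in conditions:
        vals = _group_values(df, tissue, mediator, cond)
        if len(vals) == 0:
            continue
        if len(vals) < 2:
            raise InsufficientDataError(
                f"group {cond!r} for ({tissue}, {mediator}) has n={len(vals)} < 2"
            )
        groups.append(vals)
        labels.append(cond)
    if len(groups) < 2:
        raise InsufficientDataError(
            f"need >=2 non-empty conditions for ({tissue}, {mediator}), "
            f"got {len(groups)}"
        )

    if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
        F, p = 0.0, 1.0
    else:
        F, p = stats.f_oneway(*groups)

    values = np.concatenate(groups)
    group_labels = np.concatenate([[lab] * len(g) for lab, g in zip(labels, groups)])
    res = pairwise_tukeyhsd(values, group_labels, alpha=alpha)
    pairs = [
        TukeyPair(
            condition_a=str(a),
            condition_b=str(b),
            mean_diff=float(diff),
            p_adj=float(padj),
            significant=bool(padj < alpha),
        )
        for a, b, diff, padj in zip(
            res.groupsunique[res._multicomp.pairindices[0]],
            res.groupsunique[res._multicomp.pairindices[1]],
            res.meandiffs,
            res.pvalues,
        )
    ]
    return GroupComparison(
        tissue=tissue,
        mediator=mediator,
        anova_F=float(F),
        anova_p=float(p),
        tukey_pairs=pairs,
        alpha=alpha,
    )


def ttest_vs_baseline(
    df: pd.DataFrame,
    tissue: str,
    mediator: str,
    condition: str,
    p_threshold: float = 0.05,
    baseline_condition: str = "baseline",
) -> ChangeGate:
    """Two-sided Welch t-test of ``condition`` against baseline.

    If both groups have zero variance and equal means there is no evidence of
    change: p is reported as 1 and the gate fails. Raises
    :class:`InsufficientDataError` naming the group when either side has
    fewer than two values.
    """
    base = _group_values(df, tissue, mediator, baseline_condition)
    cond = _group_values(df, tissue, mediator, condition)
    for name, vals in ((baseline_condition, base), (condition, cond)):
        if len(vals) < 2:
            raise InsufficientDataError(
                f"group {name!r} for ({tissue}, {mediator}) has n={len(vals)} < 2"
            )
    if np.ptp(base) == 0 and np.ptp(cond) == 0:
        p = 1.0 if base[0] == cond[0] else 0.0
    else:
        _, p = stats.ttest_ind(cond, base, equal_var=False)
        p = float(p)
    return ChangeGate(
        tissue=tissue,
        mediator=mediator,
        condition=condition,
        t_p=p,
        passes=bool(p < p_threshold),
    )


def gate_mediators(
    df: pd.DataFrame,
    tissue: str,
    condition: str,
    mediators,
    p_threshold: float = 0.05,
    baseline_condition: str = "baseline",
) -> list[ChangeGate]:
    """Apply :func:`ttest_vs_baseline` across a mediator panel.

    Mediators whose groups are too small are silently skipped (no gate
    emitted), matching how a screening pass treats unusable panels.
    """
    gates = []
    for m in mediators:
        try:
            gates.append(
                ttest_vs_baseline(
                    df, tissue, m, condition,
                    p_threshold=p_threshold,
                    baseline_condition=baseline_condition,
                )
            )
        except (InsufficientDataError, MissingGroupError):
            continue
    return gates


def comparisons_to_frame(comparisons) -> pd.DataFrame:
    """Flatten GroupComparison objects to a tidy CSV-ready frame."""
    rows = []
    for c in comparisons:
        for p in c.tukey_pairs:
            rows.append(
                {
                    "tissue": c.tissue,
                    "mediator": c.mediator,
                    "anova_F": c.anova_F,
                    "anova_p": c.anova_p,
                    "condition_a": p.condition_a,
                    "condition_b": p.condition_b,
                    "mean_diff": p.mean_diff,
                    "p_adj": p.p_adj,
                    "significant": p.significant,
                }
            )
    return pd.DataFrame(rows)
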