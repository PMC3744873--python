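"""Fixation time courses, the A/(A+B) ratio statistic, and effect summaries.

Gaze behavior is summarised the way VWP studies report it: per-tick mean
fixation proportions per item category, and for each competitor contrast
the ratio p(A) / (p(A) + p(B)) of mean fixation proportions over the
analysis window (word onset through the end of the test trial).  A ratio
above 0.5 means category A attracted more gaze than B; one-sample t-tests
against 0.5 are run both by instantiation (one value per trained model)
and by item (one value per target set, records pooled across
instantiations before the ratio transform).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RatioResult",
    "timecourse",
    "fixation_ratio",
    "one_sample_t",
    "effect_table",
    "EFFECT_ROWS",
    "plot_timecourses",
]


def timecourse(records, role: str) -> np.ndarray:
    """Mean fixation proportion per tick for one item category.

    When a display holds two items of the same role (the two distractors),
    their curves are averaged within the display first.
    """
    if not records:
        raise ValueError("no records")
    T = records[0].T
    acc = np.zeros(T)
    for rec in records:
        if rec.T != T:
            raise ValueError("records differ in test length")
        cols = [i for i, r in enumerate(rec.display.roles) if r == role]
        if not cols:
            raise ValueError(
                f"role {role!r} absent from condition {rec.display.condition!r}"
            )
        acc += rec.ratios[:, cols].mean(axis=1)
    return acc / len(records)


def one_sample_t(values, mu: float = 0.5):
    """Textbook one-sample t-test: t = (mean - mu) / (s / sqrt(n)), df = n - 1.

    Returns ``(t, df, p)`` with a two-sided p from the t distribution.
    Zero variance yields an infinite t (p = 0) unless the mean equals mu.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("one-sample t-test needs at least two values")
    mean = x.mean()
    s = x.std(ddof=1)
    df = n - 1
    if s == 0.0 or np.all(x == x[0]):
        if x[0] == mu:
            return 0.0, df, 1.0
        return float(np.sign(x[0] - mu) * np.inf), df, 0.0
    t = (mean - mu) / (s / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


@dataclass
class RatioResult:
    """Fixation-ratio statistic for one role contrast in one condition."""

    roleA: str
    roleB: str
    window: tuple
    mean_ratio: float
    by_instantiation: np.ndarray
    by_item: np.ndarray
    t1: float = np.nan  # by instantiation
    df1: int = 0
    p1: float = np.nan
    t2: float = np.nan  # by item
    df2: int = 0
    p2: float = np.nan

    def significant_above(self, alpha: float = 0.05) -> bool:
        """Ratio significantly greater than 0.5 in every available aggregation."""
        checks = []
        if self.by_instantiation.size >= 2:
            checks.append(self.p1 < alpha and self.t1 > 0)
        if self.by_item.size >= 2:
            checks.append(self.p2 < alpha and self.t2 > 0)
        return bool(checks) and all(checks)


def _per_record_means(records, role: str, window) -> np.ndarray:
    return np.array([rec.role_mean(role, window) for rec in records])


def fixation_ratio(records, roleA: str, roleB: str, window=None) -> RatioResult:
    """p(A)/(p(A)+p(B)) aggregated by instantiation and by item.

    ``window`` defaults to (speech onset, end of trial).  Within each
    aggregation unit the mean fixation proportions are pooled first and
    the ratio transform applied afterwards.
    """
    if not records:
        raise ValueError("no records")
    if window is None:
        window = (records[0].speech_onset, records[0].T)
    pA = _per_record_means(records, roleA, window)
    pB = _per_record_means(records, roleB, window)
    inst = np.array(sorted({rec.instantiation for rec in records}))
    items = np.array(sorted({rec.display.set_id for rec in records}))
    rec_inst = np.array([rec.instantiation for rec in records])
    rec_item = np.array([rec.display.set_id for rec in records])

    def _ratios(keys, labels):
        out = []
        for k in labels:
            sel = keys == k
            a, b = pA[sel].mean(), pB[sel].mean()
            if a + b == 0:
                out.append(np.nan)
            else:
                out.append(a / (a + b))
        return np.array(out)

    by_inst = _ratios(rec_inst, inst)
    by_item = _ratios(rec_item, items)
    res = RatioResult(
        roleA=roleA,
        roleB=roleB,
        window=window,
        mean_ratio=float(np.nanmean(by_inst)),
        by_instantiation=by_inst,
        by_item=by_item,
    )
    if by_inst.size >= 2:
        res.t1, res.df1, res.p1 = one_sample_t(by_inst)
    if by_item.size >= 2:
        res.t2, res.df2, res.p2 = one_sample_t(by_item)
    return res


#: Table-3-style contrasts: (effect label, condition, role A, role B)
EFFECT_ROWS = (
    ("target vs distractor", "visual_TP", "target", "distractor"),
    ("visual comp vs distractor (TP)", "visual_TP", "visual_comp", "distractor"),
    ("visual comp vs distractor (TA)", "visual_TA", "visual_comp", "distractor"),
    ("target vs distractor (sem)", "semantic_TP", "target", "distractor"),
    ("near sem vs distractor (TP)", "semantic_TP", "near_sem", "distractor"),
    ("far sem vs distractor (TP)", "semantic_TP", "far_sem", "distractor"),
    ("near sem vs distractor (TA)", "semantic_TA", "near_sem", "distractor"),
    ("far sem vs distractor (TA)", "semantic_TA", "far_sem", "distractor"),
    ("far vs near sem (TP)", "semantic_TP", "far_sem", "near_sem"),
    ("far vs near sem (TA)", "semantic_TA", "far_sem", "near_sem"),
    ("target vs distractor (phon)", "phon_TP", "target", "distractor"),
    ("onset vs distractor (TP)", "phon_TP", "onset_comp", "distractor"),
    ("rhyme vs distractor (TP)", "phon_TP", "rhyme_comp", "distractor"),
    ("onset vs distractor (TA)", "phon_TA", "onset_comp", "distractor"),
    ("rhyme vs distractor (TA)", "phon_TA", "rhyme_comp", "distractor"),
)


def effect_table(records_by_regime: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Summary table of every standard contrast per training regime.

    ``records_by_regime`` maps regime name -> {condition -> list of
    FixationRecord}.  Missing conditions produce an explicit gap row.
    Replication means the ratio is significantly above 0.5 (two-sided
    alpha) in every available aggregation.
    """
    rows = []
    for regime, by_condition in records_by_regime.items():
        for label, condition, roleA, roleB in EFFECT_ROWS:
            if condition not in by_condition or not by_condition[condition]:
                rows.append(
                    {
                        "effect": label,
                        "condition": condition,
                        "regime": regime,
                        "mean_ratio": np.nan,
                        "replicated": None,
                        "missing": True,
                    }
                )
                continue
            r = fixation_ratio(by_condition[condition], roleA, roleB)
            rows.append(
                {
                    "effect": label,
                    "condition": condition,
                    "regime": regime,
                    "mean_ratio": r.mean_ratio,
                    "t_by_instantiation": r.t1,
                    "p_by_instantiation": r.p1,
                    "t_by_item": r.t2,
                    "p_by_item": r.p2,
                    "replicated": r.significant_above(alpha),
                    "missing": False,
                }
            )
    cols = [
        "effect",
        "condition",
        "regime",
        "mean_ratio",
        "t_by_instantiation",
        "p_by_instantiation",
        "t_by_item",
        "p_by_item",
        "replicated",
        "missing",
    ]
    return pd.DataFrame(rows, columns=cols)


def plot_timecourses(records, path, title: str | None = None) -> None:
    """Line plot of per-role fixation time courses for one condition."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    roles = sorted(set(records[0].display.roles))
    fig, ax = plt.subplots(figsize=(6, 4))
    for role in roles:
        ax.plot(timecourse(records, role), label=role)
    ax.axvline(records[0].speech_onset, color="gray", ls="--", lw=0.8)
    ax.set_xlabel("time step")
    ax.set_ylabel("p(fix)")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def frame_to_records(df: pd.DataFrame) -> list:
    """Rebuild FixationRecord objects from a long-format export."""
    from .vwp import Display, FixationRecord

    records = []
    keys = ["instantiation", "condition", "set_id", "permutation"]
    for (inst, condition, set_id, perm), g in df.groupby(keys, sort=True):
        g = g.sort_values(["tick", "location"])
        T = g.tick.nunique()
        ratios = g.luce_ratio.to_numpy().reshape(T, 4)
        first = g[g.tick == g.tick.min()].sort_values("location")
        records.append(
            FixationRecord(
                display=Display(
                    condition=condition,
                    set_id=int(set_id),
                    permutation=int(perm),
                    item_ids=tuple(int(i) for i in first.item_id),
                    roles=tuple(first.role),
                    target_word=-1,
                ),
                ratios=ratios,
                instantiation=int(inst),
            )
        )
    return records


def records_to_frame(records) -> pd.DataFrame:
    """Long-format export: one row per (record, tick, location)."""
    rows = []
    for rec in records:
        d = rec.display
        for t in range(rec.T):
            for loc in range(4):
                rows.append(
                    {
                        "instantiation": rec.instantiation,
                        "condition": d.condition,
                        "set_id": d.set_id,
                        "permutation": d.permutation,
                        "tick": t,
                        "location": loc,
                        "role": d.roles[loc],
                        "item_id": d.item_ids[loc],
                        "luce_ratio": rec.ratios[t, loc],
                    }
                )
    return pd.DataFrame(rows)
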