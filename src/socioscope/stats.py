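"""Group-comparison machinery: per-chat vectors, SEM bars, t-tests, stars.

The chat is the statistical unit throughout: each group contributes one
value per chat, error bars show the standard error of the mean across
chats, and groups are compared with a two-sided t-test. Welch's
unequal-variance variant is the default (group sizes and variances differ
in practice); Student's pooled test is available via ``equal_var=True``.
No multiple-testing correction is applied by default; a Holm adjustment
helper is provided for users who want one.

Star conventions: ``***`` p<.001, ``**`` p<.01, ``*`` p<.05, blank
otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps


def sem(values: Sequence[float]) -> float | None:
    """Standard error of the mean: sample sd (n-1 denominator) / sqrt(n).

    Undefined (None) for fewer than two values.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return None
    return float(v.std(ddof=1) / math.sqrt(v.size))


def welch_t(
    a: Sequence[float], b: Sequence[float], equal_var: bool = False
) -> tuple[float, float, float]:
    """Two-sided t-test; Welch-Satterthwaite df unless ``equal_var``.

    Returns (t, df, p). Two identical zero-variance samples give
    (0, n_a + n_b - 2, 1) rather than NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in input")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        # degenerate: no within-group spread at all
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        return (
            math.copysign(math.inf, a.mean() - b.mean()),
            float(a.size + b.size - 2),
            0.0,
        )
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


def stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class GroupComparison:
    statistic_name: str
    label_a: str
    label_b: str
    values_a: tuple[float, ...]
    values_b: tuple[float, ...]
    mean_a: float
    mean_b: float
    sem_a: float | None
    sem_b: float | None
    t: float | None
    df: float | None
    p: float | None
    stars: str

    def to_json(self) -> dict:
        return {
            "statistic": self.statistic_name,
            "groups": {
                self.label_a: {
                    "values": list(self.values_a),
                    "mean": self.mean_a,
                    "sem": self.sem_a,
                },
                self.label_b: {
                    "values": list(self.values_b),
                    "mean": self.mean_b,
                    "sem": self.sem_b,
                },
            },
            "t": self.t,
            "df": self.df,
            "p": self.p,
            "stars": self.stars,
        }


def compare_groups(
    values_by_label: Mapping[str, Sequence[float]],
    statistic_name: str,
    equal_var: bool = False,
) -> GroupComparison:
    """Full two-group comparison of per-chat statistic vectors.

    Exactly two labels are required. A group with fewer than two chats
    yields missing t/df/p (means and SEMs are still reported).
    """
    if len(values_by_label) != 2:
        raise ValueError(f"exactly two groups required, got {sorted(values_by_label)}")
    (label_a, raw_a), (label_b, raw_b) = values_by_label.items()
    a = [float(v) for v in raw_a]
    b = [float(v) for v in raw_b]
    if len(a) >= 2 and len(b) >= 2:
        t, df, p = welch_t(a, b, equal_var=equal_var)
    else:
        t = df = p = None
    return GroupComparison(
        statistic_name=statistic_name,
        label_a=label_a,
        label_b=label_b,
        values_a=tuple(a),
        values_b=tuple(b),
        mean_a=float(np.mean(a)) if a else math.nan,
        mean_b=float(np.mean(b)) if b else math.nan,
        sem_a=sem(a),
        sem_b=sem(b),
        t=t,
        df=df,
        p=p,
        stars=stars(p) if p is not None else "",
    )


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values (optional, off by default)."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p_values[i])
        adjusted[i] = min(1.0, running)
    return adjusted


def write_comparison_tsv(comparisons: Sequence[GroupComparison], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "statistic\tgroup_a\tgroup_b\tmean_a\tsem_a\tmean_b\tsem_b\tt\tdf\tp\tstars\n"
        )
        for c in comparisons:
            fields = [
                c.statistic_name,
                c.label_a,
                c.label_b,
                f"{c.mean_a:.6g}",
                "" if c.sem_a is None else f"{c.sem_a:.6g}",
                f"{c.mean_b:.6g}",
                "" if c.sem_b is None else f"{c.sem_b:.6g}",
                "" if c.t is None else f"{c.t:.6g}",
                "" if c.df is None else f"{c.df:.6g}",
                "" if c.p is None else f"{c.p:.6g}",
                c.stars,
            ]
            fh.write("\t".join(fields) + "\n")


def plot_comparison(comparison: GroupComparison, path) -> None:
    """Bar plot of the two group means with SEM error bars and stars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3.2, 4))
    labels = [comparison.label_a, comparison.label_b]
    means = [comparison.mean_a, comparison.mean_b]
    sems = [comparison.sem_a or 0.0, comparison.sem_b or 0.0]
    ax.bar(labels, means, yerr=sems, capsize=4, color=["0.6", "0.1"])
    ax.set_ylabel(comparison.statistic_name)
    if comparison.stars:
        top = max(m + s for m, s in zip(means, sems))
        ax.text(0.5, top * 1.05, comparison.stars, ha="center", fontsize=14)
        ax.set_ylim(top=top * 1.2 if top > 0 else 1)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
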