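"""Variance partitioning, Tukey-Kramer grouping and capacity correlation.

One-way ANOVA is available both from raw per-group values and from summary
statistics alone (n, mean, SD per group), the latter because the unpaired
bootstrap leaves no raw per-replicate differences to decompose: the
within-group sum of squares is rebuilt as sum (n_i - 1) s_i^2 and the
among-group sum as sum n_i (m_i - grand)^2. Tukey's HSD uses the
Tukey-Kramer standard error for unequal group sizes and summarises the
pairwise pattern as a compact letter display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class GroupSummary:
    """(label, n, mean, dispersion) for one group.

    Provide either ``sd`` or ``sem`` (sd = sem * sqrt(n)); if both are given
    they must agree.
    """

    label: str
    n: int
    mean: float
    sd: float | None = None
    sem: float | None = None

    def __post_init__(self):
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: n must be >= 2, got {self.n}")
        if self.sd is None and self.sem is None:
            raise ValueError(f"group {self.label!r}: provide sd or sem")
        if self.sd is None:
            object.__setattr__(self, "sd", self.sem * math.sqrt(self.n))
        elif self.sem is not None and not math.isclose(
            self.sd, self.sem * math.sqrt(self.n), rel_tol=1e-6, abs_tol=1e-12
        ):
            raise ValueError(
                f"group {self.label!r}: sd {self.sd} inconsistent with "
                f"sem {self.sem} at n {self.n}"
            )
        if self.sd < 0:
            raise ValueError(f"group {self.label!r}: sd must be >= 0")


@dataclass(frozen=True)
class AnovaRow:
    source: str
    df: int
    ss: float
    ms: float | None = None
    f: float | None = None
    p: float | None = None


@dataclass(frozen=True)
class AnovaResult:
    """One-way decomposition with the percent-of-total variance partition."""

    rows: tuple[AnovaRow, ...]
    percent_among: float
    percent_within: float
    degenerate: bool = False  # zero within-variance or zero total SS

    def __getitem__(self, source: str) -> AnovaRow:
        for row in self.rows:
            if row.source == source:
                return row
        raise KeyError(source)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])


@dataclass(frozen=True)
class TukeyResult:
    """All-pairs Tukey-Kramer comparisons plus a compact letter display.

    Two groups share a letter iff their comparison is non-significant at
    ``alpha``.
    """

    comparisons: pd.DataFrame  # columns: group_1, group_2, mean_diff, q, p_adj, significant
    letters: dict[str, str]
    q_critical: float
    alpha: float


@dataclass(frozen=True)
class CorrelationResult:
    n: int
    r: float
    p: float


def anova_from_summaries(groups: list[GroupSummary]) -> AnovaResult:
    """One-way ANOVA rebuilt from per-group (n, mean, SD).

    Exactly equivalent to :func:`anova_raw` on the raw values the summaries
    were computed from. Zero within-group variance with non-zero among-group
    variance yields an infinite F with p = 0 and the result is flagged
    degenerate, as is a table with zero total SS.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    n = np.array([g.n for g in groups], dtype=float)
    m = np.array([g.mean for g in groups], dtype=float)
    s = np.array([g.sd for g in groups], dtype=float)

    n_total = n.sum()
    k = len(groups)
    grand = float((n * m).sum() / n_total)
    ss_among = float((n * (m - grand) ** 2).sum())
    ss_within = float(((n - 1) * s**2).sum())
    ss_total = ss_among + ss_within
    df_among = k - 1
    df_within = int(n_total) - k

    ms_among = ss_among / df_among
    ms_within = ss_within / df_within

    degenerate = False
    if ss_total == 0.0:
        f_stat, p = float("nan"), float("nan")
        degenerate = True
    elif ms_within == 0.0:
        f_stat, p = float("inf"), 0.0
        degenerate = True
    else:
        f_stat = ms_among / ms_within
        p = float(sps.f.sf(f_stat, df_among, df_within))

    pct_among = 100.0 * ss_among / ss_total if ss_total > 0 else float("nan")
    rows = (
        AnovaRow("among", df_among, ss_among, ms_among, f_stat, p),
        AnovaRow("within", df_within, ss_within, ms_within),
        AnovaRow("total", df_among + df_within, ss_total),
    )
    return AnovaResult(
        rows=rows,
        percent_among=pct_among,
        percent_within=100.0 - pct_among if ss_total > 0 else float("nan"),
        degenerate=degenerate,
    )


def anova_raw(groups: list[tuple[str, np.ndarray | list[float]]]) -> AnovaResult:
    """Conventional one-way ANOVA on raw per-group values.

    Computed directly from deviations (not by delegation), so agreement with
    :func:`anova_from_summaries` on the groups' computed summaries is a real
    cross-check of both routes.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = []
    for label, values in groups:
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise ValueError(f"group {label!r} has fewer than 2 values")
        arrays.append(v)

    all_values = np.concatenate(arrays)
    grand = all_values.mean()
    ss_total = float(((all_values - grand) ** 2).sum())
    ss_within = float(sum(((v - v.mean()) ** 2).sum() for v in arrays))
    ss_among = float(sum(v.size * (v.mean() - grand) ** 2 for v in arrays))

    k = len(arrays)
    df_among = k - 1
    df_within = all_values.size - k
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within

    degenerate = False
    if ss_total == 0.0:
        f_stat, p = float("nan"), float("nan")
        degenerate = True
    elif ms_within == 0.0:
        f_stat, p = float("inf"), 0.0
        degenerate = True
    else:
        f_stat = ms_among / ms_within
        p = float(sps.f.sf(f_stat, df_among, df_within))

    pct_among = 100.0 * ss_among / ss_total if ss_total > 0 else float("nan")
    rows = (
        AnovaRow("among", df_among, ss_among, ms_among, f_stat, p),
        AnovaRow("within", df_within, ss_within, ms_within),
        AnovaRow("total", df_among + df_within, ss_total),
    )
    return AnovaResult(
        rows=rows,
        percent_among=pct_among,
        percent_within=100.0 - pct_among if ss_total > 0 else float("nan"),
        degenerate=degenerate,
    )


def isolate_anova(estimates: pd.DataFrame, n_per_isolate: int = 4) -> AnovaResult:
    """Among-isolate ANOVA from per-isolate bootstrap summaries.

    Each isolate becomes a group (n = dish replicate count, mean = bootstrap
    mean, SD = bootstrap SD). Note the bootstrap SD describes the resampled
    mean-of-k, not the raw replicate spread, so the within-isolate stratum is
    narrower than a replicate-level ANOVA would give; this mirrors the
    summary-statistics procedure the capacity bootstrap feeds.
    """
    if estimates["isolate_id"].duplicated().any():
        dups = estimates.loc[estimates["isolate_id"].duplicated(), "isolate_id"]
        raise ValueError(f"duplicate isolates: {sorted(set(dups))}")
    groups = [
        GroupSummary(label=row.isolate_id, n=n_per_isolate,
                     mean=row.boot_mean, sd=row.boot_sd)
        for row in estimates.itertuples()
    ]
    return anova_from_summaries(groups)


def _studentized_range_q(
    mean_i: float, mean_j: float, n_i: int, n_j: int, ms_within: float
) -> float:
    # Tukey-Kramer SE for unequal n: sqrt((MSw/2)(1/n_i + 1/n_j))
    se = math.sqrt((ms_within / 2.0) * (1.0 / n_i + 1.0 / n_j))
    return abs(mean_i - mean_j) / se


def _compact_letter_display(
    labels: list[str],
    means: dict[str, float],
    significant: set[frozenset[str]],
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups are processed in descending mean order (ties broken by label) and
    letter sets are maximal cliques of the non-significance graph, so two
    groups share a letter iff their difference is non-significant.
    """
    order = sorted(labels, key=lambda g: (-means[g], g))
    sets: list[set[str]] = [set(order)]
    for i, gi in enumerate(order):
        for gj in order[i + 1:]:
            if frozenset((gi, gj)) not in significant:
                continue
            new_sets: list[set[str]] = []
            for s in sets:
                if gi in s and gj in s:
                    new_sets.extend((s - {gi}, s - {gj}))
                else:
                    new_sets.append(s)
            # absorb: drop empties, proper subsets and duplicates,
            # preserving insertion order for determinism
            candidates = [s for s in new_sets if s]
            sets = []
            for s in candidates:
                if any(s < t for t in candidates):
                    continue
                if s not in sets:
                    sets.append(s)
    # order letters by the highest-mean member of each set
    sets.sort(key=lambda s: min(order.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in labels}
    for letter, s in zip(alphabet, sets):
        for g in s:
            letters[g] += letter
    return letters


def tukey_hsd(
    groups: list[GroupSummary],
    ms_within: float,
    df_within: int,
    alpha: float = 0.05,
) -> TukeyResult:
    """Tukey-Kramer HSD from group summaries and the ANOVA error mean square.

    The q statistic for pair (i, j) is |m_i - m_j| divided by the
    Tukey-Kramer standard error sqrt((MS_within/2)(1/n_i + 1/n_j)); a pair
    differs significantly when q exceeds the studentized-range critical value
    q(alpha; k, df_within). Adjusted p-values are the studentized-range upper
    tail of q.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if ms_within <= 0:
        raise ValueError(f"ms_within must be > 0, got {ms_within}")
    if df_within < 1:
        raise ValueError(f"df_within must be >= 1, got {df_within}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")

    k = len(groups)
    q_crit = float(sps.studentized_range.ppf(1.0 - alpha, k, df_within))

    rows = []
    significant: set[frozenset[str]] = set()
    ordered = sorted(groups, key=lambda g: (-g.mean, g.label))
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = ordered[i], ordered[j]
            q = _studentized_range_q(gi.mean, gj.mean, gi.n, gj.n, ms_within)
            p_adj = float(sps.studentized_range.sf(q, k, df_within))
            sig = bool(q > q_crit)
            if sig:
                significant.add(frozenset((gi.label, gj.label)))
            rows.append({
                "group_1": gi.label,
                "group_2": gj.label,
                "mean_diff": gi.mean - gj.mean,
                "q": q,
                "p_adj": p_adj,
                "significant": sig,
            })

    letters = _compact_letter_display(
        [g.label for g in groups], {g.label: g.mean for g in groups}, significant
    )
    return TukeyResult(
        comparisons=pd.DataFrame(rows),
        letters=letters,
        q_critical=q_crit,
        alpha=alpha,
    )


def correlate_capacities(
    estimates_a: pd.DataFrame, estimates_b: pd.DataFrame
) -> CorrelationResult:
    """Pearson correlation of per-isolate capacities at two temperatures.

    Pairs the two capacity tables on isolate_id and correlates the bootstrap
    mean capacities; the two-sided p-value comes from the exact t transform
    t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.
    """
    ids_a = set(estimates_a["isolate_id"])
    ids_b = set(estimates_b["isolate_id"])
    if ids_a != ids_b:
        raise ValueError(
            "isolate sets differ between temperatures; symmetric difference: "
            f"{sorted(ids_a ^ ids_b)}"
        )
    a = estimates_a.set_index("isolate_id")["boot_mean"].sort_index()
    b = estimates_b.set_index("isolate_id")["boot_mean"].sort_index()
    n = len(a)
    if n < 3:
        raise ValueError(f"need at least 3 paired isolates, got {n}")
    r, p = sps.pearsonr(a.to_numpy(), b.to_numpy())
    return CorrelationResult(n=n, r=float(r), p=float(p))
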