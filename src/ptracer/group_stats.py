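"""One-way ANOVA with Student–Newman–Keuls letter groupings and mean ± SE summaries.

The SNK procedure is implemented directly from the studentized-range
distribution: means are sorted, ranges are tested stepwise from the widest
span inward, and a span containing a previously non-significant span is
not declared significant (the standard step-down protection). Letters are
assigned so that two groups share a letter iff their difference was not
declared significant.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GroupStatsError",
    "AnovaResult",
    "GroupSummary",
    "SNKResult",
    "anova_one_way",
    "snk_letters",
    "summarize_mean_se",
]


class GroupStatsError(ValueError):
    pass


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    ms_within: float
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: float
    se: float
    letters: str = ""


@dataclass(frozen=True)
class SNKResult:
    summaries: tuple[GroupSummary, ...]
    anova: AnovaResult
    alpha: float
    #: pairs of group labels whose means differ significantly
    significant_pairs: frozenset[frozenset[str]]
    flags: tuple[str, ...] = ()

    def letters(self) -> dict[str, str]:
        return {s.group: s.letters for s in self.summaries}


def _validate(data: Mapping[str, Sequence[float]], min_n: int = 2) -> dict[str, np.ndarray]:
    if len(data) < 2:
        raise GroupStatsError("need at least 2 groups")
    arrays = {str(k): np.asarray(v, dtype=float) for k, v in data.items()}
    for k, a in arrays.items():
        if a.size < min_n:
            raise GroupStatsError(f"group {k!r} needs n >= {min_n}")
    return arrays


def anova_one_way(data: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA: between/within decomposition, F and p.

    With zero within-group variance and equal means the F ratio is
    undefined; it is reported as NaN with a flag rather than raised.
    """
    arrays = _validate(data)
    k = len(arrays)
    n_total = sum(a.size for a in arrays.values())
    grand = np.concatenate(list(arrays.values())).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df_b, df_w = k - 1, n_total - k
    ms_w = ss_within / df_w
    if ms_w == 0:
        if ss_between == 0:
            return AnovaResult(float("nan"), float("nan"), df_b, df_w, 0.0,
                               flags=("zero-variance-equal-means",))
        return AnovaResult(float("inf"), 0.0, df_b, df_w, 0.0,
                           flags=("zero-within-variance",))
    F = (ss_between / df_b) / ms_w
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(float(F), p, df_b, df_w, float(ms_w))


def summarize_mean_se(data: Mapping[str, Sequence[float]]) -> list[GroupSummary]:
    """Per-group mean and standard error of the mean (SD/√n, ddof=1)."""
    arrays = _validate(data)
    return [
        GroupSummary(k, a.size, float(a.mean()), float(a.std(ddof=1) / np.sqrt(a.size)))
        for k, a in arrays.items()
    ]


def snk_letters(data: Mapping[str, Sequence[float]], alpha: float = 0.05) -> SNKResult:
    """Student–Newman–Keuls multiple comparisons with a compact letter display.

    Means are ordered descending (ties broken by group label) and every
    pair (i, j) spanning p ranks is tested against the studentized-range
    critical value q(alpha, p, df_within) at the pooled within-group mean
    square. Unequal group sizes use the harmonic-mean n (flagged). Letters
    form a cover of the non-significant ranges: groups sharing no letter
    differ at ``alpha``.
    """
    if not (0 < alpha < 1):
        raise GroupStatsError("alpha must be in (0, 1)")
    arrays = _validate(data)
    anova = anova_one_way(data)
    flags: list[str] = list(anova.flags)

    order = sorted(arrays, key=lambda g: (-arrays[g].mean(), g))
    means = np.array([arrays[g].mean() for g in order])
    sizes = np.array([arrays[g].size for g in order])
    k = len(order)

    if len(set(sizes)) > 1:
        n_eff = stats.hmean(sizes)
        flags.append("unequal-n-harmonic-mean")
    else:
        n_eff = float(sizes[0])

    sig: set[frozenset[str]] = set()
    if anova.ms_within > 0:
        se_q = np.sqrt(anova.ms_within / n_eff)
        # step-down by span width; a range inside a non-significant range is
        # never declared significant
        nonsig_spans: list[tuple[int, int]] = []
        for span in range(k, 1, -1):
            qcrit = stats.studentized_range.ppf(1 - alpha, span, anova.df_within)
            for i in range(0, k - span + 1):
                j = i + span - 1
                if any(lo <= i and j <= hi for lo, hi in nonsig_spans):
                    nonsig_spans.append((i, j))
                    continue
                q = (means[i] - means[j]) / se_q
                if q > qcrit:
                    sig.add(frozenset((order[i], order[j])))
                else:
                    nonsig_spans.append((i, j))
    elif anova.ms_within == 0 and "zero-within-variance" in flags:
        # degenerate: any mean difference is significant
        for i, j in itertools.combinations(range(k), 2):
            if means[i] != means[j]:
                sig.add(frozenset((order[i], order[j])))

    letters = _letter_display(order, sig)
    base = {s.group: s for s in summarize_mean_se(data)}
    summaries = tuple(
        GroupSummary(g, base[g].n, base[g].mean, base[g].se, letters[g]) for g in order
    )
    return SNKResult(summaries, anova, alpha, frozenset(sig), tuple(flags))


def _letter_display(order: list[str], sig: set[frozenset[str]]) -> dict[str, str]:
    """Insert-and-absorb compact letter display over descending-ordered groups."""
    k = len(order)
    # maximal runs of consecutive, mutually non-significant groups
    groupsets: list[set[str]] = []
    for i in range(k):
        cur = {order[i]}
        j = i
        while j + 1 < k and all(
            frozenset((order[j + 1], g)) not in sig for g in cur
        ):
            j += 1
            cur.add(order[j])
        groupsets.append(cur)
    maximal = [s for s in groupsets if not any(s < t for t in groupsets)]
    # dedupe preserving order
    seen: list[set[str]] = []
    for s in maximal:
        if s not in seen:
            seen.append(s)
    letters = {g: "" for g in order}
    for letter, s in zip(string.ascii_lowercase, seen):
        for g in order:
            if g in s:
                letters[g] += letter
    return letters
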