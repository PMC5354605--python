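"""Statistical layer: SEM summaries, unpaired t test, one-way ANOVA + Tukey.

The inferential toolkit matches what bench scientists run in Prism for this
kind of validation data: two groups get a two-sided unpaired Student t test
(pooled variance; Welch optional), three or more groups get an ordinary
one-way ANOVA with Tukey's HSD multiple-comparison post-test, and every
summary is mean +/- SEM.  Significance stars follow the usual convention
(* p<0.05, ** p<0.01, *** p<0.001).

Group data may be raw values or published-style summaries (mean, SEM, n);
the summary path reconstructs t = (m1-m2)/sqrt(SEM1^2+SEM2^2) with
df = n1+n2-2, which is what reproducing a printed comparison requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TestResult",
    "sem",
    "significance_stars",
    "unpaired_t",
    "anova_tukey",
    "write_report",
]


def sem(values) -> float:
    """Standard error of the mean: sample SD (n-1 denominator) / sqrt(n)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("SEM needs at least two values")
    return float(arr.std(ddof=1) / np.sqrt(arr.size))


def significance_stars(p: float) -> str:
    """'***' p<0.001, '**' p<0.01, '*' p<0.05, 'ns' otherwise."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class GroupSummary:
    """mean +/- SEM summary of one group (n = replication units)."""

    label: str
    n: int
    mean: float
    sem: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summaries need n >= 2")
        if self.sem < 0:
            raise ValueError("SEM must be non-negative")

    @classmethod
    def from_values(cls, values, label: str = "") -> "GroupSummary":
        arr = np.asarray(values, dtype=float)
        return cls(label=label, n=arr.size, mean=float(arr.mean()), sem=sem(arr))


@dataclass
class TestResult:
    """Outcome of one statistical test."""

    test: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    stars: str = ""
    pairwise: pd.DataFrame | None = None  # Tukey-adjusted pairwise table
    groups: list[GroupSummary] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")
        if not self.stars:
            self.stars = significance_stars(self.p_value)


def _as_summary(group, label: str) -> tuple[GroupSummary, np.ndarray | None]:
    if isinstance(group, GroupSummary):
        return group, None
    arr = np.asarray(group, dtype=float)
    if arr.size < 2:
        raise ValueError("t test needs n >= 2 per group")
    return GroupSummary.from_values(arr, label), arr


def unpaired_t(group_a, group_b, welch: bool = False) -> TestResult:
    """Two-sided unpaired t test on raw values or (mean, SEM, n) summaries.

    With raw values this is the Student pooled-variance test (or Welch when
    requested).  With :class:`GroupSummary` inputs the statistic is
    reconstructed from the printed summaries: t = dmean / sqrt(SEM_a^2 +
    SEM_b^2), df = n_a + n_b - 2 (pooled) or Welch-Satterthwaite.
    """
    sa, raw_a = _as_summary(group_a, "A")
    sb, raw_b = _as_summary(group_b, "B")
    if raw_a is not None and raw_b is not None:
        t, p = sps.ttest_ind(raw_a, raw_b, equal_var=not welch)
        if welch:
            va, vb = raw_a.var(ddof=1) / sa.n, raw_b.var(ddof=1) / sb.n
            df = (va + vb) ** 2 / (va**2 / (sa.n - 1) + vb**2 / (sb.n - 1))
        else:
            df = sa.n + sb.n - 2
        t, p, df = float(t), float(p), float(df)
    else:
        se = np.sqrt(sa.sem**2 + sb.sem**2)
        if se == 0:
            t = 0.0
        else:
            t = (sa.mean - sb.mean) / se
        if welch:
            va, vb = sa.sem**2, sb.sem**2
            df = (va + vb) ** 2 / (va**2 / (sa.n - 1) + vb**2 / (sb.n - 1))
        else:
            df = sa.n + sb.n - 2
        p = float(2.0 * sps.t.sf(abs(t), df))
    name = "Welch t test" if welch else "unpaired t test"
    return TestResult(test=name, statistic=float(t), df=(float(df),),
                      p_value=min(p, 1.0), groups=[sa, sb])


def anova_tukey(groups: list, labels: list[str] | None = None) -> TestResult:
    """Ordinary one-way ANOVA with Tukey's HSD post-test on >= 3 groups.

    Returns the overall F and p plus a pairwise table (group_a, group_b,
    mean_diff, p_unadj, p_adj, stars): ``p_adj`` is the Tukey-adjusted
    p-value from the studentized-range distribution, ``p_unadj`` the
    corresponding unadjusted comparison (Fisher LSD: a t test on the same
    pooled error term), so p_adj >= p_unadj always holds.  Groups with no
    variance anywhere yield F = 0, p = 1.
    """
    if len(groups) < 3:
        raise ValueError("one-way ANOVA post-test path expects >= 3 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs n >= 2")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(arrays))]
    F, p = sps.f_oneway(*arrays)
    if np.isnan(F):  # all values identical in every group: no variance at all
        F, p = 0.0, 1.0
    k = len(arrays)
    N = sum(a.size for a in arrays)
    mse = sum(a.size * a.var(ddof=0) for a in arrays) / (N - k)  # pooled error
    with np.errstate(invalid="ignore"):  # all-constant groups: 0/0 below
        hsd = sps.tukey_hsd(*arrays)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(arrays[i].mean() - arrays[j].mean())
            padj = float(hsd.pvalue[i, j])
            if np.isnan(padj):  # zero pooled variance: no evidence of a difference
                padj = 1.0
            se = np.sqrt(mse * (1.0 / arrays[i].size + 1.0 / arrays[j].size))
            if se > 0:
                p_unadj = float(2.0 * sps.t.sf(abs(diff) / se, N - k))
            else:
                p_unadj = 1.0
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "mean_diff": diff,
                    "p_unadj": p_unadj,
                    "p_adj": padj,
                    "stars": significance_stars(padj),
                }
            )
    summaries = [GroupSummary.from_values(a, lab) for a, lab in zip(arrays, labels)]
    return TestResult(
        test="one-way ANOVA + Tukey HSD",
        statistic=float(F),
        df=(float(k - 1), float(N - k)),
        p_value=float(min(max(p, 0.0), 1.0)),
        pairwise=pd.DataFrame(rows),
        groups=summaries,
    )


def write_report(results: list[TestResult], path_tsv, path_txt=None) -> None:
    """Write a figure-style report: group summaries and tests.

    ``path_tsv`` gets a machine-readable table (one row per test plus one
    per pairwise comparison); ``path_txt`` an aligned plain-text summary.
    """
    rows = []
    lines = []
    for res in results:
        dfstr = ",".join(f"{d:g}" for d in res.df)
        rows.append(
            {
                "test": res.test,
                "comparison": " vs ".join(g.label for g in res.groups),
                "statistic": res.statistic,
                "df": dfstr,
                "p_value": res.p_value,
                "stars": res.stars,
            }
        )
        lines.append(f"{res.test}: statistic={res.statistic:.4g} df={dfstr} "
                     f"p={res.p_value:.4g} {res.stars}")
        for g in res.groups:
            lines.append(f"  {g.label}: mean={g.mean:.4g} SEM={g.sem:.4g} n={g.n}")
        if res.pairwise is not None:
            for _, pr in res.pairwise.iterrows():
                rows.append(
                    {
                        "test": res.test + " (pairwise)",
                        "comparison": f"{pr.group_a} vs {pr.group_b}",
                        "statistic": pr.mean_diff,
                        "df": dfstr,
                        "p_value": pr.p_adj,
                        "stars": pr.stars,
                    }
                )
                lines.append(
                    f"  {pr.group_a} vs {pr.group_b}: diff={pr.mean_diff:.4g} "
                    f"p_adj={pr.p_adj:.4g} {pr.stars}"
                )
    pd.DataFrame(rows).to_csv(path_tsv, sep="\t", index=False)
    if path_txt is not None:
        with open(path_txt, "w") as fh:
            fh.write("\n".join(lines) + "\n")
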