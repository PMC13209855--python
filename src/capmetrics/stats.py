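"""One-way ANOVA, Tukey HSD, and compact-letter-display grouping.

Bench tables in this field report each metric as mean ± SD with n = 3
analytical replicates and superscript letters marking homogeneous Tukey
groups.  This module supports both raw replicates and summary statistics
(mean, SD, n) as first-class inputs: the summary path uses the pooled
within-group mean square MS_w = Σ(nᵢ−1)sᵢ² / Σ(nᵢ−1) and the group means
directly, and agrees exactly with the raw path when the raw data realize
the same summaries.

Tukey p-values come from the studentized range distribution with the
Tukey–Kramer standard error for unequal group sizes.  Letters are assigned
with the insert-and-absorb algorithm scanning groups by descending mean
("a" = largest), so two groups share a letter iff their difference is not
significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateVarianceError

__all__ = [
    "GroupData",
    "AnovaResult",
    "PairwiseComparison",
    "check_assumptions",
    "anova_oneway",
    "tukey_hsd",
    "compact_letter_display",
    "tukey_family_error_rate",
    "render_report",
]


@dataclass
class GroupData:
    """Either raw replicate values per group or (mean, sd, n) summaries."""

    labels: list[str]
    means: np.ndarray
    sds: np.ndarray
    ns: np.ndarray
    raw: dict[str, np.ndarray] | None = None

    @classmethod
    def from_raw(cls, groups: dict) -> "GroupData":
        labels = list(groups)
        if len(labels) < 2:
            raise ValueError("need at least two groups")
        raw = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
        for k, v in raw.items():
            if v.size < 2:
                raise ValueError(f"group '{k}' needs n >= 2, got {v.size}")
        return cls(
            labels=labels,
            means=np.array([raw[k].mean() for k in labels]),
            sds=np.array([raw[k].std(ddof=1) for k in labels]),
            ns=np.array([raw[k].size for k in labels]),
            raw=raw,
        )

    @classmethod
    def from_summary(cls, labels, means, sds, ns) -> "GroupData":
        labels = list(labels)
        if len(labels) < 2:
            raise ValueError("need at least two groups")
        ns = np.asarray(ns, dtype=int)
        if np.any(ns < 2):
            raise ValueError("each group needs n >= 2")
        return cls(
            labels=labels,
            means=np.asarray(means, dtype=float),
            sds=np.asarray(sds, dtype=float),
            ns=ns,
            raw=None,
        )

    @classmethod
    def from_summary_dict(cls, d: dict, n: int = 3) -> "GroupData":
        """From ``{label: (mean, sd)}`` with a common n (default triplicate)."""
        labels = list(d)
        return cls.from_summary(
            labels,
            [d[k][0] for k in labels],
            [d[k][1] for k in labels],
            [n] * len(labels),
        )

    @property
    def k(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    ms_within: float
    df_within: int
    df_between: int


@dataclass(frozen=True)
class PairwiseComparison:
    label_a: str
    label_b: str
    mean_difference: float  # mean(a) - mean(b)
    q_statistic: float
    p_adjusted: float
    significant: bool


def check_assumptions(g: GroupData) -> tuple[dict[str, float], float]:
    """Shapiro–Wilk normality p per group and Levene homogeneity p.

    Advisory only; requires raw replicates (summary-only input returns
    NaN markers).  Degenerate (constant) groups get NaN normality p.
    """
    if g.raw is None:
        return {lb: float("nan") for lb in g.labels}, float("nan")
    norm_p = {}
    for lb in g.labels:
        v = g.raw[lb]
        if np.ptp(v) == 0 or v.size < 3:
            norm_p[lb] = float("nan")
        else:
            norm_p[lb] = float(sps.shapiro(v).pvalue)
    lev = sps.levene(*[g.raw[lb] for lb in g.labels])
    return norm_p, float(lev.pvalue)


def _pooled_within(g: GroupData) -> tuple[float, int]:
    df_w = int(np.sum(g.ns - 1))
    ms_w = float(np.sum((g.ns - 1) * g.sds**2) / df_w)
    return ms_w, df_w


def anova_oneway(g: GroupData) -> AnovaResult:
    """Classical one-way decomposition, valid for raw or summary input."""
    ms_w, df_w = _pooled_within(g)
    grand = float(np.sum(g.ns * g.means) / np.sum(g.ns))
    ss_b = float(np.sum(g.ns * (g.means - grand) ** 2))
    df_b = g.k - 1
    if ms_w == 0 and ss_b == 0:
        raise DegenerateVarianceError(
            "all values identical across all groups; F undefined"
        )
    if ms_w == 0:
        raise DegenerateVarianceError("zero within-group variance; F undefined")
    f = (ss_b / df_b) / ms_w
    p = float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(
        f_statistic=float(f), p_value=p, ms_within=ms_w,
        df_within=df_w, df_between=df_b,
    )


def tukey_hsd(g: GroupData, alpha: float = 0.05) -> list[PairwiseComparison]:
    """All k(k−1)/2 pairwise comparisons with studentized-range adjusted
    p-values (Tukey–Kramer SE for unequal n); significant iff p ≤ alpha."""
    ms_w, df_w = _pooled_within(g)
    if ms_w == 0:
        raise DegenerateVarianceError("zero within-group variance")
    out = []
    for i in range(g.k):
        for j in range(i + 1, g.k):
            diff = g.means[i] - g.means[j]
            se = np.sqrt(ms_w / 2.0 * (1.0 / g.ns[i] + 1.0 / g.ns[j]))
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, g.k, df_w))
            p = min(1.0, max(0.0, p))
            out.append(
                PairwiseComparison(
                    label_a=g.labels[i],
                    label_b=g.labels[j],
                    mean_difference=float(diff),
                    q_statistic=float(q),
                    p_adjusted=p,
                    significant=bool(p <= alpha),
                )
            )
    return out


def compact_letter_display(
    comparisons: list[PairwiseComparison],
    means: dict[str, float],
) -> dict[str, str]:
    """Letter codes such that two groups share a letter iff their pairwise
    difference is not significant.

    Insert-and-absorb: start from one letter covering all groups; for every
    significant pair split each letter containing both; absorb letters that
    became subsets of others.  Letters are ordered by descending group mean,
    so "a" always contains the largest mean.
    """
    labels = sorted(means, key=lambda lb: -means[lb])
    rank = {lb: i for i, lb in enumerate(labels)}
    cols: list[frozenset] = [frozenset(labels)]
    for cmp_ in comparisons:
        if not cmp_.significant:
            continue
        a, b = cmp_.label_a, cmp_.label_b
        new_cols: list[frozenset] = []
        for col in cols:
            if a in col and b in col:
                new_cols.append(col - {a})
                new_cols.append(col - {b})
            else:
                new_cols.append(col)
        # absorb: drop duplicates and proper/equal subsets of other columns
        new_cols = [c for c in new_cols if c]
        kept: list[frozenset] = []
        for c in sorted(set(new_cols), key=len, reverse=True):
            if not any(c < other or c == other for other in kept):
                kept.append(c)
        cols = kept
    cols.sort(key=lambda col: min(rank[lb] for lb in col))
    letters = {lb: "" for lb in labels}
    for i, col in enumerate(cols):
        ch = _letter(i)
        for lb in col:
            letters[lb] += ch
    return {lb: "".join(sorted(letters[lb])) for lb in labels}


def _letter(i: int) -> str:
    # a..z, then aa, ab, ... for pathological cases
    if i < 26:
        return chr(ord("a") + i)
    return _letter(i // 26 - 1) + chr(ord("a") + i % 26)


def tukey_family_error_rate(
    k: int = 9,
    n: int = 3,
    reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Monte-Carlo family-wise error rate of the Tukey procedure under the
    global null (all group means equal, unit variance).

    Equivalent to running :func:`tukey_hsd` per replicate and asking whether
    any pair is declared significant; implemented via the maximum studentized
    range against the critical quantile for speed.
    """
    rng = np.random.default_rng(seed)
    df_w = k * (n - 1)
    q_crit = sps.studentized_range.ppf(1 - alpha, k, df_w)
    data = rng.normal(size=(reps, k, n))
    means = data.mean(axis=2)
    ms_w = data.var(axis=2, ddof=1).mean(axis=1)
    rng_means = means.max(axis=1) - means.min(axis=1)
    q_max = rng_means / np.sqrt(ms_w / n)
    return float(np.mean(q_max > q_crit))


def render_report(
    out_dir,
    qc_tables: dict[str, pd.DataFrame] | None = None,
    size_summaries: dict[str, "object"] | None = None,
    letters: dict[str, dict[str, str]] | None = None,
    decimals: int = 2,
) -> dict:
    """Write report CSVs shaped like the study's tables and return a manifest.

    *qc_tables* maps metric name -> frame with columns (formulation, mean,
    sd, n); *letters* maps metric name -> {formulation: letters}.  Each
    metric becomes one CSV with a formatted "mean ± SD ^letters^" column.
    *size_summaries* maps formulation -> SizeSummary.  Sections with no
    input are noted as absent in the manifest.
    """
    from pathlib import Path

    from .powder import round_half_up

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"written": [], "absent": []}

    if qc_tables:
        for metric, frame in qc_tables.items():
            frame = frame.copy()
            lets = (letters or {}).get(metric, {})
            frame["letters"] = [lets.get(f, "") for f in frame["formulation"]]
            frame["formatted"] = [
                f"{round_half_up(m, decimals):.{decimals}f} ± "
                f"{round_half_up(s, decimals):.{decimals}f}"
                + (f" {l}" if l else "")
                for m, s, l in zip(frame["mean"], frame["sd"], frame["letters"])
            ]
            path = out / f"qc_{metric}.csv"
            frame.to_csv(path, index=False)
            manifest["written"].append(path.name)
    else:
        manifest["absent"].append("qc_tables")

    if size_summaries:
        rows = []
        for code, s in size_summaries.items():
            rows.append({"formulation": code, **s.to_dict()})
        path = out / "size_summary.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        manifest["written"].append(path.name)
    else:
        manifest["absent"].append("size_summaries")

    return manifest
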