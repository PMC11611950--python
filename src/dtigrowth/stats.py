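"""Group-level statistics for the TP-vs-TRA comparison.

TP (tumor progression) and TRA (treatment-related abnormalities) subjects
are compared on their parallel and perpendicular growth percentages and on
ROI mean FA with Mann-Whitney U tests; the pooled parallel-vs-perpendicular
contrast is a one-sample t test on per-subject differences with Cohen's d;
normality screening uses a Lilliefors-corrected Kolmogorov-Smirnov test with
a seeded Monte-Carlo null (the statistic is distribution-free under the
normal null, so the null table depends only on the sample size).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DomainError

__all__ = [
    "TestResult",
    "lilliefors_normality",
    "mann_whitney_u",
    "one_sample_t",
    "cohens_d_one_sample",
    "mean_ci95",
    "cohort_compare",
    "report_markdown",
]

GROUPS = ("TP", "TRA")


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int | None = None
    effect_size: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise DomainError("p-value outside [0, 1]")

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def _as_sample(x, min_n: int, name: str = "sample") -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < min_n:
        raise DomainError(f"{name} needs at least {min_n} observations, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise DomainError(f"{name} contains non-finite values")
    return arr


def lilliefors_statistic(samples: np.ndarray) -> np.ndarray:
    """KS distance against a normal with estimated mean/SD, row-wise.

    ``samples`` is ``(m, n)``; returns ``m`` statistics.  Vectorised so that
    Monte-Carlo calibration over thousands of datasets stays cheap.
    """
    x = np.sort(np.asarray(samples, dtype=float), axis=-1)
    n = x.shape[-1]
    mu = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise DomainError("degenerate sample: zero standard deviation")
    cdf = sps.norm.cdf((x - mu) / sd)
    i = np.arange(1, n + 1)
    d_plus = (i / n - cdf).max(axis=-1)
    d_minus = (cdf - (i - 1) / n).max(axis=-1)
    return np.maximum(d_plus, d_minus)


@lru_cache(maxsize=32)
def lilliefors_null_table(n: int, n_reps: int, seed: int) -> np.ndarray:
    """Sorted Monte-Carlo null distribution of the Lilliefors statistic."""
    rng = np.random.default_rng(seed)
    null = lilliefors_statistic(rng.standard_normal((n_reps, n)))
    null.sort()
    return null


def lilliefors_normality(sample, n_reps: int = 20_000, seed: int = 0) -> TestResult:
    """Lilliefors test of composite normality with a Monte-Carlo p-value.

    The p-value is ``(1 + #{null >= observed}) / (n_reps + 1)``, the standard
    positively biased Monte-Carlo estimator.
    """
    x = _as_sample(sample, 4)
    if np.ptp(x) == 0:
        raise DomainError("degenerate sample: all values identical")
    stat = float(lilliefors_statistic(x[None, :])[0])
    null = lilliefors_null_table(x.size, n_reps, seed)
    n_ge = null.size - np.searchsorted(null, stat, side="left")
    p = (1 + n_ge) / (n_reps + 1)
    return TestResult(statistic=stat, p_value=float(min(p, 1.0)),
                      method=f"lilliefors-mc({n_reps})", n1=x.size)


def mann_whitney_u(a, b) -> TestResult:
    """Two-sided Mann-Whitney U test with midrank ties.

    Exact by enumeration when ``n1 + n2 <= 12`` and the pooled data are
    tie-free; otherwise the normal approximation with tie and continuity
    correction.  The U of identical distributions' centre (U = n1*n2/2) maps
    to p = 1 exactly.
    """
    x = _as_sample(a, 1, "a")
    y = _as_sample(b, 1, "b")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= 12 and tie_free) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    u = float(res.statistic)
    p = 1.0 if u == x.size * y.size / 2 else float(res.pvalue)
    return TestResult(statistic=u, p_value=min(p, 1.0),
                      method=f"mann-whitney-u-{method}", n1=x.size, n2=y.size)


def one_sample_t(diffs, mu0: float = 0.0) -> TestResult:
    """Two-sided one-sample Student's t test against ``mu0``."""
    x = _as_sample(diffs, 2, "diffs")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DomainError("zero standard deviation")
    t = (x.mean() - mu0) / (sd / np.sqrt(x.size))
    p = 2 * sps.t.sf(abs(t), df=x.size - 1)
    return TestResult(statistic=float(t), p_value=float(min(p, 1.0)),
                      method="one-sample-t", n1=x.size,
                      effect_size=cohens_d_one_sample(x - mu0))


def cohens_d_one_sample(diffs) -> float:
    """d = mean / SD (n-1 denominator) of the differences."""
    x = _as_sample(diffs, 2, "diffs")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DomainError("zero standard deviation")
    return float(x.mean() / sd)


def mean_ci95(sample):
    """Mean with its 95% t-based confidence interval, as (mean, lower, upper)."""
    x = _as_sample(sample, 2)
    mean = x.mean()
    half = sps.t.ppf(0.975, df=x.size - 1) * x.std(ddof=1) / np.sqrt(x.size)
    return float(mean), float(mean - half), float(mean + half)


_REQUIRED_COLS = ("subject_id", "group", "parallel_pct", "perpendicular_pct", "mean_fa")


def _validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED_COLS if c not in table.columns]
    if missing:
        raise DomainError(f"cohort table missing columns: {missing}")
    if table["subject_id"].duplicated().any():
        raise DomainError("subject_ids must be unique")
    bad = set(table["group"]) - set(GROUPS)
    if bad:
        raise DomainError(f"unknown group labels: {sorted(bad)}")
    for g in GROUPS:
        if (table["group"] == g).sum() < 2:
            raise DomainError(f"group {g} needs at least 2 subjects")
    return table


def cohort_compare(table: pd.DataFrame, per_bin_tests: bool = False,
                   holm: bool = False, normality_seed: int = 0) -> dict:
    """Full group comparison report for a cohort of growth summaries.

    Parameters
    ----------
    table
        One row per subject with columns ``subject_id``, ``group`` (TP/TRA),
        ``parallel_pct``, ``perpendicular_pct``, ``mean_fa`` (and optionally
        ``bin_0_10`` ... ``bin_80_90``).
    per_bin_tests
        Additionally run a TP-vs-TRA Mann-Whitney test per 10-degree bin.
    holm
        Apply a Holm correction over the three primary between-group tests
        (off by default: the primary report mirrors uncorrected testing).

    Returns
    -------
    dict
        JSON-serialisable report: group means with 95% CIs, Mann-Whitney
        TP-vs-TRA p-values, pooled parallel-vs-perpendicular t test with
        Cohen's d, and normality screening of the pooled vector groups.
    """
    table = _validate_cohort(table)
    tp = table[table["group"] == "TP"]
    tra = table[table["group"] == "TRA"]

    report = {"n": {"TP": int(len(tp)), "TRA": int(len(tra))}, "groups": {}}
    for name, sub in (("TP", tp), ("TRA", tra), ("all", table)):
        entry = {}
        for var in ("parallel_pct", "perpendicular_pct", "mean_fa"):
            mean, lo, hi = mean_ci95(sub[var])
            entry[var] = {"mean": mean, "ci95": [lo, hi],
                          "sd": float(sub[var].std(ddof=1))}
        report["groups"][name] = entry

    tests = {}
    for var in ("parallel_pct", "perpendicular_pct", "mean_fa"):
        tests[var] = mann_whitney_u(tp[var], tra[var]).as_dict()
    if holm:
        order = np.argsort([tests[v]["p_value"] for v in tests])
        names = list(tests)
        m = len(names)
        adj, prev = {}, 0.0
        for rank, j in enumerate(order):
            p = min(1.0, (m - rank) * tests[names[j]]["p_value"])
            prev = max(prev, p)
            adj[names[j]] = prev
        for v in names:
            tests[v]["p_holm"] = adj[v]
    report["between_group_mwu"] = tests

    diffs = table["parallel_pct"].to_numpy() - table["perpendicular_pct"].to_numpy()
    tres = one_sample_t(diffs)
    report["parallel_vs_perpendicular"] = {
        **tres.as_dict(), "cohens_d": cohens_d_one_sample(diffs)}

    normality = {}
    for var in ("parallel_pct", "perpendicular_pct"):
        try:
            normality[var] = lilliefors_normality(
                table[var], seed=normality_seed).as_dict()
        except DomainError as exc:   # e.g. a constant sample
            normality[var] = {"error": str(exc)}
    report["normality"] = normality

    if per_bin_tests:
        bins = {}
        for i in range(9):
            col = f"bin_{10*i}_{10*(i+1)}"
            if col in table.columns:
                bins[col] = mann_whitney_u(tp[col], tra[col]).as_dict()
        report["per_bin_mwu"] = bins
    return report


def report_markdown(report: dict) -> str:
    """Render a cohort report as a Markdown table block."""
    lines = ["| quantity | TP mean (95% CI) | TRA mean (95% CI) | MWU p |",
             "|---|---|---|---|"]
    labels = {"parallel_pct": "parallel growth %",
              "perpendicular_pct": "perpendicular growth %",
              "mean_fa": "mean FA"}
    for var, label in labels.items():
        cells = []
        for g in GROUPS:
            e = report["groups"][g][var]
            cells.append(f"{e['mean']:.3g} ({e['ci95'][0]:.3g}-{e['ci95'][1]:.3g})")
        p = report["between_group_mwu"][var]["p_value"]
        lines.append(f"| {label} | {cells[0]} | {cells[1]} | {p:.3g} |")
    t = report["parallel_vs_perpendicular"]
    lines.append("")
    lines.append(
        f"Parallel vs perpendicular (pooled, one-sample t on differences): "
        f"t = {t['statistic']:.3g}, p = {t['p_value']:.3g}, "
        f"Cohen's d = {t['cohens_d']:.2f} "
        f"(n = {t['n1']})")
    return "\n".join(lines)
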