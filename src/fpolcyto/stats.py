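"""Grouped Fpol statistics: summaries, Student t-tests, Bonferroni correction.

Cells are grouped by diagnosis class (malignant / benign / normal) and
processing method (automated AU vs manual MA). AU-vs-MA comparisons on
matched cells use paired two-tailed t-tests; between-diagnosis
comparisons, where no cell correspondence exists, use unpaired two-sample
Student tests with pooled variance. Significance is Bonferroni-corrected
over the family of comparisons at alpha = 0.01.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_ALPHA = 0.01


@dataclasses.dataclass(frozen=True)
class GroupSummary:
    """Per-group cell count, mean Fpol, and sample SD (n-1 denominator)."""

    group_label: str
    n: int
    mean_fpol: float
    sd_fpol: float


@dataclasses.dataclass(frozen=True)
class TestReport:
    comparison: str
    test_type: str  # "paired" or "unpaired"
    t: float
    p: float
    m: int
    alpha: float
    significant: bool


def summarize_groups(
    cells: pd.DataFrame,
    by: Sequence[str] = ("diagnosis", "method"),
    value: str = "fpol",
) -> list[GroupSummary]:
    """Mean +/- SD Fpol per group of the per-cell table.

    ``cells`` needs the grouping columns plus a ``fpol`` column. Groups
    with a single cell report SD 0 with a warning; empty groups cannot
    occur under pandas groupby and are simply absent.
    """
    for col in (*by, value):
        if col not in cells.columns:
            raise KeyError(f"cell table lacks required column {col!r}")
    out = []
    for key, grp in cells.groupby(list(by), sort=True):
        vals = grp[value].to_numpy(dtype=np.float64)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            warnings.warn(f"group {key} has no finite Fpol values; omitted")
            continue
        if vals.size == 1:
            warnings.warn(f"group {key} has a single cell; SD reported as 0")
            sd = 0.0
        else:
            sd = float(vals.std(ddof=1))
        label = key if isinstance(key, str) else "/".join(str(k) for k in key)
        out.append(GroupSummary(group_label=label, n=int(vals.size), mean_fpol=float(vals.mean()), sd_fpol=sd))
    return out


def ttest(
    a: Sequence[float],
    b: Sequence[float],
    mode: str = "unpaired",
    comparison: str = "",
    m: int = 1,
    alpha: float = DEFAULT_ALPHA,
) -> TestReport:
    """Two-tailed Student t-test between two Fpol samples.

    ``mode='paired'`` treats ``a`` and ``b`` as matched sequences (e.g.
    AU vs MA values of the same cells); ``mode='unpaired'`` uses the
    classical pooled-variance two-sample test. The significance flag
    applies the Bonferroni-corrected threshold ``alpha / m``.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if mode == "paired":
        if a.shape != b.shape:
            raise ValueError("paired test requires equal-length matched sequences")
        if a.size < 2:
            raise ValueError("paired test requires n >= 2")
        diffs = a - b
        if np.allclose(diffs.std(ddof=1), 0.0):
            if np.allclose(diffs, 0.0):
                t, p = 0.0, 1.0  # identical sequences: no evidence of difference
            else:
                t, p = np.inf * np.sign(diffs.mean()), 0.0
            warnings.warn("zero variance of paired differences; degenerate t-test")
        else:
            t, p = sps.ttest_rel(a, b)
    elif mode == "unpaired":
        if a.size < 2 or b.size < 2:
            raise ValueError("unpaired test requires n >= 2 per group")
        t, p = sps.ttest_ind(a, b, equal_var=True)
    else:
        raise ValueError("mode must be 'paired' or 'unpaired'")
    t, p = float(t), float(p)
    return TestReport(
        comparison=comparison,
        test_type=mode,
        t=t,
        p=p,
        m=m,
        alpha=alpha,
        significant=bool(p < alpha / m),
    )


def bonferroni(
    p_values: Sequence[float], alpha: float = DEFAULT_ALPHA, m: int | None = None
) -> list[bool]:
    """Bonferroni significance flags: ``p_i < alpha / m``.

    ``m`` defaults to the number of comparisons in the family (the length
    of ``p_values``).
    """
    p_values = list(p_values)
    if len(p_values) == 0:
        raise ValueError("bonferroni requires at least one p-value")
    if any(p < 0 or p > 1 for p in p_values):
        raise ValueError("p-values must lie in [0, 1]")
    m_eff = len(p_values) if m is None else m
    return [p < alpha / m_eff for p in p_values]


def analyze_groups(
    cells: pd.DataFrame, alpha: float = DEFAULT_ALPHA
) -> tuple[list[GroupSummary], list[TestReport]]:
    """Run the standard comparison family on a combined per-cell table.

    Expects columns ``method`` (AU/MA), ``diagnosis`` (malignant / benign /
    normal), and ``fpol``. For each method present, malignant-vs-benign and
    malignant-vs-normal are tested unpaired; for each diagnosis present in
    both methods, AU-vs-MA is tested unpaired on all cells (no pairing is
    available at this level). The whole set of comparisons run here forms
    one Bonferroni family.
    """
    summaries = summarize_groups(cells)
    plan: list[tuple[str, str, pd.Series, pd.Series]] = []

    def _vals(method: str, diag: str) -> np.ndarray:
        sel = cells[(cells["method"] == method) & (cells["diagnosis"] == diag)]
        v = sel["fpol"].to_numpy(dtype=np.float64)
        return v[~np.isnan(v)]

    methods = sorted(cells["method"].unique())
    diagnoses = sorted(cells["diagnosis"].unique())
    for method in methods:
        for other in ("benign", "normal"):
            if "malignant" in diagnoses and other in diagnoses:
                a, b = _vals(method, "malignant"), _vals(method, other)
                if a.size >= 2 and b.size >= 2:
                    plan.append((f"{method}: malignant vs {other}", "unpaired", a, b))
    if len(methods) == 2:
        for diag in diagnoses:
            a, b = _vals(methods[0], diag), _vals(methods[1], diag)
            if a.size >= 2 and b.size >= 2:
                plan.append((f"{diag}: {methods[0]} vs {methods[1]}", "unpaired", a, b))

    m = max(len(plan), 1)
    reports = [
        ttest(a, b, mode=mode, comparison=name, m=m, alpha=alpha)
        for name, mode, a, b in plan
    ]
    return summaries, reports
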