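"""Agreement statistics between gas-analyzer VT and the DLT.

Pearson correlation, Bland–Altman limits of agreement (mean difference
± 1.96 SD with a one-sample t-test of zero bias), the Fisher-z test for a
difference between two correlation coefficients (with Steiger's dependent-
correlation variant as an option), and binary subgroup analysis with an
interaction p-value.  Two-sided p-values throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = ["AgreementReport", "SubgroupReport", "pearson_r", "bland_altman",
           "agreement", "compare_correlations", "subgroup_analysis",
           "plot_agreement"]


@dataclass
class AgreementReport:
    n: int
    mean_diff: float            # mean of (a - b), mL/kg/min
    sd_diff: float
    loa_lower: float            # mean_diff - 1.96 sd
    loa_upper: float            # mean_diff + 1.96 sd
    mean_diff_p: float          # one-sample t-test of differences vs 0
    pearson_r: float = float("nan")
    pearson_p: float = float("nan")
    means: np.ndarray = field(default=None, repr=False)   # (a+b)/2, for plots
    diffs: np.ndarray = field(default=None, repr=False)   # a-b, for plots


@dataclass
class SubgroupReport:
    stratification: str
    strata: dict                # label -> {"n": int, "r": float, "p": float}
    interaction_p: float


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation with its two-sided p (t with n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bland_altman(method_a, method_b) -> AgreementReport:
    """Bland–Altman agreement between two paired measurement methods.

    Differences are ``a - b``; limits of agreement are mean ± 1.96 SD
    (sample SD, ddof 1).  ``mean_diff_p`` tests the mean difference against
    zero; a perfectly identical pair yields p = 1 by convention.
    """
    a = np.asarray(method_a, dtype=float)
    b = np.asarray(method_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("method_a and method_b must have equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    if sd_diff == 0.0:
        p = 1.0 if mean_diff == 0.0 else 0.0
    else:
        p = float(sps.ttest_1samp(d, 0.0).pvalue)
    return AgreementReport(
        n=len(a), mean_diff=mean_diff, sd_diff=sd_diff,
        loa_lower=mean_diff - 1.96 * sd_diff,
        loa_upper=mean_diff + 1.96 * sd_diff,
        mean_diff_p=p, means=(a + b) / 2.0, diffs=d)


def agreement(method_a, method_b) -> AgreementReport:
    """Bland–Altman report with the Pearson fields filled in."""
    report = bland_altman(method_a, method_b)
    r, p = pearson_r(method_a, method_b)
    report.pearson_r, report.pearson_p = r, p
    return report


def compare_correlations(r1: float, r2: float, n1: int, n2: int,
                         method: str = "fisher",
                         r12: float | None = None) -> tuple[float, float]:
    """Test the difference between two correlation coefficients.

    ``method="fisher"`` (default) is the independent-samples form:
    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)).  It is
    computable from the reported quantities alone and conservative when
    the two correlations are positively dependent.  ``method="steiger"``
    is the dependent-correlation test for two correlations sharing a
    variable in one sample (n1 must equal n2) and requires ``r12``, the
    correlation between the two non-shared variables.
    Returns (z, two-sided p).
    """
    for r in (r1, r2):
        if abs(r) >= 1.0:
            raise ValueError("correlations must satisfy |r| < 1")
    if n1 < 4 or n2 < 4:
        raise ValueError("need n >= 4 in each sample")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    if method == "fisher":
        se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
        z = (z1 - z2) / se
    elif method == "steiger":
        if r12 is None:
            raise ValueError("steiger method requires r12")
        if n1 != n2:
            raise ValueError("steiger method assumes one sample (n1 == n2)")
        rbar2 = ((r1 + r2) / 2.0) ** 2
        cov = (r12 * (1.0 - 2.0 * rbar2) -
               0.5 * rbar2 * (1.0 - 2.0 * rbar2 - r12 ** 2)) / (1.0 - rbar2) ** 2
        z = (z1 - z2) * np.sqrt((n1 - 3) / (2.0 - 2.0 * cov))
    else:
        raise ValueError(f"unknown method {method!r}")
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)


def subgroup_analysis(vt_vo2, dlt_vo2, labels,
                      stratification: str = "stratum",
                      min_n: int = 4) -> SubgroupReport:
    """Per-stratum correlation between VT-VO2 and DLT-VO2.

    For a binary stratification the interaction p compares the two
    per-stratum correlations with the Fisher-z test.  Strata with fewer
    than ``min_n`` members are skipped with a warning.
    """
    vt_vo2 = np.asarray(vt_vo2, dtype=float)
    dlt_vo2 = np.asarray(dlt_vo2, dtype=float)
    labels = np.asarray(labels)
    strata = {}
    for label in pd_unique(labels):
        mask = labels == label
        n = int(mask.sum())
        if n < min_n:
            warnings.warn(f"stratum {label!r} has n={n} < {min_n}; skipped")
            continue
        r, p = pearson_r(vt_vo2[mask], dlt_vo2[mask])
        strata[label] = {"n": n, "r": r, "p": p}
    interaction_p = float("nan")
    if len(strata) == 2:
        (s1, s2) = strata.values()
        _, interaction_p = compare_correlations(s1["r"], s2["r"],
                                                s1["n"], s2["n"])
    return SubgroupReport(stratification=stratification, strata=strata,
                          interaction_p=interaction_p)


def pd_unique(labels: np.ndarray):
    """Unique labels in order of first appearance."""
    _, idx = np.unique(labels, return_index=True)
    return labels[np.sort(idx)]


def plot_agreement(report: AgreementReport, path, title: str = "") -> None:
    """Side-by-side scatter and Bland–Altman panels (SVG/PNG by extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a = report.means + report.diffs / 2.0
    b = report.means - report.diffs / 2.0
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.scatter(a, b, s=12, alpha=0.7)
    lims = [min(a.min(), b.min()), max(a.max(), b.max())]
    ax1.plot(lims, lims, "k--", lw=0.8)
    ax1.set_xlabel("VT-VO2 (mL/kg/min)")
    ax1.set_ylabel("DLT-VO2 (mL/kg/min)")
    ax1.set_title(f"r = {report.pearson_r:.3f} (n = {report.n})")
    ax2.scatter(report.means, report.diffs, s=12, alpha=0.7)
    for yline, style in ((report.mean_diff, "-"),
                         (report.loa_lower, "--"), (report.loa_upper, "--")):
        ax2.axhline(yline, color="gray", ls=style, lw=0.8)
    ax2.set_xlabel("mean of methods (mL/kg/min)")
    ax2.set_ylabel("difference (mL/kg/min)")
    ax2.set_title(f"bias = {report.mean_diff:.2f} "
                  f"[{report.loa_lower:.2f}, {report.loa_upper:.2f}]")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
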