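"""Method-agreement statistics: ICC(2,1) and Bland-Altman analysis.

ICC(2,1) — intraclass correlation, two-way random effects, absolute
agreement, single rater (McGraw & Wong convention) — treats each
measurement method (or each repetition, for test-retest reliability) as a
rater of each jump. From the two-way ANOVA mean squares:

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

with MSR the between-subject, MSC the between-rater and MSE the residual
mean square, n subjects and k raters. Absolute agreement: a constant offset
between raters lowers the coefficient.

Bland-Altman analysis summarises paired differences by their mean (bias b)
and the limits of agreement [c0, c1] = [b - 1.96 SD, b + 1.96 SD], inside
which about 95% of differences are expected to fall.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class AgreementReport:
    """Paired-method statistics: ICC plus Bland-Altman bias and limits."""

    icc_2_1: float
    bias_b: float
    loa_low_c0: float
    loa_high_c1: float
    sd_diff: float
    n_pairs: int
    means: np.ndarray | None = None  # per-pair means, for plotting
    diffs: np.ndarray | None = None  # per-pair differences (method - truth)

    def to_dict(self) -> dict:
        return {"icc_2_1": self.icc_2_1, "bias_b": self.bias_b,
                "loa_low_c0": self.loa_low_c0, "loa_high_c1": self.loa_high_c1,
                "sd_diff": self.sd_diff, "n_pairs": self.n_pairs}

    def scatter_frame(self):
        """Per-pair (mean, diff) table for Bland-Altman scatter export."""
        import pandas as pd
        if self.means is None or self.diffs is None:
            raise ValueError("report carries no per-pair data")
        return pd.DataFrame({"mean_cm": self.means, "diff_cm": self.diffs})


def icc_2_1(ratings: np.ndarray) -> float:
    """ICC(2,1) of an ``n_subjects x k_raters`` matrix.

    Rows with any missing value are dropped listwise. Returns NaN when the
    total variance is zero (agreement is undefined on constant data).
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D subjects x raters matrix")
    x = x[~np.isnan(x).any(axis=1)]
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 raters")

    grand = x.mean()
    if np.allclose(x, grand):
        return float("nan")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)

    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        return float("nan")
    return float((msr - mse) / denom)


def icc_test_retest(reps: np.ndarray) -> float:
    """Intra-session test-retest reliability: ICC(2,1) with the repetitions
    of each participant treated as the raters."""
    return icc_2_1(reps)


def bland_altman(method: np.ndarray, truth: np.ndarray,
                 icc: float | None = None) -> AgreementReport:
    """Bland-Altman agreement of a candidate method against a ground truth.

    Differences are oriented method - truth, so a positive bias means the
    candidate overestimates. The limits of agreement use the sample
    standard deviation (n-1 denominator). Pairs with a missing value in
    either vector are dropped listwise. If ``icc`` is not given, ICC(2,1)
    of the two columns is computed on the same pairs.
    """
    m = np.asarray(method, dtype=float)
    t = np.asarray(truth, dtype=float)
    if m.shape != t.shape or m.ndim != 1:
        raise ValueError("method and truth must be equal-length 1-D vectors")
    keep = ~(np.isnan(m) | np.isnan(t))
    m, t = m[keep], t[keep]
    if m.size < 2:
        raise ValueError("need at least 2 complete pairs")
    diffs = m - t
    b = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    if icc is None:
        icc = icc_2_1(np.column_stack([m, t]))
    return AgreementReport(icc_2_1=float(icc), bias_b=b,
                           loa_low_c0=b - 1.96 * sd, loa_high_c1=b + 1.96 * sd,
                           sd_diff=sd, n_pairs=int(m.size),
                           means=(m + t) / 2.0, diffs=diffs)


def plot_bland_altman(report: AgreementReport, ax=None, title: str = ""):
    """Scatter of per-pair means vs differences with bias and LOA lines.

    Requires matplotlib (optional dependency); returns the axes.
    """
    import matplotlib.pyplot as plt

    if report.means is None or report.diffs is None:
        raise ValueError("report carries no per-pair data to plot")
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(report.means, report.diffs, s=18, alpha=0.7)
    ax.axhline(report.bias_b, color="k", lw=1.2, label=f"bias {report.bias_b:+.2f}")
    for y, lab in ((report.loa_low_c0, "c0"), (report.loa_high_c1, "c1")):
        ax.axhline(y, color="k", lw=1.0, ls="--",
                   label=f"{lab} {y:+.2f}")
    ax.set_xlabel("mean of methods (cm)")
    ax.set_ylabel("difference (cm)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    return ax
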