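"""Agreement and reliability statistics for paired calcium scores.

Agreement asks whether two scorings of the same scans are identical
(proportion of agreement, category shifts, Bland-Altman limits); reliability
asks whether a scoring distinguishes subjects despite rater error (weighted
kappa, intraclass correlation, Kendall's W).  This module implements both
families for a reference-vs-automated comparison and for multi-rater
tables.

Because calcium-score measurement error grows with the score, the
Bland-Altman analysis models non-uniform differences: the absolute paired
difference is regressed on the square root of the pair mean, and 95% limits
are the predicted absolute difference multiplied by ``1.96 * sqrt(pi/2)``
(the absolute difference of a zero-mean normal is half-normal, whose mean
is the normal sd times ``sqrt(2/pi)``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HALF_NORMAL_MULTIPLIER",
    "ConfusionMatrix",
    "PairedScores",
    "ShiftSummary",
    "BlandAltmanModel",
    "AgreementReport",
    "confusion_matrix",
    "proportion_agreement",
    "shift_counts",
    "false_negative_zero",
    "weighted_kappa",
    "icc",
    "kendalls_w",
    "qcd",
    "qcd_from_quartiles",
    "paired_difference_summary",
    "bland_altman_fit",
    "agreement_report",
]

#: 1.96 * sqrt(pi/2): scales a predicted mean absolute difference (the mean
#: of a half-normal) to the 95% limit of the underlying normal differences.
HALF_NORMAL_MULTIPLIER = 1.96 * math.sqrt(math.pi / 2.0)


@dataclass
class ConfusionMatrix:
    """k x k cross-table of ordered categories, reference on rows."""

    counts: np.ndarray
    labels: tuple[str, ...]
    row_name: str = "reference"
    col_name: str = "automated"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square and match the label set")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be nonnegative integers")
        if k < 2:
            raise ValueError("at least 2 categories required")

    @property
    def k(self) -> int:
        return len(self.labels)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def trace(self) -> int:
        return int(np.trace(self.counts))

    def transpose(self) -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.counts.T.copy(), self.labels, row_name=self.col_name, col_name=self.row_name
        )

    def to_pairs(self) -> tuple[list[str], list[str]]:
        """Expand counts back into per-subject (reference, automated) labels."""
        ref, auto = [], []
        for i, row_label in enumerate(self.labels):
            for j, col_label in enumerate(self.labels):
                ref.extend([row_label] * int(self.counts[i, j]))
                auto.extend([col_label] * int(self.counts[i, j]))
        return ref, auto


@dataclass
class PairedScores:
    """Per-scan reference and automated values of one continuous measure."""

    ref: np.ndarray
    auto: np.ndarray
    scan_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.ref = np.asarray(self.ref, dtype=float)
        self.auto = np.asarray(self.auto, dtype=float)
        if self.ref.shape != self.auto.shape or self.ref.ndim != 1:
            raise ValueError("ref and auto must be 1D arrays of equal length")
        if np.any(~np.isfinite(self.ref)) or np.any(~np.isfinite(self.auto)):
            raise ValueError("paired scores must not contain missing values")

    def __len__(self) -> int:
        return int(self.ref.shape[0])


def confusion_matrix(ref_labels, auto_labels, labels) -> ConfusionMatrix:
    """Cross-tabulate paired categorical ratings (reference on rows)."""
    labels = tuple(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for r, a in zip(ref_labels, auto_labels, strict=True):
        if r not in index or a not in index:
            raise ValueError(f"unknown category label in pair ({r!r}, {a!r})")
        counts[index[r], index[a]] += 1
    return ConfusionMatrix(counts, labels)


def proportion_agreement(matrix: ConfusionMatrix) -> float:
    """Fraction of subjects with identical categories: trace / total."""
    if matrix.total == 0:
        raise ValueError("empty matrix")
    return matrix.trace / matrix.total


@dataclass
class ShiftSummary:
    """Histogram of absolute category-index shifts |reference - automated|."""

    counts: np.ndarray  # counts[d] = subjects shifted by exactly d strata
    n_more_than_one: int

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def shift_counts(matrix: ConfusionMatrix) -> ShiftSummary:
    """Distribution of category shifts between the two raters."""
    if matrix.total == 0:
        raise ValueError("empty matrix")
    k = matrix.k
    hist = np.zeros(k, dtype=np.int64)
    for i in range(k):
        for j in range(k):
            hist[abs(i - j)] += matrix.counts[i, j]
    return ShiftSummary(counts=hist, n_more_than_one=int(hist[2:].sum()))


def false_negative_zero(matrix: ConfusionMatrix) -> tuple[int, float]:
    """Subjects with calcium by the reference scored zero by the automated rater.

    Returns ``(count, rate over all subjects)``; assumes the first label is
    the zero category.
    """
    count = int(matrix.counts[1:, 0].sum())
    return count, count / matrix.total


def weighted_kappa(matrix: ConfusionMatrix, weighting: str = "linear") -> float:
    """Chance-corrected agreement with distance-weighted disagreement.

    kappa_w = 1 - sum(v_ij o_ij) / sum(v_ij e_ij) with linear penalties
    v_ij = |i - j| / (k - 1) (or squared for ``weighting="quadratic"``),
    o the observed proportions and e the marginal products.
    """
    if matrix.total == 0:
        raise ValueError("empty matrix")
    k = matrix.k
    o = matrix.counts / matrix.total
    row_marg = o.sum(axis=1)
    col_marg = o.sum(axis=0)
    e = np.outer(row_marg, col_marg)
    i, j = np.indices((k, k))
    v = np.abs(i - j) / (k - 1)
    if weighting == "quadratic":
        v = v**2
    elif weighting != "linear":
        raise ValueError("weighting must be 'linear' or 'quadratic'")
    expected_penalty = float((v * e).sum())
    if expected_penalty == 0:
        raise ValueError("degenerate matrix: all mass in a single category")
    return 1.0 - float((v * o).sum()) / expected_penalty


def icc(ratings, model: str = "two-way-mixed", form: str | None = None) -> float:
    """Single-measure intraclass correlation from a two-way ANOVA table.

    ``ratings`` is an (n subjects x k raters) array with no missing cells.
    Mean squares: MSR between subjects, MSC between raters, MSE residual.

    * ``model="two-way-mixed"`` (default, consistency form):
      ``(MSR - MSE) / (MSR + (k-1) MSE)`` — raters fixed, rater bias ignored.
    * ``model="two-way-random"`` (absolute-agreement form):
      ``(MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)``.

    Pass ``form="consistency"`` or ``"agreement"`` to override the form a
    model defaults to.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be (n >= 2 subjects) x (k >= 2 raters)")
    if np.any(~np.isfinite(x)):
        raise ValueError("ratings must not contain missing cells")
    n, k = x.shape
    grand = x.mean()
    subject_means = x.mean(axis=1)
    rater_means = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum()
    ss_subjects = k * ((subject_means - grand) ** 2).sum()
    ss_raters = n * ((rater_means - grand) ** 2).sum()
    ss_error = ss_total - ss_subjects - ss_raters
    msr = ss_subjects / (n - 1)
    msc = ss_raters / (k - 1)
    mse = ss_error / ((n - 1) * (k - 1))
    if ss_total == 0:
        raise ValueError("zero total variance: ICC undefined")
    if form is None:
        form = "consistency" if model == "two-way-mixed" else "agreement"
    if model not in ("two-way-mixed", "two-way-random"):
        raise ValueError("model must be 'two-way-mixed' or 'two-way-random'")
    if form == "consistency":
        denom = msr + (k - 1) * mse
    elif form == "agreement":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    else:
        raise ValueError("form must be 'consistency' or 'agreement'")
    if denom == 0:
        raise ValueError("zero variance: ICC undefined")
    return float((msr - mse) / denom)


def kendalls_w(ratings, tie_correction: bool = True) -> float:
    """Kendall's coefficient of concordance among m raters of n subjects.

    Ranks use mid-rank ties; the tie term T_j = sum(t^3 - t) over tie groups
    of rater j is subtracted from the denominator when correction is on.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be (n >= 2 subjects) x (m >= 2 raters)")
    n, m = x.shape
    ranks = np.column_stack([stats.rankdata(x[:, j]) for j in range(m)])
    rank_sums = ranks.sum(axis=1)
    s = ((rank_sums - rank_sums.mean()) ** 2).sum()
    tie_term = 0.0
    if tie_correction:
        for j in range(m):
            _, counts = np.unique(x[:, j], return_counts=True)
            tie_term += float((counts**3 - counts).sum())
    denom = m**2 * (n**3 - n) - m * tie_term
    if denom <= 0:
        raise ValueError("all ratings constant: W undefined")
    return float(12.0 * s / denom)


def qcd_from_quartiles(q1: float, q3: float) -> float:
    """Quartile coefficient of dispersion (Q3 - Q1) / (Q3 + Q1)."""
    if q3 < q1:
        raise ValueError("Q3 must be >= Q1")
    if q1 + q3 == 0:
        return 1.0 if q3 > 0 else 0.0
    return (q3 - q1) / (q3 + q1)


def qcd(values) -> float:
    """QCD of a sample, quartiles by linear interpolation."""
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("QCD needs at least 4 values")
    q1, q3 = np.percentile(values, [25, 75])
    return qcd_from_quartiles(float(q1), float(q3))


def paired_difference_summary(paired: PairedScores) -> dict:
    """Median and quartiles of reference-minus-automated differences."""
    if len(paired) < 1:
        raise ValueError("at least one pair required")
    d = paired.ref - paired.auto
    p25, p50, p75 = np.percentile(d, [25, 50, 75])
    return {"median": float(p50), "p25": float(p25), "p75": float(p75)}


@dataclass
class BlandAltmanModel:
    """Non-uniform 95% limits of agreement for paired calcium scores.

    The absolute difference is modelled as ``a + b * sqrt(mean)``; the 95%
    limits at a pair mean x are ``+/- (a + b sqrt(x)) * 1.96 sqrt(pi/2)``,
    zero-centred, with a negative predicted absolute difference clipped to
    0 (relevant at small x when the fitted intercept is negative).
    """

    intercept: float
    slope: float
    multiplier: float = HALF_NORMAL_MULTIPLIER

    def predicted_abs_diff(self, mean) -> np.ndarray:
        x = np.asarray(mean, dtype=float)
        return np.clip(self.intercept + self.slope * np.sqrt(x), 0.0, None)

    def limit(self, mean) -> np.ndarray:
        """Magnitude of the upper 95% limit at the given pair mean(s)."""
        return self.predicted_abs_diff(mean) * self.multiplier

    def coverage(self, paired: PairedScores) -> float:
        """Fraction of paired differences inside the fitted limits."""
        means = (paired.ref + paired.auto) / 2.0
        return float(np.mean(np.abs(paired.ref - paired.auto) <= self.limit(means)))

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "slope": self.slope,
            "multiplier": self.multiplier,
        }


def bland_altman_fit(paired: PairedScores) -> BlandAltmanModel:
    """OLS of |reference - automated| on sqrt(pair mean)."""
    if len(paired) < 3:
        raise ValueError("at least 3 pairs required")
    means = (paired.ref + paired.auto) / 2.0
    if np.any(means < 0):
        raise ValueError("pair means must be nonnegative for the sqrt transform")
    x = np.sqrt(means)
    if np.ptp(x) == 0:
        raise ValueError("constant pair means: slope undefined")
    y = np.abs(paired.ref - paired.auto)
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return BlandAltmanModel(intercept=float(coef[0]), slope=float(coef[1]))


@dataclass
class AgreementReport:
    """All agreement/reliability statistics for one paired comparison."""

    categorical: dict = field(default_factory=dict)
    measures: dict = field(default_factory=dict)

    def to_json(self, **kwargs) -> str:
        return json.dumps({"categorical": self.categorical, "measures": self.measures}, **kwargs)


def agreement_report(
    matrix: ConfusionMatrix | None = None,
    measures: dict[str, PairedScores] | None = None,
) -> AgreementReport:
    """Assemble the full statistics suite for a paired score table.

    ``matrix`` drives the categorical block (proportion of agreement,
    shifts, weighted kappa, false-negative zeros); each entry of
    ``measures`` (e.g. Agatston, volume, lesion count) gets ICC, QCD,
    difference quartiles and a Bland-Altman model.  Either block may be
    omitted.
    """
    report = AgreementReport()
    if matrix is not None:
        shifts = shift_counts(matrix)
        fnz_count, fnz_rate = false_negative_zero(matrix)
        report.categorical = {
            "n": matrix.total,
            "proportion_agreement": proportion_agreement(matrix),
            "weighted_kappa": weighted_kappa(matrix),
            "shift_histogram": shifts.counts.tolist(),
            "n_shift_more_than_one": shifts.n_more_than_one,
            "false_negative_zero_count": fnz_count,
            "false_negative_zero_rate": fnz_rate,
        }
    for name, paired in (measures or {}).items():
        block: dict = {
            "n": len(paired),
            "icc_two_way_mixed": icc(np.column_stack([paired.ref, paired.auto])),
            "qcd_reference": qcd(paired.ref) if len(paired) >= 4 else None,
            "qcd_automated": qcd(paired.auto) if len(paired) >= 4 else None,
            "difference": paired_difference_summary(paired),
        }
        try:
            block["bland_altman"] = bland_altman_fit(paired).to_dict()
        except ValueError as exc:
            block["bland_altman"] = {"error": str(exc)}
        report.measures[name] = block
    return report
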