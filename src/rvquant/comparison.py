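"""Method-comparison statistics: correlation, Bland-Altman, ROC, ICC.

The central object is :class:`MethodComparison`, a model built from a long
results table (one row per subject x method) plus optional reliability
ratings; its :meth:`~MethodComparison.fit` returns a
:class:`ComparisonResults` carrying

* an agreement table per quantity (mean +/- SD for each method, paired
  difference ``standard - formula``, Bland-Altman limits, Pearson r);
* ROC analyses with DeLong-style standard errors and Youden-index cut-offs
  for detecting RV enlargement / dysfunction from the formula method, with
  the standard method defining the reference labels;
* a reliability table (per-rater mean +/- SD, paired difference, and the
  two-way random-effects absolute-agreement single-measure ICC with its
  F-based 95% CI).

The low-level statistics are also exposed as plain functions so they can be
used piecemeal (:func:`bland_altman`, :func:`roc_auc`, :func:`youden_cutoff`,
:func:`icc_absolute_single`, ...).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedSample",
    "BAResult",
    "ROCResult",
    "CutoffResult",
    "ICCResult",
    "DiffSummary",
    "pearson_r",
    "bland_altman",
    "roc_auc",
    "youden_cutoff",
    "icc_absolute_single",
    "paired_diff_summary",
    "MethodComparison",
    "ComparisonResults",
    "build_comparison_report",
]


# ---------------------------------------------------------------------------
# elementary containers and statistics


@dataclass(frozen=True)
class PairedSample:
    """Paired measurements of one quantity by two methods (x: reference)."""

    x: np.ndarray
    y: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1D arrays of equal length")

    @property
    def n(self) -> int:
        return int(self.x.size)


@dataclass(frozen=True)
class BAResult:
    """Bland-Altman agreement: bias = mean(x - y), limits = bias +/- 1.96 SD."""

    bias: float
    sd: float
    loa_low: float
    loa_high: float
    n: int


@dataclass(frozen=True)
class ROCResult:
    """Nonparametric ROC: AUC (ties count 1/2), DeLong SE, normal 95% CI.

    ``direction`` is "higher" when larger scores indicate the positive
    class (criterion "> c") and "lower" otherwise (criterion "<= c").
    ``thresholds``/``sensitivity``/``specificity`` trace the full curve.
    """

    auc: float
    se: float
    ci95: Tuple[float, float]
    thresholds: Tuple[float, ...]
    sensitivity: Tuple[float, ...]
    specificity: Tuple[float, ...]
    direction: str
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class CutoffResult:
    """Youden-optimal operating point (sens/spec in percent, J on 0-1 scale)."""

    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float
    criterion: str


@dataclass(frozen=True)
class ICCResult:
    """ICC(A,1): two-way random effects, absolute agreement, single measure."""

    icc: float
    ci95: Tuple[float, float]
    ms_rows: float
    ms_cols: float
    ms_error: float
    n_subjects: int
    n_raters: int
    model: str = "ICC(A,1)"


@dataclass(frozen=True)
class DiffSummary:
    """Mean +/- SD of elementwise differences, with a rendered string."""

    mean: float
    sd: float
    n: int
    formatted: str


def pearson_r(sample: PairedSample) -> Tuple[float, float]:
    """Product-moment correlation with its two-sided p (t-transform, n-2 df)."""
    if sample.n < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if np.std(sample.x) == 0 or np.std(sample.y) == 0:
        raise ValueError("correlation undefined: zero variance in an input")
    r, p = stats.pearsonr(sample.x, sample.y)
    return float(r), float(p)


def bland_altman(sample: PairedSample) -> BAResult:
    """Agreement of two methods via differences ``x - y``."""
    if sample.n < 2:
        raise ValueError("Bland-Altman needs n >= 2")
    d = sample.x - sample.y
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BAResult(bias=bias, sd=sd, loa_low=bias - 1.96 * sd,
                    loa_high=bias + 1.96 * sd, n=sample.n)


def paired_diff_summary(sample: PairedSample, direction: str = "x-y") -> DiffSummary:
    """Mean +/- SD of paired differences; ``direction`` is "x-y" or "y-x".

    Because the mean is linear, ``mean(x) - mean(y)`` always equals
    ``mean(x - y)`` — the identity that lets a difference column be checked
    against its two method-mean columns.
    """
    if sample.n < 2:
        raise ValueError("difference summary needs n >= 2")
    if direction == "x-y":
        d = sample.x - sample.y
    elif direction == "y-x":
        d = sample.y - sample.x
    else:
        raise ValueError(f"direction must be 'x-y' or 'y-x', got {direction!r}")
    m = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return DiffSummary(mean=m, sd=sd, n=sample.n,
                       formatted=f"{m:.1f} ± {sd:.1f}")


def _placement_values(pos: np.ndarray, neg: np.ndarray):
    """DeLong placement values: P(pos > neg) with ties counting 1/2."""
    # V10[i] = fraction of negatives below pos[i] (+ half ties), and vice versa
    diff = pos[:, None] - neg[None, :]
    h = (diff > 0).astype(float) + 0.5 * (diff == 0)
    return h.mean(axis=1), h.mean(axis=0)


def roc_auc(scores, labels, direction: str = "higher") -> ROCResult:
    """Nonparametric ROC analysis of a continuous marker.

    AUC is the Mann-Whitney concordance probability; its standard error and
    normal-approximation 95% CI come from the DeLong placement-value
    variance decomposition, with the CI clipped to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1D and equally long")
    if direction not in ("higher", "lower"):
        raise ValueError("direction must be 'higher' or 'lower'")
    s = scores if direction == "higher" else -scores
    pos, neg = s[labels == 1], s[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("ROC needs both classes present")
    v10, v01 = _placement_values(pos, neg)
    auc = float(v10.mean())
    if pos.size > 1 and neg.size > 1:
        var = v10.var(ddof=1) / pos.size + v01.var(ddof=1) / neg.size
        se = float(math.sqrt(var))
    else:
        se = float("nan")
    if math.isnan(se):
        ci = (float("nan"), float("nan"))
    else:
        ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))

    # full curve over candidate cutoffs c (criterion "s > c"), c in the
    # observed values plus one below the minimum (the "all positive" corner)
    cand = np.concatenate(([s.min() - 1.0], np.unique(s)))
    sens = np.array([(pos > c).mean() for c in cand])
    spec = np.array([(neg <= c).mean() for c in cand])
    thr = cand if direction == "higher" else -cand
    return ROCResult(auc=auc, se=se, ci95=ci,
                     thresholds=tuple(float(t) for t in thr),
                     sensitivity=tuple(float(v) for v in sens),
                     specificity=tuple(float(v) for v in spec),
                     direction=direction, n_pos=int(pos.size), n_neg=int(neg.size))


def youden_cutoff(roc: ROCResult) -> CutoffResult:
    """Operating point maximizing J = sens + spec - 1.

    Ties are broken toward higher sensitivity, then the lower cutoff.  The
    criterion renders as "> c" for higher-is-positive markers and "<= c"
    for lower-is-positive ones.
    """
    if len(roc.thresholds) == 0:
        raise ValueError("ROC result has no thresholds")
    sens = np.asarray(roc.sensitivity)
    spec = np.asarray(roc.specificity)
    thr = np.asarray(roc.thresholds)
    j = sens + spec - 1.0
    # lexicographic: max J, then max sensitivity, then the lower cutoff
    order = np.lexsort((thr, -sens, -j))
    best = order[0]
    cutoff = float(thr[best])
    op = ">" if roc.direction == "higher" else "≤"
    return CutoffResult(cutoff=cutoff,
                        sensitivity=float(sens[best]) * 100.0,
                        specificity=float(spec[best]) * 100.0,
                        youden_j=float(j[best]),
                        criterion=f"{op}{cutoff:g}")


def icc_absolute_single(ratings) -> ICCResult:
    """ICC(A,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is an (n_subjects, k_raters) table with no missing cells.
    Point estimate from the two-way ANOVA mean squares,

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n),

    95% CI by the standard F-based construction with a Satterthwaite
    denominator df.  Because MSC enters the denominator, a constant offset
    between raters lowers this ICC — unlike the consistency variant.
    """
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2:
        raise ValueError("ratings must be a 2D subjects x raters table")
    n, k = r.shape
    if k < 2:
        raise ValueError("ICC needs >= 2 raters")
    if n < 5:
        raise ValueError("ICC needs >= 5 subjects")
    if np.isnan(r).any():
        raise ValueError("ICC input has missing cells")

    grand = r.mean()
    row_m = r.mean(axis=1)
    col_m = r.mean(axis=0)
    ss_rows = k * ((row_m - grand) ** 2).sum()
    ss_cols = n * ((col_m - grand) ** 2).sum()
    ss_total = ((r - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)
    # identical raters leave only float roundoff in the column/error terms;
    # snap those to zero so duplicated ratings give ICC = 1 exactly
    tol = 1e-12 * max(msr, 1.0e-300)
    if msc < tol:
        msc = 0.0
    if mse < tol:
        mse = 0.0

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        icc = 0.0
    else:
        icc = (msr - mse) / denom

    if mse == 0.0 and msc == 0.0:
        ci = (icc, icc)  # degenerate: identical raters
    else:
        a = k * icc / (n * (1.0 - icc)) if icc < 1.0 else float("inf")
        b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1.0 else float("inf")
        if not math.isfinite(a):
            ci = (icc, icc)
        else:
            num_v = (a * msc + b * mse) ** 2
            den_v = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            v = num_v / den_v if den_v > 0 else float("inf")
            f1 = stats.f.ppf(0.975, n - 1, v)
            f2 = stats.f.ppf(0.975, v, n - 1)
            lower = (n * (msr - f1 * mse)
                     / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr))
            upper = (n * (f2 * msr - mse)
                     / (k * msc + (k * n - k - n) * mse + n * f2 * msr))
            ci = (float(min(lower, icc)), float(min(max(upper, icc), 1.0)))
    return ICCResult(icc=float(icc), ci95=ci, ms_rows=float(msr),
                     ms_cols=float(msc), ms_error=float(mse),
                     n_subjects=n, n_raters=k)


# ---------------------------------------------------------------------------
# model / results objects

_QUANTITIES = (
    ("edvi", "RV-EDV index, mL/m2"),
    ("esvi", "RV-ESV index, mL/m2"),
    ("ef", "RV-EF, %"),
)

_ROC_TARGETS = (
    # flag column in the reference rows, score column in formula rows, direction
    ("enlarged_edv", "edvi", "higher", "Enlarged RV (EDV index)"),
    ("enlarged_esv", "esvi", "higher", "Enlarged RV (ESV index)"),
    ("reduced_ef", "ef", "lower", "Reduced RV function (EF)"),
)


class MethodComparison:
    """Agreement model between a reference and a simplified RV method.

    Parameters
    ----------
    results : pandas.DataFrame
        Long table with one row per subject and method.  Required columns:
        ``subject``, ``method`` (values ``"standard"``/``"cpf"``), ``edvi``,
        ``esvi``, ``ef``.  Optional: ``edv``, ``esv``, boolean flag columns
        ``enlarged_edv``/``enlarged_esv``/``reduced_ef`` (needed for ROC).
    reliability : mapping, optional
        Maps a quantity label (e.g. ``"RV-EDV, mL"``) to a dict with keys
        ``"intra"`` and/or ``"inter"``, each an (n_subjects, 2) array of
        repeated formula-method ratings.
    """

    REFERENCE = "standard"
    FORMULA = "cpf"

    def __init__(self, results: pd.DataFrame,
                 reliability: Optional[Mapping[str, Mapping[str, np.ndarray]]] = None):
        required = {"subject", "method", "edvi", "esvi", "ef"}
        missing = required - set(results.columns)
        if missing:
            raise ValueError(f"results table missing columns: {sorted(missing)}")
        methods = set(results["method"].unique())
        if not {self.REFERENCE, self.FORMULA} <= methods:
            raise ValueError(
                f"results must contain both methods "
                f"{self.REFERENCE!r} and {self.FORMULA!r}, got {sorted(methods)}")
        self.results = results.copy()
        self.reliability = dict(reliability or {})
        wide_idx = None
        for m in (self.REFERENCE, self.FORMULA):
            sub = results[results["method"] == m].set_index("subject")
            idx = sub.index
            if idx.has_duplicates:
                raise ValueError(f"duplicate subjects for method {m!r}")
            wide_idx = idx if wide_idx is None else wide_idx.intersection(idx)
        if len(wide_idx) < 2:
            raise ValueError("need >= 2 subjects measured by both methods")
        self._subjects = wide_idx

    @classmethod
    def from_dataframe(cls, results: pd.DataFrame, **kwargs) -> "MethodComparison":
        return cls(results, **kwargs)

    def _column(self, method: str, col: str) -> np.ndarray:
        sub = self.results[self.results["method"] == method].set_index("subject")
        return sub.loc[self._subjects, col].to_numpy()

    def fit(self) -> "ComparisonResults":
        """Compute every agreement, ROC and reliability statistic."""
        n = len(self._subjects)
        agree_rows = []
        ba: Dict[str, BAResult] = {}
        for col, label in _QUANTITIES:
            x = self._column(self.REFERENCE, col).astype(float)
            y = self._column(self.FORMULA, col).astype(float)
            sample = PairedSample(x=x, y=y, label=label)
            d = paired_diff_summary(sample, "x-y")
            ba[col] = bland_altman(sample)
            try:
                r, p = pearson_r(sample)
            except ValueError:
                r, p = float("nan"), float("nan")
            agree_rows.append({
                "quantity": label,
                "standard_mean": float(np.mean(x)),
                "standard_sd": float(np.std(x, ddof=1)),
                "cpf_mean": float(np.mean(y)),
                "cpf_sd": float(np.std(y, ddof=1)),
                "diff_mean": d.mean,
                "diff_sd": d.sd,
                "loa_low": ba[col].loa_low,
                "loa_high": ba[col].loa_high,
                "r": r,
                "p": p,
            })
        agreement = pd.DataFrame(agree_rows).set_index("quantity")

        roc: Dict[str, Optional[ROCResult]] = {}
        cutoffs: Dict[str, Optional[CutoffResult]] = {}
        roc_labels: Dict[str, str] = {}
        have_flags = all(
            c in self.results.columns for c, _, _, _ in _ROC_TARGETS)
        for flag_col, score_col, direction, label in _ROC_TARGETS:
            roc_labels[flag_col] = label
            if not have_flags:
                roc[flag_col] = None
                cutoffs[flag_col] = None
                continue
            labels = self._column(self.REFERENCE, flag_col).astype(int)
            scores = self._column(self.FORMULA, score_col).astype(float)
            try:
                res = roc_auc(scores, labels, direction)
                roc[flag_col] = res
                cutoffs[flag_col] = youden_cutoff(res)
            except ValueError:
                roc[flag_col] = None
                cutoffs[flag_col] = None

        rel_rows = []
        for label, kinds in self.reliability.items():
            for kind, ratings in kinds.items():
                r2 = np.asarray(ratings, dtype=float)
                sample = PairedSample(x=r2[:, 1], y=r2[:, 0], label=label)
                d = paired_diff_summary(sample, "x-y")  # second - first
                try:
                    icc = icc_absolute_single(r2)
                except ValueError:
                    icc = None
                rel_rows.append({
                    "quantity": label,
                    "comparison": kind,
                    "mean_1": float(r2[:, 0].mean()),
                    "sd_1": float(r2[:, 0].std(ddof=1)),
                    "mean_2": float(r2[:, 1].mean()),
                    "sd_2": float(r2[:, 1].std(ddof=1)),
                    "diff_mean": d.mean,
                    "diff_sd": d.sd,
                    "icc": icc.icc if icc else float("nan"),
                    "icc_ci_low": icc.ci95[0] if icc else float("nan"),
                    "icc_ci_high": icc.ci95[1] if icc else float("nan"),
                    "n": int(r2.shape[0]),
                })
        reliability = (pd.DataFrame(rel_rows).set_index(["quantity", "comparison"])
                       if rel_rows else pd.DataFrame())

        return ComparisonResults(model=self, n_subjects=n, agreement=agreement,
                                 bland_altman=ba, roc=roc, cutoffs=cutoffs,
                                 roc_labels=roc_labels, reliability=reliability)


@dataclass
class ComparisonResults:
    """Fitted method-comparison report (Table-2 / Table-3 shaped)."""

    model: MethodComparison
    n_subjects: int
    agreement: pd.DataFrame
    bland_altman: Dict[str, BAResult]
    roc: Dict[str, Optional[ROCResult]]
    cutoffs: Dict[str, Optional[CutoffResult]]
    roc_labels: Dict[str, str]
    reliability: pd.DataFrame

    def summary(self) -> str:
        """Human-readable report of all fitted tables."""
        lines = [f"RV method comparison (n = {self.n_subjects} subjects)",
                 "", "Agreement (standard vs formula method; difference = standard - CPF)"]
        for q, row in self.agreement.iterrows():
            lines.append(
                f"  {q:24s} {row.standard_mean:7.1f} ± {row.standard_sd:5.1f}"
                f"  vs {row.cpf_mean:7.1f} ± {row.cpf_sd:5.1f}"
                f"   Δ = {row.diff_mean:6.1f} ± {row.diff_sd:5.1f}"
                f"   r = {row.r:6.3f}")
        lines.append("")
        lines.append("Detection of reference-limit abnormality (CPF scores, standard labels)")
        for key, label in self.roc_labels.items():
            res, cut = self.roc.get(key), self.cutoffs.get(key)
            if res is None:
                lines.append(f"  {label:28s} not estimable (degenerate labels)")
                continue
            lines.append(
                f"  {label:28s} AUC = {res.auc:.3f} "
                f"(95% CI {res.ci95[0]:.3f}-{res.ci95[1]:.3f}); "
                f"cut-off {cut.criterion}: sens {cut.sensitivity:.1f}%, "
                f"spec {cut.specificity:.1f}%")
        if len(self.reliability):
            lines.append("")
            lines.append("Reliability of the formula method (repeated analyses)")
            for (q, kind), row in self.reliability.iterrows():
                lines.append(
                    f"  {q:16s} {kind:5s}  {row.mean_1:7.1f} ± {row.sd_1:5.1f}"
                    f"  vs {row.mean_2:7.1f} ± {row.sd_2:5.1f}"
                    f"   Δ = {row.diff_mean:5.1f} ± {row.diff_sd:4.1f}"
                    f"   ICC = {row.icc:.4f} "
                    f"[{row.icc_ci_low:.4f}-{row.icc_ci_high:.4f}]")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-compatible representation (round-trips through json)."""
        out = {
            "n_subjects": self.n_subjects,
            "agreement": {q: {k: _jsonable(v) for k, v in row.items()}
                          for q, row in self.agreement.iterrows()},
            "roc": {},
            "reliability": {},
        }
        for key, label in self.roc_labels.items():
            res, cut = self.roc.get(key), self.cutoffs.get(key)
            if res is None:
                out["roc"][key] = None
                continue
            out["roc"][key] = {
                "label": label,
                "auc": res.auc, "se": _jsonable(res.se),
                "ci95": [_jsonable(res.ci95[0]), _jsonable(res.ci95[1])],
                "direction": res.direction,
                "n_pos": res.n_pos, "n_neg": res.n_neg,
                "cutoff": cut.cutoff, "criterion": cut.criterion,
                "sensitivity_pct": cut.sensitivity,
                "specificity_pct": cut.specificity,
                "youden_j": cut.youden_j,
            }
        for (q, kind), row in (self.reliability.iterrows()
                               if len(self.reliability) else []):
            out["reliability"].setdefault(q, {})[kind] = {
                k: _jsonable(v) for k, v in row.items()}
        return out

    def save_json(self, path, extra: Optional[dict] = None) -> None:
        payload = self.to_dict()
        if extra:
            payload.update(extra)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    # -- plots ------------------------------------------------------------
    def plot_agreement(self, quantity: str = "edvi", ax=None):
        """Scatter of formula vs standard values with a regression line."""
        import matplotlib.pyplot as plt

        x = self.model._column(MethodComparison.REFERENCE, quantity)
        y = self.model._column(MethodComparison.FORMULA, quantity)
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(x, y, s=18, alpha=0.75)
        slope, intercept = np.polyfit(x, y, 1)
        xs = np.linspace(x.min(), x.max(), 50)
        ax.plot(xs, slope * xs + intercept, "r-", lw=1.2)
        ax.set_xlabel(f"standard {quantity}")
        ax.set_ylabel(f"formula {quantity}")
        return ax

    def plot_bland_altman(self, quantity: str = "edvi", ax=None):
        """Difference-vs-mean plot with bias and 95% limits of agreement."""
        import matplotlib.pyplot as plt

        x = self.model._column(MethodComparison.REFERENCE, quantity)
        y = self.model._column(MethodComparison.FORMULA, quantity)
        ba = self.bland_altman[quantity]
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter((x + y) / 2.0, x - y, s=18, alpha=0.75)
        for val, style in ((ba.bias, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
            ax.axhline(val, color="r", ls=style, lw=1.0)
        ax.set_xlabel(f"mean of methods ({quantity})")
        ax.set_ylabel("standard - formula")
        return ax

    def plot_roc(self, target: str = "enlarged_edv", ax=None):
        """ROC curve for one classification target."""
        import matplotlib.pyplot as plt

        res = self.roc.get(target)
        if res is None:
            raise ValueError(f"no ROC available for target {target!r}")
        if ax is None:
            _, ax = plt.subplots()
        fpr = 1.0 - np.asarray(res.specificity)
        tpr = np.asarray(res.sensitivity)
        order = np.argsort(fpr, kind="stable")
        ax.plot(fpr[order], tpr[order], "-", lw=1.4)
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(f"{self.roc_labels.get(target, target)} (AUC = {res.auc:.3f})")
        return ax


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        v = v.item()
    if isinstance(v, float) and not math.isfinite(v):
        return None
    return v


def build_comparison_report(
    results: pd.DataFrame,
    reliability: Optional[Mapping[str, Mapping[str, np.ndarray]]] = None,
) -> ComparisonResults:
    """One-call wrapper: fit a :class:`MethodComparison` on a results table."""
    return MethodComparison(results, reliability=reliability).fit()
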