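"""Diagnostic screening evaluation of laxity criteria.

Any per-limb criterion (JPE, KT manual max, total rotation, pivot-shift
positivity) can be evaluated as a screening test for the lower-satisfaction
limb.  Condition status follows the split that the published screening rows
are arithmetically consistent with: the reconstructed limbs of Group 2 are
condition-positive; all Group 1 limbs plus the healthy limbs of Group 2 are
condition-negative (patients report full satisfaction with their healthy
knee); Group 3 is excluded from analysis.  With the 9/6/2 study shape this
gives 6 positives and 24 negatives.

The module provides the four Altman-Bland screening descriptors
(sensitivity, specificity, PPV, NPV), a from-scratch two-sided Fisher exact
test (hypergeometric enumeration with log-factorials), threshold search for
continuous criteria, and an inverse audit tool that recovers the integer
2x2 tables consistent with published rounded screening percentages.

A statsmodels-style surface is available: build a :class:`DiagnosticScreen`
from the per-limb analysis table, call ``fit()``, and read the
:class:`DiagnosticScreenResults` (estimates, exact p, ``summary()``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "ContingencyTable",
    "ScreeningResult",
    "dichotomize",
    "screening_values",
    "fisher_exact",
    "condition_labels",
    "evaluate_criterion",
    "recover_table",
    "DiagnosticScreen",
    "DiagnosticScreenResults",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: rows test +/-, columns condition (lower satisfaction) +/-."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        cells = (self.tp, self.fp, self.fn, self.tn)
        if any(int(c) != c or c < 0 for c in cells):
            raise ValueError("contingency cells must be nonnegative integers")
        if sum(cells) == 0:
            raise ValueError("contingency table is empty")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(tp=self.tp, fp=self.fn, fn=self.fp, tn=self.tn)


@dataclass(frozen=True)
class ScreeningResult:
    """Screening descriptors for one criterion at one operating point.

    The four descriptors are percentages; a descriptor whose denominator is
    zero is None (undefined), never 0.  ``*_rounded`` round half away from
    zero to the nearest integer, the convention of published tables.
    """

    criterion: str
    threshold: float | None
    direction: str
    table: ContingencyTable
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    p_value: float | None = None

    def _round(self, x: float | None) -> int | None:
        return None if x is None else int(math.floor(x + 0.5))

    @property
    def sensitivity_rounded(self):
        return self._round(self.sensitivity)

    @property
    def specificity_rounded(self):
        return self._round(self.specificity)

    @property
    def ppv_rounded(self):
        return self._round(self.ppv)

    @property
    def npv_rounded(self):
        return self._round(self.npv)


def dichotomize(values, threshold: float, direction: str = "greater") -> np.ndarray:
    """Binary test outcomes: positive iff strictly beyond the threshold.

    Ties (value == threshold) are test-negative.  ``direction`` is
    "greater" (large values abnormal) or "less".
    """
    values = np.asarray(values, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("criterion values must be finite")
    if direction == "greater":
        return values > threshold
    if direction == "less":
        return values < threshold
    raise ValueError("direction must be 'greater' or 'less'")


def tabulate(test_positive, condition_positive) -> ContingencyTable:
    """Cross-tabulate binary test outcomes against condition status."""
    test_positive = np.asarray(test_positive, dtype=bool)
    condition_positive = np.asarray(condition_positive, dtype=bool)
    if test_positive.shape != condition_positive.shape:
        raise ValueError("test and condition vectors differ in length")
    return ContingencyTable(
        tp=int(np.sum(test_positive & condition_positive)),
        fp=int(np.sum(test_positive & ~condition_positive)),
        fn=int(np.sum(~test_positive & condition_positive)),
        tn=int(np.sum(~test_positive & ~condition_positive)),
    )


def screening_values(
    t: ContingencyTable, criterion: str = "", threshold=None, direction: str = "greater"
) -> ScreeningResult:
    """Altman-Bland screening descriptors of a 2x2 table (without p)."""

    def ratio(num: int, den: int) -> float | None:
        return None if den == 0 else 100.0 * num / den

    return ScreeningResult(
        criterion=criterion,
        threshold=threshold,
        direction=direction,
        table=t,
        sensitivity=ratio(t.tp, t.tp + t.fn),
        specificity=ratio(t.tn, t.tn + t.fp),
        ppv=ratio(t.tp, t.tp + t.fp),
        npv=ratio(t.tn, t.tn + t.fn),
    )


# ---------------------------------------------------------------------------
# Fisher exact test
# ---------------------------------------------------------------------------

_TIE_RTOL = 1e-12  # relative tolerance for "as extreme" probability ties


def _log_comb(n: int, k: int) -> float:
    return (math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1))


def fisher_exact(t: ContingencyTable, method: str = "probability") -> float:
    """Two-sided Fisher exact p for a 2x2 table, by full enumeration.

    With margins fixed, the table is parameterised by x = tp following the
    hypergeometric distribution; log-probabilities use log-factorials.

    method
        "probability" (default): p is the total probability of all tables
        whose point probability does not exceed the observed one (within a
        1e-12 relative tolerance) — the probability-mass definition.
        "doubling": twice the smaller one-sided tail, capped at 1.

    Degenerate margins (a zero row or column total) admit only one table,
    so p = 1.
    """
    if method not in ("probability", "doubling"):
        raise ValueError("method must be 'probability' or 'doubling'")
    row1 = t.tp + t.fp        # test positive
    col1 = t.tp + t.fn        # condition positive
    n = t.n
    if row1 == 0 or col1 == 0 or row1 == n or col1 == n:
        return 1.0

    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    log_denom = _log_comb(n, row1)
    xs = np.arange(lo, hi + 1)
    logp = np.array(
        [
            _log_comb(col1, x) + _log_comb(n - col1, row1 - x) - log_denom
            for x in xs
        ]
    )
    obs = t.tp - lo
    if method == "doubling":
        p_obs = math.exp(logp[obs])
        lower = float(np.exp(logp[: obs + 1]).sum())
        upper = float(np.exp(logp[obs:]).sum())
        return min(1.0, 2.0 * min(lower, upper))
    cutoff = logp[obs] + math.log1p(_TIE_RTOL)
    p = float(np.exp(logp[logp <= cutoff]).sum())
    return min(1.0, p)


# ---------------------------------------------------------------------------
# Cohort evaluation
# ---------------------------------------------------------------------------


def condition_labels(analysis: pd.DataFrame, exclude_group3: bool = True):
    """Condition status per limb row of the analysis table.

    Returns (included_frame, condition_positive_bool_array).  Positives are
    reconstructed limbs of Group 2; negatives are all Group 1 limbs and the
    healthy limbs of Group 2; Group 3 is excluded by default (retained as
    negatives-by-VAS makes no sense for unsatisfied outliers, whose limbs
    are described individually, not analysed).
    """
    df = analysis
    if exclude_group3:
        df = df[df["group"] != 3]
    df = df.reset_index(drop=True)
    positive = (df["group"] == 2) & (df["limb"] == "reconstructed")
    return df, positive.to_numpy()


def _search_threshold(values: np.ndarray, condition: np.ndarray, direction: str):
    """Exhaustive threshold search over midpoints of sorted unique values.

    Returns (threshold, table, p).  The winning threshold minimises the
    exact two-sided Fisher p; ties break toward the smaller test-positive
    count (the more conservative operating point).
    """
    uniq = np.unique(values)
    if uniq.size < 2:
        raise ValueError("criterion is constant; no informative threshold exists")
    mids = 0.5 * (uniq[:-1] + uniq[1:])
    best = None
    for thr in mids:
        table = tabulate(dichotomize(values, thr, direction), condition)
        p = fisher_exact(table)
        n_pos = table.tp + table.fp
        key = (p, n_pos)
        if best is None or key < best[0]:
            best = (key, thr, table, p)
    _, thr, table, p = best
    return float(thr), table, p


def evaluate_criterion(
    analysis: pd.DataFrame,
    criterion: str,
    threshold="search",
    direction: str = "greater",
    exclude_group3: bool = True,
    fisher_method: str = "probability",
) -> ScreeningResult:
    """Evaluate one per-limb criterion as a screening test for lower satisfaction.

    ``criterion`` names a column of the analysis table (e.g. ``jpe_mmdeg``,
    ``kt_manmax_mm``, ``total_rot_deg``, ``pivot_shift_grade``).
    ``threshold`` is a number, or "search" for the exhaustive
    minimum-Fisher-p midpoint search.  Raises when either condition class is
    empty.
    """
    df, condition = condition_labels(analysis, exclude_group3=exclude_group3)
    if criterion not in df.columns:
        raise KeyError(f"criterion column {criterion!r} not in analysis table")
    if condition.sum() == 0 or (~condition).sum() == 0:
        raise ValueError(
            "screening needs both condition-positive and condition-negative "
            f"limbs (got {int(condition.sum())} positives of {condition.size})"
        )
    values = df[criterion].to_numpy(dtype=float)
    if isinstance(threshold, str) and threshold == "search":
        thr, table, p = _search_threshold(values, condition, direction)
    else:
        thr = float(threshold)
        table = tabulate(dichotomize(values, thr, direction), condition)
        p = fisher_exact(table, method=fisher_method)
    result = screening_values(table, criterion=criterion, threshold=thr,
                              direction=direction)
    return replace(result, p_value=p)


# ---------------------------------------------------------------------------
# Inverse audit of published rounded screening values
# ---------------------------------------------------------------------------


def _rounds_to(value: float | None, target: int) -> bool:
    return value is not None and int(math.floor(value + 0.5)) == target


def recover_table(
    rounded: tuple,
    n_max: int = 60,
    diseased=None,
    n_total=None,
) -> list[ContingencyTable]:
    """All integer 2x2 tables whose screening values round to the given ones.

    ``rounded`` is (sensitivity, specificity, ppv, npv) as integer percents;
    rounding is nearest integer, half away from zero.  ``diseased``
    optionally restricts the condition-positive count tp+fn; ``n_total``
    optionally pins the table total.  Tables are returned sorted by total n
    (then lexicographically), and an empty list means no integer table is
    consistent — a useful audit outcome in itself.
    """
    sens_t, spec_t, ppv_t, npv_t = (int(v) for v in rounded)
    if n_max > 200:
        raise ValueError("n_max above 200 is not supported (audit use only)")
    if diseased is not None:
        diseased = set(int(d) for d in diseased)
    matches = []
    for n in range(1, n_max + 1):
        if n_total is not None and n != n_total:
            continue
        for d in range(0, n + 1):
            if diseased is not None and d not in diseased:
                continue
            healthy = n - d
            for tp in range(0, d + 1):
                fn = d - tp
                for fp in range(0, healthy + 1):
                    tn = healthy - fp
                    t = ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn)
                    r = screening_values(t)
                    if (
                        _rounds_to(r.sensitivity, sens_t)
                        and _rounds_to(r.specificity, spec_t)
                        and _rounds_to(r.ppv, ppv_t)
                        and _rounds_to(r.npv, npv_t)
                    ):
                        matches.append(t)
    matches.sort(key=lambda t: (t.n, t.tp, t.fp, t.fn, t.tn))
    return matches


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------


class DiagnosticScreen:
    """Screening-test model over a per-limb analysis table.

    Parameters
    ----------
    analysis : DataFrame
        Per-limb analysis table (columns: subject_id, limb, the criterion
        columns, vas, group).
    criterion : str
        Column to evaluate as the screening test.
    direction : str
        "greater" if large values indicate the condition.
    exclude_group3 : bool
        Drop the unsatisfied-outlier group from the 2x2 (default True).

    ``fit()`` dichotomizes (fixed threshold or exhaustive search), builds
    the 2x2 table against the lower-satisfaction condition and returns a
    :class:`DiagnosticScreenResults`.
    """

    def __init__(self, analysis: pd.DataFrame, criterion: str,
                 direction: str = "greater", exclude_group3: bool = True):
        self.analysis = analysis
        self.criterion = criterion
        self.direction = direction
        self.exclude_group3 = exclude_group3

    @classmethod
    def from_dataframe(cls, analysis: pd.DataFrame, criterion: str, **kwargs):
        return cls(analysis, criterion, **kwargs)

    def fit(self, threshold="search",
            fisher_method: str = "probability") -> "DiagnosticScreenResults":
        res = evaluate_criterion(
            self.analysis,
            self.criterion,
            threshold=threshold,
            direction=self.direction,
            exclude_group3=self.exclude_group3,
            fisher_method=fisher_method,
        )
        return DiagnosticScreenResults(self, res)


class DiagnosticScreenResults:
    """Fitted screening results: operating point, descriptors, exact p."""

    def __init__(self, model: DiagnosticScreen, result: ScreeningResult):
        self.model = model
        self._result = result

    @property
    def result(self) -> ScreeningResult:
        return self._result

    @property
    def table(self) -> ContingencyTable:
        return self._result.table

    @property
    def p_value(self) -> float:
        return self._result.p_value

    def __getattr__(self, name):
        if name in ("sensitivity", "specificity", "ppv", "npv", "threshold",
                    "direction", "criterion"):
            return getattr(self._result, name)
        raise AttributeError(name)

    def to_frame(self) -> pd.DataFrame:
        r = self._result
        return pd.DataFrame(
            [
                {
                    "criterion": r.criterion,
                    "threshold": r.threshold,
                    "direction": r.direction,
                    "sensitivity": r.sensitivity,
                    "specificity": r.specificity,
                    "ppv": r.ppv,
                    "npv": r.npv,
                    "p_value": r.p_value,
                    "tp": r.table.tp,
                    "fp": r.table.fp,
                    "fn": r.table.fn,
                    "tn": r.table.tn,
                }
            ]
        )

    def summary(self) -> str:
        r = self._result
        t = r.table

        def fmt(x):
            return "undef" if x is None else f"{x:6.1f}"

        lines = [
            "Diagnostic screening results",
            "=" * 44,
            f"criterion:       {r.criterion}",
            f"direction:       {r.direction}",
            f"threshold:       {r.threshold:.4g}" if r.threshold is not None
            else "threshold:       (none)",
            f"n limbs:         {t.n} ({t.tp + t.fn} condition-positive)",
            "-" * 44,
            f"                 test+   test-",
            f"condition+       {t.tp:5d}   {t.fn:5d}",
            f"condition-       {t.fp:5d}   {t.tn:5d}",
            "-" * 44,
            f"sensitivity (%): {fmt(r.sensitivity)}",
            f"specificity (%): {fmt(r.specificity)}",
            f"PPV (%):         {fmt(r.ppv)}",
            f"NPV (%):         {fmt(r.npv)}",
            f"Fisher exact p:  {r.p_value:.4g}" if r.p_value is not None
            else "Fisher exact p:  (not computed)",
            "=" * 44,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<DiagnosticScreenResults {self._result.criterion} p={self.p_value}>"
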