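"""Agreement and diagnostic-accuracy statistics for paired binary slip
detection.

The central object is :class:`RaterAgreement`, a model built from a 2x2
contingency table (or two binary flag vectors) whose :meth:`~RaterAgreement.fit`
returns a :class:`RaterAgreementResults` carrying Cohen's kappa with its
asymptotic (Fleiss-Cohen-Everitt) confidence interval and Landis-Koch
interpretation, the diagnostic test statistics (sensitivity, specificity,
PPV, NPV) with Wald confidence intervals, the false-negative ratio, and a
``summary()`` table.

Functional wrappers (:func:`cohen_kappa`, :func:`diagnostic_stats`, ...)
expose the same computations for scripting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "ContingencyTable2x2",
    "AgreementResult",
    "ProportionEstimate",
    "DiagnosticResult",
    "RaterAgreement",
    "RaterAgreementResults",
    "crosstab",
    "combine_or",
    "cohen_kappa",
    "diagnostic_stats",
    "false_negative_ratio",
    "interpret_kappa",
    "interpret_test_stat",
    "kappa_from_counts",
    "round_half_up",
    "reproduce_paper_tables",
]

logger = logging.getLogger(__name__)

# Wald CIs use a fixed z of 1.96 (the conventional 95 % multiplier),
# matching how the diagnostic intervals are defined in this analysis.
WALD_Z = 1.96


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (so 0.605 -> 0.61, -0.185 -> -0.19)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts crossing a binary test against a binary gold standard.

    ``a``: test present & gold present; ``b``: test present & gold absent;
    ``c``: test absent & gold present; ``d``: test absent & gold absent.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name}={v!r} must be a non-negative integer")
        if self.n < 1:
            raise ValueError("table total must be >= 1")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def counts(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d], dtype=float)

    def transpose(self) -> "ContingencyTable2x2":
        """Swap the two raters (b and c exchange)."""
        return ContingencyTable2x2(self.a, self.c, self.b, self.d)

    @property
    def test_positive(self) -> int:
        return self.a + self.b

    @property
    def gold_positive(self) -> int:
        return self.a + self.c


def crosstab(x: Sequence, y: Sequence) -> ContingencyTable2x2:
    """Cross-tabulate two binary vectors into a 2x2 table.

    Pairs with a missing value on either side are dropped
    (pairwise-complete deletion); the number dropped is logged.
    """
    xs = pd.Series(x)
    ys = pd.Series(y)
    if len(xs) != len(ys):
        raise ValueError("x and y must have equal length")
    keep = xs.notna() & ys.notna()
    dropped = int((~keep).sum())
    if dropped:
        logger.info("crosstab: dropped %d incomplete pairs", dropped)
    xv = xs[keep].astype(float).to_numpy()
    yv = ys[keep].astype(float).to_numpy()
    if not np.isin(xv, (0.0, 1.0)).all() or not np.isin(yv, (0.0, 1.0)).all():
        raise ValueError("flags must be binary 0/1")
    a = int(np.sum((xv == 1) & (yv == 1)))
    b = int(np.sum((xv == 1) & (yv == 0)))
    c = int(np.sum((xv == 0) & (yv == 1)))
    d = int(np.sum((xv == 0) & (yv == 0)))
    return ContingencyTable2x2(a, b, c, d)


def combine_or(*flags: Sequence) -> pd.Series:
    """Element-wise logical OR of two or more binary flag vectors.

    A result element is 1 if any input is 1, missing if no input is 1 and
    at least one is missing, else 0.
    """
    if len(flags) < 2:
        raise ValueError("combine_or needs at least two vectors")
    frames = [pd.Series(f, dtype="Float64") for f in flags]
    n = len(frames[0])
    if any(len(f) != n for f in frames):
        raise ValueError("all vectors must have equal length")
    stacked = pd.concat(frames, axis=1)
    any_one = (stacked == 1).any(axis=1)
    any_na = stacked.isna().any(axis=1)
    out = pd.Series(np.zeros(n), dtype="Int64")
    out[any_one] = 1
    out[~any_one & any_na] = pd.NA
    return out


# ---------------------------------------------------------------------------
# Cohen's kappa


def kappa_from_counts(a, b, c, d) -> tuple[np.ndarray, np.ndarray]:
    """Cohen's kappa and its per-observation asymptotic variance.

    Vectorized over arrays of 2x2 cell counts.  The variance is the
    large-sample variance of the sample kappa derived by Fleiss, Cohen and
    Everitt (1969); divide by n for ``Var(kappa_hat)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    n = a + b + c + d
    p11, p12, p21, p22 = a / n, b / n, c / n, d / n
    r1 = p11 + p12  # rater-1 (test) positive margin
    c1 = p11 + p21  # rater-2 (gold) positive margin
    po = p11 + p22
    pe = r1 * c1 + (1 - r1) * (1 - c1)
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(pe < 1.0, (po - pe) / (1 - pe), np.nan)
        A = (
            p11 * ((1 - pe) - (r1 + c1) * (1 - po)) ** 2
            + p22 * ((1 - pe) - ((1 - r1) + (1 - c1)) * (1 - po)) ** 2
        )
        B = (1 - po) ** 2 * (
            p12 * (c1 + (1 - r1)) ** 2 + p21 * ((1 - c1) + r1) ** 2
        )
        C = (po * pe - 2 * pe + po) ** 2
        var1 = np.where(pe < 1.0, (A + B - C) / (1 - pe) ** 4, np.nan)
    return kappa, np.maximum(var1, 0.0)


@dataclass(frozen=True)
class AgreementResult:
    """Cohen's kappa with confidence interval and Landis-Koch band."""

    kappa: float
    ci_low: float
    ci_high: float
    interpretation: str
    se: float

    def __post_init__(self) -> None:
        if not self.ci_low - 1e-12 <= self.kappa <= self.ci_high + 1e-12:
            raise ValueError("kappa must lie inside its confidence interval")


def cohen_kappa(table: ContingencyTable2x2, alpha: float = 0.05) -> AgreementResult:
    """Cohen's kappa of a 2x2 table with its asymptotic Wald CI.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed and p_e the
    chance agreement; the standard error is the Fleiss-Cohen-Everitt
    large-sample SE.  Raises on the degenerate case p_e = 1 (all mass in
    one margin pair), where kappa is undefined.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    kappa, var1 = kappa_from_counts(table.a, table.b, table.c, table.d)
    if np.isnan(kappa):
        raise ValueError("kappa undefined: chance agreement p_e = 1")
    k = float(kappa)
    se = math.sqrt(float(var1) / table.n)
    z = float(norm.ppf(1 - alpha / 2))
    lo = max(k - z * se, -1.0)
    hi = min(k + z * se, 1.0)
    return AgreementResult(kappa=k, ci_low=lo, ci_high=hi,
                           interpretation=interpret_kappa(k), se=se)


def interpret_kappa(kappa: float) -> str:
    """Landis-Koch agreement band of a kappa value.

    Bands follow the printed two-decimal cut-points (<0.21 poor, 0.21-0.40
    fair, 0.41-0.60 moderate, 0.61-0.80 good, 0.81-1.00 very good), so the
    value is first rounded half-up to two decimals; anything below 0.21,
    including negative kappa, is poor.
    """
    if kappa > 1.0 + 1e-9:
        raise ValueError("kappa cannot exceed 1")
    r = round_half_up(kappa, 2)
    if r < 0.21:
        return "poor"
    if r <= 0.40:
        return "fair"
    if r <= 0.60:
        return "moderate"
    if r <= 0.80:
        return "good"
    return "very good"


def interpret_test_stat(value: float) -> str:
    """Band a diagnostic proportion: <=0.60 low, 0.61-0.80 moderate, >0.80 high."""
    if not 0.0 <= value <= 1.0:
        raise ValueError("test statistic must lie in [0, 1]")
    r = round_half_up(value, 2)
    if r <= 0.60:
        return "low"
    if r <= 0.80:
        return "moderate"
    return "high"


# ---------------------------------------------------------------------------
# Diagnostic test statistics


@dataclass(frozen=True)
class ProportionEstimate:
    """A proportion with its Wald CI and qualitative band."""

    value: float
    ci_low: float
    ci_high: float
    band: str
    numerator: int
    denominator: int


def _wald_proportion(num: int, den: int) -> Optional[ProportionEstimate]:
    if den < 1:
        return None
    p = num / den
    se = math.sqrt(p * (1 - p) / den)
    lo = max(p - WALD_Z * se, 0.0)
    hi = min(p + WALD_Z * se, 1.0)
    return ProportionEstimate(value=p, ci_low=lo, ci_high=hi,
                              band=interpret_test_stat(p),
                              numerator=num, denominator=den)


@dataclass(frozen=True)
class DiagnosticResult:
    """Se, Sp, PPV, NPV of a binary test against a gold standard.

    Any statistic whose denominator is zero is ``None`` (undefined), never
    silently 0.
    """

    se: Optional[ProportionEstimate]
    sp: Optional[ProportionEstimate]
    ppv: Optional[ProportionEstimate]
    npv: Optional[ProportionEstimate]


def diagnostic_stats(table: ContingencyTable2x2) -> DiagnosticResult:
    """Sensitivity a/(a+c), specificity d/(b+d), PPV a/(a+b), NPV d/(c+d),
    each with a 95 % Wald CI (+/- 1.96 * sqrt(p(1-p)/n), clamped to [0,1])."""
    return DiagnosticResult(
        se=_wald_proportion(table.a, table.a + table.c),
        sp=_wald_proportion(table.d, table.b + table.d),
        ppv=_wald_proportion(table.a, table.a + table.b),
        npv=_wald_proportion(table.d, table.c + table.d),
    )


def false_negative_ratio(table: ContingencyTable2x2) -> float:
    """Missed slips among all test-negative observations, c / (c + d)."""
    den = table.c + table.d
    if den < 1:
        raise ValueError("false_negative_ratio undefined: no test-negative observations")
    return table.c / den


# ---------------------------------------------------------------------------
# Model / Results objects


class RaterAgreement:
    """Agreement model for two binary slip-detection methods.

    Parameters
    ----------
    table : ContingencyTable2x2
        Counts of the test method crossed with the gold-standard method.

    Use :meth:`from_flags` or :meth:`from_dataframe` to build the model
    from observation-level binary vectors (missing pairs are dropped).
    """

    def __init__(self, table: ContingencyTable2x2):
        self.table = table

    @classmethod
    def from_flags(cls, test: Sequence, gold: Sequence) -> "RaterAgreement":
        return cls(crosstab(test, gold))

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, test: str, gold: str) -> "RaterAgreement":
        for col in (test, gold):
            if col not in data.columns:
                raise KeyError(f"column {col!r} not in data")
        return cls.from_flags(data[test], data[gold])

    def fit(self, alpha: float = 0.05) -> "RaterAgreementResults":
        agreement = cohen_kappa(self.table, alpha=alpha)
        diagnostics = diagnostic_stats(self.table)
        try:
            fn_ratio = false_negative_ratio(self.table)
        except ValueError:
            fn_ratio = None
        return RaterAgreementResults(
            table=self.table,
            agreement=agreement,
            diagnostics=diagnostics,
            fn_ratio=fn_ratio,
            alpha=alpha,
        )


@dataclass(frozen=True)
class RaterAgreementResults:
    """Fitted agreement/diagnostic statistics for one method pair."""

    table: ContingencyTable2x2
    agreement: AgreementResult
    diagnostics: DiagnosticResult
    fn_ratio: Optional[float]
    alpha: float

    @property
    def kappa(self) -> float:
        return self.agreement.kappa

    def to_dict(self) -> dict:
        t = self.table

        def prop(p: Optional[ProportionEstimate]) -> Optional[dict]:
            if p is None:
                return None
            return {
                "est": p.value,
                "ci": [p.ci_low, p.ci_high],
                "band": p.band,
            }

        return {
            "table": {"a": t.a, "b": t.b, "c": t.c, "d": t.d, "n": t.n},
            "kappa": {
                "est": self.agreement.kappa,
                "ci": [self.agreement.ci_low, self.agreement.ci_high],
                "band": self.agreement.interpretation,
            },
            "diagnostics": {
                "se": prop(self.diagnostics.se),
                "sp": prop(self.diagnostics.sp),
                "ppv": prop(self.diagnostics.ppv),
                "npv": prop(self.diagnostics.npv),
            },
            "fn_ratio": self.fn_ratio,
        }

    def summary(self) -> str:
        """Human-readable summary table (printed values rounded half-up)."""
        t = self.table
        lines = [
            "Two-rater slip-detection agreement",
            "==================================",
            f"n = {t.n}   a={t.a}  b={t.b}  c={t.c}  d={t.d}",
            f"test-positive: {t.test_positive} "
            f"({round_half_up(100 * t.test_positive / t.n, 1)}%)   "
            f"gold-positive: {t.gold_positive} "
            f"({round_half_up(100 * t.gold_positive / t.n, 1)}%)",
            f"kappa = {round_half_up(self.agreement.kappa, 2):.2f} "
            f"({round_half_up(self.agreement.ci_low, 2):.2f}-"
            f"{round_half_up(self.agreement.ci_high, 2):.2f})  "
            f"[{self.agreement.interpretation}]",
        ]
        for label, p in (("Se ", self.diagnostics.se), ("Sp ", self.diagnostics.sp),
                         ("PPV", self.diagnostics.ppv), ("NPV", self.diagnostics.npv)):
            if p is None:
                lines.append(f"{label} = undefined (zero denominator)")
            else:
                lines.append(
                    f"{label} = {round_half_up(p.value, 2):.2f} "
                    f"({round_half_up(p.ci_low, 2):.2f}-{round_half_up(p.ci_high, 2):.2f})"
                    f"  [{p.band}]"
                )
        if self.fn_ratio is not None:
            lines.append(
                f"false-negative ratio = {round_half_up(100 * self.fn_ratio, 1)}%"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Packaged-table report


def reproduce_paper_tables(out_dir=None) -> pd.DataFrame:
    """Recompute all agreement and diagnostic statistics from the packaged
    published contingency tables.

    Returns one row per method pair with raw and printed-precision values;
    when ``out_dir`` is given, writes ``paper_report.csv`` and a
    human-readable ``paper_report.txt`` there (byte-deterministic).
    """
    from . import fixtures

    rows = []
    text = []
    for fx in fixtures.all_fixtures():
        t = fx.table
        res = RaterAgreement(t).fit()
        d = res.diagnostics
        row = {
            "name": fx.name,
            "trial": fx.trial,
            "a": t.a,
            "b": t.b,
            "c": t.c,
            "d": t.d,
            "n": t.n,
            "test_positive": t.test_positive,
            "test_positive_pct": round_half_up(100 * t.test_positive / t.n, 1),
            "gold_positive": t.gold_positive,
            "gold_positive_pct": round_half_up(100 * t.gold_positive / t.n, 1),
            "kappa": res.agreement.kappa,
            "kappa_2dp": round_half_up(res.agreement.kappa, 2),
            "kappa_band": res.agreement.interpretation,
            "fn_ratio_pct": round_half_up(100 * res.fn_ratio, 1)
            if res.fn_ratio is not None else None,
        }
        for label, p in (("se", d.se), ("sp", d.sp), ("ppv", d.ppv), ("npv", d.npv)):
            row[label] = p.value if p else None
            row[f"{label}_2dp"] = round_half_up(p.value, 2) if p else None
            row[f"{label}_band"] = p.band if p else None
        rows.append(row)
        text.append(f"--- {fx.name} ({fx.source}) ---")
        text.append(res.summary())
        text.append("")
    report = pd.DataFrame(rows)
    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "paper_report.csv", index=False)
        (out / "paper_report.txt").write_text("\n".join(text), encoding="utf-8")
    return report
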