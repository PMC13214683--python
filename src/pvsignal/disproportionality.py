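"""Case/non-case disproportionality statistics for drug–event pairs.

For each drug–term pair the database is collapsed to the 2×2 table

=========  =====  ========
.          event  no event
=========  =====  ========
drug       a      b
no drug    c      d
=========  =====  ========

from which the module computes the proportional reporting ratio
(PRR = [a/(a+b)] / [c/(c+d)]), the Yates continuity-corrected Pearson
chi-squared statistic, the reporting odds ratio (ROR = ad/bc) with a
Woolf 95% CI, and the Bayesian information component
IC = log2((a+1/2)/(E+1/2)) with its lower 2.5% credibility bound taken
from the Gamma(a+1/2, 1) posterior of the observed count.

p-values from the chi-squared statistic are handled entirely on the
natural-log scale — spontaneous-reporting tables routinely produce
chi-squared values in the thousands, for which the survival function
underflows double precision — and the Benjamini–Hochberg step-up
correction is likewise evaluated in log space.

A pair is flagged as a signal when four conditions hold simultaneously:
PRR >= 2, chi-squared >= 4, at least three cases (a >= 3), and a BH
false-discovery-rate adjusted p-value below 0.05.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import special, stats

from .meddra import EventMatrix
from .srs_store import ReportSet, ROUTES, eligible_reports

logger = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # two-sided 95% standard-normal quantile


@dataclass(frozen=True)
class ContingencyTable:
    """Case/non-case 2×2 counts for one drug–event pair."""

    a: int  # drug and event
    b: int  # drug, no event
    c: int  # event, no drug
    d: int  # neither

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.n == 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def drug_total(self) -> int:
        return self.a + self.b

    @property
    def nondrug_total(self) -> int:
        return self.c + self.d

    @property
    def event_total(self) -> int:
        return self.a + self.c

    @property
    def expected_a(self) -> float:
        return self.drug_total * self.event_total / self.n


def build_table(eligible_ids: Iterable, event_ids: Iterable,
                all_ids: Iterable) -> ContingencyTable:
    """Build the 2×2 table from id sets over the post-dedup report universe."""
    universe = set(all_ids)
    if not universe:
        raise ValueError("empty report universe")
    eligible = set(eligible_ids) & universe
    event = set(event_ids) & universe
    a = len(eligible & event)
    b = len(eligible) - a
    c = len(event) - a
    d = len(universe) - a - b - c
    return ContingencyTable(a=a, b=b, c=c, d=d)


def prr(t: ContingencyTable) -> float:
    """Proportional reporting ratio; NaN when not evaluable (c = 0 or a+b = 0)."""
    if t.drug_total == 0 or t.c == 0 or t.nondrug_total == 0:
        return math.nan
    return (t.a / t.drug_total) / (t.c / t.nondrug_total)


def yates_chi2(t: ContingencyTable) -> float:
    """Pearson chi-squared with Yates continuity correction.

    Each cell contributes ``max(|O - E| - 1/2, 0)^2 / E``; the truncation
    at zero means tables within half a count of independence score 0.
    Raises on a zero marginal (the statistic is undefined there).
    """
    if min(t.drug_total, t.nondrug_total, t.event_total, t.n - t.event_total) == 0:
        raise ValueError("chi-squared undefined for a zero marginal")
    observed = np.array([t.a, t.b, t.c, t.d], dtype=float)
    expected = np.array(
        [t.drug_total * t.event_total,
         t.drug_total * (t.n - t.event_total),
         t.nondrug_total * t.event_total,
         t.nondrug_total * (t.n - t.event_total)], dtype=float) / t.n
    adj = np.maximum(np.abs(observed - expected) - 0.5, 0.0)
    return float(np.sum(adj * adj / expected))


def ror_with_ci(t: ContingencyTable, z: float = Z_95) -> tuple[float, float, float]:
    """Reporting odds ratio ad/bc with the Woolf log-scale CI.

    The point estimate needs b, c > 0; the CI needs all four cells > 0
    (no Haldane–Anscombe correction is applied — sparse pairs are
    reported not-evaluable instead). Returns ``(ror, low, high)`` with
    NaN for whichever piece is not evaluable.
    """
    if t.b == 0 or t.c == 0:
        return math.nan, math.nan, math.nan
    point = (t.a * t.d) / (t.b * t.c)
    if min(t.a, t.b, t.c, t.d) == 0:
        return point, math.nan, math.nan
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return (point, point * math.exp(-z * se), point * math.exp(z * se))


def ic_with_ic025(t: ContingencyTable) -> tuple[float, float]:
    """Information component (bits) and its lower 95% credibility bound.

    IC = log2((a + 1/2) / (E + 1/2)) with E = (a+b)(a+c)/N; the lower
    bound replaces a + 1/2 by the 2.5% quantile of a Gamma(a + 1/2)
    distribution with unit scale, i.e. the posterior of the Poisson count
    under a Jeffreys-style half-count prior. Defined for a = 0.
    """
    e = t.expected_a
    ic = math.log2((t.a + 0.5) / (e + 0.5))
    q = stats.gamma.ppf(0.025, t.a + 0.5)
    ic025 = math.log2(q / (e + 0.5)) if q > 0 else -math.inf
    return ic, ic025


def log_p_from_chi2(chi2: float) -> float:
    """Natural-log upper-tail p of the 1-df chi-squared distribution.

    Evaluated as ``ln 2 + log Phi(-sqrt(chi2))`` via the log-scale normal
    CDF, which stays finite far beyond the point where the plain survival
    function underflows (chi2 of a few thousand).
    """
    if chi2 < 0:
        raise ValueError("chi-squared statistic must be non-negative")
    if chi2 == 0:
        return 0.0
    return float(math.log(2.0) + special.log_ndtr(-math.sqrt(chi2)))


def bh_adjust_log(log_ps: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg adjusted p-values, computed entirely in log space.

    Input and output are natural-log p-values (all <= 0). For sorted
    values the candidate is ``log p_(i) + ln(m/i)``; the adjusted value is
    the running minimum from the largest rank down, capped at ln(1) = 0.
    Output is returned in the input order. Ties are handled by a stable
    sort so results are reproducible.
    """
    m = len(log_ps)
    if m == 0:
        return []
    arr = np.asarray(log_ps, dtype=float)
    if np.any(arr > 1e-12):
        raise ValueError("log p-values must be <= 0")
    order = np.argsort(arr, kind="stable")
    candidates = arr[order] + np.log(m) - np.log(np.arange(1, m + 1))
    adjusted = np.minimum.accumulate(candidates[::-1])[::-1]
    adjusted = np.minimum(adjusted, 0.0)
    out = np.empty(m)
    out[order] = adjusted
    return out.tolist()


@dataclass
class SignalResult:
    """All disproportionality statistics for one drug–term pair."""

    drug: str
    term_id: str
    level: str
    table: ContingencyTable
    prr: float
    chi2: float
    ror: float
    ror_ci: tuple[float, float]
    ic: float
    ic025: float
    log_p: float
    log_fdr_p: float = math.nan
    is_signal: bool = False

    @property
    def reporting_ratio(self) -> float:
        """Within-drug proportion of the event, a / (a+b)."""
        return self.a / self.table.drug_total if self.table.drug_total else math.nan

    @property
    def a(self) -> int:
        return self.table.a


def detect_signal(r: SignalResult, alpha_fdr: float = 0.05,
                  prr_min: float = 2.0, chi2_min: float = 4.0,
                  min_cases: int = 3) -> bool:
    """Four-condition signal rule; each condition is logged for audit."""
    conds = {
        "prr>=%.3g" % prr_min: (not math.isnan(r.prr)) and r.prr >= prr_min,
        "chi2>=%.3g" % chi2_min: r.chi2 >= chi2_min,
        "cases>=%d" % min_cases: r.a >= min_cases,
        "fdr_p<%.3g" % alpha_fdr: r.log_fdr_p < math.log(alpha_fdr),
    }
    logger.debug("signal conditions %s/%s %s: %s", r.drug, r.term_id,
                 r.level, conds)
    return all(conds.values())


def compute_pair(drug: str, term_id: str, level: str,
                 table: ContingencyTable) -> SignalResult:
    """All per-pair statistics except the (family-dependent) FDR step."""
    chi2 = yates_chi2(table)
    point, low, high = ror_with_ci(table)
    ic, ic025 = ic_with_ic025(table)
    return SignalResult(drug=drug, term_id=term_id, level=level, table=table,
                        prr=prr(table), chi2=chi2, ror=point,
                        ror_ci=(low, high), ic=ic, ic025=ic025,
                        log_p=log_p_from_chi2(chi2))


def run_screen(rs: ReportSet, matrix: EventMatrix,
               drugs: Mapping[str, Iterable[str]] | Sequence[str],
               alpha_fdr: float = 0.05, prr_min: float = 2.0,
               chi2_min: float = 4.0, min_cases: int = 3) -> list[SignalResult]:
    """Screen every drug–term pair with at least one case.

    ``drugs`` maps each drug name to its allowed administration routes
    (a bare sequence of names allows all routes). The BH family is
    per drug × per level: all terms tested for that drug at this matrix's
    level. Results are sorted by chi-squared descending within drug.
    """
    if not isinstance(drugs, Mapping):
        drugs = {name: ROUTES for name in drugs}
    universe = rs.report_ids
    by_term = matrix.reports_by_term()
    results: list[SignalResult] = []
    for drug_name, routes in drugs.items():
        eligible = eligible_reports(rs, drug_name, routes)
        per_drug: list[SignalResult] = []
        for term_id in sorted(by_term):
            table = build_table(eligible, by_term[term_id], universe)
            if table.a < 1:
                continue
            per_drug.append(compute_pair(drug_name, term_id, matrix.level, table))
        if per_drug:
            # stable sort by raw log p then term id: reproducible BH ranks
            per_drug.sort(key=lambda r: (r.log_p, r.term_id))
            adjusted = bh_adjust_log([r.log_p for r in per_drug])
            for r, adj in zip(per_drug, adjusted):
                r.log_fdr_p = adj
                r.is_signal = detect_signal(r, alpha_fdr, prr_min,
                                            chi2_min, min_cases)
        per_drug.sort(key=lambda r: -r.chi2)
        logger.info("screen %s (%s level): %d pair(s) tested, %d signal(s)",
                    drug_name, matrix.level, len(per_drug),
                    sum(r.is_signal for r in per_drug))
        results.extend(per_drug)
    return results


def volcano_data(results: Sequence[SignalResult]) -> list[tuple]:
    """(x, y, size, label) tuples for a volcano plot.

    x = log2(PRR), y = chi-squared, size proportional to the within-drug
    reporting ratio a/(a+b). Pairs with non-evaluable PRR are omitted
    (logged).
    """
    out = []
    skipped = 0
    for r in results:
        if math.isnan(r.prr) or r.prr <= 0:
            skipped += 1
            continue
        out.append((math.log2(r.prr), r.chi2, r.reporting_ratio,
                    f"{r.drug}:{r.term_id}"))
    if skipped:
        logger.info("volcano_data: omitted %d pair(s) with non-evaluable PRR",
                    skipped)
    return out
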