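"""Disproportionality statistics: 2x2 tables, ROR, Fisher exact, volcano.

The reporting odds ratio (ROR) compares the odds of a target event being
reported with a drug against the odds with all other drugs, from the 2x2
cross-tabulation of the integrated report table::

                      event      non-event
    drug of interest    a            b
    all other drugs     c            d

    ROR = (a/b) / (c/d) = (a*d) / (b*c)

When any cell is zero the Haldane continuity correction (add 0.5 to every
cell) keeps the estimate finite; the correction feeds the ROR and its Woolf
(log-scale) confidence interval only — Fisher's exact test always runs on
the raw integer cells.  A drug is flagged as a signal when ln ROR > 0, the
two-sided exact p is below alpha, and the drug has at least
``min_drug_reports`` adverse-event rows overall.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, ranksums
from sklearn.base import BaseEstimator

from thrombosignal.terms import SmqTermSet, normalize_pt

__all__ = [
    "ContingencyTable",
    "haldane",
    "ror",
    "ror_ci",
    "fisher_p",
    "contingency",
    "RorSignalScreen",
    "signal_scan",
    "volcano_points",
    "volcano_plot",
    "stratified_ror",
    "age_comparison",
    "class_summary",
]

#: p-values are floored here before -log10, keeping volcano output finite
P_FLOOR = 1e-300

RESULT_COLUMNS = ["drug_name", "a", "b", "c", "d", "ror", "ci_low", "ci_high",
                  "p", "ln_ror", "neg_log10_p", "n_drug_reports", "flagged"]


@dataclass(frozen=True)
class ContingencyTable:
    """One 2x2 report cross-tabulation; ``corrected`` marks Haldane state."""

    a: float
    b: float
    c: float
    d: float
    corrected: bool = False

    def __post_init__(self):
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError("contingency cells must be non-negative")
        if sum(cells) <= 0:
            raise ValueError("contingency table must have a positive total")

    @property
    def cells(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)

    @property
    def total(self) -> float:
        return self.a + self.b + self.c + self.d


def haldane(t: ContingencyTable) -> ContingencyTable:
    """Add 0.5 to every cell iff any cell is zero; otherwise identity."""
    if min(t.cells) == 0:
        return ContingencyTable(t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5,
                                corrected=True)
    return t


def ror(t: ContingencyTable) -> float:
    """Reporting odds ratio (a*d)/(b*c)."""
    if t.b * t.c == 0:
        raise ZeroDivisionError(
            "zero cell in the ROR denominator; apply haldane() first")
    return (t.a * t.d) / (t.b * t.c)


def ror_ci(t: ContingencyTable, z: float = 1.959963984540054) -> tuple[float, float]:
    """Woolf (log-scale) confidence interval exp(ln ROR +/- z*SE).

    SE = sqrt(1/a + 1/b + 1/c + 1/d); requires all cells > 0 (apply
    :func:`haldane` first when a cell is zero).
    """
    if min(t.cells) <= 0:
        raise ValueError("ror_ci requires all cells > 0; apply haldane() "
                         "first for tables with zero cells")
    log_ror = math.log(ror(t))
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return math.exp(log_ror - z * se), math.exp(log_ror + z * se)


def fisher_p(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p by the point-probability method.

    Sums hypergeometric point probabilities not exceeding that of the
    observed table (the minimum-likelihood two-sided convention).  Requires
    raw integer cells: the continuity correction must never precede the
    exact test.
    """
    if t.corrected:
        raise ValueError("fisher_p must run on the uncorrected table")
    cells = t.cells
    if any(abs(x - round(x)) > 1e-9 for x in cells):
        raise ValueError("fisher_p requires integer cells")
    a, b, c, d = (int(round(x)) for x in cells)
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    kmin = max(0, row1 + col1 - n)
    kmax = min(row1, col1)
    support = np.arange(kmin, kmax + 1)
    pmf = hypergeom.pmf(support, n, col1, row1)
    p_obs = pmf[a - kmin]
    # relative slack guards against floating-point ties in the pmf
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    if p >= 1.0 - 1e-9:  # the full support summed; clear accumulated error
        p = 1.0
    return min(max(p, P_FLOOR), 1.0)


def contingency(rows: pd.DataFrame, drug: str,
                terms: SmqTermSet | Iterable[str]) -> ContingencyTable:
    """Cross-tabulate the integrated table for one drug vs a term set.

    ``a`` counts rows with the drug and an in-set preferred term, ``b`` the
    drug's other rows, ``c``/``d`` the same split over all other drugs; the
    four cells always sum to ``len(rows)``.  A drug absent from ``rows``
    yields a = b = 0 (not an error).
    """
    term_keys = set(terms.pts) if isinstance(terms, SmqTermSet) else {
        normalize_pt(t) for t in terms}
    is_drug = (rows["drug_name"] == drug).to_numpy()
    is_event = rows["pt"].isin(term_keys).to_numpy()
    a = int(np.sum(is_drug & is_event))
    b = int(np.sum(is_drug & ~is_event))
    c = int(np.sum(~is_drug & is_event))
    d = int(np.sum(~is_drug & ~is_event))
    return ContingencyTable(a, b, c, d)


def _one_result(drug: str, a: int, b: int, c: int, d: int,
                alpha: float, min_reports: int,
                p_override: float | None = None) -> dict:
    raw = ContingencyTable(a, b, c, d)
    corr = haldane(raw)
    est = ror(corr)
    ci_low, ci_high = ror_ci(corr)
    p = fisher_p(raw)
    ln_ror = math.log(est) if est > 0 else -math.inf
    p_eff = p if p_override is None else p_override
    n_reports = a + b
    flagged = (ln_ror > 0) and (p_eff < alpha) and (n_reports >= min_reports)
    return {
        "drug_name": drug, "a": a, "b": b, "c": c, "d": d,
        "ror": est, "ci_low": ci_low, "ci_high": ci_high, "p": p,
        "ln_ror": ln_ror,
        "neg_log10_p": -math.log10(max(p, P_FLOOR)),
        "n_drug_reports": n_reports, "flagged": flagged,
    }


class RorSignalScreen(BaseEstimator):
    """Per-drug ROR / Fisher signal screen over an integrated report table.

    Parameters
    ----------
    term_set : SmqTermSet or iterable of str
        Preferred terms defining the target event.
    cohort : iterable of str, optional
        Drugs to screen (e.g. the steroid cohort).  Each cohort drug gets a
        result row even with zero reports; by default every drug present in
        the data is screened.
    alpha : float
        Significance level for the flag rule (raw p unless ``bh``).
    min_drug_reports : int
        Eligibility threshold on the drug's total adverse-event rows (a+b).
    bh : bool
        Apply Benjamini-Hochberg across the screened drugs and flag on the
        adjusted p.  Off by default (the flag rule uses raw p < alpha).

    Attributes
    ----------
    results_ : pandas.DataFrame
        One row per screened drug with cells, ROR, Woolf CI, exact p,
        volcano coordinates and the flag.
    flagged_drugs_ : list of str
        Drugs meeting the signal rule, in screening order.
    n_rows_ : int
        Size of the integrated table screened.
    """

    def __init__(self, term_set=None, cohort=None, alpha: float = 0.05,
                 min_drug_reports: int = 1000, bh: bool = False):
        self.term_set = term_set
        self.cohort = cohort
        self.alpha = alpha
        self.min_drug_reports = min_drug_reports
        self.bh = bh

    def fit(self, rows: pd.DataFrame, y=None) -> "RorSignalScreen":
        if self.term_set is None:
            raise ValueError("term_set is required")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        terms = self.term_set
        term_keys = set(terms.pts) if isinstance(terms, SmqTermSet) else {
            normalize_pt(t) for t in terms}

        is_event = rows["pt"].isin(term_keys)
        grouped = pd.DataFrame({
            "a": is_event.groupby(rows["drug_name"]).sum(),
            "n": rows.groupby("drug_name").size(),
        })
        total = len(rows)
        total_events = int(is_event.sum())

        if self.cohort is None:
            drugs = list(grouped.index)
        else:
            drugs = sorted(set(self.cohort))

        records = []
        for drug in drugs:
            if drug in grouped.index:
                a = int(grouped.loc[drug, "a"])
                n = int(grouped.loc[drug, "n"])
            else:
                a = n = 0
            b = n - a
            c = total_events - a
            d = (total - total_events) - b
            records.append(_one_result(drug, a, b, c, d,
                                       self.alpha, self.min_drug_reports))
        results = pd.DataFrame(records, columns=RESULT_COLUMNS)

        if self.bh and len(results):
            from statsmodels.stats.multitest import multipletests

            _, p_adj, _, _ = multipletests(results["p"], alpha=self.alpha,
                                           method="fdr_bh")
            results["p_adj"] = p_adj
            results["flagged"] = ((results["ln_ror"] > 0)
                                  & (p_adj < self.alpha)
                                  & (results["n_drug_reports"]
                                     >= self.min_drug_reports))

        self.results_ = results
        self.flagged_drugs_ = list(results.loc[results["flagged"],
                                               "drug_name"])
        self.n_rows_ = total
        return self


def signal_scan(rows: pd.DataFrame, cohort=None, terms=None,
                alpha: float = 0.05,
                min_drug_reports: int = 1000) -> pd.DataFrame:
    """Functional wrapper over :class:`RorSignalScreen`."""
    screen = RorSignalScreen(term_set=terms, cohort=cohort, alpha=alpha,
                             min_drug_reports=min_drug_reports)
    return screen.fit(rows).results_


def volcano_points(results: pd.DataFrame,
                   p_floor: float = P_FLOOR) -> pd.DataFrame:
    """(x, y) volcano coordinates: x = ln ROR, y = -log10 p (floored)."""
    return pd.DataFrame({
        "drug_name": results["drug_name"],
        "x": results["ln_ror"],
        "y": -np.log10(np.maximum(results["p"], p_floor)),
    })


def volcano_plot(results: pd.DataFrame, path, alpha: float = 0.05):
    """Render the screen as a volcano scatter (effect vs significance)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pts = volcano_points(results)
    fig, ax = plt.subplots(figsize=(7, 5))
    colors = np.where(results["flagged"], "crimson", "grey")
    ax.scatter(pts["x"], pts["y"], c=colors, s=18, alpha=0.8)
    ax.axvline(0.0, color="k", lw=0.6)
    ax.axhline(-math.log10(alpha), color="k", lw=0.6, ls="--")
    ax.set_xlabel("ln ROR")
    ax.set_ylabel("-log10 p (Fisher exact)")
    ax.set_title("Disproportionality volcano")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def stratified_ror(rows: pd.DataFrame, strata: Mapping[str, str],
                   terms) -> pd.DataFrame:
    """Per-stratum ROR vs the complementary strata (e.g. routes, sex).

    ``strata`` maps case_id -> label; unlabeled cases are excluded.  For
    each label the (a, b) cells come from its cases, (c, d) from the cases
    of every other label.
    """
    term_keys = set(terms.pts) if isinstance(terms, SmqTermSet) else {
        normalize_pt(t) for t in terms}
    labels = rows["case_id"].map(strata)
    sub = rows[labels.notna()].copy()
    sub["stratum"] = labels[labels.notna()]
    is_event = sub["pt"].isin(term_keys)
    tab = pd.DataFrame({
        "a": is_event.groupby(sub["stratum"]).sum().astype(int),
        "n": sub.groupby("stratum").size(),
    })
    total = len(sub)
    total_events = int(is_event.sum())
    records = []
    for label, row in tab.iterrows():
        a, n = int(row["a"]), int(row["n"])
        b = n - a
        c = total_events - a
        d = (total - total_events) - b
        raw = ContingencyTable(a, b, c, d)
        corr = haldane(raw)
        est = ror(corr)
        lo, hi = ror_ci(corr)
        records.append({"stratum": label, "a": a, "b": b, "c": c, "d": d,
                        "ror": est, "ci_low": lo, "ci_high": hi,
                        "p": fisher_p(raw)})
    return pd.DataFrame.from_records(records)


@dataclass(frozen=True)
class AgeComparison:
    median_event: float
    median_nonevent: float
    p: float


def age_comparison(rows: pd.DataFrame, demo: pd.DataFrame,
                   terms) -> AgeComparison:
    """Median age in event vs non-event cases with a rank-sum p-value.

    A case belongs to the event group if any of its rows carries an in-set
    preferred term; ages come from DEMO (invalid ages already missing).
    """
    term_keys = set(terms.pts) if isinstance(terms, SmqTermSet) else {
        normalize_pt(t) for t in terms}
    case_event = (rows["pt"].isin(term_keys)
                  .groupby(rows["case_id"]).any())
    ages = demo.set_index("case_id")["age_years"].dropna()
    shared = case_event.index.intersection(ages.index)
    event_ages = ages[shared][case_event[shared]]
    non_ages = ages[shared][~case_event[shared]]
    if len(event_ages) == 0 or len(non_ages) == 0:
        raise ValueError("both event and non-event groups need valid ages")
    stat = ranksums(event_ages, non_ages)
    return AgeComparison(float(event_ages.median()),
                         float(non_ages.median()),
                         float(stat.pvalue))


def class_summary(results: pd.DataFrame,
                  class_map: Mapping[str, str]) -> pd.DataFrame:
    """Aggregate the screen by drug class.

    For each class: the number of flagged members, the member count, the
    flagged percentage (one decimal), and a pooled ROR/CI/p from the
    class-pooled 2x2 (member cells summed; comparator = all non-member
    reports).  Classes with no screened member are omitted with a warning.
    """
    if results.empty:
        raise ValueError("empty screen results")
    classes = results["drug_name"].map(
        lambda n: class_map.get(n, "unclassified"))
    # margins of the full table are recoverable from any single drug's row
    first = results.iloc[0]
    total = int(first[["a", "b", "c", "d"]].sum())
    total_events = int(first["a"] + first["c"])

    known = set(class_map.values())
    missing = sorted(known - set(classes))
    if missing:
        warnings.warn(f"classes with no screened member omitted: {missing}",
                      stacklevel=2)

    records = []
    for label, grp in results.groupby(classes, sort=True):
        n_total = len(grp)
        n_flagged = int(grp["flagged"].sum())
        a = int(grp["a"].sum())
        b = int(grp["b"].sum())
        c = total_events - a
        d = (total - total_events) - b
        raw = ContingencyTable(a, b, c, d)
        corr = haldane(raw)
        lo, hi = ror_ci(corr)
        records.append({
            "class": label, "n_flagged": n_flagged, "n_total": n_total,
            "pct_flagged": round(100.0 * n_flagged / n_total, 1),
            "ror": ror(corr), "ci_low": lo, "ci_high": hi,
            "p": fisher_p(raw),
        })
    return pd.DataFrame.from_records(records)
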