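"""Ancestry disparity in germline false positives, with exact Fisher test.

Small population databases under-represent non-European germline
variation, so database filtering leaves more germline false positives in
tumor-only results for non-European patients. The comparison here is
variant-level: a 2x2 table with rows (non-European, European) and
columns (retained germline false positive, retained true somatic),
pooled over patients, tested with a two-sided Fisher's exact test. The
variant-level construction is the documented inference behind the odds
ratios; a per-patient burden table is also provided for transparency.

The two-sided p-value follows the classical probability-mass rule: the
sum of hypergeometric probabilities of all tables with the same margins
whose probability does not exceed that of the observed table. For small
tables it is computed by exact integer enumeration (binomial
coefficients compared as integers), so there is no floating-point tie
ambiguity; for large tables the same sum is evaluated in log space with
a tie tolerance, since exact big-integer binomials become impractically
slow there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    Ancestry,
    GenePanel,
    GermlineDatabase,
    PatientProfile,
    SomaticCatalog,
)
from .germline_filtering import FilterResult, FilterStrategy, apply_filter
from .panel_downsampling import downsample_to_panel, restrict_profile
from .synthetic_cohort import make_tumor_only_calls


_EXACT_ENUMERATION_LIMIT = 2000  # table total above which log-space is used


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = ancestry group and columns = (FP, not FP).

    ``a``/``b`` are the non-European row, ``c``/``d`` the European row;
    the first column is the germline-false-positive column.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def margins(self) -> tuple[int, int, int, int]:
        """(row1, row2, col1, col2) sums."""
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


def sample_odds_ratio(table: ContingencyTable2x2) -> float:
    """(a*d)/(b*c); zero-cell convention: inf / 0.0 / nan, no correction."""
    num = table.a * table.d
    den = table.b * table.c
    if den == 0:
        if num == 0:
            return math.nan
        return math.inf
    return num / den


def haldane_odds_ratio(table: ContingencyTable2x2) -> float:
    """Haldane-Anscombe corrected odds ratio (0.5 added to every cell).

    Emitted as a labeled secondary value alongside the uncorrected
    sample odds ratio; never substituted for it.
    """
    return ((table.a + 0.5) * (table.d + 0.5)) / ((table.b + 0.5) * (table.c + 0.5))


def fisher_exact_two_sided(table: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher's exact p (probability-mass rule) and sample OR.

    A zero row or column margin leaves the test undefined and raises
    ``ValueError``. The p-value is invariant under simultaneous row and
    column swaps; row swap alone gives an identical p and reciprocal OR.
    """
    r1, r2, c1, c2 = table.margins()
    if min(r1, r2, c1, c2) == 0:
        raise ValueError(
            f"table {table} has a zero margin; Fisher's test is undefined"
        )
    k_min = max(0, c1 - r2)
    k_max = min(r1, c1)
    if table.total <= _EXACT_ENUMERATION_LIMIT:
        # Hypergeometric weights over all tables with these margins, as
        # exact integers: P(k) proportional to C(r1, k) * C(r2, c1 - k).
        weights = [
            math.comb(r1, k) * math.comb(r2, c1 - k)
            for k in range(k_min, k_max + 1)
        ]
        w_obs = weights[table.a - k_min]
        p_num = sum(w for w in weights if w <= w_obs)
        p = p_num / math.comb(table.total, c1)
    else:
        # Same probability-mass rule in log space (big-integer binomials
        # are impractical here); ties tolerated to 1 part in 1e12.
        k = np.arange(k_min, k_max + 1)
        logpmf = stats.hypergeom.logpmf(k, table.total, c1, r1)
        log_obs = logpmf[table.a - k_min]
        p = float(np.exp(logpmf[logpmf <= log_obs + 1e-12]).sum())
    return min(p, 1.0), sample_odds_ratio(table)


def fp_burden_by_patient(
    cohort: Sequence[PatientProfile],
    results: Mapping[str, FilterResult],
    burden_threshold: int = 5,
) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Per-patient FP counts and per-ancestry burden summaries.

    ``results`` maps patient_id to a truth-scored :class:`FilterResult`.
    The summary reports, per ancestry group, the median FP count and the
    fraction of patients with more than ``burden_threshold`` false
    positives (strictly more; default 5).
    """
    rows = []
    for patient in cohort:
        res = results[patient.patient_id]
        if res.fp is None:
            raise ValueError(
                f"FilterResult for {patient.patient_id} lacks truth-derived fp"
            )
        rows.append(
            {
                "patient_id": patient.patient_id,
                "ancestry": patient.ancestry.value,
                "n_false_positives": res.fp,
            }
        )
    df = pd.DataFrame(rows, columns=["patient_id", "ancestry", "n_false_positives"])
    summary: dict[str, dict[str, float]] = {}
    for ancestry, grp in df.groupby("ancestry"):
        n = len(grp)
        n_over = int((grp["n_false_positives"] > burden_threshold).sum())
        summary[ancestry] = {
            "n_patients": n,
            "median_fp": float(grp["n_false_positives"].median()),
            "n_over_threshold": n_over,
            "frac_over_threshold": n_over / n,
        }
    return df, summary


def compare_ancestry(
    cohort: Sequence[PatientProfile],
    strategy: FilterStrategy,
    databases: Mapping[str, GermlineDatabase],
    catalog: SomaticCatalog,
    panel: Optional[GenePanel] = None,
) -> tuple[ContingencyTable2x2, float, float]:
    """Variant-level ancestry 2x2 and its Fisher test for one strategy.

    For each patient, tumor-only calls (optionally downsampled to a
    panel) are filtered and the retained calls classified against truth;
    germline false positives and retained true somatic calls are pooled
    by ancestry into the table. Returns ``(table, p_value, odds_ratio)``.
    """
    a = b = c = d = 0
    for patient in cohort:
        calls = make_tumor_only_calls(patient)
        truth = patient
        if panel is not None:
            calls = downsample_to_panel(calls, panel)
            truth = restrict_profile(patient, panel)
        res = apply_filter(calls, strategy, databases, catalog, truth=truth)
        if patient.ancestry is Ancestry.NON_EUROPEAN:
            a += res.fp
            b += res.tp
        else:
            c += res.fp
            d += res.tp
    table = ContingencyTable2x2(a=a, b=b, c=c, d=d)
    p, odds = fisher_exact_two_sided(table)
    return table, p, odds
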