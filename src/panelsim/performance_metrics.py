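"""Sensitivity / PPV computation and the filter-strategy sweep.

Definitions (truth = matched-analysis somatic calls):

* sensitivity = TP / (TP + FN): fraction of true somatic mutations the
  tumor-only pipeline retains;
* PPV = TP / retained: fraction of retained mutations that are truly
  somatic;
* fp_rate = FP / retained, so PPV + fp_rate = 1 when truth labels are
  complete.

Undefined ratios (zero denominator) are reported as ``None``, never 0.
The sweep pools counts over all patients (it does not average
per-patient ratios) and identifies the optimal strategy by maximizing
sensitivity x PPV, ties broken toward higher sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Optional, Sequence

from .core_io import (
    GenePanel,
    GermlineDatabase,
    PatientProfile,
    SomaticCatalog,
)
from .germline_filtering import FilterResult, FilterStrategy, apply_filter
from .panel_downsampling import downsample_to_panel, restrict_profile
from .synthetic_cohort import make_tumor_only_calls


@dataclass(frozen=True)
class StrategyPerformance:
    """Pooled performance of one strategy (counts plus derived ratios)."""

    strategy: FilterStrategy
    tp: int
    fp: int
    fn: int
    n_retained: int
    n_truth_somatic: int
    sensitivity: Optional[float]
    ppv: Optional[float]
    fp_rate: Optional[float]


def _ratios(
    tp: int, fp: int, fn: int, n_retained: int
) -> tuple[Optional[float], Optional[float], Optional[float]]:
    n_truth = tp + fn
    sens = tp / n_truth if n_truth > 0 else None
    ppv = tp / n_retained if n_retained > 0 else None
    fp_rate = fp / n_retained if n_retained > 0 else None
    return sens, ppv, fp_rate


def compute_performance(result: FilterResult) -> StrategyPerformance:
    """Ratios for a single truth-scored :class:`FilterResult`."""
    if result.tp is None or result.fp is None or result.fn is None:
        raise ValueError("FilterResult lacks truth-derived counts")
    tp, fp, fn = result.tp, result.fp, result.fn
    n_retained = len(result.retained)
    sens, ppv, fp_rate = _ratios(tp, fp, fn, n_retained)
    return StrategyPerformance(
        strategy=result.strategy,
        tp=tp,
        fp=fp,
        fn=fn,
        n_retained=n_retained,
        n_truth_somatic=tp + fn,
        sensitivity=sens,
        ppv=ppv,
        fp_rate=fp_rate,
    )


def sweep_strategies(
    cohort: Sequence[PatientProfile],
    databases: Mapping[str, GermlineDatabase],
    catalog: SomaticCatalog,
    strategies: Sequence[FilterStrategy],
    panel: GenePanel,
) -> tuple[list[StrategyPerformance], StrategyPerformance]:
    """Pooled performance per strategy at the given panel scale.

    For each patient the tumor-only calls are downsampled to the panel,
    filtered, and scored against the panel-restricted truth; counts are
    summed over patients. Returns ``(performances, best)`` where *best*
    maximizes sensitivity x PPV (ties toward higher sensitivity;
    strategies with undefined ratios never win).
    """
    if not strategies:
        raise ValueError("strategies must be nonempty")
    prepared = []
    for patient in cohort:
        truth = restrict_profile(patient, panel)
        calls = downsample_to_panel(make_tumor_only_calls(patient), panel)
        prepared.append((calls, truth))

    performances: list[StrategyPerformance] = []
    for strategy in strategies:
        tp = fp = fn = n_retained = 0
        for calls, truth in prepared:
            res = apply_filter(calls, strategy, databases, catalog, truth=truth)
            tp += res.tp
            fp += res.fp
            fn += res.fn
            n_retained += len(res.retained)
        sens, ppv, fp_rate = _ratios(tp, fp, fn, n_retained)
        performances.append(
            StrategyPerformance(
                strategy=strategy,
                tp=tp,
                fp=fp,
                fn=fn,
                n_retained=n_retained,
                n_truth_somatic=tp + fn,
                sensitivity=sens,
                ppv=ppv,
                fp_rate=fp_rate,
            )
        )

    scored = [
        p
        for p in performances
        if p.sensitivity is not None and p.ppv is not None
    ]
    if not scored:
        raise ValueError("no strategy produced defined sensitivity and PPV")
    best = max(scored, key=lambda p: (p.sensitivity * p.ppv, p.sensitivity))
    return performances, best


def proportion(
    numerator: int, denominator: int, decimals: int = 0
) -> tuple[float, str]:
    """Exact fraction plus its printed percentage form.

    Rounding is half-away-from-zero at the requested number of decimal
    places (integer percent by default). Both forms are returned so no
    information is lost, e.g. ``proportion(50, 54) == (0.9259..., "93 %")``.
    """
    if denominator <= 0:
        raise ValueError(f"denominator must be > 0, got {denominator}")
    if not 0 <= numerator <= denominator:
        raise ValueError(
            f"numerator must be in [0, denominator], got {numerator}/{denominator}"
        )
    fraction = numerator / denominator
    quantum = Decimal(1).scaleb(-decimals)
    pct = (Decimal(100 * numerator) / Decimal(denominator)).quantize(
        quantum, rounding=ROUND_HALF_UP
    )
    return fraction, f"{pct} %"
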