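"""Mutational load, neoantigen load, and panel recovery statistics.

Mutational load is mutation count per megabase of sequenced coding
territory; neoantigen load counts predicted MHC-I binders (affinity
strictly below 500 nM). Panel recovery asks what fraction of exome-
detected binders arise from mutations still visible in downsampled
panel data — recovery is at the source-mutation level (a binder is
recovered iff its source variant key appears among the panel calls);
identical peptides from different mutations are not deduplicated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from scipy import stats

from .core_io import VariantCall, VariantKey

BINDER_AFFINITY_NM = 500.0  # strict < threshold


@dataclass(frozen=True, slots=True)
class NeoantigenCandidate:
    """A candidate tumor neoantigen peptide with predicted binding affinity."""

    patient_id: str
    source: VariantKey
    peptide: str
    affinity_nm: float

    def __post_init__(self) -> None:
        if len(self.peptide) not in (9, 10):
            raise ValueError(
                f"peptide length must be 9 or 10, got {len(self.peptide)}"
            )
        if self.affinity_nm <= 0:
            raise ValueError(f"affinity_nm must be > 0, got {self.affinity_nm}")

    @property
    def is_binder(self) -> bool:
        return self.affinity_nm < BINDER_AFFINITY_NM


@dataclass(frozen=True)
class LoadComparison:
    """Per-patient (panel load, WES load) pairs and their Pearson fit."""

    pairs: tuple[tuple[float, float], ...]
    r: float
    r_squared: float
    p_value: float
    n_patients: int


def mutational_load(calls: Sequence[VariantCall], territory_mb: float) -> float:
    """Mutations per megabase: ``len(calls) / territory_mb``."""
    if territory_mb <= 0:
        raise ValueError(f"territory_mb must be > 0, got {territory_mb}")
    return len(calls) / territory_mb


def correlate_loads(pairs: Iterable[tuple[float, float]]) -> LoadComparison:
    """Pearson correlation of (panel load, WES load) pairs.

    Requires at least three pairs with nonzero variance in each
    coordinate. ``r_squared`` is the square of the product-moment r; the
    signed r and the two-sided p (t transform, n-2 df) are reported
    alongside.
    """
    pts = tuple((float(a), float(b)) for a, b in pairs)
    if len(pts) < 3:
        raise ValueError(f"need >= 3 pairs, got {len(pts)}")
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    if len(set(xs)) == 1 or len(set(ys)) == 1:
        raise ValueError("zero variance in one coordinate; correlation undefined")
    res = stats.pearsonr(xs, ys)
    r = float(res.statistic)
    return LoadComparison(
        pairs=pts,
        r=r,
        r_squared=r * r,
        p_value=float(res.pvalue),
        n_patients=len(pts),
    )


def neoantigen_load(candidates: Iterable[NeoantigenCandidate]) -> int:
    """Number of candidates with predicted affinity < 500 nM."""
    return sum(1 for c in candidates if c.is_binder)


def neoantigen_recovery(
    exome_binders: Sequence[NeoantigenCandidate],
    panel_calls: Sequence[VariantCall],
) -> tuple[int, int, Optional[float]]:
    """Fraction of exome binders whose source mutation survives in panel data.

    Returns ``(n_recovered, n_total, fraction)``; the fraction is ``None``
    (absent, not zero) when there are no exome binders.
    """
    panel_keys = {c.key for c in panel_calls}
    n_total = len(exome_binders)
    n_recovered = sum(1 for b in exome_binders if b.source in panel_keys)
    fraction = n_recovered / n_total if n_total > 0 else None
    return n_recovered, n_total, fraction
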