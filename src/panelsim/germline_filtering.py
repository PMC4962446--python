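"""The tumor-only germline-filtering cascade with COSMIC-style rescue.

Pipeline order, per variant call:

1. drop calls below the allelic-fraction floor (default 5 %);
2. a surviving call is a *database hit* if its key is a member of ANY
   database named by the strategy (union-of-membership semantics);
3. a database hit is *rescued* (kept) when rescue is enabled
   (``rescue_threshold > 0``) and the somatic catalog records the key at
   least ``rescue_threshold`` times; all other hits are removed;
4. retained = non-hit survivors + rescued hits.

When a truth profile is supplied, retained calls are scored by variant
key against the patient's true somatic and germline sets (TP / FP), and
FN counts the true somatic mutations that were not retained.

Filtering is per-variant and stateless across patients; there is no
panel-of-normals concept. Raising the rescue threshold can only shrink
the rescued set; adding a database can only shrink the retained set
(rescue is the sole recovery path).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .core_io import (
    GermlineDatabase,
    PatientProfile,
    SomaticCatalog,
    VariantCall,
)

RESCUE_THRESHOLDS = (0, 1, 3, 5, 10)
DEFAULT_MIN_ALLELIC_FRACTION = 0.05


@dataclass(frozen=True)
class FilterStrategy:
    """A named filtering recipe: databases + rescue stringency + AF floor.

    ``rescue_threshold`` takes the graded stringencies 1/3/5/10 (minimum
    catalog recurrence for rescue) or 0 to disable rescue entirely.
    """

    name: str
    databases: tuple[str, ...] = ()
    rescue_threshold: int = 0
    min_allelic_fraction: float = DEFAULT_MIN_ALLELIC_FRACTION

    def __post_init__(self) -> None:
        if self.rescue_threshold not in RESCUE_THRESHOLDS:
            raise ValueError(
                f"rescue_threshold must be one of {RESCUE_THRESHOLDS}, "
                f"got {self.rescue_threshold}"
            )
        if not 0.0 <= self.min_allelic_fraction < 1.0:
            raise ValueError(
                f"min_allelic_fraction must be in [0, 1), "
                f"got {self.min_allelic_fraction}"
            )
        # allow list input for convenience
        object.__setattr__(self, "databases", tuple(self.databases))


@dataclass
class FilterResult:
    """Outcome of one strategy on one call set, with truth-based counts.

    ``tp``/``fp``/``fn`` are populated only when a truth profile was
    provided to :func:`apply_filter` (otherwise ``None``).
    """

    strategy: FilterStrategy
    retained: list[VariantCall] = field(default_factory=list)
    removed_by_af: list[VariantCall] = field(default_factory=list)
    removed_by_database: list[VariantCall] = field(default_factory=list)
    rescued: list[VariantCall] = field(default_factory=list)
    tp: Optional[int] = None
    fp: Optional[int] = None
    fn: Optional[int] = None


def apply_filter(
    calls: Sequence[VariantCall],
    strategy: FilterStrategy,
    databases: Mapping[str, GermlineDatabase],
    catalog: SomaticCatalog,
    truth: Optional[PatientProfile] = None,
) -> FilterResult:
    """Run the four-step cascade on a call set.

    ``databases`` must contain every name the strategy references; the
    catalog supplies recurrence counts for rescue. An empty call list is
    valid and yields an all-empty result.
    """
    missing = [n for n in strategy.databases if n not in databases]
    if missing:
        raise KeyError(
            f"strategy {strategy.name!r} references unknown database(s) {missing}; "
            f"available: {sorted(databases)}"
        )
    member_sets = [databases[n].members for n in strategy.databases]

    result = FilterResult(strategy=strategy)
    for call in calls:
        if call.allelic_fraction < strategy.min_allelic_fraction:
            result.removed_by_af.append(call)
            continue
        hit = any(call.key in members for members in member_sets)
        if not hit:
            result.retained.append(call)
            continue
        if (
            strategy.rescue_threshold > 0
            and catalog.count(call.key) >= strategy.rescue_threshold
        ):
            result.rescued.append(call)
            result.retained.append(call)
        else:
            result.removed_by_database.append(call)

    if truth is not None:
        som = truth.somatic_keys
        germ = truth.germline_keys
        retained_keys = {c.key for c in result.retained}
        result.tp = sum(1 for c in result.retained if c.key in som)
        result.fp = sum(1 for c in result.retained if c.key in germ)
        result.fn = sum(1 for k in som if k not in retained_keys)
    return result


def classify_false_positives(
    result: FilterResult, truth: PatientProfile
) -> list[VariantCall]:
    """Retained calls whose key is in the patient's germline truth set.

    These are the germline false positives a tumor-only report would
    present as somatic; equals ``result.fp`` in count when the same truth
    was used for scoring.
    """
    germ = truth.germline_keys
    return [c for c in result.retained if c.key in germ]


def default_strategy_grid(
    min_allelic_fraction: float = DEFAULT_MIN_ALLELIC_FRACTION,
) -> list[FilterStrategy]:
    """The shipped sweep grid: nested database combinations x rescue thresholds.

    Database combinations follow the study's progression — allelic
    fraction only, dbSNP, dbSNP+1000 Genomes, and those along with ExAC
    (the strategies are cumulative, mirroring how filters are layered in
    practice). Each is crossed with rescue thresholds 0/1/3/5/10.
    """
    combos = {
        "af_only": (),
        "dbsnp": ("dbsnp",),
        "dbsnp_1kg": ("dbsnp", "thousand_genomes"),
        "dbsnp_1kg_exac": ("dbsnp", "thousand_genomes", "exac"),
    }
    grid = []
    for combo_name, dbs in combos.items():
        for t in RESCUE_THRESHOLDS:
            if not dbs and t > 0:
                continue  # rescue is moot without database filtering
            name = combo_name if t == 0 else f"{combo_name}_cosmic{t}"
            grid.append(
                FilterStrategy(
                    name=name,
                    databases=dbs,
                    rescue_threshold=t,
                    min_allelic_fraction=min_allelic_fraction,
                )
            )
    return grid


DEFAULT_STRATEGY = FilterStrategy(
    name="dbsnp_1kg_exac_cosmic10",
    databases=("dbsnp", "thousand_genomes", "exac"),
    rescue_threshold=10,
)
"""The study's optimal recipe: all databases (including the large WES
database) with hotspot rescue at the highest stringency (>= 10 events)."""
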