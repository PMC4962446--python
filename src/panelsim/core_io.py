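"""Domain types and tabular I/O for tumor profiling analyses.

The package works on MAF-style aggregate mutation tables: one row per
variant call, tab-separated, 1-based positions. Only single-nucleotide
variants are modeled; indel rows are rejected at parse time. Companion
formats are plain-text gene lists (one symbol per line), database
membership tables (one variant key per line) and somatic-catalog tables
(variant key plus recurrence count).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

_BASES = frozenset("ACGT")

VARIANT_TABLE_COLUMNS = [
    "patient_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "allelic_fraction",
    "origin",
    "cosmic_count",
]


class Origin(str, enum.Enum):
    """Truth label for a call: somatic, germline, or unknown (tumor-only)."""

    SOMATIC = "somatic"
    GERMLINE = "germline"
    UNKNOWN = "unknown"


class Ancestry(str, enum.Enum):
    """Self-reported ancestry group, binarized as in the source cohort."""

    EUROPEAN = "european"
    NON_EUROPEAN = "non_european"


class CancerType(str, enum.Enum):
    LUNG = "lung"
    COLON = "colon"


@dataclass(frozen=True, slots=True)
class VariantKey:
    """Genomic identity of a single-nucleotide variant.

    ``(chrom, pos, ref, alt)`` uniquely identifies a variant within one
    genome build; equality on this key is the only join used anywhere in
    the package.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) is not a variant")
        for label, allele in (("ref", self.ref), ("alt", self.alt)):
            if len(allele) != 1 or allele not in _BASES:
                raise ValueError(
                    f"{label} allele {allele!r} is not a single upper-case "
                    "base in {A,C,G,T}; only SNVs are supported"
                )


@dataclass(frozen=True, slots=True)
class VariantCall:
    """One observed variant in one patient.

    ``origin`` is the truth label; tumor-only observed data carry
    ``Origin.UNKNOWN``. ``cosmic_count`` is the somatic-catalog recurrence
    count annotated on the call (the filter consults the catalog itself).
    ``review_tier`` is the molecular-pathologist tier label (1-4); it is
    carried through as data and never computed.
    """

    key: VariantKey
    patient_id: str
    gene: str
    allelic_fraction: float
    origin: Origin = Origin.UNKNOWN
    cosmic_count: int = 0
    review_tier: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.allelic_fraction <= 1.0:
            raise ValueError(
                f"allelic_fraction must be in [0, 1], got {self.allelic_fraction}"
            )
        if self.cosmic_count < 0:
            raise ValueError(f"cosmic_count must be >= 0, got {self.cosmic_count}")
        if self.review_tier is not None and self.review_tier not in (1, 2, 3, 4):
            raise ValueError(f"review_tier must be in 1..4, got {self.review_tier}")

    def with_origin(self, origin: Origin) -> "VariantCall":
        return replace(self, origin=origin)


@dataclass(slots=True)
class PatientProfile:
    """A patient with ancestry label, cancer type, and truth variant sets.

    ``true_somatic`` holds the matched-analysis somatic calls (the truth
    set) and ``germline_variants`` the patient's germline SNPs; the two
    are disjoint by :class:`VariantKey`.
    """

    patient_id: str
    ancestry: Ancestry
    cancer_type: CancerType
    true_somatic: list[VariantCall] = field(default_factory=list)
    germline_variants: list[VariantCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        som = {c.key for c in self.true_somatic}
        germ = {c.key for c in self.germline_variants}
        overlap = som & germ
        if overlap:
            raise ValueError(
                f"patient {self.patient_id}: true_somatic and germline_variants "
                f"share {len(overlap)} keys (e.g. {next(iter(overlap))})"
            )

    @property
    def somatic_keys(self) -> frozenset[VariantKey]:
        return frozenset(c.key for c in self.true_somatic)

    @property
    def germline_keys(self) -> frozenset[VariantKey]:
        return frozenset(c.key for c in self.germline_variants)


@dataclass(frozen=True)
class GenePanel:
    """A named gene set with its sequenced coding territory in megabases.

    The special name ``"wes"`` denotes whole-exome territory; downsampling
    to it is the identity.
    """

    name: str
    genes: frozenset[str]
    territory_mb: float

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"panel {self.name!r} has no genes")
        if self.territory_mb <= 0:
            raise ValueError(
                f"panel {self.name!r} territory_mb must be > 0, got {self.territory_mb}"
            )


@dataclass(frozen=True)
class GermlineDatabase:
    """A germline population database as an exact variant-key member set."""

    name: str
    members: frozenset[VariantKey]

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.members


@dataclass(frozen=True)
class SomaticCatalog:
    """COSMIC-like somatic recurrence catalog; absent keys have count 0."""

    counts: Mapping[VariantKey, int]

    def count(self, key: VariantKey) -> int:
        return self.counts.get(key, 0)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _parse_row(row: pd.Series, row_number: int) -> VariantCall:
    try:
        pos = int(row["pos"])
        if float(row["pos"]) != pos:
            raise ValueError
    except (TypeError, ValueError):
        raise ValueError(
            f"row {row_number}: pos {row['pos']!r} is not an integer"
        ) from None
    try:
        af = float(row["allelic_fraction"])
    except (TypeError, ValueError):
        raise ValueError(
            f"row {row_number}: allelic_fraction {row['allelic_fraction']!r} "
            "is not a number"
        ) from None
    origin_raw = row.get("origin")
    if origin_raw is None or (isinstance(origin_raw, float) and pd.isna(origin_raw)):
        origin = Origin.UNKNOWN
    else:
        try:
            origin = Origin(str(origin_raw))
        except ValueError:
            raise ValueError(
                f"row {row_number}: origin {origin_raw!r} is not one of "
                "somatic/germline/unknown"
            ) from None
    cosmic_raw = row.get("cosmic_count")
    if cosmic_raw is None or (isinstance(cosmic_raw, float) and pd.isna(cosmic_raw)):
        cosmic = 0
    else:
        cosmic = int(cosmic_raw)
    try:
        key = VariantKey(
            chrom=str(row["chrom"]), pos=pos, ref=str(row["ref"]), alt=str(row["alt"])
        )
        return VariantCall(
            key=key,
            patient_id=str(row["patient_id"]),
            gene=str(row["gene"]),
            allelic_fraction=af,
            origin=origin,
            cosmic_count=cosmic,
        )
    except ValueError as exc:
        raise ValueError(f"row {row_number}: {exc}") from None


def read_variant_table(path: str | Path) -> list[VariantCall]:
    """Read a MAF-like TSV into a list of :class:`VariantCall`.

    Required columns: patient_id, chrom, pos, ref, alt, gene,
    allelic_fraction. Optional: origin (default unknown), cosmic_count
    (default 0). Malformed rows raise ``ValueError`` naming the 1-based
    data row number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""])
    required = {"patient_id", "chrom", "pos", "ref", "alt", "gene", "allelic_fraction"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    calls = []
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        calls.append(_parse_row(row, i))
    return calls


def write_variant_table(calls: Iterable[VariantCall], path: str | Path) -> None:
    """Write calls as a TSV re-readable by :func:`read_variant_table`."""
    rows = [
        {
            "patient_id": c.patient_id,
            "chrom": c.key.chrom,
            "pos": c.key.pos,
            "ref": c.key.ref,
            "alt": c.key.alt,
            "gene": c.gene,
            "allelic_fraction": repr(c.allelic_fraction),
            "origin": c.origin.value,
            "cosmic_count": c.cosmic_count,
        }
        for c in calls
    ]
    df = pd.DataFrame(rows, columns=VARIANT_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> set[str]:
    """Read a one-symbol-per-line gene list; '#' starts a comment.

    Symbols are whitespace-stripped, case-preserved and deduplicated. An
    empty result is an error: a panel with zero genes is invalid.
    """
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genes.add(line)
    if not genes:
        raise ValueError(f"{path}: gene list is empty")
    return genes


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def _read_keys(path: str | Path) -> list[tuple[VariantKey, pd.Series]]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    required = {"chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    out = []
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            key = VariantKey(
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                ref=str(row["ref"]),
                alt=str(row["alt"]),
            )
        except ValueError as exc:
            raise ValueError(f"{path} row {i}: {exc}") from None
        out.append((key, row))
    return out


def read_database(path: str | Path, name: str) -> GermlineDatabase:
    """Read a database membership TSV (chrom, pos, ref, alt) into a member set."""
    keys = frozenset(key for key, _ in _read_keys(path))
    return GermlineDatabase(name=name, members=keys)


def write_database(db: GermlineDatabase, path: str | Path) -> None:
    rows = sorted(
        ({"chrom": k.chrom, "pos": k.pos, "ref": k.ref, "alt": k.alt} for k in db.members),
        key=lambda r: (r["chrom"], r["pos"], r["ref"], r["alt"]),
    )
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"]).to_csv(
        path, sep="\t", index=False
    )


def read_catalog(path: str | Path) -> SomaticCatalog:
    """Read a COSMIC-like recurrence TSV (chrom, pos, ref, alt, count)."""
    counts: dict[VariantKey, int] = {}
    for key, row in _read_keys(path):
        if "count" not in row:
            raise ValueError(f"{path}: missing required column 'count'")
        n = int(row["count"])
        if n < 0:
            raise ValueError(f"{path}: negative count for {key}")
        counts[key] = n
    return SomaticCatalog(counts=counts)


def write_catalog(catalog: SomaticCatalog, path: str | Path) -> None:
    rows = sorted(
        (
            {"chrom": k.chrom, "pos": k.pos, "ref": k.ref, "alt": k.alt, "count": n}
            for k, n in catalog.counts.items()
        ),
        key=lambda r: (r["chrom"], r["pos"], r["ref"], r["alt"]),
    )
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "count"]).to_csv(
        path, sep="\t", index=False
    )


def calls_to_frame(calls: Sequence[VariantCall]) -> pd.DataFrame:
    """Convenience: a pandas view of calls (column order as on disk)."""
    return pd.DataFrame(
        [
            {
                "patient_id": c.patient_id,
                "chrom": c.key.chrom,
                "pos": c.key.pos,
                "ref": c.key.ref,
                "alt": c.key.alt,
                "gene": c.gene,
                "allelic_fraction": c.allelic_fraction,
                "origin": c.origin.value,
                "cosmic_count": c.cosmic_count,
            }
            for c in calls
        ],
        columns=VARIANT_TABLE_COLUMNS,
    )
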