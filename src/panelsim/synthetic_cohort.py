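"""Synthetic cohorts with the statistical structure of tumor-only profiling.

The generator emulates a clinical WES cohort of lung and colon
adenocarcinoma patients in which matched tumor-normal analysis defines
the true somatic mutations, while unmatched (tumor-only) calling admits
hundreds of residual germline variants per exome. Its pieces:

* Per-patient somatic burden is hierarchical Poisson-lognormal:
  ``N_i ~ Poisson(Lognormal(mu, sigma))``, heavy-tailed across patients,
  with a cancer-type shift on the log scale (lung above colon). With
  ``sigma -> 0`` the burden degenerates to pure Poisson, under which the
  pooled ancestry contingency cells are independent Poissons and Fisher's
  exact test is exactly calibrated (used by the null configuration).
* Germline variants are drawn from three disjoint pools - common-shared,
  ancestry-specific and private-rare. European-ancestry patients draw
  from common + private pools; non-European patients also draw from the
  ancestry-specific pool. Each population database is an independent
  Bernoulli thinning of each pool, with small databases (dbSNP, 1000
  Genomes) covering the ancestry-specific and private pools far less
  well than the large database (ExAC). This is the mechanism behind the
  ancestry disparity in tumor-only false positives.
* A fraction of somatic mutations are recurrent hotspots shared across
  patients, with heavy-tailed somatic-catalog recurrence counts; a small
  fraction of germline pool variants also appear in the catalog at low
  counts (annotation noise), which is what graded rescue stringency
  trades off against.
* Gene assignment is by panel-capture probability rather than real
  coordinates: somatic mutations land in large/medium/small panel genes
  with configured probabilities (cancer panels are enriched for mutated
  genes), germline variants land uniformly over the gene universe.
* Neoantigen candidates per somatic mutation are Poisson in number with
  lognormal binding affinities (nM); 9- and 10-mer peptides.

All randomness flows from the single config seed through one generator
in a fixed documented order (patients in index order; pools, databases
and catalog before patients), so identical configs give identical
cohorts. Neoantigen simulation uses a stream derived from (seed,
patient_id) so it is deterministic per patient and independent of call
order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .core_io import (
    Ancestry,
    CancerType,
    GenePanel,
    GermlineDatabase,
    Origin,
    PatientProfile,
    SomaticCatalog,
    VariantCall,
    VariantKey,
)
from .genomic_load import NeoantigenCandidate

GERMLINE_POOLS = ("common_shared", "ancestry_specific", "private_rare")
_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_BASES = "ACGT"


def _default_db_coverage() -> dict[str, dict[str, float]]:
    # Coverage of each germline pool (plus the somatic hotspot pool) by each
    # database. Calibrated analytically so that the expected variant-level
    # odds ratios (non-European vs European false-positive odds) are
    # ~2.5 / 1.8 / 1.2 for dbSNP / 1000 Genomes / ExAC under the default
    # pool weights, and so that the small databases cover ancestry-specific
    # and private-rare variation materially worse than ExAC.
    return {
        "dbsnp": {
            "common_shared": 0.965,
            "ancestry_specific": 0.15,
            "private_rare": 0.30,
            "hotspot": 0.50,
        },
        "thousand_genomes": {
            "common_shared": 0.93,
            "ancestry_specific": 0.35,
            "private_rare": 0.25,
            "hotspot": 0.30,
        },
        "exac": {
            "common_shared": 0.96,
            "ancestry_specific": 0.86,
            "private_rare": 0.40,
            "hotspot": 0.45,
        },
    }


def _default_pool_weights() -> dict[str, dict[str, float]]:
    # Share of a patient's germline contaminants drawn from each pool.
    return {
        "european": {
            "common_shared": 0.85,
            "ancestry_specific": 0.0,
            "private_rare": 0.15,
        },
        "non_european": {
            "common_shared": 0.60,
            "ancestry_specific": 0.25,
            "private_rare": 0.15,
        },
    }


def _default_panel_overlap() -> dict[str, float]:
    # P(a somatic mutation's gene is on the panel); calibrated from the
    # matched per-patient medians 4/2/1 over a median exome burden of 75.
    return {"large": 0.053, "medium": 0.027, "small": 0.013}


def _default_panel_sizes() -> dict[str, int]:
    return {"large": 300, "medium": 48, "small": 15}


def _default_territories() -> dict[str, float]:
    # Megabases of coding territory; panel defaults assume ~1.5 kb of
    # coding sequence per gene, WES is the conventional 30 Mb.
    return {"wes": 30.0, "large": 0.45, "medium": 0.072, "small": 0.0225}


@dataclass
class CohortSimConfig:
    """Parameters of the synthetic cohort generator.

    Defaults reproduce the study conditions of the modeled cohort: 157
    patients (82 lung / 75 colon), ~12 % non-European ancestry, a
    median exome somatic burden of 75 (lognormal rate, log-sd 0.66 from
    the printed IQR 55-134), and ~370 expected residual germline
    variants per unmatched exome (the 445 - 75 gap between unmatched
    and matched median mutation counts).
    """

    n_patients: int = 157
    frac_non_european: float = 19 / 157
    frac_lung: float = 82 / 157
    somatic_burden_log_mean: float = float(np.log(75.0))
    somatic_burden_log_sd: float = 0.66
    cancer_type_log_shift: float = 0.15  # lung +shift, colon -shift
    germline_contaminant_mean: float = 370.0
    n_common_shared: int = 30_000
    n_ancestry_specific: int = 8_000
    n_private_rare: int = 60_000
    germline_pool_weights: dict[str, dict[str, float]] = field(
        default_factory=_default_pool_weights
    )
    db_coverage: dict[str, dict[str, float]] = field(default_factory=_default_db_coverage)
    hotspot_fraction: float = 0.10
    n_hotspots: int = 400
    hotspot_count_median: float = 25.0
    cosmic_count_dispersion: float = 0.9  # log-sd of hotspot recurrence counts
    cosmic_germline_rate: float = 0.05  # germline pool variants present in catalog
    cosmic_germline_geom_p: float = 0.35  # geometric param of their low counts
    affinity_log_mean: float = float(np.log(2000.0))
    affinity_log_sd: float = 2.0
    binders_per_mutation_mean: float = 2.0  # candidate peptides per mutation
    panel_gene_overlap: dict[str, float] = field(default_factory=_default_panel_overlap)
    panel_sizes: dict[str, int] = field(default_factory=_default_panel_sizes)
    panel_territory_mb: dict[str, float] = field(default_factory=_default_territories)
    gene_universe_size: int = 18_000
    min_somatic_af: float = 0.05
    seed: int = 42

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError(f"n_patients must be > 0, got {self.n_patients}")
        for name in ("frac_non_european", "frac_lung", "hotspot_fraction",
                     "cosmic_germline_rate", "cosmic_germline_geom_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.germline_contaminant_mean < 0:
            raise ValueError("germline_contaminant_mean must be >= 0")
        for db, cov in self.db_coverage.items():
            for pool, p in cov.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"db_coverage[{db}][{pool}] must be in [0,1]")
        for anc, w in self.germline_pool_weights.items():
            if any(v < 0 for v in w.values()):
                raise ValueError(f"negative pool weight for {anc}")
            if sum(w.values()) <= 0:
                raise ValueError(f"pool weights for {anc} sum to zero")
        for panel, p in self.panel_gene_overlap.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"panel_gene_overlap[{panel}] must be in [0,1]")
        if sum(self.panel_gene_overlap.values()) > 1.0:
            raise ValueError("panel_gene_overlap probabilities sum above 1")
        if min(self.n_common_shared, self.n_ancestry_specific, self.n_private_rare) <= 0:
            raise ValueError("germline pool sizes must be > 0")
        if self.gene_universe_size <= sum(self.panel_sizes.values()):
            raise ValueError("gene_universe_size must exceed total panel genes")
        if not 0.0 <= self.min_somatic_af < 1.0:
            raise ValueError("min_somatic_af must be in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSimConfig":
        return cls(**d)


def null_config(
    n_patients: int = 40,
    germline_contaminant_mean: float = 40.0,
    somatic_rate: float = 25.0,
    db_level: float = 0.5,
    seed: int = 0,
) -> CohortSimConfig:
    """A scaled-down null configuration with ancestry-independent coverage.

    Every database covers all three germline pools at the same rate, so
    false-positive survival is independent of ancestry; the burden log-sd
    is set to ~0 (pure Poisson burden) and hotspots are disabled, making
    all four pooled contingency cells independent Poissons. Under this
    configuration the Fisher null hypothesis holds exactly, which is what
    a type-I-error calibration run requires.
    """
    cfg = CohortSimConfig(
        n_patients=n_patients,
        frac_non_european=0.5,
        somatic_burden_log_mean=float(np.log(somatic_rate)),
        somatic_burden_log_sd=1e-9,
        cancer_type_log_shift=0.0,
        germline_contaminant_mean=germline_contaminant_mean,
        n_common_shared=4000,
        n_ancestry_specific=1500,
        n_private_rare=6000,
        hotspot_fraction=0.0,
        cosmic_germline_rate=0.0,
        seed=seed,
    )
    cfg.db_coverage = {
        db: {pool: db_level for pool in (*GERMLINE_POOLS, "hotspot")}
        for db in ("dbsnp", "thousand_genomes", "exac")
    }
    return cfg


# ---------------------------------------------------------------------------
# Gene universe
# ---------------------------------------------------------------------------


def gene_name(config: CohortSimConfig, index: int) -> str:
    """Map a gene-universe index to a symbol; panel genes come first."""
    n_large = config.panel_sizes["large"]
    n_medium = config.panel_sizes["medium"]
    n_small = config.panel_sizes["small"]
    if index < n_large:
        return f"LP{index + 1:04d}"
    index -= n_large
    if index < n_medium:
        return f"MP{index + 1:04d}"
    index -= n_medium
    if index < n_small:
        return f"SP{index + 1:04d}"
    return f"G{index - n_small:05d}"


def default_panels(config: Optional[CohortSimConfig] = None) -> dict[str, GenePanel]:
    """Shipped placeholder panels (large/medium/small) plus WES.

    The placeholder gene lists have the correct sizes (300/48/15); real
    panel lists are drop-in replacements via :func:`core_io.read_gene_list`.
    The three placeholder sets are disjoint, not nested.
    """
    config = config or CohortSimConfig()
    terr = config.panel_territory_mb
    panels = {
        "large": GenePanel(
            "large",
            frozenset(f"LP{i + 1:04d}" for i in range(config.panel_sizes["large"])),
            terr["large"],
        ),
        "medium": GenePanel(
            "medium",
            frozenset(f"MP{i + 1:04d}" for i in range(config.panel_sizes["medium"])),
            terr["medium"],
        ),
        "small": GenePanel(
            "small",
            frozenset(f"SP{i + 1:04d}" for i in range(config.panel_sizes["small"])),
            terr["small"],
        ),
    }
    panels["wes"] = GenePanel(
        "wes",
        frozenset(gene_name(config, i) for i in range(config.gene_universe_size)),
        terr["wes"],
    )
    return panels


def _somatic_gene(config: CohortSimConfig, rng: np.random.Generator) -> str:
    u = rng.random()
    sizes = config.panel_sizes
    acc = 0.0
    for panel, prefix in (("small", "SP"), ("medium", "MP"), ("large", "LP")):
        acc += config.panel_gene_overlap[panel]
        if u < acc:
            return f"{prefix}{rng.integers(sizes[panel]) + 1:04d}"
    n_panel = sum(sizes.values())
    return f"G{rng.integers(config.gene_universe_size - n_panel):05d}"


def _germline_gene(config: CohortSimConfig, rng: np.random.Generator) -> str:
    return gene_name(config, int(rng.integers(config.gene_universe_size)))


# ---------------------------------------------------------------------------
# Variant key allocation
# ---------------------------------------------------------------------------


class _KeyAllocator:
    """Hands out globally unique SNV keys (sequential positions, random alleles)."""

    def __init__(self, rng: np.random.Generator):
        self._rng = rng
        self._next_pos = 1_000_000

    def new_key(self) -> VariantKey:
        pos = self._next_pos
        self._next_pos += 1
        chrom = f"chr{1 + pos % 22}"
        ref_i = int(self._rng.integers(4))
        alt_i = (ref_i + 1 + int(self._rng.integers(3))) % 4
        return VariantKey(chrom=chrom, pos=pos, ref=_BASES[ref_i], alt=_BASES[alt_i])

    def new_keys(self, n: int) -> list[VariantKey]:
        return [self.new_key() for _ in range(n)]


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


def simulate_cohort(
    config: CohortSimConfig,
) -> tuple[list[PatientProfile], dict[str, GermlineDatabase], SomaticCatalog]:
    """Generate a full cohort, its germline databases, and somatic catalog.

    Returns ``(patients, databases, catalog)``. Patients carry complete
    truth (somatic and germline variant sets); the tumor-only observed
    arm is derived with :func:`make_tumor_only_calls`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    alloc = _KeyAllocator(rng)

    # 1. Germline pools (disjoint by construction).
    pools = {
        "common_shared": alloc.new_keys(config.n_common_shared),
        "ancestry_specific": alloc.new_keys(config.n_ancestry_specific),
        "private_rare": alloc.new_keys(config.n_private_rare),
    }

    # 2. Hotspot pool: recurrent somatic variants with catalog counts and
    # panel-enriched gene assignment, shared across patients.
    hotspot_keys = alloc.new_keys(config.n_hotspots)
    hotspot_genes = [_somatic_gene(config, rng) for _ in range(config.n_hotspots)]
    hotspot_counts = np.maximum(
        1,
        np.round(
            rng.lognormal(
                np.log(config.hotspot_count_median),
                config.cosmic_count_dispersion,
                size=config.n_hotspots,
            )
        ).astype(int),
    )

    # 3. Somatic catalog: hotspots at high counts plus a thin layer of
    # germline pool variants at low counts (annotation noise).
    counts: dict[VariantKey, int] = dict(
        zip(hotspot_keys, (int(c) for c in hotspot_counts))
    )
    if config.cosmic_germline_rate > 0:
        for pool_keys in pools.values():
            mask = rng.random(len(pool_keys)) < config.cosmic_germline_rate
            low = rng.geometric(config.cosmic_germline_geom_p, size=int(mask.sum()))
            for key, c in zip(
                (k for k, m in zip(pool_keys, mask) if m), (int(v) for v in low)
            ):
                counts[key] = c
    catalog = SomaticCatalog(counts=counts)

    # 4. Databases: independent Bernoulli thinning of each pool.
    databases: dict[str, GermlineDatabase] = {}
    for db_name, coverage in config.db_coverage.items():
        members: set[VariantKey] = set()
        for pool_name, pool_keys in pools.items():
            p = coverage.get(pool_name, 0.0)
            if p > 0:
                mask = rng.random(len(pool_keys)) < p
                members.update(k for k, m in zip(pool_keys, mask) if m)
        p_hot = coverage.get("hotspot", 0.0)
        if p_hot > 0:
            mask = rng.random(len(hotspot_keys)) < p_hot
            members.update(k for k, m in zip(hotspot_keys, mask) if m)
        databases[db_name] = GermlineDatabase(name=db_name, members=frozenset(members))

    # 5. Patients, in index order. The first round(frac * n) patients are
    # non-European (group sizes exact, not binomial).
    n_non_eu = int(round(config.frac_non_european * config.n_patients))
    patients: list[PatientProfile] = []
    for i in range(config.n_patients):
        pid = f"P{i + 1:04d}"
        ancestry = Ancestry.NON_EUROPEAN if i < n_non_eu else Ancestry.EUROPEAN
        cancer = CancerType.LUNG if rng.random() < config.frac_lung else CancerType.COLON
        shift = (
            config.cancer_type_log_shift
            if cancer is CancerType.LUNG
            else -config.cancer_type_log_shift
        )

        # Somatic truth set: Poisson(lognormal rate), hotspot/novel mix.
        lam = float(
            rng.lognormal(config.somatic_burden_log_mean + shift,
                          config.somatic_burden_log_sd)
        )
        n_som = int(rng.poisson(lam))
        som_calls: list[VariantCall] = []
        seen: set[VariantKey] = set()
        for _ in range(n_som):
            if config.hotspot_fraction > 0 and rng.random() < config.hotspot_fraction:
                j = int(rng.integers(config.n_hotspots))
                key, gene = hotspot_keys[j], hotspot_genes[j]
                if key in seen:  # recurrent hotspot drawn twice for one patient
                    continue
                cosmic = int(hotspot_counts[j])
            else:
                key = alloc.new_key()
                gene = _somatic_gene(config, rng)
                cosmic = 0
            seen.add(key)
            af = config.min_somatic_af + (1.0 - config.min_somatic_af) * rng.random()
            som_calls.append(
                VariantCall(
                    key=key,
                    patient_id=pid,
                    gene=gene,
                    allelic_fraction=float(af),
                    origin=Origin.SOMATIC,
                    cosmic_count=cosmic,
                )
            )

        # Germline contaminants: Poisson total, multinomial over pools,
        # within-pool sampling without replacement.
        weights = config.germline_pool_weights[ancestry.value]
        w = np.array([weights.get(p, 0.0) for p in GERMLINE_POOLS], dtype=float)
        w = w / w.sum()
        n_germ = int(rng.poisson(config.germline_contaminant_mean))
        per_pool = rng.multinomial(n_germ, w)
        germ_calls: list[VariantCall] = []
        for pool_name, m in zip(GERMLINE_POOLS, per_pool):
            pool_keys = pools[pool_name]
            m = min(int(m), len(pool_keys))
            if m == 0:
                continue
            idx = rng.choice(len(pool_keys), size=m, replace=False)
            afs = np.clip(rng.normal(0.5, 0.1, size=m), 0.0, 1.0)
            for k_i, af in zip(idx, afs):
                key = pool_keys[int(k_i)]
                germ_calls.append(
                    VariantCall(
                        key=key,
                        patient_id=pid,
                        gene=_germline_gene(config, rng),
                        allelic_fraction=float(af),
                        origin=Origin.GERMLINE,
                        cosmic_count=catalog.count(key),
                    )
                )

        patients.append(
            PatientProfile(
                patient_id=pid,
                ancestry=ancestry,
                cancer_type=cancer,
                true_somatic=som_calls,
                germline_variants=germ_calls,
            )
        )

    return patients, databases, catalog


def make_tumor_only_calls(patient: PatientProfile) -> list[VariantCall]:
    """The unmatched observed arm: somatic + germline calls, origin stripped.

    Truth stays on the :class:`PatientProfile` for scoring; the returned
    calls all carry ``Origin.UNKNOWN``, as a tumor-only pipeline would
    see them.
    """
    return [
        c.with_origin(Origin.UNKNOWN)
        for c in (*patient.true_somatic, *patient.germline_variants)
    ]


def simulate_neoantigens(
    patient: PatientProfile, config: CohortSimConfig
) -> list[NeoantigenCandidate]:
    """Candidate neoantigen peptides for a patient's somatic mutations.

    Each somatic mutation yields a Poisson number of 9- or 10-mer
    candidate peptides with lognormal predicted binding affinities (nM);
    candidates reference their source variant key. Deterministic given
    (config.seed, patient_id).
    """
    rng = np.random.default_rng(
        (config.seed, zlib.crc32(patient.patient_id.encode()), 7)
    )
    out: list[NeoantigenCandidate] = []
    for call in patient.true_somatic:
        k = int(rng.poisson(config.binders_per_mutation_mean))
        for _ in range(k):
            length = 9 + int(rng.integers(2))
            peptide = "".join(
                _AMINO_ACIDS[i] for i in rng.integers(len(_AMINO_ACIDS), size=length)
            )
            affinity = float(
                rng.lognormal(config.affinity_log_mean, config.affinity_log_sd)
            )
            out.append(
                NeoantigenCandidate(
                    patient_id=patient.patient_id,
                    source=call.key,
                    peptide=peptide,
                    affinity_nm=affinity,
                )
            )
    return out
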