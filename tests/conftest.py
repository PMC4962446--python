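"""Shared fixtures: simulated cohorts and hand-built filtering scenes."""

import pytest

from panelsim import (
    Ancestry,
    CancerType,
    CohortSimConfig,
    GermlineDatabase,
    Origin,
    PatientProfile,
    SomaticCatalog,
    VariantCall,
    VariantKey,
    default_panels,
    simulate_cohort,
)


def vkey(pos: int, chrom: str = "chr1", ref: str = "A", alt: str = "G") -> VariantKey:
    return VariantKey(chrom=chrom, pos=pos, ref=ref, alt=alt)


def vcall(
    pos: int,
    patient: str = "P1",
    gene: str = "GENE1",
    af: float = 0.3,
    origin: Origin = Origin.UNKNOWN,
    cosmic: int = 0,
) -> VariantCall:
    return VariantCall(
        key=vkey(pos),
        patient_id=patient,
        gene=gene,
        allelic_fraction=af,
        origin=origin,
        cosmic_count=cosmic,
    )


@pytest.fixture(scope="session")
def default_study():
    """The full default synthetic cohort (the study conditions), seed-fixed."""
    config = CohortSimConfig(seed=42)
    patients, databases, catalog = simulate_cohort(config)
    return config, patients, databases, catalog, default_panels(config)


@pytest.fixture(scope="session")
def small_study():
    """A scaled-down cohort for fast structural checks."""
    config = CohortSimConfig(
        n_patients=25,
        frac_non_european=0.4,
        germline_contaminant_mean=60.0,
        somatic_burden_log_mean=3.0,
        n_common_shared=3000,
        n_ancestry_specific=1000,
        n_private_rare=5000,
        seed=11,
    )
    patients, databases, catalog = simulate_cohort(config)
    return config, patients, databases, catalog, default_panels(config)


def make_patient(
    pid: str = "P1",
    ancestry: Ancestry = Ancestry.EUROPEAN,
    somatic: list[VariantCall] = (),
    germline: list[VariantCall] = (),
) -> PatientProfile:
    return PatientProfile(
        patient_id=pid,
        ancestry=ancestry,
        cancer_type=CancerType.LUNG,
        true_somatic=list(somatic),
        germline_variants=list(germline),
    )


@pytest.fixture()
def branch_scene():
    """A six-variant scene exercising every branch of the filter cascade.

    Variants (patient P1):
      pos 1: somatic, AF 0.02            -> removed by AF gate
      pos 2: somatic, not in any db      -> retained (TP)
      pos 3: somatic hotspot, in db, cosmic 12 -> rescued at t<=10, removed at t=0
      pos 4: somatic, in db, cosmic 2    -> removed at t>=3, rescued at t in {1}
      pos 5: germline, in db, cosmic 0   -> removed by database
      pos 6: germline, not in db         -> retained (FP)
    """
    somatic = [
        vcall(1, af=0.02, origin=Origin.SOMATIC),
        vcall(2, af=0.30, origin=Origin.SOMATIC),
        vcall(3, af=0.40, origin=Origin.SOMATIC, cosmic=12),
        vcall(4, af=0.25, origin=Origin.SOMATIC, cosmic=2),
    ]
    germline = [
        vcall(5, af=0.50, origin=Origin.GERMLINE),
        vcall(6, af=0.45, origin=Origin.GERMLINE),
    ]
    patient = make_patient(somatic=somatic, germline=germline)
    calls = [c.with_origin(Origin.UNKNOWN) for c in somatic + germline]
    databases = {
        "dbsnp": GermlineDatabase("dbsnp", frozenset({vkey(3), vkey(4), vkey(5)})),
        "exac": GermlineDatabase("exac", frozenset({vkey(5)})),
    }
    catalog = SomaticCatalog(counts={vkey(3): 12, vkey(4): 2})
    return patient, calls, databases, catalog
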