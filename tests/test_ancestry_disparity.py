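"""Exact Fisher test, odds-ratio conventions, and ancestry pooling."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from panelsim import (
    Ancestry,
    ContingencyTable2x2,
    FilterStrategy,
    GermlineDatabase,
    Origin,
    SomaticCatalog,
    apply_filter,
    classify_false_positives,
    compare_ancestry,
    fisher_exact_two_sided,
    fp_burden_by_patient,
    haldane_odds_ratio,
    make_tumor_only_calls,
    proportion,
    sample_odds_ratio,
)

from conftest import make_patient, vcall


def test_symmetric_table_is_null():
    p, odds = fisher_exact_two_sided(ContingencyTable2x2(5, 5, 5, 5))
    assert p == 1.0
    assert odds == 1.0


def test_small_table_against_hand_enumeration():
    """Margins (4,4,4,4) admit 5 tables with weights 1,16,36,16,1 (total 70);
    observing a=3 gives p = (16+16+1+1)/70."""
    p, odds = fisher_exact_two_sided(ContingencyTable2x2(3, 1, 1, 3))
    assert p == pytest.approx(34 / 70, abs=1e-15)
    assert odds == 9.0


def test_row_swap_symmetry():
    rng = np.random.default_rng(0)
    for _ in range(50):
        a, b, c, d = (int(x) for x in rng.integers(1, 40, size=4))
        p1, or1 = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d))
        p2, or2 = fisher_exact_two_sided(ContingencyTable2x2(c, d, a, b))
        assert p1 == pytest.approx(p2, rel=1e-12)
        assert or1 == pytest.approx(1 / or2, rel=1e-12)
        assert 0 < p1 <= 1


@pytest.mark.parametrize("scale", [1, 40])
def test_agrees_with_scipy_in_both_regimes(scale):
    """Exact-integer (small totals) and log-space (large totals) branches both
    match scipy's two-sided Fisher."""
    rng = np.random.default_rng(scale)
    for _ in range(40):
        a, b, c, d = (int(x) for x in rng.integers(1, 30 * scale, size=4))
        p, _ = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d))
        expected = sps.fisher_exact([[a, b], [c, d]]).pvalue
        assert p == pytest.approx(expected, rel=1e-8, abs=1e-14)


def test_zero_margin_rejected():
    with pytest.raises(ValueError, match="zero margin"):
        fisher_exact_two_sided(ContingencyTable2x2(0, 0, 3, 4))
    with pytest.raises(ValueError, match="zero margin"):
        fisher_exact_two_sided(ContingencyTable2x2(0, 3, 0, 4))


def test_odds_ratio_zero_cell_conventions():
    assert sample_odds_ratio(ContingencyTable2x2(3, 0, 2, 5)) == math.inf
    assert sample_odds_ratio(ContingencyTable2x2(0, 3, 2, 5)) == 0.0
    assert math.isnan(sample_odds_ratio(ContingencyTable2x2(0, 3, 0, 5)))
    # Haldane correction is the labeled secondary value
    assert haldane_odds_ratio(ContingencyTable2x2(3, 0, 2, 5)) == pytest.approx(
        (3.5 * 5.5) / (0.5 * 2.5)
    )


def _two_group_cohort(n_fp_non_eu, n_fp_eu, n_som=4):
    patients = []
    pos = 1
    for i, (anc, n_fp) in enumerate(
        [(Ancestry.NON_EUROPEAN, n_fp_non_eu), (Ancestry.EUROPEAN, n_fp_eu)]
    ):
        somatic, germline = [], []
        for _ in range(n_som):
            somatic.append(vcall(pos, patient=f"P{i}", af=0.3, origin=Origin.SOMATIC))
            pos += 1
        for _ in range(n_fp):
            germline.append(vcall(pos, patient=f"P{i}", af=0.5, origin=Origin.GERMLINE))
            pos += 1
        patients.append(
            make_patient(pid=f"P{i}", ancestry=anc, somatic=somatic, germline=germline)
        )
    return patients


def test_compare_ancestry_matches_brute_force_pooling():
    """The assembled table equals pooling per-patient classify_false_positives
    and retained-somatic counts by hand."""
    patients = _two_group_cohort(6, 2)
    dbs = {"dbsnp": GermlineDatabase("dbsnp", frozenset())}
    catalog = SomaticCatalog({})
    strategy = FilterStrategy("s", ("dbsnp",))
    table, p, odds = compare_ancestry(patients, strategy, dbs, catalog)
    a = b = c = d = 0
    for patient in patients:
        res = apply_filter(
            make_tumor_only_calls(patient), strategy, dbs, catalog, truth=patient
        )
        n_fp = len(classify_false_positives(res, patient))
        n_tp = res.tp
        if patient.ancestry is Ancestry.NON_EUROPEAN:
            a, b = a + n_fp, b + n_tp
        else:
            c, d = c + n_fp, d + n_tp
    assert (table.a, table.b, table.c, table.d) == (a, b, c, d) == (6, 4, 2, 4)
    assert odds == pytest.approx((6 * 4) / (4 * 2))


def test_null_cohort_gives_unit_odds_ratio():
    """Two groups with identical FP proportions: OR = 1, p near 1."""
    patients = _two_group_cohort(3, 3)
    dbs: dict = {}
    table, p, odds = compare_ancestry(patients, FilterStrategy("af"), dbs, SomaticCatalog({}))
    assert odds == 1.0
    assert p == 1.0


def test_fp_burden_by_patient_brute_force(default_study):
    """Per-patient FP counts and group fractions match direct counting; the
    printed form of a 6-of-19 burden fraction is 32 %."""
    _, patients, dbs, catalog, panels = default_study
    cohort = patients[:40]
    strategy = FilterStrategy("dbsnp", ("dbsnp",))
    results = {
        p.patient_id: apply_filter(
            make_tumor_only_calls(p), strategy, dbs, catalog, truth=p
        )
        for p in cohort
    }
    df, summary = fp_burden_by_patient(cohort, results, burden_threshold=5)
    assert len(df) == len(cohort)
    for patient in cohort:
        expected = len(classify_false_positives(results[patient.patient_id], patient))
        got = df.loc[df.patient_id == patient.patient_id, "n_false_positives"].item()
        assert got == expected
    for ancestry, entry in summary.items():
        grp = df[df.ancestry == ancestry]["n_false_positives"]
        assert entry["n_patients"] == len(grp)
        assert entry["median_fp"] == grp.median()
        assert entry["frac_over_threshold"] == pytest.approx(
            (grp > 5).mean()
        )
    assert proportion(6, 19)[1] == "32 %"


def test_all_zero_fp_cohort_summary():
    patients = _two_group_cohort(0, 0)
    results = {
        p.patient_id: apply_filter(
            make_tumor_only_calls(p), FilterStrategy("af"), {}, SomaticCatalog({}),
            truth=p,
        )
        for p in patients
    }
    _, summary = fp_burden_by_patient(patients, results)
    for entry in summary.values():
        assert entry["median_fp"] == 0.0
        assert entry["frac_over_threshold"] == 0.0
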