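"""Filter cascade semantics: hand traces, truth-table oracle, monotonicity."""

import numpy as np
import pytest

from panelsim import (
    FilterStrategy,
    GermlineDatabase,
    Origin,
    SomaticCatalog,
    apply_filter,
    classify_false_positives,
)

from conftest import make_patient, vcall, vkey


def keys(calls):
    return {c.key for c in calls}


def test_branch_scene_hand_trace(branch_scene):
    """Four-step cascade on the six-variant scene, traced by hand."""
    patient, calls, databases, catalog = branch_scene
    strategy = FilterStrategy("both_t10", ("dbsnp", "exac"), rescue_threshold=10)
    res = apply_filter(calls, strategy, databases, catalog, truth=patient)
    assert keys(res.removed_by_af) == {vkey(1)}
    assert keys(res.removed_by_database) == {vkey(4), vkey(5)}
    assert keys(res.rescued) == {vkey(3)}
    assert keys(res.retained) == {vkey(2), vkey(3), vkey(6)}
    assert (res.tp, res.fp, res.fn) == (2, 1, 2)  # fn: AF-failed + unrescued

    # same scene, rescue disabled: the hotspot is lost to the database filter
    res0 = apply_filter(
        calls, FilterStrategy("both_t0", ("dbsnp", "exac")), databases, catalog,
        truth=patient,
    )
    assert vkey(3) in keys(res0.removed_by_database)
    assert res0.fn == 3
    # low stringency rescues the cosmic_count=2 variant too
    res1 = apply_filter(
        calls,
        FilterStrategy("both_t1", ("dbsnp", "exac"), rescue_threshold=1),
        databases,
        catalog,
        truth=patient,
    )
    assert keys(res1.rescued) == {vkey(3), vkey(4)}


def test_rescued_variants_are_database_hits_meeting_threshold(branch_scene):
    patient, calls, databases, catalog = branch_scene
    for t in (1, 3, 5, 10):
        strategy = FilterStrategy("s", ("dbsnp",), rescue_threshold=t)
        res = apply_filter(calls, strategy, databases, catalog)
        for c in res.rescued:
            assert any(c.key in databases[n].members for n in strategy.databases)
            assert catalog.count(c.key) >= t
        assert keys(res.rescued) <= keys(res.retained)


def test_unknown_database_and_empty_calls():
    strategy = FilterStrategy("s", ("nosuchdb",))
    with pytest.raises(KeyError, match="nosuchdb"):
        apply_filter([vcall(1)], strategy, {}, SomaticCatalog({}))
    res = apply_filter([], FilterStrategy("af"), {}, SomaticCatalog({}))
    assert res.retained == [] and res.rescued == []


def test_empty_databases_reduce_to_af_gate():
    calls = [vcall(1, af=0.01), vcall(2, af=0.049), vcall(3, af=0.05), vcall(4, af=0.9)]
    db = {"dbsnp": GermlineDatabase("dbsnp", frozenset())}
    res = apply_filter(calls, FilterStrategy("s", ("dbsnp",)), db, SomaticCatalog({}))
    assert keys(res.retained) == {vkey(3), vkey(4)}
    assert keys(res.removed_by_af) == {vkey(1), vkey(2)}
    assert res.removed_by_database == []


def _random_scene(rng, n=20):
    """A random ≤20-variant scene with database/catalog annotations."""
    somatic, germline, calls = [], [], []
    db_members: set = set()
    catalog: dict = {}
    for pos in range(1, n + 1):
        origin = Origin.SOMATIC if rng.random() < 0.5 else Origin.GERMLINE
        af = float(rng.uniform(0.0, 1.0))
        cosmic = int(rng.choice([0, 0, 1, 2, 3, 5, 8, 10, 12]))
        call = vcall(pos, af=af, origin=origin, cosmic=cosmic)
        (somatic if origin is Origin.SOMATIC else germline).append(call)
        calls.append(call.with_origin(Origin.UNKNOWN))
        if rng.random() < 0.5:
            db_members.add(vkey(pos))
        if cosmic:
            catalog[vkey(pos)] = cosmic
    patient = make_patient(somatic=somatic, germline=germline)
    dbs = {"dbsnp": GermlineDatabase("dbsnp", frozenset(db_members))}
    return patient, calls, dbs, SomaticCatalog(catalog)


def _oracle_retained(call, strategy, dbs, catalog):
    """Independent per-variant truth table of the cascade."""
    if call.allelic_fraction < strategy.min_allelic_fraction:
        return False
    hit = any(call.key in dbs[name].members for name in strategy.databases)
    if not hit:
        return True
    return strategy.rescue_threshold > 0 and (
        catalog.counts.get(call.key, 0) >= strategy.rescue_threshold
    )


@pytest.mark.parametrize("seed", range(8))
@pytest.mark.parametrize("threshold", [0, 1, 3, 5, 10])
def test_matches_per_variant_truth_table(seed, threshold):
    """apply_filter agrees with exhaustive per-variant evaluation."""
    rng = np.random.default_rng(seed)
    patient, calls, dbs, catalog = _random_scene(rng)
    strategy = FilterStrategy("s", ("dbsnp",), rescue_threshold=threshold)
    res = apply_filter(calls, strategy, dbs, catalog, truth=patient)
    expected = {c.key for c in calls if _oracle_retained(c, strategy, dbs, catalog)}
    assert keys(res.retained) == expected
    assert res.tp == len(expected & patient.somatic_keys)
    assert res.fp == len(expected & patient.germline_keys)
    assert res.fn == len(patient.somatic_keys - expected)


@pytest.mark.parametrize("seed", range(5))
def test_rescue_threshold_monotonicity(seed):
    """Raising the threshold (within 1..10) only shrinks rescued/retained and
    never touches non-hit survivors; enabling rescue never loses calls."""
    rng = np.random.default_rng(100 + seed)
    patient, calls, dbs, catalog = _random_scene(rng)
    prev = None
    base = apply_filter(calls, FilterStrategy("t0", ("dbsnp",)), dbs, catalog)
    non_hit = keys(base.retained)
    for t in (1, 3, 5, 10):
        res = apply_filter(
            calls, FilterStrategy("s", ("dbsnp",), rescue_threshold=t), dbs, catalog
        )
        assert non_hit <= keys(res.retained)  # rescue only ever adds
        if prev is not None:
            assert keys(res.rescued) <= keys(prev.rescued)
            assert keys(res.retained) <= keys(prev.retained)
        prev = res


@pytest.mark.parametrize("seed", range(5))
def test_adding_database_never_increases_retained(seed):
    rng = np.random.default_rng(200 + seed)
    patient, calls, dbs, catalog = _random_scene(rng)
    extra = {vkey(p) for p in range(1, 21) if rng.random() < 0.4}
    dbs = dict(dbs)
    dbs["exac"] = GermlineDatabase("exac", frozenset(extra))
    for t in (0, 10):
        small = apply_filter(
            calls, FilterStrategy("one", ("dbsnp",), rescue_threshold=t),
            dbs, catalog, truth=patient,
        )
        big = apply_filter(
            calls, FilterStrategy("two", ("dbsnp", "exac"), rescue_threshold=t),
            dbs, catalog, truth=patient,
        )
        assert keys(big.retained) <= keys(small.retained)
        assert big.fp <= small.fp
        assert big.tp <= small.tp


def test_classify_false_positives_consistent(branch_scene):
    patient, calls, databases, catalog = branch_scene
    strategy = FilterStrategy("s", ("dbsnp",), rescue_threshold=10)
    res = apply_filter(calls, strategy, databases, catalog, truth=patient)
    fps = classify_false_positives(res, patient)
    assert len(fps) == res.fp
    assert keys(fps) <= patient.germline_keys
    # retained set equal to the germline truth -> everything is a FP
    germ_only = apply_filter(
        [c.with_origin(Origin.UNKNOWN) for c in patient.germline_variants],
        FilterStrategy("af"),
        {},
        catalog,
        truth=patient,
    )
    assert keys(classify_false_positives(germ_only, patient)) == patient.germline_keys


def test_strategy_validation():
    with pytest.raises(ValueError, match="rescue_threshold"):
        FilterStrategy("s", (), rescue_threshold=7)
    with pytest.raises(ValueError, match="min_allelic_fraction"):
        FilterStrategy("s", (), min_allelic_fraction=1.0)
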