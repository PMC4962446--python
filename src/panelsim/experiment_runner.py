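"""End-to-end study orchestration on synthetic cohorts.

``run_study`` stitches the component stages together the way the study
design runs: simulate a cohort, evaluate the filter-strategy grid at
panel and exome scale (sensitivity/PPV sweep), compare ancestry groups
per database, correlate panel vs WES mutational load in matched and
unmatched arms, and measure neoantigen load and panel recovery. The
bundle is a directory of TSV/JSON artifacts plus a markdown summary;
every number in it is recomputable by calling the component operations
on the written intermediates. All randomness flows from the one config
seed; the log records the seed, a config hash, and per-stage row counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import yaml

from .ancestry_disparity import (
    compare_ancestry,
    fp_burden_by_patient,
    haldane_odds_ratio,
)
from .core_io import (
    write_catalog,
    write_database,
    write_gene_list,
    write_variant_table,
)
from .germline_filtering import (
    DEFAULT_STRATEGY,
    FilterStrategy,
    apply_filter,
    default_strategy_grid,
)
from .genomic_load import (
    correlate_loads,
    mutational_load,
    neoantigen_load,
    neoantigen_recovery,
)
from .panel_downsampling import downsample_to_panel, summarize_burden
from .performance_metrics import sweep_strategies
from .synthetic_cohort import (
    CohortSimConfig,
    default_panels,
    make_tumor_only_calls,
    simulate_cohort,
    simulate_neoantigens,
)

logger = logging.getLogger("panelsim")

PANEL_ORDER = ("wes", "large", "medium", "small")
ANCESTRY_STRATEGIES = {
    "dbsnp": FilterStrategy("dbsnp", ("dbsnp",)),
    "thousand_genomes": FilterStrategy("thousand_genomes", ("thousand_genomes",)),
    "exac": FilterStrategy("exac", ("exac",)),
}


def load_config(path: str | Path) -> CohortSimConfig:
    """Read a YAML/JSON study config mirroring CohortSimConfig field names."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return CohortSimConfig.from_dict(data or {})


def config_hash(config: CohortSimConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name: str):
    """Decorator-free stage guard: abort with the failing stage named."""

    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"study stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_study(
    config: CohortSimConfig,
    out_dir: Optional[str | Path] = None,
    strategies: Optional[list[FilterStrategy]] = None,
) -> dict:
    """Run the full synthetic study; optionally write the report bundle.

    Returns the report as a plain dict (JSON-serializable). When
    ``out_dir`` is given, writes the cohort intermediates (variant
    tables, databases, catalog, panel gene lists), per-panel performance
    TSVs, ``report.json`` and ``summary.md`` there. Deterministic:
    identical configs produce byte-identical bundles.
    """
    strategies = strategies or default_strategy_grid()
    report: dict = {
        "seed": config.seed,
        "config_hash": config_hash(config),
        "n_patients": config.n_patients,
    }

    with _stage("simulate"):
        patients, databases, catalog = simulate_cohort(config)
        panels = default_panels(config)
        tumor_only = {p.patient_id: make_tumor_only_calls(p) for p in patients}
        logger.info(
            "simulate: %d patients, %d tumor-only calls, catalog size %d",
            len(patients),
            sum(len(v) for v in tumor_only.values()),
            len(catalog.counts),
        )

    with _stage("burden_summary"):
        burden: dict[str, dict[str, dict[str, float]]] = {}
        for arm in ("matched", "unmatched"):
            burden[arm] = {}
            for panel_name in PANEL_ORDER:
                panel = panels[panel_name]
                counts = []
                for p in patients:
                    calls = (
                        p.true_somatic
                        if arm == "matched"
                        else tumor_only[p.patient_id]
                    )
                    counts.append(len(downsample_to_panel(calls, panel)))
                med, q1, q3 = summarize_burden(counts)
                burden[arm][panel_name] = {"median": med, "q1": q1, "q3": q3}
        report["burden_summary"] = burden

    with _stage("strategy_sweep"):
        performance: dict[str, list[dict]] = {}
        best_by_panel: dict[str, str] = {}
        for panel_name in ("large", "wes"):
            perfs, best = sweep_strategies(
                patients, databases, catalog, strategies, panels[panel_name]
            )
            performance[panel_name] = [
                {
                    "strategy": p.strategy.name,
                    "databases": list(p.strategy.databases),
                    "rescue_threshold": p.strategy.rescue_threshold,
                    "tp": p.tp,
                    "fp": p.fp,
                    "fn": p.fn,
                    "n_retained": p.n_retained,
                    "sensitivity": p.sensitivity,
                    "ppv": p.ppv,
                    "fp_rate": p.fp_rate,
                }
                for p in perfs
            ]
            best_by_panel[panel_name] = best.strategy.name
        report["performance"] = performance
        report["best_strategy"] = best_by_panel

    with _stage("ancestry"):
        ancestry: dict[str, dict] = {}
        for db_name, strategy in ANCESTRY_STRATEGIES.items():
            entry: dict = {}
            for scale, panel in (("large_panel", panels["large"]), ("exome", None)):
                try:
                    table, p_val, odds = compare_ancestry(
                        patients, strategy, databases, catalog, panel=panel
                    )
                    entry[scale] = {
                        "table": [table.a, table.b, table.c, table.d],
                        "p_value": p_val,
                        "odds_ratio": odds if odds == odds else None,
                        "haldane_odds_ratio": haldane_odds_ratio(table),
                    }
                except ValueError:  # zero margin: test undefined
                    entry[scale] = {
                        "table": None,
                        "p_value": None,
                        "odds_ratio": None,
                        "haldane_odds_ratio": None,
                    }
            results = {
                p.patient_id: apply_filter(
                    downsample_to_panel(tumor_only[p.patient_id], panels["large"]),
                    strategy,
                    databases,
                    catalog,
                    truth=p,
                )
                for p in patients
            }
            _, patient_summary = fp_burden_by_patient(patients, results)
            entry["patient_burden"] = patient_summary
            ancestry[db_name] = entry
        report["ancestry"] = ancestry

    with _stage("load_correlation"):
        filtered = {
            p.patient_id: apply_filter(
                tumor_only[p.patient_id],
                DEFAULT_STRATEGY,
                databases,
                catalog,
                truth=p,
            ).retained
            for p in patients
        }
        loads: dict[str, dict[str, list[float]]] = {"matched": {}, "unmatched": {}}
        for arm in ("matched", "unmatched"):
            for panel_name in PANEL_ORDER:
                panel = panels[panel_name]
                vals = []
                for p in patients:
                    calls = (
                        p.true_somatic if arm == "matched" else filtered[p.patient_id]
                    )
                    vals.append(
                        mutational_load(
                            downsample_to_panel(calls, panel), panel.territory_mb
                        )
                    )
                loads[arm][panel_name] = vals
        corr: dict[str, dict[str, Optional[float]]] = {}
        for arm in ("matched", "unmatched"):
            corr[arm] = {}
            wes_loads = loads["matched"]["wes"]  # WES truth load is the reference
            for panel_name in ("large", "medium", "small"):
                try:
                    cmpres = correlate_loads(zip(loads[arm][panel_name], wes_loads))
                    corr[arm][panel_name] = cmpres.r_squared
                except ValueError:
                    corr[arm][panel_name] = None
        med_load = {
            arm: {
                name: summarize_burden(vals)[0] for name, vals in loads[arm].items()
            }
            for arm in loads
        }
        report["load_correlation_r2"] = corr
        report["median_load_per_mb"] = med_load

    with _stage("neoantigens"):
        exome_binder_counts = []
        panel_binder_counts = {n: [] for n in ("large", "medium", "small")}
        recovery_counts = {n: [0, 0] for n in ("large", "medium", "small")}
        for p in patients:
            candidates = simulate_neoantigens(p, config)
            binders = [c for c in candidates if c.is_binder]
            exome_binder_counts.append(neoantigen_load(candidates))
            for panel_name in ("large", "medium", "small"):
                panel_calls = downsample_to_panel(
                    p.true_somatic, panels[panel_name]
                )
                n_rec, n_tot, _ = neoantigen_recovery(binders, panel_calls)
                recovery_counts[panel_name][0] += n_rec
                recovery_counts[panel_name][1] += n_tot
                panel_binder_counts[panel_name].append(n_rec)
        neo: dict = {
            "n_exome_binders": sum(exome_binder_counts),
            "median_exome_binders_per_patient": summarize_burden(
                exome_binder_counts
            )[0],
            "recovery": {},
            "correlation_r2": {},
            "median_panel_binders_per_patient": {},
        }
        for panel_name, (n_rec, n_tot) in recovery_counts.items():
            neo["recovery"][panel_name] = {
                "n_recovered": n_rec,
                "n_total": n_tot,
                "fraction": (n_rec / n_tot) if n_tot else None,
            }
            neo["median_panel_binders_per_patient"][panel_name] = summarize_burden(
                panel_binder_counts[panel_name]
            )[0]
            try:
                neo["correlation_r2"][panel_name] = correlate_loads(
                    zip(panel_binder_counts[panel_name], exome_binder_counts)
                ).r_squared
            except ValueError:
                neo["correlation_r2"][panel_name] = None
        report["neoantigen"] = neo

    if out_dir is not None:
        with _stage("write_bundle"):
            _write_bundle(
                Path(out_dir), config, report, patients, tumor_only, databases,
                catalog, panels,
            )
    return report


def _write_bundle(
    out: Path, config, report, patients, tumor_only, databases, catalog, panels
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cohort_dir = out / "cohort"
    cohort_dir.mkdir(exist_ok=True)
    matched = [c for p in patients for c in p.true_somatic]
    germline = [c for p in patients for c in p.germline_variants]
    observed = [c for p in patients for c in tumor_only[p.patient_id]]
    write_variant_table(matched, cohort_dir / "matched_calls.tsv")
    write_variant_table(germline, cohort_dir / "germline_truth.tsv")
    write_variant_table(observed, cohort_dir / "tumor_only_calls.tsv")
    with open(cohort_dir / "patients.tsv", "w") as fh:
        fh.write("patient_id\tancestry\tcancer_type\n")
        for p in patients:
            fh.write(f"{p.patient_id}\t{p.ancestry.value}\t{p.cancer_type.value}\n")
    for name, db in databases.items():
        write_database(db, cohort_dir / f"db_{name}.tsv")
    write_catalog(catalog, cohort_dir / "cosmic_catalog.tsv")
    for name, panel in panels.items():
        if name != "wes":
            write_gene_list(panel.genes, cohort_dir / f"panel_{name}_genes.txt")
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "summary.md", "w") as fh:
        fh.write(render_summary(report))


def render_summary(report: dict) -> str:
    """A short deterministic markdown digest of a study report."""
    lines = [
        "# Synthetic tumor profiling study",
        "",
        f"- patients: {report['n_patients']}",
        f"- seed: {report['seed']} (config hash {report['config_hash']})",
        "",
        "## Per-patient mutation counts (median [Q1-Q3])",
        "",
        "| setting | " + " | ".join(PANEL_ORDER) + " |",
        "|---|" + "---|" * len(PANEL_ORDER),
    ]
    for arm in ("matched", "unmatched"):
        cells = []
        for panel in PANEL_ORDER:
            b = report["burden_summary"][arm][panel]
            cells.append(f"{b['median']:g} [{b['q1']:g}-{b['q3']:g}]")
        lines.append(f"| {arm} | " + " | ".join(cells) + " |")
    lines += ["", "## Optimal filter strategy (sensitivity x PPV)", ""]
    for panel, name in sorted(report["best_strategy"].items()):
        lines.append(f"- {panel}: `{name}`")
    lines += ["", "## Ancestry disparity (large panel, variant level)", ""]
    for db, entry in sorted(report["ancestry"].items()):
        e = entry["large_panel"]
        odds = e["odds_ratio"]
        p = e["p_value"]
        odds_s = f"{odds:.2f}" if isinstance(odds, float) else "undefined"
        p_s = f"{p:.3g}" if isinstance(p, float) else "undefined"
        lines.append(f"- {db}: OR = {odds_s}, p = {p_s}")
    lines += ["", "## Mutational load r^2 vs WES", ""]
    for arm in ("matched", "unmatched"):
        for panel in ("large", "medium", "small"):
            r2 = report["load_correlation_r2"][arm][panel]
            r2_s = f"{r2:.3f}" if isinstance(r2, float) else "undefined"
            lines.append(f"- {arm} {panel}: {r2_s}")
    neo = report["neoantigen"]
    lines += [
        "",
        "## Neoantigens",
        "",
        f"- exome binders (<500 nM): {neo['n_exome_binders']} "
        f"(median {neo['median_exome_binders_per_patient']:g} per patient)",
    ]
    for panel, rec in sorted(neo["recovery"].items()):
        frac = rec["fraction"]
        frac_s = f"{100 * frac:.1f} %" if isinstance(frac, float) else "undefined"
        lines.append(
            f"- {panel} recovery: {rec['n_recovered']}/{rec['n_total']} ({frac_s})"
        )
    return "\n".join(lines) + "\n"
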