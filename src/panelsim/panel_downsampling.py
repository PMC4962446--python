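"""Restrict exome-scale mutation data to targeted panel gene content.

Downsampling models what a panel assay would have observed: exactly the
calls whose gene is on the panel, in stable input order. It commutes
with germline filtering (both are per-variant predicates).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .core_io import GenePanel, PatientProfile, VariantCall


def downsample_to_panel(
    calls: Sequence[VariantCall], panel: GenePanel
) -> list[VariantCall]:
    """Calls whose gene is in the panel; the ``wes`` panel is the identity."""
    if panel.name == "wes":
        return list(calls)
    genes = panel.genes
    return [c for c in calls if c.gene in genes]


def restrict_profile(patient: PatientProfile, panel: GenePanel) -> PatientProfile:
    """A truth profile restricted to panel genes (for panel-level scoring)."""
    return PatientProfile(
        patient_id=patient.patient_id,
        ancestry=patient.ancestry,
        cancer_type=patient.cancer_type,
        true_somatic=downsample_to_panel(patient.true_somatic, panel),
        germline_variants=downsample_to_panel(patient.germline_variants, panel),
    )


def summarize_burden(
    per_patient_counts: Sequence[int],
) -> tuple[float, float, float]:
    """(median, Q1, Q3) of per-patient mutation counts.

    Quantiles use linear interpolation between order statistics (the
    mainstream numerical default); permutation invariant.
    """
    if len(per_patient_counts) == 0:
        raise ValueError("cannot summarize an empty cohort")
    arr = np.asarray(per_patient_counts, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return float(med), float(q1), float(q3)
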