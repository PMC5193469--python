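"""End-to-end drivers: fixture truth -> simulated nuclei -> calls -> tables.

This is the path the acceptance analysis runs: take each fixture
case's per-arm status as the true clonal state, generate nucleus
counts through the detection model, call status with the published
cutoffs, and rebuild the cohort table from the calls.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .caller import (ArmStatus, QCPolicy, SampleCall, call_arm_status,
                     summarize_sample)
from .chromosomes import CHROM_PAIRS, CutoffSet
from .simulate import DetectionModel, nuclei_for_state

_STATUS_COLUMN = {"chr1": "status_1p", "chr19": "status_19q",
                  "chr9": "status_9p", "chr10": "status_10q"}
_CONTROL_COLUMN = {"chr9": "control_9q_deleted", "chr10": "control_10p_deleted"}


def true_state_for(row: pd.Series, chrom_id: str) -> str:
    """Map a fixture case's recorded status to a generative true state."""
    status = row[_STATUS_COLUMN[chrom_id]]
    if (chrom_id in _CONTROL_COLUMN and status == "DELETED"
            and row[_CONTROL_COLUMN[chrom_id]]):
        return "MONOSOMY"       # whole-chromosome loss
    return status


def call_cohort(
    cohort: pd.DataFrame,
    seed: int | None = None,
    cutoffs: CutoffSet | None = None,
    detection: DetectionModel | None = None,
    n_nuclei_range: tuple[int, int] = (300, 1200),
    qc_policy: QCPolicy | None = None,
) -> pd.DataFrame:
    """Simulate counts for every fixture case and re-call all four arms.

    Returns the cohort table with the four status columns (and control
    flags) replaced by the automated calls, so downstream marginal and
    deletion-count summaries exercise the full pipeline rather than
    reading the frozen truth back.
    """
    rng = np.random.default_rng(seed)
    cutoffs = cutoffs or CutoffSet.published_defaults()
    detection = detection or DetectionModel()
    qc_policy = qc_policy or QCPolicy()
    out = cohort.copy()
    for idx, row in cohort.iterrows():
        for chrom_id, chrom in CHROM_PAIRS.items():
            state = true_state_for(row, chrom_id)
            n = int(rng.integers(n_nuclei_range[0], n_nuclei_range[1] + 1))
            nuclei = nuclei_for_state(state, detection, n, rng)
            summary = summarize_sample(chrom, nuclei)
            call = call_arm_status(summary, cutoffs, chrom, qc_policy)
            out.loc[idx, _STATUS_COLUMN[chrom_id]] = call.target_status.value
            if chrom_id in _CONTROL_COLUMN:
                out.loc[idx, _CONTROL_COLUMN[chrom_id]] = call.control_arm_deleted
    return out


def features_from_row(row: pd.Series) -> "CaseFeatures":
    """Build WHO-2016 inputs from one cohort-table row."""
    from .who2016 import CaseFeatures

    return CaseFeatures(
        mvp=row["mvp"],
        necrosis=bool(row["necrosis"]),
        mitoses_per_10hpf=float(row["mitoses_per_10hpf"]),
        ki67_pct=float(row["ki67_pct"]),
        idh1r132h_positive=bool(row["idh1r132h_positive"]),
        idh2_mutant=bool(row["idh2_mutant"]),
        atrx=row["atrx"],
        ina_positive=bool(row["ina_positive"]),
        status_1p=ArmStatus(row["status_1p"]),
        status_19q=ArmStatus(row["status_19q"]),
        status_9p=ArmStatus(row["status_9p"]),
        status_10q=ArmStatus(row["status_10q"]),
        control_arm_9q_deleted=bool(row["control_9q_deleted"]),
        control_arm_10p_deleted=bool(row["control_10p_deleted"]),
    )


def diagnose_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Run the WHO-2016 engine on every case; returns label + rationale."""
    from .who2016 import integrated_diagnosis

    rows = []
    for _, row in cohort.iterrows():
        dx = integrated_diagnosis(features_from_row(row))
        rows.append({
            "case_id": row["case_id"],
            "label": dx.label,
            "lineage": dx.lineage.value,
            "grade": dx.grade,
            "rationale": " | ".join(dx.rationale),
        })
    return pd.DataFrame(rows)


def loss_percent(cohort: pd.DataFrame, status_col: str,
                 group: str | None = None) -> float:
    """Percent of cases (optionally within one group) called DELETED."""
    sub = cohort if group is None else cohort[cohort["group"] == group]
    return 100.0 * float((sub[status_col] == "DELETED").mean())
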