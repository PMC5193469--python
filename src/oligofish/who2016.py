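"""Integrated WHO-2016 diagnosis from histology, IHC and FISH calls.

Lineage is molecular: a diffuse glioma is an oligodendroglioma iff it
is IDH-mutant AND 1p- and 19q-deleted (whole-arm codeletion); every
other configuration is astrocytic.  Grade then follows histology:
glomeruloid microvascular proliferation (or a high mitotic count)
makes an oligodendroglioma anaplastic (grade III); in the astrocytic
line glomeruloid MVP or necrosis is sufficient for glioblastoma
(grade IV), and a raised mitotic count alone gives grade III.

ATRX loss and alpha-internexin are recorded as supporting markers but
are never decisive.  An IDH2 sequencing result, when supplied,
overrides a negative IDH1-R132H immunostain.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .caller import ArmStatus


class Lineage(enum.Enum):
    OLIGODENDROGLIOMA = "oligodendroglioma"
    ASTROCYTOMA = "astrocytoma"


@dataclass(frozen=True)
class GradingThresholds:
    """Mitotic-count thresholds (per 10 HPF) for anaplasia.

    WHO grading language is qualitative ("brisk mitotic activity");
    the numeric defaults are configuration, not ground truth.
    """

    og_mitoses_grade3: float = 6.0
    as_mitoses_grade3: float = 2.0

    def __post_init__(self) -> None:
        if self.og_mitoses_grade3 <= 0 or self.as_mitoses_grade3 <= 0:
            raise ValueError("grading thresholds must be positive")


@dataclass
class CaseFeatures:
    """Histological, IHC and molecular inputs for one case."""

    mvp: str = "none"                     # none | endocrinoid | glomeruloid
    necrosis: bool = False
    mitoses_per_10hpf: float = 0.0
    ki67_pct: float = 0.0
    idh1r132h_positive: bool | None = None
    idh2_mutant: bool | None = None       # sequencing override, optional
    atrx: str = "retained"                # retained | lost
    ina_positive: bool = False
    status_1p: ArmStatus = ArmStatus.NORMAL
    status_19q: ArmStatus = ArmStatus.NORMAL
    status_9p: ArmStatus = ArmStatus.NORMAL
    status_10q: ArmStatus = ArmStatus.NORMAL
    control_arm_9q_deleted: bool = False
    control_arm_10p_deleted: bool = False

    def __post_init__(self) -> None:
        if self.mvp not in {"none", "endocrinoid", "glomeruloid"}:
            raise ValueError(f"invalid mvp {self.mvp!r}")
        if self.atrx not in {"retained", "lost"}:
            raise ValueError(f"invalid atrx {self.atrx!r}")

    @property
    def idh_status(self) -> str:
        """Combined IDH status: IHC with optional IDH2 sequencing override."""
        if self.idh1r132h_positive is None and self.idh2_mutant is None:
            return "unknown"
        if self.idh1r132h_positive:
            return "mutant"
        if self.idh2_mutant:
            return "mutant"
        if self.idh1r132h_positive is False:
            return "wildtype"
        return "unknown"


@dataclass
class IntegratedDiagnosis:
    lineage: Lineage
    grade: str                 # II | III | IV
    label: str                 # OII | OIII | AII | AIII | GBM
    rationale: list[str] = field(default_factory=list)


def assign_lineage(f: CaseFeatures) -> tuple[Lineage, list[str]]:
    """Molecular lineage call: oligodendroglioma iff IDH-mutant and
    1p/19q codeleted; anything else is astrocytic."""
    if f.idh_status == "unknown":
        raise ValueError("IDH status unknown: integrated diagnosis impossible")
    rationale = []
    codeleted = (f.status_1p is ArmStatus.DELETED
                 and f.status_19q is ArmStatus.DELETED)
    if f.idh_status == "mutant" and codeleted:
        rationale.append("IDH-mutant with 1p/19q codeletion -> oligodendroglioma")
        if f.idh1r132h_positive is False and f.idh2_mutant:
            rationale.append("IDH1-R132H IHC negative; IDH2 sequencing mutant")
        return Lineage.OLIGODENDROGLIOMA, rationale
    if f.idh_status != "mutant":
        rationale.append("IDH-wildtype -> astrocytic lineage")
    elif not codeleted:
        rationale.append("1p/19q not codeleted -> astrocytic lineage")
    return Lineage.ASTROCYTOMA, rationale


def assign_grade(
    f: CaseFeatures,
    lineage: Lineage,
    thresholds: GradingThresholds = GradingThresholds(),
) -> tuple[str, list[str]]:
    """Histological grade within the assigned lineage.

    Only glomeruloid vessels count as microvascular proliferation;
    the endocrinoid (chicken-wire) pattern is the ordinary
    oligodendroglial vasculature and is not a high-grade feature.
    """
    rationale = []
    glom = f.mvp == "glomeruloid"
    if lineage is Lineage.OLIGODENDROGLIOMA:
        if glom:
            rationale.append("glomeruloid MVP -> anaplastic (grade III)")
            return "III", rationale
        if f.mitoses_per_10hpf >= thresholds.og_mitoses_grade3:
            rationale.append(
                f"mitoses {f.mitoses_per_10hpf:g} >= "
                f"{thresholds.og_mitoses_grade3:g}/10HPF -> grade III")
            return "III", rationale
        rationale.append("no MVP, low mitotic count -> grade II")
        return "II", rationale
    if glom or f.necrosis:
        which = "glomeruloid MVP" if glom else "necrosis"
        rationale.append(f"{which} -> glioblastoma (grade IV)")
        return "IV", rationale
    if f.mitoses_per_10hpf >= thresholds.as_mitoses_grade3:
        rationale.append(
            f"mitoses {f.mitoses_per_10hpf:g} >= "
            f"{thresholds.as_mitoses_grade3:g}/10HPF -> grade III")
        return "III", rationale
    rationale.append("no MVP/necrosis, low mitotic count -> grade II")
    return "II", rationale


_LABELS = {
    (Lineage.OLIGODENDROGLIOMA, "II"): "OII",
    (Lineage.OLIGODENDROGLIOMA, "III"): "OIII",
    (Lineage.ASTROCYTOMA, "II"): "AII",
    (Lineage.ASTROCYTOMA, "III"): "AIII",
    (Lineage.ASTROCYTOMA, "IV"): "GBM",
}


def integrated_diagnosis(
    f: CaseFeatures,
    thresholds: GradingThresholds = GradingThresholds(),
) -> IntegratedDiagnosis:
    """Full integrated diagnosis with an auditable rule trail."""
    lineage, r1 = assign_lineage(f)
    grade, r2 = assign_grade(f, lineage, thresholds)
    return IntegratedDiagnosis(
        lineage=lineage, grade=grade,
        label=_LABELS[(lineage, grade)], rationale=r1 + r2,
    )
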