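"""Per-nucleus FISH signal classification and tumor-level status calling.

The automated assay counts red (target-arm) and green (control-arm)
hybridization spots in every segmented interphase nucleus.  Each
nucleus is mapped to one of five categories; the tumor-level call
compares the category fractions, computed over analyzable nuclei, with
chromosome-specific cutoffs.  Cutoffs can be taken from the published
defaults or recalibrated on non-neoplastic control tissue with the
mean + 3 SD rule.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .chromosomes import ChromCutoffs, ChromPair, CutoffSet


class NucleusCategory(enum.Enum):
    """Interpretation of one nucleus's red/green spot pattern."""

    NORMAL = "NORMAL"
    TARGET_DELETED = "TARGET_DELETED"
    POLYSOMY_IMBALANCED = "POLYSOMY_IMBALANCED"
    MONOSOMY = "MONOSOMY"
    UNINFORMATIVE = "UNINFORMATIVE"


class ArmStatus(enum.Enum):
    """Tumor-level status of the target arm."""

    DELETED = "DELETED"
    IMBALANCED = "IMBALANCED"
    NORMAL = "NORMAL"


@dataclass(frozen=True)
class NucleusCount:
    """Red/green spot counts for one nucleus."""

    nucleus_id: str
    n_red: int
    n_green: int

    def __post_init__(self) -> None:
        for name, v in (("n_red", self.n_red), ("n_green", self.n_green)):
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise TypeError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")


def classify_nucleus(chrom: ChromPair, nucleus: NucleusCount) -> NucleusCategory:
    """Classify one nucleus from its red/green spot counts.

    Rules, in order:

    1. 2R/2G is NORMAL.
    2. 1R/1G is MONOSOMY (whole-chromosome loss) where the monosomy
       rule is enabled (chr9, chr10); otherwise UNINFORMATIVE.
    3. nR/nG <= 0.5 with at least two green and one red spot is
       TARGET_DELETED.
    4. nR/nG > 0.5 with at least three spots in one channel is
       POLYSOMY_IMBALANCED (relative gain).
    5. Everything else — red or green channel empty, 2R/1G, 1R/0G and
       similar truncation patterns — is UNINFORMATIVE and excluded
       from all percentage denominators.
    """
    r, g = nucleus.n_red, nucleus.n_green
    if (r, g) == (2, 2):
        return NucleusCategory.NORMAL
    if (r, g) == (1, 1):
        if chrom.monosomy_rule_enabled:
            return NucleusCategory.MONOSOMY
        return NucleusCategory.UNINFORMATIVE
    if r >= 1 and g >= 2 and r / g <= 0.5:
        return NucleusCategory.TARGET_DELETED
    if g >= 1 and r / g > 0.5 and max(r, g) >= 3:
        return NucleusCategory.POLYSOMY_IMBALANCED
    return NucleusCategory.UNINFORMATIVE


@dataclass
class SampleSummary:
    """Category composition of one sample for one probe pair.

    Percentages are over analyzable (non-UNINFORMATIVE) nuclei and are
    carried at full precision; ``pct_deleted`` includes MONOSOMY nuclei
    wherever the 1R/1G rule is enabled, since whole-chromosome loss
    removes the target arm too.
    """

    chrom_id: str
    n_total: int
    n_analyzable: int
    n_normal: int = 0
    n_deleted: int = 0
    n_imbalanced: int = 0
    n_monosomy: int = 0

    @property
    def n_uninformative(self) -> int:
        return self.n_total - self.n_analyzable

    @property
    def uninformative_fraction(self) -> float:
        return 100.0 * self.n_uninformative / self.n_total if self.n_total else 0.0

    def _pct(self, k: int) -> float:
        if self.n_analyzable == 0:
            raise ValueError("no analyzable nuclei: percentages undefined")
        return 100.0 * k / self.n_analyzable

    @property
    def pct_normal(self) -> float:
        return self._pct(self.n_normal)

    @property
    def pct_deleted(self) -> float:
        return self._pct(self.n_deleted + self.n_monosomy)

    @property
    def pct_imbalanced(self) -> float:
        return self._pct(self.n_imbalanced)

    @property
    def pct_monosomy(self) -> float:
        return self._pct(self.n_monosomy)


def summarize_sample(
    chrom: ChromPair, nuclei: Sequence[NucleusCount]
) -> SampleSummary:
    """Tally nucleus categories for one sample.

    A sample with zero analyzable nuclei is returned with
    ``n_analyzable = 0``; percentage accessors then raise, and QC
    flags the sample instead.
    """
    if len(nuclei) == 0:
        raise ValueError("summarize_sample requires at least one nucleus")
    counts = {cat: 0 for cat in NucleusCategory}
    for nuc in nuclei:
        counts[classify_nucleus(chrom, nuc)] += 1
    n_total = len(nuclei)
    return SampleSummary(
        chrom_id=chrom.id,
        n_total=n_total,
        n_analyzable=n_total - counts[NucleusCategory.UNINFORMATIVE],
        n_normal=counts[NucleusCategory.NORMAL],
        n_deleted=counts[NucleusCategory.TARGET_DELETED],
        n_imbalanced=counts[NucleusCategory.POLYSOMY_IMBALANCED],
        n_monosomy=counts[NucleusCategory.MONOSOMY],
    )


@dataclass
class QCPolicy:
    """Minimum evidence required before a call is considered reliable."""

    min_analyzable_cells: int = 50
    max_uninformative_fraction: float = 50.0

    def __post_init__(self) -> None:
        if self.min_analyzable_cells < 1:
            raise ValueError("min_analyzable_cells must be >= 1")


def qc_sample(summary: SampleSummary, policy: QCPolicy) -> tuple[bool, str]:
    """Check a sample against the QC policy.

    Fails when fewer than ``min_analyzable_cells`` nuclei were
    analyzable (the assay's weak-signal failure mode) or when the
    uninformative fraction exceeds the allowed maximum.  Failure does
    not suppress the call; it marks it unreliable, the situation in
    which a secondary manual count is indicated.
    """
    reasons = []
    if summary.n_analyzable < policy.min_analyzable_cells:
        reasons.append(
            f"analyzable nuclei {summary.n_analyzable} < "
            f"{policy.min_analyzable_cells}"
        )
    if summary.uninformative_fraction > policy.max_uninformative_fraction:
        reasons.append(
            f"uninformative fraction {summary.uninformative_fraction:.1f}% > "
            f"{policy.max_uninformative_fraction:.1f}%"
        )
    return (not reasons, "; ".join(reasons) if reasons else "ok")


@dataclass
class SampleCall:
    """Tumor-level status for one probe pair."""

    chrom_id: str
    target_status: ArmStatus
    control_arm_deleted: bool
    summary: SampleSummary
    qc_pass: bool = True
    qc_reason: str = "ok"


def call_arm_status(
    summary: SampleSummary,
    cutoffs: CutoffSet | ChromCutoffs,
    chrom: ChromPair,
    qc_policy: QCPolicy | None = None,
) -> SampleCall:
    """Call the tumor-level target-arm status from category fractions.

    Decision order, with D the deletion and I the imbalance cutoff:

    1. pct_imbalanced > I            -> IMBALANCED (overrides deletion)
    2. pct_deleted > D               -> DELETED
    3. pct_deleted + pct_imbalanced >= D -> IMBALANCED
    4. otherwise                     -> NORMAL

    Where the 1R/1G rule is enabled, the control arm (9q or 10p) is
    additionally flagged deleted when pct_monosomy >= D; whole
    chromosome loss then shows up as target DELETED plus
    ``control_arm_deleted``.
    """
    if summary.n_analyzable == 0:
        raise ValueError(f"{chrom.id}: no analyzable nuclei, cannot call status")
    cut = cutoffs[chrom.id] if isinstance(cutoffs, CutoffSet) else cutoffs
    d, i = cut.deletion_cutoff, cut.imbalance_cutoff

    if summary.pct_imbalanced > i:
        status = ArmStatus.IMBALANCED
    elif summary.pct_deleted > d:
        status = ArmStatus.DELETED
    elif summary.pct_deleted + summary.pct_imbalanced >= d:
        status = ArmStatus.IMBALANCED
    else:
        status = ArmStatus.NORMAL

    control_deleted = bool(
        chrom.monosomy_rule_enabled and summary.pct_monosomy >= cut.monosomy_cutoff
    )
    qc_pass, qc_reason = (True, "ok")
    if qc_policy is not None:
        qc_pass, qc_reason = qc_sample(summary, qc_policy)
    return SampleCall(
        chrom_id=chrom.id,
        target_status=status,
        control_arm_deleted=control_deleted,
        summary=summary,
        qc_pass=qc_pass,
        qc_reason=qc_reason,
    )


def calibrate_cutoffs(
    normal_summaries: dict[str, Sequence[SampleSummary]],
    floor: float = 5.0,
) -> CutoffSet:
    """Derive cutoffs from non-neoplastic control samples (mean + 3 SD).

    For each chromosome, the deletion cutoff is mean + 3 SD of
    ``pct_deleted`` across the control samples and the imbalance cutoff
    likewise from ``pct_imbalanced``; SD is the sample (n-1) standard
    deviation.  Both are clamped below by ``floor`` so an artifact-free
    control series cannot produce a degenerate zero cutoff.

    Parameters
    ----------
    normal_summaries : dict
        Chromosome id -> summaries of >= 2 control samples.
    floor : float
        Lower clamp in percent (default 5).
    """
    per_chrom: dict[str, ChromCutoffs] = {}
    for chrom_id, summaries in normal_summaries.items():
        if len(summaries) < 2:
            raise ValueError(
                f"{chrom_id}: need >= 2 control samples to estimate SD, "
                f"got {len(summaries)}"
            )
        pdel = np.array([s.pct_deleted for s in summaries], dtype=float)
        pimb = np.array([s.pct_imbalanced for s in summaries], dtype=float)
        d = max(floor, float(pdel.mean() + 3.0 * pdel.std(ddof=1)))
        i = max(floor, float(pimb.mean() + 3.0 * pimb.std(ddof=1)))
        per_chrom[chrom_id] = ChromCutoffs(d, i)
    return CutoffSet(per_chrom=per_chrom, source="calibrated")
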