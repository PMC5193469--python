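"""Chromosome-pair probe definitions and cutoff sets.

Each dual-color probe pair labels a target arm in red and the opposite
arm of the same chromosome in green, so the green count acts as an
internal copy-number reference.  For chromosomes 9 and 10 a 1R/1G
nucleus is read as loss of the whole chromosome (the control arm 9q or
10p can itself be lost in gliomas); for 1p and 19q the control arms are
assumed intact and 1R/1G is uninterpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ChromPair:
    """A dual-color FISH probe pair for one chromosome.

    Parameters
    ----------
    id : str
        One of ``chr1``, ``chr9``, ``chr10``, ``chr19``.
    target_locus, control_locus : str
        Cytoband labels of the red (target) and green (control) probes.
    monosomy_rule_enabled : bool
        Whether a 1R/1G nucleus is scored as whole-chromosome loss
        (chromosomes 9 and 10 only).
    """

    id: str
    target_locus: str
    control_locus: str
    monosomy_rule_enabled: bool

    def __post_init__(self) -> None:
        if self.id not in {"chr1", "chr9", "chr10", "chr19"}:
            raise ValueError(f"unknown chromosome pair {self.id!r}")
        if self.monosomy_rule_enabled and self.id in {"chr1", "chr19"}:
            raise ValueError("1R/1G rule applies only to chr9 and chr10")


CHR1 = ChromPair("chr1", "1p36.32", "1q25.2", False)
CHR9 = ChromPair("chr9", "9p21.3", "9q34.12", True)
CHR10 = ChromPair("chr10", "10q23.31", "10p12.31", True)
CHR19 = ChromPair("chr19", "19q13.33", "19p13.2", False)

CHROM_PAIRS: dict[str, ChromPair] = {c.id: c for c in (CHR1, CHR9, CHR10, CHR19)}

#: Target-arm name per probe pair, as reported in call tables.
TARGET_ARM = {"chr1": "1p", "chr9": "9p", "chr10": "10q", "chr19": "19q"}
#: Control-arm name per probe pair.
CONTROL_ARM = {"chr1": "1q", "chr9": "9q", "chr10": "10p", "chr19": "19p"}


@dataclass
class ChromCutoffs:
    """Deletion and imbalance cutoffs (percent of analyzable nuclei)."""

    deletion_cutoff: float
    imbalance_cutoff: float

    def __post_init__(self) -> None:
        for v in (self.deletion_cutoff, self.imbalance_cutoff):
            if not 0 < v < 100:
                raise ValueError(f"cutoff {v} out of (0, 100)")

    @property
    def monosomy_cutoff(self) -> float:
        # Whole-chromosome loss is called at the same rate as arm deletion.
        return self.deletion_cutoff


@dataclass
class CutoffSet:
    """Per-chromosome cutoffs with provenance.

    The defaults are the published clinical values: 55/20 for 1p and
    19q, 30/40 for 9p and 25/55 for 10q (deletion/imbalance, percent of
    analyzable nuclei); the 9p and 10q values were derived on
    non-neoplastic brain by the mean + 3 SD rule.
    """

    per_chrom: dict[str, ChromCutoffs]
    source: str = "published"

    def __getitem__(self, chrom_id: str) -> ChromCutoffs:
        return self.per_chrom[chrom_id]

    @classmethod
    def published_defaults(cls) -> "CutoffSet":
        return cls(
            per_chrom={
                "chr1": ChromCutoffs(55.0, 20.0),
                "chr19": ChromCutoffs(55.0, 20.0),
                "chr9": ChromCutoffs(30.0, 40.0),
                "chr10": ChromCutoffs(25.0, 55.0),
            },
            source="published",
        )
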