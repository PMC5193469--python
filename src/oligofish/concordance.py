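"""Manual-vs-automated concordance: agreement, Cohen's kappa, exclusions.

Agreement between the manual count (100 nuclei, one observer) and the
automated count is summarized by raw percent agreement and by Cohen's
chance-corrected kappa over the nominal status alphabet
(DELETED / IMBALANCED / NORMAL).  Cases with weak fluorescent signal
can be flagged uninterpretable and excluded before recomputing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
import pandas as pd


def round_half_up(x: float, digits: int = 0) -> float:
    """Round half away from zero, matching clinical-table formatting."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class PairedCalls:
    """Paired manual/automated status vectors with interpretability flags."""

    case_ids: list[str]
    manual: list[str]
    automated: list[str]
    interpretable: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.interpretable:
            self.interpretable = [True] * len(self.manual)
        n = len(self.case_ids)
        if not (len(self.manual) == len(self.automated)
                == len(self.interpretable) == n):
            raise ValueError("paired-call vectors must have equal length")

    def __len__(self) -> int:
        return len(self.case_ids)


def apply_exclusions(p: PairedCalls) -> tuple[PairedCalls, int]:
    """Drop uninterpretable (weak-signal) cases; return (kept, n_excluded)."""
    keep = [i for i, ok in enumerate(p.interpretable) if ok]
    kept = PairedCalls(
        case_ids=[p.case_ids[i] for i in keep],
        manual=[p.manual[i] for i in keep],
        automated=[p.automated[i] for i in keep],
        interpretable=[True] * len(keep),
    )
    return kept, len(p) - len(kept)


def percent_agreement(p: PairedCalls) -> float:
    """Raw agreement in percent (full precision; round for display)."""
    if len(p) == 0:
        raise ValueError("no cases")
    n_agree = sum(m == a for m, a in zip(p.manual, p.automated))
    return 100.0 * n_agree / len(p)


def kappa_band(kappa: float) -> str:
    """Qualitative interpretation band for a kappa value."""
    if kappa > 0.8:
        return "high"
    if kappa > 0.6:
        return "good"
    if kappa > 0.4:
        return "moderate"
    return "poor"


@dataclass
class ConcordanceResult:
    n_used: int
    n_agree: int
    percent_agreement: float
    p_observed: float
    p_expected: float
    kappa: float | None          # None when chance agreement is 1 (degenerate)
    n_excluded: int = 0

    @property
    def band(self) -> str:
        return "undefined" if self.kappa is None else kappa_band(self.kappa)


def confusion_matrix(p: PairedCalls) -> pd.DataFrame:
    """Manual (rows) x automated (columns) count table."""
    labels = sorted(set(p.manual) | set(p.automated))
    mat = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for m, a in zip(p.manual, p.automated):
        mat.loc[m, a] += 1
    return mat


def cohens_kappa(p: PairedCalls) -> ConcordanceResult:
    """Unweighted Cohen's kappa: (po - pe) / (1 - pe).

    pe is the chance agreement implied by the two raters' marginal
    distributions.  When pe = 1 (both raters constant on the same
    single category) kappa is undefined and returned as None rather
    than raising.
    """
    n = len(p)
    if n < 2:
        raise ValueError("kappa needs at least 2 paired calls")
    mat = confusion_matrix(p)
    po = float(np.trace(mat.values)) / n
    pe = float((mat.sum(axis=1).values / n) @ (mat.sum(axis=0).values / n))
    kappa = None if np.isclose(pe, 1.0) else (po - pe) / (1 - pe)
    return ConcordanceResult(
        n_used=n,
        n_agree=int(np.trace(mat.values)),
        percent_agreement=100.0 * po,
        p_observed=po,
        p_expected=pe,
        kappa=kappa,
    )


def concordance_report(p: PairedCalls) -> pd.DataFrame:
    """Concordance before and after weak-signal exclusion, as a table."""
    rows = []
    for label, calls, n_excl in (
        ("all cases", p, 0),
        ("interpretable only", *apply_exclusions(p)),
    ):
        res = cohens_kappa(calls)
        res.n_excluded = n_excl
        rows.append({
            "subset": label,
            "n_used": res.n_used,
            "n_excluded": res.n_excluded,
            "n_agree": res.n_agree,
            "percent_agreement": round_half_up(res.percent_agreement),
            "kappa": None if res.kappa is None else round(res.kappa, 3),
            "band": res.band,
        })
    return pd.DataFrame(rows)
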