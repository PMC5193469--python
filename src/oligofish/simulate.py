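"""Generative models for synthetic FISH data.

A tumor sample is modeled as a mixture of clones, each with fixed true
copy numbers of the target and control arm.  Observation is lossy:
5-um sections truncate nuclei, so every true spot is detected
independently with probability ``p_detect``; a detected spot may be
counted twice (split signal) with probability ``p_split``; and each
channel picks up a Poisson number of spurious background spots.  This
is the statistical structure the cutoff rules assume, and the basis of
all recovery tests: defaults that pass here say nothing about optical
artifacts the model does not represent (see docs/methods.md).

The module also generates non-neoplastic control series for cutoff
calibration, whole cohorts with group-specific karyotype profiles and
exponential survival, and paired manual/automated call vectors for
concordance testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .caller import ArmStatus, NucleusCount, SampleSummary, summarize_sample
from .chromosomes import CHROM_PAIRS, TARGET_ARM


@dataclass(frozen=True)
class Clone:
    """One clonal population: true copy numbers and its cell fraction."""

    copies_target: int
    copies_control: int
    fraction: float

    def __post_init__(self) -> None:
        if self.copies_target < 0 or self.copies_control < 0:
            raise ValueError("copy numbers must be >= 0")
        if not 0 <= self.fraction <= 1:
            raise ValueError("clone fraction must be in [0, 1]")


#: Canonical clone mixtures used to simulate each true arm state.  The
#: dominant-clone fraction of 0.85 reflects the near-clonal whole-arm
#: losses the assay is designed for.
TRUE_STATE_CLONES: dict[str, list[Clone]] = {
    "NORMAL": [Clone(2, 2, 1.0)],
    "DELETED": [Clone(1, 2, 0.85), Clone(2, 2, 0.15)],
    "IMBALANCED": [Clone(3, 3, 0.8), Clone(2, 2, 0.2)],
    "MONOSOMY": [Clone(1, 1, 0.85), Clone(2, 2, 0.15)],
}


@dataclass(frozen=True)
class DetectionModel:
    """Per-spot lossy observation model.

    Parameters
    ----------
    p_detect : float
        Probability a true spot is seen at all (dominated by nuclear
        truncation in thin sections).
    lambda_background : float
        Mean number of spurious spots per channel per nucleus.
    p_split : float
        Probability a detected spot is counted twice.
    """

    p_detect: float = 0.94
    lambda_background: float = 0.02
    p_split: float = 0.02

    def __post_init__(self) -> None:
        if not 0 < self.p_detect <= 1:
            raise ValueError("p_detect must be in (0, 1]")
        if self.lambda_background < 0 or self.p_split < 0 or self.p_split > 1:
            raise ValueError("invalid noise parameters")


def _observe_channel(
    rng: np.random.Generator, true_copies: np.ndarray, model: DetectionModel
) -> np.ndarray:
    """Observed spot count per nucleus for one fluorescence channel."""
    detected = rng.binomial(true_copies, model.p_detect)
    split = rng.binomial(detected, model.p_split)
    background = rng.poisson(model.lambda_background, size=true_copies.shape)
    return detected + split + background


def simulate_nuclei(
    clones: Sequence[Clone],
    model: DetectionModel,
    n: int,
    rng: np.random.Generator | int | None = None,
) -> list[NucleusCount]:
    """Draw ``n`` nucleus counts from a clone mixture under the model."""
    if n < 1:
        raise ValueError("n must be >= 1")
    fractions = np.array([c.fraction for c in clones], dtype=float)
    if not np.isclose(fractions.sum(), 1.0):
        raise ValueError(f"clone fractions sum to {fractions.sum()}, expected 1")
    rng = np.random.default_rng(rng)
    idx = rng.choice(len(clones), size=n, p=fractions)
    true_red = np.array([clones[i].copies_target for i in idx])
    true_green = np.array([clones[i].copies_control for i in idx])
    obs_red = _observe_channel(rng, true_red, model)
    obs_green = _observe_channel(rng, true_green, model)
    return [
        NucleusCount(f"n{k:05d}", int(r), int(g))
        for k, (r, g) in enumerate(zip(obs_red, obs_green))
    ]


def nuclei_for_state(
    true_state: str,
    model: DetectionModel,
    n: int,
    rng: np.random.Generator | int | None = None,
) -> list[NucleusCount]:
    """Simulate counts for a named true arm state (see TRUE_STATE_CLONES)."""
    return simulate_nuclei(TRUE_STATE_CLONES[true_state], model, n, rng)


# ---------------------------------------------------------------------------
# Non-neoplastic control series for cutoff calibration
# ---------------------------------------------------------------------------

#: Control-tissue detection assumptions per probe pair.  The 9p/9q probe
#: set is noisier than the 10q/10p one; means and between-sample jitter
#: were chosen so that the mean + 3 SD calibration lands near the
#: published 30% (9p) and 25% (10q) deletion cutoffs.  The source study
#: states no noise parameters: these are model assumptions.
CONTROL_DETECTION: dict[str, tuple[float, float]] = {
    "chr9": (0.910, 0.006),
    "chr10": (0.933, 0.008),
    "chr1": (0.933, 0.008),
    "chr19": (0.933, 0.008),
}


def simulate_normal_controls(
    chrom_id: str,
    n_samples: int = 5,
    n_nuclei: int = 100,
    rng: np.random.Generator | int | None = None,
    lambda_background: float = 0.02,
) -> list[SampleSummary]:
    """Simulate pure-diploid control samples for one probe pair.

    Each control sample gets its own detection efficiency (hybridization
    quality varies between blocks), drawn from the per-chromosome
    defaults in :data:`CONTROL_DETECTION`; 100 nuclei per sample mirrors
    a manual count.  Feeds :func:`oligofish.caller.calibrate_cutoffs`.
    """
    if n_samples < 2:
        raise ValueError("need >= 2 control samples")
    rng = np.random.default_rng(rng)
    p0, jitter = CONTROL_DETECTION[chrom_id]
    chrom = CHROM_PAIRS[chrom_id]
    out = []
    for _ in range(n_samples):
        p = float(np.clip(rng.normal(p0, jitter), 0.5, 1.0))
        model = DetectionModel(p, lambda_background, 0.02)
        nuclei = simulate_nuclei([Clone(2, 2, 1.0)], model, n_nuclei, rng)
        out.append(summarize_sample(chrom, nuclei))
    return out


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------

@dataclass
class GroupProfile:
    """Generative profile of one diagnostic group.

    ``arm_states`` maps chromosome id to a distribution over true
    states (NORMAL / DELETED / IMBALANCED / MONOSOMY); marker
    probabilities drive the IHC fields; survival is exponential with
    ``hazard_per_month``, independently censored so that a fraction
    ``censor_rate`` of cases is expected alive at analysis.
    """

    label: str
    arm_states: dict[str, dict[str, float]]
    p_idh_mutant: float
    p_atrx_lost: float
    p_ina_positive: float
    p_glomeruloid_mvp: float
    p_calcifications: float
    mitoses_mean: float
    hazard_per_month: float
    censor_rate: float

    def __post_init__(self) -> None:
        for chrom_id, dist in self.arm_states.items():
            s = sum(dist.values())
            if not np.isclose(s, 1.0):
                raise ValueError(f"{self.label}/{chrom_id}: state probs sum to {s}")


def default_group_profiles() -> dict[str, GroupProfile]:
    """Profiles whose expected frequencies match the published cohort.

    State probabilities are the observed per-group proportions of the
    33-case series (e.g. 9p deletion in 7/10 OIII and 4/4 GBM, 1p/19q
    codeletion in all oligodendrogliomas); hazards are 1/mean-OS per
    group and censor rates the per-group alive fractions.
    """
    return {
        "OII": GroupProfile(
            "OII",
            arm_states={
                "chr1": {"DELETED": 1.0},
                "chr19": {"DELETED": 1.0},
                "chr9": {"NORMAL": 11 / 13, "IMBALANCED": 2 / 13},
                "chr10": {"NORMAL": 11 / 13, "IMBALANCED": 2 / 13},
            },
            p_idh_mutant=1.0,
            p_atrx_lost=0.0,
            p_ina_positive=11 / 13,
            p_glomeruloid_mvp=0.0,
            p_calcifications=5 / 13,
            mitoses_mean=1.7,
            hazard_per_month=1 / 108,
            censor_rate=4 / 13,
        ),
        "OIII": GroupProfile(
            "OIII",
            arm_states={
                "chr1": {"DELETED": 1.0},
                "chr19": {"DELETED": 1.0},
                "chr9": {"DELETED": 0.5, "MONOSOMY": 0.2, "NORMAL": 0.2,
                         "IMBALANCED": 0.1},
                "chr10": {"NORMAL": 0.9, "IMBALANCED": 0.1},
            },
            p_idh_mutant=1.0,
            p_atrx_lost=0.0,
            p_ina_positive=0.8,
            p_glomeruloid_mvp=1.0,
            p_calcifications=0.5,
            mitoses_mean=7.0,
            hazard_per_month=1 / 86,
            censor_rate=0.2,
        ),
        "AII": GroupProfile(
            "AII",
            arm_states={
                "chr1": {"DELETED": 1 / 3, "IMBALANCED": 2 / 3},
                "chr19": {"IMBALANCED": 1.0},
                "chr9": {"NORMAL": 2 / 3, "IMBALANCED": 1 / 3},
                "chr10": {"NORMAL": 2 / 3, "IMBALANCED": 1 / 3},
            },
            p_idh_mutant=1.0,
            p_atrx_lost=1 / 3,
            p_ina_positive=0.0,
            p_glomeruloid_mvp=0.0,
            p_calcifications=0.0,
            mitoses_mean=0.0,
            hazard_per_month=1 / 156,
            censor_rate=1 / 3,
        ),
        "AIII": GroupProfile(
            "AIII",
            arm_states={
                "chr1": {"DELETED": 1 / 3, "NORMAL": 1 / 3, "IMBALANCED": 1 / 3},
                "chr19": {"NORMAL": 2 / 3, "IMBALANCED": 1 / 3},
                "chr9": {"NORMAL": 2 / 3, "IMBALANCED": 1 / 3},
                "chr10": {"NORMAL": 1.0},
            },
            p_idh_mutant=1.0,
            p_atrx_lost=2 / 3,
            p_ina_positive=0.0,
            p_glomeruloid_mvp=0.0,
            p_calcifications=2 / 3,
            mitoses_mean=3.7,
            hazard_per_month=1 / 81,
            censor_rate=0.0,
        ),
        "GBM": GroupProfile(
            "GBM",
            arm_states={
                "chr1": {"DELETED": 0.25, "NORMAL": 0.5, "IMBALANCED": 0.25},
                "chr19": {"NORMAL": 0.75, "IMBALANCED": 0.25},
                "chr9": {"DELETED": 1.0},
                "chr10": {"DELETED": 0.5, "NORMAL": 0.5},
            },
            p_idh_mutant=0.25,
            p_atrx_lost=0.25,
            p_ina_positive=0.25,
            p_glomeruloid_mvp=1.0,
            p_calcifications=0.0,
            mitoses_mean=4.3,
            hazard_per_month=1 / 19,
            censor_rate=0.0,
        ),
    }


@dataclass
class SimulatedCase:
    """One synthetic case: truth, nucleus counts, features, survival."""

    case_id: str
    group: str
    true_states: dict[str, str]            # chromosome id -> true arm state
    nuclei: dict[str, list[NucleusCount]]  # chromosome id -> counts
    features: dict[str, object]            # IHC / histology fields
    time_months: float
    event: bool


def simulate_cohort(
    profiles: dict[str, GroupProfile],
    sizes: dict[str, int],
    seed: int | np.random.Generator | None = None,
    detection: DetectionModel | None = None,
    n_nuclei_range: tuple[int, int] = (81, 1453),
) -> list[SimulatedCase]:
    """Generate a cohort of cases with counts, features and survival.

    Nuclei per case per chromosome are uniform over ``n_nuclei_range``
    (the observed range of the automated assay).  Survival times are
    exponential with the group hazard; censoring is an independent
    exponential whose rate is set so the expected censored fraction
    equals the group ``censor_rate``.
    """
    if not profiles:
        raise ValueError("no group profiles supplied")
    rng = np.random.default_rng(seed)
    detection = detection or DetectionModel()
    cases: list[SimulatedCase] = []
    k = 0
    for group, n_cases in sizes.items():
        if n_cases < 1:
            raise ValueError(f"{group}: size must be positive")
        prof = profiles[group]
        for _ in range(n_cases):
            k += 1
            true_states, nuclei = {}, {}
            for chrom_id, dist in prof.arm_states.items():
                states = sorted(dist)
                state = str(rng.choice(states, p=[dist[s] for s in states]))
                true_states[chrom_id] = state
                n = int(rng.integers(n_nuclei_range[0], n_nuclei_range[1] + 1))
                nuclei[chrom_id] = nuclei_for_state(state, detection, n, rng)
            features = {
                "idh_mutant": bool(rng.random() < prof.p_idh_mutant),
                "atrx_lost": bool(rng.random() < prof.p_atrx_lost),
                "ina_positive": bool(rng.random() < prof.p_ina_positive),
                "mvp": "glomeruloid" if rng.random() < prof.p_glomeruloid_mvp
                       else "endocrinoid",
                "calcifications": bool(rng.random() < prof.p_calcifications),
                "mitoses_per_10hpf": int(rng.poisson(prof.mitoses_mean)),
            }
            t_event = (rng.exponential(1 / prof.hazard_per_month)
                       if prof.hazard_per_month > 0 else np.inf)
            c = prof.censor_rate
            if c > 0 and prof.hazard_per_month > 0:
                censor_rate = prof.hazard_per_month * c / (1 - c)
                t_censor = rng.exponential(1 / censor_rate)
            else:
                t_censor = np.inf
            time = float(min(t_event, t_censor))
            if not np.isfinite(time):  # hazard 0 and no censoring process
                time, event = 240.0, False
            else:
                event = t_event <= t_censor
            cases.append(SimulatedCase(
                case_id=f"S{k:04d}", group=group, true_states=true_states,
                nuclei=nuclei, features=features,
                time_months=max(time, 0.1), event=bool(event),
            ))
    return cases


def simulate_survival(
    hazard_per_month: float,
    censor_rate: float,
    n: int,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times with independent exponential censoring.

    Returns (time, event) arrays; P(censored) = ``censor_rate`` exactly
    under the exponential-exponential model.  With hazard 0 all records
    are censored at an administrative horizon.
    """
    rng = np.random.default_rng(rng)
    if hazard_per_month <= 0:
        return np.full(n, 240.0), np.zeros(n, dtype=bool)
    t_event = rng.exponential(1 / hazard_per_month, size=n)
    if censor_rate > 0:
        rate = hazard_per_month * censor_rate / (1 - censor_rate)
        t_cens = rng.exponential(1 / rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    return time, t_event <= t_cens


def simulate_paired_calls(
    truth: Sequence[str],
    confusion: dict[str, dict[str, float]],
    rng: np.random.Generator | int | None = None,
) -> tuple[list[str], list[str]]:
    """Manual/automated call pairs: manual = truth, automated per row.

    ``confusion[s]`` is the distribution of the automated call given
    true status ``s``; rows must sum to 1.
    """
    rng = np.random.default_rng(rng)
    automated = []
    for s in truth:
        row = confusion[s]
        labels = sorted(row)
        probs = np.array([row[l] for l in labels], dtype=float)
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError(f"confusion row for {s!r} sums to {probs.sum()}")
        automated.append(str(rng.choice(labels, p=probs)))
    return list(truth), automated
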