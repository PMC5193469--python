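"""Simulation-based validation of the statistical machinery.

The source cohort's patient-level survival data are unpublished, so
the survival stack is validated against known generative truth
instead: log-rank type-I error under the null, Cox confidence-interval
coverage at a known hazard ratio, and recovery of true arm states by
the caller from simulated counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .caller import ArmStatus, call_arm_status, summarize_sample
from .chromosomes import CHR1, CutoffSet
from .cohort_stats import cox_fit, logrank_test
from .simulate import Clone, DetectionModel, simulate_nuclei, simulate_survival


def recovery_rates(
    n_reps: int = 200,
    n_nuclei: int = 500,
    p_detect: float = 0.9,
    deleted_fraction: float = 0.8,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Fraction of simulated tumors called DELETED / diploids called NORMAL.

    Simulates a 1p-deleted tumor (deleted clone at ``deleted_fraction``,
    remainder diploid) and a pure diploid sample per replicate, calls
    both with the published cutoffs, and reports the two success rates.
    """
    rng = np.random.default_rng(rng)
    model = DetectionModel(p_detect=p_detect)
    cutoffs = CutoffSet.published_defaults()
    deleted_mix = [Clone(1, 2, deleted_fraction),
                   Clone(2, 2, 1 - deleted_fraction)]
    n_del = n_norm = 0
    for _ in range(n_reps):
        tumor = simulate_nuclei(deleted_mix, model, n_nuclei, rng)
        call = call_arm_status(summarize_sample(CHR1, tumor), cutoffs, CHR1)
        n_del += call.target_status is ArmStatus.DELETED
        diploid = simulate_nuclei([Clone(2, 2, 1.0)], model, n_nuclei, rng)
        call = call_arm_status(summarize_sample(CHR1, diploid), cutoffs, CHR1)
        n_norm += call.target_status is ArmStatus.NORMAL
    return n_del / n_reps, n_norm / n_reps


def logrank_type1_error(
    n_reps: int = 2000,
    n_per_group: int = 40,
    hazard: float = 0.02,
    censor_rate: float = 0.2,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Rejection rate at alpha = 0.05 for two identical exponential groups."""
    rng = np.random.default_rng(rng)
    labels = np.r_[np.zeros(n_per_group), np.ones(n_per_group)]
    rejections = 0
    for _ in range(n_reps):
        t1, e1 = simulate_survival(hazard, censor_rate, n_per_group, rng)
        t2, e2 = simulate_survival(hazard, censor_rate, n_per_group, rng)
        _, p = logrank_test(np.r_[t1, t2], np.r_[e1, e2], labels)
        rejections += p < 0.05
    return rejections / n_reps


def cox_ci_coverage(
    n_reps: int = 200,
    hr: float = 2.0,
    n: int = 500,
    base_hazard: float = 0.02,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Fraction of Cox 95% CIs covering a true binary-covariate HR."""
    rng = np.random.default_rng(rng)
    covered = n_done = 0
    for _ in range(n_reps):
        x = rng.integers(0, 2, size=n)
        t = np.where(x == 1,
                     rng.exponential(1 / (base_hazard * hr), size=n),
                     rng.exponential(1 / base_hazard, size=n))
        cens = rng.exponential(1 / (0.25 * base_hazard), size=n)
        df = pd.DataFrame({
            "time_months": np.minimum(t, cens),
            "event": (t <= cens).astype(float),
            "x": x.astype(float),
        })
        res = cox_fit(df, ["x"])
        if res.converged:
            n_done += 1
            covered += bool(res.ci_lower["x"] <= hr <= res.ci_upper["x"])
    return covered / max(n_done, 1)
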