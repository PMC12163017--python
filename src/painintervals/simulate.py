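"""Seeded synthetic-cohort generator for the proof-of-concept study design.

The generator emulates an idealized before/after cohort on the 0-10
numerical pain scale: every patient reports an uncertainty interval of
the same fixed width (3 NPS units by default) centred on a latent pain
midpoint.  Pre-intervention midpoints are Normal(6.2, 1.5); each patient
then improves by a Normal(true_ate, effect_sd) amount, with the default
effect_sd of 0 giving a constant individual effect of -2 units — the
simplest structure consistent with identical pre and post dispersions.
Midpoints are clipped so that the full interval fits on the scale,
preserving the fixed interval width rather than truncating intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort_io import Cohort, PainInterval, PatientRecord

__all__ = ["SimulationConfig", "simulate_cohort", "sample_ate", "recenter_cohort"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort generator (NPS units throughout)."""

    n_patients: int = 50
    true_ate: float = -2.0
    interval_width: float = 3.0
    pre_mean: float = 6.2
    pre_sd: float = 1.5
    effect_sd: float = 0.0
    scale_min: float = 0.0
    scale_max: float = 10.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError(f"n_patients must be >= 1, got {self.n_patients}")
        if self.interval_width < 0:
            raise ValueError(f"interval_width must be >= 0, got {self.interval_width}")
        if self.pre_sd < 0 or self.effect_sd < 0:
            raise ValueError("pre_sd and effect_sd must be >= 0")
        if self.scale_min >= self.scale_max:
            raise ValueError(
                f"scale_min ({self.scale_min}) must be < scale_max ({self.scale_max})"
            )
        if self.interval_width > self.scale_max - self.scale_min:
            raise ValueError(
                f"interval_width {self.interval_width} exceeds the scale range "
                f"{self.scale_max - self.scale_min}"
            )


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate a cohort from the config; deterministic given its seed."""
    rng = np.random.default_rng(config.seed)
    half = config.interval_width / 2.0
    lo, hi = config.scale_min + half, config.scale_max - half
    pre_mid = rng.normal(config.pre_mean, config.pre_sd, size=config.n_patients)
    effect = rng.normal(config.true_ate, config.effect_sd, size=config.n_patients)
    pre_mid = np.clip(pre_mid, lo, hi)
    post_mid = np.clip(pre_mid + effect, lo, hi)
    width = len(str(config.n_patients))
    records = tuple(
        PatientRecord(
            patient_id=f"P{i + 1:0{width}d}",
            pre=PainInterval(m_pre - half, m_pre + half),
            post=PainInterval(m_post - half, m_post + half),
        )
        for i, (m_pre, m_post) in enumerate(zip(pre_mid, post_mid))
    )
    return Cohort(records, scale_min=config.scale_min, scale_max=config.scale_max)


def sample_ate(cohort: Cohort) -> float:
    """The cohort's sample ATE: mean of midpoint(post) - midpoint(pre).

    This is the quantity the bootstrap estimator targets; it differs
    from the generator's population ATE by ordinary sampling error.
    """
    return float(np.mean(cohort.post_midpoints - cohort.pre_midpoints))


def recenter_cohort(cohort: Cohort, target_sample_ate: float) -> Cohort:
    """Translate every post-interval by a constant so the sample ATE is exact.

    Only post-intervals move, preserving the pre-intensity calibration;
    widths are unchanged.  Raises if the shift would push any bound off
    the scale.
    """
    shift = target_sample_ate - sample_ate(cohort)
    records = []
    for rec in cohort.records:
        new_post = PainInterval(rec.post.lower + shift, rec.post.upper + shift)
        records.append(PatientRecord(rec.patient_id, rec.pre, new_post))
    try:
        return Cohort(tuple(records), cohort.scale_min, cohort.scale_max)
    except ValueError as exc:
        raise ValueError(
            f"recentring shift {shift:+.6g} pushes a post-interval outside "
            f"[{cohort.scale_min}, {cohort.scale_max}]: {exc}"
        ) from exc
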