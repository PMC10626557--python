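"""Synthetic chilling-injury datasets with planted severity labels.

No raw measurements from the cucumber chilling study are deposited, so the
pipeline is exercised on generated data that reproduces the statistical
structure the analysis assumes:

* Base-signal generation.  Records are drawn in *base-signal space* (Fo,
  Fm, F, Fm', Fo'), never in derived-parameter space, so every definitional
  identity (Fv = Fm − Fo, Y(II)+Y(NPQ)+Y(NO) = 1, ...) holds by
  construction and the 15-parameter matrix inherits the strong
  inter-parameter correlation that shared base signals induce.

* Class-effect profile.  Each (temperature, day) cell carries a target
  dark-adapted yield Fv/Fm and a severity tier 0–3.  Day 0 sits at the
  unstressed plateau (~0.84); severity deepens with colder temperature and
  longer exposure — at 8 °C the yield collapses toward ~0.1 by day 5 while
  at 14 °C it only sinks toward ~0.6.  Severity raises Fo and F relative
  to Fm and lowers Fm and Fm', matching the observed directional trends.

* Validation assays.  MDA content per class scales as
  (1, 1.1907, 1.2814, 1.6724) × baseline, and rapid-light-curve yields
  scale per class so that at every PAR step Y(I) and Y(CEF) fall and
  Y(ND) rises with severity, with the planted zero-noise percent changes
  at PAR 419 matching the reference effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chlf import ChlFRecord, MDASample, RLCRecord, PAR_GRADIENT, derive_rlc
from .errors import DomainError

__all__ = [
    "SyntheticConfig",
    "generate_chlf_dataset",
    "generate_mda_dataset",
    "generate_rlc_dataset",
    "default_class_profile",
    "TIER_FVFM_ANCHORS",
    "MDA_CLASS_RATIOS",
    "RLC_CLASS_SCALES",
]

#: Target mean Fv/Fm anchor of each severity tier (unstressed → severe).
TIER_FVFM_ANCHORS = (0.84, 0.65, 0.45, 0.15)

#: Expected MDA content per class relative to the unstressed baseline
#: (slight +19.07%, moderate +28.14%, severe +67.24%).
MDA_CLASS_RATIOS = (1.0, 1.1907, 1.2814, 1.6724)

#: Per-class multiplicative scales of the RLC yield curves (class 0 = 1).
#: Y(I) decreases 34.350/52.413/73.403%, Y(ND) increases
#: 68.071/103.351/114.266%, and the baseline Y(I)−Y(II) gap shrinks so
#: Y(CEF) decreases 30.396/48.467/56.246% — uniformly over PAR, so the
#: planted percent changes hold at every light level.
RLC_CLASS_SCALES = {
    "Y_I": (1.0, 1.0 - 0.34350, 1.0 - 0.52413, 1.0 - 0.73403),
    "Y_ND": (1.0, 1.0 + 0.68071, 1.0 + 1.03351, 1.0 + 1.14266),
    "gap": (1.0, 1.0 - 0.30396, 1.0 - 0.48467, 1.0 - 0.56246),
}

#: Severity tier of each (temperature, day) cell for days 1–5 (day 0 is
#: tier 0 everywhere): colder/longer exposure → deeper injury; 8 °C turns
#: severe from day 2, 14 °C stays slight until day 4.
_DEFAULT_TIERS: dict[int, tuple[int, int, int, int, int]] = {
    8: (1, 3, 3, 3, 3),
    10: (1, 2, 2, 3, 3),
    12: (1, 2, 2, 2, 2),
    14: (1, 1, 1, 2, 2),
}

#: Day-5 endpoint of the smooth per-temperature Fv/Fm trajectory.
_DAY5_FVFM = {8: 0.10, 10: 0.35, 12: 0.52, 14: 0.62}

_UNSTRESSED_FVFM = 0.84


def default_class_profile(
    temperatures: tuple[int, ...],
    days: tuple[int, ...],
) -> dict[tuple[int, int], tuple[float, int]]:
    """Target mean Fv/Fm and severity tier per (temperature, day) cell.

    The cell target blends the tier anchor (weight 0.7) with a monotone
    linear temperature/day trajectory from 0.84 down to the per-
    temperature day-5 endpoint (weight 0.3), so cells of one tier cluster
    tightly around the anchor while still ordering by temperature and day
    within the tier.
    """
    profile: dict[tuple[int, int], tuple[float, int]] = {}
    for T in temperatures:
        if T not in _DEFAULT_TIERS:
            raise DomainError(f"no default severity profile for {T} °C")
        for d in days:
            if d == 0:
                tier = 0
                raw = _UNSTRESSED_FVFM
            else:
                tier = _DEFAULT_TIERS[T][min(d, 5) - 1]
                raw = _UNSTRESSED_FVFM + (_DAY5_FVFM[T] - _UNSTRESSED_FVFM) * (min(d, 5) / 5.0)
            target = 0.7 * TIER_FVFM_ANCHORS[tier] + 0.3 * raw
            profile[(T, d)] = (target, tier)
    return profile


@dataclass
class SyntheticConfig:
    """Study-condition defaults: 4 chilling temperatures × days 0–5 with 8
    plants per group (the induction-curve sample size), 5% relative
    measurement noise."""

    temperatures: tuple[int, ...] = (8, 10, 12, 14)
    days: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    plants_per_group: int = 8
    noise_scale: float = 0.05
    seed: int = 0
    class_effect_profile: dict[tuple[int, int], tuple[float, int]] | None = None

    def __post_init__(self) -> None:
        if self.noise_scale < 0:
            raise DomainError("noise_scale must be >= 0")
        if self.plants_per_group < 1:
            raise DomainError("plants_per_group must be >= 1")
        if self.class_effect_profile is None:
            self.class_effect_profile = default_class_profile(
                self.temperatures, self.days
            )
        for (T, d), (v, tier) in self.class_effect_profile.items():
            if not 0.0 < v < 1.0:
                raise DomainError(f"profile Fv/Fm target at ({T},{d}) outside (0,1): {v}")


def _severity_fraction(target_fvfm: float) -> float:
    """0 at the unstressed plateau, 1 at full collapse of Fv/Fm."""
    return float(np.clip((_UNSTRESSED_FVFM - target_fvfm) / (_UNSTRESSED_FVFM - 0.10), 0.0, 1.0))


def _draw_record(
    plant_id: str, T: float, d: int, target_fvfm: float,
    noise: float, rng: np.random.Generator,
) -> ChlFRecord:
    """Draw one record's base signals from the latent severity state.

    Latents: dark yield v = Fv/Fm, minimum fluorescence Fo (rises mildly
    with severity), light-adapted Y(NO) and Y(II) (dissipation up,
    photochemistry down).  Signals follow deterministically:
    Fm = Fo/(1−v), F = Y(NO)·Fm, Fm' = F/(1−Y(II)), Fo' below both Fo and
    F.  Gaussian noise on the latents (truncated resampling keeps
    invariants: signals > 0, Fm/Fo ∈ [1.05, 10], Fo' < F < Fm').
    """
    s = _severity_fraction(target_fvfm)
    for _ in range(100):
        v = target_fvfm + rng.normal(0.0, 0.3 * noise)
        Fo = (330.0 + 30.0 * s) * (1.0 + rng.normal(0.0, noise))
        y_no = (0.60 + 0.25 * s) * (1.0 + rng.normal(0.0, 0.4 * noise))
        y_ii = (0.10 - 0.09 * s) * (1.0 + rng.normal(0.0, 0.4 * noise))
        fop_frac = (0.92 - 0.05 * s) * (1.0 + rng.normal(0.0, 0.2 * noise))
        if not (0.02 <= v <= 0.92):
            continue
        if Fo <= 0 or not (0.05 <= y_no <= 0.95) or not (0.0 < y_ii <= 0.5):
            continue
        Fm = Fo / (1.0 - v)
        if not (1.05 <= Fm / Fo <= 10.0):
            continue
        F = y_no * Fm
        Fm_prime = F / (1.0 - y_ii)
        Fo_prime = fop_frac * min(Fo, F)
        if not (0 < Fo_prime < F < Fm_prime):
            continue
        if Fm_prime - Fo_prime <= 0 or Fm <= Fo:
            continue
        return ChlFRecord(
            plant_id=plant_id, temperature_C=float(T), day=int(d),
            Fo=Fo, Fm=Fm, F=F, Fm_prime=Fm_prime, Fo_prime=Fo_prime,
        )
    raise DomainError(
        f"could not draw a valid record at ({T} °C, day {d}) in 100 attempts; "
        "profile or noise settings are degenerate"
    )


def generate_chlf_dataset(
    config: SyntheticConfig | None = None,
) -> tuple[list[ChlFRecord], pd.DataFrame]:
    """Generate base-signal records plus a planted-label table.

    Returns the records and a DataFrame (plant_id, temperature_C, day,
    planted_class) aligned row-for-row.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    records: list[ChlFRecord] = []
    labels: list[dict] = []
    for T in config.temperatures:
        for d in config.days:
            target, tier = config.class_effect_profile[(T, d)]
            for p in range(config.plants_per_group):
                pid = f"T{T}_d{d}_p{p + 1}"
                rec = _draw_record(pid, T, d, target, config.noise_scale, rng)
                records.append(rec)
                labels.append(
                    {"plant_id": pid, "temperature_C": float(T), "day": int(d),
                     "planted_class": tier}
                )
    return records, pd.DataFrame(labels)


def generate_mda_dataset(
    labels: np.ndarray,
    seed: int = 0,
    baseline_C: float = 12.0,
    noise_scale: float = 0.05,
) -> list[MDASample]:
    """TBA-assay absorbance samples whose expected MDA content scales per
    class as :data:`MDA_CLASS_RATIOS` × ``baseline_C`` (nmol·g⁻¹).

    The assay protocol fixes extract volume N = 5 ml and fresh mass
    W = 0.5 g; background absorbances are held at plausible constants and
    D532 is solved from the target content, so zero noise reproduces the
    class ratios exactly.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size and (labels.min() < 0 or labels.max() > 3):
        raise DomainError("labels must lie in {0,1,2,3}")
    rng = np.random.default_rng(seed)
    N, W = 5.0, 0.5
    D450, D510, D560 = 0.08, 0.25, 0.05
    samples = []
    for cls in labels:
        target = baseline_C * MDA_CLASS_RATIOS[cls] * (1.0 + rng.normal(0.0, noise_scale))
        # invert C = {6.45[D532 − (D510−D560)/2] − 0.56 D450}·N/W for D532
        core = target * W / N
        d532 = (core + 0.56 * D450) / 6.45 + (D510 - D560) / 2.0
        samples.append(MDASample(D450=D450, D510=D510, D532=d532, D560=D560, N=N, W=W))
    return samples


def _baseline_rlc_curves(par: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unstressed Y(I), Y(II), Y(ND) over the PAR gradient: saturating
    decline of the photochemical yields, saturating rise of the donor-side
    limitation (kept ≤ 0.45 so the severe-class scaling stays below 1)."""
    y_i = 0.95 / (1.0 + par / 600.0)
    y_ii = 0.55 * y_i
    y_nd = 0.45 * par / (par + 600.0)
    return y_i, y_ii, y_nd


def generate_rlc_dataset(
    labels: np.ndarray,
    seed: int = 0,
    noise_scale: float = 0.05,
    par_gradient: tuple[float, ...] = PAR_GRADIENT,
) -> list[RLCRecord]:
    """Rapid-light-curve records (one per plant × PAR step) with
    class-scaled yields; ETR(I)/ETR(II)/Y(CEF) are filled via the
    closed-form definitions.

    Class c scales the baseline Y(I) and Y(ND) curves, and the
    Y(I)−Y(II) gap, by :data:`RLC_CLASS_SCALES`; the multiplicative form
    makes the planted percent changes exact at every PAR step when
    ``noise_scale`` is zero.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size and (labels.min() < 0 or labels.max() > 3):
        raise DomainError("labels must lie in {0,1,2,3}")
    rng = np.random.default_rng(seed)
    par = np.asarray(par_gradient, dtype=float)
    y_i0, y_ii0, y_nd0 = _baseline_rlc_curves(par)
    gap0 = y_i0 - y_ii0
    records = []
    for plant_idx, cls in enumerate(labels):
        jitter = 1.0 + rng.normal(0.0, noise_scale)
        y_i = y_i0 * RLC_CLASS_SCALES["Y_I"][cls] * jitter
        gap = gap0 * RLC_CLASS_SCALES["gap"][cls] * jitter
        y_ii = np.clip(y_i - gap, 0.0, None)
        y_nd = np.clip(y_nd0 * RLC_CLASS_SCALES["Y_ND"][cls] * jitter, 0.0, 1.0)
        for k, p in enumerate(par):
            rec = RLCRecord(
                plant_id=f"c{cls}_p{plant_idx + 1}", PAR=float(p),
                Y_II=float(y_ii[k]), Y_I=float(y_i[k]), Y_ND=float(y_nd[k]),
            )
            records.append(derive_rlc(rec))
    return records
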