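"""Core PAM chlorophyll-fluorescence types and closed-form parameter math.

A dark-adapted induction protocol yields five base signals per plant —
minimum and maximum dark-adapted fluorescence (Fo, Fm), the light-adapted
steady state (F) and the light-adapted extrema (Fm', Fo') — from which all
fifteen standard quenching-analysis parameters follow in closed form:
Fv, Fv/Fm, Fv/Fo, Y(II), Y(NO), Y(NPQ), NPQ, qP, qL and qN.

PSI measurements along a rapid light curve (RLC) add the P700 yields Y(I)
and Y(ND), electron transport rates ETR(I)/ETR(II) and the cyclic-electron-
flow proxy Y(CEF) = ETR(I) − ETR(II). Lipid peroxidation is quantified as
malondialdehyde (MDA) content from the thiobarbituric-acid colorimetric
assay.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, SchemaError

__all__ = [
    "ChlFRecord",
    "DerivedChlF",
    "RLCRecord",
    "MDASample",
    "FEATURE_NAMES",
    "BASE_SIGNAL_NAMES",
    "PAR_GRADIENT",
    "ETR_FACTOR",
    "REFERENCE_GROUP_STATS",
    "derive_parameters",
    "derive_rlc",
    "compute_mda",
    "percent_change_vs_reference",
    "records_to_frame",
    "read_chlf_csv",
    "read_rlc_csv",
    "read_mda_csv",
]

#: Canonical order of the 15 induction-curve parameters used as model input.
FEATURE_NAMES: tuple[str, ...] = (
    "Fo", "Fm", "Fv", "F", "Fm_prime", "Fo_prime",
    "Fv_Fm", "Fv_Fo", "Y_II", "Y_NPQ", "Y_NO", "NPQ", "qN", "qP", "qL",
)

BASE_SIGNAL_NAMES: tuple[str, ...] = ("Fo", "Fm", "F", "Fm_prime", "Fo_prime")

#: Stepped actinic-light gradient of the rapid light curves (μmol·m⁻²·s⁻¹).
PAR_GRADIENT: tuple[float, ...] = (0, 8, 34, 92, 170, 270, 419, 609, 921, 1453, 2256)

#: Leaf absorptance (0.84) × PSII/PSI excitation partitioning (0.5) used in
#: ETR = Y × PAR × 0.84 × 0.5.  Fixed constants; no leaf-specific
#: absorptance is resolved.
ETR_FACTOR: float = 0.84 * 0.5

#: Published per-temperature group means and standard deviations of the 15
#: induction-curve parameters for cucumber seedlings pooled over 0–5 days of
#: chilling at 8/10/12/14 °C (n = 48 per group).  Used as calibration
#: anchors for the synthetic generator and for linear-identity consistency
#: checks (Fv = Fm − Fo and Y(NPQ) = 1 − Y(II) − Y(NO) hold for group means
#: because those maps are linear in the underlying parameters).
REFERENCE_GROUP_STATS: dict[str, dict[int, tuple[float, float]]] = {
    "F":        {8: (528.6, 206.5), 10: (583.6, 145.4), 12: (668.7, 166.3), 14: (723.2, 169.4)},
    "Fm_prime": {8: (554.6, 237.0), 10: (622.3, 167.9), 12: (739.8, 195.3), 14: (796.8, 201.1)},
    "Y_II":     {8: (0.033, 0.060), 10: (0.058, 0.023), 12: (0.093, 0.025), 14: (0.089, 0.026)},
    "Fo_prime": {8: (361.9, 49.0),  10: (327.0, 14.8),  12: (349.1, 28.9),  14: (337.2, 38.3)},
    "qP":       {8: (0.087, 0.098), 10: (0.129, 0.031), 12: (0.185, 0.045), 14: (0.159, 0.039)},
    "qN":       {8: (0.386, 0.211), 10: (0.446, 0.124), 12: (0.455, 0.102), 14: (0.446, 0.066)},
    "qL":       {8: (0.059, 0.060), 10: (0.076, 0.024), 12: (0.101, 0.034), 14: (0.078, 0.027)},
    "NPQ":      {8: (0.338, 0.531), 10: (0.457, 0.381), 12: (0.475, 0.270), 14: (0.466, 0.174)},
    "Y_NO":     {8: (0.806, 0.223), 10: (0.686, 0.156), 12: (0.634, 0.113), 14: (0.631, 0.082)},
    "Y_NPQ":    {8: (0.161, 0.173), 10: (0.256, 0.137), 12: (0.272, 0.099), 14: (0.281, 0.068)},
    "Fo":       {8: (347.7, 45.0),  10: (322.5, 16.4),  12: (345.3, 24.8),  14: (329.4, 36.6)},
    "Fm":       {8: (805.9, 581.6), 10: (960.1, 518.4), 12: (1115.9, 455.6), 14: (1183.5, 386.3)},
    "Fv_Fm":    {8: (0.361, 0.316), 10: (0.584, 0.161), 12: (0.652, 0.102), 14: (0.694, 0.097)},
    "Fv_Fo":    {8: (1.433, 1.971), 10: (2.015, 1.721), 12: (2.262, 1.414), 14: (2.673, 1.381)},
    "Fv":       {8: (458.1, 599.3), 10: (637.5, 524.5), 12: (770.6, 460.0), 14: (854.1, 398.6)},
}


def _require_positive(name: str, value: float) -> None:
    if not value > 0:
        raise DomainError(f"{name} must be positive, got {value!r}")


@dataclass(frozen=True)
class ChlFRecord:
    """One plant's base induction-curve fluorescence signals plus metadata.

    All signals are instrument arbitrary units (a.u.). ``day`` counts days
    of low-temperature treatment; day 0 is the pre-stress measurement.
    """

    plant_id: str
    temperature_C: float
    day: int
    Fo: float
    Fm: float
    F: float
    Fm_prime: float
    Fo_prime: float

    def __post_init__(self) -> None:
        for name in BASE_SIGNAL_NAMES:
            _require_positive(name, getattr(self, name))
        if self.day < 0:
            raise DomainError(f"day must be >= 0, got {self.day}")
        if not self.Fm > self.Fo:
            raise DomainError(
                f"Fm must exceed Fo (got Fm={self.Fm}, Fo={self.Fo})"
            )
        if self.Fm_prime < self.Fo_prime:
            raise DomainError(
                f"Fm_prime must be >= Fo_prime "
                f"(got Fm_prime={self.Fm_prime}, Fo_prime={self.Fo_prime})"
            )


@dataclass(frozen=True)
class DerivedChlF:
    """The ten derived quenching parameters of one record (Fv in a.u.)."""

    Fv: float
    Fv_Fm: float
    Fv_Fo: float
    Y_II: float
    Y_NO: float
    Y_NPQ: float
    NPQ: float
    qP: float
    qL: float
    qN: float


@dataclass
class RLCRecord:
    """One rapid-light-curve step of one plant.

    Either the raw P700 signals (P, Pm, Pm_prime) or the yields Y_I/Y_ND
    may be supplied; :func:`derive_rlc` fills the derived fields.
    """

    plant_id: str
    PAR: float
    Y_II: float
    P: float | None = None
    Pm: float | None = None
    Pm_prime: float | None = None
    Y_I: float | None = None
    Y_ND: float | None = None
    ETR_I: float | None = None
    ETR_II: float | None = None
    Y_CEF: float | None = None

    def __post_init__(self) -> None:
        if self.PAR < 0:
            raise DomainError(f"PAR must be >= 0, got {self.PAR}")


@dataclass(frozen=True)
class MDASample:
    """One TBA-assay measurement: four absorbances plus extract volume
    ``N`` (ml) and fresh tissue mass ``W`` (g)."""

    D450: float
    D510: float
    D532: float
    D560: float
    N: float
    W: float

    def __post_init__(self) -> None:
        for name in ("D450", "D510", "D532", "D560"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        _require_positive("N", self.N)
        if not self.W > 0:
            raise DomainError(f"W (fresh mass) must be positive, got {self.W}")


def derive_parameters(record: ChlFRecord) -> DerivedChlF:
    """Compute all derived quenching parameters from the base signals.

    Definitions::

        Fv    = Fm − Fo                  Y(II)  = (Fm' − F) / Fm'
        Fv/Fm = (Fm − Fo) / Fm           Y(NO)  = F / Fm
        Fv/Fo = (Fm − Fo) / Fo           Y(NPQ) = 1 − Y(II) − Y(NO)
        NPQ   = (Fm − Fm') / Fm'         qP     = (Fm' − F) / (Fm' − Fo')
        qL    = qP · Fo' / F             qN     = 1 − (Fm' − Fo') / (Fm − Fo)

    Y(NO) is taken literally as F/Fm (the instrument-dialect convention
    under which Y(II) + Y(NPQ) + Y(NO) = 1 holds identically), not the
    alternative lake-model expression.

    Raises :class:`DomainError` naming the offending quantity when a
    denominator vanishes; records with Fm' ≤ Fo' are rejected, not clamped,
    because qP and qN divide by Fm' − Fo'.
    """
    for name in ("Fm", "Fo", "Fm_prime", "F"):
        if getattr(record, name) == 0:
            raise DomainError(f"zero denominator: {name}")
    if record.Fm_prime - record.Fo_prime == 0:
        raise DomainError("zero denominator: Fm_prime - Fo_prime")
    if record.Fm - record.Fo == 0:
        raise DomainError("zero denominator: Fm - Fo")

    Fo, Fm = record.Fo, record.Fm
    F, Fmp, Fop = record.F, record.Fm_prime, record.Fo_prime
    Fv = Fm - Fo
    y_ii = (Fmp - F) / Fmp
    y_no = F / Fm
    qP = (Fmp - F) / (Fmp - Fop)
    return DerivedChlF(
        Fv=Fv,
        Fv_Fm=Fv / Fm,
        Fv_Fo=Fv / Fo,
        Y_II=y_ii,
        Y_NO=y_no,
        Y_NPQ=1.0 - y_ii - y_no,
        NPQ=(Fm - Fmp) / Fmp,
        qP=qP,
        qL=qP * Fop / F,
        qN=1.0 - (Fmp - Fop) / (Fm - Fo),
    )


def derive_rlc(record: RLCRecord) -> RLCRecord:
    """Fill Y(I)/Y(ND) (from raw P700 signals if supplied) and the derived
    ETR(I), ETR(II) and Y(CEF) = ETR(I) − ETR(II) fields in place.

    With raw signals, Y(I) = (Pm' − P)/Pm and Y(ND) = P/Pm.
    """
    if record.P is not None or record.Pm is not None or record.Pm_prime is not None:
        if record.P is None or record.Pm is None or record.Pm_prime is None:
            raise DomainError("raw P700 signals require P, Pm and Pm_prime together")
        if record.Pm <= 0:
            raise DomainError(f"Pm must be positive, got {record.Pm}")
        record.Y_I = (record.Pm_prime - record.P) / record.Pm
        record.Y_ND = record.P / record.Pm
    if record.Y_I is None:
        raise DomainError("Y_I missing: supply Y_I or raw P700 signals")
    record.ETR_I = record.Y_I * record.PAR * ETR_FACTOR
    record.ETR_II = record.Y_II * record.PAR * ETR_FACTOR
    record.Y_CEF = record.ETR_I - record.ETR_II
    return record


def compute_mda(sample: MDASample) -> float:
    """Malondialdehyde content (nmol·g⁻¹) from the TBA colorimetric assay:

        C = {6.45·[D532 − (D510 − D560)/2] − 0.56·D450} · N / W

    Linear in the extract volume N and inversely proportional to fresh
    mass W.
    """
    if sample.W <= 0:
        raise DomainError(f"W (fresh mass) must be positive, got {sample.W}")
    core = 6.45 * (sample.D532 - (sample.D510 - sample.D560) / 2.0) - 0.56 * sample.D450
    return core * sample.N / sample.W


def percent_change_vs_reference(
    values_by_class: Mapping[int, Sequence[float]],
    reference_class: int,
) -> dict[int, float]:
    """Signed percent change of each class mean relative to the reference
    class mean: 100·(mean(class) − mean(ref))/mean(ref)."""
    if reference_class not in values_by_class or len(values_by_class[reference_class]) == 0:
        raise DomainError(f"reference class {reference_class} is empty")
    ref_mean = float(np.mean(values_by_class[reference_class]))
    if ref_mean == 0:
        raise DomainError("reference class mean is zero; percent change undefined")
    return {
        cls: 100.0 * (float(np.mean(vals)) - ref_mean) / ref_mean
        for cls, vals in values_by_class.items()
    }


# ---------------------------------------------------------------------------
# tabular IO

CHLF_COLUMNS = ("plant_id", "temperature_C", "day", "Fo", "Fm", "F", "Fm_prime", "Fo_prime")
META_COLUMNS = ("plant_id", "temperature_C", "day")


def records_to_frame(records: Iterable[ChlFRecord], derive: bool = True) -> pd.DataFrame:
    """Tabulate records as one row per (plant, day); with ``derive`` the 15
    parameters are appended in canonical :data:`FEATURE_NAMES` order."""
    rows = []
    for rec in records:
        row = {c: getattr(rec, c) for c in CHLF_COLUMNS}
        if derive:
            row.update(asdict(derive_parameters(rec)))
        rows.append(row)
    frame = pd.DataFrame(rows)
    if derive:
        return frame[list(META_COLUMNS) + list(FEATURE_NAMES)]
    return frame[list(CHLF_COLUMNS)]


def _check_columns(frame: pd.DataFrame, required: Sequence[str], path: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required columns {missing}; expected {list(required)}"
        )


def read_chlf_csv(path: str) -> list[ChlFRecord]:
    """Read induction-curve base signals (one row per plant × day)."""
    frame = pd.read_csv(path)
    _check_columns(frame, CHLF_COLUMNS, path)
    records = []
    for i, row in frame.iterrows():
        try:
            records.append(
                ChlFRecord(
                    plant_id=str(row["plant_id"]),
                    temperature_C=float(row["temperature_C"]),
                    day=int(row["day"]),
                    Fo=float(row["Fo"]),
                    Fm=float(row["Fm"]),
                    F=float(row["F"]),
                    Fm_prime=float(row["Fm_prime"]),
                    Fo_prime=float(row["Fo_prime"]),
                )
            )
        except (DomainError, ValueError) as exc:
            raise SchemaError(f"{path}: row {i + 2}: {exc}") from exc
    return records


def read_rlc_csv(path: str) -> list[RLCRecord]:
    """Read long-format RLC records keyed by (plant_id, PAR)."""
    frame = pd.read_csv(path)
    _check_columns(frame, ("plant_id", "PAR", "Y_II"), path)
    records = []
    for i, row in frame.iterrows():
        kwargs = {"plant_id": str(row["plant_id"]), "PAR": float(row["PAR"]),
                  "Y_II": float(row["Y_II"])}
        for opt in ("P", "Pm", "Pm_prime", "Y_I", "Y_ND"):
            if opt in frame.columns and pd.notna(row[opt]):
                kwargs[opt] = float(row[opt])
        try:
            records.append(RLCRecord(**kwargs))
        except (DomainError, ValueError) as exc:
            raise SchemaError(f"{path}: row {i + 2}: {exc}") from exc
    return records


def read_mda_csv(path: str) -> list[MDASample]:
    """Read TBA-assay absorbance records."""
    frame = pd.read_csv(path)
    cols = ("D450", "D510", "D532", "D560", "N", "W")
    _check_columns(frame, cols, path)
    samples = []
    for i, row in frame.iterrows():
        try:
            samples.append(MDASample(**{c: float(row[c]) for c in cols}))
        except (DomainError, ValueError) as exc:
            raise SchemaError(f"{path}: row {i + 2}: {exc}") from exc
    return samples
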