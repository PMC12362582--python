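"""Chromatographic descriptor suite for chameleonic degraders.

Retention on three HPLC systems is turned into the physicochemical
descriptors used to profile beyond-Rule-of-5 compounds:

* ``log k'60 RP18`` -> **BRlogD**, a surrogate of the octanol/water
  distribution coefficient, via a fixed calibration line.
* ``log k'80 PLRP-S`` on a polymeric reversed phase, a surrogate of
  toluene/water partitioning (membrane core); its pH profile (2/7/12)
  classifies the dominant ionization state at physiological pH.
* ``log kw_IAM``, lipophilicity on an immobilized-artificial-membrane
  column extrapolated to fully aqueous eluent, and the polarity
  descriptor ``Delta log kw_IAM`` (measured minus the lipophilicity
  baseline predicted from BRlogD).
* **Chamelogk**, the chameleonicity index: the measured log k' at 100%
  organic minus the value linearly extrapolated from the 50/60/70%
  compositions. A positive deviation means the molecule folds into a
  less polar conformation once the aqueous component disappears.

All capacity factors are decadic logarithms (chromatographic convention).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from . import config as cfg
from .errors import (
    InsufficientDataError,
    InvalidDeadTimeError,
    InvalidDenominatorError,
    NonRetainedSoluteError,
)


class ChromatographicSystem(str, Enum):
    PLRP_S = "PLRP_S"
    IAM = "IAM"
    RP18 = "RP18"


class IonizationClass(str, Enum):
    NEUTRAL = "NEUTRAL"
    BASE_IONIZED = "BASE_IONIZED"
    ACID_IONIZED = "ACID_IONIZED"
    AMPHOTERIC = "AMPHOTERIC"
    UNDETERMINED = "UNDETERMINED"


@dataclass(frozen=True)
class RetentionMeasurement:
    """One isocratic retention observation.

    Times are minutes; ``organic_fraction`` is % v/v acetonitrile.
    """

    compound_id: str
    system: ChromatographicSystem
    organic_fraction: float
    ph: float
    t_r: float
    t_0: float

    def __post_init__(self) -> None:
        if self.t_0 <= 0:
            raise InvalidDeadTimeError(
                f"{self.compound_id}: dead time t0={self.t_0} must be > 0"
            )
        if self.t_r <= self.t_0:
            raise NonRetainedSoluteError(
                f"{self.compound_id}: t_r={self.t_r} <= t0={self.t_0}; "
                "solute not retained"
            )
        if not 0.0 <= self.organic_fraction <= 100.0:
            raise ValueError(
                f"organic_fraction={self.organic_fraction} outside [0, 100]"
            )

    @property
    def log_capacity_factor(self) -> float:
        return capacity_factor(self.t_r, self.t_0)


@dataclass(frozen=True)
class RetentionLine:
    """OLS line of log10 k' on organic fraction (% v/v)."""

    slope: float
    intercept: float
    r2: float
    n_points: int
    fraction_range: tuple[float, float]

    def predict(self, organic_fraction: float) -> float:
        return self.intercept + self.slope * organic_fraction


@dataclass
class DescriptorRecord:
    """Computed descriptor suite for one compound.

    Fields are ``None`` when their chromatographic inputs are absent;
    ``flags`` collects interpretation flags (e.g. excessive polarity,
    strong chameleon).
    """

    compound_id: str
    logk60_rp18: Optional[float] = None
    brlogd: Optional[float] = None
    logk80_plrps: Optional[float] = None
    logkw_iam: Optional[float] = None
    clogkw_iam: Optional[float] = None
    delta_logkw_iam: Optional[float] = None
    chamelogk: Optional[float] = None
    epsa: Optional[float] = None
    tpsa: Optional[float] = None
    etr: Optional[float] = None
    ionization_class: IonizationClass = IonizationClass.UNDETERMINED
    flags: list[str] = field(default_factory=list)


def capacity_factor(t_r: float, t_0: float) -> float:
    """log10 capacity factor, log10((t_r - t0)/t0).

    Raises for non-retained solutes (t_r <= t0) and invalid dead times.
    """
    if t_0 <= 0:
        raise InvalidDeadTimeError(f"dead time t0={t_0} must be > 0")
    if t_r <= t_0:
        raise NonRetainedSoluteError(f"t_r={t_r} <= t0={t_0}")
    return math.log10((t_r - t_0) / t_0)


def brlogd(logk60: float, *, config: cfg.PipelineConfig = cfg.DEFAULT_CONFIG) -> float:
    """Octanol/water distribution surrogate from log k'60 on the C18 phase."""
    if not math.isfinite(logk60):
        raise ValueError("logk60 must be finite")
    return config.brlogd_slope * logk60 + config.brlogd_intercept


def clogkw_iam(
    brlogd_value: float, *, config: cfg.PipelineConfig = cfg.DEFAULT_CONFIG
) -> float:
    """Lipophilicity-predicted IAM baseline (the log kw_IAM of an apolar
    compound with the same BRlogD)."""
    if not math.isfinite(brlogd_value):
        raise ValueError("brlogd must be finite")
    return config.clogkw_iam_slope * brlogd_value + config.clogkw_iam_intercept


def delta_logkw_iam(
    logkw_iam_value: float,
    brlogd_value: float,
    *,
    config: cfg.PipelineConfig = cfg.DEFAULT_CONFIG,
) -> tuple[float, bool]:
    """Polarity descriptor: measured minus predicted IAM lipophilicity.

    Returns ``(delta, excessive)`` where ``excessive`` flags values above
    the excessive-polarity threshold (default 1.5).
    """
    delta = logkw_iam_value - clogkw_iam(brlogd_value, config=config)
    return delta, delta > config.excessive_polarity_threshold


def fit_retention_line(
    points: Sequence[tuple[float, float]]
) -> RetentionLine:
    """Least-squares line of log10 k' on organic fraction.

    Exact through the points when they are collinear; raises
    :class:`InsufficientDataError` below two distinct fractions.
    """
    if len(points) < 2:
        raise InsufficientDataError(f"need >= 2 points, got {len(points)}")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.unique(x).size < 2:
        raise InsufficientDataError("all organic fractions identical")
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue**2)
    if not math.isfinite(r2):  # zero variance in y: perfect horizontal line
        r2 = 1.0
    return RetentionLine(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=min(max(r2, 0.0), 1.0),
        n_points=len(points),
        fraction_range=(float(x.min()), float(x.max())),
    )


def logkw_iam_extrapolate(
    points: Sequence[tuple[float, float]], *, at_fraction: float = 0.0
) -> float:
    """Extrapolated IAM lipophilicity log kw_IAM.

    Fits log k' against % organic over the measured range (10-50% is the
    usual design) and evaluates the line at ``at_fraction`` — 0% organic,
    i.e. pure aqueous eluent, by convention for a *w* subscript. The
    target is a parameter because other extrapolation conventions exist.
    """
    line = fit_retention_line(points)
    return line.predict(at_fraction)


CHAMELOGK_LINE_FRACTIONS = (50.0, 60.0, 70.0)


def chamelogk(
    line_points: Mapping[float, float] | Sequence[tuple[float, float]],
    measured_logk100: float,
    *,
    config: cfg.PipelineConfig = cfg.DEFAULT_CONFIG,
) -> tuple[float, bool]:
    """Chameleonicity index on the polymeric reversed phase.

    ``line_points`` must contain the 50/60/70% organic observations; any
    other compositions are ignored with a warning. The line through the
    three points is extrapolated to 100% organic and subtracted from the
    measured value there. Returns ``(chamelogk, strong)`` where ``strong``
    is True above the strong-chameleon threshold (default 0.6).
    """
    pts = dict(line_points)
    extra = set(pts) - set(CHAMELOGK_LINE_FRACTIONS)
    if extra:
        warnings.warn(
            f"ignoring non-standard compositions {sorted(extra)}; the "
            "chameleonicity line uses 50/60/70% only",
            stacklevel=2,
        )
    missing = [f for f in CHAMELOGK_LINE_FRACTIONS if f not in pts]
    if missing or measured_logk100 is None or not math.isfinite(measured_logk100):
        raise InsufficientDataError(
            f"chamelogk needs 50/60/70%% points plus the measured 100%% "
            f"value; missing fractions: {missing}"
        )
    line = fit_retention_line([(f, pts[f]) for f in CHAMELOGK_LINE_FRACTIONS])
    value = measured_logk100 - line.predict(100.0)
    return value, value > config.strong_chameleon_threshold


def classify_chameleon(
    chamelogk_value: float, *, config: cfg.PipelineConfig = cfg.DEFAULT_CONFIG
) -> bool:
    """True when the chameleonicity index marks a strong chameleon (> 0.6)."""
    return chamelogk_value > config.strong_chameleon_threshold


def etr(epsa: float, tpsa: float) -> float:
    """EPSA-to-TPSA ratio, an index of polarity masking (~0.7 for
    conformationally shielded series)."""
    if tpsa <= 0:
        raise InvalidDenominatorError(f"tpsa={tpsa} must be > 0")
    if epsa < 0:
        raise ValueError(f"epsa={epsa} must be >= 0")
    return epsa / tpsa


def ionization_class(
    logk80_by_ph: Mapping[float, float],
    *,
    config: cfg.PipelineConfig = cfg.DEFAULT_CONFIG,
) -> IonizationClass:
    """Dominant ionization state from the pH profile of log k'80 PLRP-S.

    Ionization depresses retention on the polymeric phase, so a capacity
    factor at pH 2 (or 12) that falls more than the depression threshold
    below the profile maximum signals a protonatable base (or acid).
    A profile whose pH-7 retention sits within the threshold of the
    maximum is dominated by the neutral species at physiological pH.
    """
    required = (2.0, 7.0, 12.0)
    present = {float(k): float(v) for k, v in logk80_by_ph.items()}
    if any(ph not in present for ph in required):
        warnings.warn(
            f"pH profile incomplete (have {sorted(present)}); "
            "ionization class undetermined",
            stacklevel=2,
        )
        return IonizationClass.UNDETERMINED
    thr = config.ionization_depression_threshold
    m = max(present[ph] for ph in required)
    if m - present[7.0] <= thr:
        return IonizationClass.NEUTRAL
    depressed_acidic = m - present[2.0] > thr
    depressed_basic = m - present[12.0] > thr
    if depressed_acidic and depressed_basic:
        return IonizationClass.AMPHOTERIC
    if depressed_acidic:
        return IonizationClass.BASE_IONIZED
    if depressed_basic:
        return IonizationClass.ACID_IONIZED
    return IonizationClass.UNDETERMINED


def compute_descriptors(
    measurements: Iterable[RetentionMeasurement],
    metadata: Optional[Mapping[str, Mapping[str, float]]] = None,
    *,
    config: cfg.PipelineConfig = cfg.DEFAULT_CONFIG,
) -> list[DescriptorRecord]:
    """Assemble the full descriptor suite per compound.

    ``metadata`` maps compound_id to a dict that may carry ``epsa`` and
    ``tpsa`` (measured/topological polar surface areas, Angstrom^2).
    Descriptors whose inputs are missing stay ``None``; nothing is imputed.
    """
    metadata = metadata or {}
    by_compound: dict[str, list[RetentionMeasurement]] = {}
    for m in measurements:
        by_compound.setdefault(m.compound_id, []).append(m)

    records = []
    for compound_id, obs in by_compound.items():
        rec = DescriptorRecord(compound_id=compound_id)

        rp18 = [m for m in obs if m.system is ChromatographicSystem.RP18]
        k60 = [m for m in rp18 if math.isclose(m.organic_fraction, 60.0)]
        if k60:
            rec.logk60_rp18 = k60[0].log_capacity_factor
            rec.brlogd = brlogd(rec.logk60_rp18, config=config)

        plrp = [m for m in obs if m.system is ChromatographicSystem.PLRP_S]
        neutral = [m for m in plrp if math.isclose(m.ph, 7.0)]
        k80 = [m for m in neutral if math.isclose(m.organic_fraction, 80.0)]
        if k80:
            rec.logk80_plrps = k80[0].log_capacity_factor

        line_pts = {
            m.organic_fraction: m.log_capacity_factor
            for m in neutral
            if m.organic_fraction in CHAMELOGK_LINE_FRACTIONS
        }
        k100 = [m for m in neutral if math.isclose(m.organic_fraction, 100.0)]
        if len(line_pts) == 3 and k100:
            value, strong = chamelogk(
                line_pts, k100[0].log_capacity_factor, config=config
            )
            rec.chamelogk = value
            if strong:
                rec.flags.append("strong_chameleon")

        by_ph = {
            m.ph: m.log_capacity_factor
            for m in plrp
            if math.isclose(m.organic_fraction, 80.0)
        }
        if by_ph:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rec.ionization_class = ionization_class(by_ph, config=config)

        iam = [
            (m.organic_fraction, m.log_capacity_factor)
            for m in obs
            if m.system is ChromatographicSystem.IAM
        ]
        if len(iam) >= 2:
            rec.logkw_iam = logkw_iam_extrapolate(iam)
        if rec.brlogd is not None:
            rec.clogkw_iam = clogkw_iam(rec.brlogd, config=config)
            if rec.logkw_iam is not None:
                delta, excessive = delta_logkw_iam(
                    rec.logkw_iam, rec.brlogd, config=config
                )
                rec.delta_logkw_iam = delta
                if excessive:
                    rec.flags.append("excessive_polarity")

        meta = metadata.get(compound_id, {})
        epsa_v = meta.get("epsa")
        tpsa_v = meta.get("tpsa")
        if epsa_v is not None and not (isinstance(epsa_v, float) and math.isnan(epsa_v)):
            rec.epsa = float(epsa_v)
        if tpsa_v is not None and not (isinstance(tpsa_v, float) and math.isnan(tpsa_v)):
            rec.tpsa = float(tpsa_v)
        if rec.epsa is not None and rec.tpsa is not None and rec.tpsa > 0:
            rec.etr = etr(rec.epsa, rec.tpsa)

        records.append(rec)
    return records
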