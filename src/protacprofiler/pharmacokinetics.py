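"""Noncompartmental oral bioavailability.

F% compares dose-normalized plasma exposure after oral and intravenous
administration of the same compound:

    F% = (AUC_oral / dose_oral) / (AUC_iv / dose_iv) * 100

AUC is the linear-trapezoid area under the concentration-time curve from
the first to the last observed sample, with no extrapolation to infinity
by default; a log-linear trapezoid variant is available for declining
phases. Below-limit-of-quantification samples (NaN or negative) are
dropped with a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from . import config as cfg
from .errors import InvalidProfileError, UndefinedBioavailabilityError


class Route(str, Enum):
    ORAL = "ORAL"
    IV = "IV"


class FClass(str, Enum):
    VERY_LOW = "VERY_LOW"      # F < 1%
    LOW = "LOW"                # 1% <= F <= 5%
    MEDIUM_HIGH = "MEDIUM_HIGH"  # F > 5%


@dataclass(frozen=True)
class PkProfile:
    """One dosing arm: times in hours, concentrations in ng/mL, dose mg/kg."""

    compound_id: str
    route: Route
    dose: float
    timepoints: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise InvalidProfileError(f"{self.compound_id}: dose must be > 0")
        cleaned = _drop_blq(self.timepoints, self.compound_id)
        object.__setattr__(self, "timepoints", cleaned)
        times = [t for t, _ in self.timepoints]
        if len(times) < 2:
            raise InvalidProfileError(
                f"{self.compound_id}: need >= 2 quantifiable timepoints"
            )
        if any(b <= a for a, b in zip(times, times[1:])):
            raise InvalidProfileError(
                f"{self.compound_id}: times must be strictly increasing"
            )

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.timepoints])

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for _, c in self.timepoints])


def _drop_blq(
    timepoints: Sequence[tuple[float, float]], compound_id: str
) -> tuple[tuple[float, float], ...]:
    kept, dropped = [], 0
    for t, c in timepoints:
        if c is None or not math.isfinite(c) or c < 0:
            dropped += 1
            continue
        kept.append((float(t), float(c)))
    if dropped:
        warnings.warn(
            f"{compound_id}: dropped {dropped} below-quantification sample(s)",
            stacklevel=3,
        )
    return tuple(kept)


@dataclass(frozen=True)
class BioavailabilityResult:
    compound_id: str
    auc_oral: float
    auc_iv: float
    auc_dn_oral: float
    auc_dn_iv: float
    f_percent: float
    f_class: FClass


def auc_trapezoid(
    timepoints: Sequence[tuple[float, float]], *, method: str = "linear"
) -> float:
    """Area under the curve from first to last observation (ng*h/mL).

    ``method='linear'`` is the plain trapezoid; ``'linear-log'`` uses the
    log-trapezoid on strictly declining positive segments (common NCA
    option) and the linear rule elsewhere.
    """
    times = np.asarray([t for t, _ in timepoints], dtype=float)
    conc = np.asarray([c for _, c in timepoints], dtype=float)
    if times.size < 2:
        raise InvalidProfileError("need >= 2 timepoints")
    if np.any(np.diff(times) <= 0):
        raise InvalidProfileError("times must be strictly increasing")
    if np.any(conc < 0):
        raise InvalidProfileError("concentrations must be >= 0")
    if method == "linear":
        return float(np.trapezoid(conc, times))
    if method == "linear-log":
        dt = np.diff(times)
        c1, c2 = conc[:-1], conc[1:]
        seg = np.empty_like(dt)
        declining = (c2 < c1) & (c2 > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            log_seg = dt * (c1 - c2) / np.log(c1 / c2)
        seg = np.where(declining, log_seg, dt * (c1 + c2) / 2.0)
        return float(seg.sum())
    raise ValueError(f"unknown AUC method {method!r}")


def bioavailability_class(
    f_percent: float, *, config: cfg.PipelineConfig = cfg.DEFAULT_CONFIG
) -> FClass:
    """Class boundaries: F < 1% very low, F <= 5% low, above that medium/high.

    Boundary values go to the lower-severity class.
    """
    from .errors import InvalidValueError

    if f_percent < 0 or not math.isfinite(f_percent):
        raise InvalidValueError(f"f_percent={f_percent} must be finite and >= 0")
    if f_percent < config.f_very_low_boundary:
        return FClass.VERY_LOW
    if f_percent <= config.f_low_boundary:
        return FClass.LOW
    return FClass.MEDIUM_HIGH


def oral_bioavailability(
    oral: PkProfile,
    iv: PkProfile,
    *,
    method: str = "linear",
    config: cfg.PipelineConfig = cfg.DEFAULT_CONFIG,
) -> BioavailabilityResult:
    """Noncompartmental F% from paired oral and IV profiles."""
    if oral.route is not Route.ORAL or iv.route is not Route.IV:
        raise InvalidProfileError("profiles must be (ORAL, IV) in that order")
    auc_o = auc_trapezoid(oral.timepoints, method=method)
    auc_i = auc_trapezoid(iv.timepoints, method=method)
    if auc_i <= 0:
        raise UndefinedBioavailabilityError(
            f"{iv.compound_id}: IV AUC is zero; F%% undefined"
        )
    dn_o = auc_o / oral.dose
    dn_i = auc_i / iv.dose
    f = dn_o / dn_i * 100.0
    return BioavailabilityResult(
        compound_id=oral.compound_id,
        auc_oral=auc_o,
        auc_iv=auc_i,
        auc_dn_oral=dn_o,
        auc_dn_iv=dn_i,
        f_percent=f,
        f_class=bioavailability_class(f, config=config),
    )
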