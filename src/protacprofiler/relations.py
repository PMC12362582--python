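"""Descriptor–ADME relationship layer.

Simple ordinary-least-squares relations between chromatographic
descriptors and in vitro / in vivo ADME readouts (the key one being the
inverse correlation between the Caco-2 efflux ratio and log k'80
PLRP-S), bioavailability classing and counting, and the
lipophilicity/polarity plane used to locate the region of oral
absorption. Outlier exclusion is always declarative — an explicit list
of compound ids — never automatic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

from scipy import stats

from . import config as cfg
from .errors import InsufficientDataError, InvalidValueError
from .pharmacokinetics import FClass, bioavailability_class


@dataclass
class CompoundRecord:
    """Per-compound experimental and descriptor table row.

    ``series`` groups structural analogs; ``n_linker_methyls`` counts the
    methyl substituents on the linker. ADME fields: ``f_percent`` (oral
    bioavailability, %), ``er`` (Caco-2 efflux ratio), ``papp`` (mean
    passive permeability, 1e-6 cm/s), ``solubility`` (µg/mL),
    ``clearance`` (% hepatic blood flow). Descriptor fields mirror
    :class:`~protacprofiler.chromatography.DescriptorRecord`.
    """

    compound_id: str
    series: Optional[str] = None
    n_linker_methyls: Optional[int] = None
    f_percent: Optional[float] = None
    er: Optional[float] = None
    papp: Optional[float] = None
    solubility: Optional[float] = None
    clearance: Optional[float] = None
    epsa: Optional[float] = None
    tpsa: Optional[float] = None
    brlogd: Optional[float] = None
    logk80_plrps: Optional[float] = None
    logkw_iam: Optional[float] = None
    delta_logkw_iam: Optional[float] = None
    chamelogk: Optional[float] = None
    etr: Optional[float] = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.er is not None and self.er <= 0:
            raise InvalidValueError(f"{self.compound_id}: efflux ratio must be > 0")
        if self.f_percent is not None and self.f_percent < 0:
            raise InvalidValueError(f"{self.compound_id}: F% must be >= 0")

    def get(self, name: str) -> Optional[float]:
        if hasattr(self, name):
            return getattr(self, name)
        return self.extras.get(name)


@dataclass(frozen=True)
class RelationResult:
    x_name: str
    y_name: str
    slope: float
    intercept: float
    r2: float
    n_used: int
    excluded_ids: tuple[str, ...]


def linear_relation(
    records: Sequence[CompoundRecord],
    x_field: str,
    y_field: str,
    exclude: Sequence[str] = (),
) -> RelationResult:
    """OLS fit of ``y_field`` on ``x_field`` over the retained records.

    r² is the squared Pearson correlation (identical to the coefficient
    of determination for a simple linear fit). Records missing either
    field are dropped; exclusions are explicit compound ids.
    """
    excluded = tuple(exclude)
    xs, ys = [], []
    for rec in records:
        if rec.compound_id in excluded:
            continue
        xv, yv = rec.get(x_field), rec.get(y_field)
        if xv is None or yv is None:
            continue
        if isinstance(xv, float) and math.isnan(xv):
            continue
        if isinstance(yv, float) and math.isnan(yv):
            continue
        xs.append(float(xv))
        ys.append(float(yv))
    if len(xs) < 3:
        raise InsufficientDataError(
            f"{y_field} ~ {x_field}: {len(xs)} usable records (< 3)"
        )
    fit = stats.linregress(xs, ys)
    return RelationResult(
        x_name=x_field,
        y_name=y_field,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        n_used=len(xs),
        excluded_ids=excluded,
    )


def count_class(
    records: Sequence[CompoundRecord],
    f_class: FClass,
    *,
    config: cfg.PipelineConfig = cfg.DEFAULT_CONFIG,
) -> int:
    """Number of compounds whose bioavailability class equals ``f_class``."""
    n = 0
    for rec in records:
        if rec.f_percent is None:
            continue
        if bioavailability_class(rec.f_percent, config=config) is f_class:
            n += 1
    return n


@dataclass(frozen=True)
class PlanePoint:
    compound_id: str
    brlogd: float
    delta_logkw_iam: float
    f_class: Optional[FClass]
    excessive_polarity: bool


def polarity_lipophilicity_plane(
    records: Sequence[CompoundRecord],
    *,
    config: cfg.PipelineConfig = cfg.DEFAULT_CONFIG,
) -> list[PlanePoint]:
    """(BRlogD, Δlog kw_IAM) coordinates with bioavailability class.

    High-F compounds cluster in the high-lipophilicity / low-polarity
    region of this plane. Rows missing either descriptor are skipped
    with a warning; Δ above the excessive-polarity threshold is flagged.
    """
    points = []
    skipped = 0
    for rec in records:
        if rec.brlogd is None or rec.delta_logkw_iam is None:
            skipped += 1
            continue
        f_class = (
            bioavailability_class(rec.f_percent, config=config)
            if rec.f_percent is not None
            else None
        )
        points.append(
            PlanePoint(
                compound_id=rec.compound_id,
                brlogd=rec.brlogd,
                delta_logkw_iam=rec.delta_logkw_iam,
                f_class=f_class,
                excessive_polarity=rec.delta_logkw_iam
                > config.excessive_polarity_threshold,
            )
        )
    if skipped:
        warnings.warn(f"skipped {skipped} record(s) missing plane coordinates",
                      stacklevel=2)
    return points
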