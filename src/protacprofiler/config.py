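"""Pipeline-wide configuration: calibration constants, thresholds and defaults.

Every tunable the individual stages consume lives here, so a recalibration
(new chromatographic calibration line, different vdW radii set, tighter
hydrogen-bond geometry) never requires a code change.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Mapping

# --- chromatographic calibration lines (C18 / IAM systems) -----------------
# BRlogD = BRLOGD_SLOPE * log k'60 + BRLOGD_INTERCEPT
BRLOGD_SLOPE = 3.31
BRLOGD_INTERCEPT = 2.79
# clog kw_IAM = CLOGKW_IAM_SLOPE * BRlogD + CLOGKW_IAM_INTERCEPT
CLOGKW_IAM_SLOPE = 0.92
CLOGKW_IAM_INTERCEPT = -1.03

# --- interpretation thresholds ---------------------------------------------
#: Delta log kw_IAM above which a compound is flagged "excessive polarity".
EXCESSIVE_POLARITY_THRESHOLD = 1.5
#: Chamelogk above which a compound counts as a strong chameleon.
STRONG_CHAMELEON_THRESHOLD = 0.6
#: Oral bioavailability class boundaries (percent).
F_VERY_LOW_BOUNDARY = 1.0
F_LOW_BOUNDARY = 5.0
#: Log-unit retention depression that signals ionization at a given pH.
IONIZATION_DEPRESSION_THRESHOLD = 0.3

# --- conformer descriptors --------------------------------------------------
#: Bondi van der Waals radii (Angstrom).
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "F": 1.47,
    "Cl": 1.75,
    "P": 1.80,
    "Br": 1.85,
    "I": 1.98,
}

#: Standard atomic masses (Dalton).
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "F": 18.998,
    "Cl": 35.45,
    "P": 30.974,
    "Br": 79.904,
    "I": 126.904,
}

DEFAULT_SASA_POINTS = 960
DEFAULT_PROBE_RADII = (0.0, 1.4)
WATER_PROBE_RADIUS = 1.4
#: H...acceptor cutoff (Angstrom) and minimum D-H...A angle (degrees).
IMHB_MAX_HA_DISTANCE = 2.5
IMHB_MIN_DHA_ANGLE = 120.0
#: Distance below which an H is considered covalently bonded to a heavy atom
#: when no explicit topology is available (XYZ input).
H_BOND_INFERENCE_CUTOFF = 1.2

# --- ensemble analysis -------------------------------------------------------
DEFAULT_RGYR_BIN_WIDTH = 0.25   # Angstrom
DEFAULT_PSA_BIN_WIDTH = 5.0     # Angstrom^2
#: Guide thresholds for the folded / low-polarity quadrant of property space.
RGYR_FOLDED_THRESHOLD = 7.0     # Angstrom
PSA_LOWPOLAR_THRESHOLD = 200.0  # Angstrom^2


@dataclass(frozen=True)
class PipelineConfig:
    """Bundle of every stage default; unknown keys are rejected on load."""

    probe_radii: tuple[float, ...] = DEFAULT_PROBE_RADII
    sasa_points: int = DEFAULT_SASA_POINTS
    imhb_max_ha_distance: float = IMHB_MAX_HA_DISTANCE
    imhb_min_dha_angle: float = IMHB_MIN_DHA_ANGLE
    rgyr_bin_width: float = DEFAULT_RGYR_BIN_WIDTH
    psa_bin_width: float = DEFAULT_PSA_BIN_WIDTH
    rgyr_folded_threshold: float = RGYR_FOLDED_THRESHOLD
    psa_lowpolar_threshold: float = PSA_LOWPOLAR_THRESHOLD
    brlogd_slope: float = BRLOGD_SLOPE
    brlogd_intercept: float = BRLOGD_INTERCEPT
    clogkw_iam_slope: float = CLOGKW_IAM_SLOPE
    clogkw_iam_intercept: float = CLOGKW_IAM_INTERCEPT
    excessive_polarity_threshold: float = EXCESSIVE_POLARITY_THRESHOLD
    strong_chameleon_threshold: float = STRONG_CHAMELEON_THRESHOLD
    f_very_low_boundary: float = F_VERY_LOW_BOUNDARY
    f_low_boundary: float = F_LOW_BOUNDARY
    ionization_depression_threshold: float = IONIZATION_DEPRESSION_THRESHOLD
    seed: int = 0

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise KeyError(f"unknown configuration keys: {sorted(unknown)}")
        kwargs = dict(mapping)
        if "probe_radii" in kwargs:
            kwargs["probe_radii"] = tuple(kwargs["probe_radii"])  # type: ignore[arg-type]
        return cls(**kwargs)  # type: ignore[arg-type]


DEFAULT_CONFIG = PipelineConfig()
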