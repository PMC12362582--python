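"""Ensemble-level property-space analysis.

Per-frame descriptors (radius of gyration, 3D PSA at the water probe)
are aggregated into the quantities used to compare conformational
behavior across solvents: medians and IQRs, 2D density maps over the
(R_gyr, 3D PSA 1.4 Å) plane, the conformer representing the density
maximum, the fraction of frames in the folded/low-polarity quadrant,
and polar-minus-nonpolar contrasts — the chameleonic signature being a
compact, less polar ensemble in one of the two environments.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from . import config as cfg
from .conformers import ConformerDescriptors
from .errors import EmptyEnsembleError, InvalidBinningError, LabelMismatchError


class SolventClass(str, Enum):
    POLAR = "POLAR"
    NONPOLAR = "NONPOLAR"


class SamplingMethod(str, Enum):
    CS = "CS"    # conformational sampling (implicit solvent)
    SMD = "SMD"  # steered molecular dynamics (explicit solvent)


@dataclass(frozen=True)
class EnsembleSummary:
    compound_id: str
    solvent: SolventClass
    solvent_label: str
    method: SamplingMethod
    n_frames: int
    median_rgyr: float
    median_psa14: float
    iqr_rgyr: float
    iqr_psa14: float
    density_max_frame: int
    fraction_folded_lowpolar: float


@dataclass(frozen=True)
class DensityMap:
    x_edges: np.ndarray  # R_gyr bin edges (Å)
    y_edges: np.ndarray  # 3D PSA bin edges (Å^2)
    counts: np.ndarray   # (nx, ny) frame counts
    max_bin: tuple[int, int]


def _xy(frames: Sequence[ConformerDescriptors]) -> tuple[np.ndarray, np.ndarray]:
    return (
        np.array([f.r_gyr for f in frames]),
        np.array([f.psa_14 for f in frames]),
    )


def density_map(
    frames: Sequence[ConformerDescriptors],
    x_bin_width: float = cfg.DEFAULT_RGYR_BIN_WIDTH,
    y_bin_width: float = cfg.DEFAULT_PSA_BIN_WIDTH,
) -> DensityMap:
    """2D histogram over (R_gyr, 3D PSA 1.4 Å).

    The maximum bin is the highest count; ties break toward lower PSA,
    then lower R_gyr, so the map is fully deterministic.
    """
    if not frames:
        raise EmptyEnsembleError("density map of an empty ensemble")
    if x_bin_width <= 0 or y_bin_width <= 0:
        raise InvalidBinningError(
            f"bin widths must be > 0, got ({x_bin_width}, {y_bin_width})"
        )
    x, y = _xy(frames)
    x_edges = _edges(x, x_bin_width)
    y_edges = _edges(y, y_bin_width)
    counts, _, _ = np.histogram2d(x, y, bins=(x_edges, y_edges))
    counts = counts.astype(int)
    best = counts.max()
    # candidate bins with the top count, tie-broken by (lower psa, lower rgyr)
    cand = np.argwhere(counts == best)
    order = np.lexsort((cand[:, 0], cand[:, 1]))  # primary: j (psa), then i
    i, j = cand[order[0]]
    return DensityMap(x_edges=x_edges, y_edges=y_edges, counts=counts,
                      max_bin=(int(i), int(j)))


def _edges(values: np.ndarray, width: float) -> np.ndarray:
    lo = np.floor(values.min() / width) * width
    hi = np.ceil(values.max() / width) * width
    if hi <= lo:
        hi = lo + width
    n = int(round((hi - lo) / width))
    edges = lo + width * np.arange(n + 1)
    # guard the right edge so the max value falls inside the last bin
    if edges[-1] <= values.max():
        edges = np.append(edges, edges[-1] + width)
    return edges


def density_max_conformer(
    frames: Sequence[ConformerDescriptors], dmap: DensityMap
) -> int:
    """Frame id of the representative conformer of the densest bin.

    Among the frames inside the maximum bin, the one closest to the bin
    center in z-scored (per-descriptor standardized) coordinates wins;
    exact ties break toward the lowest frame id.
    """
    if not frames:
        raise EmptyEnsembleError("no frames")
    x, y = _xy(frames)
    i, j = dmap.max_bin
    x_lo, x_hi = dmap.x_edges[i], dmap.x_edges[i + 1]
    y_lo, y_hi = dmap.y_edges[j], dmap.y_edges[j + 1]
    # match numpy.histogram2d edge semantics (right-inclusive last bin)
    in_x = (x >= x_lo) & ((x < x_hi) | (i == len(dmap.x_edges) - 2) & (x <= x_hi))
    in_y = (y >= y_lo) & ((y < y_hi) | (j == len(dmap.y_edges) - 2) & (y <= y_hi))
    members = np.where(in_x & in_y)[0]
    if members.size == 0:  # map not built from these frames
        raise EmptyEnsembleError("maximum bin holds no frames")
    sx = x.std() or 1.0
    sy = y.std() or 1.0
    cx, cy = (x_lo + x_hi) / 2.0, (y_lo + y_hi) / 2.0
    d2 = ((x[members] - cx) / sx) ** 2 + ((y[members] - cy) / sy) ** 2
    ids = np.array([frames[m].frame_id for m in members])
    order = np.lexsort((ids, d2))
    return int(ids[order[0]])


def summarize_ensemble(
    frames: Sequence[ConformerDescriptors],
    compound_id: str,
    solvent: SolventClass,
    *,
    solvent_label: str = "",
    method: SamplingMethod = SamplingMethod.CS,
    x_bin_width: float = cfg.DEFAULT_RGYR_BIN_WIDTH,
    y_bin_width: float = cfg.DEFAULT_PSA_BIN_WIDTH,
    rgyr_threshold: float = cfg.RGYR_FOLDED_THRESHOLD,
    psa_threshold: float = cfg.PSA_LOWPOLAR_THRESHOLD,
) -> EnsembleSummary:
    """Median/IQR quantifiers plus the folded/low-polarity fraction.

    Medians are the suitable central statistic for these skewed,
    multimodal property distributions; the folded/low-polarity fraction
    counts frames with R_gyr and 3D PSA both below the guide thresholds
    (defaults 7 Å and 200 Å²).
    """
    if not frames:
        raise EmptyEnsembleError(f"{compound_id}: empty ensemble")
    x, y = _xy(frames)
    dmap = density_map(frames, x_bin_width, y_bin_width)
    q75x, q25x = np.percentile(x, [75, 25])
    q75y, q25y = np.percentile(y, [75, 25])
    folded = (x < rgyr_threshold) & (y < psa_threshold)
    return EnsembleSummary(
        compound_id=compound_id,
        solvent=solvent,
        solvent_label=solvent_label or solvent.value.lower(),
        method=method,
        n_frames=len(frames),
        median_rgyr=float(np.median(x)),
        median_psa14=float(np.median(y)),
        iqr_rgyr=float(q75x - q25x),
        iqr_psa14=float(q75y - q25y),
        density_max_frame=density_max_conformer(frames, dmap),
        fraction_folded_lowpolar=float(folded.mean()),
    )


def chameleon_contrast(
    polar: EnsembleSummary, nonpolar: EnsembleSummary
) -> tuple[float, float]:
    """Polar-minus-nonpolar deltas of the median quantifiers.

    Returns ``(delta_median_rgyr, delta_median_psa14)``. A positive PSA
    delta (more exposed polarity in the polar solvent) is the expected
    chameleonic signature; a negative R_gyr delta means the molecule is
    more compact in the polar environment.
    """
    if polar.compound_id != nonpolar.compound_id:
        raise LabelMismatchError(
            f"compound mismatch: {polar.compound_id} vs {nonpolar.compound_id}"
        )
    return (
        polar.median_rgyr - nonpolar.median_rgyr,
        polar.median_psa14 - nonpolar.median_psa14,
    )
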