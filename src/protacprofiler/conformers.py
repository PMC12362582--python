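"""Per-conformer 3D descriptors.

For each frame of a conformational ensemble this module computes:

* **radius of gyration** (mass-weighted by default) — compactness and
  sphericity of the conformation;
* **solvent-accessible surface area** per atom, via a deterministic
  Shrake–Rupley scheme: a golden-spiral lattice of test points on each
  atom's inflated sphere (r_vdw + probe), a point accessible when it
  lies outside every other atom's inflated sphere;
* **3D polar surface area** at probe radii 0 Å (bare van der Waals
  surface) and 1.4 Å (water probe): the SASA summed over the polar
  atoms N, O and H bonded to N/O — the classical PSA atom set, so
  sulfur contributes nothing;
* **intramolecular hydrogen bonds**: donor–H···acceptor triples with
  N/O donors and acceptors satisfying distance and angle cutoffs.

The golden-spiral placement uses no random numbers, so every area is
bit-reproducible for a given point count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import config as cfg
from .errors import NoTopologyError, UnknownElementError

POLAR_HEAVY = frozenset({"N", "O"})


@dataclass(frozen=True)
class RadiiTable:
    """Van der Waals radii and atomic masses keyed by element symbol."""

    radii: dict[str, float] = field(default_factory=lambda: dict(cfg.BONDI_RADII))
    masses: dict[str, float] = field(default_factory=lambda: dict(cfg.ATOMIC_MASSES))

    def radius(self, element: str) -> float:
        try:
            return self.radii[element]
        except KeyError:
            raise UnknownElementError(f"no vdW radius for element {element!r}")

    def mass(self, element: str) -> float:
        try:
            return self.masses[element]
        except KeyError:
            raise UnknownElementError(f"no atomic mass for element {element!r}")


DEFAULT_RADII = RadiiTable()


@dataclass
class Conformer:
    """One frame: element symbols, Nx3 coordinates (Å), optional bonds."""

    elements: list[str]
    coords: np.ndarray
    bonds: Optional[list[tuple[int, int]]] = None
    frame_id: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.elements) == 0:
            raise ValueError("conformer needs >= 1 atom")
        if self.coords.shape != (len(self.elements), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} != ({len(self.elements)}, 3)"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def bonds_or_inferred(self) -> list[tuple[int, int]]:
        """Explicit bonds, else H–heavy bonds inferred by distance.

        Without topology only hydrogen attachment can be guessed safely:
        an H is bonded to the nearest heavy atom within the inference
        cutoff (1.2 Å). Heavy–heavy bonds are not invented.
        """
        if self.bonds is not None:
            return list(self.bonds)
        inferred: list[tuple[int, int]] = []
        heavy = [i for i, e in enumerate(self.elements) if e != "H"]
        if not heavy:
            return inferred
        heavy_xyz = self.coords[heavy]
        for i, e in enumerate(self.elements):
            if e != "H":
                continue
            d = np.linalg.norm(heavy_xyz - self.coords[i], axis=1)
            j = int(np.argmin(d))
            if d[j] < cfg.H_BOND_INFERENCE_CUTOFF:
                inferred.append((min(i, heavy[j]), max(i, heavy[j])))
        return inferred


@dataclass(frozen=True)
class ConformerDescriptors:
    frame_id: int
    r_gyr: float
    psa_0: float
    psa_14: float
    sasa_total: float
    n_imhb: int


def radius_of_gyration(
    conformer: Conformer,
    *,
    mass_weighted: bool = True,
    radii_table: RadiiTable = DEFAULT_RADII,
) -> float:
    """sqrt(sum w_i |r_i - rbar|^2 / sum w_i) with w = mass or 1."""
    if mass_weighted:
        w = np.array([radii_table.mass(e) for e in conformer.elements])
    else:
        w = np.ones(conformer.n_atoms)
    centroid = (w[:, None] * conformer.coords).sum(axis=0) / w.sum()
    sq = ((conformer.coords - centroid) ** 2).sum(axis=1)
    return float(np.sqrt((w * sq).sum() / w.sum()))


def canonical_frame(coords: np.ndarray) -> np.ndarray:
    """Rotate/translate coordinates into a deterministic principal-axis frame.

    The surface-point lattice is fixed in space, so plain sphere sampling
    is only approximately rotation invariant; expressing the molecule in
    its own principal-axis frame first (axes ordered by variance, signs
    fixed by the third moment, right-handed) makes the computed areas
    invariant under rigid motion to machine precision for molecules in
    generic position.
    """
    centered = coords - coords.mean(axis=0)
    if len(centered) == 1:
        return centered
    cov = centered.T @ centered
    _, vecs = np.linalg.eigh(cov)
    axes = vecs[:, ::-1].copy()  # descending variance
    proj = centered @ axes
    for k in range(3):
        skew = (proj[:, k] ** 3).sum()
        if skew < 0:
            axes[:, k] = -axes[:, k]
    if np.linalg.det(axes) < 0:
        axes[:, 2] = -axes[:, 2]
    return centered @ axes


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (Fibonacci spiral)."""
    k = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = k * math.pi * (3.0 - math.sqrt(5.0))
    return np.column_stack((r * np.cos(phi), r * np.sin(phi), z))


def shrake_rupley_sasa(
    conformer: Conformer,
    probe_radius: float = cfg.WATER_PROBE_RADIUS,
    n_points: int = cfg.DEFAULT_SASA_POINTS,
    *,
    radii_table: RadiiTable = DEFAULT_RADII,
) -> np.ndarray:
    """Per-atom solvent-accessible area (Å²) at the given probe radius."""
    if probe_radius < 0:
        raise ValueError("probe_radius must be >= 0")
    if n_points < 16:
        raise ValueError("n_points must be >= 16")
    radii = np.array([radii_table.radius(e) for e in conformer.elements])
    inflated = radii + probe_radius
    xyz = canonical_frame(conformer.coords)
    n = conformer.n_atoms
    sphere = golden_spiral_points(n_points)
    areas = np.empty(n)
    # neighbor prefilter: atoms can only occlude within the sum of inflated radii
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    for i in range(n):
        cutoff = inflated[i] + inflated
        neighbors = np.where((dist[i] < cutoff) & (np.arange(n) != i))[0]
        pts = xyz[i] + inflated[i] * sphere
        if neighbors.size:
            d2 = ((pts[:, None, :] - xyz[neighbors][None, :, :]) ** 2).sum(axis=-1)
            buried = (d2 < (inflated[neighbors] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * math.pi * inflated[i] ** 2 * frac
    return areas


def polar_atom_indices(conformer: Conformer) -> list[int]:
    """Indices of N, O and H bonded to N/O (classical PSA atom set)."""
    polar = [i for i, e in enumerate(conformer.elements) if e in POLAR_HEAVY]
    bonds = conformer.bonds_or_inferred()
    polar_set = set(polar)
    for a, b in bonds:
        ea, eb = conformer.elements[a], conformer.elements[b]
        if ea == "H" and eb in POLAR_HEAVY:
            polar_set.add(a)
        elif eb == "H" and ea in POLAR_HEAVY:
            polar_set.add(b)
    return sorted(polar_set)


def psa_3d(
    conformer: Conformer,
    probe_radius: float = cfg.WATER_PROBE_RADIUS,
    n_points: int = cfg.DEFAULT_SASA_POINTS,
    *,
    radii_table: RadiiTable = DEFAULT_RADII,
    sasa: Optional[np.ndarray] = None,
) -> float:
    """3D polar surface area: SASA summed over the polar atom set.

    Pass a precomputed per-atom ``sasa`` array (same probe) to avoid
    recomputing the surface.
    """
    idx = polar_atom_indices(conformer)
    if not idx:
        return 0.0
    if sasa is None:
        sasa = shrake_rupley_sasa(
            conformer, probe_radius, n_points, radii_table=radii_table
        )
    return float(sasa[idx].sum())


def find_imhb(
    conformer: Conformer,
    max_h_acceptor_dist: float = cfg.IMHB_MAX_HA_DISTANCE,
    min_dha_angle: float = cfg.IMHB_MIN_DHA_ANGLE,
) -> list[tuple[int, int, int]]:
    """Intramolecular hydrogen bonds as (donor, H, acceptor) index triples.

    Donors and acceptors are N/O; a triple qualifies when H···A is within
    the distance cutoff, the D–H···A angle meets the angular cutoff, and
    donor and acceptor are not covalently bonded to each other.
    """
    if conformer.bonds is None:
        bonds = conformer.bonds_or_inferred()
        if not bonds:
            raise NoTopologyError("bond topology required for IMHB detection")
    else:
        bonds = list(conformer.bonds)
    bonded = set()
    for a, b in bonds:
        bonded.add((a, b))
        bonded.add((b, a))
    elements = conformer.elements
    xyz = conformer.coords

    dh_pairs = [
        (a, b) if elements[a] in POLAR_HEAVY else (b, a)
        for a, b in bonds
        if {elements[a], elements[b]} & POLAR_HEAVY
        and "H" in (elements[a], elements[b])
    ]
    acceptors = [i for i, e in enumerate(elements) if e in POLAR_HEAVY]

    found = []
    for donor, h in dh_pairs:
        for acc in acceptors:
            if acc == donor or (donor, acc) in bonded or (h, acc) in bonded:
                continue
            ha = xyz[acc] - xyz[h]
            d_ha = float(np.linalg.norm(ha))
            if d_ha > max_h_acceptor_dist or d_ha == 0.0:
                continue
            hd = xyz[donor] - xyz[h]
            cosang = float(np.dot(hd, ha) / (np.linalg.norm(hd) * d_ha))
            angle = math.degrees(math.acos(min(1.0, max(-1.0, cosang))))
            if angle >= min_dha_angle:
                found.append((donor, h, acc))
    return found


def describe_conformer(
    conformer: Conformer,
    *,
    n_points: int = cfg.DEFAULT_SASA_POINTS,
    radii_table: RadiiTable = DEFAULT_RADII,
    imhb_max_ha: float = cfg.IMHB_MAX_HA_DISTANCE,
    imhb_min_angle: float = cfg.IMHB_MIN_DHA_ANGLE,
) -> ConformerDescriptors:
    """Full descriptor block for one frame."""
    sasa14 = shrake_rupley_sasa(conformer, cfg.WATER_PROBE_RADIUS, n_points,
                                radii_table=radii_table)
    sasa0 = shrake_rupley_sasa(conformer, 0.0, n_points, radii_table=radii_table)
    try:
        imhb = find_imhb(conformer, imhb_max_ha, imhb_min_angle)
    except NoTopologyError:
        imhb = []
    return ConformerDescriptors(
        frame_id=conformer.frame_id,
        r_gyr=radius_of_gyration(conformer, radii_table=radii_table),
        psa_0=psa_3d(conformer, 0.0, n_points, radii_table=radii_table, sasa=sasa0),
        psa_14=psa_3d(conformer, cfg.WATER_PROBE_RADIUS, n_points,
                      radii_table=radii_table, sasa=sasa14),
        sasa_total=float(sasa14.sum()),
        n_imhb=len(imhb),
    )
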