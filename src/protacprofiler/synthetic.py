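"""Seeded generators for every input the pipeline consumes.

Each generator emulates the statistical structure its downstream stage
assumes, with the ground truth returned alongside the observations so
recovery can be tested without circularity:

* retention tables whose log capacity factor is linear in the organic
  fraction, with a planted positive chameleonic deviation at 100%
  organic;
* bead-chain conformer ensembles whose compactness (and therefore
  radius of gyration and exposed polar area) is controlled by a folding
  bias that differs between a polar and a nonpolar solvent label;
* one-compartment oral / IV-bolus concentration curves with a known
  bioavailability;
* compound property tables with a planted linear efflux-ratio /
  lipophilicity relation and a bioavailability that decreases with
  efflux.

The chains are geometric toys, not chemically valid degraders: the
descriptors under test are purely geometric, so chemical realism adds
nothing. Every generator is a pure function of its configuration; each
draws from its own RNG stream derived from the master seed, so adding a
generator never perturbs the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .conformers import Conformer

# fixed per-generator stream labels (master seed + label -> independent RNG)
_STREAM = {"retention": 101, "ensemble": 202, "pk": 303, "table": 404}


def _rng(seed: int, stream: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAM[stream], extra])


@dataclass(frozen=True)
class PkParams:
    """One-compartment parameters: F (fraction), clearance L/h/kg, volume
    L/kg, absorption rate 1/h."""

    f_true: float = 0.20
    cl: float = 1.0
    v: float = 5.0
    ka: float = 1.5


@dataclass(frozen=True)
class RelationParams:
    slope: float = -2.0
    intercept: float = 6.0
    noise_sd: float = 0.0
    er_floor: float = 0.1


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_compounds: int = 11
    n_frames: int = 200
    chain_length: int = 30
    polar_fraction: float = 0.25
    compactness_polar: float = 0.7
    compactness_nonpolar: float = 0.2
    retention_noise_sd: float = 0.0
    chamelogk_true: float = 0.8
    pk_params: PkParams = field(default_factory=PkParams)
    relation_params: RelationParams = field(default_factory=RelationParams)

    def __post_init__(self) -> None:
        for name in ("polar_fraction", "compactness_polar", "compactness_nonpolar"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


# ---------------------------------------------------------------- retention

#: standard mobile-phase design on the polymeric phase (% organic)
RETENTION_FRACTIONS = (50.0, 60.0, 70.0, 100.0)
RETENTION_T0 = 1.0  # minutes


def gen_retention(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retention table (long CSV rows) plus a ground-truth sidecar.

    Per compound, log k' = a + b*phi at 50/60/70% organic, and the 100%
    observation is offset by the planted chameleonicity; Gaussian noise
    (sd in log10 units) is added to every log k' before conversion to a
    retention time with fixed dead time.
    """
    rng = _rng(config.seed, "retention")
    obs_rows, truth_rows = [], []
    for i in range(config.n_compounds):
        cid = f"SYN-{i + 1:03d}"
        a = rng.uniform(2.5, 3.5)      # intercept at 0% organic
        b = rng.uniform(-0.06, -0.04)  # slope per % organic
        for phi in RETENTION_FRACTIONS:
            logk = a + b * phi
            if phi == 100.0:
                logk += config.chamelogk_true
            logk += rng.normal(0.0, config.retention_noise_sd)
            t_r = RETENTION_T0 * (1.0 + 10.0**logk)
            obs_rows.append(
                {
                    "compound_id": cid,
                    "system": "PLRP_S",
                    "organic_fraction": phi,
                    "ph": 7.0,
                    "t_r": t_r,
                    "t_0": RETENTION_T0,
                }
            )
        truth_rows.append(
            {
                "compound_id": cid,
                "intercept": a,
                "slope": b,
                "chamelogk_true": config.chamelogk_true,
            }
        )
    return pd.DataFrame(obs_rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------- ensembles

_BOND_LENGTH = 1.5   # Å between consecutive beads
_MIN_SEPARATION = 1.0  # Å self-avoidance cutoff


def _chain_elements(config: GeneratorConfig, compound_index: int) -> list[str]:
    """Element assignment is a property of the compound, not the frame."""
    rng = _rng(config.seed, "ensemble", compound_index)
    elements = []
    for _ in range(config.chain_length):
        if rng.random() < config.polar_fraction:
            elements.append("N" if rng.random() < 0.5 else "O")
        else:
            elements.append("C")
    return elements


def _grow_chain(
    rng: np.random.Generator, n: int, compactness: float
) -> np.ndarray:
    """Self-avoiding biased random walk.

    Each step mixes an isotropic random direction with the unit vector
    back toward the running centroid, weighted by the compactness; steps
    that land within the self-avoidance cutoff of an existing bead are
    re-drawn (with a cap, after which the best candidate is accepted so
    generation always terminates).
    """
    coords = np.zeros((n, 3))
    for i in range(1, n):
        centroid = coords[:i].mean(axis=0)
        best, best_d = None, -1.0
        for attempt in range(60):
            # progressively relax the fold bias so a clash-free step is
            # always found and the separation cutoff is respected
            c_eff = compactness * 0.9**attempt
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            pull = centroid - coords[i - 1]
            norm = np.linalg.norm(pull)
            if norm > 1e-12:
                step = (1.0 - c_eff) * u + c_eff * pull / norm
            else:
                step = u
            step /= np.linalg.norm(step)
            cand = coords[i - 1] + _BOND_LENGTH * step
            d = np.min(np.linalg.norm(coords[: i - 1] - cand, axis=1)) if i > 1 else np.inf
            if d >= _MIN_SEPARATION:
                best = cand
                break
            if d > best_d:
                best, best_d = cand, d
        coords[i] = best
    return coords


def gen_ensemble(config: GeneratorConfig, solvent: str, *,
                 compound_index: int = 0) -> list[Conformer]:
    """Bead-chain conformer frames for one (compound, solvent) pair.

    ``solvent`` must be ``"polar"`` or ``"nonpolar"``; the corresponding
    compactness from the configuration controls the folding bias, so a
    higher polar-solvent compactness yields ensembles that are more
    compact (lower R_gyr) and less polar-exposed in the polar medium —
    the chameleonic signature the analysis stage must detect.
    """
    if solvent not in ("polar", "nonpolar"):
        raise ValueError(f"solvent must be 'polar' or 'nonpolar', got {solvent!r}")
    compactness = (
        config.compactness_polar if solvent == "polar" else config.compactness_nonpolar
    )
    elements = _chain_elements(config, compound_index)
    bonds = [(i, i + 1) for i in range(config.chain_length - 1)]
    rng = _rng(
        config.seed, "ensemble",
        1_000_000 + compound_index * 2 + (0 if solvent == "polar" else 1),
    )
    frames = []
    for f in range(config.n_frames):
        coords = _grow_chain(rng, config.chain_length, compactness)
        frames.append(
            Conformer(elements=list(elements), coords=coords, bonds=list(bonds),
                      frame_id=f)
        )
    return frames


# ----------------------------------------------------------------------- PK

ORAL_DOSE = 30.0  # mg/kg, study design
IV_DOSE = 5.0     # mg/kg

#: sparse in-vivo style sampling (h); 0 kept for the IV bolus reference
SPARSE_TIMEPOINTS = (0.0, 0.5, 1.0, 2.0, 8.0, 24.0)
#: front-loaded 8-point design spanning ~4.5 elimination half-lives
EIGHT_POINT_TIMEPOINTS = (0.0, 0.5, 1.0, 2.0, 4.0, 7.0, 11.0, 16.0)
#: dense grid for truncation-free noncompartmental recovery
DENSE_TIMEPOINTS = tuple(np.arange(0.0, 72.01, 0.25))


def one_compartment_oral(t: np.ndarray, dose: float, p: PkParams) -> np.ndarray:
    """First-order absorption: C(t) = F*D*ka / (V*(ka-ke)) * (e^-ke t - e^-ka t)."""
    ke = p.cl / p.v
    if math.isclose(p.ka, ke):
        return p.f_true * dose * p.ka * t / p.v * np.exp(-p.ka * t)
    return (
        p.f_true * dose * p.ka / (p.v * (p.ka - ke))
        * (np.exp(-ke * t) - np.exp(-p.ka * t))
    )


def one_compartment_iv(t: np.ndarray, dose: float, p: PkParams) -> np.ndarray:
    """IV bolus: C(t) = D/V * e^-ke t."""
    ke = p.cl / p.v
    return dose / p.v * np.exp(-ke * t)


def analytic_auc_oral(dose: float, p: PkParams) -> float:
    """Closed form: AUC_0-inf = F*D/CL."""
    return p.f_true * dose / p.cl


def analytic_auc_iv(dose: float, p: PkParams) -> float:
    return dose / p.cl


def gen_pk(
    config: GeneratorConfig,
    *,
    timepoints: Sequence[float] = SPARSE_TIMEPOINTS,
    noise_sd: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Oral + IV concentration tables (mg/kg doses, ng/mL concentrations).

    Multiplicative lognormal noise (``noise_sd`` on the log scale) keeps
    concentrations positive. The truth sidecar carries the planted F and
    the analytic dose-normalized AUCs. Concentrations are scaled so that
    dose in mg/kg and V in L/kg print plasma levels in ng/mL.
    """
    rng = _rng(config.seed, "pk")
    p = config.pk_params
    t = np.asarray(timepoints, dtype=float)
    rows = []
    for i in range(config.n_compounds):
        cid = f"SYN-{i + 1:03d}"
        for route, dose, curve in (
            ("ORAL", ORAL_DOSE, one_compartment_oral(t, ORAL_DOSE, p)),
            ("IV", IV_DOSE, one_compartment_iv(t, IV_DOSE, p)),
        ):
            conc = curve * 1000.0  # mg/L -> ng/mL (µg/mL -> *1000 ng/mL)
            if noise_sd > 0:
                conc = conc * np.exp(rng.normal(0.0, noise_sd, size=conc.size))
            for tj, cj in zip(t, conc):
                rows.append(
                    {
                        "compound_id": cid,
                        "route": route,
                        "dose": dose,
                        "time_h": tj,
                        "conc_ng_ml": cj,
                    }
                )
    truth = pd.DataFrame(
        [
            {
                "compound_id": f"SYN-{i + 1:03d}",
                "f_true_percent": p.f_true * 100.0,
                "auc_dn_oral": analytic_auc_oral(1.0, p) * 1000.0,
                "auc_dn_iv": analytic_auc_iv(1.0, p) * 1000.0,
            }
            for i in range(config.n_compounds)
        ]
    )
    return pd.DataFrame(rows), truth


# ------------------------------------------------------------ property table

LOGK80_RANGE = (0.2, 1.6)


def noise_sd_for_target_r2(slope: float, x_lo: float, x_hi: float,
                           target_r2: float) -> float:
    """Noise level giving a population r² equal to ``target_r2`` for x
    uniform on [x_lo, x_hi]."""
    if not 0.0 < target_r2 <= 1.0:
        raise ValueError("target_r2 must be in (0, 1]")
    var_x = (x_hi - x_lo) ** 2 / 12.0
    return abs(slope) * math.sqrt(var_x * (1.0 / target_r2 - 1.0))


def f_from_er(er: np.ndarray | float) -> np.ndarray | float:
    """Stated decreasing map from efflux ratio to oral bioavailability (%):
    F = 30 * exp(-ER / 2)."""
    return 30.0 * np.exp(-np.asarray(er, dtype=float) / 2.0)


def gen_property_table(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compound table with a planted efflux-ratio / lipophilicity line.

    log k'80 is uniform over its stated range; ER = slope*logk80 +
    intercept + Gaussian noise, floored at a small positive value; F% is
    a stated decreasing function of ER.
    """
    rng = _rng(config.seed, "table")
    rp = config.relation_params
    x = rng.uniform(*LOGK80_RANGE, size=config.n_compounds)
    noise = rng.normal(0.0, rp.noise_sd, size=config.n_compounds)
    er = np.maximum(rp.slope * x + rp.intercept + noise, rp.er_floor)
    f = f_from_er(er)
    obs = pd.DataFrame(
        {
            "compound_id": [f"SYN-{i + 1:03d}" for i in range(config.n_compounds)],
            "logk80_plrps": x,
            "er": er,
            "f_percent": f,
        }
    )
    truth = pd.DataFrame(
        {
            "slope": [rp.slope],
            "intercept": [rp.intercept],
            "noise_sd": [rp.noise_sd],
        }
    )
    return obs, truth
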