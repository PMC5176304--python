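"""Ground-truthed synthetic data for every stage of the pipeline.

These generators emulate the study's data shapes without any downloads:

* a Cn-symmetric toy oligomer with planted surface and buried residues and
  one central-ligand copy per subunit, for exercising the conjugation-site
  scan with a known answer;
* Michaelis-Menten substrate-depletion absorbance traces (20 s sampling
  over 10 min at 292 nm), integrated with fixed-step RK4;
* mono-exponential IV and absorption-elimination SC serum profiles;
* replicate per-well proliferating-cell counts with a planted true
  stimulation index (negative-binomial, n = 8 wells per condition).

Every generator is a pure function of its arguments — identical spec + seed
always reproduces identical output, byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .immuno import DonorWellCounts
from .kinetics import DEFAULT_EPSILON292, ProgressCurve
from .pk import PKProfile
from .sasa import golden_spiral_points
from .structio import Atom, Residue, Structure, assign_radii

__all__ = [
    "ToyOligomerSpec",
    "make_toy_oligomer",
    "make_progress_curves",
    "make_pk_profile",
    "make_pbmc_counts",
]


@dataclass(frozen=True)
class ToyOligomerSpec:
    n_subunits: int = 4
    n_positions: int = 8                      # residues per subunit
    planted_surface_positions: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    planted_buried_positions: tuple[int, ...] = (7, 8)
    radius: float = 60.0                      # Å, Cα shell radius
    ligand_offset: float = 5.0                # Å from the oligomer center
    rng_seed: int = 0

    def __post_init__(self):
        if set(self.planted_surface_positions) & set(self.planted_buried_positions):
            raise ValueError("planted surface/buried sets must be disjoint")
        planted = set(self.planted_surface_positions) | set(self.planted_buried_positions)
        if planted != set(range(1, self.n_positions + 1)):
            raise ValueError("planted sets must partition positions 1..n_positions")
        if self.n_subunits < 1:
            raise ValueError("need at least one subunit")


def _rotation_z(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _residue_triad(center: np.ndarray, chain_id: str, number: int, name: str, serial0: int, hetero=False):
    """A pseudo-residue: N/CA/C carbons 1.2 Å either side of the Cα."""
    offsets = {"N": np.array([-1.2, 0.0, 0.0]), "CA": np.zeros(3), "C": np.array([1.2, 0.0, 0.0])}
    elements = {"N": "N", "CA": "C", "C": "C"}
    res = Residue(chain_id, number, "", name)
    for i, (aname, off) in enumerate(offsets.items()):
        p = center + off
        res.atoms.append(
            Atom(
                serial=serial0 + i,
                name=aname,
                element=elements[aname],
                alt_loc="",
                residue_name=name,
                chain_id=chain_id,
                residue_number=number,
                insertion_code="",
                x=float(p[0]),
                y=float(p[1]),
                z=float(p[2]),
                occupancy=1.0,
                is_hetero=hetero,
            )
        )
    return res


def _burial_cage(center: np.ndarray, chain_id: str, number: int, serial0: int) -> Residue:
    """A cage residue whose 60 shell atoms entomb the residue at ``center``.

    The cage atoms carry non-CA names so the site scan skips the cage
    position itself (no alpha-carbon -> excluded and reported).
    """
    res = Residue(chain_id, number, "", "CAG")
    shell = center + 4.5 * golden_spiral_points(60)
    for i, p in enumerate(shell):
        res.atoms.append(
            Atom(
                serial=serial0 + i,
                name=f"X{i}",
                element="C",
                alt_loc="",
                residue_name="CAG",
                chain_id=chain_id,
                residue_number=number,
                insertion_code="",
                x=float(p[0]),
                y=float(p[1]),
                z=float(p[2]),
                occupancy=1.0,
                is_hetero=False,
            )
        )
    return res


def make_toy_oligomer(spec: ToyOligomerSpec) -> tuple[Structure, dict]:
    """Build a Cn-symmetric toy oligomer with a planted pass/fail answer.

    Chain 'A' places its residues on a sphere octant; chains B, C, ... are
    exact z-rotations of it, so per-chain metrics of equivalent positions
    agree to machine precision.  Buried positions get a blocker cage
    (recorded as extra cage residues numbered from 1000); each subunit also
    carries one hetero ligand residue ("LIG") holding a single "C5" atom at
    ``ligand_offset`` from the center, i.e. far inside the ligand-distance
    threshold of every planted position at the default radius.

    Returns ``(structure, truth)`` where truth lists which positions must
    pass/fail the exposure criterion and the expected ligand distance range.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_positions
    # deterministic-but-seeded placement: jittered ladder inside one wedge,
    # kept apart so planted surface residues never occlude each other
    wedge = 2 * math.pi / spec.n_subunits
    base_angles = (np.arange(n) + 0.5) / n * (wedge * 0.8) + 0.1 * wedge
    base_angles = base_angles + rng.uniform(-0.1, 0.1, size=n) * wedge / n
    zs = np.linspace(-0.55, 0.55, n) * spec.radius + rng.uniform(-1.0, 1.0, size=n)

    chain_ids = [chr(ord("A") + i) for i in range(spec.n_subunits)]
    protein_chains: dict[str, list[Residue]] = {}
    ligand_groups: list[Residue] = []
    serial = 1
    truth = {
        "must_pass": sorted(spec.planted_surface_positions),
        "must_fail": sorted(spec.planted_buried_positions),
    }

    base_centers = {}
    for idx in range(n):
        pos = idx + 1
        rho = math.sqrt(max(spec.radius**2 - zs[idx] ** 2, 1.0))
        base_centers[pos] = np.array(
            [rho * math.cos(base_angles[idx]), rho * math.sin(base_angles[idx]), zs[idx]]
        )

    # geometric feasibility: planted surface residues must not occlude each
    # other (or a burial cage), else the planted truth would be wrong
    all_centers = []
    for s_i in range(spec.n_subunits):
        rot = _rotation_z(wedge * s_i)
        all_centers.extend(rot @ base_centers[pos] for pos in range(1, n + 1))
    pts = np.vstack(all_centers)
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    if d.min() < 9.0:
        raise ValueError(
            f"geometric infeasibility: residue centers come within {d.min():.1f} Å; "
            "reduce n_positions or enlarge radius"
        )

    for s_i, cid in enumerate(chain_ids):
        rot = _rotation_z(wedge * s_i)
        residues = []
        cages = []
        for pos in range(1, n + 1):
            center = rot @ base_centers[pos]
            residues.append(_residue_triad(center, cid, pos, "GLY", serial))
            serial += 3
            if pos in spec.planted_buried_positions:
                cages.append(_burial_cage(center, cid, 1000 + pos, serial))
                serial += 60
        protein_chains[cid] = residues + cages

        lig_center = rot @ np.array([spec.ligand_offset, 0.0, 0.0])
        lig = Residue(cid, 900, "", "LIG")
        lig.atoms.append(
            Atom(
                serial=serial,
                name="C5",
                element="C",
                alt_loc="",
                residue_name="LIG",
                chain_id=cid,
                residue_number=900,
                insertion_code="",
                x=float(lig_center[0]),
                y=float(lig_center[1]),
                z=float(lig_center[2]),
                occupancy=1.0,
                is_hetero=True,
            )
        )
        serial += 1
        ligand_groups.append(lig)

    structure = Structure(protein_chains=protein_chains, ligand_groups=ligand_groups, source_id=f"toy-C{spec.n_subunits}")
    assign_radii(structure)
    truth["ligand_dist_min"] = spec.radius - spec.ligand_offset
    return structure, truth


def make_progress_curves(
    kcat: float,
    km: float,
    e0: float,
    s0_list: list[float],
    dt: float = 20.0,
    duration: float = 600.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    epsilon292: float = DEFAULT_EPSILON292,
    path_length: float = 1.0,
    rk_step: float = 1.0,
) -> list[ProgressCurve]:
    """Substrate-depletion absorbance traces from the Michaelis-Menten ODE.

    dS/dt = -kcat*E0*S/(KM+S) is integrated with fixed-step 4th-order
    Runge-Kutta (1 s), sampled on the 20 s grid for 10 min, mapped to 292 nm
    absorbance by Beer-Lambert, and optionally given additive Gaussian
    read noise (absorbance units).
    """
    if min(kcat, km, e0) <= 0:
        raise ValueError("kinetic parameters must be positive")
    rng = np.random.default_rng(seed)
    n_grid = int(round(duration / dt)) + 1
    sample_times = np.arange(n_grid) * dt

    def dS(s_):
        return -kcat * e0 * s_ / (km + s_)

    curves = []
    for s0 in s0_list:
        s = float(s0)
        t = 0.0
        samples = [s]
        next_sample = dt
        n_steps = int(round(duration / rk_step))
        for _ in range(n_steps):
            k1 = dS(s)
            k2 = dS(s + 0.5 * rk_step * k1)
            k3 = dS(s + 0.5 * rk_step * k2)
            k4 = dS(s + rk_step * k3)
            s = s + rk_step / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += rk_step
            if t >= next_sample - 1e-9:
                samples.append(s)
                next_sample += dt
        s_uM = np.array(samples[:n_grid])
        a292 = epsilon292 * path_length * s_uM * 1e-6
        if noise_sd > 0:
            a292 = a292 + rng.normal(0.0, noise_sd, size=a292.shape)
        curves.append(
            ProgressCurve(
                times=sample_times,
                a292=a292,
                s0=float(s0),
                e0=e0,
                path_length=path_length,
                curve_id=f"s0={s0:g}uM",
            )
        )
    return curves


def make_pk_profile(
    half_life: float,
    route: str,
    times: np.ndarray,
    dose: float,
    c0: float | None = None,
    cmax: float | None = None,
    ka: float = 10.0,
    noise_cv: float = 0.0,
    seed: int = 0,
    subject_id: str = "",
) -> PKProfile:
    """Synthetic serum concentration profile.

    IV: c(t) = c0 * 2^(-t / t_half).  SC: one-compartment first-order
    absorption, c(t) = A (e^{-ke t} - e^{-ka t}) with A scaled so the peak
    equals ``cmax``; with ka >> ke the tail is a clean terminal phase.
    Noise, if any, is multiplicative lognormal with the given CV.
    """
    if half_life <= 0:
        raise ValueError("half_life must be positive")
    times = np.asarray(times, dtype=float)
    ke = math.log(2) / half_life
    if route == "IV":
        if c0 is None:
            raise ValueError("IV profile requires c0")
        conc = c0 * np.exp(-ke * times)
    elif route == "SC":
        if cmax is None:
            raise ValueError("SC profile requires cmax")
        if ka <= ke:
            raise ValueError("absorption must be faster than elimination (ka > ke)")
        tmax = math.log(ka / ke) / (ka - ke)
        peak = math.exp(-ke * tmax) - math.exp(-ka * tmax)
        amp = cmax / peak
        conc = amp * (np.exp(-ke * times) - np.exp(-ka * times))
    else:
        raise ValueError(f"route must be IV or SC, got {route!r}")
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log(1.0 + noise_cv**2))
        conc = conc * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=conc.shape)
    return PKProfile(times=times, conc=conc, dose=dose, route=route, subject_id=subject_id)


def make_pbmc_counts(
    baseline_mean: float,
    true_si: float,
    n_replicates: int = 8,
    dispersion: float = 0.1,
    n_donors: int = 1,
    seed: int = 0,
) -> list[tuple[DonorWellCounts, DonorWellCounts]]:
    """Replicate treated/untreated well counts with a planted true SI.

    Counts are negative-binomial with Var = m + dispersion * m² (the
    overdispersed null realistic for per-well cell counts); ``dispersion``
    -> 0 recovers Poisson.  Returns (treated, reference) pairs per donor.
    """
    if baseline_mean <= 0 or true_si <= 0:
        raise ValueError("baseline_mean and true_si must be positive")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    rng = np.random.default_rng(seed)

    def draw(mean: float, size: int) -> np.ndarray:
        if dispersion == 0:
            return rng.poisson(mean, size=size)
        r = 1.0 / dispersion
        p = r / (r + mean)
        return rng.negative_binomial(r, p, size=size)

    out = []
    for d in range(n_donors):
        ref = DonorWellCounts(f"donor{d:04d}", "buffer", draw(baseline_mean, n_replicates))
        trt = DonorWellCounts(f"donor{d:04d}", "test", draw(baseline_mean * true_si, n_replicates))
        out.append((trt, ref))
    return out
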