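"""Seeded generators of configurations with known ground truth.

Every analysis stage in the package can be exercised against systems built
here: grafted freely-jointed chains on a spherical core (closed-form chain
statistics), a random-packed 3-site water bath with ions (known counts,
neutrality, optional cavity), charged spherical shells (closed-form Coulomb
field/potential), Brownian walkers (known diffusion coefficient), and
power-law volume-fraction profiles (known brush exponent).

The generated ground-truth metadata accompanies each output and is meant
for test suites, never for the analysis code itself.  Ideal (freely
jointed) chains and random water packings are deliberately non-physical in
their local structure; they provide exact statistical references, not
equilibrated liquids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ANG2_PER_PS_TO_M2_PER_S, AtomRecord, Frame, Topology, Trajectory
from .profiles import RadialProfile

AVOGADRO = 6.02214076e23

# TIP3P-like water geometry and charges
WATER_OH = 0.9572  # Å
WATER_ANGLE = 104.52  # degrees
WATER_Q_O = -0.834  # e
WATER_Q_H = 0.417  # e


@dataclass
class GeneratorSpec:
    """Seeded generator request: ``kind`` selects the generator, ``params``
    are its keyword arguments."""

    seed: int
    kind: str
    params: dict = field(default_factory=dict)


def generate(spec: GeneratorSpec):
    """Dispatch a :class:`GeneratorSpec` to the matching generator."""
    table = {
        "grafted_np": generate_grafted_np,
        "water_bath": generate_water_bath,
        "charged_shells": generate_charged_shells,
        "brownian": generate_brownian,
        "power_law_profile": generate_power_law_profile,
    }
    if spec.kind not in table:
        raise ValueError(f"unknown generator kind {spec.kind!r}: {sorted(table)}")
    return table[spec.kind](seed=spec.seed, **spec.params)


def fibonacci_sphere(n: int, radius: float = 1.0) -> np.ndarray:
    """n quasi-uniform points on a sphere (golden-spiral lattice)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return radius * np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def _random_unit(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# grafted nanoparticle
# ---------------------------------------------------------------------------

def generate_grafted_np(
    n_chains: int = 50,
    n_bonds: int = 10,
    bond_length: float = 1.5,
    core_radius: float = 10.0,
    box: float | None = None,
    n_frames: int = 1,
    dt: float = 10.0,
    mode: str = "fjc",
    n_core_shell: int = 64,
    seed: int = 0,
) -> tuple[Topology, Trajectory, dict]:
    """Chains grafted radially on a spherical core.

    Each chain has ``n_bonds`` bonds (``n_bonds + 1`` heavy atoms); the
    anchor-side first heavy atom sits on the core surface and the first
    bond points radially outward.  ``mode='fjc'`` draws the remaining bond
    orientations uniformly (freely-jointed chain, <h²> = N·b²);
    ``mode='straight'`` extends every bond radially, so each terminus ends
    at exactly ``core_radius + n_bonds·bond_length`` from the center.
    Chain conformations are resampled independently every frame.
    """
    if mode not in ("fjc", "straight"):
        raise ValueError("mode must be 'fjc' or 'straight'")
    if n_chains < 1 or n_bonds < 1:
        raise ValueError("need at least one chain and one bond")
    rng = np.random.default_rng(seed)
    max_extent = core_radius + n_bonds * bond_length
    if box is None:
        box = 2.0 * max_extent + 20.0
    if box < 2.0 * max_extent:
        raise ValueError("box too small for fully extended chains")

    center = np.array([box / 2.0] * 3)
    anchors_dir = fibonacci_sphere(n_chains, 1.0)
    shell = fibonacci_sphere(n_core_shell, core_radius) + center

    atoms: list[AtomRecord] = []
    atoms.append(AtomRecord("C", mass=12.011))  # core center pseudo-atom
    for _ in range(n_core_shell):
        atoms.append(AtomRecord("C", mass=12.011))
    core_idx = list(range(1 + n_core_shell))

    chains: dict[int, list[int]] = {}
    bonds: list[tuple[int, int]] = []
    peg_idx: list[int] = []
    next_idx = len(atoms)
    for c in range(n_chains):
        order = []
        for b in range(n_bonds + 1):
            element = "O" if b % 3 == 2 else "C"
            atoms.append(AtomRecord(element, mass=15.999 if element == "O" else 12.011))
            order.append(next_idx)
            peg_idx.append(next_idx)
            if b > 0:
                bonds.append((next_idx - 1, next_idx))
            next_idx += 1
        chains[c] = order

    def chain_positions(rng_frame: np.random.Generator) -> np.ndarray:
        pos = np.empty((n_chains * (n_bonds + 1), 3))
        k = 0
        for c in range(n_chains):
            u = anchors_dir[c]
            p = center + core_radius * u
            pos[k] = p
            k += 1
            for b in range(n_bonds):
                if mode == "straight" or b == 0:
                    step = bond_length * u
                else:
                    step = bond_length * _random_unit(rng_frame, 1)[0]
                p = p + step
                pos[k] = p
                k += 1
        return pos

    frames = []
    for f in range(n_frames):
        pos = np.vstack([center[None, :], shell, chain_positions(rng)])
        frames.append(Frame(pos, time=f * dt, box=np.array([box] * 3)))

    topo = Topology(
        atoms,
        bonds=bonds,
        groups={"NP_CORE": core_idx, "PEG": peg_idx},
        chains=chains,
    )
    meta = {
        "n_chains": n_chains,
        "n_bonds": n_bonds,
        "bond_length": bond_length,
        "core_radius": core_radius,
        "box": box,
        "center": center.tolist(),
        "mode": mode,
        "expected_h2": n_bonds * bond_length**2,
        "expected_d_straight": core_radius + n_bonds * bond_length,
        "atoms_per_chain": n_bonds + 1,
    }
    return topo, Trajectory(frames), meta


# ---------------------------------------------------------------------------
# water bath
# ---------------------------------------------------------------------------

def generate_water_bath(
    box: float = 30.0,
    density: float = 0.0334,
    cavity_radius: float = 0.0,
    ion_molarity: float = 0.0,
    min_dist: float = 2.0,
    max_attempts: int = 200,
    seed: int = 0,
) -> tuple[Topology, Trajectory, dict]:
    """Random-packed bath of neutral 3-site water with optional ions.

    The molecule count is ``floor(density · box³)`` (deterministic).  Oxygen
    sites are uniform random positions rejected inside the central cavity or
    within ``min_dist`` of a previous oxygen; hydrogens are placed at the
    TIP3P-like geometry in a random orientation.  Ion pairs (count
    ``round(molarity · N_A · V)``) keep the box exactly neutral.  A central
    pseudo-atom labelled NP_CORE provides the profile center.
    """
    rng = np.random.default_rng(seed)
    volume = box**3
    n_mol = int(density * volume)
    n_pairs = int(round(ion_molarity * AVOGADRO * volume * 1e-27))
    center = np.array([box / 2.0] * 3)

    def place(n: int, existing: list[np.ndarray]) -> np.ndarray:
        placed: list[np.ndarray] = []
        pool = [np.array(existing)] if existing else []
        for _ in range(n):
            for attempt in range(max_attempts):
                p = rng.uniform(0.0, box, size=3)
                if cavity_radius > 0 and np.linalg.norm(p - center) < cavity_radius:
                    continue
                ok = True
                for arr in pool + ([np.array(placed)] if placed else []):
                    d = arr - p
                    d -= box * np.round(d / box)
                    if (np.sum(d**2, axis=1) < min_dist**2).any():
                        ok = False
                        break
                if ok:
                    placed.append(p)
                    break
            else:
                raise RuntimeError(
                    f"packing failed after {max_attempts} attempts "
                    f"(density {density}, min_dist {min_dist})"
                )
        return np.array(placed) if placed else np.empty((0, 3))

    o_pos = place(n_mol, [])
    ion_pos = place(2 * n_pairs, list(o_pos)) if n_pairs else np.empty((0, 3))

    atoms: list[AtomRecord] = [AtomRecord("X", mass=1000.0)]  # center marker
    positions = [center]
    groups: dict[str, list[int]] = {"NP_CORE": [0], "WATER": [], "ION_NA": [], "ION_CL": []}
    bonds: list[tuple[int, int]] = []
    half_angle = np.deg2rad(WATER_ANGLE) / 2.0
    idx = 1
    for p in o_pos:
        axis = _random_unit(rng, 1)[0]
        ref = _random_unit(rng, 1)[0]
        perp = np.cross(axis, ref)
        perp /= np.linalg.norm(perp)
        h1 = p + WATER_OH * (np.cos(half_angle) * axis + np.sin(half_angle) * perp)
        h2 = p + WATER_OH * (np.cos(half_angle) * axis - np.sin(half_angle) * perp)
        atoms.append(AtomRecord("O", charge=WATER_Q_O, mass=15.999,
                                lj_epsilon=0.1521, lj_sigma=3.1507,
                                hbond_role="donor-heavy"))
        atoms.append(AtomRecord("H", charge=WATER_Q_H, mass=1.008, is_heavy=False,
                                hbond_role="polar-hydrogen"))
        atoms.append(AtomRecord("H", charge=WATER_Q_H, mass=1.008, is_heavy=False,
                                hbond_role="polar-hydrogen"))
        positions.extend([p, h1, h2])
        bonds.extend([(idx, idx + 1), (idx, idx + 2)])
        groups["WATER"].extend([idx, idx + 1, idx + 2])
        idx += 3
    for k, p in enumerate(ion_pos):
        if k < n_pairs:
            atoms.append(AtomRecord("Na", charge=1.0, mass=22.99))
            groups["ION_NA"].append(idx)
        else:
            atoms.append(AtomRecord("Cl", charge=-1.0, mass=35.45))
            groups["ION_CL"].append(idx)
        positions.append(p)
        idx += 1

    topo = Topology(atoms, bonds=bonds, groups=groups)
    traj = Trajectory([Frame(np.array(positions), time=0.0, box=np.array([box] * 3))])
    meta = {
        "n_molecules": n_mol,
        "n_ion_pairs": n_pairs,
        "box": box,
        "density": density,
        "cavity_radius": cavity_radius,
        "center": center.tolist(),
        "total_charge": 0.0,
    }
    return topo, traj, meta


# ---------------------------------------------------------------------------
# charged shells
# ---------------------------------------------------------------------------

def generate_charged_shells(
    shells: list[tuple[float, float, int]] = (),
    box: float = 100.0,
    seed: int = 0,
) -> tuple[Topology, Trajectory, dict]:
    """Point charges spread uniformly on concentric spheres.

    ``shells`` is a list of ``(radius, total_charge_e, n_points)``.  The
    closed-form Coulomb superposition field and potential are recorded in
    the metadata for verification: outside all shells,
    E(r) = k·ΣQ/r² and φ(r) = k·ΣQ·(1/r − 1/r_ref).
    """
    rng = np.random.default_rng(seed)
    center = np.array([box / 2.0] * 3)
    atoms: list[AtomRecord] = [AtomRecord("X", mass=1000.0)]
    positions = [center]
    groups: dict[str, list[int]] = {"NP_CORE": [0], "MOBILE": []}
    idx = 1
    for radius, q_total, n_pts in shells:
        if radius >= box / 2.0:
            raise ValueError(f"shell radius {radius} does not fit in the box")
        pts = fibonacci_sphere(n_pts, radius)
        # random rotation to decorrelate shells
        q_rot, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        pts = pts @ q_rot.T + center
        for p in pts:
            atoms.append(AtomRecord("Q", charge=q_total / n_pts, mass=1.0))
            positions.append(p)
            groups["MOBILE"].append(idx)
            idx += 1
    topo = Topology(atoms, groups=groups)
    traj = Trajectory([Frame(np.array(positions), time=0.0, box=np.array([box] * 3))])
    meta = {
        "shells": [list(s) for s in shells],
        "box": box,
        "center": center.tolist(),
        "total_charge": float(sum(q for _, q, _ in shells)),
    }
    return topo, traj, meta


# ---------------------------------------------------------------------------
# Brownian walkers
# ---------------------------------------------------------------------------

def generate_brownian(
    n_walkers: int = 100,
    n_steps: int = 1000,
    dt: float = 1.0,
    diffusion: float = 1.0e-10,
    box: float = 1.0e6,
    seed: int = 0,
) -> tuple[Topology, Trajectory, dict]:
    """Independent Brownian walkers with a known diffusion coefficient.

    ``diffusion`` is in m²·s⁻¹; per-step Gaussian displacements have
    per-dimension variance 2·D·dt after conversion to Ų·ps⁻¹.
    Trajectories are unwrapped (the box is only bookkeeping).
    """
    if dt <= 0 or n_steps < 1 or diffusion < 0:
        raise ValueError("dt, steps must be positive; diffusion must be >= 0")
    rng = np.random.default_rng(seed)
    d_ang = diffusion / ANG2_PER_PS_TO_M2_PER_S  # Ų ps⁻¹
    sigma = np.sqrt(2.0 * d_ang * dt)
    start = np.full((n_walkers, 3), box / 2.0)
    steps = rng.normal(0.0, sigma, size=(n_steps, n_walkers, 3)) if sigma > 0 else \
        np.zeros((n_steps, n_walkers, 3))
    path = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)])
    atoms = [AtomRecord("W", mass=1.0) for _ in range(n_walkers)]
    topo = Topology(atoms, groups={"WALKER": list(range(n_walkers))})
    frames = [Frame(path[k], time=k * dt, box=np.array([box] * 3))
              for k in range(n_steps + 1)]
    meta = {
        "diffusion_m2s": diffusion,
        "dt_ps": dt,
        "n_walkers": n_walkers,
        "n_steps": n_steps,
        "step_variance_ang2": 2.0 * d_ang * dt,
    }
    return topo, Trajectory(frames), meta


# ---------------------------------------------------------------------------
# power-law volume-fraction profile
# ---------------------------------------------------------------------------

def generate_power_law_profile(
    exponent: float = -4.0 / 3.0,
    amplitude: float = 1.0,
    r_lo: float = 5.0,
    r_hi: float = 30.0,
    bin_width: float = 0.1,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[RadialProfile, dict]:
    """φ(r) = A·r^α on a uniform radial grid, with optional multiplicative
    lognormal noise (``noise`` is the log-space standard deviation)."""
    if not np.isfinite(exponent):
        raise ValueError("exponent must be finite")
    if r_lo <= 0 or r_hi <= r_lo:
        raise ValueError("window must satisfy 0 < r_lo < r_hi")
    rng = np.random.default_rng(seed)
    n_bins = int(round((r_hi - r_lo) / bin_width))
    edges = r_lo + bin_width * np.arange(n_bins + 1)
    r = 0.5 * (edges[:-1] + edges[1:])
    values = amplitude * r**exponent
    if noise > 0:
        values = values * rng.lognormal(0.0, noise, size=values.shape)
    prof = RadialProfile(edges, values, "volume_fraction", 1)
    meta = {"exponent": exponent, "amplitude": amplitude, "noise": noise}
    return prof, meta
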