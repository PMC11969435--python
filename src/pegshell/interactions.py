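"""Geometric hydrogen-bond counting and group-pair nonbonded energies.

Energies are pairwise Coulomb + Lennard-Jones sums under the minimum-image
convention, with CHARMM-family combining rules (arithmetic σ, geometric ε)
and 1–2/1–3 bonded exclusions.  Electrostatics are a direct truncated sum
(12 Å default cutoff) with an optional no-cutoff mode for point-charge
reference systems; reciprocal-space methods are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import COULOMB_KCAL_MOL_ANG, Frame, Topology, Trajectory, minimum_image


@dataclass
class HBondCriteria:
    """Geometric H-bond definition.

    ``d_max``: donor-heavy to acceptor-heavy distance bound (Å).
    ``angle_max``: bound (degrees) on the deviation of the H from the
    donor→acceptor axis.  ``vertex`` selects where the angle is measured:
    ``donor`` (default) takes ∠(donor→H, donor→acceptor); ``hydrogen``
    takes the deviation from linearity of donor–H···acceptor.
    """

    d_max: float = 3.0
    angle_max: float = 20.0
    vertex: str = "donor"

    def __post_init__(self) -> None:
        if self.d_max <= 0:
            raise ValueError("d_max must be > 0")
        if not 0 < self.angle_max < 90:
            raise ValueError("angle_max must be in (0, 90) degrees")
        if self.vertex not in ("donor", "hydrogen"):
            raise ValueError("vertex must be 'donor' or 'hydrogen'")


@dataclass
class NonbondedScheme:
    """Cutoffs, switching and exclusions of the pairwise energy sum.

    ``cutoff=None`` enables the no-cutoff direct sum.  ``lj_switch`` is an
    optional ``(r_on, r_off)`` pair with ``r_off`` equal to the cutoff;
    1–2 and 1–3 bonded pairs are excluded, 1–4 included unscaled.
    """

    cutoff: float | None = 12.0
    lj_switch: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.lj_switch is not None:
            r_on, r_off = self.lj_switch
            if not 0 < r_on < r_off:
                raise ValueError("switch window must satisfy 0 < r_on < r_off")
            if self.cutoff is not None and abs(r_off - self.cutoff) > 1e-9:
                raise ValueError("switch r_off must equal the cutoff")


@dataclass
class EnergyBreakdown:
    """Coulomb + Lennard-Jones decomposition (kcal·mol⁻¹)."""

    coulomb: float
    lennard_jones: float

    @property
    def total(self) -> float:
        return self.coulomb + self.lennard_jones


@dataclass
class EnergySeriesSummary:
    """Per-frame energy series with mean ± std over the analysis window."""

    coulomb_series: np.ndarray
    lj_series: np.ndarray

    @property
    def total_series(self) -> np.ndarray:
        return self.coulomb_series + self.lj_series

    @property
    def mean(self) -> EnergyBreakdown:
        return EnergyBreakdown(float(self.coulomb_series.mean()),
                               float(self.lj_series.mean()))

    @property
    def std_total(self) -> float:
        return float(self.total_series.std(ddof=0))


# ---------------------------------------------------------------------------
# pair bookkeeping
# ---------------------------------------------------------------------------

def excluded_pairs(topology: Topology) -> set[tuple[int, int]]:
    """Bonded 1–2 and 1–3 pairs (canonical (min, max) tuples)."""
    adj = topology.bonded_neighbours()
    excl: set[tuple[int, int]] = set()
    for i, j in topology.bonds:
        excl.add((i, j))
    for j, neigh in adj.items():
        ns = sorted(neigh)
        for a in range(len(ns)):
            for b in range(a + 1, len(ns)):
                excl.add((ns[a], ns[b]))
    return excl


def _unique_pairs(selA: np.ndarray, selB: np.ndarray) -> np.ndarray:
    """Unordered pairs (i ∈ A, j ∈ B, i ≠ j); pairs inside A∩B counted once."""
    ii, jj = np.meshgrid(selA, selB, indexing="ij")
    pairs = np.stack([ii.ravel(), jj.ravel()], axis=1)
    pairs = pairs[pairs[:, 0] != pairs[:, 1]]
    pairs = np.sort(pairs, axis=1)
    return np.unique(pairs, axis=0)


def _validate_parameters(topology: Topology, indices: np.ndarray) -> None:
    q = topology.charges[indices]
    bad = indices[~np.isfinite(q)]
    if bad.size:
        raise ValueError(f"missing partial charges for atoms {bad.tolist()}")


def _switch_factor(r: np.ndarray, r_on: float, r_off: float) -> np.ndarray:
    """CHARMM energy-switching function, 1 below r_on, 0 above r_off."""
    s = np.ones_like(r)
    mid = (r > r_on) & (r < r_off)
    r2, on2, off2 = r[mid] ** 2, r_on**2, r_off**2
    s[mid] = (off2 - r2) ** 2 * (off2 + 2 * r2 - 3 * on2) / (off2 - on2) ** 3
    s[r >= r_off] = 0.0
    return s


def pair_interaction_energy(
    frame: Frame,
    topology: Topology,
    selA: np.ndarray,
    selB: np.ndarray,
    scheme: NonbondedScheme | None = None,
) -> EnergyBreakdown:
    """Nonbonded interaction energy between two selections for one frame.

    Sums Coulomb (truncated at the cutoff) and Lennard-Jones (optionally
    switched) terms over unique minimum-image pairs, skipping 1–2/1–3
    bonded exclusions.  Symmetric in A/B.
    """
    scheme = scheme or NonbondedScheme()
    selA = np.asarray(selA, dtype=np.intp)
    selB = np.asarray(selB, dtype=np.intp)
    if scheme.cutoff is not None and scheme.cutoff >= 0.5 * float(frame.box.min()):
        raise ValueError(
            f"cutoff {scheme.cutoff} Å must be below half the shortest box edge "
            f"({0.5 * float(frame.box.min()):.2f} Å)"
        )
    both = np.union1d(selA, selB)
    _validate_parameters(topology, both)
    pairs = _unique_pairs(selA, selB)
    if pairs.size == 0:
        return EnergyBreakdown(0.0, 0.0)
    excl = excluded_pairs(topology)
    if excl:
        keep = np.array([(i, j) not in excl for i, j in pairs], dtype=bool)
        pairs = pairs[keep]
    if pairs.size == 0:
        return EnergyBreakdown(0.0, 0.0)
    i, j = pairs[:, 0], pairs[:, 1]
    d = minimum_image(frame.positions[i] - frame.positions[j], frame.box)
    r = np.linalg.norm(d, axis=1)
    within = np.ones_like(r, dtype=bool)
    if scheme.cutoff is not None:
        within = r < scheme.cutoff
    r_in = r[within]
    q = topology.charges
    coulomb = float(np.sum(COULOMB_KCAL_MOL_ANG * q[i[within]] * q[j[within]] / r_in))
    sig = 0.5 * (topology.lj_sigma[i[within]] + topology.lj_sigma[j[within]])
    eps = np.sqrt(topology.lj_epsilon[i[within]] * topology.lj_epsilon[j[within]])
    active = eps > 0
    lj = 0.0
    if active.any():
        sr6 = (sig[active] / r_in[active]) ** 6
        lj_terms = 4.0 * eps[active] * (sr6**2 - sr6)
        if scheme.lj_switch is not None:
            lj_terms = lj_terms * _switch_factor(r_in[active], *scheme.lj_switch)
        lj = float(lj_terms.sum())
    return EnergyBreakdown(coulomb, lj)


def energy_series(
    traj: Trajectory,
    topology: Topology,
    pairs: dict[str, tuple[np.ndarray, np.ndarray]],
    scheme: NonbondedScheme | None = None,
) -> dict[str, EnergySeriesSummary]:
    """Per-frame group-pair energies with mean ± std over the trajectory
    window.  ``pairs`` maps a label (e.g. ``"NP/PEG"``) to (selA, selB)."""
    scheme = scheme or NonbondedScheme()
    out: dict[str, EnergySeriesSummary] = {}
    for label, (selA, selB) in pairs.items():
        cou = np.zeros(len(traj))
        lj = np.zeros(len(traj))
        for k, frame in enumerate(traj):
            e = pair_interaction_energy(frame, topology, selA, selB, scheme)
            cou[k], lj[k] = e.coulomb, e.lennard_jones
        out[label] = EnergySeriesSummary(cou, lj)
    return out


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def count_hbonds(
    frame: Frame,
    topology: Topology,
    donors_sel: np.ndarray,
    acceptors_sel: np.ndarray,
    criteria: HBondCriteria | None = None,
) -> int:
    """Count donor-H···acceptor hydrogen bonds in one frame.

    A pair counts when the minimum-image donor-heavy/acceptor-heavy
    distance is below ``d_max`` and the angular criterion passes.  A donor
    bearing two polar hydrogens can contribute two bonds.
    """
    criteria = criteria or HBondCriteria()
    adj = topology.bonded_neighbours()
    roles = [a.hbond_role for a in topology.atoms]
    donors = [int(k) for k in np.asarray(donors_sel, dtype=np.intp)
              if roles[k] == "donor-heavy"]
    acceptors = np.asarray(
        [int(k) for k in np.asarray(acceptors_sel, dtype=np.intp)
         if roles[k] == "acceptor-heavy"],
        dtype=np.intp,
    )
    if acceptors.size == 0 or not donors:
        return 0
    pos, box = frame.positions, frame.box
    cos_max = np.cos(np.deg2rad(criteria.angle_max))
    count = 0
    for d_idx in donors:
        hydrogens = [h for h in adj[d_idx] if roles[h] == "polar-hydrogen"]
        if not hydrogens:
            raise ValueError(f"donor atom {d_idx} has no bonded polar hydrogen")
        acc = acceptors[acceptors != d_idx]
        if acc.size == 0:
            continue
        da = minimum_image(pos[acc] - pos[d_idx], box)
        r_da = np.linalg.norm(da, axis=1)
        near = r_da < criteria.d_max
        if not near.any():
            continue
        da_n, r_n = da[near], r_da[near]
        for h_idx in hydrogens:
            dh = minimum_image(pos[h_idx] - pos[d_idx], box)
            if criteria.vertex == "donor":
                cosang = (da_n @ dh) / (r_n * np.linalg.norm(dh))
            else:
                ha = da_n - dh  # H -> acceptor, minimum-image consistent
                cosang = (ha @ (-dh)) / (np.linalg.norm(ha, axis=1) * np.linalg.norm(dh))
                cosang = -cosang  # deviation from linearity of D-H...A
            count += int(np.sum(cosang > cos_max))
    return count


def hbond_series(
    traj: Trajectory,
    topology: Topology,
    donors_sel: np.ndarray,
    acceptors_sel: np.ndarray,
    criteria: HBondCriteria | None = None,
) -> np.ndarray:
    """Per-frame hydrogen-bond counts."""
    return np.array(
        [count_hbonds(f, topology, donors_sel, acceptors_sel, criteria) for f in traj]
    )
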