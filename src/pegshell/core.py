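"""Shared data model: atoms, topology, frames, trajectories and selections.

Units are fixed package-wide: lengths in Å, times in ps, charges in
elementary charge e, masses in amu, energies in kcal·mol⁻¹.  Conversions
to reporting units (mV, m²·s⁻¹, nm⁻²) happen only at output boundaries.
Atom indices are 0-based internally; file writers emit each format's
native 1-based serials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import constants as _const

# Coulomb constant e²/(4πε₀) expressed in kcal·mol⁻¹·Å·e⁻², evaluated from
# CODATA constants rather than hard-coded.
COULOMB_KCAL_MOL_ANG = (
    _const.e**2 / (4.0 * np.pi * _const.epsilon_0) / _const.angstrom
    * _const.N_A / (_const.calorie * 1000.0)
)

# e/(4πε₀·Å) in volts: field/potential conversion for charges in e and radii in Å.
COULOMB_VOLT_ANG = _const.e / (4.0 * np.pi * _const.epsilon_0) / _const.angstrom

#: Conversion factor from Ų·ps⁻¹ to m²·s⁻¹.
ANG2_PER_PS_TO_M2_PER_S = 1.0e-8

#: Canonical group labels; the set is extensible (any string label is allowed).
STANDARD_GROUPS = ("NP_CORE", "PEG", "WATER", "ION_NA", "ION_CL")


@dataclass
class AtomRecord:
    """Static per-atom chemistry used by the analyses.

    ``hbond_role`` is one of ``none``, ``donor-heavy``, ``acceptor-heavy``
    or ``polar-hydrogen``.
    """

    element: str
    charge: float | None = 0.0
    mass: float = 1.0
    lj_epsilon: float = 0.0
    lj_sigma: float = 0.0
    is_heavy: bool = True
    hbond_role: str = "none"

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"atom mass must be > 0, got {self.mass}")
        if self.lj_sigma < 0 or self.lj_epsilon < 0:
            raise ValueError("LJ parameters must be >= 0")
        if self.hbond_role not in ("none", "donor-heavy", "acceptor-heavy", "polar-hydrogen"):
            raise ValueError(f"unknown hbond_role {self.hbond_role!r}")


class Topology:
    """Per-atom chemistry, bonds, group labels and PEG chain bookkeeping.

    Parameters
    ----------
    atoms
        One :class:`AtomRecord` per atom.
    bonds
        Iterable of 0-based index pairs.
    groups
        Mapping label -> iterable of atom indices.  Labels are free strings;
        the canonical ones are NP_CORE, PEG, WATER, ION_NA, ION_CL.
    chains
        Mapping chain id -> ordered heavy-atom index list from the anchor
        (NP-side) to the solution-side terminus.
    """

    def __init__(
        self,
        atoms: Sequence[AtomRecord],
        bonds: Iterable[tuple[int, int]] = (),
        groups: dict[str, Iterable[int]] | None = None,
        chains: dict[int, Sequence[int]] | None = None,
    ) -> None:
        self.atoms = list(atoms)
        n = len(self.atoms)
        self.bonds: list[tuple[int, int]] = []
        seen = set()
        for i, j in bonds:
            i, j = int(i), int(j)
            if i == j or not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"invalid bond ({i}, {j}) for {n} atoms")
            key = (min(i, j), max(i, j))
            if key not in seen:
                seen.add(key)
                self.bonds.append(key)
        self.groups: dict[str, np.ndarray] = {}
        for label, idx in (groups or {}).items():
            arr = np.asarray(sorted(set(int(k) for k in idx)), dtype=np.intp)
            if arr.size and (arr[0] < 0 or arr[-1] >= n):
                raise ValueError(f"group {label!r} has indices outside 0..{n - 1}")
            self.groups[label] = arr
        self.chains: dict[int, list[int]] = {}
        for cid, order in (chains or {}).items():
            order = [int(k) for k in order]
            if len(order) < 2:
                raise ValueError(f"chain {cid} has fewer than 2 heavy atoms")
            if any(k < 0 or k >= n for k in order):
                raise ValueError(f"chain {cid} has out-of-range indices")
            self.chains[int(cid)] = order
        self._validate()

    # -- derived arrays -------------------------------------------------
    def _validate(self) -> None:
        chain_of: dict[int, int] = {}
        for cid, order in self.chains.items():
            for k in order:
                if k in chain_of:
                    raise ValueError(f"atom {k} assigned to chains {chain_of[k]} and {cid}")
                chain_of[k] = cid
        core = set(self.groups.get("NP_CORE", ()))
        peg = set(self.groups.get("PEG", ()))
        water = set(self.groups.get("WATER", ()))
        ions = set(self.groups.get("ION_NA", ())) | set(self.groups.get("ION_CL", ()))
        for a, b, na, nb in (
            (core, peg, "NP_CORE", "PEG"),
            (core, water, "NP_CORE", "WATER"),
            (peg, water, "PEG", "WATER"),
            (peg, ions, "PEG", "ions"),
            (water, ions, "WATER", "ions"),
            (core, ions, "NP_CORE", "ions"),
        ):
            if a & b:
                raise ValueError(f"groups {na} and {nb} overlap")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def charges(self) -> np.ndarray:
        # None marks an absent charge; analyses that need charges reject NaN
        return np.array(
            [a.charge if a.charge is not None else np.nan for a in self.atoms],
            dtype=float,
        )

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    @property
    def lj_sigma(self) -> np.ndarray:
        return np.array([a.lj_sigma for a in self.atoms])

    @property
    def lj_epsilon(self) -> np.ndarray:
        return np.array([a.lj_epsilon for a in self.atoms])

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([a.is_heavy for a in self.atoms], dtype=bool)

    def bonded_neighbours(self) -> dict[int, set[int]]:
        adj: dict[int, set[int]] = {i: set() for i in range(self.n_atoms)}
        for i, j in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        return adj

    def chain_id_of(self, index: int) -> int | None:
        for cid, order in self.chains.items():
            if index in order:
                return cid
        return None

    def water_molecules(self) -> list[list[int]]:
        """Connected components of the WATER group, each [O, H, H]-like."""
        water = set(self.groups.get("WATER", ()))
        adj = self.bonded_neighbours()
        seen: set[int] = set()
        mols = []
        for start in sorted(water):
            if start in seen:
                continue
            comp, stack = [], [start]
            while stack:
                k = stack.pop()
                if k in seen:
                    continue
                seen.add(k)
                comp.append(k)
                stack.extend(m for m in adj[k] if m in water and m not in seen)
            mols.append(sorted(comp))
        return mols

    def check_water_neutrality(self, tol: float = 1e-9) -> None:
        q = self.charges
        for mol in self.water_molecules():
            net = float(q[list(mol)].sum())
            if abs(net) > tol:
                raise ValueError(f"water molecule {mol} has net charge {net:.3g} e")


@dataclass
class Frame:
    """A single configuration: positions (N, 3) in Å, time in ps, orthorhombic box."""

    positions: np.ndarray
    time: float = 0.0
    box: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 0.0]))

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (N, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions contain non-finite values")
        if self.box.shape != (3,):
            raise ValueError("box must be three orthorhombic edge lengths")
        if np.any(self.box <= 0):
            raise ValueError(f"box edges must be > 0, got {self.box}")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))


class Trajectory:
    """Time-ordered sequence of frames with a constant atom count."""

    def __init__(self, frames: Sequence[Frame]):
        frames = list(frames)
        if not frames:
            raise ValueError("trajectory must contain at least one frame")
        n = frames[0].n_atoms
        for k, f in enumerate(frames):
            if f.n_atoms != n:
                raise ValueError(
                    f"frame {k} has {f.n_atoms} atoms, expected {n} (constant atom count)"
                )
        times = np.array([f.time for f in frames])
        if len(times) > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        self.frames = frames

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, k):
        if isinstance(k, slice):
            return Trajectory(self.frames[k])
        return self.frames[k]

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def window(self, t_start: float | None = None, t_end: float | None = None) -> "Trajectory":
        """Frames with ``t_start <= time <= t_end`` (inclusive, either open)."""
        t = self.times
        mask = np.ones(len(t), dtype=bool)
        if t_start is not None:
            mask &= t >= t_start
        if t_end is not None:
            mask &= t <= t_end
        if not mask.any():
            raise ValueError("time window selects no frames")
        return Trajectory([f for f, m in zip(self.frames, mask) if m])

    def last_fraction(self, fraction: float = 0.1) -> "Trajectory":
        """The trailing ``fraction`` of frames (production-window convention)."""
        if not 0 < fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        k = max(1, int(round(fraction * len(self))))
        return Trajectory(self.frames[-k:])


@dataclass
class CenterConvention:
    """How the nanoparticle center is resolved each frame.

    ``mode``: ``core-geometric-center`` (default), ``core-center-of-mass``
    or ``fixed-atom-index``.
    """

    mode: str = "core-geometric-center"
    group: str = "NP_CORE"
    atom_index: int | None = None

    def resolve(self, frame: Frame, topology: Topology) -> np.ndarray:
        if self.mode == "fixed-atom-index":
            if self.atom_index is None or not (0 <= self.atom_index < frame.n_atoms):
                raise ValueError("fixed-atom-index center requires a valid atom_index")
            return frame.positions[self.atom_index].copy()
        if self.group not in topology.groups or topology.groups[self.group].size == 0:
            raise ValueError(
                f"center group {self.group!r} not resolvable; available: "
                f"{sorted(topology.groups)}"
            )
        idx = topology.groups[self.group]
        pos = frame.positions[idx]
        if self.mode == "core-geometric-center":
            return pos.mean(axis=0)
        if self.mode == "core-center-of-mass":
            m = topology.masses[idx]
            return (pos * m[:, None]).sum(axis=0) / m.sum()
        raise ValueError(f"unknown center mode {self.mode!r}")


def minimum_image(displacements: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors."""
    d = np.asarray(displacements, dtype=float)
    box = np.asarray(box, dtype=float)
    return d - box * np.round(d / box)


def select(topology: Topology, expression: str) -> np.ndarray:
    """Resolve a group/chain selector to a sorted 0-based atom-index array.

    Grammar: terms are group labels (``PEG``, ``WATER``, ...) or
    ``chain <id>``; terms combine left-to-right with ``and`` (intersection)
    and ``or`` (union).  Deterministic and order-stable.
    """
    tokens = expression.split()
    if not tokens:
        raise ValueError("empty selection expression")

    def term(pos: int) -> tuple[set[int], int]:
        tok = tokens[pos]
        if tok == "chain":
            if pos + 1 >= len(tokens):
                raise ValueError("'chain' requires an id")
            cid = int(tokens[pos + 1])
            if cid not in topology.chains:
                raise ValueError(
                    f"unknown chain {cid}; available: {sorted(topology.chains)}"
                )
            return set(topology.chains[cid]), pos + 2
        if tok not in topology.groups:
            raise ValueError(
                f"unknown label {tok!r}; available labels: {sorted(topology.groups)}"
            )
        return set(topology.groups[tok].tolist()), pos + 1

    result, pos = term(0)
    while pos < len(tokens):
        op = tokens[pos]
        if op not in ("and", "or"):
            raise ValueError(f"expected 'and'/'or', got {op!r}")
        rhs, pos = term(pos + 1)
        result = (result & rhs) if op == "and" else (result | rhs)
    return np.asarray(sorted(result), dtype=np.intp)
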