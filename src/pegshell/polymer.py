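"""Chain-level structure of the grafted polymer coating.

Radius of gyration, end-to-end distance, terminus-to-core distance, the
5%/95% layer thickness, displaced-volume fraction profiles, and the
Daoud–Cotton brush-scaling fit (φ ∝ r^(−4/3) in the semidilute brush
regime, with r measured from the NP surface).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import CenterConvention, Topology, Trajectory, minimum_image
from .profiles import (
    DEFAULT_BIN_WIDTH,
    RadialProfile,
    cumulative_fraction,
    radial_number_density,
)

#: Displaced volume (Å³) of one PEG heavy atom (−CH₂-equivalent group or O).
PEG_HEAVY_VOLUME = 20.0
#: Displaced volume (Å³) of one water molecule.
WATER_VOLUME = 30.0


# ---------------------------------------------------------------------------
# single-chain metrics
# ---------------------------------------------------------------------------

def unwrap_chain(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Unwrap an ordered chain across PBC, rooted at its first (anchor) atom.

    Successive atoms are placed at the minimum-image displacement from the
    previous one, so a chain whose atoms were wrapped into the primary cell
    becomes spatially contiguous.
    """
    pos = np.asarray(positions, dtype=float)
    out = pos.copy()
    steps = minimum_image(np.diff(pos, axis=0), box)
    out[1:] = out[0] + np.cumsum(steps, axis=0)
    return out


def _check_unwrapped(positions: np.ndarray, box: np.ndarray) -> None:
    steps = np.abs(np.diff(np.asarray(positions, dtype=float), axis=0))
    if np.any(steps > 0.5 * np.asarray(box)):
        raise ValueError(
            "chain appears wrapped across the periodic boundary (a bonded "
            "step exceeds half the box); unwrap before computing metrics"
        )


def radius_of_gyration(positions: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Root-mean-square distance of the chain's heavy atoms from its center.

    Default is the unweighted sum about the heavy-atom centroid, for which
    the pairwise identity Rg² = (1/2N²)ΣᵢΣⱼ|rᵢ−rⱼ|² holds exactly; pass
    masses as ``weights`` for the mass-weighted variant.  Positions must be
    unwrapped.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[0] < 1:
        raise ValueError("need at least one heavy atom")
    if weights is None:
        center = pos.mean(axis=0)
        return float(np.sqrt(np.mean(np.sum((pos - center) ** 2, axis=1))))
    w = np.asarray(weights, dtype=float)
    center = (pos * w[:, None]).sum(axis=0) / w.sum()
    return float(np.sqrt((w * np.sum((pos - center) ** 2, axis=1)).sum() / w.sum()))


def end_to_end(positions: np.ndarray) -> float:
    """Distance between the first and last heavy atoms of the ordered chain."""
    pos = np.asarray(positions, dtype=float)
    if pos.shape[0] < 2:
        raise ValueError("end-to-end distance needs at least 2 heavy atoms")
    return float(np.linalg.norm(pos[-1] - pos[0]))


def peg_np_distance(positions: np.ndarray, np_center: np.ndarray) -> float:
    """Distance from the chain's terminal (solution-side) heavy atom to the
    NP center."""
    pos = np.asarray(positions, dtype=float)
    return float(np.linalg.norm(pos[-1] - np.asarray(np_center, dtype=float)))


# ---------------------------------------------------------------------------
# ensemble summaries
# ---------------------------------------------------------------------------

@dataclass
class ChainMetricsSummary:
    """Per-chain/per-frame Rg, h, d with pooled statistics and the PEG layer
    thickness.

    ``rg``, ``h``, ``d`` are (n_chains, n_frames) arrays; means/stds pool
    over chains × frames.
    """

    rg: np.ndarray
    h: np.ndarray
    d: np.ndarray
    thk: float
    r_min: float
    r_max: float
    chain_ids: list[int] = field(default_factory=list)

    @property
    def rg_mean(self) -> float:
        return float(self.rg.mean())

    @property
    def rg_std(self) -> float:
        return float(self.rg.std(ddof=0))

    @property
    def h_mean(self) -> float:
        return float(self.h.mean())

    @property
    def h_std(self) -> float:
        return float(self.h.std(ddof=0))

    @property
    def d_mean(self) -> float:
        return float(self.d.mean())

    @property
    def d_std(self) -> float:
        return float(self.d.std(ddof=0))

    def as_dict(self) -> dict:
        return {
            "Rg_mean": self.rg_mean, "Rg_std": self.rg_std,
            "h_mean": self.h_mean, "h_std": self.h_std,
            "d_mean": self.d_mean, "d_std": self.d_std,
            "thk": self.thk, "r_min": self.r_min, "r_max": self.r_max,
        }


def layer_thickness(peg_cdf: RadialProfile) -> tuple[float, float, float]:
    """Polymer layer thickness from the normalized cumulative distribution.

    Returns ``(thk, r_min, r_max)`` where the cumulative fraction crosses
    0.05 and 0.95 (linear interpolation between bin edges): the radial
    region holding 90% of the polymer.
    """
    if peg_cdf.kind != "cumulative_fraction":
        raise ValueError("layer thickness requires a cumulative_fraction profile")
    x = np.concatenate(([peg_cdf.bin_edges[0]], peg_cdf.bin_edges[1:]))
    y = np.concatenate(([0.0], peg_cdf.values))
    if np.any(np.diff(y) < -1e-12):
        raise ValueError("cumulative distribution is not monotone")

    def crossing(level: float) -> float:
        k = int(np.searchsorted(y, level))
        if k == 0:
            return float(x[0])
        if k >= len(y):
            raise ValueError(f"cumulative distribution never reaches {level}")
        if y[k] == y[k - 1]:
            return float(x[k])
        frac = (level - y[k - 1]) / (y[k] - y[k - 1])
        return float(x[k - 1] + frac * (x[k] - x[k - 1]))

    r_min = crossing(0.05)
    r_max = crossing(0.95)
    return r_max - r_min, r_min, r_max


def chain_metrics(
    traj: Trajectory,
    topology: Topology,
    center: CenterConvention | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    mass_weighted: bool = False,
    auto_unwrap: bool = True,
) -> ChainMetricsSummary:
    """Rg, end-to-end and terminus–center distances for every chain in every
    frame, plus the PEG layer thickness from the pooled radial distribution.

    Chains are unwrapped from their anchor atom before any metric; with
    ``auto_unwrap=False`` positions are taken as-is and a chain whose bonded
    step exceeds half the box raises an error demanding an unwrap.
    """
    center = center or CenterConvention()
    if not topology.chains:
        raise ValueError("topology declares no polymer chains")
    cids = sorted(topology.chains)
    n_c, n_f = len(cids), len(traj)
    rg = np.zeros((n_c, n_f))
    h = np.zeros((n_c, n_f))
    d = np.zeros((n_c, n_f))
    for jf, frame in enumerate(traj):
        c0 = center.resolve(frame, topology)
        for jc, cid in enumerate(cids):
            order = topology.chains[cid]
            if auto_unwrap:
                pos = unwrap_chain(frame.positions[order], frame.box)
            else:
                pos = frame.positions[order]
                _check_unwrapped(pos, frame.box)
            w = topology.masses[order] if mass_weighted else None
            rg[jc, jf] = radius_of_gyration(pos, weights=w)
            h[jc, jf] = end_to_end(pos)
            d[jc, jf] = peg_np_distance(pos, c0)
    peg_sel = topology.groups.get("PEG")
    if peg_sel is None or peg_sel.size == 0:
        raise ValueError("topology has no PEG group for the layer-thickness profile")
    heavy = peg_sel[topology.heavy_mask[peg_sel]]
    density = radial_number_density(traj, heavy, center, topology, bin_width)
    thk, r_min, r_max = layer_thickness(cumulative_fraction(density))
    return ChainMetricsSummary(rg, h, d, thk, r_min, r_max, chain_ids=cids)


# ---------------------------------------------------------------------------
# volume fraction and brush scaling
# ---------------------------------------------------------------------------

def volume_fraction_profile(
    traj: Trajectory,
    topology: Topology,
    center: CenterConvention | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    r_max: float | None = None,
    peg_heavy_volume: float = PEG_HEAVY_VOLUME,
    water_volume: float = WATER_VOLUME,
) -> dict[str, RadialProfile]:
    """Displaced-volume fraction of polymer and water in 0.1 Å shells about
    the NP's geometric center.

    Every PEG heavy atom contributes ``peg_heavy_volume`` (20 Å³ by
    default); every water molecule, located at its oxygen, contributes
    ``water_volume`` (30 Å³).  Polymer and water fractions are returned
    separately.
    """
    center = center or CenterConvention(mode="core-geometric-center")
    out: dict[str, RadialProfile] = {}

    peg_sel = topology.groups.get("PEG", np.empty(0, dtype=np.intp))
    peg_heavy = peg_sel[topology.heavy_mask[peg_sel]] if peg_sel.size else peg_sel
    species = {"polymer": (peg_heavy, peg_heavy_volume)}

    water = topology.groups.get("WATER", np.empty(0, dtype=np.intp))
    if water.size:
        oxygens = np.array(
            [m[int(np.argmax(topology.heavy_mask[m]))] for m in topology.water_molecules()],
            dtype=np.intp,
        )
        species["water"] = (oxygens, water_volume)

    for name, (sel, vol) in species.items():
        if sel.size == 0:
            continue
        density = radial_number_density(traj, sel, center, topology, bin_width, r_max)
        out[name] = RadialProfile(
            density.bin_edges, density.values * vol, "volume_fraction", density.n_frames
        )
    if not out:
        raise ValueError("no PEG heavy atoms or water molecules to map volumes onto")
    return out


@dataclass
class BrushFit:
    """Least-squares power-law fit of log φ vs log r over a radial window."""

    r_lo: float
    r_hi: float
    exponent: float
    log_prefactor: float
    r_squared: float
    n_bins: int

    @property
    def prefactor(self) -> float:
        return float(np.exp(self.log_prefactor))


def daoud_cotton_fit(
    profile: RadialProfile,
    window: tuple[float, float],
    surface_radius: float = 0.0,
) -> BrushFit:
    """Fit φ(r) = A·r^α on a log-log scale; r is measured from the NP surface.

    The Daoud–Cotton star-polymer model predicts α = −4/3 in the semidilute
    brush regime.  Nonpositive bins in the window are dropped with a
    warning; at least 5 bins must remain.
    """
    r_lo, r_hi = window
    if r_hi <= r_lo:
        raise ValueError("window must satisfy r_hi > r_lo")
    r = profile.r_mid - surface_radius
    mask = (r >= r_lo) & (r <= r_hi)
    phi = profile.values[mask]
    r = r[mask]
    pos = phi > 0
    if not pos.all():
        warnings.warn(
            f"dropping {int((~pos).sum())} nonpositive volume-fraction bins "
            "from the brush fit", stacklevel=2,
        )
        r, phi = r[pos], phi[pos]
    if r.size < 5:
        raise ValueError(f"brush fit needs >= 5 positive bins in window, got {r.size}")
    x, y = np.log(r), np.log(phi)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return BrushFit(r_lo, r_hi, float(slope), float(intercept), r2, int(r.size))


def grafting_density(n_chains: int, surface_area_nm2: float) -> float:
    """Chains per nm² of nanoparticle surface."""
    if surface_area_nm2 <= 0:
        raise ValueError("surface area must be > 0")
    return n_chains / surface_area_nm2
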