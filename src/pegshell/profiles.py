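"""Spherically averaged radial profiles about the nanoparticle center.

Number density, RDF, cumulative fraction, and bulk-onset detection.  All
profiles use uniform bins (default width 0.1 Å) starting at r = 0; atom
positions are minimum-image wrapped about the center before binning.
Radii beyond half the shortest box edge sample incomplete shells and are
excluded by the default ``r_max``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CenterConvention, Topology, Trajectory, minimum_image

DEFAULT_BIN_WIDTH = 0.1


@dataclass
class RadialProfile:
    """A binned, spherically averaged quantity about the NP center.

    ``kind`` is one of ``number_density`` (Å⁻³), ``rdf`` (dimensionless),
    ``cumulative_fraction`` (dimensionless, values at the *right* edge of
    each bin) or ``volume_fraction`` (dimensionless).
    """

    bin_edges: np.ndarray
    values: np.ndarray
    kind: str
    n_frames: int = 1
    bin_width: float = field(default=DEFAULT_BIN_WIDTH)

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.bin_edges.ndim != 1 or self.bin_edges.size < 2:
            raise ValueError("bin_edges must be a 1-D array of >= 2 edges")
        widths = np.diff(self.bin_edges)
        if np.any(widths <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if not np.allclose(widths, widths[0], rtol=1e-8):
            raise ValueError("bins must be uniform")
        self.bin_width = float(widths[0])
        if self.values.shape != (self.bin_edges.size - 1,):
            raise ValueError("values must have one entry per bin")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile values must be finite")
        if self.kind == "cumulative_fraction":
            if np.any(np.diff(self.values) < -1e-12) or self.values.min() < -1e-12:
                raise ValueError("cumulative fraction must be nondecreasing in [0, 1]")

    @property
    def r_mid(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def shell_volumes(self) -> np.ndarray:
        r = self.bin_edges
        return 4.0 * np.pi / 3.0 * (r[1:] ** 3 - r[:-1] ** 3)


def _make_edges(r_max: float, bin_width: float) -> np.ndarray:
    n_bins = int(np.ceil(r_max / bin_width - 1e-9))
    return bin_width * np.arange(n_bins + 1)


def _accumulate_counts(
    traj: Trajectory,
    sel: np.ndarray,
    center: CenterConvention,
    topology: Topology,
    edges: np.ndarray,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Sum of per-frame (weighted) shell counts over the trajectory."""
    counts = np.zeros(edges.size - 1)
    for frame in traj:
        c = center.resolve(frame, topology)
        d = minimum_image(frame.positions[sel] - c, frame.box)
        r = np.linalg.norm(d, axis=1)
        h, _ = np.histogram(r, bins=edges, weights=weights)
        counts += h
    return counts


def radial_number_density(
    traj: Trajectory,
    sel: np.ndarray,
    center: CenterConvention | None = None,
    topology: Topology | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    r_max: float | None = None,
) -> RadialProfile:
    """Time-averaged number density (Å⁻³) in 0.1 Å spherical shells.

    Per-bin value = mean shell count per frame / shell volume
    4π/3·(r₂³ − r₁³).  Positions are wrapped by minimum image about the
    per-frame center before binning.
    """
    if topology is None:
        raise ValueError("topology required to resolve the center")
    center = center or CenterConvention()
    sel = np.asarray(sel, dtype=np.intp)
    if r_max is None:
        r_max = 0.5 * min(float(f.box.min()) for f in traj)
    edges = _make_edges(r_max, bin_width)
    counts = _accumulate_counts(traj, sel, center, topology, edges)
    prof = RadialProfile(edges, np.zeros(edges.size - 1), "number_density", len(traj))
    prof.values = counts / len(traj) / prof.shell_volumes
    return prof


def radial_rdf(
    traj: Trajectory,
    sel: np.ndarray,
    center: CenterConvention | None = None,
    topology: Topology | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    r_max: float | None = None,
) -> RadialProfile:
    """Center-referenced RDF: number density over the selection's mean density.

    Normalized so the RDF tends to 1 where the selection is homogeneous
    (bulk).
    """
    sel = np.asarray(sel, dtype=np.intp)
    if sel.size == 0:
        raise ValueError("RDF of an empty selection is undefined")
    density = radial_number_density(traj, sel, center, topology, bin_width, r_max)
    mean_volume = float(np.mean([f.volume for f in traj]))
    if mean_volume <= 0:
        raise ValueError("zero box volume")
    rho_bulk = sel.size / mean_volume
    return RadialProfile(
        density.bin_edges, density.values / rho_bulk, "rdf", density.n_frames
    )


def cumulative_fraction(profile: RadialProfile) -> RadialProfile:
    """Normalized cumulative radial distribution.

    Shell-weighted cumulative count divided by the total; value k is the
    fraction at the right edge of bin k.  Works for both ``number_density``
    and ``rdf`` inputs (the bulk normalization cancels).
    """
    if profile.kind not in ("number_density", "rdf"):
        raise ValueError(f"cannot accumulate a profile of kind {profile.kind!r}")
    weights = profile.values * profile.shell_volumes
    total = weights.sum()
    if total <= 0:
        raise ValueError("all-zero profile: cumulative fraction undefined")
    return RadialProfile(
        profile.bin_edges, np.cumsum(weights) / total, "cumulative_fraction",
        profile.n_frames,
    )


def bulk_onset_radius(
    water_rdf: RadialProfile,
    tol: float = 0.05,
    sustain: float = 2.0,
) -> float:
    """Radius where the bulk phase begins: the RDF's first *sustained*
    crossing of 1.

    The crossing is linearly interpolated between bin centers and must stay
    ≥ 1 − ``tol`` over the following ``sustain`` Å, which makes the
    detection robust to sub-bulk solvation-shell peaks inside the polymer
    coating.
    """
    if water_rdf.kind != "rdf":
        raise ValueError("bulk onset requires an RDF profile")
    r = water_rdf.r_mid
    v = water_rdf.values

    def sustained(r_cross: float) -> bool:
        mask = (r >= r_cross) & (r <= r_cross + sustain)
        return bool(np.all(v[mask] >= 1.0 - tol))

    if v[0] >= 1.0 and sustained(r[0]):
        return float(r[0])
    for k in range(len(v) - 1):
        if v[k] < 1.0 <= v[k + 1]:
            frac = (1.0 - v[k]) / (v[k + 1] - v[k])
            r_cross = r[k] + frac * (r[k + 1] - r[k])
            if sustained(r_cross):
                return float(r_cross)
    raise ValueError("water RDF never sustains 1: no bulk phase in box")
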