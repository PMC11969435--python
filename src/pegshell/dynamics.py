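"""Self-diffusion from the Einstein relation and two-particle aggregation.

The MSD is averaged over all time origins (FFT-based, O(T log T)) and the
diffusion coefficient follows from the linear regime: MSD(τ) = 2 n D τ
with dimensionality n = 3.  Trajectories must be unwrapped for the tracked
selection; wrapped jumps are detected and rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .core import ANG2_PER_PS_TO_M2_PER_S, Topology, Trajectory, minimum_image
from .interactions import (
    EnergyBreakdown,
    NonbondedScheme,
    energy_series,
)

DIMENSIONALITY = 3


@dataclass
class MsdCurve:
    """Mean-square displacement vs lag time.

    ``lag_times`` in ps, ``msd`` in Ų; MSD(0) = 0 by construction.
    """

    lag_times: np.ndarray
    msd: np.ndarray
    n: int = DIMENSIONALITY
    fit_window: tuple[float, float] | None = None
    slope: float | None = None
    diffusion: float | None = None  # m² s⁻¹


def _msd_fft_1d(x: np.ndarray) -> np.ndarray:
    """Time-origin-averaged MSD of a 1-D coordinate series."""
    x = x - x.mean()  # translation invariant; centering avoids cancellation
    T = x.size
    fft_len = 2 * T
    f = np.fft.rfft(x, fft_len)
    acf = np.fft.irfft(f * np.conj(f), fft_len)[:T]
    acf /= T - np.arange(T)
    sq = x**2
    csum = np.cumsum(sq)
    total = csum[-1]
    tau = np.arange(T)
    # S1(τ) = Σ_{t<T-τ} [x(t)² + x(t+τ)²], via prefix sums
    head = np.empty(T)
    head[0] = total
    head[1:] = csum[T - 2 :: -1][: T - 1]
    tail = np.empty(T)
    tail[0] = total
    tail[1:] = total - csum[: T - 1]
    return (head + tail) / (T - tau) - 2.0 * acf


def _check_unwrapped_series(series: np.ndarray, boxes: np.ndarray) -> None:
    steps = np.abs(np.diff(series, axis=0))
    if np.any(steps > 0.5 * boxes[:-1, None, :] if series.ndim == 3 else
              steps > 0.5 * boxes[:-1, :]):
        raise ValueError(
            "wrapped periodic jump detected (a per-step displacement exceeds "
            "half the box); unwrap the trajectory before the MSD analysis"
        )


def mean_square_displacement(
    traj: Trajectory,
    sel: np.ndarray,
    topology: Topology | None = None,
    max_lag: int | None = None,
    mode: str = "com",
) -> MsdCurve:
    """MSD(τ) averaged over all time origins.

    ``mode='com'`` tracks the selection's (mass-weighted, if a topology is
    given) center of mass — the nanoconjugate convention; ``mode='atoms'``
    averages per-atom MSDs over the selection, appropriate for ensembles of
    independent walkers.
    """
    sel = np.asarray(sel, dtype=np.intp)
    if sel.size == 0:
        raise ValueError("empty selection")
    times = traj.times
    dts = np.diff(times)
    if len(dts) and not np.allclose(dts, dts[0], rtol=1e-6):
        raise ValueError("MSD requires uniformly spaced frames")
    dt = float(dts[0]) if len(dts) else 1.0
    boxes = np.array([f.box for f in traj])
    T = len(traj)
    if max_lag is None:
        max_lag = T - 1
    max_lag = min(max_lag, T - 1)

    if mode == "com":
        if topology is not None:
            m = topology.masses[sel]
        else:
            m = np.ones(sel.size)
        series = np.array(
            [(f.positions[sel] * m[:, None]).sum(axis=0) / m.sum() for f in traj]
        )
        _check_unwrapped_series(series, boxes)
        msd = sum(_msd_fft_1d(series[:, k]) for k in range(3))
    elif mode == "atoms":
        series = np.array([f.positions[sel] for f in traj])  # (T, N, 3)
        _check_unwrapped_series(series, boxes)
        msd = np.zeros(T)
        for a in range(sel.size):
            msd += sum(_msd_fft_1d(series[:, a, k]) for k in range(3))
        msd /= sel.size
    else:
        raise ValueError("mode must be 'com' or 'atoms'")
    msd = np.asarray(msd)[: max_lag + 1]
    msd[0] = 0.0
    return MsdCurve(dt * np.arange(max_lag + 1), msd)


@dataclass
class DiffusionFit:
    """Linear Einstein-relation fit of the MSD."""

    diffusion: float  # m² s⁻¹
    slope: float  # Ų ps⁻¹
    intercept: float
    r_squared: float
    window: tuple[float, float]
    warning: Optional[str] = None


def diffusion_coefficient(
    msd: MsdCurve,
    fit_window: tuple[float, float] | None = None,
) -> DiffusionFit:
    """Self-diffusion coefficient D = slope/(2n) from the linear MSD regime.

    ``fit_window`` is a (t_lo, t_hi) lag-time range in ps; the default uses
    every positive lag.  The fit R² is reported and a warning recorded when
    it falls below 0.9 (non-linear MSD, e.g. ballistic motion).
    """
    t, y = msd.lag_times, msd.msd
    if fit_window is None:
        mask = t > 0
        fit_window = (float(t[mask][0]), float(t[-1]))
    else:
        mask = (t >= fit_window[0]) & (t <= fit_window[1])
    if mask.sum() < 10:
        raise ValueError("diffusion fit needs >= 10 MSD points in the window")
    res = stats.linregress(t[mask], y[mask])
    slope = float(res.slope)
    r2 = float(res.rvalue**2) if np.ptp(y[mask]) > 0 else 1.0
    d_ang = slope / (2.0 * msd.n)  # Ų ps⁻¹
    warning = None
    if r2 < 0.9:
        warning = f"MSD fit R² = {r2:.3f} < 0.9: displacement is not diffusive"
    msd.fit_window = fit_window
    msd.slope = slope
    msd.diffusion = max(d_ang, 0.0) * ANG2_PER_PS_TO_M2_PER_S
    return DiffusionFit(
        diffusion=d_ang * ANG2_PER_PS_TO_M2_PER_S,
        slope=slope,
        intercept=float(res.intercept),
        r_squared=r2,
        window=fit_window,
        warning=warning,
    )


# ---------------------------------------------------------------------------
# two-particle aggregation
# ---------------------------------------------------------------------------

@dataclass
class AggregationReport:
    """Per-frame inter-core separation and the aggregation verdict.

    ``verdict`` is ``aggregated``, ``transient-contact`` or
    ``non-aggregated``: the cores count as separated in a frame when the
    minimum-image atom-atom gap exceeds ``threshold``; the verdict requires
    the same state in more than ``persistence`` of window frames.
    """

    min_distance: np.ndarray
    verdict: str
    threshold: float
    persistence: float
    fraction_separated: float
    mean_energy: EnergyBreakdown | None = None
    energy_std: float | None = None
    extras: dict = field(default_factory=dict)


def aggregation_analysis(
    traj: Trajectory,
    topology: Topology,
    coreA_sel: np.ndarray,
    coreB_sel: np.ndarray,
    scheme: NonbondedScheme | None = None,
    contact_threshold: float = 10.0,
    persistence: float = 0.9,
    energyA_sel: np.ndarray | None = None,
    energyB_sel: np.ndarray | None = None,
) -> AggregationReport:
    """Judge whether two coated particles aggregate over the window.

    Computes the per-frame minimum-image minimum surface separation
    between the two core selections and, when ``energyA_sel``/``energyB_sel``
    are given, the mean intersystem nonbonded energy between the full
    systems.  Symmetric in A/B.
    """
    a = np.asarray(coreA_sel, dtype=np.intp)
    b = np.asarray(coreB_sel, dtype=np.intp)
    if np.intersect1d(a, b).size:
        raise ValueError("core selections overlap")
    if a.size == 0 or b.size == 0:
        raise ValueError("core selections must be nonempty")
    dmin = np.empty(len(traj))
    for k, frame in enumerate(traj):
        d = minimum_image(
            frame.positions[a][:, None, :] - frame.positions[b][None, :, :], frame.box
        )
        dmin[k] = float(np.sqrt((d**2).sum(axis=2)).min())
    frac_sep = float(np.mean(dmin > contact_threshold))
    if frac_sep > persistence:
        verdict = "non-aggregated"
    elif frac_sep < 1.0 - persistence:
        verdict = "aggregated"
    else:
        verdict = "transient-contact"
    mean_energy = None
    energy_std = None
    if energyA_sel is not None and energyB_sel is not None:
        summ = energy_series(
            traj, topology, {"intersystem": (energyA_sel, energyB_sel)}, scheme
        )["intersystem"]
        mean_energy = summ.mean
        energy_std = summ.std_total
    return AggregationReport(
        min_distance=dmin,
        verdict=verdict,
        threshold=contact_threshold,
        persistence=persistence,
        fraction_separated=frac_sep,
        mean_energy=mean_energy,
        energy_std=energy_std,
    )
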