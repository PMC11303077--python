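"""Electron transport in unbounded liquid water: public wrappers over the kernel."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .constants import CUTOFF_EV
from .nuclides import NuclideScheme, sample_decays
from .physics import PhysicsTables, build_tables

__all__ = [
    "TransportSettings",
    "EventList",
    "RadialProfile",
    "transport_electron",
    "radial_profile",
    "r_quantile",
]


@dataclass(frozen=True)
class TransportSettings:
    """Knobs of the transport model.

    cutoff_energy: tracking cutoff in eV; residual energy is deposited locally
        (sub-excitation electrons are not diffused further). Must be >= 7.4 eV.
    physics_mode: "event_by_event" samples every elastic collision
        (screened Rutherford); "condensed_history" groups elastic collisions
        above ``ch_threshold_ev`` into Gaussian deflections per step.
    max_step: optional cap on the step length in um (condensed mode), 0 = off.
    delta_threshold_ev: transfers above this spawn explicit delta rays.
    step_fraction: step length cap as a fraction of the residual CSDA range.
    """

    cutoff_energy: float = CUTOFF_EV
    physics_mode: str = "event_by_event"
    max_step: float = 0.0
    delta_threshold_ev: float = 100.0
    step_fraction: float = 0.05
    ch_threshold_ev: float = 10_000.0
    seed: int = 0

    def __post_init__(self):
        if self.cutoff_energy < CUTOFF_EV:
            raise ValueError(f"cutoff_energy must be >= {CUTOFF_EV} eV")
        if self.physics_mode not in ("event_by_event", "condensed_history"):
            raise ValueError("physics_mode must be event_by_event or condensed_history")
        if self.max_step < 0:
            raise ValueError("max_step must be > 0 (or 0 to disable)")

    @property
    def ch_mode(self) -> int:
        return 1 if self.physics_mode == "condensed_history" else 0

    def tables(self) -> PhysicsTables:
        return build_tables(wc_ev=self.delta_threshold_ev, cutoff_ev=self.cutoff_energy)


_EMPTY_TALLY = np.zeros((1, 1, 1, 1, 1, 1))
_EMPTY_ESCAPE = np.zeros((1, 2, 3))
_EMPTY_RADIAL = np.zeros(1)
_EMPTY_CENTERS = np.zeros((0, 3))
_EMPTY_EVENTS = np.zeros((0, 4))


@dataclass
class EventList:
    """Energy-deposition events of one or more electron tracks."""

    positions: np.ndarray  # (n, 3) um
    energies: np.ndarray   # (n,) eV

    @property
    def total_energy_ev(self) -> float:
        return float(self.energies.sum())

    def radii(self) -> np.ndarray:
        return np.linalg.norm(self.positions, axis=1)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            dict(x_um=self.positions[:, 0], y_um=self.positions[:, 1],
                 z_um=self.positions[:, 2], edep_eV=self.energies)
        )


def transport_electron(energy_kev: float, origin, direction,
                       settings: TransportSettings | None = None,
                       seed: int = 0) -> EventList:
    """Transport a single electron; returns its deposition events.

    The deposited energies sum to the initial energy exactly (unbounded
    medium). An electron already at/below the cutoff deposits everything at
    the origin. Non-unit directions are normalised with a warning.
    """
    settings = settings or TransportSettings()
    if energy_kev <= 0:
        raise ValueError("electron energy must be positive")
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    norm = float(np.linalg.norm(direction))
    if norm == 0:
        raise ValueError("direction must be a nonzero vector")
    if abs(norm - 1.0) > 1e-9:
        warnings.warn("direction was not a unit vector; normalising", stacklevel=2)
    direction = direction / norm
    tab = settings.tables()
    e_ev = energy_kev * 1000.0
    cap = int(4096 + 40 * e_ev ** 0.75)
    while True:
        events = np.zeros((cap, 4))
        n = _kernels.transport_batch(
            np.array([e_ev]), np.array([origin[0]]), np.array([origin[1]]),
            np.array([origin[2]]), np.array([direction[0]]),
            np.array([direction[1]]), np.array([direction[2]]),
            np.ones(1), np.zeros(1, np.int8), np.zeros(1, np.int64),
            np.zeros(1, np.int8), np.zeros(1, np.int8),
            _kernels.derive_seeds(settings.seed, seed, 1),
            *tab.as_kernel_args(),
            settings.cutoff_energy, settings.delta_threshold_ev,
            settings.step_fraction, settings.max_step, settings.ch_mode,
            settings.ch_threshold_ev,
            3, 0.0, _EMPTY_CENTERS, 0.0, 0.0, 0.0, 0.0,
            _EMPTY_TALLY, _EMPTY_ESCAPE.copy(), _EMPTY_RADIAL.copy(),
            events,
        )
        if n >= 0:
            return EventList(events[:n, :3].copy(), events[:n, 3].copy())
        cap *= 4


@dataclass
class RadialProfile:
    """Energy binned in concentric shells around a point source."""

    shell_width_um: float
    energy_ev: np.ndarray   # per shell
    overflow_ev: float
    n_histories: int

    @property
    def total_ev(self) -> float:
        return float(self.energy_ev.sum() + self.overflow_ev)

    @property
    def fractions(self) -> np.ndarray:
        return self.energy_ev / self.total_ev

    @property
    def outer_radii_um(self) -> np.ndarray:
        return self.shell_width_um * np.arange(1, len(self.energy_ev) + 1)

    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.energy_ev) / self.total_ev


def radial_profile(scheme: NuclideScheme, n_histories: int,
                   shell_width_nm: float = 1.0,
                   settings: TransportSettings | None = None,
                   seed: int = 0, max_radius_um: float | None = None,
                   sampling: str = "poisson") -> RadialProfile:
    """Score the per-decay radial energy deposition around a point source."""
    if n_histories < 1:
        raise ValueError("need at least one history")
    settings = settings or TransportSettings()
    tab = settings.tables()
    from .physics import csda_range_um

    if max_radius_um is None:
        e_max = max(
            [ln.energy for ln in scheme.lines]
            + [b.endpoint_energy for b in scheme.betas] + [1.0]
        )
        max_radius_um = 1.3 * csda_range_um(e_max * 1000.0) + 1.0
    shell_w = shell_width_nm / 1000.0
    nbins = int(np.ceil(max_radius_um / shell_w))
    radial = np.zeros(nbins + 1)

    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0xAD1A1])
    e_kev, cat, part, decay, wt = sample_decays(scheme, n_histories, rng, mode=sampling)
    n = len(e_kev)
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    zeros = np.zeros(n)
    _kernels.transport_batch(
        e_kev * 1000.0, zeros, zeros.copy(), zeros.copy(),
        u[:, 0].copy(), u[:, 1].copy(), u[:, 2].copy(),
        wt, np.zeros(n, np.int8), np.zeros(n, np.int64), part.astype(np.int8),
        cat.astype(np.int8), _kernels.derive_seeds(seed, 0xAD1A2, n),
        *tab.as_kernel_args(),
        settings.cutoff_energy, settings.delta_threshold_ev,
        settings.step_fraction, settings.max_step, settings.ch_mode,
        settings.ch_threshold_ev,
        2, 0.0, _EMPTY_CENTERS, 0.0, 0.0, 0.0, shell_w,
        _EMPTY_TALLY, _EMPTY_ESCAPE.copy(), radial,
        _EMPTY_EVENTS,
    )
    return RadialProfile(shell_w, radial[:-1], float(radial[-1]), n_histories)


def r_quantile(profile: RadialProfile, q: float) -> float:
    """Smallest shell outer radius (um) containing >= q of the deposited energy."""
    if not 0.0 < q < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    cum = profile.cumulative()
    idx = int(np.searchsorted(cum, q))
    if idx >= len(cum):
        raise ValueError("quantile falls beyond the profiled radius; increase max_radius_um")
    return float(profile.outer_radii_um[idx])
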