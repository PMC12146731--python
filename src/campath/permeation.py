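"""Permeation-event counting, conductance and selectivity statistics.

The single-channel conductance from a fixed-field simulation is

    g = I / V = (N q e / t) / (E Lz) * 1 / f_ECC

where N is the net number of permeation events over simulated time t, q the
nominal (unscaled) integer ion charge, E the applied field, Lz the box length
along the field (V = E * Lz is the nominal transmembrane voltage), and f_ECC
the electronic-continuum-correction charge-scaling factor.  The 1/f_ECC term
reflects that scaled charges feel an effective field of E * f_ECC, while the
charge carried across the membrane per event remains the nominal q.

Also provided: I-V regression through the origin, selectivity ratios, mutant
conductance fold-changes with first-order error propagation, concordance with
experimental fold-changes (Pearson), and the Arrhenius rate ratio implied by
a barrier difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fes_io import Temperature

__all__ = [
    "ELEMENTARY_CHARGE_C",
    "IonTrajectory",
    "PermeationEvent",
    "ConductanceEstimate",
    "SelectivityRatio",
    "count_permeation_events",
    "net_event_count",
    "conductance",
    "trajectory_conductance",
    "conductance_error",
    "iv_fit_through_origin",
    "selectivity_ratio",
    "fold_change",
    "pearson_vs_experiment",
    "arrhenius_rate_ratio",
]

#: Elementary charge in coulomb.
ELEMENTARY_CHARGE_C = 1.602176634e-19


@dataclass(frozen=True)
class IonTrajectory:
    """Per-ion z time series with the metadata the conductance formula needs.

    Parameters
    ----------
    times:
        Frame times in ps, strictly increasing.
    z:
        Array (n_frames, n_ions) of z positions in Angstrom, wrapped into
        the box.
    box_z:
        Box length along z in Angstrom.
    species:
        Per-ion species labels (e.g. ``"CA"``).
    charges:
        Per-ion nominal integer charges in elementary-charge units.
    e_field:
        Applied field in V/nm (magnitude along -z).
    lz_nm:
        Box length along z in nm (for the nominal voltage V = E * Lz).
    f_ecc:
        Charge scaling factor, 0 < f_ecc <= 1.
    xy:
        Optional (n_frames, n_ions, 2) lateral coordinates.
    """

    times: np.ndarray
    z: np.ndarray
    box_z: float
    species: tuple[str, ...]
    charges: tuple[float, ...]
    e_field: float
    lz_nm: float
    f_ecc: float = 1.0
    xy: np.ndarray | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        z = np.asarray(self.z, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
        if times.ndim != 1 or z.shape[0] != times.size:
            raise ValueError("times and z have inconsistent lengths")
        if not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(z)):
            raise ValueError("non-finite z position")
        if len(self.charges) != z.shape[1] or len(self.species) != z.shape[1]:
            raise ValueError("per-ion metadata length mismatch")
        if any(q == 0 for q in self.charges):
            raise ValueError("tracked ions must carry nonzero charge")
        if not 0 < self.f_ecc <= 1:
            raise ValueError("f_ecc must be in (0, 1]")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "charges", tuple(self.charges))

    @property
    def n_ions(self) -> int:
        return self.z.shape[1]

    @property
    def duration_ps(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def voltage(self) -> float:
        """Nominal transmembrane voltage E * Lz in volt."""
        return self.e_field * self.lz_nm


@dataclass(frozen=True)
class PermeationEvent:
    """One completed two-plane crossing."""

    ion: int
    time_ps: float
    direction: int  # +1 inward (above -> below), -1 reverse


@dataclass(frozen=True)
class ConductanceEstimate:
    """Net event count with the derived current and conductance."""

    n_events: int
    current_a: float
    conductance_ps: float
    sd_ps: float | None = None


@dataclass(frozen=True)
class SelectivityRatio:
    """Event-count ratio A:B; ``infinite`` flags a zero denominator."""

    ratio: float
    infinite: bool = False


def count_permeation_events(
    traj: IonTrajectory, z_upper: float, z_lower: float
) -> list[PermeationEvent]:
    """Count completed channel crossings with a two-plane state machine.

    An inward event (+1) completes when an ion last seen above ``z_upper``
    is next seen below ``z_lower``; the reverse order counts -1.  The
    hysteresis between the two planes prevents double-counting of ions
    dithering at a single plane.  Frame-to-frame jumps with |dz| > box_z/2
    are treated as periodic wraps: the ion's arming state resets, so a
    wrapped reappearance never registers as a crossing.
    """
    if not z_upper > z_lower:
        raise ValueError("z_upper must exceed z_lower")
    half = traj.box_z / 2
    if not (-half <= z_lower and z_upper <= half):
        raise ValueError("planes must lie inside the box")
    events: list[PermeationEvent] = []
    z = traj.z
    for ion in range(traj.n_ions):
        armed: str | None = None  # side the ion most recently came from
        prev = z[0, ion]
        armed = "above" if prev > z_upper else "below" if prev < z_lower else None
        for f in range(1, z.shape[0]):
            cur = z[f, ion]
            if abs(cur - prev) > half:
                # periodic wrap: re-arm from the re-entry region, no event
                armed = "above" if cur > z_upper else "below" if cur < z_lower else None
            elif cur > z_upper:
                if armed == "below":
                    events.append(PermeationEvent(ion, float(traj.times[f]), -1))
                armed = "above"
            elif cur < z_lower:
                if armed == "above":
                    events.append(PermeationEvent(ion, float(traj.times[f]), +1))
                armed = "below"
            prev = cur
    events.sort(key=lambda ev: (ev.time_ps, ev.ion))
    return events


def net_event_count(events: list[PermeationEvent]) -> int:
    """Net N = inward minus reverse crossings."""
    return sum(ev.direction for ev in events)


def conductance(
    n_events: int,
    q: float,
    t_s: float,
    e_field_v_per_nm: float,
    lz_nm: float,
    f_ecc: float = 1.0,
) -> ConductanceEstimate:
    """Conductance in pS from a net event count.

    ``q`` is the nominal integer charge in units of e (the ECC scaling does
    not change the real charge carried per permeation), ``t_s`` the simulated
    time in seconds, and ``e_field * lz`` the nominal voltage in volt.
    """
    if not t_s > 0:
        raise ValueError("simulation time must be positive")
    voltage = e_field_v_per_nm * lz_nm
    if not voltage > 0:
        raise ValueError("nominal voltage E*Lz must be positive")
    if not f_ecc > 0:
        raise ValueError("f_ecc must be positive")
    current = n_events * q * ELEMENTARY_CHARGE_C / t_s
    g_ps = current / (voltage * f_ecc) * 1e12
    return ConductanceEstimate(int(n_events), current, g_ps)


def trajectory_conductance(
    traj: IonTrajectory, z_upper: float, z_lower: float
) -> ConductanceEstimate:
    """Event counting plus the conductance formula in one step.

    Uses the charge of the first tracked ion; mixed-species trajectories
    should be split by species first.
    """
    events = count_permeation_events(traj, z_upper, z_lower)
    n = net_event_count(events)
    return conductance(
        n, traj.charges[0], traj.duration_ps * 1e-12,
        traj.e_field, traj.lz_nm, traj.f_ecc,
    )


def conductance_error(replicate_g_ps) -> float:
    """Sample SD (ddof=1) of replicate conductances, in pS."""
    g = np.asarray(replicate_g_ps, dtype=float)
    if g.size < 2:
        raise ValueError("need >= 2 replicates for an SD")
    return float(g.std(ddof=1))


def iv_fit_through_origin(voltages, currents) -> tuple[float, np.ndarray]:
    """Least-squares slope with zero intercept: g = sum(V I) / sum(V^2).

    Returns (slope, residuals).  Slope units follow the inputs (A/V if
    currents are in ampere).
    """
    v = np.asarray(voltages, dtype=float)
    i = np.asarray(currents, dtype=float)
    if v.shape != i.shape or v.ndim != 1 or v.size == 0:
        raise ValueError("voltages and currents must be equal-length 1D arrays")
    denom = float(np.sum(v * v))
    if denom == 0:
        raise ValueError("all voltages zero: slope undefined")
    slope = float(np.sum(v * i)) / denom
    return slope, i - slope * v


def selectivity_ratio(events_a: int, events_b: int) -> SelectivityRatio:
    """Event-count ratio A:B; a zero denominator yields a flagged infinity."""
    if events_b < 0:
        raise ValueError("event counts must be non-negative")
    if events_b == 0:
        return SelectivityRatio(math.inf, infinite=True)
    return SelectivityRatio(events_a / events_b, infinite=False)


def fold_change(
    g_mut: float, g_wt: float, sd_mut: float = 0.0, sd_wt: float = 0.0
) -> tuple[float, float]:
    """Mutant/wild-type conductance ratio with delta-method SD.

    sd(ratio) = ratio * sqrt((sd_mut/g_mut)^2 + (sd_wt/g_wt)^2); for
    g_mut = 0 the first term reduces to sd_mut/g_wt.
    """
    if not g_wt > 0:
        raise ValueError("wild-type conductance must be positive")
    ratio = g_mut / g_wt
    if g_mut == 0:
        sd = sd_mut / g_wt
    else:
        sd = abs(ratio) * math.sqrt((sd_mut / g_mut) ** 2 + (sd_wt / g_wt) ** 2)
    return ratio, sd


def pearson_vs_experiment(md: dict, exp: dict) -> float:
    """Pearson r between simulated and experimental per-mutant values.

    ``exp`` values may be scalars or sequences (replicate measurements from
    different studies); sequences are averaged before correlating.  Requires
    at least 3 mutants present in both mappings.
    """
    keys = [k for k in md if k in exp]
    if len(keys) < 3:
        raise ValueError("need >= 3 mutants shared between md and exp")
    x = np.array([float(md[k]) for k in keys])
    y = np.array([
        float(np.mean(exp[k])) if np.ndim(exp[k]) else float(exp[k])
        for k in keys
    ])
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero variance: correlation undefined")
    r, _ = stats.pearsonr(x, y)
    return float(r)


def arrhenius_rate_ratio(ddg_kj_per_mol: float, T: Temperature) -> float:
    """Rate ratio exp(ddG / RT) implied by a barrier difference.

    A barrier difference of 19 kJ/mol at 310 K gives ~1.6e3; the same
    difference at 300 K gives ~2.0e3.
    """
    return float(math.exp(ddg_kj_per_mol / T.rt))
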