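"""Synthetic inputs: landscapes, toy samplers and trajectory generators.

Everything the analysis pipeline consumes can be generated here without
molecular dynamics:

* closed-form toy energy landscapes with their analytic facts (well
  positions, saddle energies) recorded alongside, as fixtures for the MFEP
  machinery;
* a 1D well-tempered metadynamics toy sampler (overdamped Langevin walker
  plus adaptive Gaussian bias) whose defaults mirror production-style hill
  parameters (height 5 kJ/mol, width 0.02 nm, bias factor 5, 1 ps stride);
* an exact (Gillespie) kinetic Monte-Carlo simulator of the three-state
  knock-on permeation cycle 1 -> 2U -> 2L -> 1, emitting a permeation event
  on every completed exit step;
* a multi-ion overdamped Langevin generator for single-file z-trajectories
  under an applied field, with screened-Coulomb pair repulsion standing in
  for full electrostatics;
* coordination-geometry frame fixtures with emitted ground truth.

All generators take explicit seeds; there is no hidden global RNG state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .fes_io import Axis, EnergyGrid, Temperature
from .permeation import IonTrajectory
from .sf_binding import StateSequence

__all__ = [
    "ToyLandscapeSpec",
    "MetadConfig",
    "KnockOnModel",
    "LangevinConfig",
    "toy_landscape",
    "random_smooth_landscape",
    "synthetic_topology",
    "wt_metadynamics_1d",
    "simulate_knockon_kmc",
    "simulate_multi_ion_langevin",
    "synthetic_coordination_frames",
]

#: Conversion of q*E with q in e and E in V/nm to a force in kJ/mol/A.
_FARADAY_KJ_PER_MOL_V = 96.485332
_FORCE_PER_E_V_NM = _FARADAY_KJ_PER_MOL_V / 10.0  # kJ/mol/A per (e * V/nm)

_FAMILIES = (
    "double_well_2d",
    "bowl_2d",
    "corridor_2d",
    "triple_well_1d",
    "knockon_3d_surrogate",
)


@dataclass(frozen=True)
class ToyLandscapeSpec:
    """Closed-form landscape family plus its sampling parameters."""

    family: str
    spacing: float = 0.05
    barrier: float = 1.0  # kJ/mol, families with a saddle
    extent: float = 1.5
    curvature: float = 5.0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")


def toy_landscape(spec: ToyLandscapeSpec) -> EnergyGrid:
    """Sample a closed-form potential onto a grid.

    Analytic facts (well positions, saddle energy and location) are stored
    in ``grid.metadata["analytic"]``; they hold on the grid to within one
    grid spacing.  Refuses spacing coarser than the landscape feature scale.
    """
    h = spec.spacing
    if h > 0.5:
        raise ValueError(
            f"spacing {h} too coarse for feature scale ~1 of family {spec.family}"
        )
    L = spec.extent
    if spec.family == "double_well_2d":
        # V = barrier*(x^2-1)^2 + c*y^2: wells at (+-1, 0) at E=0, saddle at
        # the origin at E=barrier
        x = _axis_coords(-L, L, h)
        y = _axis_coords(-L, L, h)
        X, Y = np.meshgrid(x, y, indexing="ij")
        V = spec.barrier * (X ** 2 - 1) ** 2 + spec.curvature * Y ** 2
        axes = (Axis("x", x[0], x[-1], x.size), Axis("y", y[0], y[-1], y.size))
        facts = {
            "wells": [(-1.0, 0.0), (1.0, 0.0)],
            "saddle_point": (0.0, 0.0),
            "saddle_energy": spec.barrier,
            "well_energy": 0.0,
        }
    elif spec.family == "bowl_2d":
        x = _axis_coords(-L, L, h)
        X, Y = np.meshgrid(x, x, indexing="ij")
        V = spec.curvature * (X ** 2 + Y ** 2)
        axes = (Axis("x", x[0], x[-1], x.size), Axis("y", x[0], x[-1], x.size))
        facts = {"wells": [(0.0, 0.0)], "well_energy": 0.0}
    elif spec.family == "corridor_2d":
        # low-energy corridor along y = -1 between wells at (+-1, -1); a high
        # ridge fills the rest of the box, so the optimal path hugs the
        # corridor instead of cutting straight across
        x = _axis_coords(-L, L, h)
        X, Y = np.meshgrid(x, x, indexing="ij")
        ridge = 40.0 * np.exp(-((Y + 0.0) ** 2) / 0.08)
        wells = spec.curvature * ((X ** 2 - 1) ** 2 + (Y + 1) ** 2)
        corridor = 1.0 - np.exp(-((Y + 1) ** 2) / 0.05)
        V = wells * corridor + ridge + spec.barrier * (X ** 2 - 1) ** 2
        V = V - V.min()
        axes = (Axis("x", x[0], x[-1], x.size), Axis("y", x[0], x[-1], x.size))
        facts = {"corridor_y": -1.0, "wells": [(-1.0, -1.0), (1.0, -1.0)]}
    elif spec.family == "triple_well_1d":
        x = _axis_coords(-L, L, h)
        # wells at -1, 0, +1 separated by barriers of the requested height,
        # with a weak quartic confinement toward the center
        V = spec.barrier * 0.5 * (1 - np.cos(2 * np.pi * x)) \
            + spec.curvature * 0.01 * x ** 4
        axes = (Axis("x", x[0], x[-1], x.size),)
        facts = {
            "wells": [-1.0, 0.0, 1.0],
            "saddle_energy": spec.barrier,
        }
    else:  # knockon_3d_surrogate
        # three Gaussian basins placed so their centers advance in z-order
        # along each CV, mimicking the concerted three-ion translocation
        x = _axis_coords(-1.2, 1.2, max(h, 0.2))
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        centers = [(-0.6, -0.6, -0.6), (0.0, 0.0, 0.0), (0.6, 0.6, 0.6)]
        V = 6.0 + 2.0 * (X ** 2 + Y ** 2 + Z ** 2)
        for cx, cy, cz in centers:
            V -= 8.0 * np.exp(
                -(((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2) / 0.18)
            )
        V = V - V.min()
        axes = tuple(
            Axis(name, x[0], x[-1], x.size) for name in ("z1", "z2", "z3")
        )
        facts = {"basin_centers": centers}
    grid = EnergyGrid(axes, V, metadata={"analytic": facts, "family": spec.family})
    return grid


def _axis_coords(lo: float, hi: float, h: float) -> np.ndarray:
    n = int(round((hi - lo) / h)) + 1
    return np.linspace(lo, hi, n)


def random_smooth_landscape(
    seed: int,
    n_bins: int = 30,
    ndim: int = 2,
    n_wells: int | None = None,
    depth_range: tuple[float, float] = (6.0, 14.0),
) -> EnergyGrid:
    """Random smooth multi-well landscape on the unit box.

    A confining quadratic bowl plus ``n_wells`` Gaussian wells of random
    position, depth and width (2 or 3 wells by default, drawn at random),
    shifted to minimum 0.  These are the smooth random surfaces used to
    exercise path searches; they have a handful of deep basins rather than
    fine-grained noise, matching the structure of converged free-energy
    surfaces.
    """
    rng = np.random.default_rng(seed)
    if n_wells is None:
        n_wells = int(rng.integers(2, 4))
    axes = tuple(Axis(f"x{d}", 0.0, 1.0, n_bins) for d in range(ndim))
    coords = np.stack(
        np.meshgrid(*([np.linspace(0, 1, n_bins)] * ndim), indexing="ij"),
        axis=-1,
    )
    V = 10.0 * ((coords - 0.5) ** 2).sum(axis=-1)
    for c in rng.uniform(0.15, 0.85, size=(n_wells, ndim)):
        d2 = ((coords - c) ** 2).sum(axis=-1)
        V -= rng.uniform(*depth_range) * np.exp(-d2 / rng.uniform(0.01, 0.03))
    V -= V.min()
    return EnergyGrid(axes, V, metadata={"family": "random_smooth", "n_wells": n_wells})


@dataclass(frozen=True)
class MetadConfig:
    """Well-tempered metadynamics parameters for the 1D toy sampler."""

    hill_height: float = 5.0  # kJ/mol
    hill_width: float = 0.02  # nm
    bias_factor: float = 5.0
    stride_ps: float = 1.0
    temperature: Temperature = Temperature(310.0)
    total_time_ps: float = 20_000.0
    # the drift step over the steepest bias slope (~hill_height/hill_width)
    # must stay well below the hill width, or the walker mis-samples the
    # rugged instantaneous bias and freezes ripple into the estimate
    timestep_ps: float = 0.005
    diffusion_nm2_per_ps: float = 0.005
    domain: tuple[float, float] = (-0.3, 0.3)  # nm
    grid_points: int = 241
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.hill_height > 0 or not self.hill_width > 0:
            raise ValueError("hill height and width must be positive")
        if not self.bias_factor > 1:
            raise ValueError("bias factor must exceed 1")


def wt_metadynamics_1d(
    potential: Callable[[np.ndarray], np.ndarray], cfg: MetadConfig
) -> tuple[EnergyGrid, pd.DataFrame]:
    """Toy well-tempered metadynamics on a 1D potential (nm, kJ/mol).

    An overdamped Langevin walker (Euler-Maruyama, reflective domain walls)
    deposits Gaussian hills every ``stride_ps``; the hill height decays as
    exp(-V_bias / ((gamma - 1) k_B T)).  The instantaneous free-energy
    estimate is the well-tempered identity F = -gamma/(gamma-1) * V_bias; to
    suppress the residual bias fluctuations the returned surface is the
    time average of that estimate over the last half of the run (the
    pointwise SD over the averaged snapshots is stored in
    ``metadata["fes_sd"]``), shifted to minimum 0.

    Returns the reconstructed FES as an :class:`EnergyGrid` (axis in nm) and
    the hill log (time_ps, center_nm, height_kj).
    """
    rng = np.random.default_rng(cfg.seed)
    rt = cfg.temperature.rt
    gamma = cfg.bias_factor
    lo, hi = cfg.domain
    grid_x = np.linspace(lo, hi, cfg.grid_points)
    dx = grid_x[1] - grid_x[0]
    v_bias = np.zeros_like(grid_x)
    bias_force = np.zeros_like(grid_x)  # -dV_bias/dx on the grid

    beta_d = 1.0 / ((gamma - 1.0) * rt)
    dt = cfg.timestep_ps
    n_steps_per_hill = max(int(round(cfg.stride_ps / dt)), 1)
    n_hills = int(cfg.total_time_ps // cfg.stride_ps)
    mobility = cfg.diffusion_nm2_per_ps / rt  # nm^2 per ps per (kJ/mol/nm)
    noise_sd = math.sqrt(2.0 * cfg.diffusion_nm2_per_ps * dt)

    # physical force from finite differences of the potential
    u_grid = potential(grid_x)
    phys_force = -np.gradient(u_grid, dx)

    x = 0.5 * (lo + hi)
    hills = []
    if n_hills == 0:
        fes = np.zeros_like(grid_x)
        grid = EnergyGrid(
            (Axis("x", lo, hi, grid_x.size, unit="nm"),), fes
        )
        return grid, pd.DataFrame(columns=["time_ps", "center_nm", "height_kj"])

    eta = rng.standard_normal(n_hills * n_steps_per_hill)
    step = 0
    avg_start = n_hills // 2  # average the estimate over the last half
    fes_sum = np.zeros_like(grid_x)
    fes_sq = np.zeros_like(grid_x)
    n_avg = 0
    for h_i in range(n_hills):
        for _ in range(n_steps_per_hill):
            f = np.interp(x, grid_x, phys_force) + np.interp(x, grid_x, bias_force)
            x = x + mobility * f * dt + noise_sd * eta[step]
            step += 1
            # reflective walls
            if x < lo:
                x = 2 * lo - x
            elif x > hi:
                x = 2 * hi - x
        vb_x = float(np.interp(x, grid_x, v_bias))
        h = cfg.hill_height * math.exp(-vb_x * beta_d)
        two_sig2 = 2 * cfg.hill_width ** 2
        # mirror the kernel across the reflective walls so the deposited
        # bias matches the reflected dynamics (no boundary depletion)
        kern = h * (
            np.exp(-((grid_x - x) ** 2) / two_sig2)
            + np.exp(-((grid_x - (2 * lo - x)) ** 2) / two_sig2)
            + np.exp(-((grid_x - (2 * hi - x)) ** 2) / two_sig2)
        )
        v_bias += kern
        bias_force = -np.gradient(v_bias, dx)
        hills.append(((h_i + 1) * cfg.stride_ps, x, h))
        if h_i >= avg_start:
            snap = -(gamma / (gamma - 1.0)) * v_bias
            snap = snap - snap.min()
            fes_sum += snap
            fes_sq += snap ** 2
            n_avg += 1

    fes = fes_sum / n_avg
    sd = np.sqrt(np.maximum(fes_sq / n_avg - fes ** 2, 0.0))
    fes -= fes.min()
    grid = EnergyGrid(
        (Axis("x", lo, hi, grid_x.size, unit="nm"),),
        fes,
        metadata={
            "estimator": "well_tempered_time_averaged",
            "bias_factor": gamma,
            "fes_sd": sd,
        },
    )
    log = pd.DataFrame(hills, columns=["time_ps", "center_nm", "height_kj"])
    return grid, log


@dataclass(frozen=True)
class KnockOnModel:
    """Three-state knock-on cycle with forward and reverse rate constants.

    States: "1" (one ion in the filter), "2U" (two ions, upper sites),
    "2L" (two ions, lower sites).  Forward steps: entry 1 -> 2U,
    translocation 2U -> 2L, exit 2L -> 1 (a permeation event fires on each
    completed exit).  Rates in ns^-1.
    """

    k_entry: float
    k_transloc: float
    k_exit: float
    k_entry_rev: float = 0.0
    k_transloc_rev: float = 0.0
    k_exit_rev: float = 0.0

    def __post_init__(self) -> None:
        rates = (
            self.k_entry, self.k_transloc, self.k_exit,
            self.k_entry_rev, self.k_transloc_rev, self.k_exit_rev,
        )
        if any(k < 0 for k in rates):
            raise ValueError("rates must be non-negative")
        fwd = all(k > 0 for k in rates[:3])
        rev = all(k > 0 for k in rates[3:])
        if not (fwd or rev):
            raise ValueError("at least one cycle direction must be fully open")

    def rate_matrix(self) -> dict:
        return {
            ("1", "2U"): self.k_entry,
            ("2U", "2L"): self.k_transloc,
            ("2L", "1"): self.k_exit,
            ("2U", "1"): self.k_entry_rev,
            ("2L", "2U"): self.k_transloc_rev,
            ("1", "2L"): self.k_exit_rev,
        }

    def stationary_irreversible(self) -> dict:
        """Analytic stationary occupancies of the irreversible cycle.

        For a one-way cycle the occupancy of each state is proportional to
        its mean dwell time 1/k_out.
        """
        w = {"1": 1 / self.k_entry, "2U": 1 / self.k_transloc, "2L": 1 / self.k_exit}
        z = sum(w.values())
        return {s: v / z for s, v in w.items()}

    def cycle_event_rate(self) -> float:
        """Mean permeation events per ns for the irreversible cycle."""
        return 1.0 / (1 / self.k_entry + 1 / self.k_transloc + 1 / self.k_exit)


def simulate_knockon_kmc(
    model: KnockOnModel,
    duration_ns: float,
    dt_ps: float = 10.0,
    seed: int = 0,
) -> tuple[StateSequence, np.ndarray]:
    """Exact stochastic simulation of the knock-on cycle.

    The continuous-time jump process is sampled by the Gillespie algorithm
    and then resampled onto a uniform grid of spacing ``dt_ps`` (mimicking
    saved MD frames).  Returns the frame-labelled sequence and the
    permeation-event times (ns, one per completed 2L -> 1 exit).

    An absorbing state (all exit rates zero) ends the simulation early with
    the remaining frames labelled by that state.
    """
    if duration_ns < 0:
        raise ValueError("duration must be non-negative")
    rng = np.random.default_rng(seed)
    rates = model.rate_matrix()
    out_edges = {
        s: [(s2, k) for (s1, s2), k in rates.items() if s1 == s and k > 0]
        for s in ("1", "2U", "2L")
    }
    n_frames = int(round(duration_ns * 1e3 / dt_ps))
    if n_frames == 0:
        return StateSequence((), dt_ps), np.array([])
    state = "1"
    t = 0.0  # ns
    jump_times = [0.0]
    jump_states = [state]
    events = []
    dt_ns = dt_ps * 1e-3
    horizon = n_frames * dt_ns
    while t < horizon:
        edges = out_edges[state]
        total = sum(k for _, k in edges)
        if total == 0:
            break  # absorbing; remaining frames keep this label
        t += rng.exponential(1.0 / total)
        if t >= horizon:
            break
        u = rng.random() * total
        acc = 0.0
        for s2, k in edges:
            acc += k
            if u <= acc:
                if state == "2L" and s2 == "1":
                    events.append(t)
                state = s2
                break
        jump_times.append(t)
        jump_states.append(state)
    frame_t = (np.arange(n_frames) + 1) * dt_ns
    idx = np.searchsorted(np.asarray(jump_times), frame_t, side="right") - 1
    labels = tuple(jump_states[i] for i in idx)
    return StateSequence(labels, dt_ps), np.asarray(events)


@dataclass(frozen=True)
class LangevinConfig:
    """Multi-ion 1D overdamped Langevin generator configuration.

    Units: Angstrom, ps, kJ/mol.  The applied field ``e_field`` (V/nm, along
    -z) exerts a force -q * E * 9.6485 kJ/mol/A on an ion of charge q; pair
    repulsion is screened-Coulomb, f(d) = A * sign(d) * exp(-|d|/lambda)/d^2,
    a deliberate surrogate for full electrostatics that keeps ions in
    single file.
    """

    n_ions: int = 3
    charge: float = 2.0
    potential: Callable[[np.ndarray], np.ndarray] | None = None
    repulsion_amp: float = 200.0  # kJ/mol * A
    screening_a: float = 3.0
    e_field: float = 0.02  # V/nm
    friction: float = 50.0  # kJ/mol * ps / A^2
    temperature: Temperature = Temperature(310.0)
    timestep_ps: float = 0.05
    box_z: float = 60.0
    n_frames: int = 20_000
    save_stride: int = 10
    f_ecc: float = 0.87
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.friction > 0:
            raise ValueError("friction must be positive")
        step_sd = math.sqrt(
            2 * self.temperature.rt * self.timestep_ps / self.friction
        )
        if step_sd >= 0.5:
            raise ValueError(
                f"timestep too large: single-step displacement SD {step_sd:.2f} A >= 0.5 A"
            )


def simulate_multi_ion_langevin(cfg: LangevinConfig) -> IonTrajectory:
    """Euler-Maruyama integration of single-file ions under a field.

    dz_i = [ -U'(z_i) - q E_conv + sum_j f_rep(z_i - z_j) ] / friction * dt
           + sqrt(2 RT dt / friction) dW.

    The field drives ions toward negative z (inward).  Ions wrap
    periodically across ``box_z``; the returned trajectory carries the
    metadata the conductance formula needs.  Aborts if any single step
    exceeds box_z/4 (unstable parameters).
    """
    rng = np.random.default_rng(cfg.seed)
    rt = cfg.temperature.rt
    dt = cfg.timestep_ps
    half = cfg.box_z / 2
    n_save = cfg.n_frames
    n_steps = n_save * cfg.save_stride
    z = np.linspace(-half * 0.8, half * 0.8, cfg.n_ions)  # spread initial ions
    mobility = dt / cfg.friction
    noise_sd = math.sqrt(2 * rt * dt / cfg.friction)
    field_force = -cfg.charge * cfg.e_field * _FORCE_PER_E_V_NM  # toward -z

    if cfg.potential is not None:
        xg = np.linspace(-half, half, 2001)
        ug = cfg.potential(xg)
        fg = -np.gradient(ug, xg[1] - xg[0])
    else:
        xg = fg = None

    out = np.empty((n_save, cfg.n_ions))
    times = np.empty(n_save)
    eta = rng.standard_normal((n_steps, cfg.n_ions))
    max_step = cfg.box_z / 4
    for s in range(n_steps):
        force = np.full(cfg.n_ions, field_force)
        if xg is not None:
            force += np.interp(z, xg, fg)
        if cfg.n_ions > 1:
            d = z[:, None] - z[None, :]
            d -= cfg.box_z * np.round(d / cfg.box_z)  # minimum image
            np.fill_diagonal(d, np.inf)
            rep = cfg.repulsion_amp * np.sign(d) * np.exp(
                -np.abs(d) / cfg.screening_a
            ) / np.where(np.isinf(d), 1.0, d ** 2)
            rep[np.isinf(d)] = 0.0
            force += rep.sum(axis=1)
        step = mobility * force + noise_sd * eta[s]
        if np.any(np.abs(step) > max_step):
            raise RuntimeError(
                f"unstable integration at step {s}: displacement "
                f"{np.abs(step).max():.1f} A exceeds box_z/4"
            )
        z = z + step
        z = (z + half) % cfg.box_z - half  # periodic re-entry
        if (s + 1) % cfg.save_stride == 0:
            i = (s + 1) // cfg.save_stride - 1
            out[i] = z
            times[i] = (s + 1) * dt
    return IonTrajectory(
        times=times,
        z=out,
        box_z=cfg.box_z,
        species=tuple("ION" for _ in range(cfg.n_ions)),
        charges=tuple(cfg.charge for _ in range(cfg.n_ions)),
        e_field=cfg.e_field,
        lz_nm=cfg.box_z / 10.0,
        f_ecc=cfg.f_ecc,
    )


def synthetic_coordination_frames(
    oxygen_layout: pd.DataFrame,
    n_frames: int = 10,
    noise_a: float = 0.0,
    seed: int = 0,
    ion_position=(0.0, 0.0, 0.0),
    cutoff: float = 3.0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Coordinate-frame fixtures with per-frame ground-truth counts.

    ``oxygen_layout`` needs columns kind, residue_label, x, y, z (one row
    per oxygen).  Each frame jitters every atom with isotropic Gaussian
    noise of SD ``noise_a``; the emitted ground truth is the brute-force
    count of oxygens within the (closed) ``cutoff`` of the ion in that
    frame, computed from the jittered coordinates.

    Returns (frames, truth): frames in the tidy schema consumed by
    :func:`campath.sf_binding.coordination_profile`, truth of shape
    (n_frames,).
    """
    required = {"kind", "residue_label", "x", "y", "z"}
    missing = required - set(oxygen_layout.columns)
    if missing:
        raise ValueError(f"layout missing columns: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    ion = np.asarray(ion_position, dtype=float)
    oxy = oxygen_layout[["x", "y", "z"]].to_numpy(dtype=float)
    rows = []
    truth = np.zeros(n_frames)
    for f in range(n_frames):
        ion_f = ion + noise_a * rng.standard_normal(3)
        oxy_f = oxy + noise_a * rng.standard_normal(oxy.shape)
        d = np.sqrt(((oxy_f - ion_f) ** 2).sum(axis=1))
        truth[f] = float((d <= cutoff).sum())
        rows.append((f, 0, "ion", "ION", *ion_f))
        for j, (_, r) in enumerate(oxygen_layout.iterrows(), start=1):
            rows.append((f, j, r["kind"], r["residue_label"], *oxy_f[j - 1]))
    frames = pd.DataFrame(
        rows, columns=["frame", "atom_id", "kind", "residue_label", "x", "y", "z"]
    )
    return frames, truth

#: Synthetic reduced-grammar topology: one Ca2+ ion plus a glutamate residue,
#: with Ca/Na/K-oxygen pair overrides.  A hand-written stand-in for a real
#: force-field topology, sized for exercising the ECC patcher.
_SYNTHETIC_TOPOLOGY = """\
; synthetic topology fixture for ECC patching (reduced GROMACS grammar)
[ defaults ]
1 2 yes 1.0 1.0

[ atomtypes ]
; name  at.num  mass     charge  ptype  sigma          epsilon
CA      20      40.078   0.0     A      0.24357170954  0.50208
NA      11      22.990   0.0     A      0.25160        0.19246
K       19      39.098   0.0     A      0.31426        0.36401
OT      8       15.999   0.0     A      0.31507        0.63639
OC      8       15.999   0.0     A      0.30200        0.50208

[ nonbond_params ]
; i   j   func  sigma   epsilon
CA    OT  1     0.3000  0.4000 ; Ca-water oxygen override
CA    OC  1     0.2900  0.4500 ; Ca-carboxylate oxygen override
NA    OC  1     0.2800  0.3000 ; Na-carboxylate oxygen override
K     OT  1     0.3200  0.3500 ; K-water oxygen override, must survive

[ moleculetype ]
ION 1

[ atoms ]
; nr  type  resnr  residue  atom  cgnr  charge  mass
1     CA    1      CA       CA    1     2.0     40.078

[ moleculetype ]
GLU 3

[ atoms ]
; nr  type  resnr  residue  atom  cgnr  charge  mass
1     NH1   1      GLU      N     1     -0.47   14.007
2     H     1      GLU      HN    2     0.31    1.008
3     CT1   1      GLU      CA    3     0.07    12.011
4     HB1   1      GLU      HA    4     0.09    1.008
5     CT2   1      GLU      CB    5     -0.18   12.011
6     HA    1      GLU      HB1   6     0.09    1.008
7     HA    1      GLU      HB2   7     0.09    1.008
8     CT2   1      GLU      CG    8     -0.28   12.011
9     HA    1      GLU      HG1   9     0.09    1.008
10    HA    1      GLU      HG2   10    0.09    1.008
11    CC    1      GLU      CD    11    0.62    12.011
12    OC    1      GLU      OE1   12    -0.76   15.999
13    OC    1      GLU      OE2   13    -0.76   15.999
14    C     1      GLU      C     14    0.51    12.011
15    O     1      GLU      O     15    -0.51   15.999
"""


def synthetic_topology() -> str:
    """Text of a small synthetic molecular topology for ECC patch exercises.

    One Ca2+ ion plus a glutamate residue (terminal carboxylate group net
    charge -1), calcium/sodium/potassium-oxygen pair-override records, and a
    calcium atomtype carrying the unpatched Lennard-Jones sigma.
    """
    return _SYNTHETIC_TOPOLOGY
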