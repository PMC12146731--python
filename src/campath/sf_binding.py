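"""Selectivity-filter binding-site, coordination and occupancy-state analysis.

The z origin is the declared filter center (in the channel, the center of
mass of the EEEE-locus C-alpha atoms).  Analyses provided:

* time-averaged ion density along z and peak-based binding-site detection;
* coordination-number profiles (oxygens within a distance cutoff of an ion,
  split by oxygen class and residue, averaged per ion z-bin);
* per-frame occupancy-state labels for the multi-ion filter (one ion = state
  "1", two ions at the upper site pair = "2U", two at the lower pair = "2L",
  anything else = "other"), occupancy probabilities and transition-rate
  estimates with Poisson uncertainties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.spatial import cKDTree

__all__ = [
    "ZDensityProfile",
    "SiteDefinition",
    "DEFAULT_SITES",
    "StateSequence",
    "TransitionRates",
    "z_density",
    "detect_binding_sites",
    "coordination_profile",
    "assign_states",
    "label_trajectory",
    "occupancy_probabilities",
    "transition_rates",
]

#: Distance cutoff (Angstrom) for direct ion-oxygen coordination.
DEFAULT_COORDINATION_CUTOFF_A = 3.0

#: Default z bin width (Angstrom) for density and coordination profiles.
DEFAULT_BIN_WIDTH_A = 0.2

STATE_LABELS = ("1", "2U", "2L", "other")


@dataclass(frozen=True)
class ZDensityProfile:
    """Mean ion count per z-bin.

    ``edges`` has one more entry than ``counts``; the sum of counts equals
    the time-averaged number of ions inside the profiled region.
    """

    edges: np.ndarray
    counts: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class SiteDefinition:
    """Named z-intervals (Angstrom, filter-center origin) for the SF sites.

    Intervals are (lo, hi] ordered S2L < S2U < S1L < S1U along z, with V1 in
    the vestibule above the filter.  The defaults anchor to the observed
    two-ion site peaks near -2.8 and +1.7 A; boundaries are user-tunable.
    """

    sf_extent: tuple[float, float] = (-5.0, 5.0)
    s2l: tuple[float, float] = (-4.0, -1.5)
    s2u: tuple[float, float] = (-1.5, 0.5)
    s1l: tuple[float, float] = (0.5, 2.5)
    s1u: tuple[float, float] = (2.5, 5.0)
    v1: tuple[float, float] = (5.0, 10.0)

    def __post_init__(self) -> None:
        for name in ("s2l", "s2u", "s1l", "s1u", "v1", "sf_extent"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"site {name}: require lo < hi")
        if not (self.s2l[1] <= self.s2u[0] and self.s1l[1] <= self.s1u[0]):
            raise ValueError("U intervals must lie above L intervals")
        if not self.s2u[1] <= self.s1l[0]:
            raise ValueError("S1 intervals must lie above S2 intervals")

    def in_sf(self, z: float) -> bool:
        return self.sf_extent[0] <= z <= self.sf_extent[1]

    def upper(self, z: float) -> bool:
        return self.s1u[0] < z <= self.s1u[1] or self.s2u[0] < z <= self.s2u[1]

    def lower(self, z: float) -> bool:
        return self.s1l[0] < z <= self.s1l[1] or self.s2l[0] < z <= self.s2l[1]


DEFAULT_SITES = SiteDefinition()


@dataclass(frozen=True)
class StateSequence:
    """Per-frame occupancy labels with uniform frame spacing dt (ps)."""

    labels: tuple[str, ...]
    dt_ps: float

    def __post_init__(self) -> None:
        if not self.dt_ps > 0:
            raise ValueError("dt must be positive")
        object.__setattr__(self, "labels", tuple(self.labels))


@dataclass(frozen=True)
class TransitionRates:
    """Occupancy probabilities and the off-diagonal rate matrix (ns^-1).

    ``rates[(s, s2)]`` is NaN where state ``s`` was never visited (no dwell
    time to divide by); ``errors`` carries the Poisson SE of each rate.
    """

    probabilities: dict
    rates: dict
    errors: dict
    counts: dict


def z_density(
    z_frames: np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH_A,
    region: tuple[float, float] = (-10.0, 10.0),
) -> ZDensityProfile:
    """Time-averaged ion count per z-bin.

    ``z_frames`` is (n_frames, n_ions) (or 1D, one ion).  Each frame
    contributes its instantaneous in-bin ion counts; the profile is the mean
    over frames, so the bin sum equals the mean ion count in the region.
    """
    if not bin_width > 0:
        raise ValueError("bin_width must be positive")
    lo, hi = region
    if not lo < hi:
        raise ValueError("empty region")
    z = np.atleast_2d(np.asarray(z_frames, dtype=float))
    n_frames = z.shape[0]
    n_bins = max(int(round((hi - lo) / bin_width)), 1)
    edges = lo + (hi - lo) * np.arange(n_bins + 1) / n_bins
    counts, _ = np.histogram(z.ravel(), bins=edges)
    return ZDensityProfile(edges, counts / n_frames)


def detect_binding_sites(
    profile: ZDensityProfile,
    min_prominence: float = 0.05,
    min_separation: float = 1.0,
) -> list[tuple[float, float]]:
    """Density peaks passing prominence/separation filters.

    Returns (z position, height) pairs sorted by height, highest first.
    ``min_separation`` is in Angstrom and converts to a bin distance.
    """
    counts = np.asarray(profile.counts, dtype=float)
    if counts.size == 0:
        raise ValueError("empty profile")
    width = float(profile.edges[1] - profile.edges[0])
    distance = max(int(round(min_separation / width)), 1)
    peaks, props = find_peaks(counts, prominence=min_prominence, distance=distance)
    centers = profile.centers
    ranked = sorted(
        ((float(centers[p]), float(counts[p])) for p in peaks),
        key=lambda t: -t[1],
    )
    return ranked


def coordination_profile(
    frames: pd.DataFrame,
    cutoff: float = DEFAULT_COORDINATION_CUTOFF_A,
    bin_width: float = DEFAULT_BIN_WIDTH_A,
    region: tuple[float, float] = (-10.0, 10.0),
    box: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean coordination number per ion z-bin, split by oxygen class/residue.

    ``frames`` needs columns frame, atom_id, kind, residue_label, x, y, z;
    ``kind`` is ``"ion"`` for the coordinated ions and an oxygen class
    (e.g. ``"ox_carboxylate"``, ``"ox_carbonyl"``, ``"ox_water"``) otherwise.
    An oxygen coordinates an ion when their distance is <= ``cutoff``
    (closed at the boundary; minimum-image convention if ``box`` is given).

    Returns a tidy frame with columns z_center, kind, residue_label,
    mean_coordination (mean over ion observations in the bin).
    """
    required = {"frame", "atom_id", "kind", "residue_label", "x", "y", "z"}
    missing = required - set(frames.columns)
    if missing:
        raise ValueError(f"frames missing columns: {sorted(missing)}")
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")
    lo, hi = region
    n_bins = max(int(round((hi - lo) / bin_width)), 1)
    edges = lo + (hi - lo) * np.arange(n_bins + 1) / n_bins
    centers = 0.5 * (edges[:-1] + edges[1:])

    classes = sorted(
        frames.loc[frames["kind"] != "ion", ["kind", "residue_label"]]
        .drop_duplicates()
        .itertuples(index=False, name=None)
    )
    sums = {c: np.zeros(n_bins) for c in classes}
    n_obs = np.zeros(n_bins)

    for _, sub in frames.groupby("frame", sort=True):
        ions = sub[sub["kind"] == "ion"]
        oxy = sub[sub["kind"] != "ion"]
        if ions.empty:
            continue
        ion_xyz = ions[["x", "y", "z"]].to_numpy(dtype=float)
        bins = np.digitize(ion_xyz[:, 2], edges) - 1
        inside = (bins >= 0) & (bins < n_bins)
        for kind, res in classes:
            grp = oxy[(oxy["kind"] == kind) & (oxy["residue_label"] == res)]
            counts = _count_within(
                ion_xyz, grp[["x", "y", "z"]].to_numpy(dtype=float), cutoff, box
            )
            np.add.at(sums[(kind, res)], bins[inside], counts[inside])
        np.add.at(n_obs, bins[inside], 1)

    rows = []
    with np.errstate(invalid="ignore", divide="ignore"):
        for (kind, res), s in sums.items():
            mean = np.where(n_obs > 0, s / np.maximum(n_obs, 1), 0.0)
            for b in range(n_bins):
                if n_obs[b] > 0:
                    rows.append((centers[b], kind, res, mean[b]))
    out = pd.DataFrame(
        rows, columns=["z_center", "kind", "residue_label", "mean_coordination"]
    )
    out.attrs["cutoff"] = cutoff
    return out


def _count_within(
    ions: np.ndarray, oxygens: np.ndarray, cutoff: float, box: np.ndarray | None
) -> np.ndarray:
    """Per-ion count of oxygens within the (closed) cutoff."""
    if len(oxygens) == 0:
        return np.zeros(len(ions))
    if box is not None:
        box = np.asarray(box, dtype=float)
        delta = ions[:, None, :] - oxygens[None, :, :]
        delta -= box * np.round(delta / box)
        d = np.sqrt((delta ** 2).sum(axis=2))
        return (d <= cutoff).sum(axis=1).astype(float)
    tree = cKDTree(oxygens)
    return np.array([
        float(len(tree.query_ball_point(p, cutoff))) for p in ions
    ])


def assign_states(ion_z, sites: SiteDefinition = DEFAULT_SITES) -> str:
    """Occupancy label for one frame from the ion z positions.

    One ion inside the SF extent -> "1"; two ions both at upper sites ->
    "2U"; both at lower sites -> "2L"; any other arrangement (including
    empty or >2-ion filters) -> "other".  Invariant under ion order.
    """
    z_in = [z for z in np.atleast_1d(np.asarray(ion_z, dtype=float)) if sites.in_sf(z)]
    if len(z_in) == 1:
        return "1"
    if len(z_in) == 2:
        if all(sites.upper(z) for z in z_in):
            return "2U"
        if all(sites.lower(z) for z in z_in):
            return "2L"
    return "other"


def label_trajectory(
    z_frames: np.ndarray, dt_ps: float, sites: SiteDefinition = DEFAULT_SITES
) -> StateSequence:
    """Per-frame occupancy labels for a (n_frames, n_ions) z array."""
    z = np.atleast_2d(np.asarray(z_frames, dtype=float))
    return StateSequence(
        tuple(assign_states(row, sites) for row in z), dt_ps
    )


def occupancy_probabilities(seq: StateSequence) -> dict:
    """Fraction of frames per label; sums to 1 exactly."""
    if not seq.labels:
        raise ValueError("empty state sequence")
    n = len(seq.labels)
    out: dict[str, float] = {}
    for lab in seq.labels:
        out[lab] = out.get(lab, 0) + 1
    return {k: v / n for k, v in out.items()}


def transition_rates(seq: StateSequence) -> TransitionRates:
    """Per-time transition-rate estimates from a labelled sequence.

    k(s -> s') = (number of s -> s' frame transitions) /
                 (dt * number of frames labelled s, final frame excluded),
    reported in ns^-1 with Poisson SE sqrt(count) on the numerator.  Rates
    out of a never-visited state are NaN.  The estimator carries an O(k*dt)
    discretization bias; sample state sequences finely relative to the
    fastest rate.
    """
    labels = seq.labels
    if len(labels) < 2:
        raise ValueError("need >= 2 frames to estimate rates")
    states = sorted(set(labels))
    dwell = {s: 0 for s in states}  # frames in s excluding the final frame
    counts: dict[tuple[str, str], int] = {}
    for a, b in zip(labels[:-1], labels[1:]):
        dwell[a] += 1
        if a != b:
            counts[(a, b)] = counts.get((a, b), 0) + 1
    dt_ns = seq.dt_ps * 1e-3
    probs = occupancy_probabilities(seq)
    rates: dict[tuple[str, str], float] = {}
    errors: dict[tuple[str, str], float] = {}
    for a in states:
        for b in states:
            if a == b:
                continue
            c = counts.get((a, b), 0)
            if dwell[a] == 0:
                rates[(a, b)] = math.nan
                errors[(a, b)] = math.nan
            else:
                denom = dt_ns * dwell[a]
                rates[(a, b)] = c / denom
                errors[(a, b)] = math.sqrt(c) / denom
    return TransitionRates(probs, rates, errors, dict(counts))
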