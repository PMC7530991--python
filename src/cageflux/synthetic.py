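"""Forward models with known ground truth.

Three generators emulate the raw inputs of the analysis chain:

* osmotic vesicle-shrinkage traces (stopped-flow light scattering),
  integrating the volume ODE for a mixture of channel-bearing and
  channel-free vesicle subpopulations, which produces a genuinely
  biexponential signal;
* two-state wetting–dewetting occupancy time series from a
  continuous-time Markov chain;
* branched single-file water-chain coordinate frames with dipolar
  ordering, on tetrahedral arm geometry.

Every generator is seeded and returns its ground truth alongside the
data so parameter recovery can be tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .constants import V_W_M3_PER_MOL
from .hydration import ATOM_COLUMNS, HydrationTrajectory
from .vesicle import VesicleSpec

__all__ = [
    "ShrinkageGroundTruth",
    "StoppedFlowTrace",
    "ShrinkageResult",
    "OccupancyGroundTruth",
    "OccupancySeries",
    "ChainFrames",
    "simulate_shrinkage",
    "simulate_occupancy",
    "generate_chain_frames",
]

# tetrahedral arm directions (unit vectors)
_TETRA_DIRS = np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
) / math.sqrt(3.0)

_OH_LENGTH_A = 0.9572
_HOH_ANGLE_DEG = 104.52


@dataclass(frozen=True)
class ShrinkageGroundTruth:
    """True permeabilities behind a simulated shrinkage trace.

    ``pf_lipid`` is the background permeability of the bare bilayer,
    ``pf_channel`` the additional channel-mediated permeability of the
    channel-bearing subpopulation, and ``channel_fraction`` the weight of
    that subpopulation in the scattering signal.
    """

    pf_lipid_um_s: float
    pf_channel_um_s: float
    channel_fraction: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pf_lipid_um_s < 0 or self.pf_channel_um_s < 0:
            raise ValueError("permeabilities must be non-negative")
        if not (0.0 <= self.channel_fraction <= 1.0):
            raise ValueError("channel_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class StoppedFlowTrace:
    """Time-stamped stopped-flow signal (light scattering, a.u.)."""

    times_s: np.ndarray
    signal: np.ndarray
    channel_label: str = ""
    temperature_c: float = 25.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("times and signal must be equal-length 1-D arrays")
        if len(t) < 20:
            raise ValueError("a trace needs at least 20 samples")
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must start at 0 and be strictly increasing")
        if np.any(~np.isfinite(t)) or np.any(~np.isfinite(y)):
            raise ValueError("trace contains non-finite values")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "signal", y)

    @property
    def duration_s(self) -> float:
        return float(self.times_s[-1])


@dataclass(frozen=True)
class ShrinkageResult:
    """A simulated trace together with its noiseless components."""

    trace: StoppedFlowTrace
    truth: ShrinkageGroundTruth
    vesicle: VesicleSpec
    volume_channel: np.ndarray  # V/V0 of the channel-bearing subpopulation
    volume_lipid: np.ndarray  # V/V0 of the lipid-only subpopulation
    noiseless_signal: np.ndarray


def _relative_volume(
    vesicle: VesicleSpec, pf_um_s: float, times_s: np.ndarray
) -> np.ndarray:
    """Integrate dv/dt = −Pf·(S/V0)·Vw·(c_out − c_in0/v), v(0) = 1."""
    if pf_um_s == 0.0:
        return np.ones_like(times_s)
    pf_m_s = pf_um_s * 1e-6
    sv = vesicle.s_over_v0_per_m
    c_in = vesicle.c_in0_osm * 1e3  # mol m⁻³
    c_out = vesicle.c_out_osm * 1e3

    def rhs(_t: float, v: np.ndarray) -> np.ndarray:
        return -pf_m_s * sv * V_W_M3_PER_MOL * (c_out - c_in / v)

    sol = solve_ivp(
        rhs,
        (0.0, float(times_s[-1])),
        [1.0],
        t_eval=times_s,
        method="RK45",
        rtol=1e-9,
        atol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(f"volume ODE integration failed: {sol.message}")
    return sol.y[0]


def simulate_shrinkage(
    vesicle: VesicleSpec,
    truth: ShrinkageGroundTruth,
    n_points: int = 400,
    duration_s: float = 2.0,
    rescale: bool = True,
    channel_label: str = "",
) -> ShrinkageResult:
    """Simulate a stopped-flow shrinkage trace for a vesicle mixture.

    Two subpopulations shrink under the osmotic gradient: channel-bearing
    vesicles with ``Pf = pf_lipid + pf_channel`` (weight
    ``channel_fraction``) and channel-free vesicles with ``Pf = pf_lipid``.
    The scattering signal is taken proportional to the weighted fractional
    volume loss ``Σᵢ wᵢ (1 − Vᵢ/V0)``, optionally rescaled to [0, 1] over
    the window, with additive Gaussian noise of the stated standard
    deviation.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if n_points < 20:
        raise ValueError("need at least 20 samples")
    if vesicle.delta_osm < 0:
        raise ValueError("swelling regime unsupported")

    times = np.linspace(0.0, duration_s, n_points)
    v_channel = _relative_volume(
        vesicle, truth.pf_lipid_um_s + truth.pf_channel_um_s, times
    )
    v_lipid = _relative_volume(vesicle, truth.pf_lipid_um_s, times)
    phi = truth.channel_fraction
    signal = phi * (1.0 - v_channel) + (1.0 - phi) * (1.0 - v_lipid)

    if rescale:
        span = signal.max() - signal.min()
        if span > 0:
            signal = (signal - signal.min()) / span
    noiseless = signal.copy()
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        signal = signal + rng.normal(0.0, truth.noise_sd, size=signal.shape)

    trace = StoppedFlowTrace(times, signal, channel_label=channel_label)
    return ShrinkageResult(
        trace=trace,
        truth=truth,
        vesicle=vesicle,
        volume_channel=v_channel,
        volume_lipid=v_lipid,
        noiseless_signal=noiseless,
    )


# ---------------------------------------------------------------------------
# wetting–dewetting occupancy


@dataclass(frozen=True)
class OccupancyGroundTruth:
    """Two-state wetting–dewetting kinetics behind an occupancy series."""

    wetting_rate_per_s: float
    dewetting_rate_per_s: float
    filled_mean_count: float = 17.0
    frame_interval_s: float = 1e-3
    n_frames: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wetting_rate_per_s <= 0 or self.dewetting_rate_per_s <= 0:
            raise ValueError("rates must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")


@dataclass(frozen=True)
class OccupancySeries:
    """Sampled occupancy with the underlying continuous-time episodes."""

    counts: np.ndarray  # waters per frame
    truth: OccupancyGroundTruth
    dwell_times_filled_s: np.ndarray  # completed filled-state dwells
    dwell_times_empty_s: np.ndarray

    @property
    def frame_interval_s(self) -> float:
        return self.truth.frame_interval_s


def simulate_occupancy(truth: OccupancyGroundTruth) -> OccupancySeries:
    """Sample a two-state CTMC (empty ↔ filled) at the frame interval.

    Dwell times are exponential with the given rates (wetting rate =
    escape from empty, dewetting rate = escape from filled); the initial
    state is drawn from the stationary distribution.  The empty state
    emits 0 waters, the filled state a Poisson count centred on
    ``filled_mean_count`` truncated at 1.
    """
    rng = np.random.default_rng(truth.seed)
    kw, kd = truth.wetting_rate_per_s, truth.dewetting_rate_per_s
    total_time = truth.n_frames * truth.frame_interval_s

    p_filled = kw / (kw + kd)
    state = bool(rng.random() < p_filled)  # True = filled

    # continuous-time episode sequence covering the sampling window
    boundaries = [0.0]
    states = [state]
    t = 0.0
    while t < total_time:
        rate = kd if state else kw
        t += rng.exponential(1.0 / rate)
        boundaries.append(t)
        state = not state
        states.append(state)

    bounds = np.array(boundaries)
    # completed dwells: every episode except the last (right-censored)
    durations = np.diff(bounds)
    dwell_f = durations[: len(durations)][np.array(states[:-1])]
    dwell_e = durations[: len(durations)][~np.array(states[:-1])]

    sample_times = np.arange(truth.n_frames) * truth.frame_interval_s
    idx = np.searchsorted(bounds, sample_times, side="right") - 1
    frame_filled = np.array(states)[idx]

    counts = np.zeros(truth.n_frames, dtype=int)
    n_filled = int(frame_filled.sum())
    if n_filled:
        emitted = rng.poisson(truth.filled_mean_count, size=n_filled)
        counts[frame_filled] = np.maximum(emitted, 1)
    return OccupancySeries(
        counts=counts,
        truth=truth,
        dwell_times_filled_s=dwell_f,
        dwell_times_empty_s=dwell_e,
    )


# ---------------------------------------------------------------------------
# branched water chains


@dataclass(frozen=True)
class ChainFrames:
    """Generated chain frames plus ground-truth chain membership.

    ``expected_chains`` lists the chains a correct single-file detector
    should report: one chain per arm sharing the node water when three
    or more arms branch; a single through-going chain for two arms
    (the node water then has only two neighbours and is no junction);
    one plain chain for a single arm.
    """

    trajectory: HydrationTrajectory
    ground_truth: pd.DataFrame  # mol_id, arm_id, position (0 = node)
    expected_chains: tuple[tuple[int, ...], ...]
    orientations: tuple[int, ...]
    node_mol_id: int | None


def _perpendicular(d: np.ndarray) -> np.ndarray:
    probe = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(probe, d)) > 0.9:
        probe = np.array([0.0, 1.0, 0.0])
    p = probe - np.dot(probe, d) * d
    return p / np.linalg.norm(p)


def _water_hydrogens(o: np.ndarray, donate_dirs: list[np.ndarray]) -> list[np.ndarray]:
    """Place two hydrogens: donated O→H bonds first, fillers off-axis."""
    hs: list[np.ndarray] = []
    for d in donate_dirs[:2]:
        hs.append(o + _OH_LENGTH_A * d)
    while len(hs) < 2:
        ref = donate_dirs[0] if donate_dirs else np.array([0.0, 0.0, 1.0])
        p = _perpendicular(ref)
        ang = math.radians(_HOH_ANGLE_DEG)
        filler = math.cos(ang) * ref + math.sin(ang) * p
        hs.append(o + _OH_LENGTH_A * filler / np.linalg.norm(filler))
    return hs


def generate_chain_frames(
    n_arms: int,
    waters_per_arm: int,
    o_o_spacing_A: float = 2.8,
    orientation: tuple[int, ...] | None = None,
    jitter_sd_A: float = 0.0,
    seed: int = 0,
    n_frames: int = 1,
    frame_interval_ps: float = 10.0,
) -> ChainFrames:
    """Build branched single-file water chains on tetrahedral arms.

    Water oxygens are placed along ``n_arms`` straight arms (tetrahedral
    directions) meeting at a central node water (present for ≥ 2 arms);
    hydrogens are assigned so that along each arm every hydrogen bond
    points the same way — outward from the node for orientation +1,
    inward for −1 (default alternating).  At most two arms may be
    oriented outward, since the node water has only two hydrogens to
    donate.  Gaussian positional jitter is applied per molecule and per
    frame; the known chain membership is returned as ground truth.
    """
    if not (1 <= n_arms <= 4):
        raise ValueError("n_arms must be between 1 and 4 (tetrahedral geometry)")
    if waters_per_arm < 2:
        raise ValueError("need at least 2 waters per arm")
    if not (2.4 < o_o_spacing_A < 3.5):
        raise ValueError("O–O spacing outside hydrogen-bonding range (2.4–3.5 Å)")
    if orientation is None:
        orientation = tuple(1 if a % 2 == 0 else -1 for a in range(n_arms))
    if len(orientation) != n_arms or any(s not in (-1, 1) for s in orientation):
        raise ValueError("orientation must give ±1 per arm")
    has_node = n_arms >= 2
    if has_node and sum(1 for s in orientation if s == 1) > 2:
        raise ValueError("at most two arms can point outward from the node")

    rng = np.random.default_rng(seed)
    dirs = _TETRA_DIRS[:n_arms]

    # ideal geometry: (mol_id, arm, position, O, [H1, H2])
    waters: list[tuple[int, int, int, np.ndarray, list[np.ndarray]]] = []
    truth_rows = []
    node_id: int | None = None
    if has_node:
        node_id = 0
        donate = [dirs[a] for a, s in enumerate(orientation) if s == 1]
        o = np.zeros(3)
        waters.append((0, -1, 0, o, _water_hydrogens(o, donate)))
        for a in range(n_arms):
            truth_rows.append({"mol_id": 0, "arm_id": a, "position": 0})

    next_id = 1 if has_node else 0
    arm_ids: list[list[int]] = [[] for _ in range(n_arms)]
    for a in range(n_arms):
        sign = orientation[a]
        d = dirs[a]
        for j in range(1, waters_per_arm + 1):
            pos_index = j if has_node else j - 1
            o = pos_index * o_o_spacing_A * d
            if sign == 1:
                # donates outward unless it is the arm tip
                donate = [d] if j < waters_per_arm else []
            else:
                donate = [-d]  # everyone donates toward the node
            waters.append((next_id, a, pos_index, o, _water_hydrogens(o, donate)))
            truth_rows.append({"mol_id": next_id, "arm_id": a, "position": pos_index})
            arm_ids[a].append(next_id)
            next_id += 1

    if n_arms == 1:
        expected = (tuple(arm_ids[0]),)
    elif n_arms == 2:
        # degree-2 node: the two arms form one through-going chain
        expected = (tuple(reversed(arm_ids[0])) + (0,) + tuple(arm_ids[1]),)
    else:
        expected = tuple((0, *arm_ids[a]) for a in range(n_arms))

    rows = []
    for f in range(n_frames):
        for mol_id, _arm, _pos, o, hs in waters:
            offset = (
                rng.normal(0.0, jitter_sd_A, size=3)
                if jitter_sd_A > 0
                else np.zeros(3)
            )
            for atom, xyz in (("O", o), ("H1", hs[0]), ("H2", hs[1])):
                x, y, z = xyz + offset
                rows.append((f, mol_id, atom, x, y, z))
    atoms = pd.DataFrame(rows, columns=ATOM_COLUMNS)
    traj = HydrationTrajectory(atoms=atoms, frame_interval_ps=frame_interval_ps)
    return ChainFrames(
        trajectory=traj,
        ground_truth=pd.DataFrame(truth_rows),
        expected_chains=expected,
        orientations=tuple(orientation),
        node_mol_id=node_id,
    )
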