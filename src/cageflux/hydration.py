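"""Hydration statistics for water confined in channel networks.

Post-processing of per-frame water coordinates inside a membrane-spanning
channel: occupancy probability of the channel's middle segment,
wetting–dewetting kinetics, single-file water-chain extraction with
dipolar ordering, and potential-energy barrier profiles along the
channel axis.

Coordinates are in Å; times in ps unless stated otherwise.  The channel
axis defaults to z (the membrane normal).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "HydrationTrajectory",
    "OccupancyStats",
    "WettingStats",
    "WaterChain",
    "EnergyProfile",
    "occupancy_histogram",
    "wetting_transitions",
    "extract_chains",
    "energy_profile",
]

ATOM_COLUMNS = ["frame", "mol_id", "atom", "x_A", "y_A", "z_A"]


@dataclass
class HydrationTrajectory:
    """Per-frame water coordinates with a channel-segment definition.

    ``atoms`` is a long-format table with columns
    ``frame, mol_id, atom, x_A, y_A, z_A`` where ``atom`` is one of
    ``O``, ``H1``, ``H2``.  Hydrogens are optional.

    The occupancy segment is an axial interval (half-open, ``[lo, hi)``)
    along ``channel_axis``; by default a 1-nm (10 Å) window centred on
    the mean axial position of all oxygens.
    """

    atoms: pd.DataFrame
    frame_interval_ps: float = 10.0
    channel_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    segment: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        missing = [c for c in ATOM_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise ValueError(f"atoms table missing columns: {missing}")
        if self.frame_interval_ps <= 0:
            raise ValueError("frame_interval_ps must be positive")
        axis = np.asarray(self.channel_axis, dtype=float)
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise ValueError("channel_axis must be non-zero")
        self.channel_axis = axis / norm
        if self.segment is not None and self.segment[1] <= self.segment[0]:
            raise ValueError("segment must have positive length")

    @property
    def frame_ids(self) -> np.ndarray:
        return np.sort(self.atoms["frame"].unique())

    @property
    def n_frames(self) -> int:
        return len(self.frame_ids)

    @property
    def has_hydrogens(self) -> bool:
        return bool((self.atoms["atom"] != "O").any())

    def oxygens(self) -> pd.DataFrame:
        return self.atoms[self.atoms["atom"] == "O"]

    def frame(self, frame_id: int) -> pd.DataFrame:
        """All atom rows of one frame."""
        sub = self.atoms[self.atoms["frame"] == frame_id]
        if sub.empty:
            raise KeyError(f"no frame {frame_id}")
        return sub

    def default_segment(self) -> tuple[float, float]:
        """1-nm axial window centred on the oxygens' mean axial position."""
        if self.segment is not None:
            return self.segment
        ox = self.oxygens()
        axial = ox[["x_A", "y_A", "z_A"]].to_numpy() @ self.channel_axis
        center = float(axial.mean())
        return (center - 5.0, center + 5.0)


@dataclass(frozen=True)
class OccupancyStats:
    """Occupancy probability P(n_w) of the channel segment."""

    histogram: dict[int, float]
    counts: np.ndarray
    n_frames: int
    mode: int
    wetted_fraction: float
    episodes: list[tuple[str, int, int]]


@dataclass(frozen=True)
class WettingStats:
    """Run-length statistics of the filled/empty channel states."""

    episodes: list[tuple[str, int, int]]  # (state, start frame, frames)
    n_transitions: int
    mean_dwell_filled_s: float | None
    mean_dwell_empty_s: float | None
    wetting_rate_per_s: float | None  # 1 / mean empty dwell
    dewetting_rate_per_s: float | None  # 1 / mean filled dwell
    wetted_fraction: float


@dataclass(frozen=True)
class WaterChain:
    """A single-file (hydrogen-bonded) chain of waters.

    ``dipole_order`` is the mean cosine between the donated O→H bond and
    the local chain direction: +1 when every hydrogen bond points along
    the chain ordering, −1 when every bond points against it, and ``None``
    when no hydrogens are available.
    """

    mol_ids: tuple[int, ...]
    node_mol_id: int | None = None
    arm_id: int | None = None
    dipole_order: float | None = None

    def __len__(self) -> int:
        return len(self.mol_ids)


@dataclass(frozen=True)
class EnergyProfile:
    """Mean potential energy per axial position with labelled barriers."""

    positions: tuple[str, ...]
    mean_energy_kj_mol: np.ndarray
    equilibration_fraction: float
    barriers_kj_mol: dict[str, float]
    symmetric: bool


# ---------------------------------------------------------------------------
# occupancy


def _per_frame_counts(traj: HydrationTrajectory) -> np.ndarray:
    lo, hi = traj.default_segment()
    ox = traj.oxygens()
    axial = ox[["x_A", "y_A", "z_A"]].to_numpy() @ traj.channel_axis
    in_seg = (axial >= lo) & (axial < hi)
    counts = (
        pd.Series(in_seg, index=ox["frame"].to_numpy())
        .groupby(level=0)
        .sum()
        .reindex(traj.frame_ids, fill_value=0)
    )
    return counts.to_numpy(dtype=int)


def occupancy_histogram(traj: HydrationTrajectory) -> OccupancyStats:
    """Occupancy probability P(n_w) of the channel's middle segment.

    n_w is the number of water oxygens whose axial coordinate falls in
    the half-open segment ``[lo, hi)`` in each frame; the histogram is
    normalised over frames.  The mode ties break toward the smallest
    count, so an always-dry channel reports mode 0.
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    counts = _per_frame_counts(traj)
    values, freq = np.unique(counts, return_counts=True)
    hist = {int(v): float(f) / len(counts) for v, f in zip(values, freq)}
    max_p = max(hist.values())
    mode = min(v for v, p in hist.items() if p == max_p)
    if len(counts) >= 2:
        wet = wetting_transitions(counts, empty_threshold=0)
        episodes = wet.episodes
        wetted = wet.wetted_fraction
    else:
        state = "filled" if counts[0] > 0 else "empty"
        episodes = [(state, 0, 1)]
        wetted = float(counts[0] > 0)
    return OccupancyStats(
        histogram=hist,
        counts=counts,
        n_frames=len(counts),
        mode=mode,
        wetted_fraction=wetted,
        episodes=episodes,
    )


def wetting_transitions(
    occupancy: Sequence[int] | np.ndarray,
    empty_threshold: int = 0,
    frame_interval_s: float | None = None,
) -> WettingStats:
    """Wetting–dewetting episode statistics of an occupancy series.

    Frames with ``n_w <= empty_threshold`` count as the empty hydration
    state, all others as filled.  Episodes are maximal runs of one state.
    Dwell-time means exclude the first and last episodes (censored at the
    record boundaries); rates are the reciprocal mean dwells, so the
    wetting rate is the escape rate from the empty state.
    """
    series = np.asarray(occupancy, dtype=int)
    if series.ndim != 1 or len(series) < 2:
        raise ValueError("occupancy series must be 1-D with length >= 2")
    if empty_threshold < 0:
        raise ValueError("empty_threshold must be non-negative")

    filled = series > empty_threshold
    change = np.flatnonzero(np.diff(filled.astype(int))) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(series)]))
    episodes = [
        ("filled" if filled[s] else "empty", int(s), int(e - s))
        for s, e in zip(starts, ends)
    ]
    n_transitions = len(episodes) - 1

    interior = episodes[1:-1] if len(episodes) > 2 else []
    dwells = {"filled": [], "empty": []}
    for state, _, length in interior:
        dwells[state].append(length)

    def _mean_s(state: str) -> float | None:
        if frame_interval_s is None or not dwells[state]:
            return None
        return float(np.mean(dwells[state])) * frame_interval_s

    mean_f, mean_e = _mean_s("filled"), _mean_s("empty")
    return WettingStats(
        episodes=episodes,
        n_transitions=n_transitions,
        mean_dwell_filled_s=mean_f,
        mean_dwell_empty_s=mean_e,
        wetting_rate_per_s=(1.0 / mean_e) if mean_e else None,
        dewetting_rate_per_s=(1.0 / mean_f) if mean_f else None,
        wetted_fraction=float(filled.mean()),
    )


# ---------------------------------------------------------------------------
# chains


def _hbond_graph(
    opos: dict[int, np.ndarray],
    hpos: dict[int, list[np.ndarray]],
    oo_cutoff: float,
    angle_cutoff_deg: float | None,
) -> nx.Graph:
    graph = nx.Graph()
    graph.add_nodes_from(opos)
    ids = sorted(opos)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            d = float(np.linalg.norm(opos[a] - opos[b]))
            if d > oo_cutoff or d == 0.0:
                continue
            if angle_cutoff_deg is not None and (hpos.get(a) or hpos.get(b)):
                if not (
                    _donates(opos, hpos, a, b, angle_cutoff_deg)
                    or _donates(opos, hpos, b, a, angle_cutoff_deg)
                ):
                    continue
            graph.add_edge(a, b, distance=d)
    return graph


def _donates(
    opos: dict[int, np.ndarray],
    hpos: dict[int, list[np.ndarray]],
    donor: int,
    acceptor: int,
    angle_cutoff_deg: float,
) -> bool:
    """Donor O–H···acceptor-O angle criterion (angle at H)."""
    for h in hpos.get(donor, []):
        v1 = opos[donor] - h
        v2 = opos[acceptor] - h
        n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
        if n1 == 0 or n2 == 0:
            continue
        cos = float(np.dot(v1, v2) / (n1 * n2))
        angle = math.degrees(math.acos(np.clip(cos, -1.0, 1.0)))
        if angle >= angle_cutoff_deg:
            return True
    return False


def _bond_cosine(
    opos: dict[int, np.ndarray],
    hpos: dict[int, list[np.ndarray]],
    a: int,
    b: int,
) -> float | None:
    """Cosine of the donated O→H bond of pair (a, b) vs the a→b tangent."""
    tangent = opos[b] - opos[a]
    tangent = tangent / np.linalg.norm(tangent)
    best: float | None = None
    for donor, acceptor, sign in ((a, b, 1.0), (b, a, -1.0)):
        for h in hpos.get(donor, []):
            oh = h - opos[donor]
            oh = oh / np.linalg.norm(oh)
            toward = float(np.dot(oh, sign * tangent))
            if toward > 0.5:  # this H points at the acceptor: the donated bond
                cos = float(np.dot(oh, tangent))
                if best is None or abs(cos) > abs(best):
                    best = cos
    return best


def extract_chains(
    frame: pd.DataFrame,
    oo_cutoff: float = 3.5,
    angle_cutoff_deg: float | None = 140.0,
) -> list[WaterChain]:
    """Decompose one frame's hydrogen-bond network into single-file chains.

    Builds a water–water adjacency (O–O distance ≤ ``oo_cutoff`` Å and,
    when hydrogens are present, donor O–H···O angle ≥ ``angle_cutoff_deg``),
    then splits it into maximal simple paths.  Waters of degree ≥ 3 are
    branch nodes shared by every chain that meets there; each chain is
    reported with the node first.  When hydrogens are present the chain's
    dipolar order (mean cosine of donated O→H bonds against the chain
    direction) is computed; ±1 marks a perfectly ordered water wire.
    """
    if oo_cutoff <= 0:
        raise ValueError("oo_cutoff must be positive")
    ox = frame[frame["atom"] == "O"]
    if ox.empty:
        return []
    opos = {
        int(r.mol_id): np.array([r.x_A, r.y_A, r.z_A])
        for r in ox.itertuples()
    }
    hpos: dict[int, list[np.ndarray]] = {}
    for r in frame[frame["atom"] != "O"].itertuples():
        hpos.setdefault(int(r.mol_id), []).append(np.array([r.x_A, r.y_A, r.z_A]))
    if not hpos and angle_cutoff_deg is not None:
        warnings.warn(
            "no hydrogens in frame; falling back to distance-only H-bond criterion",
            stacklevel=2,
        )
        angle_cutoff_deg = None

    graph = _hbond_graph(opos, hpos, oo_cutoff, angle_cutoff_deg)
    junctions = {n for n in graph if graph.degree(n) >= 3}

    chains: list[list[int]] = []
    visited_edges: set[frozenset[int]] = set()

    def _walk(start: int, nxt: int) -> list[int]:
        path = [start, nxt]
        visited_edges.add(frozenset((start, nxt)))
        while nxt not in junctions:
            candidates = [
                m
                for m in graph.neighbors(nxt)
                if frozenset((nxt, m)) not in visited_edges
            ]
            if not candidates:
                break
            m = candidates[0]
            visited_edges.add(frozenset((nxt, m)))
            path.append(m)
            nxt = m
        return path

    for j in sorted(junctions):
        for nb in sorted(graph.neighbors(j)):
            if frozenset((j, nb)) in visited_edges:
                continue
            chains.append(_walk(j, nb))

    # components without junctions: plain paths
    leftover = graph.copy()
    leftover.remove_edges_from(tuple(e) for e in visited_edges)
    leftover.remove_nodes_from(list(nx.isolates(leftover)))
    for comp in nx.connected_components(leftover):
        sub = leftover.subgraph(comp)
        tips = [n for n in sub if sub.degree(n) == 1]
        if len(tips) == 2:
            chains.append(nx.shortest_path(sub, tips[0], tips[1]))
        else:  # cycle: open it at an arbitrary edge
            cycle = nx.find_cycle(sub)
            chains.append([e[0] for e in cycle] + [cycle[-1][1]])

    out: list[WaterChain] = []
    for path in chains:
        if len(path) < 2:
            continue
        node = path[0] if path[0] in junctions else None
        order = None
        if hpos:
            cosines = [
                c
                for a, b in zip(path, path[1:])
                if (c := _bond_cosine(opos, hpos, a, b)) is not None
            ]
            if cosines:
                order = float(np.mean(cosines))
        out.append(
            WaterChain(mol_ids=tuple(path), node_mol_id=node, dipole_order=order)
        )
    return out


# ---------------------------------------------------------------------------
# energy profiles


def energy_profile(
    per_position_series: Mapping[str, Iterable[float]],
    equilibration_fraction: float = 0.5,
    symmetry_atol: float = 1e-9,
) -> EnergyProfile:
    """Assemble an energy-barrier profile from per-position energy series.

    Each axial position's potential-energy series is averaged over its
    trailing window — the last ``ceil((1 − f)·n)`` samples, discarding the
    leading equilibration fraction ``f`` (default 0.5, i.e. the last half
    of each run).  Barriers are the energy differences between consecutive
    labelled positions, keyed ``"i-j"``; a mirror-symmetric mean profile
    sets ``symmetric``.
    """
    if not per_position_series:
        raise ValueError("no position series given")
    if not (0.0 <= equilibration_fraction < 1.0):
        raise ValueError("equilibration_fraction must be in [0, 1)")
    labels = tuple(per_position_series)
    means = []
    for lab in labels:
        series = np.asarray(list(per_position_series[lab]), dtype=float)
        if series.size == 0:
            raise ValueError(f"empty energy series at position {lab!r}")
        n_keep = math.ceil((1.0 - equilibration_fraction) * series.size)
        means.append(float(series[-n_keep:].mean()))
    profile = np.array(means)
    barriers = {
        f"{a}-{b}": float(profile[i + 1] - profile[i])
        for i, (a, b) in enumerate(zip(labels, labels[1:]))
    }
    symmetric = bool(np.allclose(profile, profile[::-1], atol=symmetry_atol))
    return EnergyProfile(
        positions=labels,
        mean_energy_kj_mol=profile,
        equilibration_fraction=equilibration_fraction,
        barriers_kj_mol=barriers,
        symmetric=symmetric,
    )
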