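"""Per-frame interface metrics for receptor-WIPI binding trajectories.

Three metrics quantify how a LIR peptide engages its binding site on a WIPI
beta-propeller, evaluated per trajectory frame:

``hbond_count``
    Number of backbone hydrogen bonds between two residue ranges (default
    peptide 35-39 on chain A vs propeller loop 129-134 on chain B).  A bond
    is a donor backbone amide N in one range and an acceptor backbone
    carbonyl O in the other (both directions) with N...O <= d_cut (3.5 A)
    and, when the amide hydrogen exists in the topology, an N-H...O angle
    >= theta_cut (150 deg); distance-only otherwise.

``insertion_depth``
    Minimum distance from any heavy atom of a probe residue (the LIR
    tryptophan, default A:36) to a single anchor atom (default the Calpha
    of B:119) — how deep the sidechain sits in its pocket.

``pocket_distance``
    Minimum distance between the sidechain heavy atoms of two pocket
    residues (default B:133 and B:169) — how far the pocket has opened.

Distances are Angstrom; no periodic-boundary handling (inputs are whole,
unwrapped molecules).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .trajectory import Trajectory, _derived_flags

DEFAULT_HBOND_DISTANCE_CUTOFF = 3.5  # N...O, Angstrom
DEFAULT_HBOND_ANGLE_CUTOFF = 150.0   # N-H...O, degrees

# backbone atoms excluded from "sidechain"; CB is sidechain
_NON_SIDECHAIN = {"N", "CA", "C", "O", "OXT"}


# ---------------------------------------------------------------------------
# Atom selection
# ---------------------------------------------------------------------------

def select_atoms(
    topology: pd.DataFrame,
    chain: str | None = None,
    residue_number: int | None = None,
    residue_range: tuple[int, int] | None = None,
    atom_names: set[str] | None = None,
    heavy_only: bool = False,
    sidechain_only: bool = False,
) -> np.ndarray:
    """Indices of atoms matching all given predicates, in topology order."""
    if "is_heavy" not in topology.columns or "is_backbone" not in topology.columns:
        topology = pd.concat([topology, _derived_flags(topology)], axis=1)
    mask = np.ones(len(topology), dtype=bool)
    if chain is not None:
        mask &= (topology["chain"] == chain).to_numpy()
    if residue_number is not None:
        mask &= (topology["residue_number"] == residue_number).to_numpy()
    if residue_range is not None:
        lo, hi = residue_range
        rn = topology["residue_number"].to_numpy()
        mask &= (rn >= lo) & (rn <= hi)
    if atom_names is not None:
        mask &= topology["atom_name"].isin(atom_names).to_numpy()
    if heavy_only:
        mask &= topology["is_heavy"].to_numpy()
    if sidechain_only:
        mask &= topology["is_heavy"].to_numpy()
        mask &= ~topology["atom_name"].isin(_NON_SIDECHAIN).to_numpy()
    return np.flatnonzero(mask)


# ---------------------------------------------------------------------------
# Frame-level metrics
# ---------------------------------------------------------------------------

def min_distance(
    coords: np.ndarray, selection_a: np.ndarray, selection_b: np.ndarray
) -> float:
    """Minimum Euclidean distance over all cross pairs of two atom selections.

    Symmetric in its arguments.  When the selections are identical sets with
    at least two atoms, the minimum runs over distinct pairs (self-pairs
    excluded).
    """
    a = np.asarray(selection_a, dtype=int)
    b = np.asarray(selection_b, dtype=int)
    if a.size == 0:
        raise ValueError("selection_a is empty")
    if b.size == 0:
        raise ValueError("selection_b is empty")
    d = cdist(coords[a], coords[b])
    same = a[:, None] == b[None, :]
    if same.all() and a.size < 2:
        raise ValueError("identical single-atom selections have no distinct pair")
    d[same] = np.inf
    return float(d.min())


def insertion_depth(
    coords: np.ndarray,
    topology: pd.DataFrame,
    probe: tuple[str, int] = ("A", 36),
    anchor: tuple[str, int, str] = ("B", 119, "CA"),
) -> float:
    """Min distance from any heavy atom of the probe residue to the anchor atom."""
    probe_idx = select_atoms(
        topology, chain=probe[0], residue_number=probe[1], heavy_only=True
    )
    if probe_idx.size == 0:
        raise ValueError(f"probe residue {probe[0]}:{probe[1]} has no heavy atoms")
    anchor_idx = select_atoms(
        topology, chain=anchor[0], residue_number=anchor[1], atom_names={anchor[2]}
    )
    if anchor_idx.size != 1:
        raise ValueError(
            f"anchor {anchor[0]}:{anchor[1]}:{anchor[2]} matches "
            f"{anchor_idx.size} atoms; need exactly 1"
        )
    return min_distance(coords, probe_idx, anchor_idx)


def pocket_distance(
    coords: np.ndarray,
    topology: pd.DataFrame,
    res_a: tuple[str, int] = ("B", 133),
    res_b: tuple[str, int] = ("B", 169),
) -> float:
    """Min distance between the sidechain heavy atoms of two residues."""
    sels = []
    for chain, resnum in (res_a, res_b):
        idx = select_atoms(
            topology, chain=chain, residue_number=resnum, sidechain_only=True
        )
        if idx.size == 0:
            raise ValueError(
                f"residue {chain}:{resnum} has no sidechain heavy atoms"
            )
        sels.append(idx)
    return min_distance(coords, sels[0], sels[1])


def _angle_deg(center: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    v1 = p1 - center
    v2 = p2 - center
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def count_backbone_hbonds(
    coords: np.ndarray,
    topology: pd.DataFrame,
    range_a: tuple[str, int, int] = ("A", 35, 39),
    range_b: tuple[str, int, int] = ("B", 129, 134),
    d_cut: float = DEFAULT_HBOND_DISTANCE_CUTOFF,
    theta_cut: float = DEFAULT_HBOND_ANGLE_CUTOFF,
) -> int:
    """Count backbone N-H...O=C hydrogen bonds between two residue ranges.

    Donors are backbone amide nitrogens of one range, acceptors backbone
    carbonyl oxygens of the other, in both directions; each (N, O) pair is
    counted at most once.  Criterion: dist(N, O) <= d_cut, and when the amide
    hydrogen (atom H or HN of the donor residue) exists in the topology, the
    N-H...O angle must be >= theta_cut.
    """
    for name, rng in (("range_a", range_a), ("range_b", range_b)):
        if select_atoms(topology, chain=rng[0], residue_range=rng[1:]).size == 0:
            raise ValueError(f"{name} {rng} selects no atoms")

    def backbone(range_spec: tuple[str, int, int], atom: str) -> np.ndarray:
        return select_atoms(
            topology, chain=range_spec[0], residue_range=range_spec[1:],
            atom_names={atom},
        )

    def amide_h(donor_row) -> int | None:
        idx = select_atoms(
            topology, chain=donor_row.chain, residue_number=donor_row.residue_number,
            atom_names={"H", "HN"},
        )
        return int(idx[0]) if idx.size else None

    count = 0
    for donors_rng, acceptors_rng in ((range_a, range_b), (range_b, range_a)):
        donor_n = backbone(donors_rng, "N")
        acceptor_o = backbone(acceptors_rng, "O")
        if donor_n.size == 0 or acceptor_o.size == 0:
            continue
        dmat = cdist(coords[donor_n], coords[acceptor_o])
        for di, dn in enumerate(donor_n):
            h = amide_h(topology.iloc[dn])
            for ai, ao in enumerate(acceptor_o):
                if dmat[di, ai] > d_cut:
                    continue
                if h is not None:
                    theta = _angle_deg(coords[h], coords[dn], coords[ao])
                    if theta < theta_cut:
                        continue
                count += 1
    return count


# ---------------------------------------------------------------------------
# Per-trajectory series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricSpec:
    """Which metric to evaluate and on which selections."""

    metric: str  # hbond_count | insertion_depth | pocket_distance
    params: dict = field(default_factory=dict)

    @classmethod
    def hbond(cls, range_a=("A", 35, 39), range_b=("B", 129, 134),
              d_cut=DEFAULT_HBOND_DISTANCE_CUTOFF,
              theta_cut=DEFAULT_HBOND_ANGLE_CUTOFF) -> "MetricSpec":
        return cls("hbond_count", dict(range_a=tuple(range_a), range_b=tuple(range_b),
                                       d_cut=d_cut, theta_cut=theta_cut))

    @classmethod
    def insertion(cls, probe=("A", 36), anchor=("B", 119, "CA")) -> "MetricSpec":
        return cls("insertion_depth", dict(probe=tuple(probe), anchor=tuple(anchor)))

    @classmethod
    def pocket(cls, res_a=("B", 133), res_b=("B", 169)) -> "MetricSpec":
        return cls("pocket_distance", dict(res_a=tuple(res_a), res_b=tuple(res_b)))

    def evaluate(self, coords: np.ndarray, topology: pd.DataFrame) -> float:
        if self.metric == "hbond_count":
            return float(count_backbone_hbonds(coords, topology, **self.params))
        if self.metric == "insertion_depth":
            return insertion_depth(coords, topology, **self.params)
        if self.metric == "pocket_distance":
            return pocket_distance(coords, topology, **self.params)
        raise ValueError(f"unknown metric {self.metric!r}")


def default_metric_specs() -> list[MetricSpec]:
    """The three canonical interface metrics with their default selections."""
    return [MetricSpec.hbond(), MetricSpec.insertion(), MetricSpec.pocket()]


@dataclass
class MetricSeries:
    """Values of one metric across sampled frames (times in ns)."""

    spec: MetricSpec
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must align")
        if self.spec.metric != "hbond_count" and np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.times, "value": self.values})

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def metric_series(
    traj: Trajectory, spec: MetricSpec, stride_ns: float = 1.0
) -> MetricSeries:
    """Evaluate a metric at the frames nearest each multiple of ``stride_ns``.

    Nearest-frame sampling, no interpolation: the metrics are nonlinear in
    the coordinates.  A stride finer than the native frame spacing triggers
    a warning and every frame is used.
    """
    times = traj.frame_times
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    native = float(np.min(np.diff(times))) if traj.n_frames > 1 else stride_ns
    if stride_ns < native - 1e-12:
        warnings.warn(
            f"stride {stride_ns} ns finer than native spacing {native} ns; "
            "using every frame",
            stacklevel=2,
        )
        frame_idx = np.arange(traj.n_frames)
    else:
        targets = np.arange(times[0], times[-1] + stride_ns / 2, stride_ns)
        frame_idx = np.unique(np.abs(times[None, :] - targets[:, None]).argmin(axis=1))
    values = [spec.evaluate(traj.frames[i], traj.topology) for i in frame_idx]
    return MetricSeries(spec=spec, times=times[frame_idx], values=np.asarray(values))
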