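"""Ground-truthed synthetic inputs for every pipeline stage.

Two generators:

* :func:`generate_lfq_dataset` emulates a bait-vs-control pull-down LFQ
  matrix: per-protein log2 baselines, per-sample systematic shifts (the
  normalization factors to recover), replicate noise, a set of spiked
  bait-specific interactors, intensity-dependent (logistic, MNAR)
  missingness, and injected contaminant / single-peptide rows.  The full
  ground truth (true factors, spiked ids, complete pre-mask matrix) is
  returned alongside the table.

* :func:`generate_toy_trajectory` builds a minimal LIR-peptide/propeller-stub
  system whose interface metrics are known by construction: bound frames
  hold three backbone hydrogen bonds inside the default criterion, the
  tryptophan-like probe within 4 A of its anchor, and the pocket residues
  beyond 6 A; unbound frames rigidly displace the peptide.  Gaussian
  coordinate jitter is added on top, with all constructed margins at least
  six jitter standard deviations away from every criterion boundary, so the
  expected h-bond counts are exact and expected distances hold within a
  6*jitter_sd band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .md_metrics import MetricSeries, MetricSpec
from .quant_io import ProteinQuantTable, SampleDesign
from .trajectory import Trajectory


# ---------------------------------------------------------------------------
# LFQ pull-down matrices
# ---------------------------------------------------------------------------

@dataclass
class LfqSimConfig:
    """Study conditions for the synthetic pull-down LFQ matrix.

    The first entry of ``groups`` is the tag-only control; spiked interactors
    are elevated in every other (bait) group.  All log2 units.
    """

    n_proteins: int = 2000
    groups: tuple[tuple[str, int], ...] = (("GST", 3), ("bait", 3))
    baseline_mean: float = 26.0
    baseline_sd: float = 2.5
    replicate_noise_sd: float = 0.25
    factor_range: float = 1.5          # true shifts drawn uniform in +/- this
    n_spiked: int = 20
    spike_log2fc: float = 2.0
    mnar_midpoint: float = 22.0
    mnar_steepness: float = 1.0
    contaminant_frac: float = 0.02
    single_peptide_frac: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name in ("contaminant_frac", "single_peptide_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("baseline_sd", "replicate_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for label, n in self.groups:
            if n < 2:
                raise ValueError(f"group {label!r} has {n} replicate(s); need >= 2")


@dataclass
class LfqGroundTruth:
    """What the generator knows: true factors, spiked proteins, complete matrix."""

    true_factors: pd.Series
    spiked_ids: set[str]
    true_matrix: pd.DataFrame

    def __post_init__(self) -> None:
        if abs(float(self.true_factors.sum())) > 1e-9 * max(1, len(self.true_factors)):
            raise ValueError("true factors must sum to zero")
        if not self.spiked_ids <= set(self.true_matrix.index):
            raise ValueError("spiked_ids must be a subset of protein ids")


def generate_lfq_dataset(
    config: LfqSimConfig | None = None,
) -> tuple[ProteinQuantTable, SampleDesign, LfqGroundTruth]:
    """Simulate a pull-down LFQ table with known ground truth.

    Cell model (log2): value = baseline_p + factor_s + spike + noise, with
    spike = ``spike_log2fc`` only for spiked proteins in bait-group samples.
    A cell goes missing with probability 1 / (1 + exp(steepness * (x - midpoint)))
    — low-intensity cells drop out preferentially (MNAR).  Contaminant and
    single-peptide rows are drawn from within ``n_proteins`` so that the
    quantifiability filter retains n_proteins * (1 - contaminant_frac -
    single_peptide_frac) rows.
    """
    config = config or LfqSimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    sample_ids, group_of = [], {}
    for label, n_rep in config.groups:
        for r in range(1, n_rep + 1):
            sid = f"{label}_{r}"
            sample_ids.append(sid)
            group_of[sid] = (label, r)
    n_samples = len(sample_ids)
    control_label = config.groups[0][0]
    bait_cols = np.array(
        [group_of[s][0] != control_label for s in sample_ids], dtype=bool
    )

    n = config.n_proteins
    n_contam = int(round(config.contaminant_frac * n))
    n_single = int(round(config.single_peptide_frac * n))
    n_quant = n - n_contam - n_single
    if n_quant < config.n_spiked:
        raise ValueError("not enough quantifiable proteins to place spikes")

    # Row layout: quantifiable proteins first, then single-peptide, then
    # contaminants; rows are shuffled at the end.
    protein_ids = np.array(
        [f"P{i:05d}" for i in range(n_quant + n_single)]
        + [f"contam_{i:03d}" for i in range(n_contam)]
    )
    genes = np.array([f"GENE{i}" for i in range(n)])
    peptide_counts = np.concatenate(
        [
            rng.integers(2, 31, size=n_quant),
            np.ones(n_single, dtype=int),
            rng.integers(2, 31, size=n_contam),
        ]
    )
    is_contam = np.zeros(n, dtype=bool)
    is_contam[n_quant + n_single:] = True

    spike_rows = rng.choice(n_quant, size=config.n_spiked, replace=False)
    spiked_ids = set(protein_ids[spike_rows])

    factors = rng.uniform(-config.factor_range, config.factor_range, size=n_samples)
    factors = factors - factors.mean()  # zero-sum gauge

    baselines = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    x = baselines[:, None] + factors[None, :]
    spike = np.zeros((n, n_samples))
    spike[np.ix_(spike_rows, np.flatnonzero(bait_cols))] = config.spike_log2fc
    x = x + spike + rng.normal(0.0, config.replicate_noise_sd, size=(n, n_samples))

    p_missing = expit(-config.mnar_steepness * (x - config.mnar_midpoint))
    mask_missing = rng.random(size=x.shape) < p_missing

    order = rng.permutation(n)
    protein_ids, genes = protein_ids[order], genes[order]
    peptide_counts, is_contam = peptide_counts[order], is_contam[order]
    x, mask_missing = x[order], mask_missing[order]

    linear = np.power(2.0, x)
    linear[mask_missing] = np.nan

    idx = pd.Index(protein_ids, name="protein_id")
    table = ProteinQuantTable(
        meta=pd.DataFrame(
            {"gene": genes, "peptide_count": peptide_counts, "is_contaminant": is_contam},
            index=idx,
        ),
        intensities=pd.DataFrame(linear, index=idx, columns=sample_ids),
    )
    design = SampleDesign(assignments=group_of)
    truth = LfqGroundTruth(
        true_factors=pd.Series(factors, index=sample_ids, name="true_factor"),
        spiked_ids=spiked_ids,
        true_matrix=pd.DataFrame(x, index=idx, columns=sample_ids),
    )
    return table, design, truth


# ---------------------------------------------------------------------------
# Toy bound -> unbound trajectory
# ---------------------------------------------------------------------------

@dataclass
class TrajSimConfig:
    """Study conditions for the toy binding trajectory.

    Frames with index < ``switch_frame`` are bound, the rest are unbound
    (the peptide rigidly displaced by ``displacement`` Angstrom).
    """

    n_frames: int = 20
    frame_dt_ns: float = 1.0
    switch_frame: int = 10
    jitter_sd: float = 0.05
    displacement: float = 15.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.switch_frame <= self.n_frames:
            raise ValueError("switch_frame must be in [0, n_frames]")
        if self.jitter_sd < 0 or self.displacement < 0:
            raise ValueError("jitter_sd and displacement must be >= 0")
        if self.n_frames < 1 or self.frame_dt_ns <= 0:
            raise ValueError("need n_frames >= 1 and frame_dt_ns > 0")


# Constructed geometry (Angstrom).  Chain A: 5-residue LIR peptide, residues
# 35-39, Trp-like residue 36 with a 10-heavy-atom sidechain.  Chain B:
# propeller stub — backbone residues 129-134 (Ile sidechain on 133), anchor
# residue 119 and Phe-like pocket residue 169.  Bound state: A35/A37/A39
# amide N sit 2.9 A above the carbonyl O of B130/B132/B134 with colinear
# N-H...O (three h-bonds); A36/A38 are lifted 2 A so no further pair comes
# within 4.9 A of the 3.5 A cutoff.
def _chain_b_backbone(resnum: int, resname: str, x: float) -> list[tuple]:
    return [
        ("B", resnum, resname, "N", "N", (x - 1.5, 0.0, 0.0)),
        ("B", resnum, resname, "H", "H", (x - 1.5, 0.0, -1.0)),
        ("B", resnum, resname, "CA", "C", (x - 0.8, 0.9, 0.0)),
        ("B", resnum, resname, "C", "C", (x, 0.0, 0.0)),
        ("B", resnum, resname, "O", "O", (x, 0.0, 1.0)),
    ]


def _chain_a_residue(resnum: int, resname: str, x: float, lift: float) -> list[tuple]:
    z = 3.9 + lift
    return [
        ("A", resnum, resname, "N", "N", (x, 0.0, z)),
        ("A", resnum, resname, "H", "H", (x, 0.0, z - 1.0)),
        ("A", resnum, resname, "CA", "C", (x + 0.9, 0.9, z + 0.4)),
        ("A", resnum, resname, "C", "C", (x + 1.8, 0.0, z)),
        ("A", resnum, resname, "O", "O", (x + 1.8, 0.0, z + 1.2)),
    ]


_TRP_SIDECHAIN = [  # attached to A36 (CA at (10.9, 0.9, 6.3)), reaching the anchor
    ("CB", "C", (10.6, -0.4, 5.6)),
    ("CG", "C", (10.4, -1.4, 4.8)),
    ("CD1", "C", (11.0, -2.0, 4.2)),
    ("CD2", "C", (9.6, -1.9, 4.4)),
    ("NE1", "N", (10.8, -3.0, 3.5)),
    ("CE2", "C", (9.9, -3.0, 3.6)),
    ("CE3", "C", (8.6, -2.0, 4.2)),
    ("CZ2", "C", (9.7, -4.0, 2.9)),
    ("CZ3", "C", (8.3, -3.0, 3.4)),
    ("CH2", "C", (9.0, -4.0, 2.8)),
]

_ILE_SIDECHAIN = [  # on B133 (CA at (19.2, 0.9, 0.0))
    ("CB", "C", (19.2, 0.9, -1.5)),
    ("CG1", "C", (19.2, 2.2, -2.0)),
    ("CG2", "C", (18.0, 0.3, -2.1)),
    ("CD1", "C", (19.2, 3.3, -1.2)),
]

_PHE_RESIDUE = [  # B169, pocket partner, >= 6 A from the Ile sidechain
    ("N", "N", (17.6, 13.4, 0.9)),
    ("CA", "C", (19.0, 13.8, 0.8)),
    ("C", "C", (20.0, 14.4, 0.0)),
    ("O", "O", (20.0, 14.4, 1.2)),
    ("CB", "C", (19.0, 12.4, 0.6)),
    ("CG", "C", (19.0, 11.7, 0.0)),
    ("CD1", "C", (18.3, 11.1, 0.0)),
    ("CD2", "C", (19.7, 11.1, 0.0)),
    ("CE1", "C", (18.3, 10.3, 0.0)),
    ("CE2", "C", (19.7, 10.3, 0.0)),
    ("CZ", "C", (19.0, 9.9, 0.0)),
]

_ANCHOR_RESIDUE = [  # B119, Calpha anchor below the Trp sidechain
    ("N", "N", (8.8, -7.6, 1.0)),
    ("CA", "C", (10.0, -6.9, 1.2)),
    ("C", "C", (11.2, -7.6, 1.0)),
    ("O", "O", (11.2, -7.6, 2.2)),
]

_A_RESNAMES = {35: "SER", 36: "TRP", 37: "VAL", 38: "GLU", 39: "LEU"}
_N_HBONDS_BOUND = 3


def _build_clean_system() -> tuple[pd.DataFrame, np.ndarray]:
    atoms: list[tuple] = []
    # peptide: bonded residues 35/37/39 over B130/B132/B134 (x = 5, 15, 25),
    # non-bonded 36/38 lifted at the midpoints
    for resnum, x, lift in ((35, 5.0, 0.0), (36, 10.0, 2.0), (37, 15.0, 0.0),
                            (38, 20.0, 2.0), (39, 25.0, 0.0)):
        atoms.extend(_chain_a_residue(resnum, _A_RESNAMES[resnum], x, lift))
        if resnum == 36:
            atoms.extend(
                ("A", 36, "TRP", name, elem, xyz) for name, elem, xyz in _TRP_SIDECHAIN
            )
    for name, elem, xyz in _ANCHOR_RESIDUE:
        atoms.append(("B", 119, "LEU", name, elem, xyz))
    for resnum in range(129, 135):
        resname = "ILE" if resnum == 133 else "GLY"
        atoms.extend(_chain_b_backbone(resnum, resname, x=5.0 * (resnum - 129)))
        if resnum == 133:
            atoms.extend(
                ("B", 133, "ILE", name, elem, xyz) for name, elem, xyz in _ILE_SIDECHAIN
            )
    atoms.extend(("B", 169, "PHE", name, elem, xyz) for name, elem, xyz in _PHE_RESIDUE)

    topology = pd.DataFrame(
        [a[:5] for a in atoms],
        columns=["chain", "residue_number", "residue_name", "atom_name", "element"],
    )
    coords = np.array([a[5] for a in atoms], dtype=float)
    return topology, coords


def _clean_min_distance(pa: np.ndarray, pb: np.ndarray) -> float:
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    return float(d.min())


def generate_toy_trajectory(
    config: TrajSimConfig | None = None,
) -> tuple[Trajectory, dict[str, MetricSeries]]:
    """Build the toy bound->unbound trajectory and its expected metric series.

    Returns the jittered trajectory plus a map metric name -> MetricSeries of
    expected values computed from the jitter-free construction: h-bond counts
    are exact (3 bound, 0 unbound); expected distances are the clean-geometry
    minima, to be compared within a 6 * jitter_sd band.
    """
    config = config or TrajSimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    topology, clean = _build_clean_system()
    chain_a = (topology["chain"] == "A").to_numpy()
    shift = np.zeros_like(clean)
    shift[chain_a, 2] = config.displacement  # rigid displacement along +z

    heavy = (topology["element"] != "H").to_numpy()
    probe = chain_a & (topology["residue_number"] == 36).to_numpy() & heavy
    anchor = (
        (topology["chain"] == "B")
        & (topology["residue_number"] == 119)
        & (topology["atom_name"] == "CA")
    ).to_numpy()
    sidechain = heavy & ~topology["atom_name"].isin(["N", "CA", "C", "O", "OXT"]).to_numpy()
    ile = (topology["chain"] == "B").to_numpy() & (topology["residue_number"] == 133).to_numpy() & sidechain
    phe = (topology["chain"] == "B").to_numpy() & (topology["residue_number"] == 169).to_numpy() & sidechain

    bound_insertion = _clean_min_distance(clean[probe], clean[anchor])
    unbound_insertion = _clean_min_distance((clean + shift)[probe], clean[anchor])
    pocket = _clean_min_distance(clean[ile], clean[phe])

    frames, exp_hbond, exp_insertion, exp_pocket = [], [], [], []
    for f in range(config.n_frames):
        bound = f < config.switch_frame
        base = clean if bound else clean + shift
        frames.append(base + rng.normal(0.0, config.jitter_sd, size=base.shape))
        exp_hbond.append(_N_HBONDS_BOUND if bound else 0)
        exp_insertion.append(bound_insertion if bound else unbound_insertion)
        exp_pocket.append(pocket)

    times = np.arange(config.n_frames, dtype=float) * config.frame_dt_ns
    traj = Trajectory(topology=topology, frames=np.stack(frames), frame_times=times)
    expected = {
        "hbond_count": MetricSeries(MetricSpec.hbond(), times, np.array(exp_hbond, float)),
        "insertion_depth": MetricSeries(MetricSpec.insertion(), times, np.array(exp_insertion)),
        "pocket_distance": MetricSeries(MetricSpec.pocket(), times, np.array(exp_pocket)),
    }
    return traj, expected
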