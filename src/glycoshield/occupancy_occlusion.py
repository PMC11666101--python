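"""Occupancy grids and glycan-occlusion scoring of annotated regions.

A conformer ensemble is converted into (i) a voxel occupancy grid - per
voxel, the fraction of frames with at least one glycan heavy atom inside
- and (ii) per-region occlusion reports: for a set of region residues
(a VSD surface, the pore mouth, or a beta-subunit interface footprint),
the fraction of residues that are glycan-contacted in at least a
threshold fraction of frames, and a blocked / partial / accessible
verdict.

Default parameters (pinned in :mod:`glycoshield.config` and echoed into
every report): glycan-to-residue contact cutoff 4.5 A, interface cutoff
5.0 A, voxel 1.0 A, frame-fraction threshold 0.5, verdict thresholds
blocked >= 0.8 coverage / accessible <= 0.2.  The source text gives only
visual verdicts; the 0.8/0.2 boundaries are artifact decisions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
import biotite.structure as struc

from glycoshield.graft_sample import ConformerEnsemble

CONTACT_CUTOFF = 4.5  # glycan heavy atom to residue heavy atom, Angstrom
INTERFACE_CUTOFF = 5.0
VOXEL_SIZE = 1.0
FRAME_FRACTION = 0.5
BLOCKED_THRESHOLD = 0.8
ACCESSIBLE_THRESHOLD = 0.2


class InterfaceWarning(UserWarning):
    pass


@dataclass
class OccupancyGrid:
    """Voxelization of glycan space: per-voxel fraction of occupied frames."""

    origin: np.ndarray
    voxel_size: float
    occupancy: np.ndarray  # 3-D array of fractions in [0, 1]

    @property
    def dimensions(self) -> tuple[int, int, int]:
        return self.occupancy.shape

    def occupied_voxels(self, min_fraction: float = 0.0) -> int:
        return int((self.occupancy > min_fraction).sum())

    def voxel_of(self, point: np.ndarray) -> tuple[int, int, int]:
        idx = np.floor((np.asarray(point) - self.origin) / self.voxel_size).astype(int)
        return tuple(idx)

    def save_npy(self, path) -> None:
        np.save(path, self.occupancy)


def build_grid(ensemble: ConformerEnsemble, voxel_size: float = VOXEL_SIZE) -> OccupancyGrid:
    """Per-voxel fraction of frames with >= 1 glycan heavy atom inside.

    Grid bounds enclose every frame; adding frames can only grow the set
    of ever-occupied voxels.
    """
    if voxel_size <= 0:
        raise ValueError("voxel size must be positive")
    if ensemble.n_frames == 0:
        raise ValueError("ensemble is empty")
    allc = ensemble.all_coords()
    origin = np.floor(allc.min(axis=0) / voxel_size) * voxel_size
    dims = np.floor((allc.max(axis=0) - origin) / voxel_size).astype(int) + 1
    counts = np.zeros(tuple(dims), dtype=np.int32)
    for f in range(ensemble.n_frames):
        xyz = ensemble.frame_coords(f)
        idx = np.floor((xyz - origin) / voxel_size).astype(int)
        uniq = np.unique(idx, axis=0)
        counts[uniq[:, 0], uniq[:, 1], uniq[:, 2]] += 1
    return OccupancyGrid(
        origin=origin, voxel_size=voxel_size, occupancy=counts / ensemble.n_frames
    )


@dataclass
class InterfaceFootprint:
    """Alpha-subunit residues contacted by a partner chain."""

    residues: tuple[int, ...]
    partner: str
    source: str
    cutoff: float
    warning: str | None = None


def extract_interface(
    structure: struc.AtomArray,
    alpha_chain: str,
    partner_chain: str,
    cutoff: float = INTERFACE_CUTOFF,
    partner_label: str | None = None,
    source: str = "",
) -> InterfaceFootprint:
    """Alpha residues with any heavy atom within ``cutoff`` of the partner."""
    a_mask = structure.chain_id == alpha_chain
    b_mask = structure.chain_id == partner_chain
    for chain, mask in ((alpha_chain, a_mask), (partner_chain, b_mask)):
        if not mask.any():
            raise ValueError(f"chain {chain!r} not found")
    tree = cKDTree(structure.coord[b_mask].astype(float))
    d, _ = tree.query(structure.coord[a_mask].astype(float), k=1)
    res = structure.res_id[a_mask]
    residues = tuple(sorted(set(res[d <= cutoff].tolist())))
    warning = None
    if not residues:
        warning = f"empty footprint: chains {alpha_chain}/{partner_chain} beyond {cutoff} A"
        warnings.warn(warning, InterfaceWarning)
    return InterfaceFootprint(
        residues=residues,
        partner=partner_label or partner_chain,
        source=source,
        cutoff=cutoff,
        warning=warning,
    )


@dataclass
class OcclusionEntry:
    """Glycan coverage of one region over an ensemble."""

    region: str
    coverage: float  # fraction of region residues contacted in >= frame_fraction of frames
    mean_contact_fraction: float  # mean over frames of the contacted-residue fraction
    verdict: str  # "blocked" | "partial" | "accessible"
    n_residues: int
    contact_cutoff: float
    frame_fraction: float
    per_residue_frequency: dict[int, float] = field(default_factory=dict, repr=False)


def verdict_for(
    coverage: float,
    blocked_threshold: float = BLOCKED_THRESHOLD,
    accessible_threshold: float = ACCESSIBLE_THRESHOLD,
) -> str:
    """Deterministic verdict: blocked at >= the upper threshold, accessible
    at <= the lower, else partial (both boundaries resolve away from partial)."""
    if coverage >= blocked_threshold:
        return "blocked"
    if coverage <= accessible_threshold:
        return "accessible"
    return "partial"


def occlusion_score(
    ensemble: ConformerEnsemble,
    region_residues,
    region_name: str = "region",
    contact_cutoff: float = CONTACT_CUTOFF,
    frame_fraction: float = FRAME_FRACTION,
    blocked_threshold: float = BLOCKED_THRESHOLD,
    accessible_threshold: float = ACCESSIBLE_THRESHOLD,
) -> OcclusionEntry:
    """Coverage of a residue set by glycan density over the ensemble.

    A residue is contacted in a frame when any of its heavy atoms lies
    within ``contact_cutoff`` of any glycan heavy atom.  An empty
    ensemble yields coverage 0 (verdict accessible).
    """
    region_residues = tuple(sorted(set(int(r) for r in region_residues)))
    if not region_residues:
        raise ValueError("region is empty")
    structure = ensemble.structure
    masks = {r: structure.res_id == r for r in region_residues}
    hits = {r: 0 for r in region_residues}
    per_frame_fraction = []
    for f in range(ensemble.n_frames):
        tree = cKDTree(ensemble.frame_coords(f))
        contacted = 0
        for r in region_residues:
            d, _ = tree.query(structure.coord[masks[r]].astype(float), k=1)
            if (d <= contact_cutoff).any():
                hits[r] += 1
                contacted += 1
        per_frame_fraction.append(contacted / len(region_residues))
    n_frames = max(ensemble.n_frames, 1)
    freq = {r: hits[r] / n_frames for r in region_residues}
    coverage = sum(v >= frame_fraction for v in freq.values()) / len(region_residues)
    if ensemble.n_frames == 0:
        coverage = 0.0
    return OcclusionEntry(
        region=region_name,
        coverage=coverage,
        mean_contact_fraction=float(np.mean(per_frame_fraction)) if per_frame_fraction else 0.0,
        verdict=verdict_for(coverage, blocked_threshold, accessible_threshold),
        n_residues=len(region_residues),
        contact_cutoff=contact_cutoff,
        frame_fraction=frame_fraction,
        per_residue_frequency=freq,
    )


def pore_block_check(
    ensemble: ConformerEnsemble,
    axis_point: np.ndarray,
    axis_dir: np.ndarray,
    radius: float = 6.0,
    length: float = 30.0,
) -> float:
    """Fraction of frames with any glycan heavy atom inside the pore cylinder.

    The cylinder starts at ``axis_point`` (the extracellular pore mouth)
    and extends ``length`` Angstrom along ``axis_dir`` away from the
    membrane - the putative ion conductance path above the channel.
    """
    axis_dir = np.asarray(axis_dir, dtype=float)
    nrm = np.linalg.norm(axis_dir)
    if nrm < 1e-9 or radius <= 0 or length <= 0:
        raise ValueError("degenerate pore axis")
    axis_dir = axis_dir / nrm
    blocked = 0
    for f in range(ensemble.n_frames):
        rel = ensemble.frame_coords(f) - np.asarray(axis_point, dtype=float)
        t = rel @ axis_dir
        radial = np.linalg.norm(rel - np.outer(t, axis_dir), axis=1)
        if bool(((t >= 0) & (t <= length) & (radial <= radius)).any()):
            blocked += 1
    return blocked / max(ensemble.n_frames, 1)


def binding_verdict(
    reports: dict[str, OcclusionEntry],
    blocked_threshold: float = BLOCKED_THRESHOLD,
    accessible_threshold: float = ACCESSIBLE_THRESHOLD,
) -> dict[str, str]:
    """Per-partner verdicts from matched occlusion reports (beta1/beta2/beta4)."""
    return {
        partner: verdict_for(entry.coverage, blocked_threshold, accessible_threshold)
        for partner, entry in reports.items()
    }


def occlusion_report_rows(reports: dict[str, OcclusionEntry]) -> list[dict]:
    return [
        {
            "region": e.region,
            "partner": partner,
            "n_residues": e.n_residues,
            "coverage": round(e.coverage, 4),
            "mean_contact_fraction": round(e.mean_contact_fraction, 4),
            "verdict": e.verdict,
            "contact_cutoff_A": e.contact_cutoff,
            "frame_fraction": e.frame_fraction,
        }
        for partner, e in reports.items()
    ]
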