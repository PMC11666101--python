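"""Synthetic fixtures for every pipeline stage.

All generators are deterministic under a fixed seed and emit
machine-readable ground truth alongside the data, so tests never need
external downloads.  Four families of fixtures are produced:

- **sequence families** with sequons planted at controlled conservation
  levels (conserved-in-all / shared-by-subset / isoform-unique columns);
  the default :func:`nav_family_params` reproduces the documented site
  architecture of the nine human Na_V isoforms in Na_V1.5 coordinates,
- **toy channels**: idealized transmembrane helical bundles whose
  extracellular loops carry Asn-X-Thr glycosites above a membrane slab,
- **toy alpha/partner complexes** with a constructed interface footprint,
- **toy Ig domains**: CA-only beta-sandwiches at beta1-Ig scale for the
  trans-dimer bridge geometry.

Toy structures use poly-alanine backbones with explicit Asn side chains
only at glycosites, keeping emitted files tiny.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import biotite.structure as struc

from glycoshield.seq_sites import (
    IsoformSequence,
    RegionAnnotation,
    Sequon,
    scan_sequons,
)
from glycoshield.variant_glyco import VariantRecord, read_variants_csv

AA_BACKGROUND = "ACDEFGHIKLMNQRSVWY"  # drawing pool for family backgrounds

NAV_ISOFORMS = [f"NaV1.{i}" for i in range(1, 10)]


# ---------------------------------------------------------------------------
# sequence families


@dataclass(frozen=True)
class PlantedColumn:
    """One sequon column planted into a family.

    ``members`` lists isoforms that carry the motif; everyone else has it
    destroyed (N replaced).  ``resolved_members`` marks which carriers
    count as structurally resolved sites.
    """

    column: int  # 1-based position of the planted Asn
    members: tuple[str, ...]
    resolved_members: tuple[str, ...] = ()
    region: str | None = None


@dataclass
class FamilyParams:
    member_ids: list[str]
    length: int
    planted: list[PlantedColumn]
    substitution_rate: float = 0.3
    conserved_flank: int = 5  # residues either side of a planted motif kept identical
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution_rate must be in [0, 1]")
        cols = sorted(p.column for p in self.planted)
        for c in cols:
            if not 1 <= c <= self.length - 2:
                raise ValueError(f"planted column {c} outside 1..{self.length - 2}")
        for a, b in zip(cols, cols[1:]):
            if b - a < 3:
                raise ValueError(f"planted columns {a} and {b} collide (need >=3 apart)")
        unknown = {m for p in self.planted for m in p.members} - set(self.member_ids)
        if unknown:
            raise ValueError(f"planted members {sorted(unknown)} not in family")


def nav_family_params(seed: int = 0) -> FamilyParams:
    """Default nine-isoform family reproducing the documented Na_V site layout.

    Planted columns use Na_V1.5 residue numbering: three conserved-in-all
    sites (291, 1365, 1380), one site shared by all but NaV1.7/NaV1.9
    (328), one shared by NaV1.5/1.7/1.8 (1388), four NaV1.5-unique sites
    on domains I and III (283, 288, 318, 1374), two NaV1.6-unique and one
    NaV1.7-unique site on domain I, the NaV1.8-unique domain II site
    (819), and five extra unresolved NaV1.4 sequons that bring its
    ECTL I motif count to seven.
    """
    all9 = tuple(NAV_ISOFORMS)
    resolved8 = tuple(i for i in all9 if i != "NaV1.9")  # no NaV1.9 structure
    planted = [
        PlantedColumn(291, all9, resolved8, "ECTL_I"),
        PlantedColumn(1365, all9, resolved8, "ECTL_III"),
        PlantedColumn(1380, all9, resolved8, "ECTL_III"),
        PlantedColumn(
            328,
            tuple(i for i in all9 if i not in ("NaV1.7", "NaV1.9")),
            tuple(i for i in resolved8 if i != "NaV1.7"),
            "ECTL_I",
        ),
        PlantedColumn(
            1388, ("NaV1.5", "NaV1.7", "NaV1.8"), ("NaV1.5", "NaV1.7", "NaV1.8"), "ECTL_III"
        ),
        # NaV1.5-unique, resolved
        PlantedColumn(283, ("NaV1.5",), ("NaV1.5",), "ECTL_I"),
        PlantedColumn(288, ("NaV1.5",), ("NaV1.5",), "ECTL_I"),
        PlantedColumn(318, ("NaV1.5",), ("NaV1.5",), "ECTL_I"),
        PlantedColumn(1374, ("NaV1.5",), ("NaV1.5",), "ECTL_III"),
        # NaV1.6-unique (domain I), resolved
        PlantedColumn(302, ("NaV1.6",), ("NaV1.6",), "ECTL_I"),
        PlantedColumn(310, ("NaV1.6",), ("NaV1.6",), "ECTL_I"),
        # NaV1.7-unique (domain I), resolved
        PlantedColumn(295, ("NaV1.7",), ("NaV1.7",), "ECTL_I"),
        # NaV1.8-unique (domain II), resolved
        PlantedColumn(819, ("NaV1.8",), ("NaV1.8",), "ECTL_II"),
        # extra NaV1.4 ECTL I motifs: present in sequence, unresolved
        # (the loop is flexible and not modelled in the structures)
        PlantedColumn(276, ("NaV1.4",), (), "ECTL_I"),
        PlantedColumn(298, ("NaV1.4",), (), "ECTL_I"),
        PlantedColumn(306, ("NaV1.4",), (), "ECTL_I"),
        PlantedColumn(313, ("NaV1.4",), (), "ECTL_I"),
        PlantedColumn(334, ("NaV1.4",), (), "ECTL_I"),
    ]
    return FamilyParams(
        member_ids=list(NAV_ISOFORMS), length=2016, planted=planted, seed=seed
    )


def nav_region_annotation(isoform_id: str) -> RegionAnnotation:
    """Named regions of the synthetic Na_V family (Na_V1.5 column coordinates)."""
    return RegionAnnotation(
        isoform_id=isoform_id,
        regions={
            "ECTL_I": (270, 340),
            "ECTL_II": (800, 840),
            "ECTL_III": (1350, 1400),
            "ECTL_IV": (1700, 1740),
            "domain_I": (1, 450),
            "domain_II": (700, 1000),
            "domain_III": (1200, 1500),
            "domain_IV": (1550, 1800),
        },
    )


def _scrub_incidental_sequons(residues: list[str], keep: set[int], rng) -> None:
    """Destroy background sequons so planted ground truth is exact.

    Random backgrounds of realistic length contain NX[S/T] matches by
    chance (~1 per 200 residues); these would pollute exact group and
    count assertions, so any sequon not at a planted column is removed by
    replacing its N+2 serine/threonine.
    """
    protected = set()
    for c in keep:
        protected.update((c, c + 2))  # planted N and S/T must survive
    for _ in range(10):
        seq = IsoformSequence("tmp", "", "".join(residues))
        extra = [s for s in scan_sequons(seq) if s.asn_position not in keep]
        if not extra:
            return
        for s in extra:
            # replace the N+2 hydroxyl residue, unless that position is part
            # of a planted motif - then remove the incidental N instead
            target = s.asn_position + 2 if s.asn_position + 2 not in protected else s.asn_position
            residues[target - 1] = str(rng.choice(list("AVLIGE")))
    raise RuntimeError("failed to scrub incidental sequons")


def make_sequence_family(
    params: FamilyParams,
) -> tuple[list[IsoformSequence], pd.DataFrame]:
    """Generate the family plus its ground-truth sequon table.

    Members diverge from a common ancestor by point substitution at
    ``substitution_rate``; each planted column then receives the motif in
    exactly its designated members (identical N and S/T; the X residue is
    free) and is destroyed (N replaced) in all others.  Incidental
    background sequons are scrubbed so the planted table is the complete
    sequon inventory.
    """
    rng = np.random.default_rng(params.seed)
    pool = np.array(list(AA_BACKGROUND))
    ancestor = rng.choice(pool, size=params.length)

    # per-column shared motif residues
    motif_x = {p.column: str(rng.choice(list("ADEFGHIKLQRVY"))) for p in params.planted}
    motif_st = {p.column: str(rng.choice(["S", "T"])) for p in params.planted}

    planted_cols = {p.column for p in params.planted}
    # sequons sit in locally conserved stretches of the extracellular loops;
    # freezing a short flank around each planted motif emulates that and
    # anchors the columns during alignment
    flank = np.zeros(params.length, dtype=bool)
    for c in planted_cols:
        lo = max(c - 1 - params.conserved_flank, 0)
        hi = min(c + 2 + params.conserved_flank, params.length)
        flank[lo:hi] = True

    seqs = []
    truth_rows = []
    for iso in params.member_ids:
        residues = ancestor.copy()
        mut = (rng.random(params.length) < params.substitution_rate) & ~flank
        residues[mut] = rng.choice(pool, size=int(mut.sum()))
        residues = list(residues)
        for p in params.planted:
            c = p.column
            if iso in p.members:
                residues[c - 1] = "N"
                residues[c] = motif_x[c]
                residues[c + 1] = motif_st[c]
                truth_rows.append(
                    {
                        "isoform": iso,
                        "asn_position": c,
                        "column": c,
                        "n_members": len(p.members),
                        "conservation": (
                            "all"
                            if set(p.members) == set(params.member_ids)
                            else ("unique" if len(p.members) == 1 else "subset")
                        ),
                        "resolved": iso in p.resolved_members,
                        "region": p.region or "",
                    }
                )
            else:
                # destroyed elsewhere: replace the asparagine
                residues[c - 1] = str(rng.choice(list("QDEKR")))
        _scrub_incidental_sequons(residues, planted_cols & _member_cols(params, iso), rng)
        seqs.append(IsoformSequence(isoform_id=iso, accession="synthetic", residues="".join(residues)))

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "isoform", "asn_position", "column", "n_members",
            "conservation", "resolved", "region",
        ],
    )
    return seqs, truth


def _member_cols(params: FamilyParams, iso: str) -> set[int]:
    return {p.column for p in params.planted if iso in p.members}


def family_sequon_sets(
    seqs: list[IsoformSequence], truth: pd.DataFrame
) -> dict[str, list[Sequon]]:
    """Scan each member, attaching resolved flags from the ground truth."""
    out = {}
    for s in seqs:
        resolved = set(
            truth.loc[
                (truth["isoform"] == s.isoform_id) & truth["resolved"], "asn_position"
            ]
        )
        out[s.isoform_id] = scan_sequons(s, resolved_positions=resolved)
    return out


# ---------------------------------------------------------------------------
# toy channel structures


@dataclass
class MembraneSlab:
    """Planar membrane stand-in: two head-group planes plus composition metadata."""

    z_inner: float
    z_outer: float
    head_tolerance: float = 3.0
    composition: pd.DataFrame | None = None

    def __post_init__(self):
        if not self.z_outer > self.z_inner:
            raise ValueError("outer plane must lie above inner plane")
        if self.composition is not None:
            for col in ("upper_pct", "inner_pct"):
                total = float(self.composition[col].sum())
                if abs(total - 100.0) > 0.1:
                    raise ValueError(f"{col} fractions sum to {total}, not 100")

    @property
    def half_thickness(self) -> float:
        return 0.5 * (self.z_outer - self.z_inner)


@dataclass
class ToyChannelParams:
    n_loops: int = 4
    helix_len: int = 26
    loop_len: int = 11
    bundle_radius: float = 11.5
    helix_rise: float = 1.5
    loop_height: float = 10.0
    z_inner: float = -40.0
    z_outer: float = 0.0
    glycosite_loops: tuple[int, ...] = (0, 1, 2, 3)  # loops carrying one site each
    seed: int = 0

    def __post_init__(self):
        if any(not 0 <= i < self.n_loops for i in self.glycosite_loops):
            raise ValueError("glycosite loop index out of range")


@dataclass
class ToyChannel:
    structure: struc.AtomArray
    sequence: IsoformSequence
    annotation: RegionAnnotation
    glycosites: list[int]  # 1-based Asn positions
    membrane: MembraneSlab
    pore_axis_point: np.ndarray  # extracellular pore mouth
    pore_axis_dir: np.ndarray  # unit vector pointing away from the membrane


def _helix_ca(n: int, base: np.ndarray, up: bool, rise: float, phase: float) -> np.ndarray:
    """CA trace of an ideal alpha-helix along +-z at lateral position ``base``."""
    t = np.arange(n)
    ang = phase + np.deg2rad(100.0) * t
    z = rise * t if up else rise * (n - 1 - t)
    return np.stack(
        [base[0] + 2.3 * np.cos(ang), base[1] + 2.3 * np.sin(ang), base[2] + z], axis=1
    )


def _loop_ca(start: np.ndarray, end: np.ndarray, n: int, height: float) -> np.ndarray:
    """CA arc bridging two helix tops, bulging upward and outward."""
    t = np.linspace(0.0, 1.0, n + 2)[1:-1]
    base = start[None, :] * (1 - t[:, None]) + end[None, :] * t[:, None]
    bulge = np.sin(np.pi * t)
    mid = 0.5 * (start + end)
    radial = mid[:2] / (np.linalg.norm(mid[:2]) + 1e-9)
    out = base.copy()
    out[:, 2] += height * bulge
    out[:, :2] += 3.0 * bulge[:, None] * radial[None, :]
    return out


def make_toy_channel(params: ToyChannelParams | None = None) -> ToyChannel:
    """Idealized helical-bundle channel with loop-borne Asn-X-Thr glycosites.

    2*n_loops transmembrane helices stand on a circle around the z axis
    (the pore axis); consecutive helix pairs are bridged by extracellular
    loops arcing above the outer membrane plane.  Each designated loop
    carries one Asn-Ala-Thr sequon at its apex, with an explicit Asn side
    chain (CB, CG, OD1, ND2) pointing up and away from the pore.
    """
    params = params or ToyChannelParams()
    n_helix = 2 * params.n_loops
    angles = 2 * np.pi * np.arange(n_helix) / n_helix

    ca: list[np.ndarray] = []
    seq_chars: list[str] = []
    regions: dict[str, tuple[int, int]] = {}
    glycosites: list[int] = []

    helix_span = params.helix_rise * (params.helix_len - 1)
    z_base = params.z_outer - helix_span  # helices span the slab
    for k in range(params.n_loops):
        a0, a1 = angles[2 * k], angles[2 * k + 1]
        b0 = np.array([params.bundle_radius * np.cos(a0), params.bundle_radius * np.sin(a0), z_base])
        b1 = np.array([params.bundle_radius * np.cos(a1), params.bundle_radius * np.sin(a1), z_base])
        h_up = _helix_ca(params.helix_len, b0, True, params.helix_rise, phase=a0)
        start = len(seq_chars) + 1
        ca.append(h_up)
        seq_chars.extend("A" * params.helix_len)
        regions[f"VSD_{k}"] = (start, start + params.helix_len - 1)

        loop = _loop_ca(h_up[-1], b1 + [0, 0, helix_span], params.loop_len, params.loop_height)
        lstart = len(seq_chars) + 1
        ca.append(loop)
        seq_chars.extend("A" * params.loop_len)
        regions[f"ECTL_{k}"] = (lstart, lstart + params.loop_len - 1)
        if k in params.glycosite_loops:
            apex = lstart + params.loop_len // 2
            glycosites.append(apex)
            seq_chars[apex - 1] = "N"
            seq_chars[apex + 1] = "T"

        h_dn = _helix_ca(params.helix_len, b1, False, params.helix_rise, phase=a1)
        ca.append(h_dn)
        seq_chars.extend("A" * params.helix_len)

    ca_xyz = np.vstack(ca)
    sequence = IsoformSequence("toy", "synthetic", "".join(seq_chars))
    atoms = _build_atoms(ca_xyz, sequence.residues)
    membrane = MembraneSlab(z_inner=params.z_inner, z_outer=params.z_outer)
    annotation = RegionAnnotation(isoform_id="toy", regions=regions)
    return ToyChannel(
        structure=atoms,
        sequence=sequence,
        annotation=annotation,
        glycosites=glycosites,
        membrane=membrane,
        pore_axis_point=np.array([0.0, 0.0, params.z_outer + 5.0]),
        pore_axis_dir=np.array([0.0, 0.0, 1.0]),
    )


def _build_atoms(ca_xyz: np.ndarray, sequence: str, chain: str = "A") -> struc.AtomArray:
    """Poly-Ala heavy-atom scaffold around a CA trace; full Asn side chains.

    Backbone N/C/O are interpolated between consecutive CA positions -
    crude stereochemistry, adequate for excluded-volume work.
    """
    n_res = len(sequence)
    assert ca_xyz.shape == (n_res, 3)
    names, elements, res_ids, res_names, coords = [], [], [], [], []
    center = ca_xyz.mean(axis=0)
    for i, aa in enumerate(sequence):
        ca = ca_xyz[i]
        prev_ca = ca_xyz[i - 1] if i > 0 else ca + [0, 0, -3.8]
        next_ca = ca_xyz[i + 1] if i < n_res - 1 else ca + [0, 0, 3.8]
        outward = ca - center
        outward[2] *= 0.3
        nrm = np.linalg.norm(outward)
        outward = outward / nrm if nrm > 1e-9 else np.array([1.0, 0, 0])
        up = np.array([0.0, 0.0, 1.0])

        res_atoms = {
            "N": ca + 0.38 * (prev_ca - ca),
            "CA": ca,
            "C": ca + 0.38 * (next_ca - ca),
            "O": ca + 0.38 * (next_ca - ca) + 0.6 * outward,
            "CB": ca + 1.53 * _mix(outward, up, 0.25),
        }
        resname = {"A": "ALA", "N": "ASN", "T": "THR"}.get(aa, "ALA")
        if aa == "N":
            cb = res_atoms["CB"]
            cg = cb + 1.52 * _mix(outward, up, 0.55)
            res_atoms["CG"] = cg
            res_atoms["OD1"] = cg + 1.23 * _mix(outward, -up, 0.2)
            res_atoms["ND2"] = cg + 1.33 * _mix(outward, up, 0.85)
        elif aa == "T":
            res_atoms["OG1"] = res_atoms["CB"] + 1.42 * _mix(outward, up, 0.5)
        for name, xyz in res_atoms.items():
            names.append(name)
            elements.append(name[0])
            res_ids.append(i + 1)
            res_names.append(resname)
            coords.append(xyz)

    arr = struc.AtomArray(len(names))
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.atom_name = np.asarray(names)
    arr.element = np.asarray(elements)
    arr.res_id = np.asarray(res_ids)
    arr.res_name = np.asarray(res_names)
    arr.chain_id = np.full(len(names), chain)
    arr.hetero = np.zeros(len(names), dtype=bool)
    return arr


def _mix(a: np.ndarray, b: np.ndarray, w: float) -> np.ndarray:
    v = (1 - w) * a + w * b
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# toy alpha/partner complexes


@dataclass
class ToyComplexParams:
    n_alpha: int = 40  # alpha-chain residues (straight segment)
    footprint: tuple[int, ...] = tuple(range(15, 27))  # designated contact residues
    partner_len: int = 12
    contact_distance: float = 4.0
    displacement: float = 0.0  # extra partner offset (100 -> no contacts)
    seed: int = 0


@dataclass
class ToyComplex:
    structure: struc.AtomArray
    alpha_chain: str
    partner_chain: str
    footprint: tuple[int, ...]


def make_toy_complex(params: ToyComplexParams | None = None) -> ToyComplex:
    """Alpha chain with a partner strand placed over a designated footprint.

    Partner CAs sit ``contact_distance`` above the footprint residues;
    all other alpha residues are kept farther than typical interface
    cutoffs by bending the alpha chain away from the partner.
    """
    params = params or ToyComplexParams()
    if max(params.footprint) > params.n_alpha:
        raise ValueError("footprint outside alpha chain")
    t = np.arange(params.n_alpha)
    alpha_ca = np.stack([3.8 * t, np.zeros_like(t, dtype=float), np.zeros_like(t, dtype=float)], axis=1)
    # bend non-footprint residues downward so only the designated set contacts
    fp = np.array(params.footprint) - 1
    mask = np.ones(params.n_alpha, dtype=bool)
    mask[fp] = False
    alpha_ca[mask, 2] -= 8.0

    p_t = np.arange(params.partner_len)
    fp_lo = alpha_ca[fp, 0].min()
    partner_ca = np.stack(
        [
            fp_lo + 3.8 * p_t * (len(fp) - 1) / max(params.partner_len - 1, 1),
            np.zeros_like(p_t, dtype=float),
            np.full(params.partner_len, params.contact_distance + params.displacement),
        ],
        axis=1,
    )
    alpha = _build_atoms_ca_only(alpha_ca, "A")
    partner = _build_atoms_ca_only(partner_ca, "B")
    return ToyComplex(
        structure=alpha + partner,
        alpha_chain="A",
        partner_chain="B",
        footprint=params.footprint,
    )


def _build_atoms_ca_only(ca_xyz: np.ndarray, chain: str) -> struc.AtomArray:
    n = len(ca_xyz)
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(ca_xyz, dtype=np.float32)
    arr.atom_name = np.full(n, "CA")
    arr.element = np.full(n, "C")
    arr.res_id = np.arange(1, n + 1)
    arr.res_name = np.full(n, "ALA")
    arr.chain_id = np.full(n, chain)
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


# ---------------------------------------------------------------------------
# toy Ig beta-sandwich


@dataclass
class ToyIgParams:
    n_strands: int = 8  # two sheets of four
    strand_len: int = 12
    strand_spacing: float = 4.8
    sheet_separation: float = 10.0
    rise: float = 3.4
    turn_clearance: float = 2.0
    seed: int = 0


@dataclass
class ToyIg:
    """CA-only idealized Ig beta-sandwich (synthetic beta1-Ig stand-in)."""

    coords: np.ndarray  # (n_res, 3)
    res_ids: np.ndarray  # 1-based
    tip_residues: np.ndarray  # residue indices at the distal (max-z) end
    base_residues: np.ndarray  # residue indices at the membrane-proximal end
    edge_residues: np.ndarray  # residue indices on the outward sheet face

    @property
    def extent(self) -> float:
        return float(self.coords[:, 2].max() - self.coords[:, 2].min())


def make_toy_ig(params: ToyIgParams | None = None) -> ToyIg:
    """Idealized beta-sandwich at beta1-Ig scale.

    Eight 12-residue strands (rise 3.4 A) in two sheets 10 A apart give a
    long axis of ~41 A, matching the dimensions of an Ig fold.  Turn
    residues extend ``turn_clearance`` beyond the strand ends.
    """
    params = params or ToyIgParams()
    per_sheet = params.n_strands // 2
    coords = []
    for s in range(params.n_strands):
        sheet = s // per_sheet
        col = s % per_sheet
        x = (col - (per_sheet - 1) / 2) * params.strand_spacing
        y = (sheet - 0.5) * params.sheet_separation
        t = np.arange(params.strand_len)
        z = params.rise * t if s % 2 == 0 else params.rise * (params.strand_len - 1 - t)
        strand = np.stack([np.full_like(t, x, dtype=float), np.full_like(t, y, dtype=float), z], axis=1)
        coords.append(strand)
        # turn residue beyond the strand end it finishes at
        end_z = strand[-1, 2]
        turn_z = end_z + params.turn_clearance if end_z > 0.5 * params.rise * params.strand_len else end_z - params.turn_clearance
        coords.append(np.array([[x + 0.5 * params.strand_spacing, y, turn_z]]))
    xyz = np.vstack(coords)
    res_ids = np.arange(1, len(xyz) + 1)
    zmax, zmin = xyz[:, 2].max(), xyz[:, 2].min()
    tip = np.nonzero(xyz[:, 2] > zmax - 3.0)[0]
    base = np.nonzero(xyz[:, 2] < zmin + 3.0)[0]
    edge = np.nonzero(xyz[:, 1] > xyz[:, 1].max() - 0.5)[0]
    return ToyIg(coords=xyz, res_ids=res_ids, tip_residues=tip, base_residues=base, edge_residues=edge)


# ---------------------------------------------------------------------------
# packaged reference tables


def _data_path(name: str):
    return resources.files("glycoshield.data").joinpath(name)


@dataclass
class ReferenceTables:
    variants: list[VariantRecord]
    resolved_sites: pd.DataFrame
    membrane_composition: pd.DataFrame
    beta1_annotation: dict
    glycan_tree: "object"


def load_reference_tables() -> ReferenceTables:
    """Packaged variant, resolved-site and membrane-composition tables."""
    from glycoshield.glycan_tree import load_representative_tree

    with resources.as_file(_data_path("variants_nav.csv")) as p:
        variants = read_variants_csv(p)
    resolved = pd.read_csv(_data_path("resolved_sites.csv").open())
    membrane = pd.read_csv(_data_path("membrane_composition.csv").open())
    beta1 = json.loads(_data_path("beta1_annotation.json").read_text())
    return ReferenceTables(
        variants=variants,
        resolved_sites=resolved,
        membrane_composition=membrane,
        beta1_annotation=beta1,
        glycan_tree=load_representative_tree(),
    )


def make_membrane_slab(z_inner: float = -40.0, z_outer: float = 0.0) -> MembraneSlab:
    """Membrane slab carrying the packaged leaflet composition as metadata."""
    comp = pd.read_csv(_data_path("membrane_composition.csv").open())
    return MembraneSlab(z_inner=z_inner, z_outer=z_outer, composition=comp)


# ---------------------------------------------------------------------------
# variant sequence contexts (synthetic scaffolds)

#: (asn_position, motif) triples per isoform; motifs carry the residues the
#: variant lists pin down (e.g. NaV1.1 H1393/T1394 fix sequon N1392 = "NHT");
#: X residues that nothing constrains are scaffolded as alanine.
_CONTEXT_SEQUONS = {
    "NaV1.1": [(338, "NAS"), (1378, "NAS"), (1392, "NHT")],
    "NaV1.5": [
        (283, "NAT"), (288, "NAT"), (291, "NAT"), (318, "NAT"), (328, "NAT"),
        (1365, "NAT"), (1374, "NAT"), (1380, "NAS"), (1388, "NAT"),
    ],
    "NaV1.6": [(1358, "NAT")],
    "NaV1.8": [(819, "NAT")],
}

_CONTEXT_LENGTH = 2016


def make_isoform_context(isoform_id: str) -> IsoformSequence:
    """Synthetic full-length scaffold carrying an isoform's documented sequons.

    The real isoform sequences are not redistributed; this scaffold is a
    glutamate background (inert for sequon scanning) with the documented
    sequon motifs written at their native residue numbers, which is all
    the mutate-and-rescan variant classifier needs.
    """
    if isoform_id not in _CONTEXT_SEQUONS:
        raise KeyError(f"no packaged sequon context for {isoform_id!r}")
    residues = ["E"] * _CONTEXT_LENGTH
    for pos, motif in _CONTEXT_SEQUONS[isoform_id]:
        residues[pos - 1 : pos + 2] = list(motif)
    return IsoformSequence(isoform_id=isoform_id, accession="synthetic-context", residues="".join(residues))
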