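"""Glycan grafting and torsional Monte Carlo conformer sampling.

This is the desk-scale stand-in for all-atom MD of glycosylated channel
surfaces: glycan trees are built residue-by-residue from rigid
monosaccharide templates onto Asn side chains, and conformers are drawn
by Metropolis sampling over the glycosidic dihedrals (phi/psi, plus
omega for 1-6 linkages) against a purely repulsive excluded-volume
energy (protein + membrane slab + inter-glycan).  There are no
electrostatics and no solvent; the quantity of interest is the geometric
envelope of clash-free conformers, not energetics.

The default protocol records 30 snapshots at an interval of 5 sweeps
over a horizon of 150 - the torsional analog of sampling an MD
trajectory every 5 ns over 150 ns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
import biotite.structure as struc

from glycoshield.glycan_tree import (
    ACCEPTOR_ATOMS,
    GlycanTree,
    MonosaccharideTemplate,
    template_for,
)
from glycoshield.synthetic_data import MembraneSlab


class GraftError(ValueError):
    """Raised when a site cannot carry a glycan."""


# -- internal-coordinate helpers --------------------------------------------


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d given chain a-b-c, bond |c-d|, angle b-c-d, torsion a-b-c-d."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n_norm = np.linalg.norm(n)
    if n_norm < 1e-8:  # collinear anchors: pick any perpendicular
        helper = np.array([1.0, 0.0, 0.0]) if abs(bc[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        n = np.cross(bc, helper)
        n_norm = np.linalg.norm(n)
    n = n / n_norm
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector a onto unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if c < -1.0 + 1e-10:
        helper = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, helper)
        axis /= np.linalg.norm(axis)
        return _axis_rotation(axis, np.pi)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K


#: direction (template frame) from the anomeric carbon toward the atom it
#: bonds back to (glycosidic O or Asn ND2); off the ring plane so ring
#: substituents stay pseudo-tetrahedral
_STEM_LOCAL = np.array([-0.82, 0.28, -0.50]) / np.linalg.norm([-0.82, 0.28, -0.50])


def _place_ring(template: MonosaccharideTemplate, anomeric_pos: np.ndarray,
                stem_pos: np.ndarray, spin_deg: float) -> np.ndarray:
    """World coordinates of a rigid ring given the anomeric-carbon position,
    the atom it bonds back to, and a spin angle about that bond."""
    u = stem_pos - anomeric_pos
    u = u / np.linalg.norm(u)
    R = _axis_rotation(u, np.deg2rad(spin_deg)) @ _rotation_between(_STEM_LOCAL, u)
    return anomeric_pos + template.coords @ R.T


# -- graft layout ------------------------------------------------------------


@dataclass(frozen=True)
class TorsionSpec:
    """One rotatable dihedral: owning linkage (-1 = Asn root) and role."""

    linkage_index: int
    role: str  # "chi" | "spin" | "omega" | "psi" | "phi"


class _GraftLayout:
    """Static atom/torsion layout for one tree.

    Atom order: for each node in topological order, the linkage oxygen
    leading to it (non-root nodes), then its template atoms.  The
    exclusion mask marks intra-glycan pairs within 2 bonds (1-2/1-3),
    which are exempt from the clash penalty.
    """

    def __init__(self, tree: GlycanTree):
        self.tree = tree
        self.order = tree.topological_order()
        self.templates = {
            nid: template_for(tree.nodes[nid].monosaccharide) for nid in self.order
        }
        self.linkage_of = {lk.child: (i, lk) for i, lk in enumerate(tree.linkages)}

        self.atom_names: list[str] = []
        self.atom_nodes: list[str] = []
        self.atom_index: dict[tuple[str, str], int] = {}
        self.oxygen_index: dict[str, int] = {}  # child node id -> O atom index
        bonds: list[tuple[int, int]] = []
        self.spec: list[TorsionSpec] = [TorsionSpec(-1, "chi"), TorsionSpec(-1, "spin")]

        for nid in self.order:
            tpl = self.templates[nid]
            if nid != tree.root:
                i_lk, lk = self.linkage_of[nid]
                o_idx = len(self.atom_names)
                self.oxygen_index[nid] = o_idx
                self.atom_names.append("O")
                self.atom_nodes.append(nid)
                acc = self.atom_index[(lk.parent, ACCEPTOR_ATOMS[lk.acceptor])]
                bonds.append((acc, o_idx))
                if lk.acceptor == 6:
                    self.spec.append(TorsionSpec(i_lk, "omega"))
                self.spec.append(TorsionSpec(i_lk, "psi"))
                self.spec.append(TorsionSpec(i_lk, "phi"))
            base = len(self.atom_names)
            for j, name in enumerate(tpl.atom_names):
                self.atom_index[(nid, name)] = base + j
                self.atom_names.append(name)
                self.atom_nodes.append(nid)
            ring = list(range(base, base + 6))
            for k in range(6):
                bonds.append((ring[k], ring[(k + 1) % 6]))
            bonds.append((base + 4, base + 6))  # R5-C6
            if nid != tree.root:
                bonds.append((self.oxygen_index[nid], self.atom_index[(nid, tpl.anomeric_atom)]))

        n = len(self.atom_names)
        adj: list[set[int]] = [set() for _ in range(n)]
        for a, b in bonds:
            adj[a].add(b)
            adj[b].add(a)
        mask = np.zeros((n, n), dtype=bool)
        for a in range(n):
            mask[a, a] = True
            for b in adj[a]:
                mask[a, b] = mask[b, a] = True
                for c in adj[b]:
                    mask[a, c] = mask[c, a] = True
        self.exclusion_mask = mask
        self.n_atoms = n

    def build_coords(self, anchor_cb, anchor_cg, anchor_nd2, torsions) -> np.ndarray:
        tvals = {(s.linkage_index, s.role): torsions[i] for i, s in enumerate(self.spec)}
        coords = np.zeros((self.n_atoms, 3))
        for nid in self.order:
            tpl = self.templates[nid]
            base = self.atom_index[(nid, tpl.atom_names[0])]
            if nid == self.tree.root:
                c1 = place_atom(
                    anchor_cb, anchor_cg, anchor_nd2,
                    MonosaccharideTemplate.BOND_ASN, 124.0, tvals[(-1, "chi")],
                )
                ring = _place_ring(tpl, c1, anchor_nd2, tvals[(-1, "spin")])
            else:
                i_lk, lk = self.linkage_of[nid]
                parent_tpl = self.templates[lk.parent]
                acc_name = ACCEPTOR_ATOMS[lk.acceptor]
                acc = coords[self.atom_index[(lk.parent, acc_name)]]
                ring_names = list(parent_tpl.atom_names[:6])
                if acc_name == "C6":
                    b_ref = coords[self.atom_index[(lk.parent, ring_names[4])]]  # ring C5
                    a_ref = coords[self.atom_index[(lk.parent, ring_names[3])]]
                    o_torsion = tvals[(i_lk, "omega")]
                else:
                    i_ring = ring_names.index(acc_name)
                    b_ref = coords[self.atom_index[(lk.parent, ring_names[(i_ring + 1) % 6])]]
                    a_ref = coords[self.atom_index[(lk.parent, ring_names[(i_ring + 2) % 6])]]
                    o_torsion = 120.0  # fixed exocyclic placement for 2/3/4 acceptors
                o_pos = place_atom(
                    a_ref, b_ref, acc,
                    MonosaccharideTemplate.BOND_GLYCOSIDIC, 109.5, o_torsion,
                )
                coords[self.oxygen_index[nid]] = o_pos
                c1 = place_atom(
                    b_ref, acc, o_pos,
                    MonosaccharideTemplate.BOND_GLYCOSIDIC, 115.0, tvals[(i_lk, "psi")],
                )
                ring = _place_ring(tpl, c1, o_pos, tvals[(i_lk, "phi")])
            coords[base : base + len(tpl.atom_names)] = ring
        return coords


# -- grafted glycans ---------------------------------------------------------


@dataclass
class GraftedGlycan:
    """A glycan tree built onto one Asn site, parameterized by its torsions.

    ``coords()`` rebuilds all heavy-atom coordinates from the rigid
    templates; bond lengths and ring geometry are exact by construction
    for any torsion vector (torsion-only flexibility).
    """

    site: int  # 1-based Asn residue id in the host structure
    tree: GlycanTree
    anchor_cb: np.ndarray
    anchor_cg: np.ndarray
    anchor_nd2: np.ndarray
    torsions: np.ndarray  # degrees
    layout: _GraftLayout

    @property
    def n_torsions(self) -> int:
        return len(self.torsions)

    @property
    def atom_names(self) -> list[str]:
        return self.layout.atom_names

    @property
    def atom_nodes(self) -> list[str]:
        return self.layout.atom_nodes

    def coords(self, torsions: np.ndarray | None = None) -> np.ndarray:
        t = self.torsions if torsions is None else torsions
        return self.layout.build_coords(self.anchor_cb, self.anchor_cg, self.anchor_nd2, t)


_DEFAULT_TORSION = {"chi": 180.0, "spin": 60.0, "omega": 60.0, "psi": 180.0, "phi": 60.0}


def graft(
    structure: struc.AtomArray,
    site: int,
    tree: GlycanTree,
    seed: int = 0,
    sequence: str | None = None,
    membrane: MembraneSlab | None = None,
    clash_cutoff: float = 2.4,
    max_attempts: int = 2000,
) -> GraftedGlycan:
    """Build a glycan onto the Asn at residue ``site`` and relax it clash-free.

    The site must be a sequon start: residue ``site`` must be Asn with a
    resolvable side-chain nitrogen and, when ``sequence`` is given, an
    intact NX[S/T] motif (a proline at N+1 admits no glycan).  The glycan
    is first built at default dihedrals, then greedily torsion-adjusted
    until the excluded-volume energy against the host vanishes.
    """
    if sequence is not None:
        if site + 2 > len(sequence) or sequence[site - 1] != "N":
            raise GraftError(f"residue {site} is not a sequon asparagine")
        if sequence[site] == "P":
            raise GraftError(f"site {site}: N+1 proline admits no glycan")
        if sequence[site + 1] not in "ST":
            raise GraftError(f"residue {site} is not a sequon start")
    res_mask = structure.res_id == site
    if not res_mask.any():
        raise GraftError(f"residue {site} absent from structure")
    if structure.res_name[res_mask][0] != "ASN":
        raise GraftError(f"residue {site} is not ASN")

    def _atom(name):
        m = res_mask & (structure.atom_name == name)
        if not m.any():
            raise GraftError(f"residue {site} lacks side-chain atom {name}")
        return structure.coord[m][0].astype(float)

    layout = _GraftLayout(tree)
    g = GraftedGlycan(
        site=site,
        tree=tree,
        anchor_cb=_atom("CB"),
        anchor_cg=_atom("CG"),
        anchor_nd2=_atom("ND2"),
        torsions=np.array([_DEFAULT_TORSION[s.role] for s in layout.spec]),
        layout=layout,
    )

    context = structure.coord[structure.res_id != site].astype(float)
    ctx_tree = cKDTree(context)

    def energy(t):
        xyz = g.coords(t)
        return (
            _masked_self_energy(xyz, layout.exclusion_mask, clash_cutoff)
            + _context_energy(xyz, ctx_tree, clash_cutoff)
            + membrane_energy(xyz, membrane)
        )

    rng = np.random.default_rng(seed)
    e = energy(g.torsions)
    attempts = 0
    while e > 0 and attempts < max_attempts:
        attempts += 1
        cand = g.torsions.copy()
        cand[rng.integers(g.n_torsions)] += rng.uniform(-60.0, 60.0)
        e_new = energy(cand)
        if e_new < e:
            g.torsions, e = cand, e_new
    if e > 0:
        raise GraftError(
            f"site {site}: no clash-free pose within {max_attempts} attempts"
        )
    return g


# -- excluded-volume energy ---------------------------------------------------


#: hard-sphere step cost per clashing pair; the quadratic core is added on
#: top, so entering any clash costs at least 1 energy unit and is
#: effectively never accepted at the default temperature
_STEP = 1.0


def _pair_penalty(d: np.ndarray, cutoff: float) -> float:
    close = d < cutoff
    if not close.any():
        return 0.0
    return float(np.sum(_STEP + (1.0 - d[close] / cutoff) ** 2))


def _masked_self_energy(xyz: np.ndarray, exclusion_mask: np.ndarray, cutoff: float) -> float:
    d = cdist(xyz, xyz)
    d = np.where(exclusion_mask, np.inf, d)
    iu = np.triu_indices(len(xyz), k=1)
    return _pair_penalty(d[iu], cutoff)


def _context_energy(xyz: np.ndarray, ctx_tree: cKDTree, cutoff: float) -> float:
    e = 0.0
    for i, neigh in enumerate(ctx_tree.query_ball_point(xyz, r=cutoff)):
        if neigh:
            d = np.linalg.norm(ctx_tree.data[neigh] - xyz[i], axis=1)
            e += _pair_penalty(d, cutoff)
    return e


def clash_energy(
    coords_a: np.ndarray,
    coords_b: np.ndarray | None = None,
    cutoff: float = 2.4,
    exclusion: set[tuple[int, int]] | None = None,
) -> float:
    """Soft repulsive penalty: sum over pairs below ``cutoff`` of (1 - d/cutoff)^2.

    Zero iff no pair lies below the cutoff; symmetric in its arguments;
    each clashing pair additionally pays a hard-sphere step cost of 1, so
    a coincident pair contributes the maximal finite penalty of 2.  With
    one argument, intra-set pairs are counted (minus ``exclusion``
    index pairs); with two, only cross pairs.
    """
    coords_a = np.asarray(coords_a, dtype=float)
    if coords_b is None:
        n = len(coords_a)
        mask = np.zeros((n, n), dtype=bool)
        np.fill_diagonal(mask, True)
        for i, j in exclusion or ():
            mask[i, j] = mask[j, i] = True
        return _masked_self_energy(coords_a, mask, cutoff)
    coords_b = np.asarray(coords_b, dtype=float)
    if len(coords_a) == 0 or len(coords_b) == 0:
        return 0.0
    return _pair_penalty(cdist(coords_a, coords_b).ravel(), cutoff)


def membrane_energy(coords: np.ndarray, membrane: MembraneSlab | None) -> float:
    """Quadratic penalty for heavy atoms inside the slab interior
    (between the leaflet planes, minus the head-group tolerance)."""
    if membrane is None:
        return 0.0
    lo = membrane.z_inner + membrane.head_tolerance
    hi = membrane.z_outer - membrane.head_tolerance
    if hi <= lo:
        return 0.0
    z = np.asarray(coords)[:, 2]
    inside = (z > lo) & (z < hi)
    if not inside.any():
        return 0.0
    depth = np.minimum(z[inside] - lo, hi - z[inside])
    return float(np.sum((depth / membrane.head_tolerance) ** 2))


# -- the sampler --------------------------------------------------------------


@dataclass
class SamplerParams:
    """Protocol knobs for the torsional Monte Carlo sampler.

    ``snapshots`` defaults to 30 = horizon 150 / interval 5, the
    torsional analog of extracting MD snapshots every 5 ns over 150 ns.
    The graft pose (t=0) is not counted as a frame.
    """

    snapshots: int = 30
    interval: int = 5  # sweeps between snapshots
    move_width: float = 30.0  # degrees, uniform proposal half-width
    temperature: float = 0.05  # units of the soft clash penalty
    clash_cutoff: float = 2.4
    seed: int = 0
    max_attempts: int = 500  # extra downhill moves to recover a clash-free state

    def __post_init__(self):
        if self.snapshots < 1:
            raise ValueError("snapshot count must be >= 1")
        if self.clash_cutoff <= 0:
            raise ValueError("clash cutoff must be positive")


@dataclass
class ConformerEnsemble:
    """Clash-free glycan conformer frames over a fixed protein frame."""

    structure: struc.AtomArray
    grafts: list[GraftedGlycan]
    frames: list[list[np.ndarray]]  # frames[f][g] = (n_atoms, 3)
    params: SamplerParams
    membrane: MembraneSlab | None
    status: str = "ok"  # "ok" | "partial"
    acceptance: float = float("nan")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame_coords(self, f: int) -> np.ndarray:
        """All glycan heavy atoms of frame ``f`` stacked into one array."""
        return np.vstack(self.frames[f])

    def all_coords(self) -> np.ndarray:
        return np.vstack([self.frame_coords(f) for f in range(self.n_frames)])

    def metadata(self) -> dict:
        return {
            "n_frames": self.n_frames,
            "sites": [g.site for g in self.grafts],
            "status": self.status,
            "acceptance": round(float(self.acceptance), 4),
            "rng": "numpy PCG64",
            "params": {
                "snapshots": self.params.snapshots,
                "interval": self.params.interval,
                "move_width_deg": self.params.move_width,
                "temperature": self.params.temperature,
                "clash_cutoff_A": self.params.clash_cutoff,
                "seed": self.params.seed,
                "max_attempts": self.params.max_attempts,
            },
        }


class _SamplerState:
    """Torsions/coords per graft with decomposed excluded-volume energies.

    ``intra[i]`` holds graft i's self + protein-context + membrane terms;
    ``inter[i, j]`` the symmetric glycan-glycan term.  A move of graft i
    only refreshes ``intra[i]`` and row/column i of ``inter``.
    """

    def __init__(self, structure, grafts, membrane, cutoff):
        self.grafts = grafts
        self.membrane = membrane
        self.cutoff = cutoff
        keep = ~np.isin(structure.res_id, [g.site for g in grafts])
        self.ctx = cKDTree(structure.coord[keep].astype(float))
        self.torsions = [g.torsions.copy() for g in grafts]
        self.coords = [g.coords(t) for g, t in zip(grafts, self.torsions)]
        n = len(grafts)
        self.intra = np.array([self._intra(i, self.coords[i]) for i in range(n)])
        self.inter = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                e = clash_energy(self.coords[i], self.coords[j], cutoff=cutoff)
                self.inter[i, j] = self.inter[j, i] = e

    def _intra(self, i: int, xyz: np.ndarray) -> float:
        g = self.grafts[i]
        return (
            _masked_self_energy(xyz, g.layout.exclusion_mask, self.cutoff)
            + _context_energy(xyz, self.ctx, self.cutoff)
            + membrane_energy(xyz, self.membrane)
        )

    def total_energy(self) -> float:
        return float(self.intra.sum() + self.inter.sum() / 2.0)

    def try_move(self, i: int, idx: int, delta: float, temperature: float, rng) -> bool:
        cand = self.torsions[i].copy()
        cand[idx] = (cand[idx] + delta + 180.0) % 360.0 - 180.0
        xyz = self.grafts[i].coords(cand)
        intra_new = self._intra(i, xyz)
        inter_new = np.array(
            [
                0.0 if j == i else clash_energy(xyz, self.coords[j], cutoff=self.cutoff)
                for j in range(len(self.grafts))
            ]
        )
        de = (intra_new - self.intra[i]) + (inter_new.sum() - self.inter[i].sum())
        if de <= 0 or rng.random() < np.exp(-de / max(temperature, 1e-12)):
            self.torsions[i] = cand
            self.coords[i] = xyz
            self.intra[i] = intra_new
            self.inter[i, :] = inter_new
            self.inter[:, i] = inter_new
            return True
        return False


def sample_ensemble(
    structure: struc.AtomArray,
    grafts: list[GraftedGlycan],
    membrane: MembraneSlab | None = None,
    params: SamplerParams | None = None,
) -> ConformerEnsemble:
    """Draw a clash-free conformer ensemble by torsional Metropolis sampling.

    Deterministic for a fixed seed.  Every recorded frame has zero
    excluded-volume energy: no heavy-atom pair below the clash cutoff
    (1-2/1-3 intra-glycan neighbors exempt) and no atom inside the
    membrane slab interior.  If a clash-free state cannot be recovered
    within the attempt budget, the partial ensemble collected so far is
    returned with ``status='partial'``.
    """
    params = params or SamplerParams()
    if not grafts:
        raise GraftError("no grafts to sample")
    rng = np.random.default_rng(params.seed)
    state = _SamplerState(structure, grafts, membrane, params.clash_cutoff)
    if state.total_energy() > 0:
        raise GraftError("sampling requires clash-free starting grafts")

    frames: list[list[np.ndarray]] = []
    n_acc = n_try = 0
    for _ in range(params.snapshots):
        for _ in range(params.interval):  # one sweep = one proposal per torsion
            for i, g in enumerate(grafts):
                for idx in range(g.n_torsions):
                    delta = rng.uniform(-params.move_width, params.move_width)
                    n_acc += state.try_move(i, idx, delta, params.temperature, rng)
                    n_try += 1
        attempts = 0
        while state.total_energy() > 0 and attempts < params.max_attempts:
            i = int(rng.integers(len(grafts)))
            idx = int(rng.integers(grafts[i].n_torsions))
            delta = rng.uniform(-params.move_width, params.move_width)
            state.try_move(i, idx, delta, 1e-12, rng)  # downhill only
            attempts += 1
        if state.total_energy() > 0:
            return ConformerEnsemble(
                structure=structure, grafts=grafts, frames=frames, params=params,
                membrane=membrane, status="partial",
                acceptance=n_acc / max(n_try, 1),
            )
        frames.append([c.copy() for c in state.coords])
    return ConformerEnsemble(
        structure=structure, grafts=grafts, frames=frames, params=params,
        membrane=membrane, status="ok", acceptance=n_acc / max(n_try, 1),
    )


def ensemble_to_atomarrays(ensemble: ConformerEnsemble) -> list[struc.AtomArray]:
    """One AtomArray per frame (glycan atoms only), for multi-model PDB export."""
    meta_names, meta_res = [], []
    for g in ensemble.grafts:
        for name in g.atom_names:
            meta_names.append("OG" if name == "O" else name)
            meta_res.append(g.site)
    out = []
    for f in range(ensemble.n_frames):
        xyz = ensemble.frame_coords(f)
        arr = struc.AtomArray(len(xyz))
        arr.coord = xyz.astype(np.float32)
        arr.atom_name = np.asarray(meta_names)
        arr.element = np.asarray([n[0] for n in meta_names])
        arr.res_id = np.asarray(meta_res)
        arr.res_name = np.full(len(xyz), "GLC")
        arr.chain_id = np.full(len(xyz), "G")
        arr.hetero = np.ones(len(xyz), dtype=bool)
        out.append(arr)
    return out
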