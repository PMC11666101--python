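"""Trans beta1-Ig dimer bridges between opposed membranes.

The beta1 subunit's extracellular Ig domain can bind another beta1
Ig-domain on an opposing membrane, bridging the two membranes - the
proposed structural basis of the ~15-30 nm cardiomyocyte perinexal
cleft.  Two homodimer modes are modelled: **tip-to-tip**, where the turn
regions distal from the transmembrane helix meet, and **side-to-side**,
where the beta-sheet faces pair laterally.

Two quantities are computed per assembly:

- :func:`max_extension_distance` - the closed-form maximum
  membrane-to-membrane distance with both flexible linkers at full
  contour extension normal to the membranes:
  ``dimer span + 2 x linker contour + 2 x anchoring offset``.
- :func:`coarse_pull` - a bead-spring, overdamped-Langevin
  constant-velocity pulling routine in which breakable interface springs
  rupture, reporting the bridge distance a configured offset before
  rupture (the analog of extracting a steered-MD frame shortly before
  dimer separation).

Linker contour length is pinned at 3.63 A per residue (trans Ca-Ca);
the linker runs from the Ig C-terminal boundary through the anchor
residue, and the residues between the anchor and the first
transmembrane residue set the membrane anchoring offset.  Distances are
reported in nm (structure coordinates stay in Angstrom).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.spatial.distance import cdist

from glycoshield.synthetic_data import ToyIg

CONTOUR_PER_RESIDUE = 3.63  # Angstrom, trans Ca-Ca


class AssemblyError(ValueError):
    pass


def load_beta1_annotation() -> dict:
    return json.loads(
        resources.files("glycoshield.data").joinpath("beta1_annotation.json").read_text()
    )


@dataclass
class LinkerModel:
    """Flexible linker from the Ig C-terminal boundary to the membrane."""

    n_residues: int  # Ig boundary + 1 .. anchor residue
    anchor_offset_residues: int  # anchor + 1 .. first TM residue - 1
    contour_per_residue: float = CONTOUR_PER_RESIDUE

    @property
    def contour(self) -> float:
        return self.n_residues * self.contour_per_residue

    @property
    def anchor_offset(self) -> float:
        return self.anchor_offset_residues * self.contour_per_residue

    @classmethod
    def from_annotation(cls, ann: dict) -> "LinkerModel":
        return cls(
            n_residues=ann["linker_anchor"] - ann["ig_end"],
            anchor_offset_residues=ann["tm_start"] - ann["linker_anchor"] - 1,
            contour_per_residue=ann.get("contour_per_residue_A", CONTOUR_PER_RESIDUE),
        )


@dataclass
class TransAssembly:
    """Two Ig rigid bodies bridging opposed parallel membranes.

    Copy A's linker exits toward membrane A (below, -z); copy B is the
    trans partner anchored to membrane B (above, +z).  ``interface``
    holds residue-index pairs (into copy A / copy B coordinate arrays)
    within the contact cutoff.
    """

    mode: str  # "tip-to-tip" | "side-to-side"
    coords_a: np.ndarray
    coords_b: np.ndarray
    interface: list[tuple[int, int]]
    linker: LinkerModel
    anchor_index_a: int  # residue index in coords_a closest to membrane A
    anchor_index_b: int
    normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    @property
    def dimer_span(self) -> float:
        """Extent of the two Ig bodies along the membrane normal (A)."""
        z = np.concatenate([self.coords_a @ self.normal, self.coords_b @ self.normal])
        return float(z.max() - z.min())

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TransAssembly":
        """Rigid transform of the whole assembly (membrane normal included)."""
        return TransAssembly(
            mode=self.mode,
            coords_a=self.coords_a @ rotation.T + translation,
            coords_b=self.coords_b @ rotation.T + translation,
            interface=list(self.interface),
            linker=self.linker,
            anchor_index_a=self.anchor_index_a,
            anchor_index_b=self.anchor_index_b,
            normal=rotation @ self.normal,
        )


# adhesive interface contacts = closest-approach pairs only; a tight cutoff
# keeps the contact set geometrically homogeneous, so rupture is cooperative
_CONTACT_CUTOFF = 4.8
_TIP_GAP = 4.5
_SIDE_GAP = 4.7


def build_dimer(ig: ToyIg, mode: str) -> TransAssembly:
    """Assemble a trans homodimer of two copies of an Ig domain.

    ``tip-to-tip``: copy B is flipped over and stacked above copy A so
    the distal turn regions meet.  ``side-to-side``: copy B is flipped
    and placed laterally so the beta-sheet faces pair over the full
    domain length.  Raises if the placement produces no interface
    contacts (e.g. a degenerate reflected copy).
    """
    A = ig.coords.copy()
    flip = np.diag([1.0, -1.0, -1.0])  # 180 degrees about x: z and y invert
    B = A @ flip.T
    zmax, zmin = A[:, 2].max(), A[:, 2].min()
    if mode in ("tip", "tip-to-tip"):
        mode = "tip-to-tip"
        # B's (flipped) distal turns now point down; stack above A
        B = B + np.array([0.0, 0.0, zmax + _TIP_GAP - B[:, 2].min()])
    elif mode in ("side", "side-to-side"):
        mode = "side-to-side"
        B = B + np.array([0.0, A[:, 1].max() + _SIDE_GAP - B[:, 1].min(), zmin - B[:, 2].min()])
    else:
        raise AssemblyError(f"unknown dimer mode {mode!r}")

    d = cdist(A, B)
    pairs = [(int(i), int(j)) for i, j in zip(*np.nonzero(d <= _CONTACT_CUTOFF))]
    if not pairs:
        raise AssemblyError(f"{mode}: placement yields no interface contacts")
    if d.min() < 2.0:
        raise AssemblyError(f"{mode}: clashing placement (min distance {d.min():.2f} A)")

    linker = LinkerModel.from_annotation(load_beta1_annotation())
    anchor_a = int(np.argmin(A[:, 2]))  # membrane-proximal end of copy A
    anchor_b = int(np.argmax(B[:, 2]))
    return TransAssembly(
        mode=mode,
        coords_a=A,
        coords_b=B,
        interface=pairs,
        linker=linker,
        anchor_index_a=anchor_a,
        anchor_index_b=anchor_b,
    )


def max_extension_distance(assembly: TransAssembly) -> float:
    """Maximum membrane-to-membrane distance (nm), closed form.

    Both linkers fully extended normal to the membranes:
    ``dimer span + 2 x linker contour + 2 x anchoring offset``.
    """
    total_A = (
        assembly.dimer_span
        + 2.0 * assembly.linker.contour
        + 2.0 * assembly.linker.anchor_offset
    )
    return total_A / 10.0


# -- coarse bead-spring pulling ----------------------------------------------


@dataclass
class PullParams:
    """Constant-velocity pulling parameters (reduced units).

    ``velocity`` is the speed of each virtual pulling anchor along the
    membrane normal (A per time unit; both anchors move, in opposite
    directions), ``spring_k`` the stiffness of the pulling springs and
    ``interface_k`` the total stiffness of the breakable interface
    (shared across its contacts).  Rupture is the event at which every
    interface contact is simultaneously stretched beyond its rest length
    + ``break_extension``; the reported bridge structure is taken
    ``report_offset`` recorded frames before rupture.
    """

    velocity: float = 5.0
    spring_k: float = 100.0
    interface_k: float = 10.0
    break_extension: float = 1.0
    dt: float = 0.0005
    gamma: float = 1.0
    temperature: float = 0.01
    max_steps: int = 60000
    record_every: int = 20
    report_offset: int = 10  # recorded frames before rupture
    seed: int = 0

    def __post_init__(self):
        if self.velocity < 0:
            raise ValueError("velocity must be >= 0")
        if self.spring_k <= 0 or self.interface_k <= 0:
            raise ValueError("spring constants must be positive")


@dataclass
class PullResult:
    status: str  # "ruptured" | "no-rupture"
    rupture_step: int | None
    rupture_distance_nm: float | None  # membrane-to-membrane at rupture
    report_distance_nm: float | None  # at the configured offset before rupture
    trajectory_distances_nm: np.ndarray
    params: PullParams

    def to_json(self) -> dict:
        return {
            "status": self.status,
            "rupture_step": self.rupture_step,
            "rupture_distance_nm": self.rupture_distance_nm,
            "report_distance_nm": self.report_distance_nm,
            "params": {
                "velocity": self.params.velocity,
                "spring_k": self.params.spring_k,
                "interface_k": self.params.interface_k,
                "break_extension_A": self.params.break_extension,
                "dt": self.params.dt,
                "max_steps": self.params.max_steps,
                "seed": self.params.seed,
            },
        }


def _bonded_pairs(n: int) -> list[tuple[int, int]]:
    return [(i, i + 1) for i in range(n - 1)]


def _zigzag_linker(start: np.ndarray, direction: np.ndarray, perp: np.ndarray,
                   n: int, bond: float, slack_angle_deg: float = 30.0) -> np.ndarray:
    """Linker bead chain with contour-preserving bonds and initial slack."""
    theta = np.deg2rad(slack_angle_deg)
    beads = []
    pos = start.copy()
    for k in range(n):
        lateral = perp if k % 2 == 0 else -perp
        pos = pos + bond * (np.cos(theta) * direction + np.sin(theta) * lateral)
        beads.append(pos.copy())
    return np.asarray(beads)


def coarse_pull(assembly: TransAssembly, params: PullParams | None = None) -> PullResult:
    """Pull the two linker anchors apart until the dimer interface ruptures.

    One bead per residue, including explicit linker beads with initial
    slack; chain bonds and an intra-domain elastic network (11 A cutoff)
    are stiff, unbreakable, and length-capped by constraint projection so
    the system cannot extend past its geometric contour.  Linker bonds
    are capped at 90% of the trans contour: under the finite forces at
    rupture a peptide chain never reaches its full contour length, so
    the dynamic model stays strictly inside the closed-form maximum of
    :func:`max_extension_distance` (which uses the full 3.63 A/residue).
    Interface contacts are harmonic springs; rupture is the event at
    which every interface contact simultaneously exceeds its rest length
    plus ``break_extension``.  Overdamped Langevin dynamics,
    deterministic for a fixed seed.
    """
    params = params or PullParams()
    rng = np.random.default_rng(params.seed)

    normal = assembly.normal / np.linalg.norm(assembly.normal)
    helper = np.array([1.0, 0.0, 0.0]) if abs(normal[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    perp = np.cross(normal, helper)
    perp /= np.linalg.norm(perp)

    na, nb = len(assembly.coords_a), len(assembly.coords_b)
    nl = assembly.linker.n_residues
    bond = assembly.linker.contour_per_residue
    dyn_bond = 0.90 * bond  # dynamic bond cap; closed form keeps the full contour
    linker_a = _zigzag_linker(assembly.coords_a[assembly.anchor_index_a], -normal, perp, nl, dyn_bond)
    linker_b = _zigzag_linker(assembly.coords_b[assembly.anchor_index_b], normal, perp, nl, dyn_bond)
    x = np.vstack([assembly.coords_a, assembly.coords_b, linker_a, linker_b]).astype(float)

    # unbreakable springs: chains + intra-domain elastic networks
    springs: list[tuple[int, int, float, float]] = []  # i, j, k, r0
    k_chain, k_enm = 400.0, 50.0

    def _add(i, j, k, r0):
        springs.append((int(i), int(j), float(k), float(r0)))

    for off, m in ((0, na), (na, nb)):
        xs = x[off : off + m]
        for i, j in _bonded_pairs(m):
            _add(off + i, off + j, k_chain, np.linalg.norm(xs[i] - xs[j]))
        d = cdist(xs, xs)
        for i, j in zip(*np.nonzero((d <= 11.0) & (d > 0))):
            if j > i + 1:
                _add(off + int(i), off + int(j), k_enm, d[i, j])
    # linker chains: bonds capped at 95% of the trans contour (finite-force
    # extensibility; the closed-form maximum uses the full contour)
    la0, lb0 = na + nb, na + nb + nl
    _add(assembly.anchor_index_a, la0, k_chain, dyn_bond)
    _add(na + assembly.anchor_index_b, lb0, k_chain, dyn_bond)
    for k in range(nl - 1):
        _add(la0 + k, la0 + k + 1, k_chain, dyn_bond)
        _add(lb0 + k, lb0 + k + 1, k_chain, dyn_bond)

    # breakable interface springs; ``interface_k`` is the stiffness of the
    # interface as a whole, shared across its contacts (keeps the dynamics
    # stable and comparable between sparse and dense interface modes)
    k_per_contact = params.interface_k / len(assembly.interface)
    iface = [
        (i, na + j, k_per_contact,
         float(np.linalg.norm(assembly.coords_a[i] - assembly.coords_b[j])))
        for i, j in assembly.interface
    ]

    si = np.array([s[0] for s in springs]); sj = np.array([s[1] for s in springs])
    sk = np.array([s[2] for s in springs]); sr = np.array([s[3] for s in springs])
    fi = np.array([s[0] for s in iface]); fj = np.array([s[1] for s in iface])
    fk = np.array([s[2] for s in iface]); fr = np.array([s[3] for s in iface])

    ia, ib = la0 + nl - 1, lb0 + nl - 1  # pulled anchor beads (M154 analogs)
    pull_a = x[ia].copy()
    pull_b = x[ib].copy()
    offset = assembly.linker.anchor_offset

    def bridge_distance() -> float:
        return float((x[ib] - x[ia]) @ normal + 2.0 * offset) / 10.0

    noise_scale = np.sqrt(2.0 * params.temperature * params.dt / params.gamma)
    distances = []
    rupture_step = None
    for step in range(params.max_steps):
        pull_a -= params.velocity * params.dt * normal
        pull_b += params.velocity * params.dt * normal

        f = np.zeros_like(x)
        dv = x[sj] - x[si]
        dl = np.linalg.norm(dv, axis=1)
        fmag = sk * (dl - sr) / np.maximum(dl, 1e-9)
        fv = fmag[:, None] * dv
        np.add.at(f, si, fv)
        np.add.at(f, sj, -fv)

        dv2 = x[fj] - x[fi]
        dl2 = np.linalg.norm(dv2, axis=1)
        fmag2 = fk * (dl2 - fr) / np.maximum(dl2, 1e-9)
        fv2 = fmag2[:, None] * dv2
        np.add.at(f, fi, fv2)
        np.add.at(f, fj, -fv2)

        f[ia] += params.spring_k * (pull_a - x[ia])
        f[ib] += params.spring_k * (pull_b - x[ib])

        x += params.dt / params.gamma * f
        if params.temperature > 0:
            x += noise_scale * rng.standard_normal(x.shape)

        # constraint projection: unbreakable bonds never exceed rest length
        for _ in range(4):
            dv = x[sj] - x[si]
            dl = np.linalg.norm(dv, axis=1)
            over = dl > sr
            if not over.any():
                break
            corr = 0.5 * ((dl[over] - sr[over]) / dl[over])[:, None] * dv[over]
            np.add.at(x, si[over], corr)
            np.add.at(x, sj[over], -corr)

        if step % params.record_every == 0:
            distances.append(bridge_distance())
        # rupture: every interface contact simultaneously beyond break length
        if (dl2 > fr + params.break_extension).all():
            rupture_step = step
            distances.append(bridge_distance())
            break

    distances = np.asarray(distances)
    if rupture_step is None:
        return PullResult(
            status="no-rupture", rupture_step=None, rupture_distance_nm=None,
            report_distance_nm=None, trajectory_distances_nm=distances, params=params,
        )
    report_idx = max(len(distances) - 1 - params.report_offset, 0)
    return PullResult(
        status="ruptured",
        rupture_step=rupture_step,
        rupture_distance_nm=float(distances[-1]),
        report_distance_nm=float(distances[report_idx]),
        trajectory_distances_nm=distances,
        params=params,
    )
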