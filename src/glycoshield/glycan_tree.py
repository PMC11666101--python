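"""Linkage-labelled glycan trees and rigid monosaccharide template geometry.

A glycan is a rooted tree of monosaccharides joined by glycosidic
linkages, each labelled with its anomeric configuration (alpha/beta) and
donor/acceptor carbon positions (e.g. Fuc alpha1-6).  For N-linked trees
the root GlcNAc is the residue bonded to the asparagine side-chain
nitrogen.

The packaged representative form - a core-fucosylated bi-antennary
complex glycan with one terminal sialic acid - is the default template
used for grafting throughout the package:

    Asn-GlcNAc(+Fuc a1-6)-GlcNAc-Man-(Man a1-3, Man a1-6),
    each arm GlcNAc(b1-2)-Gal(b1-4), one arm capped Neu5Ac.

Trees are exchanged in a small JSON schema (``nodes`` + ``linkages``);
an IUPAC-condensed text writer is provided for interoperability.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

MONOSACCHARIDES = {"GlcNAc", "Man", "Gal", "Fuc", "Neu5Ac"}

#: single-letter condensed aliases used in the IUPAC-style writer
_SHORT = {"GlcNAc": "GlcNAc", "Man": "Man", "Gal": "Gal", "Fuc": "Fuc", "Neu5Ac": "Neu5Ac"}


class GlycanSchemaError(ValueError):
    """Raised for documents that violate the glycan JSON schema."""


@dataclass(frozen=True)
class GlycanNode:
    node_id: str
    monosaccharide: str

    def __post_init__(self):
        if self.monosaccharide not in MONOSACCHARIDES:
            raise GlycanSchemaError(f"unknown monosaccharide {self.monosaccharide!r}")


@dataclass(frozen=True)
class GlycanLinkage:
    """``parent`` donates the acceptor carbon; ``child`` bonds via its anomeric carbon."""

    parent: str
    child: str
    anomeric: str  # "alpha" | "beta"
    donor: int  # anomeric carbon on the child (1, or 2 for Neu5Ac)
    acceptor: int  # acceptor carbon on the parent (2, 3, 4 or 6)

    def __post_init__(self):
        if self.anomeric not in ("alpha", "beta"):
            raise GlycanSchemaError(f"anomeric must be alpha/beta, got {self.anomeric!r}")
        if self.donor not in (1, 2) or self.acceptor not in (2, 3, 4, 6):
            raise GlycanSchemaError(
                f"unsupported linkage positions {self.donor}-{self.acceptor}"
            )

    @property
    def label(self) -> str:
        return f"{'a' if self.anomeric == 'alpha' else 'b'}{self.donor}-{self.acceptor}"


@dataclass
class GlycanTree:
    """Rooted, acyclic, connected, linkage-labelled glycan."""

    name: str
    nodes: dict[str, GlycanNode]
    linkages: list[GlycanLinkage]
    root: str
    n_linked: bool = True

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.root not in self.nodes:
            raise GlycanSchemaError(f"root {self.root!r} is not a node")
        parent_of: dict[str, str] = {}
        for lk in self.linkages:
            for nid in (lk.parent, lk.child):
                if nid not in self.nodes:
                    raise GlycanSchemaError(f"linkage references unknown node {nid!r}")
            if lk.child in parent_of:
                raise GlycanSchemaError(f"node {lk.child!r} has two parents")
            parent_of[lk.child] = lk.parent
        if self.root in parent_of:
            raise GlycanSchemaError("root must not have a parent")
        # connectivity + acyclicity: walk down from the root
        children: dict[str, list[str]] = {}
        for lk in self.linkages:
            children.setdefault(lk.parent, []).append(lk.child)
        seen = set()
        stack = [self.root]
        while stack:
            nid = stack.pop()
            if nid in seen:
                raise GlycanSchemaError("cycle detected")
            seen.add(nid)
            stack.extend(children.get(nid, []))
        if seen != set(self.nodes):
            raise GlycanSchemaError("tree is not connected")
        if self.n_linked and self.nodes[self.root].monosaccharide != "GlcNAc":
            raise GlycanSchemaError("N-linked tree root must be GlcNAc")

    # -- queries ---------------------------------------------------------

    def children(self, node_id: str) -> list[GlycanLinkage]:
        return sorted(
            (lk for lk in self.linkages if lk.parent == node_id),
            key=lambda lk: lk.acceptor,
        )

    def leaves(self) -> list[str]:
        parents = {lk.parent for lk in self.linkages}
        return [nid for nid in self.nodes if nid not in parents]

    def topological_order(self) -> list[str]:
        order, stack = [], [self.root]
        while stack:
            nid = stack.pop()
            order.append(nid)
            stack.extend(lk.child for lk in reversed(self.children(nid)))
        return order

    def __len__(self) -> int:
        return len(self.nodes)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GlycanTree):
            return NotImplemented
        return (
            self.name == other.name
            and self.nodes == other.nodes
            and sorted(self.linkages, key=lambda lk: (lk.parent, lk.child))
            == sorted(other.linkages, key=lambda lk: (lk.parent, lk.child))
            and self.root == other.root
            and self.n_linked == other.n_linked
        )

    # -- serialization ---------------------------------------------------

    def to_document(self) -> dict:
        return {
            "name": self.name,
            "n_linked": self.n_linked,
            "root": self.root,
            "nodes": [
                {"id": n.node_id, "monosaccharide": n.monosaccharide}
                for n in self.nodes.values()
            ],
            "linkages": [
                {
                    "parent": lk.parent,
                    "child": lk.child,
                    "anomeric": lk.anomeric,
                    "donor": lk.donor,
                    "acceptor": lk.acceptor,
                }
                for lk in self.linkages
            ],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_document(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def iupac_condensed(self) -> str:
        """IUPAC-condensed-style one-line form, children ordered by acceptor carbon."""

        def render(nid: str) -> str:
            kids = self.children(nid)
            prefix = ""
            for lk in kids:
                sub = render(lk.child)
                prefix += f"{sub}({lk.label})" if not prefix else f"[{sub}({lk.label})]"
            return prefix + _SHORT[self.nodes[nid].monosaccharide]

        return render(self.root)


def parse_tree(document) -> GlycanTree:
    """Parse and validate a glycan JSON document (dict, JSON string, or path)."""
    if isinstance(document, (str, Path)) and not str(document).lstrip().startswith("{"):
        document = json.loads(Path(document).read_text())
    elif isinstance(document, str):
        document = json.loads(document)
    if not isinstance(document, dict):
        raise GlycanSchemaError("glycan document must be a JSON object")
    for key in ("name", "root", "nodes", "linkages"):
        if key not in document:
            raise GlycanSchemaError(f"missing key {key!r}")
    nodes = {}
    for nd in document["nodes"]:
        node = GlycanNode(node_id=str(nd["id"]), monosaccharide=nd["monosaccharide"])
        if node.node_id in nodes:
            raise GlycanSchemaError(f"duplicate node id {node.node_id!r}")
        nodes[node.node_id] = node
    linkages = [
        GlycanLinkage(
            parent=str(lk["parent"]),
            child=str(lk["child"]),
            anomeric=lk["anomeric"],
            donor=int(lk["donor"]),
            acceptor=int(lk["acceptor"]),
        )
        for lk in document["linkages"]
    ]
    return GlycanTree(
        name=document["name"],
        nodes=nodes,
        linkages=linkages,
        root=str(document["root"]),
        n_linked=bool(document.get("n_linked", True)),
    )


def composition(tree: GlycanTree) -> dict[str, int]:
    """Multiset counts per monosaccharide (zero for absent sugars)."""
    counts = Counter(n.monosaccharide for n in tree.nodes.values())
    return {m: counts.get(m, 0) for m in sorted(MONOSACCHARIDES)}


def load_representative_tree() -> GlycanTree:
    """The packaged representative N-glycan: core-fucosylated, bi-antennary,
    one terminal Neu5Ac (recorded as alpha2-6; alpha2-3 is a config override)."""
    doc = resources.files("glycoshield.data").joinpath("glycan_representative.json")
    return parse_tree(json.loads(doc.read_text()))


# ---------------------------------------------------------------------------
# rigid template geometry


@dataclass(frozen=True)
class MonosaccharideTemplate:
    """Idealized rigid heavy-atom geometry for one sugar ring.

    The pyranose ring is modelled as a planar hexagon of six heavy atoms
    with uniform 1.52 A bonds (within the 1.3-1.6 A band expected for
    ring bonds), anchored at the anomeric carbon, plus an exocyclic C6
    used as the acceptor for 1-6 linkages.  Flexibility downstream is
    torsion-only; templates never deform.
    """

    monosaccharide: str
    atom_names: tuple[str, ...]
    coords: np.ndarray  # (n_atoms, 3), anomeric carbon at the origin

    BOND_RING = 1.52
    BOND_GLYCOSIDIC = 1.43
    BOND_ASN = 1.45

    def atom_index(self, name: str) -> int:
        return self.atom_names.index(name)

    @property
    def anomeric_atom(self) -> str:
        return self.atom_names[0]


def _hexagon_template(mono: str, anomeric_label: str) -> MonosaccharideTemplate:
    side = MonosaccharideTemplate.BOND_RING
    # hexagon in the xz-plane, anomeric carbon at the origin, ring
    # extending toward +x; tilt keeps the incoming bond off the ring plane
    names = [anomeric_label] + [f"R{i}" for i in range(2, 6)] + ["O5", "C6"]
    angles = np.deg2rad(np.arange(6) * 60.0)
    ring = np.stack(
        [side - side * np.cos(angles), np.zeros(6), side * np.sin(angles)], axis=1
    )
    # exocyclic C6 off ring atom R5 (index 4), pointing outward
    direction = ring[4] - ring.mean(axis=0)
    c6 = ring[4] + side * direction / np.linalg.norm(direction)
    coords = np.vstack([ring, c6])
    return MonosaccharideTemplate(
        monosaccharide=mono, atom_names=tuple(names), coords=coords
    )


def template_for(mono: str) -> MonosaccharideTemplate:
    if mono not in MONOSACCHARIDES:
        raise GlycanSchemaError(f"unknown monosaccharide {mono!r}")
    # Neu5Ac links through C2; hexoses through C1
    return _hexagon_template(mono, "C2" if mono == "Neu5Ac" else "C1")


#: acceptor-position -> template atom carrying the glycosidic oxygen
ACCEPTOR_ATOMS = {2: "R2", 3: "R3", 4: "R4", 6: "C6"}
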