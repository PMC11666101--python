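"""Sequon discovery and cross-isoform conservation mapping.

An N-linked glycosylation sequon is the tripeptide motif ``NX[S/T]`` where
``X`` is any residue except proline; the asparagine is the attachment
residue.  This module scans isoform sequences for sequons, aligns isoform
families, and groups sequons whose asparagines share an alignment column
into conserved-in-all / shared-by-subset / isoform-unique classes.

Residue positions are 1-based throughout (UniProt convention), so a site
reported as ``N291`` means ``sequence[290] == 'N'``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import biotite.sequence as bseq
import biotite.sequence.align as balign

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
#: residues accepted in input sequences; X is tolerated but never matches
#: any motif position (conservative treatment of ambiguity)
VALID_RESIDUES = AMINO_ACIDS | {"X"}

_SEQUON_RE = re.compile(r"(?=(N[^PX][ST]))")

# pinned alignment parameters: BLOSUM62, affine gaps (open 10, extend 0.5)
GAP_OPEN = -10.0
GAP_EXTEND = -0.5


class SequenceError(ValueError):
    """Raised for malformed sequence input."""


@dataclass(frozen=True)
class IsoformSequence:
    """One isoform's amino-acid sequence.

    ``residues`` holds one-letter codes; positions are 1-based.
    """

    isoform_id: str
    accession: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise SequenceError(f"{self.isoform_id}: empty sequence")
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise SequenceError(
                f"{self.isoform_id}: non-amino-acid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def residue_at(self, position: int) -> str:
        """One-letter code at a 1-based position."""
        if not 1 <= position <= len(self.residues):
            raise SequenceError(
                f"{self.isoform_id}: position {position} outside 1..{len(self.residues)}"
            )
        return self.residues[position - 1]


@dataclass(frozen=True)
class Sequon:
    """A single NX[S/T] motif occurrence.

    ``asn_position`` is the 1-based index of the asparagine.  ``resolved``
    marks sites that carry a resolved glycan moiety in a cryo-EM
    structure; ``region`` is an optional named-region label.
    """

    isoform_id: str
    asn_position: int
    motif: str
    resolved: bool = False
    region: str | None = None

    def __post_init__(self):
        if len(self.motif) != 3 or self.motif[0] != "N":
            raise ValueError(f"invalid sequon motif {self.motif!r}")
        if self.motif[1] == "P" or self.motif[2] not in "ST":
            raise ValueError(f"invalid sequon motif {self.motif!r}")


@dataclass(frozen=True)
class RegionAnnotation:
    """Named 1-based inclusive residue ranges on one isoform (ECTLs, VSDs, ...)."""

    isoform_id: str
    regions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def range_of(self, name: str) -> tuple[int, int]:
        if name not in self.regions:
            raise KeyError(f"unknown region {name!r} for {self.isoform_id}")
        return self.regions[name]


@dataclass
class SequonGroup:
    """Sequons from several isoforms whose N residues share one alignment column."""

    group_id: int
    column: int
    members: list[tuple[str, int]]  # (isoform_id, asn_position)
    cls: str  # "all" | "subset" | "unique"
    isoforms: frozenset[str]


@dataclass
class ConservationMap:
    """Partition of the considered sequons into alignment-column groups."""

    groups: list[SequonGroup]
    isoform_ids: list[str]

    def groups_of_class(self, cls: str) -> list[SequonGroup]:
        return [g for g in self.groups if g.cls == cls]

    def to_frame(self):
        import pandas as pd

        rows = []
        for g in self.groups:
            label = "unique" if g.cls == "unique" else g.cls
            for iso, pos in g.members:
                rows.append(
                    {
                        "group_id": g.group_id,
                        "class": label,
                        "isoform": iso,
                        "asn_position": pos,
                    }
                )
        return pd.DataFrame(rows, columns=["group_id", "class", "isoform", "asn_position"])


def scan_sequons(
    seq: IsoformSequence,
    resolved_positions: set[int] | None = None,
    annotation: RegionAnnotation | None = None,
) -> list[Sequon]:
    """Find every NX[S/T] sequon (X != P) in a sequence.

    Overlapping motifs are each reported; ``X`` residues never satisfy any
    motif position.  Returns sequons sorted by asparagine position.
    """
    resolved_positions = resolved_positions or set()
    out = []
    for m in _SEQUON_RE.finditer(seq.residues):
        pos = m.start() + 1
        motif = m.group(1)
        region = None
        if annotation is not None:
            for name, (lo, hi) in annotation.regions.items():
                if lo <= pos <= hi:
                    region = name
                    break
        out.append(
            Sequon(
                isoform_id=seq.isoform_id,
                asn_position=pos,
                motif=motif,
                resolved=pos in resolved_positions,
                region=region,
            )
        )
    return out


class MultipleAlignment:
    """A gapped multiple alignment over a fixed list of isoform sequences.

    Wraps the per-sequence trace (column -> 0-based residue index, -1 for
    gap) and exposes the column lookup the conservation mapper needs.
    """

    def __init__(self, sequences: list[IsoformSequence], trace: np.ndarray):
        if trace.ndim != 2 or trace.shape[1] != len(sequences):
            raise ValueError("trace shape does not match sequence count")
        self.sequences = list(sequences)
        self.trace = trace
        self._index = {s.isoform_id: i for i, s in enumerate(sequences)}
        # column_of[i] maps 0-based residue index -> column
        self._col_of: list[np.ndarray] = []
        for i, s in enumerate(sequences):
            cols = np.full(len(s.residues), -1, dtype=int)
            mask = trace[:, i] >= 0
            cols[trace[mask, i]] = np.nonzero(mask)[0]
            if (cols < 0).any():
                raise ValueError(f"alignment does not cover {s.isoform_id}")
            self._col_of.append(cols)

    @property
    def n_columns(self) -> int:
        return self.trace.shape[0]

    def column_of(self, isoform_id: str, position: int) -> int:
        """Alignment column (0-based) of a 1-based residue position."""
        i = self._index[isoform_id]
        if not 1 <= position <= len(self.sequences[i].residues):
            raise ValueError(
                f"position {position} outside {isoform_id} (1..{len(self.sequences[i].residues)})"
            )
        return int(self._col_of[i][position - 1])

    def gapped_rows(self) -> dict[str, str]:
        rows = {}
        for i, s in enumerate(self.sequences):
            chars = []
            for c in range(self.trace.shape[0]):
                j = self.trace[c, i]
                chars.append(s.residues[j] if j >= 0 else "-")
            rows[s.isoform_id] = "".join(chars)
        return rows

    def identity_columns(self) -> int:
        """Number of gap-free columns where all sequences agree."""
        n = 0
        for c in range(self.trace.shape[0]):
            js = self.trace[c]
            if (js < 0).any():
                continue
            chars = {self.sequences[i].residues[j] for i, j in enumerate(js)}
            if len(chars) == 1:
                n += 1
        return n

    def to_clustal(self) -> str:
        rows = self.gapped_rows()
        width = 60
        lines = ["CLUSTAL format alignment (glycoshield)", ""]
        ncol = self.n_columns
        for start in range(0, ncol, width):
            for iso, row in rows.items():
                lines.append(f"{iso:<16}{row[start:start + width]}")
            lines.append("")
        return "\n".join(lines)


def align_isoforms(seqs: list[IsoformSequence]) -> MultipleAlignment:
    """Progressive multiple alignment (BLOSUM62, affine gaps 10/0.5).

    Deterministic for fixed inputs.  Degapping any aligned row reproduces
    the input sequence exactly.
    """
    if len(seqs) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    # biotite's protein alphabet has no 'X'; substitute with a neutral
    # residue for scoring only - the trace refers back to the originals.
    prot = [bseq.ProteinSequence(s.residues.replace("X", "A")) for s in seqs]
    matrix = balign.SubstitutionMatrix.std_protein_matrix()
    alignment, *_ = balign.align_multiple(
        prot, matrix, gap_penalty=(GAP_OPEN, GAP_EXTEND)
    )
    return MultipleAlignment(seqs, np.asarray(alignment.trace))


def map_conserved_sequons(
    msa: MultipleAlignment,
    sequons: dict[str, list[Sequon]],
    resolved_only: bool = False,
) -> ConservationMap:
    """Group sequons whose asparagines occupy the same alignment column.

    Two sequons are homologous iff their N residues share a column (no
    positional fuzz).  Group class is ``all`` when every isoform in the
    alignment is present, ``unique`` for a single isoform, else
    ``subset``.  With ``resolved_only`` set, groups are *seeded* only from
    resolved sites, but membership testing spans all sequons, so an
    unresolved sequon aligned to a resolved one still joins its group.
    """
    isoform_ids = [s.isoform_id for s in msa.sequences]
    known = set(isoform_ids)
    by_column: dict[int, list[Sequon]] = {}
    for iso, sqs in sequons.items():
        if iso not in known:
            raise ValueError(f"isoform {iso!r} not in alignment")
        for sq in sqs:
            col = msa.column_of(iso, sq.asn_position)
            by_column.setdefault(col, []).append(sq)

    groups = []
    for col in sorted(by_column):
        members = by_column[col]
        if resolved_only and not any(sq.resolved for sq in members):
            continue
        isoforms = frozenset(sq.isoform_id for sq in members)
        if len(isoforms) == 1:
            cls = "unique"  # takes precedence for single-isoform alignments
        elif isoforms == frozenset(isoform_ids):
            cls = "all"
        else:
            cls = "subset"
        groups.append(
            SequonGroup(
                group_id=len(groups),
                column=col,
                members=sorted((sq.isoform_id, sq.asn_position) for sq in members),
                cls=cls,
                isoforms=isoforms,
            )
        )
    return ConservationMap(groups=groups, isoform_ids=isoform_ids)


def count_region_sequons(
    seq: IsoformSequence, annotation: RegionAnnotation, region: str
) -> int:
    """Number of sequon start (Asn) positions inside a named region."""
    lo, hi = annotation.range_of(region)
    return sum(lo <= sq.asn_position <= hi for sq in scan_sequons(seq))


def apply_substitution(seq: IsoformSequence, position: int, mutant: str) -> IsoformSequence:
    """Return a copy of ``seq`` with a single-residue substitution."""
    if mutant not in AMINO_ACIDS:
        raise SequenceError(f"invalid mutant residue {mutant!r}")
    if not 1 <= position <= len(seq.residues):
        raise SequenceError(f"position {position} outside sequence")
    residues = seq.residues[: position - 1] + mutant + seq.residues[position:]
    return replace(seq, residues=residues)
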