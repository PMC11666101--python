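"""Shared format I/O: FASTA, PDB/mmCIF structures, CSV/JSON reports.

FASTA description lines are parsed as ``isoform_id|accession``; a bare
identifier is accepted and leaves the accession empty.  Structures go
through biotite's ``AtomArray`` containers; conformer ensembles are
written as multi-model PDB (one MODEL per frame).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio
import biotite.structure.io.pdbx as pdbxio

from glycoshield.seq_sites import IsoformSequence, MultipleAlignment


# -- sequences --------------------------------------------------------------


def read_fasta(path) -> list[IsoformSequence]:
    seqs = []
    header, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if header is not None:
                    seqs.append(_make_seq(header, chunks))
                header, chunks = line[1:].strip(), []
            elif line:
                chunks.append(line)
    if header is not None:
        seqs.append(_make_seq(header, chunks))
    return seqs


def _make_seq(header: str, chunks: list[str]) -> IsoformSequence:
    first = header.split()[0]
    isoform_id, _, accession = first.partition("|")
    return IsoformSequence(
        isoform_id=isoform_id, accession=accession, residues="".join(chunks).upper()
    )


def write_fasta(seqs: list[IsoformSequence], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            label = f"{s.isoform_id}|{s.accession}" if s.accession else s.isoform_id
            fh.write(f">{label}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


def write_alignment_fasta(msa: MultipleAlignment, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for iso, row in msa.gapped_rows().items():
            fh.write(f">{iso}\n")
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")


def write_alignment_clustal(msa: MultipleAlignment, path) -> None:
    Path(path).write_text(msa.to_clustal())


# -- structures -------------------------------------------------------------


def read_structure(path) -> struc.AtomArray:
    """Read a PDB or mmCIF file into an AtomArray (first model)."""
    path = Path(path)
    if path.suffix.lower() in (".cif", ".mmcif"):
        f = pdbxio.CIFFile.read(path)
        return pdbxio.get_structure(f, model=1)
    f = pdbio.PDBFile.read(path)
    return f.get_structure(model=1)


def write_structure(atoms: struc.AtomArray, path) -> None:
    f = pdbio.PDBFile()
    f.set_structure(atoms)
    f.write(Path(path))


def write_multimodel_pdb(frames: list[struc.AtomArray], path) -> None:
    """One MODEL record per frame; all frames must share the atom layout."""
    stack = struc.stack(frames)
    f = pdbio.PDBFile()
    f.set_structure(stack)
    f.write(Path(path))


# -- reports ----------------------------------------------------------------


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify))


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (set, frozenset)):
        return sorted(x)
    raise TypeError(f"cannot serialize {type(x)}")


def write_conservation_csv(cmap, sequons, path) -> None:
    """ConservationMap as CSV: group_id, class, isoform, asn_position, motif, resolved."""
    lookup = {
        (sq.isoform_id, sq.asn_position): sq
        for sqs in sequons.values()
        for sq in sqs
    }
    with open(path, "w") as fh:
        fh.write("group_id,class,isoform,asn_position,motif,resolved\n")
        for g in cmap.groups:
            for iso, pos in g.members:
                sq = lookup[(iso, pos)]
                fh.write(
                    f"{g.group_id},{g.cls},{iso},{pos},{sq.motif},{int(sq.resolved)}\n"
                )
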