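"""Classification of missense variants by their effect on N-glycosylation sequons.

A substitution destroys a sequon when it hits the glycosylated asparagine
itself (``N-loss``), the serine/threonine at position N+2 (``ST-loss``),
or places a proline at the X position N+1 (``X-to-proline``).  A
substitution can also create a new sequon (``new-motif``).  Classification
is done by applying the substitution and re-scanning the affected window,
so motif semantics (e.g. S->T at N+2 keeps the sequon) fall out for free.

Frameshift and nonsense variants are ingested but classed
``structural``: their clinical outcomes stem from downstream effects on
the protein and carry no sequon-level call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from glycoshield.seq_sites import (
    AMINO_ACIDS,
    IsoformSequence,
    apply_substitution,
    scan_sequons,
)


class VariantDataError(ValueError):
    """Raised when a variant record contradicts the reference sequence."""


@dataclass(frozen=True)
class VariantRecord:
    """One protein-level variant.

    ``kind`` is ``missense`` (default), ``frameshift`` or ``nonsense``;
    only missense variants receive a sequon-level call.
    """

    isoform_id: str
    wild: str
    position: int
    mutant: str
    phenotype: str = ""
    source: str = ""
    kind: str = "missense"
    clinical_class: str = "pathogenic"

    @property
    def label(self) -> str:
        suffix = {"frameshift": "fs", "nonsense": "*"}.get(self.kind, self.mutant)
        return f"{self.wild}{self.position}{suffix}"


@dataclass(frozen=True)
class VariantEffect:
    """Sequon-level consequence of a variant.

    ``cls`` is ``disrupting`` | ``creating`` | ``silent`` | ``structural``
    (summary class: disrupting takes precedence when a variant both
    destroys one sequon and creates another).  ``lost`` / ``gained`` list
    the asparagine positions of destroyed / created sequons.
    """

    cls: str
    lost: tuple[int, ...] = ()
    gained: tuple[int, ...] = ()
    mechanism: str = "none"

    @property
    def affected_sequon(self) -> int | None:
        if self.lost:
            return self.lost[0]
        if self.gained:
            return self.gained[0]
        return None


def _mechanism(variant: VariantRecord, lost_asn: int) -> str:
    if variant.position == lost_asn:
        return "N-loss"
    if variant.position == lost_asn + 2:
        return "ST-loss"
    if variant.position == lost_asn + 1 and variant.mutant == "P":
        return "X-to-proline"
    return "none"


def classify_variant(seq: IsoformSequence, variant: VariantRecord) -> VariantEffect:
    """Classify one variant by mutate-and-rescan of the +-2 window."""
    wild_at = seq.residue_at(variant.position)
    if wild_at != variant.wild:
        raise VariantDataError(
            f"{variant.isoform_id} {variant.label}: reference has "
            f"{wild_at!r} at {variant.position}, record says {variant.wild!r}"
        )
    if variant.kind != "missense":
        return VariantEffect(cls="structural")
    if variant.mutant not in AMINO_ACIDS or variant.wild == variant.mutant:
        raise VariantDataError(f"invalid substitution {variant.label}")

    mutant_seq = apply_substitution(seq, variant.position, variant.mutant)
    window = range(max(1, variant.position - 2), variant.position + 1)
    wild_starts = {
        s.asn_position for s in scan_sequons(seq) if s.asn_position in window
    }
    mut_starts = {
        s.asn_position for s in scan_sequons(mutant_seq) if s.asn_position in window
    }
    lost = tuple(sorted(wild_starts - mut_starts))
    gained = tuple(sorted(mut_starts - wild_starts))

    if lost:
        return VariantEffect(
            cls="disrupting", lost=lost, gained=gained,
            mechanism=_mechanism(variant, lost[0]),
        )
    if gained:
        return VariantEffect(cls="creating", gained=gained, mechanism="new-motif")
    return VariantEffect(cls="silent")


def build_variant_report(
    seq: IsoformSequence, variants: list[VariantRecord]
) -> pd.DataFrame:
    """One row per variant with effect class, affected sequon, mechanism."""
    rows = []
    for v in variants:
        eff = classify_variant(seq, v)
        rows.append(
            {
                "isoform": v.isoform_id,
                "variant": v.label,
                "class": eff.cls,
                "affected_sequon": eff.affected_sequon,
                "lost": ";".join(map(str, eff.lost)),
                "gained": ";".join(map(str, eff.gained)),
                "mechanism": eff.mechanism,
                "phenotype": v.phenotype,
                "source": v.source,
                "clinical_class": v.clinical_class,
                "flagged_benign": v.clinical_class.lower().startswith("benign")
                or v.clinical_class.lower().startswith("likely benign"),
            }
        )
    columns = [
        "isoform", "variant", "class", "affected_sequon", "lost", "gained",
        "mechanism", "phenotype", "source", "clinical_class", "flagged_benign",
    ]
    return pd.DataFrame(rows, columns=columns)


def disrupting_count(report: pd.DataFrame) -> int:
    return int((report["class"] == "disrupting").sum())


def read_variants_csv(path) -> list[VariantRecord]:
    """Read a variant table.

    Expected columns: ``isoform``, then either ``hgvs_p`` (e.g. ``S340F``,
    ``N1392fs``) or ``wild``/``position``/``mutant``; optional
    ``phenotype``, ``source``, ``clinical_class``.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    records = []
    for _, row in df.iterrows():
        kind = "missense"
        if "hgvs_p" in df.columns and row.get("hgvs_p"):
            h = row["hgvs_p"].strip()
            wild, rest = h[0], h[1:]
            if rest.endswith("fs"):
                kind, pos, mutant = "frameshift", int(rest[:-2]), wild
            elif rest.endswith("*"):
                kind, pos, mutant = "nonsense", int(rest[:-1]), wild
            else:
                pos, mutant = int(rest[:-1]), rest[-1]
        else:
            wild = row["wild"]
            pos = int(row["position"])
            mutant = row["mutant"]
            kind = row.get("kind", "missense") or "missense"
        records.append(
            VariantRecord(
                isoform_id=row["isoform"],
                wild=wild,
                position=pos,
                mutant=mutant,
                phenotype=row.get("phenotype", ""),
                source=row.get("source", ""),
                kind=kind,
                clinical_class=row.get("clinical_class", "pathogenic") or "pathogenic",
            )
        )
    return records
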