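#!/usr/bin/env python
"""Clinical-variant report: sequon-disrupting mutations and their pathologies.

Classifies the packaged pathogenic variant lists (Dravet syndrome on
Na_V1.1, Brugada syndrome on Na_V1.5, developmental delay/seizures on
Na_V1.6, plus the Na_V1.1 frameshifts) against the documented sequon
positions and writes results/variant_report.csv.

Expected: 7 / 2 / 1 sequon-disrupting missense calls on Na_V1.1 /
Na_V1.5 / Na_V1.6; frameshifts are classed structural (no sequon call).
"""

import argparse
from pathlib import Path

import pandas as pd

from glycoshield.synthetic_data import load_reference_tables, make_isoform_context
from glycoshield.variant_glyco import build_variant_report, disrupting_count

parser = argparse.ArgumentParser()
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

tables = load_reference_tables()
reports = []
for iso in ("NaV1.1", "NaV1.5", "NaV1.6"):
    ctx = make_isoform_context(iso)
    records = [v for v in tables.variants if v.isoform_id == iso]
    report = build_variant_report(ctx, records)
    n_missense = sum(r.kind == "missense" for r in records)
    print(f"{iso}: {len(records)} variants ({n_missense} missense), "
          f"{disrupting_count(report)} sequon-disrupting")
    reports.append(report)

out = pd.concat(reports, ignore_index=True)
out.to_csv(args.outdir / "variant_report.csv", index=False)
print(f"wrote {args.outdir}/variant_report.csv")
print(out[["isoform", "variant", "class", "affected_sequon", "mechanism", "phenotype"]]
      .to_string(index=False))
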