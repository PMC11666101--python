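# glycoshield

Structural analysis of N-linked glycan shielding on voltage-gated sodium
(Na_V) channel alpha-subunits.

Na_V channels (Na_V1.1–1.9) carry N-glycans on their extracellular
turret loops at canonical sequons `NX[S/T]` (X ≠ P). Cryo-EM structures
resolve only the first sugar ring at each site, so the conformational
envelope of the full glycan trees — and what that envelope covers — is
easy to underestimate. This package asks, with desk-scale models, the
questions that follow from that envelope: which sequons are conserved
across isoforms and which are isoform-specific; whether glycan density
occludes the binding footprints of the regulatory β-subunit Ig-domains
(β1 on the domain-III VSD and ECTL I/IV; β2/β4 on the domain-II ECTL)
or the ion-conduction path above the pore; how far a trans β1–β1
Ig-domain dimer can bridge two opposed membranes (the cardiomyocyte
perinexal cleft, 15–30 nm); and which pathogenic missense variants act
by destroying a sequon — at the asparagine itself, at the S/T in
position N+2, or by placing a proline at N+1.

It is aimed at structural bioinformaticians and ion-channel biologists
who want these quantities reproducible from code rather than read off
rendered figures.

## What's inside

| module | role |
| --- | --- |
| `seq_sites` | sequon scanning, isoform alignment (BLOSUM62, affine 10/0.5), conservation mapping by alignment column |
| `variant_glyco` | mutate-and-rescan variant classifier (`N-loss` / `ST-loss` / `X-to-proline` / `new-motif`), pathology report tables |
| `glycan_tree` | linkage-labelled glycan trees (JSON schema, IUPAC-condensed export), packaged core-fucosylated bi-antennary tree with one terminal Neu5Ac, rigid ring templates |
| `graft_sample` | template grafting onto Asn side chains; torsional Metropolis Monte Carlo over glycosidic φ/ψ(/ω) with hard-sphere-soft-core excluded volume and a membrane slab — 30 clash-free snapshots per run (the 150 ns / 5 ns MD-sampling analog) |
| `occupancy_occlusion` | voxel occupancy grids, interface-footprint extraction, per-region coverage and blocked/partial/accessible verdicts, pore-cylinder checks |
| `trans_bridge` | tip-to-tip and side-to-side β1-Ig trans dimers, closed-form maximum membrane separation, coarse bead-spring constant-velocity pulling to rupture |
| `synthetic_data` | deterministic generators: nine-isoform family with planted sequon conservation, toy helical-bundle channels with loop-borne glycosites, toy α/partner complexes, β1-scale toy Ig; packaged variant/site/membrane tables |
| `pipeline`, `config`, `cli` | end-to-end runs, pinned provenance-tagged parameters, `glycoshield` command line |

Everything runs without downloads: the synthetic study system carries
the documented site architecture (in Na_V1.5 numbering), and real
FASTA/PDB inputs go through the same code paths when supplied.

## Worked example

Classify the packaged pathogenic variant lists and report the two
trans-bridge distances:

```bash
python analysis/02_variant_report.py
python analysis/05_trans_bridge.py
```

prints (abridged):

```
NaV1.1: 10 variants (7 missense), 7 sequon-disrupting
NaV1.5: 2 variants (2 missense), 2 sequon-disrupting
NaV1.6: 1 variants (1 missense), 1 sequon-disrupting
 NaV1.1   S340F disrupting   338  ST-loss       Dravet syndrome
 NaV1.1   H1393P disrupting  1392 X-to-proline  Dravet syndrome
 NaV1.1   N1392fs structural   —  none          Dravet syndrome
 NaV1.5   T320N disrupting    318 ST-loss       Brugada syndrome
...
toy Ig: 104 residues, long axis 4.14 nm
tip-to-tip: max extension 19.62 nm, rupture at 19.09 nm (4 contacts)
side-to-side: max extension 15.03 nm, rupture at 14.89 nm (48 contacts)
```

Reading this: all seven Dravet-syndrome missense variants on Na_V1.1
destroy a sequon (S340F removes the hydroxyl of the N338 motif; H1393P
places a proline at the X position of N1392), while the three
frameshifts are classed `structural` — no sequon-level call. The two
membrane-bridging geometries both land inside the 15–30 nm perinexal
window, tip-to-tip reaching farther than side-to-side, and every
bead-spring rupture stays below its closed-form geometric maximum.

The numbered scripts under `analysis/` run the remaining stages —
`01_sequon_conservation.py` (3 conserved-in-all sequon columns at
Na_V1.5 N291/N1365/N1380; 7 motifs in the Na_V1.4 ECTL I; 4
Na_V1.5-unique sites), `03_graft_and_sample.py` (30-frame clash-free
conformer ensemble, multi-model PDB), `04_occlusion.py` (a β1-like
footprint loop stays accessible under sparse glycosylation and is
covered under dense glycosylation) — writing their tables under
`results/`.

There is also a CLI for ad-hoc use:

```bash
glycoshield scan my_isoforms.fasta
glycoshield tree info
glycoshield bridge --mode tip --pull
glycoshield run --seed 1 -o out/
```

## Scope notes

The sampler is a geometric stand-in for all-atom MD: no force field, no
solvent, no electrostatics, so observations that depend on energetics
(sialic-acid/VSD attraction, lipid head-group contacts, binding
affinities) are out of scope. Docking is likewise out of scope: dimer
poses are constructed geometrically or supplied as inputs.
Sequence-based glycosylation predictors are deliberately not used.
See `docs/methods.md` for models, parameters and limitations.
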