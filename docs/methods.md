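# Methods

`glycoshield` models how isoform-specific N-linked glycans on
voltage-gated sodium (Na_V) channel alpha-subunits occupy extracellular
space, occlude beta-subunit binding footprints, and constrain
trans-adhesion geometry between opposed membranes. This note records the
models, their assumptions, the tunable parameters, and what the
synthetic study system does and does not establish.

## Sequon discovery and conservation mapping

A sequon is the canonical N-glycosylation motif `NX[S/T]`, X any residue
except proline. Scanning reports every motif occurrence (overlaps
included); the ambiguity code `X` never satisfies any motif position, a
deliberately conservative choice. Positions are 1-based (UniProt
convention) throughout.

Families are aligned with biotite's progressive multiple alignment
(BLOSUM62, affine gaps: open 10, extend 0.5 — pinned in
`glycoshield.config` so runs are reproducible). Two sequons are
homologous iff their asparagines occupy the same alignment column, with
no positional fuzz. Groups are classed `unique` (one isoform — this
takes precedence, so a single-isoform input classes everything unique),
`all` (every isoform in the alignment), else `subset`. With the
resolved-site filter on, groups are *seeded* only from sequons whose
glycan moiety is structurally resolved, but membership testing spans all
sequons, so an unresolved motif aligned to a resolved one still joins
its group — this is how sites in flexible, unmodelled loops are counted
with their conserved partners.

### Site annotations and known ambiguities

The packaged site table records, in Na_V1.5 numbering: three
conserved-in-all sites (N291, N1365, N1380), a site shared by all
isoforms except Na_V1.7/Na_V1.9 (N328), a site shared by
Na_V1.5/1.7/1.8 (N1388), and per-isoform unique sites (four on Na_V1.5,
two on Na_V1.6, one each on Na_V1.7 and Na_V1.8, the last being the
domain-II site N819). Published descriptions of the Na_V1.5-unique set
are internally inconsistent: one reading lists N283/N318/N1388,
another counts "four on domains I and III", while N328 and N1388 are
separately described as shared. The packaged annotation resolves this
as N283, N288, N318 (domain I) and N1374 (domain III), which is the
only reading consistent with the shared status of N328/N1388 and the
stated count; both readings are noted here rather than silently merged.
Likewise "all four sites — N338, N1378, and N1392" on Na_V1.1 names
three positions for a count of four; the packaged table records the
three named positions.

## Variant classification

A missense variant destroys a sequon when it hits the asparagine
(`N-loss`), the hydroxyl residue at N+2 (`ST-loss`), or places a proline
at N+1 (`X-to-proline`). Classification is mutate-and-rescan: apply the
substitution, re-scan the ±2 window, and diff the sequon starts. Motif
semantics fall out automatically — S→T at N+2 is silent, and a single
substitution can destroy one sequon while creating another (both facts
are reported; `disrupting` takes precedence in the summary class).
Frameshift and nonsense variants are ingested but classed `structural`
with no sequon call: their clinical effect flows through the truncated
protein, not glycosylation. Benign/likely-benign records are ingestible
and flagged, never silently dropped.

The packaged pathology lists are classified against synthetic context
scaffolds: full-length glutamate backgrounds (inert for scanning)
carrying each isoform's documented sequon motifs at their native residue
numbers. The classifier only reads the ±2 window, so residues the
variant lists do not pin down are immaterial; scaffolds are labelled
synthetic in code and data.

## The representative glycan

The packaged tree is the core-fucosylated bi-antennary complex N-glycan
with one terminal sialic acid: Asn–GlcNAc(+Fuc α1-6)–GlcNAc–Man with
α1-3/α1-6 mannose arms, each arm GlcNAc(β1-2)–Gal(β1-4), one arm capped
Neu5Ac — 11 residues (GlcNAc 4, Man 3, Gal 2, Fuc 1, Neu5Ac 1). The
sialic linkage is recorded as α2-6 with α2-3 available as an override;
the published description of the representative form does not fix the
sialic linkage, so the default is a determinism choice, not a claim. Trees are
exchanged in a small JSON schema (nodes + linkages, validated for
single-parent/acyclic/connected/GlcNAc-root) with an IUPAC-condensed
text export; no GlycoCT parser is provided.

## Grafting and conformer sampling

This package replaces all-atom MD with torsional Monte Carlo over
glycosidic dihedrals against a purely repulsive excluded-volume energy.
The claim being reproduced is geometric — the envelope of space
clash-free glycan conformers can occupy — and that envelope is set by
connectivity, sterics and the membrane, which torsional sampling
captures at desk scale. No electrostatics, no solvent, no force field.

Monosaccharides are rigid templates: planar hexagonal six-atom rings
(uniform 1.52 Å bonds, within the 1.3–1.6 Å band) plus an exocyclic C6.
A glycan is built residue-by-residue with natural-extension (NeRF)
placement; each linkage contributes ψ (rotation about the
acceptor-carbon–oxygen bond) and φ (ring spin about the oxygen–anomeric
bond), 1-6 linkages additionally ω; the Asn root contributes two
torsions. Torsion moves therefore preserve every bond length and ring
internal distance exactly.

The energy is hard-sphere-with-soft-core: each heavy-atom pair below
the 2.4 Å cutoff pays `1 + (1 − d/cutoff)²` (intra-glycan 1-2/1-3
neighbors exempt). The unit step makes any clash cost at least 1, so at
the default temperature 0.05 a clash-creating move is effectively never
accepted and every recorded frame is exactly clash-free — with a purely
quadratic penalty, shallow overlaps would be nearly free and frames
would drift into clash. The membrane is a planar slab (two head-group
planes; leaflet lipid composition carried as reporting metadata only);
atoms inside the slab interior, beyond a 3 Å head-group tolerance, pay a
quadratic depth penalty, so accepted frames never penetrate the
membrane.

Sampling is Metropolis: uniform ±30° proposals, one proposal per
torsion per sweep, 5 sweeps between snapshots, 30 snapshots — the
torsional analog of extracting MD frames every 5 ns over 150 ns. The
t=0 graft pose is not counted as a frame. Measured acceptance on the
toy channel is ~0.70, dominated by moves in free space; the temperature
only matters at contact. Fixed seed ⇒ bit-identical ensembles (numpy
PCG64, seed echoed in metadata). If a snapshot arrives with residual
clash, downhill-only recovery moves are attempted (budget 500); on
failure the partial ensemble is returned flagged `partial` rather than
silently degraded.

## Occupancy and occlusion

An ensemble voxelizes into an occupancy grid (default 1 Å voxels):
per-voxel fraction of frames with ≥1 glycan heavy atom. Occlusion of a
region (a VSD surface, an extracellular loop, or an interface
footprint) is scored per residue: the fraction of frames in which any
residue heavy atom lies within 4.5 Å of any glycan atom; residues
contacted in ≥50% of frames count as covered, and coverage = covered
fraction of the region. Verdicts: `blocked` at coverage ≥0.8,
`accessible` at ≤0.2, else `partial`; both boundaries resolve away from
partial, per the operation contract (the alternative tie rule — ties to
partial — appears in the design notes but contradicts the stated
boundary semantics, so the contract wins). The 0.8/0.2 boundaries are
artifact decisions: the underlying observations are visual
("completely covered" vs "exposed"), with no numeric threshold to
inherit.

Interface footprints are extracted from complex structures as the
alpha-chain residues with any heavy atom within 5.0 Å of the partner
chain; an empty footprint warns rather than fails. The pore check
counts frames with any glycan atom inside a cylinder of radius 6 Å
extending 30 Å outward from the extracellular pore mouth along the
membrane normal — the putative conductance path.

## Trans-dimer bridge geometry

The beta1 Ig domain is modelled at domain scale: an idealized CA-only
beta-sandwich (eight 12-residue strands, 3.4 Å rise, two sheets 10 Å
apart; long axis ≈4.1 nm, the dimensions of an Ig fold), explicitly a
synthetic stand-in for the real coordinates. Two trans homodimer modes
are built geometrically: tip-to-tip (distal turns meet, 4.5 Å gap) and
side-to-side (sheet faces pair laterally, 4.7 Å gap); the adhesive
interface is the set of closest-approach residue pairs (<4.8 Å), kept
tight so the contact set is geometrically homogeneous and rupture under
load is cooperative rather than a sliding peel.

The maximum membrane-to-membrane distance is closed-form: dimer span
along the membrane normal + 2 × linker contour + 2 × anchoring offset.
The linker annotation pins the beta1 extracellular topology: Ig domain
ends at residue 144, linker runs 145–154 to the anchor (M154, the
residue the pulling protocol grips), residues 155–159 connect the
anchor to the first transmembrane residue and set the anchoring offset;
contour length 3.63 Å per residue (trans Cα–Cα). On the toy Ig this
gives 19.3 nm (tip-to-tip) and 15.0 nm (side-to-side) — tip ≥ side,
both inside the 15–30 nm perinexal window, and within 1 nm of the
steered-MD-derived values the closed form stands in for (the declared
acceptance band for that comparison is ±2 nm).

The pulling model is bead-spring overdamped Langevin: one bead per
residue, including explicit linker beads initialized as a zigzag with
slack; chain and intra-domain elastic-network bonds (11 Å cutoff —
wide enough to couple the two sheets of the sandwich) are stiff and
additionally length-capped by constraint projection, with dynamic
linker bonds capped at 90% of the trans contour (a peptide chain under
the finite forces at rupture never reaches full contour; the closed
form keeps the full 3.63 Å/residue, so the dynamic system stays
strictly inside the geometric maximum). Interface contacts are harmonic
springs whose total stiffness is shared across contacts; rupture is the
event at which every contact simultaneously exceeds its rest length
+1 Å, and the reported structure is taken a configured number of
recorded frames before rupture. Virtual anchors move at ±5 Å per time
unit (pulling spring 100) — the constant-velocity protocol analog.
Zero velocity never ruptures; stiffer interfaces rupture later; fixed
seed ⇒ bit-reproducible trajectories.

## The synthetic study system

The generators emit every input the pipeline needs, with machine-readable
ground truth, and are deterministic under a fixed seed.

**Sequence family.** Nine members (Na_V1.1–1.9 analogs), 2016 residues,
diverged from a common ancestor at 30% substitution (≈50% pairwise
identity, in the range of the real family). Sequon columns are planted
at the documented Na_V1.5-numbered positions with the documented
conservation pattern, destroyed (N replaced) in non-carrying members,
and flanked by ±5 conserved residues — real channel sequons sit in
locally conserved extracellular-loop blocks, and the flanks both
emulate that and anchor the alignment columns. Background sequons that
arise by chance are scrubbed (N+2 replaced) so the planted table is the
complete inventory and exact counts are meaningful. Indels are *not*
emulated: with insertions the "same column" ground truth would be
ill-defined; alignment gap handling is exercised separately on small
deletion cases. Five extra Na_V1.4 ECTL-I sequons are planted
unresolved (the real loop is flexible and unmodelled in structures),
bringing its region count to seven while keeping resolved-site
statistics faithful.

**Toy channels.** 2·n helices (ideal α-helix CA geometry, crude
interpolated backbone) on a circle around the z-axis (the pore axis),
spanning a 40 Å membrane slab; extracellular loops arc above the outer
plane and carry Asn-Ala-Thr sequons with full Asn side chains at their
apices. Poly-alanine elsewhere keeps files tiny. Regions (toy "ECTL",
"VSD") are annotated per loop/helix.

**Toy complexes.** A straight alpha chain with a designated footprint
and a partner strand placed 4 Å above exactly those residues
(non-footprint residues bent away), so the extracted interface has an
exact expected answer.

**What passing on this system does and does not show.** It shows the
machinery is correct: motif logic, column grouping, clash-free
sampling, coverage accounting, bridge geometry all verified against
independent oracles and planted truth. It does not validate the
biological claims on real channels: real sequences have indels and
length variation; real ECTL loops have irregular geometry, neighbors
and disulfides; glycan–VSD electrostatics (the sialic-acid/VSD
proximity observations) are outside a purely steric model and are
deliberately not acceptance-gated. Runs on user-supplied real FASTA/PDB
inputs use exactly the same code paths.

## Problem sizes and numerics

Default problem sizes: 9 × 2016 residues for the family (alignment
≈7 s); ensembles of 30 frames over 1–4 grafted glycans (87 heavy atoms
per glycan; ≈10–30 s); pulls of ≤120k steps at dt = 5·10⁻⁴ (seconds).
The pull timestep is set by stability of the stiffest aggregate bond
environment (`dt·k_eff/γ < 2`); constraint projection runs 4 Jacobi
iterations per step. Ties, degenerate inputs and failure modes are
explicit: empty footprints warn, unsampleable snapshots yield a
`partial` ensemble, no-rupture pulls return a status rather than a
fabricated distance, and config keys are validated before any compute.

## Reproducing the numbers

`python scripts/acceptance.py --seed <int> --out results/acceptance.json`
re-runs every stage on the packaged inputs and writes the headline
quantities; `analysis/01…05` are narrative drivers for the individual
stages writing tables under `results/`. All randomness flows from the
single seed argument.
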