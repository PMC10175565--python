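# Methods

`metalloc` predicts where zinc ions sit in a protein structure, using
two complementary routes, and ships the evaluation protocol and the
synthetic-data generator needed to test both end to end.

## The geometric predictor

### Probability map

The PDB LINK section declares explicit metal–donor linkages.  For every
zinc in a corpus we collect the set of amino acids it is linked to,
write the multiset as a sorted one-letter string (`CCH` ≡ `CHC`), and
count occurrences over the corpus:

    P(E) = count(E) / Σ_E' count(E')

Three mining rules shape the map: links to water are discarded (water
placement is unreliable and cannot be reproduced a posteriori); zincs
left with fewer than two distinct amino-acid partners are dropped as
weak sites; and each residue contributes one letter regardless of how
many of its atoms are linked, so a bidentate carboxylate counts once.
Modified residues with a standard parent (MSE → MET, …) are mapped to
the parent letter; anything else is skipped with a warning rather than
silently, because silent skipping would bias counts invisibly.
Distance statistics over the retained links (recomputed from
coordinates, not from the optional LINK distance column, using the
population standard deviation) give the 2.2 ± 0.2 Å coordination
distance that motivates the search radius below.

### Residue scoring and site placement

Each potentially coordinating residue is represented by a *reference
point*: its donor atom, or for residues with two equivalent donors
(His, Asp, Glu) the donor midpoint, with the search radius enlarged by
the midpoint–donor distance.  The reference-atom table is:

| residue | reference | residue | reference |
|---|---|---|---|
| CYS | SG | GLN | OE1 |
| HIS | mid(ND1,NE2) | SER | OG |
| ASP | mid(OD1,OD2) | THR | OG1 |
| GLU | mid(OE1,OE2) | TYR | OH |
| ASN | OD1 | MET | SD, LYS: NZ |

A residue's score is the summed probability of every map environment
that is a sub-multiset of the letters observed within the search
radius (default 5.5 Å ≈ 2.5× the 2.2 Å coordination distance),
including the residue's own letter.  A residue surrounded by every
environment in the map therefore scores exactly 1; in practice scores
are in [0, 1).

Residues scoring at least `t × max score` (default t = 0.5) are
grouped by single-linkage connected components at twice the search
radius, and each group places a candidate site at the score-weighted
centroid of its reference points:

    r_site = Σ_i score_i · r_i / Σ_i score_i

An isolated high scorer borrows its own score for the nearest other
reference point, which degenerates the weighted average to their
midpoint.  Finally each candidate is *rescored* from the residues whose
reference points lie within 60% of the search radius (3.3 Å, enlarged
per-residue as before) of the candidate position, and candidates below
`t × best final score` are discarded.  This final pass removes
artifacts of the weighted averaging (sites stranded in empty space
score zero and vanish).

Two behavioral consequences worth knowing:

* Because high scorers are *relative* to the structure's maximum, a
  structure containing sites of very different map probability can
  drop the rarer site below threshold.  The recovery benchmarks
  therefore sample motifs on a balanced schedule, which is also the
  regime the relative threshold was designed for.
* Single-linkage grouping at 11 Å merges sites whose reference-point
  clouds approach within that distance; reference points extend ~3 Å
  from a metal, so distinct sites are only resolved when their metals
  are ≥ ~18 Å apart.  The generator's default site separation is 18 Å
  for this reason.

## The voxel/density predictor

### Voxelization

A 16 Å cubic box at 0.5 Å resolution (32³ voxels) is centered on a
residue's Cα; the box center falls midway between the two central
voxels of each axis, and values are evaluated at voxel centers with no
interpolation, which makes voxelization exactly equivariant under
rotations applied to both atoms and frame.  Eight boolean-masked
channels are painted — aromatic, hydrophobic, positive ionizable,
negative ionizable, h-bond donor, h-bond acceptor, occupancy, metal
chain — using a fixed per-atom rule table (ring atoms of F/Y/W/H are
aromatic; carbons bonded only to C/H are hydrophobic; Lys/Arg head
groups positive; carboxylates negative; backbone N/O and the usual
side-chain heteroatoms donate/accept; every heavy atom paints
occupancy; metal HETATMs paint the metal channel).  Each atom
contributes through the pair-correlation occupancy function

    v(d) = 1 − exp(−(r_vdw / d)^12),  v(0) = 1

with van der Waals radii C 1.70, N 1.55, O 1.52, S 1.80, Zn 1.39 Å,
combined across atoms by per-voxel maximum so channel values stay in
[0, 1].  Hydrogens and waters are excluded.  Target grids paint only
zinc and are binarized above 0.05, giving a ball of ~1.8 Å radius
around each ion.  Training examples balance residues within 12 Å of a
zinc (by Cα) against an equal-sized seeded draw of the rest, each
example randomly rotated before voxelization.

### The segmentation network

The model maps (8, 32, 32, 32) → (1, 32, 32, 32): six same-padded 3-D
convolutions, all with 3-voxel (1.5 Å) filters except the fifth, whose
16-voxel (8 Å) filter aggregates long-range context; ReLU throughout,
dropout p = 0.1 between layers 5 and 6, and a final sigmoid for the
per-voxel zinc probability.  Training minimizes binary cross-entropy
with AdaDelta (ρ = 0.9, ε = 1e-6) under a stepped learning rate
(lr = 0.5, γ = 0.9) and batch size 150.

The implementation is a self-contained numpy/scipy one.  Convolutions
run in the Fourier domain on a shared 48³ zero-padded transform (48 ≥
32 + 16 − 1, so the wide filter costs the same as the narrow ones, and
the circular correlations used for the gradients do not alias because
supports are 32 wide and lags at most ±8); the weight gradient of the
3-voxel layers uses 27 shifted inner products instead, which is
cheaper than per-kernel-pair inverse transforms.  Gradients are
verified against finite differences in the test suite.  The hidden
channel widths are not pinned by the architecture contract and default
to (4, 6, 6, 4, 3), sized so the model trains on a single desk CPU;
the output bias starts at −2 because the target class (zinc voxels,
<1% of a box) is rare.  The learning-rate step interval is
configurable (`lr_step_epochs`): the published schedule decays every
epoch over large-corpus epochs, whereas single-example overfitting
runs hundreds of one-step epochs and needs a proportionally longer
interval to keep the rate from vanishing.

This component is a buildable, smoke-trainable network: nothing here
attempts to reproduce the accuracy of a model trained on hundreds of
thousands of crystallographic environments, and the semantics of the
metal channel at inference (no metal in the input) are undefined
upstream — we paint zeros.

### Grid averaging and ion placement

At inference the Cys/His/Asp/Glu residues (defaults; nearly every zinc
site has one nearby) are voxelized without rotation, predicted
individually, and averaged on a global 0.5 Å grid spanning the
bounding box of all boxes: each global voxel takes the mean of
predicted values within 0.25 Å of it.  Since 0.25 Å is half the grid
spacing, a predicted point can be within range of at most one global
voxel, so the average is computed exactly by nearest-voxel snapping
(a KD-tree path handles larger merge radii).  Voxels with no
contributor are zero with count zero, and averaging never exceeds the
maximum of its inputs.

Ions are placed by thresholding the global density (default p = 0.15),
clustering the surviving voxels by average-linkage agglomerative
clustering with a 7 Å distance cutoff, and placing one ion per cluster
at the probability-weighted voxel centroid; the cluster's maximum
voxel probability is the ion's confidence.  Note that with average
linkage the inter-cluster distance of two compact blobs is essentially
their center separation, independent of the probability threshold:
raising p alone therefore never splits two peaks closer than the
cutoff, and resolving a di-nuclear site a few Å across requires
lowering the cluster cutoff below the peak separation together with a
threshold that separates the density supports.  The site count *is*
non-increasing in p for peaks farther apart than the cutoff, whose
supports shrink independently.

## Evaluation protocol

Matching is binary and clustered at 5 Å: a true site with at least one
prediction within 5 Å counts as one TP (duplicates do not inflate the
count); a true site with none is a FN; the remaining predictions are
agglomerated (average linkage, 5 Å) and each cluster is a single FP.
Precision = TP/(TP+FP), recall = TP/(TP+FN); a zero denominator yields
an explicit undefined marker, never a silent zero.  Spatial accuracy
(MAD) is the mean Euclidean distance over *all* predictions within 5 Å
of a true site — not only the best per site — each contributing its
distance to the nearest site; a prediction within 5 Å of two sites
credits both TPs but contributes one distance.  Densities are compared
with the discretized Jaccard index: both grids binarized above a
threshold, optionally with outer voxel shells trimmed to discard edge
density where the model has incomplete context, and an empty union is
scored 1.0 (both-empty agreement; our convention, since the upstream
protocol never scores zinc-free boxes).

## The synthetic-data generator

Structures are built, not downloaded.  A planted site places the donor
atoms of its motif at the vertices of an ideal tetrahedron (or
octahedron) at 2.2 Å from the metal — the mean LINK coordination
distance — perturbed by isotropic Gaussian noise (study corpora use
σ = 0.1 Å; distance-statistics checks use 0.2 Å, matching the
deposited spread).  Full heavy-atom residues grow outward from each
donor using internal-geometry templates (correct local bond lengths,
ring geometries, and donor pairs; no Ramachandran-valid backbone is
attempted, since every algorithm under test consumes side-chain
geometry, not stereochemistry).  One LINK record per residue–metal
contact carries the realized distance.  Motifs shorter than the
coordination number leave open vertices, as water-completed sites do
(e.g. the three-residue DHH motif on a tetrahedral frame).

Decoy residues — a mix of coordinating and non-coordinating types —
are scattered with no heavy atom within 6 Å of any planted metal, so
test neighborhoods cannot acquire accidental coordination.  Sites are
separated by ≥ 18 Å by default (see the single-linkage note above);
the generator enforces a 10 Å hard floor.  Corpora sample motifs on a
balanced round-robin schedule by default, or with explicit weights
when a frequency-recovery check needs them.  Everything is seeded and
bit-reproducible.

What passing these tests does *not* show: the generator has no crystal
contacts, no symmetry mates, no alternative conformations, no backbone
coordination, no solvent, and its decoys are sparser than a real
protein core.  Recovery at recall 1.0 / MAD ≲ 0.5 Å on this geometry
demonstrates correctness of the machinery, not the accuracy a trained
model or the geometric predictor achieves on deposited structures
(where reported deviations are an order of magnitude larger).

## Benchmark problem sizes

The shipped acceptance script runs, per seed: a 500-site corpus for
link statistics; 10 + 10 structure corpora (map training / held-out
evaluation) for the geometric predictor; a two-site protein for the
oracle density pipeline; 20 voxelized environments for the smoke
training check and 220 single-example steps for the overfit check —
sizes chosen so the whole run completes on one desk CPU in minutes.

## Known limitations

* The geometric predictor's relative threshold and single-linkage
  grouping behave as discussed above on multi-site structures.
* Average-linkage ion placement cannot resolve di-nuclear sites closer
  than the cluster cutoff without tightening the cutoff.
* Agglomerative clustering is quadratic in the number of
  above-threshold voxels; very large or very noisy densities should
  raise the probability threshold first.
* The network is desk-scale by design; its default widths are far
  smaller than a production segmentation model.
* mmCIF input is not supported; only PDB fixed-column format.
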