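# metalloc

Zinc-ion location prediction in protein structures, two ways:

* **Geometric predictor** — mines PDB LINK records into a probability
  map of coordination environments (sorted one-letter codes such as
  `CCHH`), scores every potentially coordinating residue by the summed
  probability of environments compatible with its neighborhood (5.5 Å
  search radius), clusters high scorers, places a candidate metal at
  the score-weighted centroid of their reference points,

      r_site = Σ_i score_i · r_i / Σ_i score_i ,

  and rescores each candidate within 60% of the search radius (3.3 Å)
  to discard implausible placements.

* **Voxel/density predictor** — paints residue-centered 16 Å boxes
  (0.5 Å grid, 32³ voxels, 8 pharmacophore channels) with the
  pair-correlation occupancy function v(d) = 1 − exp(−(r_vdw/d)¹²),
  runs them through a fully-convolutional 3-D segmentation network
  (3-voxel filters except an 8 Å filter at layer 5, sigmoid per-voxel
  zinc probability; implemented in pure numpy/scipy with FFT-domain
  convolutions and AdaDelta training at desk scale), averages the
  per-residue probability boxes on a global grid, and places one ion
  per average-linkage cluster of high-probability voxels (p > 0.15,
  7 Å cutoff) at the probability-weighted centroid.

Both feed a shared benchmark protocol: predictions within 5 Å of an
experimental site count once as a true positive, missed sites are
false negatives, stray predictions are clustered at 5 Å and counted
once per cluster; precision = TP/(TP+FP), recall = TP/(TP+FN), and the
MAD is the mean distance of all matched predictions.  Densities are
compared with a discretized Jaccard index.  A synthetic metalloprotein
generator (ideal tetrahedral/octahedral zinc sites at 2.2 Å donor
distances, correct LINK records, decoy residues, Gaussian density
fixtures) makes every stage testable without downloading a single
structure.

The package is aimed at people building or evaluating metal-site
predictors and metalloprotein design pipelines who need a transparent,
fully seeded reference implementation of this family of methods.

## Worked example

```bash
# a training corpus of three synthetic zinc proteins
mkdir -p scratch/corpus
metalloc synth --sites CCCC      --decoys 8 --seed 40 --out scratch/corpus/t0.pdb
metalloc synth --sites CCHH      --decoys 8 --seed 41 --out scratch/corpus/t1.pdb
metalloc synth --sites CCCC,CCHH --decoys 8 --seed 42 --out scratch/corpus/t2.pdb

# mine their LINK records into a probability map
metalloc build-map --pdb-dir scratch/corpus --out scratch/map.tsv
metalloc link-stats --pdb-dir scratch/corpus

# predict on a held-out structure and score the result
metalloc synth --sites CCHH,CCCC --decoys 10 --seed 99 --out scratch/eval.pdb
metalloc predict-1d --pdb scratch/eval.pdb --map scratch/map.tsv \
    --out scratch/sites.pdb --report scratch/sites.tsv
metalloc evaluate --predictions scratch/sites.pdb --reference scratch/eval.pdb \
    --out scratch/report.json
```

`link-stats` prints the metal–donor distances mined from the corpus —
`{"mean": 2.2001, "std": 0.0004, "n": 16}` for noiseless sites: the
generator plants donors at exactly 2.2 Å and the residual 0.0004 Å
spread is PDB 3-decimal coordinate rounding.  `build-map` reports
`# n_environments = 2` / `# total_count = 4` (the corpus contains the
motifs CCCC and CCHH).  The prediction step logs
`# predicted 2 sites`, and the final report reads

```json
{"tp": 2, "fp": 0, "fn": 0, "precision": 1.0, "recall": 1.0,
 "mad_mean": 0.205, "mad_std": 0.205, "mad_median": 0.205, "n_distances": 2}
```

— both planted zincs recovered: the CCCC site essentially exactly
(the score-weighted centroid of a symmetric Cys₄ shell coincides with
the metal) and the CCHH site to ~0.4 Å (the His reference midpoints
sit slightly outside the donor shell, biasing the centroid outward).

The density route works the same way from Python; see
`metalloc.voxelgrid.predict_density` / `place_ions`, and the
`voxelize`, `train-smoke`, `predict-density`, `place-ions` subcommands.

## Layout

| path | contents |
|---|---|
| `src/metalloc/pdbio.py` | PDB I/O, altLoc/model resolution, metal-site extraction, site-quality filters |
| `src/metalloc/probmap.py` | LINK-record mining, probability map, distance statistics |
| `src/metalloc/metal1d.py` | geometric predictor |
| `src/metalloc/voxelgrid.py` | voxelization, grid averaging, ion placement, cube/HDF5 I/O |
| `src/metalloc/network.py` | 3-D segmentation network (numpy/scipy) |
| `src/metalloc/metrics.py` | clustered matching, precision/recall, MAD, Jaccard |
| `src/metalloc/synthdata.py` | synthetic metalloprotein and density generator |
| `src/metalloc/cli.py` | `metalloc` command-line interface |
| `docs/methods.md` | models, parameters, numerical choices, limitations |
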