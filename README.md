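# granuleloc

Quantification of single-molecule FISH (smFISH) micrographs of early
*C. elegans* embryos: where are individual mRNAs relative to cell
membranes, nuclear peripheries and phase-separated granules, and how
strongly do they cluster?

Each mRNA appears in a 3D z-stack as a diffraction-limited spot.
`granuleloc` detects those spots, decomposes dense signal into molecule
counts, and computes location metrics that are directly comparable
between embryos, stages and transcripts:

- **Spot detection** — 3D Laplacian-of-Gaussian band-pass (size 5,
  s.d. 1 voxel), strict 26-neighborhood local-maximum pre-detection
  inside the annotated embryo outline, 3D Gaussian sub-region fitting
  (±2 px x/y, ±3 px z) and manual intensity/quality thresholds.
- **Cluster decomposition** — the median signature of isolated spots
  defines a reference single molecule; dense regions are modeled as a
  k-component mixture of reference copies (centers and a shared
  background free), with k selected by a BIC-style penalty. Output:
  per-molecule 3D coordinates, including the molecules *inside*
  clusters.
- **Cluster metrics** — DBSCAN (ε = 0.75 µm, minPts = 2 by default)
  over decomposed coordinates yields, per embryo: total RNAs, number
  of clusters, fraction of RNAs in clusters, and mean molecules per
  cluster, aggregated as mean ± s.d. per developmental stage.
- **Radial enrichment** — the distance d of every molecule to the
  nearest annotated membrane (or, signed, to the nuclear surface) is
  binned (10 µm default) and normalized by iso-distance shell volumes:

      f(b) = (n_b / Σn) / (V_b / ΣV)

  so a uniformly distributed sample scores f ≡ 1 and f > 1 means
  enrichment at that distance. Shell volumes are computed from a
  voxelized distance transform of the annotated geometry.
- **Granule co-localization** — granules detected by multi-scale LoG
  blob detection in the marker channel are modeled as spheres; an RNA
  cluster occupies the convex hull of its member positions; cluster and
  granule co-localize when the volumes overlap in at least one point.
- **Statistics** — Welch two-sample t-tests per (transcript, stage,
  metric) against a control transcript, Benjamini–Hochberg adjusted
  across the comparison family, with the usual star binning.

A synthetic-embryo generator (`granuleloc.synthetic`) renders
two-channel stacks — PSF-blurred Gaussian molecules and spherical
granules over Poisson + Gaussian read noise inside an ellipsoidal
multi-cell embryo — with full ground truth, so every stage of the
pipeline is testable without image downloads.

## Worked example

Measure membrane enrichment on a synthetic embryo generated with a
two-fold density excess within 3 µm of the membrane:

```python
import granuleloc as g

cfg = g.desk_config(
    seed=7,
    n_molecules=5000,
    model=g.MoleculeModel(kind="membrane_enriched", rho=2.0, shell_width=3.0),
)
ann = g.make_geometry(cfg)
truth = g.sample_molecules(cfg, ann)
prof = g.membrane_profile(truth.positions, ann, bin_width=3.0, shape=cfg.shape)
for lo, hi, c, v, f in zip(prof.bin_edges[:-1], prof.bin_edges[1:],
                           prof.raw_counts, prof.shell_volumes, prof.normalized):
    print(f"{lo:4.0f}-{hi:<4.0f} um  n={int(c):5d}  V={v:8.1f} um^3  normalized={f:.3f}")
```

prints

```
   0-3    um  n= 4411  V=  1833.8 um^3  normalized=1.131
   3-6    um  n=  571  V=   509.4 um^3  normalized=0.527
```

The near-membrane shell holds most of the embryo's volume, so a 2:1
*density* ratio appears as normalized frequencies of 1.13 vs 0.53 —
their ratio, 2.15, recovers the generating density ratio ρ = 2 (the
volume-weighted mean of the normalized profile is always exactly 1).

The same analyses are available from the shell:

```sh
granuleloc simulate --preset desk --out fixture/
granuleloc decompose --image fixture/smfish.tif --annotation fixture/annotation.json \
    --spacing 0.2,0.1,0.1 --intensity-threshold 50 --quality-threshold 0.4 --out molecules.tsv
granuleloc cluster --molecules molecules.tsv --out clusters.tsv
granuleloc radial  --molecules molecules.tsv --image fixture/smfish.tif \
    --annotation fixture/annotation.json --spacing 0.2,0.1,0.1 --out radial.tsv
granuleloc coloc   --molecules molecules.tsv --marker fixture/marker.tif \
    --spacing 0.2,0.1,0.1 --blob-threshold 0.1 --out coloc.tsv
```

Every command echoes its fully resolved configuration and writes it
next to the output, so results are self-describing.

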