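# squamorph

Disparity-through-time analyses of squamate feeding ecomorphology.

Mesozoic squamates (lizards, snakes, mosasauroids and kin) left a fossil
record in which tooth-bearing jaws are often the only well-preserved
elements. Tooth shape, jaw size and jaw shape are therefore the standard
proxies for dietary ecology in the group, and the central macroevolutionary
question is whether ecological *disparity* (morphological variety) tracked
or preceded taxonomic diversity through the Cretaceous. `squamorph`
implements the three coordinated analysis streams used to ask that question,
exercisable end-to-end on synthetic data with known ground truth:

1. **Dental composition** — each genus carries one or more of eight discrete
   tooth morphotypes (heterodont taxa carry several). Genera are binned into
   the 14 geological stages Kimmeridgian–Maastrichtian by range-through
   sampling, and between-bin turnover is quantified by pairwise Bray–Curtis
   dissimilarity on the per-bin compositions,
   `BC(u, v) = Σ|uᵢ − vᵢ| / Σ(uᵢ + vᵢ)`.
2. **Jaw-size disparity** — log₁₀ mandible length per genus; per-bin range,
   sample SD and mean; membership-permutation tests for disparity shifts
   between bins (pool two bins, reshuffle membership at the original sizes,
   1000 iterations, p = (1 + b)/(1 + N)); Welch and Student two-sample *t*
   contrasts on means.
3. **Jaw-shape morphospace** — 33 2-D landmarks per jaw (7 fixed + 26
   semilandmarks), mirrored to the right side, superimposed by generalized
   Procrustes analysis (translation, unit-centroid-size scaling, proper
   rotations only) and ordinated by PCA. Group disparity is the sum of score
   variances over all axes and the convex hull volume in PC1–PC3, with
   500-iteration percentile bootstrap CIs, rarefaction to a common n,
   membership-permutation difference tests, PERMANOVA-style NPMANOVA on all
   axes, and optional augmentation of under-sampled early bins with the mean
   Late Cretaceous snake shape.

The `squamorph.synthetic` module generates all three data streams with
controllable, recorded ground truth (composition regime shift, marine size
expansion, group-structured shape offsets), so every pipeline stage is
testable without any downloads.

## Worked example

```sh
squamorph simulate --seed 5 --out demo/
squamorph shape --tps demo/jaw_shapes.tps --metadata demo/jaw_shapes_meta.csv \
    --out demo/shape --seed 5
```

which prints

```
synthetic data written to demo
shape analysis outputs written to demo/shape
```

`demo/shape/explained.csv` then starts

```
axis,explained
PC1,0.6725040139990651
PC2,0.06572456112313609
PC3,0.015010419135244858
```

— PC1 carries ~67% of aligned shape variance (the synthetic generator
concentrates variation on its first two deformation modes), and
`demo/shape/disparity.json` reports, per epoch bin, the sum of variances and
PC1–PC3 hull volume with bootstrap 95% CIs: for this seed the Late
Cretaceous bin (n = 74) has sum of variances ≈ 1.08e-3 against ≈ 3.5e-4 for
the Early Cretaceous (n = 13), while the NPMANOVA p = 0.53 shows the bins'
centroids are not significantly displaced — expansion at the extremes rather than a
shift of the occupied region.

The same library surface is importable directly (`squamorph.gpa_align`,
`squamorph.pca_embed`, `squamorph.bray_curtis`,
`squamorph.permutation_disparity_test`, `squamorph.npmanova`, ...); see the
docstrings and `docs/methods.md`.

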