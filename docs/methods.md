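# Methods

## Colour measurement

Images are assumed to be calibrated 8- or 16-bit sRGB (IEC 61966-2-1);
the raw-development and profiling chain that produces such images is out
of scope. Conversion to CIE 1976 L\*a\*b\* uses the standard sRGB
pipeline (D65 white point, 2° observer) as implemented in
`skimage.color`; the package adds the domain layer on top of it.

A region's colour is estimated by placing `n_patches` (default 10)
square patches of `patch_size_px` (default 31) at uniform-random interior
positions of the annotated polygon, converting each pixel to Lab,
averaging per channel within a patch, and averaging the patch means.
Averaging happens in Lab, not in sRGB, because the quantity of interest
is a position in the perceptual space. Contrast is the **distance of
averages**: ΔE(CIE76) between two region means, not the average of
pairwise pixel distances. Patches may overlap (a `disjoint` flag rejects
overlapping placements); patch positions are returned so a user can
audit what was sampled. Costa and cell-bottom colours use 5×5-px patches
centred on annotated point lists, because costae are only a few pixels
wide.

Numerical notes: patch placement uses an integral-image test for "patch
fully inside polygon", so degenerate or too-small polygons raise a
geometry error rather than silently sampling outside; CIE76 is used
throughout (the perceptually non-uniform but historically standard
Euclidean metric), and tests verify it against an independent Euclidean
oracle at 1e−12 and against `skimage.color.deltaE_cie76`.

## Reticulation morphometrics

Cell areas are measured on binary cell-bottom masks: 4-connected
components (costae are thin, and 8-connectivity would leak across
diagonal costa junctions), components touching the raster border
excluded (partial marginal cells would bias areas downward), pixel
counts divided by the squared pixel scale. Transverse costae are counted
as maximal true-runs met along a rasterised longitudinal transect.
Automatic segmentation of costae from photographs is deliberately out of
scope: masks come from the generator or from manual annotation.

Box-plot summaries use sample extremes as whiskers and linearly
interpolated quartiles (the common type-7 rule; no rule is forced by the
data, so the most widespread default was chosen).

## Pattern classification

The decision sequence is: (1) **C** if the reticulation is structural —
`n_longitudinal ≤ 4`, `n_transverse ≤ 20` and mean cell area ≥ 0.275 mm²;
(2) else **B** if humeral–apical ΔE ≥ 36.4; (3) else **BLACK** if the
humeral mean L\* < 20 and ΔE < 8; (4) else **A**. Reticulation is
decided structurally rather than by costa/cell colour contrast because
the published costa/cell ΔE ranges of patterns A (23.5–28.8) and C
(25.0–40.9) overlap, while the costa counts and cell areas separate
cleanly; this also treats the calochromine "false costae" (a pubescence
illusion rather than cuticular ridges) by the same measured criteria.
The contrast threshold 36.4 is the midpoint of the published pattern-A
maximum (20.3) and pattern-B minimum (52.5); the cell-area threshold
0.275 mm² the midpoint of the non-reticulate maximum (0.26) and
reticulate minimum (0.29). The BLACK thresholds are plumbing with no
published range behind them; all thresholds are configurable
(`ClassifierConfig`). The default elevation split is < 1,500 m vs
≥ 1,500 m, the boundary above which the high-contrast patterns dominate.

A documented wrinkle: one survey sentence attaches "reticulate
co-mimics" to pattern A and another inverts the transverse-costa counts
of A and C; the pattern *definitions* (A dense/low-contrast, B dense/
high-contrast, C reticulate) govern the implementation.

## OTU delimitation

Uncorrected p-distance: mismatches over sites where both sequences carry
an unambiguous A/C/G/T (pairwise deletion of gaps and IUPAC ambiguity
codes). Distances from fewer than `min_overlap` (default 100) compared
sites are treated as missing to guard against spurious near-zero
distances. Multi-gene distances pool mismatches and compared sites
across genes before dividing — a length-weighted estimate — rather than
averaging per-gene ratios; per-gene matrices remain available. Whether a
species-delimitation threshold should apply to pooled or per-gene
distances is genuinely open; pooled is the default.

Clustering at the threshold (default 2.5%) is single linkage, i.e. the
transitive closure of sub-threshold links: the standard reading of a
bare distance threshold. Missing distances never link. Each OTU is
pruned to the member with the most resolved sites summed over genes,
ties broken by smallest sequence id. Morphological validation of OTUs is
represented only as a curated-override pathway (edit the OTU table), not
modelled.

## Origins and dating

Leaves are recoded focal/non-focal (missing states are wildcards) and a
two-state dynamic programme computes, for each node and state, the
minimum subtree cost together with the minimum and maximum number of
origins attainable *within minimum-cost reconstructions*. An origin is a
non-focal→focal edge transition, plus one if the root itself is
reconstructed focal. Restricting to most-parsimonious reconstructions is
essential — allowing extra losses would always permit a single ancient
origin. Both the minimum and maximum over MPRs are reported;
`terminal_only` is the identity `min_origins == focal_leaf_count`
("every focal leaf is its own origin"). Multifurcations are handled
natively by summing over children. No root-state prior is imposed by
default; `root_state="nonfocal"` encodes outgroup knowledge, and with a
symmetric focal pair the unconstrained optimum genuinely includes a
focal-root-with-losses reconstruction, so the flag matters.

Time scaling is an explicit **strict-clock stand-in**, not a relaxed
clock: per edge, t = Σ_g n_g·(ℓ_g/r_g) / Σ_g n_g over the partitions
present, with default rates cox1 0.0115, nad5 0.0177, rrnL 0.0054
subs/site/My and fragment lengths 801/1,359/831 sites. It is linear in
branch lengths and inverts noise-free clock simulations exactly. Node
ages on non-ultrametric (noisy) trees are the mean of descendant
root-to-leaf times (a `max` mode is available). Because high-contrast
patterns occur only on terminal branches, the machinery reports *split*
ages, not pattern ages — the origin of a terminal-branch pattern cannot
be dated more precisely than its stem.

## Synthetic data: what it emulates and what it does not

* **Elytron images**: a margin-padded grid of `n_longitudinal ×
  n_transverse` costae enclosing square cells of planted area, painted
  with planted region Lab means (humeral/middle/apical thirds; costa
  colour in the humeral band), Gaussian Lab noise (default σ = 2 per
  channel, a realistic texture/sensor scale), gamut-clipped conversion
  to 8-bit sRGB with the clipped fraction reported. Default colours per
  pattern are the published Lab positions where printed (B humeral
  52/33/51, B middle 64/25/52, C costa 53/19/43) and otherwise chosen so
  the planted contrasts fall inside the published ΔE ranges. Not
  emulated: specular highlights, shading, curvature, pubescence texture,
  irregular cell shapes — so image-based tests validate the sampling and
  segmentation arithmetic, not robustness to photographic artefacts.
* **Sequences**: star-of-stars genealogy (root → OTU ancestors at
  d_b/2 → members at d_w/2) under Jukes–Cantor, the simplest process
  with the closed form p = ¾(1 − e^(−4d/3)). Defaults plant expected
  within-OTU p = 0.01 and between-OTU p ≈ 0.09 at 1,000 sites — a clean
  barcode gap around the 2.5% threshold. Real mitochondrial data differ
  (rate heterogeneity, saturation, uneven sampling), so recovery rates
  here measure the clustering logic, not field performance.
* **Clock trees**: forward Yule topology rescaled to the planted crown
  age; branch lengths ℓ_g = r_g·t exactly or Poisson(r_g·t·n_g)/n_g.
  Focal states are planted on leaves chosen pairwise ≥ 4 edges apart and
  *verified* by the origin-counting DP itself to require one origin
  each; infeasible requests raise.
* **Communities**: specimen parameters drawn uniformly inside the
  published per-pattern ranges; band compositions follow planted
  proportions exactly via largest-remainder rounding (defaults: lowland
  A-dominated; mountain ≈ 30% C, 50% B, with 13 yellow/black taxa).
  `n_taxa` counts taxa *displaying* a pattern, so a dimorphic taxon
  reserves a species slot in each of its sex-specific patterns and
  claims one female and one male slot in the highest band, leaving
  proportions untouched.

All generators are deterministic given their seed.

## Problem sizes

Default test and acceptance runs use 20 OTUs × 3 sequences × 1,000
sites (30–100 seeds), 100 random ≤ 12-taxon matrices and ≤ 8-leaf trees
for oracle equivalence, 100 two-leaf clock replicates for dating
recovery, 200-specimen communities, and one synthetic elytron per
pattern (≈ 0.3–1.3 Mpx); these sizes give stable statistics for every
property tested while keeping a full run in the order of seconds.

## Known limitations

* CIE76 treats Lab as Euclidean; no CIEDE2000 option, and human (not
  predator) colour perception throughout.
* "Cell area" is strictly 2-D mask area; no attempt to quantify cell
  depth or 3-D structure.
* The strict clock ignores among-lineage rate variation; published
  relaxed-clock ages are targets for parameter-recovery testing only,
  not quantities this package claims to reproduce.
* Single-linkage threshold clustering is sensitive to chaining in
  continuously sampled divergences; the planted-partition tests assume a
  barcode gap.
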