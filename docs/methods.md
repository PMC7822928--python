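# Methods

## Overview

`operonvision` predicts operons by imitating how human curators read a
comparative genome browser.  Every consecutive gene pair on a contig becomes
one classification problem; the evidence is rendered as an image; an image
classifier scores the pair; operonic runs are merged into operon predictions.
This note records the model, its parameters and assumptions, the numerical
conventions, and what the synthetic benchmark does and does not establish.

## Coordinates and inputs

Coordinates are 0-based half-open internally; GFF3 is converted on read/write.
Intergenic distance is signed, `start(downstream) − end(upstream)`, so
overlapping genes (common inside operons) give negative gaps.  Inputs are:
GFF3 gene calls; a gene→family TSV assigning cross-genome homology families
(used for anchoring and coloring); an unordered-pair score TSV of functional
association confidences (0–1000 scale divided by 1000 on read, or already in
[0, 1] with `scale="unit"`); and a known-operon TSV
(`genome_id ⟨tab⟩ comma-joined gene ids ⟨tab⟩ source`).  Operon records are
validated as consecutive, single-contig runs; mixed strands warn rather than
error, since curated lists occasionally contain them.

## Pileup construction

For pair (g₁, g₂), g₁ is the focus gene.  The query row is the window
(pair outer bounds ± `flank_bp`, default 5000).  For each reference genome
with at least one gene of g₁'s family, one row is built around the best such
anchor — "best" meaning its flanking family set (within `flank_bp`) has the
highest Jaccard similarity to the query's flanking families, ties broken by
lowest gene id.  Rows whose anchor lies on the reverse strand are mirrored
about the window midpoint (coordinates reflected, strands toggled, order
reversed) so the anchor always points rightward, as genome browsers display
them; mirroring is an involution.  Rows are ordered by evolutionary distance,
by default 1 − Jaccard similarity of the two genomes' family-id sets — a
deliberate sequence-free proxy so the whole pipeline runs without sequence
data — or by a user-provided genome order; the stack is truncated to
`max_rows` (default 10: query + 9 references).

## Rendering

Each row maps to a horizontal band (`row_height_px` = 32) of a
`width_px` = 512 raster, query row on top.  Per row, three linear bp→pixel
maps apply: the focus span (the pair's outer bounds on the query row; a span
of equal width centered on the anchor for reference rows) fills the central
`central_fraction` = 2/3 of the width; the upstream and downstream flanks
each compress into one margin sixth.  Pixel extents round at both ends, so a
gene spanning the left half of a central span [2000, 6000) at width 512
occupies columns [85, 256).  Genes draw as arrows — rectangle body plus a
triangular head of min(25 % of length, 10 px) pointing along the display
strand; overlapping genes draw in display order so the later-starting gene
paints on top.

Colors: the two focus-pair families are blue and red in every row; the next
`palette_size` = 8 most frequent other families (count across rows, ties
lexical) receive distinct palette colors chosen to exclude blue/red/black;
everything else, including family-less genes, is black.  The published
description caps the number of distinctly colored families without stating
the cap; 8 is our configurable stand-in.

The raster's single global alpha equals the pair's association score clamped
to [`default_alpha`, 1], with `default_alpha` = 0.1 when no score exists.
One alpha per image (not per row) follows the stated encoding.  Rendering is
pure: identical pileup and config give byte-identical PNGs.

## Classification

The intended design — an ImageNet-pretrained 18-layer residual network with
its final layer retrained — is not reproducible here: no deep-learning
framework or pretrained weights exist in the execution environment, and
binary weight files cannot ship with a text-only package.  The package keeps
the transfer-learning *shape* while swapping the backbone:

* **Featurizer (frozen)**: composite RGBA over white (the score alpha thereby
  becomes a global fading of the evidence, visible to a 3-channel model),
  bilinear-resize to `input_size_px` × `input_size_px` (default 64; resize,
  never crop), scale to [0, 1], flatten.
* **Head (trained)**: scikit-learn logistic regression (lbfgs, `C` = 1.0,
  `max_iter` = 1000, fixed `random_state`), the only component that sees
  labels.

Augmentation is exactly one transform: the horizontal mirror of every
training image, matching the domain argument that left–right reflection
preserves the meaning of a neighborhood while vertical flips or crops would
not.  `PairImageClassifier` implements the scikit-learn estimator API
(`fit` / `predict` / `predict_proba` / `get_params`), so it composes with
sklearn pipelines and model selection.  The decision threshold is 0.5 by
default and only affects binary calls, never AUCs.  Training is deterministic
given the seed; models serialize losslessly with joblib.

**Attention maps.**  Gradient-weighted class-activation mapping requires a
convolutional feature hierarchy, so explanations instead use occlusion
sensitivity: an 8-px white patch slides over the model input at stride 4, and
the per-pixel mean drop in the predicted class's probability (clipped at 0)
is min–max normalized and upsampled to the input size.  All-zero maps are
legal and flagged `degenerate`.  On planted-signal images predicted operonic,
mean heat inside the central 2/3 band exceeds mean heat outside it (asserted
on the strong-signal fixture only; it is a property of that world, not a
theorem).

## Labeling and datasets

Within a known multi-gene operon, every consecutive pair is operonic.  Each
operon boundary contributes the (outside neighbor, boundary gene) pair as
non-operonic — unless the outside neighbor belongs to another multi-gene
operon, in which case the pair is dropped: labeling it non-operonic would
contradict that operon.  Single-gene operons contribute nothing to training
data; in test mode their two flanking pairs are non-operonic.  All other
pairs stay unlabeled.  Balancing subsamples the majority class uniformly
without replacement (seeded, deterministic), globally across genomes; a
per-genome option exists since the published procedure does not say which was
used.  Leave-one-genome-out splits group genomes by organism, taken as the
first two whitespace tokens of the genome name (genus + species), so strain
variants of the held-out organism never leak into training.  Mirrors are
generated at fit time, never written to manifests.

## Assembly and metrics

Pair calls merge by run-length: maximal runs of operonic calls on one contig
become predictions (≥ 2 genes; mean member probability attached for ranking);
pairs without calls count as non-operonic, so missing evidence breaks runs.
No post-hoc strand filter is applied — strand is already in the image, and
adding a filter would second-guess the classifier.

Rate metrics use the standard confusion-matrix formulas (README).  Edge
conventions: precision with TP+FP = 0 is NaN; MCC with any zero denominator
factor is 0 and flagged.  ROC/PR curves sweep the distinct scores with ties
grouped, AUC by trapezoid; grouped-tie ROC AUC equals the pairwise
concordance (Mann–Whitney) statistic, which the tests verify against a
brute-force oracle.  Exact operon matching orients both gene lists in genome
coordinate order and requires identity — an extension or a merge of two known
operons matches nothing.

## Synthetic pangenomes

The generator plants the features the literature calls most informative:
operons are co-stranded consecutive runs of 2–6 genes (length probabilities
0.35/0.30/0.15/0.10/0.10, skewed short as real operons are) with signed gaps
uniform on [−10, 30] bp; boundaries get gaps uniform on [80, 400] bp and a
strand flip with probability 0.7.  Gene lengths are uniform on [300, 1500] bp.
Reference relatives keep each query gene's family with probability 0.9 inside
operons and 0.3 elsewhere, jitter lengths by ×[0.8, 1.2], and fill
non-conserved slots with novel families at random strands.  Pair scores are
uniform [0.7, 1.0] for operonic pairs, [0.0, 0.3] for others, missing with
probability 0.1 (the renderer then falls back to alpha 0.1).  A block becomes
an operon with probability 0.6, and 10 % of singleton genes are recorded as
single-gene operons so the test-mode labeling path is exercised.  Everything
is deterministic given the seed.

Fixture scales: `unit` ≈ one organism of a 60-gene query + 2 relatives
(seconds); `integration` ≈ six organisms of 400-gene queries + 3 relatives
each (the full leave-one-organism-out benchmark runs in ~2 minutes on one
CPU).  Multi-organism fixtures are independent simulations sharing nothing,
so held-out evaluation is a genuine generalization test.

**What a green synthetic benchmark establishes — and what it does not.**  It
shows the pipeline is wired correctly end to end and that the classifier can
learn the planted visual determinants (strand consistency, spacing,
conservation, score fading) from images alone and transfer them across
organisms.  It does not establish performance on real genomes: real operons
have overlapping regulatory structure, internal promoters, uneven family
annotation quality and score coverage, and reference panels with phylogenetic
correlation — none of which the generator models.  Published headline
accuracies on real model organisms are therefore out of scope here.

## Numerical choices and degenerate inputs

* Pixel extents clamp to the raster and are at least 1 px wide.
* A focus gene without a family yields a query-only pileup (not an error);
  an empty reference list likewise.
* Anchor ties break on lowest gene id; color ranking ties break lexically —
  all orderings are total, keeping every stage deterministic.
* Scores are validated to [0, 1] after scale normalization; out-of-range is
  an error, absence is not.
* `assemble` refuses calls naming unknown genes or non-adjacent pairs.
* Empty annotations predict nothing; single-class training manifests raise.

## Known limitations

* The family-set Jaccard distance is a crude stand-in for phylogeny; with a
  provided genome order the package defers to the user.
* The logistic head sees raw downscaled pixels; it cannot learn the spatial
  compositionality a convolutional network could, and its accuracy ceiling on
  subtler-than-planted signals is correspondingly lower.
* Occlusion attention is coarser than gradient-based maps and costs one
  forward pass per patch position.
* One global alpha per image follows the stated encoding but discards any
  per-reference association information.
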