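# Methods

`cftrflow` re-implements, as one tested pipeline, the computational chain
that links a high-content siRNA screen for CFTR plasma-membrane traffic to
a prioritized protein–protein-interaction network: plate-image
quantification and modified-Z hit calling, 3D quantification of YAP1
nuclear localization, replicate-filtered AP-MS interactome set algebra,
over-representation enrichment, and two-stage candidate prioritization.
Because the raw microscopy and mass-spectrometry data behind such studies
are rarely deposited, a synthetic-data generator produces every input with
known ground truth; all statistical claims made by the test suite are
claims about recovery of that planted truth.

## Screen quantification and scoring

Each well is imaged in three aligned channels: nuclei, total CFTR
(mCherry tag) and surface CFTR (extracellular Flag tag read with a Cy5
secondary). Nuclei are Otsu-thresholded and label the seeds of a watershed
over the Otsu foreground of the total-CFTR channel; per-cell intensities
are dark-frame-corrected sums over each cell region. Background correction
uses a per-image constant (configurable dark-frame value) rather than
calibration frames. Three per-cell QC gates follow: reporter expression
(integrated total fluorescence above a threshold, default 3× the
dark-frame constant — the underlying assay publishes no number),
morphology (area bounds) and saturation (fraction of saturated pixels).
A plate passes QC only if the siCFTR transfection control reduced
total-CFTR signal by ≥ 30 % versus the negative control; the plate signal
is the median across a role's wells of the per-well median per-cell total
fluorescence (a robust variant; the underlying description does not fix
mean vs median).

The per-well statistic is the control-based **modified Z-score**

    Z = (x − median(NCtrl wells)) / sd(NCtrl wells)

computed per plate, where `x` is the well's median surface-CFTR intensity.
Despite the conventional name, the scale is the *sample* SD (n−1) of the
negative-control wells, not the MAD; a MAD variant (`robust=True`) is
available for sensitivity analysis. Z is averaged across replicate plates,
compared with the control replicates by a two-sided unpaired t-test
(pooled variance by default, Welch by option), and hits are called by
strict thresholds: enhancer iff Z > 1, inhibitor iff Z < −1. Significance
is reported alongside but does not gate the hit class. Hits are
high-confidence when ≥ 2 same-direction hits target the same gene set
(single siRNAs and two-siRNA combinations are keyed by the *set* of target
genes, so two combinations against the same pair corroborate each other)
or when a single hit carries an external-evidence flag (e.g. differential
expression of the target between the two cell lines). Top hits are
treatments that enhance traffic in the F508del line and are neutral in wt.

Z is invariant under affine rescaling of all fluorescences on a plate
(detector gain/offset cancels), which the suite checks on 1,000 random
plates. With few control wells the statistic is heavy-tailed (it behaves
like a t-variable with n_ctrl − 1 degrees of freedom); the default
simulated layout therefore places 8 NCtrl wells per 96-well plate, a
standard control-column design.

## 3D nuclear-fraction quantification

Nuclei are segmented from the nuclear-dye channel by a median filter
(physical radii 0.5 × 0.5 μm laterally, 0.6 μm axially), an intensity
threshold (explicit scalar, or Otsu when unset — the threshold used is a
logged parameter, replacing interactive thresholding for
reproducibility), a 3D morphological opening (0.7 μm in-plane), and
watershed declumping whose seeds are the regional maxima of the
anisotropic (physical-metric) distance transform, dilated in-plane by
2.1 μm. Cytoplasm is assigned by growing each nucleus to the nearest-
nucleus region within a maximum physical distance; equidistant voxels go
to the lower label (enforced by a strict-inequality per-label distance
sweep). All radii are stored in micrometres and converted per stack
geometry, so parameters transfer across magnifications.

Cells are discarded when they touch a *lateral* image face (confocal
stacks of a monolayer almost always clip cells axially, so a z-face rule
would discard everything), when the nucleus is smaller than 147 μm³, or
when the nucleus label is fragmented (more than one connected component).
Mitotic/atypical nuclei, excluded manually in interactive workflows,
are not modelled here — the generator does not produce them. The per-cell
statistic is f = nuclear / whole-cell integrated signal; each image is
summarised by the mean f of its kept cells, and groups of images are
compared by a two-sided unpaired t-test with images as statistical units.

On synthetic stacks (8 cells per 24 × 160 × 160 stack at 0.6 × 0.5 ×
0.5 μm voxels) the recovered image mean tracks the planted fraction to
within ~0.03; the residual bias is segmentation-edge erosion by the
median filter, which removes a high-density nuclear boundary shell. The
analysis of synthetic stacks uses a 4 μm cytoplasm-growth distance
matched to the simulated cell size; the published 17.7 μm default would
tile the whole field and trip the border filter for every cell in these
small test volumes.

## Interactome definition and set algebra

Protein identifications are accepted when the search engine's Unused
Protein Score is strictly above 1.3 at ≥ 95 % confidence. A protein enters
a condition's interactome when it passes that filter in ≥ 2 distinct
biological replicates (duplicate rows within a replicate count once).
Interactomes of the two conditions are partitioned into common and
condition-specific sets, and coverage against published reference
interactomes is |set ∩ ∪refs| / |set| with case-insensitive gene-symbol
matching (published lists mix identifier casing; which identifier space
the original comparison used is not recorded).

## Enrichment

Over-representation uses the one-sided hypergeometric upper tail (the
Fisher mode of the common GO web tools) with fold enrichment
FE = (k/n)/(K/N); the background defaults to all genes carrying ≥ 1
annotation and is overridable. P-values are Benjamini–Hochberg-corrected
within one collection. Thresholds are strict: p < 0.05, with FE > 8.5
(differential-term profile) or FE > 15 (global profile). Enriched
biological-process terms are grouped by a curated 11-category map
(apoptosis, barrier function, cell cycle, cell junction, cytoskeleton,
differentiation, ECM, immune system, inflammation, miRNA, stress); GMT
collections (hallmark, oncogenic signatures) are scored the same way and
reported as −log10 FDR. "GSEA" here is list-based over-representation of
an unranked interactor list, not the ranked Kolmogorov–Smirnov form. GO
graph propagation is out of scope: annotations are treated as
pre-propagated.

## Prioritization and network

Stage 1 keeps condition-specific interactors defining ≥ 1 disease-relevant
category: curated BP categories ECM and inflammation, the hallmark sets
for MYC signaling, EMT, mitotic spindle, hypoxia and TGFβ signaling, or
oncogene / oncogenic-signature membership; the bait (YAP1) and CFTR are
excluded. A Results-style profile that also admits the cell-cycle BP
category is selectable (`netprio.CATEGORY_PROFILES`); the two profiles
reflect an internal inconsistency in the source description, and the
narrower one is the default. Stage 2 keeps candidates in > 1 category
and/or in the published CFTR interactome. The network is the induced
subgraph of a score-weighted edge list (STRING-style export, scores 0–1 or
0–1000 auto-normalised) at combined score ≥ 0.4, the conventional
"medium confidence" cutoff; hubs are ranked by degree with lexicographic
tie-breaks. Edge lists are consumed from files, never fetched live, so
results are reproducible against database versioning.

## Synthetic data: what it emulates and what it does not

* **Screen plates** — non-overlapping disk cells whose painted pixel sums
  equal the true integrated intensities exactly (integer-dithered
  painting), with mean-one lognormal multiplicative noise (CV is the
  parameter; CV = 0 recovers analytic values bit-exactly), Poisson cell
  counts (mean 200/well), a 0.25 baseline surface fraction, treatment
  effects as multipliers on that fraction, siCFTR knockdown of the total
  signal (default 90 %), and optional per-cell pixel saturation at the
  dtype maximum to exercise the saturation gate. Segmentation is
  deliberately easy: the screen's hard part is the statistics, not the
  segmentation, so fixtures are parameterised for the former.
* **Confocal stacks** — ellipsoidal nuclei inside ellipsoidal cells with
  the planted per-cell nuclear share exact on the ground-truth labels;
  planted violators (sub-147 μm³ nuclei, border-clipped cells, touching
  nucleus pairs) exercise each filter. No optics: no PSF, no axial
  attenuation, no autofluorescence.
* **MS replicates** — per-replicate Bernoulli detection of planted true
  interactor sets (wt 234, F508del 352, common core 214 — the study's
  scale), passing scores for true rows, sub-threshold score or confidence
  for decoys. Default detection probability 0.9 for de-novo simulations;
  the emulation of a *deposited* identification table uses probability 1,
  since such a table records what was identified. Expected consensus
  recall follows the binomial closed form P(≥2 of 3).
* **Annotation resources** — terms/sets whose overlap with the query is an
  assigned subset of the condition-specific interactors, sized ~1.4× the
  overlap so planted terms clear both FE gates while random null sets
  cannot; category assignments are constructed so the two prioritization
  stages recover exactly 65 and 30 candidates, and the reference lists
  are built to the published coverages (79/234, 98/352). The
  published-library screen table (83 treatments, 63 hits, 24
  high-confidence, 8 top-hit siRNAs over 4 genes) is likewise a
  structural emulation: the counting and classification logic is what is
  being tested, the structure is an input.

Passing tests therefore demonstrate correctness of the statistics,
filters and set logic under controlled conditions — not robustness to
real microscopy artefacts, chromatographic variability, or annotation
incompleteness.

## Numerical choices and limitations

* Sample SD (ddof = 1) wherever an SD is taken over wells/replicates;
  SEM = sd/√n.
* Ties in cytoplasm assignment and hub ranking are deterministic (lower
  label / lexicographic).
* Medians use the midpoint convention for even counts.
* Degenerate control wells (zero spread) raise rather than return ±inf.
* t-tests on identical constant groups report p = 1.
* Problem sizes in the test-suite Monte-Carlo runs (100 plates for null
  calibration and power, 30 stacks for fraction recovery, 500 terms for
  the enrichment null, 1,000 random instances for set-algebra oracle
  equivalence) were chosen to keep each estimate's sampling error well
  inside the tolerance it is checked against.
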