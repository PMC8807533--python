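# Methods

## Measurement model

A cell's ERK activity is the ratio of median reporter intensities,
cytoplasm over nucleus, where the cytoplasm is the segmented cell mask
minus its nucleus. The median (midpoint convention for even pixel counts)
makes the readout robust to segmentation fringe pixels and is invariant
under any positive rescaling of the reporter channel — the statistic is a
pure ratio, so illumination and exposure cancel.

Cytoskeleton/process length is measured as follows: the reporter channel
is binarized (Sauvola), intersected with the cell mask, the cell body —
the nucleus dilated by a disc of `body_radius_px` (default 4, the midpoint
of the protocol's 3–5 px range) — is removed, and the remainder is
skeletonized by topology-preserving thinning. The primary length is the
skeleton pixel count; a `weighted` mode counts diagonal steps as √2, and
the longest single skeleton path is emitted as a secondary column
(`longest_path_px`) for users who prefer a maximum-extent definition of
"cell length". The two definitions are highly correlated on elongated
cells; recovery tests target the primary one. Note that any cytoplasm
annulus outside the body disc also contributes skeleton: on round cells
with large cytoplasm the measure includes a ring term of roughly the
cytoplasm circumference. This is a property of the body-exclusion
definition itself, not an implementation artifact; the length-recovery
experiment therefore uses compact-cytoplasm cells (cytoplasm contained in
the body disc) to isolate the process contribution, while the group
comparison uses the measure as defined, where the ring term is
condition-independent and cancels in rank tests.

## Segmentation

Nuclei: Gaussian smoothing (sigma 1 px, mirror boundary), a global Otsu
threshold computed on a 256-bin histogram, strict-`>` binarization, hole
filling, 8-connected labeling in raster-scan order, and an area gate
(default 50–5000 px²). Otsu candidate splits are taken only after
nonempty histogram bins (splits after empty bins duplicate the previous
partition); the returned threshold is the midpoint of the bin centers
flanking the best split, with exact ties resolved to the lowest
threshold.

Cells: the Sauvola local threshold `T = m·(1 + k·((s/R) − 1))` with
window mean `m` and standard deviation `s` over an odd square window
(default 25 px, mirror padding), `k = 0.1`, and `R` defaulting to half
the dynamic range (half the dtype range for integer images, half the
image maximum for floats). Foreground is the union of the Sauvola mask
and the nucleus pixels; each foreground pixel is assigned to the nucleus
with the shortest within-foreground 8-connected path (multi-source BFS;
equal distances go to the lower label), and foreground components
containing no nucleus are discarded. This nearest-nucleus geodesic
propagation is an equivalent-intent substitute for CellProfiler-style
secondary-object propagation; nucleus ⊆ cell holds by construction.
Touching nuclei are not declumped — merged objects are expected to be
removed by QC, matching the protocol's division of labor.

A pinned convention worth knowing: on a constant region `s = 0` gives
`T = m(1 − k) < m`, so Sauvola marks uniform *nonzero* background as
foreground. The rule is therefore only usable on offset-subtracted
images whose background is near zero — see the generator defaults below.

## Synthetic data

The generator emulates what the measurement assumes: elliptical nuclei
(radii 5–7 px) and cytoplasm bodies (9–13 px, same orientation), 1–3
straight processes per cell (width 3 px) anchored on the cytoplasm
boundary, rendered on a 768×768 grid with 55 non-overlapping cells per
field (rejection-sampled placement with a 2-px clearance; a placement
failure raises an error naming the achieved count). Reporter photometry
is uniform-fill: nucleus intensity `I_n = total/(A_n + r·A_c)` and
cytoplasm intensity `r·I_n`, so the noiseless cytoplasm/nucleus mean —
and, because fills are uniform, the median — equals the cell's true
ratio `r` exactly, and the per-cell summed signal equals the budget
`total_reporter_per_cell` (default 1.5e5 counts; DNA intensity 300
counts). Noise is `Poisson(signal + background) + N(0, sd)` clipped at
zero, defaults background 0, read-noise sd 3. The zero background models
an offset-subtracted camera, the regime in which the pinned Sauvola rule
is meaningful (see above); background speckle from read noise forms
small orphan components that the no-nucleus rule removes. Condition
presets encode the study arms: control C/N 1.8 (sd 0.3) with short
processes (12 ± 5 px), an intermediate ATRA-like arm (1.3), and an
inhibitor-like arm C/N 0.9 (sd 0.2) with elongated processes (30 ± 8 px).
Length and ratio sds, intensity scales and field geometry are the
package's own choices of a realistic regime; ratio means 1.8/0.9 are the
design anchors of the two-arm discrimination experiment.

What the generator does not emulate: point-spread-function blur,
photobleaching, uneven illumination, z-structure, touching/overlapping
cells, curved processes, and intensity heterogeneity within compartments.
Passing recovery tests therefore demonstrate correctness of the
measurement chain under its own assumptions, not robustness to every
real-microscopy artifact.

## QC

Flags only, never deletions: `border` (cell mask touches the field edge),
`area_gate` (default 100–20000 px²), `nucleus_fraction` (nucleus/cell
area outside 0.02–0.9), and per-condition outlier flags on activity and
length. The study's outlier criteria are not recoverable, so the default
is the assumption-light Tukey rule — values outside
`[Q1 − 1.5·IQR, Q3 + 1.5·IQR]` with linear-interpolation (type-7)
quartiles computed from currently passing rows; equality with a fence
passes, identical values collapse the fences and nothing is flagged, and
groups with fewer than 4 passing records skip the rule with a warning. A
percentile rule (default 1–99) is available as an alternative.

## Statistics

Mann-Whitney U is computed from midrank sums (`U = R_a − n_a(n_a+1)/2`).
For `n_a·n_b ≤ 100` the two-sided p-value is exact: all `C(n, n_a)`
assignments of the pooled values are enumerated (conditioning on the
observed values handles ties exactly) and `p = min(1, 2·min(P(U ≤ u),
P(U ≥ u)))`. Above the crossover, the tie-corrected normal approximation
with continuity correction is used (scipy). Group comparisons default to
per-cell values — the study's violin plots pool hundreds of cells — with
per-field medians carried alongside in every summary. Stars follow the
0.05/0.01/0.001 convention; no multiplicity adjustment is applied.

For qPCR, ΔCt = Ct_target − Ct_reference per (condition, replicate),
ΔΔCt = mean ΔCt(treated) − mean ΔCt(control), log2 FC = −ΔΔCt. The 95%
CI comes from the t distribution on the two-sample ΔCt difference with
Welch–Satterthwaite degrees of freedom; the p-value is the Welch
two-sample t-test (the pooled-variance Student variant is a switch,
since the source protocol names only "Student's t-test"). The reported
logarithm is base 2 — the natural base of the ΔΔCt method — with base 10
available by flag. Plate-shift invariance (adding a constant to all Ct
of one replicate) and treated/control antisymmetry hold exactly by
construction and are property-tested.

## Numerical conventions and degenerate inputs

Strict `>` against every threshold; mirror padding for all window
statistics; 8-connectivity throughout; labels assigned in raster-scan
order; empty foregrounds, empty cytoplasm, zero nuclear medians and
constant inputs yield logged flags or null statistics, never exceptions.
Determinism: every stochastic step draws from a `numpy` Generator seeded
from the run seed (per-field seeds are derived affinely and kept below
2³¹); identical config + seed reproduce byte-identical CSVs.

## Problem sizes

Recovery experiments use 2 fields (≥ 100 cells) for activity, 2×40
compact cells spanning 0–120 px for length, and the discrimination
experiment mirrors the study design at 6 fields × 55 cells per arm
(≥ 300 cells/arm after QC), repeated over 20 seeds in the test suite.
These sizes make the full suite run in about two minutes while keeping
every statistical check comfortably powered.

## Known limitations

- Nonzero uniform background defeats the pinned Sauvola rule (above);
  real images need offset subtraction upstream.
- No declumping: touching cells merge and must be caught by QC gates.
- The skeleton length includes the cytoplasm-ring term discussed above.
- Exact Mann-Whitney enumeration is limited to `n_a·n_b ≤ 100` by design;
  beyond it the asymptotic approximation is used.
- The CLI `quantify` subcommand aliases `segment` (measurement requires
  the in-memory label maps); the stage split exists in the library API.
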