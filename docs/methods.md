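# Methods

This note documents the models, algorithms and design choices behind
`limnoblot`, in the order data flows through the package.

## In-silico hybridization

A probe hit is a window of the target where the number of positions whose
base is *not* in the probe letter's IUPAC set does not exceed
`max_mismatches`. Two asymmetric degeneracy rules apply:

- a degenerate letter in the **probe** matches any base of its set —
  probes are deliberately designed degenerate;
- an `N` in the **target** matches nothing by default — it records
  sequencing uncertainty, not designed degeneracy. This is configurable
  (`target_n_matches=True`) for permissive screening.

Both strands are searched by default because the hybridized material is a
denatured double-stranded amplicon: either strand can bind a membrane-bound
probe. An antisense hit is located where the reverse complement of the
probe matches the sense strand, and is reported at the window start in
sense-strand coordinates. All coordinates are 0-based half-open.

The matcher encodes bases as 4-bit masks (A=1, C=2, G=4, T=8; a degenerate
letter is the OR of its set) so a position mismatches exactly when
`probe_mask & target_mask == 0`; windows are evaluated with a vectorized
sliding view. Its contract is pinned by a naive all-window, all-strand
enumeration oracle in the tests and the acceptance script.

In-silico PCR pairs every forward-primer sense hit with every
reverse-primer antisense hit downstream and emits the product (forward
start → end of the reverse binding site) when its length falls within
bounds. Nested PCR is function composition: the outer pair's amplicons are
re-amplified by the inner pair, with coordinates mapped back to the
original record. The packaged genus-specific pair is designed to produce a
~1,900 bp ITS amplicon, which the synthetic sequence generator reproduces
exactly.

Melting temperature offers the Wallace rule 2(A+T) + 4(G+C) — degenerate
letters contribute their per-position mean, equivalent to averaging over
expansions because the rule is additive — and a nearest-neighbor estimate
(Biopython `Tm_NN`, SantaLucia 2004 parameters, default buffer), averaging
over all concrete expansions of a degenerate oligo (capped at 512). The
panel's reported Tm values are stored as metadata and never asserted
against computed estimates: the formula and buffer conditions behind the
reported values are not published, so any equality check would be
spurious.

## Score and habitat data

Scores are ordinal {0,1,2,3} with no missing cells — the screening design
assays every habitat with every probe. Detection is defined as score ≥ 1
(weak signals count), and binarization is idempotent. Environmental
covariates other than pH may be missing; they are flagged and propagated as
NaN, and downstream stages skip — never impute — them. Alignment restricts
a score matrix and habitat table to their common habitats in matrix row
order, so results are invariant to input row order.

## Gradient profiles

Per probe: scores are summed within pH classes of width 0.2 anchored at
pH 0.0 with half-open `[low, high)` intervals (anchoring at zero makes the
class `[7.0, 7.2)` reproducible; a 1e-9 relative slack in the floor guards
against binary-representation artifacts at class edges, i.e. ~2×10⁻¹⁰ pH
units — far below measurement precision). Class sums become fractions of
the group's total score across all habitats, are rescaled so the maximum
class equals 1, and are smoothed with a centered 7-point gliding average.
Normalization precedes smoothing, matching the order in which the pipeline
defines the quantities.

Numerical/edge choices:

- Classes run contiguously from the class containing min(pH) to the class
  containing max(pH); empty classes keep value 0 and participate in
  smoothing, otherwise the gliding average would be undefined over gaps.
- Edge policy for the window: `shrink` (average only in-range positions) by
  default; `reflect` behind a flag. For gradients shorter than the window
  the effective window shrinks to 2K−1 classes.
- No correction is applied for unequal habitat counts per class (the
  profile is a *relative intensity*, not a density estimate); an optional
  per-class mean-score mode exists behind `per_class_mean` and is off by
  default.
- An all-zero score column yields an `undetected` profile (all-zero series,
  flagged) rather than an error.

### Shape classification

Field practice classifies these profiles by eye; `limnoblot` replaces that
with an explicit, parameterized rule so labels are reproducible. Peaks are
local maxima of the smoothed series at or above `peak_threshold` (default
0.5) of the series maximum; peaks closer than `min_separation` (default
1.0 pH) merge, the higher one winning (ties to the lower pH; plateau runs
report their central class). Then, in order: two peaks → `bimodal`;
occupancy — the share of classes whose smoothed value reaches 25% of the
maximum — above 60%, or more than two peaks → `broad`; a single peak is
`acidic` below 6.5, `alkaline` above 7.5, `circumneutral-narrow` between.
Occupancy is measured on the smoothed curve rather than raw sums so that
negligible tail signal does not count as occupancy. All parameters are
exposed and recorded on the label.

## Community statistics

Richness is the row sum of the binary matrix. The co-occurrence histogram
spans k = 0..n_probes and conserves the habitat count. Percentages round
half-up to one decimal (`decimal.Decimal`, not banker's rounding), matching
how survey papers print them. Per-pH-class richness uses explicit
breakpoints (default 3.8, 4.8, 5.8, 6.8, 7.8, 9.1 — classes of roughly one
pH unit spanning the surveyed gradient), half-open intervals with the last
closed so the most alkaline habitat is retained, sample SD (n−1), and SD
reported missing for single-habitat classes. The headline acid/alkaline
richness split cuts at pH 7.0 with the boundary habitat assigned to the
upper class (half-open convention).

Niche overlap between probes is Jaccard on detection sets (0 when both
empty); `shared-count` mode normalizes the shared-habitat count by the
smaller set (overlap coefficient), keeping the index in [0,1] with a unit
diagonal for any detected group. *Complete niche separation* flags pairs
both detected at least once that never co-occur.

## Distances, Mantel, PCA, clustering

Community similarity between habitats defaults to simple matching on the
binary 18-probe profile — the fraction of probes on which two habitats
agree, counting shared absences. **Caveat:** the historical analysis built
its similarity matrix with a sequence-alignment similarity tool applied to
RLBH profiles, an encoding that is not a defined matrix operation; simple
matching is this package's documented stand-in, with Jaccard optional, and
the published Mantel r for that matrix is therefore not a reproduction
target.

Geographic distance ships two modes. `equator-1d` reproduces the
historical transform exactly: each habitat collapses to latitude ×
111,319.49 m (equatorial circumference / 360), longitude is discarded, and
distances are absolute differences — a deliberately lossy 1-D projection
kept for comparability. `great-circle` (haversine, 6,371 km sphere) is the
default for new analyses and satisfies the triangle inequality. ΔpH
distance (|pH_i − pH_j|) supports testing for geographic bias in habitat
types.

The Mantel test correlates lower triangles (Pearson) and permutes rows and
columns of the second matrix jointly. Sampled mode uses
p = (count + 1)/(N + 1), so p ≥ 1/(N+1) and never 0; `exact=True`
enumerates all n! relabelings (identity included, p = count/n!) and is
checked against an independent full-enumeration oracle. Default tail is
two-sided; one-sided variants mirror distance-decay hypotheses. Null
calibration (type-I error 0.05 ± 0.02 at α = 0.05 over 1,000 replicates)
is verified in the acceptance suite. The implementation is cross-checked
against scikit-bio's Mantel in the tests.

PCA is an SVD of the column-centered (optionally unit-scaled) matrix;
explained fractions are non-increasing and sum to 1, and axis signs are
fixed deterministically by making each axis's largest-magnitude loading
positive. Probe clustering uses average-linkage hierarchical clustering on
correlation distance between occurrence columns, cut at k = 4 by default
(the number of environmentally similar probe clusters the survey
distinguished); never-detected probes are excluded, columns are processed
in lexicographic name order for deterministic ties, and zero-variance
columns get distance 0 to identical columns and the maximal correlation
distance 2 otherwise. Redundancy analysis with forward selection is
deliberately not implemented; PCA plus per-probe covariate correlations
cover that ground.

## Synthetic surveys

The generator emulates the study conditions: 161 habitats by default, 18
probe-defined groups, pH spanning 3.8–9.1.

- **Habitats.** pH is a mixture of uniforms — 70% full-range, 15% acidic
  and 15% alkaline narrower components — keeping gradient coverage roughly
  even while habitat types still cluster. Conductivity is log-normal and
  rises with pH; oxygen and the DOC-proxy absorbance anti-correlate through
  a shared humic latent factor; altitude and temperature are independent;
  coordinates fall in a Central-European box with three loose clusters tied
  to pH class, which switches the Mantel distance-decay signal on.
- **Scores.** Latent suitability is amplitude · max over optima of a
  Gaussian in pH (max, not sum, so bimodal amplitudes stay in (0,1]);
  additive N(0, 0.1) noise; thresholds 0.25/0.5/0.75 map to scores 1/2/3.
  Noise models variability of a real hybridization signal, so groups with
  amplitude 0 stay silent apart from an explicit baseline false-positive
  rate (≤ 5%), which injects spurious weak (score-1) detections. The
  threshold values are invented plumbing, exported in the truth object;
  nothing downstream depends on them.
- **Default panel ecology.** The 18 default niche specs mirror the observed
  survey qualitatively: most optima alkaline (hence richness rising with
  pH), one strictly acidic group, one circumneutral-narrow group, three
  bimodal groups with optima near pH 5.5 and 8.5, broad generalists, and
  four silent groups (two with a trace baseline) matching the probes that
  returned no usable signal.
- **Sequences.** Each group's record is exactly 1,900 bases: a concrete
  expansion of the forward primer at the start, the reverse complement of a
  concrete expansion of the reverse primer at the end, and one concrete
  expansion of the group's probe planted internally — so the
  genus-specific amplicon spans the record and the matching/PCR/coverage
  loop closes exactly.

What the generator does **not** emulate: triplicate assay noise structure,
probe cross-reactions beyond the flat baseline rate, signal-strength
compensation between probes of different brightness, chemistry of
hybridization and washing, and real biogeography. Passing recovery tests
therefore show that the pipeline's inference is correct *under its own
generative assumptions*, not that the assay is unbiased on real membranes.

## Problem sizes used in the automated checks

Matcher oracle: 1,000 random probe/sequence pairs (probes ≤ 12 nt, targets
≤ 200 nt) at 0 and 1 mismatches. Profile invariants: 200 random surveys of
5–60 habitats. Unimodal recovery: 100 replicates of 300 habitats (peak
class within ±0.2 pH of the planted optimum). Bimodal recovery: 50
replicates of the default 161-habitat survey. Mantel calibration: 1,000
null replicates, n = 20 points, 999 permutations each; exactness at n = 4
against all 24 relabelings. PCA: 20 random 10×5 binary matrices against a
direct eigensolve.

## Known limitations

- The profile classifier's thresholds (0.5 peak threshold, 1.0 pH merge
  distance, 25% occupancy floor, 60% broad cutoff) are explicit stand-ins
  for by-eye classification; different settings can relabel borderline
  profiles, which is why they are parameters, not constants.
- Coverage of a real isolate collection depends on the deposited sequences
  being supplied as FASTA; the package reports its denominator explicitly
  rather than assuming a collection size.
- The 1-D equator-distance mode is intentionally longitude-blind; use
  `great-circle` unless reproducing the historical transform.
- Ordinal scores are treated as given; the averaging of triplicate
  measurements that produced them is upstream of this package.
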