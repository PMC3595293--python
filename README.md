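# limnoblot

**In-silico reverse line blot hybridization (RLBH) profiling of bacterial
ITS microdiversity along environmental gradients.**

RLBH surveys screen environmental DNA against a membrane of group-specific
oligonucleotide probes targeting the 16S–23S rRNA internal transcribed
spacer (ITS), yielding an ordinal signal-strength score (0 = none, 1 = weak,
2 = normal, 3 = strong) for every habitat × probe combination. `limnoblot`
is the dry-lab counterpart of such a survey, built around the
*Limnohabitans* genus — an abundant freshwater betaproteobacterium whose
intra-genus ("micro") diversity was mapped across 161 standing freshwater
habitats with an 18-probe panel. The package ships that panel and its
primer pairs as a built-in resource, and provides:

- **`probe_kit`** — IUPAC-degenerate probe matching against ITS sequences on
  both strands (a probe letter like `R` matches {A,G}; an `N` in the target
  is sequencing uncertainty and matches nothing by default), in-silico PCR
  (nested PCR by composing two rounds), probe-panel coverage statistics, and
  melting-temperature estimation (Wallace rule or nearest-neighbor).
- **`score_data`** — validated habitat × probe ordinal score matrices,
  detection (0/1) binarization, habitat environment tables (pH mandatory;
  conductivity, oxygen, DOC-proxy absorbance, altitude, temperature,
  coordinates optional), and alignment of the two.
- **`gradient_profile`** — the occurrence-profile algorithm: per-probe
  scores summed in 0.2-unit pH classes, expressed as fractions of the total
  score, max-normalized to [0,1], smoothed with a centered 7-point gliding
  average; plus a deterministic shape classifier (acidic / alkaline /
  circumneutral-narrow / bimodal / broad / undetected).
- **`community_stats`** — per-habitat richness (number of groups detected),
  co-occurrence histograms, per-pH-class richness means ± SD, printed-style
  half-up percentages, and pairwise niche overlap with a complete-separation
  flag for group pairs that never share a habitat.
- **`spatial_ordination`** — community similarity (simple matching or
  Jaccard on detection profiles), geographic distance (1-D
  distance-from-equator transform or great-circle haversine), ΔpH distance,
  a permutation **Mantel test** with the (count+1)/(N+1) p estimator and an
  exact small-n enumeration mode, **PCA** of the binary detection matrix,
  and average-linkage clustering of probes into environmentally similar
  groups.
- **`synthetic_data`** — a fully seeded survey generator: habitats spanning
  pH 3.8–9.1 with correlated covariates and Central-European-like
  coordinates, ordinal scores from latent Gaussian (unimodal or bimodal) pH
  niche responses plus noise, ITS-like ~1,900 bp sequences with planted
  primer and probe sites, and an exported ground-truth object for
  parameter-recovery testing.

## The model in brief

Each probe-defined group *g* has a latent pH niche
*f_g*(pH) = *A_g* · max_μ exp(−(pH − μ)² / 2σ_g²) with one or two optima μ,
tolerance σ_g and amplitude *A_g* ∈ (0,1]; the observed ordinal score is the
number of thresholds (0.25, 0.5, 0.75) exceeded by *f_g* + ε,
ε ~ N(0, 0.1²), plus a small spurious weak-detection rate. The gradient
profile of a group is

raw_k = Σ_{habitats in pH class k} score → frac_k = raw_k / Σ raw →
norm_k = frac_k / max(frac) → smoothed by a 7-point gliding average,

and the Mantel statistic between two distance matrices is the Pearson
correlation of their lower triangles, tested by jointly permuting the rows
and columns of one matrix.

## Worked example

```python
import limnoblot as lb

bundle = lb.generate_dataset(n_habitats=161, seed=42, with_sequences=False)
b = lb.binarize(bundle.scores)

hist = lb.cooccurrence_histogram(b)
print("k=0 habitats:", hist[0], "->", lb.percentage(int(hist[0]), 161), "%")
below, above = lb.mean_richness_split(b, bundle.habitats)
print(f"mean richness: {below:.2f} (pH<7) vs {above:.2f} (pH>=7)")

profs = lb.compute_all_profiles(bundle.scores, bundle.habitats)
lab = lb.classify_distribution(profs["Lim4AusCurv"])
print("Lim4AusCurv:", lab.label, "peaks at pH", [round(p, 1) for p in lab.peaks])

res = lb.pca(b)
print(f"PC1+PC2 explain {100 * res.explained_fraction[:2].sum():.1f}% of the variance")

_, comm = lb.community_similarity(b)
geo = lb.geo_distance(bundle.habitats, "great-circle")
print(lb.mantel(comm, geo, n_permutations=999, seed=42))
```

prints

```
k=0 habitats: 2 -> 1.2 %
mean richness: 5.04 (pH<7) vs 7.63 (pH>=7)
Lim4AusCurv: bimodal peaks at pH [5.5, 8.9]
PC1+PC2 explain 74.6% of the variance
Mantel r = 0.0978, p = 0.001 (two-sided, 999 permutation relabelings)
```

Mean richness rises from 5.04 groups per acidic habitat to 7.63 per
alkaline habitat — the default generator plants alkaline-skewed niche
optima, so more groups co-occur at high pH. The bimodal group is recovered
with peaks near its two planted optima (5.5 and 8.5; the upper peak drifts
with sampling noise). The positive Mantel r reflects the generator's mild
spatial clustering of similar habitat types.

The same pipeline runs from the shell:

```bash
limnoblot simulate --out survey/ --n-habitats 161 --seed 42
limnoblot profile survey/scores.tsv survey/habitats.tsv --plot profiles.png
limnoblot richness survey/scores.tsv survey/habitats.tsv
limnoblot mantel survey/scores.tsv survey/habitats.tsv --perms 9999 --seed 1
```

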