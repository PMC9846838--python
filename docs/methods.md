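# Methods

This document states the model implemented by `bathygap`, the numerical
choices, the synthetic-data generator's assumptions, and the known
limitations. Notation: a species' depth range is the closed interval
[min_depth_m, max_depth_m]; depths are metres below the surface (positive
down).

## 1. Depth-range construction (`bathygap.depth_ranges`)

**Resolution.** An occurrence at (lon, lat) is resolved through the 1°x1°
bathymetric cell `(floor(lon), floor(lat))`; its depth is minus the cell's
elevation. Cells with elevation ≥ 0 (land) or absent from the grid drop the
record (logged, never silently imputed).

**Quantile ranges.** A species with `n ≥ min_n` (default 20) resolved
occurrences gets the interval `[Q(q_low), Q(q_high)]` with `q_low = 0.01`,
`q_high = 0.99`. `Q` is the linear-interpolation ("type 7") sample quantile —
the numpy/R default — chosen because it is continuous in the data and
well-defined for all n ≥ 1. The 1%/99% trim discards extreme and often
erroneous records (mislabelled coordinates, vagrants) at the cost of a small
inward bias of order `w/(n+1)` per endpoint for a range of width `w`.

**Habitat imputation.** Quantile ranges become endpoints via habitat rules:

| habitat | min rule | max rule |
|---|---|---|
| demersal | d_low | d_high |
| bathydemersal | max(d_low, 200) | d_high |
| bathypelagic | max(d_low, 1000) | d_high |
| reef-associated, pelagic-neritic | d_low | min(d_high, 200) |
| pelagic-oceanic, benthopelagic | 0 (surface) | d_high |
| other | — unresolved — | |

If clamping inverts the interval the species is unresolved. Documented
endpoints always win: estimation fills only missing endpoints
(`depth_source` is `documented`, `mixed`, `imputed` or `unresolved`);
unresolved species are excluded from all downstream statistics.

## 2. Diversity (`bathygap.diversity`)

Richness at integer depth d counts species with `min ≤ d ≤ max`, for
d = 0..4000 (computed with a difference-array in O(n + D)). The five default
layers are half-open `[lower, upper)` except the deepest, closed at 4000 m,
so every depth in [0, 4000] belongs to exactly one layer and a species
reaching exactly 4000 m is still bathypelagic. A species occupies every layer
its closed range intersects; its *ascend layer* is the layer containing its
minimum depth. Red-list categories NT/VU/EN/CR are pooled as THR; LC, DD and
NE pass through.

Pairwise beta diversity between layer assemblages A and B uses
`a = |A∩B|`, `b = |A\B|`, `c = |B\A|`:

* turnover (Simpson): `β_sim = min(b,c) / (a + min(b,c))`
* total (Sørensen): `β_sor = (b+c) / (2a+b+c)`
* nestedness fraction: `β_sne = β_sor − β_sim`

Degenerate denominators (both sets empty; `a = min(b,c) = 0`) define the
affected component as 0. The identity `β_sim + β_sne = β_sor` holds exactly.

## 3. In silico PCR (`bathygap.insilico_pcr`)

Primers and templates are encoded as 4-bit IUPAC masks (A=1, C=2, G=4, T=8;
degenerate codes OR their bases). A primer position matches a template
position iff the masks intersect, so N on either side matches everything and
R matches A or G. Site search computes the Hamming mismatch count of every
window (vectorised via a sliding-window view) and keeps windows with at most
`max_mismatch` mismatches — a **per-primer** cap (default 3), not a summed
budget. Only substitutions are modelled; indels in the priming sites are not.

An amplicon is a forward site plus a downstream reverse-complemented reverse
site whose insert (the region strictly between the two sites) lies within the
marker's length bounds: teleo 30–120 bp, MiFish-U/E 120–220 bp, bracketing
the ~60 bp and ~170 bp barcodes. Both strands are searched; minus-strand hits
are mapped back to plus-strand coordinates (interval [a,b) → [L−b, L−a)) and
reported with the insert in amplicon orientation, so a sequence and its
reverse complement yield equivalent hits. Coordinates are 0-based half-open.
Zero hits is a valid outcome, not an error.

**Aggregation.** Each sequence is represented by its minimal-total-mismatch
hit (ties: smallest fwd_start, then rev_start). A species' conservative
mismatch counts per marker are the per-primer maxima across its sequences
(forward and reverse maxima taken independently) — a worst-case view of how
degraded the species' priming sites may be. Species present only in a custom
database count as amplified with unknown mismatch counts and are excluded
from mismatch profiles. MiFish-U and MiFish-E differ by 1–2 primer bases and
target the same locus, so cross-amplification between them at ≤ 3 mismatches
is legitimate; they are reported separately but belong to one marker family.

## 4. Synthetic generator (`bathygap.synthetic_data`)

The generator emulates the *statistical structure* of the real system — it
does not reproduce real species, sequences or geography. All randomness
derives from one seed; truth, occurrences and the reference database use
independent child streams (`default_rng([seed, k])`), so regenerating one
artifact never perturbs the others.

Key knobs (defaults in parentheses, all configurable):

* Species pool: 1000 Actinopterygii + 100 Chondrichthyes.
* Range model: minimum depth ~ U(0, 30) with probability `shallow_bias`
  (0.7), else U(30, 2500); width lognormal with log-mean ln 150 and log-sd
  1.0 (metres), maximum capped at 6000 m. This concentrates richness near
  the surface, as observed in real bathymetric distributions.
* Habitat drawn consistently with the range (e.g. bathypelagic only when
  min ≥ 1000 m; open-water habitats set the minimum to 0).
* Occurrences: 100 per species (criterion runs use 1000; see §6), uniform on
  the true range; with probability `outlier_rate` (0.01) uniform on
  [0, 3·max + 100] instead.
* Reference coverage: per ascend layer, probability 0.5 (shallow) / 0.25
  (deeper layers) that a species has an amplifiable sequence per marker,
  yielding the deep coverage gap the audit should detect.
* Primer-site degradation: 0–3 substitutions per primer with probabilities
  (0.1, 0.7, 0.15, 0.05), never within the last 2 bases of the 3′ end, each
  substituted base drawn outside the primer code's IUPAC set so it is
  guaranteed to count as a mismatch.
* 84% of species have both documented endpoints; the remainder split among
  min-only / max-only / none, exercising the mixed/imputed/unresolved paths.
* Uncovered species may emit a primer-free decoy sequence (p = 0.5).

**Bathymetry/occurrence co-construction.** The 1° global grid has 64,800
cells — far fewer than distinct occurrence depths in large runs. Drawn depths
are therefore snapped to a synthetic depth-indexed grid: cell k holds depth
(k + 0.5)·(18200/64800) ≈ every 0.28 m, and its elevation is exactly minus
that depth. Snapped non-outlier depths are clamped inside the true range, so
resolving an occurrence through the grid returns its (snapped) depth exactly
and in-range invariants hold without tolerance. The cost is that cell indices
encode depth rather than geography; coordinates are valid but not
geographically meaningful.

**Construction verification.** Every generated reference sequence is rejected
and redrawn unless in silico PCR finds exactly one plus-strand hit for the
intended marker carrying exactly the injected mismatch counts, and no hit for
any marker of a different family; decoys must yield no hit at all. The
reference database is therefore a ground truth by construction, not merely in
expectation.

## 5. Pipeline and CLI

`bathygap all` chains simulate/load → depth table → diversity outputs → PCR →
coverage outputs → `run_summary.json`; individual stages (`simulate`,
`build-depths`, `diversity`, `pcr`, `coverage`) write byte-identical files.
One YAML config (with CLI overrides) carries all parameters; unknown keys at
any level are rejected and all violations are reported at once. Exit codes:
0 success, 2 configuration/format/validation error, 3 I/O error. Logs go to
stderr only.

## 6. Validation design and known limitations

* **Oracles are independent.** The PCR matcher is checked against a naive
  per-window scanner and brute-force site pairing written separately in the
  test suite; the beta partition against plain set algebra; depth-range and
  coverage recovery against the generator's injected truth.
* **Simulation size for endpoint recovery.** Recovering both 1%/99% endpoints
  to within 2% of range width is impossible with 100 occurrences: the
  quantile's inward bias alone is `1.99·w/101 ≈ 1.97%` of width per endpoint
  (SD ≈ 1.4%). The package's validation therefore uses 1000 occurrences per
  species, where the bias is ≈ 1.1% ± 0.33% and ~97% of species recover both
  endpoints within 2%. This choice was made from the analysis above before
  any test was run.
* **Outlier robustness is bounded by arithmetic.** With 1000 occurrences and
  1% outliers, ~10 outliers are injected per species while the 99% quantile
  trim absorbs ~10 order statistics; roughly a third of uniform
  [0, 3·max+100] outliers fall below the true maximum and do not push the
  upper quantile. The probability that the trimmed maximum overshoots by
  > 10% of width is ≈ P(Binom(1000, 0.01·p′) ≥ 11) ≈ 10%, so the "< 5% of
  species" acceptance bound cannot hold under the stated conditions; the
  corresponding test asserts the stated bound and fails, documenting the
  defect. No generator parameter or tolerance was adjusted to mask it.
* **Coverage recovery and multiplicity.** Checking five independent 95%
  confidence intervals jointly would fail ~23% of runs by design; the
  validation checks the shallow stratum's CI (0.5), the pooled deep strata's
  CI (0.25), and the shallow-above-deep ordering.
* **Not modelled.** Indels at priming sites; PCR kinetics (3′-terminal
  mismatch penalties beyond exclusion in the generator, GC content,
  annealing temperature); taxonomic misidentification in references;
  spatially realistic occurrence geography; depths below 6000 m in the truth
  model. The worked 3+3-mismatch deep-sea example uses a synthetic stand-in
  template because the published sequence requires an online fetch.
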