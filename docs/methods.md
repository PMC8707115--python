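# Methods

This note documents the models, conventions and numerical choices behind
the package, and what the synthetic-data tests do and do not establish
about real data.

## Karyomorphometry

**Measurements.** The unit of input is one metaphase spread: an ordered
list of (long arm, short arm) lengths in µm, one entry per chromosome.
Orientation is normalized on construction (the larger value is always
the long arm), so transposed columns in a measurement file are harmless.
Derived per-chromosome quantities: total length TL = L + S, arm ratio
r = L/S ≥ 1, and relative length RL = TL × 100 / ΣTL, which sums to 100
over a spread by construction.

**Levan classes.** Chromosomes are classified by arm ratio into
metacentric (m), submetacentric (sm), subtelocentric (st) and
telocentric (t) using half-open intervals closed on the larger-class
side: r ∈ [1, 1.7) → m, [1.7, 3) → sm, [3, 7) → st, [7, ∞) → t. The
boundary convention is fixed by published practice of classifying
r = 1.70 as submetacentric. The acrocentric label "a" appears in
compiled formulas from other sources and is accepted as an input label
(one-armed, like t), but the classifier never emits it; the two labels
are used inconsistently across the literature and collapsing them on
output would misrepresent sources.

**Homologue pairing and aggregation.** No pairing algorithm is ever
stated in source publications; the package follows the standard manual
practice: within each spread, chromosomes are sorted by TL descending
and consecutive entries are paired as homologues. Per size rank, the
arithmetic mean and sample SD (n−1; a single spread reports SD 0) of
TL, L, S, r and RL are taken across spreads. r and RL are computed per
spread and then averaged (mean of ratios); the alternative, the ratio of
the mean arms L̄/S̄, differs from published mean r values at 2 dp in
several table rows, confirming mean-of-ratios is the field's convention.
Tests comparing recomputed r against printed means therefore restrict
themselves to rows where the two conventions coincide at 2 dp.

**Pair-level morphology.** Morphology is assigned per homologue pair
from the mean r of the larger (first-ranked) homologue, and both
homologues inherit the pair's class. The two measured copies are one
biological chromosome; classifying them independently lets measurement
noise split a pair across classes — exactly what happens in published
tables, where a homologue with mean r = 1.61 is printed submetacentric
because its partner sits at 1.70. The pair-level rule reproduces every
printed classification cell of the four reference tables. Display order
follows table convention: classes grouped m < sm < st < t, pairs sorted
by size within a class, homologues labelled "k" and "(k)".

**Summary quantities.** 2n = number of profiles; the karyotype formula
counts chromosomes (not pairs) per class; the fundamental number is
FN = 2·(m + sm + st) + (t + a), making FN additive over disjoint formula
unions and bounded by 2n ≤ FN ≤ 2·2n with equality on the right iff no
one-armed chromosomes; KL = Σ mean TL. Male (haploid) complements are
accepted with pairing disabled; summaries then report n.

**Heteromorphism.** A pair is flagged when its homologues fall in
different Levan classes in ≥ 50% of spreads, or when their mean TLs
differ by a factor > 1.25. Both thresholds are arguments; the defaults
separate a genuine size/morphology polymorphism (such as the published
submetacentric pair-15 case) from measurement noise, which under the
simulator's realistic noise settings (2% per arm) stays far below either
trigger.

**Rounding.** Table-facing output is rounded half-to-even to 2 dp
(configurable); all internal computation is at full precision.

## Record compilation

The packaged table transcribes the published Attina compilation: 61
records across 12 genera, including five newly described karyotypes.
Counting rules chosen to reproduce the published headline numbers:

- *Unidentified* counts **records** whose epithet is a morphospecies
  label ("sp.", "sp.1", …): 10.
- *Taxa with genome size* counts **distinct taxon names** with a
  non-missing 1C value; subspecies and morphospecies labels are distinct
  taxa, repeated populations of one taxon count once: 31.
- *Mean genome size* averages each non-missing record-level value once
  (0.3759 pg → 0.38 at 2 dp). Species-level deduplication gives the same
  rounded value; the record-level rule is kept for transparency.
- The published "58 chromosome counts"/"13 of 18 genera" figures are not
  reproducible from the table itself (61 rows, 12 genera; the
  deduplication rule behind 58 is unstated), so the summary reports the
  raw row count and the distinct (taxon, karyotype) count instead.

Formula strings are parsed termwise ("<int> <label>" joined by "+",
labels m/sm/st/t/a, duplicates summed) and re-emitted canonically in
m, sm, st, t, a order; parse∘format is the identity. Validation
classifies each record as diploid-consistent (formula sums to 2n),
haploid-consistent (sums to n — some sources report haploid formulas),
inconsistent, or no-formula; the statuses over the packaged table are
frozen in a golden file, because three rows of the published compilation
are internally inconsistent and the golden file is the contract. One
karyotype cell in the source table carries two alternative formulas; the
transcription splits them into `karyotype` and `karyotype_alt` columns
so both parse. Known genus misspellings (e.g. "Serycomyrmex",
"Myrmicocripta") are normalized via a packaged synonym map.

Heterochromatin C-band codes occupy five positions — centromeric (C),
pericentromeric (PC), interstitial (IN), short arm (SA), long arm (LA) —
each +, − or blank (unknown). Blank patterns are excluded from
band-richness denominators. The n ≤ 15 vs n > 15 comparison of mean
band richness is descriptive only; the underlying claim in the
literature is qualitative and no hypothesis test is attached.

## Trait mapping and clade stasis

Trees are read as rooted Newick with branch lengths in Myr and checked
for unique tips and ultrametricity (relative tolerance 1e-6 by default,
configurable). Traits attach to tips by exact normalized name match;
an optional genus-level fallback assigns a genus-consensus haploid
number (off by default). Where a taxon has several records, the haploid
number follows the newest primary count (new-report rows supersede older
compilation rows — relevant where a re-count differs from a previously
published number) and the genome size is the first non-missing value.

A clade is *uniform* for haploid number n when all trait-bearing tips
below it carry n and at least one does. Trait-less tips are neutral —
the analysis reasons over sampled taxa only; a strict mode that lets
them break uniformity is available. The report lists the *maximal*
uniform clades (parent not uniform), which are pairwise non-nested by
construction, with crown age (max tip-to-node path, = node age on an
ultrametric tree) and stem age (crown + subtending branch). Polytomies
are single clades. Correctness of the maximal-clade scan is tested
against a brute-force oracle that enumerates every internal node.

Genome-size departures are flagged multiplicatively: GS outside
[center/factor, center·factor], defaults 0.38 pg (the compilation mean)
and 1.3. A multiplicative band is the natural scale for a quantity whose
expansions are driven by repetitive-DNA gain.

The packaged chronogram is a hand-built genus-level tree (36 tips drawn
from the compilation's taxa) with approximate crown ages (root 61 Myr;
~45 Myr for the *Apterostigma* clade, ~25 *Cyphomyrmex*, ~19 its
costatus group, ~24.8 *Mycetomoellerius*, ~16.8 *Trachymyrmex*, ~13.7
*Atta*, ~4.7 *Amoimyrmex*). It encodes the accepted genus-level topology
for fixture purposes only — it is not an inferred chronogram, its node
ages are approximate inputs, and no reported quantity depends on a
specific age.

## Synthetic generators

All generators are pure functions of (inputs, seed) with a single
explicit numpy RNG per call.

**Spreads.** Around a true karyotype (per-pair TL and r), each spread j
receives a condensation factor c_j ~ exp(N(0, σ_c)) — median 1, shared
by all chromosomes of the spread, because condensation varies jointly
within a metaphase — and each arm an independent multiplicative error
(1 + ε), ε ~ N(0, σ_a), truncated to keep lengths positive. Defaults
σ_c = 0.10, σ_a = 0.02 reflect the spread-to-spread length variation
visible in published tables (per-chromosome SDs of roughly 10–40% of the
mean, dominated by condensation) while keeping within-spread ratios
accurate to a few percent. Under these settings, aggregation of 10
spreads recovers the true morphology class of every chromosome at least
99 times in 100 seeded replicates provided true ratios sit ≥ 0.05 from
every class boundary.

**Chromosome number.** Along each branch, a continuous-time chain with
fission (n → n+1) and fusion (n → n−1) at constant rates per Myr,
sampled by Gillespie steps; fusions are suppressed at n_min (reflecting
bound) and fissions at the optional n_cap (truncation), the cap being a
device for exploring the hypothesis of an upper limit to chromosome
number — the package takes no position on its biological cause. With
equal rates and boundaries far away the tip expectation equals the root
state (martingale property, verified by Monte-Carlo within 2 SE over
500 replicates). Default rates 0.05/Myr give a handful of events per
long branch on a ~60 Myr tree, comparable to the genus-level variation
in the compilation.

**Genome size.** Brownian motion along branches (step SD
gs_sigma·√length, default 0.02 pg/√Myr around a root of 0.38 pg),
floored at 0.01 pg; optionally each fission from a supplied event log
adds a fixed jump, emulating heterochromatin-driven genome growth after
centric fission. Tip variance is σ²·(root-to-tip depth), checked across
replicates.

No published quantitative model underlies these processes — the source
literature argues verbally from fission/fusion balance and
repetitive-DNA expansion; the generators are the minimal stochastic
models consistent with those mechanisms, built for pipeline testing and
exploration, not for inference. Likelihood fitting of either process is
out of scope. What passing recovery tests show is that the *pipeline*
is unbiased under the stated noise model; they cannot validate the
noise model itself against real micrographs, nor the tree or its ages.

## Limitations

- Homologue pairing by size rank can mis-pair chromosomes of nearly
  equal length under heavy noise; banding-informed pairing is not
  implemented.
- The record table transcription inherits the internal inconsistencies
  of its source (three formula/count mismatches, mixed diploid/haploid
  conventions, one genus with records at both n = 18 and n = 19); the
  package surfaces these rather than silently repairing them.
- The fixture tree is genus-level and approximate; clade ages reported
  on it are fixture inputs, not estimates.
- Morphospecies labels ("sp.", "sp.1") from different sources may or may
  not denote the same taxon; the package treats equal labels as equal
  taxa, which can conflate records (e.g. several "Apterostigma sp."
  rows reconcile to one trait entry).
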