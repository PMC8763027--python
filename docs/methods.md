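# Methods

## The model

The analysis treats RNA folding as a genotype–phenotype (GP) map from
sequences of fixed length `L` (genotypes, `4^L` of them) to coarse-grained
secondary-structure shapes (phenotypes). Two frequency measures over
shapes are compared:

- `f_pG` — the probability that a uniformly random sequence folds to a
  structure with shape `p` (estimated by *G-sampling*: draw, fold,
  abstract, count);
- `f_p` — the fraction of a natural database's (deduplicated) sequences
  whose predicted structure has shape `p`.

Under pure phenotype bias — no selection on shape, no database artifacts —
`f_p ≈ f_pG`. Departures are informative: a shape with `f_p` far above its
binomial expectation `N·f_pG` indicates selection for that shape or
over-deposition (researcher bias); far below indicates selection against.

`f_pG · 4^L` estimates the neutral set size of shape class `p` (the number
of sequences folding into it).

## Structure representation and abstraction

Structures are nested dot-bracket strings (no pseudoknots; extended
bracket alphabets are rejected at parse time). Parsing produces a loop
decomposition: helices are maximal runs of directly stacked pairs; the
loop closed by a helix is a hairpin (0 enclosed helices), bulge (1
enclosed helix, unpaired residues on exactly one strand), internal loop
(1, both strands), or multiloop (≥2); unassigned positions at the top
level form the external loop. Lonely pairs (helices of length 1) are
legal everywhere.

Abstract shapes follow the five-level hierarchy over `[ ] _`:

| level | brackets | underscores |
|---|---|---|
| 1 | one pair per uninterrupted helix | every maximal unpaired run |
| 2 | one pair per uninterrupted helix | external + multiloop runs only |
| 3 | one pair per uninterrupted helix | none |
| 4 | helices merged across bulges/internal loops | external + multiloop runs only |
| 5 | helices merged across bulges/internal loops | none |

Conventions fixed here (the hierarchy's verbal definition leaves them
open):

- **Open chain**: a structure with no pairs has shape `_` at *every*
  level, including 3 and 5. Some abstraction tools may emit an empty
  string at the underscore-free levels; a single uniform convention keeps
  spectra well defined for unfolded sequences, which the built-in folder
  does produce at small `L`.
- A loop enclosing exactly one helix is always a bulge/internal loop
  (merged at levels 4–5); multiloops require ≥2 enclosed helices.
- Canonical shape text has no whitespace; the reader accepts and strips
  spaces, so the spaced style `[ [] [] [] ]` parses to `[[][][]]`.

`project_shape` recomputes any coarser level from the level-1 string
alone, using only bracket-tree structure to recover each underscore's
context. It is deliberately an independent code path from `abstract_shape`
(string rewriting vs. tree traversal) and the two are required to agree on
random structures — a strong internal consistency check on both.

## Folding backends

- **Built-in (`builtin`)**: base-pair maximization (the classic O(L³)
  recursion) over Watson–Crick + GU pairs with hairpin loops ≥ 3.
  Tie-breaking is fixed — prefer leaving the leftmost position unpaired,
  then the smallest partner index — so outputs are bit-reproducible
  across runs and platforms. The DP and traceback are JIT-compiled with
  numba; ~10^4 L=30 folds/second on one CPU.
- **ViennaRNA (`vienna`)**: minimum-free-energy folding at default Turner
  parameters, 37 °C, via the python bindings; `suboptimal_structures`
  exposes all structures within `delta_e` kcal/mol of the MFE. The
  backend id (name + version) is recorded in every run manifest. A missing
  backend raises; the pipeline never silently substitutes one folder for
  another, because shape frequencies are backend-dependent.

The built-in folder is a combinatorial, not thermodynamic, model: its
spectra are internally consistent and exhibit the same qualitative
phenotype bias (heavy-tailed rank–frequency spectra, concave discovery
curves), but its `f_pG` values are not comparable to an energy-based
folder's and are not estimates of the thermodynamic map's frequencies.
All synthetic-data conclusions in the test suite are about pipeline
correctness, not thermodynamic realism.

## Sampling and spectra

Sequences are drawn i.i.d. per position from a base distribution —
uniform by default, or GC-parameterized as `((1−gc)/2, gc/2, gc/2,
(1−gc)/2)` for A, C, G, U — with numpy's PCG64 generator and an explicit
integer seed; streams are reproducible bit-exactly. Sampling is with
replacement (collisions are astronomically rare at the lengths studied).

A spectrum stores raw counts; frequencies, Wilson 95% score intervals
(chosen over Wald for behaviour at small counts; computed via
statsmodels), and NSS estimates are derived on demand and recomputed —
never trusted — when a spectrum TSV is read back. Zero-count shapes are
absent rather than pseudocounted. Ranking is by descending frequency with
byte-order tie-breaks, so ranks are reproducible.

The default abstraction level per length is 3 for L ≤ 55 and 5 for
L ≥ 70 (overridable per run): the balance point between resolving enough
structural detail and keeping per-shape counts large enough for reliable
frequencies shifts coarser as strands get longer.

## Morphospace sizing

Asymptotic shape counts use the published constants for minimum hairpin 3
/ minimum helix 1: `s3(L) = 1.85·1.46^L·L^(−3/2)`,
`s5(L) = 2.44·1.32^L·L^(−3/2)`. These are asymptotic in `L`; at small `L`
they can disagree with exact enumeration and both are reported side by
side without reconciliation. Because such counts are only meaningful to
an order of magnitude, a helper reports `round(log10(x))` (ties rounding
up). Exact counterparts — structure enumeration by the unique
first-position decomposition, the matching DP count, and distinct-shape
counts — are capped at L=18 by default (the count grows ~1.8^L). The same
DP powers an exactly uniform random-structure sampler used by the
property tests.

## Natural-vs-sampled comparison

Coverage is the fraction of the database's shapes also present in the
G-sample. Correlation is Pearson's r on `(log10 f_p, log10 f_pG)` over
shapes observed in both spectra (no pseudocounts; the count of excluded
natural shapes is reported), optionally restricted to shapes with a
minimum natural count — rare shapes' log-frequencies are dominated by
sampling noise. With fewer than 3 usable shapes the correlation is
reported as undefined rather than a number.

Outlier detection tests each shared shape's natural count `k` (of `N`)
two-sided against Binomial(N, f_pG) and applies Benjamini–Hochberg across
shapes; adjusted p < α (default 0.05) flags a shape as over- or
under-represented. The test treats `f_pG` as known, so the G-sample
should be substantially larger than the database (the default synthetic
scale uses a 10:1 ratio); with comparable sizes the estimation error in
`f_pG` inflates the false-positive rate.

## Synthetic databases

The generators emulate the statistical structure the analysis assumes
about a natural database, not its biology:

- **null** — uniform random sequences, deduplicated by resampling
  (natural databases are duplicate-free after preprocessing). Passing the
  null database through the full pipeline must recover `f_pG` — the
  package-level parameter-recovery check.
- **selected** — accept–reject with per-shape fitness weights
  (probability ∝ weight / max weight; unlisted shapes weigh 1). An
  acceptance-rate floor (10^−4) turns pathological weight maps into an
  explicit failure rather than a hang.
- **deposition bias** — one shape's count inflated ×multiplier with new,
  distinct carriers obtained by point-mutating existing ones (falling
  back to conditional rejection sampling), all other shapes' counts
  untouched.
- **gc_biased** — shifted base composition, for robustness runs against a
  GC-matched G-sample.

They do not imitate taxonomic composition, family structure, or homology
redundancy; a real database's `f_p` additionally reflects phylogenetic
correlation that these generators (and hence passing tests) say nothing
about.

## Study conditions and problem sizes

The default synthetic scale — L=30, level 5, 5,000 database sequences
against 50,000 G-samples with the built-in folder — yields ≈19 G-sampled
shapes spanning >4 orders of magnitude in frequency and finishes in
seconds on one CPU. The bias-calibration check uses 20 null replicates of
1,000 sequences each against one shared 50,000-sequence G-sample (sharing
is legitimate: calibration concerns the database-side noise, and the
shared `f_pG` error is an order of magnitude smaller). Oracle checks run
at exhaustively enumerable sizes: all 4^8 sequences for spectrum
frequencies, L ≤ 12 for folding against brute-force pair maxima, L ≤ 14
for structure counting.

With the max-pair folder the level-5 shape repertoire at L=30 is a few
dozen shapes, not hundreds — the combinatorial folder is more canalizing
than a thermodynamic one. The comparison statistics are computed over the
shapes that exist; correlations are restricted to shapes with ≥5 natural
counts where stated.

## Known limitations

- No pseudoknots, no consensus/alignment folding, no partition-function
  shape probabilities.
- The built-in folder's frequencies are not thermodynamic predictions
  (see above); quantitative reproduction of published natural-RNA
  correlations requires ViennaRNA and an RNAcentral export.
- The binomial outlier test ignores uncertainty in `f_pG`; keep the
  G-sample ≥10× the database.
- Asymptotic shape counts are unreliable below L ≈ 20; use the exact
  enumerators there.
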