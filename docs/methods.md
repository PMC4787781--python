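# Methods

## Background and model

N1-methyladenosine (m¹A) carries a methyl group on the Watson–Crick face of
adenine. When a reverse transcriptase (RT) meets an m¹A in the RNA template it
either stalls — producing an abortive cDNA whose 5′ end maps one position 3′
of the modified base — or reads through, frequently incorporating a
non-complementary nucleotide. Both events leave traces in RNA-Seq data from
libraries that preserve abortive cDNAs, and the *combination* of the two is a
signature specific enough to call m¹A sites. `rtsig` implements the full
desk-side half of that idea: per-position profiles from alignments, signature
feature extraction, a supervised classifier, sequence-context analyses, and a
generative read simulator that makes the entire pipeline testable without
sequencing data.

All coordinates are 1-based on template-sense references (tRNA/rRNA-scale,
U normalized to T). Reads are template-sense, end-to-end alignments; RT
proceeds from high to low reference coordinates, so a read's leftmost mapped
position is the RT stop.

### Profile statistics

For each reference position `p` with coverage `c(p)`, read-start count
`e(p)` and per-base call counts:

* **Arrest rate** `a(p) = e(p+1) / c(p+1)` — the fraction of reads covering
  `p+1` that end there and do not cover `p`. Undefined denominators (and the
  reference 3′ terminus, which has no `p+1`) are reported as 0 with an
  explicit `arrest_undef` flag rather than NaN, so downstream filters act
  deterministically.
* **Mismatch rate** `m(p)` — non-reference base calls among the A/C/G/T calls
  at `p`; N calls and deletions are excluded from numerator and denominator.
  The **mismatch composition** is each non-reference base's share of the
  mismatched calls (sums to 1 when mismatches exist, all zeros otherwise).
  Deletions are counted in coverage under their own column; insertions have
  no reference position and are ignored.

### Signature features

One record per reference adenosine passing the candidate filters
`coverage(p) >= 10` and `coverage(p+1) >= 15` (the 3′-adjacent position is
where the arrest signal lives). The classifier features are `a`, `m`, `m/a`,
the composition shares `comp_G`, `comp_T`, `comp_C`, and the
**context-sensitive arrest rate (CSA)**: the fold change of `a(p)` over the
mean arrest rate in the ±5 nt neighborhood, truncated at reference
boundaries. The neighborhood mean excludes the center position — including
it would damp exactly the signal the feature is meant to isolate — and skips
flagged-undefined positions; this is configurable. `m/a` with `a = 0` and
CSA with a zero-mean neighborhood fall back to an ε-denominator (ε = 1e−3,
flagged) to keep features finite for the classifier. The −1/+1/+2 context
bases are recorded but deliberately excluded from the feature set: the +1
base shapes the misincorporation pattern strongly, and letting the
classifier see it directly invites sequence-context overfitting.

"Confusable" negatives (the stringent validation setting) are unmodified
adenosines with a minimum m¹A resemblance: `a >= 0.2`, or `m >= 0.2`, or
`m >= 0.1` with at least two composition shares `>= 0.1` (OR semantics; all
thresholds configurable).

## The read simulator

The generator emulates the fragmentation/size-selection RT library:

| parameter | default | meaning |
|---|---|---|
| `depth` | 1000 | accepted reads per reference |
| `frag_len_range` | 50–150 nt | gel size-selection window for RNA fragments |
| `error_rate` | 0.001 | background per-base substitution probability |
| `occupancy` (per site) | 1.0 | fraction of molecules modified |
| `p_arrest` (per site) | 0.8 | P(RT terminates \| modified encounter) |
| `misinc` (per site) | +1-base preset | emission over A/C/G/T on read-through |

Fragment 3′ ends are uniform over the reference, lengths uniform in the size
window, clipped at the 5′ boundary; clipped fragments shorter than the window
minimum are discarded (size selection acts on the RNA, before RT). Each
molecule is modified at each covered site independently with probability
`occupancy`. cDNA synthesis walks the fragment 3′→5′; at a modified site the
read terminates with probability `p_arrest` so that its leftmost position is
`site+1` (an arrest exactly at the fragment's 3′ end leaves no cDNA and is
dropped), otherwise the emitted base is drawn from `misinc`; every other
emitted base is the reference base flipped uniformly to one of the other
three with `error_rate`. Reads are emitted directly as forward-strand
end-to-end SAM alignments, which removes the mapper from the loop.

The four `misinc` presets keyed by the +1 base encode the qualitative
pattern observed at natural and synthetic sites — a 3′-U neighbor gives a
strongly T-dominated template-sense mismatch signal, G and A neighbors give
G/T mixes with low C, a C neighbor a C-heavy, T-poor pattern — with a
residual ~0.1 share of the correct base (occasional correct dTTP
incorporation). No quantitative composition table exists for these patterns,
so the preset probabilities are this package's own calibrated defaults and
are fully configurable per site. The background read-through error at
unmodified adenosines is likewise a free parameter; 0.001 is a typical
RT+sequencing substitution floor.

Closed forms under this model, used throughout the tests: the expected
arrest rate at a site is `f·p_arrest`; the expected mismatch rate among
reads covering the site is
`[f(1−p_arrest)(1−misinc_A) + (1−f)·error_rate] / (1 − f·p_arrest)`.

**What the simulator does not emulate:** ligation and PCR biases, duplicate
molecules/unique molecular indices, RNA secondary structure effects on
arrest (a documented real-data phenomenon: equally modified sites can show
very different arrest strengths), position-dependent error profiles,
cross-mapping between near-identical references, and multi-modification
interactions beyond independent sites. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated generative model,
not robustness to every artifact of real libraries.

### Occupancy titrations and linearity

In an occupancy titration the arrest rate is affine in the modified fraction
`f` (slope `p_arrest`). The read-conditional mismatch rate `m(p)` is **not**:
arrested molecules leave the site's coverage, making it hyperbolic in `f`
(`∝ f/(1−f·p_arrest)`). The affine misincorporation measure — what a
titration probes — is the **per-molecule rate**: mismatched calls at `p`
divided by the coverage at `p+1` (a pre-arrest molecule count), with
expectation `f(1−p_arrest)(1−misinc_A)`. `site_measurements` reports both;
the linearity checks regress the arrest rate and the per-molecule rate
(R² > 0.99 at depth 10,000 over the 0/25/50/75/100% series).

## Supervised prediction

A 500-tree Random Forest over the 7 features; remaining hyperparameters are
sklearn defaults and are echoed into every report. Class votes are turned
into calls with a conservative tie-break: a site is m¹A only when strictly
more than half the trees vote for it. Validation settings: (i) balanced
positives vs uniformly random negatives; (ii) negatives restricted to
confusable sites; (iii) train on tRNA-tagged instances, test on rRNA-tagged
instances only (class-disjoint by construction). Performance is the mean ±
SD of sensitivity and specificity over 10 repetitions of a stratified
five-fold cross-validation (each repetition reshuffles the partition;
everything is reproducible from a single seed via spawned seed sequences).
Leave-one-out holds out one positive and one negative per round
(min(n_pos, n_neg) rounds). Leave-feature-out evaluates either each feature
dropped singly or the named groups full / arrest-only {a, csa} /
mismatch-only {m, comp_G, comp_T, comp_C}. The kNN baseline runs the same
harness with plain Euclidean distance on the raw (unstandardized) features,
as a deliberately basic comparator. ROC curves are built from out-of-fold
positive vote fractions and integrated by trapezoid.

## Sequence-context analysis

Compositions are mapped to ternary coordinates with corners G=(0,0),
T=(1,0), C=(0.5, √3/2) (a plotting convention, recorded in output
metadata): `x = comp_T + comp_C/2`, `y = comp_C·√3/2`; the mapping is affine
and injective on the simplex. Instance reduction proceeds in three stages —
replicate means per site; means over single-linkage groups of references
with >95% global-alignment identity (identity = identities / alignment
columns, end gaps penalized, scores 2/−1/−2); means over identical
(−1,+1,+2) context triples — and is idempotent. Hierarchical clustering uses
average linkage on Euclidean distances between composition vectors.

Cluster separation by the +1 base is tested with a permutation test defined
by this package (the original verification procedure for this observation is
not publicly specified, so no equivalence is claimed): statistic
S = mean between-group − mean within-group pairwise distance; p-value is the
add-one-smoothed exceedance fraction over label permutations. Groups with
fewer than two members contribute no within-group pairs. The test is exact
under exchangeability; its type-I error at α = 0.05 is verified at
0.05 ± 0.03 by Monte Carlo.

Mismapping risk between references is summarized by a Levenshtein distance
matrix (unit-cost edit distance, computed with the edlib library and checked
against an exponential-time recursion in the tests); near-zero distances
flag isoacceptor-style confusability.

## Problem sizes and verification

The standard synthetic benchmark used by the acceptance script and tests:
45 references (~120 nt, one fully occupied site each, `p_arrest` uniform in
0.7–0.9, +1-preset misincorporation, depth 5000), setting-(i) dataset of
45+45, 10×5-fold CV — mean sensitivity and specificity are computed at run
time and land at 100% across seeds. Parameter recovery runs a 4×4
(occupancy × p_arrest) grid at depth 10,000 against the closed forms (3
binomial-SE bands); the harder mixed benchmark (half arrest-dominant, half
mismatch-dominant sites, occupancy 0.35, depth 400) separates the full
feature set from either single channel. Counting kernels are verified
against brute-force per-read enumeration oracles on randomized instances.

## Limitations

Signature strength varies with RNA structure and site context in ways the
simulator does not model; occupancy estimates from profiles are
semi-quantitative at best (arrest + misincorporation gives a lower bound,
since read-through can incorporate the correct base). Other Watson–Crick
face modifications (e.g. m⁶,⁶A) can produce indistinguishable signatures and
require orthogonal evidence; distinguishing them is out of scope, as are
transcriptome-scale scanning with multiple-testing control and any
mapper-side processing.
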