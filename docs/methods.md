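# Methods

## Scope and data flow

The pipeline mirrors how an interception is traced in practice: an aligned
mtDNA fragment per specimen (the study system concatenates two
protein-coding mitochondrial genes to 1221 bp) is collapsed to a
haplotype, placed by corrected genetic distance against (a) the haplotypes
known from the established invaded-range populations and (b) a
geographically labelled native-range panel, and classified as local
resident / within-country jump dispersal / new arrival.  Record-level
metadata (month, transport, border stage, body size, life stage,
survival, predicted origin) is summarised separately from the genetics.

## Sequence handling

Alignments are read as FASTA (Biopython), validated for equal length,
unique identifiers and nucleotide/IUPAC content, and stored uppercase.
The reading-frame check translates codon-by-codon against a named genetic
code (Biopython's tables) and reports every stop codon with a 1-based
codon position.  The default code is vertebrate mitochondrial — the genes
involved are mitochondrial, and that table's extra stops (AGA, AGG) are
exactly what a numt or misalignment tends to reveal.  The frame is a
parameter because a trimmed fragment can start mid-codon.

Haplotype collapsing is exact character identity by default.  The
`ignore-ambiguous-sites` policy drops every column containing a gap, `N`
or ambiguity code in *any* sequence before comparison; this is a global
(not pairwise) mask so that the collapse relation stays transitive.
Labels are assigned in first-appearance order with a zero-padded prefix,
making output deterministic for a fixed input order; permuting the input
can only permute labels, never the partition (tested as a property).

## Distances

Site patterns are counted under pairwise deletion: a column enters a
pair's tally only when both sequences carry an unambiguous A/C/G/T there.
The TN93 correction is implemented from its closed form (see README); the
implementation is validated against an independent matrix-exponential
oracle — build the TN93 rate matrix, compute exact expected substitution
proportions at divergence *t* with `scipy.linalg.expm`, invert through the
closed form, and require |d − t| ≤ 1e-9 over 100 random parameter draws.
Jukes–Cantor and K2P serve as limiting-case cross-checks (uniform
composition, P₁ = P₂ collapses TN93 to K2P to ≤ 1e-12).

Numerical choices:

- **Composition scope.** TN93 uses the composition pooled over the whole
  input set by default (one composition is what is reported for an
  alignment); per-pair composition is a flag.
- **Saturation.** Any non-positive logarithm argument flags the pair
  `saturated` (value NaN).  Saturated pairs are carried in the matrix but
  refused by the NJ builder with the offending pairs listed — silently
  substituting a large value would distort the tree.
- **Degenerate composition.** A term whose denominator is zero (a missing
  base class) is skipped when its substitution class was not observed,
  and raises otherwise.
- **Rounding guard.** The correction is clamped at ≥ 0; floating-point
  cancellation can otherwise produce −1e-17 on near-identical pairs.
- **Homogeneity test.** The N×4 contingency statistic against pooled
  expected frequencies, df = 3(N−1), upper-tail p from `scipy.stats.chi2`
  (the regularised incomplete gamma function).

## Neighbour joining

Standard Saitou–Nei agglomeration with the rate-corrected Q criterion.
Determinism: ties in Q are broken by the lexicographically smallest
(row, column) pair in current matrix order.  Negative branch-length
estimates (non-additive input) are clamped to zero with the deficit moved
to the sister branch of the same join, preserving each cherry's summed
length; the raw estimate is kept on the node (`raw_length`) for
diagnostics.  Consistency is tested by exact recovery (topology and
branch lengths, via path-length matrices) on random 5–8-leaf additive
metrics, plus a cross-check against scikit-bio's independent NJ
implementation.  Trees are scikit-bio `TreeNode`s rooted at the final
trifurcation; monophyly of a labelled clade is judged on the unrooted
tree (the clade's leaf set or its complement must be a subtree leaf set).
Bootstrap support is out of scope — support values in this kind of study
come from likelihood/Bayesian runs, not NJ.

## Assignment cascade

Tolerances: `identical_tol` (default 0) and `close_tol` (default 0.003
substitutions/site).  The close tolerance is the upper edge of the
0.2–0.3 % band separating established-range haplotypes from previously
undetected variants of the same source region; it is explicit and
configurable because that band is a judgement call, not a law.  The
cascade classifies on the minimum distance to the established set, then
splits local-origin detections by locality membership in the established
range.  Tier-1/2 results carry a `local-or-same-source` caveat: mtDNA
alone cannot distinguish a resident from a fresh arrival out of the very
source region the established population came from, and the pipeline
surfaces that rather than resolving it.

Source regions for new arrivals come from the nearest native-range
haplotype; all ties at the minimum are reported and a prediction match to
*any* tied locality counts (deliberately generous, and documented here).
Prediction scoring is name-based with an explicit equivalence table —
the study reasons in named localities and approximate distances, so the
bundled table encodes its documented pairings (e.g. a town bordering a
named suburb is `exact`; localities ~80–100 km apart are `near`).
Locality normalisation is case-insensitive and punctuation-stripped;
parenthetical qualifiers are sub-regions: a bare name matches any of its
own sub-regions at the exact tier, two different sub-regions of the same
base only at the near tier.  Predictions listing alternatives ("X or Y")
score by their best alternative; missing or "Unknown" predictions are a
separate `no-prediction` tier that still counts in the denominator.

The cascade is packaged as a scikit-learn-style estimator
(`HaplotypeSourceClassifier`: `fit(panel)`, `predict`, `get_params`) so it
composes with sklearn tooling; the surrounding stages (I/O, trees, record
analytics) are plain functions, since they are not fit/predict-shaped.

## Record analytics

The interception tables ship as column-for-column CSV transcriptions.
Seasons use the austral mapping (Dec–Feb summer …), the only convention
consistent with every printed seasonal proportion.  Percentages are
rounded half-away-from-zero to integers (the exact-tier share is also
reported at one decimal); denominators count detection events, so the one
group detection (eight animals in one container) is a single record with
`group_size = 8`.  Adult status is taken from the recorded flag, not
recomputed from body length.  Two fixture notes: the recorded adult flags
for the within-country table give 15/24 = 62.5 %, slightly above the
prose summary of that quantity; and the within-country transport value
printed as "Truck or trail" is transcribed as "Truck or rail" (the
enumeration the table otherwise uses).  One emerging population
(Palmerston North, established c. 2007) carries an establishment-year
flag and is excluded from the established range by default;
`established_localities(as_of_year=...)` includes it from that year on.

## Synthetic data

The generator emulates exactly the structure the cascade relies on, with
defaults set to the study system: 1221 bp, nine clades, between-clade
divergence 1.8–8.3 %, within-region divergence ≤ 0.3 %, six established
haplotypes drawn from one source locality of one clade, and the skewed
composition A = 0.326, C = 0.310, G = 0.120, T = 0.244.  Mutations are
discrete site substitutions at distinct positions with replacement bases
drawn ∝ (class weight × stationary frequency), purine transitions
weighted 20, pyrimidine 10, transversions 1 — a transition bias in the
range typical of squamate mtDNA.  Clade ancestors take half the target
band each from a common root, and pairwise p-distances are checked and
topped up where random site overlap pulls a pair under the lower band
edge (auditable, and sufficient for band emulation; no continuous-time
matrix exponential is simulated).  Localities within a clade sit ~1 %
apart — far above the within-region band and far below the between-clade
band — so source-locality assignment is well-posed.

Detections: local residents and within-country movements are established
haplotypes with up to ⌈intra-band × length⌉ − 1 extra substitutions
(i.e. same-region variation, strictly inside the close tolerance by
construction), differing only in locality; new arrivals descend from
native haplotypes outside the established clade — arrivals from the
established source region itself are excluded because they are
molecularly indistinguishable from residents (the caveat above).
Synthetic predicted origins are correct except with a configurable error
rate.  All randomness flows through one integer seed
(`numpy.random.default_rng`); identical seed + config gives
byte-identical output.

What the generator does **not** emulate: coalescent genealogy within
regions, rate variation among sites, indels and ambiguity codes, numts,
or uneven sampling of the native range.  Passing recovery tests therefore
demonstrates that the cascade is correct *given* well-separated
divergence bands — which is what the real system shows — not that it
would be robust to overlapping bands; the boundary-straddling test shows
accuracy degrading exactly there.  An optional coding mode restricts
mutations to third codon positions and forbids stop codons, for
integration tests of the reading-frame check; it is off by default since
random sequences are not open reading frames.

## Problem sizes in tests

The default test run uses 4–9 clades, 300–600 bp small panels for unit
tests and the full 9-clade, 1221 bp configuration with 300 detections for
the recovery check; the whole suite and the acceptance script each run in
seconds on one core.

## Known limitations

- Nearest-haplotype assignment, not probabilistic placement: no
  likelihood or posterior on the source region, and clade-level placement
  via tree topology is intentionally not used for assignment.
- The TN93 distance assumes stationarity and no among-site rate
  variation; +I/+G-style corrections and model selection are out of
  scope.
- Region equivalences are curated names, so scoring generalises only as
  far as the equivalence table does; users can extend the CSV.
- Distances to the established set use the same pooled panel composition
  as panel-internal distances; for very short queries this pooling can
  differ from a per-pair composition (available by flag).
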