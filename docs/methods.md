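# Methods

`motifinfo` discovers short linear motifs (SLiMs) — degenerate, fixed-width
amino-acid patterns of width 2–10 — whose presence or absence across a
proteome is maximally informative about a per-protein behavior, and then
characterizes each reported motif with non-parametric randomization
statistics. This note records the model, the numerical choices, and what the
synthetic benchmarks do and do not establish.

## Model

A motif is an ordered list of allowed residue sets, written in the standard
dialect (`S`, `.`, `[RK]`). Its *motif profile* is the binary vector over the
analysis universe marking proteins with at least one exact match. The
*behavior profile* assigns each protein a class: discrete labels directly, or
quantitative values split into equally populated bins (default 10). The score
of a motif is the plug-in mutual information (bits)

    MI(M; B) = sum_{m,b} p(m,b) log2[ p(m,b) / (p(m) p(b)) ]

between its profile and the behavior profile. MI handles binary, multi-class,
and binned quantitative behaviors uniformly, and captures both over- and
under-representation without an explicit background model.

Discovery is two-step:

1. **Seeding.** Every exact k-mer (defaults k = 3, 4, 5) occurring in at
   least `min_carrier_proteins` (default 10) distinct proteins is scored by
   MI; seeds are ranked by MI with lexicographic tie-breaks.
2. **Greedy refinement.** Each gated seed is refined by sweeping positions
   left to right; at a position the candidate moves are adding one residue to
   the allowed set (bounded by `max_degeneracy_per_position`, default 5),
   removing one residue, or replacing an interior set with the full wildcard.
   The single move with the largest strict MI increase (> 1e-12, guarding
   float ties) is accepted; sweeps repeat until a full pass accepts nothing
   (at most `max_refine_passes` = 10). Terminal positions never become
   wildcards — a terminal wildcard changes no carrier set and would create
   degenerate duplicate motifs. Width is fixed at seed width; multi-width
   output comes from iterating k.

A motif is *significant* only under the strict rule: its MI must exceed every
one of `n_rand` (default 10,000) null MI values obtained by permuting the
behavior labels. Seeds are gated before refinement, and the refined motif is
re-tested against a fresh null (stricter than gating only once; refinement
can only raise MI on the observed labels, so re-testing guards nothing by
itself — the seed gate is what carries the specificity). Reported alongside:
the null-sample z-score, the never-zero empirical p-value
(1 + #{null >= obs}) / (1 + n_rand), a jackknife robustness score (10 trials
keeping a random 2/3 of the universe; the score counts trials in which the
strict test still passes; trials emptying a class are resampled up to 100
times), and per-class hypergeometric enrichment. Robustness below the
configurable floor (default 6/10) flags the motif but does not drop it.
Redundancy is controlled with a conditional-MI test: a candidate is kept only
if, for every already-accepted motif, permuting behavior labels *within the
strata* of the accepted motif's profile leaves the candidate's conditional MI
significant — a candidate that merely restates an accepted carrier set scores
zero.

## Null sampling

For a binary presence profile, the joint table under a uniform label
permutation is fully determined by the per-class carrier counts, whose null
distribution is multivariate hypergeometric. The permutation null is
therefore sampled exactly from that distribution rather than by materializing
permutations; the two procedures are distributionally identical, and the
shortcut makes 10,000-permutation gates affordable at proteome scale. The
conditional test does the same within each stratum. Statistics that are not
functions of the joint table alone (positional bias, co-localization) permute
labels explicitly.

With few carriers the MI statistic is coarsely discrete, so the strict rule
is conservative: the observed value must *strictly* beat every null draw, and
ties — common when the null can reach the observed table exactly — count
against the motif. This is what keeps the false-positive rate low for rare
seeds, and it also makes empirical p-values super-uniform for binary-vs-
binary profiles; calibration is exact (p uniform on the attainable grid) when
either profile has enough classes for MI to be effectively continuous.

## Characterization

- **Positional bias.** Each instance's position is normalized by the number
  of valid starts, L − w + 1, so every width can reach the last bin; the
  positions are split into 10 equal-width bins and the MI between bin and
  host-protein class is tested by shuffling class labels across instances
  (abstains below 20 instances). Histograms split instances into proteins of
  significantly over-represented ("target") classes versus all others.
- **Co-occurrence / co-localization.** Co-occurrence is the MI between two
  presence profiles with a permutation null; direction (co-occur vs co-avoid)
  compares observed joint presence with its independence expectation.
  Co-localization asks whether the inter-motif distance (minimum |start_a −
  start_b| over instance pairs) is informative of behavior among co-carrying
  proteins: distances are split into 3 equal-population bins and tested by
  label shuffling (abstains below 20 co-carriers). The distance construction
  is one concrete reading of "spacing informative of behavior"; alternatives
  (e.g. closest-pair midpoints) would be equally defensible.
- **Domain overlap.** Per domain: a hypergeometric co-occurrence p, plus an
  overlap z-score comparing the number of instances intersecting a domain
  interval against a uniform-placement model: for instance i in a
  domain-bearing protein, p_i is the fraction of start offsets whose window
  would intersect the domain, and z = (ΣO_i − Σp_i) / sqrt(Σ p_i(1−p_i)).
  Positive z marks a domain signature (the motif is a conserved fragment of
  the domain); negative z marks a motif lying apart from the domain. The
  placement model reproduces the sign semantics; published magnitudes from
  other null models need not match.
- **Disorder.** An instance counts as disordered when more than half of its
  residues fall inside (merged) disorder intervals — instances and intervals
  rarely nest exactly, so a majority rule is needed; the motif's disorder
  score is the disordered fraction of its instances, and a percentile against
  all same-width exact k-mers contextualizes it (ties count half).
- **Known-motif similarity.** Max over ungapped offsets (≥ 2 aligned
  positions) of the mean per-position Jaccard index of allowed sets, with any
  wildcard-involving position contributing a fixed 0.05 so wildcard-heavy
  patterns cannot match everything. Scores are in [0, 1], symmetric, and a
  catalog match above 0.5 is called. Biological-context agreement (the
  known / semi-novel distinction) is left to the user as a manual field.
- **Term enrichment.** Upper-tail hypergeometric per flat term,
  Bonferroni-corrected over terms tested. No ontology propagation.

Enrichment heatmap cells are Bonferroni-corrected per motif over (classes ×
2 tails), since both tails are displayed; the number of motifs tested is
recorded in the output metadata rather than folded into the correction.
Signed scores are −log10(p_over) (positive = over-represented) or
+log10(p_under) (negative), with p floored at 1e-300.

## Synthetic data

The generator emulates the study conditions the statistics are meant for:
i.i.d.-residue proteomes with truncated-normal lengths (mean 400, sd 100,
min 20 by default — yeast-like scale), uniform residue frequencies unless
specified, and planted signals with exact ground truth. Planted instances
*overwrite* sequence content at a drawn position (uniform, or the first/last
10% of valid starts), so lengths and recorded positions stay exact; chance
carriers of the planted pattern are recorded as "incidental", letting
recovery metrics use either the strict (planted-only) or lenient (all
matching proteins) carrier set. With uniform residues and length ~400, the
degeneracy-40 pattern SP.[RK] matches ~10% of background proteins, so a
penetrance-0.7 planting into a 250-of-2,000 class reproduces the ~70% vs
~10% carrier-rate geometry typical of real kinase-interactor profiles.
What the generator does not model: realistic residue composition,
compositional autocorrelation, homologous sequence families, or
disorder-aware placement. Passing benchmarks therefore demonstrate estimator
correctness, calibration, and power under clean planted signals — not
performance on real proteomes, where correlated sequences can inflate carrier
counts and where behavior labels are noisy.

## Problem sizes and determinism

The benchmark suite uses 2,000-protein proteomes for recovery/specificity,
600–1,200 for interaction and quantitative scenarios, and 150–300 for
single-statistic checks; discovery gates run at 1,000 permutations in power
scenarios and 10,000 in the specificity control (the default the strict rule
is defined at). At 1,000 permutations and ~5,000 abundant seeds the expected
number of strict-rule false seeds per shuffled dataset is 1–2; at 10,000 the
pipeline reports well under one motif per shuffled dataset, the regime the
method is designed for.

All randomness flows from one caller-supplied master seed through
SHA-256-derived per-component sub-seeds (component label + trial index), so
every reported number — including every permutation draw — is exactly
reproducible, and sub-streams stay independent under reordering of
components.

## Known limitations

- Non-canonical residues (X, U, B, Z, O, J, `*`) never match any motif
  position, including the wildcard; regions of ambiguity codes are invisible
  to discovery.
- Proteins absent from the behavior file are excluded from the analysis
  universe entirely; constructing an explicit background class is the
  caller's responsibility.
- The greedy refinement is a local search with a fixed proposal order; on
  noisy data it may prune one residue from an effectively-wildcard position
  or append a low-count residue when doing so raises MI by chance.
- Variable-length or gapped motifs, regex quantifiers, and score-matrix
  matching are out of scope; matching is exact set membership at fixed width.
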