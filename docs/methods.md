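# Methods

This note records the models, conventions, and numerical choices behind
each stage, what the simulator does and does not emulate, and the known
limitations. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Synthetic communities

The simulator generates the statistical structure the analysis chain
assumes, with every random draw derived from one seed:

- **Taxonomy.** A rooted tree over the ladder
  root > domain > phylum > family > genus > species (class and order are
  padded in on load as `unranked_<rank>_<id>` nodes when a table skips
  them, so rank profiles always have a well-defined level). Each species
  has exactly one parent genus; genera are grouped pairwise into families
  and families into phyla.
- **Reference genes.** Per species, `genes_per_species` i.i.d.-uniform DNA
  sequences with lengths uniform in `gene_length_range` (default 30 genes
  of 400–1200 bp). Random references make cross-species identity ~25%,
  which is the *easy* regime for recruitment specificity; real congeneric
  genomes share far more sequence, so the measured cross-recruitment rate
  is a floor, not a field estimate.
- **Strains.** A strain is the reference with each site substituted
  independently at probability `strain_divergence` (always to a different
  base). Defaults put the sequenced environmental strain at 8% divergence —
  the ~92%-identity regime typical of recruiting an environmental
  population against a named reference genome. An optional single-base
  indel rate (default 0) exists so gap handling is testable; the default
  model is substitution-only because Illumina error and most within-species
  SNV structure are substitution-dominated.
- **Abundances.** Log-normal (μ = 0, σ = 1.5), normalized — a few dominant
  species and a long tail, the dominance structure a high Simpson λ
  implies. No claim is made that any particular field community is
  log-normal; it is the standard stand-in when only dominance is known.
- **Reads.** 2×250 bp pairs from normal-length fragments (350 ± 40 bp;
  resampling the source gene when a fragment cannot fit, erroring after
  100 rounds); the reverse mate is reverse-complemented. A pair is
  host-derived with probability `host_fraction` (default 0.1), drawn from
  one long random host genome (default 200 kb) standing in for a
  host + eukaryote reference panel. Sequencing error is per-base
  substitution at `error_rate`; qualities are constant at
  Q = round(−10·log₁₀ error_rate), capped to [2, 40]. The default error
  rate is 5×10⁻⁴ (Q33), the mostly-Q30+ regime of a well-behaved 2×250
  run; under the constant-quality model this is also the regime in which
  the Q>30/98% filter is satisfiable at all. Not emulated: PCR duplicates,
  chimeras, quality drift along the read, adapter read-through, GC bias.
  Passing tests therefore demonstrate the *logic* of each stage and its
  calibration under clean assumptions, not robustness to every artifact of
  real libraries.

Ground truth records each pair's origin (species or host), the true
abundance vector, and per-species divergence; QC, recruitment, and LCA
stages are scored against it.

## Read QC

- **Merging.** The reverse mate is reverse-complemented; overlap lengths
  are scanned from the longest possible downward and the first with
  mismatch rate ≤ 0.25 (and length ≥ 10) wins — i.e. the longest
  admissible 3′ overlap. In the overlap the higher-quality base wins and
  its quality is kept (ties keep the forward base; agreeing bases keep the
  higher quality). Pairs with no admissible overlap are counted and
  dropped. Dovetailed pairs (fragment shorter than the read) are not
  handled specially; the simulator never produces them.
- **Quality rule.** Pass iff at least 98% of bases are strictly above Q30
  (both knobs configurable; the fraction boundary is inclusive). The rule
  is a whole-read pass/fail, not a trimmer: downstream recruitment needs
  full-length reads for the 0.8 aligned-fraction filter to mean what it
  says.
- **Host subtraction.** Reads are tested against an *ordered* reference
  panel; the first reference producing an alignment with identity ≥ 0.9
  over ≥ 0.8 of the read removes the read and is credited with it
  (sequential semantics, matching the discard-as-you-go filtering style).
  Kept + removed partitions the input exactly. The thresholds mirror the
  recruitment filter and are configurable; they are conventions of this
  package, not published constants.

## Alignment engine

One seed-and-extend engine backs host subtraction and recruitment: an
exact k-mer index (default k = 15) over the reference records; probes at
non-overlapping read positions on both strands, falling back to
every-position probing when nothing seeds; candidate records/diagonals are
extended by edit-distance alignment (edlib, semi-global over the read) and
the resulting path is rescored with affine-gap scoring (match +1,
mismatch −1, gap open −4, each additional gap column −1 — this package's
constants; ranking and LCA score floors operate on this score). Because
unit-cost edit paths can re-explain adjacent substitutions as equal-cost
indel pairs, the pure-substitution interpretation at the dominant seed
diagonal is also evaluated and preferred when its affine score is at least
as good; for substitution-only reads this is the exact affine optimum
(verified against a full Smith–Waterman oracle in the tests). Since the
whole read is consumed by the semi-global extension, pipeline-produced
hits have aligned fraction 1; partial hits arise only from external
aligners or constructed inputs, and the 0.8 filter applies to them
inclusively.

Limitation: exact seeding cannot find a read whose substitutions are
spaced so that no clean 15-mer survives (possible adversarially at ≥ ~7%
divergence, vanishingly rare under random placement at ≤ 10%); seed
length is configurable where that matters.

## Pan-genomes

Genes are pooled per species, sorted longest-first (ties by gene id), and
clustered greedily in the cd-hit-est style: each gene joins the *first*
existing representative (creation order) reaching the identity threshold
(default 0.90), else founds a cluster. Identity is matching columns of
the optimal affine-gap alignment of the shorter sequence against its best
region of the longer, divided by the shorter length — the cd-hit
convention, stated explicitly because it changes membership for nested
genes (a contained gene scores 1.0). Two accelerations:

1. the shared-word prefilter (≥ 1 exact 8-mer in common) — a heuristic
   that can, on adversarial inputs, reject a pair whose identity reaches
   the threshold; an exact mode without it exists and the two are
   compared on random pools in the acceptance suite;
2. an *exact* triage bound — any alignment of the shorter (Ls) inside the
   longer (Ll) has edit count ≥ the global edit distance D, so matches
   ≤ Ls − (D − (Ll − Ls))/2; pairs whose bound falls below the threshold
   skip the affine alignment. Unlike the word prefilter this never
   changes a decision.

The affine alignment itself is Biopython's pairwise aligner; tests check
its optimal scores against an independent Gotoh dynamic program.

## Recruitment profiles

Hits below 0.8 aligned read fraction are dropped (inclusive boundary);
per read per species only the best-score hit survives (ties: higher
identity, then lexicographic target id), so paralogous representatives
are not double-counted while a read may still count toward several
*species* — the LCA stage resolves that ambiguity taxonomically rather
than by arbitrary assignment. Coverage depth divides aligned read bases
by pan-genome length (depth-style X units); breadth (fraction of
positions covered ≥ 1×) is reported alongside. Depth vectors live on the
concatenated representative axis and conserve aligned bases exactly
(integer identity, asserted in tests). Consensus is a per-position
majority vote of aligned read bases; ties fall back to the reference
base and uncovered positions are N. Coordinates are 0-based half-open
internally and 1-based inclusive in TSV outputs (stated in headers).
Recruitment is nucleotide-space only; six-frame (protein-space)
recruitment is out of scope.

## LCA profiling and marker screening

Read assignment is MEGAN-style with configurable defaults (score floor
50, top-percent window 10%): hits under the floor are discarded, hits
within the window of the best score vote, and the read is placed on the
deepest node ancestral to all voters. The defaults are conventions, not
published constants. Rank profiles climb each assignment to the requested
rank; assignments above it land in `unclassified_at_<rank>`, so profile
totals conserve the assignment count. Marker-gene screening (16S-style)
keeps reads whose best local alignment to the marker database spans ≥ 20
columns with an e-value ≤ 1e-10, where e-values use Karlin–Altschul
ungapped DNA statistics (λ = 1.33, K = 0.621 for +1/−2 scoring) with a
total-database-length size correction; the e-values are approximate and
only the threshold behaviour is contractual.

## Diversity and differential abundance

Chao1 is bias-corrected by default so F2 = 0 stays finite; the classic
F1²/(2F2) form is selectable and refuses F2 = 0. Shannon uses natural
log. Simpson is reported both as λ (dominance) and 1 − λ (Gini–Simpson)
because "Simpson diversity" is used both ways in the literature; no
adjudication is attempted. Sample clustering is complete linkage on
Bray–Curtis distances of relative proportions, with samples sorted
lexicographically first so ties break deterministically; the newick
branch lengths are merge-height differences.

The group test is a Welch t on proportions with a label-permutation null:
all C(n, nA) label assignments are enumerated when there are ≤ 2000
(p = exceedance count / assignments, so the identity assignment enforces
p ≥ 1/assignments), otherwise B random permutations give
p = (1 + exceedances)/(B + 1). Zero-variance features get t = 0 (p = 1)
when means agree and ±∞ when they do not. The FDR is estimated from the
same permutations: FDR(t) = mean permuted exceedance / max(1, observed
exceedance); a feature's q is the minimum FDR over thresholds up to its
|t|, monotonized and clipped to [0, 1]. Comparing two *unreplicated*
profiles is handled by expanding each single sample into multinomial
pseudo-replicates of the same depth — a documented stand-in for
biological replication in the metastats tradition, not a substitute for
it: with pseudo-replicates the test calibrates against resampling noise
only, and its p-values should be read as descriptive. Fold enrichment is
the focal sample's (or focal group's mean) proportion over the
across-sample mean, with zeros replaced by half the smallest nonzero
proportion in the table.

## Pipeline and reproducibility

The pipeline validates its whole config (pydantic, unknown keys rejected,
thresholds range-checked) before any stage runs. One global seed fans out
to per-stage streams through fixed offsets, and independent samples of
the same community use distinct sub-streams, so stages and samples can be
re-run in isolation. Each stage records a parameter hash and sha256
checksums of its outputs in `run_manifest.json`; a failure halts the run,
names the stage, and leaves partial outputs plus a `FAILED` marker.
Identical config + seed reproduce byte-identical outputs (asserted in the
acceptance suite).

## Problem sizes used in the checks

The acceptance suite exercises: alpha-diversity formulas on 20 fixed
vectors (< 1e-12); clustering prefilter-vs-exact equivalence on 50 random
pools of up to 50 sequences ≤ 1 kb; recruitment recovery on a 10-species,
100,000-pair community (Spearman of coverage vs truth, per-species
identity recovery within 0.01 at ≥ 5×, cross-recruitment ≤ 0.1%); LCA
versus path-intersection brute force on 1,000 hit sets over a ~200-node
taxonomy; host subtraction sensitivity/specificity on 20,000 pairs at 30%
host fraction; permutation-test exhaustive equality at 7 observations,
null p-value uniformity over 1,000 features, and FDR calibration over 20
null replicates; and byte-level determinism of two full pipeline runs.
`scripts/acceptance.py` reruns the headline study at 50,000 pairs. These
sizes were chosen as the smallest at which the targeted statistical
properties are identifiable with comfortable margins.
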