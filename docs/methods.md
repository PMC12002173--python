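# Methods

This note documents the models and procedures implemented in
`pseudolock`, the choices behind them, and what the synthetic-data
generators do and do not emulate.

## Dollo parsimony reconstruction (`pseudolock.dollo`)

A binary character (gene, domain, intact active site) evolves under the
Dollo assumption: it is gained exactly once and can only be lost
thereafter. Given a rooted tree (polytomies allowed) and tip states in
{0, 1, missing}, `infer_dollo` places

* the **gain** on the edge above the MRCA of all state-1 tips (the
  virtual root edge when that MRCA is the root), and
* one **loss** on the stem edge of every *maximal* subtree of the gain
  clade that contains at least one observed 0 and no observed 1, where
  the parent's subtree still contains an observed 1.

**Minimality and uniqueness (proof sketch).** Any single-gain history
must place the gain on or above the MRCA edge: a gain below it could not
reach all carriers. Each maximal all-absent subtree must contain at
least one 1→0 transition on the path from the gain to each of its
observed-0 tips, and distinct maximal subtrees are edge-disjoint, so
every admissible history has at least as many losses as there are
maximal all-absent subtrees — the count the construction attains.
Conversely, moving any loss deeper splits one event into several, and
moving it higher would silence an observed carrier; hence the optimum is
unique. The exhaustive-search oracle in the test suite confirms
agreement on hundreds of random trees.

**Missing data.** Missing tips are excluded from the MRCA computation
and from the loss rule (an all-missing subtree is never called a loss),
then imputed to the reconstructed state of their parent. This means an
unsampled genome never manufactures a loss event; the cost is that a
genuinely lost gene in an unsampled lineage is invisible, so loss counts
are conservative ("at least N losses").

**Edge identity.** Edges are addressed by their child node's label;
unlabeled internal nodes are auto-named `nK` by preorder index at parse
time, so annotations are stable across reruns.

## Active-site integrity calling (`pseudolock.active_site`)

PPM-family (PP2C-type) phosphatases require at least the M1 and M2
divalent metal ions for catalysis; the M3 site is dispensable. A
`CatalyticSiteModel` lists metal-coordinating positions on an ungapped
reference numbering (PPM1A by convention) with their allowed residues
and a required flag. Positions are mapped through the alignment by
counting non-gap reference characters, and each sequence is called:

* **active** — all required M1 and M2 positions carry allowed residues;
* **pseudo** — any required M1/M2 position mismatched; a gap counts as a
  mismatch, since a deleted coordinating residue cannot bind metal;
* **ambiguous** — a required position could not be mapped (reserved for
  externally supplied column maps with reference gaps).

A cysteine at any M2-role column raises `m2_zinc_flag`: replacement of
an M2 aspartate by cysteine converts the site into a structural
zinc-binding constellation, the signature by which human PHLPP2
(C799/D820/D822/D1024) was recognized as a zinc protein rather than a
phosphatase. The default allowed set for aspartate positions is strict
{D}; a conservative mode may add E. M3 mismatches are reported but never
affect the class.

The shipped `data/ppm1a_sites.json` numbering is an approximate
transcription from the structural literature and is meant to be replaced
by the user's own model file when exact numbering matters; the engine is
agnostic to the numbering scheme.

Conservation profiles report per-column residue frequencies over
non-gap characters and information content `log2(20) − H` bits; all-gap
columns are reported as undefined rather than raising.

## Phylogenomic profiling (`pseudolock.phyloprofile`)

Association between a query gene and each candidate is the **phi
coefficient** — Pearson correlation specialized to binary variables,
computed from the 2×2 contingency table with pairwise deletion of
missing entries; any zero margin makes phi undefined. Phi was chosen as
the simplest symmetric measure of binary co-distribution; Jaccard-style
overlap measures conflate prevalence with association.

**Permutation null.** Tip-shuffling ignores phylogenetic
autocorrelation and overstates significance, so the null preserves the
tree, the gene's Dollo gain edge, and its loss count, and re-places the
losses. Two placement distributions are implemented:

* `cascade` (default): losses are redrawn from the Dollo cascade itself
  — an active lineage loses with a per-branch probability estimated
  from the observed history (losses / edges at risk) — conditioned on
  the reconstructed loss count by rejection sampling. This matches the
  generative weighting of loss sets, which favors losses that prune
  large subtrees.
* `uniform`: losses placed uniformly over non-nested edge sets within
  the gain clade. This is the small-rate limit of the cascade and is
  measurably anticonservative at realistic loss rates (at 0.1 per
  branch the null p-value distribution departs from uniform and the
  empirical type-I error at α = 0.05 runs ≈ 0.067); it is retained for
  comparison.

p = (1 + exceedances) / (1 + n_perm), one-sided for large phi; q-values
are Benjamini–Hochberg across genes. Ranking is by descending phi with
lexicographic tie-breaks; undefined-phi genes rank last.

## Mutation-burden comparison (`pseudolock.burden`)

Rates are per-gene totals normalized by protein length — substitutions
per 1,000 aa, matching aggregated COSMIC-style counts; nonsynonymous
pools missense, nonsense and frameshift, with nonsense/frameshift
counted as truncating.

**Hotspots.** For a codon with k of the gene's m nonsynonymous records
over L codons, p = P[Binomial(m, 1/L) ≥ k]. Benjamini–Hochberg is
applied across **all L codons** (unmutated codons contribute p = 1):
correcting only across codons that happened to collect hits ignores the
selection effect and, at realistic event counts, calls a spurious
hotspot in ~16% of purely uniform genes at α = 0.05; with the full-gene
correction the null false-call rate stays below α. A hotspot further
requires k ≥ 3.

**CNV skew.** skew = (CNG − CNL) / (CNG + CNL) over per-sample calls,
0 when no events.

**Class rule.** tsg_like: truncating fraction ≥ 0.2 and skew ≤ −0.3;
oncogene_like: ≥ 1 hotspot and skew ≥ +0.3; otherwise neutral_like
(including mutation-free genes). If both rules fire (possible only with
nonstandard thresholds), the oncogene call wins and the conflict is
flagged. Thresholds are configurable; the defaults separate the
simulated classes with wide margins and are not tuned to any database
release.

## Assay scoring (`pseudolock.biochem`)

* **Calibration**: OLS line through (phosphate, absorbance) standards;
  fits with r² < 0.98 are refused unless forced, because a bad standard
  curve invalidates every downstream rate.
* **Endpoint rates** (malachite-green style): rate = max(0, (A − blank
  mean − intercept)/slope)/time in mol product/min; detectability is
  the standard blank mean + 3 SD limit-of-detection rule.
* **Kinetic rates** (pNPP style): slope of the longest initial window
  with OLS r² ≥ 0.99 (≥ 5 points), scaled by a mol-per-absorbance
  factor; if no window qualifies, the full course is fitted with a
  low-linearity warning. *Known limitation*: the r² threshold admits a
  few points past a hard kink, biasing the slope low by ~5–6% on a
  sharply saturating course, and it barely constrains smoothly curving
  (exponential-approach) courses at all — on such data an explicit
  kinetic model should be fitted instead.
* **Inhibitor attribution**: with f = clip(1 − rate_treated /
  rate_untreated, 0, 1) (f = 0 when the untreated signal is below
  detectability), activity is `contaminant_attributed` when f ≥ 0.9
  *and* the target enzyme is in molar excess over the inhibitor — a
  sub-stoichiometric inhibitor cannot silence the target, so near-total
  inhibition implicates a trace contaminant such as a co-purifying
  okadaic-acid-sensitive phosphatase. f < 0.1 is `target_attributed`;
  in between is `indeterminate`. The molar-excess check uses total
  concentrations, mirroring the stoichiometric argument, without Kd
  modeling.
* **Alkylation accessibility**: per-cysteine log2((I_MMTS + c)/(I_IAA +
  c)) with pseudocount c > 0; ≥ +2 is buried, ≤ −1 exposed. Within-row
  ratios cancel peptide-specific ionization efficiency, so no
  cross-peptide normalization is attempted.

## Synthetic-data generators (`pseudolock.simulate`)

All generators are pure functions of their arguments including the
seed. Defaults, chosen once as field-realistic study conditions:

* **Trees**: pure-birth topology, exponential branch lengths, tips
  `t1..tn`.
* **Dollo characters**: per-branch loss probability default 0.1 (0.05
  in long-horizon checks), drawn in preorder with one uniform variate
  per at-risk edge — the documented draw order that the independent
  re-simulation oracle replays.
* **Profile matrices**: a root-gained query; coevolving genes copy the
  query's tip profile and flip each state with the given noise;
  background genes are independent root-gained Dollo characters.
  Constant (all-present/all-absent) draws are redrawn: a profiling
  query must vary across taxa for phi to exist.
* **Catalytic alignments**: ungapped; background columns follow a
  random consensus kept with probability 0.8; pseudo-clade sequences
  break at least one required M1/M2 position with a residue drawn from
  the full palette minus the allowed set (so cysteine does appear at
  degraded aspartate positions); all other sequences carry allowed
  residues at every required position.
* **Mutation catalogs**: Poisson counts at syn 50 / nonsyn 150 per
  1,000 aa — a heavily scaled-down emulation of COSMIC-aggregated
  totals; TSG specs use truncating fraction 0.5 and CNL 0.3 per sample,
  oncogene specs concentrate half the missense events on planted
  hotspot codons and use CNG 0.3, neutral genes get uniform positions
  and 0.02/0.02 CNV rates.
* **Alkylation tables**: class means centred on the midpoint of the
  buried/exposed thresholds and separated by the requested log2 gap,
  with log-normal intensity noise (sd 0.3 in log2 units).
* **Assays**: standards on the stated line; endpoint and 30-second/90-
  minute kinetic readouts whose slopes encode true rate + contaminant
  rate, the contaminant term removed under inhibitor iff the
  okadaic-acid-sensitive flag is set; absorbance noise sd 0.002. At
  zero noise, `endpoint_rate` inverts the generator exactly.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: nucleotide-level mutation processes and
trinucleotide signatures, indel evolution and alignment error, ortholog
detection (presence/absence matrices are taken as given), across-branch
rate variation in gene loss, peptide-level ionization differences
beyond a row-wise factor, and substrate depletion or product inhibition
beyond a single saturation kink.

## Problem sizes

The test suite and the reproduction script run, per invocation: the
15-tip worked example; 200 random trees of ≤ 10 tips against the
exhaustive oracle; 500 simulated characters for the parsimony bound;
1,000 null repetitions at 199 permutations on a 30-tip tree for type-I
calibration; 30 simulated genes per class plus 1,000 neutral genes for
the burden classifier; 50 seeded assay replicates; and 20 simulated
alignments of 12 sequences for the integrity caller. These sizes give
Monte-Carlo standard errors well inside the asserted bands while
completing in about a minute on one core.
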