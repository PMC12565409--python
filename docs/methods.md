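# Methods

## The discovery model

Each upstream set is modelled window-wise. For a motif width *W*, every
length-*W* window *x* of every sequence carries an independent Bernoulli
site indicator with prior γ. Motif windows emit bases column-wise from a
position frequency matrix θ (4 × W); background windows emit iid uniform
bases. The E-step computes the posterior site probability of every window;
the M-step re-estimates θ from the posterior-weighted base counts (with a
per-cell Dirichlet pseudocount α) and γ from the mean posterior. This is a
deliberate simplification of the "any number of repetitions" site model:
overlapping windows are treated as independent, which keeps the E-step
closed-form while preserving multiple-sites-per-sequence semantics.

**Palindrome constraint.** With the constraint on, the M-step pools the
weighted counts with their reverse complement before normalising. Because
every column carries the same total weight, this equals averaging the PWM
with its reverse complement, and it is the exact maximiser of the expected
complete-data log-likelihood within the self-reverse-complementary family —
so EM monotonicity is preserved (the tests assert it per iteration) and
every returned motif satisfies θ = rc(θ) to machine precision.

**Seeding.** Candidate seeds are data windows ranked by summed k-mer
enrichment (k = 6; log observed/expected count under the sequences' own
base composition), greedily diversified to avoid overlapping picks. Each
seed initialises θ at 0.7 on the seed base (0.1 elsewhere), symmetrised
when the constraint is on.

**Model selection.** Two failure modes of the raw window-sum likelihood
surfaced during development and drove the selection design. First, a
diffuse composition-like pattern (for instance a GC-rich blob in GC-rich
sequences) accumulates a large likelihood over thousands of weak matches.
Second, for a palindromic planted motif an off-centre window symmetrises
into a blurred PWM that matches each true site at two overlapping offsets
and double-counts them. Both are artefacts of the overlapping-window
independence assumption. All comparisons are therefore made on a
**site-level criterion**: the sum of log-likelihood ratios of the called,
non-overlapping sites (posterior ≥ 0.5, greedy within-sequence
non-overlap) minus a BIC-like penalty of ½(3W+1)·ln(#windows). Per width,
four estimator states compete under this criterion: the best short-scout
state (12 EM iterations, ranked the same way), its full EM refinement, a
"sharpening" PWM rebuilt from hard counts of the confident calls
(posterior ≥ 0.99), and the EM refinement of that. The best state across
all widths in [min_width, max_width] becomes the motif; its sites are
masked (replaced by N) and the procedure repeats up to `n_motifs` times,
stopping early when the criterion is non-positive. Discovery runs the
short scouts on every third window when the window count exceeds 3000;
refinements always use all windows.

**Filtering.** A motif survives only with ≥ `min_sites` (default 50)
sites, coverage ≥ `min_coverage` (default 0.75, defined as sequences with
at least one site over sequences in the input set) and mean information
content ≥ `min_mean_ic`. The conservation floor is a package choice
(default 0.5 bits) since "non-conserved" is otherwise qualitative; it is
exposed on the CLI.

## Scanning and exact p-values

Scores are Σ_j log₂(p[b_j, j]/0.25); cells are floored at −32 bits so
zero-probability entries (possible at pseudocount 0) stay finite and the
scanner and the null distribution remain mutually consistent. Column
scores are rounded to 10⁻³-bit granules and the exact null distribution of
the total over W independent uniform bases is built by dynamic programming
(column-by-column convolution); p-values are survival probabilities of the
integer score. The DP is exact on the discretised scores — the test suite
checks equality against exhaustive enumeration of all 4^W words for
W ≤ 8. Defaults mirror single-strand promoter scanning: p ≤ 5 × 10⁻⁵, one
strand only (`norc`); with both strands enabled, minus-strand hits are
reported in forward coordinates. Windows overlapping non-ACGT characters
are skipped with a logged warning.

## Motif distance, clustering, screening

The distance between two PWMs is the minimum over all ungapped offsets
(overlap ≥ 5 columns) and both orientations of the mean per-column
total-variation distance on the overlap plus λ·(1 − overlap/max(W_a, W_b))
with λ = 0.5. Total variation is bounded in [0, 1], symmetric, zero for
identical motifs and for a motif against its own reverse complement, and
cheap to verify by brute force (the tests do exactly that). Motifs are
clustered by average linkage (UPGMA) on the pairwise distance matrix; the
tree is cut at `cutoff` and groups with fewer than `min_members` (default
5) members are dropped. Determinism is guaranteed by sorting motifs
lexicographically by id before clustering.

The **cutoff default (0.15)** was calibrated on synthetic atlases, per the
package's stated design rule that within-family distances must fall below
and between-family distances above the cut: measured within-family
distances (Dirichlet column jitter at concentration 200) peak at ~0.06
while between-family distances — including families of the same archetype
with different half-site bases — bottom out at ~0.29. The
`plot_height_histogram` helper visualises merge heights for recalibration
on other data.

The **shared motif** of a cluster aligns every member to the medoid
(member minimising summed distance; ties to the smallest id) via its best
alignment, averages the probability columns over the region covered by at
least half the members (longest contiguous such stretch), and
renormalises. **Screening** recomputes each member's distance to the
shared motif and retains the cluster only if every member is within
`match_thresh`; the default reuses the clustering cutoff so there is a
single tunable.

## Conservation typing

Information content is 2 + Σ_b p log₂ p per column (uniform background,
0·log 0 ≡ 0), giving the familiar 0–2-bit logo scale. `label_segments`
marks positions ≥ `high_thresh` (default 1.0 bit) HIGH and ≤ `low_thresh`
(default 0.5 bit) LOW; intermediate positions join the neighbouring run
whose threshold their value is closer to, and runs shorter than `min_run`
(default 2) merge into their longer neighbour. An interior HIGH run
flanked by LOW on both sides is a peak; the inverse is a valley — edge
runs never count, since both patterns are defined by flanks on both
sides. The archetype map resolves from most features down (a double peak
necessarily contains one interior valley, so peak counts take precedence
at equal depth): 4 peaks → quadruple peak, 3 peaks → triple peak,
3 valleys → triple valley, 2 peaks → double peak, 2 valleys → double
valley, then single peak / single valley; anything else — including mixed
one-peak-plus-one-valley shapes — is OTHER. Classification of a
palindromic profile is invariant under reversal; for asymmetric profiles
the short-run merge tie-breaks are position-dependent, so exact reversal
symmetry is only guaranteed for symmetric inputs.

## The synthetic generator

`build_truth_pwm` realises any archetype as a symmetric HIGH/LOW block
layout: conserved columns carry one dominant base at `high_ic` bits
(default 2.0 — the half-site contacts of a planted consensus are
invariant), unconserved columns a weak preference at `low_ic` bits
(default 0.15). Dominant bases are drawn at random with complements
mirrored across the centre, so the PWM is exactly palindromic. For the
classic half-site/gap/half-site layout the `spacer` parameter (default
13 bp, range 12–14) is the **centre-to-centre separation of the two
half-sites**, matching the geometry of a dimer contacting adjacent major
grooves; a width-17 motif with spacer 13 has 4-bp half-sites and a 9-bp
gap. An odd-width conserved centre column cannot be palindromic with a
single dominant base (A pairs with T), so it uses a self-complementary
A/T or C/G pair whose information content caps at 1 bit; block layouts
keep conserved blocks at least `min_block` (= 2) columns wide, so typing
at the default thresholds is unaffected. Layouts that cannot fit (e.g. a
quadruple peak in 17 columns) raise a configuration error.

`generate_upstream_set` draws iid background at the configured GC content
(order-0 by design, matching the scanner's null) and plants one site —
sampled column-wise from the truth PWM — at a uniform position in
round(`plant_frequency`·n) sequences, forward strand unless
`random_strand` is set. `generate_atlas` replicates family truth PWMs
with per-column Dirichlet jitter (concentration 200·p + 0.1 by default,
keeping copies within ~0.06 distance of truth). Everything is a
deterministic function of the seed.

What the generator does **not** emulate: higher-order background
composition, overlapping or variable-spacing sites, motif width variation
within a family, sequencing artefacts, and the phylogenetic correlation
of real homolog promoter sets. Passing recovery tests therefore
demonstrate correctness of the machinery under the stated model, not
performance on real genomes.

## Problem sizes and numerical choices

The validation suite uses 200 sequences × 200 bp per discovery set (the
pipeline's standard upstream length), 10 independent sets for recovery
statistics, atlases of 4–6 families × 4–6 motifs, exhaustive p-value
enumeration up to W = 8, and 100 random features for coordinate checks;
smaller 60–80-sequence sets back the fast unit tests. Coordinates are
0-based half-open everywhere internally (1-based only in human-readable
text); base order is fixed A, C, G, T; the EM pseudocount is 0.5 per cell;
EM convergence is declared at a relative objective change below 1e-4
(cap 200 iterations); contig-edge-truncated upstream regions are kept and
flagged rather than discarded.

## Known limitations

- The independence approximation over overlapping windows inflates the
  window-level likelihood of self-overlapping patterns; the site-level
  selection criterion compensates, but γ itself remains a window-level
  quantity.
- Only ungapped, fixed-width, single-PWM motifs are modelled; dyads with
  variable spacing are represented implicitly through the low-information
  spacer columns.
- The p-value null is iid uniform; no Markov background correction.
- Cluster screening uses a single global threshold; no per-cluster
  adaptivity.
- MEME-minimal is the only motif interchange format (read and write);
  HTML/XML outputs of other tools are not parsed.
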