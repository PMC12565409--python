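# palmotifs

Discovery, filtering, clustering, conservation typing and genome scanning of
**palindromic operator motifs** — the DNA sites recognised by dimeric
bacterial transcriptional regulators with helix–turn–helix (HTH) DNA-binding
domains, such as the XRE family.

A homodimeric regulator contacts two adjacent major grooves, so its operator
is (near-)palindromic: two conserved half-sites whose centres sit ~12–14 bp
apart, separated by a weakly conserved spacer. `palmotifs` takes sets of
upstream promoter regions (one set per homolog family), finds such motifs,
pools and clusters them across families, screens clusters for internal
consistency, classifies each cluster's conservation profile into peak/valley
archetypes, and scans genomes for further occurrences.

## The model

**Discovery** fits a two-component mixture to every length-*W* window of the
input sequences: background (iid uniform) or motif, with a Bernoulli site
indicator per window, so a sequence may carry zero, one or several sites
("any number of repetitions"). EM alternates posterior site probabilities

&nbsp;&nbsp;&nbsp;&nbsp;z = γ·P(x|θ) / (γ·P(x|θ) + (1−γ)·P(x|bg))

with a weighted-count update of the position frequency matrix θ. Under the
palindrome constraint the M-step pools the weighted counts with their reverse
complement — the exact maximiser within the self-reverse-complementary PWM
family — so the objective stays monotone and every returned motif satisfies
θ = rc(θ) exactly. Widths 15–25 are fitted and the winner chosen by a
penalised log-likelihood ratio summed over the non-overlapping called sites.

**Filtering** keeps motifs with ≥ 50 sites, ≥ 75% sequence coverage and mean
information content above a conservation floor. **Clustering** compares
motifs by the best-alignment mean per-column total-variation distance (both
orientations, all offsets, plus a length-mismatch penalty), builds an
average-linkage (UPGMA) tree, cuts it, and drops clusters with fewer than
five members. Each cluster's **shared motif** (medoid-anchored aligned
average) is compared back to every member; inconsistent clusters are
discarded. **Typing** segments a motif's per-position information content
(bits, uniform background) into conserved/unconserved runs and counts
interior peaks and valleys: single/double/triple peak, single/double/triple
valley, quadruple peak, or OTHER. **Scanning** scores windows by
Σ<sub>j</sub> log₂(p[b<sub>j</sub>,j]/0.25) with exact p-values from dynamic
programming over integer-discretised column scores (default threshold
5 × 10⁻⁵, single strand).

A synthetic-data module generates promoter sets with palindromic motifs of
any archetype planted at known positions, plus whole motif "atlases", so
every stage can be validated against ground truth.

## Worked example

```python
from palmotifs import *

cfg = PlantConfig(n_sequences=200, seq_length=200, width=17, spacer=13,
                  plant_frequency=0.8, seed=11)
upstream, truth = generate_upstream_set(cfg)

results = MotifDiscoveryModel(upstream, DiscoveryConfig(n_motifs=1, seed=11)).fit()
print(results.summary().to_string(index=False))
```

```
  motif  width  nsites  coverage  mean_ic_bits  criterion  em_iters  converged
motif_1     17     163     0.805        0.9497    1641.07         6       True
```

The fitted motif is a width-17 palindrome supported by 163 sites covering
80.5% of the 200 input sequences (160 sites were planted). Its consensus
equals the planted truth and the matrix is exactly self-reverse-
complementary:

```python
print(consensus_iupac(results.motifs[0].matrix, 0.4))   # AATCGGGAATCCCGATT
print(palindromicity(results.motifs[0].matrix))         # 1.0
print(len(scan(results.motifs[0].matrix, upstream)))    # 161 hits at p <= 5e-5
```

Probe design for a binding assay mutates the two most conserved positions by
the transition rules G↔A and C↔T (applying it twice restores the input):

```python
site = "AATCGGGCATTGGGATT"
design_mutant_probe(results.motifs[0].matrix, site)
# ('AATTGGGCATTGGAATT', [3, 13])
```

The same stages are available from the shell:

```sh
palmotifs simulate --seed 11 --out promoters.fa --truth-meme truth.meme
palmotifs discover promoters.fa --out motifs.meme --minw 15 --maxw 25 --pal
palmotifs filter motifs.meme --out kept.meme --min-sites 50 --min-coverage 0.75
palmotifs cluster kept.meme --outdir clusters/ --cutoff 0.15 --min-members 5
palmotifs type clusters/shared_motifs.meme --out types.tsv
palmotifs scan kept.meme promoters.fa --thresh 5e-5 --norc
palmotifs run set1.fa set2.fa --outdir run1/   # full pipeline + manifest
```

## Layout

- `palmotifs.matrix` — PWM containers and matrix maths (IC, reverse
  complement, palindromicity, IUPAC consensus)
- `palmotifs.discovery` — `MotifDiscoveryModel`/`MotifDiscoveryResults`,
  filtering, scanning, exact p-value DP
- `palmotifs.cluster` — motif distance, UPGMA clustering, shared motifs,
  screening
- `palmotifs.conservation` — peak/valley segmentation and the 7-archetype
  typing
- `palmotifs.sequence_io` — FASTA, MEME-minimal motifs, feature TSV/GFF3,
  upstream extraction, probe design
- `palmotifs.synthetic` — planted-truth generators
- `palmotifs.pipeline` / `palmotifs.cli` — end-to-end runs with manifests

See `docs/methods.md` for the modelling details, parameter defaults and
known limitations.
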