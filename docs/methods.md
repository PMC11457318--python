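# Methods

## Domain filtering

InterProScan rows are filtered to canonical resistance-protein domains by
identifier, never by score: Pfam accessions PF18052 (CC), PF00931 (NB-ARC),
PF01582 (TIR) and PF05659 (RPW8); SUPERFAMILY accessions SSF52058/SSF52047
or a case-insensitive "leucine-rich repeat" substring in the signature
description (LRR); the GO:0004672 protein-kinase-activity term on Pfam rows
(KIN); Phobius TRANSMEMBRANE and SIGNAL_PEPTIDE labels (TM, SP); and
ProSiteProfiles rows carrying InterPro IPR018392 (LysM). No e-value or
score threshold is applied. All identifiers are overridable in config.

Two choices here were genuinely open:

- **RPW8 accession.** The RPW8-NB-LRR class needs an RPW8 rule but no
  published identifier accompanies it in this workflow; Pfam PF05659, the
  Pfam RPW8 family, is the natural choice. It is configurable and its use
  is logged.
- **Scope of the kinase GO rule.** GO:0004672 is matched on Pfam rows only,
  mirroring how the filtering was described per tabsheet; a config switch
  (`kinase_go_all_analyses`) widens it to every analysis source.

Repeated or overlapping hits collapse to presence/absence; LRR repeat
counts are never used downstream.

## Classification

The decision tree is total and deterministic over all 511 non-empty subsets
of the nine domains (verified by enumeration). NB-ARC-bearing sets are
NB-LRR candidates: they become TNL/RNL/CNL only when LRR is present
(otherwise PARTIAL), typed by N-terminus with precedence TIR > RPW8 > CC —
TIR is the most specific signature, so it wins when N-terminal domains
co-occur; the precedence is logged whenever invoked. Without NB-ARC,
LysM + TM makes a LysM receptor (LysM precedes RLK/RLP because LysM
receptors are counted as their own class); LRR + TM + KIN an RLK;
LRR + TM an RLP. TM, not SP, is the membrane-anchoring requirement —
receptor topology requires a membrane anchor, while a signal peptide alone
only indicates secretion — so SP is recorded as evidence but never decides
a class.

Genes take the highest-priority class among their splice variants
(TNL > RNL > CNL > RLK > RLP > LysM > PARTIAL); a gene is complete if any
variant is. Completeness percentages are reported per subgenome as
100 · complete / (transcripts with ≥ 1 canonical domain), rounded to one
decimal.

## Cluster detection

Genes with a complete or LysM class are chained per chromosome by single
linkage: a gene joins the open chain when the gap from the chain's running
maximum end to the gene's start is ≤ the window; chains of ≥ 2 genes are
clusters. Tracking the running maximum end (rather than literally the
previous gene's end) makes the chains exactly the connected components of
the pairwise "gap ≤ window" relation, which the test suite verifies against
a brute-force transitive closure; the two rules differ only when gene
intervals nest, which annotated gene models rarely do. The default window
is 200 kb with any-class chaining — the convention of the R-gene cluster
literature, since no distance rule is published for this landscape — and
both window and class-homogeneity are exposed in config. Gaps are measured
end-to-start, not midpoint-to-midpoint, which is conservative and
deterministic. The published 16/18 cluster counts are therefore
reproduction targets under this convention, not exact replications of an
unstated rule.

## Best-hit annotation

Per query the hit with maximal bitscore wins; ties break by higher percent
identity, then lexicographically smallest subject ID, making the selection
a pure function of the hit set (invariant under row order). Bitscore rather
than e-value ranks hits because it is independent of database size. No
identity or e-value cutoff is applied by default; optional cutoffs drop
whole queries. The report writes one row per (reference, query) best-hit
pair, identity to three decimals, and suffixes "+LysM" when lysin-motif
evidence coexists with a non-LysM class.

## Phylogeny

Distances are p-distances — mismatches over comparable sites, excluding
positions gapped or 'X' in either sequence (pairwise deletion, default) or
in any sequence (complete deletion). The model is deliberately the simplest
available: the upstream tool names the method (neighbor joining, 1000
bootstrap replicates) but not the substitution model, so exact replication
of the published tree is not claimed and p-distance/pairwise-deletion, a
common default for this workflow, is exposed in config.

Neighbor joining is the classic Saitou–Nei agglomeration:
Q(i,j) = (n−2)·d(i,j) − Σₖd(i,k) − Σₖd(j,k); the joined pair takes branch
lengths lᵢ = d(i,j)/2 + (rᵢ−rⱼ)/(2(n−2)) and distances to the new node
d(u,k) = (d(i,k)+d(j,k)−d(i,j))/2. Ties on Q break by the
lexicographically smallest sorted leaf-name pair (the labels' smallest
descendant), so the output is deterministic and invariant under taxon
permutation. Negative branch lengths are clamped to zero with the deficit
logged. The implementation is exact on additive matrices (tested on 100+
random trees, n ∈ [4, 8], against a brute-force least-squares topology
oracle and scikit-bio's independent NJ).

Bootstrap supports resample alignment columns with replacement to the
original length, rebuild the tree, and label each internal edge of the
*original* tree with the integer percentage of replicates containing its
leaf bipartition — the familiar "bootstrap test" display, not a consensus
tree. Replicates in which some pair loses all comparable sites are
discarded; more than 10% discarded is an error. Supports travel as internal
node names in Newick.

Midpoint rooting places the root halfway along the longest tip-to-tip
path, ties broken by the lexicographically smallest leaf pair; rooting
preserves all pairwise path distances and keeps each support attached to
its bipartition.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes: per
transcript, domain-hit rows from the four relevant analysis sources whose
canonicalization yields exactly the planted class architecture (e.g. a TNL
transcript gets PF01582 + PF00931 + an LRR SUPERFAMILY row); 1–3 splice
variants per gene, later variants truncated with probability 0.35 by
dropping one class-required domain (→ PARTIAL); noise rows with irrelevant
signatures on every transcript; decoy genes with only irrelevant
signatures; gene placement with ≥ 500 kb between clusterable neighbors and
≤ 50 kb inside planted clusters, so any window between those gaps recovers
the planted partition exactly; partial/decoy genes fill the wide gaps at
~15 kb spacing, as they cannot join or bridge clusters. Protein alignments
are evolved down a random binary tree by per-site substitution with
probability equal to the branch length (uniform over the other 19
residues, no indels), keeping p-distance expectations analytic. BLAST
tables carry one strictly dominant planted hit per query plus lower-scoring
decoys.

Defaults are desk-sized (two subgenomes × two 8 Mb chromosomes, ~40 genes —
the test fixture); `SyntheticConfig.landscape()` scales to the published
subgenome landscape: the per-class gene counts (A: 103 CNL, 10 RNL, 69 TNL,
20 LysM, 198 RLK, 114 RLP; F: 111, 13, 74, 21, 212, 112), 16 + 18 planted
clusters of 2–4 genes with an RPW8-NB-LRR pair pinned to chromosome 7 of
each subgenome, 600 partial and 300 decoy genes per subgenome on eight
42 Mb chromosomes (Prunus-realistic lengths), and a 60-taxon NB-LRR
alignment of 300 columns.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: intron/UTR gene structure, realistic LRR repeat
counts, InterProScan score columns, annotation noise (the planted
architectures are recovered at zero noise by construction), indels and
rate heterogeneity in the alignments, and the unknown relation between the
published transcript totals (19,570 / 19,142 with ≥ 1 domain; 804 / 817
complete) and the published gene counts — the completeness percentages are
therefore checked as arithmetic on the published totals, not replanted.

## Numerical choices and degenerate inputs

- Protein coordinates 1-based inclusive (InterProScan convention); genomic
  coordinates 1-based inclusive (GFF3 convention).
- Transcript → gene collapse strips one trailing `.<integer>`; the rule is
  a configurable regex since annotations differ.
- Q-matrix tie tolerance 1e-12 absolute; tip-path ties likewise.
- A sequence pair with zero comparable sites is an error naming the pair
  (its distance is undefined); in bootstrap replicates it discards the
  replicate instead.
- Empty GFF3 → empty gene list with a warning; orphan mRNAs are errors.
- Unknown analysis sources parse to OTHER (logged, not fatal); unknown
  subgenome prefixes count under OTHER.
- MapChart positions are emitted in units of bp / 10⁶ (Mb), three
  decimals; the divisor is configurable since the published maps show
  positions without units.

## Problem sizes

The suite and the acceptance script run at desk scale by design: the
study-scale synthetic landscape (≈ 2,900 genes, ≈ 5,700 transcripts,
≈ 15,000 annotation rows), 100 random additive matrices with 4–8 taxa,
100 bootstrap replicates on 6–60 taxa, and 20-seed property sweeps. The
generator config permits annotation-scale stress runs (tens of thousands
of transcripts) but nothing in the default workflow requires them.

## Known limitations

- The deposited-workbook (tabsheets) dialect is configured, not hard-coded:
  sheet names and column layout of the deposited files are supplied in
  config, and the reader is exercised against synthetic workbooks only.
- Cluster counts depend on the window convention (see above).
- The NJ tree is built from p-distances; trees built under other distance
  models will differ in branch lengths and possibly topology.
- Best-hit reduction from 22 references to 18 transcripts reflects shared
  best subjects among queries; no acceptance threshold is modeled because
  none is published (the packaged panel also preserves the published
  "2,191 vs 2,157" RLP/RLK transcript-count discrepancy as-is, in that the
  package takes no side: both totals are upstream inputs it never
  recomputes).
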