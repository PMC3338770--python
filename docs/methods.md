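# Methods

This note documents the models and procedures `metafunc` implements, the
defaults it pins where the underlying method is conventionally left vague,
and what the synthetic-data tests do and do not establish.

## Quality control

Reads are processed in the order **adaptor binning → quality trimming →
length filter**. Adaptor-containing reads are set aside whole (the adaptor
bin is a per-read count, not a trimmed-base count), before any trimming.

*Window trimming.* Non-overlapping windows of `window` nt (default 5) are
evaluated from the 5′ end inward: a window with mean Phred quality below
`min_mean_q` (default 20) is removed entirely; the first window whose mean
**reaches** the threshold stops the scan (a mean of exactly 20 passes).
The 3′ pass then applies the same rule to the 5′-trimmed read. If fewer
than a full window of bases remain, the remainder is judged by the same
mean rule. Two alternatives — a 1-nt sliding window, or treating ==20 as
failing — are defensible; the non-overlapping/pass-at-threshold variant is
pinned because it is idempotent and monotone in the threshold, both of
which are property-tested.

*Adaptor matching.* A read is binned when any window of
`adaptor_min_match` nt (default 16) matches a same-length window of an
adaptor with at most one mismatch. This is a deterministic substring scan,
not a Smith–Waterman aligner: it is reproducible, dependency-free, and at
these lengths the two agree except on gapped adaptor fragments, which are
rare in short single-end data. A pigeonhole seed index (exact 8-mers)
keeps the scan linear in practice.

*Length filter.* Trimmed reads shorter than `min_len` = 50 nt are
discarded. Quality scores are Phred+33 by default (Phred+64 via a flag).

## Read classification

Evidence streams are heterogeneous (BLAST tabular for rRNA and peptide
searches, SAM for host and bacterial-genome mapping), so categories are
made disjoint by a strict precedence ladder:

    adaptor ≻ rRNA ≻ host transcript ≻ host genome ≻ bacterial nt ≻ bacterial peptide ≻ unassigned

- rRNA: any hit against the rRNA reference with bit score **strictly**
  greater than 50. At ~76 nt, 50 bits corresponds to a near-exact match
  of ~25 residues; weaker matches are uninformative.
- Host / bacterial nt: a primary, non-unmapped SAM record against the
  respective reference; secondary/supplementary records are ignored.
- Bacterial peptide: a translated hit with identity ≥ 85% over > 65% of
  the read length (coverage = 3·aligned-aa / read-nt). The high-quality
  gate is the default because low-identity 25-residue matches carry
  essentially no assignment information; it can be disabled
  (`hq_peptide_only=False`) to count any translated hit.
- Best hits are chosen by highest bit score, then lowest E-value, then
  lexicographically smallest subject id — fully deterministic.

Yield percentages are of **non-adaptor** reads, rounded half-up to one
decimal (the convention of printed yield tables). The bacterial column
counts peptide-mapped reads only; nucleotide-mapped bacterial reads are
reported in their own column.

## Abundance

RPKM = 10⁹·C/(L·N) with N fixed per sample as the number of reads mapped
to bacterial transcripts. Class aggregation sums member RPKMs with an
**equal-split rule**: a transcript carrying k labels (a multi-letter COG,
say) contributes RPKM/k to each label. The rule is chosen for additivity —
total mass is conserved under any covering label map — and is
property-tested. Ranks are dense (1..n), ties broken lexicographically.
Taxon-profile percentages use the printed-table convention: one decimal,
two decimals below 1%.

## Gene families (Markov clustering)

The all-vs-all similarity graph has an edge (a, b) when any hit in either
direction passes E < 10⁻⁵; the weight is the best bit score over both
directions. Bit scores (not −log E) are used because they are
database-size independent. Self-hits are dropped.

The MCL iteration is implemented from scratch on dense numpy arrays, per
connected component (flow cannot cross components, and per-component
matrices keep the dense algebra small):

| parameter | default | role |
|---|---|---|
| inflation | 2.6 | granularity: elementwise power after expansion |
| expansion | 2 | matrix power: flow spreading |
| self-loop | max column weight | regularization; damps oscillation |
| prune threshold | 1e-5 | absolute; a column's maximum always survives |
| convergence tol | 1e-6 | max elementwise change |
| max iterations | 200 | non-convergence returns the current state with a warning |

Clusters are read off the converged matrix as attractor systems (positive
diagonal), merged transitively when they share members; residual
unassigned nodes (possible only without full convergence) follow their
strongest outgoing flow. Families are named GF1, GF2, … by descending
size, ties by lexicographically smallest member. The implementation is
checked against an independent sparse reference implementation (different
data structures, different cluster read-out) on seed-pinned random graphs.

## COG / EC assignment and enrichment

Assignments use the best qualifying hit under per-namespace E-value caps:
10⁻³ for COG, 10⁻¹⁰ for EC (misassigned enzyme activities propagate into
the metabolic network, so the enzyme cap is stricter). EC strings are
validated as four dot-separated fields; truncated strings are padded with
trailing dashes (`3.2.1` → `3.2.1.-`) with a warning.

The enrichment statistic is a one-sample proportion Z-score per category,
z = (p_s − p_b)/√(p_b(1−p_b)/n). The frequencies are RPKM-weighted, but n
(`n_effective`) is the **read count** underlying the classified
transcripts, because a sampling variance needs a count; this is an
interpretation choice, documented here deliberately, and its null
behaviour is verified by Monte-Carlo calibration (multinomial draws from
the background at n = 500 reject |z| > 2 at the nominal 4.55% rate).
`Uncharacterized` mass appears in distributions but is excluded from the
test by default. |z| > 2 with no multiplicity correction is the
significance convention; with ~25 categories, expect ~1 false positive
per sample under the null.

## Networks

*Metabolic.* EC nodes; an edge joins two enzymes sharing any
non-blacklisted compound as substrate or product (direction ignored),
labeled with the union of shared compounds. A currency-metabolite
blacklist (H₂O, H⁺, ATP/ADP/AMP, NAD(P)(H), CO₂, phosphates, CoA) is
applied by default — without it the network is near-complete and path
structure is meaningless — and can be disabled. Expression overlays never
change topology.

*Betweenness.* Unweighted shortest paths, endpoints excluded, normalized
per connected component by (n−1)(n−2)/2 so a path or star centre scores
exactly 1 within its component. Components with fewer than 3 nodes score
0. Computed with the standard Brandes algorithm (via networkx) and
verified against brute-force all-pairs path enumeration on small graphs.

*Conservation vs expression.* On a protein-interaction scaffold each gene
carries an ortholog genome count (out of a configurable total, default
1078) and a summed-RPKM expression. Discordant genes are flagged by
quantile bands (default quartiles): `conserved_silent` (top-quartile
conservation, bottom-quartile expression) and `rare_expressed` (the
converse). A degenerate axis — all values equal, e.g. an empty ortholog
table — yields no flags on that axis.

## Synthetic communities

The generator emulates a defined-flora mouse-gut sample: eight taxa with
fixed relative abundances (a Bacteroidetes member dominant at 0.45, three
Lachnospiraceae, one Clostridiaceae, two Lactobacillaceae, one
Deferribacteraceae), 40 transcripts per taxon, 76-nt single-end reads with
a good-quality body (Q35) and a 6-nt Q2 tail, and per-sample read
composition of 23% adaptor, 53% rRNA, 6% host and the remaining 18%
bacterial mRNA (5% of which is nucleotide-mappable) — proportions in the
range observed for quality-filtered gut metatranscriptomes.

Design choices that matter for interpretation:

- **Length ladder.** Transcript lengths follow a fixed 200–1500 nt grid
  identical across taxa, and mRNA reads sample transcripts in proportion
  to length within a taxon chosen by abundance. With identical length
  multisets, mean transcript length cancels between taxa, so both the
  per-taxon read marginal and the expected RPKM share equal the specified
  abundance — making abundance recovery a well-posed test.
- **Planted families** are mutated copies (5% substitution) of a common
  ancestor, so they are genuine sequence-sharing groups; but homology
  search is never run — `simulate_hits` emits the alignment evidence
  directly from the truth table, with spurious hits injected at a
  configurable rate, mostly below the classification cutoffs.
- **Identifiability scrubbing.** Non-adaptor reads and reference
  transcripts are regenerated if they contain a chance 16-mer adaptor
  match (expected about once per 10⁵ random reads); otherwise the truth
  table would contain planted contradictions and exact recovery would be
  ill-posed.
- All randomness flows from explicit seeds; outputs are byte-identical
  across runs.

What passing tests therefore show: the pipeline's logic — thresholds,
ladders, normalization, clustering, statistics — is correct on data whose
truth is known. What they do not show: robustness to real alignment
artefacts (gapped adaptors, chimeras, quality-by-cycle error structure,
conservation-biased peptide mappability, rRNA depletion bias), none of
which the generator models.

## Problem sizes

The default test and acceptance runs use 4,000–100,000 reads per sample,
25 random graphs (≤30 nodes) for the clustering cross-check, 20 graphs
(≤12 nodes) for the centrality cross-check, and 2,000 Monte-Carlo draws at
n = 500 for the null calibration — sizes at which the statistical
tolerances quoted in the tests (binomial/multinomial standard errors) are
meaningful and the full suite runs in well under a minute on one core.

## Known limitations

- The classifier trusts its evidence files; it does not re-score
  alignments or model mapping ambiguity beyond primary-record selection.
- RPKM is the only normalization; no cross-sample statistical
  normalization or differential-expression testing is provided.
- MCL is dense per component: components beyond ~5,000 nodes will be slow
  and memory-hungry; the intended scale is the de novo family structure
  of one study's transcript catalogue, clustered component by component.
- The enrichment Z treats categories independently and ignores the
  compositional coupling of frequencies; it is a screening statistic, not
  an inferential model.
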