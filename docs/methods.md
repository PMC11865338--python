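# Methods

## Model and procedure

The package treats a curated corpus of directional microbiota-disturbance
evidence as the primary observable: one row states that source *s*
documented entity *i* (a dietary fiber intervention or a disease state)
increasing or decreasing taxon *m* at some reported rank, optionally at a
named body site. Magnitudes are deliberately not modeled — published
studies rarely report comparable effect sizes, so only the sign and the
count of independent reports carry information.

**Upward propagation.** A report at a low rank implies disturbance of
every ancestor taxon its lineage names, so each row contributes one
signed event at its reported rank and at every strictly higher rank
(species < genus < family < order < class < phylum). Propagation is never
downward: a phylum-level report says nothing about member genera. A
microbe missing from the lineage table contributes at its reported rank
only (counted and logged, not fatal), because curated names often lack
full lineages. A row whose reported rank contradicts the taxonomy is an
error — that is a curation defect, not missing data. A source that
genuinely reported both a genus and its phylum is counted at the phylum
twice (once directly, once propagated); no per-source deduplication
beyond exact-duplicate rows is attempted, since evidence rows are the
unit of observation.

**Quantification.** Per rank, tallies of increases and decreases become
a net direction α = sign(c_inc − c_dec) and net count C = |c_inc − c_dec|
(ties zero out — the corpus is then uninformative about that cell), and a
strength D = α·C·ln(N/n). The log factor is an inverse-document-frequency
coefficient: N is the number of entities carrying any evidence at the
rank, n the number associated with the taxon. A taxon disturbed by every
entity scores exactly zero everywhere; it cannot discriminate.

**Similarity.** Per rank, SIM is the cosine of two entities' D-vectors.
Its significance is assessed by treating SIM like a correlation
coefficient over the m taxa in the pair's joint support (taxa where
either vector is nonzero): t = SIM·√(df/(1−SIM²)), df = m − 2, giving a
deviation σ = SIM/t = √((1−SIM²)/df) that is finite and positive for all
|SIM| < 1 including SIM = 0, and a rank weight W = 1/σ (the weight is the
inverse *deviation*, not the inverse variance). Ranks with df < 1 or an
all-zero vector are excluded from both sums of the aggregation

    SIM_ij = Σ W_r SIM_r / Σ W_r,    σ̄ = √(1/Σ W_r).

The weighted p-value is the two-tailed Student-t tail of SIM_ij/σ̄ on
df = (Σ contributing m) − 2 degrees of freedom; this df convention is a
package choice (the construction of the aggregate test is otherwise
under-determined) and is reported in the output for transparency.
|SIM| is clamped at 1 − 10⁻¹² before t so identical-profile pairs get a
very large but finite weight. FDR is controlled per run (one family per
network mode) with Benjamini–Hochberg; self-pairs are reported with
similarity 1 but excluded from the family.

**Networks and coherency.** Edges carry the weighted similarity and its
sign; the FDR < 0.05 filter is strict. The triangle census classifies a
three-node loop as coherent iff the product of its three edge signs is
positive (structural balance: all-positive loops and loops with two
negative edges are self-consistent). The census runs on the *unfiltered*
network of all defined pairs, since loop statistics are a property of the
whole similarity structure, not of the thresholded skeleton. It is
computed with exact integer trace identities — trace(E³)/6 triangles,
trace(S³)/6 = coherent − incoherent — rather than a cubic scan; a
brute-force triple enumeration is kept in the test suite as an
independent oracle.

**Permutation null.** Each iteration permutes, independently within each
rank, every entity's D-vector across the taxon axis — preserving each
entity's multiset of strengths while destroying taxon alignment — and
recomputes all similarities and the census ratio. This is the most
literal reading of "randomize the quantitative relationships between
microbiota and entity"; a global matrix shuffle is available behind
`null_model="global"`. Census ratios with zero incoherent loops are NaN
sentinels, excluded from the null median with their count reported. The
fold of observed over null-median ratio summarizes the network's excess
coherence.

**Disturbance scores.** Evidence is segmented by body site; sites with a
single disease are dropped (no within-site contrast exists). N and n are
recomputed site-locally, strengths pass through D̂ = 2/(1+e^(−D)) − 1
(the logistic map into (−1, 1), identically tanh(D/2); implemented with
`scipy.special.expit` for numerical stability), and
DS = √(Σ_ranks Σ_taxa D̂²). Because propagation writes one report into
several ranks, DS intentionally counts a disturbance at every rank it
reaches. The signed D̂ table is emitted alongside DS so direction
information lost in the norm remains available. For a disease with k
evidence-bearing cells, 0 ≤ DS < √k strictly.

**Clustering and comparison.** Entities are clustered on distance
1 − SIM (range [0, 2]) with complete linkage; the distance transform is a
package choice (only the linkage is canonical) — the monotone
alternative √(2(1−SIM)) yields the same merge order under complete
linkage on these matrices. The fiber-mode default cut is k = 6; disease
mode defaults to dendrogram-only output. Similarity matrices from two
sources are compared by Pearson correlation over common off-diagonal
upper-triangle pairs, optionally within entity categories.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_disturbances` | 3 | entities documented with fewer distinct disturbed taxa are removed before similarity (single pass, counted at the reported-rank layer) |
| `fdr_threshold` | 0.05 | strict upper bound for network edges |
| `iterations` | 10 000 | permutation-null draws (tests and the acceptance script use 200; the summary statistic is a null median, stable far below the default) |
| `align` | union | cross-set taxon-vector alignment; `intersection` available for sensitivity analysis |
| `k` | 6 | fiber-mode cluster count |

All randomness flows from explicit integer seeds; identical inputs,
config and seed reproduce outputs byte-for-byte (provenance logs contain
no timestamps for this reason).

## The synthetic generator

`bhwa.synth` emulates the statistical shape of curated corpora: a random
six-rank taxonomy, per-entity sparse signed genus profiles (defaults:
20 entities, 6–14 evidence rows each over 40 genera, rank mix dominated
by genus-level reports at 84%, 10% per-row direction conflicts — chosen
to resemble a small literature-derived fiber database). Entities belong
to blocks; block profiles over genera are planted at genus rank and
propagated by the *real* taxonomy machinery, so synthetic runs exercise
the same code paths as real data. `within_block_agreement` w perturbs an
entity's profile from its block's independently per taxon with
probability (1 − w)/2 (w = 1 copies the block exactly);
`between_block_agreement` sets per-taxon sign agreement between block
profiles.

Recovery experiments use a denser configuration (10 entities, 18–22 rows
over 25 genera, w = 1, fully opposed blocks, no conflicts): exact
two-block recovery requires same-block entities to share genus-level
support of at least three taxa so the high-weight genus rank contributes,
which the sparse default — faithful to real corpora — does not guarantee.
Under the dense planted conditions, recovery is exact (ARI = 1) and
within-block mean similarity exceeds between-block mean in 100/100 seeds.
Note what passing these tests does **not** show: real corpora have
heavy-tailed taxon frequencies, correlated sources, and incomplete
lineages, none of which the generator reproduces; synthetic results
validate the machinery, not biological conclusions. A fully separated
two-block network is perfectly structurally balanced (every triangle
coherent), so the census ratio is undefined there; null-model and census
demonstrations therefore use the noisier defaults.

## Numerical choices and degenerate inputs

- Cosines are computed over full aligned vectors (zeros contribute
  nothing, so this equals the support-restricted cosine); support size
  only enters df.
- A rank with fewer than two evidence-bearing entities cannot be
  quantified (ln(N/n) degenerate) and is skipped in multi-rank runs,
  raised in direct calls.
- Pairs with no contributing rank have undefined similarity: reported as
  NaN, excluded from FDR, never edges, and rejected by clustering with
  the offending pairs named.
- Zero weighted similarity ⇒ no edge (sign undefined).
- Taxon names must be unique across ranks within one analysis; homonyms
  raise rather than silently merge.
- Entity and microbe names match case-insensitively after whitespace
  normalization; the first-seen spelling is canonical. No fuzzy matching.

## Known limitations

- Direction-only evidence: effect magnitudes, dosages and study quality
  are not modeled.
- The aggregate t-test construction (correlation-style t per rank, summed
  support df) is a modeling convention, not a derived sampling
  distribution; p-values are heuristic significance indices, which is
  also why FDR control and permutation nulls accompany them.
- Upward propagation double-counts a source that reports several ranks of
  one lineage; sensitivity of results to this convention has not been
  quantified.
- Body-site scores on reference curated databases (e.g. GI-tract values
  for specific diseases) and cross-source matrix correlations depend on
  the exact curation snapshot used; they are integration goals against
  such external data, not unit-level guarantees of this package.
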