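# Methods

## The procedure

`policymap` implements a dictionary-based content-mapping pipeline with four
stages.

**Preprocessing.** Text is NFC-normalized, lowercased, and split into
maximal runs of ASCII letters/digits (hyphenated compounds therefore split;
punctuation, including curly quotes, is discarded; numerals are kept by
default because policy texts cite bill numbers, with a `drop_numerals`
flag). Stop words are removed before lemmatization — the order is a package
choice; both orders give identical streams for the packaged stop list, which
contains only uninflected function words. The lemmatizer is a deterministic
exception-table + suffix-rule reducer (plural `-s/-es/-ies`, verbal
`-ing/-ed` where a stem of ≥ 3 characters containing a vowel remains,
doubled final consonants undoubled). A single rule pass is not idempotent
(stripping `-ing` can expose a trailing `-s`), so rules are iterated to a
fixed point, making `lemmatize ∘ lemmatize = lemmatize` hold by
construction. The rules are deliberately crude — `series → sery` — but
bit-stable, which matters more here than linguistic perfection: every count
downstream depends on the stream, and the interface is pluggable if a
model-based lemmatizer is preferred.

**Dictionary induction.** For each area, every lemma of the area sub-corpus
(length ≥ 3, not purely numeric) is scored by tf·idf per document, with
tf(w,d) = count(w,d)/|d| and idf(w) = log(N/df(w)), aggregated across the
documents containing it, ranked (score descending, ties alphabetical), and
cut at `ceil(fraction × candidates)` with `fraction` defaulting to the first
percentile (0.01). A term surviving the cut in ≥ 2 areas is *ambiguous*; per
owning area it receives the two co-occurring lemmas with highest Jaccard
coefficient over document sets as context terms.

Four knobs matter and are recorded in `Taxonomy.build_config`:

| knob | default | meaning |
|---|---|---|
| `fraction` | 0.01 | percentile cut on the ranked candidate list |
| `idf_base` | e | log base (2, 10 available; rescales, never reorders) |
| `aggregation` | mean | per-term aggregation over containing documents (`sum`, `max` available) |
| `per_area_idf` | True | df statistics within the area sub-corpus vs pooled |

**A note on `mean` vs `sum`.** With `aggregation="mean"` a term that occurs
once in a single document scores tf·log N — the hapax maximum — so the top
of the ranking is dominated by the rarest terms regardless of whether they
are area-characteristic. This is the classic TF-IDF hapax sensitivity; at
reference-corpus scale it is usually tamed by sheer vocabulary size, and
`mean` is kept as the default for its robustness to a single outlier
abstract. The *synthetic recovery experiments*, however, use
`aggregation="sum"` with pooled IDF (`per_area_idf=False`): an
area-exclusive term then carries a high pooled IDF (it appears in only one
area's fifth of the corpus) and its summed within-area tf dominates any
shared-pool term, which either appears everywhere (idf → 0) or rarely
(negligible summed tf). This configuration recovers 100% of the planted
vocabulary under the default study conditions with a wide margin, and is
what the acceptance experiments, the CLI example config and the README
example use.

**Classification.** A document's hits per area sum the occurrence counts of
that area's d-words, except that an ambiguous d-word counts only when one of
its context terms for that area occurs anywhere in the document (no window:
policy summaries are one or two sentences, so document-level co-occurrence
is the only defensible unit; an ambiguous d-word with no recorded context
terms never counts). Assignment is argmax of hits, ties broken by more
distinct matched d-words, then alphabetically; all-zero documents are
`unclassified`, a category the share report keeps separate. Shares are
document-level percentages rounded half-away-from-zero to one decimal
(phrase shares to two); occurrence-level shares (`by="hits"`) are exposed
behind a flag.

**Phrases.** Frequent expressions are contiguous 2–4-grams over the
preprocessed lemma stream — stop words therefore never interrupt a phrase
("rules of the school" yields the bigram `rule school`) — counted by
document frequency (once per document), filtered at `min_df` (default 2),
and pruned by a maximal-phrase rule: an n-gram contained in a longer
retained n-gram with identical document frequency is suppressed. Yearly
trends zero-fill gap years inside the observed span and report the mean
(two decimals) and range of yearly document frequencies.

**Clustering and reporting.** Categories are compared by the Jaccard
coefficient of their document-occurrence sets (documents with ≥ 1 hit);
empty-vs-empty is defined as 0 off-diagonal, the diagonal is 1. The
similarity matrix is converted to dissimilarity d = 1 − s (standard,
order-preserving) and agglomerated by unweighted average linkage (UPGMA):
inter-cluster distance is the mean over all leaf pairs, maintained
incrementally with the size-weighted Lance–Williams update, which is exact
for UPGMA. Tie merges resolve by the alphabetically smallest pair of
cluster labels and leaves are ordered by left-first traversal, so dendrogram
artifacts are byte-reproducible. UPGMA heights are monotone
non-decreasing, asserted in tests. Dendrograms export to Newick with branch
lengths equal to merge-height differences; heatmap tables permute a
row-normalized cross-tabulation by leaf order (values untouched) and can be
rendered with a single sequential colormap (brightest = highest), headless.

UPGMA is implemented in the package rather than delegated to
`scipy.cluster.hierarchy` because the tie and traversal conventions above
are part of the contract; scipy's `linkage(..., "average")` serves as an
independent cross-check on tie-free random matrices in the test suite,
alongside an O(n³) brute-force reference that recomputes every inter-cluster
distance from leaf pairs.

## The synthetic generator

The generator emulates the two corpora the pipeline assumes, with
ground truth for every planted feature.

*Scientific corpus*: five areas × 60 documents (each 80–120 tokens), each
token drawn from the area's 40-word specialized pool with probability
φ = 0.7, otherwise from a 120-word shared pool under a Zipf(1.0) rank
distribution — the heavy-tailed background vocabulary real abstracts have.

*Policy corpus*: 500 documents; per document a dominant area is drawn
uniformly and the Dirichlet concentration (default (6.0, 0.4, 0.4, 0.4,
0.4)) is rotated so its peak sits on that area — a single fixed vector would
make one area systematically dominant — then θ ~ Dirichlet(α); each token
comes from the shared pool with probability 0.2 (`background_rate`),
otherwise from area pool a with probability θ_a. The recorded dominant area
is argmax θ. State, year (2003–2013) and 1–2 settings are sampled uniformly
(a `state_weights` option skews states for realistic demos); phrases can be
planted verbatim into a chosen number of documents.

Vocabularies are three-syllable consonant-vowel pseudo-words, drawn without
replacement from a seeded permutation and filtered against the stop list.
They are fixed points of the lemmatizer and disjoint from English function
words, so planted structure survives preprocessing exactly; an
`overlap_count` option plants identical terms in two pools to exercise the
ambiguity machinery. All draws come from one seeded NumPy generator, so
identical configs produce byte-identical corpora.

**What passing the synthetic suite does and does not show.** The generator's
documents are bags of pseudo-words: no syntax, no polysemy, no journal
style, uniform metadata. Recovery rates near 100% show the pipeline's
machinery is correct and well-conditioned under its own assumptions
(area-exclusive vocabulary, mixture-dominated policies); they say nothing
about how sharply real scientific areas separate, where vocabulary overlap,
editorial conventions and OCR noise will lower both dictionary purity and
classification confidence.

## Numerical and degenerate-input conventions

- IDF of a corpus-absent term is an error, never infinity; a term in every
  document scores exactly 0.
- A single-document area gives all terms idf 0: ranking degrades to
  alphabetical, selection still works.
- Rounding of reported percentages is half-away-from-zero (`Decimal
  ROUND_HALF_UP` on the absolute value), one decimal for shares, two for
  phrase percentages; published phrase percentages computed by truncation
  may differ from ours by 0.01.
- Row normalization drops zero-total rows with a warning; an all-zero table
  is an error.
- Similarity matrices are validated (symmetry to 1e-12, unit diagonal,
  [0, 1] bounds) before clustering.

## Problem sizes

The default study conditions (300 reference documents, 500 policies,
~160-term candidate lists, 200 random matrices of order ≤ 7 for the UPGMA
cross-check) were chosen so that every recovery experiment is exact enough
to be diagnostic while the whole suite runs in seconds on one core; they
are scaled-down but structurally faithful counterparts of a reference
corpus of thousands of abstracts and ~1600 policy summaries.
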