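# Methods

## The retrieval model

A citation subset is the set of PubMed records whose `Language` list
contains the target 3-letter code. Because PubMed's language tags are
occasionally wrong, an optional *plausibility* filter additionally requires
an original-language (vernacular) title as a proxy for genuinely non-English
text. It is **off by default**: the filter is a heuristic of this package,
no authoritative exclusion rule exists, and coverage must not silently drop
citations. A citation listing several languages belongs to every listed
language's subset. A missing publication year is kept and set to the
sentinel −1, which sorts last under both (descending-year) rankings.

Queries are interpreted against a multilingual MeSH-style terminology:

1. **Normalization** — case folding; œ/æ expanded to oe/ae; the elided
   articles `l' d' j' n' s' t' qu'` removed with the apostrophe acting as a
   separator; combining diacritics stripped (NFD); tokens are maximal runs
   of ASCII letters/digits. The map is idempotent, and concept lookup is
   invariant under it (case, accents, ligatures, elision).
2. **Segmentation** — a whole-string match against predefined-query labels
   wins outright; otherwise greedy longest-match, left to right, against
   labels, synonyms, acronyms and metaterm names. Ties between equal-length
   matches are broken by kind priority `predefined > metaterm > descriptor >
   supplementary > qualifier` (configurable); an ambiguous acronym resolves
   to its first listed sense, logged. Stop words are removed only from the
   residual words, never from candidate concept spans, so multiword labels
   containing function words ("maladie de Crohn") match whole.
3. **Connective** — AND over all terms. The keyword baselines the harness
   emulates behave conjunctively on multiword queries, and the predefined-
   query expressions are therefore parsed as AND-joined descriptor[/qualifier]
   terms as well (the canonical example, natremia → sodium/blood, is a
   single term; OR would break the conjunctive contract).

At retrieval time a concept term matches a citation annotated with the
concept — hierarchy-expanded through tree-number prefixes by default — or
carrying all of the term's tokens in a title field. Metaterm links are
likewise hierarchy-expanded at query time (metaterms exist to broaden overly
specific descriptors; expansion is a flag for callers who want the narrow
reading). Explosion happens at query time rather than index time to keep the
index small and the behavior switchable. Residual word terms search title,
vernacular title and abstract by default (configurable — whether abstracts
should count at all is a legitimate design axis, so it is exposed).

### Scoring

Scores live on a 0–100 scale. Each term earns the credit of the best
channel it matched, and the score is `100 · Σ credits / #terms`:

| channel                              | credit |
|--------------------------------------|--------|
| query word in a title field          | 1.0    |
| major-topic annotation (human)       | 1.0    |
| minor-topic annotation               | 0.7    |
| word found only in the abstract      | 0.5    |
| annotation assigned programmatically | ×0.8   |

The anchor — a query perfectly matched in the title and as human-assigned
major topics scores exactly 100 — is the fixed point of the design; the
partial credits are this package's choice, picked to make the intended
ordering (title = major > minor > abstract, human > automatic) strict, and
are configurable. Equal scores are broken by publication year then PMID,
both descending; `lifo` ranking ignores scores entirely and uses year then
PMID descending (publication year is the recency proxy; entry dates are not
parsed). Both rankings share one boolean match set, so coverage is
ranking-independent.

### Strategy emulations

`title_only` restricts every query token to the vernacular-title postings
with no concept mapping — a `term[TT]` field search. `all_fields` matches
case-folded tokens (apostrophes kept inside tokens, diacritics kept) across
all fields plus the labels/synonyms of annotated concepts. The weak
normalization is deliberate: the coverage gap of keyword baselines on French
queries comes precisely from unhandled elision and accentuation, and the
emulation makes that gap a testable property rather than an anecdote.

## Evaluation protocol

Per query and strategy, the first ≤20 ranked PMIDs and the total hit count
are recorded; every ranked citation is judged on a 3-level scale. *Strict*
precision counts only fully relevant citations, *relaxed* also counts
partially relevant ones; the denominator is the number retrieved (≤20).
Pooling is **micro-averaged** (Σ relevant / Σ retrieved): it is the unique
rule consistent with all five published pooled totals, including the arms
where some queries retrieved fewer than 20 (or zero) citations. Queries
with zero retrieved contribute to neither sum. Three sensitivity scenarios
re-pool after (1) excluding a query, (2) zeroing its retrieved count for
named strategies, (3) assuming all its retrieved citations relevant.

Statistics: Pearson r with a Fisher-z 95% CI; an unpaired two-sided
Mann-Whitney rank test (mid-ranks for ties; exact by full enumeration of
rank assignments when n+m ≤ 16, otherwise a tie-corrected normal
approximation with 0.5 continuity correction); Fisher's exact two-sided
test, with a zero margin returning p = 1 under a warning. Two-sided tests
throughout; the coverage comparison is unpaired as the test's name implies,
although the queries coincide — a paired alternative would be a different
test. The 2×2 for the precision comparison pools strict counts across
queries (relevant vs not, by strategy); this reconstruction is the
documented assumption and the computed p (0.005-level) should be read as
order-of-magnitude support, not a to-the-digit replay, since the original
table construction is not recoverable from printed data.

## Packaged study tables

The per-query response-time, coverage and precision tables of the published
evaluation ship as checksum-verified TSV. Retrieved counts are 20 except
where the source's footnotes say fewer (those equal the coverage counts
below 20, and the loader asserts the footnoted cells). Per-query relevant
counts are recovered as `round(precision × retrieved)`; the loader asserts
that re-deriving the 2-decimal precision from each recovered count
reproduces the printed value, so the reconstruction is exact, not
approximate.

## What the synthetic generators model

`generate_mini_mesh` emits a hand-inspectable terminology: a descriptor
forest (tree numbers with dot-separated positions), bilingual labels and
synonyms built from a closed pseudo-word vocabulary with injected French
diacritics and ligatures, a deliberately shared ambiguous acronym,
partially translated supplementary concepts, metaterms and
descriptor/qualifier predefined queries. `generate_corpus` emits
PubmedArticleSet XML (default **665 citations**, a 1:1000-scale echo of the
real French subset; 85% French / 15% English; years 1995–2014; 20% of
annotations marked programmatically assigned) plus a relevance key. For
each planted concept, the keyed records — and only they — are relevant: 60%
carry the concept's French label in the vernacular title (*title
evidence*), 40% are only MeSH-annotated with it (*synonym-only*), and 20%
are graded partially relevant so strict and relaxed readings diverge.
Background vocabulary is disjoint from terminology labels at the token
level, and background annotations avoid the planted concepts' exploded
sets; planted concepts must be pairwise hierarchy-disjoint (the generator
rejects overlapping ones), otherwise one query's exploded match set would
swallow another's planted records.

This construction makes retrieval exactly decidable — semantic search must
recover the planted set with precision 1.0 and the title-restricted
strategy exactly the title-evidence subset. What it deliberately does *not*
model: real lexical ambiguity (planted labels never collide with background
text), graded topical drift, translation errors between query and corpus
language, or realistic term-frequency distributions. Passing the planted
tests therefore demonstrates the machinery (normalization, segmentation,
posting construction, explosion, ranking bookkeeping) — not retrieval
quality on real literature, which is what the packaged study tables speak
to.

## Problem sizes and numerics

The test suite and the acceptance script run on a 12-descriptor terminology
and corpora of 200–665 citations with 2–3 planted queries of 8–12 relevant
records — large enough to exercise every code path (multiword labels,
acronyms, hierarchy, facets, both evidence kinds and judgment levels) while
every oracle (linear scans, prefix scans, permutation and hypergeometric
enumerations) stays exact and cheap. All generators are driven by a single
integer seed through `random.Random`; identical seeds give byte-identical
terminologies, corpora and search outputs. Scores are plain floats — the
credit table produces well-separated values, so no tolerance machinery is
needed beyond `pytest.approx` in tests. Degenerate inputs are errors, not
silent defaults: empty queries, constant vectors under correlation, empty
samples under the rank test, pooled precision with nothing retrieved,
hierarchy lookups of unknown identifiers.

## Known limitations

- Only French normalization is tuned; the machinery is language-generic but
  elision handling and stop-word lists for other languages are stubs.
- `all_fields` is an emulation of a moving target; it models the documented
  normalization gaps, not any vendor's current behavior.
- The LIFO recency proxy is publication year + PMID, not database entry
  date.
- Index persistence is a manifest (the index is derived data rebuilt at
  load); at desk scale this is cheap, at production scale one would
  serialize postings.
- The credit table's partial weights are a design choice, not estimated
  from data; only the orderings they induce are meaningful.
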