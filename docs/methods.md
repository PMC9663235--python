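# Methods

## The model

The package implements a rule-based syndrome-differentiation loop for the TCM
inquiry step. Its premise: the other three diagnostic methods (inspection,
auscultation, palpation) produce a shortlist of candidate syndromes, and
inquiry discriminates among them with as few, as targeted questions as
possible.

**Knowledge representation.** Inquiry evidence is atomic question–answer
pairs `z = (q, a)`. A syndrome is an ordered chain of such pairs,
`h = {z_1 … z_n}`, and the chain is *contextual*: each non-terminal pair's
answer points to the next pair's question, and the final answer names the
syndrome itself (the terminal link, which doubles as the reverse index from
pairs to syndromes). The question base groups questions into the 13
Ten-Brief-Inquiries categories in their classical order (cold and heat,
sweat, pain, taste, ears, eyes, chest, hypochondrium, stomach and abdomen,
sleep, thirst, appetite, stool and urine) and numbers them sequentially
across categories, so ascending question id reproduces consultation order.

**Assumptions encoded as validation rules.** `next` pointers are
forward-only (target id strictly greater than the owner's), which is the
minimal rule guaranteeing every chain — and hence every consultation —
terminates; a syndrome's sequence must be exactly such a chain (codes
`CYCLE`, `BROKEN_CHAIN`, `SEQUENCE_ORDER`); terminal pairs are unique per
syndrome (`NO_TERMINAL`); ids are unique (`DUPLICATE_ID`) and all references
resolve (`DANGLING_NEXT`, `DANGLING_SYMPTOM`). Category/id monotonicity
(`CATEGORY_ORDER`) and questions no syndrome ever asks
(`UNREACHABLE_QUESTION`) are reported as warnings — hand-authored bases can
violate them harmlessly — and `--strict` promotes the former to an error.
An answer may reference a syndrome without being its terminal pair: the last
question of a base has no later question to point to, so its non-terminal
answers must fall back to syndrome references.

**Matching degree.** Differentiation scores a candidate by the containment
fraction `|symptoms(h) ∩ symptoms(patient)| / |symptoms(h)|` on id identity.
This is the minimal reading of "compare the syndrome's symptom set to the
patient's and rank by matching degree": symptoms outside a syndrome's
sequence neither help nor penalize it, and a contradictory answer costs
exactly the lost match. The confirmation threshold τ defaults to 0.6 —
unstated in the source material; chosen so a full match is confirmed and a
half match is not, which reproduces the worked example's single-syndrome
outcome. Ties break by matched count, then name, making output deterministic.

**Bayesian framework.** The `bayes_framework` module implements the
probabilistic view separately: single-symptom posteriors
`P(y|x) = P(x|y)P(y)/P(x)` (with `P(x)` supplied or computed by total
probability), per-modality posteriors as the naive-Bayes product under the
framework's conditional-independence assumption (normalized within the
modality), and a cross-modality combination that is literally the sum
`Σ_i P(y|s_i)`. The sum is kept as printed even though it is not a
probability; a `normalize` flag (default off) rescales across syndromes and
never changes the ranking. The framework is decoupled from the set-overlap
engine because the link between the two was never made concrete; it is an
optional, exploratory scoring path (`model_from_kb` builds hit/miss
likelihoods with `p_hit = 0.9` and uniform priors).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `threshold` (τ) | 0.6 | minimum matching degree for confirmation |
| `set_sizes` | (2, 3) | candidate-set sizes in the evaluation protocol |
| `sets_per_size` | 10 | protocol repetitions per size (20 sets total) |
| `none_prob` | 0.0 | chance a simulated random answer is "none" |
| `p_hit` | 0.9 | hit likelihood in the Bayes adapter |
| generator defaults | see below | study conditions for synthetic bases |

The random answer policy never answers "none" by default, imitating a
simulated patient who always picks one candidate answer; `none_prob` exists
for robustness studies only.

## Synthetic data

No clinical base is available (the original 225-syndrome base was never
published), so `fixtures.generate_kb` emulates the *structure* of one:
category-ranked, sequentially numbered questions; forward answer chains;
syndromes as chain walks with unique fresh terminal answers; optional
question-sharing between syndromes controlled by `overlap` (probability per
step of re-using an existing chain edge or question; 0 gives pairwise
disjoint sequences). The first syndrome's chain is anchored at question 1 —
an inquiry always has an entry point, and no forward pointer can ever target
the first question. Leftover answers are wired to the earliest
not-yet-reachable later question (so nearly every question sits on some
chain), or to a random syndrome on the last question.

Defaults — all 13 categories × 3 questions × 4 answers (39 questions), 12
syndromes of 2–4 symptoms, overlap 0.3 — are a desk-scale base: large enough
that candidate sets of 2–3 syndromes produce non-trivial, partially
overlapping Q&A lists, small enough that seeded sweeps of hundreds of bases
run in seconds. Feasibility is checked on expected demand
(`n_syndromes × mean length × (1 − overlap) ≤ n_questions`); residually
infeasible draws raise a generation error rather than loop.

What the generator does **not** emulate: clinically meaningful question
text, realistic symptom co-occurrence, inter-syndrome semantic similarity,
or the size and redundancy of a real 225-syndrome base. Passing tests
therefore demonstrate the *algorithms'* correctness on structurally faithful
inputs, not clinical validity, and the synthetic average question counts are
not comparable to any clinically measured figure.

## Evaluation protocol

`run_protocol` samples candidate sets uniformly without replacement within a
set (sizes and repetitions per `ProtocolConfig`), deduces each set's Q&A
list, simulates a consultation, differentiates, and aggregates mean question
counts per set size. Expert 1–5 quality scores are human judgments with no
machine substitute; the report instead carries the **recovery rate** under
the oracle policy: a uniformly chosen member of each set is planted as
truth, the oracle answers that syndrome's own answers (and "none"
elsewhere), and recovery is the fraction of runs whose primary syndrome
equals the truth. When no candidate's sequence nests inside another's, the
truth is the unique full match and recovery is provably 1. One seeded stream
drives the whole run — set sampling first, then per-set truth and answer
draws — so a report is a pure function of (base, config) and repeated runs
are byte-identical. `trim_mean` (drop one highest and one lowest, then
average; requires ≥ 3 values) is provided for aggregating any per-set
column.

## Serialization

JSON (schema version "1") is canonical and round-trips every knowledge base
exactly; records are sorted (questions by id, syndromes by name) so output
is byte-stable. The five-column CSV dialect
(`Question no.,Question,Answer no.,Answer,Next`, with blank question cells
continuing the previous question) mirrors the classical question-base table
layout. CSV carries no categories and no symptom sequences, so import
assigns the rank-1 category and recovers each syndrome from its terminal
link as a single-symptom sequence; one CSV import is stable under further
save/load cycles. All text is NFC-normalized and trimmed on input; syndrome
names are case-sensitive foreign keys (silent case-folding would hide
authoring errors).

## Numerical and degenerate-input choices

- Matching degrees are exact small-integer ratios; no tolerance is needed.
- Prior sums are checked to 1e-9; posteriors with `P(x) = 0`, or modality
  posteriors whose weights all vanish, raise `UndefinedEvidenceError` rather
  than return NaN.
- `threshold = 0` confirms every candidate; `threshold > 1` confirms none
  (scores are still reported).
- An empty candidate set deduces an empty Q&A list; an empty patient record
  scores 0 against every candidate.
- Traversal errors name the failing step; unknown syndromes are reported all
  at once.

## Test problem sizes

Seeded sweeps use a small base shape (4 categories × 3 questions × 3
answers, 5 syndromes): 100 round-trip bases, 200 deduction-oracle bases, 500
matching-degree draws against a quadratic-scan oracle, 56 single-defect
mutations for validator completeness, and 30–40-seed invariant sweeps. These
sizes keep the full suite under a few seconds while exercising every
structural regime (disjoint, overlapping, single-symptom, full-base
candidate sets).

## Known limitations

- Single-select answers only; no multi-select or free-text replies.
- One ordered chain per syndrome; syndromes with several disjoint inquiry
  chains are not representable.
- The matching degree is uncalibrated set overlap; it is not a posterior
  probability and does not penalize extraneous symptoms.
- CSV is an interchange subset, not a full serialization.
- The client–server deployment of the original system is out of scope; the
  library plus CLI replace it.
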