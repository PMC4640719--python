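# Methods

## The network model

`herblink` models an integrated bio-pharmacological knowledge network over
five node classes: traditional herbal medicines (TKM), drugs/compounds,
diseases, proteins, and side effects. Each class has its own identifier
namespace — PubChem CID for drugs and Entrez Gene ID for proteins (decimal
integers ≥ 1), MeSH descriptors for diseases and side effects (`D` followed
by six or nine digits, covering both the pre- and post-2014 descriptor
dialects), and Med CD tokens for herbal medicines. The Med CD format is not
publicly specified, so TKM identifiers are by default any non-empty token
free of reserved delimiters, with an optional globally installable
validation regex (`set_tkm_id_pattern`).

Edges are undirected and restricted to eight legal class pairings:
TKM–Disease, TKM–Drug, Drug–Disease, Drug–Drug, Drug–Protein,
Drug–Side-Effect, Disease–Protein, Protein–Protein. There is deliberately
no TKM–Protein category: literature-known TKM–protein pairs are evaluation
input, never network edges. Re-inserting an edge with the same endpoint
pair and category merges provenance labels instead of duplicating the edge,
so all neighborhood counts are over distinct nodes, never source
multiplicity. Self-loops are rejected even in the two same-class
categories.

Shortest-path queries treat every category as traversable at unit cost.
Ties among equal-length paths are broken by expanding neighbors in
lexicographic `(entity_class, identifier)` order, which makes the returned
path deterministic; no weighting scheme is defensible from the available
information, so none is offered.

## Shared-neighbor inference

For a TKM *t* and protein *p* the evidence is

- `shared_disease_count` = |N(t, TKM–Disease) ∩ N(p, Disease–Protein)|,
- `shared_drug_count` = |N(t, TKM–Drug) ∩ N(p, Drug–Protein)|,

counted over distinct intermediates. Only disease and drug intermediates
are counted; side-effect-, drug–drug- and protein–protein-mediated
two-hop paths are not evidence channels. Candidate pairs are enumerated
sparsely (TKM → intermediate → protein); the dense TKM × protein
cross-product is never materialized.

Three scoring modes exist: the raw disease count, the raw drug count, and
the weighted combination `w_drug · drugs + w_disease · diseases` with
defaults `w_drug = 2`, `w_disease = 1`. The drug weight reflects that
curated compound–protein interactions are higher-fidelity evidence than
disease co-annotation; the disease weight of 1 is the implied unit weight
(a weight of 2 is only meaningful relative to it). Both weights are
exposed as parameters and must be positive.

The two-category retention filter keeps a pair only if it shares at least
one disease **and** at least one drug (per-channel minima are parameters,
default 1 and 1). `infer_links` in combined mode returns exactly the
retained set, which by construction equals the intersection of the
disease-only and drug-only candidate sets.

## ROC evaluation

Known TKM–protein positives label the pairs; negatives default to the
enumerated candidate pairs of TKMs that possess at least one known
positive (`candidates_only`). This restriction mirrors validating against
a small literature-curated positive set: for medicines without any known
target the label is undefined rather than negative. The `all_pairs`
policy additionally counts every score-0 pair of those TKMs as negative;
it is exposed because the choice materially changes the AUC and no
single policy is canonical. Known pairs that are not candidates enter as
positives with score 0, so recall against the full known set is always
measured.

Scores are small integers, so ties dominate. The ROC sweep therefore
emits one operating point per distinct score value (scikit-learn's
`roc_curve` without intermediate dropping), and the trapezoidal area is
then exactly the tie-corrected Mann–Whitney statistic
P(S⁺ > S⁻) + ½ P(S⁺ = S⁻); the suite checks this identity against
`scipy.stats.mannwhitneyu` to 1e-9.

For the three-mode comparison (`compare_modes`), the labeled universe is
the union of the modes' candidate sets and each mode's scoring function is
evaluated on every pair of that universe (a pair without evidence in a
channel scores 0 there), so all modes share the same `n_pos`/`n_neg` and
the AUCs are directly comparable. The retention filter selects the final
reported link set; it does not truncate the ROC ranking. Truncating
instead (scoring filtered-out pairs as 0 in the combined mode) caps the
combined mode's achievable AUC at the fraction of positives that happen to
carry both evidence channels and makes the combined mode strictly worse
than the drug channel whenever disease evidence is incomplete — the
opposite of what a weighted *combination* is for.

## The synthetic generator

`synthgen.generate` emulates the regime in which the method is claimed to
work: true TKM–protein associations exist, drug-mediated evidence for them
is frequent and clean, disease-mediated evidence is rarer and noisier.

Per TKM, `links_per_tkm` (default 5) planted associations are drawn over
distinct proteins. Each planted pair is independently witnessed through
the drug channel with probability `p_drug_evidence` (default 0.9) and
through the disease channel with probability `p_disease_evidence`
(default 0.6). A fired channel wires `1 + Poisson(extra)` distinct
intermediates (`drug_witness_extra = disease_witness_extra = 1.0`),
connecting the TKM and the protein through each. The multiplicity matters:
with exactly one intermediate per fired channel every candidate — true or
spurious — scores 1, counts carry almost no ranking information, and the
heavier disease noise makes the disease channel anti-predictive. Real
curated networks support a true association through several shared
annotations, and the multiplicity is what produces the monotone
count-probability relationship the inference relies on.

Noise adds, per TKM, `Poisson(drug_noise)` (default 2.0) spurious
drug wirings and `Poisson(disease_noise)` (default 6.0) disease wirings to
uniformly drawn non-planted proteins; a wiring is re-drawn (up to 100
attempts) whenever it would incidentally complete a planted pair, so the
planted truth is recoverable only through the deliberate evidence wiring.
Background edges populate the four categories not involved in inference
(Drug–Drug, Protein–Protein, Drug–Disease, Drug–Side-Effect) so generated
networks exercise the full schema. Default pool sizes are 50 TKMs,
400 drugs, 150 diseases, 600 proteins, 100 side effects — large enough
that AUCs are stable to a few percent across seeds yet a full
generate-infer-evaluate cycle takes well under a second.

Identifiers are minted in the real namespaces (sequential integers for
CIDs and gene IDs, D-numbers for MeSH-style descriptors, side-effect
descriptors offset into the `D9xxxxx` range), so namespace validation is
exercised end to end. The same config and seed reproduce the network
byte-for-byte through the canonical TSV writer.

What the generator does **not** emulate: the skewed degree distributions
of real curated databases, correlated annotations (diseases sharing
protein sets, drug families), incomplete ground truth (here the planted
set is exhaustive), and identifier mapping noise. Passing tests on
synthetic data therefore demonstrate correctness of the machinery and the
qualitative drug > disease evidence ordering under controlled conditions,
not the numeric AUC levels reachable on any real database.

## Numerical and design choices

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; the generator's seed is part of its config, and replicate/sweep
  seeds are derived deterministically from it (kept below 2³¹).
- Canonical serialization: rows sorted by (category, endpoints), smaller
  endpoint first, provenance labels sorted — two equal network values
  write identical bytes regardless of construction order.
- The connection-probability curve bins candidate pairs by their count in
  the selected mode; the k = 0 bin is estimated from a seeded uniform
  sample of non-candidate pairs (default cap 2000) because materializing
  all zero-count pairs is quadratic. Monotonicity is assessed with a
  one-sided Spearman trend test at the pair level (α = 0.05).
- Degenerate inputs fail loudly: empty known-positive sets, single-class
  ROC input, infeasible generator configs and malformed TSV rows all raise
  with messages naming the offending value, file and line.

## Known limitations

- Inference is specific to TKM–protein targets; no other pair type is
  scored.
- The evaluation's negative-set construction is a modeling choice, not a
  ground truth; both policies are reported options and AUCs should only be
  compared within one policy.
- Shared-neighbor counting uses set semantics over already-normalized
  identifiers; synonym resolution and cross-database identifier mapping
  are out of scope and assumed done upstream.
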