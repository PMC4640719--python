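# herblink

Network-pharmacology tooling for herbal medicines: a five-partite
bio-pharmacological network (traditional herbal medicines, drugs,
diseases, proteins, side effects) with shared-neighbor inference of
herbal-medicine protein targets, ROC/AUC validation against
literature-known pairs, shortest-path queries, and a synthetic-network
generator with planted ground truth.

## The problem

Mechanistic knowledge for traditional herbal medicines (TKMs) is sparse:
direct TKM–protein interaction data barely exist, while TKM–disease and
TKM–compound annotations are comparatively rich. `herblink` exploits the
structure of an integrated knowledge network to predict protein targets
for a herbal medicine from the intermediates it shares with a protein:

- **shared diseases** — diseases the TKM is indicated for that are also
  annotated to the protein,
- **shared drugs** — compounds of the TKM that are curated interactors of
  the protein.

For a TKM *t* and protein *p*, with neighborhood counts
*D(t,p)* = shared diseases and *C(t,p)* = shared drugs, the combined score
is

```
S(t, p) = w_drug · C(t, p) + w_disease · D(t, p),    w_drug = 2, w_disease = 1
```

and a pair is retained as an inferred link only if it shares at least one
node from *each* category (*D* ≥ 1 and *C* ≥ 1). The drug channel is
up-weighted because curated compound–protein interactions are
higher-fidelity evidence than disease co-annotation. Predictions are
validated by ROC analysis against known TKM–protein pairs; with count
scores heavily tied, the trapezoidal AUC equals the tie-corrected
Mann–Whitney statistic P(S⁺ > S⁻) + ½ P(S⁺ = S⁻).

The network schema has five node classes with strict identifier
namespaces (PubChem CID, Entrez Gene ID, MeSH descriptor, Med CD token)
and exactly eight legal edge categories; TKM–protein is deliberately not
one of them — known pairs are evaluation input, never edges.

## Worked example

Given `edges.tsv` describing one TKM annotated to two diseases and one
compound, where both diseases and the compound point to protein 1 and the
compound also binds protein 2:

```
$ herblink --log-level ERROR build edges.tsv
nodes	6
DISEASE_PROTEIN	2
DRUG_DISEASE	0
DRUG_DRUG	0
DRUG_PROTEIN	2
DRUG_SIDE_EFFECT	0
PROTEIN_PROTEIN	0
TKM_DISEASE	2
TKM_DRUG	1
edges_total	7

$ herblink --log-level ERROR infer edges.tsv --out links.tsv && cat links.tsv
tkm_id	protein_id	shared_disease_count	shared_drug_count	score	passes_filter
t1	1	2	1	4	true

$ herblink --log-level ERROR path edges.tsv TKM:t1 PROTEIN:2
TKM:t1 -[TKM_DRUG]- DRUG:5 -[DRUG_PROTEIN]- PROTEIN:2
```

Protein 1 shares two diseases and one drug with the TKM, so its combined
score is 2·1 + 1·2 = 4 and it passes the two-category filter; protein 2
is reachable only through the drug and is therefore not retained as an
inferred link, though the path query still explains how it connects.

Other subcommands: `eval` (ROC/AUC of the three scoring modes against a
known-positives TSV), `simulate` (synthetic network with planted truth)
and `sweep` (AUC versus a generator parameter). Every command is a thin
wrapper over the `herblink` library modules (`netmodel`, `io`,
`inference`, `evaluation`, `synthgen`).

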