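# pubmed-expand

Query expansion for PubMed based on UMLS synonymy. Given a free-text
term, the package maps it to a MeSH descriptor, gathers the
descriptor's entry terms and the cross-terminology synonyms sharing a
UMLS concept (CUI), and emits five Boolean query forms as exact PubMed
query strings:

| label | form |
|-------|------|
| q1 | automatic term mapping of a preferred term: `"t"[MeSH Terms] OR (token AND group) OR "t"[All Fields]` |
| q2 | automatic term mapping of an entry term / synonym: q1 plus the matched term's own expansion |
| q3 | entry-term expansion: `"t"[MeSH Terms] OR ((preferred + entry terms as [TIAB] phrases) NOT MEDLINE[SB])` |
| q4 | UMLS-synonym expansion: q3's [TIAB] block plus every deduplicated UMLS synonym, excluding `(MEDLINE[SB] OR OldMedline[SB])` |
| q5 | `q4 NOT q3` — the citations only the synonym expansion retrieves |

Alongside the builder there is a local retrieval engine with
PubMed-like Boolean/field semantics (plus an optional live E-utilities
client), the evaluation statistics used to assess such expansions
(precision at two relevance levels with 95% CIs, multi-rater Fleiss
kappa, Spearman factor correlations, tie-corrected Friedman and
chi-square tests), the increase-in-retrieval report, and a fixture
generator that produces a self-contained mini-MeSH, MRCONSO-layout
concept table, citation corpora with by-construction expected counts,
and rater judgment tables with tunable agreement.

## CLI

All commands live under one entry point:

```sh
# generate a self-contained data set
pubmed-expand fixtures --out demo --seed 1

# expand a term to query strings (label<TAB>string, one per line)
pubmed-expand expand --term "Myocardial infarct" --all-strategies \
    --mesh demo/mesh.tsv --mrconso demo/mrconso.rrf

# hit counts per query form against a local corpus
pubmed-expand counts --term "Myocardial infarction" --provider local \
    --corpus demo/corpus.jsonl --mesh demo/mesh.tsv --mrconso demo/mrconso.rrf

# precision table + kappa from a judgments CSV (term,rank,pmid,rater,rating)
pubmed-expand evaluate --judgments demo/judgments.csv

# increase-in-retrieval table with Total row from a TSV of (term, q5, q3)
pubmed-expand report --counts counts.tsv
```

`expand --drop-nos` removes synonyms ending in ", NOS" from q4 (they
are kept by default).

## Inputs

- **MeSH descriptors** — either the NLM MeSH XML descriptor format
  (subset) or a tabular dialect: TSV with columns `ui`,
  `preferred_term`, `entry_terms` (semicolon-joined), `tree_numbers`
  (semicolon-joined).
- **Concept table** — pipe-delimited MRCONSO.RRF column layout; the
  columns used are CUI, LAT, SDUI, SAB, TTY, STR and SUPPRESS. The
  descriptor-to-CUI mapping is derived from the MeSH-sourced rows.
- **Citation corpus** — JSON lines, one citation per line with `pmid`,
  `title`, `abstract`, `mesh_terms`, `subsets` (MEDLINE / OldMedline /
  premedline) and `pub_date`; a PubmedArticle XML subset reader is also
  provided.

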