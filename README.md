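# jatscite

Extract inline citations, citation contexts (citing sentences), and
sentence-level annotations from JATS-standard XML articles (including the
pre-JATS NLM DTD dialects used by PubMed Central's open-access subset).

For each article the pipeline:

1. builds the reference registry from `<ref>` elements, resolving nested
   multi-work references and XML-tagged PMIDs;
2. segments the article into components — abstract, body, tables, figures,
   back matter — and ordered text fragments with their section context;
3. maps section titles/labels/sec-types to IMRaD categories with a
   configurable cue-rule table (abstract and back matter are always
   `NoIMRaD`);
4. detects explicit inline citations through `<xref>`/`rid` resolution and
   expands implicitly-mentioned citation ranges (both tagging styles —
   paired xrefs and single range markers — across all separator variants:
   hyphen, en dash, minus sign, and doubled runs of these);
5. rewrites citation markers as `|ref-id|` tokens, tokenizes the text into
   sentences (table cells count as one sentence each), and assembles one
   output row per sentence / per (sentence, inline citation) pair;
6. optionally reconciles XML-tagged PMIDs against an external candidate-ID
   table and a cited-PMID list, producing `intxt_pmid_source`, `best_id`,
   `best_source`, and `best_id_diff`.

Output is a UTF-8 TSV with the columns `pmcid, pmid, location, IMRaD,
sentence_id, total_sentences, intxt_id, intxt_pmid, intxt_pmid_source,
intxt_mark, best_id, best_source, best_id_diff, progression` plus a
trailing `text` column (suppressible with `--no-text`). `progression` is
the ceiling centile of a sentence within its component (or within the main
text with `--progression-mode maintext`).

## CLI

Process a directory of `.xml` files into one TSV plus a JSON run summary:

```bash
jatscite run INPUT_DIR -o out.tsv
jatscite run INPUT_DIR -o out.tsv --contexts-only --no-text \
    --progression-mode maintext --config config.yaml \
    --candidates candidates.tsv --entrez cited.tsv
```

One file's failure never aborts the batch; failures are listed in the
summary (`out.tsv.summary.json`), and the exit status is non-zero only when
every file failed. Reruns on the same inputs are byte-identical.

Generate a synthetic fixture corpus with its ground-truth manifest:

```bash
jatscite generate corpus/ -n 50 --seed 1
jatscite generate corpus/ -n 50 --seed 1 --missing-xref-rate 0.02
```

This writes `article_*.xml`, `manifest.tsv` (the expected pipeline output,
built by construction), and `corpus_config.json`.

### Reconciliation input formats

`--candidates` — per-reference candidate-ID table (TSV with header):

```
pmcid	ref_id	candidate_id	id_space	probability	confirmations
123456	B3	28222903	pmid	0.999	icite;entrez
```

`id_space` is `pmid` or `non_pmid`; `confirmations` is a semicolon-joined
list of confirming source names. References absent from the table are
treated as not cross-checked (`PMID_XML` / `NONE_XML`).

`--entrez` — cited-PMID list per citing article (TSV with header):

```
pmcid	cited_pmid
123456	28222903
```

### YAML config

Recognized keys: `imrad_rules` (label → cue list; `*` suffix = word-prefix
wildcard), `location_labels` (component → emitted label string),
`thresholds` (`default`, `confirmed_pmid`, `non_pmid`,
`preference_margin`), `abbreviations` (sentence-tokenizer guard list),
`progression_mode`, `include_text`, `contexts_only`.

## Library use

```python
from jatscite import parse_article, process_article

root = parse_article("PMC123456.xml")
records, stats = process_article(root)
```
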