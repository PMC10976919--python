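# tnstager

Rule-based extraction of **T and N stage** (TNM, 8th edition, lung cancer)
from free-text chest **CT** and **PET-CT** radiology reports, including a
**metabolic overruling layer**: on PET-CT, stated FDG avidity overrules the
CT size criterion for lymph-node pathology in both directions (an enlarged
node without uptake is non-pathological; a small avid node is pathological).

Because real staging corpora are confidential, the package ships a
**synthetic labeled-report generator** (findings-first, so gold labels are
guaranteed by construction, with tunable adversarial distractors) and an
**evaluation harness** (accuracies, support-weighted P/R/F1, confusion
matrices, categorized error report), making the whole pipeline testable
end to end without clinical data.

## Pipeline

```
raw text ─ clean (length-preserving) ─ sectionize ─ detect modality
         ─ split sentences ─ extract measurements (mm) + anatomical blacklist
         ─ match lexicon concepts ─ assign assertions (ConText-style
           negation/uncertainty trigger scopes)
         ─ aggregate tumor + node findings (incl. FDG avidity)
         ─ map T (size buckets + feature overruling) and N (station map,
           PET overruling) ─ TNResult {t, n, trace}
```

All vocabulary (concepts, modifier triggers, section headings, blacklist,
abbreviations) lives in a swappable YAML lexicon
(`src/tnstager/data/default_lexicon.yaml`); the TNM-8 numeric tables live in
a versioned rules file (`src/tnstager/data/rules/tnm8.yaml`).

## CLI

```bash
# generate a labeled synthetic corpus (prints the stage mix)
tnstager generate --n 163 --seed 7 --petct-frac 0.6 --output corpus.jsonl \
    --adversarial negation=0.2 --adversarial missing_subheadings=0.1

# stage a corpus (JSONL or a directory of .txt files)
tnstager stage --input corpus.jsonl --output preds.jsonl --trace
tnstager stage --input reports_dir/ --format txt_dir --output preds.jsonl

# score predictions against gold labels
tnstager evaluate --predictions preds.jsonl --gold corpus.jsonl \
    --metrics-out metrics.json --errors-out errors.csv

# validate a (custom) lexicon
tnstager validate-lexicon --lexicon my_lexicon.yaml
```

Input JSONL fields: `report_id`, `text`, optional `modality` (`CT`/`PETCT`),
optional `gold_t`, `gold_n`. Output of `stage`: one JSON line
`{report_id, t, n[, trace]}` per report.

## Layout

```
src/tnstager/
  corpus_io.py          # JSONL / txt corpora, sectionizer, modality detection
  preprocess.py         # cleaning, sentence split, measurements, blacklist
  lexicon.py            # YAML vocabulary loading + validation
  context_engine.py     # concept matching + negation/uncertainty scopes
  findings.py           # tumor/node aggregation, avidity matching
  staging.py            # TNM-8 T/N mapping, PET overruling, stage_report
  synthetic_reports.py  # labeled report generator (findings-first)
  evaluation.py         # metrics, confusion matrices, error report
  cli.py                # click CLI: stage / generate / evaluate / validate-lexicon
  data/                 # default lexicon, TNM-8 rules, sentence templates
tests/                  # pytest suite incl. tests/test_acceptance.py
scripts/acceptance.py   # acceptance report entry point
```
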