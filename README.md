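# codres

Composite drug-repurposing scoring and re-ranking for stage-resolved
disease contrasts.

Candidate inhibitor drugs arrive as connectivity-map-style scores in
[-1, 1] keyed by (tool, gene-selection method, dataset, stage contrast).
`codres` filters them by an inhibition threshold with tool- and
dataset-level consensus, computes four normalized component scores —

- **inhibition**: per-stage sum of qualifying score magnitudes, divided by
  the stage maximum;
- **structural druglikeness**: `1 - violations / max violations`;
- **functional relevance**: mean per-target-gene enrichment, divided by the
  batch maximum;
- **side effects**: `1 - S / S_max` with `S = sum(class count x class
  index)` over 8 severity classes (unknown profiles score 0);

— and combines them as a weighted sum (default weights 0.4 / 0.2 / 0.2 /
0.2) to re-rank drugs per stage, reporting each drug's signed re-ranking
shift against the inhibition-only ordering. It also clusters drugs by
binary-fingerprint similarity (Soergel distance, Ward linkage, dendrogram
cut) and selects the top-scored representative of each structural cluster,
builds up/down gene signatures from differential-expression tables with
cross-method and cross-dataset consensus, and provides pathway-set and
drug/microRNA common-target overlap utilities.

The package ships transcribed reference tables (21 drugs x 3 component
scores, four per-stage inhibition columns with published composite values
and shifts, four per-experiment pathway lists) as regression fixtures, plus
seeded synthetic generators that return their own ground truth.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the criterion-level suite (golden-table
reproduction, component-score contracts over 1000 random batches,
consensus-filter oracle equivalence, planted-cluster recovery across 100
seeds, pathway-core intersection).

## CLI

One subcommand per pipeline stage, so upstream tool outputs can be slotted
in at any boundary:

```sh
codres make-fixtures --out fx/                       # materialize fixtures
codres select-genes  --deg fx/synthetic_deg.tsv --out genes/
codres filter-drugs  --scores fx/synthetic_scores.tsv --out inhib/
codres score         --components components.tsv --weights 0.4,0.2,0.2,0.2 --out ranked/
codres rank-shift    --inhib a.tsv --codres b.tsv --out shifts/
codres cluster       --fingerprints fx/synthetic_fingerprints.tsv \
                     --ranking ranked/ranked.tsv --cut 1.0 --out clusters/
codres overlap-pathways --pathways fx/pathways_IPF_vs_Normal.txt \
                        --pathways fx/pathways_Stage1_vs_Normal.txt --out pathways/
codres overlap-targets  --targets targets.tsv --upregulated up.txt --out overlap/
```

Every command writes a `manifest.json` (config, input checksums, package
version) next to its outputs. All tables are UTF-8 CSV/TSV with
auto-detected delimiters; real-valued columns are written both rounded to
3 decimals and at full precision.

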