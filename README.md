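# modulome

Inference of **iModulons** — independently modulated gene sets — from
bacterial expression compendia, with regulon-based annotation and
condition-dependent activity analysis.

## The problem

The transcriptional regulatory network (TRN) of a bacterium links
transcription factors (TFs) to the genes they control. Bottom-up methods
(ChIP-seq) map one TF at a time; a top-down alternative decomposes a
compendium of transcriptomes **X** (genes × samples, log-scale,
centered to a reference condition) by independent component analysis:

```
X ≈ M · A
```

where **M** (genes × components) holds statistically independent gene-weight
signatures and **A** (components × samples) their activities per sample. Each
component's heavy tail of large-|weight| genes is an *iModulon*: a
data-driven analogue of a regulon. Comparing iModulons with curated regulons
recovers known regulatory interactions and proposes new ones, and the A
matrix shows which gene programs switch on under which growth conditions —
e.g. trade-offs between stress-induced and growth-associated programs in
lactic acid bacteria.

The pipeline implements:

- **Preprocessing / QC** — log2(x+1) transform of RPKM values, per-gene
  centering against a reference condition, replicate-vs-non-replicate
  Pearson-correlation quality check.
- **Robust ICA** — many FastICA runs (log-cosh contrast, parallel fixed-point
  search, tolerance 1e-7), each on a bootstrap resample of the samples;
  pooled sources clustered by DBSCAN on `1 − |r|`; each cluster recurring in
  at least half the restarts contributes its centrotype as a component.
  A is the least-squares projection of X on the retained components.
- **Dimensionality selection** — sweep candidate dimensions and pick the
  smallest one maximizing the number of robust, non-single-gene components
  (the OptICA idea).
- **Member-gene extraction** — iterative D'Agostino K² thresholding
  (cutoff 550): strip the largest-|weight| gene until the remaining weights
  look normal; the stripped genes are the members.
- **Annotation** — two-sided Fisher exact tests of members against every
  regulon, Benjamini–Hochberg FDR < 1e-5, recall/precision, combinatorial
  `R1+R2` / `R1/R2` labels, TF-expression correlation validation, and
  strand-aware 200-bp upstream-region extraction for external motif tools.
- **Activity analysis** — per-condition activity tables, ranked condition
  contrasts, weighted TF–gene correlation networks, activity–activity
  trade-off correlations, aggregate expression of gene programs.
- **Synthetic compendia** — a generator with planted M/A structure,
  replicate layout, TF genes and jittered regulons, so every stage is
  testable against ground truth.

## Worked example

```python
from modulome import (SyntheticConfig, generate_compendium, log_transform,
                      center_to_reference, qc_replicates, robust_ica,
                      explained_variance, extract_imodulons)
from modulome.annotation import RegulonDB, annotate_imodulons
from modulome.scoring import score_recovery

cfg = SyntheticConfig(n_genes=1000, n_samples=50, n_modules=5,
                      module_size_range=(8, 15), n_replicate_groups=25,
                      replicates_per_group=2, noise_sd=0.1, seed=1)
truth = generate_compendium(cfg)
logged = log_transform(truth.compendium)
centered = center_to_reference(logged)

report = qc_replicates(logged)
dec = robust_ica(centered.values, 5, n_restarts=20, base_seed=2)
ims = extract_imodulons(dec)
db = RegulonDB(universe=set(truth.gene_ids), regulons=truth.regulons)
annotate_imodulons(ims, db)
score = score_recovery(truth, dec, ims)
```

Output:

```
QC: median replicate PCC = 0.920, non-replicate = 0.480, pass = True
robust components: 5, explained variance = 0.927
iModulon sizes: {'IM-1': 8, 'IM-2': 11, 'IM-3': 12, 'IM-4': 15, 'IM-5': 14}
labels: {'IM-1': 'TF_mod05', 'IM-2': 'TF_mod01', 'IM-3': 'TF_mod02', 'IM-4': 'TF_mod04', 'IM-5': 'TF_mod03'}
recovery vs planted truth: mean |r| = 0.984, membership F1 = 1.000
```

Replicate samples correlate far above non-replicates (QC passes); the five
planted modules come back as five robust components explaining 93% of the
centered variance; K² extraction recovers every planted member set (F1 = 1),
and each iModulon's top Fisher hit is its planted regulator.

The same pipeline runs from the shell:

```
modulome run --set output_dir=out --set dimension=5 --set n_restarts=20
modulome qc --set expression_path=out/expression.tsv --set metadata_path=out/metadata.tsv
```

Real compendia enter as a genes × samples TSV of RPKM values plus a sample
metadata TSV (`sample_id, project, condition, replicate_group,
is_reference`) and a two-column regulon TSV (`regulator, gene`); pass their
paths via `expression_path`, `metadata_path`, `regulons_path`.

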