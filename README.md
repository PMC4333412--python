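# nfatseq

Tools for integrating NFATc2 ChIP-seq binding with expression changes in
dectin-1-stimulated dendritic cells.

Curdlan (a β-1,3-glucan) ligates the dectin-1 receptor on dendritic cells and
activates, among other pathways, calcineurin/NFAT signalling; FK506
(tacrolimus) blocks NFAT nuclear translocation. Given peak calls for the
NFATc2 transcription factor under three conditions — untreated, curdlan, and
curdlan + FK506 — together with replicate expression measurements for the
same contrasts, this package answers the questions such an experiment poses:

- **Where does the factor bind?** Each peak summit is classified into six
  location categories (intragenic, 5′/3′ proximal, 5′/3′ distal within
  100 kb of the transcriptional unit, gene desert beyond), and summit-to-TSS
  distances are profiled.
- **Which genes respond, and which need NFAT?** A two-group Welch test with
  Benjamini–Hochberg correction and the |FC| ≥ 1.5, adjusted p < 0.05 filter
  yields dectin-1-regulated sets (curdlan vs untreated) and NFAT-dependent
  sets (curdlan+FK506 vs curdlan); their overlap is summarized Venn-style.
- **Is binding coupled to response?** Genes are ranked by log₂ fold change
  and a 50-gene moving window reports the fraction with a summit within
  20 kb of the TSS; peaks are stratified by height (0–20 / 20–30 / 30–50 /
  50–100) against the activated-gene fraction; nearest-summit distance is
  recorded per gene.
- **Which genes are direct targets?** A gene is called a direct target when
  a site within 30 kb of its TSS gains ≥ 1.5× height on stimulation and
  falls to ≤ 1/1.5 of the stimulated height under FK506 (heights get a +1
  pseudocount; peaks are matched across conditions by id or by
  reciprocal-nearest summits within 200 bp).
- **What is the binding sequence?** Summit-centered 201-bp windows feed an
  IUPAC consensus scanner (e.g. the NFAT consensus `NANWGGAAAANN`), an
  empirical enrichment test against dinucleotide-shuffled backgrounds, a
  one-occurrence-per-sequence (OOPS) EM motif discoverer, and a PWM-library
  scanner with a core-score cutoff.
- **How much occupancy does qPCR see?** ΔCt-based percent input
  (`100·2^((Ct_input − log₂(1/input_fraction)) − Ct_IP)`), relative occupancy
  against a control region per plate, and fold change against the untreated
  baseline.

A first-class synthetic-data module generates genomes, gene models,
condition-coupled peak sets, replicate expression matrices and planted
motifs with a ground-truth manifest, so every analysis above can be checked
against what was planted.

## Worked example

Generate a dataset and run the expression integration (the numbered scripts
under `analysis/` run the full narrative; outputs land under `results/`):

```sh
python analysis/01_simulate.py
python analysis/03_differential_expression.py
python analysis/04_integrate_binding_expression.py
```

`03_differential_expression.py` prints (noise sd 0.25 log₂ units, 5
replicates/condition):

```
 n_dectin_up  n_dectin_down  n_nfat_up  n_nfat_down  n_common_up  ...
         515            325        161           80          125
125.0 genes are up-regulated by both dectin-1 stimulation and the NFAT
pathway: 24.3% of dectin-1-activated and 77.6% of NFAT-activated genes
```

The generator planted 515/323 dectin-regulated and 171/82 NFAT-dependent
genes with a 135-gene common up-set; under replicate noise the thresholds
recover 515/325/161/80 with a 125-gene overlap — on noiseless data the
recovery is exact and the overlap percentages are 26.2% and 78.9%.
`04_integrate_binding_expression.py` then reports

```
bound fraction, top-ranked tenth of windows: 0.738; bottom tenth: 0.503
direct targets: 50 called, precision 1.000, recall 1.000
```

i.e. binding is over-represented among up-regulated genes, and all 50
planted direct targets (and no others) are recovered from the
condition-matched peak heights.

The same operations are available as a CLI
(`nfatseq simulate|annotate|de|venn|integrate|motif|quant`, each accepting
`--config JSON --seed N`) or directly from Python:

```python
from nfatseq import RunConfig, diffexpr, synthetic

cfg = RunConfig()
params = synthetic.SimParams(noise_sd_log2=0.0)
_, genes, peaks, expr, samples, truth = synthetic.simulate_dataset(params, cfg)
sets = diffexpr.nfat_dependent_sets(expr, samples, cfg)
print(diffexpr.venn_summary(sets["dectin_up"], sets["dectin_down"],
                            sets["nfat_up"], sets["nfat_down"]))
```

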