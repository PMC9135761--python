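# gutdynamics

Chromatin-accessibility analysis of early gut organogenesis, packaged as
a tested, reusable pipeline.  During gut-tube development, organ fates
(intestine, stomach, lung, pancreas, esophagus, ...) are foreshadowed by
organ-specific patterns of open chromatin before and alongside
transcriptional changes.  `gutdynamics` implements the statistics used
to quantify that relationship:

* **per-cell QC and gene activity scores** from scATAC-seq fragments
  (≥ 1000 fragments and TSS enrichment ≥ 4; distance-weighted 500 bp
  bins within 100 kb of the gene body), and marker-based organ labeling
  of cell clusters with one level of hierarchical refinement;
* **organ-specific peak/gene calling** on bulk accessibility or
  expression by quantile normalization, log transform, K-means, and a
  per-feature fold filter (target / mean of other organs ≥ 2.5), plus
  rank-sum marker calling on single cells (FDR ≤ 0.05, log2FC ≥ 1.5 / 1)
  and one-sided hypergeometric overlap enrichment between peak sets;
* the **gene–peak association score** — for a target gene set,

  *association = (O_T / G_T) / (O / G)*,

  the rate of carrying a target peak within ±50 kb of the TSS relative
  to the genome-wide rate (1 = no association);
* the **relative motif enrichment score** — a signed −log10 p of a
  two-sided rank-sum test comparing stage-to-stage accessibility fold
  changes of motif-overlapping versus motif-free peaks, with motif sites
  from a built-in exact-p-value PWM scanner (positive = accessibility
  gained during development at the motif);
* **KO peak-fate analysis** — gained / maintained / lost peaks by KO/WT
  fold change (threshold 2, pseudocount 0.5), per-cell deviation
  z-scores of any peak set against accessibility-matched backgrounds,
  organ overlap fractions, and UpSet-style categorization of DE genes by
  the peak fates within their 50 kb TSS flank;
* **foregut lineage restriction** — peaks commonly open early but closed
  per organ later, repressed genes (fold change < 0.5 with pseudocount
  0.5), refinement of each repressed-gene category by its closed peaks,
  and exact binomial comparison of the refined fractions.

A synthetic-data module generates organ-structured fragments, bulk
stage/KO counts, expression tables and planted motif sites with known
ground truth, so the entire pipeline runs and is validated end to end
without external data.  See `docs/methods.md` for the models, defaults
and design decisions.

## Worked example

Run a small synthetic study end to end (a YAML config can override any
threshold; defaults are the study values):

```yaml
# example.yaml
outdir: example_run
seed: 7
sim:
  n_contigs: 2
  contig_length_bp: 1000000
  n_genes: 60
  organs: [intestine, stomach, lung]
  n_cells_per_organ: 60
  n_peaks_total: 600
  n_temporal_gained_peaks: 30
  n_temporal_up_genes: 8
  n_ko_gained: 30
  n_ko_lost: 30
  fragment_rate: 1500
kmeans_k: 6
n_top_genes: 8
n_top_peaks: 30
```

```bash
gutdynamics run-all --config example.yaml
```

prints one record per stage (abridged):

```json
{"stage": "qc", "status": "ok", "n_input": 180,
 "removed_low_fragments": 7, "removed_low_tss": 4, "n_retained": 173}
{"stage": "label", "status": "ok", "n_clusters": 3, "label_recovery": 1.0}
{"stage": "organ_specific", "status": "ok", "specific_peak_recovery": 0.9917}
{"stage": "temporal", "status": "ok", "association_diag_mean": 1.187,
 "tallies": {"intestine": "8/8", "stomach": "7/8", "lung": "8/8"}}
{"stage": "ko", "status": "ok", "n_gained": 95, "n_lost": 67,
 "ko_gained_recovery": 1.0, "ko_lost_recovery": 1.0}
```

Reading the numbers: 7 of 180 simulated cells were planted below the
1000-fragment QC bar and all were removed (4 more failed the TSS
filter); all 3 cell clusters were labeled with their true organ from
marker gene scores; 99.2% of planted organ-specific peaks were recalled
at the fold ≥ 2.5 rule; the association-score diagonal (same-organ gene
and peak sets) averages 1.19, above the null value of 1, with 8/8, 7/8
and 8/8 of each organ's top upregulated genes carrying a gained peak in
their TSS flank; and every planted KO-gained and KO-lost peak was
recovered by the fold-change partition.  Stage outputs (BED, TSV,
MatrixMarket, JSON) land under `example_run/`, together with the
resolved config and its hash.

The same stages are available as library functions
(`gutdynamics.association_score`, `gutdynamics.scan_pwm`,
`gutdynamics.deviation_zscore`, ...) for use on real matrices and peak
sets.

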