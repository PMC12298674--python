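# polysplice

Alternative-splicing reprogramming and subgenome expression bias in
allopolyploid transcriptomes: a tested, reusable analysis pipeline.

Allopolyploid plants carry two parental subgenomes (here A and B) whose
duplicated gene copies — homoeologs — can respond differently to stress.
Two regulatory layers are analyzed jointly: **alternative splicing** (AS),
quantified per local event as percent-spliced-in, and **subgenome
expression bias**, the systematic dominance of one homoeolog copy. The
pipeline takes transcript models (GTF), transcript abundance (TPM), gene
counts, per-event inclusion/exclusion read counts, a BLAST tabular hit
table and a gene→term map for three condition groups × three replicates,
and produces event catalogs, differential-splicing and
differential-expression calls, bias-transition tables, and integration
statistics.

## The core quantities

* **PSI** (percent spliced in) for event *e* in sample *s*:
  `PSI = Σ TPM(inclusion isoforms) / Σ TPM(all event isoforms)` ∈ [0, 1].
* **ΔPSI** = mean PSI(treatment) − mean PSI(control); events with
  |ΔPSI| > 0.2 and binomial p < 0.05 are significant, and are classified
  **gained** (control PSI ≈ 0/1, treatment intermediate), **lost** (the
  mirror), or **DAS** (any other quantitative shift).
* Local events are enumerated from exon-chain differences in four types:
  intron retention (IR), exon skipping (ES), alternative donor (A5) and
  alternative acceptor (A3), with event ids
  `gene;TYPE:chrom:n1-n2:n3-n4:strand` (coordinate pairs are the flanking
  junction/exon anchors; for A5/A3 the two alternative introns).
* **DEGs**: |log2FC| ≥ 2 and BH q < 0.05 under a median-of-ratios
  normalized negative-binomial Wald test.
* **Bias classes** per homoeolog pair and condition from
  `log2((mean_A + 1)/(mean_B + 1))`: A-bias (≥ 1), B-bias (≤ −1),
  balanced, or low-expression; transitions between conditions are
  cross-tabulated with percentages.
* **Enrichment**: hypergeometric upper tail with BH correction;
  GeneRatio = k/M (list∩term over term size in the background).

Real sequencing data are out of scope at desk scale; a bundled synthetic
generator (`polysplice.synthetic_data`) emulates the full study design —
two subgenomes, homoeolog pairs, planted events of every category, planted
DEGs and bias shifts — and emits a truth ledger against which recovery is
measured. See `docs/methods.md` for the full model description.

## Worked example

```bash
python analysis/01_simulate.py --seed 1     # synthetic fixture
python analysis/02_run_pipeline.py          # full pipeline on it
python analysis/03_recovery_benchmarks.py   # recovery vs planted truth
python analysis/04_published_statistics.py  # printed-count statistics
```

The pipeline run prints, for the default seed-1 fixture:

```
reports written to .../results/reports
  catalog: 128 events
  active-event composition AG: IR 24.6%, ES 24.6%, A5 25.4%, A3 25.4%
  ...
  DSE composition CGvsAG: DAS 34.4%, gain 32.3%, lost 33.3%
  subgenome DEG chi2 CGvsAG: 0.03 (p=0.874)
```

All 128 planted events are re-identified at id level; the differential
splicing composition reflects the planted 32/32/32 gained/lost/DAS design
(the near-one-third split is the planted composition, not an inference
artifact), and the subgenome DEG chi-square is null because the default
fixture plants DEGs symmetrically across subgenomes. The recovery
benchmark reports:

```
                         metric  value    n
       dse_recovery_sensitivity 0.9896   96
         dse_recovery_precision 0.9896   96
       deg_recovery_sensitivity 1.0000  100
               deg_recovery_fdr 0.0000  100
binomial_test_null_p05_rate_pct 4.4500 2000
```

i.e. 95/96 planted effect events recovered with the correct three-way
label, all 100 planted DEGs found with no false calls, and a calibrated
binomial test under the null. The published-statistics script recomputes,
from the study's printed DEG/expressed counts per subgenome, Yates-corrected
χ² = 3.82 (p = 0.051) and 6.58 (p = 0.010), and the balanced→biased
transition percentages 16.60 / 16.05 / 11.30 / 11.36 from the printed
count/total pairs.

A `polysplice` CLI wraps the same library: `polysplice simulate --seed 1
--out fix/`, `polysplice run --config pipeline.yaml`, plus stage entry
points (`events`, `psi`, `dse`, `de`, `bias`, `integrate`).

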