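# m6akit

Differential m6A (N6-methyladenosine) analysis for MeRIP-seq-style
IP/input count data, built as a tested, fully synthetic-data-driven
pipeline. It is aimed at computational biologists who want a transparent,
desk-scale re-implementation of the analysis pattern behind paired
tumor/paratumor (or hypoxia/normoxia) epitranscriptome studies: which
transcript regions gain or lose m6A, how those changes pair with
expression changes, and which candidate genes fall out of the joint
screen — plus the downstream kinetics and mass-spectrometry arithmetic
those studies rely on.

## What it computes

- **Window enrichment and peak calling.** For each tiled transcript
  window, a one-sided exact test of the 2x2 table
  `[ip, total_ip − ip; input, total_input − input]` asks whether the
  window's share of IP reads exceeds its share of input reads;
  significant windows (p < 0.05) merge into peaks (gap ≤ 1 window, ≥ 2
  significant windows), and peaks are assigned to 5'UTR/CDS/3'UTR by
  midpoint.
- **Differential methylation.** Per peak, a two-sided exact test on
  `[IP_B, input_B; IP_A, input_A]` with
  `log2FC = log2(((IP_B+1)/(input_B+1)) / ((IP_A+1)/(input_A+1)))` and
  Benjamini–Hochberg FDR; peaks are called hyper/hypo at p < 0.05 and
  q < 0.05.
- **Quadrant classification.** Genes with both a directional peak and a
  directional CPM expression change are binned into hyper-up /
  hyper-down / hypo-up / hypo-down per patient; percentages are averaged
  over the cohort, high-frequency hyper-up genes (≥ 3 patients) are
  listed, and two > 2-fold lists (knockdown-upregulated x
  hypermethylated-and-upregulated) intersect into candidate targets.
- **Gene-set enrichment.** A from-scratch weighted running-sum statistic
  (hits add `|score|^p/Σ|score|^p`, misses subtract `1/(N−N_hits)`; ES =
  extreme running value) with a gene-label permutation NES and p-value,
  and the 14-gene hypoxia metagene signature built in.
- **Kinetics and quantification.** First-order decay fits
  `N_t/N_0 = e^(−kt)` (log-linear through the origin, `t½ = ln2/k`),
  linear standard-curve calibration per nucleoside channel
  (m6A 282→150, A 268→136) yielding m6A/A ratios, and qPCR
  `percent input = 100·2^(ΔCt)` enrichment.
- **Synthetic cohort generator.** Ground-truthed paired cohorts with
  planted peaks (3'UTR/CDS-biased), planted quadrant structure,
  negative-binomial counts, decay series and calibration standards, so
  every stage is testable end to end with no external data.

## Worked example

Run the numbered analysis drivers (or equivalently `m6akit run`):

```bash
python analysis/01_simulate_cohort.py --seed 0
python analysis/02_call_differential_peaks.py
python analysis/03_quadrants_and_screen.py
python analysis/04_hypoxia_gsea.py
python analysis/05_kinetics_and_msquant.py
```

which prints (seed 0):

```
  transcripts: 1000, methylated: 317, differential (quadrant-labeled): 162
  planted quadrant counts: {'hyper-up': 106, 'hyper-down': 23, 'hypo-down': 19, 'hypo-up': 14}
called 405 peaks (5'UTR 10.1%, CDS 39.0%, 3'UTR 50.9%)
differential peaks at p<0.05, q<0.05: 169 (78.1% hyper, 21.9% hypo)
cohort-mean quadrant percentages: {'hyper-up': 69.69, 'hyper-down': 12.01, 'hypo-up': 10.03, 'hypo-down': 8.27}
high-frequency hyper-up genes (>= 3 patients): 83; top: ['ADM', 'G00227', ...]
screen: 116 knockdown-up genes x 23 hyper-and-up genes -> 19 candidates
HYPOXIA_METAGENE_14: ES=0.898 NES=2.178 p=0.001894 (14/14 genes in ranking)
control: true k=0.35/h, fitted k=0.350/h, mean t1/2=1.98 h, mean r2=0.998
treated: true k=0.18/h, fitted k=0.181/h, mean t1/2=3.84 h, mean r2=0.990
paratumor: true m6A/A=0.0100, estimated=0.0095
tumor: true m6A/A=0.0150, estimated=0.0132
```

Reading this: the cohort planted 70% of its differential transcripts as
hyper-up, and the recovered cohort-mean hyper-up share is 69.7%; peaks
concentrate in the 3'UTR and CDS as planted; the significant peaks split
~78/22 into methylation gains vs losses; the hypoxia signature — embedded
in upregulated genes — scores a strongly positive NES with a permutation
p ≈ 0.002; decay fits recover the planted degradation rates, with the
treated (stabilised) condition showing the longer half-life; and the
calibrated m6A/A ratios track the planted values.

The same workflow is scriptable through the `m6akit` CLI
(`simulate`, `callpeaks`, `diffpeaks`, `quadrants`, `screen`, `gsea`,
`decay`, `msquant`, `run`, `config`), all driven by one YAML config and a
single global seed; rerunning with the same seed reproduces every output
byte for byte.

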