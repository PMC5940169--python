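# ohnoretain

Retention-rate analysis of gene families passing through nested
whole-genome duplications (WGDs), built for comparative genomicists
studying ohnolog retention — in particular the vertebrate pigmentation
gene repertoire across the two basal vertebrate rounds (1R/2R), the
teleost-specific third round (Ts3R) and the salmonid-specific fourth
round (Ss4R).

## The statistic

Every gene lineage alive at a WGD is one *duplication opportunity*: it
either keeps both post-WGD copies (retention, score 1) or loses one
(score 0). The retention rate of a stratum S of opportunities is

    RR(S) = (# retained in S) / |S|

Strata cross the WGD event with family copy-class after 1R/2R
(monogenic vs multigenic), pigmentation-gene (PG) status, functional
category, and the lineage's outcome at the previous WGD (for
conditional, "predestination"-style analyses). Rates are kept as exact
count pairs and only rendered as one-decimal percentages at the
reporting boundary. Observed rates are compared against genome-wide
baseline ranges (one-sample score chi-square versus the nearest bound),
between strata (2x2 chi-square, Yates correction on by default), and
across functional categories (Wald test on a binomial GLM). The
compound 1R/2R era uses node-averaging: a retained first-round
duplicate contributes two second-round duplication nodes, a lost one
contributes a single node, and the family rate is the mean node outcome.

The package also contains a generative simulator: families evolve
through VGD1 → VGD2 → TSGD → SSGD, each surviving lineage retaining its
duplicate with probability `logistic(base_logit[event] + beta·x +
gamma·carryover)`, which supports calibration (parameter-recovery)
experiments and null-distribution checks.

## Worked example

```python
from ohnoretain import build_summary_report
from ohnoretain.datasets import BASELINES, curated_dataset

genes, events = curated_dataset()   # 169-family curated reference counts
report = build_summary_report(genes, events, BASELINES)
print(report.to_text())
```

prints (abridged):

```
Retention-rate summary
families: 169 (77 monogenic / 92 multigenic, 54.4% multigenic); genes: 328 (184 PG + 144 non-PG)

event  overall_pg          pg_monogenic        pg_multigenic       nonpg_multigenic
TSGD   34.2% (63/184)      16.9% (13/77)       46.7% (50/107)      37.1% (52/140)
SSGD   72.8% (177/243)     72.2% (65/90)       73.2% (112/153)     71.5% (133/186)

SSGD retention conditioned on TSGD outcome
  pg_pooled_prior_retained         72.3% (86/119)
  pg_pooled_prior_lost             73.4% (91/124)

compound 1R/2R era: family-mean RR 31.4% over 169 families (baseline 17.0-34.5%, within range: True)

statistical tests
  pg_monogenic_vs_pg_multigenic@TSGD           yates_chi2       stat=16.41 df=1 p=5.09e-05
  pg_monogenic_vs_pg_multigenic@SSGD           yates_chi2       stat=0.0002753 df=1 p=0.987
  pg_pooled_prior_retained_vs_pg_pooled_prior_lost@SSGD yates_chi2  stat=0.002667 df=1 p=0.959
  overall_pg@TSGD_vs_baseline                  one_sample_prop  stat=32.87 df=1 p=9.83e-09
```

Reading: PGs were retained after the teleost round at 34.2% — far above
the 4–18% genome-wide range (p ≈ 1e-8) — but the excess is carried by
multigenic families (46.7% vs 16.9%, p ≈ 5e-5 corrected); after the
salmonid round retention is uniformly high (~72–73%) regardless of
copy-class or of the Ts3R outcome (p ≈ 0.99 / 0.96), while the compound
1R/2R era sits inside the genome-wide range.

The same analysis runs from the shell:

```sh
ohnoretain simulate --seed 1 --out sim/            # synthetic dataset + ground truth
ohnoretain analyze --genes sim/gene_table.tsv --events sim/event_table.tsv --out report/
ohnoretain recover --replicates 50 --out recovery/ # simulate-then-re-estimate calibration
ohnoretain report --report report/report.json
```

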