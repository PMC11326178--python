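# spliceburden

Cohort-scale analysis of aberrant alternative splicing from rMATS-style
junction-count tables, built for tumor cohorts that lack matched normal
tissue (the motivating setting is pediatric CNS tumors profiled by bulk
RNA-seq).

Given one `*.MATS.JC.txt` table per sample per splice type (skipped exon,
A5SS, A3SS, retained intron), the package:

1. recomputes percent-spliced-in from length-normalized junction counts,
   `PSI = (IJC/IncFormLen) / (IJC/IncFormLen + SJC/SkipFormLen)`,
   filters events with fewer than 10 supporting junction reads, and
   harmonizes events across samples into a cohort PSI matrix;
2. calls an event *differential* in a sample when its PSI is an outlier
   against the cohort distribution of that event (z-score strictly beyond
   |2|, sign-aware: inclusion gain vs skipping), and summarizes each
   sample by the **Splicing Burden Index (SBI)** — the fraction of its
   measured events called differential — with high/low strata at the
   cohort quartiles (≥ Q3 / ≤ Q1);
3. finds recurrent (≥ 2 supporting samples) differential events per group
   and decomposes them into group-specific vs shared sets;
4. clusters samples by Ward/Euclidean linkage on the top 5,000 most
   variable skipped-exon PSI values and tests cluster–histology
   association with two-sided Fisher exact tests (sample odds ratio,
   Haldane-corrected when a cell is zero, BH-adjusted);
5. maps cassette exons through transcript CDS models onto 1-based protein
   residues (`residue = floor(cds_offset/3) + 1`) and classifies events
   whose exon overlaps a UniProt-style functional site (domain, disulfide
   bond, modified residue, localization signal) as functional-site
   gain/loss/mixed, with a kinase short-list filter;
6. scores single-sample gene-set activity with a deterministic
   rank-weighted running-sum statistic (ssGSEA-style, `alpha = 0.25`),
   compares scores between clusters, and correlates pathway scores with
   protein abundance;
7. fits Kaplan–Meier/log-rank and Cox proportional-hazards models
   (Efron ties, factor reference levels, interactions, quartile
   stratification) for OS/EFS, plus expression–burden correlation panels
   with BH FDR;
8. compares small paired replicate designs (e.g. 3 treated vs 3 control
   morpholino replicates) by exhaustive label-permutation of ΔPSI, with
   DS/DE/dependency set logic and hypergeometric over-representation.

A synthetic-data module generates rMATS-like cohorts, paired designs and
toy GTF/feature annotations with exact ground truth, so every stage is
testable without access to controlled patient data.

## Worked example

```python
import spliceburden as sb
from spliceburden.synthetic import CohortSpec, simulate_cohort
from spliceburden.cluster_enrich import (
    hierarchical_cluster, select_variable_events, cluster_enrichment,
)

spec = CohortSpec(n_samples=100, n_events=1000, n_clusters=3,
                  aberrant_fraction=[0.0, 0.1], seed=42)
cohort = simulate_cohort(spec)

tables = [sb.apply_junction_filter(t, min_reads=10) for t in cohort.tables]
matrix = sb.build_psi_matrix(tables)
calls = sb.call_differential(sb.event_zscores(matrix), threshold=2)
sbi = sb.splicing_burden_index(calls)
print(sbi.head())
```

```
  sample_id splice_type  n_differential  n_measured    sbi stratum
0     S0000          SE              38        1000  0.038    high
1     S0001          SE              34        1000  0.034     mid
2     S0002          SE               9        1000  0.009     mid
3     S0003          SE              59        1000  0.059    high
4     S0004          SE              41        1000  0.041    high
```

Half the samples carry a planted 10% aberrant-event fraction, so their
SBI (~0.05–0.06) sits well above the null samples (~0.01–0.04, the
two-sided tail mass of the z > |2| caller); the cohort median here is
0.0280. Clustering the same matrix recovers the three planted groups
exactly and the enrichment table ties each cluster to its dominant
histology label:

```python
assign = hierarchical_cluster(select_variable_events(matrix, 1000), k=3)
enr = cluster_enrichment(assign, cohort.clinical.set_index("sample_id")["histology"])
print(enr.sort_values("p").head(3))
```

```
 cluster label  odds_ratio            p        p_adj
       3 hist2  258.125000 4.417434e-20 3.975691e-19
       2 hist3  116.000000 2.363348e-16 1.063507e-15
       1 hist1   66.666667 2.252770e-12 6.758310e-12
```

The same flow is available from the shell:

```bash
splice-burden simulate --samples 100 --events 1000 --clusters 3 --seed 42 --out sim/
splice-burden burden --rmats-dir sim/ --type SE --zthresh 2 --out sbi.tsv
splice-burden run --config run.yaml     # full pipeline with manifest
```

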