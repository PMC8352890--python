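# imcorr — correlative intima–media expression analysis

`imcorr` implements a paired-compartment RNA-seq analysis for discovering
flow-induced vascular-remodeling signals.  When blood flow in an artery
changes, the endothelial cells of the **intima** sense the altered wall shear
stress (WSS) and signal to the smooth-muscle cells of the **media**, which
carry out the structural remodeling.  The package identifies candidate
intima-to-media signals by correlating gene expression between the two
compartments across matched tissue samples taken from discrete flow
environments — the design of a rabbit bilateral-carotid-ligation experiment
with 16 samples: 2 tissues × 2 locations (straight basilar artery *BA*,
basilar terminus *BT*) × 2 conditions (ligated, sham) × 2 animals, each with
a local mean WSS from ~10 to ~130 Pa.

The pipeline, starting from a gene-level count matrix:

1. **QC** — compartment purity from marker genes (endothelial
   *PECAM1/VWF/CDH5* vs smooth-muscle *DES/ACTA2/MYH11* intima/media RPKM
   ratios) and a PCA overview of all samples.
2. **Differential expression** — per compartment and location, ligated vs
   sham: genes with maximum group-mean expression > 1 RPKM are tested with a
   negative-binomial exact-style conditional test (method-of-moments
   dispersions with shrinkage); Benjamini–Hochberg correction; DEG ⇔
   q < 0.05.
3. **Correlation screen** — the core step: every intimal DEG is correlated
   (Pearson) with every medial DEG over the eight matched measurements
   x<sub>g</sub> = (expression at animal × location), keeping pairs with
   |r| > 0.9 **and** p < 10⁻⁴.  Per-intimal-gene correlate tallies
   (n_total = n_pos + n_neg) feed the candidate rule: extracellular product
   **and** > 200 medial correlates.
4. **Ontology enrichment** — per candidate and correlation sign, the medial
   correlates are tested for term over-representation (hypergeometric,
   q < 0.05 per query), significant terms are pooled across the queries of a
   (direction × sign) stratum and ranked by occurrence; terms present in
   > 50% of queries are summarized REVIGO-style by greedy clustering on
   SimRel/Lin semantic similarity (cutoff 0.90).
5. **Dose–response** — candidate intimal expression vs local WSS is
   classified as `linear_increasing` (r ≥ 0.8, positive slope), `plateau`
   (rise then flat above a knee), or `peaked_decline` (maximum below 40 Pa,
   near-zero above 50 Pa).

A first-class synthetic-data generator (`imcorr.simulate`) emulates this
design with planted ground truth — tissue markers with realistic
cross-contamination, intimal signal genes following WSS dose–response
shapes, medial responders whose log-expression is coupled to their signal
gene, and null genes — so every stage is testable end to end without the
original sequencing data.

## Worked example

Run the full pipeline on the default synthetic dataset (2000 genes, 16
samples, 18 planted signal genes with 48 responders each):

```python
from imcorr import RunConfig, SimulationConfig, run_all

report = run_all(RunConfig(simulation=SimulationConfig(), out_dir="demo", seed=1))
print(report["pairs"])
print(report["marker_purity"]["PECAM1"]["mean_ratio"])
print(len(report["candidates"]), report["candidates"][0])
print(report["dose_response"]["SIGUP01"], report["dose_response"]["SIGDN01"])
```

prints (numbers from this exact run):

```
{'total': 381688, 'positive': 189487, 'negative': 192201}
126.7
17 {'intimal_gene': 'SIGUP01', 'direction_under_flow': 'up', 'n_total': 240,
    'n_pos': 120, 'n_neg': 120, 'product_class': 'kinase'}
linear_increasing peaked_decline
```

Reading this: 381,688 intima–media gene pairs pass the |r| > 0.9, p < 10⁻⁴
screen (the total is always positive + negative by construction); the
endothelial marker PECAM1 is ~127-fold enriched in intima over media,
confirming microdissection purity; 17 extracellular-product intimal genes
have > 200 medial correlates (5 up-regulated by flow, 12 down-regulated);
and the dose–response stage classifies the up-candidates as linear in WSS
and the down-candidates as peaked declines.  The enrichment stage recovers
the planted gene-ontology modules only in the two strata where they were
planted (positive correlates of up-candidates; negative correlates of
down-candidates) — the mirror strata are empty.

The same analysis is scriptable from the shell:

```bash
imcorr simulate --out data --seed 3          # write a synthetic dataset
imcorr run-all --synthetic --out demo --seed 1
imcorr report --report demo/report.json     # re-validate count identities
```

For real data, point `RunConfig` (or a YAML config for `imcorr run-all
--config`) at a counts TSV (`gene_id`, `length_bp`, one column per sample),
a sample table (animal, tissue, location, condition, local mean WSS in Pa),
an extracellular-product annotation TSV, a GMT gene-set file and an OBO
ontology.

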