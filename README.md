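# radiotsh

Radiogenomic analysis of **cellular tumor–stroma heterogeneity (TSH)** in
breast cancer: a reusable, tested pipeline linking bulk transcriptomics of
paired tumor/stroma samples, cell-population networks, survival statistics,
and DCE-MRI radiomics of the tumor and its peritumoral stroma.

## The problem

Solid tumors and their surrounding stroma exchange cells and signals, and
the *imbalance* of immune/stromal cell populations between the two
compartments carries prognostic information.  From bulk expression of
paired tumor and stroma samples, ten cell populations (eight immune
lineages plus endothelial cells and fibroblasts) are scored by the
marker-gene-mean estimator

  A(c, s) = mean over marker genes g of c of log2(x_gs + 1),

and the TSH statistic of a population is its relative tumor-vs-stroma
difference

  TSH = (A_tumor − A_stroma) / A_stroma.

Thresholding TSH (default 0.3512, for cytotoxic lymphocytes) stratifies
patients into good- and poor-survival groups, compared by Kaplan–Meier /
log-rank and multivariate Cox models (10-year administrative censoring,
Benjamini–Hochberg correction across populations).  Per group and region,
a cell-correlation network (edges at Pearson r > 0.5) is summarized by a
nine-parameter topology panel (Cytoscape NetworkAnalyzer conventions).

On the imaging side, DCE-MRI series (one precontrast volume S0 plus 3–6
postcontrast volumes) are resampled to 0.8 × 0.8 × 2 mm, normalized by the
parenchymal mean, reduced to three phase maps (S0, S_I = intermediate −
S0, S_L = last − S0), segmented with a spatially regularized fuzzy
c-means seeded at the tumor center, and surrounded by a 25-voxel (20 mm)
peritumoral stroma band.  A 572-feature radiomic vector is extracted:
18 first-order + 75 texture features (GLCM 24, GLRLM 16, GLSZM 16,
GLDM 14, NGTDM 5) per region {tumor, stroma} × phase {S0, S_I, S_L},
plus 14 tumor shape features.  A genetic algorithm under tenfold
cross-validation selects features for a random-forest classifier whose
predicted poor-class probability is the *imaging TSH score*; thresholding
it at 0.5 yields prognostic groups validated by log-rank, adjusted Cox
and likelihood-ratio tests.

All inputs can be simulated with known ground truth
(`radiotsh.synthetic_data`): marker-structured expression cohorts with
planted abundances, multi-phase tumor phantoms with known masks and
controllable texture, and exponential survival with a planted group
hazard ratio.

## Worked example

```python
import radiotsh.synthetic_data as sd
from radiotsh import cell_abundance, tsh_stats, cell_network

markers = sd.generate_markers(seed=7)
cohort = sd.generate_expression_cohort(
    sd.SyntheticCohortConfig(n_patients=200, n_genes=500, seed=11), markers)

ab = {r: cell_abundance.estimate_abundance(
          cell_abundance.filter_genes(e), markers)
      for r, e in [("tumor", cohort.tumor_expr), ("stroma", cohort.stroma_expr)]}
tsh = tsh_stats.tsh_table(ab["tumor"], ab["stroma"])
groups = tsh_stats.stratify(tsh["Cytotoxic lymphocytes"], threshold=0.3512)
print(groups.value_counts().to_dict())

surv = sd.generate_survival(cohort.groups, cohort.config)
stat, p = tsh_stats.logrank_test(surv, groups)
print(f"log-rank chi2 = {stat:.1f}, p = {p:.2e}")

good = cohort.groups[cohort.groups == "good"].index
net = cell_network.build_network(ab["tumor"].loc[good])
print(cell_network.topology(net).as_series().round(2).to_dict())
```

prints

```
{'poor': 101, 'good': 99}
log-rank chi2 = 27.9, p = 1.25e-07
{'node_number': 10.0, 'edge_number': 45.0, 'network_density': 1.0,
 'network_diameter': 1.0, 'characteristic_path_length': 1.0,
 'clustering_coefficient': 1.0, 'network_centralization': 0.0,
 'network_heterogeneity': 0.0, 'mean_degree': 9.0}
```

i.e. the TSH threshold nearly reproduces the planted 100/100 group split
(99/101 at log2 noise 0.3), the TSH-derived groups separate survival under
the planted hazard ratio of 3, and the good-survival group — generated
with strong inter-cell-type correlation — forms a complete 45-edge network
(the poor group's network is empty).

The same steps are scriptable from the shell (`radiotsh simulate
expression`, `radiotsh abundance`, `radiotsh tsh score|stratify`,
`radiotsh network topology`, `radiotsh features extract`, ...).

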