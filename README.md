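# multiregion

Analysis of intratumoral heterogeneity from **multiregional tumor
sequencing** — several spatially separated samples of one patient's tumor
(and its metastases), each with somatic variant calls. Solid tumors such
as gastric adenocarcinoma grow by lateral expansion with spatially
separated subclones, so a single biopsy can badly misrepresent the
tumor's mutational landscape: it misses region-confined mutations and can
make subclonal mutations look clonal (the *clonal illusion*). This
package quantifies those effects and is aimed at cancer-genomics analysts
working with multi-sample somatic variant tables.

## What it computes

* **Variant filtering and cross-sample recovery** — the somatic filter
  chain (AF ≥ 5%, depth ≥ 10 in tumor or matched normal, ≥ 2 alt reads,
  homopolymer AF > 10%, no strand bias/blacklist, population AF < 1%,
  cancer-gene-census rescue for database-unknown variants), then
  per-patient recovery of sub-threshold calls anchored by another region;
  TMB per megabase and MSI-score classification.
* **Heterogeneity statistics** — the sharing spectrum (variants present
  in exactly *k* of *n* regions), single-sample miss rates,
  primary-vs-metastasis private/shared counts, multi-hit genes
  (parallel-evolution candidates), and copy-number heterogeneity
  (deletion: total CN = 0; amplification: total CN ≥ 6).
* **Clonality** — the cancer cell fraction
  `CCF = VAF·(ρ·CN_t + (1−ρ)·CN_n)/(ρ·m)` with exact
  (Clopper–Pearson) 95% CI; a variant is *subclonal* when the CI upper
  bound is < 0.95. Per-sample vs pooled per-patient calls expose clonal
  illusions. The apparent-clonal curve `C(n)` is fit with
  `C(n) = c_inf + (C(1) − c_inf)·g^(n−1)` to estimate the tumor's
  **balance factor** g, and `P_correct(n) = 1 − g^n` converts g into the
  number of regional samples needed for reliable clonal identification.
* **Neutral-evolution test** — under neutral growth the cumulative count
  of subclonal mutations follows `M(f) = (μ/β)·(1/f − 1/f_max)`. A
  through-origin fit of M(f) against 1/f inside a window below the clonal
  peak yields R² (neutral when R² ≥ 0.98) and a Kolmogorov distance
  between the normalized empirical and theoretical curves, per sample and
  on pooled (mean) VAFs.
* **Region phylogenies** — exact maximum-parsimony trees over regions
  (binary presence characters, matched normal as outgroup) via
  branch-and-bound with Fitch scoring; all co-optimal topologies; CCF
  ordering/sibling constraints between clone clusters; newick output.
* **IHC H-scores** — `H = 0·pct0 + 1·pct1 + 2·pct2 + 3·pct3` ∈ [0, 300]
  and p53 quartile grouping (Q1/Q4 vs Q2/Q3).
* **Simulator** — synthetic multiregional tumors with a truncal clone,
  user-declared subclones with per-region cell fractions, a neutral 1/f²
  mutation tail, purity/copy-number effects, and Poisson–binomial read
  sampling, with a full ground-truth table. Every analysis above is
  testable against it without any external data.

## Worked example

```bash
python examples/04_clonality_and_sampling.py
```

prints (abridged):

```
pooled clonality: {'total': 619, 'clonal': 30, 'clonal_pct': 4.8, ...}
clonal illusion: 18 variants clonal in >= 1 region but subclonal patient-wide
apparent-clonal curve C(n): [119.4  84.   68.1  64.   64. ]
balance factor g = 0.37, asymptotic clonal count ~ 62 (true truncal count: 30)
g = 0.37: 3 samples reach P(correct) = 0.951
g = 0.56: 4 samples reach P(correct) = 0.902
g = 0.20: 2 samples reach P(correct) = 0.960
```

The simulated five-region tumor carries 30 truncal mutations plus two
subclones, one near fixation in two regions. Pooling all regions calls
only the 30 truncal variants (4.8%) clonal, while 18 subclone mutations
look clonal inside their own regions — the clonal illusion. The
shared-variant curve C(n) shrinks with each added region; its geometric
fit gives the balance factor g, from which `1 − g^n` says how many
biopsies are needed before the apparent clonal set can be trusted.

The other `examples/*.py` scripts cover simulation, filtering/recovery,
sharing spectra and CNV heterogeneity, the neutrality panel, parsimony
trees, and IHC scoring; a thin `multiregion` CLI
(`simulate | filter | het | clonality | neutrality | phylo | ihc | report`)
wraps the same functions for shell pipelines.

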