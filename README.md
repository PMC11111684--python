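# retrowas

Retrotranscriptome-wide association analysis: summary-statistic TWAS over
a feature panel that treats human endogenous retroviruses (HERVs) as
locus-resolved expression features alongside canonical genes.

Most HERV expression studies aggregate reads per repeat family, which
destroys the locus information needed to connect a specific provirus to a
regulatory variant and a trait.  `retrowas` implements the full
locus-resolved pipeline for researchers who want to test, extend or audit
that methodology:

1. **Quantification** — ambiguously mapped fragments from homologous HERV
   copies are reassigned to their most probable source locus by a
   Bayesian EM algorithm over candidate alignment scores.
2. **Expression preparation** — joint count/TPM expression filtering, TMM
   normalisation, logCPM, and residualisation on clinical/technical
   covariates, genotype PCs and surrogate variables.
3. **Genotype QC & harmonisation** — MAF/HWE/missingness variant filters,
   heterozygosity and method-of-moments relatedness (pihat) sample
   filters, allele-aware alignment of GWAS summary statistics.
4. **SNP weights** — per-feature cis-heritability (REML, boundary-mixture
   LRT gate at p < 0.01) and cross-validated expression weights from top
   eQTL, lasso, elastic net and BLUP.
5. **Association** — `Z = w'z / sqrt(w'Rw)` per feature from GWAS
   z-scores and reference LD, Bonferroni-corrected per trait.
6. **Conditional/joint analysis and fine-mapping** — greedy conditionally
   independent selection within loci, SNP-level conditioning, and
   posterior inclusion probabilities (PIPs) by Bayesian configuration
   averaging; features that are jointly significant *and* have PIP > 0.5
   are labelled high-confidence risk features.
7. **Co-expression** — signed WGCNA-style network (beta = 12), topological
   overlap, module detection with eigengene merging, hypergeometric GO
   enrichment of each module's canonical genes.

The cohorts such a study needs are access-restricted, so the package
ships a first-class synthetic-data module (`retrowas.synthdata`) that
generates every input with known ground truth — LD-structured genotypes,
cis-regulated counts with HERVs lower-expressed than genes, expression-
mediated GWAS z-scores, modular co-expression structure, and multi-mapped
fragments — and the whole pipeline is validated against that truth.
`docs/methods.md` documents every model and default.

## Worked example

The numbered scripts under `analysis/` run the synthetic study end to end
(master seed as optional argument, default 1), writing tables under
`results/pipeline/`.  The same steps are available as CLI subcommands
(`retrowas simulate|quantify|prep|qc|weights|assoc|postprocess|coexpress|run`).

```bash
python analysis/01_simulate_cohort.py     # cohort + ground truth
python analysis/02_quantify_hervs.py      # EM fragment reassignment
python analysis/05_build_weights.py       # cis-h2 gate + SNP weights
python analysis/06_run_rtwas.py           # association
python analysis/07_conditional_finemap.py # conditional + fine-mapping
```

Output of the weight, association and fine-mapping steps at seed 1:

```
features tested: 120; cis-heritable (LRT p < 0.01 with a usable CV winner): 58
  gene: 38/80 cis-heritable (48%)
  herv: 20/40 cis-heritable (50%)
winning methods: {'top1': 23, 'lasso': 19, 'enet': 13, 'blup': 3}

features tested: 58; per-trait significance threshold 8.621e-04
Bonferroni-significant: 1 (100% HERV, 0% gene)
       feature  cls best_method         z            p       bonf_p
HARLEQUIN_7q06 herv        enet 19.734755 1.084710e-86 6.291317e-85
      GENE0066 gene       lasso -2.772331 5.565638e-03 3.228070e-01

loci: 1; jointly selected features: 1
high-confidence risk features: ['HARLEQUIN_7q06']
       feature  cls         z       bonf_p  joint_selected  pip            tier
HARLEQUIN_7q06 herv 19.734755 6.291317e-85            True  1.0 high_confidence
```

Reading: of 120 simulated features, 58 pass the cis-heritability gate and
enter the TWAS.  The one feature whose expression was simulated to
mediate trait risk — the HERV locus `HARLEQUIN_7q06`, cis-h2 0.4,
mediation effect 0.1, GWAS N = 100,000 — is the only Bonferroni-
significant association (Z = 19.7); it survives conditional analysis and
fine-maps to PIP = 1.0, so the pipeline calls it a high-confidence risk
HERV, exactly matching the planted truth.  The EM quantification step
recovers the fragment mixture to max |pi_hat − pi_true| = 0.0089 on
20,000 fragments, and the co-expression step detects a turquoise module
whose canonical genes are enriched for the planted gene set
(Bonferroni p = 1.9e-20, enrichment ratio 3.2).

## Layout

```
analysis/          numbered narrative drivers (01_simulate ... 08_coexpression)
src/retrowas/      library: synthdata, herv_quant, expression_prep,
                   genotype_qc, cis_weights, rtwas_assoc, postprocess,
                   coexpress, io, pipeline, cli
tests/             pytest suite incl. end-to-end statistical checks
scripts/           acceptance.py
docs/methods.md    models, defaults, limitations
```
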