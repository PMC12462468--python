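# mlof

Structure-based prediction of missense disease mechanisms.

Pathogenic missense variants act through different molecular mechanisms:
most destabilise the protein and cause loss of function (LOF), but many
act through gain-of-function (GOF) or dominant-negative (DN) effects.
Knowing which mechanism a group of variants uses matters for interpreting
dominant disease, dosage sensitivity and therapy choice, yet it usually
requires bespoke experiments. `mlof` estimates it from two structural
properties of the variant set on a predicted monomer structure:

* **EDC** (extent of disease clustering) — LOF variants spread through
  the structure while non-LOF variants cluster at functional sites.  For
  every confidently modelled residue *i* the distance to the nearest
  disease position and to the nearest non-disease residue is measured on
  the Cα trace, and

  `EDC = log10( mean_i min_j d(i, disease_j) ) / log10( mean_i min_k d(i, nondisease_k) )`

  so clustered disease positions give EDC > 1.  Residues with pLDDT < 70
  are excluded.
* **mean ΔΔG_rank** — predicted folding-stability changes (ΔΔG, kcal/mol,
  FoldX-style) are rank-normalised within each protein to [0, 1]
  (0 mildest, 1 most damaging) over all substitutions reachable by a
  single nucleotide change, and averaged over the variant set.

Each metric is converted to a LOF probability against Gaussian kernel
densities fitted separately to LOF-mechanism and non-LOF-mechanism
reference genes (1024 grid points, 3× the Sheather–Jones bandwidth,
observations capped at empirical 10th/90th-percentile bounds):

`P_LOF(x) = f_LOF(x′) / (f_LOF(x′) + f_non-LOF(x′))`

and the two are combined by a case-specific weighted mean — each metric
weighted by the evidence behind the *other* one —

`mLOF = (w_EDC · P_LOF(EDC) + w_ΔΔG · P_LOF(ΔΔG)) / (w_EDC + w_ΔΔG)`

with `w_EDC` the number of variants entering mean ΔΔG_rank and `w_ΔΔG`
the number of residue positions entering EDC.  Gene-level mechanism
priors pDN/pGOF/pLOF are then updated on the odds scale,

`postLOF = mLOF·pLOF / (mLOF·pLOF + (1−mLOF)(1−pLOF))`

(and with `1−mLOF` for the DN and GOF updates); the highest posterior is
the suggested mechanism.  An mLOF score of 0.508 is the default
LOF / non-LOF decision threshold.

The package also ships the surrounding analyses: AUROC / balanced
precision-recall evaluation, ROC-optimal thresholds, bootstrap intervals,
SD-based classification of multiplexed-assay scores, phenotype
inheritance/mechanism classification, mechanism composition and
hybrid-gene fractions with credible intervals, divergent phenotype-pair
ranking, Lin semantic similarity over an ontology, and seeded synthetic
generators for every input format.

## Worked example

```python
from mlof import MlofModel, compute_edc, mean_ddg_rank, rank_normalise, posterior
from mlof.bayes import PriorRecord
from mlof.synthetic import (CohortSpec, make_cohort, make_toy_structure,
                            make_clustered_variants, make_ddg_table)

# fit a reference model from a labelled gene table (here: synthetic)
reference, _ = make_cohort(CohortSpec(seed=1))
results = MlofModel.from_dataframe(reference).fit()
print(results.summary())

# score a LOF-like fixture: dispersed, destabilising variants
protein = make_toy_structure(80, "globule", 90.0, seed=11, protein_id="SYN1")
variants = make_clustered_variants(protein, 28, clustering=0.0, seed=12)
edc = compute_edc(protein, variants)
ddg = mean_ddg_rank(
    rank_normalise(make_ddg_table(protein, "lof_like", seed=13,
                                  pathogenic_positions=variants.positions)),
    variants)
score = results.score(edc, ddg)
post = posterior(score.mlof, PriorRecord("SYN1", p_dn=0.3, p_gof=0.2, p_lof=0.8))
print(f"EDC={edc.edc:.3f}  mean ΔΔG_rank={ddg.mean_rank:.3f}  "
      f"mLOF={score.mlof:.3f}  postLOF={post.post_lof:.3f}")
```

prints

```
mLOF reference model
====================
reference genes: 150 LOF / 150 non-LOF
bandwidth multiplier: 3.0  cap mode: class  cap quantiles: (0.1, 0.9)
  EDC       grid [0.2127, 2.1557] n=1024  h_LOF=0.1314 h_nonLOF=0.1872  caps [0.9037, 1.4303]
  DDG_RANK  grid [-0.4029, 1.4117] n=1024  h_LOF=0.0917 h_nonLOF=0.1488  caps [0.1746, 0.8359]
EDC=1.059  mean ΔΔG_rank=0.795  mLOF=0.778  postLOF=0.933
```

The fixture's variants are spread through the structure (EDC near 1) and
strongly destabilising (mean ΔΔG_rank 0.79), so both marginals favour
LOF; the combined mLOF of 0.78 sits well above the 0.508 threshold, and
the 0.8 gene prior sharpens it to a LOF posterior of 0.93.

The same pipeline is available from the shell:

```bash
mlof fit reference.tsv model.json
mlof score SYN1 G12R,L34P,... --structure SYN1.pdb --ddg SYN1_ddg.tsv \
     --model model.json --priors priors.tsv
mlof evaluate scores.tsv
mlof phenotypes annotations.tsv
mlof simulate fixtures/ --seed 1
```

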