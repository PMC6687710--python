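# sccproteo

Proteogenomic analysis of multi-plex, isobaric-label (TMT) tumor cohorts:
from peptide-spectrum matches to cohort-wide protein abundances, proteomic
subtypes, cross-omic associations, and outcome meta-analysis — together
with a fully specified synthetic cohort generator that provides ground
truth for every stage.

## The problem

Deep tumor proteomes are measured a handful of samples at a time: each
TMT plex multiplexes a few tumors plus replicate aliquots of a common
reference pool into one mass-spectrometry run. Turning dozens of such
runs into one coherent cohort matrix requires

1. **FDR-controlled identification** — deciding which spectra and protein
   groups to trust, using target-decoy score competition;
2. **Bridging** — removing per-run batch effects and placing every tumor
   on one comparable abundance scale via the shared reference pool;
3. **Unsupervised subtype discovery** that is robust to resampling;
4. **Association and integration statistics** connecting the protein
   matrix to mutations, copy number, transcripts, functional screens and
   survival.

`sccproteo` implements this pipeline end to end. Standard numerics
(exact tests, hierarchical clustering, survival machinery, multiple
testing) come from scipy / statsmodels / scikit-learn / lifelines; the
domain-specific procedures — pool-referenced rank-invariant
normalization, cross-plex internal-reference scaling, two-step FDR
assembly, consensus CDF-area model selection, the ordinal CMH statistic,
Storey q-values, empirical-Bayes random-effects pooling, and the
vulnerability intersection cascade — are implemented and tested here.

## Worked example

```python
from sccproteo.synthetic_cohort import CohortConfig, generate_cohort
from sccproteo.psm_assembly import two_step_assembly, filter_by_observation
from sccproteo.tmt_bridge import bridge_cohort
from sccproteo.subtype_discovery import (
    select_variable_features, consensus_cluster, select_k,
)
from sklearn.metrics import adjusted_rand_score

config = CohortConfig()  # 108 tumors, 29 six-channel plexes, seed 1234
cohort = generate_cohort(config)
print(f"{len(cohort.psms):,} PSMs across {config.n_plexes} plexes")

assembled = two_step_assembly(cohort.psms)
print(f"{len(assembled.groups)} protein groups at "
      f"{assembled.protein_fdr:.2%} protein-level FDR")

bridged = bridge_cohort(assembled.psms, cohort.design)
matrix = filter_by_observation(bridged.matrix, 0.5)
print(f"bridged matrix: {matrix.shape[0]} proteins x {matrix.shape[1]} tumors")

features = select_variable_features(matrix, n=1000)
result = consensus_cluster(matrix.loc[features], k_range=range(2, 9),
                           n_resamples=250, seed=1234)
k = select_k(result)
ari = adjusted_rand_score(cohort.truth.subtype_label.loc[matrix.columns],
                          result.labels[k].loc[matrix.columns])
print(f"consensus clustering chose k={k}; ARI vs truth = {ari:.3f}")
```

Output (about 10 s on one CPU):

```
184,949 PSMs across 29 plexes
1959 protein groups at 0.05% protein-level FDR
bridged matrix: 1959 proteins x 108 tumors
consensus clustering chose k=4; ARI vs truth = 0.964
```

## Command line

Every stage is also a CLI command operating on plain TSV/JSON files:

```sh
sccproteo simulate  --out data --seed 1234            # synthetic cohort
sccproteo assemble  --psms data/psms.tsv --out asm    # two-step FDR assembly
sccproteo bridge    --psms asm/retained_psms.tsv --design data/design.tsv --out brg
sccproteo subtype   --matrix brg/protein_matrix.tsv --out sub
sccproteo associate --matrix brg/protein_matrix.tsv --labels sub/subtype_labels.tsv \
                    --mutations data/mutations.tsv --out assoc
sccproteo integrate --protein brg/protein_matrix.tsv --rna data/rna.tsv \
                    --cnv-segments data/cnv_segments.tsv \
                    --genes-bed data/gene_models.bed --out integ
sccproteo run-all   --out full_run                    # everything + manifest
sccproteo validate  --config pipeline.yaml            # config linting
```

`run-all` writes a `manifest.json` recording package and library
versions, the resolved configuration, per-stage derived seeds, and
per-stage row counts; reruns with the same configuration produce a
byte-identical manifest.

## Package layout

| Module | Contents |
| --- | --- |
| `synthetic_cohort` | Multi-omic cohort simulator with known ground truth |
| `psm_assembly` | Target-decoy FDR filtering, two-step protein assembly |
| `tmt_bridge` | Rank-invariant normalization, pool-referenced bridging |
| `subtype_discovery` | Consensus clustering, CDF-area k selection, centroids |
| `association_stats` | Rank-sum DE, Fisher/CMH tests, BH and Storey q, ORA |
| `integration` | Cross-omic Spearman, differential correlation, cascade, CNV |
| `outcome_meta` | Log-rank, univariate Cox (Breslow/Efron), EB meta-analysis |
| `pipeline`, `cli` | Orchestration, manifest, command-line interface |

See `docs/methods.md` for the statistical model behind the simulator and
the numerical choices in each procedure.

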