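# rnage

Transcriptome-based **relative-age scoring** for bulk and single-cell
expression data. `rnage` derives hierarchical, tissue-specific aging gene
signatures from young-vs-old differential-expression studies, scores how
much *transcriptionally older* one sample group is than another, and runs
an in silico perturbation screen that flags age-inducing or rejuvenating
treatments.

It is aimed at researchers who need to quantify age-related manipulations
— induced aging or rejuvenation of primary cells and stem-cell-derived
lineages — without a chronological-age training cohort: the score is
relative between two conditions, not an absolute age prediction.

## Method

**Signature derivation.** Given K young-vs-old DE tables (default six:
three primary-fibroblast, two frontal-cortex, one substantia-nigra
dataset), each gene *i*'s log2 fold change L<sub>i,j</sub> (oriented
log2(old/young)) is discretized at ±0.1:

    L̄ᵢⱼ = +1 if Lᵢⱼ ≥ 0.1,  −1 if Lᵢⱼ ≤ −0.1,  0 otherwise

and its p-values are combined across all K datasets with **Edgington's
method** — the combined p is the Irwin–Hall CDF of Σ<sub>j</sub> p<sub>ij</sub>
under the uniform null. Genes are then assigned hierarchically and
mutually exclusively to classes by full directional agreement over
class-defining dataset subsets: **Pan** (|Σ L̄| = 6 over all datasets),
**pF** (= 3 over the fibroblast datasets), **Neuronal** (= 3 over the CNS
datasets), **FC** (= 2 over the frontal-cortex datasets), **SN** (changed
in the substantia-nigra dataset), each class excluding genes captured
earlier. Per class the top 100 genes by combined p form the signature
Ĝ<sub>k</sub>, with the marker vector M<sub>k</sub> of shared ±1
directions.

**RNAge score.** For a test matrix with groups of sizes n and m, each
signature gene gets a Welch two-sample t-statistic

    tᵢ = (μᵢ,₁ − μᵢ,₂) / √(S²ᵢ,₁/n + S²ᵢ,₂/m)

(tᵢ = 0 for signature genes absent from the test data), and

    RNAgeₖ = Σᵢ tᵢ·Mₖ[i] / Nₖ        Percentage scoreₖ = #{Aᵢ > 0} / Nₖ

where A<sub>i</sub> = t<sub>i</sub>·M<sub>k</sub>[i] and N<sub>k</sub> is
the number of signature genes present in the test data. Positive RNAge
means group1 is transcriptionally older.

**Screen.** Perturbation replicates are matched to same-plate controls,
each (perturbation, dose, time, plate) group is scored, plate scores are
averaged per condition and conditions per perturbation, and per-class
z-values call hits at |z| > 3 SD (*ager* above, *rejuvenator* below).

## Worked example

Everything below runs on synthetic data with planted ground truth — no
download needed.

```python
from rnage import *

cfg = SimulationConfig(seed=1)                      # 10,000 genes, 200 planted per class
tables, truth = simulate_training_tables(cfg)       # six DE tables
sigs, audit = derive_signatures(tables)             # Pan/pF/Neuronal/FC/SN signatures

# an "old vs young fibroblast" cohort: Pan+pF effects planted, group1 older
expr, grouping, _ = simulate_cohort(cfg, truth, older_group="group1",
                                    affected_classes=("Pan", "pF"))
results, _ = compute_all_subscores(expr, grouping, sigs)
print(scores_frame(results).round(3).to_string(index=False))
```

```
   class  rnage_score  percentage_score  n_overlap
     Pan        8.890              1.00        100
      pF        8.965              1.00        100
Neuronal        0.107              0.53        100
      FC       -0.050              0.51        100
      SN       -0.066              0.50        100
```

The fibroblast-relevant scores (Pan, pF) are strongly positive — group1 is
transcriptionally older — with every signature gene moving in the expected
direction (percentage 1.00), while the CNS classes sit in the null band
(|score| ≪ 1, percentage ≈ 0.5). The same stages are available as a CLI:

```
rnage simulate training --seed 1 --out-dir train/
rnage derive --de Total_pF=train/de_Total_pF.tsv ... --out signatures.tsv
rnage score --expr expr.tsv --groups groups.tsv --signatures signatures.tsv --out scores.tsv
rnage screen --expr level3.gct --meta inst_info.tsv --signatures signatures.tsv --out screen.tsv
```

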