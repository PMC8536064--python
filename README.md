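# pepscreen

In-silico screening of **dual-functional food-derived peptides**: short
peptides that both disrupt bile-acid (BA) micelles — precipitating micellar
cholesterol and thereby lowering its intestinal absorption — and are well
suited to direct intestinal delivery on heat-treated (HT) porous silica gel,
which shields adsorbed peptides from gastric proteolysis at pH 2 and
releases hydrophobic, negatively charged peptides at pH 7.

The package is aimed at food-science and bioactive-peptide researchers who
want to run, audit, or extend this kind of screen on their own protein sets,
classifiers and delivery-score maps.

## The screen

1. **Library.** Every protein in an edible-protein FASTA is cut into all
   overlapping k-mers (k = 4–7, one-residue shift). Windows sharing a
   sequence are merged into one *independent peptide* with full provenance
   (parent id, 1-based start_end positions).
2. **First screen (bioactivity).** A probability model of BA-binding
   activity scores every peptide; peptides with p > 0.5 survive. Either a
   trainable random forest over composition features or a transparent
   logistic surrogate over residue-class presence can be used.
3. **Second screen (delivery).** Each survivor is placed at its
   (mean hydrophobicity, mean pI) coordinates,

   &nbsp;&nbsp; hydrophobicity = (Σᵢ Xᵢ)/k, &nbsp; pI = (Σᵢ Yᵢ)/k,

   where Xᵢ, Yᵢ are per-residue scale values (scales are swappable data
   files), and scored on a delivery-score surface by bilinear
   interpolation. Peptides with score > 50 are the finalists, reported
   with provenance.

Around the screen the package provides residue-class enrichment statistics
(2×2 contingency tables and odds ratios for basic {R,K}, acidic {D,E} and
aromatic {F,Y,W} classes), a declarative protease rule engine (cut sites,
complete digestion, intact-release tests, minimal releasable
super-peptides, purification-yield arithmetic), four-parameter logistic
dose-response fitting with DC50 (the concentration halving micellar
cholesterol), and seeded synthetic-data generators for every input.

## Worked example

```python
import numpy as np
from pepscreen import (
    SyntheticConfig, SurrogateLogistic, gen_proteins, gen_surface,
    default_hydrophobicity, default_residue_pi, run_pipeline,
)

cfg = SyntheticConfig(seed=1, n_proteins=20)
model = SurrogateLogistic(intercept=-1.2, basic_weight=np.log(6.5),
                          acidic_weight=-np.log(22.0), aromatic_weight=np.log(2.5))
res = run_pipeline(gen_proteins(cfg), model, gen_surface(cfg),
                   default_hydrophobicity(), default_residue_pi())
print(res.stage_summary["library_total_joint"],
      res.stage_summary["first_screen_survivors"],
      res.stage_summary["finalists"])
print(res.candidates.head(3).to_string(index=False))
```

prints

```
15631 3624 241
peptide      protein position  probability  delivery_score
  VLKII synthetic_11    62_66     0.661907       78.530592
CIMCKLL synthetic_08    93_99     0.661907       77.577117
  LVIKV synthetic_20  103_107     0.661907       77.327805
```

— 15,631 independent 4–7-mers from 20 synthetic proteins, 3,624 scoring
above 0.5 with the logistic model, and 241 finalists whose delivery score
exceeds 50; the top candidates are strongly hydrophobic, low-pI peptides,
exactly the corner the synthetic surface rewards. (Finalist sequences vary
with the seed.)

The same flow is available from the shell:

```bash
pepscreen simulate --seed 1 --outdir fixtures/
pepscreen train --data fixtures/labeled_peptides.tsv --seed 1 --out model.joblib
pepscreen screen-all --fasta fixtures/proteins.fasta --model model.joblib \
    --surface fixtures/surface.json --outdir screen_out/
pepscreen fit-dc50 --data fixtures/dose_response.tsv --fix-top 100 --fix-bottom 0
```

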