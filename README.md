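# loopforest

Supervised prediction of CTCF-mediated chromatin loops from genomic and
epigenomic features.

CTCF, together with cohesin, anchors most of the long-range chromatin loops
that organise mammalian genomes into insulated neighbourhoods.  ChIA-PET
gives a direct, protein-centric catalogue of these loops, but the assay is
costly and library-hungry; in most cell types only CTCF ChIP-seq, DNase-seq,
histone-mark ChIP-seq and RNA-seq are available.  `loopforest` is for
computational biologists who want to infer the CTCF loopome from those
cheaper assays: it learns a random-forest classifier on ChIA-PET-defined
loops in one cell type and predicts loops genome-wide in the same or a
different cell type, with motif-orientation baselines, multi-level
evaluation protocols, Hi-C contact validation and interaction-network
analysis built in.

## The model

A candidate loop is an ordered pair of CTCF binding sites (peak summit
± 500 bp) on one chromosome, 10 kb–1 Mb apart (summit to summit).  Each
candidate is summarised by a fixed-order feature vector:

* **genomic scalars** — loop length; the motif-orientation code
  (0 = no motif on either anchor, 1 = one anchor only, 2 = divergent ←→,
  3 = tandem →→/←←, 4 = convergent →←, using each anchor's strongest FIMO
  occurrence within summit ± 1 kb); motif strength and phastCons
  conservation (summit ± 20 bp), each as the mean and population SD over the
  anchor pair;
* **expression** — mean FPKM of genes whose promoter (TSS ± 2 kb) lies
  inside the loop span;
* **per-track signal** (canonically CTCF, RAD21, DNase and 11 histone
  marks): *local* mean/SD of anchor RPKM (summit ± 2 kb), *in-between* RPKM
  over the loop interior, and two *flanking* RPKMs from each anchor to the
  nearest outside CTCF site.

Under the canonical 14-track configuration this is 7 + 14 × 5 = **77
features**.  Reads are de-duplicated and masked to signal-enriched regions
before quantification; RPKM uses the library's total mapped reads as
denominator.

Training positives are significant ChIA-PET loops (FDR ≤ 0.05, PET ≥ 2);
negatives are random same-chromosome site pairs in the same length range
with no ChIA-PET support (PET ≥ 1) and absent from a Hi-C loop list, sampled
at 5× the positives.  A 3× "wiring" negative set re-pairs the positive
loops' own anchors to isolate connectivity prediction from anchor detection.
The classifier is a `RandomForestClassifier` (500 trees, √p features per
split) behind a feature-order contract; performance is reported as AU-ROC /
AU-PR from five iterations of stratified 10-fold cross-validation with 95%
confidence intervals, and as precision/recall at the 0.5 probability
cut-off.

Everything is testable offline: `loopforest.simulate` generates a complete
self-consistent toy genome in which planted true loops carry elevated
CTCF/RAD21 anchor signal, a convergent-motif bias, suppressed in-loop
expression and enriched Hi-C contacts, with the truth exported as a sidecar.

## Worked example

```python
import numpy as np
import loopforest as lf

fx = lf.generate_fixture()                      # default planted world
sites = fx.sites()
positives = lf.select_positives(fx.loop_calls)  # 600 loops
negatives = lf.build_negatives(sites, positives, fx.loop_calls,
                               fx.hic_loops, ratio=5.0, seed=11)
X = lf.featurize(positives + negatives, fx.bundle())   # 3600 x 77
y = np.r_[np.ones(len(positives)), np.zeros(len(negatives))]

perf = lf.cross_validate(X, y, folds=10, iterations=5, seed=0)
print(f"AU-ROC {perf.auroc_mean:.3f}  AU-PR {perf.aupr_mean:.3f}")

model = lf.train(X, y, seed=1)
for name, value in lf.feature_importance(model)[:4]:
    print(f"{name:18s} {value:.3f}")
```

prints

```
AU-ROC 0.966  AU-PR 0.765
CTCF_local_avg     0.234
RAD21_local_avg    0.228
CTCF_local_std     0.037
RAD21_local_std    0.036
```

AU-ROC 0.966 means the forest almost perfectly separates planted loops from
random site pairs; AU-PR 0.765 is measured against the 1/6 chance level set
by the 5:1 class ratio.  The importance ranking recovers the planted effect
structure: CTCF and cohesin (RAD21) anchor intensity dominate, exactly the
signals the generator elevated at true-loop anchors.

The same pipeline is available from a shell:

```bash
loopforest fixtures --out demo --seed 3
loopforest prepare   --config demo/config.yaml --out demo/training
loopforest featurize --config demo/config.yaml --training demo/training --out demo/feat
loopforest cv        --config demo/config.yaml --features demo/feat --out demo/cv
loopforest train     --config demo/config.yaml --features demo/feat --out demo/model
loopforest predict   --config demo/config.yaml --model demo/model/model.joblib --out demo/pred
loopforest hic-test  --config demo/config.yaml --predictions demo/pred/predictions.bedpe --out demo/hic
loopforest network   --config demo/config.yaml --loops demo/training/positives.bedpe --out demo/net --hubs
```

## Acceptance script

`scripts/acceptance.py` re-runs the whole method from scratch on the default
synthetic world: it generates the fixture, builds the 5:1 training set,
featurizes, performs repeated 10-fold cross-validation, ranks feature
importances, runs the naive and intensity-thresholded motif-orientation
baselines, scans the genome de novo, categorises predictions by ChIA-PET
support (with and without 15% PET thinning), validates predictions against
the Hi-C matrix with length-matched controls, evaluates transfer to a
diverged second cell type (loop, anchor and wiring level), and builds the
interaction network with hub calling.

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

All randomness derives from `--seed`; the metrics are printed to stdout and
the results manifest is written to `--out`.

## Documentation

`docs/methods.md` describes the model, the synthetic world and its
limitations, numerical conventions and design choices in detail.
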