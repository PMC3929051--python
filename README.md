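# bovscan

Selection-signature and population-structure toolkit for multi-breed
diploid SNP panels (54K-chip style data in PLINK text format). It
implements, as one reproducible pipeline:

- **genotype I/O** — PLINK text `.ped`/`.map` reader/writer with a
  dosage data model (breed label carried in the family-ID column) and
  autosome/mapped-position restriction;
- **two-pass QC cascade** — simultaneous sample/marker call-rate
  filtering, pooled MAF filter, upper-tail heterozygosity-outlier
  removal (robust normal model + Benjamini–Hochberg FDR), within-breed
  Hardy–Weinberg exact-test filtering, then a second call-rate/MAF pass
  on the pooled filtered data;
- **fixation-index genome scan** — per-locus sample-size-corrected
  Nei–Chesser estimator, SNP-window averaging (non-overlapping groups or
  1-step sliding), genome-wide empirical 1%/99% quantile thresholds,
  one-breed-versus-rest contrasts, outlier-region merging and a BED
  interval annotator;
- **kinship + MDS** — allele-frequency-standardised genomic kinship,
  `d = 0.5 − k` distances, Torgerson classical multidimensional scaling,
  per-breed cluster centres and centre–centre distances;
- **admixture clustering** — Gibbs sampler for the K-population
  admixture model with a multi-run `lnP(D)` harness, label-switching
  alignment, and the Evanno ΔK model-choice statistic;
- **synthetic data** — a Balding–Nichols generator (drifted breeds,
  breed-specific "selected" blocks, missingness, planted HWE violations,
  admixed individuals) whose expected fixation index has the closed form
  `F(1−1/s)/(1−F/s)`, giving every estimator an analytic target.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (closed-form
GST recovery, enumeration oracles for the HWE exact test and BH rule,
MDS reconstruction, admixture/ΔK recovery on simulated truth, pipeline
determinism). The ΔK recovery test is the slow one (~2.5 min); the full
suite runs in ~5 minutes.

## CLI

```bash
bovscan simulate --seed 1 --out-prefix panel            # synthetic .ped/.map + truth
bovscan qc --ped panel.ped --map panel.map --out-prefix clean
bovscan fst-scan --ped clean.ped --map clean.map --window 8 \
    --groups one-vs-rest --out-prefix scan
bovscan mds --ped clean.ped --map clean.map --out-prefix mds
bovscan admixture --ped clean.ped --map clean.map --k 2:5 --runs 5 \
    --burnin 5000 --sweeps 10000 --seed 1 --out-prefix adm
bovscan pipeline --config run.yaml --out-dir out        # everything at once
```

All outputs are TSV (regions also as BED); every pipeline run records
its config hash and seed, and identical config+seed reruns are
byte-identical.

## Library use

```python
from bovscan import (SimulationConfig, simulate_panel, run_qc_pipeline,
                     fst_profile, scan, mds_embedding, gibbs_admixture)

gm, truth = simulate_panel(SimulationConfig(seed=1))
clean, report = run_qc_pipeline(gm)
result = scan(clean, width=8)             # windows + quantile thresholds
```
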