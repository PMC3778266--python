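# roiconcord

Do two independent morphometry techniques agree on *which* brain regions
distinguish amyloid-positive from amyloid-negative cognitively normal
elderly? If elevated brain amyloid produced a consistent early atrophy
signature, surface-based cortical thickness and voxel-based gray-matter
volume should rank the same regions of interest (ROIs) as most
discriminative. `roiconcord` is a reusable pipeline for that cross-technique
concordance analysis, built for biostatisticians and imaging researchers
working with ROI-level morphometry exports.

## What it computes

For each group comparison (CN− vs CN+, CN− vs MCI/AD+, CN+ vs MCI/AD+) and
each technique:

- **Per-ROI discrimination** — Mann-Whitney AUROC effect size,
  `AUROC = U/(n_a·n_b)` = P(reference subject's measure > affected
  subject's measure), with midrank ties and two-sided p (exact for small
  tie-free samples, tie-corrected normal approximation otherwise);
- **Rank uncertainty** — ROIs ranked 1 (best) to R (worst) by AUROC, with
  95% bootstrap confidence intervals for each ROI's rank (B = 1000 subject
  resamples, stratified by group);
- **Cross-technique agreement** — Lin's concordance correlation coefficient
  between the two techniques' rank vectors,
  `CCC = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²)`,
  plus per-ROI Spearman correlations of the raw harmonized measures;
- **Cohort construction** — amyloid classification from the continuous PET
  ratio (cut-point 1.5; sensitivity variants at 1.4 and with the 1.3–1.5
  borderline band excluded), and a propensity-matched (age, sex, education)
  amyloid-negative comparison group;
- **Harmonization** — technique-specific sub-ROIs combined onto a common
  28-ROI set: volumes summed and divided by intracranial volume, thickness
  combined by surface-area-weighted mean, hemispheres pooled.

A built-in synthetic cohort generator (single-factor latent atrophy model
with per-technique loadings, see `docs/methods.md`) makes the entire
pipeline testable without any imaging data and provides closed-form oracles
(`true_auroc(δ, λ) = Φ(λδ/√2)`) for calibration.

## Worked example

```python
from roiconcord import SimConfig, StudyConfig, BootstrapConfig, run_study

config = StudyConfig(
    sim=SimConfig(n_per_group=(215, 115, 88)),   # CN-, CN+, MCI/AD+
    bootstrap=BootstrapConfig(B=1000),
    seed=42,
)
report = run_study(config)

for comp, rep in report.concordance.items():
    print(f"{comp:24s} CCC = {rep.ccc:+.2f}")
print(f"median cross-technique Spearman rho = {report.spearman_median:.2f} "
      f"(range {report.spearman_range[0]:.2f} to {report.spearman_range[1]:.2f})")

rt = report.rank_tables[("CN_NEG vs MCI_AD_POS", "freesurfer")].table
print(rt.sort_values("rank").head(5)[["auroc", "rank", "ci_low", "ci_high"]].round(3))
```

prints

```
CN_NEG vs CN_POS         CCC = +0.17
CN_NEG vs MCI_AD_POS     CCC = +0.72
CN_POS vs MCI_AD_POS     CCC = +0.74
median cross-technique Spearman rho = 0.50 (range 0.35 to 0.57)
                   auroc  rank  ci_low  ci_high
roi
hippocampus        0.765   1.0     1.0      5.0
entorhinal         0.739   2.0     1.0      8.0
middle_temporal    0.707   3.0     1.0     11.0
inferior_temporal  0.696   4.0     1.0     14.0
parahippocampal    0.695   5.0     1.0     13.0
```

Read it as: with the generator's default conditions — weak, scattered
effects in amyloid-positive normals, a strong medial-temporal/parietal
signature in the impaired group — the two techniques agree well on which
ROIs separate normals from patients (CCC ≈ 0.7, hippocampus and entorhinal
cortex on top with tight rank intervals) but barely agree at all on a
CN−/CN+ signature (CCC ≈ 0.2): exactly the asymmetry the concordance
statistic is designed to expose. An AUROC of 0.765 means that ~77% of the
time a random CN− subject has more hippocampal tissue than a random
impaired subject.

The same study runs from the shell:

```bash
roiconcord simulate --out cohort/          # or bring your own CSVs
roiconcord run --input-dir cohort/ --seed 42 --out study/
roiconcord report study/
```

`study/` then contains the rank tables (`ranks_*.csv`: roi, auroc, p, rank,
ci_low, ci_high — the tabular equivalent of a forest plot), concordance
tables and JSON, matched pairs, the demographics summary and a manifest;
each sensitivity variant gets a `variant_*/` subdirectory with the same
layout. To analyze real exports, provide `subjects.csv` plus one
measurement CSV per technique (columns `<sub_roi>_<hemisphere>_<measure>`)
and, if your parcellation differs from the packaged default, your own ROI
map CSV.

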