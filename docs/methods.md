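# Methods

## Scope and assumptions

`tkidist` computes steady-state, blood-referenced tissue partitioning of
three basic lipophilic EGFR-TKI PET tracers. The model assumes passive
transport only, non-saturating (microdose) conditions, well-stirred
tissues at steady state, and negligible metabolism and elimination over
the scan window; the liver is excluded because it is the main
metabolizing organ for all three drugs and its uptake would violate that
assumption. Everything is a closed-form algebraic evaluation — there is
no differential-equation integration, no fitting and no randomness.

Two base-model branches follow the classical mechanistic tissue-
partitioning framework for ionizable drugs. A compound is classified by
its pKa: weak base (pKa ≤ 7, erlotinib at 5.5) or strong base (pKa > 7,
afatinib 8.2, osimertinib 9.0). Weak bases are mostly neutral at plasma
pH, so extracellular albumin binding dominates; strong bases are mostly
protonated, so binding to negatively charged acidic phospholipids (AP⁻)
and ion trapping in acidic lysosomes dominate. The ionization identity
used throughout is the base form of Henderson–Hasselbalch
(`fraction protonated = 1/(1+10^(pH−pKa))`); a transposed orientation
appears in some printed sources and is available behind the
`printed_orientation` flag of `fraction_protonated` for comparison, but
the default is the orientation that yields the textbook percentages
(erlotinib ≈ 99% neutral, osimertinib ≈ 98% protonated at pH 7.4).

## Parameters

All defaults live in `src/tkidist/data/parameters.yaml`; every field has
a provenance entry (`tkidist.params.provenance_of`). The important ones:

* **Compound** — log P (3.3/3.6/3.2), pKa (5.5/8.2/9.0), fraction unbound
  in plasma fu (0.088/0.095/0.017), blood:plasma ratio B:P
  (0.95/1.27/0.79, measured in the tracer studies) and wild-type EGFR Kd
  (2164/2/155 nM) for erlotinib/afatinib/osimertinib.
* **Tissue** — fractional volumes of neutral lipids, neutral
  phospholipids, extra- and intracellular water; AP⁻ concentration
  (mg/g); albumin tissue-to-plasma ratio; EGFR concentration (nM; 0 for
  brain and bone where no reliable receptor data exist); pH of extra- and
  intracellular water (7.4 and 7.0 except the acidic tumor
  microenvironment at pH_ew 6.7). A 7.22 literature value for lung
  extracellular pH exists; 7.4 is the default and 7.22 remains selectable
  through the override mechanism.
* **Cell types** — lysosome-bearing populations per tissue: lung carries
  alveolar macrophages (4.1%, F_lys 0.078, pH_lys 4.75), type II cells
  (8.3%, 0.03, 5.1) and residual cells (87.6%, 0.01, 5.1); the
  immune-deprived tumor carries residual cells only. Spleen, kidney and
  brain carry a single residual population with the whole-tissue
  lysosomal volume fraction and a default lysosomal pH of 5.3. Bone has
  no determined lysosomal volume and therefore no lysosome term.
* **Blood** — hematocrit 0.45, plasma pH 7.4, blood-cell intracellular pH
  7.22, and the blood-cell composition (f_iw 0.60, f_nl 0.0017, f_np
  0.0029, AP⁻ 0.50 mg/g) that anchors the AP⁻ calibration.

Tumor composition is lung-derived by hallmark overrides: residual cells
only (immune deprivation), pH_ew 6.7 (acidotic microenvironment), EGFR
299 nM (overexpression); AP⁻ concentration and albumin ratio are
inherited from lung. Lung and tumor use the whole-tissue intracellular
water fraction 0.43 rather than the 0.45 of the cell-type sub-table —
the value consistent with the reproduced EGFR contributions.

## Calibrations

Two association constants are derived rather than taken from tables:

* `Ka_ALB·[ALB]_plasma = 1/fu − 1` attributes all plasma binding to
  albumin. A plasma-lipid-corrected variant was considered and rejected:
  only the uncorrected form reproduces the reference erlotinib lung
  decomposition and total TBR.
* `Ka_AP` is solved from the blood-cell mass balance: the unbound
  blood-cell partition coefficient `Kpu_BC = (B:P − (1−H))/(H·fu)` minus
  its intracellular-water and neutral-lipid parts is attributed to AP⁻
  binding of the protonated species. This yields ≈ 24.5 (afatinib) and
  ≈ 41.3 (osimertinib) per mg/g. The calibration is a reconstruction of
  an appendix-housed procedure; it reproduces all reference AP⁻
  contributions to within a few percent and is exactly invariant to
  rescaling of the assumed blood-cell AP⁻ concentration.

Throughout the lipid terms, `P` is the printed log P value used directly
(not its antilog). That convention is what the partitioning framework
was calibrated with here — it reproduces the reference neutral-lipid
contributions — and a standards-compliant `10^logP` mode is available via
`p_convention="antilog"`.

## Lysosomal sequestration

`Kpu_lys`, the lysosome-to-cytosol coefficient of one cell population,
has two modes. `ph_only` is pure ion trapping,
`If(pKa, pH_lys, pH_iw)`. `membrane` (the final model) adds binding of
the protonated species to the lysosomal membrane, assumed to share the
AP⁻ composition of the cell's outer membrane — implemented with the same
AP⁻ machinery using the tissue's own AP⁻ concentration. Using each
tissue's own membrane composition (rather than a single lung value) is
what reproduces the reference spleen, kidney and brain predictions; for
lung and tumor the two choices coincide at 0.57 mg/g. The tissue term
sums `F_cell·F_lys·Kpu_lys` over cell populations and scales by the
plasma→cytosol ionization factor.

## Scenarios

The final model: EGFR binding on, membrane-mode lysosomes, immune-
deprived tumor, tumor pH_ew 6.7, perfusion coefficient 1 and no
vasculature penalty. The ablation suite changes exactly one field each:
`no_egfr`, `ph_only_lysosome`, `no_immune_deprivation` (tumor receives
the lung cell mix), `vascularized` (tumor prediction × 0.36, the
tumor/lung microvessel-density ratio from CD31⁺ histology) and
`neutral_tumor_ew` (pH_ew 7.4). Scenario prediction errors are always
recomputed against the same observed fixture, never cached. Weak-base
predictions are bitwise invariant to the lysosome and immune toggles.

## Validation statistics

`PE = (PRED − OBS)/((PRED+OBS)/2)·100%` — the ambiguous "mean of the
pair" denominator is implemented as the arithmetic mean, which
antisymmetrizes the error and bounds it in (−200, 200). Pearson r uses
the standardized-sum formula with sample standard deviations and is
cross-checked against a covariance-based oracle in the tests; its
significance uses the t statistic with n−2 degrees of freedom
(interpreting the source's "two-sample t-test" phrasing as the standard
correlation test). Fold accuracy counts predicted/observed ratios in the
closed interval [1/3, 3], per compound, over available observations
only; with 5 available erlotinib tissues and one within 3-fold this
yields 20% (a published 16.6% figure implies a denominator of 6, i.e.
counting the unavailable brain cell; the implementation reports 20% and
documents the difference). Three dispersion bands for the PEs are
selectable: `sd` (mean ± 1 SD — numerically identical to the band the
source comparison labels a "CI95% of the data": (−126.0, 104.9) on the
fixture), `percentile` (empirical 2.5/97.5) and `normal` (mean ± 1.96
SD). Zero variance in either margin flags the correlation undefined
rather than silently returning 0.

## The bundled fixture

`observed_tbr.csv` carries the PET-image-derived TBR means and SDs for 3
tracers × 6 tissues (17 available pairs; erlotinib brain was outside the
scan field of view). `reference_predictions.csv` carries the predicted
TBRs reported alongside those observations by the original model
implementation; it is used to exercise the statistics layer and as a
regression reference for this package's predictions — it is never used
inside the model itself. Passing tests show the closed-form model and
statistics are implemented consistently with those references; they say
nothing about patients beyond what the 17 fixture pairs encode (small
cohorts, microdose conditions, 1–2 h post-injection).

## Numerical choices and degenerate inputs

No tolerances or iteration anywhere: every quantity is a finite
composition of exponentials and ratios, exactly reproducible across
runs. Degenerate inputs are rejected with typed errors: non-positive
values in `prediction_error`, fu outside (0, 1], a blood:plasma ratio at
or below 1−H (implies non-positive cell concentration), a blood-cell
balance over-explained without AP⁻, weak/strong model mismatches, and
unknown names or invariant violations in parameter overrides. An empty
cell-type list yields a zero lysosome term rather than an error (bone).
Tables are emitted with 4 significant digits; the JSON validation report
keeps full precision. Percentage decompositions are reported over the
components applicable to the compound's model; the reference erlotinib
lung column is known not to sum to 100% (its extracellular-water cell is
inconsistent with its own total), and the implementation reports the
self-consistent decomposition instead of reproducing that cell.

## Known limitations

No transporter influx/efflux (the main suspected cause of the erlotinib
kidney/spleen underpredictions and afatinib brain overprediction), no
alpha-1-acid glycoprotein binding, wild-type EGFR affinity everywhere
(mutant affinity would raise tumor binding for erlotinib/osimertinib),
no saturation — predictions apply to microdose PET, not therapeutic
dosing, where lysosomal and target binding saturate — and no CNS-
specific physiology. Membrane affinity is approximated through log P
rather than measured membrane partitioning. All problem sizes are
trivial (18 grid cells, 5 scenarios); the entire suite, CLI and
acceptance script run in seconds.
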