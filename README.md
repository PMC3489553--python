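# traffickpk

Pharmacokinetic quantification of immune-cell trafficking from
gamma-counter data, for researchers who inject radiolabeled lymphocytes
intravenously and ask how many enter the brain and peripheral tissues, how
fast they leave the blood, and whether the cells or the target tissues
drive the differences between experimental groups.

## What it computes

Each mouse contributes an injection check (total injected cpm, `Inj`), the
radioactivity of its blood RBC pellet (labeled cells sediment with the red
cells), and the cpm and wet weight of dissected tissues. From these:

* **Dose fractions** — `%Inj/ml = 100·Cp/Inj` with `Cp` the pellet cpm per
  ml, and `%Inj/g = 100·(tissue cpm)/Inj/(tissue wt)`.
* **Tissue/RBC uptake ratios** — `(cpm/g of tissue)/(cpm/µl of RBC
  pellet)`, a distribution-volume-like measure in µl/g that is insensitive
  to blood clearance. The identity `%Inj/g = ratio × %Inj/ml / 1000` links
  the two families.
* **Blood clearance** — ordinary least squares of `log10(%Inj/ml)` on time;
  half-time `= log10(2)/(−slope)` and initial volume of distribution
  `Vd = 100/10^intercept`. A non-negative slope or a non-significant
  regression is classified as no measurable clearance (steady state).
* **Capillary depletion** — parenchyma (supernatant) and capillary (pellet)
  fraction/pellet ratios of cortical homogenate, and the parenchymal
  percentage `100·P/(P+C)` that tells how much of the brain signal fully
  crossed the blood–brain barrier.
* **Cell-number back-calculations** — lymphocytes per gram of tissue,
  `(blood lymphocytes/µl ÷ hematocrit) × tissue/RBC ratio`, and per organ.
* **2×2 Cells×Mouse variance partitioning** — a two-way ANOVA over cell
  source and host, reporting each effect's percentage of the total sum of
  squares (eta-squared) as its share of the trafficking variance, with
  Newman–Keuls (factorial designs) and Bonferroni-by-time (time courses)
  post-tests. Type I/II/III sums of squares are supported for unbalanced
  designs (Type III by default).

A synthetic-study generator (`traffickpk.simulate`) emulates the whole
measurement chain — mono-exponential blood clearance, steady-state tissue
ratios with multiplicative Cells/Mouse/interaction fold-effects, lognormal
mouse-to-mouse variability, Poisson counting noise — so every estimator can
be validated against known truth.

## Worked example

```bash
$ traffick-pk worked-examples
parenchymal fraction for ratios (28.5, 6.7) ul/g: 81.0% of brain-associated label beyond the capillary wall
processing control, ratios (0.57, 0.82): 41.0% segregating with parenchyma
6000 lymphocytes/ul blood, hematocrit 0.40, ratio 10 ul/g: 150,000 lymphocytes/g of brain
  x 0.45 g brain: 67,500 lymphocytes per brain
intercept log10(%Inj/ml) = 0.5: Vd = 31.62 ml; with a 2 ml vascular space, 93.7% of cells are in tissue beds at t=0
brain uptake 0.02 %Inj/g: one cell per 5,000 injected
spleen at 20 %Inj/g, weight 0.123 g: sequesters 2.46% of the dose
```

Reading these: of the label retained by brain after vascular washout, 81%
is in the parenchyma (the cells crossed the capillary wall completely; the
ex-vivo processing control, where nothing should have crossed, splits
roughly evenly at 41%). A brain/RBC ratio of 10 µl/g converts to about
150,000 lymphocytes per gram of brain and ~67,500 per whole brain. A Vd of
31.6 ml against a ~2 ml vascular space means ~94% of injected cells sit in
tissue beds at time zero; a spleen taking up 20 %Inj/g holds ~2.5% of the
whole dose.

An end-to-end factorial run, with a 2.5-fold cell-source effect on brain
and a 0.5-fold host effect on spleen in the generator:

```bash
$ traffick-pk simulate --scenario scenario.json --out study.csv --truth truth.json
wrote 168 records to study.csv
$ traffick-pk analyze --input study.csv --out results/
```

`results/anova_brain.csv` then attributes 59% of brain-uptake variance to
Cells (F = 48.6, P < 0.0001; Mouse 5%, n.s.), while
`results/anova_spleen.csv` attributes 68% of spleen variance to Mouse
(F = 55.8, P < 0.0001), and the lymph nodes show no significant effects —
the attribution machinery recovers which side of the cell–tissue
interaction the generator put the effect on.

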