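# Methods

## Labeling model

Continuous D₂O administration (an i.p. bolus followed by enriched drinking
water) raises the deuterium mole fraction of body water to a plateau p.
Newly synthesized protein incorporates deuterium at metabolically
exchangeable C–H positions, shifting peptide isotope envelopes toward
heavier isotopomers. All protein kinetics in this package are driven by one
observable per peptide per animal: the *relative* M0 abundance, the first
isotope peak's area divided by the summed area of the tracked peaks
(default 5 peaks, configurable).

Assumptions inherited from the experimental design:

* **Steady state.** Protein pool sizes do not change over the labeling
  window, so the synthesis rate constant equals the replacement rate and
  τ½ = ln 2 / k.
* **Stable precursor.** Body water reaches its plateau within days, which is
  fast relative to every measurable protein half-life (weeks to years), so
  peptide plateau envelopes are computed at the fitted (or configured)
  plateau enrichment, not the instantaneous enrichment. The serum
  time-course fit carries the full bolus + rise model; the plateau scalar is
  what propagates downstream (cohort-level by default).
* **Single dynamic pool per protein** in the default fit; the plateau is
  fixed from the isotope model rather than fit per protein, because typical
  designs have only 3–4 labeling durations.

## Isotope envelopes

Natural envelopes are the convolution of per-element multinomial isotope
patterns at fixed terrestrial abundances (C 0.9893/0.0107; H
0.999885/0.000115; N 0.99636/0.00364; O 0.99757/0.00038/0.00205; S
0.9499/0.0075/0.0425/–/0.0001, indexed by nominal mass shift), computed on
the full mass-shift grid and then truncated and renormalized. Enriched
envelopes give the n exchangeable hydrogen sites a heavy probability of
(natural ²H + p); the remaining hydrogens stay natural. Per-residue
exchangeable-site counts are real-valued averages (the Commerford-derived
table used across the D₂O-MIDA literature, shipped as
`data/residue_formulas.csv` and overridable), so the enriched hydrogen
channel uses a gamma-function generalization of the binomial; it reduces to
the exact binomial at integer counts. Working arrays carry 12 peaks beyond
the reported window so truncation tail mass is negligible (< 1e-6 for
tryptic peptide sizes).

## Rate fitting and aggregation

Per peptide, k is fit by bounded nonlinear least squares (k ∈ [0, 2]/day)
on M0(t) = M0ᵖˡᵃᵗ + (M0ⁿᵃᵗ − M0ᵖˡᵃᵗ)e^(−kt); day-0 (unlabeled control)
animals anchor M0ⁿᵃᵗ empirically when present, otherwise the isotope model
supplies it. A peptide is *measurable* only if its fitted total M0 decline
over the observed window exceeds 3× the residual SD — this guards against
converting noise-level declines into apparent (extremely long) half-lives;
the point estimate is still reported. Arbitrary duration subsets can be
excluded (e.g. a mis-dosed cohort); on noise-free data this changes k by
< 1e-6.

Peptide rates are screened with an iterative two-sided Grubbs test
(α = 0.05 default, one removal per iteration, test run whenever n ≥ 3; with
n < 3 all values are retained with a warning). The protein k is the mean of
retained measurable peptide rates and the pooled SD is
√(Σ dfᵢ·sᵢ² / Σ dfᵢ) over per-peptide rate variances (dfᵢ = nᵢ − 1).
Proteins with no measurable peptide are flagged and rendered as dashes.

## Quantification

Concentration = geomean over unique peptides of (peptide area / total BSA
standard area) × spike/load, defaults 8 pmol BSA into 0.05 mg total protein
(160 pmol/mg at unit ratio). A `top2` mode restricts to the two
largest-area peptides, matching an alternative convention for the same
quantity; the default uses all peptides. Absolute synthesis defaults to
concentration × k; a divide-by-half-life mode (= ×k/ln 2) is retained
because both conventions appear in practice, and the mode is recorded in
run metadata.

## Nucleic turnover

Fraction-new is ratio-based MIDA: f = (sample − unlabeled)/(max − unlabeled),
where the unlabeled derivative standard supplies the natural-abundance
correction and the fully-new ratio is base + (1−p)^(−n) − 1 for n
deuterium-accessible derivative sites (default 4.0 per molecule,
configurable — instrument-specific transition details are deliberately
abstracted into one ratio column). Values are clipped to [0, 1] with clip
counts surfaced; clean input never clips.

The two-pool fit uses f(t) = F(1 − e^(−k_fast t)) with the slow pool
treated as unlabeled over the window. If the series slope over durations is
not significantly nonzero (linear regression, α = 0.05), the plateau was
reached before the first sampling time: F is the series mean, the fast
half-life upper bound is t_min·ln2/ln 20 (time to 95% labeling), and the
slow half-life lower bound is t_max. Otherwise the kinetic fit resolves
k_fast directly.

## Group statistics

Unpaired two-tailed Welch t-tests (Welch–Satterthwaite df, 95% CI of the
difference) compare age groups; group sizes differ and variances are
expected to change with age, so pairing is neither possible nor assumed.
BH-FDR flags are computed per outcome family at q = 0.05. The inversion
utilities recover (mean_young, mean_old) from a printed (fold, difference)
pair — the identity mean_young = diff/(fold − 1) — and are exercised
against the bundled published summary tables.

## Synthetic studies

`simulate.generate_study` emits serum, peptide-isotopomer and nucleic CSVs
from a declared truth, using the package's own forward model, so a
noise-free round trip is exact (≤ 1e-6 relative on k and concentration).
Defaults mirror the motivating design: two age cohorts (5 and 3 animals per
duration), durations 15/30/45/60 d, 3 unlabeled controls per age,
p₀ = 2% → plateau 5.5% at 0.5/day, multiplicative log-normal area noise
(CV 2%), additive Gaussian noise on the fraction-new scale (SD 0.02), and
2% multiplicative serum noise. `paper_like_truth()` seeds per-protein
truths from the bundled published fold/difference tables where the
inversion is well conditioned (|fold − 1| ≥ 0.05 and a sign-consistent
pair); other entries carry flagged placeholders, dashed half-life rows
become k = 0, and peptide sequences are synthetic tryptic-like stand-ins
(real tables don't print them) except decorin's worked-example peptide.

What the generator does **not** emulate: chromatographic interference,
retention-time drift, charge states, missing peptides, between-animal
biological variance in k (noise is purely measurement-level), or
enrichment ramp-up effects on early-labeled protein. A green
parameter-recovery test therefore establishes estimator correctness under
the stated noise model, not robustness to raw-data pathologies.

## Numerical choices

* Envelope truncation: full-grid convolution, truncate, renormalize;
  envelopes sum to 1 within 1e-9.
* Rate fits compare the bounded optimum against the k = 0 boundary
  explicitly (trust-region solvers can stall near a bound on flat series).
* Constant serum series bypass the optimizer (exact constant model).
* Grubbs critical values from the t-distribution formula
  G = (n−1)/√n · √(t²/(n−2+t²)), t = t₁₋α/(2n),n−2.
* Half-lives are reported in days and years (365 d/yr, 3 significant
  figures at the reporting layer); not-measurable entries are dashes in
  rendered tables and NaN in memory — never infinities.
* All randomness flows from explicit integer seeds; identical
  (config, seed) reproduce output byte-for-byte.

## Known limitations

* Cohort-level precursor enrichment (no per-animal p), matching the default
  analysis mode; per-animal precursor handling would require per-animal
  serum series.
* The measurability threshold (3× residual SD) is a heuristic; proteins
  near the threshold can flip between "dash" and a very long half-life
  under resampling.
* Per-animal half-life distributions are not modeled, so group comparisons
  of half-lives are only available through the per-animal concentration ×
  group-k synthesis layer, not as a direct half-life Welch test.
* The generalized-binomial treatment of fractional exchangeable-site counts
  is a modeling convention; alternative conventions (rounding, site-count
  mixtures) differ at the < 1e-3 level for typical peptides.
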