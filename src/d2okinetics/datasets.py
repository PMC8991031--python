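"""Published summary-table entries from the murine cartilage D2O aging study.

A 60-day heavy-water labeling experiment in female C57BL/6J mice compared
knee articular cartilage at 25 vs 90 weeks of age across a 36-protein
targeted panel. The raw mass-spectrometry data are not shipped; what is
bundled here are the printed per-protein summary statistics — fold-changes
(90wk:25wk) and mean differences (90wk - 25wk) — for concentration,
half-life, and absolute synthesis, plus the peptide counts per protein.
These serve two purposes:

* reconstruction identities: group means can be recovered from a
  (fold, difference) pair via :func:`d2okinetics.groupstats.invert_comparison`,
* parameterizing the synthetic-study generator with realistic truths.

Units: concentrations in pmol per microgram total protein (differences were
printed as x 10^-2 of that unit and are stored here already rescaled);
half-life differences in days (printed as x 10^3); absolute synthesis in
pmol per mg total protein per day (printed as x 10^-4). A ``None`` entry is
a dash in the source table: deuterium incorporation was undetectable within
the 60-day window.
"""

from __future__ import annotations

__all__ = [
    "CONCENTRATION_TABLE",
    "HALF_LIFE_TABLE",
    "ABSOLUTE_SYNTHESIS_TABLE",
    "REPORTED_VALUES",
    "DCN_EXAMPLE_PEPTIDE",
]

# One real tryptic peptide of decorin (DCN) shown in the study's worked example.
DCN_EXAMPLE_PEPTIDE = "ASYSAVSLYGNPVR"

# protein -> (fold_change_90_to_25, mean_difference_90_minus_25 [pmol/ug])
CONCENTRATION_TABLE: dict[str, tuple[float, float]] = {
    "ACAN": (1.96, 0.286), "ASPN": (1.24, 0.0096), "BGN": (0.76, -0.222),
    "DCN": (1.00, 0.0022), "FMOD": (0.52, -0.544), "FN1": (1.89, 0.136),
    "LUM": (1.17, 0.0704), "OGN": (0.79, -0.0226), "PRELP": (0.64, -0.260),
    "PRG4": (2.02, 0.0759),
    "COL1A1": (0.85, -0.0936), "COL2A1": (0.64, -0.248),
    "COL6A1": (0.98, 0.0116), "COL6A2": (1.01, 0.0056),
    "COL6A3": (0.85, -0.0562), "COL9A1": (0.86, -0.0066),
    "COL11A1": (0.76, -0.0067), "COL12A1": (0.73, -0.0256),
    "CHAD": (0.76, -0.174), "CHIL3": (0.38, -0.0387), "CILP": (0.57, -0.0098),
    "CLU": (2.37, 0.100), "COMP": (0.62, -0.184), "LMNA": (0.91, -0.0041),
    "MATN1": (0.56, -0.0058), "MATN3": (0.60, -0.0171),
    "MFGE8": (0.43, -0.530), "SPP1": (0.59, -0.074), "THBS1": (0.72, -0.0278),
    "VTN": (1.11, 0.0168),
    "ACTBG": (0.61, -0.200), "HSP90B": (0.82, 0.0109), "HSPA1A": (0.57, -0.0545),
    "HSPA5": (0.69, -0.0272), "PPIA": (0.54, -0.0130), "TUBA": (0.51, -0.0837),
}

# protein -> (n_peptides, fold_change, mean_difference [days]) ; None = dash
HALF_LIFE_TABLE: dict[str, tuple[int | None, float | None, float | None]] = {
    "ACAN": (4, 22.0, 22100.0), "ASPN": (2, 0.54, -1440.0),
    "BGN": (6, 1.52, 880.0), "DCN": (6, 1.54, 27.0),
    "FMOD": (3, 1.93, 7150.0), "FN1": (6, 2.27, 110.0),
    "LUM": (4, 1.34, 29.0), "OGN": (2, 88.0, 137000.0),
    "PRELP": (4, 1.70, 270.0), "PRG4": (4, 1.72, 24.0),
    "COL1A1": (2, 45.0, 135000.0), "COL2A1": (4, None, None),
    "COL6A1": (12, None, None), "COL6A2": (7, 2.0, 121000.0),
    "COL6A3": (15, 1.57, 6000.0), "COL9A1": (4, None, None),
    "COL11A1": (2, None, None), "COL12A1": (4, None, None),
    "CHAD": (4, 46.0, 277000.0), "CHIL3": (2, 1.08, 8.0),
    "CILP": (3, 1.69, 91.0), "CLU": (3, 2.93, 139.0),
    "COMP": (2, 2.33, 117.0), "LMNA": (7, 1.12, 8.0),
    "MATN1": (None, None, None), "MATN3": (4, 1.56, 114.0),
    "MFGE8": (5, 0.78, -55.0), "SPP1": (3, None, None),
    "THBS1": (3, 3.67, 660.0), "VTN": (3, 2.84, 436.0),
}

# protein -> (fold_change, mean_difference [pmol/mg/day]) ; None = dash
ABSOLUTE_SYNTHESIS_TABLE: dict[str, tuple[float | None, float | None]] = {
    "ACAN": (0.09, -2.58e-4), "ASPN": (2.29, 0.16e-4), "BGN": (0.50, -2.67e-4),
    "DCN": (0.65, -36.8e-4), "FMOD": (0.27, -1.07e-4), "FN1": (0.83, -2.94e-4),
    "LUM": (0.88, -5.85e-4), "OGN": (0.01, -0.69e-4), "PRELP": (0.38, -11.5e-4),
    "PRG4": (1.18, 3.96e-4),
    "COL1A1": (0.02, -2.05e-4), "COL2A1": (0.0, -0.053e-4),
    "COL6A1": (0.98, -0.00042e-4), "COL6A2": (0.51, -0.018e-4),
    "COL6A3": (0.54, -0.165e-4), "COL9A1": (None, None),
    "COL11A1": (None, None), "COL12A1": (0.0, -0.0069e-4),
    "CHAD": (0.17, -1.20e-4), "CHIL3": (0.35, -4.01e-4), "CILP": (0.35, -1.21e-4),
    "CLU": (0.81, -1.96e-4), "COMP": (0.26, -40.4e-4), "LMNA": (0.82, -1.20e-4),
    "MATN1": (None, None), "MATN3": (0.38, -1.30e-4), "MFGE8": (0.55, -16.7e-4),
    "SPP1": (0.0, -0.017e-4), "THBS1": (0.20, -3.25e-4), "VTN": (0.39, -4.10e-4),
}

# Headline values from the study's results narrative, used in worked examples.
REPORTED_VALUES = {
    "body_water_plateau": 0.055,          # serum enrichment plateau, fraction
    "prg4_half_life_25wk_days": 32.8,     # shortest half-life in the panel
    "prg4_half_life_diff_days": 23.7,     # 90wk - 25wk, Welch CI [17.7, 29.8]
    "dcn_half_life_diff_days": 27.3,
    "col1a1_half_life_25wk_days": 3081.0,   # reported as 8.5 yr
    "col12a1_half_life_25wk_days": 277259.0,  # reported as 760 yr
    "fmod_conc_25wk_pmol_per_ug": 1.12,   # highest panel concentration
    "matn1_conc_90wk_pmol_per_ug": 0.0073,  # lowest detected concentration
    "dcn_abs_synth_25wk": 0.011,          # pmol/mg total protein per day
    "nucleic_fraction_new_plateau": 0.6,  # DNA and RNA, both ages
    "n_25wk": 20,
    "n_90wk": 11,
}
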