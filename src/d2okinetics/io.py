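"""Table readers/writers and the end-to-end analysis pipeline.

Input dialects (UTF-8 CSV, header row, long format):

* peptide table: protein, peptide, animal_id, age_group, label_days,
  isotopomer_index, area — one isotopomer peak area per row,
* serum table: animal_id, age_group, day, enrichment (fractions; raw
  instrument readings are first mapped through
  :func:`d2okinetics.precursor.calibrate_enrichment`),
* nucleic table: molecule, animal_id, age_group, label_days, ratio —
  rows with label_days = 0 are the unlabeled derivative standard.

``run_pipeline`` chains precursor fit -> peptide kinetics -> protein
aggregation -> quantification -> nucleic fits -> group comparison and
returns an :class:`AnalysisReport`. Not-measurable kinetic entries are NaN
internally and rendered as dashes in output tables, never as numbers.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .groupstats import compare_groups
from .isotope import (
    ExchangeableHydrogenTable,
    composition_of_peptide,
    labeled_envelope,
    natural_envelope,
)
from .kinetics import (
    PeptideTimeCourse,
    ProteinKineticResult,
    aggregate_protein,
    fit_peptide_k,
)
from .nucleic import FractionNewSeries, fraction_new, max_ratio_for_precursor, two_pool_fit
from .precursor import DEFAULT_PLATEAU, fit_precursor
from .quantify import absolute_synthesis, concentration_from_internal_standard
from .simulate import StudyBundle

logger = logging.getLogger("d2okinetics")

__all__ = ["RowError", "PipelineOptions", "AnalysisReport",
           "read_peptide_table", "read_serum_table", "read_nucleic_table",
           "relative_m0", "run_pipeline", "DASH"]

DASH = "-"
PEPTIDE_COLUMNS = ["protein", "peptide", "animal_id", "age_group",
                   "label_days", "isotopomer_index", "area"]
SERUM_COLUMNS = ["animal_id", "age_group", "day", "enrichment"]
NUCLEIC_COLUMNS = ["molecule", "animal_id", "age_group", "label_days", "ratio"]


@dataclass(frozen=True)
class RowError:
    line: int          # 1-based line number in the file (header = line 1)
    message: str


@dataclass
class PipelineOptions:
    """Every mode choice of the analysis, recorded in the report metadata."""

    fixed_p: float | None = None          # None -> fit plateau from serum
    default_p: float = DEFAULT_PLATEAU    # used when no serum table either
    concentration_mode: str = "all"       # "all" | "top2"
    synthesis_mode: str = "multiply"      # "multiply" | "divide"
    exclude_durations: tuple = ()         # label days dropped from rate fits
    grubbs_alpha: float = 0.05
    n_peaks: int = 5
    nucleic_sites: dict = field(
        default_factory=lambda: {"DNA": 4.0, "RNA": 4.0})
    fdr_q: float = 0.05
    bsa_protein: str = "BSA"
    exchange_table_path: str | None = None

    def config_hash(self) -> str:
        payload = {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in self.__dict__.items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    precursor_p: float
    precursor_fit: object | None
    protein_table: pd.DataFrame      # one row per (protein, age_group)
    comparisons: dict                # family -> comparison DataFrame
    nucleic_table: pd.DataFrame
    metadata: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rendered = self.protein_table.copy()
        for col in ("k", "pooled_sd", "half_life_days", "half_life_years",
                    "abs_synthesis"):
            rendered[col] = [
                DASH if not m or not np.isfinite(v) else v
                for v, m in zip(rendered[col], rendered["measurable"])
            ]
        rendered.to_csv(outdir / "protein_kinetics.csv", index=False)
        self.nucleic_table.to_csv(outdir / "nucleic_turnover.csv", index=False)
        for family, table in self.comparisons.items():
            table.to_csv(outdir / f"comparison_{family}.csv", index=False)
        (outdir / "run_metadata.json").write_text(
            json.dumps(self.metadata, indent=2, sort_keys=True))


def _read_table(path, required: list[str], numeric: dict[str, bool]):
    """Read and validate a long-format CSV; collect row-level errors."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")
    errors: list[RowError] = []
    keep = np.ones(len(df), dtype=bool)
    for col, nonneg in numeric.items():
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        for i in np.flatnonzero(bad):
            errors.append(RowError(int(i) + 2,
                                   f"non-numeric {col}: {df[col].iloc[i]!r}"))
        if nonneg:
            neg = vals < 0
            for i in np.flatnonzero(neg):
                errors.append(RowError(int(i) + 2,
                                       f"negative {col}: {vals.iloc[i]}"))
            bad = bad | neg
        df[col] = vals
        keep &= ~bad.to_numpy()
    out = df.loc[keep, required].reset_index(drop=True)
    if errors:
        logger.warning("%s: %d row(s) rejected", path.name, len(errors))
    return out, errors


def read_peptide_table(path):
    """Validated peptide isotopomer records; returns (DataFrame, row errors)."""
    df, errors = _read_table(
        path, PEPTIDE_COLUMNS,
        {"label_days": False, "isotopomer_index": False, "area": True})
    df["label_days"] = df["label_days"].astype(float)
    df["isotopomer_index"] = df["isotopomer_index"].astype(int)
    return df, errors


def read_serum_table(path):
    df, errors = _read_table(path, SERUM_COLUMNS,
                             {"day": False, "enrichment": True})
    return df, errors


def read_nucleic_table(path):
    df, errors = _read_table(path, NUCLEIC_COLUMNS,
                             {"label_days": False, "ratio": True})
    return df, errors


def relative_m0(sub: pd.DataFrame) -> float:
    """Relative M0 abundance of one peptide in one animal: first peak / total."""
    areas = sub.sort_values("isotopomer_index")["area"].to_numpy()
    total = areas.sum()
    if total <= 0:
        raise ValueError("zero total isotopomer area")
    return float(areas[0] / total)


def _peptide_m0_table(pep: pd.DataFrame, bsa_protein: str) -> pd.DataFrame:
    rows = []
    mask = pep["protein"] != bsa_protein
    for (protein, peptide, animal, age, days), sub in pep[mask].groupby(
            ["protein", "peptide", "animal_id", "age_group", "label_days"],
            sort=True):
        rows.append({"protein": protein, "peptide": peptide,
                     "animal_id": animal, "age_group": age,
                     "label_days": days, "m0": relative_m0(sub)})
    return pd.DataFrame(rows)


def run_pipeline(
    peptides: pd.DataFrame,
    serum: pd.DataFrame | None = None,
    nucleic: pd.DataFrame | None = None,
    options: PipelineOptions | None = None,
    exchange_table: ExchangeableHydrogenTable | None = None,
) -> AnalysisReport:
    """Execute the full analysis on in-memory tables.

    Accepts the output of :func:`d2okinetics.simulate.generate_study` or
    tables loaded with the readers above. Deterministic given inputs and
    options.
    """
    opts = options or PipelineOptions()
    table = exchange_table or (
        ExchangeableHydrogenTable.from_csv(opts.exchange_table_path)
        if opts.exchange_table_path else ExchangeableHydrogenTable())

    # ---- stage 1: precursor enrichment ----------------------------------
    precursor_fit = None
    if opts.fixed_p is not None:
        p = opts.fixed_p
    elif serum is not None and len(serum):
        precursor_fit = fit_precursor(serum["day"].to_numpy(),
                                      serum["enrichment"].to_numpy())
        p = precursor_fit.p_max
        logger.info("precursor plateau fit: p_max=%.4f", p)
    else:
        p = opts.default_p
    logger.info("stage precursor: p=%.4f", p)

    # ---- stage 2: peptide kinetics --------------------------------------
    m0 = _peptide_m0_table(peptides, opts.bsa_protein)
    if opts.exclude_durations:
        m0 = m0[~m0["label_days"].isin(opts.exclude_durations)]

    env_cache: dict[str, tuple[float, float]] = {}

    def m0_refs(seq: str) -> tuple[float, float]:
        if seq not in env_cache:
            comp = composition_of_peptide(seq)
            nat = float(natural_envelope(comp, opts.n_peaks)[0])
            plat = float(labeled_envelope(comp, table.peptide_sites(seq), p,
                                          opts.n_peaks)[0])
            env_cache[seq] = (nat, plat)
        return env_cache[seq]

    results: list[ProteinKineticResult] = []
    kin_rows = []
    for (protein, age), sub in m0.groupby(["protein", "age_group"], sort=True):
        fits = []
        for peptide, psub in sub.groupby("peptide", sort=True):
            m0_nat, m0_plat = m0_refs(peptide)
            day0 = psub.loc[psub["label_days"] == 0, "m0"]
            if len(day0):   # unlabeled controls anchor natural abundance
                m0_nat = float(day0.mean())
            tc = PeptideTimeCourse(protein, peptide,
                                   psub["label_days"].to_numpy(),
                                   psub["m0"].to_numpy())
            try:
                fits.append(fit_peptide_k(tc, m0_nat, m0_plat))
            except ValueError as exc:
                logger.warning("%s/%s (%s): %s", protein, peptide, age, exc)
        if not fits:
            continue
        res = aggregate_protein(fits, grubbs_alpha=opts.grubbs_alpha)
        if res.peptides_removed:
            logger.info("%s (%s): Grubbs removed %d peptide rate(s)",
                        protein, age, len(res.peptides_removed))
        results.append(res)
        kin_rows.append({"protein": protein, "age_group": age, "k": res.k,
                         "pooled_sd": res.pooled_sd,
                         "n_peptides": res.n_peptides,
                         "half_life_days": res.half_life_days,
                         "half_life_years": res.half_life_years,
                         "measurable": res.measurable})
    kin = pd.DataFrame(kin_rows)

    # ---- stage 3: quantification ----------------------------------------
    conc_rows = []
    bsa = peptides[peptides["protein"] == opts.bsa_protein]
    for (animal, age), sub in peptides[
            peptides["protein"] != opts.bsa_protein].groupby(
            ["animal_id", "age_group"], sort=True):
        bsa_area = bsa.loc[bsa["animal_id"] == animal, "area"].sum()
        if bsa_area <= 0:
            logger.warning("animal %s: no BSA standard rows, skipped", animal)
            continue
        for protein, psub in sub.groupby("protein", sort=True):
            areas = psub.groupby("peptide")["area"].sum().to_dict()
            conc = concentration_from_internal_standard(
                areas, bsa_area, protein=protein, mode=opts.concentration_mode)
            conc_rows.append({"protein": protein, "animal_id": animal,
                              "age_group": age,
                              "conc": conc.pmol_per_mg,
                              "n_peptides": conc.n_peptides})
    conc_df = pd.DataFrame(conc_rows)

    group_conc = conc_df.groupby(["protein", "age_group"], sort=True)["conc"] \
                        .mean().rename("conc_pmol_per_mg").reset_index()
    prot = group_conc.merge(kin, on=["protein", "age_group"], how="left")
    prot["measurable"] = prot["measurable"].fillna(False).astype(bool)
    abs_rates = []
    for row in prot.itertuples():
        from .quantify import ProteinConcentration
        pc = ProteinConcentration(row.protein, row.conc_pmol_per_mg, (), 0)
        k = row.k if np.isfinite(row.k) else 0.0
        rate = absolute_synthesis(pc, k if row.measurable else 0.0,
                                  measurable=bool(row.measurable),
                                  mode=opts.synthesis_mode)
        abs_rates.append(rate.rate if rate.measurable else np.nan)
    prot["abs_synthesis"] = abs_rates

    # ---- stage 4: nucleic turnover --------------------------------------
    nuc_rows = []
    if nucleic is not None and len(nucleic):
        for (mol, age), sub in nucleic.groupby(["molecule", "age_group"],
                                               sort=True):
            std = sub.loc[sub["label_days"] == 0, "ratio"]
            if not len(std):
                logger.warning("%s (%s): no unlabeled standard rows", mol, age)
                continue
            base = float(std.mean())
            n_sites = opts.nucleic_sites.get(mol, 4.0)
            max_ratio = max_ratio_for_precursor(p, n_sites, base)
            lab = sub[sub["label_days"] > 0]
            fracs = [fraction_new(r, base, max_ratio) for r in lab["ratio"]]
            series = FractionNewSeries(mol, lab["label_days"].to_numpy(),
                                       np.array(fracs))
            if series.n_clipped:
                logger.info("%s (%s): %d fraction-new value(s) clipped",
                            mol, age, series.n_clipped)
            fit = two_pool_fit(series)
            nuc_rows.append({"molecule": mol, "age_group": age,
                             "fast_fraction": fit.fast_fraction,
                             "fast_half_life_upper": fit.fast_half_life_upper,
                             "slow_half_life_lower": fit.slow_half_life_lower,
                             "plateau_reached": fit.plateau_reached,
                             "n_clipped": series.n_clipped})
    nuc = pd.DataFrame(nuc_rows)

    # ---- stage 5: group comparison --------------------------------------
    comparisons: dict[str, pd.DataFrame] = {}
    ages = sorted(conc_df["age_group"].unique()) if len(conc_df) else []
    if len(ages) == 2:
        comparisons["concentration"] = compare_groups(
            conc_df, value="conc", q=opts.fdr_q)
        synth = conc_df.merge(kin[["protein", "age_group", "k", "measurable"]],
                              on=["protein", "age_group"], how="inner")
        synth = synth[synth["measurable"]]
        if len(synth):
            factor = 1.0 if opts.synthesis_mode == "multiply" else 1.0 / np.log(2)
            synth = synth.assign(abs_rate=synth["conc"] * synth["k"] * factor)
            both = synth.groupby("protein")["age_group"].nunique()
            synth = synth[synth["protein"].isin(both[both == 2].index)]
            if len(synth):
                comparisons["absolute_synthesis"] = compare_groups(
                    synth, value="abs_rate", q=opts.fdr_q)

    metadata = {
        "package_version": __version__,
        "config_hash": opts.config_hash(),
        "precursor_p": p,
        "precursor_source": ("fixed" if opts.fixed_p is not None
                             else "fitted" if precursor_fit is not None
                             else "default"),
        "concentration_mode": opts.concentration_mode,
        "synthesis_mode": opts.synthesis_mode,
        "exclude_durations": list(opts.exclude_durations),
        "grubbs_alpha": opts.grubbs_alpha,
        "n_peaks": opts.n_peaks,
        "fdr_q": opts.fdr_q,
    }
    return AnalysisReport(precursor_p=p, precursor_fit=precursor_fit,
                          protein_table=prot, comparisons=comparisons,
                          nucleic_table=nuc, metadata=metadata)


def run_pipeline_on_bundle(bundle: StudyBundle,
                           options: PipelineOptions | None = None
                           ) -> AnalysisReport:
    """Convenience wrapper: run the full pipeline on a synthetic study bundle."""
    return run_pipeline(bundle.peptides, bundle.serum, bundle.nucleic, options)
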