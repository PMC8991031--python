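"""Protein responses, BSA-normalized concentrations, absolute synthesis rates.

A known spike of bovine serum albumin (default 8 pmol into 0.05 mg total
protein) is digested alongside the sample, so peptide peak areas convert to
absolute amounts: concentration = geometric mean over peptides of
(peptide area / BSA reference area) x spike / load, in pmol per mg total
protein. Absolute synthesis multiplies concentration by the protein's rate
constant k (1/day); a division-by-half-life mode (differing exactly by ln 2)
is kept for compatibility with summary tables that use that convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ProteinConcentration",
    "AbsoluteSynthesisRate",
    "protein_response",
    "concentration_from_internal_standard",
    "absolute_synthesis",
    "BSA_SPIKE_PMOL",
    "PROTEIN_LOAD_MG",
]

BSA_SPIKE_PMOL = 8.0
PROTEIN_LOAD_MG = 0.05


@dataclass(frozen=True)
class ProteinConcentration:
    protein: str
    pmol_per_mg: float       # pmol per mg total protein
    peptide_ratios: tuple    # per-peptide area ratios vs the BSA reference
    n_peptides: int
    mode: str = "all"        # "all" peptides or "top2" best-detected


@dataclass(frozen=True)
class AbsoluteSynthesisRate:
    protein: str
    rate: float              # pmol per mg total protein per day
    mode: str                # "multiply" (conc x k) or "divide" (conc / half-life)
    measurable: bool


def protein_response(peak_areas) -> float:
    """Total integrated area over all peptides monitored for a protein."""
    areas = np.asarray(peak_areas, dtype=float)
    if areas.size == 0:
        raise ValueError("need >= 1 peptide area")
    if np.any(areas < 0):
        raise ValueError("negative peak area")
    return float(areas.sum())


def concentration_from_internal_standard(
    peptide_areas: dict[str, float],
    bsa_areas,
    bsa_spike_pmol: float = BSA_SPIKE_PMOL,
    protein_load_mg: float = PROTEIN_LOAD_MG,
    protein: str = "",
    mode: str = "all",
) -> ProteinConcentration:
    """Targeted protein concentration via the BSA internal standard.

    ``peptide_areas`` maps peptide sequence -> integrated area; ``bsa_areas``
    is the BSA standard's area(s), summed into one reference response.
    ``mode="top2"`` restricts the geometric mean to the two largest-area
    peptides (the best-detected ones); default uses all unique peptides.
    """
    if not peptide_areas:
        raise ValueError("need >= 1 peptide area")
    bsa_ref = protein_response(np.atleast_1d(bsa_areas))
    if bsa_ref <= 0:
        raise ValueError("BSA reference area must be positive")
    if mode not in ("all", "top2"):
        raise ValueError(f"unknown concentration mode {mode!r}")
    items = sorted(peptide_areas.items(), key=lambda kv: (-kv[1], kv[0]))
    if mode == "top2":
        items = items[:2]
    ratios = np.array([area / bsa_ref for _, area in items], dtype=float)
    if np.any(ratios < 0):
        raise ValueError("negative peak area")
    geo = float(np.exp(np.mean(np.log(ratios)))) if np.all(ratios > 0) else 0.0
    conc = geo * bsa_spike_pmol / protein_load_mg
    return ProteinConcentration(protein=protein, pmol_per_mg=conc,
                                peptide_ratios=tuple(ratios),
                                n_peptides=len(ratios), mode=mode)


def absolute_synthesis(
    conc: ProteinConcentration,
    k: float,
    measurable: bool = True,
    mode: str = "multiply",
) -> AbsoluteSynthesisRate:
    """Absolute synthesis rate of a protein, pmol/mg total protein per day.

    ``multiply`` mode: concentration x k. ``divide`` mode: concentration /
    half-life = concentration x k / ln 2. The two differ exactly by ln 2;
    the mode used is recorded on the result.
    """
    if k < 0:
        raise ValueError("rate constant k must be >= 0")
    if mode not in ("multiply", "divide"):
        raise ValueError(f"unknown synthesis mode {mode!r}")
    if not measurable or k == 0:
        return AbsoluteSynthesisRate(conc.protein, 0.0, mode, measurable=False)
    rate = conc.pmol_per_mg * k
    if mode == "divide":
        rate /= math.log(2)
    return AbsoluteSynthesisRate(conc.protein, float(rate), mode, measurable=True)
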