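"""Forward model of peptide isotope envelopes under heavy-water labeling.

Newly synthesized protein incorporates deuterium from body water at
metabolically exchangeable hydrogen positions. This shifts intensity out of
the monoisotopic (M0) peak of a peptide's isotope envelope into heavier
isotopomers (M+1, M+2, ...). The module provides:

* elemental composition of tryptic peptides,
* natural-abundance isotope envelopes by polynomial convolution,
* deuterium-enriched plateau envelopes at a given body-water enrichment ``p``,
* the expected first-order M0 decay curve used for rate fitting.

Envelope values are *relative* abundances: each peak divided by the summed
area of the ``n_peaks`` tracked peaks, so an envelope always sums to one.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.special import gammaln

__all__ = [
    "ElementalComposition",
    "ExchangeableHydrogenTable",
    "ISOTOPE_ABUNDANCES",
    "MONOISOTOPIC_MASS",
    "composition_of_peptide",
    "natural_envelope",
    "labeled_envelope",
    "expected_M0",
    "load_residue_table",
    "DEFAULT_N_PEAKS",
]

DEFAULT_N_PEAKS = 5

# Fixed terrestrial isotope abundances, indexed by nominal mass shift.
# Shipped as constants so envelopes are deterministic across platforms.
ISOTOPE_ABUNDANCES: dict[str, tuple[float, ...]] = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
}

MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}

_ELEMENTS = ("C", "H", "N", "O", "S")
_WATER = {"C": 0, "H": 2, "N": 0, "O": 1, "S": 0}


@dataclass(frozen=True)
class ElementalComposition:
    """Atom counts of a peptide (C, H, N, O, S)."""

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    S: int = 0

    def __post_init__(self) -> None:
        for el in _ELEMENTS:
            n = getattr(self, el)
            if not isinstance(n, (int, np.integer)) or n < 0:
                raise ValueError(f"atom count {el}={n!r} must be a nonnegative integer")

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        return ElementalComposition(
            **{el: getattr(self, el) + getattr(other, el) for el in _ELEMENTS}
        )

    @property
    def total_atoms(self) -> int:
        return sum(getattr(self, el) for el in _ELEMENTS)

    @property
    def monoisotopic_mass(self) -> float:
        return sum(getattr(self, el) * MONOISOTOPIC_MASS[el] for el in _ELEMENTS)


def _read_residue_csv(path) -> tuple[dict, dict]:
    formulas: dict[str, ElementalComposition] = {}
    exchangeable: dict[str, float] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            res = row["residue"].strip()
            formulas[res] = ElementalComposition(
                C=int(row["C"]), H=int(row["H"]), N=int(row["N"]),
                O=int(row["O"]), S=int(row["S"]),
            )
            exchangeable[res] = float(row["exchangeable_H"])
    return formulas, exchangeable


def load_residue_table(path: str | Path | None = None) -> tuple[dict, dict]:
    """Load residue formulas and exchangeable-hydrogen counts.

    Returns ``(formulas, exchangeable)`` where ``formulas`` maps one-letter
    residue codes to :class:`ElementalComposition` (residue = amino acid minus
    water) and ``exchangeable`` maps codes to the number of deuterium-accessible
    hydrogen sites per residue. The default table ships with the package; any
    CSV with columns ``residue,C,H,N,O,S,exchangeable_H`` may be substituted.
    """
    if path is None:
        ref = resources.files("d2okinetics.data").joinpath("residue_formulas.csv")
        with resources.as_file(ref) as p:
            return _read_residue_csv(p)
    return _read_residue_csv(path)


_DEFAULT_FORMULAS, _DEFAULT_EXCHANGEABLE = load_residue_table()


class ExchangeableHydrogenTable:
    """Per-residue deuterium-accessible hydrogen site counts.

    The counts are real-valued: they reflect the average number of C-bound
    hydrogens per residue that equilibrate with body water during biosynthesis,
    estimated from long-term labeling experiments. Totals for a peptide are
    the sum over its residues.
    """

    def __init__(self, counts: dict[str, float] | None = None):
        self.counts = dict(_DEFAULT_EXCHANGEABLE if counts is None else counts)
        for res, n in self.counts.items():
            if n < 0:
                raise ValueError(f"exchangeable count for {res} must be >= 0, got {n}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ExchangeableHydrogenTable":
        _, exch = load_residue_table(path)
        return cls(exch)

    def peptide_sites(self, sequence: str) -> float:
        """Total deuterium-accessible sites of a peptide (strictly > 0)."""
        if not sequence:
            raise ValueError("empty peptide has no exchangeable sites")
        try:
            total = sum(self.counts[res] for res in sequence)
        except KeyError as exc:
            raise ValueError(f"no exchangeable-H entry for residue {exc.args[0]!r}")
        return total


def composition_of_peptide(
    sequence: str, formulas: dict[str, ElementalComposition] | None = None
) -> ElementalComposition:
    """Elemental composition of a linear peptide: residue sum plus one water."""
    if not sequence:
        raise ValueError("empty peptide sequence")
    formulas = _DEFAULT_FORMULAS if formulas is None else formulas
    comp = ElementalComposition(**_WATER)
    for i, res in enumerate(sequence):
        if res not in formulas:
            raise ValueError(
                f"unknown residue {res!r} at position {i + 1} in {sequence!r}"
            )
        comp = comp + formulas[res]
    return comp


def _element_power(dist: tuple[float, ...], count: int) -> np.ndarray:
    """Isotope distribution of `count` identical atoms (full convolution)."""
    out = np.array([1.0])
    base = np.asarray(dist, dtype=float)
    n = count
    # exponentiation by squaring keeps this cheap for H counts in the hundreds
    while n > 0:
        if n & 1:
            out = np.convolve(out, base)
        base = np.convolve(base, base)
        n >>= 1
    return out


def _site_binomial(n_sites: float, q: float, length: int) -> np.ndarray:
    """Probability of k heavy atoms among ``n_sites`` sites, k = 0..length-1.

    Exact binomial for integer ``n_sites``; for real-valued site counts the
    binomial coefficient is continued through the gamma function. Terms with
    k > n_sites are zero. The caller renormalizes after truncation.
    """
    if n_sites < 0:
        raise ValueError("site count must be >= 0")
    if n_sites == 0 or q == 0.0:
        out = np.zeros(length)
        out[0] = 1.0
        return out
    k = np.arange(length, dtype=float)
    out = np.zeros(length)
    valid = k <= n_sites
    kk = k[valid]
    log_coef = gammaln(n_sites + 1) - gammaln(kk + 1) - gammaln(n_sites - kk + 1)
    out[valid] = np.exp(
        log_coef + kk * np.log(q) + (n_sites - kk) * np.log1p(-q)
    )
    return out


def _truncate_normalize(dist: np.ndarray, n_peaks: int) -> np.ndarray:
    if len(dist) < n_peaks:
        dist = np.pad(dist, (0, n_peaks - len(dist)))
    env = np.asarray(dist[:n_peaks], dtype=float)
    total = env.sum()
    if total <= 0:
        raise ValueError("degenerate envelope: no probability mass in tracked peaks")
    return env / total


def natural_envelope(comp: ElementalComposition, n_peaks: int = DEFAULT_N_PEAKS) -> np.ndarray:
    """Natural-abundance isotope envelope, truncated to ``n_peaks`` and renormalized.

    The envelope is the convolution of per-element multinomial isotope
    patterns at standard terrestrial abundances, on the nominal mass-shift
    grid (M0, M+1, ...).
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    if comp.total_atoms == 0:
        raise ValueError("all-zero composition has no isotope envelope")
    dist = np.array([1.0])
    for el in _ELEMENTS:
        count = getattr(comp, el)
        if count:
            dist = np.convolve(dist, _element_power(ISOTOPE_ABUNDANCES[el], count))
    return _truncate_normalize(dist, n_peaks)


def labeled_envelope(
    comp: ElementalComposition,
    n_exchangeable: float,
    p: float,
    n_peaks: int = DEFAULT_N_PEAKS,
) -> np.ndarray:
    """Plateau envelope of protein synthesized at body-water enrichment ``p``.

    ``n_exchangeable`` hydrogen sites carry heavy-isotope probability equal to
    the natural deuterium abundance plus ``p``; the remaining hydrogens and all
    other elements stay at natural abundance. ``p = 0`` reproduces the natural
    envelope.
    """
    if not 0.0 <= p < 0.2:
        raise ValueError(f"precursor enrichment p={p} outside [0, 0.2)")
    if n_exchangeable < 0 or n_exchangeable > comp.H:
        raise ValueError(
            f"n_exchangeable={n_exchangeable} outside [0, total H={comp.H}]"
        )
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    if comp.total_atoms == 0:
        raise ValueError("all-zero composition has no isotope envelope")

    # generous working length so truncation to n_peaks loses only tail mass
    work = n_peaks + 12
    h_nat = ISOTOPE_ABUNDANCES["H"][1]
    dist = np.array([1.0])
    for el in ("C", "N", "O", "S"):
        count = getattr(comp, el)
        if count:
            dist = np.convolve(dist, _element_power(ISOTOPE_ABUNDANCES[el], count))
    dist = np.convolve(dist, _site_binomial(n_exchangeable, h_nat + p, work))
    dist = np.convolve(dist, _site_binomial(comp.H - n_exchangeable, h_nat, work))
    return _truncate_normalize(dist, n_peaks)


def expected_M0(t, k: float, M0_nat: float, M0_plateau: float):
    """Expected relative M0 abundance after ``t`` days of labeling.

    First-order turnover toward the precursor-determined plateau:
    ``M0(t) = M0_plateau + (M0_nat - M0_plateau) * exp(-k t)``.
    Accepts scalar or array ``t``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("labeling time t must be >= 0")
    if k < 0:
        raise ValueError("rate constant k must be >= 0")
    if not 0.0 <= M0_plateau <= M0_nat <= 1.0:
        raise ValueError("require 0 <= M0_plateau <= M0_nat <= 1")
    out = M0_plateau + (M0_nat - M0_plateau) * np.exp(-k * t_arr)
    return float(out) if np.isscalar(t) else out
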