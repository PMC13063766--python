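"""Theoretical amyloid-beta variant mass list.

Human A-beta (the APP fragment spanning residues 672-714, A-beta numbering
1-43) is proteolytically ragged at both termini: in addition to the canonical
full-length species A-beta 1-40 and 1-42, N-terminally truncated (A-beta x-40/x-42),
C-terminally truncated (A-beta 1-y, y < 40) and bi-terminally truncated species
occur in plaques, plus pyroglutamate-cyclised forms at the internal glutamates
E3 and E11 (a net water loss of 18.011 Da).

This module enumerates that variant space, computes elemental compositions and
monoisotopic [M+H]+ masses, and predicts isotope envelopes by convolution of
natural isotope abundances. The resulting curated mass list drives in-situ
annotation of reflector-mode MALDI-TOF imaging spectra (singly charged ions,
m/z 2500-5000).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ABETA_SEQUENCE",
    "PROTON_MASS",
    "NEUTRON_SPACING",
    "ElementalComposition",
    "IsotopeEnvelope",
    "PeptideVariant",
    "MassListConfig",
    "composition_of",
    "monoisotopic_mass",
    "isotope_envelope",
    "enumerate_variants",
    "variant_name",
    "masslist_to_frame",
    "write_masslist",
    "read_masslist",
]

#: Canonical human A-beta 1-43 (UniProt APP positions 672-714).
ABETA_SEQUENCE = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIAT"

PROTON_MASS = 1.007276
#: Average mass spacing between adjacent isotopologues of a peptide (Da),
#: dominated by the 13C-12C difference.
NEUTRON_SPACING = 1.0033548

_ELEMENTS = ("C", "H", "N", "O", "S")

# Monoisotopic masses of the lightest isotope of each element (Da).
_MONO_MASS = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}

# Natural isotope abundances binned by nominal mass shift (offset 0 = lightest).
_ISOTOPE_ABUNDANCE = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
}

# Residue (amino acid minus water) elemental compositions, standard 20 letters.
_RESIDUE_COMP: dict[str, tuple[int, int, int, int, int]] = {
    #      C   H   N  O  S
    "G": (2, 3, 1, 1, 0),
    "A": (3, 5, 1, 1, 0),
    "S": (3, 5, 1, 2, 0),
    "P": (5, 7, 1, 1, 0),
    "V": (5, 9, 1, 1, 0),
    "T": (4, 7, 1, 2, 0),
    "C": (3, 5, 1, 1, 1),
    "L": (6, 11, 1, 1, 0),
    "I": (6, 11, 1, 1, 0),
    "N": (4, 6, 2, 2, 0),
    "D": (4, 5, 1, 3, 0),
    "Q": (5, 8, 2, 2, 0),
    "K": (6, 12, 2, 1, 0),
    "E": (5, 7, 1, 3, 0),
    "M": (5, 9, 1, 1, 1),
    "H": (6, 7, 3, 1, 0),
    "F": (9, 9, 1, 1, 0),
    "R": (6, 12, 4, 1, 0),
    "Y": (9, 9, 1, 2, 0),
    "W": (11, 10, 2, 1, 0),
}

_WATER = (0, 2, 0, 1, 0)


class InvalidSequenceError(ValueError):
    """Raised for sequences containing non-standard residue letters."""


@dataclass(frozen=True)
class ElementalComposition:
    """Element counts (C, H, N, O, S) of a neutral molecule."""

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    S: int = 0

    def __post_init__(self) -> None:
        for el in _ELEMENTS:
            if getattr(self, el) < 0:
                raise ValueError(f"negative {el} count in composition")

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        return ElementalComposition(
            *(getattr(self, el) + getattr(other, el) for el in _ELEMENTS)
        )

    def as_dict(self) -> dict[str, int]:
        return {el: getattr(self, el) for el in _ELEMENTS}

    def formula(self) -> str:
        return "".join(
            f"{el}{getattr(self, el)}" for el in _ELEMENTS if getattr(self, el) > 0
        )


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Isotopologue pattern of a peptide, aggregated by nominal mass shift.

    ``offsets[i]`` counts extra neutrons relative to the monoisotopic peak,
    ``probabilities`` are the corresponding fractions (sum 1 after pruning and
    renormalisation) and ``mz_positions`` the singly protonated m/z of each
    isotopologue.
    """

    offsets: tuple[int, ...]
    probabilities: tuple[float, ...]
    mz_positions: tuple[float, ...]

    def __post_init__(self) -> None:
        if not len(self.offsets) == len(self.probabilities) == len(self.mz_positions):
            raise ValueError("envelope field lengths differ")
        total = float(np.sum(self.probabilities))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"envelope probabilities sum to {total!r}, not 1")
        if np.any(np.asarray(self.probabilities) < 0):
            raise ValueError("negative isotopologue probability")
        spacing = np.diff(self.mz_positions)
        if len(spacing) and not np.all((spacing >= 1.0023) & (spacing <= 1.0040)):
            raise ValueError("isotopologue spacing outside [1.0023, 1.0040] Da")


@dataclass(frozen=True)
class PeptideVariant:
    """One A-beta truncation/modification species.

    ``start``/``end`` are 1-based inclusive residue positions on A-beta 1-43
    numbering; ``pyroglu`` marks N-terminal pyroglutamate (only possible where
    the first residue is E or Q, i.e. A-beta positions 3 and 11).
    """

    start: int
    end: int
    pyroglu: bool
    sequence: str
    composition: ElementalComposition
    mono_mass: float
    mz_mh: float
    envelope: IsotopeEnvelope

    @property
    def name(self) -> str:
        return variant_name(self.start, self.end, self.pyroglu)

    def __post_init__(self) -> None:
        if not (1 <= self.start < self.end <= len(ABETA_SEQUENCE)):
            raise ValueError(f"invalid residue span {self.start}-{self.end}")
        expected = ABETA_SEQUENCE[self.start - 1 : self.end]
        if self.sequence != expected:
            raise ValueError("sequence does not match canonical A-beta substring")
        if self.pyroglu and self.sequence[0] not in "EQ":
            raise ValueError("pyroglutamate requires an N-terminal E or Q")
        if abs(self.mz_mh - (self.mono_mass + PROTON_MASS)) > 1e-6:
            raise ValueError("mz_mh inconsistent with mono_mass + proton")


def variant_name(start: int, end: int, pyroglu: bool) -> str:
    """Field-style species symbol, e.g. ``Abeta4-42`` or ``AbetapE3-42``."""
    return f"Abeta{'pE' if pyroglu else ''}{start}-{end}"


@dataclass(frozen=True)
class MassListConfig:
    """Enumeration space for the curated mass list.

    Defaults span every species reported in plaques by single-plaque MALDI-MSI
    of AD/DS tissue, with margin; the acquisition m/z window supplies the hard
    constraint.
    """

    start_range: tuple[int, int] = (1, 12)
    end_range: tuple[int, int] = (34, 43)
    allow_pyroglu_at: frozenset[int] = frozenset({3, 11})
    mz_window: tuple[float, float] = (2500.0, 5000.0)
    envelope_prune: float = 1e-6

    def __post_init__(self) -> None:
        lo, hi = self.mz_window
        if not lo < hi:
            raise ValueError("mz_window lower bound must be below upper bound")
        for a, b in (self.start_range, self.end_range):
            if not (1 <= a <= b <= len(ABETA_SEQUENCE)):
                raise ValueError("residue ranges must lie within [1, 43]")
        if not 0.0 < self.envelope_prune < 1.0:
            raise ValueError("envelope_prune must be in (0, 1)")


def composition_of(sequence: str, pyroglu: bool = False) -> ElementalComposition:
    """Elemental composition of a peptide: residue sum + H2O.

    Pyroglutamate cyclisation removes H2O from an N-terminal glutamate
    (or NH3 from a glutamine).
    """
    if not sequence:
        raise InvalidSequenceError("empty sequence")
    counts = [0, 0, 0, 0, 0]
    for aa in sequence:
        try:
            res = _RESIDUE_COMP[aa]
        except KeyError:
            raise InvalidSequenceError(f"unknown residue letter {aa!r}") from None
        for i in range(5):
            counts[i] += res[i]
    for i in range(5):
        counts[i] += _WATER[i]
    if pyroglu:
        first = sequence[0]
        if first == "E":
            counts[1] -= 2  # -H2O
            counts[3] -= 1
        elif first == "Q":
            counts[1] -= 3  # -NH3
            counts[2] -= 1
        else:
            raise InvalidSequenceError(
                "pyroglutamate requires an N-terminal E or Q residue"
            )
    return ElementalComposition(*counts)


def monoisotopic_mass(composition: ElementalComposition) -> float:
    """Monoisotopic (lightest-isotope) mass in Da."""
    return float(
        sum(getattr(composition, el) * _MONO_MASS[el] for el in _ELEMENTS)
    )


def _element_distribution(abundances: tuple[float, ...], n: int) -> np.ndarray:
    """Nominal-mass isotope distribution of ``n`` atoms of one element.

    Convolution power computed by binary exponentiation; tails below 1e-15
    are trimmed to keep lengths bounded.
    """
    base = np.asarray(abundances, dtype=float)
    result = np.array([1.0])
    power = base
    while n:
        if n & 1:
            result = np.convolve(result, power)
            result = _trim(result)
        n >>= 1
        if n:
            power = _trim(np.convolve(power, power))
    return result


def _trim(p: np.ndarray, floor: float = 1e-15) -> np.ndarray:
    nz = np.nonzero(p > floor)[0]
    if len(nz) == 0:
        return p[:1]
    return p[: nz[-1] + 1]


def isotope_envelope(
    composition: ElementalComposition, prune: float = 1e-6
) -> IsotopeEnvelope:
    """Aggregated (nominal-mass) isotope envelope of a composition.

    The per-element distributions are convolved, offsets with probability
    below ``prune`` are discarded, and the remainder renormalised. m/z
    positions assume charge +1 and the average isotopologue spacing.
    """
    if not 0.0 < prune < 1.0:
        raise ValueError("prune must be in (0, 1)")
    dist = np.array([1.0])
    for el in _ELEMENTS:
        n = getattr(composition, el)
        if n:
            dist = _trim(np.convolve(dist, _element_distribution(_ISOTOPE_ABUNDANCE[el], n)))
    keep = np.nonzero(dist >= prune)[0]
    probs = dist[keep]
    probs = probs / probs.sum()
    mono = monoisotopic_mass(composition)
    mz = mono + keep * NEUTRON_SPACING + PROTON_MASS
    return IsotopeEnvelope(
        offsets=tuple(int(k) for k in keep),
        probabilities=tuple(float(p) for p in probs),
        mz_positions=tuple(float(m) for m in mz),
    )


def make_variant(
    start: int, end: int, pyroglu: bool = False, prune: float = 1e-6
) -> PeptideVariant:
    """Fully populated :class:`PeptideVariant` for one (start, end, pyroglu)."""
    seq = ABETA_SEQUENCE[start - 1 : end]
    comp = composition_of(seq, pyroglu=pyroglu)
    mono = monoisotopic_mass(comp)
    return PeptideVariant(
        start=start,
        end=end,
        pyroglu=pyroglu,
        sequence=seq,
        composition=comp,
        mono_mass=mono,
        mz_mh=mono + PROTON_MASS,
        envelope=isotope_envelope(comp, prune=prune),
    )


def enumerate_variants(config: MassListConfig | None = None) -> list[PeptideVariant]:
    """All variants in the configured truncation space whose [M+H]+ falls in
    the m/z window, sorted by m/z. Pure function of the configuration."""
    cfg = config or MassListConfig()
    out: list[PeptideVariant] = []
    lo, hi = cfg.mz_window
    for start in range(cfg.start_range[0], cfg.start_range[1] + 1):
        pyro_options = (False, True) if start in cfg.allow_pyroglu_at else (False,)
        for end in range(max(cfg.end_range[0], start + 1), cfg.end_range[1] + 1):
            for pyro in pyro_options:
                if pyro and ABETA_SEQUENCE[start - 1] not in "EQ":
                    continue
                v = make_variant(start, end, pyro, prune=cfg.envelope_prune)
                if lo <= v.mz_mh <= hi:
                    out.append(v)
    out.sort(key=lambda v: v.mz_mh)
    return out


# ---------------------------------------------------------------------------
# CSV export / import (stable column order)

_CSV_COLUMNS = [
    "name",
    "start",
    "end",
    "pyroglu",
    "sequence",
    "mono_mass",
    "mz_mh",
    "envelope_offsets",
    "envelope_probabilities",
]


def masslist_to_frame(variants: Iterable[PeptideVariant]) -> pd.DataFrame:
    rows = []
    for v in variants:
        rows.append(
            {
                "name": v.name,
                "start": v.start,
                "end": v.end,
                "pyroglu": v.pyroglu,
                "sequence": v.sequence,
                "mono_mass": v.mono_mass,
                "mz_mh": v.mz_mh,
                "envelope_offsets": ";".join(str(o) for o in v.envelope.offsets),
                "envelope_probabilities": ";".join(
                    f"{p:.10g}" for p in v.envelope.probabilities
                ),
            }
        )
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def write_masslist(variants: Iterable[PeptideVariant], path) -> None:
    masslist_to_frame(variants).to_csv(path, index=False)


def read_masslist(path) -> list[PeptideVariant]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        out.append(make_variant(int(row["start"]), int(row["end"]), bool(row["pyroglu"])))
    return out
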