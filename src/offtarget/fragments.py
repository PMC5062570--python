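"""Theoretical b/y fragment ions, peak matching and adduct site localization.

A covalent adduct (here a photoaffinity-probe crosslink of +562.1738 Da)
shifts the mass of every fragment ion that contains the modified residue.
Comparing which b/y ions appear shifted versus unshifted in an MS2 spectrum
therefore brackets the attachment site to a residue interval: a shifted b_k
proves the site lies within the first k residues, an unshifted b_k proves it
lies beyond them (and symmetrically for y ions read from the C terminus).

All masses are monoisotopic.  Only b and y series are computed; the peptides
are given, not produced by an in-silico digest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "PROTON",
    "WATER",
    "PROBE_ADDUCT",
    "CARBAMIDOMETHYL",
    "OXIDATION",
    "RESIDUE_MASSES",
    "PeptideSpec",
    "TheoreticalIon",
    "PeakList",
    "IonMatch",
    "LocalizationResult",
    "theoretical_fragments",
    "match_peaks",
    "localize",
    "read_mgf",
    "write_mgf",
]

PROTON = 1.007276
WATER = 18.010565

# common fixed/variable modification deltas (Da)
PROBE_ADDUCT = 562.1738
CARBAMIDOMETHYL = 57.02146
OXIDATION = 15.9949

# monoisotopic residue masses of the 20 standard amino acids (Da)
RESIDUE_MASSES: Dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}


class UnknownResidueError(ValueError):
    def __init__(self, residue: str):
        self.residue = residue
        super().__init__(f"unknown amino-acid residue {residue!r}")


@dataclass(frozen=True)
class PeptideSpec:
    """A peptide with optional position-resolved mass modifications.

    ``modifications`` maps 1-based residue positions to mass deltas in Da.
    """

    sequence: str
    modifications: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence is empty")
        for aa in self.sequence:
            if aa not in RESIDUE_MASSES:
                raise UnknownResidueError(aa)
        for pos in self.modifications:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(
                    f"modification position {pos} outside peptide of "
                    f"length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue_masses(self) -> np.ndarray:
        """Per-residue masses including any modification deltas."""
        m = np.array([RESIDUE_MASSES[a] for a in self.sequence])
        for pos, delta in self.modifications.items():
            m[pos - 1] += delta
        return m

    def precursor_mh(self) -> float:
        """Singly protonated precursor mass MH+."""
        return float(self.residue_masses().sum() + WATER + PROTON)


@dataclass(frozen=True)
class TheoreticalIon:
    series: str  # 'b' or 'y'
    ordinal: int  # 1 .. len-1
    charge: int
    mz: float

    @property
    def label(self) -> str:
        return f"{self.series}{self.ordinal}{'+' * self.charge}"


@dataclass
class PeakList:
    """An MS2 spectrum as sorted m/z-intensity arrays."""

    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float = 0.0
    precursor_charge: int = 1
    title: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        if np.any(self.intensity < 0):
            raise ValueError("peak intensities must be non-negative")


def theoretical_fragments(
    peptide: PeptideSpec, max_charge: int = 1
) -> List[TheoreticalIon]:
    """All b/y ions of ``peptide`` up to ``max_charge``.

    Singly charged b_k = (sum of first k residue masses, mods included)
    + proton; y_k adds water for the C-terminal hydroxyl.  Higher charges
    follow m/z = (neutral + z * proton) / z.
    """
    n = len(peptide)
    masses = peptide.residue_masses()
    prefix = np.cumsum(masses)
    total = prefix[-1]
    ions: List[TheoreticalIon] = []
    for k in range(1, n):
        b_neutral = prefix[k - 1]
        y_neutral = total - prefix[n - k - 1] + WATER
        for z in range(1, max_charge + 1):
            ions.append(TheoreticalIon("b", k, z, (b_neutral + z * PROTON) / z))
            ions.append(TheoreticalIon("y", k, z, (y_neutral + z * PROTON) / z))
    return ions


@dataclass(frozen=True)
class IonMatch:
    ion: TheoreticalIon
    peak_mz: float
    peak_intensity: float
    error_da: float


def match_peaks(
    ions: Sequence[TheoreticalIon],
    peaks: PeakList,
    fragment_tol: float = 0.8,
) -> List[IonMatch]:
    """Greedy assignment of observed peaks to theoretical ions.

    Each peak is consumed by at most one ion; conflicts go to the ion with
    the smaller mass error, ties to the lower ordinal.  Matches farther than
    ``fragment_tol`` Da (strict) are rejected.
    """
    if not fragment_tol > 0:
        raise ValueError("fragment tolerance must be positive")
    if peaks.mz.size == 0 or not ions:
        return []
    # candidate (ion, nearest peak) pairs ordered by |error| then ordinal
    candidates: List[Tuple[float, int, int, int]] = []
    for i, ion in enumerate(ions):
        j = int(np.searchsorted(peaks.mz, ion.mz))
        for jj in (j - 1, j):
            if 0 <= jj < peaks.mz.size:
                err = abs(peaks.mz[jj] - ion.mz)
                if err < fragment_tol:
                    candidates.append((err, ion.ordinal, i, jj))
    candidates.sort()
    used_peaks: set = set()
    used_ions: set = set()
    matches: List[IonMatch] = []
    for err, _ordinal, i, jj in candidates:
        if i in used_ions or jj in used_peaks:
            continue
        used_ions.add(i)
        used_peaks.add(jj)
        ion = ions[i]
        matches.append(
            IonMatch(ion, float(peaks.mz[jj]), float(peaks.intensity[jj]),
                     float(peaks.mz[jj] - ion.mz))
        )
    matches.sort(key=lambda m: (m.ion.series, m.ion.ordinal, m.ion.charge))
    return matches


@dataclass(frozen=True)
class LocalizationResult:
    """Smallest residue interval (1-based, inclusive) consistent with the ions."""

    interval: Tuple[int, int]
    shifted_ions: Tuple[str, ...]
    unshifted_ions: Tuple[str, ...]


class LocalizationConflictError(ValueError):
    def __init__(self, conflicts: Iterable[str]):
        self.conflicts = tuple(conflicts)
        super().__init__(
            "contradictory site-localization evidence from ions: "
            + ", ".join(self.conflicts)
        )


def localize(
    unshifted: Sequence[TheoreticalIon],
    shifted: Sequence[TheoreticalIon],
    peptide_length: int,
) -> LocalizationResult:
    """Intersect b/y shift constraints into the smallest consistent interval.

    For a peptide of length n with a single adduct at unknown site s:
    a shifted b_k implies s <= k, an unshifted b_k implies s > k;
    a shifted y_k implies s >= n - k + 1, an unshifted y_k implies s <= n - k.
    """
    if peptide_length < 1:
        raise ValueError("peptide_length must be >= 1")
    if not shifted:
        raise ValueError("at least one shifted ion is required to localize")
    lo, hi = 1, peptide_length
    lo_from, hi_from = "", ""
    for ion in shifted:
        if ion.series == "b":
            if ion.ordinal < hi:
                hi, hi_from = ion.ordinal, ion.label
        else:  # y
            bound = peptide_length - ion.ordinal + 1
            if bound > lo:
                lo, lo_from = bound, ion.label
    for ion in unshifted:
        if ion.series == "b":
            bound = ion.ordinal + 1
            if bound > lo:
                lo, lo_from = bound, ion.label
        else:
            bound = peptide_length - ion.ordinal
            if bound < hi:
                hi, hi_from = bound, ion.label
    if lo > hi:
        raise LocalizationConflictError(x for x in (lo_from, hi_from) if x)
    return LocalizationResult(
        interval=(lo, hi),
        shifted_ions=tuple(i.label for i in shifted),
        unshifted_ions=tuple(i.label for i in unshifted),
    )


def read_mgf(path) -> List[PeakList]:
    """Read all spectra from an MGF file."""
    from pyteomics import mgf

    out: List[PeakList] = []
    with mgf.read(str(path)) as reader:
        for spec in reader:
            params = spec.get("params", {})
            pep = params.get("pepmass", (0.0,))
            charge = params.get("charge", [1])
            out.append(
                PeakList(
                    mz=spec["m/z array"],
                    intensity=spec["intensity array"],
                    precursor_mz=float(pep[0]) if pep and pep[0] else 0.0,
                    precursor_charge=int(charge[0]) if charge else 1,
                    title=str(params.get("title", "")),
                )
            )
    return out


def write_mgf(peaklists: Sequence[PeakList], path) -> None:
    from pyteomics import mgf

    spectra = []
    for i, pl in enumerate(peaklists):
        spectra.append(
            {
                "m/z array": pl.mz,
                "intensity array": pl.intensity,
                "params": {
                    "title": pl.title or f"spectrum_{i}",
                    "pepmass": pl.precursor_mz,
                    "charge": pl.precursor_charge,
                },
            }
        )
    mgf.write(spectra, str(path), file_mode="w")
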