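"""Peptidoform masses, b/y fragment ions, peak matching and MGF I/O.

Endogenous peptidomics searches are enzyme-free, so peptidoforms here carry
the variable modifications typical of mature bioactive peptides: C-terminal
amidation, methionine oxidation and N-terminal pyroglutamate formation from
Gln or Glu. Fragmentation follows the HCD-style b/y model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from pyteomics import mgf as _pyteomics_mgf

__all__ = [
    "PROTON_MASS",
    "WATER_MASS",
    "RESIDUE_MASS",
    "Peptidoform",
    "Spectrum",
    "FragmentSet",
    "UnsupportedResidueError",
    "monoisotopic_mass",
    "fragment_mz",
    "match_peaks",
    "read_mgf",
    "write_mgf",
]

# Monoisotopic constants (Da). Proton and water from CODATA/IUPAC atomic
# masses; residue masses are the standard monoisotopic amino-acid residue
# table (peptide-bond residues, i.e. amino acid minus water).
PROTON_MASS = 1.007276
WATER_MASS = 18.010565

RESIDUE_MASS: dict[str, float] = {
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

# Modification mass deltas (Da).
AMIDATION_DELTA = -0.98402          # C-terminal -OH -> -NH2
OXIDATION_DELTA = +15.99491         # Met oxidation
PYRO_GLU_FROM_Q_DELTA = -17.02655   # loss of NH3 from N-terminal Gln
PYRO_GLU_FROM_E_DELTA = -18.01056   # loss of H2O from N-terminal Glu


class UnsupportedResidueError(ValueError):
    """Sequence contains a residue outside the 20 canonical amino acids."""


@dataclass(frozen=True)
class Peptidoform:
    """A peptide sequence plus its variable modification state.

    Parameters
    ----------
    sequence
        Uppercase amino-acid string.
    c_term_amidated
        C-terminal amidation (-0.98402 Da, applied to the peptide / y ions).
    oxidized_positions
        0-based indices of oxidized methionines.
    pyro_glu
        Pyroglutamate at position 1 (residue must be Q or E).
    """

    sequence: str
    c_term_amidated: bool = False
    oxidized_positions: frozenset[int] = field(default_factory=frozenset)
    pyro_glu: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "oxidized_positions", frozenset(self.oxidized_positions)
        )
        if not self.sequence:
            raise ValueError("empty peptidoform sequence")
        for i in self.oxidized_positions:
            if not 0 <= i < len(self.sequence):
                raise ValueError(f"oxidized position {i} out of range")
            if self.sequence[i] != "M":
                raise ValueError(
                    f"oxidized position {i} is {self.sequence[i]!r}, not M"
                )
        if self.pyro_glu and self.sequence[0] not in ("Q", "E"):
            raise ValueError(
                "pyro_glu requires an N-terminal Q or E, got "
                f"{self.sequence[0]!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def mods_string(self) -> str:
        """Canonical semicolon-separated 'pos:name' modification string.

        Positions are 1-based; 0 denotes the N-terminus and -1 the C-terminus
        (PSM-table dialect).
        """
        parts: list[str] = []
        if self.pyro_glu:
            parts.append("0:pyro_glu")
        for i in sorted(self.oxidized_positions):
            parts.append(f"{i + 1}:oxidation")
        if self.c_term_amidated:
            parts.append("-1:amidation")
        return ";".join(parts)

    @classmethod
    def from_mods_string(cls, sequence: str, mods: str) -> "Peptidoform":
        """Parse the PSM-table 'pos:name' dialect back into a Peptidoform."""
        amid = False
        pyro = False
        oxidized: set[int] = set()
        for token in filter(None, (t.strip() for t in mods.split(";"))):
            pos_s, _, name = token.partition(":")
            pos = int(pos_s)
            name = name.lower()
            if name == "amidation":
                amid = True
            elif name == "pyro_glu":
                pyro = True
            elif name == "oxidation":
                oxidized.add(pos - 1)
            else:
                raise ValueError(f"unknown modification {name!r}")
        return cls(sequence, c_term_amidated=amid,
                   oxidized_positions=frozenset(oxidized), pyro_glu=pyro)


@dataclass
class Spectrum:
    """A centroided MS/MS spectrum with optional RT and ion mobility."""

    spectrum_id: str
    precursor_mz: float
    precursor_charge: int
    peaks_mz: np.ndarray
    peaks_intensity: np.ndarray
    rt: float | None = None
    inv_k0: float | None = None
    extra_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.peaks_mz = np.asarray(self.peaks_mz, dtype=float)
        self.peaks_intensity = np.asarray(self.peaks_intensity, dtype=float)
        if self.peaks_mz.shape != self.peaks_intensity.shape:
            raise ValueError("peak m/z and intensity arrays differ in length")
        if np.any(self.peaks_intensity < 0):
            raise ValueError("negative peak intensity")
        order = np.argsort(self.peaks_mz, kind="stable")
        self.peaks_mz = self.peaks_mz[order]
        self.peaks_intensity = self.peaks_intensity[order]


@dataclass(frozen=True)
class FragmentSet:
    """Theoretical b/y fragment m/z values, per fragment charge.

    ``b[z]`` and ``y[z]`` are arrays indexed by fragment length 1..n-1.
    """

    b: dict[int, np.ndarray]
    y: dict[int, np.ndarray]

    @property
    def n_fragments(self) -> int:
        return len(next(iter(self.b.values())))

    def vector_mz(self, charges: Sequence[int] = (1,)) -> np.ndarray:
        """Flatten into the canonical feature order: b then y, per charge."""
        parts = []
        for z in charges:
            parts.append(self.b[z])
            parts.append(self.y[z])
        return np.concatenate(parts)


def _residue_masses(p: Peptidoform) -> np.ndarray:
    masses = np.empty(len(p.sequence))
    for i, aa in enumerate(p.sequence):
        try:
            masses[i] = RESIDUE_MASS[aa]
        except KeyError:
            raise UnsupportedResidueError(
                f"unsupported residue {aa!r} at position {i} in "
                f"{p.sequence!r}"
            ) from None
    for i in p.oxidized_positions:
        masses[i] += OXIDATION_DELTA
    return masses


def _pyro_glu_delta(p: Peptidoform) -> float:
    if not p.pyro_glu:
        return 0.0
    return (PYRO_GLU_FROM_Q_DELTA if p.sequence[0] == "Q"
            else PYRO_GLU_FROM_E_DELTA)


def monoisotopic_mass(p: Peptidoform) -> float:
    """Neutral monoisotopic mass of a peptidoform in Da."""
    mass = float(_residue_masses(p).sum()) + WATER_MASS
    mass += _pyro_glu_delta(p)
    if p.c_term_amidated:
        mass += AMIDATION_DELTA
    return mass


def fragment_mz(p: Peptidoform, max_frag_charge: int = 1) -> FragmentSet:
    """Theoretical singly/multiply protonated b and y ion m/z values.

    b_i covers the i N-terminal residues (pyro-glu applies here); y_i covers
    the i C-terminal residues plus water (amidation applies here). Charged
    variants are (m + (z-1)*proton)/z of the singly charged ion.
    """
    if len(p.sequence) < 2:
        raise ValueError("fragmentation requires length >= 2")
    if max_frag_charge < 1:
        raise ValueError("max_frag_charge must be >= 1")
    res = _residue_masses(p)
    prefix = np.cumsum(res)[:-1]                       # b_1 .. b_{n-1}
    suffix = np.cumsum(res[::-1])[:-1]                 # y_1 .. y_{n-1}
    b1 = prefix + _pyro_glu_delta(p) + PROTON_MASS
    y1 = suffix + WATER_MASS + PROTON_MASS
    if p.c_term_amidated:
        y1 = y1 + AMIDATION_DELTA
    b = {1: b1}
    y = {1: y1}
    for z in range(2, max_frag_charge + 1):
        b[z] = (b1 + (z - 1) * PROTON_MASS) / z
        y[z] = (y1 + (z - 1) * PROTON_MASS) / z
    return FragmentSet(b=b, y=y)


def fragment_charges_for_precursor(precursor_charge: int) -> tuple[int, ...]:
    """Fragment charges to consider: 1 and 2 for precursors of charge >= 2."""
    return (1, 2) if precursor_charge >= 2 else (1,)


def match_peaks(
    s: Spectrum, theoretical_mz: np.ndarray | "FragmentSet", tol: float = 0.02
) -> np.ndarray:
    """Intensity of the nearest observed peak within +-tol of each ion.

    Matching is non-exclusive: one observed peak may satisfy several
    theoretical ions. Distance ties go to the higher-intensity peak.
    Unmatched positions get 0.
    """
    if tol < 0:
        raise ValueError("tolerance must be non-negative")
    if isinstance(theoretical_mz, FragmentSet):
        theoretical_mz = theoretical_mz.vector_mz()
    theo = np.asarray(theoretical_mz, dtype=float)
    mz = s.peaks_mz
    inten = s.peaks_intensity
    out = np.zeros(len(theo))
    if len(mz) == 0:
        return out
    idx = np.searchsorted(mz, theo)
    for k, t in enumerate(theo):
        best_d = None
        best_i = 0.0
        for j in (idx[k] - 1, idx[k]):
            if 0 <= j < len(mz):
                d = abs(mz[j] - t)
                if d <= tol and (
                    best_d is None or d < best_d
                    or (d == best_d and inten[j] > best_i)
                ):
                    best_d, best_i = d, inten[j]
        out[k] = best_i
    return out


# ---------------------------------------------------------------------------
# MGF I/O (pyteomics-backed)
# ---------------------------------------------------------------------------

def _check_mgf_blocks(path: str) -> None:
    """Raise on unbalanced BEGIN IONS/END IONS with a line number."""
    open_line = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip().upper()
            if token == "BEGIN IONS":
                if open_line is not None:
                    raise ValueError(
                        f"{path}: BEGIN IONS at line {lineno} before block "
                        f"opened at line {open_line} was terminated"
                    )
                open_line = lineno
            elif token == "END IONS":
                if open_line is None:
                    raise ValueError(
                        f"{path}: END IONS without BEGIN IONS at line {lineno}"
                    )
                open_line = None
    if open_line is not None:
        raise ValueError(
            f"{path}: unterminated BEGIN IONS block opened at line {open_line}"
        )


def read_mgf(path: str) -> list[Spectrum]:
    """Read an MGF file into Spectrum objects.

    TITLE becomes the spectrum id; PEPMASS, CHARGE ('2+' dialect) and
    RTINSECONDS are mapped to the corresponding fields; any other header keys
    are kept in ``extra_params`` so a write/read round trip preserves them.
    """
    _check_mgf_blocks(path)
    spectra: list[Spectrum] = []
    with _pyteomics_mgf.MGF(path, convert_arrays=1) as reader:
        for entry in reader:
            params = dict(entry["params"])
            title = str(params.pop("title", f"spectrum_{len(spectra)}"))
            pepmass = params.pop("pepmass", (0.0,))
            precursor_mz = float(pepmass[0]) if pepmass else 0.0
            charge_val = params.pop("charge", None)
            charge = int(charge_val[0]) if charge_val else 0
            rt = params.pop("rtinseconds", None)
            rt = float(rt) if rt is not None else None
            inv_k0 = params.pop("1/k0", None)
            inv_k0 = float(inv_k0) if inv_k0 is not None else None
            extra = {str(k): str(v) for k, v in params.items()}
            spectra.append(
                Spectrum(
                    spectrum_id=title,
                    precursor_mz=precursor_mz,
                    precursor_charge=charge,
                    peaks_mz=entry["m/z array"],
                    peaks_intensity=entry["intensity array"],
                    rt=rt,
                    inv_k0=inv_k0,
                    extra_params=extra,
                )
            )
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str) -> None:
    """Write spectra as MGF; peaks are written with 6-decimal m/z."""
    entries = []
    for s in spectra:
        params: dict = {
            "TITLE": s.spectrum_id,
            "PEPMASS": s.precursor_mz,
        }
        if s.precursor_charge:
            params["CHARGE"] = f"{s.precursor_charge}+"
        if s.rt is not None:
            params["RTINSECONDS"] = s.rt
        if s.inv_k0 is not None:
            params["1/K0"] = s.inv_k0
        params.update({k.upper(): v for k, v in s.extra_params.items()})
        entries.append(
            {
                "params": params,
                "m/z array": s.peaks_mz,
                "intensity array": s.peaks_intensity,
            }
        )
    with open(path, "w") as fh:
        _pyteomics_mgf.write(entries, fh)
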