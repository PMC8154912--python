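"""Genetic code tables, substitution classes, amino-acid property scales,
and pairwise distortion matrices.

The distortion matrix ``d(aa_i, aa_j)`` assigns a non-negative cost to
mistranslating or mutating amino acid ``aa_i`` into ``aa_j`` on the scale
of one physicochemical property; synonymous changes cost zero.  Four scales
ship with the package (polar requirement, hydropathy, molecular volume,
isoelectric point), transcribed from the classic error-minimization
literature sources; see the headers of the TSV files under ``data/``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np

__all__ = [
    "STOP",
    "NUCLEOTIDES",
    "AMINO_ACIDS",
    "SENSE_CODONS",
    "STOP_CODONS",
    "ALL_CODONS",
    "SCALE_NAMES",
    "GeneticCode",
    "PropertyScale",
    "DistortionMatrix",
    "standard_code",
    "classify_substitution",
    "single_nt_neighbors",
    "build_distortion_matrix",
    "load_builtin_scale",
    "load_scale_tsv",
    "builtin_scales",
]

STOP = "*"
NUCLEOTIDES = ("A", "C", "G", "T")
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

SCALE_NAMES = (
    "polar_requirement",
    "hydropathy",
    "molecular_volume",
    "isoelectric_point",
)

# Standard genetic code (NCBI translation table 1), DNA alphabet.
_STANDARD_TABLE: dict[str, str] = {}
_BASES = "TCAG"
_AA_ORDER = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            _STANDARD_TABLE[_b1 + _b2 + _b3] = _AA_ORDER[16 * _i + 4 * _j + _k]

ALL_CODONS = tuple(sorted(_STANDARD_TABLE))
SENSE_CODONS = tuple(c for c in ALL_CODONS if _STANDARD_TABLE[c] != STOP)
STOP_CODONS = tuple(c for c in ALL_CODONS if _STANDARD_TABLE[c] == STOP)


def _validate_codon(codon: str) -> str:
    if not isinstance(codon, str) or len(codon) != 3 or any(b not in NUCLEOTIDES for b in codon):
        raise ValueError(f"not a valid ACGT codon: {codon!r}")
    return codon


@dataclass(frozen=True)
class GeneticCode:
    """Codon -> amino acid mapping; stop codons map to :data:`STOP`."""

    table: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.table) != 64 or set(self.table) != set(ALL_CODONS):
            raise ValueError("genetic code must map exactly the 64 ACGT codons")
        bad = {aa for aa in self.table.values() if aa != STOP and aa not in AMINO_ACIDS}
        if bad:
            raise ValueError(f"non-canonical amino acid symbols in code: {sorted(bad)}")

    def translate(self, codon: str) -> str:
        return self.table[_validate_codon(codon)]

    def is_stop(self, codon: str) -> bool:
        return self.translate(codon) == STOP

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if self.table[c] != STOP)

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if self.table[c] == STOP)

    def amino_acids(self) -> tuple[str, ...]:
        return tuple(sorted({aa for aa in self.table.values() if aa != STOP}))


def standard_code() -> GeneticCode:
    """Return the standard genetic code (61 sense codons, 3 stops)."""
    return GeneticCode(dict(_STANDARD_TABLE))


def classify_substitution(b_from: str, b_to: str) -> Literal["transition", "transversion"]:
    """Classify a single-nucleotide substitution.

    Transitions exchange bases within a chemical class (A<->G purines,
    C<->T pyrimidines); the remaining eight ordered pairs are transversions.
    """
    for b in (b_from, b_to):
        if b not in NUCLEOTIDES:
            raise ValueError(f"not an ACGT nucleotide: {b!r}")
    if b_from == b_to:
        raise ValueError(f"identical bases ({b_from}) are not a substitution")
    same_class = ({b_from, b_to} <= PURINES) or ({b_from, b_to} <= PYRIMIDINES)
    return "transition" if same_class else "transversion"


def single_nt_neighbors(codon: str) -> list[tuple[str, str]]:
    """All 9 codons one substitution away, with their substitution class.

    Every codon has exactly 3 transition neighbors (one per position) and
    6 transversion neighbors.
    """
    _validate_codon(codon)
    out = []
    for pos in range(3):
        for b in NUCLEOTIDES:
            if b == codon[pos]:
                continue
            neighbor = codon[:pos] + b + codon[pos + 1 :]
            out.append((neighbor, classify_substitution(codon[pos], b)))
    return out


@dataclass(frozen=True)
class PropertyScale:
    """One physicochemical property value per canonical amino acid."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name!r} missing amino acids: {sorted(missing)}")
        if any(v is None or not np.isfinite(v) for v in self.values.values()):
            raise ValueError(f"scale {self.name!r} has non-finite values")

    def __getitem__(self, aa: str) -> float:
        return float(self.values[aa])

    def shifted(self, c: float) -> "PropertyScale":
        return PropertyScale(self.name, {aa: v + c for aa, v in self.values.items()})

    def scaled(self, c: float) -> "PropertyScale":
        return PropertyScale(self.name, {aa: v * c for aa, v in self.values.items()})


@dataclass(frozen=True)
class DistortionMatrix:
    """Pairwise amino-acid cost d(aa_i, aa_j); zero on the diagonal."""

    scale_name: str
    amino_acids: tuple[str, ...]
    d: np.ndarray = field(repr=False)

    def cost(self, aa_i: str, aa_j: str) -> float:
        i = self.amino_acids.index(aa_i)
        j = self.amino_acids.index(aa_j)
        return float(self.d[i, j])

    @property
    def max_cost(self) -> float:
        return float(self.d.max())


def build_distortion_matrix(
    scale: PropertyScale,
    code: GeneticCode | None = None,
    form: Literal["squared", "absolute"] = "squared",
) -> DistortionMatrix:
    """Distortion matrix from a property scale.

    d(aa_i, aa_j) = (v_i - v_j)**2 by default (``form="squared"``), or
    |v_i - v_j| with ``form="absolute"``.  Either way d is symmetric,
    non-negative and zero for synonymous pairs.
    """
    if code is None:
        code = standard_code()
    aas = code.amino_acids()
    missing = set(aas) - set(scale.values)
    if missing:
        raise ValueError(f"scale {scale.name!r} lacks values for {sorted(missing)}")
    v = np.array([scale[aa] for aa in aas], dtype=float)
    diff = v[:, None] - v[None, :]
    if form == "squared":
        d = diff**2
    elif form == "absolute":
        d = np.abs(diff)
    else:
        raise ValueError(f"unknown distortion form: {form!r}")
    return DistortionMatrix(scale_name=scale.name, amino_acids=tuple(aas), d=d)


def load_scale_tsv(path: str | Path, name: str | None = None) -> PropertyScale:
    """Read a two-column (amino acid, value) TSV; '#' lines are comments."""
    path = Path(path)
    values: dict[str, float] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, val = line.split("\t")
        values[aa.strip()] = float(val)
    return PropertyScale(name or path.stem, values)


def load_builtin_scale(name: str) -> PropertyScale:
    if name not in SCALE_NAMES:
        raise ValueError(f"unknown scale {name!r}; built-ins are {SCALE_NAMES}")
    ref = importlib.resources.files("codefidelity.data") / f"{name}.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_scale_tsv(path, name)


def builtin_scales(names: Iterable[str] = SCALE_NAMES) -> list[PropertyScale]:
    """The four built-in scales, in canonical order by default."""
    return [load_builtin_scale(n) for n in names]
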