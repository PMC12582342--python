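"""Peptide elemental composition, natural isotope patterns and
deuterium-exchangeable hydrogen counts.

This is the chemistry layer underneath the turnover kinetics: the natural
(unlabelled) m0/m1 pattern of a peptide fixes its baseline relative
isotopomer abundance, and the number of deuterium-accessible C-H positions
(``N``) fixes how far that abundance can rise at a given precursor
enrichment.

Isotope patterns are computed at unit-mass resolution: isotopologues are
aggregated by nominal mass shift relative to the monoisotopic species, so
``pattern[1]`` is everything one nominal mass unit heavy (13C, 2H, 15N,
17O, 33S combined), which is what a low-resolution m0/m1 readout sees.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
from pyteomics import mass as _pmass

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: carbamidomethylation of cysteine, the usual fixed alkylation
CARBAMIDOMETHYL = {"C": 2, "H": 3, "N": 1, "O": 1}
#: oxidation (typically of methionine), the usual variable modification
OXIDATION = {"O": 1}

_ELEMENTS = ("C", "H", "N", "O", "S")


def _read_two_column(name: str) -> list[list[str]]:
    text = (
        importlib.resources.files("proteoturn.data").joinpath(name).read_text()
    )
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


def load_exchangeable_h_table(path=None) -> dict[str, float]:
    """Per-residue count of deuterium-accessible C-H positions.

    The bundled defaults are the Commerford-derived empirical values that
    are standard in D2O protein-turnover work; supply ``path`` (two-column
    residue/value TSV) to substitute your own table.
    """
    if path is None:
        rows = _read_two_column("exchangeable_h.tsv")
    else:
        with open(path) as fh:
            rows = [
                ln.strip().split("\t")
                for ln in fh
                if ln.strip() and not ln.startswith("#")
            ]
    table = {r[0]: float(r[1]) for r in rows}
    for v in table.values():
        if v < 0:
            raise ValueError("exchangeable-H counts must be non-negative")
    return table


def load_isotope_abundances(path=None) -> dict[str, np.ndarray]:
    """Element -> abundance vector indexed by nominal mass shift."""
    if path is None:
        rows = _read_two_column("isotope_abundances.tsv")
    else:
        with open(path) as fh:
            rows = [
                ln.strip().split("\t")
                for ln in fh
                if ln.strip() and not ln.startswith("#")
            ]
    by_el: dict[str, dict[int, float]] = {}
    for el, shift, ab in rows:
        by_el.setdefault(el, {})[int(shift)] = float(ab)
    out = {}
    for el, shifts in by_el.items():
        vec = np.zeros(max(shifts) + 1)
        for s, a in shifts.items():
            vec[s] = a
        out[el] = vec / vec.sum()
    return out


@dataclass(frozen=True)
class PeptideSpec:
    """A peptide sequence plus its modifications.

    fixed_mods are (residue_letter, formula_delta) pairs applied at every
    occurrence of the residue; variable_mods are (position, formula_delta)
    pairs applied at specific (0-based) positions. charge is metadata only.
    """

    sequence: str
    fixed_mods: tuple = (("C", tuple(sorted(CARBAMIDOMETHYL.items()))),)
    variable_mods: tuple = ()
    charge: int = 2

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        for i, aa in enumerate(self.sequence):
            if aa not in STANDARD_RESIDUES:
                raise ValueError(
                    f"unknown residue {aa!r} at position {i} in "
                    f"{self.sequence!r}"
                )
        for pos, _ in self.variable_mods:
            if not 0 <= pos < len(self.sequence):
                raise ValueError(
                    f"variable modification position {pos} outside sequence "
                    f"of length {len(self.sequence)}"
                )


@dataclass(frozen=True)
class ElementalComposition:
    """Integer atom counts over C, H, N, O, S."""

    counts: tuple

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "ElementalComposition":
        for el, n in d.items():
            if n < 0:
                raise ValueError(f"negative count for element {el}")
        return cls(tuple((el, int(d.get(el, 0))) for el in _ELEMENTS))

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        a, b = self.as_dict(), other.as_dict()
        return ElementalComposition.from_dict(
            {el: a.get(el, 0) + b.get(el, 0) for el in _ELEMENTS}
        )

    @property
    def n_atoms(self) -> int:
        return sum(n for _, n in self.counts)


WATER = ElementalComposition.from_dict({"H": 2, "O": 1})


@dataclass
class IsotopePattern:
    """Relative abundances of mass isotopomers m0..mK (truncated)."""

    abundances: np.ndarray = field(default_factory=lambda: np.array([1.0]))

    @property
    def m0(self) -> float:
        return float(self.abundances[0])

    @property
    def m1(self) -> float:
        return float(self.abundances[1]) if len(self.abundances) > 1 else 0.0

    def normalized(self) -> "IsotopePattern":
        return IsotopePattern(self.abundances / self.abundances.sum())

    def natural_ria(self) -> float:
        """Baseline m1/(m0+m1) of the unlabelled peptide."""
        return self.m1 / (self.m0 + self.m1)


def composition_from_sequence(spec: PeptideSpec) -> ElementalComposition:
    """Elemental composition: residue formulas + one water + mod deltas."""
    comp = WATER
    fixed = {res: dict(delta) for res, delta in spec.fixed_mods}
    for aa in spec.sequence:
        pa = _pmass.std_aa_comp[aa]
        comp = comp + ElementalComposition.from_dict(dict(pa))
        if aa in fixed:
            comp = comp + ElementalComposition.from_dict(fixed[aa])
    for _, delta in spec.variable_mods:
        comp = comp + ElementalComposition.from_dict(dict(delta))
    return comp


def natural_isotope_pattern(
    comp: ElementalComposition,
    order: int = 4,
    abundances: dict[str, np.ndarray] | None = None,
) -> IsotopePattern:
    """Natural isotope pattern of a composition by polynomial convolution.

    Each atom contributes its element's abundance vector (indexed by nominal
    mass shift); the molecular pattern is the convolution of all of them,
    truncated at ``order`` heavy shifts. Truncation discards mass, so the
    result sums to slightly less than 1; use ``.normalized()`` when a
    probability vector is needed.
    """
    if order < 1:
        raise ValueError("truncation order must be >= 1")
    ab = abundances if abundances is not None else load_isotope_abundances()
    pattern = np.zeros(order + 1)
    pattern[0] = 1.0
    for el, n in comp.counts:
        if n == 0:
            continue
        el_vec = ab[el][: order + 1]
        # convolve n identical atoms in O(log n) doublings
        el_pow = np.zeros(order + 1)
        el_pow[0] = 1.0
        base = el_vec.copy()
        k = n
        while k:
            if k & 1:
                el_pow = np.convolve(el_pow, base)[: order + 1]
            k >>= 1
            if k:
                base = np.convolve(base, base)[: order + 1]
        pattern = np.convolve(pattern, el_pow)[: order + 1]
    return IsotopePattern(pattern)


def exchangeable_h_count(
    sequence: str, table: dict[str, float] | None = None
) -> float:
    """Total deuterium-accessible C-H positions N of a peptide.

    Additive over residues; modifications contribute nothing (their
    hydrogens are not placed by cytosolic amino-acid metabolism).
    """
    if table is None:
        table = load_exchangeable_h_table()
    total = 0.0
    for i, aa in enumerate(sequence):
        if aa not in table:
            raise KeyError(
                f"residue {aa!r} at position {i} missing from "
                "exchangeable-H table"
            )
        total += table[aa]
    return total
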