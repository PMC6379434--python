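"""Glycerophospholipid formula assembly, monoisotopic [M-H]- masses, and
accurate-mass annotation of screened markers.

Species are written in the standard shorthand nomenclature, e.g.
``PA(16:0_18:1)`` (sn-positions unresolved, ``_``), ``PE(18:1/18:1)``
(resolved, ``/``), ``PE(P-18:1/18:1)`` (plasmalogen / alkenyl ether chain),
``PE(O-18:2/18:1)`` (alkyl ether chain).  A P- chain is isomeric with the
O- chain carrying one more counted double bond, so both shorthands map to
one elemental formula and are reported together as a dual assignment.

Formula assembly
----------------
glycerophosphate core C3H9O6P, plus per chain
  acyl(c:d)      + C_c H_{2c-2d-2} O        (esterified fatty acid)
  alkyl O-(c:d)  + C_c H_{2c-2d}            (ether)
  alkenyl P-(c:d) = O-(c:d+1)               (vinyl ether)
plus the head-group increment
  PA +0, PE +C2H5N, PS +C3H5NO2, PI +C6H10O5,
  PIP +C6H10O5 +HPO3, PIP2 +C6H10O5 +2 HPO3.

The deprotonated ion mass is neutral - proton, where the proton mass is an
H atom minus an electron; including the electron mass is required to land
monoisotopic [M-H]- values at the 4th decimal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

# ---------------------------------------------------------------------------
# constants (IUPAC/CODATA monoisotopic masses, Da)
# ---------------------------------------------------------------------------

MONOISOTOPIC_MASS: Dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
}
ELECTRON_MASS: float = 0.000548579909
PROTON_MASS: float = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS

ACYL = "acyl"
ALKYL = "alkyl"     # O- prefix
ALKENYL = "alkenyl"  # P- prefix (plasmalogen)

_HEADGROUPS: Dict[str, Dict[str, int]] = {
    "PA": {},
    "PE": {"C": 2, "H": 5, "N": 1},
    "PS": {"C": 3, "H": 5, "N": 1, "O": 2},
    "PI": {"C": 6, "H": 10, "O": 5},
    "PIP": {"C": 6, "H": 11, "O": 8, "P": 1},
    "PIP2": {"C": 6, "H": 12, "O": 11, "P": 2},
}


@dataclass(frozen=True)
class ElementalFormula:
    """Non-negative element counts over C, H, N, O, P."""

    counts: Tuple[Tuple[str, int], ...]

    @staticmethod
    def from_dict(d: Dict[str, int]) -> "ElementalFormula":
        clean = {el: int(n) for el, n in d.items() if n}
        if any(n < 0 for n in clean.values()):
            raise ValueError(f"negative element count in {d}")
        unknown = set(clean) - set(MONOISOTOPIC_MASS)
        if unknown:
            raise ValueError(f"unknown elements {unknown}")
        order = ["C", "H", "N", "O", "P"]
        return ElementalFormula(tuple((el, clean[el]) for el in order if el in clean))

    def as_dict(self) -> Dict[str, int]:
        return dict(self.counts)

    @property
    def monoisotopic_mass(self) -> float:
        return sum(MONOISOTOPIC_MASS[el] * n for el, n in self.counts)

    def __str__(self) -> str:
        return "".join(f"{el}{n}" if n > 1 else el for el, n in self.counts)


@dataclass(frozen=True)
class Chain:
    carbons: int
    double_bonds: int
    linkage: str = ACYL

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValueError("chain needs at least 2 carbons")
        if self.double_bonds < 0:
            raise ValueError("double bond count must be non-negative")
        if self.linkage not in (ACYL, ALKYL, ALKENYL):
            raise ValueError(f"unknown linkage {self.linkage!r}")


@dataclass(frozen=True)
class LipidSpecies:
    """A glycerophospholipid at chain-composition level.

    ``chain_level`` records whether sn-positions are resolved ("/") or not
    ("_"); it affects the printed name only, never the mass.
    """

    lipid_class: str
    chains: Tuple[Chain, ...]
    chain_level: str = "unresolved"

    def __post_init__(self) -> None:
        if self.lipid_class not in _HEADGROUPS:
            raise ValueError(f"unknown lipid class {self.lipid_class!r}")
        if not 1 <= len(self.chains) <= 2:
            raise ValueError("1 or 2 chains supported")
        ethers = sum(c.linkage in (ALKYL, ALKENYL) for c in self.chains)
        if ethers > 1:
            raise ValueError("at most one ether-linked chain")
        if self.chain_level not in ("resolved", "unresolved"):
            raise ValueError("chain_level must be resolved or unresolved")

    @property
    def name(self) -> str:
        sep = "/" if self.chain_level == "resolved" else "_"
        parts = []
        for c in self.chains:
            prefix = {ACYL: "", ALKYL: "O-", ALKENYL: "P-"}[c.linkage]
            parts.append(f"{prefix}{c.carbons}:{c.double_bonds}")
        return f"{self.lipid_class}({sep.join(parts)})"

    def __str__(self) -> str:
        return self.name


_CHAIN_RE = re.compile(r"^(?P<prefix>[OP]-)?(?P<c>\d+):(?P<d>\d+)$")
_NAME_RE = re.compile(r"^(?P<cls>[A-Za-z0-9]+)\((?P<chains>[^)]+)\)$")


def parse_lipid(name: str) -> LipidSpecies:
    """Parse shorthand such as ``PS(18:0_22:6)`` or ``PE(P-18:1/18:1)``."""
    m = _NAME_RE.match(name.strip())
    if not m:
        raise ValueError(f"cannot parse lipid shorthand {name!r}")
    cls = m.group("cls").upper()
    body = m.group("chains")
    level = "resolved" if "/" in body else "unresolved"
    chains = []
    for part in re.split(r"[/_]", body):
        cm = _CHAIN_RE.match(part.strip())
        if not cm:
            raise ValueError(f"cannot parse chain {part!r} in {name!r}")
        linkage = {"O-": ALKYL, "P-": ALKENYL, None: ACYL}[cm.group("prefix")]
        chains.append(Chain(int(cm.group("c")), int(cm.group("d")), linkage))
    return LipidSpecies(cls, tuple(chains), chain_level=level)


# ---------------------------------------------------------------------------
# formula and mass
# ---------------------------------------------------------------------------

def formula_of(sp: LipidSpecies) -> ElementalFormula:
    """Elemental formula from the assembly rules in the module docstring."""
    counts = {"C": 3, "H": 9, "N": 0, "O": 6, "P": 1}  # glycerophosphate core
    for el, n in _HEADGROUPS[sp.lipid_class].items():
        counts[el] = counts.get(el, 0) + n
    for ch in sp.chains:
        c, d = ch.carbons, ch.double_bonds
        if ch.linkage == ACYL:
            add = {"C": c, "H": 2 * c - 2 * d - 2, "O": 1}
        elif ch.linkage == ALKYL:
            add = {"C": c, "H": 2 * c - 2 * d}
        else:  # alkenyl P- == alkyl O- with one more double bond
            add = {"C": c, "H": 2 * c - 2 * (d + 1)}
        for el, n in add.items():
            counts[el] = counts.get(el, 0) + n
    return ElementalFormula.from_dict(counts)


def monoisotopic_mz(sp: LipidSpecies, adduct: str = "[M-H]-") -> float:
    """Monoisotopic m/z of the deprotonated ion (full float precision;
    report rounded to 4 decimals)."""
    if adduct != "[M-H]-":
        raise ValueError("only the [M-H]- adduct is supported")
    return formula_of(sp).monoisotopic_mass - PROTON_MASS


def ppm_error(measured: float, theoretical: float) -> float:
    """|theoretical - measured| / theoretical x 1e6 (report to 1 decimal)."""
    if measured <= 0 or theoretical <= 0:
        raise ValueError("masses must be positive")
    return abs(theoretical - measured) / theoretical * 1e6


# ---------------------------------------------------------------------------
# candidate matching
# ---------------------------------------------------------------------------

@dataclass
class AnnotatedMarker:
    """A measured marker m/z with its candidate species (isomers grouped)."""

    measured_mz: float
    species: List[LipidSpecies]
    theoretical_mz: float
    ppm: float
    adduct: str = "[M-H]-"
    auc: Optional[float] = None

    @property
    def assignment(self) -> str:
        return " | ".join(sp.name for sp in self.species)


def match_peaks(
    markers: Sequence[float],
    panel: Sequence[LipidSpecies],
    tol_ppm: float,
    aucs: Optional[Sequence[float]] = None,
) -> List[List[AnnotatedMarker]]:
    """For each measured marker m/z, all panel species whose [M-H]- mass lies
    within ``tol_ppm``, sorted by |ppm|.  Species with identical elemental
    formulas (e.g. a P- chain and its O- isomer) are merged into one dual
    assignment.  Returns one (possibly empty) candidate list per marker.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    # group panel species by formula so isomers collapse to one candidate
    by_formula: Dict[ElementalFormula, List[LipidSpecies]] = {}
    for sp in panel:
        by_formula.setdefault(formula_of(sp), []).append(sp)
    candidates = [
        (f.monoisotopic_mass - PROTON_MASS, sps) for f, sps in by_formula.items()
    ]
    out: List[List[AnnotatedMarker]] = []
    for i, measured in enumerate(markers):
        hits = []
        for theo, sps in candidates:
            err = ppm_error(measured, theo)
            if err <= tol_ppm:
                hits.append(
                    AnnotatedMarker(
                        measured_mz=float(measured),
                        species=list(sps),
                        theoretical_mz=theo,
                        ppm=err,
                        auc=None if aucs is None else float(aucs[i]),
                    )
                )
        hits.sort(key=lambda h: h.ppm)
        out.append(hits)
    return out


def annotation_table(annotated: Sequence[List[AnnotatedMarker]]):
    """Flatten match_peaks output into a DataFrame mirroring a marker report:
    measured m/z, theoretical m/z (4 dp), ppm (1 dp), assignment, AUC."""
    import pandas as pd

    rows = []
    for hits in annotated:
        for h in hits:
            rows.append(
                {
                    "measured_mz": round(h.measured_mz, 4),
                    "theoretical_mz": round(h.theoretical_mz, 4),
                    "ppm": round(h.ppm, 1),
                    "adduct": h.adduct,
                    "assignment": h.assignment,
                    "auc": h.auc,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["measured_mz", "theoretical_mz", "ppm", "adduct", "assignment", "auc"],
    )
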