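"""Exact-mass arithmetic and structural templates for polar lipids and pigments.

Monoisotopic masses of elemental formulas, single-charge adduct ion m/z
(electron mass included), fatty-acyl chain formulas, and whole-species
formulas assembled from class templates (headgroup backbone + esterified
chains). Class templates and the pigment catalog are shipped as an editable
YAML config (``data/classes.yaml``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import yaml

__all__ = [
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "ElementalFormula",
    "AcylChain",
    "Adduct",
    "PROTON_ADDUCT",
    "SODIUM_ADDUCT",
    "RegioRule",
    "NeutralLoss",
    "LipidClassTemplate",
    "LipidSpecies",
    "Pigment",
    "LipidConfig",
    "monoisotopic_mass",
    "ion_mz",
    "acyl_formula",
    "species_formula",
    "acyl_loss_fragment_mz",
    "rdbe",
    "load_config",
]

# IUPAC 2021 monoisotopic masses (lightest stable isotope), Da.
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "Cu": 62.9295975,
    "Mg": 23.9850417,
    "P": 30.97376163,
}

ELECTRON_MASS = 0.00054857990907  # Da

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class UnknownElementError(KeyError):
    """Raised for an element symbol without a tabulated monoisotopic mass."""


class ElementalFormula:
    """Immutable element -> count mapping with +/- arithmetic.

    Counts are strictly positive for present elements; subtraction that
    would drive any count below zero raises ``ValueError``.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Optional[Mapping[str, int]] = None):
        clean: dict[str, int] = {}
        for sym, n in (counts or {}).items():
            n = int(n)
            if n < 0:
                raise ValueError(f"negative count for element {sym}")
            if n > 0:
                clean[sym] = n
        self._counts = clean

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse a Hill-style string like ``'C43H68O10'`` or ``'H2O'``."""
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(text.strip()):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            pos = m.end()
            sym = m.group(1)
            counts[sym] = counts.get(sym, 0) + (int(m.group(2)) if m.group(2) else 1)
        if pos != len(text.strip()):
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(counts)

    @property
    def counts(self) -> Mapping[str, int]:
        return dict(self._counts)

    def __getitem__(self, sym: str) -> int:
        return self._counts.get(sym, 0)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        out = dict(self._counts)
        for sym, n in other._counts.items():
            out[sym] = out.get(sym, 0) + n
        return ElementalFormula(out)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        out = dict(self._counts)
        for sym, n in other._counts.items():
            new = out.get(sym, 0) - n
            if new < 0:
                raise ValueError(
                    f"subtraction drives element {sym} below zero "
                    f"({out.get(sym, 0)} - {n})"
                )
            if new == 0:
                out.pop(sym, None)
            else:
                out[sym] = new
        return ElementalFormula(out)

    def __mul__(self, k: int) -> "ElementalFormula":
        return ElementalFormula({s: n * k for s, n in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ElementalFormula) and self._counts == other._counts

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def __bool__(self) -> bool:
        return bool(self._counts)

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        def key(sym: str):
            return {"C": (0, ""), "H": (1, "")}.get(sym, (2, sym))

        return "".join(
            f"{s}{n if n != 1 else ''}"
            for s, n in sorted(self._counts.items(), key=lambda kv: key(kv[0]))
        )

    def __repr__(self) -> str:
        return f"ElementalFormula({self!s})"


H2O = ElementalFormula.parse("H2O")
TRIMETHYLAMINE = ElementalFormula.parse("C3H9N")  # the 59 Da betaine neutral loss


def monoisotopic_mass(formula: ElementalFormula) -> float:
    """Monoisotopic (lightest stable isotope) mass of a neutral formula, Da."""
    total = 0.0
    for sym, n in formula.counts.items():
        try:
            total += MONOISOTOPIC_MASS[sym] * n
        except KeyError:
            raise UnknownElementError(
                f"no monoisotopic mass tabulated for element {sym!r}"
            ) from None
    return total


@dataclass(frozen=True)
class Adduct:
    """Singly charged positive-mode adduct: M + added formula - one electron."""

    name: str
    added: ElementalFormula
    charge: int = 1

    def __post_init__(self):
        if self.charge != 1:
            raise ValueError("only +1 adducts are supported (positive ESI)")


PROTON_ADDUCT = Adduct("[M+H]+", ElementalFormula.parse("H"))
SODIUM_ADDUCT = Adduct("[M+Na]+", ElementalFormula.parse("Na"))
BARE_CATION = Adduct("[M]+", ElementalFormula({}))  # loss of one electron only

ADDUCTS: Mapping[str, Adduct] = {
    a.name: a for a in (PROTON_ADDUCT, SODIUM_ADDUCT, BARE_CATION)
}


def ion_mz(neutral: ElementalFormula, adduct: Adduct) -> float:
    """m/z of the singly charged cation; the electron mass is subtracted.

    The electron term matters at the instrument's ppm-level mass accuracy:
    the Cu(CH3CN)2+ lock mass 144.9821 is only reproduced when it is kept.
    """
    if adduct.charge != 1:
        raise ValueError("only +1 adducts are supported")
    return (
        monoisotopic_mass(neutral) + monoisotopic_mass(adduct.added) - ELECTRON_MASS
    ) / adduct.charge


@dataclass(frozen=True, order=True)
class AcylChain:
    """Fatty acyl chain in C:db notation (e.g. 18:3)."""

    carbons: int
    double_bonds: int

    def __post_init__(self):
        if self.carbons < 2:
            raise ValueError(f"acyl chain needs >= 2 carbons, got {self.carbons}")
        if not (0 <= self.double_bonds <= self.carbons // 2):
            raise ValueError(
                f"double bonds {self.double_bonds} outside [0, {self.carbons // 2}]"
                f" for a C{self.carbons} chain"
            )

    @classmethod
    def parse(cls, text: str) -> "AcylChain":
        c, d = text.split(":")
        return cls(int(c), int(d))

    def __str__(self) -> str:
        return f"{self.carbons}:{self.double_bonds}"


def acyl_formula(chain: AcylChain) -> ElementalFormula:
    """Free fatty acid formula CnH(2n-2d)O2 of an acyl chain."""
    return ElementalFormula(
        {"C": chain.carbons, "H": 2 * chain.carbons - 2 * chain.double_bonds, "O": 2}
    )


@dataclass(frozen=True)
class RegioRule:
    """Which adduct's acyl-loss fragments rank the sn positions.

    ``sn1_more_intense`` True means the sn-1 loss fragment [M+X-R1CO2H]+ is
    the more intense of the pair (galactolipid/sulfolipid convention); False
    means the sn-2 loss dominates (betaine convention).
    """

    adduct_name: str
    sn1_more_intense: bool


@dataclass(frozen=True)
class NeutralLoss:
    """Characteristic class neutral loss; formula-based or nominal-mass window."""

    name: str
    formula: Optional[ElementalFormula] = None
    nominal_mass: Optional[float] = None
    required: bool = True  # catalogued-but-unobserved losses set this False

    @property
    def mass(self) -> float:
        if self.formula is not None:
            return monoisotopic_mass(self.formula)
        assert self.nominal_mass is not None
        return self.nominal_mass


@dataclass(frozen=True)
class LipidClassTemplate:
    """Structural template of a lipid class.

    ``backbone`` is the headgroup + glycerol (or sphingoid base) with free
    hydroxyls at every acyl position; esterification removes one H2O per
    occupied position.
    """

    name: str
    backbone: ElementalFormula
    n_acyl: int
    regio_rule: Optional[RegioRule] = None
    neutral_losses: Sequence[NeutralLoss] = field(default_factory=tuple)
    lineage: Optional[str] = None  # 'green' / 'brown' restriction, betaines
    smiles: Optional[str] = None  # backbone structure used for validation

    def __post_init__(self):
        if self.n_acyl not in (1, 2):
            raise ValueError("acyl positions must be 1 or 2")


@dataclass(frozen=True)
class LipidSpecies:
    """A concrete lipid: class template plus sn-1 (and sn-2) acyl chains."""

    template: LipidClassTemplate
    sn1: AcylChain
    sn2: Optional[AcylChain] = None

    def __post_init__(self):
        if (self.sn2 is None) != (self.template.n_acyl == 1):
            raise ValueError(
                f"{self.template.name} has {self.template.n_acyl} acyl position(s); "
                f"sn2 must be {'absent' if self.template.n_acyl == 1 else 'present'}"
            )

    @property
    def chains(self) -> tuple[AcylChain, ...]:
        return (self.sn1,) if self.sn2 is None else (self.sn1, self.sn2)

    @property
    def label(self) -> str:
        return f"{self.template.name} " + "/".join(str(c) for c in self.chains)

    def __str__(self) -> str:
        return self.label


def species_formula(species: LipidSpecies) -> ElementalFormula:
    """Neutral formula: backbone + sum of free fatty acids - one H2O per ester."""
    total = species.template.backbone
    for chain in species.chains:
        total = total + acyl_formula(chain) - H2O
    return total


def acyl_loss_fragment_mz(species: LipidSpecies, adduct: Adduct, position: int) -> float:
    """m/z of the [M+X-RCO2H]+ fragment after loss of the free fatty acid."""
    if position not in (1, 2):
        raise ValueError("position must be 1 or 2")
    chain = species.sn1 if position == 1 else species.sn2
    if chain is None:
        raise ValueError(
            f"{species.label} has no acyl chain at sn-{position} (lyso form)"
        )
    return ion_mz(species_formula(species), adduct) - monoisotopic_mass(
        acyl_formula(chain)
    )


def rdbe(formula: ElementalFormula) -> float:
    """Ring-plus-double-bond equivalents: C - H/2 + N/2 + 1 (O, S neutral)."""
    return formula["C"] - formula["H"] / 2 + formula["N"] / 2 + 1


@dataclass(frozen=True)
class Pigment:
    """Named pigment with a fixed elemental formula (no chain combinatorics)."""

    name: str
    formula: ElementalFormula
    rule: Optional[str] = None  # 'dehydration_series' | 'loss_80' | 'diagnostics'
    diagnostic_mz: Sequence[float] = field(default_factory=tuple)
    unverified: bool = False


@dataclass
class LipidConfig:
    """Parsed class-template + pigment catalog with engine parameters."""

    templates: dict[str, LipidClassTemplate]
    pigments: dict[str, Pigment]
    chain_carbons: tuple[int, int] = (12, 24)
    chain_double_bonds: tuple[int, int] = (0, 6)
    precursor_tol_ppm: float = 3.0
    fragment_tol_ppm: float = 10.0
    fragment_tol_da: float = 0.005
    regio_ratio_threshold: float = 1.2
    nominal_loss_window_da: float = 0.5
    dehydration_min_losses: int = 2
    diagnostics_min_matches: int = 2

    def fragment_tolerance(self, mz: float) -> float:
        """Absolute fragment window: max(ppm-scaled, fixed Da floor)."""
        return max(self.fragment_tol_ppm * 1e-6 * mz, self.fragment_tol_da)


def _parse_neutral_loss(entry: Mapping) -> NeutralLoss:
    formula = (
        ElementalFormula.parse(entry["formula"]) if entry.get("formula") else None
    )
    return NeutralLoss(
        name=entry["name"],
        formula=formula,
        nominal_mass=entry.get("nominal_mass"),
        required=entry.get("required", True),
    )


def load_config(path: Optional[str] = None) -> LipidConfig:
    """Load class templates and the pigment catalog from YAML.

    Without ``path`` the packaged default (``data/classes.yaml``) is used.
    Pigment entries with a null formula are skipped (catalog stubs).
    """
    if path is None:
        text = (
            resources.files("chemoclock").joinpath("data/classes.yaml").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)

    templates: dict[str, LipidClassTemplate] = {}
    for entry in raw["classes"]:
        rule = None
        if entry.get("regio_rule"):
            rr = entry["regio_rule"]
            rule = RegioRule(rr["adduct"], rr["more_intense"] == "sn1")
        templates[entry["name"]] = LipidClassTemplate(
            name=entry["name"],
            backbone=ElementalFormula.parse(entry["backbone"]),
            n_acyl=int(entry["acyl_positions"]),
            regio_rule=rule,
            neutral_losses=tuple(
                _parse_neutral_loss(nl) for nl in entry.get("neutral_losses", [])
            ),
            lineage=entry.get("lineage"),
            smiles=entry.get("smiles"),
        )

    pigments: dict[str, Pigment] = {}
    for entry in raw["pigments"]:
        if not entry.get("formula"):
            continue
        pigments[entry["name"]] = Pigment(
            name=entry["name"],
            formula=ElementalFormula.parse(entry["formula"]),
            rule=entry.get("rule"),
            diagnostic_mz=tuple(entry.get("diagnostic_mz", [])),
            unverified=entry.get("unverified", False),
        )

    params = raw.get("parameters", {})
    cfg = LipidConfig(templates=templates, pigments=pigments)
    for key in (
        "precursor_tol_ppm",
        "fragment_tol_ppm",
        "fragment_tol_da",
        "regio_ratio_threshold",
        "nominal_loss_window_da",
        "dehydration_min_losses",
        "diagnostics_min_matches",
    ):
        if key in params:
            setattr(cfg, key, type(getattr(cfg, key))(params[key]))
    if "chain_carbons" in params:
        cfg.chain_carbons = tuple(params["chain_carbons"])
    if "chain_double_bonds" in params:
        cfg.chain_double_bonds = tuple(params["chain_double_bonds"])
    return cfg
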