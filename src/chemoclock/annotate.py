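"""Rule engine turning MS2 spectra into lipid/pigment annotations.

Implements the identification logic used for the 12-strain study: raw-formula
matching of the precursor against the class-template chain space and pigment
catalog, acyl-chain decomposition, sn-regiochemistry from the relative
intensity of the two acyl-loss fragments, the 59 Da trimethylamine loss for
betaine confirmation with lineage-prior DGTS/DGTA disambiguation, and
xanthophyll isomer rules (prasinoxanthin dehydration series, violaxanthin
80 Da loss, fucoxanthin diagnostic ions).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .chem import (
    ADDUCTS,
    Adduct,
    AcylChain,
    LipidClassTemplate,
    LipidConfig,
    LipidSpecies,
    Pigment,
    MONOISOTOPIC_MASS,
    acyl_formula,
    acyl_loss_fragment_mz,
    ion_mz,
    load_config,
    monoisotopic_mass,
    species_formula,
)

__all__ = [
    "Ms2Spectrum",
    "FragmentIon",
    "RegioResult",
    "Annotation",
    "LineagePrior",
    "match_candidates",
    "decompose_acyls",
    "assign_regiochemistry",
    "classify_betaine",
    "classify_xanthophyll",
    "annotate",
    "read_mgf",
    "write_mgf",
    "read_peaklist_csv",
    "annotations_to_tsv",
]

INSTRUMENT_MZ_RANGE = (133.4, 2000.0)
WATER_MASS = 18.0105646863


def _tma_mass() -> float:
    """Monoisotopic mass of the 59 Da trimethylamine neutral loss."""
    from .chem import TRIMETHYLAMINE

    return monoisotopic_mass(TRIMETHYLAMINE)


@dataclass
class Ms2Spectrum:
    """Precursor plus fragment peak list.

    ``peaks`` is an (n, 2) array of (m/z, intensity), kept sorted by m/z;
    the precursor must sit inside the instrument acquisition range.
    """

    precursor_mz: float
    peaks: np.ndarray
    rt_min: Optional[float] = None
    adduct_hint: Optional[str] = None
    spectrum_id: Optional[str] = None

    def __post_init__(self):
        peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        if peaks.size and np.any(peaks[:, 1] < 0):
            raise ValueError("fragment intensities must be >= 0")
        self.peaks = peaks[np.argsort(peaks[:, 0])] if peaks.size else peaks
        lo, hi = INSTRUMENT_MZ_RANGE
        if not (lo <= self.precursor_mz <= hi):
            raise ValueError(
                f"precursor m/z {self.precursor_mz} outside instrument range {lo}-{hi}"
            )

    def match_peak(self, target_mz: float, tol_da: float) -> Optional[tuple[float, float]]:
        """Most intense peak within ``tol_da`` of ``target_mz``, or None."""
        if not self.peaks.size:
            return None
        mzs = self.peaks[:, 0]
        lo = np.searchsorted(mzs, target_mz - tol_da, side="left")
        hi = np.searchsorted(mzs, target_mz + tol_da, side="right")
        if hi <= lo:
            return None
        window = self.peaks[lo:hi]
        best = window[np.argmax(window[:, 1])]
        return float(best[0]), float(best[1])


@dataclass(frozen=True)
class FragmentIon:
    """A matched fragment with its interpreted role."""

    observed_mz: float
    intensity: float
    role: str  # 'sn1-loss' | 'sn2-loss' | 'acyl-loss' | 'neutral-loss-...' | 'diagnostic'
    theoretical_mz: float
    ppm_error: float

    def as_dict(self) -> dict:
        return {
            "mz": round(self.observed_mz, 5),
            "intensity": self.intensity,
            "role": self.role,
            "theoretical_mz": round(self.theoretical_mz, 5),
            "ppm": round(self.ppm_error, 2),
        }


@dataclass
class RegioResult:
    """Outcome of the intensity-ordering regiochemistry rule.

    ``status`` is relative to the candidate's given chain order: 'assigned'
    when the spectrum supports the order as given, 'swapped' when it supports
    the reverse, 'ambiguous' otherwise (missing fragment, tie within the
    ratio threshold, or no rule for the adduct).
    """

    status: str
    sn1: Optional[AcylChain]
    sn2: Optional[AcylChain]
    evidence: list[FragmentIon] = field(default_factory=list)
    reason: Optional[str] = None


@dataclass
class Annotation:
    """Best interpretation of one spectrum."""

    label: str
    species: Optional[LipidSpecies] = None
    pigment: Optional[str] = None
    adduct: Optional[str] = None
    regio_status: str = "ambiguous"
    tier: int = 0  # 0 none < 1 formula-only < 2 class+chains < 3 +regiochemistry
    evidence: list[FragmentIon] = field(default_factory=list)
    lineage_prior_used: bool = False
    precursor_ppm: Optional[float] = None
    co_annotations: list[str] = field(default_factory=list)
    note: Optional[str] = None


@dataclass
class LineagePrior:
    """Strain -> lineage label ('green' or 'brown').

    Encodes the phylogenetic prior that DGTS occurs in the green lineage
    while DGTA is restricted to the brown (haptophyte/stramenopile) algae.
    """

    labels: Mapping[str, str]

    def label(self, strain: str) -> Optional[str]:
        return self.labels.get(strain)


# ---------------------------------------------------------------------------
# Candidate enumeration
# ---------------------------------------------------------------------------


def _composition_table(config: LipidConfig):
    """Cached (mass-sorted) table of class composition masses.

    Rows are (neutral mass, template name, total carbons, total double
    bonds); 2-acyl classes are tabulated on summed-chain compositions,
    1-acyl classes per chain.
    """
    cached = getattr(config, "_composition_table", None)
    if cached is not None:
        return cached
    cmin, cmax = config.chain_carbons
    dmin, dmax = config.chain_double_bonds
    mH = MONOISOTOPIC_MASS["H"]
    mC = MONOISOTOPIC_MASS["C"]
    mO = MONOISOTOPIC_MASS["O"]
    rows: list[tuple[float, str, int, int]] = []
    for name, tpl in config.templates.items():
        backbone_mass = monoisotopic_mass(tpl.backbone)
        if tpl.n_acyl == 1:
            for c in range(cmin, cmax + 1):
                for d in range(dmin, min(dmax, c // 2) + 1):
                    mass = backbone_mass + c * mC + (2 * c - 2 * d - 2) * mH + mO
                    rows.append((mass, name, c, d))
        else:
            for tc in range(2 * cmin, 2 * cmax + 1):
                for td in range(2 * dmin, 2 * dmax + 1):
                    if not decompose_acyls(tpl, tc, td, config):
                        continue
                    mass = backbone_mass + tc * mC + (2 * tc - 2 * td - 4) * mH + 2 * mO
                    rows.append((mass, name, tc, td))
    rows.sort(key=lambda r: r[0])
    table = (
        np.array([r[0] for r in rows]),
        [(r[1], r[2], r[3]) for r in rows],
    )
    config._composition_table = table
    return table


def decompose_acyls(
    template: LipidClassTemplate,
    total_carbons: int,
    total_double_bonds: int,
    config: Optional[LipidConfig] = None,
    chain_carbons: Optional[tuple[int, int]] = None,
    chain_double_bonds: Optional[tuple[int, int]] = None,
) -> list[tuple[AcylChain, AcylChain]]:
    """All unordered chain pairs summing to the given totals.

    Pairs are canonically ordered (smaller chain first by (carbons, db)) and
    deduplicated; an empty list means the composition has no valid split
    inside the configured chain space.
    """
    if chain_carbons is None:
        chain_carbons = config.chain_carbons if config else (12, 24)
    if chain_double_bonds is None:
        chain_double_bonds = config.chain_double_bonds if config else (0, 6)
    cmin, cmax = chain_carbons
    dmin, dmax = chain_double_bonds
    pairs = []
    for c1 in range(cmin, total_carbons // 2 + 1):
        c2 = total_carbons - c1
        if not (cmin <= c2 <= cmax) or c2 < c1:
            continue
        for d1 in range(dmin, min(dmax, c1 // 2) + 1):
            d2 = total_double_bonds - d1
            if not (dmin <= d2 <= min(dmax, c2 // 2)):
                continue
            if c1 == c2 and d2 < d1:
                continue  # unordered: keep one representative
            pairs.append((AcylChain(c1, d1), AcylChain(c2, d2)))
    return pairs


Candidate = tuple[Union[LipidSpecies, Pigment], Adduct]


def match_candidates(
    precursor_mz: float,
    adducts: Sequence[Adduct],
    tol_ppm: float,
    config: LipidConfig,
) -> list[Candidate]:
    """Exhaustive precursor match over the template chain space and pigments.

    Every returned candidate's theoretical ion m/z lies within ``tol_ppm`` of
    the precursor; 2-acyl compositions are expanded into all isomeric chain
    splits (canonical order).
    """
    if not adducts:
        raise ValueError("adduct set must not be empty")
    if tol_ppm <= 0:
        raise ValueError("tolerance must be > 0")
    masses, rows = _composition_table(config)
    out: list[Candidate] = []
    tol_da = tol_ppm * 1e-6 * precursor_mz
    for adduct in adducts:
        shift = monoisotopic_mass(adduct.added) - 0.00054857990907
        target = precursor_mz - shift  # neutral mass window
        if masses.size:
            lo = np.searchsorted(masses, target - tol_da, side="left")
            hi = np.searchsorted(masses, target + tol_da, side="right")
            for idx in range(lo, hi):
                name, c, d = rows[idx]
                tpl = config.templates[name]
                if tpl.n_acyl == 1:
                    out.append((LipidSpecies(tpl, AcylChain(c, d)), adduct))
                else:
                    for ch1, ch2 in decompose_acyls(tpl, c, d, config):
                        out.append((LipidSpecies(tpl, ch1, ch2), adduct))
        for pigment in config.pigments.values():
            theo = ion_mz(pigment.formula, adduct)
            if abs(theo - precursor_mz) <= tol_ppm * 1e-6 * theo:
                out.append((pigment, adduct))
    return out


# ---------------------------------------------------------------------------
# Evidence rules
# ---------------------------------------------------------------------------


def _match_fragment(
    spectrum: Ms2Spectrum, theo_mz: float, role: str, config: LipidConfig
) -> Optional[FragmentIon]:
    hit = spectrum.match_peak(theo_mz, config.fragment_tolerance(theo_mz))
    if hit is None:
        return None
    mz, inten = hit
    return FragmentIon(mz, inten, role, theo_mz, (mz - theo_mz) / theo_mz * 1e6)


def assign_regiochemistry(
    spectrum: Ms2Spectrum,
    species: LipidSpecies,
    adduct: Adduct,
    config: LipidConfig,
) -> RegioResult:
    """Order the two acyl chains from acyl-loss fragment intensities.

    Searches both [M+X-RCO2H]+ fragments at the fragment tolerance. If both
    are found, the class rule's intensity ordering decides which chain sits
    at sn-1; the larger/smaller intensity ratio must reach the configured
    ambiguity threshold. The decision is invariant under uniform intensity
    scaling (it only uses the ratio).
    """
    tpl = species.template
    if tpl.n_acyl != 2 or species.sn2 is None:
        raise ValueError("regiochemistry needs two acyl positions")
    rule = tpl.regio_rule
    if rule is None or rule.adduct_name != adduct.name:
        return RegioResult(
            "ambiguous", None, None,
            reason=f"no regiochemistry rule for {tpl.name} {adduct.name}",
        )
    frag1 = _match_fragment(
        spectrum, acyl_loss_fragment_mz(species, adduct, 1), "sn1-loss", config
    )
    frag2 = _match_fragment(
        spectrum, acyl_loss_fragment_mz(species, adduct, 2), "sn2-loss", config
    )
    evidence = [f for f in (frag1, frag2) if f is not None]
    if frag1 is None or frag2 is None:
        return RegioResult(
            "ambiguous", None, None, evidence, reason="acyl-loss fragment missing"
        )
    if species.sn1 == species.sn2:
        return RegioResult("assigned", species.sn1, species.sn2, evidence)
    hi, lo = max(frag1.intensity, frag2.intensity), min(frag1.intensity, frag2.intensity)
    if lo == 0 and hi == 0:
        return RegioResult("ambiguous", None, None, evidence, reason="zero intensities")
    if lo > 0 and hi / lo < config.regio_ratio_threshold:
        return RegioResult(
            "ambiguous", None, None, evidence,
            reason=f"intensity ratio {hi / lo:.3g} below threshold",
        )
    # Which loss fragment should dominate for the chain order as given?
    sn1_loss_dominates = frag1.intensity > frag2.intensity
    as_given = sn1_loss_dominates == rule.sn1_more_intense
    if as_given:
        return RegioResult("assigned", species.sn1, species.sn2, evidence)
    return RegioResult("swapped", species.sn2, species.sn1, evidence)


def classify_betaine(
    spectrum: Ms2Spectrum,
    species: LipidSpecies,
    adduct: Adduct,
    strain: Optional[str],
    prior: Optional[LineagePrior],
    config: LipidConfig,
) -> tuple[str, bool, list[FragmentIon]]:
    """Resolve the mass-isomeric DGTS/DGTA pair.

    Betaine confirmation requires the 59 Da trimethylamine neutral loss; the
    class is then decided by the strain's lineage (DGTS in the green lineage,
    DGTA in the brown algae). Returns (class name or 'undetermined',
    lineage_prior_used, evidence).
    """
    theo = ion_mz(species_formula(species), adduct) - _tma_mass()
    frag = _match_fragment(spectrum, theo, "neutral-loss-59", config)
    if frag is None:
        return "undetermined", False, []
    label = prior.label(strain) if (prior is not None and strain is not None) else None
    if label == "green":
        return "DGTS", True, [frag]
    if label == "brown":
        return "DGTA", True, [frag]
    return "undetermined", False, [frag]


def classify_xanthophyll(
    spectrum: Ms2Spectrum,
    candidates: Sequence[tuple[Pigment, Adduct]],
    config: LipidConfig,
) -> tuple[Optional[Pigment], list[FragmentIon], list[str]]:
    """Disambiguate isomeric pigments by their fragmentation rules.

    prasinoxanthin: >= ``dehydration_min_losses`` successive water losses;
    violaxanthin: nominal 80 Da loss within the configured window;
    fucoxanthin: >= ``diagnostics_min_matches`` of its diagnostic m/z.
    Returns (winner or None, evidence, isomer names considered).
    """
    names = [p.name for p, _ in candidates]
    best: Optional[Pigment] = None
    best_evidence: list[FragmentIon] = []
    for pigment, adduct in candidates:
        evidence: list[FragmentIon] = []
        fired = False
        if pigment.rule == "dehydration_series":
            series = []
            n = 1
            while True:
                frag = _match_fragment(
                    spectrum, spectrum.precursor_mz - n * WATER_MASS,
                    f"dehydration-{n}", config,
                )
                if frag is None:
                    break
                series.append(frag)
                n += 1
            if len(series) >= config.dehydration_min_losses:
                fired = True
                evidence = series
        elif pigment.rule == "loss_80":
            target = spectrum.precursor_mz - 80.0
            hit = spectrum.match_peak(target, config.nominal_loss_window_da)
            if hit is not None:
                fired = True
                evidence = [
                    FragmentIon(hit[0], hit[1], "neutral-loss-80", target,
                                (hit[0] - target) / target * 1e6)
                ]
        elif pigment.rule == "diagnostics":
            hits = [
                f
                for mz in pigment.diagnostic_mz
                if (f := _match_fragment(spectrum, mz, "diagnostic", config))
            ]
            if len(hits) >= config.diagnostics_min_matches:
                fired = True
                evidence = hits
        if fired and len(evidence) > len(best_evidence):
            best, best_evidence = pigment, evidence
    return best, best_evidence, names


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def _score_lipid(
    spectrum: Ms2Spectrum,
    species: LipidSpecies,
    adduct: Adduct,
    strain: Optional[str],
    prior: Optional[LineagePrior],
    config: LipidConfig,
) -> Annotation:
    tpl = species.template
    evidence: list[FragmentIon] = []
    theo_precursor = ion_mz(species_formula(species), adduct)
    ppm = (spectrum.precursor_mz - theo_precursor) / theo_precursor * 1e6

    for pos in range(1, tpl.n_acyl + 1):
        frag = _match_fragment(
            spectrum,
            acyl_loss_fragment_mz(species, adduct, pos),
            f"sn{pos}-loss" if tpl.n_acyl == 2 else "acyl-loss",
            config,
        )
        if frag is not None:
            evidence.append(frag)
    for nl in tpl.neutral_losses:
        if not nl.required:
            continue
        if nl.formula is not None:
            frag = _match_fragment(
                spectrum, theo_precursor - nl.mass, f"neutral-loss-{nl.name}", config
            )
        else:
            target = theo_precursor - nl.mass
            hit = spectrum.match_peak(target, config.nominal_loss_window_da)
            frag = (
                FragmentIon(hit[0], hit[1], f"neutral-loss-{nl.name}", target,
                            (hit[0] - target) / target * 1e6)
                if hit
                else None
            )
        if frag is not None and all(
            abs(frag.observed_mz - e.observed_mz) > 1e-9 for e in evidence
        ):
            evidence.append(frag)

    ann = Annotation(
        label=species.label,
        species=species,
        adduct=adduct.name,
        evidence=evidence,
        precursor_ppm=ppm,
    )

    # Lineage-prior resolution of the mass-isomeric betaine pair.
    if tpl.name in ("DGTS", "DGTA") and tpl.n_acyl == 2:
        cls, used, extra = classify_betaine(
            spectrum, species, adduct, strain, prior, config
        )
        ann.lineage_prior_used = used
        if cls == "undetermined":
            ann.note = "betaine class undetermined (59 Da loss or lineage missing)"
            if not extra:  # trimethylamine loss absent: betaine not confirmed
                ann.tier = 1 if evidence == [] else 1
                ann.label = f"DGTA|DGTS {'/'.join(str(c) for c in species.chains)}"
                ann.species = None
                return ann
            ann.label = f"DGTA|DGTS {'/'.join(str(c) for c in species.chains)}"
        elif cls != tpl.name:
            # Evidence points to the isomeric class: relabel.
            other = config.templates[cls]
            species = LipidSpecies(other, species.sn1, species.sn2)
            ann.species = species
            ann.label = species.label

    if tpl.n_acyl == 2:
        regio = assign_regiochemistry(spectrum, species, adduct, config)
        if regio.status in ("assigned", "swapped") and regio.sn1 is not None:
            ordered = LipidSpecies(species.template, regio.sn1, regio.sn2)
            ann.species = ordered
            if not ann.label.startswith("DGTA|DGTS"):
                ann.label = ordered.label
            # chains are reported in the evidence-supported sn order
            ann.regio_status = "assigned"
            ann.tier = 3
        else:
            ann.regio_status = "ambiguous"
            ann.tier = 2 if evidence else 1
        for f in regio.evidence:
            if all(abs(f.observed_mz - e.observed_mz) > 1e-9 or f.role != e.role
                   for e in ann.evidence):
                ann.evidence.append(f)
    else:
        ann.regio_status = "n/a"
        ann.tier = 2 if evidence else 1
    return ann


def annotate(
    spectrum: Ms2Spectrum,
    strain: Optional[str] = None,
    prior: Optional[LineagePrior] = None,
    config: Optional[LipidConfig] = None,
) -> Annotation:
    """Annotate one spectrum: candidates -> evidence scoring -> best hit.

    Ranking is (matched fragments desc, regiochemistry resolved first,
    |precursor ppm| asc); surviving ties are reported as co-annotations.
    Deterministic given the configuration.
    """
    if config is None:
        config = load_config()
    adducts = (
        [ADDUCTS[spectrum.adduct_hint]]
        if spectrum.adduct_hint
        else [ADDUCTS["[M+H]+"], ADDUCTS["[M+Na]+"]]
    )
    candidates = match_candidates(
        spectrum.precursor_mz, adducts, config.precursor_tol_ppm, config
    )
    if not candidates:
        return Annotation(label="unknown", tier=0)

    scored: list[Annotation] = []
    pigment_cands = [(o, a) for o, a in candidates if isinstance(o, Pigment)]
    lipid_cands = [(o, a) for o, a in candidates if isinstance(o, LipidSpecies)]

    for species, adduct in lipid_cands:
        scored.append(_score_lipid(spectrum, species, adduct, strain, prior, config))

    if pigment_cands:
        winner, evidence, isomers = classify_xanthophyll(spectrum, pigment_cands, config)
        if winner is not None:
            theo = ion_mz(winner.formula, pigment_cands[0][1])
            scored.append(
                Annotation(
                    label=winner.name,
                    pigment=winner.name,
                    adduct=next(a.name for p, a in pigment_cands if p is winner),
                    regio_status="n/a",
                    tier=2,
                    evidence=evidence,
                    precursor_ppm=(spectrum.precursor_mz - theo) / theo * 1e6,
                )
            )
        else:
            # No rule fired: formula-level hit, isomers listed.
            pigment, adduct = pigment_cands[0]
            theo = ion_mz(pigment.formula, adduct)
            unique = len({p.name for p, _ in pigment_cands}) == 1
            scored.append(
                Annotation(
                    label=pigment.name if unique else "|".join(sorted(set(isomers))),
                    pigment=pigment.name if unique else None,
                    adduct=adduct.name,
                    regio_status="n/a",
                    tier=2 if unique else 1,
                    precursor_ppm=(spectrum.precursor_mz - theo) / theo * 1e6,
                    note=None if unique else "isomeric pigments unresolved",
                )
            )

    def rank_key(a: Annotation):
        return (
            -len(a.evidence),
            0 if a.regio_status in ("assigned", "swapped") else 1,
            abs(a.precursor_ppm) if a.precursor_ppm is not None else np.inf,
            a.label,  # deterministic final tie-break
        )

    scored.sort(key=rank_key)
    best = scored[0]
    if len(best.evidence) == 0 and best.tier <= 1:
        # Pure formula match with no structural evidence at all.
        if not any(len(a.evidence) for a in scored):
            best.co_annotations = [a.label for a in scored[1:6] if a.label != best.label]
            return best
    best.co_annotations = [
        a.label
        for a in scored[1:]
        if rank_key(a)[:3] == rank_key(best)[:3] and a.label != best.label
    ]
    return best


# ---------------------------------------------------------------------------
# I/O: MGF, CSV peak lists, TSV annotations
# ---------------------------------------------------------------------------


def read_mgf(path: str) -> list[Ms2Spectrum]:
    """Read spectra from a standard MGF file (PEPMASS, RTINSECONDS)."""
    from pyteomics import mgf

    spectra = []
    with mgf.MGF(path) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            rt = params.get("rtinseconds")
            spectra.append(
                Ms2Spectrum(
                    precursor_mz=float(params["pepmass"][0]),
                    peaks=np.column_stack(
                        [entry["m/z array"], entry["intensity array"]]
                    ),
                    rt_min=float(rt) / 60.0 if rt is not None else None,
                    spectrum_id=params.get("title", f"spectrum_{i}"),
                )
            )
    return spectra


def write_mgf(spectra: Iterable[Ms2Spectrum], path: str) -> None:
    """Write spectra as MGF (BEGIN IONS/END IONS blocks)."""
    from pyteomics import mgf

    entries = []
    for i, s in enumerate(spectra):
        params = {"pepmass": s.precursor_mz, "title": s.spectrum_id or f"spectrum_{i}"}
        if s.rt_min is not None:
            params["rtinseconds"] = s.rt_min * 60.0
        entries.append(
            {
                "params": params,
                "m/z array": s.peaks[:, 0] if s.peaks.size else np.array([]),
                "intensity array": s.peaks[:, 1] if s.peaks.size else np.array([]),
            }
        )
    mgf.write(entries, path, file_mode="w")


def read_peaklist_csv(path: str) -> list[Ms2Spectrum]:
    """Read the documented CSV peak-list dialect.

    Columns: spectrum_id, precursor_mz, rt_min, mz, intensity — one row per
    fragment peak, grouped by spectrum_id (file order preserved).
    """
    groups: dict[str, dict] = {}
    order: list[str] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            sid = row["spectrum_id"]
            if sid not in groups:
                groups[sid] = {
                    "precursor_mz": float(row["precursor_mz"]),
                    "rt_min": float(row["rt_min"]) if row.get("rt_min") else None,
                    "peaks": [],
                }
                order.append(sid)
            groups[sid]["peaks"].append((float(row["mz"]), float(row["intensity"])))
    return [
        Ms2Spectrum(
            precursor_mz=g["precursor_mz"],
            peaks=np.array(g["peaks"]),
            rt_min=g["rt_min"],
            spectrum_id=sid,
        )
        for sid, g in ((sid, groups[sid]) for sid in order)
    ]


def annotations_to_tsv(
    annotations: Sequence[tuple[Ms2Spectrum, Annotation]], path: str
) -> None:
    """One row per spectrum: label, adduct, tier, regio status, evidence JSON."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["spectrum_id", "precursor_mz", "rt_min", "label", "adduct", "tier",
             "regio_status", "lineage_prior_used", "co_annotations", "evidence"]
        )
        for spectrum, ann in annotations:
            writer.writerow(
                [
                    spectrum.spectrum_id or "",
                    f"{spectrum.precursor_mz:.5f}",
                    "" if spectrum.rt_min is None else f"{spectrum.rt_min:.3f}",
                    ann.label,
                    ann.adduct or "",
                    ann.tier,
                    ann.regio_status,
                    int(ann.lineage_prior_used),
                    ";".join(ann.co_annotations),
                    json.dumps([e.as_dict() for e in ann.evidence]),
                ]
            )
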