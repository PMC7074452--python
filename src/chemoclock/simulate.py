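"""Simulation of metabolome evolution along a phylogeny, and of the LC-MS
measurement process, so every pipeline stage is testable end to end.

The model: metabolite presence evolves by Poisson gain/loss events along
branches; log-abundances of present metabolites follow Brownian motion
(variance per unit branch length); clade markers are forced present in their
clade and absent elsewhere. Measurement renders each metabolite at a fixed
(m/z, RT) identity with multiplicative lognormal noise, sub-tolerance m/z-RT
jitter, medium-only blank features, and optional bacterial-contamination
admixture drawn from a shared bacterial feature pool. MS2 fixture spectra
are generated as the exact inverse of the annotation rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .annotate import Ms2Spectrum
from .chem import (
    ADDUCTS,
    Adduct,
    LipidConfig,
    LipidSpecies,
    Pigment,
    ion_mz,
    load_config,
    monoisotopic_mass,
    species_formula,
    acyl_loss_fragment_mz,
)
from .features import ChromatographicRun
from .chemotax import PhyloTree

__all__ = [
    "EvolutionParams",
    "SimulatedStudy",
    "FIXTURE_TREE_NEWICK",
    "FIXTURE_LINEAGE",
    "FIXTURE_CLADES",
    "fixture_tree",
    "simulate_tree",
    "evolve_metabolome",
    "render_runs",
    "simulate_study",
    "generate_ms2_fixture",
    "contamination_scenario_params",
]


def _rng(seed: Optional[int] = None, rng: Optional[np.random.Generator] = None):
    return rng if rng is not None else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

# Fixed 12-strain fixture tree mirroring the study design: a Mamiellales
# clade (two O. tauri strains, O. mediterraneus, B. prasinos, M. commoda,
# Mantoniella), the Chlorellales P. costavermella, basal Chlorophytes
# (two Nephroselmis strains, Pyramimonas), and a brown outgroup
# (P. tricornutum, P. lutheri). Branch lengths in substitutions/site.
FIXTURE_TREE_NEWICK = (
    "((((((O_tauri_1:0.010,O_tauri_2:0.010):0.020,O_mediterraneus:0.030):0.050,"
    "B_prasinos:0.080):0.020,(M_commoda:0.070,Mantoniella_sp:0.070):0.030):0.150,"
    "(P_costavermella:0.200,((Nephroselmis_A:0.020,Nephroselmis_B:0.020):0.100,"
    "Pyramimonas_sp:0.120):0.080):0.050):0.300,"
    "(P_tricornutum:0.250,P_lutheri:0.250):0.350);"
)

FIXTURE_LINEAGE: Mapping[str, str] = {
    "O_tauri_1": "green", "O_tauri_2": "green", "O_mediterraneus": "green",
    "B_prasinos": "green", "M_commoda": "green", "Mantoniella_sp": "green",
    "P_costavermella": "green", "Nephroselmis_A": "green",
    "Nephroselmis_B": "green", "Pyramimonas_sp": "green",
    "P_tricornutum": "brown", "P_lutheri": "brown",
}

FIXTURE_CLADES: Mapping[str, tuple[str, ...]] = {
    "mamiellales": ("O_tauri_1", "O_tauri_2", "O_mediterraneus", "B_prasinos",
                    "M_commoda", "Mantoniella_sp"),
    "chlorellales": ("P_costavermella",),
    "basal_chlorophytes": ("Nephroselmis_A", "Nephroselmis_B", "Pyramimonas_sp"),
    "outgroup": ("P_tricornutum", "P_lutheri"),
}


def fixture_tree() -> PhyloTree:
    return PhyloTree.from_newick(FIXTURE_TREE_NEWICK)


def simulate_tree(
    n_taxa: int,
    seed: Optional[int] = None,
    birth_rate: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> PhyloTree:
    """Pure-birth (Yule) tree: exponential waiting times, uniform splits.

    Branch lengths are in the same units as the birth rate's inverse;
    deterministic given the seed.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    gen = _rng(seed, rng)

    class _Node:
        __slots__ = ("birth", "children", "label", "end")

        def __init__(self, birth):
            self.birth = birth
            self.children = []
            self.label = None
            self.end = None

    root = _Node(0.0)
    a, b = _Node(0.0), _Node(0.0)
    root.children = [a, b]
    leaves = [a, b]
    t = 0.0
    while True:
        t += gen.exponential(1.0 / (birth_rate * len(leaves)))
        if len(leaves) == n_taxa:
            break
        i = int(gen.integers(len(leaves)))
        parent = leaves[i]
        parent.end = t
        c1, c2 = _Node(t), _Node(t)
        parent.children = [c1, c2]
        leaves[i] = c1
        leaves.append(c2)
    for k, lf in enumerate(leaves):
        lf.end = t
        lf.label = f"t{k + 1}"

    def newick(node) -> str:
        if not node.children:
            return f"{node.label}:{node.end - node.birth:.10g}"
        inner = ",".join(newick(c) for c in node.children)
        length = "" if node is root else f":{node.end - node.birth:.10g}"
        return f"({inner}){length}"

    return PhyloTree.from_newick(newick(root) + ";")


# ---------------------------------------------------------------------------
# Metabolome evolution
# ---------------------------------------------------------------------------


@dataclass
class EvolutionParams:
    """Study conditions for the simulated metabolomes.

    Gain/loss rates are whole-metabolome Poisson event rates per unit branch
    length; log-abundance diffuses with ``bm_var`` per unit branch length;
    ``noise_cv`` is the multiplicative (lognormal) measurement coefficient
    of variation per replicate.
    """

    n_ancestral: int = 300
    gain_rate: float = 5.0
    loss_rate: float = 5.0
    bm_var: float = 1.0
    noise_cv: float = 0.2
    replicates: int = 3
    # clade name -> number of forced lineage markers; clades maps names to leaves
    markers: Mapping[str, int] = field(default_factory=dict)
    clades: Mapping[str, Sequence[str]] = field(default_factory=dict)
    # strain -> fraction of its features that are bacterial-only
    contamination: Mapping[str, float] = field(default_factory=dict)
    bacterial_pool: int = 300
    n_medium: int = 30
    n_blank_reps: int = 2
    n_qc: int = 1
    # abundance scales (natural-log); areas span orders of magnitude
    ancestral_log_mean: float = math.log(5e7)
    ancestral_log_sd: float = 1.5
    marker_log_mean: float = math.log(8e8)
    marker_log_sd: float = 0.3
    bacterial_log_mean: float = math.log(1e7)
    bacterial_log_sd: float = 0.8
    medium_log_mean: float = math.log(2e7)
    medium_log_sd: float = 0.8
    # rendering jitter, within half the grouping tolerances
    mz_jitter_ppm: float = 1.5
    rt_jitter_min: float = 0.05
    mz_range: tuple[float, float] = (250.0, 1200.0)
    rt_range: tuple[float, float] = (2.2, 17.8)

    def __post_init__(self):
        if min(self.gain_rate, self.loss_rate, self.bm_var, self.noise_cv) < 0:
            raise ValueError("rates, variance and CV must be >= 0")
        for strain, f in self.contamination.items():
            if not 0 <= f <= 1:
                raise ValueError(f"contamination fraction for {strain} outside [0,1]")


@dataclass
class SimulatedStudy:
    """Ground truth of one simulated study."""

    tree: PhyloTree
    truth: pd.DataFrame          # metabolites x strains, true abundance (0 = absent)
    marker_ids: list[str]
    bacterial: pd.DataFrame      # bacterial pool x strains (0 where clean)
    medium_levels: pd.Series     # medium feature -> true level
    params: EvolutionParams
    identities: Optional[pd.DataFrame] = None  # assigned by render_runs


def evolve_metabolome(
    tree: PhyloTree,
    params: EvolutionParams,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedStudy:
    """Evolve presence and log-abundance along the tree.

    Presence: Poisson(gain_rate * L) gains of brand-new metabolites and
    Poisson(loss_rate * L) losses of uniformly chosen present ones per
    branch. Abundance: Brownian motion of the natural-log abundance with
    variance ``bm_var * L``. Deterministic given the seed.
    """
    gen = _rng(seed, rng)
    counter = [0]

    def new_ids(k: int) -> list[str]:
        ids = [f"M{counter[0] + i:05d}" for i in range(k)]
        counter[0] += k
        return ids

    ancestral = new_ids(params.n_ancestral)
    root_state = {
        mid: params.ancestral_log_mean + params.ancestral_log_sd * gen.standard_normal()
        for mid in ancestral
    }

    leaf_states: dict[str, dict[str, float]] = {}

    def walk(node, state: dict[str, float]):
        for child in node.child_nodes():
            L = float(child.edge.length or 0.0)
            s = dict(state)
            if L > 0:
                n_gain = gen.poisson(params.gain_rate * L)
                for mid in new_ids(int(n_gain)):
                    s[mid] = (
                        params.ancestral_log_mean
                        + params.ancestral_log_sd * gen.standard_normal()
                    )
                n_loss = min(int(gen.poisson(params.loss_rate * L)), len(s))
                if n_loss:
                    drop = gen.choice(sorted(s), size=n_loss, replace=False)
                    for mid in drop:
                        del s[mid]
                if s and params.bm_var > 0:
                    step = math.sqrt(params.bm_var * L)
                    keys = sorted(s)
                    moves = gen.standard_normal(len(keys)) * step
                    for mid, dv in zip(keys, moves):
                        s[mid] += dv
            if child.is_leaf():
                leaf_states[child.taxon.label] = s
            else:
                walk(child, s)

    walk(tree.tree.seed_node, root_state)
    strains = tree.leaf_labels

    # lineage markers: forced present in their clade, absent elsewhere
    marker_ids: list[str] = []
    marker_abund: dict[str, dict[str, float]] = {}
    for clade, k in params.markers.items():
        members = params.clades.get(clade)
        if members is None:
            raise ValueError(f"marker clade {clade!r} has no leaf list in params.clades")
        for _ in range(int(k)):
            mid = f"K{len(marker_ids):03d}_{clade}"
            marker_ids.append(mid)
            base = params.marker_log_mean + params.marker_log_sd * gen.standard_normal()
            marker_abund[mid] = {
                s: base + params.marker_log_sd * gen.standard_normal()
                for s in members
            }

    all_ids = sorted({mid for s in leaf_states.values() for mid in s}) + marker_ids
    truth = pd.DataFrame(0.0, index=all_ids, columns=strains)
    for strain, s in leaf_states.items():
        for mid, logv in s.items():
            truth.loc[mid, strain] = math.exp(logv)
    for mid in marker_ids:
        for strain, logv in marker_abund[mid].items():
            truth.loc[mid, strain] = math.exp(logv)

    # shared bacterial pool; contaminated strains carry a prefix of it
    bact_ids = [f"B{i:04d}" for i in range(params.bacterial_pool)]
    pool_base = params.bacterial_log_mean + params.bacterial_log_sd * gen.standard_normal(
        params.bacterial_pool
    )
    bacterial = pd.DataFrame(0.0, index=bact_ids, columns=strains)
    for strain, frac in params.contamination.items():
        if strain not in truth.columns:
            raise ValueError(f"contaminated strain {strain!r} not a tree leaf")
        n_algal = int((truth[strain] > 0).sum())
        n_bact = min(int(round(frac * n_algal / max(1e-9, 1 - frac))),
                     params.bacterial_pool) if frac < 1 else params.bacterial_pool
        for i in range(n_bact):
            # per-strain wobble around the shared pool level (same bacteria)
            bacterial.iloc[i, bacterial.columns.get_loc(strain)] = math.exp(
                pool_base[i] + 0.3 * gen.standard_normal()
            )

    medium_ids = [f"X{i:03d}" for i in range(params.n_medium)]
    medium = pd.Series(
        np.exp(
            params.medium_log_mean
            + params.medium_log_sd * gen.standard_normal(params.n_medium)
        ),
        index=medium_ids,
    )

    return SimulatedStudy(
        tree=tree,
        truth=truth,
        marker_ids=marker_ids,
        bacterial=bacterial,
        medium_levels=medium,
        params=params,
    )


# ---------------------------------------------------------------------------
# Rendering runs
# ---------------------------------------------------------------------------


def _assign_identities(
    ids: Sequence[str], params: EvolutionParams, gen: np.random.Generator
) -> pd.DataFrame:
    """Fixed (m/z, RT) identity per metabolite, pairwise separable under the
    grouping tolerances (distinct in m/z by >4x ppm tolerance or in RT)."""
    mzs: list[float] = []
    rts: list[float] = []
    for _ in ids:
        for _attempt in range(1000):
            mz = gen.uniform(*params.mz_range)
            rt = gen.uniform(*params.rt_range)
            ok = all(
                abs(mz - m) / m > 12e-6 or abs(rt - r) > 0.25
                for m, r in zip(mzs, rts)
            )
            if ok:
                break
        else:
            raise RuntimeError("could not place a separable feature identity")
        mzs.append(mz)
        rts.append(rt)
    return pd.DataFrame({"mz": mzs, "rt_min": rts}, index=pd.Index(ids, name="metabolite"))


def render_runs(
    study: SimulatedStudy,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[ChromatographicRun]:
    """Render replicate algal runs, blanks and a QC from the ground truth.

    area = true abundance x lognormal(CV) noise; m/z and RT jitter stay
    within half the grouping tolerances so grouping can round-trip the true
    metabolite count. Blanks carry medium-only features; contaminated
    strains additionally carry their bacterial features. Medium background
    is present in every run at its blank level.
    """
    params = study.params
    gen = _rng(seed, rng)
    all_ids = (
        list(study.truth.index)
        + list(study.bacterial.index)
        + list(study.medium_levels.index)
    )
    ident = _assign_identities(all_ids, params, gen)
    study.identities = ident

    sigma = math.sqrt(math.log(1.0 + params.noise_cv**2))

    def noisy(true_area: float) -> float:
        if sigma == 0:
            return true_area
        return float(true_area * np.exp(gen.standard_normal() * sigma - sigma**2 / 2))

    def jitter(mid: str) -> tuple[float, float]:
        mz, rt = ident.loc[mid, "mz"], ident.loc[mid, "rt_min"]
        if params.mz_jitter_ppm > 0:
            mz = mz * (1 + gen.uniform(-params.mz_jitter_ppm, params.mz_jitter_ppm) * 1e-6)
        if params.rt_jitter_min > 0:
            rt = rt + gen.uniform(-params.rt_jitter_min, params.rt_jitter_min)
        return float(mz), float(rt)

    runs: list[ChromatographicRun] = []
    strains = list(study.truth.columns)
    for strain in strains:
        present = study.truth.index[study.truth[strain] > 0]
        bact = study.bacterial.index[study.bacterial[strain] > 0]
        for rep in range(1, params.replicates + 1):
            rows = []
            for mid in present:
                mz, rt = jitter(mid)
                rows.append((mz, rt, noisy(float(study.truth.loc[mid, strain]))))
            for mid in bact:
                mz, rt = jitter(mid)
                rows.append((mz, rt, noisy(float(study.bacterial.loc[mid, strain]))))
            for mid, level in study.medium_levels.items():
                mz, rt = jitter(mid)
                rows.append((mz, rt, noisy(float(level))))
            runs.append(
                ChromatographicRun(
                    sample_id=f"{strain}_r{rep}",
                    role="algal",
                    strain=strain,
                    replicate=rep,
                    features=pd.DataFrame(rows, columns=["mz", "rt_min", "area"]),
                )
            )
    for rep in range(1, params.n_blank_reps + 1):
        rows = []
        for mid, level in study.medium_levels.items():
            mz, rt = jitter(mid)
            rows.append((mz, rt, noisy(float(level))))
        runs.append(
            ChromatographicRun(
                sample_id=f"blank_r{rep}",
                role="blank",
                strain=None,
                replicate=rep,
                features=pd.DataFrame(rows, columns=["mz", "rt_min", "area"]),
            )
        )
    qc_truth = study.truth.mean(axis=1)
    for rep in range(1, params.n_qc + 1):
        rows = []
        for mid, level in qc_truth[qc_truth > 0].items():
            mz, rt = jitter(mid)
            rows.append((mz, rt, noisy(float(level))))
        for mid, level in study.medium_levels.items():
            mz, rt = jitter(mid)
            rows.append((mz, rt, noisy(float(level))))
        runs.append(
            ChromatographicRun(
                sample_id=f"QC_r{rep}",
                role="QC",
                strain=None,
                replicate=rep,
                features=pd.DataFrame(rows, columns=["mz", "rt_min", "area"]),
            )
        )
    return runs


def simulate_study(
    tree: Optional[PhyloTree] = None,
    n_taxa: int = 12,
    params: Optional[EvolutionParams] = None,
    seed: Optional[int] = None,
) -> tuple[SimulatedStudy, list[ChromatographicRun]]:
    """Convenience: tree (fixture by default when n_taxa == 12) -> study -> runs."""
    params = params or EvolutionParams()
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    s_tree, s_evo, s_render = (np.random.default_rng(c) for c in ss.spawn(3))
    if tree is None:
        tree = fixture_tree() if n_taxa == 12 else simulate_tree(n_taxa, rng=s_tree)
    study = evolve_metabolome(tree, params, rng=s_evo)
    runs = render_runs(study, rng=s_render)
    return study, runs


def contamination_scenario_params() -> EvolutionParams:
    """The designed bacterial-contamination scenario on the fixture tree.

    Mantoniella and Pyramimonas (different true clades) both carry a ~1:1
    bacterial admixture from a shared pool, at abundances below the algal
    top-10 range; clade markers anchor the major-metabolite chemotaxonomy.
    """
    return EvolutionParams(
        markers={"mamiellales": 3, "basal_chlorophytes": 3, "outgroup": 3,
                 "chlorellales": 2},
        clades=FIXTURE_CLADES,
        contamination={"Mantoniella_sp": 0.5, "Pyramimonas_sp": 0.5},
    )


# ---------------------------------------------------------------------------
# MS2 fixture spectra
# ---------------------------------------------------------------------------


def generate_ms2_fixture(
    target: Union[LipidSpecies, Pigment, str],
    adduct: Optional[Adduct] = None,
    regio_canonical: bool = True,
    n_decoys: int = 0,
    ppm_jitter: float = 0.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    config: Optional[LipidConfig] = None,
) -> Ms2Spectrum:
    """Emit a spectrum obeying the class fragmentation rules for ``target``.

    Lipids get both acyl-loss fragments with the intensity ordering required
    by the class regio rule (reversed when ``regio_canonical`` is False) and
    any required characteristic neutral loss (59 Da for betaines). Pigments
    get their rule peaks (dehydration series, nominal 80 Da loss, or the
    fucoxanthin diagnostics). Optional uniform ppm jitter on fragments and
    uniformly placed decoy peaks.
    """
    gen = _rng(seed, rng)
    config = config or load_config()
    if isinstance(target, str):
        if target not in config.pigments:
            raise ValueError(f"unsupported pigment {target!r}")
        target = config.pigments[target]

    peaks: list[tuple[float, float]] = []
    if isinstance(target, LipidSpecies):
        tpl = target.template
        if adduct is None:
            adduct = (
                ADDUCTS[tpl.regio_rule.adduct_name]
                if tpl.regio_rule
                else ADDUCTS["[M+H]+"]
            )
        precursor = ion_mz(species_formula(target), adduct)
        if tpl.n_acyl == 2:
            f1 = acyl_loss_fragment_mz(target, adduct, 1)
            f2 = acyl_loss_fragment_mz(target, adduct, 2)
            rule = tpl.regio_rule
            if rule is not None and rule.adduct_name == adduct.name:
                hi, lo = 100.0, 40.0
                sn1_intensity = hi if rule.sn1_more_intense else lo
                sn2_intensity = lo if rule.sn1_more_intense else hi
                if not regio_canonical:
                    sn1_intensity, sn2_intensity = sn2_intensity, sn1_intensity
            else:
                sn1_intensity = sn2_intensity = 80.0
            peaks += [(f1, sn1_intensity), (f2, sn2_intensity)]
        else:
            peaks.append((acyl_loss_fragment_mz(target, adduct, 1), 70.0))
        for nl in tpl.neutral_losses:
            if nl.required:
                peaks.append((precursor - nl.mass, 60.0))
    elif isinstance(target, Pigment):
        if adduct is None:
            adduct = ADDUCTS["[M+H]+"]
        precursor = ion_mz(target.formula, adduct)
        if target.rule == "dehydration_series":
            for n, inten in enumerate((100.0, 60.0, 30.0), start=1):
                peaks.append((precursor - n * 18.0105646863, inten))
        elif target.rule == "loss_80":
            peaks.append((precursor - 80.03, 100.0))
        elif target.rule == "diagnostics":
            for mz, inten in zip(target.diagnostic_mz, (100.0, 80.0, 60.0)):
                peaks.append((mz, inten))
        else:
            peaks.append((precursor - 18.0105646863, 50.0))
    else:
        raise ValueError(f"unsupported fixture target {target!r}")

    if ppm_jitter > 0:
        peaks = [
            (mz * (1 + gen.uniform(-ppm_jitter, ppm_jitter) * 1e-6), inten)
            for mz, inten in peaks
        ]
    for _ in range(n_decoys):
        peaks.append((gen.uniform(150.0, max(200.0, precursor - 5.0)), gen.uniform(5.0, 30.0)))

    label = target.label if isinstance(target, LipidSpecies) else target.name
    return Ms2Spectrum(
        precursor_mz=precursor,
        peaks=np.array(peaks),
        adduct_hint=adduct.name,
        spectrum_id=f"{label} {adduct.name}",
    )
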