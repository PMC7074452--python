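"""End-to-end orchestration: simulate -> features -> annotate -> chemotax.

A single seed governs every stage (per-stage sub-streams are derived
deterministically), so re-running with an identical configuration reproduces
identical numerical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import yaml

from . import annotate as ann_mod
from . import features as feat_mod
from .annotate import LineagePrior, annotate, annotations_to_tsv
from .chem import AcylChain, LipidSpecies, load_config
from .chemotax import (
    DistanceMatrix,
    complete_linkage,
    mantel,
    patristic,
    pca,
    spearman_distance,
)
from .features import (
    FeatureMatrix,
    gap_fill,
    group_features,
    hide_blank,
    intensity_floor,
    presence_states,
    read_runs_csv,
    select_major,
    sharing_summary,
    window_rt,
    write_matrix_tsv,
    write_runs_csv,
)
from .chemotax import PhyloTree
from .simulate import (
    EvolutionParams,
    FIXTURE_LINEAGE,
    generate_ms2_fixture,
    simulate_study,
)

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("chemoclock.pipeline")


@dataclass
class RunConfig:
    """All pipeline parameters; defaults match the study's stated values
    (2-18 min window, 0.1 min alignment shift, 3 ppm, 2e6 floor, top 10)."""

    out_dir: str = "chemoclock_out"
    seed: int = 0
    simulate: bool = True
    n_taxa: int = 12
    runs_csv: Optional[str] = None
    tree_path: Optional[str] = None
    rt_window: tuple[float, float] = (2.0, 18.0)
    rt_tol: float = 0.1
    ppm: float = 3.0
    min_area: float = 2e6
    blank_ratio: float = 5.0
    top_n: int = 10
    n_perm: int = 999
    annotate_demo: bool = True
    evolution: EvolutionParams = field(default_factory=EvolutionParams)
    lineage: Mapping[str, str] = field(default_factory=lambda: dict(FIXTURE_LINEAGE))

    def validate(self) -> None:
        if self.rt_window[0] >= self.rt_window[1]:
            raise ValueError("rt_window lo must be < hi")
        if min(self.rt_tol, self.ppm) <= 0:
            raise ValueError("rt_tol and ppm must be > 0")
        if self.top_n < 1 or self.n_perm < 1:
            raise ValueError("top_n and n_perm must be >= 1")
        if not self.simulate:
            if not self.runs_csv or not Path(self.runs_csv).exists():
                raise FileNotFoundError(
                    f"runs CSV not found: {self.runs_csv!r} (or pass simulate=True)"
                )
            if not self.tree_path or not Path(self.tree_path).exists():
                raise FileNotFoundError(
                    f"tree file not found: {self.tree_path!r} (or pass simulate=True)"
                )

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        evo = EvolutionParams(**raw.pop("evolution", {}))
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(evolution=evo, **raw)
        if isinstance(cfg.rt_window, list):
            cfg.rt_window = tuple(cfg.rt_window)
        return cfg


def _demo_annotation_panel(out_path: str, lineage: Mapping[str, str], seed: int) -> int:
    """Annotate one noiseless fixture spectrum per supported class/pigment."""
    config = load_config()
    rng = np.random.default_rng(seed)
    panel = []
    demo_chains = {
        "MGDG": (AcylChain(18, 3), AcylChain(16, 4)),
        "SQDG": (AcylChain(16, 0), AcylChain(18, 3)),
        "DGTS": (AcylChain(16, 0), AcylChain(18, 1)),
        "DGTA": (AcylChain(22, 6), AcylChain(20, 5)),
        "DGCC": (AcylChain(14, 0), AcylChain(22, 6)),
        "MGMG": (AcylChain(18, 3),),
        "lyso-DGTS": (AcylChain(16, 0),),
        "Cer": (AcylChain(16, 0),),
    }
    green_strain = next((s for s, l in lineage.items() if l == "green"), None)
    brown_strain = next((s for s, l in lineage.items() if l == "brown"), None)
    prior = LineagePrior(lineage)
    for name, chains in demo_chains.items():
        tpl = config.templates[name]
        species = LipidSpecies(tpl, *chains)
        spectrum = generate_ms2_fixture(species, rng=rng, config=config)
        strain = brown_strain if tpl.lineage == "brown" else green_strain
        panel.append((spectrum, annotate(spectrum, strain, prior, config)))
    for pigment in ("prasinoxanthin", "violaxanthin", "fucoxanthin"):
        spectrum = generate_ms2_fixture(pigment, rng=rng, config=config)
        panel.append((spectrum, annotate(spectrum, None, None, config)))
    annotations_to_tsv(panel, out_path)
    return len(panel)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the machine-readable report (also written
    to ``<out_dir>/report.json``)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "artifacts": {}}
    t0 = time.time()

    def stage(name):
        logger.info("stage %-10s %.2fs", name, time.time() - t0)

    ss = np.random.SeedSequence(config.seed)
    seed_sim, seed_annot, seed_mantel_whole, seed_mantel_major = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    )

    # --- inputs -----------------------------------------------------------
    if config.simulate:
        study, runs = simulate_study(
            n_taxa=config.n_taxa, params=config.evolution, seed=seed_sim
        )
        tree = study.tree
        write_runs_csv(runs, str(out / "runs.csv"))
        (out / "tree.nwk").write_text(tree.to_newick() + "\n")
        truth = {
            "marker_ids": study.marker_ids,
            "medium_ids": list(study.medium_levels.index),
            "contaminated": {
                s: int((study.bacterial[s] > 0).sum())
                for s in study.bacterial.columns
                if (study.bacterial[s] > 0).any()
            },
            "n_metabolites": int((study.truth > 0).any(axis=1).sum()),
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
        report["artifacts"]["runs"] = "runs.csv"
        report["artifacts"]["tree"] = "tree.nwk"
    else:
        runs = read_runs_csv(config.runs_csv)
        tree = PhyloTree.from_newick(config.tree_path)
    stage("inputs")

    # --- feature pipeline -------------------------------------------------
    runs = [window_rt(r, *config.rt_window) for r in runs]
    matrix = group_features(runs, rt_tol=config.rt_tol, mass_tol_ppm=config.ppm)
    n_grouped = matrix.n_features
    matrix = intensity_floor(matrix, config.min_area)
    if matrix.blank_sample_ids():
        matrix = hide_blank(matrix, config.blank_ratio)
    else:
        logger.info("no blank runs: blank hiding skipped")
    matrix = gap_fill(matrix)
    share = sharing_summary(matrix)
    write_matrix_tsv(matrix, str(out / "feature_matrix_whole"))
    report["artifacts"]["feature_matrix_whole"] = "feature_matrix_whole.tsv"
    report["counts"] = {
        "grouped_features": n_grouped,
        "after_filters": matrix.n_features,
        "detected_per_species": share.per_species,
        "unique_features": share.unique,
        "shared_features": share.shared,
        "detected_total": share.total,
    }
    stage("features")

    # --- major metabolites ------------------------------------------------
    major, top_lists = select_major(matrix, config.top_n)
    write_matrix_tsv(major, str(out / "feature_matrix_major"))
    presence = presence_states(matrix, top_lists)
    presence.to_csv(out / "presence_matrix.tsv", sep="\t")
    report["artifacts"]["feature_matrix_major"] = "feature_matrix_major.tsv"
    report["artifacts"]["presence_matrix"] = "presence_matrix.tsv"
    report["counts"]["major_union"] = major.n_features
    stage("major")

    # --- annotation demo panel -------------------------------------------
    if config.annotate_demo:
        n = _demo_annotation_panel(
            str(out / "annotations.tsv"), config.lineage, seed_annot
        )
        report["artifacts"]["annotations"] = "annotations.tsv"
        report["counts"]["annotated_spectra"] = n
    stage("annotate")

    # --- chemotaxonomy ----------------------------------------------------
    algal = matrix.algal_sample_ids()
    replicate_table = matrix.areas[algal].T  # samples x features
    pca_whole = pca(replicate_table, scale=True)
    major_table = major.areas[algal].T
    pca_major = pca(major_table, scale=True)
    report["pca"] = {
        "whole": {
            "pc1": round(float(pca_whole.explained_fraction[0]), 6),
            "pc2": round(float(pca_whole.explained_fraction[1]), 6),
            "pc1_pc2": round(float(pca_whole.explained_fraction[:2].sum()), 6),
        },
        "major": {
            "pc1": round(float(pca_major.explained_fraction[0]), 6),
            "pc2": round(float(pca_major.explained_fraction[1]), 6),
            "pc1_pc2": round(float(pca_major.explained_fraction[:2].sum()), 6),
        },
    }

    d_whole = spearman_distance(matrix)
    d_major = spearman_distance(major)
    dend_whole = complete_linkage(d_whole)
    dend_major = complete_linkage(d_major)
    (out / "dendrogram_whole.nwk").write_text(dend_whole.to_newick() + "\n")
    (out / "dendrogram_major.nwk").write_text(dend_major.to_newick() + "\n")
    d_whole.to_tsv(str(out / "distance_whole.tsv"))
    d_major.to_tsv(str(out / "distance_major.tsv"))

    d_patristic = patristic(tree)
    if set(d_patristic.labels) != set(d_whole.labels):
        raise ValueError(
            "tree leaves and strain labels disagree: "
            f"{sorted(set(d_patristic.labels) ^ set(d_whole.labels))}"
        )
    d_patristic = d_patristic.reorder(d_whole.labels)
    d_patristic.to_tsv(str(out / "patristic.tsv"))
    report["artifacts"].update(
        {
            "dendrogram_whole": "dendrogram_whole.nwk",
            "dendrogram_major": "dendrogram_major.nwk",
            "patristic": "patristic.tsv",
        }
    )

    m_whole = mantel(d_whole, d_patristic, n_perm=config.n_perm, seed=seed_mantel_whole)
    m_major = mantel(d_major, d_patristic, n_perm=config.n_perm, seed=seed_mantel_major)
    report["mantel"] = {
        "whole": {"r": round(m_whole.r, 6), "p": m_whole.p_value,
                  "n_perm": m_whole.n_perm},
        "major": {"r": round(m_major.r, 6), "p": m_major.p_value,
                  "n_perm": m_major.n_perm},
    }
    stage("chemotax")

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
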