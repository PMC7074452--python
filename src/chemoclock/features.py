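"""Preprocessing of per-run feature tables into sample x feature matrices.

Mirrors the untargeted workflow applied to the 12-strain dataset: retention
time windowing (2-18 min), greedy centroid grouping at 0.1 min / 3 ppm,
minimum-intensity filtering (2e6), blank hiding, zero gap filling with
provenance flags, per-species sharing summaries, and the top-N
"major-metabolite" matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChromatographicRun",
    "FeatureMatrix",
    "SharingSummary",
    "window_rt",
    "group_features",
    "intensity_floor",
    "hide_blank",
    "gap_fill",
    "sharing_summary",
    "select_major",
    "presence_states",
    "read_runs_csv",
    "write_runs_csv",
]

logger = logging.getLogger("chemoclock.features")

RT_WINDOW = (2.0, 18.0)  # analysis window, min
DEFAULT_RT_TOL = 0.1     # max alignment shift, min
DEFAULT_PPM = 3.0        # grouping mass tolerance
DEFAULT_MIN_AREA = 2e6   # minimum peak intensity
DEFAULT_BLANK_RATIO = 5.0

RUN_COLUMNS = ["sample_id", "role", "strain", "replicate", "mz", "rt_min", "area"]


@dataclass
class ChromatographicRun:
    """One LC-MS run: sample metadata plus its (m/z, RT, area) features."""

    sample_id: str
    role: str  # 'algal' | 'blank' | 'QC'
    strain: Optional[str]
    replicate: int
    features: pd.DataFrame  # columns mz, rt_min, area

    def __post_init__(self):
        f = pd.DataFrame(self.features, columns=["mz", "rt_min", "area"]).astype(float)
        if (f["area"] < 0).any():
            raise ValueError(f"negative areas in run {self.sample_id}")
        self.features = f.reset_index(drop=True)


def window_rt(
    run: ChromatographicRun, lo: float = RT_WINDOW[0], hi: float = RT_WINDOW[1]
) -> ChromatographicRun:
    """Drop features outside the [lo, hi] retention window (boundaries kept)."""
    if not lo < hi:
        raise ValueError("window requires lo < hi")
    kept = run.features[(run.features.rt_min >= lo) & (run.features.rt_min <= hi)]
    return replace(run, features=kept.reset_index(drop=True))


@dataclass
class FeatureMatrix:
    """Grouped features x samples with per-cell provenance.

    ``areas`` holds XIC areas (NaN = missing until gap filling); ``observed``
    flags genuinely measured cells; ``features`` carries consensus (m/z, RT)
    per group and ``samples`` the role/strain/replicate metadata.
    """

    areas: pd.DataFrame      # index: feature id, columns: sample id
    observed: pd.DataFrame   # same shape, bool
    features: pd.DataFrame   # index: feature id; columns mz, rt_min
    samples: pd.DataFrame    # index: sample id; columns role, strain, replicate

    @property
    def n_features(self) -> int:
        return len(self.features)

    def algal_sample_ids(self) -> list[str]:
        return list(self.samples.index[self.samples.role == "algal"])

    def blank_sample_ids(self) -> list[str]:
        return list(self.samples.index[self.samples.role == "blank"])

    def subset(self, feature_ids: Sequence) -> "FeatureMatrix":
        idx = list(feature_ids)
        return FeatureMatrix(
            areas=self.areas.loc[idx].copy(),
            observed=self.observed.loc[idx].copy(),
            features=self.features.loc[idx].copy(),
            samples=self.samples.copy(),
        )

    def strain_means(self, fill: float = 0.0) -> pd.DataFrame:
        """Strain-mean abundance profiles (algal samples; missing -> ``fill``)."""
        algal = self.algal_sample_ids()
        filled = self.areas[algal].fillna(fill)
        strains = self.samples.loc[algal, "strain"]
        return filled.T.groupby(strains).mean().T


def group_features(
    runs: Sequence[ChromatographicRun],
    rt_tol: float = DEFAULT_RT_TOL,
    mass_tol_ppm: float = DEFAULT_PPM,
) -> FeatureMatrix:
    """Greedy centroid grouping of features across runs.

    Features are processed in descending area (ties broken by m/z, RT,
    sample id, so the result is invariant to run order); each either joins
    the nearest existing group lying within both tolerances of the group
    centroid or seeds a new group. Centroids are intensity-weighted means.
    If a run contributes several members to one group, its most intense
    member provides the area.
    """
    if not runs:
        raise ValueError("at least one run required")
    frames = []
    for run in runs:
        f = run.features.copy()
        f["sample_id"] = run.sample_id
        frames.append(f)
    allf = pd.concat(frames, ignore_index=True)
    samples = pd.DataFrame(
        {
            "role": [r.role for r in runs],
            "strain": [r.strain for r in runs],
            "replicate": [r.replicate for r in runs],
        },
        index=pd.Index([r.sample_id for r in runs], name="sample_id"),
    )
    if allf.empty:
        empty = pd.DataFrame(index=pd.Index([], name="feature_id"), columns=samples.index)
        return FeatureMatrix(
            areas=empty.astype(float),
            observed=empty.astype(bool),
            features=pd.DataFrame(columns=["mz", "rt_min"]),
            samples=samples,
        )

    allf = allf.sort_values(
        ["area", "mz", "rt_min", "sample_id"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)

    n = len(allf)
    mzs = allf["mz"].to_numpy()
    rts = allf["rt_min"].to_numpy()
    areas = allf["area"].to_numpy()

    cap = n
    c_mz = np.empty(cap)
    c_rt = np.empty(cap)
    c_w = np.empty(cap)
    n_groups = 0
    assignment = np.empty(n, dtype=int)

    for i in range(n):
        mz, rt, w = mzs[i], rts[i], areas[i]
        gid = -1
        if n_groups:
            dm = np.abs(c_mz[:n_groups] - mz)
            dr = np.abs(c_rt[:n_groups] - rt)
            ok = (dm <= mass_tol_ppm * 1e-6 * c_mz[:n_groups]) & (dr <= rt_tol)
            if ok.any():
                # nearest by combined normalized distance
                score = np.where(
                    ok,
                    dm / (mass_tol_ppm * 1e-6 * np.maximum(c_mz[:n_groups], 1e-12))
                    + dr / rt_tol,
                    np.inf,
                )
                gid = int(np.argmin(score))
        if gid < 0:
            gid = n_groups
            c_mz[gid] = mz
            c_rt[gid] = rt
            c_w[gid] = max(w, 1e-12)
            n_groups += 1
        else:
            w_eff = max(w, 1e-12)
            tot = c_w[gid] + w_eff
            c_mz[gid] = (c_mz[gid] * c_w[gid] + mz * w_eff) / tot
            c_rt[gid] = (c_rt[gid] * c_w[gid] + rt * w_eff) / tot
            c_w[gid] = tot
        assignment[i] = gid

    allf["group"] = assignment
    # one area per run per group: most intense member
    cell = allf.groupby(["group", "sample_id"])["area"].max()
    areas_df = cell.unstack("sample_id").reindex(
        index=range(n_groups), columns=samples.index
    )
    # stable feature ids ordered by (mz, rt)
    feat = pd.DataFrame(
        {"mz": c_mz[:n_groups], "rt_min": c_rt[:n_groups]},
        index=pd.RangeIndex(n_groups),
    )
    order = feat.sort_values(["mz", "rt_min"]).index
    feat = feat.loc[order].reset_index(drop=True)
    feat.index = pd.Index([f"F{i:05d}" for i in range(len(feat))], name="feature_id")
    areas_df = areas_df.loc[order]
    areas_df.index = feat.index
    return FeatureMatrix(
        areas=areas_df.astype(float),
        observed=areas_df.notna(),
        features=feat,
        samples=samples,
    )


def intensity_floor(
    matrix: FeatureMatrix, min_area: float = DEFAULT_MIN_AREA
) -> FeatureMatrix:
    """Remove groups whose maximum observed area is below ``min_area``.

    The boundary is inclusive: a group peaking exactly at ``min_area`` stays.
    """
    if matrix.n_features == 0 or min_area <= 0:
        return matrix
    observed_areas = matrix.areas.where(matrix.observed)
    keep = observed_areas.max(axis=1).fillna(0) >= min_area
    return matrix.subset(matrix.features.index[keep])


def hide_blank(
    matrix: FeatureMatrix, ratio: float = DEFAULT_BLANK_RATIO
) -> FeatureMatrix:
    """Hide chemical background using blank runs.

    A group is removed when max(algal area) / max(blank area) < ratio;
    groups never observed in any blank are always retained.
    """
    blanks = matrix.blank_sample_ids()
    if not blanks:
        raise ValueError("no blank samples present")
    if matrix.n_features == 0:
        return matrix
    observed_areas = matrix.areas.where(matrix.observed)
    blank_max = observed_areas[blanks].max(axis=1)
    algal_max = observed_areas[matrix.algal_sample_ids()].max(axis=1).fillna(0.0)
    in_blank = blank_max.notna() & (blank_max > 0)
    keep = ~in_blank | (algal_max / blank_max.where(in_blank) >= ratio)
    keep = keep.fillna(True)
    return matrix.subset(matrix.features.index[keep])


def gap_fill(matrix: FeatureMatrix) -> FeatureMatrix:
    """Zero-fill missing cells; provenance stays in ``observed``.

    Downstream statistics are rank-based (Spearman), which tolerates the
    zero convention; re-integration from raw chromatograms is out of scope.
    """
    return FeatureMatrix(
        areas=matrix.areas.fillna(0.0),
        observed=matrix.observed.copy(),
        features=matrix.features.copy(),
        samples=matrix.samples.copy(),
    )


@dataclass
class SharingSummary:
    """Counts of features detected per species, unique to one, and shared."""

    per_species: dict[str, int]
    unique: int
    shared: int
    total: int


def sharing_summary(
    matrix: FeatureMatrix, species_map: Optional[Mapping[str, str]] = None
) -> SharingSummary:
    """Detected / unique / shared feature counts at the species level.

    A feature counts as detected in a species when any replicate of any of
    its strains has an *observed* (not gap-filled) cell. The identity
    unique + shared = total holds by construction.
    """
    algal = matrix.algal_sample_ids()
    strains = matrix.samples.loc[algal, "strain"]
    species = (
        strains.map(lambda s: species_map.get(s, s)) if species_map else strains
    )
    det = matrix.observed[algal].T.groupby(species).any().T  # features x species
    per_species = det.sum(axis=0).astype(int).to_dict()
    n_species_per_feature = det.sum(axis=1)
    detected_any = n_species_per_feature > 0
    unique = int((n_species_per_feature == 1).sum())
    shared = int((n_species_per_feature >= 2).sum())
    return SharingSummary(
        per_species=per_species,
        unique=unique,
        shared=shared,
        total=int(detected_any.sum()),
    )


def select_major(
    matrix: FeatureMatrix, n: int = 10
) -> tuple[FeatureMatrix, dict[str, list[str]]]:
    """Top-n features per strain by strain-mean area; union across strains.

    Ranking uses strain means over replicates (missing cells as 0); ties are
    broken by (area desc, consensus m/z asc, RT asc) for determinism.
    Returns the restricted matrix and the per-strain top lists.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > matrix.n_features:
        logger.warning(
            "top-n %d exceeds feature count %d; using all features",
            n, matrix.n_features,
        )
        n = matrix.n_features
    means = matrix.strain_means(fill=0.0)
    top_lists: dict[str, list[str]] = {}
    for strain in means.columns:
        ranking = pd.DataFrame(
            {
                "area": means[strain],
                "mz": matrix.features["mz"],
                "rt_min": matrix.features["rt_min"],
            }
        ).sort_values(["area", "mz", "rt_min"], ascending=[False, True, True],
                      kind="mergesort")
        top_lists[strain] = list(ranking.index[:n])
    union: list[str] = []
    seen = set()
    for fid in matrix.features.index:  # preserve feature order
        if fid in seen:
            continue
        if any(fid in tops for tops in top_lists.values()):
            union.append(fid)
            seen.add(fid)
    return matrix.subset(union), top_lists


def presence_states(
    matrix: FeatureMatrix, top_lists: Mapping[str, list[str]]
) -> pd.DataFrame:
    """Three-state per-strain feature matrix: top-N, detected, not detected."""
    algal = matrix.algal_sample_ids()
    strains = matrix.samples.loc[algal, "strain"]
    detected = matrix.observed[algal].T.groupby(strains).any().T
    out = pd.DataFrame(
        "not_detected", index=matrix.features.index, columns=detected.columns
    )
    out = out.where(~detected, "detected")
    for strain, tops in top_lists.items():
        if strain in out.columns:
            idx = [fid for fid in tops if fid in out.index]
            out.loc[idx, strain] = "top"
    return out


def write_matrix_tsv(matrix: FeatureMatrix, prefix: str) -> None:
    """Write a matrix as TSV triplet: wide areas, provenance sidecar, samples.

    ``<prefix>.tsv`` holds feature_id, mz, rt_min plus one area column per
    sample (empty cell = missing); ``<prefix>.provenance.tsv`` marks each
    cell observed / gap-filled / absent; ``<prefix>.samples.tsv`` carries the
    sample metadata.
    """
    wide = pd.concat([matrix.features, matrix.areas], axis=1)
    wide.to_csv(f"{prefix}.tsv", sep="\t", float_format="%.6f")
    prov = pd.DataFrame("absent", index=matrix.areas.index, columns=matrix.areas.columns)
    prov = prov.mask(matrix.observed, "observed")
    prov = prov.mask(~matrix.observed & matrix.areas.notna(), "gap-filled")
    prov.to_csv(f"{prefix}.provenance.tsv", sep="\t")
    matrix.samples.to_csv(f"{prefix}.samples.tsv", sep="\t")


def read_matrix_tsv(prefix: str) -> FeatureMatrix:
    """Read a matrix written by :func:`write_matrix_tsv`."""
    wide = pd.read_csv(f"{prefix}.tsv", sep="\t", index_col=0)
    features = wide[["mz", "rt_min"]]
    areas = wide.drop(columns=["mz", "rt_min"]).astype(float)
    prov = pd.read_csv(f"{prefix}.provenance.tsv", sep="\t", index_col=0)
    samples = pd.read_csv(f"{prefix}.samples.tsv", sep="\t", index_col=0)
    samples["strain"] = samples["strain"].where(samples["strain"].notna(), None)
    return FeatureMatrix(
        areas=areas,
        observed=prov == "observed",
        features=features,
        samples=samples,
    )


def read_runs_csv(path: str) -> list[ChromatographicRun]:
    """Read runs from CSV (sample_id, role, strain, replicate, mz, rt_min, area)."""
    df = pd.read_csv(path)
    missing = set(RUN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"run CSV missing columns: {sorted(missing)}")
    runs = []
    for sid, grp in df.groupby("sample_id", sort=False):
        head = grp.iloc[0]
        strain = head["strain"]
        runs.append(
            ChromatographicRun(
                sample_id=str(sid),
                role=str(head["role"]),
                strain=None if pd.isna(strain) else str(strain),
                replicate=int(head["replicate"]),
                features=grp[["mz", "rt_min", "area"]],
            )
        )
    return runs


def write_runs_csv(runs: Sequence[ChromatographicRun], path: str) -> None:
    frames = []
    for run in runs:
        f = run.features.copy()
        f.insert(0, "sample_id", run.sample_id)
        f.insert(1, "role", run.role)
        f.insert(2, "strain", run.strain if run.strain is not None else "")
        f.insert(3, "replicate", run.replicate)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")
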