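"""Orchestrated accuracy studies: reproducibility and trueness.

Two headline workflows over a grid of phantoms × acquisition-setting
analogues × repeated segmentations:

* **Reproducibility** (:func:`run_reproducibility`) — segment each
  volume repeatedly with independently sampled operator thresholds and
  assess, at three levels: (1) MAD/SDAD between repeated meshes at
  their original position over unified bilateral measurement areas,
  (2) the six rigid movement components of the best-fit (point-to-plane
  ICP) superimposition on a reference area, (3) MAD/SDAD after
  superimposition.
* **Trueness** (:func:`run_trueness`) — segment each volume once,
  best-fit it to the analytic ground-truth mesh (the gold-standard
  stand-in), and summarise MAD/SDAD over measurement areas selected
  once on the ground truth and transferred by centroid matching.

Both attach the nonparametric statistical layer (Kruskal–Wallis across
settings, pairwise Mann–Whitney with Bonferroni adjustment) — once with
all measurement areas pooled as one variable (per-area summary values
are the statistical unit) and once per area.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .deviation import (
    DistanceSamples,
    closest_distances,
    distance_map,
    export_distance_map,
    summarise,
)
from .mesh_ops import (
    MeasurementArea,
    TriMesh,
    grow_patch,
    map_area,
    nearest_triangle,
    unify_areas,
)
from .phantom import (
    PhantomSpec,
    face_like_spec,
    ground_truth_mesh,
    sample_operator_thresholds,
    simulate_acquisition,
    surface_radius,
)
from .registration import ICPSettings, decompose_transform, icp_register
from .segmentation import extract_isosurface, keep_main_components
from .stats import bonferroni, describe, kruskal_wallis, mann_whitney, wilcoxon_signed_rank
from .mesh_ops import apply_transform

__all__ = [
    "StudyConfig",
    "ReproReport",
    "TruenessReport",
    "default_study_config",
    "demo_study_config",
    "run_reproducibility",
    "run_trueness",
    "export_report",
    "load_report",
    "repeated_segmentation_emulation",
]

PRE = "pre-superimposition"
POST = "post-superimposition"
POOLED_AREA = "all-areas-pooled"

#: unit anchor directions (X lateral, Y vertical, Z anteroposterior) for
#: the bilateral measurement-area analogues and the superimposition
#: reference area on face-like phantoms
DEFAULT_AREA_ANCHORS: dict[str, list[tuple[float, float, float]]] = {
    "forehead": [(-0.30, 0.62, 0.72), (0.30, 0.62, 0.72)],
    "zygoma": [(-0.78, 0.10, 0.61), (0.78, 0.10, 0.61)],
    "maxilla": [(-0.25, -0.55, 0.79), (0.25, -0.55, 0.79)],
}
DEFAULT_REFERENCE_ANCHORS: list[tuple[float, float, float]] = [(0.0, 0.15, 0.99)]


@dataclass
class StudyConfig:
    """Declarative description of one study run.

    ``settings`` maps an acquisition-setting analogue name to the
    phantom spec that emulates it.  ``area_triangles`` is the *total*
    triangle count of each unified bilateral measurement area (the
    protocol uses 2000 for reproducibility, 4000 for trueness);
    per-anchor patches get an equal share.
    """

    settings: dict[str, PhantomSpec]
    n_subjects: int = 3
    repeats: int = 2
    threshold_spread: float = 0.01
    min_component_fraction: float = 0.01
    area_anchors: dict[str, list[tuple[float, float, float]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_AREA_ANCHORS.items()}
    )
    reference_anchors: list[tuple[float, float, float]] = field(
        default_factory=lambda: list(DEFAULT_REFERENCE_ANCHORS)
    )
    repro_area_triangles: int = 2000
    trueness_area_triangles: int = 4000
    reference_triangles: int = 2000
    truth_edge_mm: float = 0.25
    icp: ICPSettings = field(default_factory=ICPSettings)
    distance_mode: str = "surface"
    repro_map_scale: float = 0.1
    trueness_map_scale: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.repeats < 2:
            raise ValueError("reproducibility requires at least 2 repeats per volume")
        if self.n_subjects < 1:
            raise ValueError("need at least 1 subject")
        if not self.settings:
            raise ValueError("no acquisition settings configured")

    # -- serialisation -------------------------------------------------
    def as_dict(self) -> dict:
        return {
            "settings": {k: v.as_dict() for k, v in self.settings.items()},
            "n_subjects": self.n_subjects,
            "repeats": self.repeats,
            "threshold_spread": self.threshold_spread,
            "min_component_fraction": self.min_component_fraction,
            "area_anchors": {k: [list(a) for a in v] for k, v in self.area_anchors.items()},
            "reference_anchors": [list(a) for a in self.reference_anchors],
            "repro_area_triangles": self.repro_area_triangles,
            "trueness_area_triangles": self.trueness_area_triangles,
            "reference_triangles": self.reference_triangles,
            "truth_edge_mm": self.truth_edge_mm,
            "icp": {
                "estimated_overlap": self.icp.estimated_overlap,
                "metric": self.icp.metric,
                "nn_search": self.icp.nn_search,
                "sampling_fraction": self.icp.sampling_fraction,
                "iterations": self.icp.iterations,
                "convergence_tol": self.icp.convergence_tol,
            },
            "distance_mode": self.distance_mode,
            "repro_map_scale": self.repro_map_scale,
            "trueness_map_scale": self.trueness_map_scale,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        d["settings"] = {k: PhantomSpec.from_dict(v) for k, v in d["settings"].items()}
        d["area_anchors"] = {
            k: [tuple(a) for a in v] for k, v in d.get("area_anchors", DEFAULT_AREA_ANCHORS).items()
        }
        d["reference_anchors"] = [tuple(a) for a in d.get("reference_anchors", DEFAULT_REFERENCE_ANCHORS)]
        if "icp" in d:
            d["icp"] = ICPSettings(**d["icp"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def default_study_config(seed: int = 0) -> StudyConfig:
    """The four acquisition-setting analogues at their native voxel sizes.

    Mirrors a CT-like anisotropic grid (0.49 × 0.49 × 0.31 mm), two
    isotropic CBCT analogues (0.3 mm and 0.2 mm) and an ultra-low-dose
    variant of the finest grid with doubled noise.  Blur/noise levels
    are engineering choices (no scanner calibration data exist).
    """
    base = dict(psf_fwhm=0.6, noise_sigma=40.0, seed=seed)
    return StudyConfig(
        settings={
            "ct": face_like_spec(spacing=(0.49, 0.49, 0.31), psf_fwhm=0.8,
                                 noise_sigma=40.0, seed=seed),
            "cbct_03": face_like_spec(spacing=(0.3, 0.3, 0.3), **base),
            "cbct_02": face_like_spec(spacing=(0.2, 0.2, 0.2), psf_fwhm=0.5,
                                      noise_sigma=40.0, seed=seed),
            "cbct_02_low": face_like_spec(spacing=(0.2, 0.2, 0.2), psf_fwhm=0.5,
                                          noise_sigma=80.0, seed=seed),
        },
        seed=seed,
    )


def demo_study_config(seed: int = 0) -> StudyConfig:
    """Coarse desk-scale configuration for examples and fast runs.

    Smaller phantoms on coarser grids with proportionally smaller
    measurement areas; the workflow and every contract are identical to
    :func:`default_study_config`.
    """
    axes = (16.0, 19.0, 15.0)
    mk = lambda sp, fw, ns: face_like_spec(  # noqa: E731
        semi_axes=axes, spacing=sp, psf_fwhm=fw, noise_sigma=ns, seed=seed
    )
    return StudyConfig(
        settings={
            "ct": mk((0.85, 0.85, 0.62), 1.4, 40.0),
            "cbct": mk((0.7, 0.7, 0.7), 1.2, 40.0),
            "cbct_low": mk((0.7, 0.7, 0.7), 1.2, 80.0),
        },
        n_subjects=2,
        repeats=2,
        repro_area_triangles=400,
        trueness_area_triangles=800,
        reference_triangles=600,
        truth_edge_mm=0.8,
        seed=seed,
    )


# ----------------------------------------------------------------------
# reports
# ----------------------------------------------------------------------

@dataclass
class ReproReport:
    """Reproducibility results: deviations, movements, thresholds, stats."""

    config: StudyConfig
    deviations: pd.DataFrame  # setting, subject, pair, area, stage, mad, sdad, max_abs, n
    movements: pd.DataFrame  # setting, subject, pair, component, value
    thresholds: pd.DataFrame  # setting, subject, stream, session, threshold
    stat_results: dict
    map_cases: list[dict] = field(default_factory=list)
    meshes: dict = field(default_factory=dict, repr=False)
    kind: str = "reproducibility"


@dataclass
class TruenessReport:
    """Trueness results: post-superimposition deviations vs ground truth."""

    config: StudyConfig
    deviations: pd.DataFrame
    movements: pd.DataFrame
    thresholds: pd.DataFrame
    stat_results: dict
    map_cases: list[dict] = field(default_factory=list)
    meshes: dict = field(default_factory=dict, repr=False)
    kind: str = "trueness"


# ----------------------------------------------------------------------
# helpers
# ----------------------------------------------------------------------

def _derived_seed(base: int, *indices: int) -> int:
    h = hashlib.sha256(("/".join(map(str, (base, *indices)))).encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def _anchor_point(spec: PhantomSpec, direction) -> np.ndarray:
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    return float(surface_radius(spec, u[None, :])[0]) * u


def _build_areas(
    mesh: TriMesh,
    spec: PhantomSpec,
    anchors: dict[str, list],
    total_triangles: int,
    mesh_id: str,
) -> dict[str, MeasurementArea]:
    """Bilateral patches grown to an exact count, unified per anatomy."""
    areas: dict[str, MeasurementArea] = {}
    for name, dirs in anchors.items():
        per_patch = total_triangles // len(dirs)
        patches = []
        for d in dirs:
            seed_tri = nearest_triangle(mesh, _anchor_point(spec, d))
            patches.append(grow_patch(mesh, seed_tri, per_patch, mesh_id=mesh_id, name=name))
        areas[name] = unify_areas(patches)
    return areas


def _reference_area(mesh, spec, anchors, n_triangles, mesh_id) -> MeasurementArea:
    per_patch = n_triangles // len(anchors)
    patches = [
        grow_patch(mesh, nearest_triangle(mesh, _anchor_point(spec, d)), per_patch,
                   mesh_id=mesh_id, name="reference")
        for d in anchors
    ]
    return unify_areas(patches)


def _segment(volume, threshold, spec, min_frac) -> TriMesh:
    return keep_main_components(
        extract_isosurface(volume, threshold, value_range=spec.intensity_range), min_frac
    )


def _pooled_summary(per_area_samples: dict[str, DistanceSamples], stage: str):
    pooled = np.concatenate([s.distances for s in per_area_samples.values()])
    ids = np.concatenate([s.vertex_ids for s in per_area_samples.values()])
    pts = np.concatenate([s.closest_points for s in per_area_samples.values()])
    return summarise(DistanceSamples(ids, pooled, pts), stage=stage, area_name=POOLED_AREA)


def _family_stats(dev: pd.DataFrame, value_col: str, stage: str) -> dict:
    """Kruskal–Wallis across settings + pairwise Mann–Whitney (Bonferroni).

    Run once with all per-area summary values pooled as one variable,
    then per measurement area.
    """
    out: dict = {}
    sub = dev[(dev["stage"] == stage) & (dev["area"] != POOLED_AREA)]
    scopes = {"pooled": sub}
    for area in sorted(sub["area"].unique()):
        scopes[f"area:{area}"] = sub[sub["area"] == area]
    for scope, frame in scopes.items():
        groups = {s: g[value_col].to_numpy() for s, g in frame.groupby("setting")}
        names = sorted(groups)
        entry: dict = {"groups": {s: describe(groups[s]).__dict__ for s in names if len(groups[s])}}
        if len(names) >= 2 and all(len(groups[s]) >= 1 for s in names):
            try:
                entry["kruskal_wallis"] = kruskal_wallis([groups[s] for s in names]).as_dict()
                pairs = list(combinations(names, 2))
                raw = [mann_whitney(groups[a], groups[b]) for a, b in pairs]
                adj = bonferroni([r.p_value for r in raw])
                entry["pairwise"] = {
                    f"{a}|{b}": {**r.as_dict(), "p_adjusted": float(p)}
                    for (a, b), r, p in zip(pairs, raw, adj)
                }
            except ValueError as exc:
                entry["note"] = f"degenerate: {exc}"
        out[scope] = entry
    return out


def _threshold_stats(thresholds: pd.DataFrame) -> dict:
    """Intra- vs inter-operator threshold reproducibility (two streams)."""
    out: dict = {}
    intra, inter = [], []
    intra_by_setting: dict[str, list] = {}
    inter_by_setting: dict[str, list] = {}
    for (setting, subject), g in thresholds.groupby(["setting", "subject"]):
        a = g[(g["stream"] == "operator_a")].sort_values("session")["threshold"].to_numpy()
        b = g[(g["stream"] == "operator_b")].sort_values("session")["threshold"].to_numpy()
        if len(a) >= 2:
            intra.append(a[1] - a[0])
            intra_by_setting.setdefault(setting, []).append(a[1] - a[0])
        if len(a) >= 1 and len(b) >= 1:
            inter.append(b[0] - a[0])
            inter_by_setting.setdefault(setting, []).append(b[0] - a[0])
    for label, diffs, by_setting in (
        ("intra_operator", intra, intra_by_setting),
        ("inter_operator", inter, inter_by_setting),
    ):
        entry: dict = {"n": len(diffs)}
        if diffs:
            entry["describe"] = describe(diffs).__dict__
            try:
                entry["wilcoxon"] = wilcoxon_signed_rank(diffs).as_dict()
            except ValueError as exc:
                entry["wilcoxon_note"] = str(exc)
            if len(by_setting) >= 2 and all(v for v in by_setting.values()):
                try:
                    entry["kruskal_wallis_settings"] = kruskal_wallis(
                        [by_setting[s] for s in sorted(by_setting)]
                    ).as_dict()
                except ValueError as exc:
                    entry["kruskal_note"] = str(exc)
        out[label] = entry
    if intra and inter:
        try:
            out["intra_vs_inter"] = mann_whitney(intra, inter).as_dict()
        except ValueError as exc:
            out["intra_vs_inter_note"] = str(exc)
    return out


# ----------------------------------------------------------------------
# reproducibility workflow
# ----------------------------------------------------------------------

def run_reproducibility(config: StudyConfig) -> ReproReport:
    """Three-level intra-operator reproducibility study. See module docs."""
    dev_rows, mov_rows, thr_rows = [], [], []
    meshes: dict = {}
    map_cases: list[dict] = []

    for s_idx, (setting, spec0) in enumerate(sorted(config.settings.items())):
        pair_records = []  # (subject, pair_label, mesh_a, mesh_b, mean_mad)
        for subj in range(config.n_subjects):
            spec = replace(
                spec0, seed=_derived_seed(config.seed, s_idx, subj, 0)
            )
            volume = simulate_acquisition(spec)
            base = spec.midpoint_threshold
            thr_a = sample_operator_thresholds(
                base, config.threshold_spread, spec.intensity_full_range,
                config.repeats, _derived_seed(config.seed, s_idx, subj, 1),
                value_range=spec.intensity_range,
            )
            thr_b = sample_operator_thresholds(
                base, config.threshold_spread, spec.intensity_full_range,
                config.repeats, _derived_seed(config.seed, s_idx, subj, 2),
                value_range=spec.intensity_range,
            )
            for stream, thr in (("operator_a", thr_a), ("operator_b", thr_b)):
                for sess, t in enumerate(thr):
                    thr_rows.append(
                        dict(setting=setting, subject=subj, stream=stream,
                             session=sess, threshold=float(t))
                    )
            try:
                reps = [
                    _segment(volume, t, spec, config.min_component_fraction)
                    for t in thr_a
                ]
            except ValueError as exc:
                # a failed repeat aborts this volume, not the study
                dev_rows.append(dict(setting=setting, subject=subj, pair="aborted",
                                     area="none", stage="error", mad=np.nan,
                                     sdad=np.nan, max_abs=np.nan, n=0,
                                     note=str(exc)))
                continue
            for r, mesh in enumerate(reps):
                meshes[(setting, subj, r)] = mesh

            for i, j in combinations(range(config.repeats), 2):
                mesh_a, mesh_b = reps[i], reps[j]
                pair = f"{i}-{j}"
                mesh_id = f"{setting}/s{subj}/r{i}"
                areas = _build_areas(mesh_a, spec, config.area_anchors,
                                     config.repro_area_triangles, mesh_id)
                ref = _reference_area(mesh_a, spec, config.reference_anchors,
                                      config.reference_triangles, mesh_id)

                pre_samples = {
                    name: closest_distances(mesh_a, mesh_b, area, config.distance_mode)
                    for name, area in areas.items()
                }
                for name, smp in pre_samples.items():
                    s = summarise(smp, PRE, name)
                    dev_rows.append(dict(setting=setting, subject=subj, pair=pair,
                                         area=name, stage=PRE, mad=s.mad, sdad=s.sdad,
                                         max_abs=s.max_abs, n=s.n_samples, note=""))
                sp = _pooled_summary(pre_samples, PRE)
                dev_rows.append(dict(setting=setting, subject=subj, pair=pair,
                                     area=POOLED_AREA, stage=PRE, mad=sp.mad,
                                     sdad=sp.sdad, max_abs=sp.max_abs,
                                     n=sp.n_samples, note=""))

                transform, _ = icp_register(mesh_a, mesh_b, ref, config.icp)
                dof = decompose_transform(transform)
                for comp, val in dof.as_dict().items():
                    mov_rows.append(dict(setting=setting, subject=subj, pair=pair,
                                         component=comp, value=float(val)))

                mesh_a_post = apply_transform(mesh_a, transform)
                post_samples = {
                    name: closest_distances(mesh_a_post, mesh_b, area, config.distance_mode)
                    for name, area in areas.items()
                }
                for name, smp in post_samples.items():
                    s = summarise(smp, POST, name)
                    dev_rows.append(dict(setting=setting, subject=subj, pair=pair,
                                         area=name, stage=POST, mad=s.mad, sdad=s.sdad,
                                         max_abs=s.max_abs, n=s.n_samples, note=""))
                sp = _pooled_summary(post_samples, POST)
                dev_rows.append(dict(setting=setting, subject=subj, pair=pair,
                                     area=POOLED_AREA, stage=POST, mad=sp.mad,
                                     sdad=sp.sdad, max_abs=sp.max_abs,
                                     n=sp.n_samples, note=""))
                mean_mad = float(np.mean([summarise(s, PRE, n).mad
                                          for n, s in pre_samples.items()]))
                pair_records.append((subj, pair, (setting, subj, i), (setting, subj, j), mean_mad))

        # colour-map representatives: min / median / max pre-superimposition MAD
        if pair_records:
            order = sorted(pair_records, key=lambda r: r[-1])
            picks = {"min": order[0], "median": order[len(order) // 2], "max": order[-1]}
            for which, rec in picks.items():
                map_cases.append(dict(setting=setting, case=which, subject=rec[0],
                                      pair=rec[1], query_key=rec[2], target_key=rec[3],
                                      mean_mad=rec[4], scale=config.repro_map_scale))

    deviations = pd.DataFrame(dev_rows)
    movements = pd.DataFrame(mov_rows)
    thresholds = pd.DataFrame(thr_rows)
    stat_results = {
        "thresholds": _threshold_stats(thresholds),
        "mad_pre": _family_stats(deviations, "mad", PRE),
        "mad_post": _family_stats(deviations, "mad", POST),
        "sdad_pre": _family_stats(deviations, "sdad", PRE),
        "sdad_post": _family_stats(deviations, "sdad", POST),
    }
    return ReproReport(config=config, deviations=deviations, movements=movements,
                       thresholds=thresholds, stat_results=stat_results,
                       map_cases=map_cases, meshes=meshes)


# ----------------------------------------------------------------------
# trueness workflow
# ----------------------------------------------------------------------

def run_trueness(config: StudyConfig) -> TruenessReport:
    """Trueness vs the analytic gold-standard mesh. See module docs."""
    dev_rows, mov_rows, thr_rows = [], [], []
    meshes: dict = {}
    map_cases: list[dict] = []

    for s_idx, (setting, spec0) in enumerate(sorted(config.settings.items())):
        case_records = []
        for subj in range(config.n_subjects):
            spec = replace(spec0, seed=_derived_seed(config.seed, s_idx, subj, 0))
            truth = ground_truth_mesh(spec, config.truth_edge_mm)
            truth_id = f"{setting}/s{subj}/truth"
            # measurement areas selected once, on the gold-standard surface
            areas = _build_areas(truth, spec, config.area_anchors,
                                 config.trueness_area_triangles, truth_id)
            ref_truth = _reference_area(truth, spec, config.reference_anchors,
                                        config.reference_triangles, truth_id)

            volume = simulate_acquisition(spec)
            thr = sample_operator_thresholds(
                spec.midpoint_threshold, config.threshold_spread,
                spec.intensity_full_range, 1,
                _derived_seed(config.seed, s_idx, subj, 1),
                value_range=spec.intensity_range,
            )
            thr_rows.append(dict(setting=setting, subject=subj, stream="operator_a",
                                 session=0, threshold=float(thr[0])))
            try:
                seg = _segment(volume, thr[0], spec, config.min_component_fraction)
            except ValueError as exc:
                dev_rows.append(dict(setting=setting, subject=subj, pair="aborted",
                                     area="none", stage="error", mad=np.nan,
                                     sdad=np.nan, max_abs=np.nan, n=0, note=str(exc)))
                continue
            seg_id = f"{setting}/s{subj}/seg"
            meshes[(setting, subj, "seg")] = seg
            meshes[(setting, subj, "truth")] = truth

            ref_seg = map_area(ref_truth, truth, seg, target_mesh_id=seg_id)
            transform, _ = icp_register(seg, truth, ref_seg, config.icp)
            for comp, val in decompose_transform(transform).as_dict().items():
                mov_rows.append(dict(setting=setting, subject=subj, pair="vs-truth",
                                     component=comp, value=float(val)))
            seg_fit = apply_transform(seg, transform)
            meshes[(setting, subj, "seg_fit")] = seg_fit

            samples = {
                name: closest_distances(truth, seg_fit, area, config.distance_mode)
                for name, area in areas.items()
            }
            for name, smp in samples.items():
                s = summarise(smp, POST, name)
                dev_rows.append(dict(setting=setting, subject=subj, pair="vs-truth",
                                     area=name, stage=POST, mad=s.mad, sdad=s.sdad,
                                     max_abs=s.max_abs, n=s.n_samples, note=""))
            sp = _pooled_summary(samples, POST)
            dev_rows.append(dict(setting=setting, subject=subj, pair="vs-truth",
                                 area=POOLED_AREA, stage=POST, mad=sp.mad, sdad=sp.sdad,
                                 max_abs=sp.max_abs, n=sp.n_samples, note=""))
            case_records.append((subj, (setting, subj, "truth"), (setting, subj, "seg_fit"), sp.mad))

        if case_records:
            order = sorted(case_records, key=lambda r: r[-1])
            picks = {"min": order[0], "median": order[len(order) // 2], "max": order[-1]}
            for which, rec in picks.items():
                map_cases.append(dict(setting=setting, case=which, subject=rec[0],
                                      pair="vs-truth", query_key=rec[1], target_key=rec[2],
                                      mean_mad=rec[3], scale=config.trueness_map_scale))

    deviations = pd.DataFrame(dev_rows)
    movements = pd.DataFrame(mov_rows)
    thresholds = pd.DataFrame(thr_rows)
    stat_results = {
        "mad_post": _family_stats(deviations, "mad", POST),
        "sdad_post": _family_stats(deviations, "sdad", POST),
    }
    return TruenessReport(config=config, deviations=deviations, movements=movements,
                          thresholds=thresholds, stat_results=stat_results,
                          map_cases=map_cases, meshes=meshes)


# ----------------------------------------------------------------------
# export / reload
# ----------------------------------------------------------------------

def _flag_outliers(df: pd.DataFrame, value_col: str, group_cols: list[str]) -> pd.DataFrame:
    """Box-plot outlier flags: beyond 1.5× and 3× IQR from the median."""
    df = df.copy()
    df["outlier_1_5"] = False
    df["outlier_3"] = False
    for _, idx in df.groupby(group_cols).groups.items():
        v = df.loc[idx, value_col]
        med = v.median()
        iqr = v.quantile(0.75) - v.quantile(0.25)
        if iqr > 0:
            df.loc[idx, "outlier_1_5"] = (v - med).abs() > 1.5 * iqr
            df.loc[idx, "outlier_3"] = (v - med).abs() > 3.0 * iqr
    return df


def export_report(report, out_dir) -> None:
    """Write a study report: CSV tables, stats JSON, maps, run manifest.

    The manifest (config dict, config hash, seed, package version) is
    sufficient to re-run the study bit-identically.
    """
    out = os.fspath(out_dir)
    os.makedirs(out, exist_ok=True)
    dev = _flag_outliers(report.deviations, "mad", ["setting", "stage", "area"]) \
        if len(report.deviations) else report.deviations
    dev.to_csv(os.path.join(out, "deviations.csv"), index=False)
    report.movements.to_csv(os.path.join(out, "movements.csv"), index=False)
    report.thresholds.to_csv(os.path.join(out, "thresholds.csv"), index=False)
    with open(os.path.join(out, "stats.json"), "w") as fh:
        json.dump(report.stat_results, fh, indent=2, sort_keys=True)
    manifest = {
        "kind": report.kind,
        "package": "osseosurf",
        "version": __version__,
        "seed": report.config.seed,
        "config_hash": report.config.config_hash(),
        "config": report.config.as_dict(),
        "euler_convention": "fixed-axis-XYZ",
        "distance_pooling": "raw distances pooled within each unified area before summarising",
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    if report.map_cases and report.meshes:
        maps_dir = os.path.join(out, "maps")
        os.makedirs(maps_dir, exist_ok=True)
        for case in report.map_cases:
            q = report.meshes.get(tuple(case["query_key"]))
            t = report.meshes.get(tuple(case["target_key"]))
            if q is None or t is None:
                continue
            dmap = distance_map(q, t, scale=case["scale"])
            stem = f"{case['setting']}_{case['case']}"
            export_distance_map(
                dmap,
                ply_path=os.path.join(maps_dir, stem + ".ply"),
                png_path=os.path.join(maps_dir, stem + ".png"),
                title=f"{case['setting']} ({case['case']}, ±{case['scale']} mm)",
            )


def load_report(out_dir):
    """Reload an exported report (tables and stats; meshes are not stored)."""
    out = os.fspath(out_dir)
    with open(os.path.join(out, "manifest.json")) as fh:
        manifest = json.load(fh)
    with open(os.path.join(out, "stats.json")) as fh:
        stat_results = json.load(fh)
    config = StudyConfig.from_dict(manifest["config"])
    frames = {
        name: pd.read_csv(os.path.join(out, f"{name}.csv"))
        for name in ("deviations", "movements", "thresholds")
    }
    cls = ReproReport if manifest["kind"] == "reproducibility" else TruenessReport
    return cls(config=config, deviations=frames["deviations"],
               movements=frames["movements"], thresholds=frames["thresholds"],
               stat_results=stat_results, kind=manifest["kind"])


# ----------------------------------------------------------------------
# scaled emulation of the printed reproducibility bounds
# ----------------------------------------------------------------------

def repeated_segmentation_emulation(
    seed: int,
    spec: PhantomSpec | None = None,
    repeats: int = 3,
    threshold_spread: float = 0.01,
    icp: ICPSettings | None = None,
    reference_triangles: int = 2000,
) -> dict:
    """Repeated-segmentation emulation on one noisy face-like phantom.

    Segments the same degraded volume ``repeats`` times with thresholds
    independently perturbed within ±``threshold_spread`` of the full
    intensity range around the bone/water midpoint, then measures, for
    every unordered pair of repeats:

    * the maximum per-vertex closest-point distance over the full
      surface at the original position (the colour maps' whole-surface
      bound), and
    * the six movement components of the point-to-plane best fit on the
      reference area.

    Returns the per-pair values plus the two headline maxima
    (``max_vertex_distance_mm`` and ``max_movement_component``).
    """
    spec = spec or face_like_spec(
        spacing=(0.3, 0.3, 0.3), psf_fwhm=0.6, noise_sigma=40.0, seed=seed
    )
    icp = icp or ICPSettings()
    volume = simulate_acquisition(spec)
    thresholds = sample_operator_thresholds(
        spec.midpoint_threshold, threshold_spread, spec.intensity_full_range,
        repeats, _derived_seed(seed, 7), value_range=spec.intensity_range,
    )
    reps = [_segment(volume, t, spec, 0.01) for t in thresholds]

    pair_rows = []
    for i, j in combinations(range(repeats), 2):
        samples = closest_distances(reps[i], reps[j])
        ref = _reference_area(reps[i], spec, DEFAULT_REFERENCE_ANCHORS,
                              min(reference_triangles, reps[i].n_faces // 2),
                              f"rep{i}")
        transform, _ = icp_register(reps[i], reps[j], ref, icp)
        dof = decompose_transform(transform)
        pair_rows.append({
            "pair": f"{i}-{j}",
            "threshold_i": float(thresholds[i]),
            "threshold_j": float(thresholds[j]),
            "max_vertex_distance_mm": float(samples.distances.max()),
            "mad_mm": float(samples.distances.mean()),
            "sixdof": dof.as_dict(),
            "max_movement_component": dof.max_component(),
            "n_vertices": len(samples),
        })
    return {
        "thresholds": [float(t) for t in thresholds],
        "pairs": pair_rows,
        "max_vertex_distance_mm": max(r["max_vertex_distance_mm"] for r in pair_rows),
        "max_movement_component": max(r["max_movement_component"] for r in pair_rows),
    }
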