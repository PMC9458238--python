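"""End-to-end orchestration: simulate, preprocess, segment, quantify
heterogeneity, run differential analysis, annotate, and report.

Stages communicate through files inside the run directory, so each
intermediate artifact can be inspected and re-used.  Every run writes a
machine-readable ``report.json`` and a provenance log (stage order,
parameters, input hashes); identical configurations produce identical
reports.

The module also hosts the cohort-level analyses used throughout:
:func:`analyze_study` pools all patients of a study bundle through one
preprocessing + DivIK segmentation and summarizes per-ROI heterogeneity,
and :func:`null_calibration` estimates the false-positive rate of the
group comparison on identically simulated arms.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as msio
from .differential import differential_components
from .heterogeneity import compare_groups, similarity_distribution, simpson_index
from .preprocess import (
    MSIDataset,
    PreprocessParams,
    PreprocessResult,
    preprocess_pipeline,
)
from .segmentation import DivikParams, SegmentationTree, cluster_sizes, divik
from .synthetic import SimulationConfig, StudyBundle, simulate_two_arm_study

__all__ = [
    "RunConfig",
    "PipelineError",
    "run_pipeline",
    "analyze_study",
    "null_calibration",
]


class PipelineError(RuntimeError):
    """A stage could not run; the message names the missing dependency."""


# ---------------------------------------------------------------------------
# Desk-scale study presets
# ---------------------------------------------------------------------------
#
# These are the standing conditions used by the worked example, the test
# suite and the reproduction script.  They keep the structure of the
# imaged cohort (shared peptide species, several spatially coherent
# clusters per ROI, realistic acquisition noise) at a problem size that
# runs on one CPU in minutes.


def two_arm_study_conditions(seed: int = 1):
    """High-ITH arm (4 balanced clusters) vs low-ITH arm (2 skewed
    clusters), 20 patients per arm, with per-patient Dirichlet variability
    of cluster composition."""
    high = SimulationConfig(
        mz_min=700.0,
        mz_max=1200.0,
        n_channels=5000,
        n_peaks=60,
        roi_shape=(16, 16),
        n_clusters_per_roi=4,
        cluster_proportions="balanced",
        proportion_concentration=50.0,
        n_patients_per_group=20,
        seed=seed,
    )
    low = dataclasses.replace(
        high, n_clusters_per_roi=2, cluster_proportions="skewed"
    )
    return high, low


def study_analysis_params():
    """Preprocessing and segmentation settings for the study presets."""
    prep = PreprocessParams(baseline_window=151, gmm_tol=1e-6)
    seg = DivikParams(max_levels=1, k_max=8, seed=0)
    return prep, seg


def null_calibration_conditions(seed: int = 0) -> SimulationConfig:
    """One tiny arm condition used for both arms of the null study."""
    return SimulationConfig(
        mz_min=700.0,
        mz_max=900.0,
        n_channels=1500,
        n_peaks=20,
        roi_shape=(10, 10),
        n_clusters_per_roi=4,
        cluster_proportions="balanced",
        proportion_concentration=50.0,
        n_patients_per_group=8,
        seed=seed,
    )


def null_calibration_params():
    prep = PreprocessParams(baseline_window=101, gmm_tol=1e-6)
    seg = DivikParams(max_levels=1, k_max=5, seed=0)
    return prep, seg


STAGES = (
    "simulate",
    "preprocess",
    "segment",
    "heterogeneity",
    "differential",
    "annotate",
    "report",
)


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    ``pooling`` controls which ROIs are clustered together: ``"all"``
    pools every dataset (the default, mirroring a cohort-level
    segmentation); per-patient schemes can be added by running separate
    configs.
    """

    out_dir: str
    seed: int = 0
    stages: tuple = STAGES[:-2]  # annotate is opt-in (needs a library)
    simulation: dict = field(default_factory=dict)
    simulation_low: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    divik: dict = field(default_factory=dict)
    level: int = 1
    max_pairs: int = 20_000
    pooling: str = "all"
    library_path: str | None = None
    annotation_tol: float = 5e-4

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"stage '{stage}' requires {path.name}, produced by stage "
            f"'{produced_by}' — run that stage first"
        )
    return path


# ---------------------------------------------------------------------------
# Cohort-level analysis (in memory)
# ---------------------------------------------------------------------------


def analyze_study(
    bundle: StudyBundle,
    *,
    preprocess_params: PreprocessParams | None = None,
    divik_params: DivikParams | None = None,
    level: int = 1,
    max_pairs: int = 20_000,
    seed: int = 0,
) -> dict:
    """Pooled analysis of a two-arm study bundle.

    All patients' spectra are preprocessed and segmented together; per
    tumor ROI the Simpson diversity (at the requested segmentation level)
    and the median intra-ROI similarity are computed, then compared
    between arms with the Wilcoxon rank-sum test.  Cluster contributions
    per ROI are reported for the cluster-composition contrast.
    """
    result: PreprocessResult = preprocess_pipeline(
        bundle.datasets(), preprocess_params
    )
    ds = result.dataset
    tree: SegmentationTree = divik(result.abundances, divik_params)
    labels = tree.labels(level, clip=True)
    cluster_ids = np.unique(labels)

    rows = []
    for roi_id, meta in ds.roi_meta.iterrows():
        if meta["tissue"] != "T":
            continue
        mask = ds.roi_labels == roi_id
        if mask.sum() < 2:
            continue
        counts = cluster_sizes(tree, level, mask) if tree.n_levels >= level else {
            0: int(mask.sum())
        }
        d = simpson_index(counts)
        sim = similarity_distribution(
            result.abundances.values,
            np.flatnonzero(mask),
            max_pairs=max_pairs,
            seed=seed + roi_id,
            context="intra-T",
            patient_id=meta["patient_id"],
        )
        contributions = {
            int(c): float(np.sum(labels[mask] == c) / mask.sum()) for c in cluster_ids
        }
        rows.append(
            {
                "patient_id": meta["patient_id"],
                "group": meta["group"],
                "n_clusters": len(counts),
                "simpson_d": d,
                "median_similarity": sim.median,
                "contributions": contributions,
            }
        )
    per_roi = pd.DataFrame(rows)
    arms = list(bundle.arm_names)
    by_arm = {a: per_roi[per_roi["group"] == a] for a in arms}
    simpson_cmp = compare_groups(
        {a: by_arm[a]["simpson_d"].to_numpy() for a in arms}
    )
    similarity_cmp = compare_groups(
        {a: by_arm[a]["median_similarity"].to_numpy() for a in arms}
    )
    contribution_tests = {}
    for c in cluster_ids:
        vals = {
            a: np.array([r[int(c)] for r in by_arm[a]["contributions"]])
            for a in arms
        }
        if all(len(v) >= 2 for v in vals.values()):
            contribution_tests[int(c)] = compare_groups(vals)
    return {
        "per_roi": per_roi,
        "n_components": result.model.n_components,
        "n_levels": tree.n_levels,
        "n_clusters_level": int(len(cluster_ids)),
        "simpson_comparison": simpson_cmp,
        "similarity_comparison": similarity_cmp,
        "contribution_tests": contribution_tests,
        "tree": tree,
        "preprocess": result,
    }


def null_calibration(
    base_config: SimulationConfig,
    *,
    n_replicates: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    preprocess_params: PreprocessParams | None = None,
    divik_params: DivikParams | None = None,
    level: int = 1,
    max_pairs: int = 2000,
) -> dict:
    """Rejection rate of the arm comparison when both arms are identical.

    Each replicate simulates two arms from the same configuration
    (independent random streams), runs the pooled pipeline and records
    the two-sided Wilcoxon p-value on per-patient Simpson diversity.
    Under the null the rejection rate at ``alpha`` should be close to
    ``alpha``.
    """
    p_values = []
    for rep in range(n_replicates):
        rep_seed = int(
            np.random.SeedSequence([seed, rep]).generate_state(1)[0] % (2**31)
        )
        cfg_a = dataclasses.replace(base_config, seed=rep_seed)
        cfg_b = dataclasses.replace(base_config, seed=rep_seed)
        bundle = simulate_two_arm_study(cfg_a, cfg_b, arm_names=("A", "B"))
        report = analyze_study(
            bundle,
            preprocess_params=preprocess_params,
            divik_params=divik_params,
            level=level,
            max_pairs=max_pairs,
            seed=rep_seed,
        )
        p_values.append(report["simpson_comparison"]["p_value"])
    p_values = np.asarray(p_values)
    return {
        "p_values": p_values,
        "rejection_rate": float(np.mean(p_values < alpha)),
        "alpha": alpha,
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------------------
# File-based pipeline
# ---------------------------------------------------------------------------


def _stage_simulate(config: RunConfig, out: Path, log: list) -> None:
    cfg_high = SimulationConfig(**{"seed": config.seed, **config.simulation})
    low_kwargs = {**config.simulation, **config.simulation_low}
    cfg_low = SimulationConfig(**{"seed": config.seed, **low_kwargs})
    bundle = simulate_two_arm_study(cfg_high, cfg_low)
    sim_dir = out / "sim"
    sim_dir.mkdir(parents=True, exist_ok=True)
    metas = []
    for i, pat in enumerate(bundle.patients):
        msio.write_matrix(pat.dataset, sim_dir / f"{pat.patient_id}.bin")
        msio.write_ground_truth(pat.truth, sim_dir / f"{pat.patient_id}.truth.json")
        meta = pat.dataset.roi_meta.copy()
        meta.insert(0, "file", f"{pat.patient_id}.bin")
        metas.append(meta)
    pd.concat(metas, ignore_index=True).to_csv(
        sim_dir / "meta.tsv", sep="\t", index=False
    )
    log.append({"stage": "simulate", "n_patients": len(bundle.patients)})


def _load_sim(out: Path, stage: str) -> list[MSIDataset]:
    sim_dir = out / "sim"
    meta_path = _require(sim_dir / "meta.tsv", stage, "simulate")
    meta = pd.read_csv(meta_path, sep="\t")
    datasets = []
    for fname, rows in meta.groupby("file", sort=False):
        ds = msio.read_matrix(
            sim_dir / fname, roi_meta=rows.drop(columns=["file"]).reset_index(drop=True)
        )
        datasets.append(ds)
    return datasets


def _stage_preprocess(config: RunConfig, out: Path, log: list) -> None:
    import h5py

    datasets = _load_sim(out, "preprocess")
    result = preprocess_pipeline(datasets, PreprocessParams(**config.preprocess))
    with h5py.File(out / "abundances.h5", "w") as fh:
        fh.create_dataset("values", data=result.abundances.values)
        fh.create_dataset("component_ids", data=result.abundances.component_ids)
        fh.create_dataset("roi_labels", data=result.dataset.roi_labels)
        fh.create_dataset("means", data=result.model.means)
        fh.create_dataset("sigmas", data=result.model.sigmas)
        fh.create_dataset("weights", data=result.model.weights)
    result.dataset.roi_meta.to_csv(out / "roi_meta.tsv", sep="\t", index=False)
    result.model.to_json(out / "model.json")
    log.append(
        {
            "stage": "preprocess",
            "provenance": list(result.provenance),
            "n_components": result.model.n_components,
            "n_outliers": int(result.outlier_flags.sum()),
        }
    )


def _read_abundances(out: Path, stage: str):
    import h5py

    path = _require(out / "abundances.h5", stage, "preprocess")
    with h5py.File(path, "r") as fh:
        values = fh["values"][...]
        roi_labels = fh["roi_labels"][...]
    return values, roi_labels


def _stage_segment(config: RunConfig, out: Path, log: list) -> None:
    values, _ = _read_abundances(out, "segment")
    params = DivikParams(**{"seed": config.seed, **config.divik})
    tree = divik(values, params)
    msio.write_tree(tree, out / "tree")
    log.append(
        {
            "stage": "segment",
            "n_levels": tree.n_levels,
            "clusters_per_level": [tree.n_clusters(lv) for lv in range(1, tree.n_levels + 1)],
        }
    )


def _stage_heterogeneity(config: RunConfig, out: Path, log: list) -> dict:
    values, roi_labels = _read_abundances(out, "heterogeneity")
    labels_path = _require(out / "tree" / "labels.tsv", "heterogeneity", "segment")
    labels_df = pd.read_csv(labels_path, sep="\t")
    col = f"level_{min(config.level, labels_df.shape[1] - 1)}"
    labels = (
        labels_df[col].to_numpy()
        if col in labels_df
        else np.zeros(len(labels_df), dtype=int)
    )
    roi_meta = pd.read_csv(_require(out / "roi_meta.tsv", "heterogeneity", "preprocess"), sep="\t")
    rows = []
    for roi_id, meta in roi_meta.iterrows():
        mask = roi_labels == roi_id
        if meta["tissue"] != "T" or mask.sum() < 2:
            continue
        ids, counts = np.unique(labels[mask], return_counts=True)
        sim = similarity_distribution(
            values,
            np.flatnonzero(mask),
            max_pairs=config.max_pairs,
            seed=config.seed + roi_id,
            patient_id=meta["patient_id"],
        )
        rows.append(
            {
                "patient_id": meta["patient_id"],
                "group": meta["group"],
                "n_clusters": len(ids),
                "simpson_d": simpson_index(counts),
                "median_similarity": sim.median,
            }
        )
    het = pd.DataFrame(rows)
    het.to_csv(out / "heterogeneity.tsv", sep="\t", index=False)
    groups = het["group"].unique().tolist()
    comp = {}
    if len(groups) == 2 and all((het["group"] == g).sum() >= 2 for g in groups):
        comp = {
            "simpson": compare_groups(
                {g: het.loc[het["group"] == g, "simpson_d"] for g in groups}
            ),
            "similarity": compare_groups(
                {g: het.loc[het["group"] == g, "median_similarity"] for g in groups}
            ),
        }
    log.append({"stage": "heterogeneity", "n_rois": len(het)})
    return comp


def _stage_differential(config: RunConfig, out: Path, log: list) -> dict:
    values, roi_labels = _read_abundances(out, "differential")
    roi_meta = pd.read_csv(_require(out / "roi_meta.tsv", "differential", "preprocess"), sep="\t")
    group_of_roi = roi_meta["group"].to_numpy()
    pixel_group = np.where(roi_labels >= 0, group_of_roi[roi_labels], "none")
    groups = [g for g in pd.unique(pixel_group) if g != "none"]
    summary: dict = {}
    if len(groups) == 2:
        a = np.flatnonzero(pixel_group == groups[0])
        b = np.flatnonzero(pixel_group == groups[1])
        table = differential_components(
            values, a, b, contrast=f"{groups[0]}-vs-{groups[1]}"
        )
        table.to_csv(out / "effect_sizes.tsv", sep="\t", index=False)
        summary = {
            "contrast": f"{groups[0]}-vs-{groups[1]}",
            "n_selected_medium": int(table["selected"].sum()),
            "magnitude_counts": table["magnitude"].value_counts().to_dict(),
        }
    log.append({"stage": "differential", **summary})
    return summary


def _stage_annotate(config: RunConfig, out: Path, log: list) -> None:
    from .annotation import PeptideLibrary, match_components
    from .preprocess import ComponentModel

    if config.library_path is None:
        raise PipelineError(
            "stage 'annotate' requires a peptide library; set library_path"
        )
    model = ComponentModel.from_json(
        _require(out / "model.json", "annotate", "preprocess")
    )
    library = PeptideLibrary.from_tsv(config.library_path)
    table = match_components(model, library, tol=config.annotation_tol)
    table.to_csv(out / "annotations.tsv", sep="\t", index=False)
    log.append({"stage": "annotate", "n_matches": len(table)})


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in canonical order and write the run
    report plus a provenance log into the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")
    unknown = set(config.stages) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stages {sorted(unknown)}")
    log: list = []
    report: dict = {"seed": config.seed, "stages": []}
    for stage in STAGES:
        if stage not in config.stages and stage != "report":
            continue
        if stage == "simulate":
            _stage_simulate(config, out, log)
        elif stage == "preprocess":
            _stage_preprocess(config, out, log)
        elif stage == "segment":
            _stage_segment(config, out, log)
        elif stage == "heterogeneity":
            report["group_comparisons"] = _stage_heterogeneity(config, out, log)
        elif stage == "differential":
            report["differential"] = _stage_differential(config, out, log)
        elif stage == "annotate":
            _stage_annotate(config, out, log)
        report["stages"].append(stage)
    # config.json echoes the (path-bearing) input and is not an artifact
    artifacts = sorted(
        p
        for p in out.rglob("*")
        if p.is_file()
        and p.name not in ("report.json", "provenance.json", "config.json")
    )
    provenance = {
        "log": log,
        "artifact_hashes": {str(p.relative_to(out)): _hash_file(p) for p in artifacts},
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1, default=str)
    report["provenance_digest"] = hashlib.sha256(
        json.dumps(provenance, sort_keys=True, default=str).encode()
    ).hexdigest()
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report
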