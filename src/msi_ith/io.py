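"""File formats: imzML, the internal binary matrix, and TSV/JSON sidecars.

imzML is the community exchange format for MSI data (continuous mode: one
shared m/z axis).  For fast round-trips the package also defines a simple
binary matrix container:

* 8-byte little-endian unsigned header length ``L``;
* ``L`` bytes of UTF-8 JSON with keys ``shape`` (pixels, channels),
  ``dtype`` (always ``float32``), ``mz_axis``, ``coords`` and
  ``roi_labels``;
* the pixel x channel intensity matrix as C-order float32.

ROI/patient metadata travel in a TSV sidecar with one row per ROI
(``roi_id``, ``patient_id``, ``group``, ``tissue``, ``lhr_category``);
ground truth is JSON.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import AbundanceMatrix, MSIDataset
from .segmentation import SegmentationTree
from .synthetic import GroundTruth

__all__ = [
    "write_imzml",
    "read_imzml",
    "write_matrix",
    "read_matrix",
    "write_roi_meta",
    "read_roi_meta",
    "write_ground_truth",
    "write_tree",
    "write_abundances_tsv",
    "write_cluster_map_png",
]


# ---------------------------------------------------------------------------
# imzML
# ---------------------------------------------------------------------------


def write_imzml(dataset: MSIDataset, path) -> None:
    """Write a dataset as continuous-mode imzML (plus the paired .ibd)."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    path = str(path)
    with ImzMLWriter(path, mode="continuous") as writer:
        for p in range(dataset.n_pixels):
            x, y = dataset.coords[p]
            writer.addSpectrum(
                dataset.mz_axis,
                np.asarray(dataset.spectra[p], dtype=float),
                (int(x) + 1, int(y) + 1),  # imzML coordinates are 1-based
            )


def read_imzml(path, roi_meta: pd.DataFrame | None = None,
               roi_labels: np.ndarray | None = None) -> MSIDataset:
    """Read an imzML file into an :class:`MSIDataset`.

    Continuous mode uses the shared axis directly; processed mode
    resamples every spectrum onto the axis of the first pixel.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    parser = ImzMLParser(str(path))
    mz0, _ = parser.getspectrum(0)
    mz0 = np.asarray(mz0, dtype=float)
    n = len(parser.coordinates)
    spectra = np.empty((n, len(mz0)), dtype=float)
    coords = np.empty((n, 2), dtype=int)
    for p in range(n):
        mz, inten = parser.getspectrum(p)
        mz = np.asarray(mz, dtype=float)
        inten = np.asarray(inten, dtype=float)
        if len(mz) == len(mz0) and np.allclose(mz, mz0):
            spectra[p] = inten
        else:
            spectra[p] = np.interp(mz0, mz, inten)
        coords[p] = (parser.coordinates[p][0] - 1, parser.coordinates[p][1] - 1)
    if roi_labels is None:
        roi_labels = np.zeros(n, dtype=int)
    if roi_meta is None:
        roi_meta = pd.DataFrame(
            [{"patient_id": "P01", "group": "NED", "tissue": "T",
              "lhr_category": "intermediate"}]
        )
    return MSIDataset(
        mz_axis=mz0, spectra=spectra, coords=coords,
        roi_labels=roi_labels, roi_meta=roi_meta,
    )


# ---------------------------------------------------------------------------
# Internal binary matrix format
# ---------------------------------------------------------------------------

_MAGIC = "msi-ith-matrix-v1"


def write_matrix(dataset: MSIDataset, path) -> None:
    header = json.dumps(
        {
            "magic": _MAGIC,
            "shape": list(dataset.spectra.shape),
            "dtype": "float32",
            "mz_axis": dataset.mz_axis.tolist(),
            "coords": dataset.coords.tolist(),
            "roi_labels": dataset.roi_labels.tolist(),
        }
    ).encode()
    with open(path, "wb") as fh:
        fh.write(struct.pack("<Q", len(header)))
        fh.write(header)
        fh.write(np.ascontiguousarray(dataset.spectra, dtype=np.float32).tobytes())


def read_matrix(path, roi_meta: pd.DataFrame | None = None) -> MSIDataset:
    with open(path, "rb") as fh:
        (hlen,) = struct.unpack("<Q", fh.read(8))
        header = json.loads(fh.read(hlen).decode())
        if header.get("magic") != _MAGIC:
            raise ValueError("not an msi-ith matrix file")
        shape = tuple(header["shape"])
        data = np.frombuffer(fh.read(), dtype=np.float32).reshape(shape)
    if roi_meta is None:
        roi_meta = pd.DataFrame(
            [{"patient_id": "P01", "group": "NED", "tissue": "T",
              "lhr_category": "intermediate"}]
        )
    return MSIDataset(
        mz_axis=np.asarray(header["mz_axis"], dtype=float),
        spectra=np.asarray(data, dtype=float),
        coords=np.asarray(header["coords"], dtype=int),
        roi_labels=np.asarray(header["roi_labels"], dtype=int),
        roi_meta=roi_meta,
    )


# ---------------------------------------------------------------------------
# Sidecars
# ---------------------------------------------------------------------------


def write_roi_meta(dataset: MSIDataset, path) -> None:
    meta = dataset.roi_meta.copy()
    meta.insert(0, "roi_id", np.arange(len(meta)))
    meta.to_csv(path, sep="\t", index=False)


def read_roi_meta(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").drop(columns=["roi_id"], errors="ignore")


def write_ground_truth(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "peak_means": truth.peak_means.tolist(),
                "peak_sigmas": truth.peak_sigmas.tolist(),
                "cluster_label_map": truth.cluster_label_map.tolist(),
                "cluster_mean_profiles": truth.cluster_mean_profiles.tolist(),
                "outlier_mask": truth.outlier_mask.astype(int).tolist(),
            },
            fh,
        )


def write_tree(tree: SegmentationTree, out_dir) -> None:
    """Serialize a segmentation tree: node table as JSON, labels as TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nodes = {
        str(nid): {
            "level": n.level,
            "parent": n.parent,
            "n_pixels": int(len(n.pixel_index)),
            "chosen_k": n.chosen_k,
            "dunn": None if n.dunn is None else float(n.dunn),
            "children": n.children,
            "feature_mask": None
            if n.feature_mask is None
            else np.flatnonzero(n.feature_mask).tolist(),
        }
        for nid, n in tree.nodes.items()
    }
    with open(out_dir / "tree.json", "w") as fh:
        json.dump({"n_pixels": tree.n_pixels, "n_levels": tree.n_levels,
                   "nodes": nodes}, fh, indent=1)
    labels = pd.DataFrame({"pixel_id": np.arange(tree.n_pixels)})
    for lv in range(1, tree.n_levels + 1):
        labels[f"level_{lv}"] = tree.labels(lv)
    labels.to_csv(out_dir / "labels.tsv", sep="\t", index=False)


def write_abundances_tsv(abundances: AbundanceMatrix, path) -> None:
    pd.DataFrame(
        abundances.values,
        columns=[f"c{int(k)}" for k in abundances.component_ids],
    ).to_csv(path, sep="\t", index=False)


def write_cluster_map_png(
    coords: np.ndarray, labels: np.ndarray, path, dpi: int = 100
) -> None:
    """Render per-pixel cluster labels as a PNG label image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = np.asarray(coords, dtype=int)
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(coords[:, 0], coords[:, 1], c=labels, s=4, cmap="tab20", marker="s")
    ax.set_aspect("equal")
    ax.invert_yaxis()
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
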