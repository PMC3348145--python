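"""Readers and writers for the pipeline's plain-text and image formats.

Conventions: sample_id is the join key everywhere; expression matrices are
TSV with genes in rows and a header of sample ids; clinical tables are TSV
with columns sample_id, response, os_months, os_event, pfs_months,
pfs_event, age, stage, grade; images are 8-bit grayscale PNG or TIFF with a
JSON ground-truth sidecar when synthetic.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .synthetic import EllipseSpec, ImageGroundTruth


def write_image(path: str | Path, image: np.ndarray) -> None:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, image)
    else:
        iio.imwrite(path, image)


def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return tifffile.imread(path)
    return iio.imread(path)


def write_truth(path: str | Path, truth: ImageGroundTruth) -> None:
    payload = {
        "image_shape": list(truth.image_shape),
        "seed": truth.seed,
        "nuclei": [dataclasses.asdict(e) for e in truth.nuclei],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path: str | Path) -> ImageGroundTruth:
    payload = json.loads(Path(path).read_text())
    return ImageGroundTruth(
        nuclei=[EllipseSpec(**e) for e in payload["nuclei"]],
        image_shape=tuple(payload["image_shape"]),
        seed=payload["seed"],
    )


def write_expression(path: str | Path, matrix: pd.DataFrame) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def read_expression(path: str | Path) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", index_col="gene_id")
    matrix.columns.name = "sample_id"
    return matrix


def write_clinical(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index_label="sample_id")


def read_clinical(path: str | Path) -> pd.DataFrame:
    required = {"response", "os_months", "os_event", "pfs_months", "pfs_event"}
    table = pd.read_csv(path, sep="\t", index_col="sample_id",
                        dtype={"stage": str, "grade": str})
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"clinical table {path} lacks columns: {sorted(missing)}")
    return table


def read_labels(path: str | Path) -> pd.Series:
    return read_clinical(path)["response"]


def write_feature_matrix(path: str | Path, matrix: pd.DataFrame) -> None:
    matrix.to_csv(path, index_label="sample_id")


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample_id")
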