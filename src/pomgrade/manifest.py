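"""Manifest and image I/O: PNG trees with CSV label manifests.

A dataset on disk is a directory of PNGs plus a ``manifest.csv`` with
columns (path, fruit_id, view_id, label[, provenance]); paths are relative
to the manifest's directory, labels are grade codes 0/1/2.
"""

from __future__ import annotations

import os
from typing import List, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .grades import GradeLabel
from .sample import ImageSample

MANIFEST_COLUMNS = ["path", "fruit_id", "view_id", "label", "provenance"]


def write_samples(samples: Sequence[ImageSample], out_dir: str,
                  manifest_name: str = "manifest.csv") -> pd.DataFrame:
    """Write PNGs under ``out_dir/<grade-name>/`` plus a manifest CSV."""
    rows = []
    for i, s in enumerate(samples):
        rel = os.path.join(s.label.name,
                           f"fruit{s.fruit_id}_view{s.view_id}_{s.provenance}_{i}.png")
        path = os.path.join(out_dir, rel)
        os.makedirs(os.path.dirname(path), exist_ok=True)
        iio.imwrite(path, s.pixels)
        rows.append(dict(path=rel, fruit_id=s.fruit_id, view_id=s.view_id,
                         label=s.label.code, provenance=s.provenance))
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(os.path.join(out_dir, manifest_name), index=False)
    return manifest


def read_manifest(manifest_path: str) -> pd.DataFrame:
    df = pd.read_csv(manifest_path)
    missing = {"path", "fruit_id", "view_id", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest {manifest_path} missing columns {missing}")
    if "provenance" not in df.columns:
        df["provenance"] = "original"
    return df


def load_samples(manifest_path: str) -> List[ImageSample]:
    """Load every image referenced by a manifest."""
    root = os.path.dirname(os.path.abspath(manifest_path))
    df = read_manifest(manifest_path)
    samples = []
    for row in df.itertuples(index=False):
        px = np.asarray(iio.imread(os.path.join(root, row.path)))
        if px.ndim == 2:
            px = np.stack([px] * 3, axis=-1)
        samples.append(ImageSample(pixels=px[:, :, :3].astype(np.uint8),
                                   label=GradeLabel(int(row.label)),
                                   fruit_id=int(row.fruit_id),
                                   view_id=int(row.view_id),
                                   provenance=str(row.provenance)))
    return samples


def write_manifest_rows(samples: Sequence[ImageSample], paths: Sequence[str],
                        out_csv: str) -> pd.DataFrame:
    rows = [dict(path=p, fruit_id=s.fruit_id, view_id=s.view_id,
                 label=s.label.code, provenance=s.provenance)
            for s, p in zip(samples, paths)]
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    df.to_csv(out_csv, index=False)
    return df
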