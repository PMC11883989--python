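"""Readers and writers for the pipeline's standard formats.

Images are single- or multi-page TIFF (tifffile); count matrices are TSV
with genes in rows and a header row of sample ids; gene sets are GMT;
ground truth and run metadata are JSON sidecars; configuration is YAML.
Every writer here has a paired reader that round-trips without loss.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "write_tiff", "read_tiff",
    "write_counts_tsv", "read_counts_tsv",
    "write_gmt", "read_gmt",
    "write_json", "read_json",
    "read_yaml", "write_yaml",
]


def write_tiff(path, image: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32),
                     photometric="minisblack")


def read_tiff(path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_counts_tsv(path, counts: pd.DataFrame) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_gmt(path, gene_sets: dict) -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, "na", *map(str, members)]) + "\n")


def read_gmt(path) -> dict:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3 and parts[0]:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.bool_):
            return bool(obj)
        return super().default(obj)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, cls=_NumpyEncoder, indent=1,
                                     sort_keys=True))


def read_json(path):
    return json.loads(Path(path).read_text())


def read_yaml(path):
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(path, obj) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
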