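"""Dataset containers, file formats, and model persistence.

Expression matrices travel either as a MatrixMarket triplet directory
(``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv``, the common
single-cell layout with genes as rows) or as a single delimited table
(objects as rows, header of gene names).  Coordinates and labels live in
companion delimited files keyed by object id.  Fitted models round-trip
through a single versioned JSON archive; float64 values survive the trip
bit-exactly because JSON serialization uses shortest-round-trip reprs.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

FIT_FORMAT_VERSION = 1

__all__ = [
    "Dataset",
    "read_dataset",
    "write_dataset",
    "save_fit",
    "load_fit",
    "FIT_FORMAT_VERSION",
]


@dataclass
class Dataset:
    """An objects-by-genes matrix with names and optional annotations."""

    counts: np.ndarray
    gene_names: list
    obs_names: list
    coords: np.ndarray | None = None
    labels: np.ndarray | None = None
    label_order: list | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n, m = self.counts.shape
        if len(self.gene_names) != m:
            raise ValueError(
                f"{len(self.gene_names)} gene names for {m} matrix columns"
            )
        if len(self.obs_names) != n:
            raise ValueError(
                f"{len(self.obs_names)} object ids for {n} matrix rows"
            )
        if len(set(self.gene_names)) != m:
            dupes = sorted({g for g in self.gene_names
                            if self.gene_names.count(g) > 1})
            raise ValueError(f"duplicate gene names: {dupes[:10]}")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=np.float64)
            if self.coords.shape != (n, 2):
                raise ValueError(f"coords must be ({n}, 2), got {self.coords.shape}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (n,):
                raise ValueError(f"labels must be ({n},), got {self.labels.shape}")
            if self.label_order is not None:
                known = {str(l) for l in self.label_order}
                unknown = sorted({str(l) for l in self.labels.tolist()
                                  if str(l) not in known})
                if unknown:
                    raise ValueError(f"labels outside declared order: {unknown}")

    @property
    def n_obs(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


def _read_names(path: str) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def _read_companion(path: str, obs_names: list, n_value_cols: int):
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < n_value_cols + 1:
        raise ValueError(f"{path}: expected id column plus {n_value_cols} value column(s)")
    df = df.set_index(df.columns[0])
    missing = [o for o in obs_names if o not in df.index]
    if missing:
        raise ValueError(f"{path}: missing entries for objects {missing[:10]}")
    return df.loc[obs_names]


def read_dataset(path: str, format: str = "mtx_dir") -> Dataset:
    """Read an expression dataset plus optional coordinate/label companions.

    ``mtx_dir``: a directory with ``matrix.mtx``, ``genes.tsv``,
    ``barcodes.tsv`` and optionally ``coords.tsv`` / ``labels.tsv``.
    Orientation is auto-detected from the matrix dimensions against the
    companion name files; genes-as-rows matrices are transposed to
    objects x genes.

    ``delimited``: a single table whose header row names the genes and
    whose first column holds object ids; optional companions sit next to
    it as ``<stem>.coords.tsv`` / ``<stem>.labels.tsv``.
    """
    if format == "mtx_dir":
        mtx_path = os.path.join(path, "matrix.mtx")
        genes = _read_names(os.path.join(path, "genes.tsv"))
        barcodes = _read_names(os.path.join(path, "barcodes.tsv"))
        raw = mmread(mtx_path)
        mat = raw.toarray() if hasattr(raw, "toarray") else np.asarray(raw)
        if mat.shape == (len(genes), len(barcodes)):
            counts = mat.T
        elif mat.shape == (len(barcodes), len(genes)):
            counts = mat
        else:
            raise ValueError(
                f"matrix shape {mat.shape} matches neither genes x barcodes "
                f"({len(genes)}, {len(barcodes)}) nor its transpose"
            )
        coords = labels = label_order = None
        coords_path = os.path.join(path, "coords.tsv")
        if os.path.exists(coords_path):
            coords = _read_companion(coords_path, barcodes, 2).iloc[:, :2].to_numpy(
                dtype=np.float64
            )
        labels_path = os.path.join(path, "labels.tsv")
        if os.path.exists(labels_path):
            df = _read_companion(labels_path, barcodes, 1)
            # companion files carry labels as text; keep them as strings
            labels = df.iloc[:, 0].astype(str).to_numpy()
            order_path = os.path.join(path, "label_order.tsv")
            if os.path.exists(order_path):
                label_order = _read_names(order_path)
        return Dataset(counts=counts, gene_names=genes, obs_names=barcodes,
                       coords=coords, labels=labels, label_order=label_order)
    if format == "delimited":
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        stem, _ = os.path.splitext(path)
        obs = [str(o) for o in df.index]
        coords = labels = None
        cpath = stem + ".coords.tsv"
        if os.path.exists(cpath):
            coords = _read_companion(cpath, obs, 2).iloc[:, :2].to_numpy(np.float64)
        lpath = stem + ".labels.tsv"
        if os.path.exists(lpath):
            labels = _read_companion(lpath, obs, 1).iloc[:, 0].to_numpy()
        return Dataset(counts=df.to_numpy(), gene_names=list(df.columns),
                       obs_names=obs, coords=coords, labels=labels)
    raise ValueError(f"unknown format {format!r}; expected 'mtx_dir' or 'delimited'")


def write_dataset(ds: Dataset, path: str, format: str = "mtx_dir") -> None:
    """Write a dataset in a format :func:`read_dataset` can read back."""
    if format == "mtx_dir":
        os.makedirs(path, exist_ok=True)
        # genes-as-rows, the prevailing single-cell triplet convention
        mmwrite(os.path.join(path, "matrix.mtx"), coo_matrix(ds.counts.T))
        with open(os.path.join(path, "genes.tsv"), "w") as fh:
            fh.writelines(f"{g}\n" for g in ds.gene_names)
        with open(os.path.join(path, "barcodes.tsv"), "w") as fh:
            fh.writelines(f"{o}\n" for o in ds.obs_names)
        if ds.coords is not None:
            with open(os.path.join(path, "coords.tsv"), "w") as fh:
                fh.write("obs\tx\ty\n")
                for o, (x, y) in zip(ds.obs_names, ds.coords):
                    fh.write(f"{o}\t{float(x)!r}\t{float(y)!r}\n")
        if ds.labels is not None:
            with open(os.path.join(path, "labels.tsv"), "w") as fh:
                fh.write("obs\tlabel\n")
                for o, l in zip(ds.obs_names, ds.labels):
                    fh.write(f"{o}\t{l}\n")
            if ds.label_order is not None:
                with open(os.path.join(path, "label_order.tsv"), "w") as fh:
                    fh.writelines(f"{l}\n" for l in ds.label_order)
        return
    if format == "delimited":
        pd.DataFrame(ds.counts, index=ds.obs_names, columns=ds.gene_names).to_csv(
            path, sep="\t"
        )
        stem, _ = os.path.splitext(path)
        if ds.coords is not None:
            pd.DataFrame(ds.coords, index=ds.obs_names, columns=["x", "y"]).to_csv(
                stem + ".coords.tsv", sep="\t", index_label="obs"
            )
        if ds.labels is not None:
            pd.DataFrame({"label": ds.labels}, index=ds.obs_names).to_csv(
                stem + ".labels.tsv", sep="\t", index_label="obs"
            )
        return
    raise ValueError(f"unknown format {format!r}")


def save_fit(fit, path: str) -> None:
    """Serialize a fitted pipeline to a single versioned JSON archive."""
    payload = {"format_version": FIT_FORMAT_VERSION, "fit": fit.to_dict()}
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_fit(path: str):
    """Load a fitted pipeline archive written by :func:`save_fit`."""
    from .pipeline import FitResult

    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupted model archive {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ValueError(f"{path} is not a model archive")
    version = payload["format_version"]
    if version != FIT_FORMAT_VERSION:
        raise ValueError(
            f"model archive version {version} unsupported "
            f"(this build reads version {FIT_FORMAT_VERSION})"
        )
    return FitResult.from_dict(payload["fit"])
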