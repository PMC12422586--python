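"""Readers, writers and the model archive.

Counts travel as TSV/CSV (gene-id first column, sample-id header) or
MatrixMarket triplets with gene/sample index sidecar files.  A fitted
:class:`~depsim.copula.ReferenceModel` is archived as a single ``.npz``
container of named arrays plus a JSON metadata block; the round trip is
exact, so a reloaded model simulates bit-identically under equal seeds.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio, sparse

from ._version import __version__ as _pkg_version
from .marginals import CountsMatrix, MarginalModel
from .covariance import CovarianceFactors
from .copula import ReferenceModel

__all__ = ["read_counts", "write_counts", "save_model", "load_model"]

ARCHIVE_FORMAT_VERSION = 1


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("tsv", "csv", "mtx", "txt"):
        return "tsv" if suffix == "txt" else suffix
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def read_counts(
    path: str | Path, format: str | None = None, *, counts_mode: bool = True
) -> CountsMatrix:
    """Read a genes x samples matrix from TSV/CSV or MatrixMarket.

    For ``mtx``, gene and sample ids are read from sibling files
    ``<stem>.genes.txt`` and ``<stem>.samples.txt`` (one id per line).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt in ("tsv", "csv"):
        df = pd.read_csv(path, sep="\t" if fmt == "tsv" else ",", index_col=0)
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()[:5]
            raise ValueError(f"duplicate gene ids in {path.name}: {dups}")
        values = df.to_numpy(dtype=float)
        gene_ids = df.index.to_numpy(dtype=object)
        sample_ids = df.columns.to_numpy(dtype=object)
    elif fmt == "mtx":
        mat = spio.mmread(path)
        values = np.asarray(
            mat.todense() if sparse.issparse(mat) else mat, dtype=float
        )
        gene_ids = np.loadtxt(
            path.with_suffix("").with_suffix(".genes.txt"), dtype=str, ndmin=1
        ).astype(object)
        sample_ids = np.loadtxt(
            path.with_suffix("").with_suffix(".samples.txt"), dtype=str, ndmin=1
        ).astype(object)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return CountsMatrix(
        values=values,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        counts_mode=counts_mode,
    )


def write_counts(
    data, path: str | Path, format: str | None = None
) -> None:
    """Write a CountsMatrix or SimulatedDataset to TSV/CSV or MTX."""
    path = Path(path)
    fmt = _infer_format(path, format)
    values = np.asarray(data.values)
    gene_ids = np.asarray(data.gene_ids)
    sample_ids = np.asarray(
        getattr(data, "sample_ids", [f"sample_{j}" for j in range(values.shape[1])])
    )
    if fmt in ("tsv", "csv"):
        df = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t" if fmt == "tsv" else ",")
    elif fmt == "mtx":
        spio.mmwrite(path, sparse.coo_matrix(values))
        np.savetxt(path.with_suffix("").with_suffix(".genes.txt"), gene_ids, fmt="%s")
        np.savetxt(
            path.with_suffix("").with_suffix(".samples.txt"), sample_ids, fmt="%s"
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")


def save_model(model: ReferenceModel, path: str | Path) -> None:
    """Archive a fitted model as named arrays + a JSON metadata block."""
    path = Path(path)
    meta = {
        "archive_format_version": ARCHIVE_FORMAT_VERSION,
        "package_version": _pkg_version,
        "family": model.marginals.family,
        "method": model.factors.method,
        "k": model.factors.k,
        "c": model.factors.c,
        "metadata": model.metadata,
        "has_size_factors": model.size_factors is not None,
        "param_keys": sorted(model.marginals.params.keys()),
    }
    arrays = {
        "gene_ids": model.gene_ids.astype(str),
        "sample_ids": model.sample_ids.astype(str),
        "D": model.factors.D,
        "U": model.factors.U,
        "W": model.factors.W,
        "degenerate": (
            np.zeros(model.p, dtype=bool)
            if model.marginals.degenerate is None
            else model.marginals.degenerate
        ),
        "meta_json": np.array(json.dumps(meta)),
    }
    if model.size_factors is not None:
        arrays["size_factors"] = np.asarray(model.size_factors, dtype=float)
    for key, val in model.marginals.params.items():
        arrays[f"param_{key}"] = np.asarray(val)
    np.savez(path, **arrays)


def load_model(
    path: str | Path, *, expect_gene_ids=None
) -> ReferenceModel:
    """Load an archived model; the inverse of :func:`save_model`.

    ``expect_gene_ids`` (optional) refuses archives fitted on a
    different gene set.
    """
    path = Path(path)
    try:
        with np.load(path, allow_pickle=False) as npz:
            arrays = {k: npz[k] for k in npz.files}
    except Exception as exc:
        raise ValueError(f"cannot read model archive {path.name!r}: {exc}") from exc
    if "meta_json" not in arrays:
        raise ValueError(f"{path.name!r} is not a depsim model archive")
    meta = json.loads(str(arrays["meta_json"]))
    if meta.get("archive_format_version") != ARCHIVE_FORMAT_VERSION:
        raise ValueError(
            f"archive format version {meta.get('archive_format_version')} "
            f"is not supported (expected {ARCHIVE_FORMAT_VERSION})"
        )
    gene_ids = arrays["gene_ids"].astype(object)
    if expect_gene_ids is not None and not np.array_equal(
        gene_ids, np.asarray(expect_gene_ids, dtype=object)
    ):
        raise ValueError("archive was fitted on a different gene set")
    params = {
        key: arrays[f"param_{key}"] for key in meta["param_keys"]
    }
    marginals = MarginalModel(
        family=meta["family"],
        gene_ids=gene_ids,
        params=params,
        degenerate=arrays["degenerate"],
    )
    factors = CovarianceFactors(
        D=arrays["D"],
        U=arrays["U"],
        W=arrays["W"],
        k=int(meta["k"]),
        method=meta["method"],
        c=meta["c"],
    )
    return ReferenceModel(
        marginals=marginals,
        factors=factors,
        size_factors=arrays.get("size_factors"),
        gene_ids=gene_ids,
        sample_ids=arrays["sample_ids"].astype(object),
        metadata=meta["metadata"],
    )
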