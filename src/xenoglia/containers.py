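"""In-memory containers and on-disk formats for the pipeline.

The central objects are genes x cells sparse matrices with barcode/feature
sidecars, written and read as 10x-style Matrix Market triplets
(``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


@dataclass
class CountMatrix:
    """Raw UMI counts, genes in rows and droplet barcodes in columns.

    ``library_ids`` maps each barcode to its sequencing library; QC outlier
    rules are applied per library.
    """

    matrix: sp.csr_matrix
    genes: pd.Index
    barcodes: pd.Index
    library_ids: pd.Series | None = None

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        self.genes = pd.Index(self.genes)
        self.barcodes = pd.Index(self.barcodes)
        if self.matrix.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )
        if self.library_ids is not None:
            self.library_ids = pd.Series(
                np.asarray(self.library_ids), index=self.barcodes
            )

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]

    def subset(self, genes=None, barcodes=None) -> "CountMatrix":
        """Return a copy restricted to the given gene / barcode labels."""
        gi = slice(None) if genes is None else self.genes.get_indexer(pd.Index(genes))
        bi = (
            slice(None)
            if barcodes is None
            else self.barcodes.get_indexer(pd.Index(barcodes))
        )
        if genes is not None and (np.asarray(gi) < 0).any():
            raise KeyError("unknown gene label in subset request")
        if barcodes is not None and (np.asarray(bi) < 0).any():
            raise KeyError("unknown barcode label in subset request")
        m = self.matrix.tocsr()[gi][:, bi]
        lib = None
        if self.library_ids is not None:
            lib = self.library_ids.iloc[bi] if barcodes is not None else self.library_ids
        return CountMatrix(
            matrix=m,
            genes=self.genes[gi] if genes is not None else self.genes,
            barcodes=self.barcodes[bi] if barcodes is not None else self.barcodes,
            library_ids=None if lib is None else lib.to_numpy(),
        )


@dataclass
class HashMatrix:
    """Hashtag-oligo (HTO) counts, one row per hash, one column per barcode."""

    matrix: np.ndarray
    hashes: pd.Index
    barcodes: pd.Index

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        self.hashes = pd.Index(self.hashes)
        self.barcodes = pd.Index(self.barcodes)
        if self.matrix.shape != (len(self.hashes), len(self.barcodes)):
            raise ValueError("hash matrix shape does not match sidecars")


@dataclass
class NormalizedMatrix:
    """Normalized expression (genes x cells) plus a provenance tag."""

    matrix: sp.csr_matrix
    genes: pd.Index
    barcodes: pd.Index
    transform: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        self.genes = pd.Index(self.genes)
        self.barcodes = pd.Index(self.barcodes)


def write_mtx_dir(counts: CountMatrix, out_dir: str | Path) -> Path:
    """Write a 10x-style triplet: matrix.mtx, features.tsv, barcodes.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out_dir / "matrix.mtx", counts.matrix.tocoo())
    pd.Series(counts.genes).to_csv(
        out_dir / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(counts.barcodes).to_csv(
        out_dir / "barcodes.tsv", sep="\t", header=False, index=False
    )
    if counts.library_ids is not None:
        counts.library_ids.rename("library_id").to_csv(
            out_dir / "libraries.tsv", sep="\t", header=True
        )
    return out_dir


def read_mtx_dir(in_dir: str | Path) -> CountMatrix:
    """Read a triplet written by :func:`write_mtx_dir`."""
    in_dir = Path(in_dir)
    m = sp.csr_matrix(scipy.io.mmread(in_dir / "matrix.mtx"))
    genes = pd.read_csv(in_dir / "features.tsv", sep="\t", header=None)[0]
    barcodes = pd.read_csv(in_dir / "barcodes.tsv", sep="\t", header=None)[0]
    lib_path = in_dir / "libraries.tsv"
    libs = None
    if lib_path.exists():
        libs = pd.read_csv(lib_path, sep="\t", index_col=0)["library_id"].to_numpy()
    return CountMatrix(matrix=m, genes=genes, barcodes=barcodes, library_ids=libs)


def write_image(channels: dict[str, np.ndarray], pixel_size_um: float, out: str | Path) -> None:
    """Write named channels as a multi-page TIFF with a JSON sidecar.

    The sidecar records physical pixel size and the channel order; TIFF pages
    follow that order.
    """
    import tifffile

    out = Path(out)
    names = list(channels)
    stack = np.stack([np.asarray(channels[n], dtype=np.float32) for n in names])
    tifffile.imwrite(out, stack)
    sidecar = {"pixel_size_um": pixel_size_um, "channels": names}
    out.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_image(path: str | Path) -> tuple[dict[str, np.ndarray], float]:
    import tifffile

    path = Path(path)
    stack = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    if stack.ndim == 2:
        stack = stack[None]
    channels = {n: stack[i] for i, n in enumerate(meta["channels"])}
    return channels, float(meta["pixel_size_um"])
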