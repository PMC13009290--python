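"""Genomic relationship matrix from SNP dosages (VanRaden method 2).

With dosage ``x_ik`` in {0, 1, 2} and in-sample allele frequency ``p_k``,
each marker is centred and standardized individually before averaging:

    G_ij = (1/m) * sum_k (x_ik - 2 p_k)(x_jk - 2 p_k) / (2 p_k (1 - p_k))

Markers below a minor-allele-frequency floor, or with zero variance, are
dropped.  Missing dosages are mean-imputed per SNP.  A small identity blend
keeps G positive definite for downstream REML.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class RelationshipMatrix:
    ids: list
    G: np.ndarray = field(repr=False)
    blend: float = 0.0

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in relationship matrix")
        G = np.asarray(self.G, dtype=float)
        if G.shape != (len(self.ids), len(self.ids)):
            raise ValueError("G shape does not match ids")
        if not np.allclose(G, G.T, atol=1e-8):
            raise ValueError("relationship matrix is not symmetric")
        self.G = (G + G.T) / 2.0

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, ids) -> np.ndarray:
        pos = {fid: i for i, fid in enumerate(self.ids)}
        try:
            return np.array([pos[str(i)] for i in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"fish {e} absent from relationship matrix") from None


def compute_grm(
    dosages: np.ndarray,
    ids,
    min_maf: float = 0.01,
    blend: float = 0.01,
) -> RelationshipMatrix:
    """Build a VanRaden-2 GRM from a fish x SNP dosage matrix.

    Parameters
    ----------
    dosages : array (n, m) with entries in {0, 1, 2}; NaN = missing.
    ids : fish identifiers, one per row.
    min_maf : markers with minor allele frequency below this are dropped.
    blend : fraction of identity mixed in, ``(1-blend) G + blend I``.
    """
    X = np.asarray(dosages, dtype=float)
    n, m = X.shape
    if n < 2:
        raise ValueError("need at least two individuals")
    valid = ~np.isnan(X)
    if not ((X[valid] >= 0) & (X[valid] <= 2)).all():
        raise ValueError("dosages must lie in [0, 2]")

    p = np.nanmean(X, axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    keep = (maf >= min_maf) & (np.nanvar(X, axis=0) > 0)
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("dropping %d of %d SNPs below MAF %.3g or monomorphic", n_drop, m, min_maf)
    if not keep.any():
        raise ValueError("all SNPs filtered out")
    X = X[:, keep]
    p = p[keep]

    # per-SNP mean imputation of missing dosages
    if np.isnan(X).any():
        X = np.where(np.isnan(X), 2 * p, X)

    W = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
    G = (W @ W.T) / W.shape[1]
    G = (G + G.T) / 2.0
    if blend > 0:
        G = (1 - blend) * G + blend * np.eye(n)
    return RelationshipMatrix(ids=list(ids), G=G, blend=blend)


# ---------------------------------------------------------------------------
# I/O: dense text format (portable) and an .npz cache (fast)


def write_grm(path, rm: RelationshipMatrix) -> None:
    """Dense text format: header line of ids, then one matrix row per line."""
    with open(path, "w") as fh:
        fh.write("# growvar GRM, blend=%.6g\n" % rm.blend)
        fh.write("\t".join(rm.ids) + "\n")
        for row in rm.G:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_grm(path, atol: float = 1e-6) -> RelationshipMatrix:
    with open(path) as fh:
        header = fh.readline()
        blend = 0.0
        if header.startswith("#"):
            if "blend=" in header:
                blend = float(header.split("blend=")[1])
            header = fh.readline()
        ids = header.rstrip("\n").split("\t")
        rows = [np.fromstring(line, sep="\t") for line in fh if line.strip()]
    G = np.array(rows)
    if G.shape != (len(ids), len(ids)):
        raise ValueError(
            f"GRM file malformed: {len(ids)} ids but matrix shape {G.shape}"
        )
    if not np.allclose(G, G.T, atol=atol):
        raise ValueError("GRM file asymmetric beyond tolerance")
    return RelationshipMatrix(ids=ids, G=G, blend=blend)


def write_grm_cache(path, rm: RelationshipMatrix) -> None:
    np.savez_compressed(path, ids=np.array(rm.ids), G=rm.G, blend=rm.blend)


def read_grm_cache(path) -> RelationshipMatrix:
    z = np.load(path, allow_pickle=False)
    return RelationshipMatrix(ids=list(z["ids"]), G=z["G"], blend=float(z["blend"]))
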