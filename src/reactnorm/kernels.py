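"""Covariance kernels for lines, environments and their interactions.

The genomic relationship matrix G measures marker-based similarity
between lines; its environmental analogue Omega measures similarity
between environmental conditions computed from standardized ECs. Both
are cross-product (Gram) kernels divided by the number of columns, so
with SD-standardized columns the diagonal averages exactly one and the
attached variance parameter is on the trait scale.

Record-level covariance structures arise by expanding an entity kernel
through an incidence map (Z K Z'), and interaction structures are
Hadamard (cell-by-cell) products of record-level kernels: the covariance
of a product of two independent random linear scores is the Hadamard
product of the scores' covariances, which is how a marker-by-EC
interaction with p*Q explicit product contrasts collapses into a single
kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import DataError, ECTable, GenotypeMatrix, standardize_columns

__all__ = [
    "KernelMatrix",
    "IncidenceMap",
    "build_genomic_kernel",
    "build_ec_kernel",
    "expand_to_records",
    "incidence_kernel",
    "hadamard",
    "khatri_rao_oracle",
    "interaction_contrast_count",
    "factor_psd",
    "rowwise_khatri_rao",
]

SYM_TOL = 1e-10
PSD_RELATIVE_TOL = 1e-8


@dataclass(frozen=True)
class KernelMatrix:
    """Symmetric PSD similarity matrix over an ordered list of entities."""

    values: np.ndarray
    labels: tuple[str, ...]
    provenance: str = "kernel"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DataError("kernel must be square")
        if v.shape[0] != len(self.labels):
            raise DataError("kernel size does not match label list")
        if len(set(self.labels)) != len(self.labels):
            raise DataError("kernel labels must be unique")
        if v.size and np.max(np.abs(v - v.T)) > SYM_TOL * max(1.0, np.max(np.abs(v))):
            raise DataError("kernel is not symmetric")
        self.check_psd()

    @property
    def size(self) -> int:
        return self.values.shape[0]

    def check_psd(self, rel_tol: float = PSD_RELATIVE_TOL) -> None:
        """Fail when the minimum eigenvalue is materially negative.

        Kernels here are Gram matrices, so a true negative eigenvalue
        indicates a construction bug; nothing is clipped silently.
        """
        if self.values.size == 0:
            return
        eigvals = np.linalg.eigvalsh(self.values)
        lo, hi = eigvals[0], max(eigvals[-1], 0.0)
        if lo < -rel_tol * max(hi, 1.0):
            raise DataError(
                f"kernel {self.provenance!r} not PSD: min eig {lo:.3e}, max {hi:.3e}"
            )

    def diagonal_mean(self) -> float:
        return float(np.trace(self.values) / self.size)

    def label_index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.labels)}

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels)).to_csv(path)

    @classmethod
    def from_csv(cls, path, provenance: str = "kernel") -> "KernelMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(
            values=frame.to_numpy(dtype=float),
            labels=tuple(str(c) for c in frame.columns),
            provenance=provenance,
        )


@dataclass(frozen=True)
class IncidenceMap:
    """Total map from record index to entity index (one entity per record)."""

    entity_index: np.ndarray  # int per record
    entity_labels: tuple[str, ...]

    def __post_init__(self):
        idx = np.asarray(self.entity_index, dtype=int)
        object.__setattr__(self, "entity_index", idx)
        if idx.size and (idx.min() < 0 or idx.max() >= len(self.entity_labels)):
            raise DataError("incidence map references an unknown entity")

    @property
    def n_records(self) -> int:
        return self.entity_index.size

    @property
    def n_entities(self) -> int:
        return len(self.entity_labels)

    def one_hot(self) -> np.ndarray:
        z = np.zeros((self.n_records, self.n_entities))
        z[np.arange(self.n_records), self.entity_index] = 1.0
        return z


# ---------------------------------------------------------------------------
# Entity-level kernels
# ---------------------------------------------------------------------------


def build_genomic_kernel(g: GenotypeMatrix, scaling: str = "sd") -> KernelMatrix:
    """Genomic relationship matrix over lines.

    With ``scaling="sd"`` each marker column is centered and divided by
    its population SD, and G = X_s X_s' / p (diagonal mean exactly 1).
    With ``scaling="freq"`` the classical allele-frequency form is used:
    G_jj' = p^-1 sum_m (x_jm - 2 theta_m)(x_j'm - 2 theta_m) / (2 theta_m (1 - theta_m)).
    """
    x = g.values
    if np.isnan(x).any():
        raise DataError("genotypes contain missing calls; impute first")
    p = g.n_markers
    if p < 1:
        raise DataError("no markers")
    if scaling == "sd":
        xs, _, _ = standardize_columns(x, divisor="population", names=g.marker_ids)
    elif scaling == "freq":
        theta = g.allele_freq if g.allele_freq is not None else g.allele_frequencies()
        bad = np.flatnonzero((theta <= 0) | (theta >= 1))
        if bad.size:
            names = [g.marker_ids[b] for b in bad[:10]]
            raise DataError(f"allele frequency outside (0,1) for markers: {names}")
        xs = (x - 2.0 * theta) / np.sqrt(2.0 * theta * (1.0 - theta))
    else:
        raise DataError(f"unknown scaling {scaling!r}")
    values = xs @ xs.T / p
    return KernelMatrix(values=values, labels=tuple(g.line_ids), provenance="G")


def build_ec_kernel(w: ECTable, scaling: str = "sd") -> KernelMatrix:
    """Environmental-covariate kernel Omega over EC rows.

    Computed as the genomic kernel but from standardized ECs:
    Omega = W W' / Q, so the diagonal mean is exactly 1.
    """
    if scaling != "sd":
        raise DataError("EC kernels support SD scaling only")
    if not w.is_standardized:
        raise DataError("standardize the EC table before building Omega")
    q = w.n_covariates
    if q < 1:
        raise DataError("no environmental covariates")
    values = w.values @ w.values.T / q
    return KernelMatrix(values=values, labels=tuple(w.row_keys), provenance="Omega")


# ---------------------------------------------------------------------------
# Record-level kernels
# ---------------------------------------------------------------------------


def expand_to_records(
    k: KernelMatrix, imap: IncidenceMap, record_labels=None
) -> KernelMatrix:
    """Z K Z': record-level kernel with entries k[map(r), map(r')]."""
    if imap.n_entities != k.size:
        raise DataError("incidence map does not match kernel size")
    ix = imap.entity_index
    values = k.values[np.ix_(ix, ix)]
    labels = _record_labels(record_labels, imap.n_records)
    return KernelMatrix(values=values, labels=labels, provenance=f"Z[{k.provenance}]Z")


def incidence_kernel(imap: IncidenceMap, record_labels=None) -> KernelMatrix:
    """Z Z': 1 where two records share the mapped entity, else 0."""
    ix = imap.entity_index
    values = (ix[:, None] == ix[None, :]).astype(float)
    labels = _record_labels(record_labels, imap.n_records)
    return KernelMatrix(values=values, labels=labels, provenance="ZZ")


def hadamard(k1: KernelMatrix, k2: KernelMatrix) -> KernelMatrix:
    """Cell-by-cell (Schur) product of two record-level kernels.

    PSD is preserved by the Schur product theorem; the result is
    re-checked against the eigenvalue tolerance on construction.
    """
    if k1.size != k2.size:
        raise DataError("Hadamard product requires equal sizes")
    if k1.labels != k2.labels:
        raise DataError("Hadamard product requires identical record labels")
    return KernelMatrix(
        values=k1.values * k2.values,
        labels=k1.labels,
        provenance=f"({k1.provenance})o({k2.provenance})",
    )


def interaction_contrast_count(n_markers: int, n_ecs: int) -> int:
    """Number of explicit first-order marker-by-EC product contrasts."""
    return int(n_markers) * int(n_ecs)


def khatri_rao_oracle(
    x_std: np.ndarray, w_std: np.ndarray, max_contrasts: int = 200_000
) -> tuple[KernelMatrix, int]:
    """Brute-force interaction kernel from all p*Q explicit contrasts.

    Builds every product column {x_.m * w_.q} over records and returns
    the cross-product kernel divided by p*Q together with the contrast
    count. Algebraically identical to the Hadamard product of the two
    rank-factored kernels, ((XX'/p) o (WW'/Q)); kept as an independent
    check at small sizes.
    """
    x = np.asarray(x_std, dtype=float)
    w = np.asarray(w_std, dtype=float)
    if x.shape[0] != w.shape[0]:
        raise DataError("marker and EC grids must be row-aligned to records")
    n, p = x.shape
    q = w.shape[1]
    count = interaction_contrast_count(p, q)
    if count > max_contrasts:
        raise DataError(f"{count} contrasts exceed the oracle cap {max_contrasts}")
    contrasts = rowwise_khatri_rao(x, w)  # (n, p*q)
    values = contrasts @ contrasts.T / count
    labels = _record_labels(None, n)
    return KernelMatrix(values=values, labels=labels, provenance="contrast-oracle"), count


# ---------------------------------------------------------------------------
# Factorizations (shared by the sampler and the simulator)
# ---------------------------------------------------------------------------


def factor_psd(values: np.ndarray, rel_tol: float = 1e-8) -> np.ndarray:
    """Return B with B B' = K, keeping eigenpairs above a relative cutoff."""
    values = np.asarray(values, dtype=float)
    eigval, eigvec = np.linalg.eigh(values)
    top = max(eigval[-1], 0.0)
    keep = eigval > rel_tol * max(top, 1e-300)
    if not keep.any():
        raise DataError("kernel has no positive eigenvalues")
    return eigvec[:, keep] * np.sqrt(eigval[keep])


def rowwise_khatri_rao(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """All column-by-column products, row-aligned: (n, ra*rb).

    If A A' and B B' are two record kernels, the row-wise Khatri-Rao
    product C satisfies C C' = (A A') o (B B'), which is how interaction
    kernels are factored without forming any dense n x n intermediate.
    """
    n = a.shape[0]
    if b.shape[0] != n:
        raise DataError("row counts differ")
    return (a[:, :, None] * b[:, None, :]).reshape(n, -1)


def _record_labels(record_labels, n: int) -> tuple[str, ...]:
    if record_labels is None:
        return tuple(f"rec{i}" for i in range(n))
    labels = tuple(record_labels)
    if len(labels) != n:
        raise DataError("record label list has wrong length")
    return labels
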