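"""Input tables for multi-environment trials: phenotypes, markers, covariates.

Three delimited-text tables drive the analysis:

* a long-format phenotype table with one yield record per
  (environment, line, replicate), where an *environment* is a
  location-by-year combination;
* a genotype matrix of lines by bi-allelic SNPs coded 0/1/2 with
  missing calls allowed;
* a table of continuous environmental covariates (ECs), keyed either by
  environment or by environment-by-line combination.

Quality control follows standard practice in genomic prediction: markers
are filtered on minor-allele frequency and missingness, remaining
missing genotypes are imputed with twice the estimated allele frequency,
and ECs are screened for near-constant columns and for columns with too
many gross outliers before centering and scaling to unit variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "DataError",
    "PhenotypeTable",
    "GenotypeMatrix",
    "ECTable",
    "read_phenotypes",
    "read_genotypes",
    "read_ec_table",
    "filter_markers",
    "impute_genotypes",
    "qc_environmental_covariates",
    "standardize_columns",
]


class DataError(ValueError):
    """Raised when an input table violates a structural invariant."""


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhenotypeTable:
    """Replicated trait records y_ijk indexed by environment i, line j, rep k.

    ``environments`` and ``lines`` are registries in first-appearance
    order; ``env_codes`` / ``line_codes`` give each record's integer
    index into them.
    """

    frame: pd.DataFrame  # columns: environment, line, replicate, value
    environments: tuple[str, ...]
    lines: tuple[str, ...]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PhenotypeTable":
        required = {"environment", "line", "value"}
        missing = required - set(frame.columns)
        if missing:
            raise DataError(f"phenotype table lacks columns: {sorted(missing)}")
        frame = frame.copy()
        if "replicate" not in frame.columns:
            frame["replicate"] = 1
        frame["environment"] = frame["environment"].astype(str)
        frame["line"] = frame["line"].astype(str)
        frame["replicate"] = frame["replicate"].astype(int)
        if (frame["replicate"] < 1).any():
            raise DataError("replicate indices must be >= 1")
        values = pd.to_numeric(frame["value"], errors="coerce")
        bad = frame.index[values.isna() & frame["value"].notna()]
        if len(bad):
            raise DataError(f"non-numeric trait values at rows {list(bad[:10])}")
        if values.isna().any():
            raise DataError("missing trait values are not allowed in input")
        frame["value"] = values.astype(float)
        dup = frame.duplicated(["environment", "line", "replicate"], keep=False)
        if dup.any():
            offenders = (
                frame.loc[dup, ["environment", "line", "replicate"]]
                .drop_duplicates()
                .to_records(index=False)
                .tolist()
            )
            raise DataError(f"duplicate (environment, line, replicate): {offenders[:10]}")
        envs = tuple(dict.fromkeys(frame["environment"]))
        lines = tuple(dict.fromkeys(frame["line"]))
        frame = frame[["environment", "line", "replicate", "value"]].reset_index(drop=True)
        return cls(frame=frame, environments=envs, lines=lines)

    @property
    def n_records(self) -> int:
        return len(self.frame)

    @property
    def n_environments(self) -> int:
        return len(self.environments)

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def env_codes(self) -> np.ndarray:
        idx = {e: i for i, e in enumerate(self.environments)}
        return self.frame["environment"].map(idx).to_numpy()

    @property
    def line_codes(self) -> np.ndarray:
        idx = {l: i for i, l in enumerate(self.lines)}
        return self.frame["line"].map(idx).to_numpy()

    @property
    def values(self) -> np.ndarray:
        return self.frame["value"].to_numpy(dtype=float)

    def record_labels(self) -> tuple[str, ...]:
        f = self.frame
        return tuple(
            f"{e}:{l}:{r}"
            for e, l, r in zip(f["environment"], f["line"], f["replicate"])
        )


def read_phenotypes(path, delimiter: str | None = None) -> PhenotypeTable:
    """Read a long-format phenotype file (header row required, UTF-8)."""
    frame = pd.read_csv(path, sep=delimiter, engine="python", encoding="utf-8")
    return PhenotypeTable.from_frame(frame)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenotypeMatrix:
    """Lines x markers grid of 0/1/2 calls; np.nan marks a missing call."""

    values: np.ndarray  # float (J, p)
    line_ids: tuple[str, ...]
    marker_ids: tuple[str, ...]
    allele_freq: np.ndarray | None = None  # theta_m per retained marker

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise DataError("genotype matrix must be 2-dimensional")
        if v.shape != (len(self.line_ids), len(self.marker_ids)):
            raise DataError("genotype shape does not match id lists")
        observed = v[~np.isnan(v)]
        # raw calls are 0/1/2; imputed cells hold 2*theta, so only the
        # dosage range is enforced here
        if observed.size and ((observed < 0) | (observed > 2)).any():
            raise DataError("genotype dosages must lie in [0, 2] (or missing)")

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """theta_m = (mean of non-missing calls)/2 per marker."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            theta = np.nanmean(self.values, axis=0) / 2.0
        return theta


def read_genotypes(path, delimiter: str | None = None, missing: str = "NA") -> GenotypeMatrix:
    """Read a genotype file: first column line id, then one column per marker."""
    frame = pd.read_csv(
        path, sep=delimiter, engine="python", encoding="utf-8", na_values=[missing]
    )
    line_ids = tuple(frame.iloc[:, 0].astype(str))
    markers = tuple(frame.columns[1:])
    values = frame.iloc[:, 1:].to_numpy(dtype=float)
    return GenotypeMatrix(values=values, line_ids=line_ids, marker_ids=markers)


def filter_markers(
    g: GenotypeMatrix, maf_min: float = 0.03, missing_max: float = 0.10
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop markers with low minor-allele frequency or too many missing calls.

    MAF is min(theta, 1 - theta) with theta estimated from non-missing
    calls. Returns the filtered matrix (allele frequencies attached) and
    a removal log with one row per dropped marker.
    """
    if g.n_markers < 1:
        raise DataError("genotype matrix has no markers")
    miss_share = np.isnan(g.values).mean(axis=0)
    theta = g.allele_frequencies()
    with np.errstate(invalid="ignore"):
        maf = np.minimum(theta, 1.0 - theta)
    reasons = []
    drop = np.zeros(g.n_markers, dtype=bool)
    for m in range(g.n_markers):
        why = []
        if miss_share[m] > missing_max:
            why.append(f"missing share {miss_share[m]:.3f} > {missing_max}")
        if np.isnan(maf[m]):
            why.append("no observed calls")
        elif maf[m] < maf_min:
            why.append(f"MAF {maf[m]:.4f} < {maf_min}")
        if why:
            drop[m] = True
            reasons.append(
                {
                    "marker": g.marker_ids[m],
                    "maf": maf[m],
                    "missing_share": miss_share[m],
                    "reason": "; ".join(why),
                }
            )
    keep = ~drop
    if not keep.any():
        raise DataError("all markers removed by QC")
    log = pd.DataFrame(reasons, columns=["marker", "maf", "missing_share", "reason"])
    out = GenotypeMatrix(
        values=g.values[:, keep],
        line_ids=g.line_ids,
        marker_ids=tuple(np.array(g.marker_ids)[keep]),
        allele_freq=theta[keep],
    )
    return out, log


def impute_genotypes(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing call at marker m with 2*theta_m.

    theta_m comes from the attached allele frequencies if present,
    otherwise from the non-missing calls. Imputation preserves each
    marker's mean by construction.
    """
    theta = g.allele_freq if g.allele_freq is not None else g.allele_frequencies()
    if np.isnan(theta).any():
        bad = [g.marker_ids[m] for m in np.flatnonzero(np.isnan(theta))]
        raise DataError(f"cannot impute markers with no observed calls: {bad[:10]}")
    values = g.values.copy()
    rows, cols = np.nonzero(np.isnan(values))
    values[rows, cols] = 2.0 * theta[cols]
    return replace(g, values=values, allele_freq=np.asarray(theta, dtype=float))


# ---------------------------------------------------------------------------
# Environmental covariates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ECTable:
    """Environmental covariates keyed by environment or (environment, line).

    ``row_keys`` holds the environment id per row, or ``env::line``
    composite keys when covariates vary by line within environment.
    After :meth:`standardized`, per-column means and population SDs are
    recorded and each column has mean 0 and unit variance.
    """

    values: np.ndarray  # float (rows, Q)
    row_keys: tuple[str, ...]
    covariate_ids: tuple[str, ...]
    keying: str = "environment"  # or "environment_line"
    means: np.ndarray | None = None
    sds: np.ndarray | None = None
    is_standardized: bool = False

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.row_keys), len(self.covariate_ids)):
            raise DataError("EC table shape does not match key/id lists")
        if len(set(self.row_keys)) != len(self.row_keys):
            raise DataError("duplicate EC row keys")

    @property
    def n_covariates(self) -> int:
        return self.values.shape[1]

    def standardized(self, divisor: str = "population") -> "ECTable":
        std, means, sds = standardize_columns(
            self.values, divisor=divisor, names=self.covariate_ids
        )
        return replace(self, values=std, means=means, sds=sds, is_standardized=True)


def read_ec_table(path, delimiter: str | None = None) -> ECTable:
    """Read an EC file: first column environment id (optional second column
    line id), remaining columns covariates."""
    frame = pd.read_csv(path, sep=delimiter, engine="python", encoding="utf-8")
    cols = list(frame.columns)
    if len(cols) > 1 and cols[1].lower() == "line":
        keys = tuple(
            f"{e}::{l}" for e, l in zip(frame.iloc[:, 0].astype(str), frame.iloc[:, 1].astype(str))
        )
        values = frame.iloc[:, 2:].to_numpy(dtype=float)
        ids = tuple(cols[2:])
        keying = "environment_line"
    else:
        keys = tuple(frame.iloc[:, 0].astype(str))
        values = frame.iloc[:, 1:].to_numpy(dtype=float)
        ids = tuple(cols[1:])
        keying = "environment"
    return ECTable(values=values, row_keys=keys, covariate_ids=ids, keying=keying)


def qc_environmental_covariates(
    w: ECTable,
    repeat_max: float = 0.30,
    outlier_max: float = 0.002,
    sd_mult: float = 4.0,
) -> tuple[ECTable, pd.DataFrame]:
    """Drop covariate columns that are near-constant or outlier-ridden.

    A column is removed when the share of rows equal to its modal value
    exceeds ``repeat_max``, or when more than ``outlier_max`` of its
    values fall outside mean +/- ``sd_mult`` SD (population SD over all
    rows). Returns the reduced table and a per-column removal log.
    """
    if w.n_covariates < 1:
        raise DataError("EC table has no covariate columns")
    n = w.values.shape[0]
    drop = np.zeros(w.n_covariates, dtype=bool)
    reasons = []
    for q in range(w.n_covariates):
        col = w.values[:, q]
        counts = pd.Series(col).value_counts(dropna=False)
        repeat_share = counts.iloc[0] / n
        mean = col.mean()
        sd = col.std(ddof=0)
        outlier_share = float(np.mean(np.abs(col - mean) > sd_mult * sd)) if sd > 0 else 0.0
        why = []
        if repeat_share > repeat_max:
            why.append(f"repeated-value share {repeat_share:.3f} > {repeat_max}")
        if outlier_share > outlier_max:
            why.append(f"outlier share {outlier_share:.4f} > {outlier_max}")
        if why:
            drop[q] = True
            reasons.append(
                {
                    "covariate": w.covariate_ids[q],
                    "repeat_share": repeat_share,
                    "outlier_share": outlier_share,
                    "reason": "; ".join(why),
                }
            )
    keep = ~drop
    log = pd.DataFrame(reasons, columns=["covariate", "repeat_share", "outlier_share", "reason"])
    if not keep.any():
        warnings.warn("all environmental covariates removed by QC", stacklevel=2)
    out = replace(
        w,
        values=w.values[:, keep],
        covariate_ids=tuple(np.array(w.covariate_ids)[keep]),
    )
    return out, log


def standardize_columns(
    m, divisor: str = "population", names=None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center each column to mean 0 and scale to unit variance.

    ``divisor`` chooses the population (n) or sample (n-1) SD; the
    population divisor makes the cross-product kernels built downstream
    have a unit diagonal mean exactly.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2:
        raise DataError("expected a 2-dimensional grid")
    if divisor not in ("population", "sample"):
        raise DataError(f"unknown divisor {divisor!r}")
    ddof = 0 if divisor == "population" else 1
    means = m.mean(axis=0)
    sds = m.std(axis=0, ddof=ddof)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        label = [names[z] for z in zero[:10]] if names is not None else list(zero[:10])
        raise DataError(f"zero-variance column(s): {label}")
    return (m - means) / sds, means, sds
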