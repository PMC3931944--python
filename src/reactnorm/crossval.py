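"""Cross-validation designs and prediction-accuracy metrics.

Two designs mirror the prediction problems of multi-environment trials:
CV1 assigns whole lines to folds, so a held-out line has no record in
any environment (newly developed lines); CV2 assigns individual plot
records to folds, mimicking incomplete field trials where every line
keeps records in some environments.

Accuracy targets within-environment performance: both observed records
and model predictions are pre-corrected with the estimated environment
plus EC contribution eta_ij = E_i + w_ij taken from the most
comprehensive model fitted in the same fold, and accuracy is the
Pearson correlation of the pooled corrected vectors, with a
large-sample parametric CI and a record-resampling bootstrap CI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import DataError, PhenotypeTable
from .kernels import KernelMatrix
from .model import (
    COMPREHENSIVE_MODEL,
    ModelSpec,
    PosteriorSamples,
    PriorSpec,
    fit_gibbs,
    make_model,
    normalize_abbreviation,
)

__all__ = [
    "FoldAssignment",
    "CVResult",
    "make_folds",
    "run_cv",
    "predictive_correlation",
    "parametric_ci",
    "bootstrap_ci",
    "percentile_grid",
    "percent_change",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoldAssignment:
    """Record-to-fold map for a CV1 or CV2 design."""

    design: str  # "CV1" | "CV2"
    record_folds: np.ndarray  # fold id (0-based) per record
    n_folds: int
    seed: int

    def test_mask(self, fold: int) -> np.ndarray:
        return self.record_folds == fold


@dataclass
class CVResult:
    """Pooled adjusted phenotypes/predictions and accuracy of one model."""

    abbreviation: str
    design: str
    adjusted_y: np.ndarray
    adjusted_pred: np.ndarray
    record_folds: np.ndarray
    rho: float
    ci_parametric: tuple[float, float]
    ci_bootstrap: tuple[float, float] | None
    n: int

    def summary_row(self) -> dict:
        row = {
            "model": self.abbreviation,
            "design": self.design,
            "rho": round(self.rho, 3),
            "ci_par_low": self.ci_parametric[0],
            "ci_par_high": self.ci_parametric[1],
            "n": self.n,
        }
        if self.ci_bootstrap is not None:
            row["ci_boot_low"] = round(self.ci_bootstrap[0], 3)
            row["ci_boot_high"] = round(self.ci_bootstrap[1], 3)
        return row


def make_folds(
    data: PhenotypeTable, design: str, folds: int = 10, seed: int = 0
) -> FoldAssignment:
    """Randomly assign lines (CV1) or records (CV2) to folds.

    Units are shuffled with the given seed and dealt round-robin, so
    fold sizes differ by at most one unit.
    """
    design = design.upper()
    if design not in ("CV1", "CV2"):
        raise DataError(f"unknown design {design!r}")
    if folds < 2:
        raise DataError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    n = data.n_records
    if design == "CV1":
        if data.n_lines < folds:
            raise DataError(f"CV1 needs >= {folds} lines, got {data.n_lines}")
        perm = rng.permutation(data.n_lines)
        fold_of_line = np.empty(data.n_lines, dtype=int)
        fold_of_line[perm] = np.arange(data.n_lines) % folds
        record_folds = fold_of_line[data.line_codes]
    else:
        if n < folds:
            raise DataError(f"CV2 needs >= {folds} records, got {n}")
        perm = rng.permutation(n)
        record_folds = np.empty(n, dtype=int)
        record_folds[perm] = np.arange(n) % folds
    if len(np.unique(record_folds)) != folds:
        raise DataError("a fold received no records")
    return FoldAssignment(design=design, record_folds=record_folds, n_folds=folds, seed=seed)


def run_cv(
    data: PhenotypeTable,
    models: list[str],
    G: KernelMatrix,
    Omega: KernelMatrix,
    fold: FoldAssignment,
    prior: PriorSpec | None = None,
    iters: int = 12000,
    burn: int = 2000,
    thin: int = 5,
    seed: int = 0,
    bootstrap_reps: int = 10000,
) -> dict[str, CVResult]:
    """Cross-validate a list of models under one fold assignment.

    In every fold the comprehensive model (E + G + W + GxW + GxE) is
    fitted first with the fold's responses masked; its posterior-mean
    intercept, environment and EC contributions give the correction
    eta_ij = mu + E_i + w_ij for the fold's test records. Including the
    fold's intercept makes the correction the model's full
    environment-level prediction, so fold-specific intercept noise
    cancels between the correction and every evaluated model instead of
    leaking into the pooled correlation. Each evaluated
    model is then fitted on the same training records, and its test
    predictions and the test phenotypes are both corrected by eta
    before pooling across folds. The same partition serves the
    correction model and every evaluated model.
    """
    wanted = [normalize_abbreviation(m) for m in models]
    y = data.values
    n = data.n_records
    specs: dict[str, ModelSpec] = {}
    for abbr in dict.fromkeys(wanted + [COMPREHENSIVE_MODEL]):
        specs[abbr] = make_model(abbr, data, G, Omega)

    eta = np.full(n, np.nan)
    preds = {abbr: np.full(n, np.nan) for abbr in wanted}
    seeds = np.random.SeedSequence(seed).generate_state(
        (len(specs) + 1) * fold.n_folds
    ) % (2**31)
    seed_iter = iter(seeds.tolist())

    for f in range(fold.n_folds):
        test = fold.test_mask(f)
        y_train = y.copy()
        y_train[test] = np.nan
        comp_post = fit_gibbs(
            specs[COMPREHENSIVE_MODEL], y_train, prior=prior,
            iters=iters, burn=burn, thin=thin, seed=next(seed_iter),
        )
        eta[test] = (
            float(comp_post.mu_chain.mean())
            + comp_post.term_posterior_mean["E"][test]
            + comp_post.term_posterior_mean["W"][test]
        )
        for abbr in wanted:
            if abbr == COMPREHENSIVE_MODEL:
                post: PosteriorSamples = comp_post
            else:
                post = fit_gibbs(
                    specs[abbr], y_train, prior=prior,
                    iters=iters, burn=burn, thin=thin, seed=next(seed_iter),
                )
            preds[abbr][test] = post.linpred_mean[test]
        logger.info("fold %d/%d done", f + 1, fold.n_folds)

    results: dict[str, CVResult] = {}
    boot_seeds = np.random.SeedSequence(seed + 1).generate_state(len(wanted)) % (2**31)
    for abbr, bseed in zip(wanted, boot_seeds.tolist()):
        adj_y = y - eta
        adj_p = preds[abbr] - eta
        rho = predictive_correlation(adj_y, adj_p)
        ci_par = parametric_ci(rho, n)
        ci_boot = (
            bootstrap_ci(adj_y, adj_p, reps=bootstrap_reps, seed=bseed)
            if bootstrap_reps and bootstrap_reps > 0
            else None
        )
        results[abbr] = CVResult(
            abbreviation=abbr,
            design=fold.design,
            adjusted_y=adj_y,
            adjusted_pred=adj_p,
            record_folds=fold.record_folds.copy(),
            rho=rho,
            ci_parametric=ci_par,
            ci_bootstrap=ci_boot,
            n=n,
        )
    return results


def predictive_correlation(adjusted_y, adjusted_pred) -> float:
    """Pearson correlation of the pooled adjusted vectors (not per-fold)."""
    a = np.asarray(adjusted_y, dtype=float)
    b = np.asarray(adjusted_pred, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DataError("adjusted vectors must be 1-d and equally long")
    if a.size < 3:
        raise DataError("need at least 3 paired records")
    if np.isnan(a).any() or np.isnan(b).any():
        raise DataError("adjusted vectors contain missing values")
    if a.std() == 0 or b.std() == 0:
        raise DataError("correlation undefined for a constant vector")
    return float(np.corrcoef(a, b)[0, 1])


def parametric_ci(rho: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Large-sample CI: rho +/- z * sqrt((1 - rho^2) / (n - 2)), 3 decimals."""
    if n <= 2:
        raise DataError("need n > 2 for the large-sample interval")
    if abs(rho) >= 1:
        raise DataError("|rho| must be < 1")
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt((1.0 - rho**2) / (n - 2))
    return (round(float(rho - half), 3), round(float(rho + half), 3))


def bootstrap_ci(
    adjusted_y,
    adjusted_pred,
    reps: int = 10000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile CI from resampling record pairs with replacement.

    Degenerate resamples (a constant vector) are redrawn and counted in
    the module log; the correlation of each resample is computed from
    sufficient statistics so the default 10,000 replicates stay cheap.
    """
    a = np.asarray(adjusted_y, dtype=float)
    b = np.asarray(adjusted_pred, dtype=float)
    n = a.size
    if b.size != n:
        raise DataError("paired vectors must be equally long")
    if n < 10:
        raise DataError("need at least 10 records to bootstrap")
    rng = np.random.default_rng(seed)
    out = np.empty(reps)
    filled = 0
    redrawn = 0
    chunk = max(1, min(reps, int(4e6 // n)))
    while filled < reps:
        take = min(chunk, reps - filled)
        idx = rng.integers(0, n, size=(take, n))
        sa, sb = a[idx], b[idx]
        sa = sa - sa.mean(axis=1, keepdims=True)
        sb = sb - sb.mean(axis=1, keepdims=True)
        va = np.einsum("ij,ij->i", sa, sa)
        vb = np.einsum("ij,ij->i", sb, sb)
        ok = (va > 0) & (vb > 0)
        redrawn += int((~ok).sum())
        cov = np.einsum("ij,ij->i", sa, sb)[ok]
        r = cov / np.sqrt(va[ok] * vb[ok])
        take_ok = min(r.size, reps - filled)
        out[filled : filled + take_ok] = r[:take_ok]
        filled += take_ok
    if redrawn:
        logger.info("bootstrap redrew %d degenerate resamples", redrawn)
    lo = (1.0 - level) / 2.0
    return (
        float(np.quantile(out, lo)),
        float(np.quantile(out, 1.0 - lo)),
    )


def percentile_grid(
    adjusted_y, adjusted_pred, cuts: tuple[float, ...] = (20, 50, 80)
) -> pd.DataFrame:
    """Conditional class table of observed given predicted performance.

    Both vectors are cut into len(cuts)+1 classes at their own empirical
    percentiles (ties broken by stable ordinal rank), and cell (a, b)
    holds the proportion of observed class a among records in predicted
    class b, so every column sums to one. With the default 20/50/80
    cuts, the top-right cells answer questions like "of the lines
    predicted in the top 20 %, how many performed above the median?".
    """
    a = np.asarray(adjusted_y, dtype=float)
    b = np.asarray(adjusted_pred, dtype=float)
    if a.size != b.size:
        raise DataError("vectors must be equally long")
    n = a.size
    if n < 20:
        raise DataError("need at least 20 records for a percentile grid")
    edges = np.asarray(cuts, dtype=float) / 100.0
    if not (np.diff(edges) > 0).all() or edges.min() <= 0 or edges.max() >= 1:
        raise DataError("cuts must be strictly increasing percentages in (0, 100)")
    cls_a = _percentile_classes(a, edges)
    cls_b = _percentile_classes(b, edges)
    k = edges.size + 1
    table = np.zeros((k, k))
    for col in range(k):
        in_col = cls_b == col
        if in_col.sum() == 0:
            continue
        for row in range(k):
            table[row, col] = np.mean(cls_a[in_col] == row)
    labels = _class_labels(cuts)
    return pd.DataFrame(table, index=labels, columns=labels)


def _percentile_classes(x: np.ndarray, edges: np.ndarray) -> np.ndarray:
    ranks = stats.rankdata(x, method="ordinal")
    return np.searchsorted(edges, ranks / x.size, side="left")


def _class_labels(cuts) -> list[str]:
    bounds = ["0"] + [f"P{int(c)}" for c in cuts] + ["100"]
    return [f"{lo}-{hi}" for lo, hi in zip(bounds[:-1], bounds[1:])]


def percent_change(a: float, b: float) -> int:
    """Relative change from a to b as a whole percentage: round(100 (b-a)/a)."""
    if a == 0:
        raise DataError("baseline value must be nonzero")
    return int(round(100.0 * (b - a) / a))
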