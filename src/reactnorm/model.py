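"""The seven-model family and its Bayesian variance-component sampler.

Every model has the form

    y = mu + sum_k u_k + eps,    u_k ~ N(0, K_k sigma2_k),
    eps ~ N(0, I sigma2_eps),

where each K_k is a record-level covariance kernel: an incidence kernel
for environment (E) or line (L) main effects, the expanded genomic
kernel Z G Z' for marker main effects (G), the expanded EC kernel for
environmental-covariate main effects (W), and Hadamard products
[Z G Z'] o [Z_E Z_E'] and [Z G Z'] o Omega for the marker-by-environment
(GxE) and marker-by-EC (GxW) interactions.

Fitting is by Gibbs sampling in the eigenbasis of each kernel: writing
u_k = B_k alpha_k with B_k B_k' = K_k, the coefficients alpha_k are
standard-normal a priori, their full conditional is Gaussian, and each
variance has a scaled-inverse-chi-square full conditional. Records with
a missing response are excluded from the likelihood and their linear
predictor is accumulated as the model's prediction, which is the single
mechanism both cross-validation designs rely on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import DataError, PhenotypeTable
from .kernels import (
    IncidenceMap,
    KernelMatrix,
    factor_psd,
    rowwise_khatri_rao,
)

__all__ = [
    "MODEL_TERMS",
    "COMPREHENSIVE_MODEL",
    "normalize_abbreviation",
    "ModelSpec",
    "PriorSpec",
    "PosteriorSamples",
    "VarianceComponents",
    "make_model",
    "fit_gibbs",
    "variance_table",
    "within_environment_percentages",
    "phenotypic_correlation",
    "genetic_correlation",
]

#: Random terms entering each named model, in sampler update order.
MODEL_TERMS: dict[str, tuple[str, ...]] = {
    "EL": ("E", "L"),
    "EG": ("E", "G"),
    "ELW": ("E", "L", "W"),
    "EGW": ("E", "G", "W"),
    "EGW-GxE": ("E", "G", "W", "GxE"),
    "EGW-GxW": ("E", "G", "W", "GxW"),
    "EGW-GxWGxE": ("E", "G", "W", "GxW", "GxE"),
}

COMPREHENSIVE_MODEL = "EGW-GxWGxE"

_CANONICAL = {k.upper().replace("-", ""): k for k in MODEL_TERMS}


def normalize_abbreviation(abbr: str) -> str:
    """Map spellings like ``"EGW-G x WG x E"`` to the canonical key."""
    squashed = (
        abbr.replace("×", "x")
        .replace(" ", "")
        .replace("*", "x")
        .replace("-", "")
        .upper()
    )
    if squashed in _CANONICAL:
        return _CANONICAL[squashed]
    raise DataError(f"unknown model abbreviation {abbr!r}; choose from {list(MODEL_TERMS)}")


@dataclass(frozen=True)
class RecordTerm:
    """One random term: a name plus a factor B with B B' = K (record level)."""

    name: str
    factor: np.ndarray  # (n_records, rank)

    @property
    def rank(self) -> int:
        return self.factor.shape[1]

    def kernel(self, labels=None) -> KernelMatrix:
        """Materialize the dense record-level kernel (for checks at small n)."""
        values = self.factor @ self.factor.T
        labs = tuple(labels) if labels is not None else tuple(
            f"rec{i}" for i in range(values.shape[0])
        )
        return KernelMatrix(values=values, labels=labs, provenance=self.name)


@dataclass(frozen=True)
class ModelSpec:
    """A named member of the model family bound to one data set's records."""

    abbreviation: str
    terms: tuple[RecordTerm, ...]
    n_records: int
    record_labels: tuple[str, ...]

    def term_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.terms)


@dataclass(frozen=True)
class PriorSpec:
    """Scaled-inverse-chi-square hyperparameters via an R2 partition.

    The residual receives a prior share ``r2_residual`` of the response
    variance and the rest is split equally among the random terms; each
    scale is S = var(y) * R2 * (df + 2) so the prior mode sits at the
    partitioned variance, following the convention of Bayesian
    genomic-prediction software.
    """

    df: float = 5.0
    residual_df: float = 5.0
    r2_residual: float = 0.5

    def __post_init__(self):
        if self.df <= 0 or self.residual_df <= 0:
            raise DataError("prior degrees of freedom must be positive")
        if not 0 < self.r2_residual < 1:
            raise DataError("r2_residual must lie in (0, 1)")

    def scales(self, var_y: float, term_names) -> tuple[dict[str, float], float]:
        names = list(term_names)
        r2_term = (1.0 - self.r2_residual) / max(len(names), 1)
        s_terms = {n: var_y * r2_term * (self.df + 2.0) for n in names}
        s_eps = var_y * self.r2_residual * (self.residual_df + 2.0)
        return s_terms, s_eps


@dataclass
class PosteriorSamples:
    """Thinned post-burn-in chains and posterior summaries of one fit."""

    abbreviation: str
    variance_chains: dict[str, np.ndarray]  # includes "residual"
    mu_chain: np.ndarray
    term_posterior_mean: dict[str, np.ndarray]  # per-record, all records
    linpred_mean: np.ndarray
    linpred_sd: np.ndarray
    observed: np.ndarray  # bool mask over records
    settings: dict

    def variance_means(self) -> dict[str, float]:
        return {k: float(v.mean()) for k, v in self.variance_chains.items()}

    def chains_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({k: v for k, v in self.variance_chains.items()})
        frame["mu"] = self.mu_chain
        return frame


@dataclass(frozen=True)
class VarianceComponents:
    """Posterior-mean variances and within-environment percentages.

    Percentages are relative to the total variance minus the variance
    of the environment main effect, i.e. for every non-E term t,
    100 * sigma2_t / (sum over non-E terms + residual), to 1 decimal.
    """

    abbreviation: str
    estimates: dict[str, float]  # includes "residual"
    percentages: dict[str, float]  # non-E terms + residual

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, est in self.estimates.items():
            rows.append(
                {
                    "term": name,
                    "estimate": est,
                    "pct_within_environment": self.percentages.get(name, float("nan")),
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model construction
# ---------------------------------------------------------------------------


def make_model(
    abbr: str,
    data: PhenotypeTable,
    G: KernelMatrix,
    Omega: KernelMatrix | None = None,
) -> ModelSpec:
    """Assemble the record-level random terms of a named model.

    ``G`` is the line-level genomic kernel; ``Omega`` the EC kernel over
    environment rows (or environment-by-line rows keyed ``env::line``),
    required whenever the model contains a W or GxW term. Interaction
    terms are built directly in factored form: the row-wise Khatri-Rao
    product of two kernel factors yields a factor of their Hadamard
    product, so no dense record-by-record matrix is ever formed.
    """
    canonical = normalize_abbreviation(abbr)
    names = MODEL_TERMS[canonical]
    needs_omega = any(n in ("W", "GxW") for n in names)
    if needs_omega and Omega is None:
        raise DataError(f"model {canonical} requires an EC kernel Omega")

    env_codes = data.env_codes
    line_codes = data.line_codes
    n = data.n_records

    g_index = G.label_index()
    try:
        line_to_g = np.array([g_index[l] for l in data.lines])
    except KeyError as exc:
        raise DataError(f"line {exc.args[0]!r} absent from the genomic kernel") from exc
    b_g_lines = factor_psd(G.values)
    b_g = b_g_lines[line_to_g][line_codes]  # (n, rank_G)

    z_e = IncidenceMap(env_codes, data.environments).one_hot()
    z_l = IncidenceMap(line_codes, data.lines).one_hot()

    b_w = None
    if Omega is not None:
        om_index = Omega.label_index()
        keys = _omega_record_keys(data, Omega)
        try:
            rec_to_om = np.array([om_index[k] for k in keys])
        except KeyError as exc:
            raise DataError(f"record key {exc.args[0]!r} absent from Omega") from exc
        b_w = factor_psd(Omega.values)[rec_to_om]  # (n, rank_Omega)

    builders = {
        "E": lambda: z_e,
        "L": lambda: z_l,
        "G": lambda: b_g,
        "W": lambda: b_w,
        "GxE": lambda: rowwise_khatri_rao(b_g, z_e),
        "GxW": lambda: rowwise_khatri_rao(b_g, b_w),
    }
    terms = tuple(RecordTerm(name=name, factor=builders[name]()) for name in names)
    return ModelSpec(
        abbreviation=canonical,
        terms=terms,
        n_records=n,
        record_labels=data.record_labels(),
    )


def _omega_record_keys(data: PhenotypeTable, Omega: KernelMatrix) -> list[str]:
    """Record keys into Omega: environment ids, or env::line composites."""
    if any("::" in lab for lab in Omega.labels):
        frame = data.frame
        return [f"{e}::{l}" for e, l in zip(frame["environment"], frame["line"])]
    return list(data.frame["environment"])


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------


def fit_gibbs(
    spec: ModelSpec,
    y: np.ndarray,
    prior: PriorSpec | None = None,
    iters: int = 12000,
    burn: int = 2000,
    thin: int = 5,
    seed: int = 0,
    fixed_variances: dict[str, float] | None = None,
) -> PosteriorSamples:
    """Sample the posterior of one model by blocked Gibbs updates.

    ``y`` may contain NaN for records whose response is unobserved
    (e.g. the test fold of a cross-validation); those records do not
    enter the likelihood but their linear predictors are accumulated as
    predictions. ``fixed_variances`` pins named variances (term names
    or ``"residual"``) instead of sampling them, which turns the fit
    into a Monte-Carlo evaluation of the corresponding BLUP.

    Each term's coefficients are updated as a block: with u = B alpha
    and B'B = U D U' precomputed once, the rotated coefficients have a
    diagonal-precision Gaussian full conditional, so one update costs
    two matrix-vector products. Variances are sampled from
    scaled-inv-chi-square(df + rank, S + alpha'alpha) full conditionals.
    """
    prior = prior or PriorSpec()
    y = np.asarray(y, dtype=float)
    if y.shape != (spec.n_records,):
        raise DataError("response length does not match the model's records")
    if np.isinf(y).any():
        raise DataError("response contains non-finite (infinite) values")
    observed = ~np.isnan(y)
    n_obs = int(observed.sum())
    if n_obs < 1:
        raise DataError("no observed responses")
    if iters <= burn:
        raise DataError("iters must exceed burn")
    if thin < 1:
        raise DataError("thin must be >= 1")
    fixed_variances = {**(fixed_variances or {})}

    rng = np.random.default_rng(seed)
    y_obs = y[observed]
    var_y = float(y_obs.var()) if n_obs > 1 else 1.0
    var_y = max(var_y, 1e-12)
    s_terms, s_eps = prior.scales(var_y, spec.term_names())

    # Per-term rotated design: BU = B_obs @ U with eig(B_obs' B_obs) = U D U'.
    rotated_obs, rotated_all, eigvals = [], [], []
    for term in spec.terms:
        b_obs = term.factor[observed]
        m = b_obs.T @ b_obs
        d, u = np.linalg.eigh(m)
        d = np.clip(d, 0.0, None)
        rotated_obs.append(np.ascontiguousarray(b_obs @ u))
        rotated_all.append(np.ascontiguousarray(term.factor @ u))
        eigvals.append(d)

    names = spec.term_names()
    r2_term = (1.0 - prior.r2_residual) / max(len(names), 1)
    sigma2 = {
        name: fixed_variances.get(name, var_y * r2_term) for name in names
    }
    sigma2_eps = fixed_variances.get("residual", var_y * prior.r2_residual)
    betas = [np.zeros(t.rank) for t in spec.terms]
    mu = float(y_obs.mean())
    e = y_obs - mu

    n_saved = (iters - burn + thin - 1) // thin
    chains = {name: np.empty(n_saved) for name in names}
    chains["residual"] = np.empty(n_saved)
    mu_chain = np.empty(n_saved)
    term_sum = {name: np.zeros(spec.n_records) for name in names}
    lin_sum = np.zeros(spec.n_records)
    lin_sumsq = np.zeros(spec.n_records)
    saved = 0

    for it in range(iters):
        for t, name in enumerate(names):
            bu = rotated_obs[t]
            d = eigvals[t]
            resid_plus = e + bu @ betas[t]
            c = bu.T @ resid_plus
            shrink = d + sigma2_eps / sigma2[name]
            mean = c / shrink
            sd = np.sqrt(sigma2_eps / shrink)
            betas[t] = mean + sd * rng.standard_normal(mean.size)
            e = resid_plus - bu @ betas[t]
            if name not in fixed_variances:
                ss = s_terms[name] + betas[t] @ betas[t]
                sigma2[name] = ss / rng.chisquare(prior.df + betas[t].size)

        resid_plus = e + mu
        mu = float(resid_plus.mean()) + float(
            rng.standard_normal() * np.sqrt(sigma2_eps / n_obs)
        )
        e = resid_plus - mu
        if "residual" not in fixed_variances:
            ss = s_eps + e @ e
            sigma2_eps = ss / rng.chisquare(prior.residual_df + n_obs)

        if it >= burn and (it - burn) % thin == 0:
            lin = np.full(spec.n_records, mu)
            for t, name in enumerate(names):
                contrib = rotated_all[t] @ betas[t]
                term_sum[name] += contrib
                lin += contrib
                chains[name][saved] = sigma2[name]
            chains["residual"][saved] = sigma2_eps
            mu_chain[saved] = mu
            lin_sum += lin
            lin_sumsq += lin * lin
            saved += 1

    lin_mean = lin_sum / saved
    lin_var = np.maximum(lin_sumsq / saved - lin_mean**2, 0.0)
    return PosteriorSamples(
        abbreviation=spec.abbreviation,
        variance_chains=chains,
        mu_chain=mu_chain,
        term_posterior_mean={k: v / saved for k, v in term_sum.items()},
        linpred_mean=lin_mean,
        linpred_sd=np.sqrt(lin_var),
        observed=observed,
        settings={
            "iters": iters,
            "burn": burn,
            "thin": thin,
            "seed": seed,
            "n_saved": saved,
            "prior_df": prior.df,
            "fixed_variances": dict(fixed_variances),
        },
    )


def within_environment_percentages(estimates: dict[str, float]) -> dict[str, float]:
    """Shares of the within-environment variance, to 1 decimal.

    The environment main effect is a nuisance for within-environment
    ranking, so each remaining component (including the residual) is
    expressed relative to the total variance minus the E variance:
    pct_t = 100 * sigma2_t / (sum over non-E terms + residual).
    """
    non_e = {k: v for k, v in estimates.items() if k != "E"}
    total = sum(non_e.values())
    if total <= 0:
        raise DataError("within-environment variance must be positive")
    return {k: round(100.0 * v / total, 1) for k, v in non_e.items()}


def variance_table(post: PosteriorSamples) -> VarianceComponents:
    """Posterior-mean variance components with within-environment shares."""
    estimates = post.variance_means()
    return VarianceComponents(
        abbreviation=post.abbreviation,
        estimates=estimates,
        percentages=within_environment_percentages(estimates),
    )


# ---------------------------------------------------------------------------
# Closed-form correlation functions (marker + EC + interaction model)
# ---------------------------------------------------------------------------


def phenotypic_correlation(
    sigma2_w: float,
    sigma2_g: float,
    sigma2_gw: float,
    sigma2_eps: float,
    g_jj: float,
    om_ij_ij: float,
    om_i2j_i2j: float,
    om_ij_i2j: float,
) -> float:
    """Correlation between two records of one line under different conditions.

    For the model y = mu + w + g + gw + eps, the covariance between
    records of line j in environments i and i' is
    Omega_ij,i'j s2_w + G_jj s2_g + Omega_ij,i'j G_jj s2_gw, and the
    correlation divides by the two records' phenotypic SDs (which
    include the residual variance).
    """
    _check_nonneg(sigma2_w, sigma2_g, sigma2_gw, sigma2_eps)
    num = om_ij_i2j * sigma2_w + g_jj * sigma2_g + om_ij_i2j * g_jj * sigma2_gw
    v1 = om_ij_ij * sigma2_w + g_jj * sigma2_g + om_ij_ij * g_jj * sigma2_gw + sigma2_eps
    v2 = om_i2j_i2j * sigma2_w + g_jj * sigma2_g + om_i2j_i2j * g_jj * sigma2_gw + sigma2_eps
    if v1 <= 0 or v2 <= 0:
        raise DataError("phenotypic variance must be positive")
    return num / np.sqrt(v1 * v2)


def genetic_correlation(
    sigma2_g: float,
    sigma2_gw: float,
    g_jj: float,
    om_ij_ij: float,
    om_i2j_i2j: float,
    om_ij_i2j: float,
) -> float:
    """Genetic correlation of one line's genetic merit across two conditions.

    Without interaction variance this is 1 regardless of the EC kernel;
    interaction variance pulls it toward the environmental similarity
    Omega_ij,i'j and can make it negative under crossover conditions.
    """
    _check_nonneg(sigma2_g, sigma2_gw)
    num = g_jj * sigma2_g + om_ij_i2j * g_jj * sigma2_gw
    v1 = g_jj * sigma2_g + om_ij_ij * g_jj * sigma2_gw
    v2 = g_jj * sigma2_g + om_i2j_i2j * g_jj * sigma2_gw
    if v1 <= 0 or v2 <= 0:
        raise DataError("genetic variance must be positive")
    return num / np.sqrt(v1 * v2)


def _check_nonneg(*variances: float) -> None:
    if any(v < 0 for v in variances):
        raise DataError("variance components must be non-negative")
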