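"""Block Gibbs sampler for the variance-component mixed model.

All location blocks are sampled from their exact multivariate-normal full
conditionals, and every variance from its scaled-inverse-chi-square full
conditional. The genetic blocks use a one-time whitening: with G = L L'
(Cholesky of the regularized relationship matrix) and the record->individual
map Z, the matrix L' Z'Z L is eigendecomposed once (V D V'); writing the
effect as g = L V w makes the full-conditional precision of w diagonal,

    prec(w) = D / sigma2_e + I / sigma2_g ,

for any current pair of variances, so each joint block draw costs O(N n)
per iteration after the O(n^3) setup. g' G^{-1} g = w'w, which feeds the
variance draw directly.

Flat priors (scale 0, degrees of freedom -2) are the default for every
variance; the conjugate draw is sigma2 = (SS + nu S) / chi2_{dim + nu}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import linalg

from .design import DesignSet, ModelSpec
from .grm import RelationshipMatrix

FLAT_PRIOR = (0.0, -2.0)
VARIANCE_FLOOR = 1e-12


@dataclass(frozen=True)
class ChainConfig:
    """MCMC protocol. The long default (200k iterations, 10k burn-in,
    thinning 100) retains 1900 samples; :meth:`short` is the scaled-down
    chain used for quick studies."""

    n_iter: int = 200_000
    burn_in: int = 10_000
    thin: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if (self.n_iter - self.burn_in) % self.thin != 0:
            raise ValueError("(n_iter - burn_in) must be a multiple of thin")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin

    @classmethod
    def short(cls, seed: int = 0) -> "ChainConfig":
        return cls(n_iter=20_000, burn_in=2_000, thin=10, seed=seed)


@dataclass
class PosteriorChain:
    """Retained Gibbs samples plus accumulated posterior means."""

    samples: pd.DataFrame              # var_* columns, b (if fitted), deviance
    beta_samples: pd.DataFrame         # fixed effects incl. the f slope "b"
    fitted_mean: np.ndarray            # posterior-mean linear predictor per record
    genetic_means: dict[str, np.ndarray]
    pe_mean: np.ndarray | None
    y: np.ndarray = field(repr=False)
    spec: ModelSpec | None = None
    config: ChainConfig | None = None

    @property
    def variance_columns(self) -> list[str]:
        return [c for c in self.samples.columns if c.startswith("var_")]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_tsv(self, path) -> None:
        self.samples.to_csv(path, sep="\t", index=False)


def _draw_variance(rng: np.random.Generator, ss: float, dim: int,
                   prior: tuple[float, float]) -> float:
    scale, nu = prior
    df = dim + nu
    if df <= 0:
        raise ValueError(f"variance full conditional has non-positive df {df}")
    draw = (ss + nu * scale) / rng.chisquare(df)
    return max(draw, VARIANCE_FLOOR)


def gibbs_sample(design: DesignSet, grms: Mapping[str, RelationshipMatrix],
                 config: ChainConfig,
                 priors: Mapping[str, tuple[float, float]] | None = None,
                 include_pe: bool = True) -> PosteriorChain:
    """Run the block Gibbs sampler for the model declared in ``design.spec``.

    ``grms`` must contain a regularized relationship matrix for every genetic
    term of the model, indexed by the same individuals as the design.
    """
    priors = dict(priors or {})
    spec = design.spec
    terms = list(spec.terms)
    for t in terms:
        if t not in grms:
            raise ValueError(f"no relationship matrix supplied for term {t!r}")
        if grms[t].n != design.n_individuals:
            raise ValueError(f"relationship matrix {t!r} dimension mismatch")

    y = design.y
    n_rec = design.n_records
    n_ind = design.n_individuals
    idx = design.indiv_index
    counts = design.record_counts

    # fixed effects and the inbreeding covariate sampled as one joint block
    if design.f_record is not None:
        C = np.column_stack([design.X, design.f_record])
        c_names = design.x_names + ["b"]
    else:
        C = design.X
        c_names = list(design.x_names)
    p = C.shape[1]
    if p > 0:
        ctc = C.T @ C
        U = linalg.cholesky(ctc, lower=False)  # C'C = U'U

    # One-time whitening per genetic term. P = L V maps the rotated effect
    # w to individual-level genetic values; record-level projections go
    # through Z by aggregation (bincount) so each block draw costs O(n^2).
    P = {}       # n x n map from w to g
    d_eig = {}
    for t in terms:
        try:
            L = linalg.cholesky(grms[t].values, lower=True)
        except linalg.LinAlgError as err:
            raise ValueError(
                f"relationship matrix {t!r} is not positive definite; "
                "apply regularize() first"
            ) from err
        K = L.T @ (counts[:, None] * L)
        d, V = linalg.eigh(K)
        d = np.clip(d, 0.0, None)
        P[t] = L @ V
        d_eig[t] = d

    rng = np.random.default_rng(config.seed)

    # initial state: equal split of the phenotypic variance
    var_y = float(np.var(y)) or 1.0
    n_comp = len(terms) + int(include_pe) + 1
    variances = {t: var_y / (2 * n_comp) for t in terms}
    if include_pe:
        variances["pe"] = var_y / (2 * n_comp)
    variances["e"] = var_y / 2.0

    beta = np.zeros(p)
    w = {t: np.zeros(n_ind) for t in terms}
    g_vec = {t: np.zeros(n_ind) for t in terms}
    pe = np.zeros(n_ind)
    fixed_contrib = np.zeros(n_rec)
    contrib = {t: np.zeros(n_rec) for t in terms}
    pe_rec = np.zeros(n_rec)
    resid = y.copy()

    S = config.n_retained
    var_store = {k: np.empty(S) for k in variances}
    beta_store = np.empty((S, p))
    deviance = np.empty(S)
    fitted_sum = np.zeros(n_rec)
    g_sum = {t: np.zeros(n_ind) for t in terms}
    pe_sum = np.zeros(n_ind)

    s = 0
    for it in range(1, config.n_iter + 1):
        var_e = variances["e"]

        if p > 0:
            r = resid + fixed_contrib
            mean = linalg.cho_solve((U, False), C.T @ r)
            z = rng.standard_normal(p)
            beta = mean + np.sqrt(var_e) * linalg.solve_triangular(U, z, lower=False)
            fixed_contrib = C @ beta
            resid = r - fixed_contrib

        for t in terms:
            r = resid + contrib[t]
            zr = np.bincount(idx, weights=r, minlength=n_ind)
            v = P[t].T @ zr
            prec = d_eig[t] / var_e + 1.0 / variances[t]
            w_t = v / (var_e * prec) + rng.standard_normal(n_ind) / np.sqrt(prec)
            w[t] = w_t
            g_vec[t] = P[t] @ w_t
            contrib[t] = g_vec[t][idx]
            resid = r - contrib[t]
            variances[t] = _draw_variance(rng, float(w_t @ w_t), n_ind,
                                          priors.get(t, FLAT_PRIOR))

        if include_pe:
            r = resid + pe_rec
            u = np.bincount(idx, weights=r, minlength=n_ind)
            prec = counts / var_e + 1.0 / variances["pe"]
            pe = u / (var_e * prec) + rng.standard_normal(n_ind) / np.sqrt(prec)
            pe_rec = pe[idx]
            resid = r - pe_rec
            variances["pe"] = _draw_variance(rng, float(pe @ pe), n_ind,
                                             priors.get("pe", FLAT_PRIOR))

        variances["e"] = _draw_variance(rng, float(resid @ resid), n_rec,
                                        priors.get("e", FLAT_PRIOR))

        if it > config.burn_in and (it - config.burn_in) % config.thin == 0:
            var_e = variances["e"]
            if not (np.isfinite(var_e) and np.isfinite(resid).all()):
                raise RuntimeError(f"non-finite sampler state at iteration {it}")
            for k, v in variances.items():
                var_store[k][s] = v
            beta_store[s] = beta
            rss = float(resid @ resid)
            deviance[s] = n_rec * np.log(2.0 * np.pi * var_e) + rss / var_e
            fitted_sum += y - resid
            for t in terms:
                g_sum[t] += g_vec[t]
            if include_pe:
                pe_sum += pe
            s += 1

    cols = {f"var_{k}": var_store[k] for k in variances}
    beta_df = pd.DataFrame(beta_store, columns=c_names)
    samples = pd.DataFrame(cols)
    if "b" in beta_df.columns:
        samples["b"] = beta_df["b"].to_numpy()
    samples["deviance"] = deviance

    return PosteriorChain(
        samples=samples,
        beta_samples=beta_df,
        fitted_mean=fitted_sum / S,
        genetic_means={t: g_sum[t] / S for t in terms},
        pe_mean=(pe_sum / S) if include_pe else None,
        y=y,
        spec=spec,
        config=config,
    )


def dic(chain: PosteriorChain) -> tuple[float, float]:
    """Deviance information criterion with Spiegelhalter's pD.

    Uses the conditional deviance given all location parameters; the plug-in
    deviance is evaluated at the posterior means of the linear predictor and
    of the residual variance.
    """
    dbar = float(chain.samples["deviance"].mean())
    var_e = float(chain.samples["var_e"].mean())
    n = chain.y.shape[0]
    rss = float(np.sum((chain.y - chain.fitted_mean) ** 2))
    dhat = n * np.log(2.0 * np.pi * var_e) + rss / var_e
    p_d = dbar - dhat
    return dbar + p_d, p_d


def effective_sample_size(x: np.ndarray) -> float:
    """ESS = S / (1 + 2 sum rho_k) with Geyer's initial-positive-sequence
    truncation of the autocorrelation sum."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples for an ESS estimate")
    xc = x - x.mean()
    var0 = float(xc @ xc) / n
    if var0 <= 0.0 or np.isclose(var0, 0.0, atol=1e-300):
        warnings.warn("constant chain: reporting ESS = chain length")
        return float(n)
    # autocovariance by FFT
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    # sum Gamma_m = rho_{2m} + rho_{2m+1} while positive
    tau = -1.0
    m = 0
    while 2 * m + 1 < n:
        gamma = rho[2 * m] + rho[2 * m + 1]
        if gamma <= 0.0:
            break
        tau += 2.0 * gamma
        m += 1
    tau = max(tau, 1.0 / n)
    return float(n / tau)


@dataclass
class VarianceSummary:
    """Posterior summaries of variance components and the derived ratios."""

    model: str
    component_mean: dict[str, float]
    component_sd: dict[str, float]
    h2: float
    h2_sd: float
    d2: float | None
    d2_sd: float | None
    i2: float | None
    i2_sd: float | None
    ess: dict[str, float]
    dic: float
    p_d: float
    b_mean: float | None = None
    b_sd: float | None = None

    def as_dict(self) -> dict:
        return {
            "model": self.model,
            "component_mean": self.component_mean,
            "component_sd": self.component_sd,
            "h2": self.h2, "h2_sd": self.h2_sd,
            "d2": self.d2, "d2_sd": self.d2_sd,
            "i2": self.i2, "i2_sd": self.i2_sd,
            "ess": self.ess,
            "dic": self.dic, "p_d": self.p_d,
            "b_mean": self.b_mean, "b_sd": self.b_sd,
        }


def phenotypic_variance_samples(chain: PosteriorChain) -> np.ndarray:
    """Per-sample total variance: all genetic components + pe + e."""
    return chain.samples[chain.variance_columns].sum(axis=1).to_numpy()


def variance_ratios(chain: PosteriorChain, spec: ModelSpec | None = None) -> VarianceSummary:
    """Posterior means/SDs of components and of h2, d2 and i2.

    Ratios are computed per retained sample against that sample's total
    variance, then averaged; i2 sums whichever pairwise epistatic
    components the model includes.
    """
    spec = spec or chain.spec
    if chain.n_samples == 0:
        raise ValueError("empty chain")
    samples = chain.samples
    sigma_p = phenotypic_variance_samples(chain)

    comp_mean = {c: float(samples[c].mean()) for c in chain.variance_columns}
    comp_sd = {c: float(samples[c].std(ddof=1)) for c in chain.variance_columns}

    h2_s = samples["var_A"].to_numpy() / sigma_p
    d2_s = samples["var_D"].to_numpy() / sigma_p if "D" in spec.terms else None
    epi = [t for t in ("AA", "AD", "DD") if t in spec.terms]
    i2_s = sum(samples[f"var_{t}"].to_numpy() for t in epi) / sigma_p if epi else None

    ess = {c: (effective_sample_size(samples[c].to_numpy())
               if chain.n_samples >= 4 else float("nan"))
           for c in chain.variance_columns}
    dic_val, p_d = dic(chain)

    b_mean = b_sd = None
    if "b" in samples.columns:
        b_mean = float(samples["b"].mean())
        b_sd = float(samples["b"].std(ddof=1))

    return VarianceSummary(
        model=spec.name,
        component_mean=comp_mean,
        component_sd=comp_sd,
        h2=float(h2_s.mean()), h2_sd=float(h2_s.std(ddof=1)),
        d2=float(d2_s.mean()) if d2_s is not None else None,
        d2_sd=float(d2_s.std(ddof=1)) if d2_s is not None else None,
        i2=float(i2_s.mean()) if i2_s is not None else None,
        i2_sd=float(i2_s.std(ddof=1)) if i2_s is not None else None,
        ess=ess,
        dic=dic_val,
        p_d=p_d,
        b_mean=b_mean,
        b_sd=b_sd,
    )
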