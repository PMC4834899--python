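"""Composable Bayesian linear models with Gibbs sampling.

The sampler implements the Bayesian Lasso of Park & Casella for marker
effects (normal conditional prior ``alpha_j ~ N(0, tau2_j * sigma2_e)`` with
exponential mixing ``tau2_j ~ Exp(lambda2 / 2)`` and a Gamma hyperprior on
``lambda2``) combined with Gaussian-kernel random effects (pedigree additive
``u`` with kernel A, gametic ``g`` with kernel L through the incidence M,
i.i.d. cage effects) and flat-prior fixed effects.  Three model kinds are
assembled from these blocks:

* ADD   : intercept [+ covariates] [+ u] [+ cage] + one Lasso block on the
          additive codes W (p columns);
* POE   : the same plus the gametic term, with two Lasso blocks on the
          maternal and paternal allele indicators (2p columns);
* ADD_POE: additive Lasso block on markers outside a significant set Phi
          plus parental blocks on markers inside Phi (p - |Phi| + 2|Phi|).

Gaussian random terms are sampled in the eigenbasis of their
individual-level covariance ``K_eff = Inc @ K @ Inc.T``: with one record
per individual the full conditional is diagonal there, so each update costs
two matrix-vector products.  Unobserved (masked) phenotypes are imputed
from their predictive distribution every sweep, which makes prediction for
a test set a by-product of the chain: the prediction is the posterior mean
of the full linear predictor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .genotypes import OrderedGenotypes
from .kinship import RelationshipMatrices

__all__ = [
    "FixedBlock", "GaussianRandomBlock", "LassoMarkerBlock", "ModelSpec",
    "McmcConfig", "Priors", "FitResult",
    "code_additive", "code_parental", "assemble_model", "default_priors",
    "run_gibbs", "posterior_predict",
]

VAR_FLOOR = 1e-10  # numerical floor on sampled tau2 and variance components


# ---------------------------------------------------------------------------
# model terms
# ---------------------------------------------------------------------------

@dataclass
class FixedBlock:
    """Fixed-effect design with an improper flat prior."""
    name: str
    X: np.ndarray  # n x k


@dataclass
class GaussianRandomBlock:
    """Random effect with covariance ``K_eff * sigma2`` at the individual level.

    ``K_eff`` is the incidence-collapsed kernel Inc @ K @ Inc.T; the sampled
    state is the n-vector of per-individual contributions.  The
    eigendecomposition is computed lazily and cached so repeated fits on the
    same kernel (e.g. across scenarios) pay for it once.
    """
    name: str
    K_eff: np.ndarray      # n x n PSD
    fixed_var: Optional[float] = None
    _eig: Optional[tuple] = field(default=None, repr=False, compare=False)

    def eig(self, tol: float = 1e-10):
        if self._eig is None:
            d, U = np.linalg.eigh(self.K_eff)
            if d.min() < -1e-6 * max(d.max(), 1.0):
                raise ValueError("random-effect kernel is not positive semidefinite")
            keep = d > tol * max(d.max(), 1.0)
            # float32 eigenvectors: rotations are the sampler's bandwidth
            # bottleneck and Monte-Carlo noise dwarfs the rounding error
            self._eig = (d[keep], np.ascontiguousarray(U[:, keep], dtype=np.float32))
        return self._eig


@dataclass
class LassoMarkerBlock:
    """Marker covariates under the Bayesian Lasso prior.

    ``X`` is column-centered with the means stored for prediction on new
    genotype matrices.  ``fixed_tau2`` freezes the mixing scales (then the
    block behaves as ridge regression with penalty 1/fixed_tau2).
    """
    name: str
    X: np.ndarray          # n x p, float64, column-centered
    col_means: np.ndarray
    marker_ids: np.ndarray
    fixed_tau2: Optional[float] = None


@dataclass
class ModelSpec:
    kind: str
    ids: np.ndarray
    fixed: list = field(default_factory=list)
    gaussian: list = field(default_factory=list)
    lasso: list = field(default_factory=list)
    share_lambda: bool = True
    info: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_marker_coefficients(self) -> int:
        return int(sum(b.X.shape[1] for b in self.lasso))

    def lambda_groups(self) -> list:
        """Indices of Lasso blocks sharing one lambda2 each."""
        if self.share_lambda or len(self.lasso) <= 1:
            return [list(range(len(self.lasso)))]
        return [[i] for i in range(len(self.lasso))]


@dataclass(frozen=True)
class McmcConfig:
    iterations: int = 60_000
    burn_in: int = 10_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in + self.thin - 1) // self.thin


@dataclass
class Priors:
    """Hyperparameters for every variance component and lambda group."""
    S_e: float
    df_e: float
    gaussian_S: dict          # block name -> scale
    gaussian_df: dict
    lambda_shape: float
    lambda_rate: dict         # group index -> rate
    lambda_init: dict         # group index -> prior mode (used to start the chain)


@dataclass
class FitResult:
    model: ModelSpec
    mcmc: McmcConfig
    priors: Priors
    mask_observed: np.ndarray
    linpred_mean: np.ndarray          # posterior mean of the full linear predictor
    means: dict                        # name -> posterior mean of effects
    samples: dict                      # name -> retained samples (variances, lambda2, alpha, fixed)

    @property
    def n_retained(self) -> int:
        return len(self.samples["sigma2_e"])


# ---------------------------------------------------------------------------
# genotype coding
# ---------------------------------------------------------------------------

def code_additive(genotypes: OrderedGenotypes) -> np.ndarray:
    """Additive genotype codes W = maternal + paternal in {0, 1, 2}."""
    return genotypes.W


def code_parental(genotypes: OrderedGenotypes):
    """Validated (maternal, paternal) A1 indicator matrices.

    ``maternal[i, j] = paternal[i, j] = 1`` is an A1A1 genotype;
    ``maternal = 1, paternal = 0`` is A2A1 with the maternal allele written
    first.  Column centering (with stored means) is applied downstream when
    the matrices enter a marker block.
    """
    return genotypes.maternal, genotypes.paternal


def _center(X: np.ndarray, dtype=np.float32):
    """Column-center and cast; the rounded matrix IS the model's design."""
    X = np.asarray(X, dtype=np.float64)
    mu = X.mean(axis=0)
    return np.asfortranarray(X - mu, dtype=dtype), mu


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------

def assemble_model(kind: str,
                   genotypes: OrderedGenotypes,
                   kinship: Optional[RelationshipMatrices] = None,
                   covariates: Optional[np.ndarray] = None,
                   cage: Optional[np.ndarray] = None,
                   phi: Optional[Sequence] = None,
                   include_polygenic: bool = False,
                   include_gametic: bool = False,
                   share_lambda: bool = True) -> ModelSpec:
    """Build an ADD, POE or ADD_POE model specification.

    Parameters
    ----------
    kind
        "ADD", "POE" or "ADD_POE" (case-insensitive).
    kinship
        Pedigree relationship matrices; required when ``include_polygenic``
        (kernel A) or ``include_gametic`` (kernel L via M) is requested.
        Rows are matched to ``genotypes.ids``.
    cage
        Integer / string labels per individual; adds an i.i.d. random group
        effect.
    phi
        Marker ids with significant parent-of-origin effects (ADD_POE only).
    """
    kind = kind.upper().replace("-", "_")
    if kind not in ("ADD", "POE", "ADD_POE"):
        raise ValueError(f"unknown model kind {kind!r}")
    n = genotypes.n_individuals
    spec = ModelSpec(kind=kind, ids=np.asarray(genotypes.ids),
                     share_lambda=share_lambda)
    # intercept + optional fixed covariates
    X = np.ones((n, 1))
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
        if covariates.shape[0] != n:
            covariates = covariates.T
        X = np.hstack([X, covariates])
    spec.fixed.append(FixedBlock("fixed", np.asfortranarray(X)))

    if include_polygenic or include_gametic:
        if kinship is None:
            raise ValueError("pedigree relationship matrices required for u/g terms")
        pos = {int(i): k for k, i in enumerate(kinship.ids)}
        try:
            rows = np.array([pos[int(i)] for i in genotypes.ids])
        except KeyError as err:
            raise ValueError(f"individual {err} missing from pedigree") from None
    if include_polygenic:
        spec.gaussian.append(GaussianRandomBlock("u", kinship.A[np.ix_(rows, rows)]))
    if include_gametic:
        if kind == "ADD":
            raise ValueError("the gametic term belongs to the POE-type models")
        gam = np.empty((n, 2), dtype=np.int64)
        for k, i in enumerate(genotypes.ids):
            gam[k] = kinship.gamete_rows[int(i)]
        rp, rm = gam[:, 0], gam[:, 1]
        K = (kinship.L[np.ix_(rp, rp)] + kinship.L[np.ix_(rp, rm)]
             + kinship.L[np.ix_(rm, rp)] + kinship.L[np.ix_(rm, rm)])
        spec.gaussian.append(GaussianRandomBlock("g", K))
    if cage is not None:
        cage = np.asarray(cage)
        _, inv = np.unique(cage, return_inverse=True)
        C = np.zeros((n, inv.max() + 1))
        C[np.arange(n), inv] = 1.0
        spec.gaussian.append(GaussianRandomBlock("cage", C @ C.T))

    mat, pat = code_parental(genotypes)
    if kind == "ADD":
        Xw, mw = _center(code_additive(genotypes))
        spec.lasso.append(LassoMarkerBlock("markers_add", Xw, mw,
                                           genotypes.marker_ids))
    elif kind == "POE":
        Xm, mm = _center(mat)
        Xp, mp = _center(pat)
        spec.lasso.append(LassoMarkerBlock("markers_maternal", Xm, mm,
                                           genotypes.marker_ids))
        spec.lasso.append(LassoMarkerBlock("markers_paternal", Xp, mp,
                                           genotypes.marker_ids))
    else:  # ADD_POE
        phi = set() if phi is None else set(np.asarray(phi).tolist())
        unknown = phi - set(genotypes.marker_ids.tolist())
        if unknown:
            raise ValueError(f"phi contains unknown markers: {sorted(unknown)[:5]}")
        in_phi = np.array([m in phi for m in genotypes.marker_ids])
        if (~in_phi).any():
            Xw, mw = _center(code_additive(genotypes)[:, ~in_phi])
            spec.lasso.append(LassoMarkerBlock("markers_add", Xw, mw,
                                               genotypes.marker_ids[~in_phi]))
        if in_phi.any():
            Xm, mm = _center(mat[:, in_phi])
            Xp, mp = _center(pat[:, in_phi])
            spec.lasso.append(LassoMarkerBlock("markers_maternal", Xm, mm,
                                               genotypes.marker_ids[in_phi]))
            spec.lasso.append(LassoMarkerBlock("markers_paternal", Xp, mp,
                                               genotypes.marker_ids[in_phi]))
        spec.info["phi"] = sorted(phi)
    return spec


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

def default_priors(y: np.ndarray, model: ModelSpec,
                   mask_observed: Optional[np.ndarray] = None,
                   df: float = 5.0, R2_residual: float = 0.5) -> Priors:
    """Weakly-informative defaults scaled to the phenotypic variance.

    Every scaled-inverse-chi2 prior gets ``df = 5`` and scale
    ``S = var(y) * share * (df + 2) / normalizer`` where the normalizer is
    the mean diagonal of the term's kernel (1 for the residual).  The
    residual takes a variance share of 0.5 and the remaining 0.5 is split
    equally among the non-residual terms.  Each lambda2 gets a
    Gamma(1.1, rate) hyperprior with the rate chosen so the prior mode is
    ``2 (1 - R2) * sum_j mean(x_j^2) / R2`` for that marker group.
    """
    y = np.asarray(y, dtype=np.float64)
    if mask_observed is not None:
        y = y[np.asarray(mask_observed, dtype=bool)]
    vy = float(np.var(y))
    if vy <= 0:
        raise ValueError("phenotype variance must be positive")
    groups = model.lambda_groups()
    # every block (Gaussian or Lasso) is one term in the variance budget;
    # a lambda group's share is the sum of its blocks' shares
    n_terms = len(model.gaussian) + len(model.lasso)
    share = (1.0 - R2_residual) / n_terms if n_terms else 0.0
    gaussian_S, gaussian_df = {}, {}
    for blk in model.gaussian:
        norm = float(np.mean(np.diag(blk.K_eff)))
        gaussian_S[blk.name] = vy * share * (df + 2.0) / max(norm, VAR_FLOOR)
        gaussian_df[blk.name] = df
    shape = 1.1
    lambda_rate, lambda_init = {}, {}
    for gi, g in enumerate(groups):
        msx = sum(float(np.mean(model.lasso[b].X**2, axis=0).sum()) for b in g)
        r2_g = share * len(g)
        mode = (2.0 * (1.0 - r2_g) * max(msx, VAR_FLOOR) / r2_g
                if r2_g else 1.0)
        lambda_rate[gi] = (shape - 1.0) / mode
        lambda_init[gi] = mode
    return Priors(
        S_e=vy * R2_residual * (df + 2.0),
        df_e=df,
        gaussian_S=gaussian_S,
        gaussian_df=gaussian_df,
        lambda_shape=shape,
        lambda_rate=lambda_rate,
        lambda_init=lambda_init,
    )


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _coeff_gibbs(X, xtx, prior_prec, sigma2_e, beta, e, z):
    """Sequential single-site updates of regression coefficients.

    Full conditional of beta_j: normal with precision
    (xtx_j + prior_prec_j) / sigma2_e; the residual vector e is kept in
    sync.  prior_prec_j = 0 encodes a flat prior.
    """
    n, p = X.shape
    for j in range(p):
        rhs = 0.0
        for i in range(n):
            rhs += X[i, j] * e[i]
        rhs += xtx[j] * beta[j]
        c = xtx[j] + prior_prec[j]
        mean = rhs / c
        new = mean + math.sqrt(sigma2_e / c) * z[j]
        d = new - beta[j]
        for i in range(n):
            e[i] -= X[i, j] * d
        beta[j] = new


def run_gibbs(model: ModelSpec, priors: Priors, mcmc: McmcConfig,
              y: np.ndarray, mask_observed: Optional[np.ndarray] = None,
              fixed_sigma2_e: Optional[float] = None,
              update_lambda: bool = True,
              keep_effect_samples: bool = True) -> FitResult:
    """Run the Gibbs sampler and return posterior summaries.

    Sampling order within a sweep is fixed: fixed effects -> marker blocks
    -> Gaussian blocks -> tau2/lambda2 -> variance components -> masked
    phenotypes.  Masked phenotypes are imputed from N(linear predictor,
    sigma2_e) each sweep, so test-set prediction is the posterior mean of
    the linear predictor.
    """
    y = np.asarray(y, dtype=np.float64).copy()
    n = len(y)
    if n != model.n:
        raise ValueError("phenotype length does not match the model")
    obs = (np.ones(n, dtype=bool) if mask_observed is None
           else np.asarray(mask_observed, dtype=bool).copy())
    if not obs.any():
        raise ValueError("at least one phenotype must be observed")
    rng = np.random.default_rng(mcmc.seed)

    y_work = y.copy()
    y_work[~obs] = y[obs].mean()
    e = y_work.copy()

    # fixed blocks
    fixed_state = []
    for blk in model.fixed:
        X = np.asfortranarray(blk.X, dtype=np.float64)
        fixed_state.append(dict(X=X, xtx=np.einsum("ij,ij->j", X, X),
                                beta=np.zeros(X.shape[1]),
                                prior_prec=np.zeros(X.shape[1])))
    # lasso blocks
    groups = model.lambda_groups()
    group_of = {}
    for gi, g in enumerate(groups):
        for b in g:
            group_of[b] = gi
    lasso_state = []
    for blk in model.lasso:
        X = blk.X if blk.X.flags.f_contiguous else np.asfortranarray(blk.X)
        xtx = np.einsum("ij,ij->j", X.astype(np.float64, copy=False),
                        X.astype(np.float64, copy=False))
        if (xtx <= 0).any():
            raise ValueError(f"constant marker column in block {blk.name}")
        p = X.shape[1]
        tau2 = (np.full(p, blk.fixed_tau2) if blk.fixed_tau2 is not None
                else np.ones(p))
        lasso_state.append(dict(X=X, xtx=xtx, alpha=np.zeros(p), tau2=tau2,
                                frozen=blk.fixed_tau2 is not None, name=blk.name))
    lambda2 = {gi: priors.lambda_init.get(gi, 1.0) for gi in range(len(groups))}

    # gaussian blocks (eigenbasis)
    gauss_state = []
    for blk in model.gaussian:
        d, U = blk.eig()
        s2 = blk.fixed_var if blk.fixed_var is not None else float(np.var(y_work)) * 0.25
        gauss_state.append(dict(d=d, U=U, delta=np.zeros(len(d)),
                                h=np.zeros(n), sigma2=s2,
                                frozen=blk.fixed_var is not None,
                                S=priors.gaussian_S.get(blk.name, 1.0),
                                df=priors.gaussian_df.get(blk.name, 5.0),
                                name=blk.name))
    sigma2_e = fixed_sigma2_e if fixed_sigma2_e is not None else float(np.var(y_work)) * 0.5
    p_lasso_total = sum(st["X"].shape[1] for st in lasso_state)

    # storage
    nr = mcmc.n_retained
    linpred_sum = np.zeros(n)
    samples = {"sigma2_e": np.empty(nr)}
    for gi in range(len(groups)):
        samples[f"lambda2_{gi}"] = np.empty(nr)
    for st in gauss_state:
        samples[f"sigma2_{st['name']}"] = np.empty(nr)
    if keep_effect_samples:
        for st in lasso_state:
            samples[f"alpha_{st['name']}"] = np.empty((nr, st["X"].shape[1]))
        for k, st in enumerate(fixed_state):
            samples[f"beta_fixed{k}"] = np.empty((nr, st["X"].shape[1]))
    gauss_h_sum = {st["name"]: np.zeros(n) for st in gauss_state}

    r = 0
    for t in range(mcmc.iterations):
        for st in fixed_state:
            _coeff_gibbs(st["X"], st["xtx"], st["prior_prec"], sigma2_e,
                         st["beta"], e, rng.standard_normal(st["X"].shape[1]))
        for st in lasso_state:
            _coeff_gibbs(st["X"], st["xtx"], 1.0 / st["tau2"], sigma2_e,
                         st["alpha"], e, rng.standard_normal(st["X"].shape[1]))
        for st in gauss_state:
            e += st["h"]
            v = (st["U"].T @ e.astype(np.float32)).astype(np.float64)
            prec = 1.0 / sigma2_e + 1.0 / (st["d"] * st["sigma2"])
            mean = v / sigma2_e / prec
            st["delta"] = mean + rng.standard_normal(len(v)) / np.sqrt(prec)
            st["h"] = (st["U"] @ st["delta"].astype(np.float32)).astype(np.float64)
            e -= st["h"]
        for bi, st in enumerate(lasso_state):
            if st["frozen"]:
                continue
            lam2 = lambda2[group_of[bi]]
            mu_ig = np.sqrt(lam2 * sigma2_e / np.maximum(st["alpha"]**2, 1e-300))
            mu_ig = np.minimum(mu_ig, 1e12)
            inv_tau2 = rng.wald(mu_ig, lam2)
            st["tau2"] = np.maximum(1.0 / np.maximum(inv_tau2, 1e-300), VAR_FLOOR)
        if update_lambda:
            for gi, g in enumerate(groups):
                if all(lasso_state[b]["frozen"] for b in g):
                    continue
                p_g = sum(lasso_state[b]["X"].shape[1] for b in g)
                sum_tau2 = sum(lasso_state[b]["tau2"].sum() for b in g)
                lambda2[gi] = rng.gamma(priors.lambda_shape + p_g,
                                        1.0 / (priors.lambda_rate[gi] + sum_tau2 / 2.0))
        for st in gauss_state:
            if st["frozen"]:
                continue
            quad = float(np.sum(st["delta"]**2 / st["d"]))
            st["sigma2"] = max((quad + st["S"]) / rng.chisquare(len(st["d"]) + st["df"]),
                               VAR_FLOOR)
        if fixed_sigma2_e is None:
            scale = float(e @ e) + priors.S_e
            dof = n + priors.df_e
            for st in lasso_state:
                scale += float(np.sum(st["alpha"]**2 / st["tau2"]))
            dof += p_lasso_total
            sigma2_e = max(scale / rng.chisquare(dof), VAR_FLOOR)
        if (~obs).any():
            linpred_miss = y_work[~obs] - e[~obs]
            e[~obs] = math.sqrt(sigma2_e) * rng.standard_normal((~obs).sum())
            y_work[~obs] = linpred_miss + e[~obs]

        if t >= mcmc.burn_in and (t - mcmc.burn_in) % mcmc.thin == 0:
            linpred_sum += y_work - e
            samples["sigma2_e"][r] = sigma2_e
            for gi in range(len(groups)):
                samples[f"lambda2_{gi}"][r] = lambda2[gi]
            for st in gauss_state:
                samples[f"sigma2_{st['name']}"][r] = st["sigma2"]
                gauss_h_sum[st["name"]] += st["h"]
            if keep_effect_samples:
                for st in lasso_state:
                    samples[f"alpha_{st['name']}"][r] = st["alpha"]
                for k, st in enumerate(fixed_state):
                    samples[f"beta_fixed{k}"][r] = st["beta"]
            r += 1

    means = {"linpred": linpred_sum / nr}
    for st in lasso_state:
        means[f"alpha_{st['name']}"] = (samples[f"alpha_{st['name']}"].mean(axis=0)
                                        if keep_effect_samples else None)
    for k, st in enumerate(fixed_state):
        means[f"beta_fixed{k}"] = (samples[f"beta_fixed{k}"].mean(axis=0)
                                   if keep_effect_samples else None)
    for name, hs in gauss_h_sum.items():
        means[f"h_{name}"] = hs / nr
    return FitResult(model=model, mcmc=mcmc, priors=priors,
                     mask_observed=obs, linpred_mean=linpred_sum / nr,
                     means=means, samples=samples)


def posterior_predict(fit: FitResult, target_ids: Sequence) -> np.ndarray:
    """Posterior-mean linear predictor for individuals present in the fit."""
    pos = {}
    for k, i in enumerate(fit.model.ids):
        pos[i] = k
    try:
        rows = [pos[i] for i in np.asarray(target_ids)]
    except KeyError as err:
        raise KeyError(f"individual {err} was not part of the fitted model") from None
    return fit.linpred_mean[list(rows)]
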