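"""Bayesian variance-component estimation and hybrid prediction.

Each random term contributes a hybrid-level covariance ``sigma2_t * T K T'``
(``T`` maps line effects to hybrids; identity for hybrid-level terms).  The
model is fit as Bayesian ridge regression on eigendecomposed covariances:
with ``T K T' = V L V'`` and design ``B = V L^{1/2}``, coefficients
``v ~ N(0, sigma2_t I)`` give ``B v`` exactly the required covariance, so
term variances are reported directly on the kinship scale (all matrices have
mean diagonal 1).

The Gibbs sampler uses conjugate updates throughout: a flat prior on the
intercept, scaled-inverse-chi-square priors on every variance, and blocked
coefficient updates.  Within a term the coefficients are updated jointly:
the observed-row design is rotated once so its cross-product is diagonal,
making the conditional posterior of the block independent across
coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import LineGenotypes, HybridPedigree, PhenotypeTable
from .encoding import (
    compute_allele_freqs,
    center_line_genotypes,
    build_parent_incidence,
    build_dominance_incidence,
    derive_hybrid_genotypes,
    noia_codings,
)
from .kinship import (
    KinshipMatrix,
    additive_kinship,
    dominance_kinship,
    epistatic_within,
    epistatic_across,
    gmodel_kinships,
)

__all__ = [
    "MODEL_CODES",
    "ChainConfig",
    "ModelTerm",
    "ModelSpec",
    "PosteriorSamples",
    "FitSummary",
    "eigen_design",
    "assemble_model",
    "gibbs_fit",
    "summarize_fit",
    "predict_hybrids",
]

# The model menu: which random terms each code expands to.  The r terms
# (i.i.d. "residual genetic" line effects absorbing unmodeled higher-order
# within-group epistasis) are appended when with_r is requested; they apply
# to GCA-type models only, since G-models act at the hybrid level where each
# hybrid has a single record.
MODEL_CODES: dict[str, tuple[str, ...]] = {
    "GCA:A": ("A1", "A2"),
    "GCA:AD": ("A1", "A2", "D"),
    "GCA:AAA12": ("A1", "A2", "AA12"),
    "GCA:ADAA12": ("A1", "A2", "D", "AA12"),
    "GCA:ADAA11AA22AA12": ("A1", "A2", "D", "AA11", "AA22", "AA12"),
    "G:A": ("AH",),
    "G:ADH": ("AH", "DH"),
    "G:AAAH": ("AH", "AAH"),
    "G:ADHAAH": ("AH", "DH", "AAH"),
}


@dataclass
class ChainConfig:
    """MCMC settings.  Defaults: 30,000 retained samples from 60,000
    iterations after 30,000 burn-in with thinning of 10."""

    n_iter: int = 60_000
    burn_in: int = 30_000
    thin: int = 10
    seed: int = 0
    prior_df: float = 5.0
    #: share of the phenotypic variance assigned a priori to the genetic
    #: terms jointly (split equally among them); the rest goes to the residual
    prior_genetic_share: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.burn_in < self.n_iter):
            raise ValueError("need 0 < burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_samples(self) -> int:
        return (self.n_iter - self.burn_in + self.thin - 1) // self.thin


@dataclass
class ModelTerm:
    """One random term: a full-hybrid-set design whose Gram matrix is the
    term's (mapped) covariance structure.

    For line-mapped terms, ``line_cov`` (the line-level covariance K) and
    ``incidence`` (T, hybrids x lines) are kept alongside the design: the
    sampler uses them to integrate out entire groups of coefficient blocks
    that share an incidence space when updating their variances.
    """

    name: str
    design: np.ndarray  # (n_all_hybrids, m)
    kinship_name: str
    variance_symbol: str
    mapping: str = "hybrids"  # {"lines1", "lines2", "hybrids"}
    line_cov: np.ndarray | None = None
    incidence: np.ndarray | None = None


@dataclass
class ModelSpec:
    model_code: str
    with_r: bool
    hybrid_ids: list[str]
    terms: list[ModelTerm]
    intercept: bool = True

    @property
    def n_hybrids(self) -> int:
        return len(self.hybrid_ids)


@dataclass
class PosteriorSamples:
    """Raw MCMC output: variance samples per term (plus ``"residual"``),
    intercept and deviance samples, and posterior-mean term contributions
    at the hybrid level (full hybrid set, including prediction targets)."""

    variance_samples: dict[str, np.ndarray]
    mu_samples: np.ndarray
    deviance_samples: np.ndarray
    effect_means: dict[str, np.ndarray]
    hybrid_ids: list[str]
    obs_hybrid_ids: list[str]
    chain: ChainConfig


@dataclass
class FitSummary:
    model_code: str
    variances: dict[str, tuple[float, float]]  # name -> (post. mean, post. SD)
    H2_mean: float
    H2_sd: float
    dic: float
    mean_deviance: float
    p_d: float
    aggregates: dict[str, float] = field(default_factory=dict)
    notes: str = (
        "H2 numerator includes every fitted genetic term (r included); "
        "DIC uses the conditional Gaussian deviance given sampled effects."
    )


def eigen_design(
    K: KinshipMatrix | np.ndarray,
    T: np.ndarray | None = None,
    tol: float = 1e-10,
    ridge: float = 1e-8,
) -> np.ndarray:
    """Design matrix B with B B' = T K T' (up to dropped-eigenvalue mass).

    The hybrid-level covariance ``C = T K T'`` is symmetrized, given a tiny
    diagonal ridge (numerical PSD guard, applied here only — stored kinships
    are never modified), and eigendecomposed; eigenvalues below
    ``tol * lambda_max`` (or below zero) are dropped and ``B = V L^{1/2}``.
    """
    Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=np.float64)
    C = Kv if T is None else T @ Kv @ T.T
    C = (C + C.T) / 2.0
    if ridge:
        C = C + ridge * np.eye(C.shape[0])
    lam, V = np.linalg.eigh(C)
    # ridge-order eigenvalues carry no real structure: use the ridge as an
    # absolute retention floor so rank-deficient T K T' keeps its true rank
    keep = lam > max(tol * lam[-1], 10.0 * ridge)
    if not keep.any():
        raise ValueError("all eigenvalues dropped: covariance is numerically null")
    return V[:, keep] * np.sqrt(lam[keep])[None, :]


def assemble_model(
    g1: LineGenotypes,
    g2: LineGenotypes,
    ped: HybridPedigree,
    model_code: str,
    with_r: bool = True,
    tol: float = 1e-10,
    ridge: float = 1e-8,
) -> ModelSpec:
    """Build every design of a stock model over the full hybrid set.

    Designs cover all hybrids named in the pedigree, independent of
    phenotype availability, so prediction targets always have rows.
    """
    if model_code not in MODEL_CODES:
        raise KeyError(f"unknown model code {model_code!r}; choose from {sorted(MODEL_CODES)}")
    term_names = list(MODEL_CODES[model_code])
    is_gca = model_code.startswith("GCA:")
    if with_r:
        if not is_gca:
            raise ValueError(
                "residual genetic r effects apply to GCA-type models only "
                "(G-models act at the hybrid level with one record per hybrid)"
            )
        term_names += ["r1", "r2"]

    ped.validate_against(g1, g2)
    f1, f2 = compute_allele_freqs(g1), compute_allele_freqs(g2)
    Z1, Z2 = center_line_genotypes(g1, f1), center_line_genotypes(g2, f2)
    T1 = build_parent_incidence(ped, g1, 1)
    T2 = build_parent_incidence(ped, g2, 2)

    kin: dict[str, tuple[KinshipMatrix | np.ndarray, np.ndarray | None]] = {}
    if is_gca:
        GA1 = additive_kinship(Z1, f1, group=1)
        GA2 = additive_kinship(Z2, f2, group=2)
        need = set(term_names)
        if "A1" in need:
            kin["A1"] = (GA1, T1)
        if "A2" in need:
            kin["A2"] = (GA2, T2)
        if "D" in need or "AA12" in need:
            if "D" in need:
                W = build_dominance_incidence(Z1, Z2, ped)
                kin["D"] = (dominance_kinship(W, f1, f2), None)
            if "AA12" in need:
                kin["AA12"] = (epistatic_across(GA1, GA2, T1, T2, ped.hybrid_ids), None)
        if "AA11" in need:
            kin["AA11"] = (epistatic_within(GA1), T1)
        if "AA22" in need:
            kin["AA22"] = (epistatic_within(GA2), T2)
        if "r1" in need:
            kin["r1"] = (np.eye(g1.n_lines), T1)
        if "r2" in need:
            kin["r2"] = (np.eye(g2.n_lines), T2)
    else:
        H = derive_hybrid_genotypes(g1, g2, ped)
        gm = gmodel_kinships(noia_codings(H))
        mapping = {"AH": "GAH", "DH": "DH", "AAH": "GAAH"}
        for t in term_names:
            kin[t] = (gm[mapping[t]], None)

    terms = []
    for t in term_names:
        K, T = kin[t]
        B = eigen_design(K, T, tol=tol, ridge=ridge)
        kname = K.name if isinstance(K, KinshipMatrix) else "I"
        if T is None:
            mapping, line_cov = "hybrids", None
        else:
            mapping = "lines1" if T is T1 else "lines2"
            line_cov = K.values if isinstance(K, KinshipMatrix) else np.asarray(K)
        terms.append(ModelTerm(t, B, kname, f"sigma2_{t}", mapping, line_cov, T))
    return ModelSpec(model_code, with_r, list(ped.hybrid_ids), terms)


def _scaled_inv_chi2(rng: np.random.Generator, df: float, ss: float) -> float:
    return ss / rng.chisquare(df)


def _slice_sample_log_var(
    rng: np.random.Generator,
    current: float,
    S: np.ndarray,
    t2_over_S: np.ndarray,
    sig2_e: float,
    df0: float,
    S0: float,
    width: float = 1.0,
    max_steps: int = 30,
) -> float:
    """Slice-sample a term variance on the log scale from its collapsed
    conditional (coefficients integrated out).

    In the rotated basis the data project onto the term's column space with
    independent coordinates t_j ~ N(0, S_j sigma2 + sigma2_e), so the
    marginal log-density of x = log(sigma2) is evaluated in O(m); a
    stepping-out/shrinkage slice update then moves sigma2 without waiting
    for the coefficient block to drift.
    """

    def logpost(x: float) -> float:
        s2 = np.exp(x)
        den = S * s2 + sig2_e
        loglik = -0.5 * float(np.sum(np.log(den) + t2_over_S / den))
        # scaled-inv-chi2 prior plus log-scale Jacobian
        logprior = -(df0 / 2.0) * x - df0 * S0 / (2.0 * s2)
        return loglik + logprior

    x0 = np.log(current)
    f0 = logpost(x0)
    logy = f0 + np.log(rng.random())
    lo = x0 - width * rng.random()
    hi = lo + width
    for _ in range(max_steps):
        if logpost(lo) <= logy:
            break
        lo -= width
    for _ in range(max_steps):
        if logpost(hi) <= logy:
            break
        hi += width
    while True:
        x1 = lo + (hi - lo) * rng.random()
        if logpost(x1) > logy:
            return float(np.exp(x1))
        if x1 < x0:
            lo = x1
        else:
            hi = x1


class _LineGroup:
    """Sampler machinery for the random terms sharing one line-incidence T.

    Additive, within-group epistatic and residual-genetic terms of the same
    heterotic group all act through ``T g`` with line-level covariance
    ``Sigma(sig2) = sum_t sig2_t K_t``.  The marginal likelihood of the
    group's variances, with every coefficient block integrated out, costs
    only O(n_lines^3) via the Woodbury identity, so each variance can be
    slice-sampled from its collapsed conditional; the coefficient blocks are
    then drawn jointly from their exact multivariate-normal conditional.
    Integrating out the whole group is what decorrelates weakly identified
    pairs (e.g. additive vs residual genetic when the realized additive
    relationship matrix is close to identity).
    """

    def __init__(self, idxs: list[int], M: "ModelSpec", obs: np.ndarray, rot_obs: list):
        self.idxs = idxs
        terms = [M.terms[i] for i in idxs]
        self.names = [t.name for t in terms]
        self.Ks = [t.line_cov for t in terms]
        Tobs = terms[0].incidence[obs]
        self.Tobs = Tobs
        self.counts = Tobs.sum(axis=0)
        self.sqrt_counts = np.sqrt(self.counts)
        self.B = [rot_obs[i] for i in idxs]  # observed-row designs
        self.sizes = [b.shape[1] for b in self.B]
        # pairwise cross-products for the joint coefficient draw
        mtot = sum(self.sizes)
        self.BtB = np.empty((mtot, mtot))
        off = np.cumsum([0] + self.sizes)
        self.offsets = off
        for a in range(len(self.B)):
            for b in range(a, len(self.B)):
                blk = self.B[a].T @ self.B[b]
                self.BtB[off[a]:off[a + 1], off[b]:off[b + 1]] = blk
                self.BtB[off[b]:off[b + 1], off[a]:off[a + 1]] = blk.T

    def _logmarg(self, sig2_grp: np.ndarray, u: np.ndarray, yy: float, sig2_e: float) -> float:
        """-2x log marginal likelihood terms that depend on the group variances.

        With C = sig2_e I + T Sigma T':  logdet(C) = n log sig2_e +
        logdet(I + Dh Sigma Dh / sig2_e) and, by Woodbury, y' C^-1 y =
        (y'y - u' (sig2_e I + Sigma D)^-1 Sigma u) / sig2_e, where u = T'y,
        D = diag(per-line record counts) and Dh = sqrt(D).
        """
        Sigma = sum(s * K for s, K in zip(sig2_grp, self.Ks))
        n1 = Sigma.shape[0]
        A = np.eye(n1) + (self.sqrt_counts[:, None] * Sigma * self.sqrt_counts[None, :]) / sig2_e
        L = np.linalg.cholesky(A)
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        x = np.linalg.solve(sig2_e * np.eye(n1) + Sigma * self.counts[None, :], Sigma @ u)
        quad = (yy - float(u @ x)) / sig2_e
        return -0.5 * (logdet + quad)

    def update(
        self,
        rng: np.random.Generator,
        resid: np.ndarray,
        coef: list,
        sig2: np.ndarray,
        sig2_e: float,
        fixed: dict[str, float],
        df0: float,
        S0_t: float,
        width: float = 1.0,
        max_steps: int = 30,
    ) -> np.ndarray:
        # residual with the whole group's contribution restored
        ystar = resid + sum(B @ coef[i] for B, i in zip(self.B, self.idxs))
        u = self.Tobs.T @ ystar
        yy = float(ystar @ ystar)

        # slice-sample each variance from the group-collapsed conditional
        for pos_in_grp, t_idx in enumerate(self.idxs):
            if self.names[pos_in_grp] in fixed:
                continue

            def logpost(x: float) -> float:
                trial = sig2[self.idxs].copy()
                trial[pos_in_grp] = np.exp(x)
                return (
                    self._logmarg(trial, u, yy, sig2_e)
                    - (df0 / 2.0) * x
                    - df0 * S0_t / (2.0 * np.exp(x))
                )

            x0 = np.log(sig2[t_idx])
            logy = logpost(x0) + np.log(rng.random())
            lo = x0 - width * rng.random()
            hi = lo + width
            for _ in range(max_steps):
                if logpost(lo) <= logy:
                    break
                lo -= width
            for _ in range(max_steps):
                if logpost(hi) <= logy:
                    break
                hi += width
            while True:
                x1 = lo + (hi - lo) * rng.random()
                if logpost(x1) > logy:
                    sig2[t_idx] = float(np.exp(x1))
                    break
                if x1 < x0:
                    lo = x1
                else:
                    hi = x1

        # joint draw of all coefficient blocks given the variances
        mtot = self.BtB.shape[0]
        P = self.BtB / sig2_e
        inv_prior = np.concatenate([
            np.full(m, 1.0 / sig2[i]) for m, i in zip(self.sizes, self.idxs)
        ])
        P[np.diag_indices(mtot)] += inv_prior
        rhs = np.concatenate([B.T @ ystar for B in self.B]) / sig2_e
        L = np.linalg.cholesky(P)
        mean = np.linalg.solve(L.T, np.linalg.solve(L, rhs))
        v_all = mean + np.linalg.solve(L.T, rng.standard_normal(mtot))
        off = self.offsets
        for k, t_idx in enumerate(self.idxs):
            coef[t_idx] = v_all[off[k]:off[k + 1]]
        return ystar - sum(B @ coef[i] for B, i in zip(self.B, self.idxs))


def gibbs_fit(
    y: PhenotypeTable,
    M: ModelSpec,
    C: ChainConfig,
    fixed_variances: dict[str, float] | None = None,
) -> PosteriorSamples:
    """Gibbs sampler for all variances and effects of a model.

    ``fixed_variances`` clamps named variances (term names and/or
    ``"residual"``) so only effects are sampled for them — at fully clamped
    variances the posterior mean of the genetic values is the BLUP solution
    of Henderson's mixed-model equations.

    Samples are reproducible bit-for-bit for a given seed.
    """
    if not np.isfinite(y.values).all():
        raise ValueError("non-finite phenotype values")
    pos = {h: i for i, h in enumerate(M.hybrid_ids)}
    missing = [h for h in y.hybrid_ids if h not in pos]
    if missing:
        raise KeyError(f"phenotyped hybrids absent from the model designs: {missing[:5]}")
    obs = np.array([pos[h] for h in y.hybrid_ids])
    yv = y.values.astype(np.float64)
    nobs = yv.size
    fixed_variances = fixed_variances or {}

    # Hybrid-level terms: rotate the observed-row design so B'B is diagonal;
    # the coefficient block then has an independent conditional posterior and
    # its variance a cheap collapsed (coefficients-integrated) conditional.
    # Line-mapped terms are handled in groups sharing an incidence space
    # (see _LineGroup): their variances are updated with every coefficient
    # block of the group integrated out, which is what lets the sampler move
    # along weakly identified ridges such as additive vs residual genetic.
    rot_obs, rot_full, diag_S = [], [], []
    single_idx, grouped = [], {}
    for t_idx, t in enumerate(M.terms):
        if t.line_cov is not None and t.incidence is not None:
            grouped.setdefault(t.mapping, []).append(t_idx)
            rot_obs.append(t.design[obs])
            rot_full.append(t.design)
            diag_S.append(None)
        else:
            Bobs = t.design[obs]
            S, Q = np.linalg.eigh(Bobs.T @ Bobs)
            S = np.clip(S, 0.0, None)
            rot_obs.append(Bobs @ Q)
            rot_full.append(t.design @ Q)
            diag_S.append(S)
            single_idx.append(t_idx)
    groups = [_LineGroup(idxs, M, obs, rot_obs) for idxs in grouped.values()]

    vy = float(np.var(yv))
    n_terms = len(M.terms)
    df0 = C.prior_df
    # prior scale chosen so the prior mode equals an equal split of the
    # phenotypic variance across terms (mode of scaled-inv-chi2 = df*S/(df+2))
    S0_t = vy * C.prior_genetic_share / max(n_terms, 1) * (df0 + 2.0) / df0
    S0_e = vy * (1.0 - C.prior_genetic_share) * (df0 + 2.0) / df0

    rng = np.random.default_rng(C.seed)
    mu = float(np.mean(yv))
    coef = [np.zeros(B.shape[1]) for B in rot_obs]
    sig2 = np.array([
        fixed_variances.get(t.name, vy * C.prior_genetic_share / max(n_terms, 1))
        for t in M.terms
    ])
    sig2_e = fixed_variances.get("residual", vy * (1.0 - C.prior_genetic_share))
    resid = yv - mu

    n_keep = C.n_samples
    var_samples = {t.name: np.empty(n_keep) for t in M.terms}
    var_samples["residual"] = np.empty(n_keep)
    mu_samples = np.empty(n_keep)
    dev_samples = np.empty(n_keep)
    coef_sums = [np.zeros(B.shape[1]) for B in rot_obs]
    mu_sum = 0.0
    k = 0

    for it in range(C.n_iter):
        # intercept (flat prior)
        resid += mu
        mu = float(rng.normal(np.mean(resid), np.sqrt(sig2_e / nobs)))
        resid -= mu

        for t_idx in single_idx:
            term = M.terms[t_idx]
            B, S, v = rot_obs[t_idx], diag_S[t_idx], coef[t_idx]
            r_plus = resid + B @ v
            t2 = B.T @ r_plus
            if term.name not in fixed_variances:
                # collapsed update: sigma2_t from its marginal with the
                # coefficient block integrated out, then the block exactly —
                # one joint draw from p(sigma2_t, v | rest)
                pos_S = S > 1e-12
                sig2[t_idx] = _slice_sample_log_var(
                    rng, sig2[t_idx], S[pos_S],
                    t2[pos_S] ** 2 / S[pos_S], sig2_e, df0, S0_t,
                )
            prec = S / sig2_e + 1.0 / sig2[t_idx]
            mean_v = t2 / sig2_e / prec
            v_new = mean_v + rng.standard_normal(v.size) / np.sqrt(prec)
            resid = r_plus - B @ v_new
            coef[t_idx] = v_new

        for grp in groups:
            resid = grp.update(rng, resid, coef, sig2, sig2_e, fixed_variances, df0, S0_t)

        if "residual" not in fixed_variances:
            ss = float(resid @ resid) + df0 * S0_e
            sig2_e = _scaled_inv_chi2(rng, df0 + nobs, ss)

        if it >= C.burn_in and (it - C.burn_in) % C.thin == 0:
            for t_idx, term in enumerate(M.terms):
                var_samples[term.name][k] = sig2[t_idx]
                coef_sums[t_idx] += coef[t_idx]
            var_samples["residual"][k] = sig2_e
            mu_samples[k] = mu
            ssr = float(resid @ resid)
            dev_samples[k] = nobs * np.log(2.0 * np.pi * sig2_e) + ssr / sig2_e
            mu_sum += mu
            k += 1

    effect_means = {
        term.name: rot_full[t_idx] @ (coef_sums[t_idx] / n_keep)
        for t_idx, term in enumerate(M.terms)
    }
    return PosteriorSamples(
        var_samples, mu_samples, dev_samples, effect_means,
        list(M.hybrid_ids), list(y.hybrid_ids), C,
    )


_AGG_KEYS = {"A1", "A2", "D", "AA11", "AA22", "AA12", "r1", "r2"}


def summarize_fit(S: PosteriorSamples, M: ModelSpec, y: PhenotypeTable) -> FitSummary:
    """Posterior summaries: variances, broad-sense heritability, DIC, and the
    GCA/SCA aggregate variances (GCA-type models).

    H2 is computed per sample as the ratio of the summed genetic-term
    variances (r included) to that sum plus the residual variance.  DIC =
    mean deviance + pD, with pD = mean deviance minus the deviance at the
    posterior means (conditional Gaussian deviance given sampled effects).
    """
    variances = {
        name: (float(np.mean(s)), float(np.std(s)))
        for name, s in S.variance_samples.items()
    }
    genetic = np.zeros_like(S.mu_samples)
    for t in M.terms:
        genetic = genetic + S.variance_samples[t.name]
    h2 = genetic / (genetic + S.variance_samples["residual"])

    pos = {h: i for i, h in enumerate(S.hybrid_ids)}
    obs = np.array([pos[h] for h in S.obs_hybrid_ids])
    fitted = float(np.mean(S.mu_samples)) + sum(
        S.effect_means[t.name][obs] for t in M.terms
    )
    sig2_e_bar = float(np.mean(S.variance_samples["residual"]))
    ssr = float(np.sum((y.values - fitted) ** 2))
    d_hat = y.n * np.log(2.0 * np.pi * sig2_e_bar) + ssr / sig2_e_bar
    d_bar = float(np.mean(S.deviance_samples))
    p_d = d_bar - d_hat
    dic = d_bar + p_d

    aggregates: dict[str, float] = {}
    if M.model_code.startswith("GCA:"):
        comp = {t.name: variances[t.name][0] for t in M.terms if t.name in _AGG_KEYS}
        from .locus import genotypic_variance_partition

        aggregates = genotypic_variance_partition(comp)

    return FitSummary(
        M.model_code, variances,
        float(np.mean(h2)), float(np.std(h2)),
        float(dic), d_bar, float(p_d), aggregates,
    )


def predict_hybrids(
    S: PosteriorSamples, M: ModelSpec, target: list[str] | HybridPedigree
) -> pd.Series:
    """Predicted total genetic value (intercept + all term contributions at
    posterior-mean coefficients) for the requested hybrids.

    T0 hybrids (no parent phenotyped) still receive informative predictions
    through the marker-based relationship structure baked into the designs.
    """
    hybrid_ids = target.hybrid_ids if isinstance(target, HybridPedigree) else list(target)
    pos = {h: i for i, h in enumerate(S.hybrid_ids)}
    missing = [h for h in hybrid_ids if h not in pos]
    if missing:
        raise KeyError(f"hybrids absent from the model designs: {missing[:5]}")
    idx = np.array([pos[h] for h in hybrid_ids])
    pred = float(np.mean(S.mu_samples)) + sum(
        S.effect_means[t.name][idx] for t in M.terms
    )
    return pd.Series(pred, index=hybrid_ids, name="predicted")
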