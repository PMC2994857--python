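"""Mechanistic model of mutagenic PCR via an error-prone polymerase.

Instead of treating mutagenic PCR as a black box, this module models it as
``k`` thermal cycles of low-fidelity strand synthesis.  The polymerase is a
4x4 column-stochastic operator ``T`` whose entry ``tau[i, j]`` is the
probability that adduct nucleotide ``i`` is paired against template
nucleotide ``j``; for a faithful polymerase the counter-diagonal entries
(A against T, C against G, ...) are close to one.  A single cycle acts on a
sense/nonsense strand-frequency pair ``(s, n)`` as

    Phi(s, n) = ( (s + T n) / 2 , (n + T s) / 2 ),

i.e. each cycle doubles the pool: the old strand plus a freshly synthesized
complement-template copy, then random reassociation averages the pair.
Iterating ``Phi`` k times from each pure starting nucleotide (paired with
its complement) yields the overall per-nucleotide PCR mutation matrix
``P(T, k)``, a highly nonlinear function of ``T``.

Inference works on the log parameterization ``Ttilde = log tau`` with the
four column-sum constraints quotiented out (12 free degrees of freedom;
adding a constant to one column's log-parameters leaves ``T`` unchanged).
The multinomial likelihood of a misincorporation count matrix under
``P(T, k)`` is combined with the Jeffreys prior — the square root of the
12-dimensional pseudo-determinant of the Fisher Information Matrix on the
quotient space — to give a reparameterization-invariant MAP estimate, and
Metropolis sampling with a Laplace-approximation proposal targets the exact
posterior.

All derivatives of ``P`` with respect to the log-parameters are propagated
through the cycle recursion by forward-mode first/second-order
differentiation arithmetic, which stays numerically stable for the typical
k of around 30.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

from .bayes_multinomial import MutationMatrix
from .seqdata import COMPLEMENT_INDEX, MisincorporationCounts

#: Default number of mutagenic PCR thermal cycles.
DEFAULT_CYCLES = 30

# vec(T) ordering is column-major ('F'): parameter a = 4*j + i for entry (i, j).
N_PARAMS = 16


def _column_basis() -> np.ndarray:
    """The four column-constraint directions e1..e4 in vec space (16x4)."""
    E = np.zeros((N_PARAMS, 4))
    for j in range(4):
        E[4 * j : 4 * j + 4, j] = 1.0
    return E


CONSTRAINT_BASIS = _column_basis()
#: Orthonormal basis of the 12-dimensional quotient space (16x12): the
#: orthogonal complement of the four column-constraint directions.
QUOTIENT_BASIS = np.linalg.svd(CONSTRAINT_BASIS, full_matrices=True)[0][:, 4:]


def complement_operator() -> np.ndarray:
    """The perfect-fidelity polymerase: exact Watson-Crick complementation."""
    K = np.zeros((4, 4))
    K[COMPLEMENT_INDEX, np.arange(4)] = 1.0
    return K


@dataclass
class PolymeraseMatrix:
    """Column-stochastic Taq misincorporation operator."""

    T: np.ndarray

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        if self.T.shape != (4, 4):
            raise ValueError("T must be 4x4")
        if np.any(self.T < 0):
            raise ValueError("entries must be non-negative")
        if not np.allclose(self.T.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("columns must sum to 1")

    @property
    def log_params(self) -> np.ndarray:
        """Ttilde = log vec(T), column-major; requires strictly positive T."""
        return np.log(self.T).ravel(order="F")

    @classmethod
    def from_log_params(cls, ttilde: np.ndarray) -> "PolymeraseMatrix":
        return cls(_t_from_log(np.asarray(ttilde, dtype=float)))


@dataclass
class StrandPair:
    """Sense/nonsense nucleotide frequency pair at one site."""

    s: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        for v in (self.s, self.n):
            if v.shape != (4,) or np.any(v < -1e-12) or abs(v.sum() - 1) > 1e-9:
                raise ValueError("strand vectors must be probability 4-vectors")


@dataclass
class FisherInfo:
    """Expected Fisher information of the count likelihood in log-parameters.

    ``F`` is 16x16 and symmetric, with exactly four null directions spanned
    by the column-constraint vectors.  ``pseudo_log_det`` is the log
    determinant of ``F`` projected onto the 12-dimensional quotient space.
    """

    F: np.ndarray
    column_totals: np.ndarray
    pseudo_log_det: float = field(init=False)

    def __post_init__(self) -> None:
        Fq = QUOTIENT_BASIS.T @ self.F @ QUOTIENT_BASIS
        sign, logdet = np.linalg.slogdet(Fq)
        if sign <= 0:
            raise np.linalg.LinAlgError("projected Fisher information is singular")
        self.pseudo_log_det = float(logdet)

    @property
    def projected(self) -> np.ndarray:
        """The 12x12 quotient-space block."""
        return QUOTIENT_BASIS.T @ self.F @ QUOTIENT_BASIS


def _t_from_log(ttilde: np.ndarray) -> np.ndarray:
    """Column-normalized exp of the log-parameters (softmax per column)."""
    W = ttilde.reshape(4, 4, order="F")
    W = W - W.max(axis=0)  # gauge freedom: stabilize before exponentiation
    E = np.exp(W)
    return E / E.sum(axis=0)


def _t_derivatives(ttilde: np.ndarray, order: int = 1):
    """T and its derivatives w.r.t. the 16 log-parameters.

    Returns ``(T, dT, d2T)`` with ``dT`` of shape (4, 4, 16) and ``d2T`` of
    shape (4, 4, 16, 16) (``None`` unless ``order >= 2``).  Only parameters
    belonging to a column affect that column (softmax derivatives).
    """
    T = _t_from_log(ttilde)
    dT = np.zeros((4, 4, N_PARAMS))
    d2T = np.zeros((4, 4, N_PARAMS, N_PARAMS)) if order >= 2 else None
    I4 = np.eye(4)
    for j in range(4):
        sig = T[:, j]
        # d sigma_i / d t_r = sigma_i (delta_ir - sigma_r)
        J = sig[:, None] * (I4 - sig[None, :])
        dT[:, j, 4 * j : 4 * j + 4] = J
        if order >= 2:
            # d2 sigma_i / dt_r dt_q =
            #   sigma_i (d_ir - s_r)(d_iq - s_q) - sigma_i s_r (d_rq - s_q)
            A = (I4 - sig[None, :])  # A[i, r] = delta_ir - sigma_r
            H = (
                sig[:, None, None] * A[:, :, None] * A[:, None, :]
                - sig[:, None, None]
                * sig[None, :, None]
                * (I4[None, :, :] - sig[None, None, :])
            )
            d2T[:, j, 4 * j : 4 * j + 4, 4 * j : 4 * j + 4] = H
    return T, dT, d2T


def pcr_cycle(sp: StrandPair, T: PolymeraseMatrix | np.ndarray) -> StrandPair:
    """One PCR cycle: denature, synthesize with errors, reassociate."""
    Tm = T.T if isinstance(T, PolymeraseMatrix) else np.asarray(T)
    return StrandPair(0.5 * (sp.s + Tm @ sp.n), 0.5 * (sp.n + Tm @ sp.s))


def pcr_mutation_matrix(
    T: PolymeraseMatrix | np.ndarray, k: int
) -> MutationMatrix:
    """Per-nucleotide mutation matrix implied by ``k`` cycles of PCR.

    Column ``l`` is the sense-strand distribution after ``k`` cycles started
    from pure nucleotide ``l`` paired with its complement.  The cycle
    recursion is iterated directly, which avoids the underflow of the
    expanded binomial polynomial.
    """
    if k < 0 or int(k) != k:
        raise ValueError("k must be a non-negative integer")
    Tm = T.T if isinstance(T, PolymeraseMatrix) else np.asarray(T, dtype=float)
    S = np.eye(4)  # column l: sense distribution started from nucleotide l
    N = np.eye(4)[COMPLEMENT_INDEX]  # paired complement strands
    for _ in range(int(k)):
        S, N = 0.5 * (S + Tm @ N), 0.5 * (N + Tm @ S)
    return MutationMatrix(S, source="pcr_model_map")


def pcr_model_with_derivatives(ttilde: np.ndarray, k: int, order: int = 1):
    """``P(T(ttilde), k)`` with forward-mode derivatives in log-parameters.

    Returns ``(P, dP, d2P)``: ``dP`` has shape (4, 4, 16), ``d2P`` shape
    (4, 4, 16, 16) (``None`` for ``order < 2``).  The derivative recursion
    mirrors the cycle operator:

        s' = (s + T n)/2
        ds' = (ds + dT n + T dn)/2
        d2s' = (d2s + d2T n + dT_a dn_b + dT_b dn_a + T d2n)/2
    """
    T, dT, d2T = _t_derivatives(ttilde, order=order)
    S = np.eye(4)
    N = np.eye(4)[COMPLEMENT_INDEX]
    dS = np.zeros((4, 4, N_PARAMS))
    dN = np.zeros((4, 4, N_PARAMS))
    if order >= 2:
        d2S = np.zeros((4, 4, N_PARAMS, N_PARAMS))
        d2N = np.zeros((4, 4, N_PARAMS, N_PARAMS))
    for _ in range(int(k)):
        TS, TN = T @ S, T @ N
        dTS = np.einsum("ija,jl->ila", dT, S) + np.einsum("ij,jla->ila", T, dS)
        dTN = np.einsum("ija,jl->ila", dT, N) + np.einsum("ij,jla->ila", T, dN)
        if order >= 2:
            d2TS = (
                np.einsum("ijab,jl->ilab", d2T, S)
                + np.einsum("ija,jlb->ilab", dT, dS)
                + np.einsum("ijb,jla->ilab", dT, dS)
                + np.einsum("ij,jlab->ilab", T, d2S)
            )
            d2TN = (
                np.einsum("ijab,jl->ilab", d2T, N)
                + np.einsum("ija,jlb->ilab", dT, dN)
                + np.einsum("ijb,jla->ilab", dT, dN)
                + np.einsum("ij,jlab->ilab", T, d2N)
            )
            d2S, d2N = 0.5 * (d2S + d2TN), 0.5 * (d2N + d2TS)
        S, N = 0.5 * (S + TN), 0.5 * (N + TS)
        dS, dN = 0.5 * (dS + dTN), 0.5 * (dN + dTS)
    if order >= 2:
        return S, dS, d2S
    return S, dS, None


def counts_log_likelihood(
    C: MisincorporationCounts, T: PolymeraseMatrix | np.ndarray, k: int
) -> float:
    """Log probability of the count matrix under the PCR model.

    The product of four multinomial distributions, one per wild-type
    nucleotide column, including the multinomial coefficients.  Returns
    ``-inf`` (no exception) if the model assigns zero probability to an
    observed event.
    """
    P = pcr_mutation_matrix(T, k).matrix
    return _multinomial_log_likelihood(C.counts, P)


def _multinomial_log_likelihood(counts: np.ndarray, P: np.ndarray) -> float:
    counts = np.asarray(counts, dtype=float)
    with np.errstate(divide="ignore"):
        logp = np.log(P)
    if np.any((counts > 0) & np.isneginf(logp)):
        return -np.inf
    ll = float(np.sum(counts * np.where(counts > 0, logp, 0.0)))
    # multinomial coefficients, one per column
    ll += float(np.sum(gammaln(counts.sum(axis=0) + 1)) - np.sum(gammaln(counts + 1)))
    return ll


def fisher_information(
    T: PolymeraseMatrix | np.ndarray | None,
    column_totals: np.ndarray,
    k: int,
    *,
    ttilde: np.ndarray | None = None,
    include_hessian_term: bool = False,
) -> FisherInfo:
    """Expected Fisher information of the count likelihood in log-parameters.

    Uses ``E[c_ij] ~= c_+j p_ij`` (the observed column totals stand in for
    the wild-type base composition).  The exact expected information reduces
    to the score outer product

        F_ab = sum_ij c_+j (dp_ij/da)(dp_ij/db) / p_ij ,

    because the Hessian term ``-sum_ij c_+j d2p_ij/dadb`` vanishes
    identically: every column of ``P`` sums to one for all parameter values,
    so all its derivatives cancel over ``i``.  Set
    ``include_hessian_term=True`` to evaluate the full expression anyway
    (it agrees to rounding error and exists mainly for verification).
    """
    if ttilde is None:
        Tm = T.T if isinstance(T, PolymeraseMatrix) else np.asarray(T, dtype=float)
        ttilde = np.log(Tm).ravel(order="F")
    ttilde = np.asarray(ttilde, dtype=float)
    order = 2 if include_hessian_term else 1
    P, dP, d2P = pcr_model_with_derivatives(ttilde, k, order=order)
    w = np.asarray(column_totals, dtype=float)[None, :] / P  # c_+j / p_ij
    F = np.einsum("ij,ija,ijb->ab", w, dP, dP)
    if include_hessian_term:
        F = F - np.einsum("j,ijab->ab", np.asarray(column_totals, dtype=float), d2P)
    F = 0.5 * (F + F.T)
    return FisherInfo(F, np.asarray(column_totals, dtype=float))


def jeffreys_log_prior(
    T: PolymeraseMatrix | np.ndarray | None,
    column_totals: np.ndarray,
    k: int,
    *,
    ttilde: np.ndarray | None = None,
) -> float:
    """Log of the Jeffreys prior: half the log pseudo-determinant of the FIM.

    Computed on the 12-dimensional quotient space, so the prior is invariant
    under per-column shifts of the log-parameters (the gauge freedom of the
    column-sum constraints).
    """
    info = fisher_information(T, column_totals, k, ttilde=ttilde)
    return 0.5 * info.pseudo_log_det


def log_posterior(
    ttilde: np.ndarray, C: MisincorporationCounts, k: int
) -> float:
    """Unnormalized log posterior: multinomial likelihood plus Jeffreys prior."""
    T = _t_from_log(np.asarray(ttilde, dtype=float))
    ll = counts_log_likelihood(C, T, k)
    if not np.isfinite(ll):
        return -np.inf
    try:
        lp = jeffreys_log_prior(None, C.column_totals, k, ttilde=ttilde)
    except np.linalg.LinAlgError:
        return -np.inf
    return ll + lp


def initial_polymerase(C: MisincorporationCounts, k: int) -> PolymeraseMatrix:
    """Starting polymerase for optimization.

    Linearizing the cycle recursion around the perfect-complement operator
    ``K`` shows the observed mutation matrix satisfies ``P - I ~ (k/2) D K``
    with ``T = K + D``, so the relative-frequency estimate of ``P`` is pulled
    back by ``D = (2/k) (P_rel - I) K`` and clipped to positive mass.
    """
    K = complement_operator()
    P_rel = C.counts / C.column_totals
    D = (2.0 / max(k, 1)) * (P_rel - np.eye(4)) @ K
    T0 = K + D
    T0 = np.clip(T0, 1e-8, None)
    T0 = T0 / T0.sum(axis=0)
    return PolymeraseMatrix(T0)


@dataclass
class MapFit:
    """Result of a MAP fit of the polymerase model."""

    T: PolymeraseMatrix
    P: MutationMatrix
    k: int
    log_posterior: float
    z: np.ndarray  # quotient-space coordinates of the optimum
    info: FisherInfo
    n_iter: int

    def posterior_sd_P(self) -> np.ndarray:
        """Laplace-approximation posterior SD of each entry of ``P``.

        Delta method: propagate the inverse projected FIM through the
        Jacobian of ``P`` with respect to the quotient coordinates.
        """
        cov_z = np.linalg.inv(self.info.projected)
        _, dP, _ = pcr_model_with_derivatives(
            QUOTIENT_BASIS @ self.z, self.k, order=1
        )
        J = np.einsum("ija,ab->ijb", dP, QUOTIENT_BASIS)  # (4,4,12)
        var = np.einsum("ija,ab,ijb->ij", J, cov_z, J)
        return np.sqrt(np.maximum(var, 0.0))


def map_estimate(
    C: MisincorporationCounts,
    k: int = DEFAULT_CYCLES,
    *,
    gtol: float = 1e-6,
    maxiter: int = 500,
) -> MapFit:
    """Maximum a posteriori polymerase fit over the 12-d.o.f. quotient space.

    Maximizes multinomial log likelihood plus the Jeffreys log prior by
    quasi-Newton (BFGS) in the quotient coordinates, started from the
    linearized relative-frequency pull-back.  The likelihood gradient is
    analytic (forward-mode derivatives of ``P``); the slowly varying prior
    gradient is evaluated by central differences.
    """
    totals = C.column_totals.astype(float)
    t0 = initial_polymerase(C, k).log_params
    z0 = QUOTIENT_BASIS.T @ t0

    def neg_log_post(z: np.ndarray) -> float:
        lp = log_posterior(QUOTIENT_BASIS @ z, C, k)
        return np.inf if not np.isfinite(lp) else -lp

    def neg_grad(z: np.ndarray) -> np.ndarray:
        ttilde = QUOTIENT_BASIS @ z
        P, dP, _ = pcr_model_with_derivatives(ttilde, k, order=1)
        g_ll = np.einsum("ij,ija->a", C.counts / P, dP) @ QUOTIENT_BASIS
        # prior gradient: central differences in quotient coordinates
        g_pr = np.empty_like(z)
        h = 1e-5
        for a in range(z.size):
            zp, zm = z.copy(), z.copy()
            zp[a] += h
            zm[a] -= h
            lp_p = jeffreys_log_prior(None, totals, k, ttilde=QUOTIENT_BASIS @ zp)
            lp_m = jeffreys_log_prior(None, totals, k, ttilde=QUOTIENT_BASIS @ zm)
            g_pr[a] = (lp_p - lp_m) / (2 * h)
        return -(g_ll + g_pr)

    res = minimize(
        neg_log_post,
        z0,
        jac=neg_grad,
        method="BFGS",
        options={"gtol": gtol, "maxiter": maxiter},
    )
    if not np.all(np.isfinite(res.x)):
        raise RuntimeError(f"MAP optimization failed: {res.message}")
    z = res.x
    ttilde = QUOTIENT_BASIS @ z
    T = PolymeraseMatrix.from_log_params(ttilde)
    P = pcr_mutation_matrix(T, k)
    P.source = "pcr_model_map"
    info = fisher_information(None, totals, k, ttilde=ttilde)
    return MapFit(
        T=T,
        P=P,
        k=k,
        log_posterior=-res.fun,
        z=z,
        info=info,
        n_iter=int(res.nit),
    )


@dataclass
class ChainSettings:
    """Metropolis chain configuration.  ``seed`` is mandatory."""

    length: int = 50_000
    burn_in: int = 5_000
    thin: int = 10
    seed: int = 0
    target_acceptance: tuple[float, float] = (0.10, 0.40)
    adapt_batches: int = 10
    adapt_batch_size: int = 200


@dataclass
class PosteriorChain:
    """Thinned Metropolis draws of the polymerase posterior."""

    T_draws: np.ndarray  # (m, 4, 4)
    P_draws: np.ndarray  # (m, 4, 4)
    acceptance_rate: float
    proposal_scale: float
    map_fit: MapFit


def sample_posterior_T(
    C: MisincorporationCounts,
    k: int = DEFAULT_CYCLES,
    chain: ChainSettings | None = None,
    map_fit: MapFit | None = None,
) -> PosteriorChain:
    """Metropolis sampling of the polymerase posterior.

    Random-walk Metropolis in the 12-dimensional quotient log-space with a
    multivariate normal proposal whose covariance is the inverse projected
    FIM at the MAP (the Laplace approximation), rescaled during a short
    adaptation phase to reach a workable acceptance rate.  Rejection
    guarantees the chain targets the exact posterior; the approximation only
    affects efficiency.
    """
    chain = chain or ChainSettings()
    fit = map_fit or map_estimate(C, k)
    rng = np.random.default_rng(chain.seed)
    cov = np.linalg.inv(fit.info.projected)
    L = np.linalg.cholesky(0.5 * (cov + cov.T))
    scale = 2.38 / np.sqrt(cov.shape[0])

    def step(z, lp, s):
        zp = z + s * (L @ rng.standard_normal(z.size))
        lpp = log_posterior(QUOTIENT_BASIS @ zp, C, k)
        if np.log(rng.random()) < lpp - lp:
            return zp, lpp, True
        return z, lp, False

    z = fit.z.copy()
    lp = log_posterior(QUOTIENT_BASIS @ z, C, k)
    # adaptation: tune the proposal scale toward the target acceptance band
    lo, hi = chain.target_acceptance
    for _ in range(chain.adapt_batches):
        acc = 0
        for _ in range(chain.adapt_batch_size):
            z, lp, a = step(z, lp, scale)
            acc += a
        rate = acc / chain.adapt_batch_size
        if rate < lo:
            scale /= 1.5
        elif rate > hi:
            scale *= 1.5
        else:
            break
    accepted = 0
    kept = []
    for i in range(chain.length):
        z, lp, a = step(z, lp, scale)
        accepted += a
        if i >= chain.burn_in and (i - chain.burn_in) % chain.thin == 0:
            kept.append(z.copy())
    rate = accepted / chain.length
    if rate < 0.005:
        import warnings

        warnings.warn(
            f"Metropolis acceptance rate {rate:.4f} below 0.5% after adaptation",
            RuntimeWarning,
            stacklevel=2,
        )
    Z = np.array(kept)
    T_draws = np.empty((len(Z), 4, 4))
    P_draws = np.empty((len(Z), 4, 4))
    for m, zz in enumerate(Z):
        Tm = _t_from_log(QUOTIENT_BASIS @ zz)
        T_draws[m] = Tm
        P_draws[m] = pcr_mutation_matrix(Tm, k).matrix
    return PosteriorChain(
        T_draws=T_draws,
        P_draws=P_draws,
        acceptance_rate=rate,
        proposal_scale=scale,
        map_fit=fit,
    )
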