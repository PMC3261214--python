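"""Logistic item-response calibration by marginal maximum likelihood.

Model
-----
Each patient ``s`` carries a scalar latent trait ``theta_s`` (here: degree
of confidence in the diagnosis the code set describes); each code ``i`` has
a discrimination ``alpha_i`` and a location ``beta_i``.  The two-parameter
logistic (2PL) response function for the endorsement indicator ``X_si`` is

    P(X_si = 1 | theta_s) = exp(alpha_i (theta_s - beta_i))
                            / (1 + exp(alpha_i (theta_s - beta_i)))

The 1PL variant shares a single slope across codes (per-code locations);
the 3PL variant adds a lower asymptote ``gamma_i`` in [0, 1):
``P = gamma + (1 - gamma) * 2PL``.

Estimation is marginal maximum likelihood (MML): ``theta`` is integrated
out over a standard-normal prior discretised on a fixed quadrature grid,
and the marginal likelihood is maximised over the item parameters with the
Bock-Aitkin EM algorithm.  The E-step forms, at every quadrature node, the
posterior-expected number of patients (``n_k``) and endorsements per item
(``r_ik``); the M-step refits each item's logistic curve to those expected
counts by damped Newton iterations.  A small number of post-EM Newton
cycles (one safeguarded Newton step per item against fresh expected counts)
polishes the solution.  The trait metric is identified by fixing the prior
to the grid (mean 0, SD 1).

Standard errors come from the observed information of the marginal
log-likelihood (complete-data information minus the posterior score
covariance, i.e. the missing information), assembled across all items and
inverted; they are mapped to the slope-threshold parameterisation by the
delta method.

Before fitting, items are screened on the correlation between each code's
indicator and the rest-score (sum of all other codes): codes correlating
below a threshold (default -0.15) sit outside the measurable range of the
trait and are excluded, as are degenerate (zero-variance) codes.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse
from scipy.special import expit, log_expit
from scipy.stats import norm

from .records import ResponseMatrix

logger = logging.getLogger("epirt.irt")

MODELS = ("1pl", "2pl", "3pl")
_SLOPE_MIN, _SLOPE_MAX = 1e-3, 60.0
_P_EPS = 1e-12


# ---------------------------------------------------------------------------
# quadrature and the response function


@dataclasses.dataclass(frozen=True)
class QuadratureGrid:
    """Discretised trait prior: ordered nodes with normalised weights."""

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if nodes.ndim != 1 or nodes.shape != weights.shape:
            raise ValueError("nodes and weights must be 1-D arrays of equal length")
        if not (np.diff(nodes) > 0).all():
            raise ValueError("nodes must be strictly increasing")
        if (weights <= 0).any():
            raise ValueError("weights must be positive")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights / weights.sum())

    @classmethod
    def normal(cls, size: int = 21, bound: float = 6.0, mean: float = 0.0, sd: float = 1.0):
        """Equally spaced nodes on ``mean +/- bound*sd`` with normal mass."""
        nodes = np.linspace(mean - bound * sd, mean + bound * sd, size)
        return cls(nodes=nodes, weights=norm.pdf(nodes, loc=mean, scale=sd))

    def shifted(self, delta: float) -> "QuadratureGrid":
        return QuadratureGrid(nodes=self.nodes + delta, weights=self.weights)


def irf(theta, alpha, beta, gamma=0.0):
    """Item response function P(endorse | theta); stable for large logits."""
    z = np.asarray(alpha) * (np.asarray(theta) - np.asarray(beta))
    return gamma + (1.0 - np.asarray(gamma)) * expit(z)


# ---------------------------------------------------------------------------
# item screening


def screen_items(
    data: ResponseMatrix | np.ndarray,
    threshold: float = -0.15,
    code_ids: np.ndarray | None = None,
) -> tuple[np.ndarray, list[dict]]:
    """Screen codes on the item-rest correlation.

    For each code, the Pearson (point-biserial) correlation between its 0/1
    indicator and the rest-score — the per-patient sum of all *other*
    codes — is computed.  Codes with correlation below ``threshold`` are
    excluded (recorded with the correlation); codes whose correlation is
    undefined because either variable is constant are excluded with reason
    ``"degenerate"``.

    Returns (kept column indices, exclusion records).
    """
    if isinstance(data, ResponseMatrix):
        X = data.X
        code_ids = data.code_ids
    else:
        X = np.asarray(data)
        if code_ids is None:
            code_ids = np.arange(X.shape[1])
    if X.shape[1] < 2:
        raise ValueError("screening needs at least 2 codes")
    Xf = X.astype(float)
    total = Xf.sum(axis=1)
    kept, excluded = [], []
    for i in range(X.shape[1]):
        x = Xf[:, i]
        rest = total - x
        if x.std() == 0.0 or rest.std() == 0.0:
            excluded.append({"code": code_ids[i], "correlation": np.nan, "reason": "degenerate"})
            continue
        r = float(np.corrcoef(x, rest)[0, 1])
        if r < threshold:
            excluded.append({"code": code_ids[i], "correlation": r, "reason": "rest_correlation"})
        else:
            kept.append(i)
    return np.asarray(kept, dtype=int), excluded


# ---------------------------------------------------------------------------
# marginal likelihood


def _probs(alpha, beta, gamma, nodes) -> np.ndarray:
    """P_ik = P(endorse item i | theta = node k); (m, K), clipped."""
    z = np.asarray(alpha)[:, None] * (nodes[None, :] - np.asarray(beta)[:, None])
    p = np.asarray(gamma)[:, None] + (1.0 - np.asarray(gamma))[:, None] * expit(z)
    return np.clip(p, _P_EPS, 1.0 - _P_EPS)


def _pattern_loglik(X: np.ndarray, P: np.ndarray) -> np.ndarray:
    """log P(x_s | theta_k) for every patient and node; (n, K)."""
    Xf = X.astype(float)
    logP = np.log(P)
    log1mP = np.log1p(-P)
    return Xf @ logP + (1.0 - Xf) @ log1mP  # P passed as (m, K)


def marginal_loglik(
    X: np.ndarray,
    alpha: np.ndarray,
    beta: np.ndarray,
    grid: QuadratureGrid,
    gamma: np.ndarray | float = 0.0,
    return_posterior: bool = False,
):
    """Marginal log-likelihood sum_s log sum_k w_k P(x_s | theta_k).

    Computed in log space; finite for any binary response matrix,
    including all-zero rows and extreme item parameters.
    """
    X = np.asarray(X)
    gamma = np.broadcast_to(np.asarray(gamma, dtype=float), np.shape(alpha)).copy()
    P = _probs(alpha, beta, gamma, grid.nodes)
    ll = _pattern_loglik(X, P) + np.log(grid.weights)[None, :]
    top = ll.max(axis=1, keepdims=True)
    marg = top[:, 0] + np.log(np.exp(ll - top).sum(axis=1))
    total = float(marg.sum())
    if not return_posterior:
        return total
    post = np.exp(ll - marg[:, None])
    return total, post, P


# ---------------------------------------------------------------------------
# M-step machinery (weighted logistic fits to expected counts)


def _q_value(a, d, theta, n_k, r_k) -> float:
    z = a * theta + d
    return float(r_k @ log_expit(z) + (n_k - r_k) @ log_expit(-z))


def _newton_item_2pl(theta, n_k, r_k, a0, d0, max_iter=50, tol=1e-9, penalty_sd=None):
    """Damped Newton ascent of the weighted Bernoulli log-likelihood.

    Optionally adds a lognormal penalty on the slope,
    ``-(log a)^2 / (2 penalty_sd^2)``, used to stabilise very thin items.
    """

    def objective(a, d):
        q = _q_value(a, d, theta, n_k, r_k)
        if penalty_sd is not None:
            q -= np.log(a) ** 2 / (2.0 * penalty_sd**2)
        return q

    a, d = float(a0), float(d0)
    q = objective(a, d)
    for _ in range(max_iter):
        p = expit(a * theta + d)
        resid = r_k - n_k * p
        ga = float(theta @ resid)
        gd = float(resid.sum())
        w = n_k * p * (1.0 - p)
        haa = float(w @ theta**2)
        had = float(w @ theta)
        hdd = float(w.sum())
        if penalty_sd is not None:
            la = np.log(a)
            ga -= la / (a * penalty_sd**2)
            haa += (1.0 - la) / (a**2 * penalty_sd**2)
        det = haa * hdd - had**2
        if det <= 1e-14 * max(haa * hdd, 1e-30):
            break
        da = (hdd * ga - had * gd) / det
        dd = (haa * gd - had * ga) / det
        step = 1.0
        for _ in range(30):
            a_new = float(np.clip(a + step * da, _SLOPE_MIN, _SLOPE_MAX))
            d_new = d + step * dd
            q_new = objective(a_new, d_new)
            if q_new >= q - 1e-12:
                break
            step *= 0.5
        if q_new < q - 1e-9:  # no ascent possible
            break
        moved = max(abs(a_new - a), abs(d_new - d))
        a, d, q = a_new, d_new, q_new
        if moved < tol:
            break
    return a, d, q


def _newton_intercepts(theta, n_k, R, a, D, iters=25, tol=1e-10):
    """Per-item 1-D Newton on intercepts for a shared slope (vectorised)."""
    D = D.copy()
    for _ in range(iters):
        Z = a * theta[None, :] + D[:, None]
        p = expit(Z)
        g = (R - n_k[None, :] * p).sum(axis=1)
        h = (n_k[None, :] * p * (1.0 - p)).sum(axis=1)
        step = g / np.maximum(h, 1e-12)
        step = np.clip(step, -4.0, 4.0)
        D = D + step
        if np.abs(step).max() < tol:
            break
    return D


def _newton_shared_slope(theta, n_k, R, a, D, iters=25, tol=1e-10):
    for _ in range(iters):
        Z = a * theta[None, :] + D[:, None]
        p = expit(Z)
        g = float((theta[None, :] * (R - n_k[None, :] * p)).sum())
        h = float((theta[None, :] ** 2 * n_k[None, :] * p * (1.0 - p)).sum())
        if h <= 1e-12:
            break
        step = float(np.clip(g / h, -2.0, 2.0))
        a = float(np.clip(a + step, _SLOPE_MIN, _SLOPE_MAX))
        if abs(step) < tol:
            break
    return a


_GUESS_MIN = 1e-6


def _fit_item_3pl(theta, n_k, r_k, a0, d0, g0, guess_prior, guess_max):
    """Bounded maximisation of the weighted 3PL log-likelihood per item.

    A weak Beta(a, b) prior on the lower asymptote keeps it away from
    degenerate corners; the asymptote is capped (default 0.5).
    """
    pa, pb = guess_prior

    def neg(params):
        a, d, g = params
        p = g + (1.0 - g) * expit(a * theta + d)
        p = np.clip(p, _P_EPS, 1.0 - _P_EPS)
        q = float(r_k @ np.log(p) + (n_k - r_k) @ np.log1p(-p))
        q += (pa - 1.0) * np.log(g) + (pb - 1.0) * np.log1p(-g)
        return -q

    res = scipy.optimize.minimize(
        neg,
        x0=[a0, d0, max(g0, 1e-3)],
        method="L-BFGS-B",
        bounds=[(_SLOPE_MIN, _SLOPE_MAX), (-60.0, 60.0), (_GUESS_MIN, guess_max)],
    )
    if neg(res.x) <= neg([a0, d0, max(g0, _GUESS_MIN)]):
        return float(res.x[0]), float(res.x[1]), float(res.x[2])
    return a0, d0, max(g0, _GUESS_MIN)


# ---------------------------------------------------------------------------
# the model object


class CodeIRT:
    """Logistic IRT calibration model for a binary endorsement matrix.

    Parameters
    ----------
    data
        A :class:`~epirt.records.ResponseMatrix`, or a plain (n, m) binary
        array (``code_ids`` may then label the columns).
    model
        ``"1pl"`` (shared slope), ``"2pl"`` (default) or ``"3pl"``.
    grid, grid_size, grid_bound
        Trait-prior quadrature: ``grid_size`` equally spaced nodes on
        ``[-grid_bound, grid_bound]`` with standard-normal weights
        renormalised to unit mass, unless an explicit grid is given.
    screen, screen_threshold
        Apply the item-rest correlation screen before fitting.
    slope_penalty_sd
        Optional lognormal penalty SD on slopes (off by default); mildly
        stabilises items endorsed by a handful of patients.
    guess_prior, guess_max
        3PL lower-asymptote Beta-prior shape and upper bound.

    Examples
    --------
    >>> model = CodeIRT(matrix, model="2pl")
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(
        self,
        data,
        model: str = "2pl",
        code_ids=None,
        grid: QuadratureGrid | None = None,
        grid_size: int = 21,
        grid_bound: float = 6.0,
        screen: bool = True,
        screen_threshold: float = -0.15,
        slope_penalty_sd: float | None = None,
        guess_prior: tuple[float, float] = (1.25, 6.0),
        guess_max: float = 0.5,
    ):
        if model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        if isinstance(data, ResponseMatrix):
            self.matrix = data
            X = data.X
            code_ids = data.code_ids
            self.terms = data.terms or {}
        else:
            self.matrix = None
            X = np.asarray(data)
            if not np.isin(X, (0, 1)).all():
                raise ValueError("responses must be binary")
            if code_ids is None:
                code_ids = np.array([f"item{i}" for i in range(X.shape[1])])
            self.terms = {}
        self.X_all = X.astype(np.uint8)
        self.code_ids_all = np.asarray(code_ids)
        self.model = model
        self.grid = grid if grid is not None else QuadratureGrid.normal(grid_size, grid_bound)
        self.screen = screen
        self.screen_threshold = screen_threshold
        self.slope_penalty_sd = slope_penalty_sd
        self.guess_prior = guess_prior
        self.guess_max = guess_max

    @classmethod
    def from_events(cls, events, config, model: str = "2pl", **kwargs) -> "CodeIRT":
        """Build the model straight from an event table.

        Runs the records pipeline (deduplicate, cohort, matrix) with the
        given :class:`~epirt.records.CohortConfig`.
        """
        from . import records

        ev = records.deduplicate_same_date(events)
        cohort = records.build_cohort(ev, config)
        matrix = records.build_response_matrix(ev, cohort, config)
        return cls(matrix, model=model, **kwargs)

    # -- initial values ----------------------------------------------------

    def _init_params(self, X):
        n = X.shape[0]
        rate = np.clip(X.mean(axis=0), 0.5 / n, 1.0 - 0.5 / n)
        beta = -norm.ppf(rate)
        alpha = np.ones(X.shape[1])
        return alpha, beta

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        criterion: float = 0.01,
        max_em: int = 20,
        max_newton: int = 2,
        start: tuple | None = None,
        compute_se: bool = True,
        low_information_threshold: int = 5,
    ) -> "CodeIRTResults":
        """Estimate item parameters by Bock-Aitkin EM with Newton polish.

        Stops when the largest absolute parameter change in a cycle falls
        below ``criterion`` (default 0.01), or when the EM (default 20) and
        Newton (default 2) cycle budgets are exhausted; in the latter case
        the result is returned with ``converged=False`` rather than raising.
        ``start`` may carry (alpha, beta) or (alpha, beta, gamma) warm-start
        arrays for the kept items.
        """
        kept, excluded = self._apply_screen()
        X = np.ascontiguousarray(self.X_all[:, kept])
        codes = self.code_ids_all[kept]
        m = X.shape[1]
        if m == 0:
            raise ValueError("no items survive screening")

        if start is not None:
            alpha = np.array(start[0], dtype=float).copy()
            beta = np.array(start[1], dtype=float).copy()
            gamma = (
                np.array(start[2], dtype=float).copy()
                if len(start) > 2
                else np.zeros(m)
            )
            if self.model == "3pl":
                gamma = np.maximum(gamma, _GUESS_MIN)
        else:
            alpha, beta = self._init_params(X)
            gamma = np.full(m, 0.02) if self.model == "3pl" else np.zeros(m)
        if self.model == "1pl":
            alpha = np.full(m, float(alpha.mean()))

        nodes, weights = self.grid.nodes, self.grid.weights
        a = alpha.copy()
        d = -alpha * beta
        g = gamma.copy()

        trace: list[float] = []
        em_used = newton_used = 0
        converged = False
        max_change = np.inf

        def estep(a, d, g):
            al = a
            be = -d / a
            ll, post, P = marginal_loglik(X, al, be, self.grid, gamma=g, return_posterior=True)
            n_k = post.sum(axis=0)
            R = post.T @ X.astype(float)  # (K, m)
            return -2.0 * ll, post, P, n_k, R.T  # R -> (m, K)

        m2ll, post, P, n_k, R = estep(a, d, g)
        trace.append(m2ll)

        def mstep(a, d, g, n_k, R, single_step: bool):
            iters = 1 if single_step else 50
            if self.model == "1pl":
                for _ in range(1 if single_step else 4):
                    d = _newton_intercepts(nodes, n_k, R, a[0], d, iters=1 if single_step else 25)
                    a_shared = _newton_shared_slope(nodes, n_k, R, a[0], d, iters=1 if single_step else 25)
                    a = np.full_like(a, a_shared)
            elif self.model == "2pl":
                for i in range(m):
                    ai, di, _ = _newton_item_2pl(
                        nodes, n_k, R[i], a[i], d[i],
                        max_iter=iters, penalty_sd=self.slope_penalty_sd,
                    )
                    a[i], d[i] = ai, di
            else:
                for i in range(m):
                    a[i], d[i], g[i] = _fit_item_3pl(
                        nodes, n_k, R[i], a[i], d[i], g[i], self.guess_prior, self.guess_max
                    )
            return a, d, g

        def param_change(a0, d0, g0, a1, d1, g1):
            b0, b1 = -d0 / a0, -d1 / a1
            ch = max(np.abs(a1 - a0).max(), np.abs(b1 - b0).max())
            if self.model == "3pl":
                ch = max(ch, np.abs(g1 - g0).max())
            return float(ch)

        for _ in range(max_em):
            a_new, d_new, g_new = mstep(a.copy(), d.copy(), g.copy(), n_k, R, single_step=False)
            max_change = param_change(a, d, g, a_new, d_new, g_new)
            a, d, g = a_new, d_new, g_new
            em_used += 1
            m2ll, post, P, n_k, R = estep(a, d, g)
            if m2ll > trace[-1] + 1e-6 * (1.0 + abs(m2ll)) and self.model != "3pl":
                warnings.warn("deviance increased during an EM cycle", RuntimeWarning)
            trace.append(m2ll)
            if max_change < criterion:
                converged = True
                break

        for _ in range(max_newton):
            if converged and newton_used == 0 and max_newton > 0:
                pass  # still run the polish cycles; steps are tiny once converged
            a_new, d_new, g_new = mstep(a.copy(), d.copy(), g.copy(), n_k, R, single_step=True)
            max_change = param_change(a, d, g, a_new, d_new, g_new)
            a, d, g = a_new, d_new, g_new
            newton_used += 1
            m2ll, post, P, n_k, R = estep(a, d, g)
            trace.append(m2ll)
            if max_change < criterion:
                converged = True
                break
        if max_change >= criterion:
            converged = False
            logger.warning(
                "estimation stopped at max_change=%.4g after %d EM / %d Newton cycles",
                max_change, em_used, newton_used,
            )

        alpha_hat = a
        beta_hat = -d / a
        gamma_hat = g

        eap, eap_sd = _eap_from_posterior(post, nodes)

        se_alpha = np.full(m, np.nan)
        se_beta = np.full(m, np.nan)
        se_gamma = np.full(m, np.nan)
        if compute_se:
            try:
                cov = observed_information_cov(
                    X, post, P, a, d, g, nodes, model=self.model
                )
                se_alpha, se_beta, se_gamma = _delta_se(cov, a, d, g, self.model)
            except np.linalg.LinAlgError:
                warnings.warn(
                    "information matrix singular; standard errors reported as missing",
                    RuntimeWarning,
                )

        n_endorsed = X.sum(axis=0)
        flags = np.where(n_endorsed < low_information_threshold, "low-information", "")
        items = pd.DataFrame(
            {
                "code": codes,
                "term": [self.terms.get(c, "") for c in codes],
                "model": self.model,
                "alpha": alpha_hat,
                "se_alpha": se_alpha,
                "beta": beta_hat,
                "se_beta": se_beta,
                "gamma": gamma_hat if self.model == "3pl" else 0.0,
                "se_gamma": se_gamma if self.model == "3pl" else 0.0,
                "n_endorsed": n_endorsed,
                "flag": flags,
            }
        )
        return CodeIRTResults(
            model_obj=self,
            model=self.model,
            items=items,
            excluded_items=excluded,
            minus2_loglik=trace[-1],
            trace=trace,
            em_cycles_used=em_used,
            newton_cycles_used=newton_used,
            converged=converged,
            max_last_change=max_change,
            criterion=criterion,
            eap_theta=eap,
            eap_sd=eap_sd,
            kept_columns=kept,
            X=X,
            grid=self.grid,
        )

    def _apply_screen(self):
        if not self.screen:
            # degenerate columns still cannot be fit; exclude them
            kept, excluded = [], []
            for i in range(self.X_all.shape[1]):
                col = self.X_all[:, i]
                if col.min() == col.max():
                    excluded.append(
                        {"code": self.code_ids_all[i], "correlation": np.nan, "reason": "degenerate"}
                    )
                else:
                    kept.append(i)
            return np.asarray(kept, dtype=int), excluded
        return screen_items(self.X_all, self.screen_threshold, self.code_ids_all)


def _eap_from_posterior(post, nodes):
    mean = post @ nodes
    second = post @ nodes**2
    var = np.maximum(second - mean**2, 0.0)
    return mean, np.sqrt(var)


# ---------------------------------------------------------------------------
# observed information / standard errors


def _score_factors(a, d, g, nodes, model):
    """Per-item score ingredients.

    Returns P (m, K) and derivative stacks F1, F0 of shape (m, K, p) with
    u_i(x, k) = x * F1[i, k] + (1 - x) * F0[i, k] the score of item i's
    free parameters for response x at node k.
    """
    z = a[:, None] * nodes[None, :] + d[:, None]
    sig = expit(z)
    P = np.clip(g[:, None] + (1.0 - g[:, None]) * sig, _P_EPS, 1.0 - _P_EPS)
    if model == "3pl":
        dP = np.stack(
            [
                (1.0 - g[:, None]) * sig * (1.0 - sig) * nodes[None, :],
                (1.0 - g[:, None]) * sig * (1.0 - sig),
                np.broadcast_to(1.0 - sig, sig.shape),
            ],
            axis=2,
        )
    else:
        pq = sig * (1.0 - sig)
        dP = np.stack([pq * nodes[None, :], pq], axis=2)
    F1 = dP / P[:, :, None]
    F0 = -dP / (1.0 - P)[:, :, None]
    return P, dP, F1, F0


def observed_information_cov(X, post, P_unused, a, d, g, nodes, model="2pl"):
    """Covariance of the item-parameter estimates (slope-intercept scale).

    Louis-type observed information of the marginal log-likelihood: the
    posterior-expected complete-data (Fisher) information minus the
    posterior covariance of the per-patient score, assembled over *all*
    items (cross-item blocks included) and inverted.  For the 1PL the
    shared slope is handled by the appropriate linear contrast.
    Returns the full covariance matrix in parameter order
    (item0 params..., item1 params, ...).
    """
    n, m = X.shape
    K = len(nodes)
    P, dP, F1, F0 = _score_factors(a, d, g, nodes, model)
    pc = F1.shape[2]
    Xf = X.astype(float)
    Xs = scipy.sparse.csr_matrix(Xf)

    S0 = post.sum(axis=0)  # (K,)
    S1 = (post.T @ Xf).T  # (m, K)
    C = np.empty((K, m, m))
    for k in range(K):
        C[k] = (Xs.multiply(post[:, k : k + 1]).T @ Xs).toarray()

    # complete-data (Fisher) information, block-diagonal
    h = dP**2  # only needed via dP outer; build per item
    comp = np.zeros((m * pc, m * pc))
    for i in range(m):
        w = S0 / (P[i] * (1.0 - P[i]))  # (K,)
        block = np.einsum("k,ka,kb->ab", w, dP[i], dP[i])
        comp[i * pc : (i + 1) * pc, i * pc : (i + 1) * pc] = block

    # E[u u^T] summed over patients
    EUU = np.zeros((m * pc, m * pc))
    for i in range(m):
        si = slice(i * pc, (i + 1) * pc)
        # diagonal block: x^2 = x
        w1 = S1[i]
        w0 = S0 - S1[i]
        EUU[si, si] = np.einsum("k,ka,kb->ab", w1, F1[i], F1[i]) + np.einsum(
            "k,ka,kb->ab", w0, F0[i], F0[i]
        )
        for j in range(i + 1, m):
            sj = slice(j * pc, (j + 1) * pc)
            c = C[:, i, j]
            w11 = c
            w10 = S1[i] - c
            w01 = S1[j] - c
            w00 = S0 - S1[i] - S1[j] + c
            blk = (
                np.einsum("k,ka,kb->ab", w11, F1[i], F1[j])
                + np.einsum("k,ka,kb->ab", w10, F1[i], F0[j])
                + np.einsum("k,ka,kb->ab", w01, F0[i], F1[j])
                + np.einsum("k,ka,kb->ab", w00, F0[i], F0[j])
            )
            EUU[si, sj] = blk
            EUU[sj, si] = blk.T

    # sum_s E[u] E[u]^T via per-patient posterior score means
    G1 = post @ F1.transpose(1, 0, 2).reshape(K, m * pc)  # (n, m*pc)
    G0 = post @ F0.transpose(1, 0, 2).reshape(K, m * pc)
    xrep = np.repeat(Xf, pc, axis=1)
    A = xrep * G1 + (1.0 - xrep) * G0
    AA = A.T @ A

    info = comp - (EUU - AA)

    if model == "1pl":
        # contrast: shared slope = sum of per-item slope directions
        M = np.zeros((m + 1, m * pc))
        for i in range(m):
            M[0, i * pc] = 1.0  # slope component
            M[1 + i, i * pc + 1] = 1.0  # intercept component
        info = M @ info @ M.T
    cov = np.linalg.inv(info)
    return cov


def _delta_se(cov, a, d, g, model):
    """Map slope-intercept covariance to SEs of (alpha, beta, gamma)."""
    m = len(a)
    se_alpha = np.full(m, np.nan)
    se_beta = np.full(m, np.nan)
    se_gamma = np.full(m, np.nan)
    beta = -d / a
    if model == "1pl":
        v_a = cov[0, 0]
        for i in range(m):
            v_d = cov[1 + i, 1 + i]
            c_ad = cov[0, 1 + i]
            se_alpha[i] = np.sqrt(max(v_a, 0.0))
            var_b = (beta[i] ** 2 * v_a + v_d + 2.0 * beta[i] * c_ad) / a[i] ** 2
            se_beta[i] = np.sqrt(max(var_b, 0.0))
        return se_alpha, se_beta, se_gamma
    pc = 3 if model == "3pl" else 2
    for i in range(m):
        blk = cov[i * pc : (i + 1) * pc, i * pc : (i + 1) * pc]
        v_a, v_d, c_ad = blk[0, 0], blk[1, 1], blk[0, 1]
        se_alpha[i] = np.sqrt(max(v_a, 0.0))
        var_b = (beta[i] ** 2 * v_a + v_d + 2.0 * beta[i] * c_ad) / a[i] ** 2
        se_beta[i] = np.sqrt(max(var_b, 0.0))
        if model == "3pl":
            se_gamma[i] = np.sqrt(max(blk[2, 2], 0.0))
    return se_alpha, se_beta, se_gamma


# ---------------------------------------------------------------------------
# results


@dataclasses.dataclass
class CodeIRTResults:
    """Fitted calibration: item parameters, uncertainty and diagnostics.

    Attributes
    ----------
    items
        One row per calibrated code: ``alpha`` (discrimination), ``beta``
        (location), ``gamma`` (lower asymptote, 3PL), their standard
        errors, endorsement counts and fit flags.
    excluded_items
        Codes removed by the screen (with the item-rest correlation) or as
        degenerate; together with ``items`` they cover every input code.
    minus2_loglik, trace
        Final deviance and its value after every E-step (non-increasing
        across EM cycles).
    eap_theta, eap_sd
        Expected-a-posteriori trait score and posterior SD per patient.
    """

    model_obj: CodeIRT
    model: str
    items: pd.DataFrame
    excluded_items: list
    minus2_loglik: float
    trace: list
    em_cycles_used: int
    newton_cycles_used: int
    converged: bool
    max_last_change: float
    criterion: float
    eap_theta: np.ndarray
    eap_sd: np.ndarray
    kept_columns: np.ndarray
    X: np.ndarray
    grid: QuadratureGrid

    @property
    def n_patients(self) -> int:
        return self.X.shape[0]

    @property
    def n_items(self) -> int:
        return self.X.shape[1]

    @property
    def n_free_parameters(self) -> int:
        m = self.n_items
        return {"1pl": m + 1, "2pl": 2 * m, "3pl": 3 * m}[self.model]

    def predict_prob(self, theta) -> np.ndarray:
        """Endorsement probabilities P(theta) for every calibrated item."""
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        return irf(
            theta[:, None],
            self.items["alpha"].to_numpy()[None, :],
            self.items["beta"].to_numpy()[None, :],
            self.items["gamma"].to_numpy()[None, :],
        )

    def intercept_form(self) -> pd.DataFrame:
        """Item parameters in slope-intercept form (a*theta + d)."""
        a = self.items["alpha"].to_numpy()
        b = self.items["beta"].to_numpy()
        return pd.DataFrame({"code": self.items["code"], "a": a, "d": -a * b})

    def item_fit(self, n_intervals: int = 10, min_expected: float = 5.0) -> pd.DataFrame:
        from .fitstats import item_fit_table

        return item_fit_table(self, n_intervals=n_intervals, min_expected=min_expected)

    def compare(self, other: "CodeIRTResults"):
        from .fitstats import compare_models

        return compare_models(self, other)

    def to_items_csv(self, path) -> None:
        """Write items.csv in the fixed documented column order."""
        cols = [
            "code", "term", "model", "alpha", "se_alpha", "beta", "se_beta",
            "gamma", "se_gamma", "n_endorsed", "flag",
        ]
        out = self.items[cols].copy()
        screen_map = {
            e["code"]: e.get("correlation", np.nan) for e in self.excluded_items
        }
        out["screened_correlation"] = out["code"].map(screen_map)
        out.to_csv(path, index=False)

    def plot_item_curves(self, codes=None, ax=None):
        """Plot fitted item response curves over the trait range."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        theta = np.linspace(self.grid.nodes[0], self.grid.nodes[-1], 200)
        probs = self.predict_prob(theta)
        for j, code in enumerate(self.items["code"]):
            if codes is not None and code not in codes:
                continue
            ax.plot(theta, probs[:, j], label=str(code))
        ax.set_xlabel("latent trait")
        ax.set_ylabel("P(endorse)")
        ax.set_ylim(0, 1)
        return ax

    def summary(self) -> str:
        lines = [
            f"{self.model.upper()} item-response calibration (marginal maximum likelihood)",
            f"patients: {self.n_patients}   items kept: {self.n_items}   "
            f"excluded: {len(self.excluded_items)}",
            f"-2 log-likelihood: {self.minus2_loglik:.2f}",
            f"EM cycles: {self.em_cycles_used}   Newton cycles: {self.newton_cycles_used}   "
            f"converged: {self.converged} (last change {self.max_last_change:.4g} "
            f"vs criterion {self.criterion})",
            "",
        ]
        cols = ["code", "alpha", "se_alpha", "beta", "se_beta"]
        if self.model == "3pl":
            cols += ["gamma", "se_gamma"]
        cols += ["n_endorsed"]
        lines.append(self.items[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}"))
        if self.excluded_items:
            lines.append("")
            lines.append(f"excluded codes ({len(self.excluded_items)}):")
            for e in self.excluded_items[:15]:
                corr = e.get("correlation")
                corr_s = "" if corr is None or (isinstance(corr, float) and np.isnan(corr)) else f" r={corr:.3f}"
                lines.append(f"  {e['code']}: {e['reason']}{corr_s}")
            if len(self.excluded_items) > 15:
                lines.append(f"  ... and {len(self.excluded_items) - 15} more")
        return "\n".join(lines)
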