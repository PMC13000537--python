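"""Nonlinear multilevel (mixed-effects) model of the cortisol response curve.

Each individual i has curve parameters theta_i = (alpha, beta, A, b0,
b1, dT) drawn around population fixed effects, with log-normal random
effects for the positivity-constrained alpha, beta, A and normal random
effects for b0, b1, dT.  Covariates (gender and acute-stress-test dummy
codes) act linearly on the transformed scale.  Observations follow a
"constant" (homoscedastic Gaussian) error model around the individual
curve.

Estimation is an EM scheme with a Laplace-approximate E-step: per
individual, the posterior mode of the random effects is found by a
damped Gauss-Newton solver (vectorized over all individuals sharing a
sample count), with the Laplace posterior covariance supplying the
uncertainty corrections in the M-step variance updates.  For a model
that is linear in its random effects this is exact EM for a linear
mixed model and converges to its maximum-likelihood solution; the
nonlinear case inherits the usual Laplace approximation.

Shrinkage arises naturally: the Gaussian prior on the random effects
pulls every individual's estimate toward the population mean, the more
strongly the fewer or noisier that individual's samples are.

Dummy coding of the acute stress test factor: (1) all control
conditions, (2) gTSST-stress, (3) SECPT-stress, (4) MAST-stress, with
TSST-stress as the reference category.  Which dummy carries effects on
beta and b0 is configurable; the default places them on the MAST dummy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import digamma, gammaln
from sklearn.base import BaseEstimator

from .curve import GammaKernelParams, ResponseCurveParams
from .errors import ConvergenceError, ValidationError
from .preprocess import ParticipantSeries

__all__ = [
    "PARAMETERS",
    "DEFAULT_FAMILIES",
    "DEFAULT_COVARIATES",
    "MultilevelSpec",
    "MultilevelGammaModel",
    "covariate_frame",
    "fit_multilevel",
    "evaluate_covariate",
    "retention_decision",
]

PARAMETERS = ("alpha", "beta", "A", "b0", "b1", "dT")
DEFAULT_FAMILIES = {
    "alpha": "log", "beta": "log", "A": "log",
    "b0": "identity", "b1": "identity", "dT": "identity",
}
#: Final retained covariate-effect map: gender on A and b0; the control-
#: condition dummy on A, b0, b1, dT; the MAST dummy on beta and b0.
DEFAULT_COVARIATES = {
    "A": ("female", "control"),
    "b0": ("female", "control", "mast"),
    "b1": ("control",),
    "dT": ("control",),
    "beta": ("mast",),
}

_EPS_X = 1e-10
_OMEGA_FLOOR = 1e-12


@dataclass(frozen=True)
class MultilevelSpec:
    """Declarative description of the multilevel model structure."""

    parameters: tuple[str, ...] = PARAMETERS
    random_effects: tuple[str, ...] | None = None  # None -> all parameters
    families: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_FAMILIES))
    covariates: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATES)
    )
    error_model: str = "constant"

    def __post_init__(self) -> None:
        if self.error_model != "constant":
            raise ValidationError("only the 'constant' error model is supported")
        for p in self.parameters:
            if p not in PARAMETERS:
                raise ValidationError(f"unknown parameter {p!r}")
        rand = self.parameters if self.random_effects is None else self.random_effects
        for p, covs in self.covariates.items():
            if p in self.parameters and p not in rand:
                raise ValidationError(
                    f"covariate effects on {p!r} require it to carry a random effect"
                )


def covariate_frame(series_list: Sequence[ParticipantSeries]) -> pd.DataFrame:
    """Dummy-coded covariate table, one row per participant series.

    Columns: female; control (dummy 1, all control conditions); gtsst
    (dummy 2); secpt (dummy 3); mast (dummy 4).  TSST-stress is the
    implicit reference category.
    """
    rows = []
    for s in series_list:
        stress = s.condition == "stress"
        rows.append(
            {
                "participant_id": s.participant_id,
                "female": float(s.gender == "F"),
                "control": float(not stress),
                "gtsst": float(stress and s.test_type == "gTSST"),
                "secpt": float(stress and s.test_type == "SECPT"),
                "mast": float(stress and s.test_type == "MAST"),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# vectorized curve forward model and Jacobians on the transformed scale
# ---------------------------------------------------------------------------

def _natural(zeta_col: np.ndarray, family: str) -> np.ndarray:
    return np.exp(zeta_col) if family == "log" else zeta_col


def _forward(nat: dict[str, np.ndarray], T: np.ndarray):
    """Curve values for a batch. nat values are (n, 1); T is (n, m)."""
    x = T - nat["dT"]
    pos = x > _EPS_X
    xs = np.where(pos, x, 1.0)
    alpha, beta = nat["alpha"], nat["beta"]
    logf = (
        alpha * np.log(beta)
        - gammaln(alpha)
        + (alpha - 1.0) * np.log(xs)
        - beta * xs
    )
    f = np.where(pos, np.exp(logf), 0.0)
    g = nat["A"] * f + nat["b0"] + nat["b1"] * x
    return g, f, x, pos


def _partials(nat, f, x, pos, names: Sequence[str]) -> np.ndarray:
    """Natural-scale partial derivatives dg/dtheta, stacked (n, m, len(names))."""
    alpha, beta, A, b1 = nat["alpha"], nat["beta"], nat["A"], nat["b1"]
    xs = np.where(pos, x, 1.0)
    cols = []
    for name in names:
        if name == "A":
            cols.append(f)
        elif name == "b0":
            cols.append(np.ones_like(f))
        elif name == "b1":
            cols.append(x)
        elif name == "alpha":
            cols.append(np.where(pos, A * f * (np.log(beta) + np.log(xs) - digamma(alpha)), 0.0))
        elif name == "beta":
            cols.append(A * f * (alpha / beta - xs) * pos)
        elif name == "dT":
            cols.append(np.where(pos, -A * f * ((alpha - 1.0) / xs - beta), 0.0) - b1)
        else:  # pragma: no cover
            raise ValidationError(f"unknown parameter {name!r}")
    return np.stack(cols, axis=-1)


@dataclass
class _Batch:
    """Individuals sharing a sample count, stacked for vectorized solves."""

    index: np.ndarray       # positions in the original series list
    T: np.ndarray           # (n, m) sample times
    Y: np.ndarray           # (n, m) cortisol values
    eta: np.ndarray         # (n, p_rand) random-effect modes (transformed scale)
    V: np.ndarray | None = None  # (n, p_rand, p_rand) Laplace posterior covariance
    z: np.ndarray | None = None  # (n, K, p_rand) CRN draws for the MC E-step
    m1: np.ndarray | None = None   # (n, p_rand) posterior mean of eta
    m2: np.ndarray | None = None   # (n, p_rand) posterior mean of eta^2
    Eres: np.ndarray | None = None  # (n,) posterior mean of ||y - g||^2
    logmarg: np.ndarray | None = None  # (n,) IS estimate of log marginal likelihood


class _Engine:
    """Internal state shared by fit and apply passes."""

    def __init__(self, params, rand, families, fixed_values):
        self.params = tuple(params)
        self.rand = tuple(rand)
        self.rand_pos = [self.params.index(p) for p in self.rand]
        self.shared = tuple(p for p in self.params if p not in self.rand)
        self.families = dict(families)
        self.fixed_values = dict(fixed_values)

    def zeta_full(self, mu: np.ndarray, eta: np.ndarray) -> np.ndarray:
        zeta = mu.copy()
        zeta[:, self.rand_pos] += eta
        return zeta

    def nat_dict(self, zeta: np.ndarray) -> dict[str, np.ndarray]:
        nat = {}
        for j, p in enumerate(self.params):
            nat[p] = _natural(zeta[:, j], self.families[p])[:, None]
        for p in PARAMETERS:
            if p not in nat:
                nat[p] = np.full((zeta.shape[0], 1), float(self.fixed_values[p]))
        return nat

    def jacobian(self, nat, f, x, pos, names) -> np.ndarray:
        """dg/dzeta for the given parameter names (chain rule for log families)."""
        J = _partials(nat, f, x, pos, names)
        for j, p in enumerate(names):
            if self.families[p] == "log":
                J[:, :, j] *= nat[p]
        return J

    # -- MAP of random effects for one batch -------------------------------
    def solve_map(self, batch: _Batch, mu: np.ndarray, omega: np.ndarray,
                  sigma2: float, max_iter: int = 40) -> None:
        n = batch.T.shape[0]
        pr = len(self.rand)
        eta = batch.eta
        inv_omega = 1.0 / omega
        eye = np.eye(pr)

        def objective(e):
            nat = self.nat_dict(self.zeta_full(mu, e))
            g, _, _, _ = _forward(nat, batch.T)
            r = batch.Y - g
            return (r**2).sum(axis=1) / (2 * sigma2) + 0.5 * ((e**2) * inv_omega).sum(axis=1)

        lam = np.full(n, 1e-3)
        phi = objective(eta)
        for _ in range(max_iter):
            nat = self.nat_dict(self.zeta_full(mu, eta))
            g, f, x, pos = _forward(nat, batch.T)
            r = batch.Y - g
            Jr = self.jacobian(nat, f, x, pos, self.rand)
            grad = -np.einsum("nmp,nm->np", Jr, r) / sigma2 + eta * inv_omega
            H = np.einsum("nmp,nmq->npq", Jr, Jr) / sigma2 + np.diag(inv_omega)
            accepted = np.zeros(n, dtype=bool)
            step_norm = 0.0
            for _inner in range(8):
                todo = ~accepted
                if not todo.any():
                    break
                Hd = H[todo] + lam[todo, None, None] * eye
                delta = -np.linalg.solve(Hd, grad[todo][:, :, None])[:, :, 0]
                delta = np.clip(delta, -1.5, 1.5)
                trial = eta.copy()
                trial[todo] += delta
                phi_trial = objective(trial)
                better = np.zeros(n, dtype=bool)
                better[todo] = phi_trial[todo] <= phi[todo] + 1e-12
                eta[better] = trial[better]
                phi[better] = phi_trial[better]
                lam[better] = np.maximum(lam[better] * 0.3, 1e-8)
                lam[todo & ~better] *= 5.0
                accepted |= better
                if better.any():
                    step_norm = max(step_norm, float(np.abs(delta).max()))
            if step_norm < 1e-9:
                break
        # Laplace posterior covariance at the mode (undamped Hessian)
        nat = self.nat_dict(self.zeta_full(mu, eta))
        g, f, x, pos = _forward(nat, batch.T)
        Jr = self.jacobian(nat, f, x, pos, self.rand)
        H = np.einsum("nmp,nmq->npq", Jr, Jr) / sigma2 + np.diag(inv_omega)
        batch.eta = eta
        batch.V = np.linalg.inv(H)

    # -- importance-sampled posterior moments ------------------------------
    def is_moments(self, batch: _Batch, mu: np.ndarray, omega: np.ndarray,
                   sigma2: float, inflation: float = 1.5) -> None:
        """Self-normalized IS moments of the random effects.

        Proposal: Gaussian centred at the MAP mode with the Laplace
        covariance inflated by ``inflation`` (common random numbers in
        ``batch.z`` keep the EM deterministic).  The M-step built on
        these moments makes the EM fixed point the exact marginal-ML
        solution rather than its Laplace approximation.
        """
        n, m = batch.T.shape
        pr = len(self.rand)
        K = batch.z.shape[1]
        cV = inflation * batch.V
        L = np.linalg.cholesky(cV)
        E = batch.eta[:, None, :] + np.einsum("npq,nkq->nkp", L, batch.z)  # (n,K,pr)

        zeta = np.repeat(mu[:, None, :], K, axis=1)
        zeta[:, :, self.rand_pos] += E
        zeta2 = zeta.reshape(n * K, -1)
        nat = self.nat_dict(zeta2)
        T2 = np.repeat(batch.T, K, axis=0)
        g, _, _, _ = _forward(nat, T2)
        r2 = ((np.repeat(batch.Y, K, axis=0) - g) ** 2).sum(axis=1).reshape(n, K)

        log_target = (
            -0.5 * m * np.log(2 * np.pi * sigma2)
            - r2 / (2 * sigma2)
            - 0.5 * ((E**2) / omega).sum(axis=2)
            - 0.5 * np.sum(np.log(2 * np.pi * omega))
        )
        d = E - batch.eta[:, None, :]
        Vinv = np.linalg.inv(cV)
        _, logdet = np.linalg.slogdet(cV)
        log_q = (
            -0.5 * np.einsum("nkp,npq,nkq->nk", d, Vinv, d)
            - 0.5 * (logdet[:, None] + pr * np.log(2 * np.pi))
        )
        lw = log_target - log_q
        lw_max = lw.max(axis=1, keepdims=True)
        w = np.exp(lw - lw_max)
        wsum = w.sum(axis=1, keepdims=True)
        w /= wsum
        batch.m1 = np.einsum("nk,nkp->np", w, E)
        batch.m2 = np.einsum("nk,nkp->np", w, E**2)
        batch.Eres = np.einsum("nk,nk->n", w, r2)
        batch.logmarg = (lw_max[:, 0] + np.log(wsum[:, 0] / K))

    def log_marginal(self, batch: _Batch, mu: np.ndarray, omega: np.ndarray,
                     sigma2: float, inflation: float = 1.5) -> float:
        """IS estimate of the batch's marginal log-likelihood at given
        population parameters, reusing the stored proposal (mode, V, CRN)."""
        n, m = batch.T.shape
        pr = batch.eta.shape[1]
        K = batch.z.shape[1]
        cV = inflation * batch.V
        L = np.linalg.cholesky(cV)
        E = batch.eta[:, None, :] + np.einsum("npq,nkq->nkp", L, batch.z)
        zeta = np.repeat(mu[:, None, :], K, axis=1)
        zeta[:, :, self.rand_pos] += E
        nat = self.nat_dict(zeta.reshape(n * K, -1))
        g, _, _, _ = _forward(nat, np.repeat(batch.T, K, axis=0))
        r2 = ((np.repeat(batch.Y, K, axis=0) - g) ** 2).sum(axis=1).reshape(n, K)
        log_target = (
            -0.5 * m * np.log(2 * np.pi * sigma2)
            - r2 / (2 * sigma2)
            - 0.5 * ((E**2) / omega).sum(axis=2)
            - 0.5 * np.sum(np.log(2 * np.pi * omega))
        )
        d = E - batch.eta[:, None, :]
        Vinv = np.linalg.inv(cV)
        _, logdet = np.linalg.slogdet(cV)
        log_q = (
            -0.5 * np.einsum("nkp,npq,nkq->nk", d, Vinv, d)
            - 0.5 * (logdet[:, None] + pr * np.log(2 * np.pi))
        )
        lw = log_target - log_q
        lw_max = lw.max(axis=1, keepdims=True)
        return float(np.sum(lw_max[:, 0] + np.log(np.exp(lw - lw_max).mean(axis=1))))


def _prepare_batches(series_list: Sequence[ParticipantSeries]) -> list[_Batch]:
    by_m: dict[int, list[int]] = {}
    for i, s in enumerate(series_list):
        if s.n_samples < 2:
            raise ValidationError(
                f"{s.participant_id}: needs >= 2 samples for multilevel fitting"
            )
        by_m.setdefault(s.n_samples, []).append(i)
    batches = []
    for m in sorted(by_m):
        idx = np.array(by_m[m])
        T = np.stack([series_list[i].times_array() for i in idx])
        Y = np.stack([series_list[i].cortisol_array() for i in idx])
        batches.append(_Batch(index=idx, T=T, Y=Y, eta=np.zeros((idx.size, 0))))
    return batches


class MultilevelGammaModel(BaseEstimator):
    """Nonlinear mixed-effects gamma-curve model with shrinkage.

    Parameters
    ----------
    parameters : tuple of str
        Curve parameters included in the model; excluded ones are held
        at ``fixed_values`` (defaults: b1 = 0, dT = 0).
    random_effects : tuple of str or None
        Parameters carrying individual random effects (default: all
        included parameters).  Included parameters without a random
        effect are estimated as shared fixed effects.
    families : mapping or None
        'log' or 'identity' random-effect scale per parameter.
    covariates : mapping or None
        Parameter -> tuple of covariate column names (see
        :func:`covariate_frame`).  ``None`` disables covariate effects;
        the final retained effect map is available as ``DEFAULT_COVARIATES``.
    max_iter, tol : EM iteration budget and relative-change tolerance.
    seed : int
        Recorded for reproducibility of any future stochastic variants;
        the Laplace-EM itself is deterministic.

    Fitted attributes: ``fixed_effects_`` (transformed scale),
    ``fixed_effects_natural_``, ``covariate_coefs_`` (estimate, SE, p,
    CV%), ``omega_`` (random-effect variances), ``sigma_`` (residual
    SD), ``loglik_``, ``bic_``, ``individual_params_`` (DataFrame of
    per-participant empirical-Bayes curve parameters), ``diagnostics_``
    (per-participant MAE and bias), ``n_iter_``, ``converged_``.
    """

    def __init__(
        self,
        parameters: tuple[str, ...] = PARAMETERS,
        random_effects: tuple[str, ...] | None = None,
        families: Mapping[str, str] | None = None,
        covariates: Mapping[str, tuple[str, ...]] | None = None,
        fixed_values: Mapping[str, float] | None = None,
        max_iter: int = 60,
        tol: float = 1e-5,
        mc_samples: int = 96,
        is_inflation: float = 1.5,
        compute_se: bool = True,
        require_convergence: bool = False,
        seed: int = 0,
    ):
        self.parameters = parameters
        self.random_effects = random_effects
        self.families = families
        self.covariates = covariates
        self.fixed_values = fixed_values
        self.max_iter = max_iter
        self.tol = tol
        self.mc_samples = mc_samples
        self.is_inflation = is_inflation
        self.compute_se = compute_se
        self.require_convergence = require_convergence
        self.seed = seed

    # -- configuration -----------------------------------------------------
    def _setup(self):
        params = tuple(self.parameters)
        rand = tuple(self.random_effects) if self.random_effects is not None else params
        for p in rand:
            if p not in params:
                raise ValidationError(f"random effect on {p!r} but it is not a model parameter")
        families = dict(DEFAULT_FAMILIES)
        if self.families:
            families.update(self.families)
        fixed = {"alpha": 3.0, "beta": 0.1, "A": 100.0, "b0": 5.0, "b1": 0.0, "dT": 0.0}
        if self.fixed_values:
            fixed.update(self.fixed_values)
        covs = {k: tuple(v) for k, v in (self.covariates or {}).items()}
        for p in covs:
            if p not in rand:
                raise ValidationError(
                    f"covariate effects on {p!r} require a random effect on it"
                )
        return _Engine(params, rand, families, fixed), covs

    def _designs(self, engine: _Engine, covs, series_list):
        frame = covariate_frame(series_list)
        designs = {}
        for p in engine.params:
            names = covs.get(p, ())
            X = np.column_stack(
                [np.ones(len(series_list))] + [frame[c].to_numpy() for c in names]
            )
            designs[p] = (X, ("intercept",) + tuple(names))
        return designs

    def _mu_matrix(self, engine, designs, coefs, n):
        mu = np.empty((n, len(engine.params)))
        for j, p in enumerate(engine.params):
            X, _ = designs[p]
            mu[:, j] = X @ coefs[p]
        return mu

    def _initial_coefs(self, engine, series_list):
        """Seed fixed effects from a pooled amplitude-model fit when possible."""
        from .asm import fit_population_curve

        baselines = np.array([s.baseline() for s in series_list])
        init_nat = {"alpha": 3.0, "beta": 0.1, "A": 150.0,
                    "b0": float(baselines.mean()), "b1": 0.0, "dT": 0.0}
        try:
            pop = fit_population_curve(series_list)
            if pop.A_pop > 0 and pop.kernel.alpha > 1:
                init_nat.update(
                    {"alpha": pop.kernel.alpha, "beta": pop.kernel.beta,
                     "A": pop.A_pop, "b0": pop.b0_pop}
                )
        except Exception:
            pass  # heuristics above remain
        coefs = {}
        for p in engine.params:
            v = init_nat[p]
            if engine.families[p] == "log":
                v = np.log(max(v, 1e-6))
            coefs[p] = np.array([v])
        return coefs

    # -- fitting -----------------------------------------------------------
    def fit(self, X: Sequence[ParticipantSeries], y=None) -> "MultilevelGammaModel":
        series_list = list(X)
        if len(series_list) < 2:
            raise ValidationError("multilevel fitting needs >= 2 participants")
        engine, covs = self._setup()
        if not engine.rand:
            raise ValidationError("at least one parameter must carry a random effect")
        designs = self._designs(engine, covs, series_list)
        batches = _prepare_batches(series_list)
        rng = np.random.default_rng(self.seed)
        for b in batches:
            b.eta = np.zeros((b.index.size, len(engine.rand)))
            if self.mc_samples > 0:
                # common random numbers: drawn once, reused every iteration,
                # so the MC-EM is a deterministic fixed-point iteration
                b.z = rng.standard_normal(
                    (b.index.size, self.mc_samples, len(engine.rand))
                )
        n = len(series_list)
        n_obs = int(sum(s.n_samples for s in series_list))

        coefs = self._initial_coefs(engine, series_list)
        for p in engine.params:
            X_p, names = designs[p]
            coefs[p] = np.concatenate([coefs[p], np.zeros(len(names) - 1)])
        omega = np.array(
            [0.1 if engine.families[p] == "log" else (1.0 if p == "b0" else
             (1e-3 if p == "b1" else 9.0)) for p in engine.rand]
        )
        sigma2 = 1.0

        converged = False
        n_iter = 0
        use_mc = self.mc_samples > 0
        for n_iter in range(1, self.max_iter + 1):
            state0 = self._pack_state(engine, coefs, omega, sigma2)
            mu = self._mu_matrix(engine, designs, coefs, n)
            # E-step: MAP mode + Laplace covariance, then MC posterior moments
            m1 = np.zeros((n, len(engine.rand)))
            m2 = np.zeros((n, len(engine.rand)))
            Eres = np.zeros(n)
            for b in batches:
                engine.solve_map(b, mu[b.index], omega, sigma2)
                if use_mc:
                    engine.is_moments(b, mu[b.index], omega, sigma2, self.is_inflation)
                    m1[b.index] = b.m1
                    m2[b.index] = b.m2
                    Eres[b.index] = b.Eres
                else:
                    Vd = np.einsum("npp->np", b.V)
                    m1[b.index] = b.eta
                    m2[b.index] = b.eta**2 + Vd
            # M-step
            mu_old = mu
            for k, p in enumerate(engine.rand):
                X_p, _ = designs[p]
                j = engine.params.index(p)
                target = mu_old[:, j] + m1[:, k]  # posterior mean of zeta
                coefs[p], *_ = np.linalg.lstsq(X_p, target, rcond=None)
                a = mu_old[:, j] - X_p @ coefs[p]
                Ed2 = m2[:, k] + 2.0 * a * m1[:, k] + a**2
                omega[k] = max(float(np.mean(Ed2)), _OMEGA_FLOOR)
            zeta_hat = mu_old.copy()
            for b in batches:
                zeta_hat[np.ix_(b.index, engine.rand_pos)] = (
                    mu_old[np.ix_(b.index, engine.rand_pos)] + b.eta
                )
            if engine.shared:
                self._shared_step(engine, designs, coefs, batches, mu_old, zeta_hat, n)
            # residual variance (MC expectation, or Laplace trace correction)
            if use_mc:
                sigma2 = max(float(Eres.sum()) / n_obs, 1e-10)
            else:
                mu = self._mu_matrix(engine, designs, coefs, n)
                rss, trace = 0.0, 0.0
                for b in batches:
                    zeta = mu[b.index].copy()
                    zeta[:, engine.rand_pos] += b.eta
                    nat = engine.nat_dict(zeta)
                    g, f, x, pos = _forward(nat, b.T)
                    r = b.Y - g
                    rss += float((r**2).sum())
                    Jr = engine.jacobian(nat, f, x, pos, engine.rand)
                    trace += float(np.einsum("nmp,npq,nmq->", Jr, b.V, Jr))
                sigma2 = max((rss + trace) / n_obs, 1e-10)
            state1 = self._pack_state(engine, coefs, omega, sigma2)
            rel = np.max(np.abs(state1 - state0) / (np.abs(state0) + 1e-8))
            if rel < self.tol:
                converged = True
                break
        if not converged and self.require_convergence:
            raise ConvergenceError(
                f"EM did not converge in {self.max_iter} iterations",
                diagnostics={"last_rel_change": float(rel)},
            )

        self._finalize(engine, covs, designs, series_list, batches, coefs, omega,
                       sigma2, n_obs, n_iter, converged)
        return self

    def _pack_state(self, engine, coefs, omega, sigma2):
        return np.concatenate(
            [coefs[p] for p in engine.params] + [omega, [sigma2]]
        )

    def _shared_step(self, engine, designs, coefs, batches, mu, zeta_hat, n):
        """One damped Gauss-Newton step on parameters without random effects."""
        shared = engine.shared
        pos = [engine.params.index(p) for p in shared]
        H = np.zeros((len(shared), len(shared)))
        gvec = np.zeros(len(shared))
        for b in batches:
            zeta = zeta_hat[b.index]
            nat = engine.nat_dict(zeta)
            g, f, x, posmask = _forward(nat, b.T)
            r = b.Y - g
            Js = engine.jacobian(nat, f, x, posmask, shared)
            H += np.einsum("nmp,nmq->pq", Js, Js)
            gvec += np.einsum("nmp,nm->p", Js, r)
        try:
            delta = np.linalg.solve(H + 1e-10 * np.eye(len(shared)), gvec)
        except np.linalg.LinAlgError:
            return
        delta = np.clip(delta, -1.0, 1.0)
        for d, p in zip(delta, shared):
            coefs[p] = coefs[p] + np.array([d])
            zeta_hat[:, engine.params.index(p)] += d

    def _finalize(self, engine, covs, designs, series_list, batches, coefs, omega,
                  sigma2, n_obs, n_iter, converged):
        n = len(series_list)
        use_mc = self.mc_samples > 0
        mu = self._mu_matrix(engine, designs, coefs, n)
        for b in batches:
            engine.solve_map(b, mu[b.index], omega, sigma2)
            if use_mc:
                engine.is_moments(b, mu[b.index], omega, sigma2, self.is_inflation)

        zeta_hat = mu.copy()
        zeta_mean = mu.copy()
        Vdiag = np.zeros((n, len(engine.rand)))
        loglik = 0.0
        mae = np.zeros(n)
        bias = np.zeros(n)
        pr = len(engine.rand)
        for b in batches:
            zeta = mu[b.index].copy()
            zeta[:, engine.rand_pos] += b.eta
            zeta_hat[b.index] = zeta
            if use_mc:
                zeta_mean[np.ix_(b.index, engine.rand_pos)] = (
                    mu[np.ix_(b.index, engine.rand_pos)] + b.m1
                )
            else:
                zeta_mean[b.index] = zeta
            Vdiag[b.index] = np.einsum("npp->np", b.V)
            nat = engine.nat_dict(zeta)
            g, _, _, _ = _forward(nat, b.T)
            r = b.Y - g
            m = b.T.shape[1]
            if use_mc:
                loglik += float(b.logmarg.sum())
            else:
                sign, logdetV = np.linalg.slogdet(b.V)
                loglik += float(
                    np.sum(
                        -0.5 * m * np.log(2 * np.pi * sigma2)
                        - (r**2).sum(axis=1) / (2 * sigma2)
                        - 0.5 * ((b.eta**2) / omega).sum(axis=1)
                        - 0.5 * np.sum(np.log(2 * np.pi * omega))
                        + 0.5 * pr * np.log(2 * np.pi)
                        + 0.5 * logdetV
                    )
                )
            mae[b.index] = np.abs(r).mean(axis=1)
            bias[b.index] = r.mean(axis=1)

        if self.compute_se:
            se_map = self._fixed_effect_se(engine, designs, batches, coefs, omega,
                                           sigma2, Vdiag, n)
        else:
            se_map = {p: float("nan") for p in engine.params}

        k_fixed = sum(len(designs[p][1]) for p in engine.params)
        k_total = k_fixed + pr + 1
        self._engine = engine
        self._coefs = {p: coefs[p].copy() for p in engine.params}
        self.fixed_effects_ = {p: float(coefs[p][0]) for p in engine.params}
        self.fixed_effects_natural_ = {
            p: float(_natural(np.array([coefs[p][0]]), engine.families[p])[0])
            for p in engine.params
        }
        self.fixed_effect_se_ = se_map
        self.omega_ = {p: float(omega[k]) for k, p in enumerate(engine.rand)}
        self.sigma_ = float(np.sqrt(sigma2))
        self.loglik_ = loglik
        self.bic_ = float(k_total * np.log(n_obs) - 2 * loglik)
        self.n_obs_ = n_obs
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.participant_ids_ = [s.participant_id for s in series_list]
        self.covariate_coefs_ = self._covariate_inference(
            engine, covs, designs, zeta_mean, Vdiag, omega
        )
        self.individual_params_ = self._individual_frame(engine, series_list, zeta_hat)
        self.diagnostics_ = pd.DataFrame(
            {"participant_id": self.participant_ids_, "mae": mae, "bias": bias}
        )
        self._omega_vec = omega
        self._sigma2 = sigma2

    def _fixed_effect_se(self, engine, designs, batches, coefs, omega, sigma2,
                         Vdiag, n) -> dict[str, float]:
        """Wald SEs of the fixed-effect intercepts (transformed scale).

        From the observed information of the marginal log-likelihood over
        all fixed-effect coefficients jointly (numerical central
        differences on the importance-sampled likelihood with a frozen
        proposal), holding variance components at their estimates.  The
        joint Hessian captures ridges between weakly separated
        parameters such as alpha and beta.  Without MC samples, falls
        back to the naive sqrt((omega + mean V) / n).
        """
        if self.mc_samples <= 0:
            out = {}
            for p in engine.params:
                if p in engine.rand:
                    k = engine.rand.index(p)
                    out[p] = float(np.sqrt((omega[k] + Vdiag[:, k].mean()) / n))
                else:
                    out[p] = float("nan")
            return out
        labels, sizes = [], []
        for p in engine.params:
            sizes.append(len(designs[p][1]))
            labels.append(p)
        c0 = np.concatenate([coefs[p] for p in engine.params])

        def loglik(cvec):
            split = np.split(cvec, np.cumsum(sizes)[:-1])
            mu = np.empty((n, len(engine.params)))
            for j, p in enumerate(engine.params):
                X_p, _ = designs[p]
                mu[:, j] = X_p @ split[j]
            return sum(
                engine.log_marginal(b, mu[b.index], omega, sigma2, self.is_inflation)
                for b in batches
            )

        p_dim = c0.size
        h = 1e-3 * np.maximum(np.abs(c0), 1.0)
        f0 = loglik(c0)
        H = np.zeros((p_dim, p_dim))
        fp = np.zeros(p_dim)
        fm = np.zeros(p_dim)
        for j in range(p_dim):
            e = np.zeros(p_dim)
            e[j] = h[j]
            fp[j] = loglik(c0 + e)
            fm[j] = loglik(c0 - e)
            H[j, j] = (fp[j] + fm[j] - 2 * f0) / h[j] ** 2
        for j in range(p_dim):
            for k in range(j + 1, p_dim):
                ej = np.zeros(p_dim); ej[j] = h[j]
                ek = np.zeros(p_dim); ek[k] = h[k]
                H[j, k] = H[k, j] = (
                    loglik(c0 + ej + ek) - loglik(c0 + ej - ek)
                    - loglik(c0 - ej + ek) + loglik(c0 - ej - ek)
                ) / (4 * h[j] * h[k])
        info = -H
        try:
            cov = np.linalg.pinv(info)
            var = np.diag(cov)
        except np.linalg.LinAlgError:
            var = np.full(p_dim, np.nan)
        out = {}
        offset = 0
        for p, size in zip(labels, sizes):
            v = var[offset]
            out[p] = float(np.sqrt(v)) if v > 0 else float("nan")
            offset += size
        return out

    def _covariate_inference(self, engine, covs, designs, zeta_hat, Vdiag, omega):
        """Approximate Wald inference: WLS of EB estimates on the design,
        weighted by 1 / (omega + posterior variance)."""
        rows = []
        for p, names in covs.items():
            X_p, labels = designs[p]
            j = engine.params.index(p)
            k = engine.rand.index(p)
            w = 1.0 / (omega[k] + Vdiag[:, k])
            res = sm.WLS(zeta_hat[:, j], X_p, weights=w).fit()
            for c, label in enumerate(labels):
                if label == "intercept":
                    continue
                est, se, pval = res.params[c], res.bse[c], res.pvalues[c]
                rows.append(
                    {"parameter": p, "covariate": label, "estimate": float(est),
                     "se": float(se), "p": float(pval),
                     "cv_pct": float(100.0 * se / abs(est)) if est != 0 else np.inf}
                )
        return pd.DataFrame(rows, columns=["parameter", "covariate", "estimate",
                                           "se", "p", "cv_pct"])

    def _individual_frame(self, engine, series_list, zeta_hat):
        rows = []
        for i, s in enumerate(series_list):
            nat = {}
            for j, p in enumerate(engine.params):
                nat[p] = float(_natural(np.array([zeta_hat[i, j]]), engine.families[p])[0])
            for p in PARAMETERS:
                nat.setdefault(p, float(engine.fixed_values[p]))
            rows.append({"participant_id": s.participant_id, **nat})
        return pd.DataFrame(rows)

    # -- prediction --------------------------------------------------------
    def predict_individual(self, participant_id: str) -> ResponseCurveParams:
        """Empirical-Bayes curve parameters for a fitted participant."""
        self._check_fitted()
        df = self.individual_params_
        hit = df[df["participant_id"] == participant_id]
        if hit.empty:
            raise ValidationError(f"unknown participant_id {participant_id!r}")
        row = hit.iloc[0]
        return ResponseCurveParams(
            GammaKernelParams(row["alpha"], row["beta"]),
            float(row["A"]), float(row["b0"]), float(row["b1"]), float(row["dT"]),
        )

    def predict(self, series: ParticipantSeries, times=None) -> np.ndarray:
        from .curve import evaluate_curve

        params = self.predict_individual(series.participant_id)
        t = series.times_array() if times is None else np.asarray(times, dtype=float)
        return evaluate_curve(params, t)

    def estimate_individuals(
        self, X: Sequence[ParticipantSeries]
    ) -> pd.DataFrame:
        """Empirical-Bayes estimates for *new* series, population held fixed.

        This is how a trained multilevel model is applied to data it was
        not fitted on: only the individual random effects are estimated,
        shrunk toward the trained population distribution.
        """
        self._check_fitted()
        series_list = list(X)
        engine = self._engine
        covs = {p: tuple(v) for p, v in (self.covariates or {}).items()}
        designs = self._designs(engine, covs, series_list)
        n = len(series_list)
        mu = np.empty((n, len(engine.params)))
        for j, p in enumerate(engine.params):
            X_p, _ = designs[p]
            mu[:, j] = X_p @ self._coefs[p]
        batches = _prepare_batches(series_list)
        for b in batches:
            b.eta = np.zeros((b.index.size, len(engine.rand)))
            engine.solve_map(b, mu[b.index], self._omega_vec, self._sigma2)
        zeta_hat = mu.copy()
        for b in batches:
            zeta_hat[np.ix_(b.index, engine.rand_pos)] = (
                mu[np.ix_(b.index, engine.rand_pos)] + b.eta
            )
        return self._individual_frame(engine, series_list, zeta_hat)

    def _check_fitted(self) -> None:
        if not hasattr(self, "individual_params_"):
            raise ValidationError("MultilevelGammaModel is not fitted yet; call fit first")


def fit_multilevel(
    dataset: Iterable[ParticipantSeries],
    spec: MultilevelSpec | None = None,
    seed: int = 0,
    **kwargs,
) -> MultilevelGammaModel:
    """Functional wrapper: fit a :class:`MultilevelGammaModel` from a spec."""
    spec = spec or MultilevelSpec()
    model = MultilevelGammaModel(
        parameters=spec.parameters,
        random_effects=spec.random_effects,
        families=dict(spec.families),
        covariates={k: tuple(v) for k, v in spec.covariates.items()},
        seed=seed,
        **kwargs,
    )
    return model.fit(list(dataset))


def retention_decision(p: float, cv_pct: float, delta_bic: float) -> dict:
    """Apply the covariate retention rule.

    Retain iff p < .05 AND CV <= 25% AND the covariate does not worsen
    BIC (delta_bic = BIC(with) - BIC(without) <= 0).
    """
    checks = {
        "p_below_.05": p < 0.05,
        "cv_at_most_25pct": cv_pct <= 25.0,
        "bic_not_worse": delta_bic <= 0.0,
    }
    return {"retain": all(checks.values()), "checks": checks,
            "p": p, "cv_pct": cv_pct, "delta_bic": delta_bic}


def evaluate_covariate(
    fit_with: MultilevelGammaModel,
    fit_without: MultilevelGammaModel,
    coefficient: tuple[str, str],
) -> dict:
    """Retention decision for one covariate effect from two nested fits.

    ``coefficient`` is a (parameter, covariate) pair present in
    ``fit_with`` but not ``fit_without``.
    """
    if fit_with.n_obs_ != fit_without.n_obs_:
        raise ValidationError("fits are not nested: different observation counts")
    param, cov = coefficient
    table = fit_with.covariate_coefs_
    row = table[(table["parameter"] == param) & (table["covariate"] == cov)]
    if row.empty:
        raise ValidationError(f"coefficient {coefficient} not in fit_with")
    without_table = fit_without.covariate_coefs_
    if not without_table.empty and not without_table[
        (without_table["parameter"] == param) & (without_table["covariate"] == cov)
    ].empty:
        raise ValidationError("fits are not nested: coefficient present in both")
    row = row.iloc[0]
    return retention_decision(
        p=float(row["p"]), cv_pct=float(row["cv_pct"]),
        delta_bic=float(fit_with.bic_ - fit_without.bic_),
    )
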