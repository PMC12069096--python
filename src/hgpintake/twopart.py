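"""Correlated two-part mixed model for usual intake of episodically consumed foods.

The model (the NCI usual-intake method) has two linked parts for the daily
intake :math:`R_{ij}` of person *i* on recall day *j*:

* probability part: ``logit P(R_ij > 0 | i) = x_ij' b1 + u_1i``
* amount part, on consumption days: ``g(R_ij; lam) = x_ij' b2 + u_2i + eps_ij``

where ``g`` is the Box-Cox transform, ``eps_ij ~ N(0, s2_eps)``, and the
person-level random intercepts ``(u_1i, u_2i)`` are bivariate normal with
variances ``s2_u1``, ``s2_u2`` and correlation ``rho`` — consumption
frequency and consumption-day amount are allowed to covary.  Estimation is
survey-weighted maximum likelihood: the random effects are integrated out by
Gauss-Hermite quadrature on a standardized product grid, the Box-Cox
Jacobian ``R^(lam-1)`` is included in the positive-amount density so the
transform parameter is estimated jointly with everything else, and the
marginal log-likelihood has an exact analytic gradient (the quadrature nodes
are fixed on the standardized scale).

Usual intake for a person is the long-run day average
``E_w[ P(cons | u_1) * E(R | R>0, u_2) ]`` over the weekday/weekend mix; the
distribution of usual intake in the population is obtained by Monte Carlo:
each survey person contributes ``n_sim`` "pseudo-persons" with fresh draws
of ``(u_1, u_2)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy import stats

from .design import build_design_matrix, design_columns, age_group
from .quantiles import weighted_quantile

__all__ = [
    "boxcox",
    "inv_boxcox",
    "TwoPartParams",
    "TwoPartMixedModel",
    "TwoPartResults",
    "UsualIntakeDraws",
    "ConvergenceError",
    "simulate_usual_intake",
    "summarize_groups",
    "WEEKDAY_MIX",
]

#: usual-day prediction convention: (P(weekday), P(end-of-week)) = (4/7, 3/7)
WEEKDAY_MIX = ((0.0, 4.0 / 7.0), (1.0, 3.0 / 7.0))

MIN_BOTH_DAY_CONSUMERS = 50


# ---------------------------------------------------------------------------
# Box-Cox transform
# ---------------------------------------------------------------------------

def boxcox(x, lam):
    """Box-Cox transform ``(x**lam - 1)/lam`` (``log x`` at lam == 0)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("boxcox requires strictly positive x")
    if lam == 0:
        return np.log(x)
    return (np.power(x, lam) - 1.0) / lam


def inv_boxcox(y, lam):
    """Exact inverse of :func:`boxcox`; raises outside the support."""
    y = np.asarray(y, dtype=float)
    if lam == 0:
        return np.exp(y)
    arg = 1.0 + lam * y
    if np.any(arg <= 0):
        raise ValueError("inv_boxcox outside support: 1 + lam*y must be > 0")
    return np.power(arg, 1.0 / lam)


def _dboxcox_dlam(x, lam):
    # d/dlam of (x^lam - 1)/lam
    xl = np.power(x, lam)
    return (xl * (lam * np.log(x) - 1.0) + 1.0) / lam**2


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class TwoPartParams:
    """All parameters of the two-part model, on the natural scale.

    ``beta_prob`` and ``beta_amount`` are pandas Series indexed by the
    fixed-effect column names of the cohort's design basis.
    """

    beta_prob: pd.Series
    beta_amount: pd.Series
    var_u1: float
    var_u2: float
    rho: float
    var_eps: float
    lam: float
    cohort: str = "child"
    #: multiplier applied to amounts before the Box-Cox transform (the
    #: amount model is fitted on ``amount_scale * R``; simulated intakes
    #: are divided back).  Power transforms are not scale-equivariant, so
    #: very small per-bodyweight intakes are rescaled to order 1-10 for a
    #: well-conditioned fit.
    amount_scale: float = 1.0

    def __post_init__(self):
        if self.var_u1 < 0 or self.var_u2 < 0 or self.var_eps < 0:
            raise ValueError("variance components must be >= 0")
        if not -1 < self.rho < 1:
            raise ValueError("rho must lie in (-1, 1)")

    @property
    def sd_u1(self):
        return float(np.sqrt(self.var_u1))

    @property
    def sd_u2(self):
        return float(np.sqrt(self.var_u2))

    @property
    def sd_eps(self):
        return float(np.sqrt(self.var_eps))

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort,
            "beta_prob": {k: float(v) for k, v in self.beta_prob.items()},
            "beta_amount": {k: float(v) for k, v in self.beta_amount.items()},
            "var_u1": float(self.var_u1),
            "var_u2": float(self.var_u2),
            "rho": float(self.rho),
            "var_eps": float(self.var_eps),
            "lam": float(self.lam),
            "amount_scale": float(self.amount_scale),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TwoPartParams":
        return cls(
            beta_prob=pd.Series(d["beta_prob"]),
            beta_amount=pd.Series(d["beta_amount"]),
            var_u1=d["var_u1"],
            var_u2=d["var_u2"],
            rho=d["rho"],
            var_eps=d["var_eps"],
            lam=d["lam"],
            cohort=d.get("cohort", "child"),
            amount_scale=d.get("amount_scale", 1.0),
        )


class ConvergenceError(RuntimeError):
    """Fit failed to converge; carries the best parameters seen."""

    def __init__(self, msg, params=None, grad_norm=None):
        super().__init__(msg)
        self.params = params
        self.grad_norm = grad_norm


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class TwoPartMixedModel:
    """Survey-weighted correlated two-part mixed model.

    Build with :meth:`from_dataframe` from person-day records; ``fit``
    returns a :class:`TwoPartResults`.
    """

    def __init__(self, person_index, X, amount, weights, cohort,
                 person_ids=None, lam_bounds=(0.01, 1.0), n_quad=15,
                 amount_scale=1.0):
        order = np.argsort(person_index, kind="stable")
        self.person_index = np.asarray(person_index)[order]
        self.X = np.asarray(X, dtype=float)[order]
        self.amount = np.asarray(amount, dtype=float)[order]
        if np.any(self.amount < 0):
            raise ValueError("amounts must be >= 0 (0 = no consumption)")
        if amount_scale == "auto":
            pos = self.amount[self.amount > 0]
            if len(pos) == 0:
                raise ValueError("degenerate fit: no consumption days observed")
            # power of ten putting the median positive amount near 5
            amount_scale = 10.0 ** round(np.log10(5.0 / np.median(pos)))
        self.amount_scale = float(amount_scale)
        if not self.amount_scale > 0:
            raise ValueError("amount_scale must be > 0")
        self.amount = self.amount * self.amount_scale
        self.cohort = cohort
        self.colnames = design_columns(cohort)
        if self.X.shape[1] != len(self.colnames):
            raise ValueError("design matrix does not match cohort basis")
        self.lam_bounds = tuple(lam_bounds)
        self.n_quad = int(n_quad)

        # standardize non-constant columns internally (conditioning of the
        # spline/interaction basis); coefficients are mapped back to the
        # original basis in params_from_theta
        mu = self.X.mean(axis=0)
        sd = self.X.std(axis=0)
        mu[0] = 0.0
        sd[0] = 1.0
        sd[sd == 0] = 1.0
        self._xmean = mu
        self._xscale = sd
        self.X = (self.X - mu) / sd

        # contiguous person blocks
        uniq, starts = np.unique(self.person_index, return_index=True)
        starts = np.sort(starts)
        self.person_starts = starts
        self.n_persons = len(starts)
        self.person_ids = np.asarray(person_ids) if person_ids is not None \
            else self.person_index[starts]
        # integer person label per obs row
        lbl = np.zeros(len(self.person_index), dtype=np.int64)
        lbl[starts[1:]] = 1
        self.person_label = np.cumsum(lbl)

        w = np.asarray(weights, dtype=float)[order]
        if np.any(w <= 0):
            raise ValueError("survey weights must be > 0")
        wp = w[starts]
        # weights are person-level; normalize to mean 1 within the fit
        self.weights_person = wp / wp.mean()

        self.y = (self.amount > 0).astype(float)
        if self.y.sum() == 0:
            raise ValueError("degenerate fit: no consumption days observed")
        if self.y.sum() == len(self.y):
            raise ValueError("degenerate fit: consumption on every person-day")
        self.pos_mask = self.amount > 0
        self.Xp = self.X[self.pos_mask]
        self.R = self.amount[self.pos_mask]
        self.logR = np.log(self.R)
        self.pos_person = self.person_label[self.pos_mask]
        pstart = np.flatnonzero(np.r_[True, np.diff(self.pos_person) != 0])
        self.pos_starts = pstart
        self.pos_upersons = self.pos_person[pstart]

        # persons consuming on >= 2 days (both recall days)
        cons_days = np.bincount(self.person_label, weights=self.y,
                                minlength=self.n_persons)
        self.n_both_day_consumers = int((cons_days >= 2).sum())

        self._set_quadrature(self.n_quad)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_dataframe(cls, df, cohort, amount_col="amount",
                       weight_col="weight", person_col="person_id",
                       lam_bounds=(0.01, 1.0), n_quad=15, amount_scale=1.0):
        """Build from a person-day DataFrame.

        Required columns: ``person_col``, ``gender``, ``age``,
        ``end_of_week``, ``second_recall``, ``amount_col`` (0 on
        non-consumption days) and ``weight_col`` (person-level survey
        weight, repeated on each day row).  ``amount_scale="auto"``
        rescales positive amounts to a well-conditioned magnitude before
        the Box-Cox transform (reported back in the fitted parameters).
        """
        X = build_design_matrix(df, cohort).to_numpy()
        codes, uniq = pd.factorize(df[person_col], sort=True)
        return cls(
            person_index=codes,
            X=X,
            amount=df[amount_col].to_numpy(dtype=float),
            weights=df[weight_col].to_numpy(dtype=float),
            cohort=cohort,
            person_ids=np.asarray(uniq),
            lam_bounds=lam_bounds,
            n_quad=n_quad,
            amount_scale=amount_scale,
        )

    # -- quadrature -------------------------------------------------------
    def _set_quadrature(self, n_quad):
        x, w = np.polynomial.hermite_e.hermegauss(n_quad)
        lw = np.log(w) - 0.5 * np.log(2 * np.pi)
        z1 = np.repeat(x, n_quad)
        z2 = np.tile(x, n_quad)
        self._z1 = z1
        self._z2 = z2
        self._logw = np.add.outer(lw, lw).ravel()
        self.n_quad = n_quad

    # -- parameter transform ----------------------------------------------
    @property
    def n_fixed(self):
        return self.X.shape[1]

    @property
    def n_params(self):
        return 2 * self.n_fixed + 5

    def _unpack(self, theta):
        p = self.n_fixed
        b1 = theta[:p]
        b2 = theta[p:2 * p]
        a1, a2, r, t, el = theta[2 * p:]
        s1 = np.exp(a1)
        s2 = np.exp(a2)
        rho = np.tanh(r)
        sig = np.exp(t)
        lo, hi = self.lam_bounds
        sl = expit(el)
        lam = lo + (hi - lo) * sl
        dlam = (hi - lo) * sl * (1 - sl)
        return b1, b2, s1, s2, rho, sig, lam, dlam

    def _beta_to_std(self, b):
        """Original-basis coefficients -> standardized-basis coefficients."""
        b = np.asarray(b, dtype=float)
        bs = b * self._xscale
        bs[0] = b[0] + float(b[1:] @ self._xmean[1:])
        return bs

    def _beta_from_std(self, bs):
        bs = np.asarray(bs, dtype=float)
        b = bs / self._xscale
        b[0] = bs[0] - float((bs[1:] / self._xscale[1:]) @ self._xmean[1:])
        return b

    def _beta_backtransform_matrix(self):
        """Jacobian d(b_original)/d(b_standardized), one fixed-effect block."""
        p = self.n_fixed
        A = np.diag(1.0 / self._xscale)
        A[0, 0] = 1.0
        A[0, 1:] = -self._xmean[1:] / self._xscale[1:]
        return A

    def _pack_natural(self, params: TwoPartParams):
        lo, hi = self.lam_bounds
        lam = np.clip(params.lam, lo + 1e-9, hi - 1e-9 if hi < 1 else hi)
        frac = np.clip((lam - lo) / (hi - lo), 1e-9, 1 - 1e-9)
        return np.concatenate([
            self._beta_to_std(params.beta_prob.to_numpy(dtype=float)),
            self._beta_to_std(params.beta_amount.to_numpy(dtype=float)),
            [0.5 * np.log(max(params.var_u1, 1e-8)),
             0.5 * np.log(max(params.var_u2, 1e-8)),
             np.arctanh(np.clip(params.rho, -0.999, 0.999)),
             0.5 * np.log(max(params.var_eps, 1e-8)),
             np.log(frac / (1 - frac))],
        ])

    def params_from_theta(self, theta) -> TwoPartParams:
        b1, b2, s1, s2, rho, sig, lam, _ = self._unpack(theta)
        rho = float(np.clip(rho, -1 + 1e-12, 1 - 1e-12))
        return TwoPartParams(
            beta_prob=pd.Series(self._beta_from_std(b1),
                                index=self.colnames),
            beta_amount=pd.Series(self._beta_from_std(b2),
                                  index=self.colnames),
            var_u1=s1**2, var_u2=s2**2, rho=rho,
            var_eps=sig**2, lam=float(lam), cohort=self.cohort,
            amount_scale=self.amount_scale,
        )

    # -- likelihood --------------------------------------------------------
    def loglike_components(self, theta, want_grad=True, want_scores=False):
        """Weighted marginal log-likelihood, analytic gradient, scores.

        Returns ``(ll, grad, scores)`` where ``ll = sum_i w_i log L_i`` with
        mean-1 weights, ``grad`` its exact gradient in the unconstrained
        parameterization, and ``scores`` the per-person *unweighted* score
        matrix (n_persons, n_params) when requested.
        """
        b1, b2, s1, s2, rho, sig, lam, dlam = self._unpack(theta)
        z1, z2, logw = self._z1, self._z2, self._logw
        Q = z1.size
        u1q = s1 * z1
        cq = rho * z1 + np.sqrt(1 - rho**2) * z2
        u2q = s2 * cq

        eta1 = self.X @ b1                       # (N,)
        # binary part, all obs x nodes
        h = eta1[:, None] + u1q[None, :]         # (N, Q)
        lB = self.y[:, None] * h - np.logaddexp(0.0, h)

        # amount part, positive obs x nodes
        zamt = boxcox(self.R, lam)
        eta2 = self.Xp @ b2
        e = (zamt - eta2)[:, None] - u2q[None, :]     # (Np, Q)
        sig2 = sig * sig
        lA = (-0.5 * np.log(2 * np.pi) - np.log(sig)
              - 0.5 * e * e / sig2
              + ((lam - 1.0) * self.logR)[:, None])

        # per-person log joint at each node
        ell = np.add.reduceat(lB, self.person_starts, axis=0)
        sumsA = np.add.reduceat(lA, self.pos_starts, axis=0)
        ell[self.pos_upersons] += sumsA
        ell += logw[None, :]

        m = ell.max(axis=1)
        A = np.exp(ell - m[:, None])
        Li = A.sum(axis=1)
        logLi = m + np.log(Li)
        w = self.weights_person
        ll = float(np.dot(w, logLi))
        if not want_grad and not want_scores:
            return ll, None, None

        P = A / Li[:, None]                      # posterior node weights
        p = self.n_fixed

        # per-obs node coefficients
        CB = P[self.person_label]                # (N, Q)
        CA = P[self.pos_person]                  # (Np, Q)
        dB = self.y[:, None] - expit(h)          # (N, Q)
        es = e / sig2                            # (Np, Q)

        def assemble(CB, CA, per_person=False):
            DB = CB * dB
            DA = CA * es
            coefB = DB.sum(axis=1)
            coefA = DA.sum(axis=1)
            wA = CA.sum(axis=1)                  # ~1 (or w) per positive obs
            E2 = CA * (es * e)                   # e^2/sig^2 weighted
            dz = _dboxcox_dlam(self.R, lam)

            g_a1 = DB @ u1q
            g_a2 = DA @ u2q
            du2dr = s2 * (z1 - rho * z2 / np.sqrt(1 - rho**2)) * (1 - rho**2)
            g_r = DA @ du2dr
            g_t = E2.sum(axis=1) - wA
            g_lam = (-coefA * dz + wA * self.logR) * dlam

            if not per_person:
                grad = np.empty(self.n_params)
                grad[:p] = self.X.T @ coefB
                grad[p:2 * p] = self.Xp.T @ coefA
                grad[2 * p] = g_a1.sum()
                grad[2 * p + 1] = g_a2.sum()
                grad[2 * p + 2] = g_r.sum()
                grad[2 * p + 3] = g_t.sum()
                grad[2 * p + 4] = g_lam.sum()
                return grad
            # per-person score matrix
            S = np.zeros((self.n_persons, self.n_params))
            Sb1 = np.add.reduceat(self.X * coefB[:, None],
                                  self.person_starts, axis=0)
            S[:, :p] = Sb1
            Sb2 = np.add.reduceat(self.Xp * coefA[:, None],
                                  self.pos_starts, axis=0)
            S[self.pos_upersons, p:2 * p] = Sb2
            S[:, 2 * p] = np.add.reduceat(g_a1, self.person_starts)
            for k, g in ((1, g_a2), (2, g_r), (3, g_t), (4, g_lam)):
                col = np.zeros(self.n_persons)
                col[self.pos_upersons] = np.add.reduceat(g, self.pos_starts)
                S[:, 2 * p + k] = col
            return S

        grad = None
        if want_grad:
            grad = assemble(CB * w[self.person_label, None],
                            CA * w[self.pos_person, None])
        scores = None
        if want_scores:
            scores = assemble(CB, CA, per_person=True)
        return ll, grad, scores

    def loglike(self, theta):
        return self.loglike_components(theta, want_grad=False)[0]

    # -- starting values ---------------------------------------------------
    def _start_params(self, rng):
        import statsmodels.api as sm
        p = self.n_fixed
        wobs = self.weights_person[self.person_label]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(self.y, self.X, family=sm.families.Binomial(),
                         var_weights=wobs)
            b1 = glm.fit(maxiter=100).params
        # amount start: Box-Cox MLE on positive amounts, then weighted OLS
        lo, hi = self.lam_bounds
        try:
            lam0 = float(stats.boxcox_normmax(self.R, method="mle"))
        except Exception:
            lam0 = 0.5 * (lo + hi)
        lam0 = float(np.clip(lam0, lo + 0.02 * (hi - lo), hi - 0.02 * (hi - lo)))
        zamt = boxcox(self.R, lam0)
        wpos = wobs[self.pos_mask]
        WX = self.Xp * wpos[:, None]
        b2, *_ = np.linalg.lstsq(WX.T @ self.Xp + 1e-8 * np.eye(p),
                                 WX.T @ zamt, rcond=None)
        resid = zamt - self.Xp @ b2
        v = max(float(np.average(resid**2, weights=wpos)), 1e-4)
        theta0 = np.concatenate([
            b1, b2,
            [np.log(0.7),                       # sd_u1 start
             0.5 * np.log(0.4 * v),             # sd_u2 start (40% of resid var)
             np.arctanh(0.3),
             0.5 * np.log(0.6 * v),
             np.log((lam0 - lo) / (hi - lam0))],
        ])
        return theta0

    # -- fit ---------------------------------------------------------------
    def fit(self, start_params=None, max_starts=3, gtol=1e-4, maxiter=500,
            seed=0, cov_type="sandwich", warn_small=True):
        """Maximize the weighted marginal likelihood.

        Up to ``max_starts`` optimizer runs (first from data-driven starting
        values or ``start_params``, later ones perturbed) stopping at the
        first run whose scaled gradient sup-norm falls below ``gtol``.
        """
        if warn_small and self.n_both_day_consumers < MIN_BOTH_DAY_CONSUMERS:
            warnings.warn(
                f"only {self.n_both_day_consumers} persons consume on both "
                f"days (< {MIN_BOTH_DAY_CONSUMERS}); estimates may be unstable",
                UserWarning, stacklevel=2)
        rng = np.random.default_rng(seed)
        n = self.n_persons

        def objective(theta):
            ll, g, _ = self.loglike_components(theta)
            return -ll / n, -g / n

        if start_params is None:
            theta0 = self._start_params(rng)
        elif isinstance(start_params, TwoPartParams):
            theta0 = self._pack_natural(start_params)
        else:
            theta0 = np.asarray(start_params, dtype=float)

        best = None
        for attempt in range(max_starts):
            if attempt == 0:
                t0 = theta0
            else:
                # continue from the best point so far, lightly perturbed
                t0 = best[0].x + rng.normal(0, 0.02 * attempt,
                                            size=theta0.shape)
            res = minimize(objective, t0, jac=True, method="L-BFGS-B",
                           options={"maxiter": maxiter, "ftol": 1e-12,
                                    "gtol": 0.1 * gtol, "maxcor": 30})
            gnorm = float(np.max(np.abs(res.jac)))
            if best is None or res.fun < best[0].fun:
                best = (res, gnorm)
            if gnorm < gtol:
                break
        res, gnorm = best
        converged = gnorm < gtol
        theta = res.x
        if not converged:
            raise ConvergenceError(
                f"no convergence after {max_starts} starts "
                f"(grad sup-norm {gnorm:.2e} >= {gtol:g})",
                params=self.params_from_theta(theta), grad_norm=gnorm)
        ll = -res.fun * n
        cov = self._cov_params(theta, cov_type)
        return TwoPartResults(self, theta, ll, cov, cov_type,
                              converged=converged, grad_norm=gnorm,
                              n_iter=res.nit)

    # -- covariance --------------------------------------------------------
    def _num_hessian(self, theta, eps=1e-5):
        k = theta.size
        H = np.zeros((k, k))
        for j in range(k):
            tp = theta.copy(); tp[j] += eps
            tm = theta.copy(); tm[j] -= eps
            gp = self.loglike_components(tp)[1]
            gm = self.loglike_components(tm)[1]
            H[:, j] = (gp - gm) / (2 * eps)
        return -0.5 * (H + H.T)          # negative-loglik Hessian, symmetrized

    def _cov_params(self, theta, cov_type):
        H = self._num_hessian(theta)
        try:
            Hinv = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            Hinv = np.linalg.pinv(H)
        if cov_type == "hessian":
            return Hinv
        _, _, scores = self.loglike_components(theta, want_grad=False,
                                               want_scores=True)
        ws = scores * self.weights_person[:, None]
        meat = ws.T @ ws
        return Hinv @ meat @ Hinv


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

class TwoPartResults:
    """Fitted two-part model: estimates, uncertainties, diagnostics."""

    def __init__(self, model, theta, llf, cov_unc, cov_type,
                 converged, grad_norm, n_iter):
        self.model = model
        self.theta = np.asarray(theta, dtype=float)
        self.llf = float(llf)
        self.cov_type = cov_type
        self.converged = bool(converged)
        self.grad_norm = float(grad_norm)
        self.n_iter = int(n_iter)
        self.params = model.params_from_theta(theta)
        self._cov_unc = cov_unc
        # delta-method Jacobian unconstrained -> natural: fixed-effect
        # blocks undo the internal column standardization; the tail is
        # diagonal (variances via log-sd, rho via atanh, lam via logistic)
        p = model.n_fixed
        _, _, s1, s2, rho, sig, lam, dlam = model._unpack(theta)
        J = np.zeros((model.n_params, model.n_params))
        A = model._beta_backtransform_matrix()
        J[:p, :p] = A
        J[p:2 * p, p:2 * p] = A
        J[2 * p, 2 * p] = 2 * s1**2
        J[2 * p + 1, 2 * p + 1] = 2 * s2**2
        J[2 * p + 2, 2 * p + 2] = 1 - rho**2
        J[2 * p + 3, 2 * p + 3] = 2 * sig**2
        J[2 * p + 4, 2 * p + 4] = dlam
        self.cov_params = J @ cov_unc @ J.T
        se = np.sqrt(np.clip(np.diag(self.cov_params), 0, None))
        names = ([f"prob:{c}" for c in model.colnames]
                 + [f"amt:{c}" for c in model.colnames]
                 + ["var_u1", "var_u2", "rho", "var_eps", "lam"])
        vals = np.concatenate([
            self.params.beta_prob.to_numpy(),
            self.params.beta_amount.to_numpy(),
            [s1**2, s2**2, self.params.rho, sig**2, lam]])
        self.param_table = pd.DataFrame(
            {"estimate": vals, "se": se}, index=names)
        self.bse = self.param_table["se"]

    @property
    def fixed_effects(self) -> pd.DataFrame:
        p = self.model.n_fixed
        return self.param_table.iloc[: 2 * p]

    def summary(self) -> str:
        m = self.model
        tab = self.param_table.copy()
        tab["z"] = tab["estimate"] / tab["se"].where(tab["se"] > 0)
        tab["P>|z|"] = 2 * stats.norm.sf(np.abs(tab["z"]))
        lines = [
            "Correlated two-part mixed model (usual intake)",
            "=" * 58,
            f"cohort: {m.cohort}    persons: {m.n_persons}    "
            f"obs: {len(m.y)}",
            f"both-day consumers: {m.n_both_day_consumers}    "
            f"quadrature nodes: {m.n_quad}^2",
            f"log-likelihood: {self.llf:.3f}    converged: {self.converged} "
            f"(grad {self.grad_norm:.1e}, {self.n_iter} iters, "
            f"cov: {self.cov_type})",
            "-" * 58,
            tab.to_string(float_format=lambda v: f"{v:.5g}"),
            "=" * 58,
        ]
        return "\n".join(lines)

    def simulate_usual_intake(self, persons, n_sim=100, seed=0,
                              n_eps_quad=9):
        """Monte Carlo pseudo-person usual-intake draws; see module docs."""
        return simulate_usual_intake(self.params, persons, n_sim=n_sim,
                                     seed=seed, n_eps_quad=n_eps_quad)


# ---------------------------------------------------------------------------
# Usual-intake simulation
# ---------------------------------------------------------------------------

@dataclass
class UsualIntakeDraws:
    """Per-person simulated usual daily intakes with survey weights."""

    person_id: np.ndarray
    draws: np.ndarray            # (n_persons, n_sim)
    weights: np.ndarray          # person-level survey weights
    n_truncated: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_sim(self):
        return self.draws.shape[1]

    def pooled(self):
        """Flattened (values, weights) with each draw at weight w_i/n_sim."""
        v = self.draws.ravel()
        w = np.repeat(self.weights / self.n_sim, self.n_sim)
        return v, w

    def to_frame(self) -> pd.DataFrame:
        n, s = self.draws.shape
        return pd.DataFrame({
            "person_id": np.repeat(self.person_id, s),
            "draw": np.tile(np.arange(1, s + 1), n),
            "usual_ug_per_kg_day": self.draws.ravel(),
            "weight": np.repeat(self.weights, s),
        })


def _usual_day_means(params: TwoPartParams, persons: pd.DataFrame):
    """Linear predictors under the usual-day convention, per weekday mix."""
    rows = []
    for eow, prob in WEEKDAY_MIX:
        d = pd.DataFrame({
            "gender": persons["gender"].to_numpy(),
            "age": persons["age"].to_numpy(dtype=float),
            "end_of_week": eow,
            "second_recall": 0.0,      # first-recall mode
        })
        X = build_design_matrix(d, params.cohort).to_numpy()
        rows.append((prob,
                     X @ params.beta_prob.to_numpy(dtype=float),
                     X @ params.beta_amount.to_numpy(dtype=float)))
    return rows


def simulate_usual_intake(params: TwoPartParams, persons: pd.DataFrame,
                          n_sim=100, seed=0, n_eps_quad=9) -> UsualIntakeDraws:
    """Simulate ``n_sim`` usual daily intakes per person ("pseudo-persons").

    Each draw samples the person's random intercepts ``(u1, u2)`` from the
    fitted bivariate normal; usual intake for that draw averages, over the
    4/7 weekday / 3/7 end-of-week mix, the consumption probability times the
    expected consumption-day amount.  The amount back-transform
    ``E_eps[inv_boxcox(m + u2 + eps)]`` is evaluated by ``n_eps_quad``-point
    Gauss-Hermite integration; nodes falling outside the Box-Cox support are
    truncated at the boundary (value 0) and counted.
    """
    rng = np.random.default_rng(seed)
    n = len(persons)
    s1 = params.sd_u1
    s2 = params.sd_u2
    rho = params.rho
    sig = params.sd_eps
    lam = params.lam

    z = rng.standard_normal((2, n, n_sim))
    u1 = s1 * z[0]
    u2 = s2 * (rho * z[0] + np.sqrt(1 - rho**2) * z[1])

    xk, wk = np.polynomial.hermite_e.hermegauss(n_eps_quad)
    wk = wk / wk.sum()
    epsk = sig * xk

    total = np.zeros((n, n_sim))
    n_trunc = 0
    for prob_w, eta1, eta2 in _usual_day_means(params, persons):
        pcons = expit(eta1[:, None] + u1)
        m = eta2[:, None] + u2
        amt = np.zeros_like(m)
        for e_k, w_k in zip(epsk, wk):
            arg = 1.0 + lam * (m + e_k)
            bad = arg <= 0
            n_trunc += int(bad.sum())
            amt += w_k * np.power(np.clip(arg, 0.0, None), 1.0 / lam)
        total += prob_w * pcons * amt
    total /= params.amount_scale      # back to the caller's amount units

    weights = persons["weight"].to_numpy(dtype=float) if "weight" in persons \
        else np.ones(n)
    pid = persons["person_id"].to_numpy() if "person_id" in persons \
        else np.arange(n)
    return UsualIntakeDraws(person_id=pid, draws=total, weights=weights,
                            n_truncated=n_trunc,
                            meta={"n_sim": n_sim, "seed": seed,
                                  "cohort": params.cohort})


# ---------------------------------------------------------------------------
# Group summaries
# ---------------------------------------------------------------------------

def summarize_groups(draws: UsualIntakeDraws, persons: pd.DataFrame,
                     both_day_eaters=None, min_eaters=MIN_BOTH_DAY_CONSUMERS
                     ) -> pd.DataFrame:
    """Survey-weighted mean/median/P95/P99 of usual intake per gender x age band.

    ``persons`` rows must align with ``draws.person_id``; pooled
    pseudo-person draws carry weight ``w_i / n_sim``.  ``both_day_eaters``
    is an optional boolean array marking persons who consumed on both recall
    days (reported as the eaters column and used for the small-group flag).
    """
    persons = persons.reset_index(drop=True)
    if not np.array_equal(np.asarray(persons["person_id"]), draws.person_id):
        raise ValueError("persons must align with draws.person_id")
    groups = persons["age"].map(age_group)
    rows = []
    for (gender, band), idx in persons.groupby(
            [persons["gender"], groups], sort=True).groups.items():
        idx = np.asarray(idx)
        sub = draws.draws[idx].ravel()
        w = np.repeat(draws.weights[idx], draws.n_sim)
        n_eat = (int(np.asarray(both_day_eaters)[idx].sum())
                 if both_day_eaters is not None else None)
        flagged = n_eat is not None and n_eat < min_eaters
        if flagged:
            warnings.warn(
                f"group {gender}/{band}: only {n_eat} both-day eaters "
                f"(< {min_eaters})", UserWarning, stacklevel=2)
        med, p95, p99 = weighted_quantile(sub, [0.5, 0.95, 0.99], w)
        rows.append({
            "gender": gender, "age_group": band,
            "n_total": len(idx), "n_eaters_both_days": n_eat,
            "mean": float(np.average(sub, weights=w)),
            "median": float(med), "p95": float(p95), "p99": float(p99),
            "small_group_flag": bool(flagged),
        })
    out = pd.DataFrame(rows)
    order = {label: i for i, (label, *_rest) in enumerate(
        [(g[0], None) for g in (("1-5",), ("6-9",), ("10-19",),
                                ("20-54",), ("55+",))])}
    out["__o"] = out["age_group"].map(order)
    out = out.sort_values(["gender", "__o"]).drop(columns="__o")
    return out.reset_index(drop=True)
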