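"""Allometric clearance modeling across species by nonlinear mixed effects.

The structural model is the classical body-weight power law

    CL_ij = alpha_TV * exp(eta_alpha,i) * BW_j ** (beta_TV * exp(eta_beta,i))

for antibody ``i`` observed in species ``j`` with body weight ``BW_j``
(absolute CL in L/day, BW in kg).  Inter-antibody random effects ``eta``
are normal on the log scale (variance ``omega2``) and shared across an
antibody's species observations; residual error is proportional,
``y = f * (1 + eps)`` with ``eps ~ N(0, sigma2)``.

Estimation maximizes the marginal likelihood.  With a single scalar random
effect the marginal integral is one-dimensional, so the primary estimator
is adaptive Gauss-Hermite quadrature (AGQ) centered and scaled at the
per-antibody posterior mode: effectively exact for moderate node counts
and cheap at these problem sizes.  A Laplace approximation (AGQ with one
node) is available as a fast path for bootstrap resampling.  The objective
function value (OFV) is -2 x log marginal likelihood including 2*pi
constants; only differences between nested models are interpreted
(drop >= 3.841 is significant at alpha=0.05, df=1).

Human CL translation from a single non-clinical species uses the fixed-
exponent scaling rule CL_human = CL_species * (BW_human/BW_species)**beta
in absolute units, equivalently per-kg CL times (BW ratio)**(beta-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.special import logsumexp, roots_hermite

from .datasets import BODY_WEIGHTS_KG, CrossSpeciesDataset, to_absolute_cl

__all__ = [
    "AllometricModelSpec",
    "AllometricModel",
    "AllometricResults",
    "BootstrapResult",
    "ScalingResult",
    "compute_ofv",
    "compare_models",
    "scale_human_cl",
    "fold_error_summary",
    "bootstrap_fit",
]

LRT_THRESHOLD_1DF = 3.841  # chi2(1) critical value at alpha = 0.05

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class AllometricModelSpec:
    """Model structure: species, random-effect placement, estimation method."""

    species: tuple[str, ...] = ("monkey", "human")
    random_effect_on: tuple[str, ...] = ("alpha",)
    error_model: str = "proportional"
    estimation: str = "agq"  # "agq" | "laplace"
    agq_nodes: int = 31

    def __post_init__(self):
        if len(self.species) < 2:
            raise ValueError("species_set needs at least two species")
        bad = set(self.random_effect_on) - {"alpha", "beta"}
        if bad:
            raise ValueError(f"unknown random effect target(s): {sorted(bad)}")
        if self.error_model != "proportional":
            raise ValueError("only the proportional error model is supported")
        if self.estimation not in ("agq", "laplace"):
            raise ValueError("estimation must be 'agq' or 'laplace'")

    @property
    def n_random(self) -> int:
        return len(self.random_effect_on)

    def param_names(self) -> list[str]:
        names = ["alpha_tv", "beta_tv"]
        names += [f"omega2_{t}" for t in self.random_effect_on]
        names.append("sigma2")
        return names


def _tensor_nodes(n_nodes: int, d: int):
    z1, w1 = roots_hermite(n_nodes)
    if d == 1:
        return z1[:, None], np.log(w1)
    zz = np.array([[a, b] for a in z1 for b in z1])
    lw = np.add.outer(np.log(w1), np.log(w1)).ravel()
    return zz, lw


class AllometricModel:
    """Nonlinear mixed-effects allometric CL model bound to a dataset.

    Parameters
    ----------
    cl_abs : absolute clearance observations, L/day
    body_weight : body weight per observation, kg
    antibody : cluster label per observation (random effects are shared
        within a label)
    spec : model structure

    Use :meth:`from_dataset` to build from a :class:`CrossSpeciesDataset`
    (weight-normalized CL is converted to L/day with the standard species
    body weights).
    """

    def __init__(self, cl_abs, body_weight, antibody, spec: AllometricModelSpec | None = None):
        y = np.asarray(cl_abs, dtype=float)
        bw = np.asarray(body_weight, dtype=float)
        labels = np.asarray(antibody)
        if not (y.shape == bw.shape == labels.shape) or y.ndim != 1:
            raise ValueError("cl_abs, body_weight and antibody must be equal-length 1-D")
        if np.any(y <= 0) or np.any(bw <= 0):
            raise ValueError("clearances and body weights must be positive")
        self.spec = spec or AllometricModelSpec()
        # stable-sort observations by first appearance of the cluster label
        names, first_idx = np.unique(labels, return_index=True)
        order_of = {n: k for k, n in enumerate(names[np.argsort(first_idx)])}
        gidx = np.array([order_of[l] for l in labels])
        srt = np.argsort(gidx, kind="stable")
        self.y = y[srt]
        self.bw = bw[srt]
        self.group = gidx[srt]
        self.names = list(names[np.argsort(first_idx)])
        self.n_groups = len(self.names)
        if self.n_groups < 5:
            raise ValueError("need at least 5 antibodies to fit the mixed model")
        self.ptr = np.searchsorted(self.group, np.arange(self.n_groups))
        self.logbw = np.log(self.bw)

    @classmethod
    def from_dataset(
        cls,
        ds: CrossSpeciesDataset,
        species: Sequence[str] = ("monkey", "human"),
        body_weights: dict[str, float] | None = None,
        **spec_kwargs,
    ) -> "AllometricModel":
        bws = body_weights or BODY_WEIGHTS_KG
        y, bw, lab = [], [], []
        for rec in ds:
            for sp in species:
                cl = rec.value(sp, "CL")
                if cl is not None:
                    y.append(to_absolute_cl(cl, bws[sp]))
                    bw.append(bws[sp])
                    lab.append(rec.name)
        spec = AllometricModelSpec(species=tuple(species), **spec_kwargs)
        return cls(y, bw, lab, spec)

    # ---- parameter vector <-> natural parameters -------------------------
    # theta (estimation scale): [log alpha, beta, log omega2 per RE, log sigma2]

    def _unpack(self, theta):
        la, beta = theta[0], theta[1]
        d = self.spec.n_random
        # variance floor (1e-10) keeps exactly-fitting data identifiable:
        # without it, sigma2 -> 0 lets the etas absorb any alpha offset
        om2 = np.exp(np.clip(theta[2 : 2 + d], -23.0, 6.0))
        sg2 = float(np.exp(np.clip(theta[2 + d], -23.0, 6.0)))
        return float(np.exp(la)), float(beta), om2, sg2

    def _pack(self, alpha, beta, omega2, sigma2):
        return np.r_[np.log(alpha), beta, np.log(np.atleast_1d(omega2)), np.log(sigma2)]

    # ---- inner problem ---------------------------------------------------

    def _h_terms(self, eta_obs1, eta_obs2, alpha, beta, sg2):
        """Per-observation -2log density terms, any leading broadcast shape."""
        expo = beta * np.exp(eta_obs2) if eta_obs2 is not None else beta
        logf = np.log(alpha) + (eta_obs1 if eta_obs1 is not None else 0.0) + expo * self.logbw
        r = self.y * np.exp(-logf)
        return _LOG2PI + np.log(sg2) + 2.0 * logf + (r - 1.0) ** 2 / sg2

    def _h(self, eta, alpha, beta, om2, sg2):
        """Joint -log density per group, eta shape (..., n_groups, d)."""
        on = self.spec.random_effect_on
        e1 = eta[..., self.group, on.index("alpha")] if "alpha" in on else None
        e2 = eta[..., self.group, on.index("beta")] if "beta" in on else None
        terms = self._h_terms(e1, e2, alpha, beta, sg2)
        per_group = np.add.reduceat(terms, self.ptr, axis=-1)
        prior = np.sum(_LOG2PI + np.log(om2) + eta**2 / om2, axis=-1)
        return 0.5 * (per_group + prior)

    def _grad_hess(self, eta, alpha, beta, om2, sg2):
        """Analytic gradient and Hessian of h per group; eta (n_groups, d)."""
        on = self.spec.random_effect_on
        d = len(on)
        e1 = eta[self.group, on.index("alpha")] if "alpha" in on else None
        e2 = eta[self.group, on.index("beta")] if "beta" in on else None
        expo = beta * np.exp(e2) if e2 is not None else beta
        logf = np.log(alpha) + (e1 if e1 is not None else 0.0) + expo * self.logbw
        r = self.y * np.exp(-logf)
        a_term = 1.0 - r * (r - 1.0) / sg2  # d(term)/d logf per obs (x1)
        b_term = r * (2.0 * r - 1.0) / sg2  # d2(term)/d logf^2 per obs
        D = []
        for t in on:
            D.append(np.ones_like(logf) if t == "alpha" else expo * self.logbw)
        grad = np.empty((self.n_groups, d))
        hess = np.empty((self.n_groups, d, d))
        for k in range(d):
            grad[:, k] = np.add.reduceat(a_term * D[k], self.ptr) + eta[:, k] / om2[k]
            for l in range(d):
                hkl = np.add.reduceat(b_term * D[k] * D[l], self.ptr)
                if on[k] == "beta" and on[l] == "beta":
                    hkl = hkl + np.add.reduceat(a_term * D[k], self.ptr)
                hess[:, k, l] = hkl + (1.0 / om2[k] if k == l else 0.0)
        return grad, hess

    def _inner_modes(self, alpha, beta, om2, sg2, eta0=None, tol=1e-10, max_iter=60):
        """Posterior modes of eta per group by damped Newton (vectorized)."""
        d = self.spec.n_random
        eta = np.zeros((self.n_groups, d)) if eta0 is None else np.array(eta0, dtype=float)
        h = self._h(eta, alpha, beta, om2, sg2)
        for _ in range(max_iter):
            grad, hess = self._grad_hess(eta, alpha, beta, om2, sg2)
            # regularize non-PD Hessians toward the prior precision
            if d == 1:
                H = hess[:, 0, 0]
                bad = H <= 1e-12
                H = np.where(bad, 1.0 / om2[0] + 1e-6, H)
                step = (grad[:, 0] / H)[:, None]
                hess = H[:, None, None]
            else:
                det = hess[:, 0, 0] * hess[:, 1, 1] - hess[:, 0, 1] * hess[:, 1, 0]
                tr = hess[:, 0, 0] + hess[:, 1, 1]
                bad = (det <= 1e-12) | (tr <= 0)
                if np.any(bad):
                    bump = np.where(bad, np.abs(tr) + 1.0, 0.0)
                    hess = hess + bump[:, None, None] * np.eye(2)
                step = np.linalg.solve(hess, grad[..., None])[..., 0]
            step = np.clip(step, -5.0, 5.0)
            t = np.ones(self.n_groups)
            for _ in range(30):
                trial = eta - t[:, None] * step
                h_new = self._h(trial, alpha, beta, om2, sg2)
                worse = h_new > h + 1e-14
                if not np.any(worse):
                    break
                t = np.where(worse, t / 2.0, t)
            eta = eta - t[:, None] * step
            h = self._h(eta, alpha, beta, om2, sg2)
            if np.max(np.abs(t[:, None] * step)) < tol:
                break
        _, hess = self._grad_hess(eta, alpha, beta, om2, sg2)
        return eta, hess

    # ---- objective -------------------------------------------------------

    def ofv(self, params=None, theta=None, method=None, nodes=None, eta0=None):
        """-2 x log marginal likelihood (2*pi constants included).

        ``params`` is (alpha, beta, omega2, sigma2) on the natural scale
        with ``omega2`` scalar or per-random-effect sequence; omega2 = 0
        collapses exactly to the no-random-effect likelihood.
        """
        if theta is None:
            alpha, beta, omega2, sigma2 = params
            om2 = np.atleast_1d(np.asarray(omega2, dtype=float))
            if sigma2 <= 0 or alpha <= 0 or np.any(om2 < 0):
                raise ValueError("invalid variance or coefficient parameters")
            if np.all(om2 == 0.0):
                return self._ofv_no_re(alpha, beta, sigma2)
            theta = self._pack(alpha, beta, om2, sigma2)
        method = method or self.spec.estimation
        nodes = 1 if method == "laplace" else (nodes or self.spec.agq_nodes)
        return self._ofv_theta(theta, nodes, eta0=eta0)[0]

    def _ofv_no_re(self, alpha, beta, sg2):
        terms = self._h_terms(None, None, alpha, beta, sg2)
        return float(np.sum(terms))

    def _ofv_theta(self, theta, n_nodes, eta0=None):
        alpha, beta, om2, sg2 = self._unpack(theta)
        d = self.spec.n_random
        eta_hat, hess = self._inner_modes(alpha, beta, om2, sg2, eta0=eta0)
        if d == 1:
            H = hess[:, 0, 0]
            logdet = np.log(H)
            scale = (1.0 / np.sqrt(H))[:, None, None]  # (n_groups,1,1)
        else:
            sign, logdet = np.linalg.slogdet(hess)
            if np.any(sign <= 0):
                return np.inf, eta_hat
            # inverse square root via Cholesky of H^{-1}
            Hinv = np.linalg.inv(hess)
            scale = np.linalg.cholesky(Hinv)  # (n_groups,d,d)
        z, logw = _tensor_nodes(n_nodes, d)  # z: (K,d)
        # eta points: mode + sqrt(2)*A z  -> shape (K, n_groups, d)
        shift = np.sqrt(2.0) * np.einsum("gab,kb->kga", scale, z)
        pts = eta_hat[None, :, :] + shift
        hvals = self._h(pts, alpha, beta, om2, sg2)  # (K, n_groups)
        zsq = np.sum(z**2, axis=1)
        log_integrand = logw[:, None] + zsq[:, None] - hvals
        loglik = (d / 2.0) * np.log(2.0) - 0.5 * logdet + logsumexp(log_integrand, axis=0)
        return float(-2.0 * np.sum(loglik)), eta_hat

    # ---- fitting ---------------------------------------------------------

    def _start_theta(self, omega2_init=0.2, sigma2_init=0.1):
        slope, intercept = np.polyfit(self.logbw, np.log(self.y), 1)
        d = self.spec.n_random
        return np.r_[intercept, slope, np.log(omega2_init) * np.ones(d), np.log(sigma2_init)]

    def fit(
        self,
        start=None,
        method: str | None = None,
        nodes: int | None = None,
        fix_beta: float | None = None,
        restarts: int = 3,
        compute_se: bool = True,
        xatol: float = 1e-8,
        fatol: float = 1e-9,
    ) -> "AllometricResults":
        """Maximize the marginal likelihood; returns :class:`AllometricResults`.

        Starting values are pooled log-log least squares for (alpha, beta)
        with omega2 = 0.2, sigma2 = 0.1; on failure the start is jittered
        up to ``restarts`` times.  ``fix_beta`` profiles the model with the
        exponent held fixed.
        """
        method = method or self.spec.estimation
        n_nodes = 1 if method == "laplace" else (nodes or self.spec.agq_nodes)
        theta0 = np.asarray(start, dtype=float) if start is not None else self._start_theta()

        if fix_beta is not None:
            mask = np.ones(len(theta0), dtype=bool)
            mask[1] = False

            def obj(t_red):
                full = np.empty(len(theta0))
                full[mask] = t_red
                full[1] = fix_beta
                return self._ofv_theta(full, n_nodes)[0]

            x0 = theta0[mask]
        else:

            def obj(t):
                return self._ofv_theta(t, n_nodes)[0]

            x0 = theta0

        rng = np.random.default_rng(0)
        best = None
        for attempt in range(restarts + 1):
            if best is None:
                xstart = x0
            else:
                # polish from the incumbent, with a small jitter after the first retry
                xstart = best.x + (rng.normal(0, 0.1, size=len(x0)) if attempt > 1 else 0.0)
            res = optimize.minimize(
                obj,
                xstart,
                method="Nelder-Mead",
                options=dict(xatol=xatol, fatol=fatol, maxiter=5000, maxfev=5000),
            )
            if best is None or res.fun < best.fun:
                best = res
            if best.success:
                break
        theta_hat = np.empty(len(theta0))
        if fix_beta is not None:
            theta_hat[mask] = best.x
            theta_hat[1] = fix_beta
        else:
            theta_hat = best.x
        ofv, eta_hat = self._ofv_theta(theta_hat, n_nodes)
        cov = None
        messages = []
        if compute_se:
            free = np.ones(len(theta_hat), dtype=bool)
            if fix_beta is not None:
                free[1] = False
            cov, msg = self._theta_cov(theta_hat, n_nodes, free)
            if msg:
                messages.append(msg)
        return AllometricResults(
            model=self,
            theta=theta_hat,
            ofv=ofv,
            converged=bool(best.success),
            cov_theta=cov,
            eta=eta_hat,
            method=method,
            n_nodes=n_nodes,
            fixed_beta=fix_beta,
            messages=messages,
        )

    def _theta_cov(self, theta, n_nodes, free):
        """Covariance of free theta from the observed information (central differences)."""
        idx = np.flatnonzero(free)
        k = len(idx)
        h = 1e-3 * np.maximum(1.0, np.abs(theta[idx]))
        H = np.zeros((k, k))
        f0 = self._ofv_theta(theta, n_nodes)[0]

        def f(t):
            return self._ofv_theta(t, n_nodes)[0]

        for a in range(k):
            for b in range(a, k):
                ea = np.zeros_like(theta)
                eb = np.zeros_like(theta)
                ea[idx[a]] = h[a]
                eb[idx[b]] = h[b]
                if a == b:
                    val = (f(theta + ea) - 2 * f0 + f(theta - ea)) / h[a] ** 2
                else:
                    val = (f(theta + ea + eb) - f(theta + ea - eb) - f(theta - ea + eb) + f(theta - ea - eb)) / (
                        4 * h[a] * h[b]
                    )
                H[a, b] = H[b, a] = val
        # OFV = -2 log L  =>  information = Hessian(OFV)/2
        try:
            cov_free = 2.0 * np.linalg.inv(H)
            if np.any(np.diag(cov_free) <= 0):
                return None, "observed information not positive definite; SEs unavailable"
        except np.linalg.LinAlgError:
            return None, "singular information matrix; SEs unavailable"
        cov = np.full((len(theta), len(theta)), np.nan)
        cov[np.ix_(idx, idx)] = cov_free
        return cov, ""


@dataclass
class AllometricResults:
    """Fitted allometric NLMEM: estimates, uncertainties, diagnostics."""

    model: AllometricModel
    theta: np.ndarray
    ofv: float
    converged: bool
    cov_theta: np.ndarray | None
    eta: np.ndarray
    method: str
    n_nodes: int
    fixed_beta: float | None = None
    messages: list[str] = field(default_factory=list)

    # -- estimates on the natural scale --
    @property
    def spec(self) -> AllometricModelSpec:
        return self.model.spec

    @property
    def alpha_tv(self) -> float:
        return float(np.exp(self.theta[0]))

    @property
    def beta_tv(self) -> float:
        return float(self.theta[1])

    @property
    def omega2(self) -> dict[str, float]:
        d = self.spec.n_random
        return {t: float(np.exp(self.theta[2 + k])) for k, t in enumerate(self.spec.random_effect_on)}

    @property
    def omega2_alpha(self) -> float | None:
        return self.omega2.get("alpha")

    @property
    def sigma2(self) -> float:
        return float(np.exp(self.theta[2 + self.spec.n_random]))

    @property
    def params(self) -> dict[str, float]:
        out = {"alpha_tv": self.alpha_tv, "beta_tv": self.beta_tv}
        out.update({f"omega2_{t}": v for t, v in self.omega2.items()})
        out["sigma2"] = self.sigma2
        return out

    @property
    def eta_by_antibody(self) -> dict[str, np.ndarray]:
        return {n: self.eta[i] for i, n in enumerate(self.model.names)}

    @property
    def n_antibodies(self) -> int:
        return self.model.n_groups

    @property
    def n_obs(self) -> int:
        return len(self.model.y)

    # -- uncertainties --
    def _se_theta(self):
        if self.cov_theta is None:
            return None
        return np.sqrt(np.diag(self.cov_theta))

    @property
    def se(self) -> dict[str, float] | None:
        """Delta-method standard errors on the natural scale."""
        set_ = self._se_theta()
        if set_ is None:
            return None
        names = self.spec.param_names()
        vals = list(self.params.values())
        out = {}
        for k, (nm, v) in enumerate(zip(names, vals)):
            out[nm] = float(v * set_[k]) if nm != "beta_tv" else float(set_[k])
        return out

    @property
    def rse_pct(self) -> dict[str, float] | None:
        se = self.se
        if se is None:
            return None
        return {nm: 100.0 * abs(se[nm] / v) if v != 0 else np.nan for nm, v in self.params.items()}

    @property
    def ci95(self) -> dict[str, tuple[float, float]] | None:
        """Wald 95% intervals: log scale for alpha/omega2/sigma2, identity for beta."""
        set_ = self._se_theta()
        if set_ is None:
            return None
        names = self.spec.param_names()
        out = {}
        for k, nm in enumerate(names):
            if nm == "beta_tv":
                out[nm] = (self.theta[1] - 1.96 * set_[1], self.theta[1] + 1.96 * set_[1])
            else:
                lo = np.exp(self.theta[k] - 1.96 * set_[k])
                hi = np.exp(self.theta[k] + 1.96 * set_[k])
                out[nm] = (float(lo), float(hi))
        return out

    # -- predictions / scaling --
    def predict(self, body_weight_kg, antibody: str | None = None) -> np.ndarray:
        """Typical (or antibody-conditional, via its EB eta) absolute CL in L/day."""
        bw = np.asarray(body_weight_kg, dtype=float)
        alpha, beta = self.alpha_tv, self.beta_tv
        if antibody is not None:
            e = self.eta_by_antibody[antibody]
            on = self.spec.random_effect_on
            if "alpha" in on:
                alpha = alpha * float(np.exp(e[on.index("alpha")]))
            if "beta" in on:
                beta = beta * float(np.exp(e[on.index("beta")]))
        return alpha * bw**beta

    def scale_human_cl(self, ds: CrossSpeciesDataset, source_species: str, beta: float | None = None) -> "ScalingResult":
        """Single-species human CL scaling using this fit's exponent by default."""
        return fold_error_summary(ds, source_species, self.beta_tv if beta is None else beta)

    def bootstrap(self, n_replicates: int = 2000, seed: int | None = None, method: str = "laplace") -> "BootstrapResult":
        return _bootstrap_model(self.model, self, n_replicates=n_replicates, seed=seed, method=method)

    def summary(self) -> str:
        lines = []
        sp = "-".join(self.spec.species)
        lines.append("Allometric CL mixed-effects model")
        lines.append("=" * 58)
        lines.append(f"Species set:      {sp}")
        lines.append(f"Antibodies:       {self.n_antibodies}   observations: {self.n_obs}")
        est = "adaptive Gauss-Hermite" if self.method == "agq" else "Laplace"
        lines.append(f"Estimation:       {est} ({self.n_nodes} node{'s' if self.n_nodes > 1 else ''})")
        lines.append(f"Random effects:   eta on {', '.join(self.spec.random_effect_on)} (log-normal)")
        lines.append(f"Residual model:   proportional")
        lines.append(f"OFV (-2LL):       {self.ofv:.3f}")
        lines.append(f"Converged:        {self.converged}")
        if self.fixed_beta is not None:
            lines.append(f"beta fixed at:    {self.fixed_beta}")
        lines.append("-" * 58)
        lines.append(f"{'parameter':<14}{'estimate':>12}{'%RSE':>9}{'95% CI':>22}")
        rse = self.rse_pct
        ci = self.ci95
        for nm, v in self.params.items():
            r = f"{rse[nm]:.0f}" if rse else "--"
            c = f"[{ci[nm][0]:.4g}, {ci[nm][1]:.4g}]" if ci else "--"
            lines.append(f"{nm:<14}{v:>12.4g}{r:>9}{c:>22}")
        for m in self.messages:
            lines.append(f"note: {m}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "species": list(self.spec.species),
            "random_effect_on": list(self.spec.random_effect_on),
            "estimation": self.method,
            "nodes": self.n_nodes,
            "params": self.params,
            "se": self.se,
            "rse_pct": self.rse_pct,
            "ci95": {k: list(v) for k, v in self.ci95.items()} if self.ci95 else None,
            "ofv": self.ofv,
            "converged": self.converged,
            "n_antibodies": self.n_antibodies,
            "n_obs": self.n_obs,
            "eta": {k: list(v) for k, v in self.eta_by_antibody.items()},
            "notes": self.messages,
        }

    def plot_gof(self, ax=None):
        """Observed vs antibody-conditional predicted CL (log-log), unity line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.model
        on = self.spec.random_effect_on
        e1 = self.eta[m.group, on.index("alpha")] if "alpha" in on else 0.0
        e2 = self.eta[m.group, on.index("beta")] if "beta" in on else 0.0
        pred = self.alpha_tv * np.exp(e1) * m.bw ** (self.beta_tv * np.exp(e2))
        ax.loglog(pred, m.y, "o", mfc="none")
        lim = [min(pred.min(), m.y.min()) * 0.7, max(pred.max(), m.y.max()) * 1.4]
        ax.plot(lim, lim, "k-", lw=1)
        ax.plot(lim, [2 * v for v in lim], "k--", lw=0.8)
        ax.plot(lim, [0.5 * v for v in lim], "k--", lw=0.8)
        ax.set_xlabel("predicted CL (L/day)")
        ax.set_ylabel("observed CL (L/day)")
        return ax


def compute_ofv(ds: CrossSpeciesDataset, spec: AllometricModelSpec, params, **kwargs) -> float:
    """OFV of given natural-scale parameters (alpha, beta, omega2, sigma2)."""
    model = AllometricModel.from_dataset(
        ds,
        species=spec.species,
        random_effect_on=spec.random_effect_on,
        estimation=spec.estimation,
        agq_nodes=spec.agq_nodes,
    )
    return model.ofv(params=params, **kwargs)


@dataclass(frozen=True)
class ModelComparison:
    delta_ofv: float
    threshold: float
    full_selected: bool
    added_parameter: str


def compare_models(fit_reduced: AllometricResults, fit_full: AllometricResults, threshold: float = LRT_THRESHOLD_1DF) -> ModelComparison:
    """Likelihood-ratio selection between nested fits differing by one parameter.

    The full model is selected iff OFV drops by at least 3.841
    (chi-square, alpha = 0.05, 1 df).
    """
    red, full = fit_reduced.spec, fit_full.spec
    if tuple(red.species) != tuple(full.species):
        raise ValueError("models are fit to different species sets; not nested")
    red_re, full_re = set(red.random_effect_on), set(full.random_effect_on)
    if not (red_re < full_re and len(full_re - red_re) == 1):
        raise ValueError("specs are not nested with exactly one added random effect")
    added = (full_re - red_re).pop()
    delta = fit_reduced.ofv - fit_full.ofv
    return ModelComparison(
        delta_ofv=float(delta),
        threshold=threshold,
        full_selected=bool(delta >= threshold),
        added_parameter=f"omega2_{added}",
    )


def scale_human_cl(cl_nonclinical, bw_source_kg, bw_target_kg=BODY_WEIGHTS_KG["human"], beta=0.85):
    """Fixed-exponent single-species scaling of weight-normalized CL.

    Per-kg form of CL_target = CL_source * (BW_target/BW_source)**beta:
    the per-kg value transforms with exponent (beta - 1).
    """
    cl = np.asarray(cl_nonclinical, dtype=float)
    if np.any(cl <= 0) or bw_source_kg <= 0 or bw_target_kg <= 0:
        raise ValueError("clearance and body weights must be positive")
    out = cl * (bw_target_kg / bw_source_kg) ** (beta - 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class ScalingResult:
    """Per-antibody observed vs scaled human CL and fold-error summary."""

    source_species: str
    beta: float
    antibodies: list[str]
    observed: np.ndarray  # human CL, mL/h/kg
    scaled: np.ndarray  # human CL scaled from the source species, mL/h/kg
    ratio: np.ndarray  # observed / scaled
    within_2fold: np.ndarray  # 0.5 <= ratio <= 2.0, bounds inclusive

    @property
    def n(self) -> int:
        return len(self.antibodies)

    @property
    def n_within(self) -> int:
        return int(self.within_2fold.sum())

    @property
    def fraction_within(self) -> float:
        return self.n_within / self.n

    @property
    def pct_within(self) -> float:
        return 100.0 * self.fraction_within

    @property
    def mean_ratio(self) -> float:
        return float(self.ratio.mean())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "antibody": self.antibodies,
                "observed_human_cl": self.observed,
                "scaled_human_cl": self.scaled,
                "ratio_obs_over_scaled": self.ratio,
                "within_2fold": self.within_2fold,
            }
        )


def fold_error_summary(ds: CrossSpeciesDataset, source_species: str, beta: float) -> ScalingResult:
    """Scale human CL from one non-clinical species; summarize 2-fold accuracy.

    Uses antibodies with CL in both the source species and human.  The
    2-fold band is inclusive: ratio in [0.5, 2.0] counts as within.
    """
    from .datasets import complete_cases

    names, src, obs = complete_cases(ds, source_species, "human", "CL")
    if len(names) == 0:
        raise ValueError("no antibodies with CL in both species")
    scaled = scale_human_cl(src, BODY_WEIGHTS_KG[source_species], BODY_WEIGHTS_KG["human"], beta)
    ratio = obs / scaled
    within = (ratio >= 0.5) & (ratio <= 2.0)
    return ScalingResult(
        source_species=source_species,
        beta=float(beta),
        antibodies=names,
        observed=obs,
        scaled=np.asarray(scaled),
        ratio=ratio,
        within_2fold=within,
    )


@dataclass
class BootstrapResult:
    """Cluster-bootstrap distributions of the model parameters."""

    n_replicates: int
    seed: int | None
    param_names: list[str]
    estimates: np.ndarray  # (n_ok, n_params) natural scale
    point_estimates: dict[str, float]
    n_failed: int

    @property
    def mean(self) -> dict[str, float]:
        return dict(zip(self.param_names, self.estimates.mean(axis=0)))

    @property
    def se(self) -> dict[str, float]:
        return dict(zip(self.param_names, self.estimates.std(axis=0, ddof=1)))

    def percentile_ci(self, level: float = 95.0) -> dict[str, tuple[float, float]]:
        lo, hi = (100 - level) / 2, 100 - (100 - level) / 2
        out = {}
        for k, nm in enumerate(self.param_names):
            out[nm] = tuple(np.percentile(self.estimates[:, k], [lo, hi]))
        return out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.estimates, columns=self.param_names)

    def summary(self) -> str:
        lines = [f"Cluster bootstrap: {self.n_replicates} replicates ({self.n_failed} failed), seed={self.seed}"]
        ci = self.percentile_ci()
        lines.append(f"{'parameter':<14}{'point':>10}{'boot mean':>11}{'boot SE':>10}{'95% CI':>24}")
        for nm in self.param_names:
            c = ci[nm]
            lines.append(
                f"{nm:<14}{self.point_estimates[nm]:>10.4g}{self.mean[nm]:>11.4g}{self.se[nm]:>10.3g}"
                f"   [{c[0]:.4g}, {c[1]:.4g}]"
            )
        return "\n".join(lines)


def _bootstrap_model(model: AllometricModel, fit: AllometricResults, n_replicates: int, seed: int | None, method: str):
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    spec = model.spec
    n = model.n_groups
    names = model.names
    # index observations by group for fast resampled-model construction
    by_group = [slice(model.ptr[g], model.ptr[g + 1] if g + 1 < n else len(model.y)) for g in range(n)]
    est, failed = [], 0
    warm = fit.theta.copy()
    for _ in range(n_replicates):
        idx = rng.integers(0, n, size=n)
        y, bw, lab = [], [], []
        for k, g in enumerate(idx):
            sl = by_group[g]
            y.append(model.y[sl])
            bw.append(model.bw[sl])
            lab.extend([f"rep{k}"] * (sl.stop - sl.start))
        try:
            bm = AllometricModel(np.concatenate(y), np.concatenate(bw), np.array(lab), spec)
            bf = bm.fit(start=warm, method=method, restarts=1, compute_se=False, xatol=1e-6, fatol=1e-8)
            if not bf.converged or not np.isfinite(bf.ofv):
                failed += 1
                continue
            est.append(list(bf.params.values()))
        except (ValueError, np.linalg.LinAlgError):
            failed += 1
    if not est:
        raise RuntimeError("all bootstrap replicates failed to converge")
    return BootstrapResult(
        n_replicates=n_replicates,
        seed=seed,
        param_names=spec.param_names(),
        estimates=np.asarray(est),
        point_estimates=fit.params,
        n_failed=failed,
    )


def bootstrap_fit(
    ds: CrossSpeciesDataset,
    species: Sequence[str],
    n_replicates: int = 2000,
    seed: int | None = None,
    method: str = "laplace",
    **spec_kwargs,
) -> BootstrapResult:
    """Fit, then cluster-bootstrap (resampling whole antibodies with replacement).

    The resampling pool is the full dataset; each replicate keeps the
    original dataset size and is refit on the complete-case observations
    it contains.  Failed replicates are counted, never silently dropped.
    """
    model = AllometricModel.from_dataset(ds, species=species, **spec_kwargs)
    fit = model.fit()
    return _bootstrap_model(model, fit, n_replicates=n_replicates, seed=seed, method=method)
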