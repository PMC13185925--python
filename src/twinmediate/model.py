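"""Multi-group FIML path-model fitting: Model and Results objects.

``PathModel`` binds a :class:`~twinmediate.ram.PathModelSpec` to data
(one frame of observed variables per group) and minimises the pooled
FIML deviance with a quasi-Newton optimizer, falling back on jittered
multi-starts.  ``PathModelResults`` carries estimates, Wald standard
errors from the inverse numerical Hessian, optional family-clustered
sandwich errors, likelihood-ratio tests, delta-method inference for
derived effects, and model-implied standardization.
"""

from __future__ import annotations

from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_fprime, approx_hess1

from .fiml import NONPD_PENALTY, PatternData
from .ram import PathModelSpec


class ConvergenceError(RuntimeError):
    pass


def lrt(full, nested, tol: float = 1e-4):
    """Likelihood-ratio test of a nested against a full model.

    Returns ``(chi2, df, p)`` with ``chi2 = nested.minus2ll -
    full.minus2ll``.  A materially negative chi-square indicates an
    optimization failure and raises; tiny negative values are clipped.
    """
    df = full.n_params - nested.n_params
    if df <= 0:
        raise ValueError("nested model must have fewer free parameters than full")
    chi2 = nested.minus2ll - full.minus2ll
    if chi2 < -tol * max(1.0, abs(full.minus2ll)):
        raise ConvergenceError(
            f"nested model fits better than full (chi2 = {chi2:.4g}); "
            "refit with more starts"
        )
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), p


class PathModel:
    """FIML estimator for a multi-group path model.

    Parameters
    ----------
    spec
        Compiled path-model specification.
    data
        Mapping from group name to a DataFrame containing (at least) the
        spec's observed columns; missing values are handled pattern-wise.
    """

    def __init__(self, spec: PathModelSpec, data: Mapping[str, pd.DataFrame]):
        self.spec = spec
        missing_groups = [g for g in spec.groups if g not in data]
        if missing_groups:
            raise ValueError(f"no data supplied for groups {missing_groups}")
        self._raw: dict[str, np.ndarray] = {}
        self._patterns: dict[str, PatternData] = {}
        for g in spec.groups:
            frame = data[g]
            absent = [c for c in spec.observed if c not in frame.columns]
            if absent:
                raise ValueError(f"group {g!r}: missing observed columns {absent}")
            y = frame[spec.observed].to_numpy(dtype=float)
            self._raw[g] = y
            self._patterns[g] = PatternData(y)
        self.n_used = {g: p.n_used for g, p in self._patterns.items()}
        if sum(self.n_used.values()) == 0:
            raise ValueError("no rows with any observed data")

    # ------------------------------------------------------------------
    def minus2ll(self, theta: np.ndarray) -> float:
        total = 0.0
        for g in self.spec.groups:
            sigma, mu = self.spec.implied_moments(theta, g)
            total += self._patterns[g].minus2ll(sigma, mu)
        return total

    def casewise_minus2ll(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        out = {}
        for g in self.spec.groups:
            sigma, mu = self.spec.implied_moments(theta, g)
            out[g] = self._patterns[g].casewise_minus2ll(sigma, mu, self._raw[g])
        return out

    # ------------------------------------------------------------------
    def fit(self, *, tol: float = 1e-8, max_iter: int = 2000, n_starts: int = 5,
            seed: int = 0, compute_se: bool = True,
            cluster: Mapping[str, np.ndarray] | None = None,
            start_values: np.ndarray | None = None) -> "PathModelResults":
        """Minimise the FIML deviance; jittered restarts on failure.

        ``cluster`` maps group name to per-row cluster ids for a CR1
        family-clustered sandwich covariance (useful when rows are
        individuals nested in families rather than independent pairs).
        """
        if self.spec.n_free == 0:
            raise ValueError("model has no free parameters")
        rng = np.random.default_rng(seed)
        x0 = self.spec.start_values() if start_values is None else np.asarray(
            start_values, float)
        bounds = self.spec.bounds()
        # precondition: optimize in units of the start magnitudes so that
        # variance and path parameters are comparably scaled
        scale = np.maximum(np.abs(x0), 0.1)
        lo = np.array([b[0] for b in bounds]) / scale
        hi = np.array([b[1] for b in bounds]) / scale
        sbounds = list(zip(lo, hi))

        def objective(u):
            return self.minus2ll(u * scale)

        u0 = x0 / scale
        best = None
        for attempt in range(max(1, n_starts)):
            us = u0 if attempt == 0 else u0 + rng.normal(
                scale=0.25 * (1.0 + np.abs(u0)))
            us = np.clip(us, lo, hi)
            res = optimize.minimize(
                objective, us, method="L-BFGS-B", bounds=sbounds,
                options={"ftol": tol, "gtol": 1e-7, "maxiter": max_iter,
                         "maxfun": 10 * max_iter},
            )
            ok = res.fun < NONPD_PENALTY / 10
            if best is None or (ok and res.fun < best.fun - 1e-10):
                best = res
            if ok and res.success:
                best = res if res.fun <= best.fun + 1e-10 else best
                break
        best.x = best.x * scale
        grad_norm = float(np.max(np.abs(np.atleast_1d(best.jac))))
        converged = bool(best.fun < NONPD_PENALTY / 10 and
                         (best.success or grad_norm < 1e-2))
        theta = np.asarray(best.x, float)

        cov = None
        cov_robust = None
        flat_idx: list[int] = []
        if compute_se and converged:
            hess = approx_hess1(theta, lambda t: 0.5 * self.minus2ll(t))
            cov, flat_idx = self._safe_inverse(hess)
            if cluster is not None and cov is not None:
                cov_robust = self._cluster_sandwich(theta, cov, cluster)
        return PathModelResults(
            model=self, params=theta, minus2ll=float(best.fun),
            converged=converged, gradient_norm=grad_norm, n_iter=int(best.nit),
            cov_params_arr=cov, cov_robust_arr=cov_robust,
            flat_param_idx=flat_idx,
        )

    @staticmethod
    def _safe_inverse(hess: np.ndarray) -> np.ndarray | None:
        """Invert the Hessian over its well-determined curvature directions.

        When a variance-component path sits at an effective boundary
        (e.g. a Cholesky diagonal at zero) the likelihood is locally
        flat, or numerically indefinite, along that direction; plainly
        inverting then pollutes every parameter's variance.  Dropping
        near-null and negative eigendirections yields the covariance
        conditional on the boundary solution — the conventional
        reporting choice for boundary twin-model fits.
        """
        if not np.all(np.isfinite(hess)):
            return None, []
        hess = 0.5 * (hess + hess.T)
        eigval, eigvec = np.linalg.eigh(hess)
        floor = 1e-8 * max(float(eigval.max()), 1.0)
        keep = eigval > floor
        if not keep.any():
            return None, list(range(hess.shape[0]))
        vec = eigvec[:, keep]
        cov = (vec / eigval[keep]) @ vec.T
        # parameters loading heavily on dropped directions: their reported
        # variances are conditional on those flat directions
        dropped = eigvec[:, ~keep]
        flat_idx = []
        if dropped.size:
            mass = (dropped ** 2).sum(axis=1)
            flat_idx = list(np.flatnonzero(mass > 0.25))
        return 0.5 * (cov + cov.T), flat_idx

    def _cluster_sandwich(self, theta, cov, cluster):
        """CR1 sandwich over cluster-level score contributions."""
        scores = []
        for g in self.spec.groups:
            ids = np.asarray(cluster[g])
            if ids.shape[0] != self._raw[g].shape[0]:
                raise ValueError(f"group {g!r}: cluster ids do not match rows")
            # jacobian of per-row loglik (= -0.5 * casewise m2ll) wrt theta
            jac = approx_fprime(
                theta, lambda t, g=g: -0.5 * self._casewise_group(t, g),
                centered=True)
            frame = pd.DataFrame(jac)
            frame["_c"] = ids
            scores.append(frame.groupby("_c").sum().to_numpy())
        score_mat = np.vstack(scores)
        n_clusters = score_mat.shape[0]
        if n_clusters < 2:
            raise ValueError("clustered covariance needs at least two clusters")
        meat = score_mat.T @ score_mat * (n_clusters / (n_clusters - 1))
        # cov approximates the inverse Hessian of -loglik
        return cov @ meat @ cov

    def _casewise_group(self, theta, g):
        sigma, mu = self.spec.implied_moments(theta, g)
        return self._patterns[g].casewise_minus2ll(sigma, mu, self._raw[g])


class PathModelResults:
    """Estimates, uncertainty and derived-effect inference for a fitted model."""

    def __init__(self, model, params, minus2ll, converged, gradient_norm,
                 n_iter, cov_params_arr=None, cov_robust_arr=None,
                 flat_param_idx=()):
        self.model = model
        self.spec = model.spec
        self.labels = model.spec.free_labels
        self.params = pd.Series(params, index=self.labels, name="estimate")
        self.minus2ll = minus2ll
        self.converged = converged
        self.gradient_norm = gradient_norm
        self.n_iter = n_iter
        self.n_params = len(self.labels)
        self.n_used = model.n_used
        self._cov = cov_params_arr
        self._cov_robust = cov_robust_arr
        #: parameters whose curvature direction was numerically flat
        #: (boundary or weakly identified); their SEs are conditional
        self.weakly_determined = [self.labels[i] for i in flat_param_idx]

    # -- information criteria -----------------------------------------
    @property
    def aic(self) -> float:
        return self.minus2ll + 2 * self.n_params

    @property
    def bic(self) -> float:
        n = sum(self.n_used.values())
        return self.minus2ll + np.log(n) * self.n_params

    # -- uncertainty --------------------------------------------------
    def cov_params(self, robust: bool = False) -> pd.DataFrame:
        arr = self._cov_robust if robust else self._cov
        if arr is None:
            raise ConvergenceError(
                "parameter covariance unavailable "
                + ("(no cluster ids supplied)" if robust else "(fit not converged)")
            )
        return pd.DataFrame(arr, index=self.labels, columns=self.labels)

    def se(self, robust: bool = False) -> pd.Series:
        var = np.diag(self.cov_params(robust).to_numpy())
        return pd.Series(np.sqrt(np.clip(var, 0, None)), index=self.labels, name="se")

    def conf_int(self, alpha: float = 0.05, robust: bool = False) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        se = self.se(robust)
        return pd.DataFrame(
            {"lower": self.params - z * se, "upper": self.params + z * se}
        )

    def pvalues(self, robust: bool = False) -> pd.Series:
        z = self.params / self.se(robust)
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.labels, name="p")

    # -- derived effects ----------------------------------------------
    def delta_method(self, fn: Callable[[pd.Series], float], *,
                     alpha: float = 0.05, robust: bool = False):
        """First-order delta-method inference for a scalar function of params.

        ``fn`` receives a Series indexed by parameter label.  Returns
        ``(value, se, (lower, upper))``.
        """
        theta = self.params.to_numpy()
        cov = self.cov_params(robust).to_numpy()

        def as_series(t):
            return fn(pd.Series(t, index=self.labels))

        value = float(as_series(theta))
        grad = approx_fprime(theta, as_series, centered=True).ravel()
        var = float(grad @ cov @ grad)
        se = np.sqrt(max(var, 0.0))
        z = stats.norm.ppf(1 - alpha / 2)
        return value, se, (value - z * se, value + z * se)

    # -- standardization ----------------------------------------------
    def implied_sds(self, group: str, theta=None) -> pd.Series:
        sigma_full, _ = self.spec.implied_moments(
            self.params.to_numpy() if theta is None else theta, group, full=True)
        sd = np.sqrt(np.clip(np.diag(sigma_full), 0, None))
        return pd.Series(sd, index=self.spec.variables)

    def std_path_fn(self, label: str, group: str | None = None):
        """Callable theta -> standardized value of a labelled path.

        Standardization rescales by the model-implied standard deviations
        of the path's tail (source) and head (destination) variables.
        """
        entries = self.spec.path_entries(label)
        if not entries:
            raise KeyError(f"{label!r} is not a directed-path parameter")
        g, src, dst, scale = entries[0] if group is None else next(
            e for e in entries if e[0] == group)
        k = self.labels.index(label)
        i_src = self.spec.variables.index(src)
        i_dst = self.spec.variables.index(dst)

        def fn(theta):
            t = np.asarray(theta, float)
            sigma_full, _ = self.spec.implied_moments(t, g, full=True)
            sd_src = np.sqrt(max(sigma_full[i_src, i_src], 0.0))
            sd_dst = np.sqrt(sigma_full[i_dst, i_dst])
            if sd_dst <= 0:
                raise ZeroDivisionError(f"zero implied variance for {dst!r}")
            return t[k] * scale * sd_src / sd_dst

        return fn

    def standardized_paths(self, labels=None, group=None, robust=False,
                           alpha=0.05) -> pd.DataFrame:
        """Standardized path coefficients with delta-method intervals."""
        labels = labels or [lab for lab in self.labels
                            if self.spec.path_entries(lab)]
        rows = []
        for lab in labels:
            fn = self.std_path_fn(lab, group)
            value, se, (lo, hi) = self.delta_method(
                lambda s, fn=fn: fn(s.to_numpy()), alpha=alpha, robust=robust)
            rows.append({"label": lab, "raw": self.params[lab], "std": value,
                         "se": se, "lower": lo, "upper": hi})
        return pd.DataFrame(rows).set_index("label")

    # -- reporting ----------------------------------------------------
    def lrt(self, nested) -> tuple[float, int, float]:
        return lrt(self, nested)

    def summary(self, robust: bool = False) -> str:
        lines = [
            "Path model fit (FIML)",
            "=" * 58,
            f"groups: {', '.join(f'{g} (n={n})' for g, n in self.n_used.items())}",
            f"-2lnL = {self.minus2ll:.3f}   params = {self.n_params}   "
            f"AIC = {self.aic:.2f}   BIC = {self.bic:.2f}",
            f"converged: {self.converged}   |grad| = {self.gradient_norm:.2e}",
        ]
        if self.weakly_determined:
            lines.append("weakly determined (conditional SEs): "
                         + ", ".join(self.weakly_determined))
        lines.append("-" * 58)
        try:
            tab = pd.DataFrame({
                "estimate": self.params,
                "se": self.se(robust),
            })
            ci = self.conf_int(robust=robust)
            tab["[0.025"] = ci["lower"]
            tab["0.975]"] = ci["upper"]
            lines.append(tab.to_string(float_format=lambda v: f"{v: .4f}"))
        except ConvergenceError:
            lines.append(self.params.to_string(float_format=lambda v: f"{v: .4f}"))
            lines.append("(standard errors unavailable)")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<PathModelResults: -2lnL={self.minus2ll:.2f}, "
                f"{self.n_params} params, converged={self.converged}>")
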