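"""Pattern-wise full-information maximum likelihood for Gaussian data.

Rows are grouped by their missing-data pattern; each pattern contributes
through its sufficient statistics (count, mean, scatter), so the -2 log
likelihood is exact FIML at the cost of one small Cholesky per pattern:

    -2 lnL = sum_p [ n_p (k_p log 2 pi + log|Sigma_p|)
                     + tr(Sigma_p^-1 W_p) + n_p d_p' Sigma_p^-1 d_p ]

with ``W_p`` the centred scatter and ``d_p`` the mean residual of
pattern ``p`` on its observed coordinates.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.linalg import cho_factor, cho_solve

_LOG2PI = math.log(2.0 * math.pi)

#: Penalty returned when an implied covariance is not positive definite;
#: large enough to repel the optimizer, finite so line searches recover.
NONPD_PENALTY = 1e12


class PatternData:
    """Sufficient statistics of one group's data, split by missing pattern."""

    def __init__(self, y: np.ndarray):
        y = np.asarray(y, dtype=float)
        self.n_rows, self.n_vars = y.shape
        observed = ~np.isnan(y)
        # drop rows with nothing observed
        keep = observed.any(axis=1)
        y, observed = y[keep], observed[keep]
        self.n_used = int(keep.sum())
        self.patterns: list[tuple[np.ndarray, int, np.ndarray, np.ndarray]] = []
        if self.n_used == 0:
            return
        codes = observed @ (1 << np.arange(self.n_vars, dtype=np.int64))
        for code in np.unique(codes):
            rows = y[codes == code]
            idx = np.flatnonzero(observed[codes == code][0])
            sub = rows[:, idx]
            n_p = sub.shape[0]
            mean = sub.mean(axis=0)
            centred = sub - mean
            scatter = centred.T @ centred
            self.patterns.append((idx, n_p, mean, scatter))

    def minus2ll(self, sigma: np.ndarray, mu: np.ndarray) -> float:
        """-2 log likelihood; NONPD_PENALTY-scaled value if Sigma_p not PD."""
        total = 0.0
        for idx, n_p, mean, scatter in self.patterns:
            sig = sigma[np.ix_(idx, idx)]
            try:
                c, low = cho_factor(sig, lower=True)
            except np.linalg.LinAlgError:
                ev = np.linalg.eigvalsh(sig)
                return NONPD_PENALTY * (1.0 + float(np.abs(ev[ev < 0]).sum()))
            logdet = 2.0 * float(np.log(np.diag(c)).sum())
            d = mean - mu[idx]
            quad_mean = float(d @ cho_solve((c, low), d))
            quad_scatter = float(np.trace(cho_solve((c, low), scatter)))
            total += n_p * (len(idx) * _LOG2PI + logdet + quad_mean) + quad_scatter
        return total

    def casewise_minus2ll(self, sigma, mu, y: np.ndarray) -> np.ndarray:
        """Per-row -2 log likelihood contributions (for score-based inference)."""
        y = np.asarray(y, dtype=float)
        out = np.zeros(y.shape[0])
        observed = ~np.isnan(y)
        codes = observed @ (1 << np.arange(y.shape[1], dtype=np.int64))
        for code in np.unique(codes):
            mask = codes == code
            idx = np.flatnonzero(observed[mask][0])
            if idx.size == 0:
                continue
            sub = y[mask][:, idx]
            sig = sigma[np.ix_(idx, idx)]
            c, low = cho_factor(sig, lower=True)
            logdet = 2.0 * float(np.log(np.diag(c)).sum())
            resid = sub - mu[idx]
            solved = cho_solve((c, low), resid.T).T
            quad = np.einsum("ij,ij->i", resid, solved)
            out[mask] = idx.size * _LOG2PI + logdet + quad
        return out
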