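"""Two-factor exploratory factor analysis over the mediator battery.

Maximum-likelihood extraction (via scikit-learn's FactorAnalysis)
followed by promax rotation, yielding an oblique pattern matrix and the
factor correlation.  Operates on Pearson correlations of the composite
scores, consistent with the downstream models which treat composites as
continuous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import FactorAnalysis

from .cohort import TwinCohort


@dataclass
class FactorSolution:
    loadings: pd.DataFrame          # pattern matrix, variables x factors
    factor_correlation: float
    method_tag: str
    communalities: pd.Series
    n_used: int

    def assign_factors(self) -> pd.Series:
        """Dominant factor per variable (by absolute pattern loading)."""
        return self.loadings.abs().idxmax(axis=1)


def _varimax(lam: np.ndarray, max_iter: int = 200, tol: float = 1e-8) -> np.ndarray:
    """Orthogonal varimax rotation matrix for a loading matrix."""
    p, k = lam.shape
    rot = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        lrot = lam @ rot
        grad = lam.T @ (lrot ** 3 - lrot @ np.diag((lrot ** 2).sum(axis=0)) / p)
        u, s, vt = np.linalg.svd(grad)
        rot = u @ vt
        var_new = s.sum()
        if var_new - var_old < tol:
            break
        var_old = var_new
    return rot


def _promax(lam: np.ndarray, power: int = 4):
    """Promax oblique rotation: least-squares fit to a varimax target
    raised to a power, normalised so factors keep unit variance.

    Returns the pattern matrix and the factor correlation matrix.
    """
    # Kaiser-normalize rows for the varimax step, then restore scale
    h = np.sqrt((lam ** 2).sum(axis=1))
    h[h == 0] = 1.0
    lam_n = lam / h[:, None]
    vmax = (lam_n @ _varimax(lam_n)) * h[:, None]
    target = np.abs(vmax) ** power * np.sign(vmax)
    u, *_ = np.linalg.lstsq(vmax, target, rcond=None)
    d = np.diag(np.linalg.inv(u.T @ u))
    u = u * np.sqrt(d)              # U <- U diag(sqrt(d))
    pattern = vmax @ u
    ui = np.linalg.inv(u)
    phi = ui @ ui.T
    return pattern, phi


def efa_two_factor(data: TwinCohort | pd.DataFrame, mediators=None,
                   rotate: bool = True) -> FactorSolution:
    """Two-factor ML EFA with promax rotation on mediator composites.

    ``data`` may be a cohort (mediator columns selected automatically)
    or a plain DataFrame of variables.  Complete cases are used for the
    extraction; at least three variables are required.
    """
    if isinstance(data, TwinCohort):
        frame = data.data[mediators or data.mediator_columns]
    else:
        frame = data[mediators] if mediators is not None else data
    frame = frame.dropna()
    if frame.shape[1] < 3:
        raise ValueError("factor analysis needs at least three variables")
    if len(frame) <= frame.shape[1]:
        raise ValueError("too few complete rows for factor extraction")
    corr = np.corrcoef(frame.to_numpy(float), rowvar=False)
    eigmin = float(np.linalg.eigvalsh(corr)[0])
    if eigmin <= 1e-10:
        raise ValueError(
            "correlation matrix of the mediators is not positive definite "
            f"(min eigenvalue {eigmin:.2e}); consider smoothing or dropping "
            "collinear scales")
    z = (frame - frame.mean()) / frame.std(ddof=1)
    fa = FactorAnalysis(n_components=2, svd_method="lapack")
    fa.fit(z.to_numpy(float))
    lam = fa.components_.T  # variables x 2, unrotated ML loadings
    if rotate:
        pattern, phi_mat = _promax(lam)
        phi = float(phi_mat[0, 1])
        tag = "ml+promax"
    else:
        pattern, phi, tag = lam, 0.0, "ml"
    # orient each factor so its largest-magnitude loading is positive
    for k in range(pattern.shape[1]):
        j = np.argmax(np.abs(pattern[:, k]))
        if pattern[j, k] < 0:
            pattern[:, k] *= -1.0
            # flipping one factor flips the correlation sign
            phi = -phi if pattern.shape[1] == 2 else phi
    loadings = pd.DataFrame(pattern, index=frame.columns,
                            columns=["factor1", "factor2"])
    comm = (loadings ** 2).sum(axis=1).clip(upper=1.0)
    return FactorSolution(
        loadings=loadings, factor_correlation=float(np.clip(phi, -0.999, 0.999)),
        method_tag=tag, communalities=comm, n_used=len(frame),
    )


def factor_groups(solution: FactorSolution, min_per_factor: int = 2
                  ) -> dict[str, list[str]]:
    """Indicator groups per factor, ordered by loading strength.

    Variables go to their dominant factor; within each factor they are
    sorted by absolute pattern loading (descending), so the first
    indicator is a sensible marker for factor scaling.  If a factor ends
    up with fewer than ``min_per_factor`` indicators, the weakest
    members of the other factor are reassigned.
    """
    assign = solution.assign_factors()
    groups = {
        f: sorted(
            [v for v in assign.index if assign[v] == f],
            key=lambda v: -abs(solution.loadings.loc[v, f]))
        for f in solution.loadings.columns
    }
    names = list(groups)
    for f in names:
        other = next(o for o in names if o != f)
        while len(groups[f]) < min_per_factor and \
                len(groups[other]) > min_per_factor:
            groups[f].append(groups[other].pop())
    return groups


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker's congruence between two loading vectors (sign-invariant)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    return float(abs(a @ b) / np.sqrt((a @ a) * (b @ b)))


def congruence_matched(est: pd.DataFrame, truth: np.ndarray) -> float:
    """Minimum Tucker congruence after best column matching.

    Compares an estimated pattern matrix with a generating loading
    matrix up to column permutation and sign.
    """
    est_arr = est.to_numpy(float)
    truth = np.asarray(truth, float)
    k = truth.shape[1]
    best = -np.inf
    from itertools import permutations

    for perm in permutations(range(k)):
        cong = min(tucker_congruence(est_arr[:, j], truth[:, perm[j]])
                   for j in range(k))
        best = max(best, cong)
    return best
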