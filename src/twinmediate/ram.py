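"""RAM-notation path-model specification.

A model over observed and latent variables is held as three matrices per
group: ``A`` (directed paths, acyclic), ``S`` (symmetric covariances)
and ``m`` (means), with a selection filter picking out the observed
variables.  Entries are fixed values or labelled free parameters; a
label shared across entries (or groups) imposes an equality constraint,
optionally scaled per entry (e.g. a dizygotic cross-twin genetic
covariance of ``0.5 * rho_g``).  The model-implied moments are

    Sigma = F (I - A)^-1 S (I - A)^-T F',   mu = F (I - A)^-1 m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class StructuralError(ValueError):
    """Raised for cyclic path structures or singular systems."""


@dataclass
class Parameter:
    label: str
    start: float
    lower: float = -np.inf
    upper: float = np.inf


class PathModelSpec:
    """Multi-group structural path model with labelled equality constraints."""

    def __init__(self, observed, latent=(), groups=("all",)):
        self.observed = list(observed)
        self.latent = list(latent)
        self.variables = self.observed + self.latent
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("variable names must be unique across observed and latent")
        self.groups = list(groups)
        self._idx = {v: i for i, v in enumerate(self.variables)}
        # entry key: (matrix, i, j, group) -> (label | None, value, scale)
        self._entries: dict[tuple, tuple] = {}
        self.params: dict[str, Parameter] = {}
        self._compiled = None

    # -- building -----------------------------------------------------
    def _register(self, label, start, lower, upper):
        if label not in self.params:
            self.params[label] = Parameter(label, float(start), lower, upper)

    def _add(self, matrix, v1, v2, *, value=None, label=None, start=0.1,
             lower=-np.inf, upper=np.inf, scale=1.0, group=None):
        if (value is None) == (label is None):
            raise ValueError("specify exactly one of value= (fixed) or label= (free)")
        i, j = self._idx[v1], self._idx[v2]
        if matrix == "S" and i < j:
            i, j = j, i
        groups = self.groups if group is None else [group]
        for g in groups:
            if g not in self.groups:
                raise ValueError(f"unknown group {g!r}")
            key = (matrix, i, j, g)
            if key in self._entries:
                raise ValueError(
                    f"duplicate {matrix} entry for ({v1}, {v2}) in group {g!r}"
                )
            self._entries[key] = (label, value, float(scale))
        if label is not None:
            self._register(label, start, lower, upper)
        self._compiled = None

    def add_path(self, src, dst, **kw):
        """Directed path src -> dst (coefficient sits in A[dst, src])."""
        self._add("A", dst, src, **kw)

    def add_cov(self, v1, v2, **kw):
        self._add("S", v1, v2, **kw)

    def add_var(self, v, **kw):
        self._add("S", v, v, **kw)

    def add_mean(self, v, **kw):
        self._add("M", v, v, **kw)

    # -- compilation --------------------------------------------------
    @property
    def free_labels(self) -> list[str]:
        return list(self.params)

    @property
    def n_free(self) -> int:
        return len(self.params)

    def start_values(self) -> np.ndarray:
        return np.array([p.start for p in self.params.values()])

    def bounds(self) -> list[tuple[float, float]]:
        return [(p.lower, p.upper) for p in self.params.values()]

    def _check_acyclic(self):
        n = len(self.variables)
        adj = [[] for _ in range(n)]
        for (matrix, i, j, _g), _ in self._entries.items():
            if matrix == "A":
                adj[j].append(i)  # edge j -> i
        state = [0] * n
        stack: list[int] = []

        def visit(u):
            state[u] = 1
            stack.append(u)
            for w in adj[u]:
                if state[w] == 1:
                    cycle = stack[stack.index(w):] + [w]
                    names = " -> ".join(self.variables[k] for k in cycle)
                    raise StructuralError(f"directed paths contain a cycle: {names}")
                if state[w] == 0:
                    visit(w)
            state[u] = 2
            stack.pop()

        for u in range(n):
            if state[u] == 0:
                visit(u)

    def compile(self):
        """Freeze entries into fixed base matrices plus sparse free updates."""
        if self._compiled is not None:
            return self._compiled
        self._check_acyclic()
        n = len(self.variables)
        pidx = {lab: k for k, lab in enumerate(self.params)}
        comp = {}
        for g in self.groups:
            A0 = np.zeros((n, n))
            S0 = np.zeros((n, n))
            M0 = np.zeros(n)
            upd = {"A": [], "S": [], "M": []}
            for (matrix, i, j, grp), (label, value, scale) in self._entries.items():
                if grp != g:
                    continue
                if label is None:
                    if matrix == "A":
                        A0[i, j] = value * scale
                    elif matrix == "S":
                        S0[i, j] = value * scale
                        S0[j, i] = value * scale
                    else:
                        M0[i] = value * scale
                else:
                    upd[matrix].append((i, j, pidx[label], scale))
            comp[g] = (A0, S0, M0, {k: np.array(v, dtype=float).reshape(-1, 4)
                                    for k, v in upd.items()})
        obs_idx = np.array([self._idx[v] for v in self.observed])
        self._compiled = (comp, obs_idx)
        return self._compiled

    def matrices(self, theta, group):
        comp, _ = self.compile()
        A0, S0, M0, upd = comp[group]
        A = A0.copy()
        S = S0.copy()
        M = M0.copy()
        for i, j, k, scale in upd["A"]:
            A[int(i), int(j)] = theta[int(k)] * scale
        for i, j, k, scale in upd["S"]:
            v = theta[int(k)] * scale
            S[int(i), int(j)] = v
            S[int(j), int(i)] = v
        for i, j, k, scale in upd["M"]:
            M[int(i)] = theta[int(k)] * scale
        return A, S, M

    def implied_moments(self, theta, group, full=False):
        """Model-implied covariance and mean vector for one group.

        With ``full=True`` the moments over all variables (latent
        included) are returned, as needed for standardization.
        """
        _, obs_idx = self.compile()
        A, S, M = self.matrices(np.asarray(theta, float), group)
        n = A.shape[0]
        try:
            B = np.linalg.solve(np.eye(n) - A, np.eye(n))
        except np.linalg.LinAlgError as exc:
            raise StructuralError("(I - A) is singular") from exc
        sigma = B @ S @ B.T
        sigma = 0.5 * (sigma + sigma.T)
        mu = B @ M
        if full:
            return sigma, mu
        return sigma[np.ix_(obs_idx, obs_idx)], mu[obs_idx]

    def path_entries(self, label):
        """All (group, src, dst, scale) locations where a label sits in A."""
        out = []
        for (matrix, i, j, g), (lab, _v, scale) in self._entries.items():
            if matrix == "A" and lab == label:
                out.append((g, self.variables[j], self.variables[i], scale))
        return out
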