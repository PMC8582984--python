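"""Optimal-scaling categorical PCA (princals-style alternating least squares).

The model assigns each category of each variable a numeric quantification
and each variable a p-vector of component loadings, chosen so that the
rank-one expansion ``G_j z_j a_j'`` of every variable is as close as possible
(least squares) to a common matrix of object scores X with X'X = n I:

    sigma(X, z, a) = (1/m) * sum_j || X - G_j z_j a_j' ||^2

where G_j is variable j's indicator matrix.  Scaling levels restrict z_j:
*nominal* leaves it free, *ordinal* forces it monotone in the category order
(weighted isotonic regression), *numeric* fixes it to the standardized
category values, which makes the procedure identical to classical PCA on the
standardized data — the property used as this module's oracle.

The object-score update uses the orthogonal Procrustes projection, which is
the exact minimiser over centred column-orthonormal X, so the loss sequence
is non-increasing by construction.  After convergence the solution is
rotated to its principal axes so components come out in decreasing
variance-accounted-for (VAF) order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

LEVELS = ("nominal", "ordinal", "numeric")


@dataclass
class ScalingSpec:
    """Fitting options for :func:`fit_princals`.

    scaling may be a single level applied to every variable or a sequence
    with one level per variable.
    """

    scaling: object = "ordinal"
    ndim: int = 2
    tol: float = 1e-6
    max_iter: int = 500
    seed: int = 0

    def levels(self, m: int) -> list:
        levels = [self.scaling] * m if isinstance(self.scaling, str) else list(self.scaling)
        if len(levels) != m:
            raise ValueError(f"got {len(levels)} scaling levels for {m} variables")
        bad = sorted(set(levels) - set(LEVELS))
        if bad:
            raise ValueError(f"unknown scaling level(s) {bad}; expected {LEVELS}")
        return levels

    def __post_init__(self):
        if self.ndim < 1:
            raise ValueError("ndim must be >= 1")
        if self.tol <= 0:
            raise ValueError("tolerance must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class PrincalsModel:
    """Fitted optimal-scaling PCA solution."""

    object_scores: np.ndarray          # n x p, centred, X'X = n I, principal axes
    loadings: np.ndarray               # m x p, row j = a_j
    quantifications: list              # per variable: DataFrame(category, count, z)
    vaf: np.ndarray                    # p VAF shares in [0, 1], non-increasing
    loss_history: np.ndarray           # loss per iteration, non-increasing
    converged: bool
    n_iter: int
    variable_names: list
    spec: ScalingSpec

    @property
    def n(self) -> int:
        return self.object_scores.shape[0]

    @property
    def ndim(self) -> int:
        return self.object_scores.shape[1]

    def vaf_table(self) -> pd.DataFrame:
        cum = np.cumsum(self.vaf)
        return pd.DataFrame({
            "component": np.arange(1, self.ndim + 1),
            "vaf": self.vaf,
            "cumulative_vaf": cum,
        })


def _weighted_pava(y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted isotonic (non-decreasing) regression; pool-adjacent-violators."""
    vals = list(y[:1])
    wts = list(w[:1])
    counts = [1]
    for yi, wi in zip(y[1:], w[1:]):
        vals.append(yi)
        wts.append(wi)
        counts.append(1)
        while len(vals) > 1 and vals[-2] > vals[-1]:
            wtot = wts[-2] + wts[-1]
            vals[-2] = (wts[-2] * vals[-2] + wts[-1] * vals[-1]) / wtot
            wts[-2] = wtot
            counts[-2] += counts[-1]
            del vals[-1], wts[-1], counts[-1]
    return np.repeat(vals, counts)


def _codes_and_categories(data):
    """Factorise each column; categories in sorted order (defines ordinality)."""
    if isinstance(data, pd.DataFrame):
        names = [str(c) for c in data.columns]
        cols = [data[c].to_numpy() for c in data.columns]
    else:
        arr = np.asarray(data)
        if arr.ndim != 2:
            raise ValueError("data must be 2-D")
        names = [f"v{j}" for j in range(arr.shape[1])]
        cols = [arr[:, j] for j in range(arr.shape[1])]
    codes, cats = [], []
    for name, col in zip(names, cols):
        if pd.isna(col).any():
            raise ValueError(f"variable {name!r} has missing values")
        uniq, code = np.unique(col, return_inverse=True)
        codes.append(code)
        cats.append(uniq)
    return names, codes, cats


def fit_princals(data, spec: ScalingSpec | None = None) -> PrincalsModel:
    """Fit the alternating-least-squares optimal-scaling PCA.

    Parameters
    ----------
    data : array or DataFrame, shape (n, m)
        Categorical data; each column is one variable.  Category order (for
        ordinal/numeric levels) is the sorted order of the observed values.
    spec : ScalingSpec
        Scaling levels, dimensionality, convergence control and seed.
    """
    spec = spec or ScalingSpec()
    names, codes, cats = _codes_and_categories(data)
    n = len(codes[0])
    m = len(names)
    p = spec.ndim
    levels = spec.levels(m)

    for name, c in zip(names, cats):
        if len(c) < 2:
            raise ValueError(f"variable {name!r} is constant (single observed category)")
    if n <= p:
        raise ValueError(f"need n > ndim; got n={n}, ndim={p}")

    # stacked sparse indicator matrix over all variables' categories
    ks = np.array([len(c) for c in cats])
    offsets = np.concatenate([[0], np.cumsum(ks)])
    total = int(offsets[-1])
    col_idx = np.concatenate([codes[j] + offsets[j] for j in range(m)])
    row_idx = np.tile(np.arange(n), m)
    G = sparse.csr_matrix(
        (np.ones(n * m), (row_idx, col_idx)), shape=(n, total)
    )
    d = np.asarray(G.sum(axis=0)).ravel()  # category counts, all > 0

    # initial quantifications: standardized category values (z'Dz = n, z'd = 0)
    def _standardize(z, dj):
        z = z - (dj @ z) / n
        s = np.sqrt(dj @ z**2 / n)
        return z / s if s > 1e-12 else None

    zs = []
    for j in range(m):
        vals = cats[j]
        numeric_vals = pd.to_numeric(pd.Series(vals), errors="coerce").to_numpy(float)
        base = numeric_vals if not np.isnan(numeric_vals).any() else np.arange(ks[j], dtype=float)
        z = _standardize(base, d[offsets[j]:offsets[j + 1]])
        if z is None:
            raise ValueError(f"variable {names[j]!r} has degenerate category values")
        zs.append(z)
        if levels[j] == "numeric" and np.isnan(numeric_vals).any():
            raise ValueError(f"variable {names[j]!r}: numeric level needs numeric categories")

    rng = np.random.default_rng(spec.seed)
    X = rng.standard_normal((n, p))
    X -= X.mean(axis=0)
    Q, _ = np.linalg.qr(X)
    X = np.sqrt(n) * Q

    A = np.zeros((m, p))
    W = np.zeros((total, p))
    loss_history = []
    converged = False

    for iteration in range(spec.max_iter):
        M = G.T @ X  # total x p; block j = G_j' X
        for j in range(m):
            sl = slice(offsets[j], offsets[j + 1])
            Mj = M[sl]
            dj = d[sl]
            z = zs[j]
            a = Mj.T @ z / n
            if levels[j] != "numeric":
                denom = a @ a
                if denom > 1e-24:
                    z_t = (Mj / dj[:, None]) @ a / denom
                    if levels[j] == "ordinal":
                        z_up = _weighted_pava(z_t, dj)
                        z_dn = -_weighted_pava(-z_t, dj)
                        sse_up = dj @ (z_t - z_up) ** 2
                        sse_dn = dj @ (z_t - z_dn) ** 2
                        flip = sse_dn < sse_up
                        z_t = -z_dn if flip else z_up
                    else:
                        flip = False
                    z_new = _standardize(z_t, dj)
                    if z_new is not None:
                        z = z_new
                        if flip:
                            a = -a
                    # else: restriction collapsed; keep previous quantification
                zs[j] = z
                a = Mj.T @ z / n  # optimal loadings for the final z
            A[j] = a
            W[sl] = np.outer(z, a)

        GW = G @ W
        Xhat = GW - GW.mean(axis=0)
        U, _, Vt = np.linalg.svd(Xhat, full_matrices=False)
        X = np.sqrt(n) * (U @ Vt)

        loss = (m * n * p - 2.0 * np.sum(X * GW) + np.sum(d[:, None] * W**2)) / (n * m)
        loss_history.append(loss)
        if iteration > 0 and loss_history[-2] - loss < spec.tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"princals did not converge in {spec.max_iter} iterations"
            f" (last loss decrease {loss_history[-2] - loss_history[-1]:.2e})"
            if len(loss_history) > 1 else "princals did not converge",
            stacklevel=2,
        )

    # rotate to principal axes: diagonalise A'A, order by decreasing variance
    evals, evecs = np.linalg.eigh(A.T @ A)
    order = np.argsort(evals)[::-1]
    T = evecs[:, order]
    # deterministic sign: make each rotated loading column sum non-negative
    signs = np.sign((A @ T).sum(axis=0))
    signs[signs == 0] = 1.0
    T = T * signs
    X = X @ T
    A = A @ T
    vaf = np.maximum(evals[order], 0.0) / m

    quantifications = [
        pd.DataFrame({
            "category": cats[j],
            "count": d[offsets[j]:offsets[j + 1]].astype(int),
            "quantification": zs[j],
        })
        for j in range(m)
    ]

    return PrincalsModel(
        object_scores=X,
        loadings=A,
        quantifications=quantifications,
        vaf=vaf,
        loss_history=np.asarray(loss_history),
        converged=converged,
        n_iter=len(loss_history),
        variable_names=names,
        spec=spec,
    )


def select_components(model: PrincalsModel, variance_threshold: float = 0.8
                      ) -> np.ndarray:
    """Leading object-score columns reaching the cumulative-VAF threshold.

    k is the smallest number of components whose cumulative VAF share is
    >= the threshold (inclusive).  If the fitted components cannot reach it,
    an error advises refitting with a larger dimensionality.
    """
    if not 0 < variance_threshold <= 1:
        raise ValueError("variance_threshold must be in (0, 1]")
    cum = np.cumsum(model.vaf)
    reach = np.nonzero(cum >= variance_threshold - 1e-12)[0]
    if len(reach) == 0:
        raise ValueError(
            f"fitted {model.ndim} components explain only {cum[-1]:.3f} of the"
            f" variance (< {variance_threshold}); refit with a larger ndim"
        )
    k = int(reach[0]) + 1
    return model.object_scores[:, :k]
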