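"""Genomic relationship matrices, REML variance components, and BLUP.

The mixed model is

.. math::

    y = Xb + g + \\epsilon,\\qquad
    g \\sim N(0, G\\sigma_g^2),\\qquad
    \\epsilon \\sim N(0, I\\sigma_e^2),

with fixed effects (intercept, sex, slaughter age) in ``X`` and the
relationship matrix ``G`` built from marker or haplotype-allele dosages.

Two GRM constructions are offered.  ``vanraden1`` (default) divides the
cross-product of the *centered* design by :math:`2\\sum_j p_j(1-p_j)` —
the standard allele-frequency-weighted construction whose diagonal
averages ~1 for unrelated individuals.  ``paper_literal`` applies the same
divisor to the centered-*and-scaled* design, reproducing the printed
formula pair :math:`G = MM'/2\\sum p(1-p)` with
:math:`m_{ij} = (x_{ij}-2p_j)/\\sqrt{2p_j(1-p_j)}`; this double-scales
relative to either standard construction and is kept for faithfulness.

REML exploits the single genetic variance component: after projecting out
the fixed effects, one eigendecomposition of the projected ``G`` reduces
the restricted likelihood to a cheap one-dimensional profile in the
variance ratio :math:`\\lambda = \\sigma_g^2/\\sigma_e^2`, maximized by a
grid pass plus bounded refinement.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .hapcode import DiplotypeMatrix, standardize


class ConvergenceError(RuntimeError):
    """REML failed to converge; carries the likelihood trace."""

    def __init__(self, msg, trace=None):
        super().__init__(msg)
        self.trace = trace or []


@dataclass
class GRM:
    """Symmetric genomic relationship matrix with construction metadata."""

    values: np.ndarray
    mode: str
    scale_const: float
    n_markers: int
    ridge: float = 0.0

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def diag_mean(self) -> float:
        return float(np.mean(np.diag(self.values)))


@dataclass
class MixedModelSpec:
    """Aligned observation vector and fixed-effect design for one trait."""

    y: np.ndarray
    X: np.ndarray
    ids: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X rows must align with y")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("fixed-effect design is rank deficient")


@dataclass
class VarianceEstimate:
    sigma_g2: float
    sigma_e2: float
    h2: float
    se_h2: float
    se_sigma_g2: float
    se_sigma_e2: float
    loglik: float
    n_iter: int
    converged: bool
    boundary: bool = False
    trace: list = field(default_factory=list)


@dataclass
class BlupSolution:
    beta: np.ndarray
    g_hat: np.ndarray
    gebv: np.ndarray
    u_hat: np.ndarray | None = None


def fixed_effects_design(pheno, trait: str):
    """Build a MixedModelSpec (intercept + sex indicator + age) for a trait.

    Rows with a missing trait value are dropped.
    """
    df = pheno.data
    keep = df[trait].notna()
    df = df.loc[keep]
    sex = pd.Categorical(df["sex"])
    X = np.column_stack(
        [
            np.ones(len(df)),
            (sex.codes == 1).astype(float) if len(sex.categories) > 1
            else np.zeros(len(df)),
            df["age"].to_numpy(dtype=float),
        ]
    )
    if len(sex.categories) == 1:
        X = X[:, [0, 2]]  # drop degenerate sex column
    return MixedModelSpec(df[trait].to_numpy(dtype=float), X, df["id"].to_numpy())


def build_grm(
    m: DiplotypeMatrix | np.ndarray,
    mode: str = "vanraden1",
    freqs: np.ndarray | None = None,
    ridge_eps: float = 1e-6,
    min_eig: float = 1e-8,
) -> GRM:
    """Construct G from a dosage design (DiplotypeMatrix or raw array).

    Fixed columns are dropped before scaling.  If the smallest eigenvalue
    of the result falls below ``min_eig``, ``ridge_eps`` is added to the
    diagonal (recorded in ``GRM.ridge``) so downstream solves are stable.
    """
    if isinstance(m, DiplotypeMatrix):
        X, p = m.X, m.freqs
    else:
        X = np.asarray(m, dtype=float)
        if freqs is None:
            p = X.sum(axis=0) / (2 * X.shape[0])
        else:
            p = np.asarray(freqs, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 marker columns")
    smode = "centered" if mode == "vanraden1" else "centered_scaled"
    if mode not in ("vanraden1", "paper_literal"):
        raise ValueError(f"unknown GRM mode {mode!r}")
    M, keep, _ = standardize(X, p, smode)
    c = float(2 * np.sum(p[keep] * (1 - p[keep])))
    if c <= 0 or keep.size == 0:
        raise ValueError("degenerate scaling constant: all markers fixed")
    G = (M @ M.T) / c
    G = (G + G.T) / 2
    ridge = 0.0
    w = np.linalg.eigvalsh(G)
    if w[0] < min_eig:
        ridge = ridge_eps
        G = G + ridge * np.eye(G.shape[0])
    return GRM(G, mode, c, int(keep.size), ridge)


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------


def _project_out(X: np.ndarray, G: np.ndarray, y: np.ndarray):
    """Eigen-structure of G restricted to the orthocomplement of col(X)."""
    n, p = X.shape
    Q, _ = np.linalg.qr(X, mode="complete")
    A = Q[:, p:]  # n x (n-p) orthonormal basis of the residual space
    GA = A.T @ G @ A
    xi, U = np.linalg.eigh((GA + GA.T) / 2)
    xi = np.clip(xi, 0.0, None)
    eta = U.T @ (A.T @ y)
    return xi, eta, n - p


def _restricted_ll(lam: float, xi: np.ndarray, eta: np.ndarray, df: int) -> float:
    """Profile restricted log-likelihood at variance ratio lam = sg2/se2.

    The residual variance is profiled out analytically.
    """
    d = lam * xi + 1.0
    s2 = float(np.sum(eta * eta / d)) / df
    return -0.5 * (df * (np.log(2 * np.pi * s2) + 1.0) + float(np.sum(np.log(d))))


def reml_fit(
    spec: MixedModelSpec,
    G: GRM | np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 200,
    grid: tuple = (-6.0, 6.0, 49),
) -> VarianceEstimate:
    """Estimate (sigma_g^2, sigma_e^2) by REML via a 1-D profile search.

    A log10 grid over the variance ratio locates the basin; bounded Brent
    refinement drives the restricted log-likelihood change below ``tol``.
    Estimates at the search boundary are clamped to zero genetic (or
    residual) variance.  Standard errors come from the observed
    information of the restricted likelihood in (sigma_g^2, sigma_e^2),
    with the h^2 SE by the delta method.
    """
    Gm = G.values if isinstance(G, GRM) else np.asarray(G, dtype=float)
    xi, eta, df = _project_out(spec.X, Gm, spec.y)

    trace: list[float] = []
    best = -np.inf

    def ll_of_log10(t: float) -> float:
        nonlocal best
        v = _restricted_ll(10.0 ** t, xi, eta, df)
        best = max(best, v)
        trace.append(best)
        return v

    lo, hi, npts = grid
    ts = np.linspace(lo, hi, int(npts))
    vals = [ll_of_log10(t) for t in ts]
    i = int(np.argmax(vals))

    boundary = False
    if i == 0 and vals[0] >= vals[1] - tol:
        lam = 0.0
        boundary = True
        ll = _restricted_ll(0.0, xi, eta, df)
        best = max(best, ll)
        trace.append(best)
    else:
        a = ts[max(i - 1, 0)]
        b = ts[min(i + 1, len(ts) - 1)]
        res = optimize.minimize_scalar(
            lambda t: -ll_of_log10(t),
            bounds=(a, b),
            method="bounded",
            options={"xatol": 1e-10, "maxiter": max_iter},
        )
        if not res.success and len(trace) >= max_iter:
            raise ConvergenceError("REML profile search did not converge", trace)
        lam = 10.0 ** float(res.x)
        ll = -float(res.fun)
        if i == len(ts) - 1 and abs(res.x - hi) < 1e-6:
            boundary = True  # essentially pure genetic variance

    d = lam * xi + 1.0
    sigma_e2 = float(np.sum(eta * eta / d)) / df
    sigma_g2 = lam * sigma_e2
    h2 = sigma_g2 / (sigma_g2 + sigma_e2) if (sigma_g2 + sigma_e2) > 0 else 0.0

    se_g, se_e, se_h2 = _reml_standard_errors(sigma_g2, sigma_e2, xi, eta)
    return VarianceEstimate(
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        h2=float(h2),
        se_h2=se_h2,
        se_sigma_g2=se_g,
        se_sigma_e2=se_e,
        loglik=ll,
        n_iter=len(trace),
        converged=True,
        boundary=boundary,
        trace=trace,
    )


def _reml_standard_errors(sg2, se2, xi, eta):
    """Observed-information SEs in (sigma_g^2, sigma_e^2) and for h^2."""
    w = sg2 * xi + se2
    if np.any(w <= 0):
        return np.nan, np.nan, np.nan
    e2 = eta * eta

    def hess(a, b):  # a, b are the per-eigenvalue derivatives of w
        return -0.5 * float(np.sum(-a * b / w**2 + 2 * a * b * e2 / w**3))

    H = np.array([[hess(xi, xi), hess(xi, 1.0)], [hess(xi, 1.0), hess(1.0, 1.0)]])
    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        return np.nan, np.nan, np.nan
    if np.any(np.diag(cov) < 0):
        return np.nan, np.nan, np.nan
    se_g, se_e = np.sqrt(np.diag(cov))
    tot = sg2 + se2
    grad = np.array([se2 / tot**2, -sg2 / tot**2])  # d h2 / d(sg2, se2)
    var_h2 = float(grad @ cov @ grad)
    return float(se_g), float(se_e), float(np.sqrt(max(var_h2, 0.0)))


# ---------------------------------------------------------------------------
# BLUP
# ---------------------------------------------------------------------------


def blup_gebv(spec: MixedModelSpec, G: GRM | np.ndarray, v: VarianceEstimate) -> BlupSolution:
    """Solve for fixed effects and genetic values at the REML estimates.

    ``beta`` is the GLS estimate; ``g_hat = sigma_g^2 G V^{-1}(y - X beta)``
    with ``V = G sigma_g^2 + I sigma_e^2``.  GEBVs for training individuals
    are ``g_hat`` itself.
    """
    if not v.converged:
        raise ValueError("variance estimate did not converge")
    Gm = G.values if isinstance(G, GRM) else np.asarray(G, dtype=float)
    n = Gm.shape[0]
    V = v.sigma_g2 * Gm + v.sigma_e2 * np.eye(n)
    try:
        cf = linalg.cho_factor(V)
    except linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            f"V singular (cond ~ {np.linalg.cond(V):.3g})"
        ) from e
    Viy = linalg.cho_solve(cf, spec.y)
    ViX = linalg.cho_solve(cf, spec.X)
    XtViX = spec.X.T @ ViX
    beta = np.linalg.solve(XtViX, spec.X.T @ Viy)
    resid = spec.y - spec.X @ beta
    g_hat = v.sigma_g2 * (Gm @ linalg.cho_solve(cf, resid))
    return BlupSolution(beta=beta, g_hat=g_hat, gebv=g_hat.copy())


def grm_solve(G: GRM | np.ndarray, b: np.ndarray, rcond: float = 1e-10) -> np.ndarray:
    """Apply the pseudo-inverse of the *un-ridged* G to a vector.

    A column-centered GRM is always singular (its rows sum to zero, so the
    all-ones vector is a null direction); genetic values from BLUP lie in
    the range of G because the GLS residuals are V^{-1}-orthogonal to the
    intercept, so the Moore-Penrose inverse is the exact generalized
    inverse for back-solving and prediction.  Any diagnostic ridge recorded
    on the GRM is removed before inverting.
    """
    if isinstance(G, GRM):
        Gm = G.values - G.ridge * np.eye(G.n)
    else:
        Gm = np.asarray(G, dtype=float)
    w, U = np.linalg.eigh((Gm + Gm.T) / 2)
    inv = np.where(w > rcond * w.max(), 1.0 / np.where(w > 0, w, 1.0), 0.0)
    return U @ (inv * (U.T @ b))


def backsolve_marker_effects(
    M: np.ndarray,
    G: GRM | np.ndarray,
    g_hat: np.ndarray,
    mode: str = "vanraden1",
    scale_const: float | None = None,
    n_individuals: int | None = None,
) -> np.ndarray:
    """Back-solve marker (haplotype-allele) effects from genetic values.

    ``vanraden1``: ``u = M' G^+ g_hat / c`` with ``c = 2 sum p(1-p)`` (the
    GRM scale constant), which makes ``M u = g_hat`` exact when G was built
    from this same centered M.  ``paper_literal`` divides by the number of
    individuals N instead, matching the printed back-solution.
    """
    Gm_shape = G.n if isinstance(G, GRM) else np.asarray(G).shape[0]
    if mode == "vanraden1":
        if scale_const is None:
            if not isinstance(G, GRM):
                raise ValueError("scale_const required when G is a bare array")
            scale_const = G.scale_const
        s = 1.0 / scale_const
    elif mode == "paper_literal":
        s = 1.0 / float(n_individuals or Gm_shape)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return s * (M.T @ grm_solve(G, g_hat))


def predict_new(G_new: np.ndarray, G: GRM | np.ndarray, g_hat: np.ndarray) -> np.ndarray:
    """GEBVs for new individuals from their relatedness rows to the
    training set: ``G_new G^+ g_hat`` (equivalently ``M_new u``)."""
    return np.asarray(G_new) @ grm_solve(G, g_hat)
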