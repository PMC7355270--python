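"""Independent pathway (biometric factor) models for twin data.

The independent pathway model replaces the free Cholesky covariance of each
variance component with a factor structure: per component (A, D, E) two
correlated common factors — one for hyperactivity-type and one for
inattention-type phenotypes — load directly on the phenotypes, and each
phenotype keeps a residual whose cross-twin correlation is free per
zygosity (absorbing residual genetic and environmental influences).  It is
fitted to raw twin data with the same FIML engine as the Cholesky model.

When a raw-data fit is infeasible (the source study's own attempt failed to
converge under heavy missingness), a confirmatory two-factor model can be
fitted directly to a printed genetic correlation matrix by unweighted least
squares — point estimates only, as the study did.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize

from .ade_model import ModelSpec
from .fiml_fit import (
    FitOptions,
    _PENALTY,
    _pack,
    numerical_hessian,
)
from . import fiml_fit

__all__ = [
    "FactorSpec",
    "IndependentPathwayResult",
    "CFAResult",
    "fit_independent_pathway",
    "fit_cfa_on_matrix",
]

_LOG2PI = float(np.log(2.0 * np.pi))

#: cross-twin weights (MZ, DZ) of the common-factor components
_WEIGHTS = {"A": (1.0, 0.5), "D": (1.0, 0.25), "E": (0.0, 0.0)}


@dataclass(frozen=True)
class FactorSpec:
    """Assignment of phenotypes to common factors and active components.

    ``factor_assignment`` maps every phenotype to one factor label (e.g.
    ``HYP`` or ``INATT``); ``components_with_factors`` lists which variance
    components carry the two-factor structure.  Residuals always have free
    variances and cross-twin correlations per zygosity.
    """

    factor_assignment: dict[str, str]
    components_with_factors: tuple[str, ...] = ("A", "D", "E")
    sex_effect: bool = True

    def __post_init__(self) -> None:
        bad = set(self.components_with_factors) - set("ADE")
        if bad:
            raise ValueError(f"unknown components: {sorted(bad)}")
        object.__setattr__(
            self,
            "components_with_factors",
            tuple(c for c in ("A", "D", "E") if c in self.components_with_factors),
        )

    @property
    def factors(self) -> tuple[str, ...]:
        seen: list[str] = []
        for f in self.factor_assignment.values():
            if f not in seen:
                seen.append(f)
        return tuple(seen)


@dataclass
class IndependentPathwayResult:
    spec: FactorSpec
    phenotypes: tuple[str, ...]
    loadings: dict[str, np.ndarray]  # per component, length M (own factor)
    factor_correlations: dict[str, float]
    residual_variances: np.ndarray
    residual_corr_mz: np.ndarray
    residual_corr_dz: np.ndarray
    intercepts: np.ndarray
    beta_sex: np.ndarray
    loglik: float
    n_pairs_used: int
    converged: bool
    gradient_norm: float
    n_params: int
    flat_directions: list[str] = field(default_factory=list)
    boundary_flags: list[str] = field(default_factory=list)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * np.log(self.n_pairs_used)


def _param_names(spec: FactorSpec, phenos: tuple[str, ...], sex: bool) -> list[str]:
    names = []
    for c in spec.components_with_factors:
        names += [f"loading_{c}[{p}]" for p in phenos]
        names += [f"factor_corr_{c}"]
    names += [f"resid_sd[{p}]" for p in phenos]
    names += [f"resid_corr_mz[{p}]" for p in phenos]
    names += [f"resid_corr_dz[{p}]" for p in phenos]
    names += [f"intercept[{p}]" for p in phenos]
    if sex:
        names += [f"beta_sex[{p}]" for p in phenos]
    return names


def fit_independent_pathway(
    data: pd.DataFrame,
    spec: FactorSpec,
    options: FitOptions | None = None,
) -> IndependentPathwayResult:
    """Fit the two-common-factor independent pathway model by FIML.

    Each component in ``components_with_factors`` contributes
    ``Lambda_c Phi_c Lambda_c'`` to the within-twin covariance, weighted by
    the zygosity's allele sharing cross twins (A: 1/0.5, D: 1/0.25, E: 0).
    Residuals contribute ``diag(v)`` within twins and ``diag(v * r_zyg)``
    cross twins.  Non-convergence is a legitimate outcome and is reported
    with the flattest likelihood directions named.
    """
    if options is None:
        options = FitOptions(n_starts=3)
    phenos = tuple(spec.factor_assignment.keys())
    factors = spec.factors
    if len(factors) < 1:
        raise ValueError("at least one factor required")
    m = len(phenos)
    fidx = np.array([factors.index(spec.factor_assignment[p]) for p in phenos])
    mspec = ModelSpec(
        phenotypes=phenos,
        teacher_rated=(False,) * m,
        components=("A", "D", "E"),
        rater=False,
        sex_effect=spec.sex_effect,
    )
    packed = _pack(data, mspec)
    n = max(packed.n_pairs, 1)
    ncomp = len(spec.components_with_factors)
    two_factor = len(factors) == 2

    # layout: per component [loadings (m), phi (1 if two factors)],
    # then resid_sd (m), r_mz (m), r_dz (m), intercepts (m), beta (m)
    sizes = ncomp * (m + (1 if two_factor else 0)) + 3 * m + m + (m if spec.sex_effect else 0)

    def unpack(x: np.ndarray):
        pos = 0
        lam: dict[str, np.ndarray] = {}
        phi: dict[str, float] = {}
        for c in spec.components_with_factors:
            lam[c] = x[pos : pos + m]
            pos += m
            if two_factor:
                phi[c] = float(x[pos])
                pos += 1
            else:
                phi[c] = 1.0
        v = x[pos : pos + m] ** 2
        pos += m
        rmz = x[pos : pos + m]
        pos += m
        rdz = x[pos : pos + m]
        pos += m
        inter = x[pos : pos + m]
        pos += m
        beta = x[pos : pos + m] if spec.sex_effect else np.zeros(m)
        return lam, phi, v, rmz, rdz, inter, beta

    onehot = np.zeros((m, max(len(factors), 1)))
    onehot[np.arange(m), fidx] = 1.0

    def sigma_blocks(x: np.ndarray):
        lam, phi, v, rmz, rdz, inter, beta = unpack(x)
        within = np.diag(v).astype(float)
        cross = {"MZ": np.diag(v * rmz), "DZ": np.diag(v * rdz)}
        for c in spec.components_with_factors:
            big = onehot * lam[c][:, None]  # M x F loading matrix
            if two_factor:
                phi_m = np.array([[1.0, phi[c]], [phi[c], 1.0]])
            else:
                phi_m = np.eye(onehot.shape[1])
            b = big @ phi_m @ big.T
            within += b
            wmz, wdz = _WEIGHTS[c]
            cross["MZ"] += wmz * b
            cross["DZ"] += wdz * b
        return within, cross, inter, beta

    def per_group_loglik(x: np.ndarray) -> float:
        within, cross, inter, beta = sigma_blocks(x)
        total = 0.0
        from scipy.linalg import cho_factor, cho_solve

        base = np.tile(inter, 2)
        for g in packed.groups:
            sig = np.block(
                [[within, cross[g.zygosity]], [cross[g.zygosity], within]]
            )[np.ix_(g.obs, g.obs)]
            try:
                c = cho_factor(sig, lower=True)
            except np.linalg.LinAlgError:
                return -np.inf
            mu_full = base[None, :] + np.concatenate(
                [np.outer(g.sex[:, 0], beta), np.outer(g.sex[:, 1], beta)], axis=1
            )
            r = g.y - mu_full[:, g.obs]
            quad = np.einsum("ij,ji->i", r, cho_solve(c, r.T))
            logdet = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
            total += float(
                np.sum(-0.5 * (len(g.obs) * _LOG2PI + logdet + quad))
            )
        return total

    def objective(x: np.ndarray) -> float:
        ll = per_group_loglik(x)
        return -ll / n if np.isfinite(ll) else _PENALTY

    # bounds: correlations inside (-1, 1); everything else free
    bounds = []
    for c in spec.components_with_factors:
        bounds += [(None, None)] * m
        if two_factor:
            bounds += [(-0.999, 0.999)]
    bounds += [(None, None)] * m  # resid sd
    bounds += [(-0.999, 0.999)] * (2 * m)
    bounds += [(None, None)] * m
    if spec.sex_effect:
        bounds += [(None, None)] * m

    # moment-ish start: equal loadings 0.5, phi 0.4, residual sd from data
    c1 = [f"{p}_1" for p in phenos]
    c2 = [f"{p}_2" for p in phenos]
    sd0 = np.nanstd(
        np.vstack([data[c1].to_numpy(float), data[c2].to_numpy(float)]), axis=0
    )
    sd0 = np.where(np.isfinite(sd0) & (sd0 > 0), sd0, 1.0)
    mean0 = np.nanmean(
        np.vstack([data[c1].to_numpy(float), data[c2].to_numpy(float)]), axis=0
    )
    x0_parts = []
    for c in spec.components_with_factors:
        x0_parts.append(0.5 * sd0)
        if two_factor:
            x0_parts.append([0.4])
    x0_parts += [0.6 * sd0, 0.2 * np.ones(m), 0.1 * np.ones(m), mean0]
    if spec.sex_effect:
        x0_parts.append(np.zeros(m))
    x0 = np.concatenate([np.atleast_1d(p) for p in x0_parts])
    assert len(x0) == sizes

    rng = np.random.default_rng(options.seed)
    best = None
    for k in range(options.n_starts):
        s = x0 if k == 0 else x0 * (
            1.0 + options.jitter * rng.standard_normal(len(x0))
        ) + 0.02 * rng.standard_normal(len(x0))
        res = minimize(
            objective,
            s,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": options.maxiter, "ftol": 1e-12, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res
    x = best.x.copy()

    # canonicalize signs: per component factor block, majority-positive loadings
    names = _param_names(spec, phenos, spec.sex_effect)
    pos = 0
    for c in spec.components_with_factors:
        lam = x[pos : pos + m]
        for f in range(len(factors)):
            sel = fidx == f
            if np.sum(np.sign(lam[sel])) < 0:
                lam[sel] *= -1.0
                # flipping one factor's loadings flips phi's sign
                if two_factor:
                    x[pos + m] *= -1.0
        x[pos : pos + m] = lam
        pos += m + (1 if two_factor else 0)
    # residual sds positive by convention
    x[pos : pos + m] = np.abs(x[pos : pos + m])

    ll = per_group_loglik(x)
    grad = fiml_fit._central_gradient(objective, x)
    gnorm = float(np.max(np.abs(grad)))
    # at active bounds the projected gradient matters, not the raw one
    at_bound = [
        i
        for i, (lo, hi) in enumerate(bounds)
        if (lo is not None and x[i] <= lo + 1e-9)
        or (hi is not None and x[i] >= hi - 1e-9)
    ]
    free_idx = [i for i in range(len(x)) if i not in at_bound]
    gnorm_free = float(np.max(np.abs(grad[free_idx]))) if free_idx else 0.0
    converged = bool(np.isfinite(ll)) and gnorm_free <= max(options.gtol, 1e-5)

    flat: list[str] = []
    boundary = [names[i] for i in at_bound]
    if not converged:
        hess = numerical_hessian(objective, x)
        w, vec = np.linalg.eigh(0.5 * (hess + hess.T))
        direction = vec[:, 0]
        order = np.argsort(-np.abs(direction))[:3]
        flat = [names[i] for i in order]
        warnings.warn(
            "independent pathway fit did not converge; flattest directions: "
            + ", ".join(flat)
        )
    if boundary:
        warnings.warn("parameters at a bound: " + ", ".join(boundary))

    lam, phi, v, rmz, rdz, inter, beta = unpack(x)
    return IndependentPathwayResult(
        spec=spec,
        phenotypes=phenos,
        loadings=lam,
        factor_correlations=phi,
        residual_variances=v,
        residual_corr_mz=rmz,
        residual_corr_dz=rdz,
        intercepts=inter,
        beta_sex=beta,
        loglik=float(ll),
        n_pairs_used=packed.n_pairs,
        converged=converged,
        gradient_norm=gnorm_free,
        n_params=len(x),
        flat_directions=flat,
        boundary_flags=boundary,
    )


# ---------------------------------------------------------------------------
# confirmatory factor fit to a printed correlation matrix
# ---------------------------------------------------------------------------


@dataclass
class CFAResult:
    phenotypes: tuple[str, ...]
    loadings: np.ndarray
    uniquenesses: np.ndarray
    factor_correlation: float
    discrepancy: float
    method: str
    heywood: list[str]
    n_starts_used: int


def _cfa_setup(corr: np.ndarray, factor_assignment: dict[str, str]):
    corr = np.asarray(corr, dtype=float)
    phenos = tuple(factor_assignment.keys())
    m = len(phenos)
    if corr.shape != (m, m):
        raise ValueError("correlation matrix does not match the assignment")
    if not np.allclose(corr, corr.T, atol=1e-8) or not np.allclose(
        np.diag(corr), 1.0, atol=1e-6
    ):
        raise ValueError("input must be a symmetric correlation matrix")
    factors: list[str] = []
    for f in factor_assignment.values():
        if f not in factors:
            factors.append(f)
    fidx = np.array([factors.index(factor_assignment[p]) for p in phenos])
    return corr, phenos, m, factors, fidx


def fit_cfa_on_matrix(
    corr: np.ndarray,
    factor_assignment: dict[str, str],
    method: str = "ml",
    n_starts: int = 20,
    seed: int = 0,
) -> CFAResult:
    """Two-factor confirmatory fit to a (genetic) correlation matrix.

    ``method="ml"`` (default) minimizes the normal-theory discrepancy
    ``log|Sigma| + tr(S Sigma^-1) - log|S| - M`` over loadings, the factor
    correlation and free uniquenesses, with
    ``Sigma = Lambda Phi Lambda' + diag(psi)``.  ``method="uls"`` minimizes
    the unweighted least-squares discrepancy
    ``sum_{i<j} (corr_ij - implied_ij)^2`` over loadings and the factor
    correlation; with only off-diagonal elements entering, uniquenesses are
    then determined as ``1 - loading^2``.  The two discrepancies weight the
    residuals differently and can prefer visibly different solutions on the
    same matrix; ML matches what mainstream SEM software computes on a
    correlation matrix.  Point estimates only (no standard errors); Heywood
    cases (|loading| > 1) are flagged but returned.
    """
    corr, phenos, m, factors, fidx = _cfa_setup(corr, factor_assignment)
    two = len(factors) == 2
    rng = np.random.default_rng(seed)
    if method == "uls":
        iu, ju = np.triu_indices(m, k=1)
        target = corr[iu, ju]
        same = (fidx[iu] == fidx[ju]).astype(float)

        def residuals(x: np.ndarray) -> np.ndarray:
            lam = x[:m]
            phi = x[m] if two else 1.0
            factor_w = np.where(same == 1.0, 1.0, phi)
            return lam[iu] * lam[ju] * factor_w - target

        best = None
        for k in range(n_starts):
            lam0 = np.full(m, 0.6) if k == 0 else rng.uniform(0.1, 0.95, size=m)
            phi0 = 0.5 if k == 0 else rng.uniform(-0.5, 0.95)
            x0 = np.concatenate([lam0, [phi0]]) if two else lam0
            lb = np.concatenate([np.full(m, -2.0), [-0.999]]) if two else np.full(m, -2.0)
            ub = np.concatenate([np.full(m, 2.0), [0.999]]) if two else np.full(m, 2.0)
            res = least_squares(residuals, x0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14)
            if best is None or res.cost < best.cost - 1e-15:
                best = res
        lam = best.x[:m].copy()
        phi = float(best.x[m]) if two else 1.0
        psi = None
        disc = float(2.0 * best.cost)
    elif method == "ml":
        onehot = np.zeros((m, len(factors)))
        onehot[np.arange(m), fidx] = 1.0
        sign_s, logdet_s = np.linalg.slogdet(corr)
        if sign_s <= 0:
            logdet_s = np.linalg.slogdet(corr + 1e-6 * np.eye(m))[1]

        def ml_obj(x: np.ndarray) -> float:
            lam = x[:m]
            phi_ = float(x[m]) if two else 1.0
            psi_ = x[m + (1 if two else 0):] ** 2
            big = onehot * lam[:, None]
            phi_m = np.array([[1.0, phi_], [phi_, 1.0]]) if two else np.eye(len(factors))
            sigma = big @ phi_m @ big.T + np.diag(psi_)
            sign, logdet = np.linalg.slogdet(sigma)
            if sign <= 0:
                return 1e6
            return logdet + float(np.trace(np.linalg.solve(sigma, corr))) - logdet_s - m

        bounds = [(-2.0, 2.0)] * m + ([(-0.999, 0.999)] if two else []) + [(1e-4, 2.0)] * m
        best = None
        for k in range(n_starts):
            lam0 = np.full(m, 0.6) if k == 0 else rng.uniform(0.1, 0.95, size=m)
            phi0 = [0.5 if k == 0 else rng.uniform(-0.5, 0.95)] if two else []
            psi0 = np.full(m, 0.7) if k == 0 else rng.uniform(0.3, 0.95, size=m)
            x0 = np.concatenate([lam0, phi0, psi0])
            res = minimize(ml_obj, x0, method="L-BFGS-B", bounds=bounds,
                           options={"maxiter": 2000, "ftol": 1e-14})
            if best is None or res.fun < best.fun - 1e-14:
                best = res
        lam = best.x[:m].copy()
        phi = float(best.x[m]) if two else 1.0
        psi = best.x[m + (1 if two else 0):] ** 2
        disc = float(best.fun)
    else:
        raise ValueError(f"unknown method {method!r}")

    # canonical signs: majority-positive per factor; a flip of one factor
    # flips the factor correlation
    for f in range(len(factors)):
        sel = fidx == f
        if np.sum(np.sign(lam[sel])) < 0:
            lam[sel] *= -1.0
            phi = -phi
    heywood = [phenos[i] for i in range(m) if abs(lam[i]) > 1.0 + 1e-8]
    if heywood:
        warnings.warn("Heywood solution: loadings above 1 for " + ", ".join(heywood))
    return CFAResult(
        phenotypes=phenos,
        loadings=lam,
        uniquenesses=(1.0 - lam**2) if psi is None else psi,
        factor_correlation=phi,
        discrepancy=disc,
        method=method,
        heywood=heywood,
        n_starts_used=n_starts,
    )
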