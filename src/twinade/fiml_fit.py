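"""Full-information maximum likelihood for raw twin data with missing values.

Each pair contributes the multivariate-normal log density of its *observed*
coordinates, with mean and covariance obtained by selecting the observed
rows/columns of the pair's group-expected moments (analytic marginalization
of the missing coordinates).  Pairs are grouped by zygosity, teacher
sharing and missingness pattern so the objective is evaluated with a
handful of Cholesky factorizations per iteration rather than one per pair.

Standard errors come in two flavours: plain observed-information SEs and
the sandwich estimator A^-1 B A^-1 (A = observed information, B = sum of
per-pair score outer products), the raw-data analogue of the MLR robust
errors the source methodology reports.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .ade_model import (
    ADEParameters,
    ModelSpec,
    build_group_cov,
    build_means,
    canonicalize_signs,
    group_blocks,
    pack_parameters,
    unpack_parameters,
)
from .data import TwinPairRecord
from .utils import psd_project, safe_cholesky

__all__ = [
    "FitOptions",
    "FitResult",
    "StandardErrors",
    "SexModerationTest",
    "ModelComparison",
    "pair_loglik",
    "total_loglik",
    "fit",
    "robust_se",
    "lrt_sex_moderation",
    "compare_models",
]

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))
_PENALTY = 1.0e6  # per-pair-scale objective value returned off the PD cone


# ---------------------------------------------------------------------------
# data packing
# ---------------------------------------------------------------------------


@dataclass
class _Group:
    """Pairs sharing (zygosity, teacher sharing, missingness pattern)."""

    zygosity: str
    same_teacher: bool
    obs: np.ndarray  # observed coordinate indices into 0..2M-1
    y: np.ndarray  # (n_pairs, n_obs) observed values
    sex: np.ndarray  # (n_pairs, 2) sex codes
    rows: np.ndarray  # original row positions


@dataclass
class _PackedData:
    groups: list[_Group]
    n_pairs: int
    n_dropped: int
    fingerprint: str


def _fingerprint(data: pd.DataFrame, spec: ModelSpec) -> str:
    cols = ["zygosity", "sex1", "sex2", "same_teacher"] + [
        f"{p}_{t}" for p in spec.phenotypes for t in (1, 2)
    ]
    raw = pd.util.hash_pandas_object(data[cols], index=False).to_numpy()
    return hashlib.sha1(raw.tobytes()).hexdigest()[:16]


def _pack(data: pd.DataFrame, spec: ModelSpec) -> _PackedData:
    m = spec.n_phenotypes
    cols = [f"{p}_1" for p in spec.phenotypes] + [f"{p}_2" for p in spec.phenotypes]
    y = data[cols].to_numpy(dtype=float)
    zyg = data["zygosity"].astype(str).str.upper().to_numpy()
    sex = data[["sex1", "sex2"]].to_numpy(dtype=float)
    if spec.rater and "same_teacher" in data.columns:
        st = data["same_teacher"].to_numpy().astype(bool)
    else:
        st = np.zeros(len(data), dtype=bool)
    observed = ~np.isnan(y)
    keep = observed.any(axis=1)
    n_dropped = int((~keep).sum())
    groups: list[_Group] = []
    idx_all = np.arange(len(data))
    # group rows by (zygosity, same_teacher, missingness pattern)
    pat_codes = observed.dot(1 << np.arange(2 * m, dtype=np.int64))
    frame_rows = idx_all[keep]
    buckets: dict[tuple, list[int]] = {}
    for i in frame_rows:
        k = (zyg[i], bool(st[i]), int(pat_codes[i]))
        buckets.setdefault(k, []).append(i)
    for (z, s, _), rows in sorted(buckets.items(), key=lambda kv: kv[0][:2] + (kv[0][2],)):
        rows = np.asarray(rows)
        obs = np.flatnonzero(observed[rows[0]])
        groups.append(
            _Group(
                zygosity=z,
                same_teacher=s,
                obs=obs,
                y=y[np.ix_(rows, obs)],
                sex=sex[rows],
                rows=rows,
            )
        )
    return _PackedData(
        groups=groups,
        n_pairs=int(keep.sum()),
        n_dropped=n_dropped,
        fingerprint=_fingerprint(data, spec),
    )


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def _group_sigmas(
    params: ADEParameters, spec: ModelSpec, groups: list[_Group]
) -> dict[tuple[str, bool], np.ndarray]:
    out: dict[tuple[str, bool], np.ndarray] = {}
    for g in groups:
        k = (g.zygosity, g.same_teacher)
        if k not in out:
            within, cross = group_blocks(params, spec, g.zygosity, g.same_teacher)
            out[k] = np.block([[within, cross], [cross, within]])
    return out


def _packed_loglik(
    params: ADEParameters,
    spec: ModelSpec,
    packed: _PackedData,
    per_pair: bool = False,
):
    """Total (or per-pair) observed-data log-likelihood."""
    sigmas = _group_sigmas(params, spec, packed.groups)
    base = np.tile(params.intercepts, 2)
    beta = params.beta_sex
    total = 0.0
    n_rows = 1 + max((int(g.rows.max()) for g in packed.groups), default=0)
    pairs = np.full(n_rows, np.nan)
    ok = True
    for g in packed.groups:
        sigma = sigmas[(g.zygosity, g.same_teacher)][np.ix_(g.obs, g.obs)]
        try:
            c = cho_factor(sigma, lower=True)
        except np.linalg.LinAlgError:
            ok = False
            if per_pair:
                pairs[g.rows] = -np.inf
                continue
            break
        k = len(g.obs)
        logdet = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
        mu_full = base[None, :] + np.concatenate(
            [np.outer(g.sex[:, 0], beta), np.outer(g.sex[:, 1], beta)], axis=1
        )
        r = g.y - mu_full[:, g.obs]
        sol = cho_solve(c, r.T)
        quad = np.einsum("ij,ji->i", r, sol)
        ll = -0.5 * (k * _LOG2PI + logdet + quad)
        if per_pair:
            pairs[g.rows] = ll
        total += float(ll.sum())
    if per_pair:
        return pairs
    return total if ok else -np.inf


def _packed_loglik_grad(
    params: ADEParameters,
    spec: ModelSpec,
    packed: _PackedData,
) -> tuple[float, np.ndarray | None]:
    """Log-likelihood and its analytic gradient in packed-parameter order.

    Uses the standard multivariate-normal matrix calculus: with
    G = 0.5 (Sigma^-1 S Sigma^-1 - n Sigma^-1) accumulated per group
    (S = sum of residual outer products), the gradient with respect to each
    Cholesky factor is 2 (M_W + w_zyg M_C) Delta restricted to the lower
    triangle, where M_W/M_C collect the within- and cross-block parts of G.
    Returns (-inf, None) off the positive-definite cone.
    """
    m = spec.n_phenotypes
    sigmas = _group_sigmas(params, spec, packed.groups)
    base = np.tile(params.intercepts, 2)
    beta = params.beta_sex
    total = 0.0
    mw = np.zeros((m, m))
    mc_zyg = {"MZ": np.zeros((m, m)), "DZ": np.zeros((m, m))}
    mc_st = np.zeros((m, m))
    g_inter = np.zeros(m)
    g_beta = np.zeros(m)
    for g in packed.groups:
        sigma = sigmas[(g.zygosity, g.same_teacher)][np.ix_(g.obs, g.obs)]
        try:
            c = cho_factor(sigma, lower=True)
        except np.linalg.LinAlgError:
            return -np.inf, None
        k = len(g.obs)
        n_g = g.y.shape[0]
        logdet = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
        mu_full = base[None, :] + np.concatenate(
            [np.outer(g.sex[:, 0], beta), np.outer(g.sex[:, 1], beta)], axis=1
        )
        r = g.y - mu_full[:, g.obs]
        sol = cho_solve(c, r.T)  # k x n, columns Sigma^-1 r_p
        quad = np.einsum("ij,ji->i", r, sol)
        total += float(np.sum(-0.5 * (k * _LOG2PI + logdet + quad)))
        inv = cho_solve(c, np.eye(k))
        g_obs = 0.5 * (sol @ sol.T - n_g * inv)
        g_big = np.zeros((2 * m, 2 * m))
        g_big[np.ix_(g.obs, g.obs)] = g_obs
        g11, g12 = g_big[:m, :m], g_big[:m, m:]
        g21, g22 = g_big[m:, :m], g_big[m:, m:]
        mw += g11 + g22
        mc = g12 + g21
        mc_zyg[g.zygosity] += mc
        if g.same_teacher:
            mc_st += mc
        # mean gradients: dll/dmu = Sigma^-1 r per pair, scattered
        tot_obs = sol.sum(axis=1)
        w1 = sol @ g.sex[:, 0]
        w2 = sol @ g.sex[:, 1]
        for i, coord in enumerate(g.obs):
            if coord < m:
                g_inter[coord] += tot_obs[i]
                g_beta[coord] += w1[i]
            else:
                g_inter[coord - m] += tot_obs[i]
                g_beta[coord - m] += w2[i]

    rows, cols = np.tril_indices(m)
    parts: list[np.ndarray] = []
    for comp in spec.components:
        wmz, wdz = {"A": (1.0, 0.5), "C": (1.0, 1.0), "D": (1.0, 0.25), "E": (0.0, 0.0)}[comp]
        mat = mw + wmz * mc_zyg["MZ"] + wdz * mc_zyg["DZ"]
        grad_delta = 2.0 * mat @ params.delta(comp)
        parts.append(grad_delta[rows, cols])
    if spec.rater:
        grad_lam = 2.0 * (mw + mc_st) @ params.rater_loadings
        lam_t = grad_lam[spec.teacher_idx]
        parts.append(np.array([lam_t.sum()]) if spec.equal_rater_loadings else lam_t)
    parts.append(g_inter)
    if spec.sex_effect:
        parts.append(g_beta)
    return total, np.concatenate(parts)


def pair_loglik(
    params: ADEParameters,
    record: TwinPairRecord,
    spec: ModelSpec | None = None,
) -> float:
    """Log density of one pair's observed phenotype subvector.

    Missing coordinates are marginalized analytically (row/column deletion
    from the group covariance).  A non-positive-definite observed submatrix
    yields ``-inf`` with a logged flag, never an exception.
    """
    y = record.y
    obs = np.flatnonzero(~np.isnan(y))
    if obs.size == 0:
        raise ValueError("record has no observed values")
    g = build_group_cov(
        params, record.zygosity, record.same_teacher, spec=spec, validate=False
    )
    mu = build_means(params, record.sex1, record.sex2)
    sigma = g.sigma[np.ix_(obs, obs)]
    try:
        c = cho_factor(sigma, lower=True)
    except np.linalg.LinAlgError:
        logger.warning(
            "pair %s: observed-submatrix not positive definite", record.pair_id
        )
        return -np.inf
    r = y[obs] - mu[obs]
    logdet = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    quad = float(r @ cho_solve(c, r))
    return -0.5 * (obs.size * _LOG2PI + logdet + quad)


def total_loglik(
    params: ADEParameters, data: pd.DataFrame, spec: ModelSpec
) -> float:
    """Casewise FIML log-likelihood of a wide-format dataset."""
    return float(_packed_loglik(params, spec, _pack(data, spec)))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class FitOptions:
    """Optimizer settings; defaults favour reproducibility over speed."""

    n_starts: int = 5
    seed: int = 0
    maxiter: int = 2000
    gtol: float = 1e-5  # gradient sup-norm, per-pair scale, for `converged`
    jitter: float = 0.1


@dataclass
class StandardErrors:
    observed: np.ndarray
    sandwich: np.ndarray
    cov_observed: np.ndarray
    cov_sandwich: np.ndarray
    notes: list[str] = field(default_factory=list)


@dataclass
class FitResult:
    estimates: ADEParameters
    spec: ModelSpec
    x: np.ndarray
    loglik: float
    n_pairs_used: int
    converged: bool
    gradient_norm: float
    n_function_evals: int
    start_logliks: list[float]
    data_fingerprint: str
    se: StandardErrors | None = None

    @property
    def n_params(self) -> int:
        return len(self.x)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * np.log(self.n_pairs_used)


def _pairwise_cross_cov(y1: np.ndarray, y2: np.ndarray) -> np.ndarray:
    """Pairwise-complete cross-twin covariance E[(y1 - m)(y2 - m)^T], symmetrized."""
    m = y1.shape[1]
    mu1 = np.nanmean(y1, axis=0)
    mu2 = np.nanmean(y2, axis=0)
    out = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            a = y1[:, i] - mu1[i]
            b = y2[:, j] - mu2[j]
            mask = ~np.isnan(a) & ~np.isnan(b)
            out[i, j] = np.mean(a[mask] * b[mask]) if mask.sum() > 2 else 0.0
    return 0.5 * (out + out.T)


def _starting_values(
    data: pd.DataFrame, spec: ModelSpec
) -> ADEParameters:
    """Moment-based starting values.

    Delta_E from the Cholesky of half the pooled phenotypic covariance,
    Delta_A from the Cholesky of 0.8 x the (PSD-projected) MZ cross-twin
    covariance, Delta_D small; intercepts/sex effects from phenotype means.
    """
    m = spec.n_phenotypes
    c1 = [f"{p}_1" for p in spec.phenotypes]
    c2 = [f"{p}_2" for p in spec.phenotypes]
    y1 = data[c1].to_numpy(dtype=float)
    y2 = data[c2].to_numpy(dtype=float)
    stacked = np.vstack([y1, y2])
    pooled = pd.DataFrame(stacked).cov(min_periods=3).to_numpy()
    pooled = psd_project(np.where(np.isfinite(pooled), pooled, 0.0), 1e-4)
    mz = data["zygosity"].astype(str).str.upper().to_numpy() == "MZ"
    cross = _pairwise_cross_cov(y1[mz], y2[mz]) if mz.any() else 0.3 * pooled
    delta_e = safe_cholesky(0.5 * pooled, 1e-4)
    delta_a = safe_cholesky(psd_project(0.8 * cross, 1e-4))
    delta_d = 0.05 * np.eye(m)
    sex_stack = np.concatenate(
        [data["sex1"].to_numpy(dtype=float), data["sex2"].to_numpy(dtype=float)]
    )
    inter = np.zeros(m)
    beta = np.zeros(m)
    for j in range(m):
        v = stacked[:, j]
        mask = ~np.isnan(v)
        if spec.sex_effect and len(np.unique(sex_stack[mask])) == 2:
            b = np.polyfit(sex_stack[mask], v[mask], 1)
            beta[j], inter[j] = b[0], b[1]
        else:
            inter[j] = np.nanmean(v)
    lam = np.zeros(m)
    lam[spec.teacher_idx] = 0.3
    return ADEParameters(
        delta_a=delta_a if "A" in spec.components else None,
        delta_d=delta_d if "D" in spec.components else None,
        delta_c=0.05 * np.eye(m) if "C" in spec.components else None,
        delta_e=delta_e,
        rater_loadings=lam if spec.rater else np.zeros(m),
        intercepts=inter,
        beta_sex=beta,
    )


def _central_gradient(f, x: np.ndarray, h: float = 1e-6) -> np.ndarray:
    g = np.empty_like(x)
    for i in range(len(x)):
        hi = h * (1.0 + abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += hi
        xm[i] -= hi
        g[i] = (f(xp) - f(xm)) / (2.0 * hi)
    return g


def numerical_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian; O(p^2) function evaluations."""
    p = len(x)
    hs = h * (1.0 + np.abs(x))
    hess = np.empty((p, p))
    f0 = f(x)
    for i in range(p):
        xp, xm = x.copy(), x.copy()
        xp[i] += hs[i]
        xm[i] -= hs[i]
        hess[i, i] = (f(xp) - 2.0 * f0 + f(xm)) / hs[i] ** 2
    for i in range(p):
        for j in range(i + 1, p):
            xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
            xpp[[i, j]] += hs[[i, j]]
            xmm[[i, j]] -= hs[[i, j]]
            xpm[i] += hs[i]
            xpm[j] -= hs[j]
            xmp[i] -= hs[i]
            xmp[j] += hs[j]
            hess[i, j] = hess[j, i] = (
                f(xpp) - f(xpm) - f(xmp) + f(xmm)
            ) / (4.0 * hs[i] * hs[j])
    return hess


def fit(
    data: pd.DataFrame,
    spec: ModelSpec,
    options: FitOptions | None = None,
) -> FitResult:
    """Maximize the FIML log-likelihood by multi-start quasi-Newton.

    Starting values are moment-based; additional starts jitter them with
    seeded noise and the best final likelihood is kept, so the fit is
    deterministic under a fixed seed.  The sign indeterminacy of the
    Cholesky factors is resolved post hoc (nonnegative diagonals), since
    ``Delta @ Delta.T`` is sign-invariant.  Non-convergence is reported via
    the ``converged`` flag and diagnostics, never silently.
    """
    if options is None:
        options = FitOptions()
    packed = _pack(data, spec)
    if packed.n_pairs < 30:
        warnings.warn(f"only {packed.n_pairs} usable pairs; estimates will be unstable")
    zygs = {g.zygosity for g in packed.groups}
    if {"A", "D"} <= set(spec.components) and len(zygs) < 2:
        warnings.warn(
            "data contain a single zygosity: A and D are not separately "
            "identified; expect rank-deficient information"
        )
    n = max(packed.n_pairs, 1)

    def objective(x: np.ndarray) -> float:
        ll = _packed_loglik(unpack_parameters(x, spec), spec, packed)
        if not np.isfinite(ll):
            return _PENALTY
        return -ll / n

    def objective_grad(x: np.ndarray) -> tuple[float, np.ndarray]:
        ll, grad = _packed_loglik_grad(unpack_parameters(x, spec), spec, packed)
        if not np.isfinite(ll) or grad is None:
            return _PENALTY, np.zeros_like(x)
        return -ll / n, -grad / n

    x0 = pack_parameters(_starting_values(data, spec), spec)
    rng = np.random.default_rng(options.seed)
    starts = [x0]
    for _ in range(options.n_starts - 1):
        starts.append(x0 * (1.0 + options.jitter * rng.standard_normal(len(x0)))
                      + 0.01 * rng.standard_normal(len(x0)))
    best = None
    start_lls: list[float] = []
    nfev = 0
    for s in starts:
        res = minimize(
            objective_grad,
            s,
            jac=True,
            method="L-BFGS-B",
            options={
                "maxiter": options.maxiter,
                "maxfun": 10 * options.maxiter * max(len(x0), 1),
                "ftol": 1e-13,
                "gtol": 1e-7,
            },
        )
        nfev += res.nfev
        start_lls.append(-res.fun * n)
        if best is None or res.fun < best.fun:
            best = res
    x = best.x
    params = canonicalize_signs(unpack_parameters(x, spec), spec)
    x = pack_parameters(params, spec)
    ll = _packed_loglik(params, spec, packed)
    grad = _central_gradient(objective, x)
    gnorm = float(np.max(np.abs(grad)))
    converged = bool(np.isfinite(ll)) and gnorm <= options.gtol
    if not converged:
        logger.warning(
            "fit did not meet the gradient tolerance (sup-norm %.2e > %.0e)",
            gnorm,
            options.gtol,
        )
    return FitResult(
        estimates=params,
        spec=spec,
        x=x,
        loglik=float(ll),
        n_pairs_used=packed.n_pairs,
        converged=converged,
        gradient_norm=gnorm,
        n_function_evals=nfev,
        start_logliks=start_lls,
        data_fingerprint=packed.fingerprint,
    )


def robust_se(fitres: FitResult, data: pd.DataFrame) -> StandardErrors:
    """Observed-information and sandwich (robust) standard errors.

    The sandwich estimator is A^-1 B A^-1 with A the observed information
    (numerical Hessian of the total negative log-likelihood) and B the sum
    of per-pair score outer products.  Under correct specification the two
    agree asymptotically; under misspecification the sandwich remains
    consistent.  Parameters with no curvature are reported as NaN.
    """
    spec = fitres.spec
    packed = _pack(data, spec)
    if packed.fingerprint != fitres.data_fingerprint:
        raise ValueError("dataset does not match the one used for the fit")
    x = fitres.x

    def total_nll(v: np.ndarray) -> float:
        ll = _packed_loglik(unpack_parameters(v, spec), spec, packed)
        return -ll if np.isfinite(ll) else _PENALTY * packed.n_pairs

    def per_pair(v: np.ndarray) -> np.ndarray:
        return _packed_loglik(unpack_parameters(v, spec), spec, packed, per_pair=True)

    p = len(x)
    scores = np.empty((len(per_pair(x)), p))
    for i in range(p):
        h = 1e-5 * (1.0 + abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        scores[:, i] = (per_pair(xp) - per_pair(xm)) / (2.0 * h)
    scores = scores[~np.isnan(scores).any(axis=1)]
    b = scores.T @ scores
    a = numerical_hessian(total_nll, x)
    a = 0.5 * (a + a.T)
    notes: list[str] = []
    w = np.linalg.eigvalsh(a)
    if w.min() <= 1e-10 * max(w.max(), 1.0):
        notes.append(
            "observed information is singular or indefinite; SEs for the "
            "affected directions are undefined (reported as NaN)"
        )
        cov_obs = np.linalg.pinv(a)
    else:
        cov_obs = np.linalg.inv(a)
    cov_sw = cov_obs @ b @ cov_obs
    with np.errstate(invalid="ignore"):
        se_obs = np.sqrt(np.where(np.diag(cov_obs) > 0, np.diag(cov_obs), np.nan))
        se_sw = np.sqrt(np.where(np.diag(cov_sw) > 0, np.diag(cov_sw), np.nan))
    return StandardErrors(
        observed=se_obs,
        sandwich=se_sw,
        cov_observed=cov_obs,
        cov_sandwich=cov_sw,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# sex-moderation LRT and model comparison
# ---------------------------------------------------------------------------


@dataclass
class SexModerationTest:
    lrt: float
    df: int
    p_value: float
    loglik_free: float
    loglik_equated: float
    component_tests: dict[str, tuple[float, int, float]]
    n_pairs_male: int
    n_pairs_female: int
    messages: list[str] = field(default_factory=list)


def _two_group_fit(
    data_by_sex: dict[int, pd.DataFrame],
    spec: ModelSpec,
    free: frozenset[str],
    options: FitOptions,
) -> tuple[float, int]:
    """Joint fit of male and female groups with selected components freed.

    Components in ``free`` get sex-specific Cholesky factors; all others
    (and the rater loadings) are equated.  Intercepts are always
    sex-specific, so the equated model is identical to a pooled fit with a
    sex main effect.  Returns (loglik, n_parameters).
    """
    spec_u = ModelSpec(
        phenotypes=spec.phenotypes,
        teacher_rated=spec.teacher_rated,
        components=spec.components,
        rater=spec.rater,
        equal_rater_loadings=spec.equal_rater_loadings,
        sex_effect=False,
    )
    packed = {s: _pack(d, spec_u) for s, d in data_by_sex.items()}
    m = spec.n_phenotypes
    tril = m * (m + 1) // 2
    layout: list[tuple[str, bool]] = [(c, c in free) for c in spec_u.components]
    n_rater = (
        0
        if not spec_u.rater
        else (1 if spec_u.equal_rater_loadings else len(spec_u.teacher_idx))
    )

    def split(x: np.ndarray) -> dict[int, ADEParameters]:
        pos = 0
        deltas: dict[int, dict[str, np.ndarray]] = {0: {}, 1: {}}
        rows, cols = np.tril_indices(m)
        for comp, is_free in layout:
            for sex in (0, 1):
                if sex == 1 and not is_free:
                    deltas[1][comp] = deltas[0][comp]
                    continue
                d = np.zeros((m, m))
                d[rows, cols] = x[pos : pos + tril]
                pos += tril
                deltas[sex][comp] = d
        lam = np.zeros(m)
        if n_rater:
            if spec_u.equal_rater_loadings:
                lam[spec_u.teacher_idx] = x[pos]
            else:
                lam[spec_u.teacher_idx] = x[pos : pos + n_rater]
            pos += n_rater
        out = {}
        for sex in (0, 1):
            inter = x[pos : pos + m]
            pos += m
            out[sex] = ADEParameters(
                delta_a=deltas[sex].get("A"),
                delta_d=deltas[sex].get("D"),
                delta_c=deltas[sex].get("C"),
                delta_e=deltas[sex]["E"],
                rater_loadings=lam,
                intercepts=inter,
                beta_sex=np.zeros(m),
            )
        return out

    n_par = sum(tril * (2 if is_free else 1) for _, is_free in layout) + n_rater + 2 * m
    n_tot = sum(p.n_pairs for p in packed.values())

    def objective(x: np.ndarray) -> float:
        prm = split(x)
        total = 0.0
        for sex, pk in packed.items():
            ll = _packed_loglik(prm[sex], spec_u, pk)
            if not np.isfinite(ll):
                return _PENALTY
            total += ll
        return -total / n_tot

    # starting values: per-sex moment starts, averaged for equated components
    starts_by_sex = {
        s: _starting_values(d, spec_u) for s, d in data_by_sex.items()
    }
    rows, cols = np.tril_indices(m)
    x0_parts: list[np.ndarray] = []
    for comp, is_free in layout:
        for sex in (0, 1):
            if sex == 1 and not is_free:
                continue
            if is_free:
                d = starts_by_sex[sex].delta(comp)
            else:
                d = 0.5 * (starts_by_sex[0].delta(comp) + starts_by_sex[1].delta(comp))
            x0_parts.append(d[rows, cols])
    if n_rater:
        lam0 = 0.5 * (
            starts_by_sex[0].rater_loadings + starts_by_sex[1].rater_loadings
        )
        lam_t = lam0[spec_u.teacher_idx]
        x0_parts.append(lam_t[:1] if spec_u.equal_rater_loadings else lam_t)
    for sex in (0, 1):
        x0_parts.append(starts_by_sex[sex].intercepts)
    x0 = np.concatenate(x0_parts)

    rng = np.random.default_rng(options.seed)
    best = None
    for k in range(options.n_starts):
        s = x0 if k == 0 else x0 * (
            1.0 + options.jitter * rng.standard_normal(len(x0))
        ) + 0.01 * rng.standard_normal(len(x0))
        res = minimize(
            objective,
            s,
            method="L-BFGS-B",
            options={"maxiter": options.maxiter, "ftol": 1e-12, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res
    return float(-best.fun * n_tot), n_par


def lrt_sex_moderation(
    data: pd.DataFrame,
    phenotype: str,
    spec: ModelSpec | None = None,
    options: FitOptions | None = None,
    include_opposite_sex: bool = False,
    component_tests: bool = True,
) -> SexModerationTest:
    """Likelihood-ratio test of sex differences in A, D, E variance components.

    Same-sex pairs are split by sex; the free model gives each sex its own
    univariate A, D, E components while the equated model shares them (a
    3-df test at the default ADE specification).  Component-wise 1-df tests
    free one component at a time.  Opposite-sex pairs are excluded by
    default from both models so the likelihoods remain nested; passing
    ``include_opposite_sex=True`` adds them to the equated fit only, which
    uses more data but renders the LRT approximate (different likelihoods).
    """
    if options is None:
        options = FitOptions(n_starts=2)
    if spec is not None:
        j = spec.index_of(phenotype)
        uni = ModelSpec(
            phenotypes=(phenotype,),
            teacher_rated=(spec.teacher_rated[j],),
            components=spec.components,
            rater=spec.rater and spec.teacher_rated[j],
            sex_effect=False,
        )
    else:
        uni = ModelSpec(
            phenotypes=(phenotype,),
            teacher_rated=(False,),
            components=("A", "D", "E"),
            rater=False,
            sex_effect=False,
        )
    cols = ["pair_id", "zygosity", "sex1", "sex2"] + (
        ["same_teacher"] if "same_teacher" in data.columns else []
    ) + [f"{phenotype}_1", f"{phenotype}_2"]
    sub = data[cols].copy()
    same_sex = sub["sex1"] == sub["sex2"]
    messages: list[str] = []
    groups = {s: sub[same_sex & (sub["sex1"] == s)] for s in (0, 1)}
    for s, g in groups.items():
        if len(g) < 20:
            messages.append(
                f"only {len(g)} same-sex pairs with sex={s}; test is unreliable"
            )
            warnings.warn(messages[-1])
    if include_opposite_sex:
        messages.append(
            "opposite-sex pairs entered the equated model only; the LRT "
            "compares likelihoods of different datasets and is approximate"
        )

    ll_eq, p_eq = _two_group_fit(groups, uni, frozenset(), options)
    ll_free, p_free = _two_group_fit(groups, uni, frozenset({"A", "D", "E"}), options)
    lrt = max(2.0 * (ll_free - ll_eq), 0.0)
    df = p_free - p_eq
    comp_tests: dict[str, tuple[float, int, float]] = {}
    for comp in ("A", "D", "E") if component_tests else ():
        ll_c, p_c = _two_group_fit(groups, uni, frozenset({comp}), options)
        stat = max(2.0 * (ll_c - ll_eq), 0.0)
        d1 = p_c - p_eq
        comp_tests[comp] = (stat, d1, float(stats.chi2.sf(stat, d1)))
    return SexModerationTest(
        lrt=lrt,
        df=df,
        p_value=float(stats.chi2.sf(lrt, df)),
        loglik_free=ll_free,
        loglik_equated=ll_eq,
        component_tests=comp_tests,
        n_pairs_male=len(groups[0]),
        n_pairs_female=len(groups[1]),
        messages=messages,
    )


@dataclass
class ModelComparison:
    delta_loglik: float
    df: int
    p_value: float | None
    aic: tuple[float, float]
    bic: tuple[float, float]
    nested: bool


def compare_models(
    fit_a: FitResult, fit_b: FitResult, nested: bool = True
) -> ModelComparison:
    """LRT (for nested fits) plus AIC/BIC for two fits on the same dataset.

    BIC uses the number of pairs as the sample size.  ``fit_a`` should be
    the more general model; the fits are ordered internally by parameter
    count, so argument order does not matter.
    """
    if fit_a.data_fingerprint != fit_b.data_fingerprint:
        raise ValueError("fits are based on different datasets")
    big, small = (
        (fit_a, fit_b) if fit_a.n_params >= fit_b.n_params else (fit_b, fit_a)
    )
    delta = big.loglik - small.loglik
    df = big.n_params - small.n_params
    p = None
    if nested:
        stat = max(2.0 * delta, 0.0)
        p = 1.0 if df == 0 and stat <= 0 else float(stats.chi2.sf(stat, max(df, 1)))
        if df == 0:
            p = 1.0 if stat <= 1e-8 else 0.0
    return ModelComparison(
        delta_loglik=delta,
        df=df,
        p_value=p,
        aic=(fit_a.aic, fit_b.aic),
        bic=(fit_a.bic, fit_b.bic),
        nested=nested,
    )
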