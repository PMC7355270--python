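"""Independent brute-force oracles used to check the package's fast paths.

Everything here is deliberately naive: direct formulas, dense grids,
per-element loops, scipy reference densities.  Nothing imports the code
paths it is used to verify beyond parameter containers.
"""

import numpy as np
from scipy import stats
from scipy.optimize import minimize

from twinade.ade_model import build_group_cov, build_means, unpack_parameters


def brute_cholesky_cov(delta):
    """Sigma_ij = sum_k delta_ik delta_jk, elementwise loops."""
    delta = np.asarray(delta, float)
    m = delta.shape[0]
    out = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            out[i, j] = sum(delta[i, k] * delta[j, k] for k in range(m))
    return out


def oracle_pair_loglik(params, record, spec=None):
    """Observed-submatrix normal density straight from scipy."""
    y = record.y
    obs = ~np.isnan(y)
    sigma = build_group_cov(
        params, record.zygosity, record.same_teacher, spec=spec, validate=False
    ).sigma
    mu = build_means(params, record.sex1, record.sex2)
    return stats.multivariate_normal(
        mean=mu[obs], cov=sigma[np.ix_(obs, obs)]
    ).logpdf(y[obs])


def grouped_stats_loglik(params, data, spec):
    """Sufficient-statistics likelihood for complete data.

    Pairs are grouped by (zygosity, same_teacher, sex1, sex2); each group
    contributes through its count, mean vector and scatter matrix only:
    ll = -n/2 [2M log 2pi + log|S|] - 1/2 tr(S^-1 W) - n/2 (m-mu)' S^-1 (m-mu).
    """
    phenos = spec.phenotypes
    cols = [f"{p}_1" for p in phenos] + [f"{p}_2" for p in phenos]
    y = data[cols].to_numpy(float)
    assert not np.isnan(y).any(), "oracle requires complete data"
    keys = list(
        zip(
            data["zygosity"].astype(str).str.upper(),
            data["same_teacher"].to_numpy().astype(bool)
            if spec.rater
            else [False] * len(data),
            data["sex1"],
            data["sex2"],
        )
    )
    total = 0.0
    for key in sorted(set(keys)):
        rows = [i for i, k in enumerate(keys) if k == key]
        zyg, st, s1, s2 = key
        yk = y[rows]
        n, k = yk.shape
        sigma = build_group_cov(params, zyg, st, spec=spec, validate=False).sigma
        mu = build_means(params, int(s1), int(s2))
        ybar = yk.mean(axis=0)
        dev = yk - ybar
        scatter = dev.T @ dev
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return -np.inf
        inv = np.linalg.inv(sigma)
        d = ybar - mu
        total += (
            -0.5 * n * (k * np.log(2 * np.pi) + logdet)
            - 0.5 * np.trace(inv @ scatter)
            - 0.5 * n * d @ inv @ d
        )
    return float(total)


def grouped_stats_fit(data, spec, x0, maxiter=3000):
    """Independent ML fit through the sufficient-statistics likelihood."""

    def obj(x):
        ll = grouped_stats_loglik(unpack_parameters(x, spec), data, spec)
        return -ll / len(data) if np.isfinite(ll) else 1e6

    res = minimize(
        obj, x0, method="L-BFGS-B", options={"maxiter": maxiter, "ftol": 1e-13}
    )
    return -res.fun * len(data), res.x


def grid_argmax_lambda(y, lo=-6.0, hi=3.0, step=0.01):
    """Dense-grid maximizer of the Box-Cox profile log-likelihood."""
    y = np.asarray(y, float)
    y = y[~np.isnan(y)]
    log1p_sum = np.log1p(y).sum()
    best_l, best_ll = None, -np.inf
    for lam in np.arange(lo, hi + step / 2, step):
        z = np.log1p(y) if lam == 0 else ((y + 1.0) ** lam + 1.0) / lam
        var = z.var()
        if var <= 0:
            continue
        ll = -0.5 * len(y) * np.log(var) + (lam - 1.0) * log1p_sum
        if ll > best_ll:
            best_l, best_ll = lam, ll
    return best_l, best_ll
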