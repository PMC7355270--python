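"""Published multivariate ADE estimates for eight ADHD rating-scale phenotypes.

A large Dutch twin-register study of 12-year-olds reported a multivariate
ADE Cholesky decomposition of four inattention (INATT) and four
hyperactivity (HYP) measures: mother ratings on the SWAN and the Conners'
Parent Rating Scale (CPRS), and teacher ratings on the ASEBA Teacher Report
Form (TRF) and the Conners' Teacher Rating Scale (CTRS).  The raw twin data
are registry-held and not public, but the printed summary tables fully
determine the standardized model.  This module stores those estimates —
they serve as realistic generating values for the synthetic-data module,
as inputs to the derivation chain, and as cross-check targets in tests.

Conventions: phenotypes in the fixed order below; sex coded 0 = boys,
1 = girls; ``CORR_*`` are full symmetric component correlation matrices;
``PROP_AD``/``PROP_E`` hold the printed proportions of phenotypic
covariance attributable to genetic (A + D) and unshared-environmental (E)
effects (diagonal = standardized variance shares).
"""

from __future__ import annotations

import numpy as np

from .ade_model import ADEParameters, ModelSpec
from .utils import psd_project, safe_cholesky

__all__ = [
    "PHENOTYPES",
    "TEACHER_RATED",
    "model_spec",
    "cholesky_parameters",
]

PHENOTYPES = (
    "SWAN_HYP",
    "CPRS_HYP",
    "TRF_HYP",
    "CTRS_HYP",
    "SWAN_INATT",
    "CPRS_INATT",
    "TRF_INATT",
    "CTRS_INATT",
)

#: TRF and CTRS are teacher ratings; SWAN and CPRS are mother ratings.
TEACHER_RATED = (False, False, True, True, False, False, True, True)

#: zygosity-by-sex group sizes of the study sample (pairs)
GROUP_SIZES = {
    "MZ_male": 268,
    "DZ_male": 263,
    "MZ_female": 352,
    "DZ_female": 241,
    "DZ_opposite_sex": 469,
}

#: fraction of teacher-rated pairs rated by the same teacher
SAME_TEACHER_FRACTION = 0.572

# --- univariate results -----------------------------------------------------

#: sex main effect in pooled-SD units (girls minus boys)
BETA_SEX = np.array([-0.14, -0.23, -0.29, -0.29, -0.17, -0.21, -0.23, -0.090])

#: phenotypic cross-twin correlations from the univariate models
R_MZ = np.array([0.899, 0.781, 0.651, 0.718, 0.853, 0.735, 0.670, 0.733])
R_DZ = np.array([0.364, 0.311, 0.260, 0.093, 0.412, 0.239, 0.05, 0.370])

#: standardized teacher-rater variance shares (univariate; zero for mother)
RATER_R2 = np.array([0.0, 0.0, 0.206, 0.331, 0.0, 0.0, 0.242, 0.193])

#: univariate standardized variance components (r2 + a2 + d2 + e2 = 1)
UNI_A2 = np.array([0.852, 0.464, 0.000, 0.000, 0.794, 0.221, 0.000, 0.591])
UNI_D2 = np.array([0.063, 0.317, 0.548, 0.484, 0.059, 0.514, 0.515, 0.000])
UNI_E2 = np.array([0.085, 0.219, 0.246, 0.185, 0.147, 0.265, 0.244, 0.216])

#: estimates of the power-transform exponent for the censored scales
#: (the near-normal SWAN scales were not transformed)
LAMBDA_HAT = {
    "CPRS_INATT": -1.474,
    "CPRS_HYP": -3.158,
    "CTRS_INATT": -1.053,
    "CTRS_HYP": -3.579,
    "TRF_INATT": -2.737,
    "TRF_HYP": -3.579,
}

# --- multivariate results ---------------------------------------------------

#: standardized variance components of the multivariate Cholesky model
#: (rater variance excluded from the denominator: a2 + d2 + e2 = 1)
A2 = np.array([0.687, 0.510, 0.230, 0.225, 0.609, 0.369, 0.176, 0.643])
D2 = np.array([0.226, 0.275, 0.454, 0.492, 0.234, 0.369, 0.482, 0.084])
H2 = np.array([0.912, 0.784, 0.683, 0.717, 0.844, 0.738, 0.658, 0.727])
E2 = np.array([0.088, 0.216, 0.317, 0.283, 0.156, 0.262, 0.342, 0.273])


def _from_lower(rows: list[list[float]]) -> np.ndarray:
    m = len(rows) + 1
    out = np.eye(m)
    for i, row in enumerate(rows, start=1):
        for j, v in enumerate(row):
            out[i, j] = out[j, i] = v
    return out


CORR_A = _from_lower(
    [
        [0.357],
        [0.369, 0.159],
        [0.304, 0.031, 0.942],
        [0.995, 0.401, 0.314, 0.231],
        [0.392, 0.967, 0.296, 0.231, 0.418],
        [0.449, 0.355, 0.372, 0.354, 0.481, 0.454],
        [0.373, 0.288, 0.552, 0.590, 0.377, 0.449, 0.952],
    ]
)

CORR_D = _from_lower(
    [
        [0.859],
        [0.651, 0.595],
        [0.643, 0.704, 0.824],
        [0.504, 0.576, 0.543, 0.783],
        [0.436, 0.214, 0.509, 0.542, 0.810],
        [0.489, 0.357, 0.925, 0.754, 0.640, 0.741],
        [0.450, 0.231, 0.334, 0.373, 0.767, 0.957, 0.563],
    ]
)

CORR_AD = _from_lower(
    [
        [0.502],
        [0.450, 0.361],
        [0.413, 0.359, 0.862],
        [0.866, 0.454, 0.388, 0.452],
        [0.394, 0.641, 0.414, 0.409, 0.553],
        [0.409, 0.329, 0.757, 0.637, 0.500, 0.615],
        [0.380, 0.265, 0.393, 0.416, 0.439, 0.528, 0.627],
    ]
)

CORR_E = _from_lower(
    [
        [0.387],
        [0.002, 0.254],
        [0.169, 0.283, 0.460],
        [0.549, 0.207, 0.248, 0.116],
        [0.384, 0.239, 0.143, 0.144, 0.471],
        [0.138, 0.116, 0.254, 0.167, 0.209, 0.227],
        [0.136, 0.082, 0.173, 0.213, 0.259, 0.340, 0.418],
    ]
)


def _prop_matrix(diag: np.ndarray, upper_rows: list[list[float]]) -> np.ndarray:
    m = diag.shape[0]
    out = np.diag(diag).astype(float)
    for i, row in enumerate(upper_rows):
        for k, v in enumerate(row):
            j = i + 1 + k
            out[i, j] = out[j, i] = v
    return out


#: proportion of phenotypic (co)variance attributable to A + D
#: (diagonal: broad-sense heritability)
PROP_AD = _prop_matrix(
    H2,
    [
        [0.888, 0.999, 0.926, 0.922, 0.847, 0.930, 0.936],
        [0.799, 0.794, 0.907, 0.896, 0.882, 0.909],
        [0.814, 0.842, 0.877, 0.859, 0.845],
        [0.935, 0.884, 0.894, 0.835],
        [0.821, 0.885, 0.865],
        [0.863, 0.810],
        [0.772],
    ],
)

#: proportion of phenotypic (co)variance attributable to E
PROP_E = _prop_matrix(
    E2,
    [
        [0.112, 0.001, 0.074, 0.078, 0.153, 0.070, 0.064],
        [0.201, 0.206, 0.093, 0.104, 0.118, 0.091],
        [0.186, 0.158, 0.123, 0.141, 0.155],
        [0.065, 0.116, 0.106, 0.165],
        [0.179, 0.115, 0.135],
        [0.137, 0.190],
        [0.228],
    ],
)

#: model-implied phenotypic correlations (computed from the components above)
PHENO_CORR = _from_lower(
    [
        [0.478],
        [0.355, 0.331],
        [0.361, 0.339, 0.741],
        [0.824, 0.407, 0.350, 0.376],
        [0.382, 0.544, 0.335, 0.337, 0.532],
        [0.341, 0.268, 0.591, 0.489, 0.421, 0.497],
        [0.330, 0.220, 0.328, 0.360, 0.397, 0.478, 0.561],
    ]
)

#: confirmatory two-factor solution fitted to the A + D correlation matrix
#: (point estimates only; the study's own raw-data factor fit did not converge)
CFA_LOADINGS_HYP = np.array([0.366, 0.427, 0.918, 0.925])
CFA_LOADINGS_INATT = np.array([0.476, 0.680, 0.901, 0.704])
CFA_FACTOR_CORRELATION = 0.75


def model_spec(subset: tuple[str, ...] | None = None, **kwargs) -> ModelSpec:
    """ADE model specification for (a subset of) the eight phenotypes."""
    phenos = PHENOTYPES if subset is None else tuple(subset)
    idx = [PHENOTYPES.index(p) for p in phenos]
    return ModelSpec(
        phenotypes=phenos,
        teacher_rated=tuple(TEACHER_RATED[i] for i in idx),
        **kwargs,
    )


def cholesky_parameters(
    subset: tuple[str, ...] | None = None,
) -> tuple[ADEParameters, ModelSpec]:
    """Generating parameters at the published standardized magnitudes.

    Component covariances are rebuilt from the standardized variance shares
    and component correlation matrices; because the printed (3-decimal)
    correlations need not be exactly positive semidefinite, each component
    matrix is eigenvalue-clipped before taking its Cholesky factor.  The
    A + D + E variance of every phenotype is one; teacher-rated phenotypes
    carry rater variance *on top*, sized so that the rater share of their
    total variance matches the univariate estimates.
    """
    spec = model_spec(subset)
    idx = np.array([PHENOTYPES.index(p) for p in spec.phenotypes])

    def comp_sigma(shares: np.ndarray, corr: np.ndarray) -> np.ndarray:
        s = np.sqrt(shares[idx])
        return psd_project(np.outer(s, s) * corr[np.ix_(idx, idx)], floor=1e-8)

    sigma_a = comp_sigma(A2, CORR_A)
    sigma_d = comp_sigma(D2, CORR_D)
    sigma_e = comp_sigma(E2, CORR_E)
    r2 = RATER_R2[idx]
    # total variance 1/(1 - r2) so the rater share of the total equals r2
    lam = np.sqrt(r2 / (1.0 - r2))
    params = ADEParameters(
        delta_a=safe_cholesky(sigma_a),
        delta_d=safe_cholesky(sigma_d),
        delta_e=safe_cholesky(sigma_e),
        rater_loadings=lam,
        intercepts=np.zeros(len(idx)),
        beta_sex=BETA_SEX[idx],
    )
    return params, spec
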