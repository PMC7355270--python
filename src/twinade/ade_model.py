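"""Expected mean and covariance structure of the multivariate ADE twin model.

The classical twin design decomposes the phenotypic covariance of M traits
into additive genetic (A), dominance (D) and unshared environmental (E)
components, each parameterized by a Cholesky factor so that
``Sigma_X = Delta_X @ Delta_X.T`` is positive semidefinite by construction.
Monozygotic (MZ) co-twins share all additive and dominance effects
(cross-twin weights 1 and 1); dizygotic (DZ) co-twins share them with
weights 0.5 and 0.25.  A shared-environment component C (cross-twin weight 1
in both zygosities) is supported for completeness.

Teacher-rated traits additionally carry a rater factor: a single latent
factor per teacher, loading on all teacher-rated phenotypes, whose
cross-twin correlation is 1 when both twins are rated by the same teacher
and 0 otherwise.  Sex enters the means only, as a main effect with
coefficients equal across twins and zygosities (coded 0 = boys, 1 = girls).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ModelSpec",
    "ADEParameters",
    "GroupCovariance",
    "cholesky_cov",
    "build_group_cov",
    "build_means",
    "expected_twin_correlations",
    "n_free_params",
    "pack_parameters",
    "unpack_parameters",
]

#: cross-twin weights (MZ, DZ) per variance component
CROSS_WEIGHTS = {"A": (1.0, 0.5), "D": (1.0, 0.25), "C": (1.0, 1.0), "E": (0.0, 0.0)}

_COMPONENT_ORDER = ("A", "C", "D", "E")


@dataclass(frozen=True)
class ModelSpec:
    """Which phenotypes are modelled and which components are active.

    Parameters
    ----------
    phenotypes
        Ordered trait labels (e.g. ``("SWAN_HYP", "CPRS_HYP", ...)``).
    teacher_rated
        Boolean per phenotype; the rater factor may load only on these.
    components
        Subset of ``{"A", "C", "D", "E"}``; ``"E"`` is mandatory (it carries
        measurement error and keeps the within-twin covariance proper).
    rater
        Whether the teacher-rater factor is part of the model.
    equal_rater_loadings
        Constrain all rater loadings to a single value.
    sex_effect
        Include a per-phenotype sex main-effect coefficient in the means.
    """

    phenotypes: tuple[str, ...]
    teacher_rated: tuple[bool, ...] = ()
    components: tuple[str, ...] = ("A", "D", "E")
    rater: bool = True
    equal_rater_loadings: bool = False
    sex_effect: bool = True

    def __post_init__(self) -> None:
        if not self.teacher_rated:
            object.__setattr__(self, "teacher_rated", (False,) * self.n_phenotypes)
        if len(self.teacher_rated) != self.n_phenotypes:
            raise ValueError("teacher_rated must have one flag per phenotype")
        bad = set(self.components) - set(_COMPONENT_ORDER)
        if bad:
            raise ValueError(f"unknown components: {sorted(bad)}")
        if "E" not in self.components:
            raise ValueError("the E component is mandatory")
        comps = tuple(c for c in _COMPONENT_ORDER if c in self.components)
        object.__setattr__(self, "components", comps)
        if self.rater and not any(self.teacher_rated):
            object.__setattr__(self, "rater", False)

    @property
    def n_phenotypes(self) -> int:
        return len(self.phenotypes)

    @property
    def teacher_idx(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.teacher_rated))

    def index_of(self, phenotype: str) -> int:
        try:
            return self.phenotypes.index(phenotype)
        except ValueError:
            raise KeyError(f"unknown phenotype {phenotype!r}") from None


def _as_lower_triangular(delta: np.ndarray, name: str = "delta") -> np.ndarray:
    delta = np.asarray(delta, dtype=float)
    if delta.ndim != 2 or delta.shape[0] != delta.shape[1]:
        raise ValueError(f"{name} must be a square matrix")
    if not np.allclose(delta, np.tril(delta)):
        raise ValueError(f"{name} must be lower triangular")
    return delta


@dataclass
class ADEParameters:
    """Cholesky factors, rater loadings and mean parameters of the model.

    ``delta_a``, ``delta_d``, ``delta_e`` (and optionally ``delta_c``) are
    M x M lower-triangular factors of the component covariance matrices.
    ``rater_loadings`` is a length-M vector, nonzero only at teacher-rated
    phenotypes.  ``intercepts`` and ``beta_sex`` parameterize the means.
    """

    delta_a: np.ndarray | None
    delta_d: np.ndarray | None
    delta_e: np.ndarray
    rater_loadings: np.ndarray | None = None
    intercepts: np.ndarray | None = None
    beta_sex: np.ndarray | None = None
    delta_c: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.delta_e = _as_lower_triangular(self.delta_e, "delta_e")
        m = self.delta_e.shape[0]
        for attr in ("delta_a", "delta_d", "delta_c"):
            val = getattr(self, attr)
            if val is not None:
                val = _as_lower_triangular(val, attr)
                if val.shape[0] != m:
                    raise ValueError(f"{attr} dimension mismatch")
                setattr(self, attr, val)
        for attr, default in (
            ("rater_loadings", 0.0),
            ("intercepts", 0.0),
            ("beta_sex", 0.0),
        ):
            val = getattr(self, attr)
            if val is None:
                val = np.full(m, default)
            else:
                val = np.asarray(val, dtype=float).ravel()
                if val.shape[0] != m:
                    raise ValueError(f"{attr} must have length {m}")
            setattr(self, attr, val)

    @property
    def n_phenotypes(self) -> int:
        return self.delta_e.shape[0]

    def delta(self, component: str) -> np.ndarray | None:
        return {
            "A": self.delta_a,
            "C": self.delta_c,
            "D": self.delta_d,
            "E": self.delta_e,
        }[component]

    def sigma(self, component: str) -> np.ndarray:
        """Component covariance ``Delta @ Delta.T`` (zeros if absent)."""
        d = self.delta(component)
        if d is None:
            m = self.n_phenotypes
            return np.zeros((m, m))
        return d @ d.T

    @property
    def sigma_rater(self) -> np.ndarray:
        lam = self.rater_loadings
        return np.outer(lam, lam)

    def copy(self) -> "ADEParameters":
        return replace(
            self,
            delta_a=None if self.delta_a is None else self.delta_a.copy(),
            delta_d=None if self.delta_d is None else self.delta_d.copy(),
            delta_c=None if self.delta_c is None else self.delta_c.copy(),
            delta_e=self.delta_e.copy(),
            rater_loadings=self.rater_loadings.copy(),
            intercepts=self.intercepts.copy(),
            beta_sex=self.beta_sex.copy(),
        )


@dataclass(frozen=True)
class GroupCovariance:
    """Expected 2M x 2M covariance for one zygosity-by-teacher-sharing group."""

    zygosity: str
    same_teacher: bool
    sigma: np.ndarray

    @property
    def n_phenotypes(self) -> int:
        return self.sigma.shape[0] // 2

    @property
    def within(self) -> np.ndarray:
        m = self.n_phenotypes
        return self.sigma[:m, :m]

    @property
    def cross(self) -> np.ndarray:
        m = self.n_phenotypes
        return self.sigma[m:, :m]


def cholesky_cov(delta: np.ndarray) -> np.ndarray:
    """Covariance implied by a lower-triangular factor: ``delta @ delta.T``."""
    delta = _as_lower_triangular(delta)
    return delta @ delta.T


def _check_zygosity(zygosity: str) -> str:
    z = str(zygosity).upper()
    if z not in ("MZ", "DZ"):
        raise ValueError(f"zygosity must be 'MZ' or 'DZ', got {zygosity!r}")
    return z


def group_blocks(
    params: ADEParameters,
    spec: ModelSpec,
    zygosity: str,
    same_teacher: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Within-twin and cross-twin M x M blocks for one group (no validation)."""
    zyg_i = 0 if zygosity == "MZ" else 1
    m = params.n_phenotypes
    within = np.zeros((m, m))
    cross = np.zeros((m, m))
    for comp in spec.components:
        s = params.sigma(comp)
        within += s
        w = CROSS_WEIGHTS[comp][zyg_i]
        if w:
            cross += w * s
    if spec.rater:
        sr = params.sigma_rater
        within += sr
        if same_teacher:
            cross += sr
    return within, cross


def build_group_cov(
    params: ADEParameters,
    zygosity: str,
    same_teacher: bool = False,
    spec: ModelSpec | None = None,
    validate: bool = True,
) -> GroupCovariance:
    """Assemble the expected 2M x 2M covariance for one group.

    The within-twin block is ``Sigma_A + Sigma_D + Sigma_E`` plus the rank-1
    rater covariance; the cross-twin block weights A and D by the zygosity's
    allele-sharing (1/1 for MZ, 0.5/0.25 for DZ) and includes the rater
    covariance only when the twins share a teacher.
    """
    zygosity = _check_zygosity(zygosity)
    if spec is None:
        spec = ModelSpec(
            phenotypes=tuple(f"P{i + 1}" for i in range(params.n_phenotypes)),
            teacher_rated=tuple(l != 0 for l in params.rater_loadings),
            components=tuple(
                c for c in ("A", "C", "D", "E") if params.delta(c) is not None
            ),
            rater=bool(np.any(params.rater_loadings != 0)),
        )
    if params.n_phenotypes != spec.n_phenotypes:
        raise ValueError("params dimension does not match spec phenotypes")
    if validate:
        sigma_e = params.sigma("E")
        if np.linalg.matrix_rank(sigma_e) < params.n_phenotypes:
            raise ValueError("improper E covariance (singular)")
        lam = params.rater_loadings
        if np.any(lam[~np.asarray(spec.teacher_rated)] != 0):
            raise ValueError("rater loading nonzero at a non-teacher phenotype")
    within, cross = group_blocks(params, spec, zygosity, same_teacher)
    sigma = np.block([[within, cross], [cross, within]])
    return GroupCovariance(zygosity=zygosity, same_teacher=same_teacher, sigma=sigma)


def build_means(params: ADEParameters, sex1: int, sex2: int) -> np.ndarray:
    """Length-2M mean vector: per-twin mean = intercepts + beta_sex * sex."""
    for s in (sex1, sex2):
        if s not in (0, 1):
            raise ValueError(f"sex must be coded 0 (boy) or 1 (girl), got {s!r}")
    return np.concatenate(
        [
            params.intercepts + params.beta_sex * sex1,
            params.intercepts + params.beta_sex * sex2,
        ]
    )


def expected_twin_correlations(
    params: ADEParameters,
    phenotype: int | str,
    spec: ModelSpec | None = None,
    same_teacher: bool = False,
) -> tuple[float, float]:
    """Model-implied within-phenotype cross-twin correlations (r_MZ, r_DZ).

    These drive the classical model-choice heuristic: r_MZ > 2 r_DZ points
    to dominance (ADE family) rather than shared environment (ACE).
    """
    if isinstance(phenotype, str):
        if spec is None:
            raise ValueError("a ModelSpec is required to resolve a phenotype label")
        j = spec.index_of(phenotype)
    else:
        j = int(phenotype)
    out = []
    for zyg in ("MZ", "DZ"):
        g = build_group_cov(params, zyg, same_teacher, spec=spec, validate=False)
        v = g.within[j, j]
        if v <= 0:
            raise ValueError("zero phenotypic variance, correlation undefined")
        out.append(g.cross[j, j] / v)
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Parameter vectorization.  The ordering is fixed so fits are reproducible:
# lower triangle of Delta_A (row-major), then Delta_C if active, Delta_D,
# Delta_E, rater loadings (teacher-rated slots only, or one shared value),
# intercepts, beta_sex.
# ---------------------------------------------------------------------------


def _tril_size(m: int) -> int:
    return m * (m + 1) // 2


def n_free_params(spec: ModelSpec) -> int:
    m = spec.n_phenotypes
    n = len(spec.components) * _tril_size(m)
    if spec.rater:
        n += 1 if spec.equal_rater_loadings else len(spec.teacher_idx)
    n += m  # intercepts
    if spec.sex_effect:
        n += m
    return n


def pack_parameters(params: ADEParameters, spec: ModelSpec) -> np.ndarray:
    m = spec.n_phenotypes
    rows, cols = np.tril_indices(m)
    parts: list[np.ndarray] = []
    for comp in spec.components:
        d = params.delta(comp)
        if d is None:
            raise ValueError(f"spec requires component {comp} but delta is missing")
        parts.append(d[rows, cols])
    if spec.rater:
        lam = params.rater_loadings[spec.teacher_idx]
        parts.append(lam[:1] if spec.equal_rater_loadings else lam)
    parts.append(params.intercepts)
    if spec.sex_effect:
        parts.append(params.beta_sex)
    return np.concatenate(parts)


def unpack_parameters(x: np.ndarray, spec: ModelSpec) -> ADEParameters:
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != n_free_params(spec):
        raise ValueError(
            f"expected {n_free_params(spec)} parameters, got {x.shape[0]}"
        )
    m = spec.n_phenotypes
    rows, cols = np.tril_indices(m)
    pos = 0
    deltas: dict[str, np.ndarray] = {}
    for comp in spec.components:
        d = np.zeros((m, m))
        d[rows, cols] = x[pos : pos + _tril_size(m)]
        pos += _tril_size(m)
        deltas[comp] = d
    lam = np.zeros(m)
    if spec.rater:
        if spec.equal_rater_loadings:
            lam[spec.teacher_idx] = x[pos]
            pos += 1
        else:
            lam[spec.teacher_idx] = x[pos : pos + len(spec.teacher_idx)]
            pos += len(spec.teacher_idx)
    intercepts = x[pos : pos + m]
    pos += m
    beta = x[pos : pos + m] if spec.sex_effect else np.zeros(m)
    return ADEParameters(
        delta_a=deltas.get("A"),
        delta_d=deltas.get("D"),
        delta_c=deltas.get("C"),
        delta_e=deltas["E"],
        rater_loadings=lam,
        intercepts=intercepts,
        beta_sex=beta,
    )


def canonicalize_signs(params: ADEParameters, spec: ModelSpec) -> ADEParameters:
    """Resolve the sign indeterminacy of the Cholesky parameterization.

    ``Delta @ Delta.T`` is invariant to flipping the sign of any column of
    ``Delta``; the convention here is nonnegative diagonals.  The rank-1
    rater covariance is invariant to a global sign flip of the loadings;
    the convention is a nonnegative first teacher loading.
    """
    out = params.copy()
    for comp in spec.components:
        d = out.delta(comp)
        if d is None:
            continue
        for k in range(d.shape[0]):
            if d[k, k] < 0:
                d[:, k] *= -1.0
    t = spec.teacher_idx
    if spec.rater and len(t) and out.rater_loadings[t[0]] < 0:
        out.rater_loadings *= -1.0
    return out
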