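"""Synthetic twin-pair data with the exact structure the ADE analysis assumes.

The registry data behind the published study are not public, so every
downstream stage is exercised on simulated pairs: multivariate-normal
phenotype vectors drawn from the model's group covariance (zygosity by
teacher-sharing), sex main effects on the means, an optional mapping back
to skewed left-censored raw scales, and blockwise missing data mimicking a
design where the SWAN was collected only in sub-projects and teacher
ratings exist only for pairs whose schools participated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ade_model import ADEParameters, ModelSpec, build_group_cov
from .transform import boxcox_inverse

__all__ = [
    "MissingnessSpec",
    "SimulationDesign",
    "RawScaleSpec",
    "simulate_pairs",
    "apply_raw_scale",
    "impose_missingness",
    "phenotype_block",
]

META_COLUMNS = ["pair_id", "zygosity", "sex1", "sex2", "same_teacher"]


@dataclass(frozen=True)
class MissingnessSpec:
    """Blockwise missing-data probabilities.

    ``mother_twin``: each twin's mother-rated (non-SWAN) block is missing
    independently.  ``swan_pair``: the SWAN block is missing for the whole
    pair (it was collected only in sub-projects, i.e. per family).
    ``teacher_twin``: each twin's teacher block is missing jointly (a twin
    is either rated by a teacher on all teacher scales or on none).
    Defaults mirror the registry study's sparsity.
    """

    mother_twin: float = 0.31
    swan_pair: float = 0.69
    teacher_twin: float = 0.56

    def __post_init__(self) -> None:
        for name in ("mother_twin", "swan_pair", "teacher_twin"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} probability must be in [0, 1], got {p}")


@dataclass(frozen=True)
class SimulationDesign:
    """Sample composition of a simulated twin study.

    Defaults reproduce the published study's conditions: 620 MZ and 973 DZ
    pairs, 48.2 % of DZ pairs opposite-sex, 57.2 % of teacher-rated pairs
    sharing a teacher, and blockwise missingness at registry magnitudes.
    """

    n_mz_pairs: int = 620
    n_dz_pairs: int = 973
    prop_female: float = 0.54
    prop_opposite_sex_dz: float = 0.482
    prop_same_teacher: float = 0.572
    missingness: MissingnessSpec = field(default_factory=MissingnessSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mz_pairs < 0 or self.n_dz_pairs < 0:
            raise ValueError("pair counts must be nonnegative")
        for name in ("prop_female", "prop_opposite_sex_dz", "prop_same_teacher"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")


@dataclass(frozen=True)
class RawScaleSpec:
    """How a latent (transform-scale) phenotype maps back to its raw scale.

    ``relative-normal`` scales (SWAN-like 7-point relative judgements) pass
    through unchanged; ``absolute-censored`` scales (symptom counts averaged
    over few items) are produced by inverting the power transform with
    exponent ``inverse_lambda`` and flooring at the censoring point, which
    yields the left-censored positively skewed distributions seen in real
    rating data.
    """

    phenotype: str
    kind: str = "relative-normal"
    inverse_lambda: float = -3.0
    floor: float = 0.0
    reverse_coded: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("relative-normal", "absolute-censored"):
            raise ValueError(f"unknown scale kind {self.kind!r}")
        if self.kind == "absolute-censored":
            if not np.isfinite(self.floor):
                raise ValueError("absolute-censored scales need a finite floor")
            if self.inverse_lambda == 0:
                raise ValueError("inverse_lambda must be nonzero")


def phenotype_block(phenotype: str, teacher_rated: bool) -> str:
    """Missingness block of a phenotype: 'swan', 'teacher' or 'mother'."""
    if teacher_rated:
        return "teacher"
    if phenotype.upper().startswith("SWAN"):
        return "swan"
    return "mother"


def simulate_pairs(
    params: ADEParameters,
    spec: ModelSpec,
    design: SimulationDesign,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw a wide-format twin dataset from the model run forward.

    Each pair's 2M phenotype vector is multivariate normal with mean given
    by the sex coefficients and covariance from the pair's zygosity and
    teacher-sharing group.  Opposite-sex DZ pairs share the same covariance
    structure as same-sex DZ pairs; sex enters the means only.
    """
    if params.n_phenotypes != spec.n_phenotypes:
        raise ValueError(
            f"params are {params.n_phenotypes}-variate but spec lists "
            f"{spec.n_phenotypes} phenotypes"
        )
    if rng is None:
        rng = np.random.default_rng(design.seed)
    m = spec.n_phenotypes
    n = design.n_mz_pairs + design.n_dz_pairs
    zyg = np.array(["MZ"] * design.n_mz_pairs + ["DZ"] * design.n_dz_pairs)

    # sexes: MZ pairs are same-sex; DZ pairs are opposite-sex with the given
    # probability, otherwise same-sex.  Twin order within opposite-sex pairs
    # is random.
    sex1 = np.empty(n, dtype=int)
    sex2 = np.empty(n, dtype=int)
    same_sex_female = rng.random(n) < design.prop_female
    sex1[:] = same_sex_female.astype(int)
    sex2[:] = sex1
    is_dz = zyg == "DZ"
    opp = is_dz & (rng.random(n) < design.prop_opposite_sex_dz)
    first_is_girl = rng.random(n) < 0.5
    sex1[opp] = first_is_girl[opp].astype(int)
    sex2[opp] = 1 - sex1[opp]

    same_teacher = rng.random(n) < design.prop_same_teacher

    y = np.empty((n, 2 * m))
    for zygosity in ("MZ", "DZ"):
        for st in (False, True):
            mask = (zyg == zygosity) & (same_teacher == st)
            k = int(mask.sum())
            if k == 0:
                continue
            cov = build_group_cov(params, zygosity, st, spec=spec, validate=False).sigma
            # degenerate covariances (e.g. a pure-A model) are legitimate to
            # simulate from; fall back to an eigenvalue square root
            try:
                chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                w, v = np.linalg.eigh(0.5 * (cov + cov.T))
                chol = v @ np.diag(np.sqrt(np.maximum(w, 0.0)))
            y[mask] = rng.standard_normal((k, 2 * m)) @ chol.T
    means = (
        np.tile(params.intercepts, 2)[None, :]
        + np.concatenate(
            [np.outer(sex1, params.beta_sex), np.outer(sex2, params.beta_sex)],
            axis=1,
        )
    )
    y += means

    data = {
        "pair_id": np.arange(1, n + 1),
        "zygosity": zyg,
        "sex1": sex1,
        "sex2": sex2,
        "same_teacher": same_teacher,
    }
    for j, p in enumerate(spec.phenotypes):
        data[f"{p}_1"] = y[:, j]
        data[f"{p}_2"] = y[:, m + j]
    return pd.DataFrame(data)


def apply_raw_scale(
    data: pd.DataFrame, specs: list[RawScaleSpec]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Map transform-scale phenotypes back to raw scales.

    Absolute-censored phenotypes are pushed through the inverse power
    transform and floored at the censoring point; latent values outside the
    image of the forward transform are clamped to the floor and counted.
    Returns the mapped dataset and the per-phenotype clamp counts.
    """
    out = data.copy()
    clamped: dict[str, int] = {}
    for rs in specs:
        cols = [f"{rs.phenotype}_1", f"{rs.phenotype}_2"]
        missing = [c for c in cols if c not in out.columns]
        if missing:
            raise KeyError(f"columns not found: {missing}")
        if rs.kind == "relative-normal":
            if rs.reverse_coded:
                out[cols] = -out[cols]
            continue
        n_clamped = 0
        for c in cols:
            t = out[c].to_numpy(dtype=float)
            obs = ~np.isnan(t)
            y = boxcox_inverse(t, rs.inverse_lambda)
            bad = obs & (np.isnan(y) | (y < rs.floor))
            n_clamped += int(bad.sum())
            y[bad] = rs.floor
            y[~obs] = np.nan
            if rs.reverse_coded:
                y = -y
            out[c] = y
        clamped[rs.phenotype] = n_clamped
    return out, clamped


def impose_missingness(
    data: pd.DataFrame,
    spec: ModelSpec,
    design: SimulationDesign,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Mask phenotype values blockwise, missing completely at random.

    The mother-rated block is masked per twin, the SWAN block per pair and
    the teacher block jointly per twin, with the probabilities in
    ``design.missingness``.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed + 1)
    ms = design.missingness
    out = data.copy()
    n = len(out)
    blocks: dict[str, list[str]] = {"mother": [], "swan": [], "teacher": []}
    for p, tr in zip(spec.phenotypes, spec.teacher_rated):
        blocks[phenotype_block(p, tr)].append(p)
    swan_pair = rng.random(n) < ms.swan_pair
    for twin in (1, 2):
        mother_twin = rng.random(n) < ms.mother_twin
        teacher_twin = rng.random(n) < ms.teacher_twin
        for block, mask in (
            ("mother", mother_twin),
            ("swan", swan_pair),
            ("teacher", teacher_twin),
        ):
            cols = [f"{p}_{twin}" for p in blocks[block]]
            if cols:
                out.loc[mask, cols] = np.nan
    return out
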