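"""From fitted Cholesky parameters to the quantities twin studies report.

Given component covariance matrices Sigma_A, Sigma_D, Sigma_E, this module
computes standardized variance components (narrow- and broad-sense
heritabilities, a2/d2/e2), component correlation matrices (genetic A, D,
A + D and environmental E), the proportion of each phenotypic covariance
attributable to broad-sense genetic effects, and the model-implied
phenotypic correlation matrix.  Rater variance is *excluded* from the
denominators throughout: the reported components describe the phenotypes
corrected for rater (and sex) effects.

The same chain can be run directly from published standardized summaries
(heritabilities plus component correlation matrices) via the
``*_from_tables`` helpers, which is how printed results of a study whose
raw data are private can be reconstructed and checked for internal
consistency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ade_model import ADEParameters

__all__ = [
    "DecompositionTables",
    "standardized_components",
    "component_correlations",
    "covariance_proportions",
    "implied_phenotypic_correlations",
    "bivariate_decomposition",
    "decompose",
    "implied_correlations_from_tables",
    "genetic_shares_from_tables",
]


@dataclass
class DecompositionTables:
    """The full derivation-chain output for one fitted model."""

    phenotypes: tuple[str, ...]
    std_components: pd.DataFrame
    corr_A: np.ndarray
    corr_D: np.ndarray
    corr_AD: np.ndarray
    corr_E: np.ndarray
    prop_AD: np.ndarray
    prop_E: np.ndarray
    implied_pheno_corr: np.ndarray


def _sigmas(params: ADEParameters) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return params.sigma("A"), params.sigma("D"), params.sigma("E")


def standardized_components(
    params: ADEParameters, phenotypes: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Per-phenotype a2, d2, e2 and broad-sense h2 = a2 + d2.

    The denominator is the A + D + E variance; rater variance is excluded,
    so adding a rater factor changes nothing here.
    """
    sa, sd, se = _sigmas(params)
    tot = np.diag(sa) + np.diag(sd) + np.diag(se)
    if np.any(tot <= 0):
        raise ValueError("zero total (A+D+E) variance for some phenotype")
    a2 = np.diag(sa) / tot
    d2 = np.diag(sd) / tot
    e2 = np.diag(se) / tot
    idx = (
        list(phenotypes)
        if phenotypes is not None
        else [f"P{i + 1}" for i in range(len(tot))]
    )
    return pd.DataFrame(
        {"a2": a2, "d2": d2, "e2": e2, "h2_broad": a2 + d2}, index=idx
    )


def _corr_from_cov(cov: np.ndarray) -> np.ndarray:
    """Correlation matrix; entries involving a zero variance are NaN, not 0."""
    v = np.diag(cov).copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(v > 0, np.sqrt(v), np.nan)
        out = cov / np.outer(s, s)
    return out


def component_correlations(
    params: ADEParameters,
) -> dict[str, np.ndarray]:
    """A, D, A + D and E correlation matrices.

    corr_X[i, j] = Sigma_X[i, j] / sqrt(Sigma_X[i, i] * Sigma_X[j, j]);
    the A + D matrix uses the summed genetic covariance.  Entries whose
    component variance is estimated at zero are undefined and reported as
    NaN — a phenotype can have no additive variance, in which case its
    additive correlations do not exist rather than being zero.
    """
    sa, sd, se = _sigmas(params)
    return {
        "A": _corr_from_cov(sa),
        "D": _corr_from_cov(sd),
        "AD": _corr_from_cov(sa + sd),
        "E": _corr_from_cov(se),
    }


def covariance_proportions(
    params: ADEParameters,
) -> tuple[np.ndarray, np.ndarray]:
    """Proportions of phenotypic (co)variance attributable to A + D and to E.

    Elementwise (Sigma_A + Sigma_D) / (Sigma_A + Sigma_D + Sigma_E) and its
    E complement; the diagonal of the genetic matrix is the broad-sense
    heritability.  Off-diagonal entries with zero total covariance are NaN.
    """
    sa, sd, se = _sigmas(params)
    tot = sa + sd + se
    with np.errstate(invalid="ignore", divide="ignore"):
        prop_ad = np.where(tot != 0, (sa + sd) / tot, np.nan)
        prop_e = np.where(tot != 0, se / tot, np.nan)
    return prop_ad, prop_e


def implied_phenotypic_correlations(params: ADEParameters) -> np.ndarray:
    """Model-implied phenotypic correlation matrix.

    Computed two algebraically identical ways and cross-checked: (i) the
    path rule r_ph[i,j] = sqrt(h2_i) * r_AD[i,j] * sqrt(h2_j)
    + sqrt(e2_i) * r_E[i,j] * sqrt(e2_j); (ii) normalizing
    Sigma_A + Sigma_D + Sigma_E to a correlation matrix.
    """
    sa, sd, se = _sigmas(params)
    direct = _corr_from_cov(sa + sd + se)
    comps = standardized_components(params)
    corr = component_correlations(params)
    h = np.sqrt(comps["h2_broad"].to_numpy())
    e = np.sqrt(comps["e2"].to_numpy())
    r_ad = np.nan_to_num(corr["AD"])
    r_e = np.nan_to_num(corr["E"])
    paths = np.outer(h, h) * r_ad + np.outer(e, e) * r_e
    np.fill_diagonal(paths, 1.0)
    if not np.allclose(paths, direct, atol=1e-10, equal_nan=True):
        raise AssertionError("path-rule and normalization routes disagree")
    return direct


@dataclass
class BivariateDecomposition:
    """The two-phenotype narrative: paths behind one phenotypic correlation."""

    phenotype_i: str
    phenotype_j: str
    h2_i: float
    h2_j: float
    e2_i: float
    e2_j: float
    corr_AD: float
    corr_E: float
    genetic_path: float
    environmental_path: float
    implied_phenotypic_corr: float
    genetic_share: float

    def __str__(self) -> str:  # Fig-2-style text block
        return (
            f"Bivariate decomposition: {self.phenotype_i} vs {self.phenotype_j}\n"
            f"  broad-sense h2: {self.h2_i:.3f} / {self.h2_j:.3f}\n"
            f"  A+D correlation: {self.corr_AD:.3f}   E correlation: {self.corr_E:.3f}\n"
            f"  genetic path  sqrt(h2_i)*r_AD*sqrt(h2_j) = {self.genetic_path:.3f}\n"
            f"  environment   sqrt(e2_i)*r_E *sqrt(e2_j) = {self.environmental_path:.3f}\n"
            f"  implied phenotypic correlation = {self.implied_phenotypic_corr:.3f}\n"
            f"  genetic share of the covariance = {self.genetic_share:.3f}\n"
        )


def bivariate_decomposition(
    params: ADEParameters,
    i: int | str,
    j: int | str,
    phenotypes: tuple[str, ...] | None = None,
) -> BivariateDecomposition:
    """Decompose one phenotypic correlation into its genetic and E paths."""
    if phenotypes is not None:
        i = phenotypes.index(i) if isinstance(i, str) else int(i)
        j = phenotypes.index(j) if isinstance(j, str) else int(j)
    i, j = int(i), int(j)
    if i == j:
        raise ValueError("bivariate decomposition needs two distinct phenotypes")
    comps = standardized_components(params)
    corr = component_correlations(params)
    h2 = comps["h2_broad"].to_numpy()
    e2 = comps["e2"].to_numpy()
    r_ad = corr["AD"][i, j]
    r_e = corr["E"][i, j]
    gpath = float(np.sqrt(h2[i]) * r_ad * np.sqrt(h2[j]))
    epath = float(np.sqrt(e2[i]) * r_e * np.sqrt(e2[j]))
    total = gpath + epath
    labels = phenotypes or tuple(f"P{k + 1}" for k in range(len(h2)))
    return BivariateDecomposition(
        phenotype_i=labels[i],
        phenotype_j=labels[j],
        h2_i=float(h2[i]),
        h2_j=float(h2[j]),
        e2_i=float(e2[i]),
        e2_j=float(e2[j]),
        corr_AD=float(r_ad),
        corr_E=float(r_e),
        genetic_path=gpath,
        environmental_path=epath,
        implied_phenotypic_corr=total,
        genetic_share=float(gpath / total) if total != 0 else float("nan"),
    )


def decompose(
    params: ADEParameters, phenotypes: tuple[str, ...] | None = None
) -> DecompositionTables:
    """Run the whole derivation chain for one parameter set."""
    comps = standardized_components(params, phenotypes)
    corr = component_correlations(params)
    prop_ad, prop_e = covariance_proportions(params)
    return DecompositionTables(
        phenotypes=tuple(comps.index),
        std_components=comps,
        corr_A=corr["A"],
        corr_D=corr["D"],
        corr_AD=corr["AD"],
        corr_E=corr["E"],
        prop_AD=prop_ad,
        prop_E=prop_e,
        implied_pheno_corr=implied_phenotypic_correlations(params),
    )


# ---------------------------------------------------------------------------
# reconstruction from printed standardized summaries
# ---------------------------------------------------------------------------


def implied_correlations_from_tables(
    h2: np.ndarray, e2: np.ndarray, corr_ad: np.ndarray, corr_e: np.ndarray
) -> np.ndarray:
    """Phenotypic correlations implied by standardized summary tables.

    r_ph[i, j] = sqrt(h2_i) * r_AD[i, j] * sqrt(h2_j)
               + sqrt(e2_i) * r_E[i, j] * sqrt(e2_j).
    """
    h = np.sqrt(np.asarray(h2, dtype=float))
    e = np.sqrt(np.asarray(e2, dtype=float))
    out = np.outer(h, h) * np.asarray(corr_ad) + np.outer(e, e) * np.asarray(corr_e)
    np.fill_diagonal(out, 1.0)
    return out


def genetic_shares_from_tables(
    h2: np.ndarray, e2: np.ndarray, corr_ad: np.ndarray, corr_e: np.ndarray
) -> np.ndarray:
    """Share of each implied phenotypic covariance carried by the genetic path."""
    h = np.sqrt(np.asarray(h2, dtype=float))
    e = np.sqrt(np.asarray(e2, dtype=float))
    genetic = np.outer(h, h) * np.asarray(corr_ad)
    total = genetic + np.outer(e, e) * np.asarray(corr_e)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total != 0, genetic / total, np.nan)
    return out
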