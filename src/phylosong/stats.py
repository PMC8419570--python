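"""Distance-matrix comparison statistics.

Four analyses relate an acoustic distance matrix (or the nine per-feature
matrices) to a genetic distance matrix over the same species:

* closest-relative test — paired t-test across species of the acoustic
  distance to the closest genetic relative vs the mean acoustic distance to
  all other species;
* per-species correlations — Pearson r between a species' genetic distances
  and each of its nine acoustic feature distances, averaged per species;
* Mantel test — permutation test for correlation between two distance
  matrices, jointly relabelling rows and columns (one-tailed, greater);
* body-mass-controlled regressions — per-species OLS of genetic distance on
  the nine feature distances plus absolute log body-mass differences, all
  variables z-scored within the regression; betas averaged across species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .distances import DistanceMatrix
from .exceptions import DegenerateMatrixError, LabelAlignmentError

logger = logging.getLogger(__name__)


def _aligned(Dg: DistanceMatrix, other: DistanceMatrix) -> DistanceMatrix:
    if set(Dg.labels) != set(other.labels):
        missing = sorted(set(Dg.labels) - set(other.labels))
        extra = sorted(set(other.labels) - set(Dg.labels))
        raise LabelAlignmentError(
            f"distance matrices disagree on species "
            f"(missing: {missing}, extra: {extra})",
            missing=missing,
            extra=extra,
        )
    return other.reorder(Dg.labels)


# ---------------------------------------------------------------------------
# closest-relative test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestResult:
    """Paired t-test: acoustic distance to closest relative vs others."""

    statistic: float
    df: int
    p: float
    per_species: pd.DataFrame = field(repr=False)  # columns d_closest, d_other


def closest_relative_test(Dg: DistanceMatrix, Da: DistanceMatrix) -> TestResult:
    """Is each species acoustically closer to its closest genetic relative?

    For species i, d_closest is the acoustic distance to the species with the
    smallest genetic distance to i (ties averaged), and d_other is the mean
    acoustic distance to the remaining species (closest excluded). The paired
    two-tailed t-test is on d_other - d_closest with df = n - 1.
    """
    if Dg.n < 3:
        raise ValueError("closest-relative test needs at least 3 species")
    Da = _aligned(Dg, Da)
    n = Dg.n
    d_closest = np.empty(n)
    d_other = np.empty(n)
    for i in range(n):
        g = Dg.values[i].copy()
        g[i] = np.inf
        gmin = g.min()
        tied = np.isclose(g, gmin) & (np.arange(n) != i)
        others = (~tied) & (np.arange(n) != i)
        d_closest[i] = Da.values[i, tied].mean()
        d_other[i] = Da.values[i, others].mean() if others.any() else np.nan
    per_species = pd.DataFrame(
        {"d_closest": d_closest, "d_other": d_other}, index=Dg.labels
    )
    diffs = d_other - d_closest
    if np.allclose(diffs, 0.0):
        t, p = 0.0, 1.0
    else:
        t, p = scipy.stats.ttest_1samp(diffs, 0.0)
    return TestResult(float(t), n - 1, float(p), per_species)


# ---------------------------------------------------------------------------
# per-species correlations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesCorrelationResult:
    per_species_r: pd.Series = field(repr=False)  # mean r over features
    per_species_by_feature: pd.DataFrame = field(repr=False)
    mean_r: float = 0.0
    sd_r: float = 0.0


def species_mean_correlations(Dg: DistanceMatrix, feature_matrices) -> SpeciesCorrelationResult:
    """Per-species Pearson r between genetic and acoustic feature distances.

    For species i and feature f, r is the correlation over j != i between
    Dg(i, j) and D_f(i, j); the species' score is the mean r over the
    features. Feature/species combinations with zero variance in either
    vector are skipped and logged.
    """
    if Dg.n < 4:
        raise ValueError("per-species correlations need at least 4 species")
    mats = {name: _aligned(Dg, m) for name, m in dict(feature_matrices).items()}
    n = Dg.n
    rows = {}
    for i, sp in enumerate(Dg.labels):
        mask = np.arange(n) != i
        g = Dg.values[i, mask]
        rs = {}
        for name, m in mats.items():
            a = m.values[i, mask]
            if np.ptp(g) == 0 or np.ptp(a) == 0:
                logger.warning(
                    "species %s / feature %s: constant distances, r skipped",
                    sp, name,
                )
                rs[name] = np.nan
                continue
            rs[name] = scipy.stats.pearsonr(g, a).statistic
        rows[sp] = rs
    by_feature = pd.DataFrame.from_dict(rows, orient="index")
    per_species = by_feature.mean(axis=1, skipna=True)
    return SpeciesCorrelationResult(
        per_species_r=per_species,
        per_species_by_feature=by_feature,
        mean_r=float(per_species.mean()),
        sd_r=float(per_species.std(ddof=1)),
    )


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int
    tail: str = "greater"


def mantel_test(
    D1: DistanceMatrix, D2: DistanceMatrix, n_perm: int = 5000, seed: int = 0
) -> MantelResult:
    """Permutation Mantel test (one-tailed, greater).

    r is the Pearson correlation of the upper-triangle off-diagonals. The
    null distribution relabels the rows and columns of D2 jointly n_perm
    times; p is the proportion of permuted r >= observed r (permutations
    only in the denominator, so p = 0 is attainable).
    """
    if D1.n < 3:
        raise ValueError("Mantel test needs at least 3 objects")
    D2 = _aligned(D1, D2)
    n = D1.n
    iu = np.triu_indices(n, k=1)
    v1 = D1.values[iu]
    v2 = D2.values[iu]
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        raise DegenerateMatrixError(
            "constant off-diagonal distances; Mantel r undefined"
        )
    v1c = v1 - v1.mean()
    v1c /= np.linalg.norm(v1c)

    def corr(vec):
        vc = vec - vec.mean()
        return float(v1c @ vc / np.linalg.norm(vc))

    r_obs = corr(v2)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        vp = D2.values[np.ix_(perm, perm)][iu]
        if corr(vp) >= r_obs:
            count += 1
    return MantelResult(r_obs, count / n_perm, n_perm)


# ---------------------------------------------------------------------------
# body-mass-controlled regressions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionResult:
    """Standardized per-species OLS betas and their across-species summary."""

    per_species_beta: pd.DataFrame = field(repr=False)
    mean_beta: pd.Series = field(repr=False)
    sd_beta: pd.Series = field(repr=False)
    skipped: tuple = ()


def _zscore(a: np.ndarray) -> np.ndarray:
    return (a - a.mean()) / a.std(ddof=1)


def species_regressions(
    Dg: DistanceMatrix, feature_matrices, masses
) -> RegressionResult:
    """Per-species OLS of genetic distance on feature distances + log-mass.

    For each species i the response Dg(i, j), j != i, is regressed on the
    nine acoustic feature distances and |ln m_i - ln m_j|; response and
    predictors are z-scored within each regression so betas are standardized
    and comparable across predictors. Species with rank-deficient designs
    are skipped and logged. Betas are summarized as mean +/- sd across
    species.
    """
    mats = {name: _aligned(Dg, m) for name, m in dict(feature_matrices).items()}
    masses = pd.Series(masses).astype(float)
    masses.index = masses.index.astype(str)
    if (masses <= 0).any():
        raise ValueError("body masses must be positive")
    missing = [sp for sp in Dg.labels if sp not in masses.index]
    if missing:
        raise LabelAlignmentError(
            f"species missing from body-mass table: {missing}", missing=missing
        )
    n = Dg.n
    p = len(mats) + 1
    if n - 1 < p + 2:
        raise ValueError(
            f"{n} species give {n - 1} observations per regression; "
            f"need at least {p + 2} for {p} predictors"
        )
    logm = np.log(masses[list(Dg.labels)].to_numpy())
    names = list(mats) + ["log_mass"]
    betas, skipped = {}, []
    for i, sp in enumerate(Dg.labels):
        mask = np.arange(n) != i
        y = Dg.values[i, mask]
        cols = [m.values[i, mask] for m in mats.values()]
        cols.append(np.abs(logm[i] - logm[mask]))
        X = np.column_stack(cols)
        if np.ptp(y) == 0 or np.any(np.ptp(X, axis=0) == 0):
            logger.warning("species %s: constant response/predictor, skipped", sp)
            skipped.append(sp)
            continue
        Xz = np.apply_along_axis(_zscore, 0, X)
        yz = _zscore(y)
        if np.linalg.matrix_rank(Xz) < Xz.shape[1]:
            logger.warning("species %s: rank-deficient design, skipped", sp)
            skipped.append(sp)
            continue
        design = np.column_stack([np.ones(len(yz)), Xz])
        beta, *_ = np.linalg.lstsq(design, yz, rcond=None)
        betas[sp] = beta[1:]
    if not betas:
        raise DegenerateMatrixError("all species-wise regressions were skipped")
    per_species = pd.DataFrame.from_dict(betas, orient="index", columns=names)
    return RegressionResult(
        per_species_beta=per_species,
        mean_beta=per_species.mean(),
        sd_beta=per_species.std(ddof=1),
        skipped=tuple(skipped),
    )
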