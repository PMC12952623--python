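"""Twin variance-component modelling of edge phenotypes.

The classical univariate twin design: a trait measured in monozygotic (MZ)
and dizygotic (DZ) pairs is decomposed into additive genetic (A), common
environment (C) or dominance (D), and unique environment (E) variance.  A
pair's two values are modelled as bivariate normal with a common mean and an
exchangeable covariance whose off-diagonal encodes genetic sharing:

    ACE:  var = a2 + c2 + e2,  cov_MZ = a2 + c2,        cov_DZ = a2/2 + c2
    ADE:  var = a2 + d2 + e2,  cov_MZ = a2 + d2,        cov_DZ = a2/2 + d2/4
    AE :  var = a2 + e2,       cov_MZ = a2,             cov_DZ = a2/2
    E  :  var = e2,            cov = 0

Fits are maximum likelihood in the path-coefficient parameterization
(optimize a, c, e unconstrained, square for variances), with the phenotype
z-standardized cohort-wide first.  The likelihood is evaluated from per-
zygosity sufficient statistics, so a fit costs the same for 16 pairs as for
40000.  Model choice follows the twin-literature recipe: intraclass
correlations decide ACE vs ADE, AIC decides whether C (or D) is retained,
and the significance of A is a likelihood-ratio test of AE against E.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .io import RegionGroupMap

ModelName = Literal["ACE", "ADE", "AE", "E"]

_LOG_2PI = float(np.log(2.0 * np.pi))


class GeneticsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Paired phenotypes and sufficient statistics

@dataclass(frozen=True)
class PairStats:
    """Sufficient statistics of one zygosity group for the pair likelihood."""

    n: int          # number of pairs
    t: float        # sum of (x1 + x2)
    q: float        # sum of (x1^2 + x2^2)
    p: float        # sum of (x1 * x2)

    @classmethod
    def from_values(cls, v1: np.ndarray, v2: np.ndarray) -> "PairStats":
        v1 = np.asarray(v1, dtype=float)
        v2 = np.asarray(v2, dtype=float)
        return cls(n=len(v1), t=float(np.sum(v1 + v2)),
                   q=float(np.sum(v1 ** 2 + v2 ** 2)),
                   p=float(np.sum(v1 * v2)))


def _split_pairs(pairs: pd.DataFrame) -> tuple[PairStats, PairStats]:
    """(MZ stats, DZ stats) from a (zygosity, value1, value2) frame."""
    for col in ("zygosity", "value1", "value2"):
        if col not in pairs.columns:
            raise GeneticsError(f"paired phenotype frame missing column {col!r}")
    vals = pairs[["value1", "value2"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise GeneticsError("non-finite phenotype value")
    mz = pairs[pairs["zygosity"] == "MZ"]
    dz = pairs[pairs["zygosity"] == "DZ"]
    return (PairStats.from_values(mz["value1"].to_numpy(), mz["value2"].to_numpy()),
            PairStats.from_values(dz["value1"].to_numpy(), dz["value2"].to_numpy()))


def standardize_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Z-standardize value1/value2 jointly across the whole cohort."""
    out = pairs.copy()
    vals = out[["value1", "value2"]].to_numpy(dtype=float)
    mu = vals.mean()
    sd = vals.std(ddof=0)
    if sd == 0:
        raise GeneticsError("phenotype has zero variance across the cohort")
    out[["value1", "value2"]] = (vals - mu) / sd
    return out


# ---------------------------------------------------------------------------
# Intraclass correlation and family choice

def intraclass_correlation(values1: Iterable[float],
                           values2: Iterable[float]) -> float:
    """One-way random-effects ANOVA ICC for groups of size two.

    ICC = (MSB - MSW) / (MSB + MSW) with MSB the between-pair and MSW the
    within-pair mean square; clipped to [-1, 1].  Requires >= 3 pairs.
    """
    v1 = np.asarray(list(values1), dtype=float)
    v2 = np.asarray(list(values2), dtype=float)
    n = len(v1)
    if n < 3 or len(v2) != n:
        raise GeneticsError("ICC needs at least 3 complete pairs")
    means = (v1 + v2) / 2.0
    grand = means.mean()
    msb = 2.0 * np.sum((means - grand) ** 2) / (n - 1)
    msw = np.sum((v1 - v2) ** 2) / (2.0 * n)
    denom = msb + msw
    if denom == 0:
        return 0.0
    return float(np.clip((msb - msw) / denom, -1.0, 1.0))


def twin_iccs(pairs: pd.DataFrame) -> tuple[float, float]:
    """(rMZ, rDZ) intraclass correlations of a paired-phenotype frame."""
    mz = pairs[pairs["zygosity"] == "MZ"]
    dz = pairs[pairs["zygosity"] == "DZ"]
    return (intraclass_correlation(mz["value1"], mz["value2"]),
            intraclass_correlation(dz["value1"], dz["value2"]))


def choose_family(r_mz: float, r_dz: float) -> ModelName:
    """ADE when rMZ exceeds twice rDZ (dominance signature), else ACE.

    The boundary rMZ == 2 rDZ goes to ACE: equality is the purely additive
    pattern and C, unlike D, can absorb any residual shared similarity.
    """
    if not (np.isfinite(r_mz) and np.isfinite(r_dz)):
        raise GeneticsError("ICCs must be finite")
    return "ADE" if r_mz > 2.0 * r_dz else "ACE"


# ---------------------------------------------------------------------------
# Maximum-likelihood fits

@dataclass
class VarianceComponentFit:
    """One model's ML solution on the standardized phenotype."""

    model: ModelName
    a2: float
    c2: float          # D variance under ADE; 0 under AE/E
    e2: float
    mean: float
    loglik: float
    n_params: int
    converged: bool

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    @property
    def total_variance(self) -> float:
        return self.a2 + self.c2 + self.e2

    @property
    def a_fraction(self) -> float:
        tot = self.total_variance
        return self.a2 / tot if tot > 0 else 0.0


def _group_loglik(s: PairStats, mu: float, var: float, cov: float) -> float:
    """Bivariate-normal log-likelihood of one zygosity group at (mu, var, cov)."""
    if s.n == 0:
        return 0.0
    det = var * var - cov * cov
    if det <= 0 or var <= 0:
        return -np.inf
    qq = s.q - 2.0 * mu * s.t + 2.0 * s.n * mu * mu      # sum (x-mu)^2+(y-mu)^2
    pp = s.p - mu * s.t + s.n * mu * mu                  # sum (x-mu)(y-mu)
    return (-s.n * _LOG_2PI - 0.5 * s.n * np.log(det)
            - (var * qq - 2.0 * cov * pp) / (2.0 * det))


def _model_cov(model: ModelName, a2: float, c2: float,
               e2: float) -> tuple[float, float, float]:
    """(var, cov_MZ, cov_DZ) for the component variances of a model."""
    var = a2 + c2 + e2
    if model == "ACE":
        return var, a2 + c2, 0.5 * a2 + c2
    if model == "ADE":
        return var, a2 + c2, 0.5 * a2 + 0.25 * c2
    if model == "AE":
        return var, a2, 0.5 * a2
    if model == "E":
        return var, 0.0, 0.0
    raise GeneticsError(f"unknown model {model!r}")


def pair_loglik(model: ModelName, mz: PairStats, dz: PairStats, mu: float,
                a2: float, c2: float, e2: float) -> float:
    var, cov_mz, cov_dz = _model_cov(model, a2, c2, e2)
    return (_group_loglik(mz, mu, var, cov_mz)
            + _group_loglik(dz, mu, var, cov_dz))


_N_PARAMS = {"ACE": 4, "ADE": 4, "AE": 3, "E": 2}


def _fit_e(mz: PairStats, dz: PairStats) -> VarianceComponentFit:
    # Independent-normal ML is closed form: grand mean, mean squared deviation.
    n_obs = 2 * (mz.n + dz.n)
    mu = (mz.t + dz.t) / n_obs
    q = mz.q + dz.q
    e2 = q / n_obs - mu * mu
    if e2 <= 0:
        raise GeneticsError("phenotype has zero variance; E model undefined")
    ll = pair_loglik("E", mz, dz, mu, 0.0, 0.0, e2)
    return VarianceComponentFit("E", 0.0, 0.0, e2, mu, ll, _N_PARAMS["E"], True)


def _starting_points(model: ModelName, mz: PairStats, dz: PairStats,
                     ) -> list[np.ndarray]:
    """Multi-start path coefficients: Falconer-derived, equal split, E-dominant."""
    def icc(s: PairStats) -> float:
        if s.n < 2:
            return 0.0
        mu = s.t / (2 * s.n)
        var = s.q / (2 * s.n) - mu * mu
        cov = s.p / s.n - mu * mu
        return cov / var if var > 0 else 0.0

    r_mz, r_dz = icc(mz), icc(dz)
    a2 = float(np.clip(2.0 * (r_mz - r_dz), 0.01, 0.95))
    c2 = float(np.clip(2.0 * r_dz - r_mz, 0.01, 0.95))
    e2 = float(np.clip(1.0 - r_mz, 0.05, 0.99))
    mu0 = (mz.t + dz.t) / (2 * (mz.n + dz.n))
    starts = []
    if model in ("ACE", "ADE"):
        starts.append([mu0, np.sqrt(a2), np.sqrt(c2), np.sqrt(e2)])
        starts.append([mu0, np.sqrt(1 / 3), np.sqrt(1 / 3), np.sqrt(1 / 3)])
        starts.append([mu0, 0.1, 0.1, 1.0])
    else:  # AE
        starts.append([mu0, np.sqrt(np.clip(a2 + c2, 0.01, 0.95)),
                       np.sqrt(e2)])
        starts.append([mu0, np.sqrt(0.5), np.sqrt(0.5)])
        starts.append([mu0, 0.1, 1.0])
    return [np.array(s, dtype=float) for s in starts]


def fit_variance_components(pairs: pd.DataFrame, model: ModelName,
                            standardize: bool = True) -> VarianceComponentFit:
    """ML fit of one twin model to a (zygosity, value1, value2) frame.

    The phenotype is z-standardized cohort-wide first (disable with
    ``standardize=False`` for pre-scaled data).  Requires >= 4 pairs per
    zygosity.  The optimizer is quasi-Newton (L-BFGS-B) on the free mean and
    the path coefficients; three starts are tried and the best kept.
    """
    if standardize:
        pairs = standardize_pairs(pairs)
    mz, dz = _split_pairs(pairs)
    if mz.n < 4 or dz.n < 4:
        raise GeneticsError(
            f"need >= 4 pairs per zygosity for ML fit (got {mz.n} MZ, {dz.n} DZ)"
        )
    if model == "E":
        return _fit_e(mz, dz)
    if model not in _N_PARAMS:
        raise GeneticsError(f"unknown model {model!r}")

    has_c = model in ("ACE", "ADE")

    # Tiny floor on e2 keeps the likelihood bounded when the ML solution sits
    # on the e -> 0 boundary (e.g. twins that are exact copies); negligible
    # (< 1e-8 variance units) away from the boundary.
    e2_floor = 1e-8

    def negll(theta: np.ndarray) -> float:
        mu = theta[0]
        a2 = theta[1] ** 2
        c2 = theta[2] ** 2 if has_c else 0.0
        e2 = theta[-1] ** 2 + e2_floor
        ll = pair_loglik(model, mz, dz, mu, a2, c2, e2)
        if not np.isfinite(ll):
            return 1e12
        return -ll

    best: optimize.OptimizeResult | None = None
    any_converged = False
    for x0 in _starting_points(model, mz, dz):
        res = optimize.minimize(negll, x0, method="L-BFGS-B",
                                options={"maxiter": 500, "ftol": 1e-12,
                                         "gtol": 1e-8})
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    theta = best.x
    a2 = float(theta[1] ** 2)
    c2 = float(theta[2] ** 2) if has_c else 0.0
    e2 = float(theta[-1] ** 2 + e2_floor)
    ll = pair_loglik(model, mz, dz, float(theta[0]), a2, c2, e2)
    if not any_converged:
        raise GeneticsError(f"{model} fit did not converge after multi-start")
    return VarianceComponentFit(model, a2, c2, e2, float(theta[0]), float(ll),
                                _N_PARAMS[model], True)


def select_model(fit_full: VarianceComponentFit,
                 fit_ae: VarianceComponentFit) -> VarianceComponentFit:
    """AIC model selection between the full (ACE/ADE) and the AE fit.

    Ties go to AE, the model with fewer parameters.
    """
    if not (fit_full.converged and fit_ae.converged):
        raise GeneticsError("model selection requires converged fits")
    return fit_ae if fit_ae.aic <= fit_full.aic else fit_full


def heritability_percent(fit: VarianceComponentFit) -> float:
    """Heritability of an AE fit: a2 / (a2 + e2) x 100."""
    if fit.model != "AE":
        raise GeneticsError("heritability_percent is defined for the AE model")
    tot = fit.a2 + fit.e2
    if tot == 0:
        raise GeneticsError("a2 + e2 is zero")
    return 100.0 * fit.a2 / tot


def test_genetic_effect(pairs: pd.DataFrame, standardize: bool = True,
                        boundary_mixture: bool = False,
                        ) -> tuple[float, float, VarianceComponentFit,
                                   VarianceComponentFit]:
    """Likelihood-ratio test of A: AE against the E submodel.

    chi2 = 2 (logL_AE - logL_E), clipped at zero.  The reference distribution
    is chi-square with 1 df; since a2 sits on the boundary of its space this
    is conservative.  ``boundary_mixture=True`` uses the 0.5*chi2(0) +
    0.5*chi2(1) mixture instead (less conservative).

    Returns (chi2, p, fit_ae, fit_e).
    """
    if standardize:
        pairs = standardize_pairs(pairs)
    fit_ae = fit_variance_components(pairs, "AE", standardize=False)
    fit_e = fit_variance_components(pairs, "E", standardize=False)
    chi2 = max(0.0, 2.0 * (fit_ae.loglik - fit_e.loglik))
    p = float(stats.chi2.sf(chi2, df=1))
    if boundary_mixture:
        p = 0.5 * p if chi2 > 0 else 1.0
    if chi2 == 0.0:
        p = 1.0
    return chi2, p, fit_ae, fit_e


# not a unit test, despite the field-standard name
test_genetic_effect.__test__ = False  # type: ignore[attr-defined]


def adjust_pvalues(pvalues: Sequence[float],
                   method: Literal["bonferroni", "bh"] = "bonferroni",
                   alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Multiple-testing correction: (adjusted p, significance flags)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise GeneticsError("p-values must lie in [0, 1]")
    sm_method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[method]
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method=sm_method)
    return p_adj, reject


def compare_mz_dz_similarity(r_mz: float, r_dz: float, n_mz: int,
                             n_dz: int) -> tuple[float, float]:
    """Fisher r-to-z comparison of MZ and DZ intraclass correlations.

    z = (atanh rMZ - atanh rDZ) / sqrt(1/(nMZ-3) + 1/(nDZ-3)), two-sided p.
    Correlations at +-1 are clipped to +-0.999999 with a warning.
    """
    if n_mz <= 3 or n_dz <= 3:
        raise GeneticsError("need more than 3 pairs per zygosity")
    import logging
    clip = 0.999999
    if abs(r_mz) >= 1 or abs(r_dz) >= 1:
        logging.getLogger("twinconn").warning(
            "ICC at +-1 clipped to +-%g for Fisher z", clip)
    zm = np.arctanh(np.clip(r_mz, -clip, clip))
    zd = np.arctanh(np.clip(r_dz, -clip, clip))
    z = (zm - zd) / np.sqrt(1.0 / (n_mz - 3) + 1.0 / (n_dz - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# Per-edge scan and summaries

@dataclass
class EdgeGeneticsResult:
    edge: tuple[str, str]
    model: ModelName
    a_fraction: float
    chi2: float
    p: float
    p_adjusted: float = float("nan")
    significant: bool = False
    r_mz: float = float("nan")
    r_dz: float = float("nan")


def edge_heritability_scan(table, manifest,
                           family: Literal["auto", "ACE", "ADE", "AE"] = "auto",
                           correction: Literal["bonferroni", "bh"] = "bonferroni",
                           alpha: float = 0.05) -> pd.DataFrame:
    """Fit the twin model to every edge of a differential phenotype table.

    Per edge: intraclass correlations per zygosity, family choice (ACE vs
    ADE by the rMZ vs 2 rDZ rule, unless forced), AIC selection of the full
    model against AE, and the AE-vs-E likelihood-ratio test of A, corrected
    across edges.  The reported ``A_effect`` is the additive fraction of the
    AIC-selected model.

    Returns a DataFrame with columns ROI1, ROI2, A_effect, chi2, p,
    p_adjusted, significant, model, r_mz, r_dz.
    """
    from .io import TwinManifest  # local import to avoid cycle in type hints

    if not isinstance(manifest, TwinManifest):
        raise GeneticsError("manifest must be a TwinManifest")
    if manifest.n_mz < 4 or manifest.n_dz < 4:
        raise GeneticsError("need >= 4 pairs per zygosity")
    rows = []
    for edge in table.edges:
        col = table.values[edge]
        recs = []
        for p_ in manifest.pairs:
            recs.append((p_.zygosity, col[p_.subject1], col[p_.subject2]))
        pairs = pd.DataFrame(recs, columns=["zygosity", "value1", "value2"])
        pairs = standardize_pairs(pairs)
        r_mz, r_dz = twin_iccs(pairs)
        fam = choose_family(r_mz, r_dz) if family == "auto" else family
        fit_ae = fit_variance_components(pairs, "AE", standardize=False)
        if fam == "AE":
            chosen = fit_ae
        else:
            fit_full = fit_variance_components(pairs, fam, standardize=False)
            chosen = select_model(fit_full, fit_ae)
        chi2, p, _, _ = test_genetic_effect(pairs, standardize=False)
        rows.append({
            "ROI1": edge[0], "ROI2": edge[1],
            "A_effect": chosen.a_fraction, "chi2": chi2, "p": p,
            "model": chosen.model, "r_mz": r_mz, "r_dz": r_dz,
        })
    df = pd.DataFrame(rows)
    p_adj, sig = adjust_pvalues(df["p"], method=correction, alpha=alpha)
    df["p_adjusted"] = p_adj
    df["significant"] = sig
    return df


def rank_top_edges(results: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Top-k edges by additive fraction among significant edges.

    Ties break lexicographically on the (ROI1, ROI2) label pair.  When fewer
    than k edges pass the flag, the full sorted passing list is returned.
    """
    if results.empty:
        raise GeneticsError("no edge results to rank")
    passing = results[results["significant"]] if "significant" in results else results
    ordered = passing.sort_values(
        by=["A_effect", "ROI1", "ROI2"], ascending=[False, True, True],
        kind="mergesort",
    )
    return ordered.head(k).reset_index(drop=True)


def region_contribution_summary(results: pd.DataFrame,
                                groups: Mapping[str, str]) -> pd.Series:
    """Percentage of significant edges touching each anatomical group.

    An edge counts toward a group when at least one endpoint belongs to it
    (an edge with both endpoints in the group counts once); an edge may
    therefore count toward two groups and percentages can exceed 100 in sum.
    With zero significant edges every percentage is missing (NaN).
    """
    groups = RegionGroupMap(groups)
    names = sorted(set(groups.values()))
    sig = results[results["significant"]]
    if len(sig) == 0:
        return pd.Series({g: np.nan for g in names}, name="percent")
    counts = {g: 0 for g in names}
    for row in sig.itertuples(index=False):
        touched = {groups.get(row.ROI1), groups.get(row.ROI2)} - {None}
        for g in touched:
            counts[g] += 1
    return pd.Series({g: 100.0 * counts[g] / len(sig) for g in names},
                     name="percent")
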