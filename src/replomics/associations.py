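"""Dual-regression association testing across multi-omic feature types.

Baseline-BMI effects confound naive weight-loss associations: subjects with
high baseline BMI lose more weight on follow-up (regression to the mean), so
any feature correlated with BMI looks weight-loss-associated.  The framework
here therefore fits two models per feature:

* the **weight-loss model** — feature ~ group + baseline_bmi + age + sex,
  with the group indicator as the target covariate, and
* the **BMI model** — feature ~ baseline_bmi + age + sex, with baseline BMI
  as the target covariate and no group term.

Continuous (log-scale) and ordinal features use ordinary least squares (the
"linear model without shrinkage" route); sequencing counts use per-feature
negative-binomial log-link regression with median-of-ratios size factors as
offsets.  Every reported t (or Wald pseudo-t) statistic is the coefficient
divided by its estimated standard error.  P values are Benjamini-Hochberg
adjusted within each data type, and each feature is classed ``bmi_only``,
``wl_only``, ``both`` or ``neither`` from the two FDR values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .feature_prep import poscounts_size_factors

__all__ = [
    "ModelSpec",
    "GaussianAssociation",
    "NegativeBinomialAssociation",
    "DualAssociation",
    "fit_gaussian",
    "fit_negative_binomial",
    "adjust_fdr",
    "classify_features",
    "correlate_tstats",
    "srm_change_model",
    "richness_models",
    "baseline_group_tests",
    "paired_difference_tests",
]

TARGETS = ("weight_loss", "baseline_bmi")
DEFAULT_WL_COVARIATES = ("baseline_bmi", "age", "sex")
DEFAULT_BMI_COVARIATES = ("age", "sex")


@dataclass
class ModelSpec:
    """Declarative description of one association model.

    ``target`` is the covariate whose coefficient is reported; the
    weight-loss target always adjusts for baseline BMI.  No interaction
    terms are fitted.
    """

    target: str
    covariates: tuple[str, ...] = ()
    family: str = "gaussian_identity"
    offset: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.target not in TARGETS:
            raise ValueError(f"target must be one of {TARGETS}, got {self.target!r}")
        if self.target == "weight_loss" and "baseline_bmi" not in self.covariates:
            raise ValueError(
                "weight-loss models must adjust for baseline_bmi"
            )
        if self.family not in ("gaussian_identity", "negative_binomial_log"):
            raise ValueError(f"unknown family {self.family!r}")


def _encode_column(meta: pd.DataFrame, name: str, sex_reference: str) -> np.ndarray:
    if name == "weight_loss":
        return (meta["group"] == "weight_loss").to_numpy(dtype=float)
    if name == "sex":
        levels = set(map(str, meta["sex"].unique()))
        if not levels <= {"female", "male"}:
            raise ValueError(f"sex must be female/male, got {levels}")
        return (meta["sex"].astype(str) != sex_reference).to_numpy(dtype=float)
    return meta[name].to_numpy(dtype=float)


def _design_matrix(
    meta: pd.DataFrame,
    target: str,
    covariates: Sequence[str],
    sex_reference: str = "female",
) -> tuple[np.ndarray, list[str]]:
    """Design with intercept first, target second, covariates after."""
    names = ["intercept", target, *covariates]
    cols = [np.ones(len(meta))]
    for name in names[1:]:
        cols.append(_encode_column(meta, name, sex_reference))
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # point at the columns involved in the collinearity
        bad = [
            names[j]
            for j in range(1, X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    return X, names


def _align_meta(features: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    m = meta.copy()
    if "sample_id" not in m.columns:
        m["sample_id"] = m["subject_id"]
    m = m.set_index("sample_id")
    missing = [s for s in features.columns if s not in m.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    return m.loc[list(features.columns)]


class GaussianAssociation(BaseEstimator):
    """Per-feature OLS of a feature matrix on a target plus covariates.

    Equivalent to fitting a linear model feature-by-feature with no
    shrinkage between features; ordinal responses are treated as numeric.
    All features share one design matrix, so the fits are vectorised.

    Attributes
    ----------
    results_ : DataFrame
        One row per feature: ``coef, se, t, p, n, flag`` for the target
        term.  Zero-variance features get coef 0, p 1 and a flag.
    """

    def __init__(
        self,
        target: str = "weight_loss",
        covariates: Sequence[str] = DEFAULT_WL_COVARIATES,
        sex_reference: str = "female",
    ) -> None:
        self.target = target
        self.covariates = covariates
        self.sex_reference = sex_reference

    def fit(self, X: pd.DataFrame, meta: pd.DataFrame) -> "GaussianAssociation":
        ModelSpec(self.target, tuple(self.covariates))  # validate contract
        m = _align_meta(X, meta)
        design, names = _design_matrix(
            m, self.target, self.covariates, self.sex_reference
        )
        Y = X.to_numpy(dtype=float)
        if np.isnan(Y).any():
            raise ValueError("feature matrix contains missing values; prepare first")
        n, p = design.shape
        if n <= p:
            raise ValueError(f"need more samples ({n}) than parameters ({p})")
        xtx_inv = np.linalg.inv(design.T @ design)
        beta = Y @ design @ xtx_inv.T  # features x parameters
        resid = Y - beta @ design.T
        dof = n - p
        sigma2 = (resid**2).sum(axis=1) / dof
        se_all = np.sqrt(np.outer(sigma2, np.diag(xtx_inv)))
        j = names.index(self.target)
        coef = beta[:, j].copy()
        se = se_all[:, j].copy()
        zero_var = Y.var(axis=1) == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            t = coef / se
        pvals = 2.0 * st.t.sf(np.abs(t), dof)
        coef[zero_var] = 0.0
        t[zero_var] = 0.0
        pvals[zero_var] = 1.0
        self.design_columns_ = names
        self.dof_ = dof
        self.results_ = pd.DataFrame(
            {
                "feature_id": X.index,
                "coef": coef,
                "se": se,
                "t": t,
                "p": pvals,
                "n": n,
                "flag": np.where(zero_var, "zero_variance", ""),
            }
        ).set_index("feature_id")
        return self


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    size = 1.0 / alpha
    prob = size / (size + mu)
    return float(st.nbinom.logpmf(y, size, prob).sum())


def _mle_alpha(y: np.ndarray, mu: np.ndarray) -> float:
    """Profile-likelihood dispersion given fitted means."""
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda la: -_nb_loglik(y, mu, np.exp(la)),
        bounds=(np.log(1e-8), np.log(100.0)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(np.exp(res.x))


def _mom_alpha(y: np.ndarray, mu: np.ndarray, n_params: int) -> float:
    """Pearson moment estimator of the NB2 dispersion."""
    dof = max(len(y) - n_params, 1)
    num = ((y - mu) ** 2 - mu).sum()
    den = (mu**2).sum()
    return float(np.clip(num / den * len(y) / dof, 1e-8, 100.0))


class NegativeBinomialAssociation(BaseEstimator):
    """Per-feature NB log-link regression with size-factor offsets.

    Dispersion is estimated feature-by-feature: a Poisson fit seeds the
    means, the NB2 dispersion alpha is profiled by maximum likelihood given
    those means, and the GLM is refit at the estimated alpha (two rounds).
    A Pearson method-of-moments estimate is the fallback when the profile
    step fails.  No information is shared across features.  Wald pseudo-t =
    coef / se, two-sided normal p value.

    Attributes
    ----------
    results_ : DataFrame
        Per feature: ``coef, se, t, p, n, dispersion, flag``.  All-zero
        features are flagged ``all_zero`` and carry NaN statistics;
        non-converged fits are flagged ``not_converged`` (exclude both from
        FDR sets).
    size_factors_ : Series
    """

    def __init__(
        self,
        target: str = "weight_loss",
        covariates: Sequence[str] = DEFAULT_WL_COVARIATES,
        size_factors: pd.Series | None = None,
        dispersion: str = "mle",
        sex_reference: str = "female",
    ) -> None:
        self.target = target
        self.covariates = covariates
        self.size_factors = size_factors
        self.dispersion = dispersion
        self.sex_reference = sex_reference

    def fit(self, X: pd.DataFrame, meta: pd.DataFrame) -> "NegativeBinomialAssociation":
        ModelSpec(self.target, tuple(self.covariates), family="negative_binomial_log")
        arr = X.to_numpy()
        if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
            raise ValueError("count matrix must hold non-negative integers")
        m = _align_meta(X, meta)
        design, names = _design_matrix(
            m, self.target, self.covariates, self.sex_reference
        )
        j = names.index(self.target)
        if self.size_factors is None:
            sf = poscounts_size_factors(X)
        else:
            sf = self.size_factors.reindex(X.columns)
            if sf.isna().any() or (sf <= 0).any():
                raise ValueError("size factors must be positive for every sample")
        offset = np.log(sf.to_numpy(dtype=float))

        rows = []
        for fid, y in zip(X.index, X.to_numpy(dtype=float)):
            row = {"feature_id": fid, "n": design.shape[0]}
            if not y.any():
                rows.append({**row, "flag": "all_zero"})
                continue
            try:
                rows.append({**row, **self._fit_one(y, design, offset, j), "flag": ""})
            except Exception:
                rows.append({**row, "flag": "not_converged"})
        cols = ["coef", "se", "t", "p", "n", "dispersion", "flag"]
        self.size_factors_ = sf
        self.design_columns_ = names
        self.results_ = (
            pd.DataFrame(rows).set_index("feature_id").reindex(columns=cols)
        )
        return self

    def _fit_one(
        self, y: np.ndarray, design: np.ndarray, offset: np.ndarray, j: int
    ) -> dict:
        pois = sm.GLM(y, design, family=sm.families.Poisson(), offset=offset).fit()
        mu = pois.mu
        alpha = 1e-8
        fit = pois
        if isinstance(self.dispersion, (int, float)):
            alpha = float(self.dispersion)
            if alpha > 0:
                fit = sm.GLM(
                    y,
                    design,
                    family=sm.families.NegativeBinomial(alpha=alpha),
                    offset=offset,
                ).fit()
        elif self.dispersion != "poisson":
            for _ in range(2):
                try:
                    alpha = _mle_alpha(y, mu, )
                except Exception:
                    alpha = _mom_alpha(y, mu, design.shape[1])
                if alpha <= 2e-8:
                    fit, mu = pois, pois.mu
                    break
                fit = sm.GLM(
                    y,
                    design,
                    family=sm.families.NegativeBinomial(alpha=alpha),
                    offset=offset,
                ).fit()
                mu = fit.mu
        coef = float(fit.params[j])
        se = float(fit.bse[j])
        t = coef / se
        return {
            "coef": coef,
            "se": se,
            "t": t,
            "p": float(2.0 * st.norm.sf(abs(t))),
            "dispersion": alpha,
        }


def fit_gaussian(
    features: pd.DataFrame, meta: pd.DataFrame, spec: ModelSpec
) -> pd.DataFrame:
    """OLS target-term statistics per feature (thin wrapper)."""
    return GaussianAssociation(spec.target, tuple(spec.covariates)).fit(
        features, meta
    ).results_


def fit_negative_binomial(
    counts: pd.DataFrame,
    size_factors: pd.Series | None,
    meta: pd.DataFrame,
    spec: ModelSpec,
) -> pd.DataFrame:
    """NB target-term statistics per feature (thin wrapper)."""
    return NegativeBinomialAssociation(
        spec.target, tuple(spec.covariates), size_factors=size_factors
    ).fit(counts, meta).results_


def adjust_fdr(pvalues: Sequence[float], method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    Call once per data type; NaNs pass through untouched and do not count
    toward the number of tests.
    """
    p = np.asarray(pvalues, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    if ok.sum():
        out[ok] = multipletests(p[ok], method=method)[1]
    return out


def classify_features(
    fdr_bmi: Sequence[float], fdr_wl: Sequence[float], alpha: float = 0.05
) -> np.ndarray:
    """Class label from the two FDR slots at one significance threshold."""
    b = np.asarray(fdr_bmi, dtype=float) < alpha
    w = np.asarray(fdr_wl, dtype=float) < alpha
    out = np.where(
        b & w, "both", np.where(b, "bmi_only", np.where(w, "wl_only", "neither"))
    )
    return out


def correlate_tstats(
    t_bmi: Sequence[float], t_wl: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation between the two models' t statistics."""
    a = np.asarray(t_bmi, dtype=float)
    b = np.asarray(t_wl, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need two equal-length vectors of at least 3 t statistics")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("t statistic vectors must not contain missing values")
    if a.std() == 0 or b.std() == 0:
        warnings.warn("zero-variance t vector: correlation undefined")
        return float("nan"), float("nan")
    rho, p = st.pearsonr(a, b)
    return float(rho), float(p)


class DualAssociation(BaseEstimator):
    """Fit the weight-loss and BMI models per feature and classify.

    Parameters
    ----------
    kind:
        ``"continuous_log"`` / ``"ordinal"`` (both OLS) or ``"count"`` (NB
        with size-factor offsets).
    alpha:
        FDR threshold for the four-way classification.
    size_factors:
        Optional precomputed size factors for count matrices (computed by
        the poscounts rule when omitted).

    Attributes
    ----------
    results_ : DataFrame
        Per feature: ``coef_wl, se_wl, t_wl, p_wl, fdr_wl, coef_bmi,
        se_bmi, t_bmi, p_bmi, fdr_bmi, class, n_samples, flag``.
    tstat_correlation_ : tuple(rho, p)
        Pearson correlation between t_bmi and t_wl over clean features.
    """

    def __init__(
        self,
        kind: str = "continuous_log",
        alpha: float = 0.05,
        size_factors: pd.Series | None = None,
        sex_reference: str = "female",
    ) -> None:
        self.kind = kind
        self.alpha = alpha
        self.size_factors = size_factors
        self.sex_reference = sex_reference

    def _single(self, target, covariates, X, meta):
        if self.kind == "count":
            est = NegativeBinomialAssociation(
                target, covariates,
                size_factors=self.size_factors,
                sex_reference=self.sex_reference,
            )
        elif self.kind in ("continuous_log", "ordinal"):
            est = GaussianAssociation(
                target, covariates, sex_reference=self.sex_reference
            )
        else:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        return est.fit(X, meta).results_

    def fit(self, X: pd.DataFrame, meta: pd.DataFrame) -> "DualAssociation":
        wl = self._single("weight_loss", DEFAULT_WL_COVARIATES, X, meta)
        bmi = self._single("baseline_bmi", DEFAULT_BMI_COVARIATES, X, meta)
        res = pd.DataFrame(index=X.index)
        for tag, single in (("wl", wl), ("bmi", bmi)):
            for col in ("coef", "se", "t", "p"):
                res[f"{col}_{tag}"] = single[col]
        flags = wl.get("flag", "").astype(str)
        if "flag" in bmi:
            flags = np.where(flags.astype(bool), flags, bmi["flag"].astype(str))
        res["flag"] = flags
        # features flagged (all-zero / non-converged / zero-variance) are
        # excluded from the FDR set; zero-variance OLS rows keep p = 1
        testable = res["flag"].isin(["", "zero_variance"])
        for tag in ("wl", "bmi"):
            fdr = np.full(len(res), np.nan)
            fdr[testable.to_numpy()] = adjust_fdr(
                res.loc[testable, f"p_{tag}"].to_numpy()
            )
            res[f"fdr_{tag}"] = fdr
        cls = classify_features(res["fdr_bmi"], res["fdr_wl"], self.alpha)
        cls[~testable.to_numpy()] = "neither"
        zero_var = res["flag"] == "zero_variance"
        cls[zero_var.to_numpy()] = "neither"
        res["class"] = cls
        res["n_samples"] = X.shape[1]
        self.results_ = res
        clean = res[testable & res["t_wl"].notna() & res["t_bmi"].notna()]
        if len(clean) >= 3 and clean["t_wl"].std() > 0 and clean["t_bmi"].std() > 0:
            self.tstat_correlation_ = correlate_tstats(
                clean["t_bmi"], clean["t_wl"]
            )
        else:
            self.tstat_correlation_ = (float("nan"), float("nan"))
        return self


def srm_change_model(
    deltas: pd.DataFrame, meta: pd.DataFrame, alpha_fdr: float = 0.1
) -> pd.DataFrame:
    """Weight-loss model on within-subject log-ratio changes (SRM panel).

    OLS of each protein's change on group + baseline BMI + age + sex, BH
    adjusted within the panel; ``significant`` marks fdr < ``alpha_fdr``.
    """
    res = GaussianAssociation("weight_loss", DEFAULT_WL_COVARIATES).fit(
        deltas, meta
    ).results_.rename(
        columns={"coef": "coef_wl", "se": "se_wl", "t": "t_wl", "p": "p_wl"}
    )
    res["fdr_wl"] = adjust_fdr(res["p_wl"])
    res["significant"] = res["fdr_wl"] < alpha_fdr
    return res


def richness_models(richness: pd.Series, meta: pd.DataFrame) -> pd.DataFrame:
    """The two gene-richness regressions.

    Model ``bmi``: richness ~ baseline_bmi + sex + age (does BMI predict
    baseline gene richness?  the reported slope is genes lost per BMI
    unit).  Model ``weight_loss``: richness ~ group + baseline_bmi + sex +
    age (is baseline richness predictive of later weight loss, adjusting
    for BMI?).  Returns one row per model with the target term's
    coefficient, t and p.
    """
    rich = pd.DataFrame([richness.rename("richness")])
    rich.index = ["richness"]
    rows = []
    for target, covs in (
        ("baseline_bmi", ("sex", "age")),
        ("weight_loss", ("baseline_bmi", "sex", "age")),
    ):
        fit = GaussianAssociation(target, covs).fit(rich, meta).results_.iloc[0]
        rows.append(
            {
                "model": target,
                "coef": fit["coef"],
                "se": fit["se"],
                "t": fit["t"],
                "p": fit["p"],
                "n": fit["n"],
                "flag": fit["flag"],
            }
        )
    return pd.DataFrame(rows)


def baseline_group_tests(
    markers: pd.DataFrame, meta: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Unadjusted two-group and correlation structure of baseline markers.

    Returns ``(welch, rho, rho_p)``: per-marker Welch unequal-variance t
    tests between the weight-loss and no-weight-loss groups, and the marker
    x marker Pearson correlation matrix with its two-sided test p values.
    Markers with fewer than 2 samples in a group are skipped (NaN row).
    """
    m = _align_meta(markers, meta)
    wl = (m["group"] == "weight_loss").to_numpy()
    nwl = (m["group"] == "no_weight_loss").to_numpy()
    rows = []
    for fid, y in zip(markers.index, markers.to_numpy(dtype=float)):
        a, b = y[wl], y[nwl]
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if len(a) < 2 or len(b) < 2:
            rows.append({"feature_id": fid, "skipped": True})
            continue
        t, p = st.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "feature_id": fid,
                "mean_wl": a.mean(),
                "mean_nwl": b.mean(),
                "t": float(t),
                "p": float(p),
                "skipped": False,
            }
        )
    welch = pd.DataFrame(rows).set_index("feature_id")

    k = len(markers)
    rho = pd.DataFrame(np.eye(k), index=markers.index, columns=markers.index)
    rho_p = pd.DataFrame(np.zeros((k, k)), index=markers.index, columns=markers.index)
    vals = markers.to_numpy(dtype=float)
    for i in range(k):
        for jj in range(i + 1, k):
            r, p = st.pearsonr(vals[i], vals[jj])
            rho.iloc[i, jj] = rho.iloc[jj, i] = r
            rho_p.iloc[i, jj] = rho_p.iloc[jj, i] = p
    return welch, rho, rho_p


def paired_difference_tests(
    baseline: pd.DataFrame, followup: pd.DataFrame
) -> pd.DataFrame:
    """Paired t tests of follow-up minus baseline per marker.

    For baseline-vs-follow-up chemistries; pairs with a missing member are
    dropped per marker.
    """
    if not baseline.index.equals(followup.index) or not baseline.columns.equals(
        followup.columns
    ):
        raise ValueError("baseline and followup must share features and samples")
    rows = []
    for fid in baseline.index:
        a = baseline.loc[fid].to_numpy(dtype=float)
        b = followup.loc[fid].to_numpy(dtype=float)
        ok = ~(np.isnan(a) | np.isnan(b))
        if ok.sum() < 2:
            rows.append({"feature_id": fid, "skipped": True})
            continue
        t, p = st.ttest_rel(b[ok], a[ok])
        rows.append(
            {
                "feature_id": fid,
                "mean_diff": float((b[ok] - a[ok]).mean()),
                "t": float(t),
                "p": float(p),
                "n_pairs": int(ok.sum()),
                "skipped": False,
            }
        )
    return pd.DataFrame(rows).set_index("feature_id")
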