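"""Epigenetic clocks and seasonal age-acceleration testing.

An epigenetic clock is a penalized linear model predicting chronological age
(years) from methylation beta values at CpG sites.  Fitting uses the
elastic net with mixing parameter alpha (glmnet convention; default 0.5,
i.e. an equal blend of lasso and ridge) and a penalty strength chosen by
k-fold cross-validation.

Age acceleration is defined as the residual from an ordinary least-squares
regression of predicted epigenetic age on chronological age: negative
residuals mean epigenetically younger than expected for one's age.  The
seasonal contrast in age acceleration is tested with a linear mixed model —
season and birthplace as fixed effects, individual identity as a random
intercept, fitted by REML — so that repeated samples from the same animal
are handled correctly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold


@dataclass
class ClockModel:
    """An affine age predictor: ``age = intercept + sum_j w_j * beta_j``."""

    intercept: float
    coefficients: dict[str, float]          # probe id -> years per beta unit
    mixing_parameter: float
    penalty_strength: float
    training_probe_ids: list[str] = field(default_factory=list)

    @property
    def nonzero_coefficients(self) -> dict[str, float]:
        return {p: w for p, w in self.coefficients.items() if w != 0.0}

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# intercept\t{self.intercept!r}\n")
            fh.write(f"# mixing\t{self.mixing_parameter!r}\n")
            fh.write(f"# penalty\t{self.penalty_strength!r}\n")
            fh.write("probe_id\tweight\n")
            for p in self.coefficients:
                fh.write(f"{p}\t{self.coefficients[p]!r}\n")

    @classmethod
    def load(cls, path) -> "ClockModel":
        header: dict[str, float] = {}
        coefs: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    key, val = line.lstrip("# ").split("\t")
                    header[key] = float(val)
                elif line and not line.startswith("probe_id"):
                    p, w = line.split("\t")
                    coefs[p] = float(w)
        return cls(intercept=header["intercept"],
                   coefficients=coefs,
                   mixing_parameter=header["mixing"],
                   penalty_strength=header["penalty"],
                   training_probe_ids=list(coefs))


def fit_clock(
    betas: pd.DataFrame,
    ages: pd.Series | np.ndarray,
    mixing: float = 0.5,
    cv_folds: int = 10,
    seed: int = 0,
    penalty: float | None = None,
) -> ClockModel:
    """Fit an elastic-net clock of age on beta values.

    Parameters
    ----------
    betas
        Probes × samples beta matrix; columns must align with ``ages``.
    ages
        Chronological age in years per sample (exact ages only — samples with
        minimum ages should be excluded before fitting).
    mixing
        Elastic-net mixing parameter in [0, 1] (1 = lasso, 0 = ridge;
        glmnet's alpha).
    cv_folds
        Folds for cross-validated selection of the penalty strength
        (minimum-MSE rule).
    penalty
        Skip cross-validation and use this penalty strength directly.
    """
    ages = np.asarray(ages, dtype=float)
    if betas.shape[1] != len(ages):
        raise ValueError("number of samples in betas and ages differ")
    X = betas.to_numpy(float).T                       # samples × probes
    if np.isnan(X).any():
        raise ValueError("missing beta values at training sites")
    if np.allclose(X.std(axis=0), 0.0):
        raise ValueError("all-constant predictor matrix")
    if penalty is None:
        if len(ages) < 2 * cv_folds:
            raise ValueError(
                f"need at least {2 * cv_folds} samples for {cv_folds}-fold "
                "cross-validation")
        cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        est = ElasticNetCV(l1_ratio=mixing, cv=cv, alphas=100,
                           max_iter=50_000, tol=1e-6)
        est.fit(X, ages)
        chosen_penalty = float(est.alpha_)
        coef, intercept = est.coef_, float(est.intercept_)
    else:
        est = ElasticNet(alpha=penalty, l1_ratio=mixing, max_iter=200_000,
                         tol=1e-8)
        est.fit(X, ages)
        chosen_penalty = float(penalty)
        coef, intercept = est.coef_, float(est.intercept_)
    probe_ids = list(betas.index)
    return ClockModel(
        intercept=intercept,
        coefficients={p: float(w) for p, w in zip(probe_ids, coef) if w != 0.0},
        mixing_parameter=float(mixing),
        penalty_strength=chosen_penalty,
        training_probe_ids=probe_ids,
    )


def predict_ages(
    model: ClockModel, betas: pd.DataFrame, sheet: pd.DataFrame
) -> pd.DataFrame:
    """Predict epigenetic ages and compute age-acceleration residuals.

    The residual for each sample comes from an OLS regression of predicted
    age on chronological age fitted over all supplied samples, so residuals
    sum to zero across the prediction set.
    """
    missing = [p for p in model.nonzero_coefficients if p not in betas.index]
    if missing:
        raise KeyError(f"model probes missing from beta matrix: {missing[:5]}")
    pred = np.full(betas.shape[1], model.intercept, dtype=float)
    nz = model.nonzero_coefficients
    if nz:
        probes = list(nz)
        weights = np.array([nz[p] for p in probes])
        pred = model.intercept + weights @ betas.loc[probes].to_numpy(float)

    table = sheet.set_index("sample_id").loc[list(betas.columns)].reset_index()
    table = table[[c for c in ("sample_id", "individual_id", "season",
                               "birthplace", "age_years", "age_is_minimum")
                   if c in table.columns]].copy()
    table = table.rename(columns={"age_years": "chronological_age"})
    table["predicted_age"] = pred
    table["residual"] = _ols_residuals(
        table["chronological_age"].to_numpy(float), pred)
    return table


def _ols_residuals(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Residuals of y on (1, x); falls back to demeaning if x is constant."""
    if np.ptp(x) == 0:
        return y - y.mean()
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def clock_fit_metrics(table: pd.DataFrame) -> tuple[float, float]:
    """(r², MAE) of the clock fit.

    r² is from the least-squares regression of predicted on chronological
    age; MAE is the *median* absolute error |predicted − chronological| in
    years (the conventional clock accuracy summary).
    """
    if len(table) < 3:
        raise ValueError("need at least 3 samples")
    x = table["chronological_age"].to_numpy(float)
    y = table["predicted_age"].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in chronological age")
    if np.ptp(y) == 0:
        r2 = 0.0
    else:
        r2 = float(stats.pearsonr(x, y)[0] ** 2)
    mae = float(np.median(np.abs(y - x)))
    return r2, mae


@dataclass
class SeasonEffectResult:
    """Mixed-model test of the seasonal contrast in age acceleration.

    ``season_effect`` is the winter-minus-summer adjusted difference in
    epigenetic age (years); negative = winter epigenetically younger.
    Denominator degrees of freedom follow the containment rule: season (a
    within-individual effect) is tested against the within-individual
    stratum, birthplace (between-individual) against the individual stratum.
    """

    season_effect: float
    standard_error: float
    F_statistic: float
    df_num: int
    df_den: int
    p_value: float
    birthplace_F: float | None = None
    birthplace_df_den: int | None = None
    birthplace_p: float | None = None
    var_individual: float = np.nan
    var_residual: float = np.nan
    n_samples: int = 0
    n_individuals: int = 0


def test_season_effect(table: pd.DataFrame,
                       include_birthplace: bool = True) -> SeasonEffectResult:
    """Test whether age acceleration differs between winter and summer.

    Fits ``residual ~ season [+ birthplace] + (1 | individual)`` by REML and
    reports a Wald F-test (1 numerator df) per fixed effect with containment
    denominator df.  Requires at least two individuals sampled in both
    seasons; with no within-individual seasonal contrast the effect is
    inestimable and an error is raised.
    """
    t = table.copy()
    t["winter"] = (t["season"] == "winter").astype(float)
    t["wild"] = (t["birthplace"] == "wild").astype(float) \
        if "birthplace" in t else 0.0

    by_ind = t.groupby("individual_id")["winter"]
    paired = (by_ind.nunique() > 1)
    n_pairs = int(paired.sum())
    if n_pairs < 2:
        raise ValueError(
            "season effect inestimable: need >= 2 individuals sampled in "
            "both seasons")

    n = len(t)
    n_ind = t["individual_id"].nunique()
    birthplace_varies = include_birthplace and t["wild"].nunique() > 1
    # containment denominator df
    df_season = n - n_ind - 1
    df_birth = n_ind - 2 if birthplace_varies else None

    # degenerate design: within-individual differences carry no variance,
    # REML residual variance is 0 and the Wald test is a point mass
    diffs = _pair_differences(t)
    if np.allclose(np.var(diffs), 0.0):
        eff = float(np.mean(diffs))
        big = np.inf if eff != 0 else 0.0
        return SeasonEffectResult(
            season_effect=eff, standard_error=0.0, F_statistic=big,
            df_num=1, df_den=df_season,
            p_value=0.0 if eff != 0 else 1.0,
            birthplace_F=None, birthplace_df_den=df_birth, birthplace_p=None,
            var_individual=np.nan, var_residual=0.0,
            n_samples=n, n_individuals=n_ind)

    import statsmodels.formula.api as smf

    formula = "residual ~ winter + wild" if birthplace_varies else "residual ~ winter"
    import warnings

    model = smf.mixedlm(formula, data=t, groups=t["individual_id"])
    # l-bfgs with tight tolerances is most precise but can hit a singular
    # information matrix when the individual variance collapses to 0;
    # derivative-free powell then still converges
    fit = None
    for method, opts in ((["lbfgs"], {"factr": 10.0, "pgtol": 1e-12}),
                         (["powell"], {"xtol": 1e-10, "ftol": 1e-10}),
                         (["nm"], {})):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = model.fit(reml=True, method=method, **opts)
            break
        except (np.linalg.LinAlgError, ValueError):
            continue
    if fit is None:
        raise RuntimeError("mixed-model REML fit failed to converge")

    coef = float(fit.fe_params["winter"])
    se = float(fit.bse_fe["winter"])
    F = (coef / se) ** 2
    p = float(stats.f.sf(F, 1, df_season))

    bF = bp = None
    if birthplace_varies:
        bcoef, bse = float(fit.fe_params["wild"]), float(fit.bse_fe["wild"])
        bF = (bcoef / bse) ** 2
        bp = float(stats.f.sf(bF, 1, df_birth))

    return SeasonEffectResult(
        season_effect=coef, standard_error=se, F_statistic=float(F),
        df_num=1, df_den=df_season, p_value=p,
        birthplace_F=bF, birthplace_df_den=df_birth, birthplace_p=bp,
        var_individual=float(fit.cov_re.iloc[0, 0]),
        var_residual=float(fit.scale),
        n_samples=n, n_individuals=n_ind)


def _pair_differences(t: pd.DataFrame) -> np.ndarray:
    """Winter-minus-summer residual differences for complete pairs."""
    diffs = []
    for _, grp in t.groupby("individual_id"):
        w = grp.loc[grp["winter"] == 1, "residual"]
        s = grp.loc[grp["winter"] == 0, "residual"]
        if len(w) and len(s):
            diffs.append(w.mean() - s.mean())
    return np.array(diffs)
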