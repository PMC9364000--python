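"""Age-adjusted paired differential-methylation detection.

The procedure identifies CpG sites whose methylation differs between the
hibernation (winter) and active (summer) seasons independent of age:

1. per probe, fit an OLS of beta on age over all samples pooled and keep the
   residuals (age adjustment);
2. per probe, compare winter and summer age-adjusted values from the same
   individuals with a random-intercept model — on complete pairs this is
   computed through its exact paired-difference equivalence (a paired t-test
   on within-individual winter-minus-summer differences), which is identical
   to the REML mixed model on balanced data and vectorizes over the whole
   array; the explicit per-probe REML fit is available via ``method="reml"``;
3. adjust raw p-values with the Benjamini–Yekutieli (BY) step-up procedure,
   which controls the FDR under arbitrary dependence between probes;
4. call sites with adjusted p below threshold as DMPs, "winter-up" when the
   seasonal coefficient is positive (winter coded 1, summer 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class AgeAdjustedMatrix:
    """Per-probe age-regression residuals plus the fit provenance."""

    residuals: pd.DataFrame      # probes × samples
    slopes: pd.Series            # beta units per year, per probe
    intercepts: pd.Series        # beta units, per probe


def age_adjust(betas: pd.DataFrame, sheet: pd.DataFrame) -> AgeAdjustedMatrix:
    """Regress out age per probe: OLS of beta on age over all samples pooled.

    Samples from both seasons enter one regression per probe; the returned
    residual matrix has the same shape as the input.  Probes with missing
    values fall back to a per-probe fit on their observed samples.
    """
    ages = (sheet.set_index("sample_id")
                 .loc[list(betas.columns), "age_years"].to_numpy(float))
    if len(ages) < 3:
        raise ValueError("need at least 3 samples for age adjustment")
    if np.ptp(ages) == 0:
        raise ValueError("zero age variance: cannot adjust for age")

    B = betas.to_numpy(float)
    X = np.column_stack([np.ones_like(ages), ages])
    if np.isnan(B).any():
        coefs = np.empty((B.shape[0], 2))
        resid = np.full_like(B, np.nan)
        for i in range(B.shape[0]):
            ok = ~np.isnan(B[i])
            if ok.sum() < 3 or np.ptp(ages[ok]) == 0:
                coefs[i] = (np.nanmean(B[i]), 0.0)
                resid[i, ok] = B[i, ok] - coefs[i, 0]
                continue
            c, *_ = np.linalg.lstsq(X[ok], B[i, ok], rcond=None)
            coefs[i] = c
            resid[i, ok] = B[i, ok] - X[ok] @ c
    else:
        coefs = np.linalg.lstsq(X, B.T, rcond=None)[0].T   # probes × 2
        resid = B - coefs @ X.T

    idx = betas.index
    return AgeAdjustedMatrix(
        residuals=pd.DataFrame(resid, index=idx, columns=betas.columns),
        slopes=pd.Series(coefs[:, 1], index=idx, name="age_slope"),
        intercepts=pd.Series(coefs[:, 0], index=idx, name="intercept"),
    )


def _complete_pairs(sheet: pd.DataFrame,
                    sample_ids: list[str]) -> tuple[list[str], list[str]]:
    """(winter sample ids, summer sample ids) for individuals with both."""
    sub = sheet[sheet["sample_id"].isin(sample_ids)]
    winter_ids, summer_ids = [], []
    for _, grp in sub.groupby("individual_id", sort=True):
        w = grp.loc[grp["season"] == "winter", "sample_id"]
        s = grp.loc[grp["season"] == "summer", "sample_id"]
        if len(w) and len(s):
            winter_ids.append(w.iloc[0])
            summer_ids.append(s.iloc[0])
    return winter_ids, summer_ids


def paired_season_test(
    adjusted: AgeAdjustedMatrix,
    sheet: pd.DataFrame,
    method: str = "paired",
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Per-probe seasonal test on age-adjusted methylation.

    Returns a table sorted by raw p with columns ``probe_id``, ``coef``
    (winter-minus-summer residual difference), ``std_coef`` (coefficient
    after z-scoring the probe's residuals), ``p_raw``, ``p_by``,
    ``direction`` (filled by :func:`call_directions`), ``n_pairs`` and
    ``tested``.  Probes with fewer than ``min_pairs`` usable pairs are
    reported untested with p = 1.
    """
    if method not in ("paired", "reml"):
        raise ValueError(f"unknown method {method!r}")
    resid = adjusted.residuals
    winter_ids, summer_ids = _complete_pairs(sheet, list(resid.columns))
    if len(winter_ids) < 2:
        raise ValueError("need >= 2 individuals with both seasons present")

    W = resid[winter_ids].to_numpy(float)
    S = resid[summer_ids].to_numpy(float)
    D = W - S                                       # probes × pairs

    if method == "reml":
        rows = [_reml_probe_test(resid, sheet, pid, winter_ids, summer_ids)
                for pid in resid.index]
        out = pd.DataFrame(rows)
    else:
        n_pairs = np.sum(~np.isnan(D), axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            coef = np.nanmean(D, axis=1)
            sd = np.nanstd(D, axis=1, ddof=1)
            se = sd / np.sqrt(n_pairs)
            t = np.where(se > 0, coef / np.where(se > 0, se, 1.0),
                         np.where(coef == 0, 0.0, np.inf))
            p = 2.0 * stats.t.sf(np.abs(t), np.maximum(n_pairs - 1, 1))
            p = np.where(np.isinf(t), 0.0, p)
            p = np.where((se == 0) & (coef == 0), 1.0, p)
            resid_sd = np.nanstd(resid.to_numpy(float), axis=1, ddof=1)
            std_coef = np.where(resid_sd > 0, coef / np.where(resid_sd > 0, resid_sd, 1.0), 0.0)
        tested = n_pairs >= min_pairs
        out = pd.DataFrame({
            "probe_id": resid.index,
            "coef": np.where(tested, coef, np.nan),
            "std_coef": np.where(tested, std_coef, np.nan),
            "p_raw": np.where(tested, p, 1.0),
            "n_pairs": n_pairs,
            "tested": tested,
        })

    out["p_by"] = np.nan
    mask = out["tested"].to_numpy(bool)
    if mask.any():
        out.loc[mask, "p_by"] = by_fdr(out.loc[mask, "p_raw"].to_numpy())
    out["direction"] = "none"
    return out.sort_values("p_raw", kind="mergesort").reset_index(drop=True)


def _reml_probe_test(resid, sheet, probe_id, winter_ids, summer_ids) -> dict:
    """Explicit random-intercept REML fit for one probe (reference path)."""
    import statsmodels.formula.api as smf

    sample_ids = winter_ids + summer_ids
    y = resid.loc[probe_id, sample_ids].to_numpy(float)
    sub = sheet.set_index("sample_id").loc[sample_ids].reset_index()
    ok = ~np.isnan(y)
    n_pairs = min(ok[: len(winter_ids)].sum(), ok[len(winter_ids):].sum())
    df = pd.DataFrame({"y": y[ok],
                       "winter": (sub["season"] == "winter").astype(float)[ok],
                       "ind": sub["individual_id"][ok]})
    tested = n_pairs >= 3 and df["y"].std() > 0
    if not tested:
        return {"probe_id": probe_id, "coef": np.nan, "std_coef": np.nan,
                "p_raw": 1.0, "n_pairs": int(n_pairs), "tested": False}
    model = smf.mixedlm("y ~ winter", data=df, groups=df["ind"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(reml=True, method=["lbfgs"], factr=10.0,
                            pgtol=1e-12)
        except (np.linalg.LinAlgError, ValueError):
            fit = model.fit(reml=True, method=["powell"], xtol=1e-10,
                            ftol=1e-10)
    coef = float(fit.fe_params["winter"])
    se = float(fit.bse_fe["winter"])
    tstat = coef / se if se > 0 else np.inf * np.sign(coef)
    p = float(2.0 * stats.t.sf(abs(tstat), n_pairs - 1))
    sd_all = float(df["y"].std(ddof=1))
    return {"probe_id": probe_id, "coef": coef,
            "std_coef": coef / sd_all if sd_all > 0 else 0.0,
            "p_raw": p, "n_pairs": int(n_pairs), "tested": True}


def by_fdr(p_values) -> np.ndarray:
    """Benjamini–Yekutieli step-up adjusted p-values.

    ``adj_(i) = min_{j >= i} min(1, m c(m) p_(j) / j)`` with
    ``c(m) = sum_{k=1..m} 1/k``; input order is preserved.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def call_directions(table: pd.DataFrame, threshold: float = 0.05) -> pd.DataFrame:
    """Assign winter-up / winter-down / none by coefficient sign at BY p < threshold."""
    out = table.copy()
    sig = out["p_by"] < threshold
    out["direction"] = np.select(
        [sig & (out["coef"] > 0), sig & (out["coef"] < 0)],
        ["winter-up", "winter-down"], default="none")
    return out


def direction_summary(table: pd.DataFrame) -> dict:
    """Counts of DMP direction calls plus a 50:50 goodness-of-fit test."""
    n_up = int((table["direction"] == "winter-up").sum())
    n_down = int((table["direction"] == "winter-down").sum())
    total = n_up + n_down
    summary = {"n_dmps": total, "n_winter_up": n_up, "n_winter_down": n_down,
               "proportion_up": n_up / total if total else np.nan}
    if total:
        chi = (n_up - total / 2) ** 2 / (total / 2) \
            + (n_down - total / 2) ** 2 / (total / 2)
        summary["balance_chi_sq"] = float(chi)
        summary["balance_p"] = float(stats.chi2.sf(chi, 1))
    return summary


def standardized_effect(adjusted: AgeAdjustedMatrix, sheet: pd.DataFrame,
                        probe: str) -> float:
    """Seasonal coefficient in residual-SD units for one probe.

    The probe's age-adjusted residuals are z-scored across samples before the
    paired comparison, so the coefficient is scale-free and comparable across
    probes.  Zero residual variance yields 0 with a warning.
    """
    if probe not in adjusted.residuals.index:
        raise KeyError(probe)
    r = adjusted.residuals.loc[probe]
    sd = float(r.std(ddof=1))
    if sd == 0 or np.isnan(sd):
        warnings.warn(f"probe {probe} has zero residual variance; "
                      "standardized effect set to 0", RuntimeWarning,
                      stacklevel=2)
        return 0.0
    winter_ids, summer_ids = _complete_pairs(sheet, list(adjusted.residuals.columns))
    z = (r - r.mean()) / sd
    return float(np.nanmean(z[winter_ids].to_numpy() - z[summer_ids].to_numpy()))


def detect_dmps(betas: pd.DataFrame, sheet: pd.DataFrame,
                fdr: float = 0.05, method: str = "paired") -> pd.DataFrame:
    """Full chain: age adjustment, paired seasonal test, BY-FDR, direction calls."""
    adjusted = age_adjust(betas, sheet)
    table = paired_season_test(adjusted, sheet, method=method)
    return call_directions(table, threshold=fdr)
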