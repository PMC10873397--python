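"""Individual-level association engine.

Covers the birth-cohort-style arm of the analysis: OLS of each
(rank-normalised) metabolite on the weighted AD genetic risk score with
age and sex adjustment, per-SNP metabolite GWAS within age strata (the
input to the two-sample MR arm), GRS-versus-confounder pleiotropy checks,
and APOE carrier-group contrasts.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genetics import ApoeDiplotype, GrsVector, InstrumentTable, SummaryStats
from .results import EffectEstimate

logger = logging.getLogger(__name__)

__all__ = [
    "fit_ols",
    "grs_metabolite_assoc",
    "snp_metabolite_gwas",
    "confounder_check",
    "apoe_contrast",
]

#: minimum stratum size for an association fit
DEFAULT_MIN_N = 30


def fit_ols(
    y, design, add_intercept: bool = True
) -> Tuple[np.ndarray, np.ndarray, int]:
    """Ordinary least squares with classical SEs; the shared kernel.

    Rows with any missing value are dropped listwise; an intercept is
    prepended unless already present.  Returns ``(coefficients, ses,
    residual df)`` with the intercept first.  Raises on rank deficiency
    or ``n ≤ p``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    y, X = y[keep], X[keep]
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"too few complete rows (n={n}, p={p})")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    fit = sm.OLS(y, X).fit()
    return fit.params, fit.bse, int(fit.df_resid)


def _ols_estimate(
    y: np.ndarray,
    x: np.ndarray,
    covariates: Optional[np.ndarray],
    method: str,
    metabolite: str = "",
    stratum: str = "",
    min_n: int = DEFAULT_MIN_N,
) -> EffectEstimate:
    """OLS of y on x (+ covariates); returns the estimate for x with a
    normal-quantile 95% CI."""
    X = x[:, None] if covariates is None else np.column_stack([x, covariates])
    keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    n = int(keep.sum())
    if n < min_n:
        raise ValueError(f"stratum has n={n} complete rows, below minimum {min_n}")
    coef, ses, _ = fit_ols(y[keep], X[keep])
    beta, se = float(coef[1]), float(ses[1])
    p = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else np.nan
    return EffectEstimate(beta=beta, se=se, n=n, method=method,
                          metabolite=metabolite, stratum=stratum, p_value=p)


def grs_metabolite_assoc(
    phenotypes: pd.DataFrame,
    grs: GrsVector,
    metabolite: str,
    covariates: Sequence[str] = ("age", "sex"),
    stratum: str = "",
    min_n: int = DEFAULT_MIN_N,
    scale: bool = True,
) -> EffectEstimate:
    """Effect of the AD GRS on one rank-normalised metabolite.

    ``phenotypes`` must be indexed by sample_id (one row per sample, one
    timepoint) and carry the metabolite and covariate columns; the GRS is
    joined on sample id.  The OLS estimate — SD units per log-odds of
    liability — is multiplied by ln 2 (estimate, SE and CI alike) so it
    reads as SD per doubling of genetic liability, unless ``scale`` is
    False.
    """
    df = phenotypes.join(grs.scores.rename("grs_score"), how="inner")
    if df.empty:
        raise ValueError("no overlap between phenotype rows and GRS samples")
    cov = df[list(covariates)].to_numpy(dtype=float) if covariates else None
    est = _ols_estimate(
        df[metabolite].to_numpy(dtype=float),
        df["grs_score"].to_numpy(dtype=float),
        cov, method=f"grs_{grs.variant}", metabolite=metabolite,
        stratum=stratum, min_n=min_n,
    )
    return est.scale_to_doubling() if scale else est


def snp_metabolite_gwas(
    dosages: pd.DataFrame,
    phenotypes: pd.DataFrame,
    instrument: InstrumentTable,
    metabolite: str,
    covariates: Sequence[str] = ("age", "sex"),
    min_n: int = DEFAULT_MIN_N,
) -> SummaryStats:
    """Per-SNP OLS GWAS of one metabolite within a stratum.

    One regression per instrument SNP (effect-allele dosage plus
    covariates), emitting beta, se, eaf and n in the standard summary
    schema with the instrument's allele orientation.  Monomorphic SNPs in
    the stratum yield a row with missing beta and a log entry.
    """
    inst = instrument.table.set_index("snp")
    present = [s for s in inst.index if s in dosages.columns]
    if not present:
        raise ValueError("no instrument SNPs in the dosage matrix")
    df = phenotypes.join(dosages[present], how="inner")
    y = df[metabolite].to_numpy(dtype=float)
    cov = df[list(covariates)].to_numpy(dtype=float) if covariates else None
    rows = []
    for snp in present:
        g = df[snp].to_numpy(dtype=float)
        obs = np.isfinite(g) & np.isfinite(y)
        if cov is not None:
            obs &= np.all(np.isfinite(cov), axis=1)
        rec = {
            "snp": snp,
            "effect_allele": inst.at[snp, "effect_allele"],
            "other_allele": inst.at[snp, "other_allele"],
            "beta": np.nan, "se": np.nan,
            "eaf": float(np.mean(g[obs]) / 2.0) if obs.any() else np.nan,
            "n": int(obs.sum()),
        }
        if obs.sum() >= min_n and np.nanstd(g[obs]) > 0:
            est = _ols_estimate(y, g, cov, method="snp_gwas", min_n=min_n)
            rec["beta"], rec["se"] = est.beta, est.se
        else:
            logger.info("SNP %s monomorphic or underpowered in stratum "
                        "(n=%d); emitting missing beta", snp, int(obs.sum()))
        rows.append(rec)
    return SummaryStats(pd.DataFrame(rows))


def confounder_check(
    grs: GrsVector,
    covariate: pd.Series,
    kind: str = "continuous",
    min_n: int = DEFAULT_MIN_N,
) -> EffectEstimate:
    """Association of the GRS with a putative confounder.

    A genuinely liability-specific instrument should be unrelated to
    non-metabolic traits (BMI, education, smoking, ...); systematic
    association flags pleiotropy.  Continuous covariates use OLS of the
    covariate on the GRS; binary covariates logistic regression.  The
    estimate is left unscaled.
    """
    df = pd.DataFrame({"grs_score": grs.scores}).join(
        covariate.rename("covariate"), how="inner"
    ).dropna()
    if len(df) < min_n:
        raise ValueError(f"only {len(df)} complete observations, below {min_n}")
    x = df["grs_score"].to_numpy(dtype=float)
    c = df["covariate"].to_numpy(dtype=float)
    if kind == "continuous":
        if np.std(c) == 0:
            raise ValueError("constant covariate")
        return _ols_estimate(c, x, None, method="confounder_ols",
                             metabolite=str(covariate.name), min_n=min_n)
    if kind == "binary":
        levels = np.unique(c)
        if levels.size != 2:
            raise ValueError("binary covariate must take exactly two values")
        cb = (c == levels.max()).astype(float)
        X = sm.add_constant(x)
        fit = sm.Logit(cb, X).fit(disp=0)
        beta, se = float(fit.params[1]), float(fit.bse[1])
        p = 2.0 * stats.norm.sf(abs(beta) / se)
        return EffectEstimate(beta=beta, se=se, n=len(df),
                              method="confounder_logit",
                              metabolite=str(covariate.name), p_value=p)
    raise ValueError(f"unknown covariate kind {kind!r}")


def apoe_contrast(
    phenotypes: pd.DataFrame,
    diplotypes: ApoeDiplotype,
    contrast: str,
    metabolite: str,
    covariates: Sequence[str] = ("age", "sex"),
    stratum: str = "",
    min_group: int = 10,
    min_n: int = DEFAULT_MIN_N,
) -> EffectEstimate:
    """Mean metabolite difference for APOE carrier groups vs ε3/ε3.

    ``contrast`` is ``"e4_vs_e3e3"`` (ε4 carriers against ε3 homozygotes,
    omitting all ε2 carriers) or ``"e2_vs_e3e3"`` (ε2 carriers against
    ε3 homozygotes, omitting all ε4 carriers); ε2/ε4 heterozygotes are
    excluded from both.  Covariate-adjusted OLS on a carrier indicator;
    the estimate is a mean difference in SD units and is *not* ln2-scaled.
    """
    if contrast not in ("e4_vs_e3e3", "e2_vs_e3e3"):
        raise ValueError(f"unknown contrast {contrast!r}")
    carrier_group = "e4_carrier" if contrast.startswith("e4") else "e2_carrier"
    calls = diplotypes.calls
    keep = calls["group"].isin([carrier_group, "e3e3"])
    df = phenotypes.join(calls.loc[keep, ["group"]], how="inner")
    n_carrier = int((df["group"] == carrier_group).sum())
    n_ref = int((df["group"] == "e3e3").sum())
    if n_carrier < min_group or n_ref < min_group:
        raise ValueError(
            f"{contrast}: carrier n={n_carrier}, reference n={n_ref}, "
            f"below minimum group size {min_group}"
        )
    indicator = (df["group"] == carrier_group).astype(float).to_numpy()
    cov = df[list(covariates)].to_numpy(dtype=float) if covariates else None
    return _ols_estimate(
        df[metabolite].to_numpy(dtype=float), indicator, cov,
        method=contrast, metabolite=metabolite, stratum=stratum, min_n=min_n,
    )
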