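"""Two-sample Mendelian randomization estimators on harmonized summary
statistics.

Genetic liability to disease is the exposure and each metabolite the
outcome ("reverse MR"): per-SNP Wald ratios ``Γ_j / γ_j`` are combined by
inverse-variance weighting, MR-Egger regression, the weighted median and
the weighted mode — four estimators whose validity rests on different
assumptions about directional (horizontal) pleiotropy.  All estimators
are implemented from first principles here; results are reported per
doubling of liability by multiplying per-log-odds estimates by ln 2.

The model-object surface follows the statsmodels convention:
:class:`ReverseMR` is built from exposure and outcome tables and its
:meth:`ReverseMR.fit` returns a :class:`ReverseMRResults` carrying
:class:`~lifemr.results.EffectEstimate` rows and a ``summary()`` table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genetics import InstrumentTable, SummaryStats, harmonize
from .results import LN2, Z_95, EffectEstimate, estimates_to_frame, scale_to_doubling

logger = logging.getLogger(__name__)

__all__ = [
    "HarmonizedPair",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "weighted_mode",
    "scale_to_doubling",
    "run_mr_panel",
    "ReverseMR",
    "ReverseMRResults",
]


@dataclass
class HarmonizedPair:
    """Allele-aligned SNP→exposure and SNP→outcome estimates.

    ``gamma``/``se_gamma`` are the SNP→liability log-odds effects and
    their SEs; ``big_gamma``/``se_big_gamma`` the SNP→metabolite effects
    (SD units).  Effect alleles are aligned across the two.
    """

    snp: np.ndarray
    gamma: np.ndarray
    se_gamma: np.ndarray
    big_gamma: np.ndarray
    se_big_gamma: np.ndarray
    metabolite: str = ""

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("snp", "gamma", "se_gamma", "big_gamma", "se_big_gamma"):
            v = np.asarray(getattr(self, name))
            arrays[name] = v if name == "snp" else v.astype(float)
        lengths = {len(v) for v in arrays.values()}
        if len(lengths) != 1:
            raise ValueError("all fields must have equal length")
        if len(arrays["snp"]) == 0:
            raise ValueError("harmonized pair needs at least one SNP")
        if len(set(arrays["snp"])) != len(arrays["snp"]):
            raise ValueError("duplicate SNP ids")
        for name in ("se_gamma", "se_big_gamma"):
            if not np.all(arrays[name] > 0):
                raise ValueError(f"{name} must be strictly positive")
        for name, v in arrays.items():
            object.__setattr__(self, name, v)

    @property
    def n_snps(self) -> int:
        return len(self.snp)

    @classmethod
    def from_summary(
        cls,
        exposure: Union[InstrumentTable, SummaryStats],
        outcome: SummaryStats,
        palindrome_policy: str = "eaf",
        metabolite: str = "",
    ) -> "HarmonizedPair":
        """Harmonize the outcome to the exposure's effect alleles and merge."""
        if isinstance(exposure, SummaryStats):
            exposure = InstrumentTable(exposure.table)
        aligned = harmonize(exposure, outcome, palindrome_policy=palindrome_policy)
        exp = exposure.table.set_index("snp")
        out = aligned.table.set_index("snp")
        shared = [s for s in exp.index if s in out.index]
        return cls(
            snp=np.asarray(shared, dtype=object),
            gamma=exp.loc[shared, "beta"].to_numpy(dtype=float),
            se_gamma=exp.loc[shared, "se"].to_numpy(dtype=float),
            big_gamma=out.loc[shared, "beta"].to_numpy(dtype=float),
            se_big_gamma=out.loc[shared, "se"].to_numpy(dtype=float),
            metabolite=metabolite,
        )

    def drop(self, snp_ids: Sequence[str]) -> "HarmonizedPair":
        keep = ~np.isin(self.snp, list(snp_ids))
        if not keep.any():
            raise ValueError("dropping these SNPs would leave an empty pair")
        return HarmonizedPair(
            snp=self.snp[keep], gamma=self.gamma[keep],
            se_gamma=self.se_gamma[keep], big_gamma=self.big_gamma[keep],
            se_big_gamma=self.se_big_gamma[keep], metabolite=self.metabolite,
        )

    def oriented(self) -> "HarmonizedPair":
        """Flip each SNP's (γ, Γ) pair sign so that every γ_j ≥ 0."""
        s = np.where(self.gamma < 0, -1.0, 1.0)
        return HarmonizedPair(
            snp=self.snp, gamma=self.gamma * s, se_gamma=self.se_gamma,
            big_gamma=self.big_gamma * s, se_big_gamma=self.se_big_gamma,
            metabolite=self.metabolite,
        )

    def wald_ratios(self) -> Tuple[np.ndarray, np.ndarray]:
        """Per-SNP ratios and their first-order SEs σ_Γ/|γ|."""
        if np.any(self.gamma == 0):
            raise ZeroDivisionError("Wald ratio undefined for γ = 0")
        return self.big_gamma / self.gamma, self.se_big_gamma / np.abs(self.gamma)


def _estimate(beta, se, method, metabolite, **kw) -> EffectEstimate:
    p = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else (0.0 if beta else 1.0)
    return EffectEstimate(beta=float(beta), se=float(se), n=kw.pop("n", 0),
                          method=method, metabolite=metabolite, p_value=float(p),
                          **kw)


def wald_ratio(pair: HarmonizedPair, second_order_se: bool = False) -> EffectEstimate:
    """Single-SNP causal estimate Γ/γ with delta-method SE.

    First-order SE is σ_Γ/|γ|; the optional second-order SE adds the
    exposure-uncertainty term: se² = σ_Γ²/γ² + Γ²σ_γ²/γ⁴.
    """
    if pair.n_snps != 1:
        raise ValueError("wald_ratio expects exactly one SNP")
    g, sg = float(pair.gamma[0]), float(pair.se_gamma[0])
    G, sG = float(pair.big_gamma[0]), float(pair.se_big_gamma[0])
    if g == 0:
        raise ZeroDivisionError("Wald ratio undefined for γ = 0")
    beta = G / g
    var = sG ** 2 / g ** 2
    if second_order_se:
        var += G ** 2 * sg ** 2 / g ** 4
    return _estimate(beta, np.sqrt(var), "wald", pair.metabolite, n_snps=1)


def ivw(
    pair: HarmonizedPair, effects_model: str = "multiplicative_random"
) -> EffectEstimate:
    """Inverse-variance-weighted estimate: WLS of Γ on γ through the origin.

    ``beta = Σ w_j γ_j Γ_j / Σ w_j γ_j²`` with weights ``w_j = σ_Γj⁻²``.
    The fixed-effects SE is ``(Σ w_j γ_j²)^{-1/2}``; the default
    multiplicative-random-effects SE inflates it by
    ``max(1, sqrt(Q/(J−1)))`` where Q is Cochran's heterogeneity
    statistic.  With a single SNP the estimator falls back to the Wald
    ratio with a warning.
    """
    if effects_model not in ("multiplicative_random", "fixed"):
        raise ValueError(f"unknown effects model {effects_model!r}")
    if pair.n_snps < 2:
        warnings.warn("IVW with one SNP falls back to the Wald ratio")
        res = wald_ratio(pair)
        return res
    w = pair.se_big_gamma ** -2
    denom = np.sum(w * pair.gamma ** 2)
    beta = np.sum(w * pair.gamma * pair.big_gamma) / denom
    se_fixed = denom ** -0.5
    q = float(np.sum(w * (pair.big_gamma - beta * pair.gamma) ** 2))
    df = pair.n_snps - 1
    se = se_fixed
    if effects_model == "multiplicative_random":
        se = se_fixed * max(1.0, np.sqrt(q / df))
    return _estimate(beta, se, "ivw", pair.metabolite, n_snps=pair.n_snps,
                     q_stat=q, q_df=df)


def mr_egger(pair: HarmonizedPair) -> Tuple[EffectEstimate, EffectEstimate]:
    """MR-Egger regression: WLS of Γ on γ with an intercept.

    The pair is first oriented so every γ_j ≥ 0 (results are invariant to
    per-SNP sign flips by construction).  Weights are σ_Γj⁻²; SEs come
    from the WLS covariance inflated by ``max(1, sqrt(RSS_w/(J−2)))``.
    Returns ``(slope, intercept)``; the intercept estimates the average
    directional pleiotropic effect per SNP.
    """
    if pair.n_snps < 3:
        raise ValueError("MR-Egger requires at least 3 SNPs")
    p = pair.oriented()
    if np.allclose(p.gamma, p.gamma[0]):
        raise ValueError("all γ identical: Egger slope/intercept unidentifiable")
    w = p.se_big_gamma ** -2
    x, y = p.gamma, p.big_gamma
    sw, swx, swx2 = w.sum(), np.sum(w * x), np.sum(w * x * x)
    swy, swxy = np.sum(w * y), np.sum(w * x * y)
    det = sw * swx2 - swx ** 2
    slope = (sw * swxy - swx * swy) / det
    intercept = (swx2 * swy - swx * swxy) / det
    resid = y - intercept - slope * x
    df = p.n_snps - 2
    rss_w = float(np.sum(w * resid ** 2))
    phi = max(1.0, np.sqrt(rss_w / df))
    se_slope = np.sqrt(sw / det) * phi
    se_int = np.sqrt(swx2 / det) * phi
    met = pair.metabolite
    return (
        _estimate(slope, se_slope, "egger_slope", met, n_snps=pair.n_snps,
                  q_stat=rss_w, q_df=df),
        _estimate(intercept, se_int, "egger_intercept", met, n_snps=pair.n_snps,
                  q_stat=rss_w, q_df=df),
    )


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q) -> np.ndarray:
    """Quantiles of a weighted sample via cumulative-midpoint interpolation."""
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    w = w / w.sum()
    p = np.cumsum(w) - 0.5 * w
    return np.interp(q, p, v)


def _median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    w = weights / weights.sum()
    heavy = np.flatnonzero(w > 0.5)
    if heavy.size:  # breakdown case: a dominant instrument decides
        return float(ratios[heavy[0]])
    return float(_weighted_quantile(ratios, w, 0.5))


def _parametric_boot(
    pair: HarmonizedPair, n_boot: int, seed: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Resample (γ*, Γ*) from their sampling distributions; return ratio
    and weight matrices of shape (n_boot, J)."""
    rng = np.random.default_rng(seed)
    g = rng.normal(pair.gamma, pair.se_gamma, size=(n_boot, pair.n_snps))
    G = rng.normal(pair.big_gamma, pair.se_big_gamma, size=(n_boot, pair.n_snps))
    g = np.where(g == 0, np.finfo(float).tiny, g)
    ratios = G / g
    weights = (g / pair.se_big_gamma) ** 2
    return ratios, weights


def weighted_median(
    pair: HarmonizedPair, n_boot: int = 1000, seed: int = 0
) -> EffectEstimate:
    """Weighted-median estimator, consistent when valid instruments carry
    at least half the total weight.

    Wald ratios are ordered and assigned normalized inverse-variance
    weights (variance from the first-order Wald SE); the estimate is the
    linear interpolation of the ordered ratios across cumulative weight
    midpoints at 0.5.  If a single instrument carries more than half the
    weight its ratio is returned directly.  The SE is the standard
    deviation over ``n_boot`` parametric resamples of (γ, Γ); ``n_boot =
    0`` skips the bootstrap and reports a NaN SE.
    """
    if pair.n_snps < 3:
        raise ValueError("weighted median requires at least 3 SNPs")
    ratios, ses = pair.wald_ratios()
    weights = ses ** -2
    beta = _median_point(ratios, weights)
    se = np.nan
    if n_boot > 0:
        r, w = _parametric_boot(pair, n_boot, seed)
        boots = np.array([_median_point(r[b], w[b]) for b in range(n_boot)])
        se = float(boots.std(ddof=1))
    return _estimate(beta, se, "weighted_median", pair.metabolite,
                     n_snps=pair.n_snps, n_boot=n_boot or None)


def _silverman_bandwidth(ratios: np.ndarray, weights: np.ndarray,
                         factor: float) -> float:
    w = weights / weights.sum()
    mean = np.sum(w * ratios)
    sd = np.sqrt(np.sum(w * (ratios - mean) ** 2))
    q1, q3 = _weighted_quantile(ratios, w, [0.25, 0.75])
    iqr = q3 - q1
    spreads = [s for s in (sd, iqr / 1.349) if s > 0]
    if not spreads:
        return 0.0
    return factor * 0.9 * min(spreads) * len(ratios) ** (-1 / 5)


def _kde_argmax(ratios: np.ndarray, weights: np.ndarray, h: float,
                n_grid: int = 512) -> float:
    """Argmax of the weighted Gaussian KDE: coarse grid + bounded refine."""
    w = weights / weights.sum()
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, n_grid)

    def density(x):
        x = np.atleast_1d(x)
        return np.exp(-0.5 * ((x[:, None] - ratios[None, :]) / h) ** 2) @ w

    i = int(np.argmax(density(grid)))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    res = optimize.minimize_scalar(lambda x: -density(x)[0],
                                   bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    return float(res.x)


def _mode_point(ratios: np.ndarray, weights: np.ndarray, factor: float) -> float:
    h = _silverman_bandwidth(ratios, weights, factor)
    if h == 0.0:  # all ratios identical
        return float(ratios[0])
    return _kde_argmax(ratios, weights, h)


def weighted_mode(
    pair: HarmonizedPair,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> EffectEstimate:
    """Weighted-mode estimator: the peak of a weighted kernel density over
    the Wald ratios, consistent when the largest homogeneous cluster of
    instruments is valid.

    Bandwidth uses the modified Silverman rule ``h = φ·0.9·min(SD_w,
    IQR_w/1.349)·J^{-1/5}`` on the weighted ratio distribution; the
    estimate is the argmax of the weighted Gaussian KDE (512-point grid
    with bounded local refinement).  SE via the same parametric bootstrap
    as the weighted median.
    """
    if pair.n_snps < 3:
        raise ValueError("weighted mode requires at least 3 SNPs")
    ratios, ses = pair.wald_ratios()
    weights = ses ** -2
    beta = _mode_point(ratios, weights, bandwidth_factor)
    se = np.nan
    if n_boot > 0:
        r, w = _parametric_boot(pair, n_boot, seed)
        boots = np.array([_mode_point(r[b], w[b], bandwidth_factor)
                          for b in range(n_boot)])
        se = float(boots.std(ddof=1))
    return _estimate(beta, se, "weighted_mode", pair.metabolite,
                     n_snps=pair.n_snps, n_boot=n_boot or None)


_METHODS = {
    "ivw": lambda pair, n_boot, seed, **kw: [ivw(pair, **kw)],
    "egger": lambda pair, n_boot, seed, **kw: list(mr_egger(pair)),
    "weighted_median": lambda pair, n_boot, seed, **kw: [
        weighted_median(pair, n_boot=n_boot, seed=seed)],
    "weighted_mode": lambda pair, n_boot, seed, **kw: [
        weighted_mode(pair, n_boot=n_boot, seed=seed)],
    "wald": lambda pair, n_boot, seed, **kw: [wald_ratio(pair)],
}

DEFAULT_METHODS = ("ivw", "egger", "weighted_median", "weighted_mode")


class ReverseMR:
    """Two-sample reverse-MR model: disease liability → metabolite.

    Parameters
    ----------
    exposure
        Instrument table (SNP→liability weights and SEs); its effect
        alleles define the harmonized orientation.
    outcome
        SNP→metabolite summary statistics, or a mapping of metabolite
        name → summary statistics for a panel.
    palindrome_policy
        Passed to allele harmonization.
    """

    def __init__(
        self,
        exposure: InstrumentTable,
        outcome: Union[SummaryStats, Dict[str, SummaryStats]],
        palindrome_policy: str = "eaf",
    ) -> None:
        self.exposure = exposure
        self.outcomes: Dict[str, SummaryStats] = (
            outcome if isinstance(outcome, dict) else {"outcome": outcome}
        )
        self.palindrome_policy = palindrome_policy

    def pair(self, metabolite: str, exclude_apoe: bool = False) -> HarmonizedPair:
        exp = self.exposure.without_apoe() if exclude_apoe else self.exposure
        return HarmonizedPair.from_summary(
            exp, self.outcomes[metabolite],
            palindrome_policy=self.palindrome_policy, metabolite=metabolite,
        )

    def fit(
        self,
        methods: Sequence[str] = DEFAULT_METHODS,
        exclude_apoe: str = "both",
        n_boot: int = 1000,
        seed: int = 0,
        scale: str = "doubling",
        effects_model: str = "multiplicative_random",
    ) -> "ReverseMRResults":
        """Run the requested estimators for every metabolite.

        ``exclude_apoe`` ∈ {"with", "without", "both"} controls whether
        the APOE-isoform SNPs are included in the instrument, excluded,
        or both variants reported.  With ``scale="doubling"`` every
        liability-effect estimate (not the Egger intercept) is multiplied
        by ln 2 so results read as SD change per doubling of liability.
        """
        if exclude_apoe not in ("with", "without", "both"):
            raise ValueError("exclude_apoe must be 'with', 'without' or 'both'")
        variants = {"with": [False], "without": [True], "both": [False, True]}
        unknown = set(methods) - set(_METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")
        estimates: List[EffectEstimate] = []
        for met in self.outcomes:
            for drop_apoe in variants[exclude_apoe]:
                pair = self.pair(met, exclude_apoe=drop_apoe)
                stratum = "without_APOE" if drop_apoe else "with_APOE"
                for m in methods:
                    kw = {"effects_model": effects_model} if m == "ivw" else {}
                    if m == "ivw" and pair.n_snps < 2:
                        res = [wald_ratio(pair)]
                    else:
                        res = _METHODS[m](pair, n_boot, seed, **kw)
                    for r in res:
                        r = replace(r, stratum=stratum, metabolite=met)
                        if scale == "doubling" and r.method != "egger_intercept":
                            r = r.scale_to_doubling()
                        estimates.append(r)
        return ReverseMRResults(self, estimates)


@dataclass
class ReverseMRResults:
    """Estimates from :meth:`ReverseMR.fit` with a summary table."""

    model: ReverseMR
    estimates: List[EffectEstimate]

    @property
    def table(self) -> pd.DataFrame:
        return estimates_to_frame(self.estimates)

    def __getitem__(self, method: str) -> List[EffectEstimate]:
        return [e for e in self.estimates if e.method == method]

    def summary(self) -> str:
        df = self.table
        cols = ["metabolite", "stratum", "method", "beta", "se",
                "ci_low", "ci_high", "p_value", "n_snps"]
        lines = ["Reverse MR: liability → metabolites",
                 "(beta in SD units per doubling of liability; "
                 "egger_intercept per SNP, unscaled)", ""]
        lines.append(df[cols].to_string(index=False,
                                        float_format=lambda v: f"{v: .4f}"))
        return "\n".join(lines)


def run_mr_panel(
    exposure: InstrumentTable,
    outcome: Union[SummaryStats, Dict[str, SummaryStats]],
    methods: Sequence[str] = DEFAULT_METHODS,
    exclude_apoe: str = "both",
    n_boot: int = 1000,
    seed: int = 0,
    palindrome_policy: str = "eaf",
) -> List[EffectEstimate]:
    """Functional wrapper: fit the full estimator panel, ln2-scaled."""
    model = ReverseMR(exposure, outcome, palindrome_policy=palindrome_policy)
    return model.fit(methods=methods, exclude_apoe=exclude_apoe,
                     n_boot=n_boot, seed=seed).estimates
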