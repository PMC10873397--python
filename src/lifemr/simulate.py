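"""Synthetic cohort and summary-statistic generator.

Individual-level cohort data from birth cohorts and biobanks cannot be
redistributed, so every downstream stage of the analysis is exercised on
synthetic cohorts with the statistical structure the analysis assumes:
Hardy-Weinberg genotypes at ~25 unlinked loci (the two APOE-isoform SNPs
drawn jointly as haplotype pairs), a weighted log-odds liability score,
metabolites generated as linear functions of that liability plus optional
per-allele direct (pleiotropic) SNP effects, age and sex covariates over
multiple timepoints, and configurable genotype missingness.

The generator also emits paired two-sample GWAS summary statistics
(SNP→liability and SNP→metabolite) with GWAS-scale standard errors and
deliberately scrambled allele orientations, so that harmonization is
exercised on every run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genetics import APOE_SNPS, COMPLEMENT, InstrumentTable, SummaryStats

__all__ = [
    "Timepoint",
    "GenerativeSpec",
    "Cohort",
    "simulate_cohort",
    "simulate_summary_stats",
    "example_instrument_table",
    "pleiotropy_effects",
    "write_cohort",
]


@dataclass(frozen=True)
class Timepoint:
    """Age distribution at one assessment wave (years)."""

    label: str
    age_mean: float
    age_sd: float = 1.0


#: default haplotype frequencies (ε2, ε3, ε4) matching UK population values
DEFAULT_APOE_HAPLOTYPE_FREQS = (0.08, 0.77, 0.15)


def example_instrument_table() -> InstrumentTable:
    """A synthetic 25-SNP Alzheimer's-liability instrument.

    Effect alleles are the risk-increasing alleles, so all weights are
    positive log odds ratios.  Ids follow the well-known AD loci (APOE,
    BIN1, CLU, ...) but the weights and frequencies are illustrative
    values in the published range, not any study's published estimates.
    The APOE ε4-defining SNP carries the dominant weight; rs9331896
    (CLU) is included so proxy substitution can be exercised.
    """
    rows = [
        # snp, risk (effect) allele, other, log-OR weight, se, risk-allele eaf
        ("rs429358", "C", "T", 1.12, 0.02, 0.15),    # APOE e4-defining
        ("rs7412", "C", "T", 0.47, 0.03, 0.92),      # APOE e2-defining (risk = C)
        ("rs6733839", "T", "C", 0.18, 0.015, 0.40),  # BIN1
        ("rs9331896", "T", "C", 0.15, 0.015, 0.62),  # CLU
        ("rs10933431", "C", "G", 0.12, 0.02, 0.75),
        ("rs9271058", "A", "T", 0.10, 0.02, 0.30),
        ("rs75932628", "T", "C", 0.45, 0.08, 0.02),  # TREM2 (rare)
        ("rs9473117", "C", "A", 0.09, 0.015, 0.28),
        ("rs12539172", "C", "T", 0.09, 0.015, 0.69),
        ("rs10808026", "C", "A", 0.10, 0.016, 0.80),
        ("rs73223431", "T", "C", 0.08, 0.014, 0.36),
        ("rs9331942", "A", "G", 0.07, 0.02, 0.68),
        ("rs3740688", "T", "G", 0.08, 0.014, 0.55),
        ("rs7933202", "C", "A", 0.09, 0.014, 0.36),
        ("rs3851179", "G", "A", 0.11, 0.014, 0.64),
        ("rs11218343", "T", "C", 0.22, 0.03, 0.96),  # SORL1
        ("rs17125924", "G", "A", 0.14, 0.022, 0.10),
        ("rs12881735", "T", "C", 0.08, 0.016, 0.78),
        ("rs3752246", "G", "C", 0.14, 0.02, 0.18),   # ABCA7
        ("rs28394864", "A", "G", 0.07, 0.013, 0.48),
        ("rs6024870", "G", "A", 0.11, 0.02, 0.91),
        ("rs7920721", "G", "A", 0.08, 0.014, 0.39),
        ("rs138190086", "A", "G", 0.22, 0.04, 0.02),
        ("rs593742", "A", "G", 0.08, 0.015, 0.73),
        ("rs7185636", "T", "C", 0.10, 0.017, 0.82),
    ]
    df = pd.DataFrame(
        rows, columns=["snp", "effect_allele", "other_allele", "beta", "se", "eaf"]
    )
    return InstrumentTable(df)


@dataclass
class GenerativeSpec:
    """Parameters of the synthetic cohort generator.

    ``theta`` maps each metabolite name to its true effect per unit
    log-odds of liability (SD units) — the target of all recovery tests.
    ``pleiotropy`` maps SNP id to a direct per-allele metabolite effect
    α_j (SD per effect allele), applied to every metabolite, used to
    exercise the MR estimators' differing robustness to directional
    pleiotropy.  ``covariate_effects`` maps metabolite →
    (age_slope per year, sex difference).
    """

    instrument: InstrumentTable
    n_samples: int = 2000
    theta: Mapping[str, float] = field(default_factory=lambda: {"metab_1": 0.1})
    pleiotropy: Mapping[str, float] = field(default_factory=dict)
    covariate_effects: Mapping[str, Tuple[float, float]] = field(default_factory=dict)
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    timepoints: Sequence[Timepoint] = field(
        default_factory=lambda: (Timepoint("t0", 50.0, 8.0),)
    )
    apoe_haplotype_freqs: Tuple[float, float, float] = DEFAULT_APOE_HAPLOTYPE_FREQS
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.instrument.table) == 0:
            raise ValueError("generative spec needs at least one SNP")
        if self.n_samples < 2:
            raise ValueError("n_samples must be at least 2")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        eaf = self.instrument.table["eaf"].to_numpy(dtype=float)
        if not np.all((eaf > 0) & (eaf < 1)):
            raise ValueError("all allele frequencies must lie strictly in (0, 1)")
        h = np.asarray(self.apoe_haplotype_freqs, dtype=float)
        if not (np.all(h > 0) and abs(h.sum() - 1.0) < 1e-9):
            raise ValueError("APOE haplotype frequencies must be positive and sum to 1")
        unknown = set(self.pleiotropy) - set(self.instrument.table["snp"])
        if unknown:
            raise ValueError(f"pleiotropy refers to unknown SNPs {sorted(unknown)}")

    @property
    def metabolites(self) -> List[str]:
        return list(self.theta)


@dataclass
class Cohort:
    """Individual-level synthetic cohort.

    ``dosages``: samples × SNPs effect-allele dosage matrix (NaN missing).
    ``phenotypes``: long table with one row per sample × timepoint
    (columns sample_id, timepoint, age, sex, one column per metabolite).
    ``liability``: the true weighted log-odds liability per sample, kept
    for diagnostics and recovery tests.
    """

    dosages: pd.DataFrame
    phenotypes: pd.DataFrame
    eligibility: pd.Series
    liability: pd.Series

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.index

    def metabolite_names(self) -> List[str]:
        reserved = {"sample_id", "timepoint", "age", "sex"}
        return [c for c in self.phenotypes.columns if c not in reserved]

    def at_timepoint(self, label: str) -> pd.DataFrame:
        sub = self.phenotypes[self.phenotypes["timepoint"] == label]
        if sub.empty:
            raise KeyError(f"no timepoint {label!r}")
        return sub.set_index("sample_id")


def _simulate_dosages(spec: GenerativeSpec, rng: np.random.Generator) -> pd.DataFrame:
    table = spec.instrument.table
    n = spec.n_samples
    snps = table["snp"].tolist()
    g = np.empty((n, len(snps)), dtype=float)
    apoe_present = [s for s in spec.instrument.apoe_ids if s in snps]
    for j, (snp, f) in enumerate(zip(snps, table["eaf"])):
        if snp in apoe_present:
            continue  # filled below from haplotypes
        g[:, j] = rng.binomial(2, f, size=n)
    if len(apoe_present) == 2:
        # haplotypes 0=e2, 1=e3, 2=e4 drawn in pairs so that the two
        # defining-SNP genotypes co-occur realistically
        hap = rng.choice(3, size=(n, 2), p=np.asarray(spec.apoe_haplotype_freqs))
        e4_count = (hap == 2).sum(axis=1).astype(float)  # rs429358 C count
        e2_count = (hap == 0).sum(axis=1).astype(float)  # rs7412 T count
        id_429358, id_7412 = spec.instrument.apoe_ids
        ea = table.set_index("snp")["effect_allele"]
        # dosage columns count the instrument's effect allele
        g[:, snps.index(id_429358)] = (
            e4_count if ea[id_429358] == "C" else 2.0 - e4_count
        )
        g[:, snps.index(id_7412)] = (
            e2_count if ea[id_7412] == "T" else 2.0 - e2_count
        )
    elif apoe_present:
        j = snps.index(apoe_present[0])
        g[:, j] = rng.binomial(2, table.loc[table["snp"] == apoe_present[0],
                                            "eaf"].iloc[0], size=n)
    ids = pd.Index([f"S{i:06d}" for i in range(n)], name="sample_id")
    return pd.DataFrame(g, index=ids, columns=snps)


def _apply_missingness(
    dosages: pd.DataFrame, rate: float, rng: np.random.Generator
) -> pd.DataFrame:
    if rate == 0.0:
        return dosages
    g = dosages.to_numpy().copy()
    mask = rng.random(g.shape) < rate
    # every retained sample keeps at least one observed SNP
    all_gone = mask.all(axis=1)
    if all_gone.any():
        cols = rng.integers(0, g.shape[1], size=int(all_gone.sum()))
        mask[np.flatnonzero(all_gone), cols] = False
    g[mask] = np.nan
    return pd.DataFrame(g, index=dosages.index, columns=dosages.columns)


def simulate_cohort(spec: GenerativeSpec) -> Cohort:
    """Draw one cohort from the generative model.

    Dosages are Binomial(2, f_j), independent across SNPs (linkage
    equilibrium) except the two APOE SNPs, which come from joint haplotype
    draws.  For sample i with liability ``L_i = Σ_j w_j g_ij`` each
    metabolite at each timepoint is

        M_i = θ·L_i + Σ_j α_j g_ij + age_slope·age_i + sex_diff·sex_i + ε_i

    with ε ~ Normal(0, noise_sd²).  Missingness is applied to the dosage
    matrix completely at random at ``missing_rate``, with the guarantee
    that every sample keeps at least one observed SNP.  Identical spec and
    seed give byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    table = spec.instrument.table
    full = _simulate_dosages(spec, rng)
    w = table["beta"].to_numpy(dtype=float)
    liability = pd.Series(full.to_numpy() @ w, index=full.index, name="liability")

    alpha = np.array([spec.pleiotropy.get(s, 0.0) for s in table["snp"]])
    direct = full.to_numpy() @ alpha

    sex = rng.integers(0, 2, size=spec.n_samples).astype(float)
    rows = []
    for tp in spec.timepoints:
        age = rng.normal(tp.age_mean, tp.age_sd, size=spec.n_samples)
        block = pd.DataFrame(
            {"sample_id": full.index, "timepoint": tp.label, "age": age, "sex": sex}
        )
        for met, theta in spec.theta.items():
            slope, sexdiff = spec.covariate_effects.get(met, (0.0, 0.0))
            eps = rng.normal(0.0, spec.noise_sd, size=spec.n_samples)
            block[met] = (
                theta * liability.to_numpy() + direct
                + slope * age + sexdiff * sex + eps
            )
        rows.append(block)
    phenotypes = pd.concat(rows, ignore_index=True)

    dosages = _apply_missingness(full, spec.missing_rate, rng)
    eligibility = pd.Series(True, index=full.index, name="eligible")
    return Cohort(dosages=dosages, phenotypes=phenotypes,
                  eligibility=eligibility, liability=liability)


def _gwas_se(eaf: np.ndarray, n: int) -> np.ndarray:
    """Standard GWAS variance approximation se = 1/sqrt(2 f (1-f) n)."""
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)


def _scramble_alleles(
    df: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Randomize strand and effect/other ordering (harmonization fodder)."""
    out = df.copy()
    for i in out.index:
        ea, oa = out.at[i, "effect_allele"], out.at[i, "other_allele"]
        if rng.random() < 0.5:  # report the opposite strand
            ea, oa = COMPLEMENT[ea], COMPLEMENT[oa]
        if rng.random() < 0.5:  # swap effect/other orientation
            ea, oa = oa, ea
            out.at[i, "beta"] = -out.at[i, "beta"]
            out.at[i, "eaf"] = 1.0 - out.at[i, "eaf"]
        out.at[i, "effect_allele"], out.at[i, "other_allele"] = ea, oa
    return out


def simulate_summary_stats(
    spec: GenerativeSpec,
    n_exposure: int,
    n_outcome: int,
    seed: Optional[int] = None,
    metabolite: Optional[str] = None,
    scramble: bool = True,
) -> Tuple[SummaryStats, SummaryStats]:
    """Paired two-sample GWAS summary statistics for one metabolite.

    The exposure table carries estimated SNP→liability effects
    ``γ̂_j = w_j + Normal(0, se_γj²)`` and the outcome table estimated
    SNP→metabolite effects ``Γ̂_j = θ·w_j + α_j + Normal(0, se_Γj²)``,
    with GWAS-scale standard errors ``se = 1/sqrt(2 f (1-f) n)``.  The
    two tables use independent noise (non-overlapping samples).  With
    ``scramble`` the outcome alleles are emitted on randomized strands
    and orderings so allele harmonization is always exercised.
    """
    if n_exposure < 2 or n_outcome < 2:
        raise ValueError("sample sizes must be at least 2")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    table = spec.instrument.table
    met = metabolite or next(iter(spec.theta))
    theta = spec.theta[met]
    w = table["beta"].to_numpy(dtype=float)
    eaf = table["eaf"].to_numpy(dtype=float)
    alpha = np.array([spec.pleiotropy.get(s, 0.0) for s in table["snp"]])

    se_x = _gwas_se(eaf, n_exposure)
    se_y = _gwas_se(eaf, n_outcome)
    gamma_hat = w + rng.normal(0.0, se_x)
    big_gamma_hat = theta * w + alpha + rng.normal(0.0, se_y)

    base = table[["snp", "effect_allele", "other_allele"]].copy()
    exposure = base.copy()
    exposure["beta"] = gamma_hat
    exposure["se"] = se_x
    exposure["eaf"] = eaf
    exposure["n"] = n_exposure
    outcome = base.copy()
    outcome["beta"] = big_gamma_hat
    outcome["se"] = se_y
    outcome["eaf"] = eaf
    outcome["n"] = n_outcome
    if scramble:
        outcome = _scramble_alleles(outcome, rng)
    return SummaryStats(exposure), SummaryStats(outcome)


def pleiotropy_effects(
    instrument: InstrumentTable,
    sd: float,
    mean: float = 0.0,
    rho_with_weights: float = 0.0,
    seed: int = 0,
) -> Dict[str, float]:
    """Draw per-SNP direct effects α_j ~ Normal(mean, sd²).

    With ``rho_with_weights`` = 0 the α_j are independent of the
    instrument weights (the InSIDE condition holds by construction); a
    nonzero value correlates α_j with w_j to violate InSIDE for stress
    tests.
    """
    rng = np.random.default_rng(seed)
    w = instrument.table["beta"].to_numpy(dtype=float)
    z = rng.normal(size=len(w))
    w_std = (w - w.mean()) / w.std() if w.std() > 0 else np.zeros_like(w)
    draw = mean + sd * (rho_with_weights * w_std
                        + np.sqrt(max(0.0, 1 - rho_with_weights ** 2)) * z)
    return dict(zip(instrument.table["snp"], draw))


def write_cohort(cohort: Cohort, out_dir) -> Dict[str, Path]:
    """Write dosage and phenotype TSVs (``NA`` marks missing dosages)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "dosages": out / "dosages.tsv",
        "phenotypes": out / "phenotypes.tsv",
    }
    cohort.dosages.reset_index().to_csv(
        paths["dosages"], sep="\t", index=False, na_rep="NA"
    )
    cohort.phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False)
    return paths
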