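"""Life-course orchestration of the three analysis arms.

The full design runs (i) a GRS arm at each assessment timepoint of a
longitudinal cohort (score → metabolite OLS, per doubling of liability),
(ii) a two-sample MR arm within age tertiles of an adult cohort (per-SNP
metabolite GWAS feeding the estimator suite, with and without the APOE
SNPs), and (iii) APOE ε4/ε2 carrier contrasts per stratum — all on
rank-inverse-normal metabolites, emitting one forest-plot-ready long
table per arm plus a machine-readable provenance block.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__ as _version
from .association import (
    apoe_contrast,
    grs_metabolite_assoc,
    snp_metabolite_gwas,
)
from .genetics import (
    InstrumentTable,
    apoe_defining_dosages,
    classify_apoe,
    compute_grs,
)
from .mr import DEFAULT_METHODS, ReverseMR
from .results import EffectEstimate, estimates_to_frame
from .simulate import Cohort
from .transforms import rank_inverse_normal

logger = logging.getLogger(__name__)

__all__ = ["StratumSpec", "RunConfig", "PipelineResults",
           "assign_age_tertiles", "run_pipeline"]


@dataclass(frozen=True)
class StratumSpec:
    """One analysis stratum: a timepoint or an age tertile."""

    label: str
    rule: str            # "timepoint" | "age_tertile"
    n: int
    age_min: float
    age_max: float


def assign_age_tertiles(ages: pd.Series) -> Tuple[List[StratumSpec], pd.Series]:
    """Split samples into three contiguous age-rank groups.

    Samples are ranked by age (ties broken by stable input order) and cut
    into tertiles whose sizes differ by at most one, the remainder going
    to the youngest groups.  Returns the stratum descriptions (with the
    observed age bounds) and a per-sample tertile index (0 = youngest).
    """
    vals = ages.to_numpy(dtype=float)
    n = len(vals)
    if n < 3:
        raise ValueError("age tertiles need at least 3 samples")
    order = np.argsort(vals, kind="stable")
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    labels = np.empty(n, dtype=int)
    start = 0
    strata = []
    for t, size in enumerate(sizes):
        idx = order[start:start + size]
        labels[idx] = t
        strata.append(StratumSpec(
            label=f"tertile_{t + 1}", rule="age_tertile", n=size,
            age_min=float(vals[idx].min()), age_max=float(vals[idx].max()),
        ))
        start += size
    if strata[0].age_max == strata[-1].age_min:
        logger.warning("age ties span tertile boundaries; bounds overlap")
    return strata, pd.Series(labels, index=ages.index, name="age_tertile")


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    ``arms`` selects which analyses execute; policies mirror the module
    defaults (GRS missingness rescaling, frequency-based palindrome
    alignment, multiplicative-random-effects IVW).
    """

    instrument: InstrumentTable
    cohort: Cohort
    arms: Sequence[str] = ("grs", "mr", "apoe")
    metabolites: Optional[Sequence[str]] = None
    covariates: Sequence[str] = ("age", "sex")
    missing_policy: str = "rescale"
    palindrome_policy: str = "eaf"
    effects_model: str = "multiplicative_random"
    mr_methods: Sequence[str] = DEFAULT_METHODS
    mr_timepoint: Optional[str] = None
    n_boot: int = 1000
    min_n: int = 30
    min_group: int = 10
    seed: int = 0
    out_dir: Optional[Path] = None

    def __post_init__(self) -> None:
        unknown = set(self.arms) - {"grs", "mr", "apoe"}
        if unknown:
            raise ValueError(f"unknown arms {sorted(unknown)}")


@dataclass
class PipelineResults:
    """Per-arm long-format result tables plus provenance."""

    tables: Dict[str, pd.DataFrame]
    strata: List[StratumSpec]
    provenance: Dict[str, object]

    def forest_table(self) -> pd.DataFrame:
        """All arms stacked, keyed metabolite × stratum × method."""
        frames = [t.assign(arm=a) for a, t in self.tables.items() if not t.empty]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    def write(self, out_dir) -> Dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for arm, table in self.tables.items():
            p = out / f"results_{arm}.tsv"
            table.to_csv(p, sep="\t", index=False)
            paths[arm] = p
        prov = out / "provenance.json"
        prov.write_text(json.dumps(self.provenance, indent=2, default=str))
        paths["provenance"] = prov
        forest = out / "forest.tsv"
        self.forest_table().to_csv(forest, sep="\t", index=False)
        paths["forest"] = forest
        return paths


def _int_panel(frame: pd.DataFrame, metabolites: Sequence[str]) -> pd.DataFrame:
    out = frame.copy()
    for met in metabolites:
        out[met] = rank_inverse_normal(out[met].to_numpy(dtype=float))
    return out


def _run_grs_arm(config: RunConfig, metabolites: Sequence[str]) -> List[EffectEstimate]:
    cohort = config.cohort
    estimates = []
    scores = {
        "with_APOE": compute_grs(cohort.dosages, config.instrument,
                                 missing_policy=config.missing_policy,
                                 include_apoe=True),
        "without_APOE": compute_grs(cohort.dosages, config.instrument,
                                    missing_policy=config.missing_policy,
                                    include_apoe=False),
    }
    for tp in cohort.phenotypes["timepoint"].unique():
        phenos = _int_panel(cohort.at_timepoint(tp), metabolites)
        for met in metabolites:
            for variant, grs in scores.items():
                try:
                    est = grs_metabolite_assoc(
                        phenos, grs, met, covariates=config.covariates,
                        stratum=f"{tp}:{variant}", min_n=config.min_n,
                    )
                except ValueError as exc:
                    logger.warning("GRS arm skipped %s at %s (%s): %s",
                                   met, tp, variant, exc)
                    continue
                logger.info("grs arm: stratum=%s metabolite=%s n=%d",
                            est.stratum, met, est.n)
                estimates.append(est)
    return estimates


def _run_mr_arm(
    config: RunConfig, metabolites: Sequence[str]
) -> Tuple[List[EffectEstimate], List[StratumSpec]]:
    cohort = config.cohort
    tp = config.mr_timepoint or cohort.phenotypes["timepoint"].iloc[0]
    phenos = cohort.at_timepoint(tp)
    strata, tertile = assign_age_tertiles(phenos["age"])
    estimates = []
    for spec, t in zip(strata, range(3)):
        sub = phenos[tertile == t]
        sub = _int_panel(sub, metabolites)
        outcomes = {}
        for met in metabolites:
            outcomes[met] = snp_metabolite_gwas(
                cohort.dosages, sub, config.instrument, met,
                covariates=config.covariates, min_n=config.min_n,
            )
        model = ReverseMR(config.instrument, outcomes,
                          palindrome_policy=config.palindrome_policy)
        fit = model.fit(methods=config.mr_methods, exclude_apoe="both",
                        n_boot=config.n_boot, seed=config.seed,
                        effects_model=config.effects_model)
        for est in fit.estimates:
            estimates.append(replace(est, stratum=f"{spec.label}:{est.stratum}"))
        logger.info("mr arm: stratum=%s n=%d estimates=%d",
                    spec.label, spec.n, len(fit.estimates))
    return estimates, strata


def _run_apoe_arm(config: RunConfig, metabolites: Sequence[str]) -> List[EffectEstimate]:
    cohort = config.cohort
    c4, t2 = apoe_defining_dosages(cohort.dosages, config.instrument)
    diplo = classify_apoe(c4, t2, sample_ids=cohort.dosages.index)
    estimates = []
    for tp in cohort.phenotypes["timepoint"].unique():
        phenos = _int_panel(cohort.at_timepoint(tp), metabolites)
        for met in metabolites:
            for contrast in ("e4_vs_e3e3", "e2_vs_e3e3"):
                try:
                    est = apoe_contrast(
                        phenos, diplo, contrast, met,
                        covariates=config.covariates, stratum=str(tp),
                        min_group=config.min_group, min_n=config.min_n,
                    )
                except ValueError as exc:
                    logger.warning("APOE arm skipped %s/%s at %s: %s",
                                   contrast, met, tp, exc)
                    continue
                estimates.append(est)
                logger.info("apoe arm: stratum=%s contrast=%s metabolite=%s n=%d",
                            tp, contrast, met, est.n)
    return estimates


def run_pipeline(config: RunConfig) -> PipelineResults:
    """Execute the requested arms and collect forest-plot-ready tables.

    A failure inside one arm aborts that arm only (logged); if every
    requested arm produces an empty table the run raises.  Reruns with
    identical config and seed produce byte-identical tables.
    """
    metabolites = list(config.metabolites or config.cohort.metabolite_names())
    if not metabolites:
        raise ValueError("no metabolites to analyse")
    tables: Dict[str, pd.DataFrame] = {}
    strata: List[StratumSpec] = []
    runners = {"grs": _run_grs_arm, "mr": None, "apoe": _run_apoe_arm}
    for arm in config.arms:
        try:
            if arm == "mr":
                estimates, strata = _run_mr_arm(config, metabolites)
            else:
                estimates = runners[arm](config, metabolites)
            tables[arm] = estimates_to_frame(estimates)
        except Exception:
            logger.exception("arm %r aborted", arm)
            tables[arm] = pd.DataFrame()
    if all(t.empty for t in tables.values()):
        raise RuntimeError("pipeline produced no results")
    provenance = {
        "package": "lifemr",
        "version": _version,
        "seed": config.seed,
        "arms": list(config.arms),
        "metabolites": metabolites,
        "policies": {
            "missing_policy": config.missing_policy,
            "palindrome_policy": config.palindrome_policy,
            "effects_model": config.effects_model,
            "n_boot": config.n_boot,
        },
        "n_samples": int(len(config.cohort.sample_ids)),
        "strata": [dataclasses.asdict(s) for s in strata],
    }
    results = PipelineResults(tables=tables, strata=strata, provenance=provenance)
    if config.out_dir is not None:
        results.write(config.out_dir)
    return results
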