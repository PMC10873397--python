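"""Result containers shared across the GRS, MR and APOE arms.

Every analysis arm emits :class:`EffectEstimate` rows: a point estimate in
SD units of the (rank-normalised) metabolite, its standard error, a 95%
confidence interval, and bookkeeping (method label, stratum, sample size,
whether the per-doubling-of-liability scaling has been applied).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd

LN2 = math.log(2.0)
#: normal 97.5% quantile used for all confidence intervals
Z_95 = 1.959963984540054


@dataclass(frozen=True)
class EffectEstimate:
    """One result row: an effect of genetic liability (or APOE carriage).

    ``beta`` is in SD units of the metabolite — per doubling of genetic
    liability when ``scaled_by_ln2`` is True, per log-odds of liability
    (or per carrier group for APOE contrasts) otherwise.
    """

    beta: float
    se: float
    n: int
    method: str
    metabolite: str = ""
    stratum: str = ""
    ci_low: float = field(default=np.nan)
    ci_high: float = field(default=np.nan)
    p_value: float = field(default=np.nan)
    scaled_by_ln2: bool = False
    n_snps: Optional[int] = None
    q_stat: Optional[float] = None
    q_df: Optional[int] = None
    n_boot: Optional[int] = None

    def __post_init__(self) -> None:
        if np.isnan(self.ci_low) and np.isfinite(self.se):
            object.__setattr__(self, "ci_low", self.beta - Z_95 * self.se)
            object.__setattr__(self, "ci_high", self.beta + Z_95 * self.se)

    def scale_to_doubling(self) -> "EffectEstimate":
        """Convert a per-log-odds estimate to per-doubling by multiplying
        beta, SE and both CI bounds by ln 2.  Guarded against double
        application."""
        if self.scaled_by_ln2:
            raise ValueError("estimate is already on the per-doubling scale")
        return replace(
            self,
            beta=self.beta * LN2,
            se=self.se * LN2,
            ci_low=self.ci_low * LN2,
            ci_high=self.ci_high * LN2,
            scaled_by_ln2=True,
        )


def scale_to_doubling(result: EffectEstimate) -> EffectEstimate:
    """Functional alias for :meth:`EffectEstimate.scale_to_doubling`."""
    return result.scale_to_doubling()


def estimates_to_frame(estimates: Iterable[EffectEstimate]) -> pd.DataFrame:
    """Long-format results table, directly consumable as forest-plot input."""
    rows = []
    for e in estimates:
        rows.append(
            {
                "metabolite": e.metabolite,
                "stratum": e.stratum,
                "method": e.method,
                "beta": e.beta,
                "se": e.se,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "p_value": e.p_value,
                "n": e.n,
                "n_snps": e.n_snps,
                "q_stat": e.q_stat,
                "q_df": e.q_df,
                "scaled_by_ln2": e.scaled_by_ln2,
            }
        )
    return pd.DataFrame(rows)
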