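"""Instrument handling: allele harmonization, proxy substitution, weighted
genetic risk scores, and APOE diplotype classification.

The genetic instrument for Alzheimer's disease liability is a table of
genome-wide-significant SNPs with external log-odds-ratio weights from a
clinical case-control GWAS.  Two scores are built from it — one including
and one excluding the two APOE-isoform-defining SNPs (rs429358 and rs7412)
— so that APOE-driven and polygenic effects can be separated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: rs429358-C marks the epsilon-4 haplotype, rs7412-T the epsilon-2 one.
APOE_SNPS = ("rs429358", "rs7412")

#: Palindromic ambiguity band: a palindromic SNP whose allele frequency is
#: within this distance of 0.5 cannot be aligned by frequency and is dropped.
PALINDROME_EAF_BAND = 0.08

INSTRUMENT_COLUMNS = ["snp", "effect_allele", "other_allele", "beta", "se"]
SUMMARY_COLUMNS = ["snp", "effect_allele", "other_allele", "beta", "se", "eaf", "n"]


def _check_alleles(df: pd.DataFrame, label: str) -> None:
    for col in ("effect_allele", "other_allele"):
        bad = ~df[col].isin(VALID_ALLELES)
        if bad.any():
            raise ValueError(
                f"{label}: invalid alleles {sorted(df.loc[bad, col].unique())}"
            )
    same = df["effect_allele"] == df["other_allele"]
    if same.any():
        raise ValueError(f"{label}: effect and other allele identical for "
                         f"{df.loc[same, 'snp'].tolist()}")


@dataclass
class InstrumentTable:
    """SNP → disease weights defining genetic liability.

    ``table`` columns: snp, effect_allele, other_allele, beta (log-odds per
    effect allele), se, and optionally eaf.  ``apoe_ids`` flags the SNPs
    that define the APOE isoforms.
    """

    table: pd.DataFrame
    apoe_ids: Tuple[str, ...] = APOE_SNPS

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in INSTRUMENT_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"instrument table lacks columns {missing}")
        if t["snp"].duplicated().any():
            raise ValueError("instrument SNP ids must be unique")
        if not np.isfinite(t["beta"].to_numpy(dtype=float)).all():
            raise ValueError("instrument weights must be finite")
        _check_alleles(t, "instrument")
        self.table = t.reset_index(drop=True)

    @property
    def snps(self) -> pd.Index:
        return pd.Index(self.table["snp"])

    def without_apoe(self) -> "InstrumentTable":
        """Drop the APOE-isoform SNPs (for the APOE-excluded score / MR)."""
        keep = ~self.table["snp"].isin(self.apoe_ids)
        return InstrumentTable(self.table.loc[keep].reset_index(drop=True),
                               apoe_ids=self.apoe_ids)

    def weights(self) -> pd.Series:
        return self.table.set_index("snp")["beta"]

    @classmethod
    def from_tsv(cls, path, apoe_ids: Tuple[str, ...] = APOE_SNPS) -> "InstrumentTable":
        return cls(pd.read_csv(path, sep="\t"), apoe_ids=apoe_ids)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class SummaryStats:
    """Per-SNP association estimates (beta, se, alleles, eaf, n)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.copy()
        for col in ("eaf", "n"):
            if col not in t.columns:
                t[col] = np.nan
        missing = [c for c in SUMMARY_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"summary-stats table lacks columns {missing}")
        _check_alleles(t, "summary stats")
        self.table = t.reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path) -> "SummaryStats":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ProxyRecord:
    proxy_id: str
    r2: float
    distance_kb: float


class ProxyMap:
    """User-supplied LD proxies: original SNP id → (proxy id, r², distance).

    Proxy *search* against a reference panel is out of scope; this consumes
    a pre-computed mapping and enforces the r² and distance thresholds
    (defaults r² ≥ 0.8 within 10,000 kb).
    """

    def __init__(
        self,
        mapping: Mapping[str, ProxyRecord] | Mapping[str, tuple],
        r2_threshold: float = 0.8,
        max_distance_kb: float = 10_000.0,
    ) -> None:
        self.r2_threshold = r2_threshold
        self.max_distance_kb = max_distance_kb
        self.mapping: Dict[str, ProxyRecord] = {}
        for orig, rec in mapping.items():
            if not isinstance(rec, ProxyRecord):
                rec = ProxyRecord(*rec)
            self.mapping[orig] = rec

    def lookup(self, snp_id: str) -> Optional[ProxyRecord]:
        rec = self.mapping.get(snp_id)
        if rec is None:
            return None
        if rec.r2 < self.r2_threshold or rec.distance_kb > self.max_distance_kb:
            logger.warning(
                "proxy %s for %s rejected (r2=%.3f, distance=%.0f kb)",
                rec.proxy_id, snp_id, rec.r2, rec.distance_kb,
            )
            return None
        return rec

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "ProxyMap":
        df = pd.read_csv(path, sep="\t")
        mapping = {
            row["snp"]: ProxyRecord(row["proxy"], float(row["r2"]),
                                    float(row.get("distance_kb", 0.0)))
            for _, row in df.iterrows()
        }
        return cls(mapping, **kwargs)


def _is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT[a1] == a2


def harmonize(
    instrument: InstrumentTable,
    stats: SummaryStats,
    palindrome_policy: str = "eaf",
) -> SummaryStats:
    """Align summary statistics to the instrument's effect alleles.

    Rows whose effect/other alleles are swapped relative to the instrument
    get their beta sign flipped and eaf reflected; rows on the opposite
    strand are complemented first.  Palindromic SNPs (A/T or C/G) are
    handled per ``palindrome_policy``:

    - ``"eaf"`` (default): align by allele frequency when both tables have
      an eaf further than :data:`PALINDROME_EAF_BAND` from 0.5; otherwise
      drop the row as frequency-uninformative.
    - ``"drop"``: drop all palindromic rows.
    - ``"keep"``: assume same strand and align by allele letters.

    Irreconcilable rows are dropped with a logged reason; the dropped rows
    are recorded in ``result.table.attrs['harmonization_log']``.  Raises if
    no row survives.  The operation is idempotent.
    """
    if palindrome_policy not in ("eaf", "drop", "keep"):
        raise ValueError(f"unknown palindrome policy {palindrome_policy!r}")
    inst = instrument.table.set_index("snp")
    shared = [s for s in stats.table["snp"] if s in inst.index]
    if not shared:
        raise ValueError("no shared SNPs between instrument and summary stats")

    out_rows, log = [], []
    for _, row in stats.table.iterrows():
        snp = row["snp"]
        if snp not in inst.index:
            log.append({"snp": snp, "action": "dropped", "reason": "not in instrument"})
            continue
        ea_i = inst.at[snp, "effect_allele"]
        oa_i = inst.at[snp, "other_allele"]
        ea_s, oa_s = row["effect_allele"], row["other_allele"]
        beta, eaf = float(row["beta"]), float(row["eaf"])
        rec = row.to_dict()

        if _is_palindromic(ea_i, oa_i):
            if palindrome_policy == "drop":
                log.append({"snp": snp, "action": "dropped",
                            "reason": "palindromic (policy=drop)"})
                continue
            if {ea_s, oa_s} != {ea_i, oa_i}:
                log.append({"snp": snp, "action": "dropped",
                            "reason": "irreconcilable alleles"})
                continue
            if palindrome_policy == "keep":
                flip = ea_s != ea_i
            else:  # align by frequency
                eaf_i = float(inst.at[snp, "eaf"]) if "eaf" in inst.columns else np.nan
                if (not np.isfinite(eaf) or not np.isfinite(eaf_i)
                        or abs(eaf - 0.5) <= PALINDROME_EAF_BAND
                        or abs(eaf_i - 0.5) <= PALINDROME_EAF_BAND):
                    log.append({"snp": snp, "action": "dropped",
                                "reason": "palindromic, frequency uninformative"})
                    continue
                flip = (eaf > 0.5) != (eaf_i > 0.5)
        else:
            if {ea_s, oa_s} == {ea_i, oa_i}:
                flip = ea_s != ea_i
            elif {COMPLEMENT[ea_s], COMPLEMENT[oa_s]} == {ea_i, oa_i}:
                ea_s, oa_s = COMPLEMENT[ea_s], COMPLEMENT[oa_s]
                flip = ea_s != ea_i
            else:
                log.append({"snp": snp, "action": "dropped",
                            "reason": "irreconcilable alleles"})
                continue

        if flip:
            beta = -beta
            eaf = 1.0 - eaf if np.isfinite(eaf) else eaf
        rec.update(effect_allele=ea_i, other_allele=oa_i, beta=beta, eaf=eaf)
        out_rows.append(rec)
        if flip:
            log.append({"snp": snp, "action": "flipped", "reason": "allele swap"})

    if not out_rows:
        raise ValueError("harmonization retained zero rows")
    result = SummaryStats(pd.DataFrame(out_rows))
    result.table.attrs["harmonization_log"] = log
    return result


def apply_proxies(
    instrument: InstrumentTable,
    available_ids: Iterable[str],
    proxies: Optional[ProxyMap] = None,
) -> InstrumentTable:
    """Substitute proxy SNP ids for instrument SNPs absent from a dataset.

    Weights are carried over unchanged; an absent SNP with no acceptable
    proxy stays in the table under its original id (the GRS missingness
    policy then applies) with a warning.  Substitutions are recorded in
    ``result.table.attrs['proxy_log']``.
    """
    available = set(available_ids)
    table = instrument.table.copy()
    log = []
    for i, snp in enumerate(table["snp"]):
        if snp in available:
            continue
        rec = proxies.lookup(snp) if proxies is not None else None
        if rec is None:
            logger.warning("SNP %s absent and no acceptable proxy; left missing", snp)
            log.append({"snp": snp, "action": "missing"})
            continue
        table.loc[table.index[i], "snp"] = rec.proxy_id
        log.append({"snp": snp, "action": "proxied", "proxy": rec.proxy_id,
                    "r2": rec.r2})
        logger.info("substituted proxy %s (r2=%.2f) for %s", rec.proxy_id,
                    rec.r2, snp)
    out = InstrumentTable(table, apoe_ids=instrument.apoe_ids)
    out.table.attrs["proxy_log"] = log
    return out


@dataclass
class GrsVector:
    """Per-sample weighted genetic risk score in log-odds units."""

    scores: pd.Series          # index: sample_id
    n_snps_used: pd.Series     # index: sample_id
    variant: str               # "with_APOE" | "without_APOE"
    excluded_samples: Tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"score": self.scores, "n_snps_used": self.n_snps_used,
             "variant": self.variant}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().rename_axis("sample_id").reset_index().to_csv(
            path, sep="\t", index=False
        )


MISSING_POLICIES = ("rescale", "sum_observed", "mean_dosage_impute")


def compute_grs(
    dosages: pd.DataFrame,
    instrument: InstrumentTable,
    missing_policy: str = "rescale",
    include_apoe: bool = True,
) -> GrsVector:
    """Weighted GRS over effect-allele dosages, tolerating missing genotypes.

    ``dosages`` is samples × SNPs with entries in [0, 2] counting the
    instrument's effect allele (NaN = missing).  Missingness policies:

    - ``rescale`` (default): observed weighted sum × Σ_all |w| / Σ_obs |w|,
      keeping scores comparable across missingness patterns;
    - ``sum_observed``: raw observed weighted sum;
    - ``mean_dosage_impute``: missing dosage replaced by 2·eaf (needs eaf).

    Samples with zero observed instrument SNPs are excluded and listed in
    ``GrsVector.excluded_samples``.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    inst = instrument if include_apoe else instrument.without_apoe()
    w = inst.weights()
    present = [s for s in w.index if s in dosages.columns]
    if not present:
        raise ValueError("no overlap between instrument SNPs and dosage columns")
    w = w.loc[present]
    g = dosages[present].to_numpy(dtype=float)
    bad = np.isfinite(g) & ((g < 0) | (g > 2))
    if bad.any():
        raise ValueError("dosages must lie in [0, 2] or be missing")
    wv = w.to_numpy()
    obs = np.isfinite(g)
    n_used = obs.sum(axis=1)

    if missing_policy == "mean_dosage_impute":
        if "eaf" not in inst.table.columns or inst.table["eaf"].isna().any():
            raise ValueError("mean_dosage_impute requires instrument eaf")
        eaf = inst.table.set_index("snp").loc[present, "eaf"].to_numpy(dtype=float)
        g_filled = np.where(obs, g, 2.0 * eaf[None, :])
        scores = g_filled @ wv
    else:
        scores = np.nansum(g * wv[None, :], axis=1)
        if missing_policy == "rescale":
            w_abs = np.abs(wv)
            denom = (obs * w_abs[None, :]).sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                scores = scores * np.where(denom > 0, w_abs.sum() / denom, np.nan)

    keep = n_used >= 1
    excluded = tuple(dosages.index[~keep].astype(str))
    if excluded:
        logger.info("excluded %d samples with no observed instrument SNP",
                    len(excluded))
    return GrsVector(
        scores=pd.Series(scores[keep], index=dosages.index[keep], name="score"),
        n_snps_used=pd.Series(n_used[keep], index=dosages.index[keep],
                              name="n_snps_used"),
        variant="with_APOE" if include_apoe else "without_APOE",
        excluded_samples=excluded,
    )


# ---------------------------------------------------------------------------
# APOE diplotypes

#: (rs429358 C-dosage, rs7412 T-dosage) → (diplotype, carrier group).
#: C at rs429358 marks an ε4 haplotype, T at rs7412 an ε2 haplotype; the
#: combinations requiring a rare ε1 (C,T) haplotype are flagged ambiguous.
APOE_LOOKUP = {
    (0, 0): ("e3/e3", "e3e3"),
    (0, 1): ("e2/e3", "e2_carrier"),
    (0, 2): ("e2/e2", "e2_carrier"),
    (1, 0): ("e3/e4", "e4_carrier"),
    (2, 0): ("e4/e4", "e4_carrier"),
    (1, 1): ("e2/e4", "excluded"),
    (1, 2): ("ambiguous", "excluded"),
    (2, 1): ("ambiguous", "excluded"),
    (2, 2): ("ambiguous", "excluded"),
}

#: dosages are hard-called by rounding only when within this distance of an
#: integer; otherwise the sample is unclassifiable.
HARD_CALL_TOLERANCE = 0.1


@dataclass
class ApoeDiplotype:
    """Per-sample ε-diplotype call and carrier-group assignment.

    Groups: ``e4_carrier`` = {ε3/ε4, ε4/ε4}; ``e2_carrier`` = {ε2/ε3,
    ε2/ε2}; ``e3e3`` is the reference; ε2/ε4 heterozygotes and ambiguous
    or unclassifiable calls are ``excluded`` from both carrier contrasts.
    """

    calls: pd.DataFrame  # columns: diplotype, group; index: sample_id

    def group_counts(self) -> pd.Series:
        return self.calls["group"].value_counts()

    def mask(self, group: str) -> pd.Series:
        return self.calls["group"] == group


def apoe_defining_dosages(
    dosages: pd.DataFrame, instrument: InstrumentTable
) -> Tuple[pd.Series, pd.Series]:
    """Extract the ε4-defining rs429358-C and ε2-defining rs7412-T dosages.

    Dosage columns count the instrument's effect allele, which for a
    risk-oriented instrument is C at both APOE SNPs; this helper flips
    orientation where needed so classification always sees C counts at
    rs429358 and T counts at rs7412.
    """
    id_429358, id_7412 = instrument.apoe_ids
    for snp in (id_429358, id_7412):
        if snp not in dosages.columns:
            raise ValueError(f"APOE SNP {snp} missing from dosage matrix")
    ea = instrument.table.set_index("snp")["effect_allele"]
    c4 = dosages[id_429358]
    if ea[id_429358] != "C":
        c4 = 2.0 - c4
    t2 = dosages[id_7412]
    if ea[id_7412] != "T":
        t2 = 2.0 - t2
    return c4, t2


def _hard_call(dosage: np.ndarray) -> np.ndarray:
    rounded = np.rint(dosage)
    ok = np.isfinite(dosage) & (np.abs(dosage - rounded) <= HARD_CALL_TOLERANCE)
    ok &= (rounded >= 0) & (rounded <= 2)
    out = np.where(ok, rounded, np.nan)
    return out


def classify_apoe(
    dosage_rs429358_C, dosage_rs7412_T, sample_ids=None
) -> ApoeDiplotype:
    """Classify APOE ε-diplotypes from the two defining SNP dosages.

    ``dosage_rs429358_C`` counts the ε4-defining C allele at rs429358;
    ``dosage_rs7412_T`` counts the ε2-defining T allele at rs7412.  Dosages
    are hard-called (see :data:`HARD_CALL_TOLERANCE`); unclassifiable
    samples are flagged and excluded.
    """
    c4 = _hard_call(np.asarray(dosage_rs429358_C, dtype=float))
    t2 = _hard_call(np.asarray(dosage_rs7412_T, dtype=float))
    if c4.shape != t2.shape:
        raise ValueError("dosage vectors must have equal length")
    if sample_ids is None:
        sample_ids = pd.RangeIndex(len(c4))
    diplo, group = [], []
    n_unclass = 0
    for a, b in zip(c4, t2):
        if np.isnan(a) or np.isnan(b):
            diplo.append("unclassifiable")
            group.append("excluded")
            n_unclass += 1
        else:
            d, g = APOE_LOOKUP[(int(a), int(b))]
            diplo.append(d)
            group.append(g)
    if n_unclass:
        logger.info("APOE classification: %d unclassifiable samples", n_unclass)
    calls = pd.DataFrame({"diplotype": diplo, "group": group},
                         index=pd.Index(sample_ids, name="sample_id"))
    return ApoeDiplotype(calls)
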