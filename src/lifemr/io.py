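"""Readers for the flat-file cohort formats.

Dosage matrices travel as TSV (rows = samples, columns = SNP ids, ``NA``
for missing) and phenotypes as a long TSV (sample_id, timepoint, age,
sex, one column per metabolite).  Genotypes may alternatively arrive as
VCF with a DS (dosage) or GT field, read through pysam.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def read_dosages_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    return df.set_index(df.columns[0]).astype(float)


def read_phenotypes_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_dosages_vcf(path) -> pd.DataFrame:
    """Extract an effect-allele dosage matrix (samples × variants) from a
    VCF, preferring the DS FORMAT field and falling back to GT allele
    counts.  Dosages are counts of the ALT allele."""
    import pysam  # optional dependency, only needed for VCF input

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    ids, columns = [], []
    for rec in vf.fetch() if vf.index is not None else vf:
        name = rec.id or f"{rec.chrom}:{rec.pos}"
        col = np.full(len(samples), np.nan)
        for i, s in enumerate(samples):
            call = rec.samples[s]
            if "DS" in call and call["DS"] is not None:
                col[i] = float(call["DS"])
            elif call.get("GT") is not None and None not in call["GT"]:
                col[i] = float(sum(1 for a in call["GT"] if a == 1))
        ids.append(name)
        columns.append(col)
    return pd.DataFrame(
        np.column_stack(columns) if columns else np.empty((len(samples), 0)),
        index=pd.Index(samples, name="sample_id"),
        columns=ids,
    )
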