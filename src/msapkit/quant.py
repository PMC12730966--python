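"""Relative expression from qPCR threshold cycles (2^-ddCt).

No amplification-efficiency correction is applied.  Replicate handling:
technical replicates are averaged to one Ct per biological replicate,
fold changes are computed per biological replicate against the mean
control dCt, and conditions are reported as mean +/- SD of those folds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ValidationError

__all__ = ["relative_expression", "summarize_replicates", "read_ct_table"]

CT_COLUMNS = ("sample", "condition", "gene", "replicate", "ct")


def relative_expression(
    ct_gene_trt: float,
    ct_ref_trt: float,
    ct_gene_ctl: float,
    ct_ref_ctl: float,
) -> float:
    """Fold change 2^-(dCt_treated - dCt_control).

    dCt = Ct(gene) - Ct(reference) within each condition.  Adding any
    constant to all four Cts leaves the result unchanged.
    """
    cts = (ct_gene_trt, ct_ref_trt, ct_gene_ctl, ct_ref_ctl)
    if not all(isinstance(c, (int, float)) and math.isfinite(c) for c in cts):
        raise ValidationError(f"all Ct values must be finite numbers, got {cts}")
    ddct = (ct_gene_trt - ct_ref_trt) - (ct_gene_ctl - ct_ref_ctl)
    return float(2.0 ** (-ddct))


def read_ct_table(path) -> pd.DataFrame:
    """Read a Ct table CSV with columns sample, condition, gene, replicate, ct."""
    df = pd.read_csv(path)
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"Ct table missing column(s): {missing}")
    return df


def _validate_ct(df: pd.DataFrame) -> None:
    ct = pd.to_numeric(df["ct"], errors="coerce")
    bad = df.loc[~np.isfinite(ct) | (ct <= 0)]
    if not bad.empty:
        row = bad.iloc[0]
        raise ValidationError(
            f"invalid Ct {row['ct']!r} for sample {row['sample']!r}, gene {row['gene']!r}"
        )


def summarize_replicates(
    records: pd.DataFrame,
    gene: str,
    reference_gene: str,
    control_condition: str,
) -> pd.DataFrame:
    """Per-condition fold change (mean +/- SD over biological replicates).

    ``records`` must have columns sample, condition, gene, replicate, ct
    (``replicate`` indexes technical replicates; ``sample`` identifies
    the biological replicate).  The control condition's mean dCt is the
    calibrator, so identical control replicates give fold exactly 1.0.
    """
    missing = [c for c in CT_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"Ct table missing column(s): {missing}")
    _validate_ct(records)
    sub = records[records["gene"].isin([gene, reference_gene])].copy()
    if sub[sub["gene"] == gene].empty:
        raise ValidationError(f"no Ct records for gene {gene!r}")
    # technical replicates -> one Ct per (sample, gene)
    ct = (
        sub.groupby(["condition", "sample", "gene"], sort=False)["ct"]
        .mean()
        .unstack("gene")
    )
    if reference_gene not in ct.columns:
        raise ValidationError(f"no Ct records for reference gene {reference_gene!r}")
    if ct[reference_gene].isna().any():
        bad = ct.index[ct[reference_gene].isna()][0]
        raise ValidationError(
            f"missing reference gene {reference_gene!r} for sample {bad}"
        )
    ct = ct.dropna(subset=[gene])
    dct = ct[gene] - ct[reference_gene]
    conditions = dct.index.get_level_values("condition")
    if control_condition not in set(conditions):
        raise ValidationError(f"control condition {control_condition!r} not present")
    calibrator = dct[conditions == control_condition].mean()
    fold = 2.0 ** (-(dct - calibrator))
    out = (
        fold.groupby(level="condition", sort=False)
        .agg(fold_mean="mean", fold_sd="std", n_replicates="count")
        .reset_index()
    )
    out["fold_sd"] = out["fold_sd"].fillna(0.0)
    out["gene"] = gene
    return out[["gene", "condition", "fold_mean", "fold_sd", "n_replicates"]]
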