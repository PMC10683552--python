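"""Comparative ddCt relative quantification with primer-efficiency correction.

Implements the standard comparative-Ct workflow for the social-status qPCR
experiment: technical replicates are averaged per sample, each target gene is
normalized to the housekeeping reference (actb2) to give dCt, group means are
normalized to the social-isolate control group to give ddCt, and relative
expression is computed with per-gene amplification efficiencies.

Two efficiency corrections are offered:

* ``"pfaffl"`` (default): ratio = E_target^(-dCtl_target) / E_ref^(-dCtl_ref),
  where dCtl_gene = mean Ct(group, gene) - mean Ct(control, gene) on raw Ct;
* ``"simple"``: ratio = E_target^(-ddCt).

Both collapse to the textbook 2^(-ddCt) when every efficiency is 100%.
Results are reported as fold change and log2(fold).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "load_efficiencies",
    "amplification_factor",
    "delta_ct",
    "delta_delta_ct",
    "relative_expression",
    "analyze",
    "DEFAULT_REFERENCE_GENE",
    "DEFAULT_CONTROL_GROUP",
]

DEFAULT_REFERENCE_GENE = "actb2"
DEFAULT_CONTROL_GROUP = "isolate"

REQUIRED_COLUMNS = ("sample_id", "group", "gene", "replicate", "Ct")


def amplification_factor(efficiency_percent: float) -> float:
    """Per-cycle amplification factor from a printed efficiency percent.

    100% efficiency doubles the template each cycle (factor 2.0); published
    efficiencies above 100% are common assay artifacts and are accepted with
    a warning once the factor exceeds 2.0.
    """
    if efficiency_percent <= 0:
        raise ValueError("efficiency_percent must be > 0")
    factor = 1.0 + efficiency_percent / 100.0
    if factor > 2.5:
        raise ValueError(f"amplification factor {factor:.3f} > 2.5 is not plausible")
    if factor > 2.0:
        warnings.warn(
            f"efficiency {efficiency_percent}% (> 100%) yields factor {factor:.3f}",
            stacklevel=2,
        )
    return factor


def load_efficiencies(table: pd.DataFrame) -> pd.Series:
    """Amplification factors per gene from a (gene, efficiency_percent) table."""
    if not {"gene", "efficiency_percent"}.issubset(table.columns):
        raise ValueError("efficiency table needs columns gene, efficiency_percent")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = table.set_index("gene")["efficiency_percent"].map(amplification_factor)
    out.name = "amplification_factor"
    return out


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"Ct table is missing columns: {sorted(missing)}")
    if (records["Ct"] <= 0).any():
        raise ValueError("Ct values must be > 0")
    return records


def delta_ct(
    records: pd.DataFrame, reference_gene: str = DEFAULT_REFERENCE_GENE
) -> pd.DataFrame:
    """Per-sample per-gene dCt = Ct(gene) - Ct(reference).

    Technical replicates are averaged per (sample, gene) first.  Returns a
    tidy frame with columns sample_id, group, gene, Ct_mean, dCt.
    """
    records = _validate_records(records)
    ct = (
        records.groupby(["sample_id", "group", "gene"], as_index=False)["Ct"]
        .mean()
        .rename(columns={"Ct": "Ct_mean"})
    )
    ref = ct[ct["gene"] == reference_gene].set_index("sample_id")["Ct_mean"]
    missing = sorted(set(ct["sample_id"]) - set(ref.index))
    if missing:
        raise ValueError(
            f"samples lack reference gene {reference_gene!r}: {missing}"
        )
    ct["dCt"] = ct["Ct_mean"] - ct["sample_id"].map(ref)
    return ct


def delta_delta_ct(
    dcts: pd.DataFrame, control_group: str = DEFAULT_CONTROL_GROUP
) -> pd.DataFrame:
    """Group-level ddCt = mean dCt(group, gene) - mean dCt(control, gene).

    The control group's own ddCt is zero by construction.  Returns columns
    group, gene, dCt_mean, ddCt.
    """
    if control_group not in set(dcts["group"]):
        raise ValueError(f"control group {control_group!r} absent from data")
    g = dcts.groupby(["group", "gene"], as_index=False)["dCt"].mean()
    g = g.rename(columns={"dCt": "dCt_mean"})
    ctrl = g[g["group"] == control_group].set_index("gene")["dCt_mean"]
    missing = sorted(set(g["gene"]) - set(ctrl.index))
    if missing:
        raise ValueError(f"control group lacks genes: {missing}")
    g["ddCt"] = g["dCt_mean"] - g["gene"].map(ctrl)
    return g


def relative_expression(
    ddct: float,
    target_factor: float,
    reference_factor: float | None = None,
    d_ct_ref_shift: float = 0.0,
    method: str = "pfaffl",
) -> tuple[float, float]:
    """Fold change and log2(fold) for one (group, gene) ddCt.

    For ``method="pfaffl"`` the reference-gene shift between the group and
    the control group (``d_ct_ref_shift``, on raw Ct) enters through the
    reference efficiency; ``ddct`` must then be the raw target-gene Ct shift
    minus that reference shift, so that target shift = ddct + d_ct_ref_shift.
    With equal efficiencies or zero reference shift this collapses to
    E_target^(-ddct).  ``method="simple"`` uses E_target^(-ddct) directly.
    """
    if method not in ("pfaffl", "simple"):
        raise ValueError("method must be 'pfaffl' or 'simple'")
    if method == "simple" or reference_factor is None:
        fold = target_factor ** (-ddct)
    else:
        target_shift = ddct + d_ct_ref_shift
        fold = target_factor ** (-target_shift) / reference_factor ** (-d_ct_ref_shift)
    return fold, math.log2(fold)


def analyze(
    records: pd.DataFrame,
    efficiencies: pd.Series | pd.DataFrame,
    reference_gene: str = DEFAULT_REFERENCE_GENE,
    control_group: str = DEFAULT_CONTROL_GROUP,
    method: str = "pfaffl",
) -> pd.DataFrame:
    """Full comparative-Ct pipeline on a tidy Ct table.

    Returns one row per (group, gene) excluding the reference gene and the
    control group's self-comparison, with columns group, gene, dCt_mean,
    ddCt, fold_change, log2_fold.
    """
    if isinstance(efficiencies, pd.DataFrame):
        efficiencies = load_efficiencies(efficiencies)
    genes = set(records["gene"])
    missing_eff = sorted(g for g in genes if g not in efficiencies.index)
    if missing_eff:
        raise ValueError(f"no efficiency for genes: {missing_eff}")

    dct = delta_ct(records, reference_gene)
    ddct = delta_delta_ct(dct, control_group)

    # raw reference-gene Ct shift of each group vs control (for Pfaffl)
    ct_ref = (
        records[records["gene"] == reference_gene]
        .groupby("group")["Ct"]
        .mean()
    )
    ref_shift = ct_ref - ct_ref.loc[control_group]

    e_ref = float(efficiencies.loc[reference_gene])
    rows = []
    for _, row in ddct.iterrows():
        if row["gene"] == reference_gene or row["group"] == control_group:
            continue
        fold, log2_fold = relative_expression(
            row["ddCt"],
            float(efficiencies.loc[row["gene"]]),
            e_ref,
            d_ct_ref_shift=float(ref_shift.loc[row["group"]]),
            method=method,
        )
        rows.append(
            {
                "group": row["group"],
                "gene": row["gene"],
                "dCt_mean": row["dCt_mean"],
                "ddCt": row["ddCt"],
                "fold_change": fold,
                "log2_fold": log2_fold,
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty and (out["fold_change"] <= 0).any():
        raise AssertionError("fold change must be positive")
    return out
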