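"""ΔΔCt relative quantification of qPCR data.

A Ct table holds one row per (sample, group, gene, Ct).  For a target gene,
each sample's dCt is Ct(target) - Ct(reference gene), technical replicates
averaged on the Ct scale first; ΔΔCt subtracts the mean dCt of the reference
group, and RQ = 2^(-ΔΔCt) assuming perfect amplification efficiency.  The
geometric mean of reference-group RQs is 1 by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["ddct_rq", "dose_response_summary", "read_ct_csv"]

REQUIRED_COLUMNS = ("sample", "group", "gene", "ct")


def _validate_ct(ct: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    return ct


def ddct_rq(
    ct: pd.DataFrame,
    target_gene: str,
    ref_gene: str = "Gapdh",
    ref_group: str | None = None,
) -> pd.DataFrame:
    """Per-sample relative quantity of ``target_gene`` by the ΔΔCt method.

    Replicate Ct rows are averaged per (sample, gene) before any subtraction;
    ΔΔCt is normalized to the mean dCt of ``ref_group``.  Returns a frame
    with columns ``sample, group, dct, ddct, rq``.
    """
    ct = _validate_ct(ct)
    mean_ct = (
        ct.groupby(["sample", "group", "gene"], sort=False)["ct"].mean().reset_index()
    )
    wide = mean_ct.pivot_table(index=["sample", "group"], columns="gene", values="ct")
    for gene in (target_gene, ref_gene):
        if gene not in wide.columns:
            raise ValueError(f"gene {gene!r} absent from the Ct table")
    missing_ref = wide.index[wide[ref_gene].isna()].tolist()
    if missing_ref:
        raise ValueError(f"samples missing reference-gene Ct: {missing_ref}")
    out = wide.reset_index()[["sample", "group"]].copy()
    out["dct"] = (wide[target_gene] - wide[ref_gene]).to_numpy()
    if ref_group is None:
        ref_group = out["group"].iloc[0]
    in_ref = out["group"] == ref_group
    if not in_ref.any():
        raise ValueError(f"reference group {ref_group!r} has no samples for {target_gene!r}")
    out["ddct"] = out["dct"] - out.loc[in_ref, "dct"].mean()
    out["rq"] = 2.0 ** (-out["ddct"])
    return out


def dose_response_summary(
    rq_by_dose: pd.DataFrame,
    dose_col: str = "dose",
    rq_col: str = "rq",
    direction: str = "max",
) -> tuple[pd.DataFrame, list]:
    """Mean RQ per dose group and the extremal dose(s).

    ``direction="max"`` reports the dose(s) with maximal mean RQ (peaking
    markers); ``"min"`` the minimal (inhibited markers).  Ties report every
    extremal dose.  Requires >= 2 dose groups.
    """
    if direction not in ("max", "min"):
        raise ValueError("direction must be 'max' or 'min'")
    means = rq_by_dose.groupby(dose_col, sort=True)[rq_col].mean().rename("mean_rq")
    if len(means) < 2:
        raise ValueError("dose-response summary needs >= 2 dose groups")
    extreme = means.max() if direction == "max" else means.min()
    arg = sorted(means.index[np.isclose(means, extreme)].tolist())
    return means.reset_index(), arg


def read_ct_csv(path) -> pd.DataFrame:
    """Read a Ct table CSV with columns sample, group, gene, ct."""
    return _validate_ct(pd.read_csv(path))
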