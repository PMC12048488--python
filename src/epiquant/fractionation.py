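"""Nuclear/cytosolic ratio analysis with marker-based fraction QC.

Per-protein log2 nucleus/cytoplasm (N/C) ratios are computed cell-wise on
matched fraction matrices (defined only where both fractions are
observed; antisymmetric under fraction swap) and aggregated per protein
over all condition/replicate samples.  Fraction quality is verified by
requiring at least ``fold_min`` (default four-fold) enrichment of nuclear
markers in the nuclear fraction and of cytosolic markers in the cytosolic
fraction.  Ratios use unnormalized within-fraction intensities by
default; optional median-centering per fraction is available for loading
correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "nc_log2_ratio",
    "aggregate_nc",
    "qc_fraction_markers",
    "aggregate_group",
    "median_center",
    "FractionQC",
]


def median_center(matrix: pd.DataFrame) -> pd.DataFrame:
    """Divide each column by its median (per-fraction loading correction)."""
    return matrix.div(matrix.median(axis=0, skipna=True), axis=1)


def nc_log2_ratio(
    nuclear: pd.DataFrame,
    cytosolic: pd.DataFrame,
    center: bool = False,
) -> pd.DataFrame:
    """Cell-wise log2(nuclear / cytosolic) on matched matrices.

    Columns are aligned by name (condition/replicate samples); a cell with
    either fraction missing or non-positive is NA.
    """
    common = [c for c in nuclear.columns if c in cytosolic.columns]
    if not common:
        raise ValueError("no shared samples between the two fraction matrices")
    proteins = nuclear.index.intersection(cytosolic.index)
    nuc = nuclear.loc[proteins, common]
    cyt = cytosolic.loc[proteins, common]
    if center:
        nuc, cyt = median_center(nuc), median_center(cyt)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2(nuc.where(nuc > 0)) - np.log2(cyt.where(cyt > 0))
    ratio.index.name = "Protein"
    return ratio


def aggregate_nc(ratios: pd.DataFrame) -> pd.DataFrame:
    """Per-protein aggregate over all condition/replicate values."""
    out = pd.DataFrame(
        {
            "mean_log2_nc": ratios.mean(axis=1, skipna=True),
            "median_log2_nc": ratios.median(axis=1, skipna=True),
            "n_values": ratios.notna().sum(axis=1),
        }
    )
    out.index.name = "Protein"
    return out


@dataclass
class FractionQC:
    verdict: str  # "pass" | "fail" | "indeterminate"
    nuclear_marker_fold: float
    cytosolic_marker_fold: float
    per_marker: pd.DataFrame


def qc_fraction_markers(
    ratios: pd.DataFrame,
    nuclear_markers: list[str],
    cytosolic_markers: list[str],
    fold_min: float = 4.0,
) -> FractionQC:
    """Marker-based fractionation QC.

    Passes when the mean linear N/C of nuclear markers and the mean linear
    C/N of cytosolic markers both reach ``fold_min`` (strict thresholds,
    i.e. 3.9-fold fails a 4-fold requirement).  With no quantified marker
    in either compartment the verdict is indeterminate.
    """
    agg = aggregate_nc(ratios)
    nuc = [m for m in nuclear_markers if m in agg.index and agg.loc[m, "n_values"] > 0]
    cyt = [
        m for m in cytosolic_markers if m in agg.index and agg.loc[m, "n_values"] > 0
    ]
    per_marker = pd.concat(
        [
            agg.loc[nuc].assign(compartment="nuclear"),
            agg.loc[cyt].assign(compartment="cytosolic"),
        ]
    ) if (nuc or cyt) else pd.DataFrame()
    if not nuc or not cyt:
        warnings.warn("markers missing for at least one compartment", stacklevel=2)
        return FractionQC("indeterminate", np.nan, np.nan, per_marker)
    # mean linear fold over markers (mean of per-marker linear mean ratios)
    nuc_fold = float(np.mean(2.0 ** agg.loc[nuc, "mean_log2_nc"]))
    cyt_fold = float(np.mean(2.0 ** (-agg.loc[cyt, "mean_log2_nc"])))
    verdict = "pass" if (nuc_fold >= fold_min and cyt_fold >= fold_min) else "fail"
    return FractionQC(verdict, nuc_fold, cyt_fold, per_marker)


def aggregate_group(
    ratios: pd.DataFrame, protein_groups: dict[str, list[str]]
) -> pd.DataFrame:
    """Pooled log2 N/C distribution summaries per protein group.

    For each named group the log2 N/C values of all member proteins are
    pooled across samples; empty groups (no member quantified) are
    omitted with a warning.  Summaries are invariant to the order in
    which member proteins are listed.
    """
    rows = []
    for name in sorted(protein_groups):
        members = [m for m in protein_groups[name] if m in ratios.index]
        values = ratios.loc[members].to_numpy(dtype=float).ravel()
        values = values[np.isfinite(values)]
        if len(members) == 0 or values.size == 0:
            warnings.warn(f"group {name!r} has no quantified members; omitted",
                          stacklevel=2)
            continue
        rows.append(
            {
                "group": name,
                "n_proteins": len(members),
                "n_values": int(values.size),
                "mean_log2_nc": float(np.mean(values)),
                "median_log2_nc": float(np.median(values)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["group", "n_proteins", "n_values", "mean_log2_nc",
                 "median_log2_nc"],
    )
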