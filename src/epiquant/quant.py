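"""Bait-normalized quantitative contrasts across the interactome design.

Prey abundances from an IP depend on how much bait each IP captured, so
all contrasts operate on prey/bait intensity ratios within each run.
Group summaries are means of normalized abundances on the linear scale
with ratios reported as log2 of the ratio of means (matching the
"ratio of abundances" semantics of the figures); significance uses
unpaired two-sample t-tests on log2-transformed values.  Missing values
are never imputed: operations propagate NA and record the number of
observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "normalize_to_bait",
    "scale_to_proteome",
    "contrast_ratio",
    "epitope_preference_summary",
    "age_polyq_gain",
    "tissue_enrichment",
    "assemble_priority_set",
    "set_overlap",
    "run_priority_pipeline",
    "PrioritySet",
    "PRESETS",
]

#: named filter presets: (polyQ/age gain fold, tissue-enrichment fold)
PRESETS = {
    "main-text": {"gain_fold": 5.0, "tissue_fold": 4.0},
    "fig6-legend": {"gain_fold": 2.5, "tissue_fold": 2.0},
}

P_DEGENERATE = float(np.nextafter(0, 1))


def normalize_to_bait(
    intensities: pd.DataFrame, design: pd.DataFrame, bait: str = "HTT"
) -> pd.DataFrame:
    """Divide each prey intensity by the bait intensity of the same run.

    Only bait (non-IgG) runs are kept; a run in which the bait itself was
    not quantified is dropped with a warning.  The bait row is removed
    from the result (its normalized value is identically 1).
    """
    if bait not in intensities.index:
        raise ValueError(f"bait protein {bait!r} not found in the matrix")
    runs = design.loc[design["bait"] != "IgG", "run_id"].tolist()
    runs = [r for r in runs if r in intensities.columns]
    bait_levels = intensities.loc[bait, runs]
    missing = bait_levels.index[bait_levels.isna()].tolist()
    if missing:
        warnings.warn(
            f"bait {bait!r} not quantified in run(s) {missing}; dropped",
            stacklevel=2,
        )
        runs = [r for r in runs if r not in set(missing)]
    norm = intensities.loc[:, runs].div(intensities.loc[bait, runs], axis=1)
    return norm.drop(index=bait)


def scale_to_proteome(
    ip_abundance: pd.Series, proteome_abundance: pd.Series
) -> pd.Series:
    """IP-level over proteome-level abundance per matched condition.

    Exposes capture-efficiency differences net of expression changes.
    Unmatched conditions and zero/missing proteome values give NA, never
    infinity.
    """
    proteome = proteome_abundance.reindex(ip_abundance.index)
    denom = proteome.where(proteome > 0)
    return (ip_abundance / denom).rename("ip_over_proteome")


def _design_runs(design: pd.DataFrame, stratum: dict | None) -> pd.DataFrame:
    sub = design[design["bait"] != "IgG"]
    if stratum:
        for column, value in stratum.items():
            sub = sub[sub[column] == value]
    return sub


def _row_ttest(
    la: np.ndarray, lb: np.ndarray, welch: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise unpaired t-test on (preys x replicates) log2 matrices.

    Returns (p_value, degenerate flag).  When both groups have zero
    variance the p-value is 1 for equal means and a zero-adjacent sentinel
    otherwise, with the degenerate flag set.
    """
    n1 = np.sum(~np.isnan(la), axis=1)
    n2 = np.sum(~np.isnan(lb), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1, m2 = np.nanmean(la, axis=1), np.nanmean(lb, axis=1)
        v1 = np.nanvar(la, axis=1, ddof=1)
        v2 = np.nanvar(lb, axis=1, ddof=1)
    ok = (n1 >= 2) & (n2 >= 2)
    p = np.full(la.shape[0], np.nan)
    degenerate = np.zeros(la.shape[0], dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        if welch:
            se2 = v1 / n1 + v2 / n2
            df = se2**2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
        else:
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            se2 = sp2 * (1.0 / n1 + 1.0 / n2)
            df = n1 + n2 - 2.0
        t = (m1 - m2) / np.sqrt(se2)
    finite = ok & np.isfinite(t)
    p[finite] = 2.0 * stats.t.sf(np.abs(t[finite]), df[finite])
    zero_var = ok & ~np.isfinite(t) & (se2 == 0)
    degenerate |= zero_var
    p[zero_var & (m1 == m2)] = 1.0
    p[zero_var & (m1 != m2)] = P_DEGENERATE
    return p, degenerate


def contrast_ratio(
    norm: pd.DataFrame,
    design: pd.DataFrame,
    column: str,
    group_a: str,
    group_b: str,
    stratum: dict | None = None,
    min_obs: int = 2,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-prey log2 ratio of group means on one contrast axis.

    ``column`` is a design column (``epitope_class``, ``age``,
    ``genotype``, ``tissue``); ``stratum`` holds other design columns
    fixed.  The ratio is ``log2(mean_A) - log2(mean_B)`` on linear
    normalized abundances; the p-value is an unpaired t-test on log2
    values (Student by default, Welch optional).  Rows with fewer than
    ``min_obs`` observations in either group are NA.
    """
    sub = _design_runs(design, stratum)
    runs_a = [r for r in sub.loc[sub[column] == group_a, "run_id"]
              if r in norm.columns]
    runs_b = [r for r in sub.loc[sub[column] == group_b, "run_id"]
              if r in norm.columns]
    if not runs_a or not runs_b:
        raise ValueError(
            f"contrast {column}: {group_a!r} vs {group_b!r} has an empty "
            f"group within stratum {stratum!r}"
        )
    a = norm[runs_a].to_numpy(dtype=float)
    b = norm[runs_b].to_numpy(dtype=float)
    n_a = np.sum(~np.isnan(a), axis=1)
    n_b = np.sum(~np.isnan(b), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_a, mean_b = np.nanmean(a, axis=1), np.nanmean(b, axis=1)
    valid = (n_a >= min_obs) & (n_b >= min_obs)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2_ratio = np.where(valid, np.log2(mean_a) - np.log2(mean_b), np.nan)
        la = np.where(a > 0, np.log2(a), np.nan)
        lb = np.where(b > 0, np.log2(b), np.nan)
    p, degenerate = _row_ttest(la, lb, welch=welch)
    p[~valid] = np.nan
    return pd.DataFrame(
        {
            "prey": norm.index,
            "log2_ratio": log2_ratio,
            "mean_a": np.where(n_a > 0, mean_a, np.nan),
            "mean_b": np.where(n_b > 0, mean_b, np.nan),
            "n_a": n_a,
            "n_b": n_b,
            "p_value": p,
            "degenerate_variance": degenerate,
        }
    )


def epitope_preference_summary(
    records: pd.DataFrame, threshold: float = 2.5
) -> pd.DataFrame:
    """Per-prey, per-tissue epitope preference from stratum-level ratios.

    ``records`` is a long table with columns ``prey``, ``tissue``,
    ``stratum`` and ``log2_ratio`` (N-terminal over Central).  For each
    prey and tissue the stratum ratio of maximal absolute value is kept
    and classified: ``N-term`` above ``+threshold``, ``Central`` below
    ``-threshold``, otherwise ``shared`` (strict inequalities).  Preys
    with no defined stratum ratio are ``unclassified``.
    """
    def summarize(group: pd.DataFrame) -> pd.Series:
        ratios = group["log2_ratio"].dropna()
        if ratios.empty:
            return pd.Series({"log2_ratio": np.nan, "preference": "unclassified"})
        best = ratios.loc[ratios.abs().idxmax()]
        if best > threshold:
            label = "N-term"
        elif best < -threshold:
            label = "Central"
        else:
            label = "shared"
        return pd.Series({"log2_ratio": best, "preference": label})

    out = (
        records.groupby(["prey", "tissue"], sort=True)[["log2_ratio"]]
        .apply(summarize)
        .reset_index()
    )
    return out


def _tissue_group_means(
    norm: pd.DataFrame, design: pd.DataFrame, extra: dict | None = None
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-tissue (mean, n) arrays over all matching bait runs."""
    out = {}
    sub = _design_runs(design, extra)
    for tissue, rows in sub.groupby("tissue", sort=True):
        runs = [r for r in rows["run_id"] if r in norm.columns]
        if not runs:
            continue
        values = norm[runs].to_numpy(dtype=float)
        n = np.sum(~np.isnan(values), axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(values, axis=1)
        out[tissue] = (mean, n)
    return out


def age_polyq_gain(
    norm: pd.DataFrame,
    design: pd.DataFrame,
    fold_min: float = 5.0,
    target_tissue: str = "striatum",
    genotype_test: str = "Q140",
    genotype_ref: str = "Q20",
    age_new: str = "40wk",
    age_ref: str = "8wk",
    min_obs: int = 2,
) -> pd.DataFrame:
    """PolyQ-dependent age gain per prey and tissue.

    For each tissue the age ratio (new over reference age) of mean
    normalized abundance is computed per genotype, and the gain is the
    ratio of those ratios (expanded over control genotype).  A prey passes
    when its gain exceeds ``fold_min`` in the target tissue and does not
    exceed ``fold_min`` in any other tissue where the gain is defined
    (rows missing another tissue's gain are flagged partial).
    """
    tissues = sorted(design.loc[design["bait"] != "IgG", "tissue"].unique())
    gains = {}
    for tissue in tissues:
        ratios = {}
        for genotype in (genotype_test, genotype_ref):
            means = {}
            for age in (age_new, age_ref):
                groups = _tissue_group_means(
                    norm, design, {"genotype": genotype, "age": age}
                )
                if tissue not in groups:
                    means = None
                    break
                mean, n = groups[tissue]
                means[age] = np.where(n >= min_obs, mean, np.nan)
            if means is None:
                ratios = None
                break
            with np.errstate(divide="ignore", invalid="ignore"):
                ratios[genotype] = means[age_new] / means[age_ref]
        if ratios is None:
            gains[tissue] = np.full(len(norm.index), np.nan)
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                gains[tissue] = ratios[genotype_test] / ratios[genotype_ref]
    frame = pd.DataFrame(gains, index=norm.index)
    others = [t for t in tissues if t != target_tissue]
    target = frame[target_tissue]
    other_vals = frame[others]
    exceeds_other = (other_vals > fold_min).any(axis=1)
    partial = other_vals.isna().any(axis=1)
    passes = (target > fold_min) & ~exceeds_other
    out = frame.add_prefix("gain_")
    out["passes"] = passes.fillna(False)
    out["partial"] = partial
    out.index.name = "prey"
    return out


def tissue_enrichment(
    norm: pd.DataFrame,
    design: pd.DataFrame,
    fold_min: float = 4.0,
    min_obs: int = 2,
) -> pd.DataFrame:
    """Per-prey, per-target-tissue enrichment over every other tissue.

    The statistic is the minimum over other tissues of
    ``log2(mean_target / mean_other)``; a prey is enriched in the target
    tissue iff that minimum exceeds ``log2(fold_min)``.  Comparisons with
    a tissue in which the prey is unquantified use the available tissues
    only and are flagged partial; a prey absent from the target tissue is
    NA.
    """
    groups = _tissue_group_means(norm, design)
    tissues = sorted(groups)
    means = {
        t: np.where(n >= min_obs, mean, np.nan) for t, (mean, n) in groups.items()
    }
    rows = []
    threshold = np.log2(fold_min)
    for target in tissues:
        others = [t for t in tissues if t != target]
        with np.errstate(divide="ignore", invalid="ignore"):
            log2s = np.column_stack(
                [np.log2(means[target]) - np.log2(means[o]) for o in others]
            )
        defined = ~np.isnan(log2s)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            min_log2 = np.nanmin(log2s, axis=1)
        any_defined = defined.any(axis=1)
        min_log2 = np.where(any_defined, min_log2, np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "prey": norm.index,
                    "tissue": target,
                    "min_log2_enrichment": min_log2,
                    "enriched": any_defined & (min_log2 > threshold),
                    "partial": any_defined & ~defined.all(axis=1),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


@dataclass
class PrioritySet:
    """Union of tissue-enriched and polyQ/age-gain prey sets."""

    striatum_enriched: set = field(default_factory=set)
    polyq_gain: set = field(default_factory=set)

    @property
    def union(self) -> set:
        return self.striatum_enriched | self.polyq_gain

    def provenance(self) -> pd.DataFrame:
        rows = []
        for prey in sorted(self.union):
            enriched = prey in self.striatum_enriched
            gain = prey in self.polyq_gain
            flag = "both" if enriched and gain else (
                "enriched-only" if enriched else "gain-only"
            )
            rows.append({"prey": prey, "provenance": flag})
        return pd.DataFrame(rows, columns=["prey", "provenance"])


def assemble_priority_set(
    striatum_enriched: set, polyq_gain: set
) -> PrioritySet:
    return PrioritySet(set(striatum_enriched), set(polyq_gain))


def set_overlap(query: set, reference: set) -> tuple[set, set, set]:
    """(shared, unique-to-query, unique-to-reference): a partition of the union."""
    query, reference = set(query), set(reference)
    return query & reference, query - reference, reference - query


def run_priority_pipeline(
    counts: pd.DataFrame,
    intensities: pd.DataFrame,
    design: pd.DataFrame,
    bait: str = "HTT",
    preset: str = "main-text",
    target_tissue: str = "striatum",
    **score_kwargs,
) -> dict:
    """Specificity filtering followed by priority-set assembly.

    Returns a dict with the specificity score table, the bait-normalized
    abundances of passing preys, the tissue-enrichment and gain tables and
    the assembled :class:`PrioritySet`.
    """
    from .specificity import passing_union, score_experiment

    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    folds = PRESETS[preset]
    scores = score_experiment(counts, design, exclude_bait=bait, **score_kwargs)
    passing = sorted(passing_union(scores))
    norm = normalize_to_bait(intensities, design, bait=bait)
    norm = norm.loc[[p for p in passing if p in norm.index]]
    enrich = tissue_enrichment(norm, design, fold_min=folds["tissue_fold"])
    enriched_set = set(
        enrich.loc[
            (enrich["tissue"] == target_tissue) & enrich["enriched"], "prey"
        ]
    )
    gain = age_polyq_gain(
        norm, design, fold_min=folds["gain_fold"], target_tissue=target_tissue
    )
    gain_set = set(gain.index[gain["passes"]])
    priority = assemble_priority_set(enriched_set, gain_set)
    return {
        "scores": scores,
        "normalized": norm,
        "tissue_enrichment": enrich,
        "polyq_gain": gain,
        "priority": priority,
    }
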