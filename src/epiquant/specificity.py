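"""Interaction-specificity scoring of spectral counts against IgG controls.

The stage reproduces the standard AP-MS specificity workflow: contaminant
removal, selection of the two highest-count replicates per prey within each
bait sample group, construction of per-prey virtual negative controls from
the pooled IgG runs, probabilistic bait-versus-control scoring, and BFDR
filtering (``BFDR <= 1%`` and average bait SPC ``>= 5``).

The score itself is a transparent two-component Poisson model in the SAINT
family: for each retained bait replicate count ``x`` the probability of
true interaction is the likelihood ratio

    P = Pois(x; lam1) / (Pois(x; lam0) + Pois(x; lam1))

with ``lam0 = mean(virtual controls) + eps`` and ``lam1 = max(mean of
retained bait counts, f_min * lam0)`` (equal priors).  ``avg_probability``
averages P over the retained replicates, and the BFDR at rank ``r`` of the
descending ``avg_probability`` ordering is the cumulative mean of
``1 - avg_probability`` (ties share the worst BFDR of their block).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import CONTAMINANT_PREFIXES, strip_contaminants

__all__ = [
    "sample_groups",
    "preprocess_counts",
    "build_virtual_controls",
    "score_interactions",
    "compute_bfdr",
    "filter_interactions",
    "score_experiment",
    "passing_union",
]

GROUP_KEYS = ["tissue", "genotype", "age", "epitope_class"]


def sample_groups(design: pd.DataFrame) -> dict[str, list[str]]:
    """Bait sample groups (tissue x genotype x age x epitope pool) -> runs.

    Run lists are sorted lexicographically so that downstream tie-breaking
    is deterministic.  IgG control runs are excluded.
    """
    bait = design[design["bait"] != "IgG"]
    groups: dict[str, list[str]] = {}
    for keys, sub in bait.groupby(GROUP_KEYS, sort=True):
        label = "|".join(str(k) for k in keys)
        groups[label] = sorted(sub["run_id"])
    return groups


def control_runs(design: pd.DataFrame) -> list[str]:
    return sorted(design.loc[design["bait"] == "IgG", "run_id"])


def preprocess_counts(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    k: int = 2,
    contaminant_prefixes: tuple[str, ...] = CONTAMINANT_PREFIXES,
) -> pd.DataFrame:
    """Contaminant removal plus top-``k`` replicate selection per group.

    Within each bait sample group only the ``k`` highest replicate counts
    of each prey are retained (the rest become NaN); ties are broken in
    favor of lexicographically-first run ids.  Control (IgG) runs pass
    through unreduced.  A bait group with fewer than ``k`` replicates is an
    error naming the group.
    """
    counts = strip_contaminants(counts, prefixes=contaminant_prefixes)
    out = counts.astype(float).copy()
    for label, runs in sample_groups(design).items():
        if len(runs) < k:
            raise ValueError(
                f"sample group {label!r} has {len(runs)} replicates; "
                f"at least {k} are required"
            )
        values = counts[runs].to_numpy(dtype=float)
        # stable argsort on negated values: ties keep earlier (lexicographic)
        order = np.argsort(-values, axis=1, kind="stable")
        keep = np.zeros_like(values, dtype=bool)
        rows = np.arange(values.shape[0])[:, None]
        keep[rows, order[:, :k]] = True
        out[runs] = np.where(keep, values, np.nan)
    return out


def build_virtual_controls(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    m: int = 10,
    mode: str = "rank-central",
) -> pd.DataFrame:
    """Per-prey virtual negative control from the pooled IgG runs.

    The pooled control counts of each prey are sorted in descending order
    and ``m`` values are selected:

    - ``rank-central`` (default): the ``m`` rank-central values, i.e. the
      block centered on the median rank (for a pool of 37 and ``m=10``,
      descending ranks 14-23);
    - ``below-max``: the ``m`` values immediately below the maximum
      (descending ranks 2 to ``m+1``).

    With fewer than ``m`` pooled controls the whole pool is used and a
    warning is emitted.
    """
    controls = control_runs(design)
    values = counts[controls].to_numpy(dtype=float)
    n = values.shape[1]
    values = -np.sort(-values, axis=1)  # descending
    if n < m:
        warnings.warn(
            f"only {n} pooled control runs (< m={m}); using the full pool",
            stacklevel=2,
        )
        selected = values
    else:
        if mode == "rank-central":
            start = (n - m) // 2
        elif mode == "below-max":
            start = min(1, n - m)
        else:
            raise ValueError(f"unknown virtual-control mode {mode!r}")
        selected = values[:, start : start + m]
    return pd.DataFrame(
        selected,
        index=counts.index,
        columns=[f"vc{i + 1}" for i in range(selected.shape[1])],
    )


def _poisson_logpmf(x: np.ndarray, lam: np.ndarray) -> np.ndarray:
    return x * np.log(lam) - lam - gammaln(x + 1.0)


def score_interactions(
    preprocessed: pd.DataFrame,
    design: pd.DataFrame,
    virtual_controls: pd.DataFrame,
    eps: float = 0.1,
    f_min: float = 2.0,
) -> pd.DataFrame:
    """Two-component Poisson probability of true interaction per prey/group.

    Returns a tidy table with one row per (prey, sample_group):
    ``avg_probability`` (NaN for an empty bait group), ``avg_bait_spc``
    (mean of the retained replicate counts) and ``n_rep``.
    """
    lam0 = virtual_controls.mean(axis=1).to_numpy(dtype=float) + eps
    frames = []
    for label, runs in sample_groups(design).items():
        x = preprocessed[runs].to_numpy(dtype=float)
        retained = ~np.isnan(x)
        n_rep = retained.sum(axis=1)
        with np.errstate(invalid="ignore"):
            bait_mean = np.where(n_rep > 0, np.nanmean(x, axis=1), np.nan)
        lam1 = np.maximum(bait_mean, f_min * lam0)
        xf = np.where(retained, x, 0.0)
        log_l1 = _poisson_logpmf(xf, lam1[:, None])
        log_l0 = _poisson_logpmf(xf, lam0[:, None])
        with np.errstate(over="ignore"):
            prob = 1.0 / (1.0 + np.exp(log_l0 - log_l1))
        prob = np.where(retained, prob, np.nan)
        with np.errstate(invalid="ignore"):
            avg_p = np.where(n_rep > 0, np.nanmean(prob, axis=1), np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "prey": preprocessed.index,
                    "sample_group": label,
                    "avg_probability": avg_p,
                    "avg_bait_spc": bait_mean,
                    "n_rep": n_rep,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def compute_bfdr(avg_probability: pd.Series) -> pd.Series:
    """BFDR per prey: cumulative mean of ``1 - avg_probability``.

    Preys are ranked by ``avg_probability`` descending; tied probabilities
    share the worst (largest) BFDR of their tied block.  The result is
    aligned to the input index; NaN probabilities yield NaN.
    """
    probs = avg_probability.to_numpy(dtype=float)
    result = np.full(probs.shape, np.nan)
    valid = ~np.isnan(probs)
    if valid.sum() == 0:
        return pd.Series(result, index=avg_probability.index, name="bfdr")
    pv = probs[valid]
    order = np.argsort(-pv, kind="stable")
    sorted_p = pv[order]
    cum = np.cumsum(1.0 - sorted_p) / np.arange(1, len(sorted_p) + 1)
    # within a tie block the cumulative mean is non-decreasing, so the
    # worst BFDR of the block is the one at its last position
    block = pd.Series(cum).groupby(sorted_p, sort=False).transform("max")
    unsorted = np.empty_like(cum)
    unsorted[order] = block.to_numpy()
    result[valid] = unsorted
    return pd.Series(result, index=avg_probability.index, name="bfdr")


def filter_interactions(
    scores: pd.DataFrame, bfdr_max: float = 0.01, spc_min: float = 5.0
) -> pd.DataFrame:
    """Apply the pass rule ``bfdr <= bfdr_max AND avg_bait_spc >= spc_min``."""
    out = scores.copy()
    out["passes"] = (out["bfdr"] <= bfdr_max) & (out["avg_bait_spc"] >= spc_min)
    out["passes"] = out["passes"].fillna(False)
    return out


def score_experiment(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    k: int = 2,
    m: int = 10,
    eps: float = 0.1,
    f_min: float = 2.0,
    bfdr_max: float = 0.01,
    spc_min: float = 5.0,
    vc_mode: str = "rank-central",
    contaminant_prefixes: tuple[str, ...] = CONTAMINANT_PREFIXES,
    exclude_bait: str | None = None,
) -> pd.DataFrame:
    """Full specificity stage: preprocess, score, BFDR and filter.

    BFDR is computed within each sample group (scoring is per condition).
    ``exclude_bait`` removes the bait protein itself from the ranked prey
    list (it is trivially enriched in its own IPs).
    """
    pre = preprocess_counts(
        counts, design, k=k, contaminant_prefixes=contaminant_prefixes
    )
    if exclude_bait is not None and exclude_bait in pre.index:
        pre = pre.drop(index=exclude_bait)
    vcontrols = build_virtual_controls(pre, design, m=m, mode=vc_mode)
    scores = score_interactions(pre, design, vcontrols, eps=eps, f_min=f_min)
    scores["bfdr"] = (
        scores.groupby("sample_group", sort=False)["avg_probability"]
        .transform(lambda s: compute_bfdr(s))
        .to_numpy()
    )
    return filter_interactions(scores, bfdr_max=bfdr_max, spc_min=spc_min)


def passing_union(scores: pd.DataFrame) -> set[str]:
    """High-confidence prey set: union of passing preys across conditions."""
    return set(scores.loc[scores["passes"], "prey"])
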