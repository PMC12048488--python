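"""Thermal proximity coaggregation: melt-curve fitting and curve distances.

Relative solubility over a temperature ladder is modeled with a
three-parameter descending logistic

    s(T) = (1 - p) / (1 + exp(k * (T - Tm))) + p

where ``Tm`` is the melting temperature (half-denaturation point), ``p``
the non-denaturing plateau and ``k > 0`` the transition steepness.  The
fit uses a deterministic coarse grid over (Tm, k) — with the plateau
solved in closed form, since the model is linear in p — followed by local
bounded least-squares refinement.  A derivative-free start matters on
five-point curves, which otherwise trap gradient fits in local minima.

Coaggregation of a protein pair is quantified by Euclidean distances
between their replicate solubility vectors over all ordered cross-replicate
pairs (i != j), giving r*(r-1) distances (six for three replicates), and a
condition shift in those distances is tested with an unpaired t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .simulate import melt_model

__all__ = [
    "normalize_solubility",
    "fit_melt_curve",
    "fit_melt_curves",
    "delta_tm",
    "cross_replicate_distances",
    "distance_shift_test",
    "MeltFit",
]

TM_GRID = np.arange(30.0, 70.0 + 1e-9, 0.5)
K_GRID = np.geomspace(0.05, 2.0, 25)


def normalize_solubility(
    abundances: np.ndarray, temperatures: np.ndarray
) -> np.ndarray:
    """Relative solubility: divide by the lowest-temperature abundance.

    The reference (lowest-temperature) point becomes exactly 1; interior
    missing values are retained as NaN.  A missing or zero reference makes
    the whole curve undefined (all-NaN) with a warning.
    """
    abundances = np.asarray(abundances, dtype=float)
    temperatures = np.asarray(temperatures, dtype=float)
    if abundances.shape != temperatures.shape:
        raise ValueError("abundances and temperatures must align")
    ref = abundances[np.argmin(temperatures)]
    if not np.isfinite(ref) or ref <= 0:
        warnings.warn(
            "reference-temperature abundance missing or zero; curve dropped",
            stacklevel=2,
        )
        return np.full_like(abundances, np.nan)
    return abundances / ref


@dataclass
class MeltFit:
    tm: float
    plateau: float
    slope: float
    rss: float
    ok: bool
    note: str = ""


def _grid_best(temps: np.ndarray, sol: np.ndarray) -> tuple[float, float, float]:
    """Best (tm, k, p) on the coarse grid, p solved in closed form."""
    tm = TM_GRID[:, None, None]
    k = K_GRID[None, :, None]
    sigma = 1.0 / (1.0 + np.exp(k * (temps[None, None, :] - tm)))
    one_minus = 1.0 - sigma
    # s = sigma + p * (1 - sigma)  =>  least-squares p per (tm, k)
    num = np.sum((sol[None, None, :] - sigma) * one_minus, axis=-1)
    den = np.sum(one_minus**2, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.clip(num / den, 0.0, 0.999)
    resid = sigma + p[:, :, None] * one_minus - sol[None, None, :]
    rss = np.sum(resid**2, axis=-1)
    i, j = np.unravel_index(np.argmin(rss), rss.shape)
    return float(TM_GRID[i]), float(K_GRID[j]), float(p[i, j])


def fit_melt_curve(
    temperatures: np.ndarray, solubility: np.ndarray
) -> MeltFit:
    """Least-squares logistic fit of one melt curve.

    Requires at least 3 non-missing points; data with no melting
    transition (no net decrease in solubility) yield an NA fit with a
    diagnostic note.  The fitted Tm is constrained to the observed
    temperature span extended by 10 degrees C on each side.
    """
    temps = np.asarray(temperatures, dtype=float)
    sol = np.asarray(solubility, dtype=float)
    mask = np.isfinite(sol) & np.isfinite(temps)
    temps, sol = temps[mask], sol[mask]
    if temps.size < 3:
        return MeltFit(np.nan, np.nan, np.nan, np.nan, False, "too few points")
    order = np.argsort(temps)
    temps, sol = temps[order], sol[order]
    if sol[-1] >= sol[0]:
        return MeltFit(np.nan, np.nan, np.nan, np.nan, False, "no melting")

    tm0, k0, p0 = _grid_best(temps, sol)
    lo_tm, hi_tm = temps.min() - 10.0, temps.max() + 10.0

    def residuals(theta):
        tm, log_k, p = theta
        return melt_model(temps, tm, p, np.exp(log_k)) - sol

    try:
        fit = optimize.least_squares(
            residuals,
            x0=[np.clip(tm0, lo_tm, hi_tm), np.log(k0), p0],
            bounds=([lo_tm, np.log(1e-3), 0.0], [hi_tm, np.log(50.0), 0.999]),
        )
        tm, log_k, p = fit.x
        rss = float(2.0 * fit.cost)
    except Exception as exc:  # pragma: no cover - defensive
        return MeltFit(np.nan, np.nan, np.nan, np.nan, False, f"fit failed: {exc}")
    return MeltFit(float(tm), float(p), float(np.exp(log_k)), rss, True)


def fit_melt_curves(curves: pd.DataFrame) -> pd.DataFrame:
    """Fit every (protein, condition, replicate) curve of a long table.

    ``curves`` columns: protein, condition, replicate, temperature,
    solubility.  Returns one row per curve with the fit parameters.
    """
    rows = []
    for (protein, condition, replicate), group in curves.groupby(
        ["protein", "condition", "replicate"], sort=True
    ):
        fit = fit_melt_curve(
            group["temperature"].to_numpy(), group["solubility"].to_numpy()
        )
        rows.append(
            {
                "protein": protein,
                "condition": condition,
                "replicate": replicate,
                "tm": fit.tm,
                "plateau": fit.plateau,
                "slope": fit.slope,
                "rss": fit.rss,
                "ok": fit.ok,
                "note": fit.note,
            }
        )
    return pd.DataFrame(rows)


def delta_tm(
    fits_a: pd.DataFrame, fits_b: pd.DataFrame
) -> pd.DataFrame:
    """Per-protein melting-temperature shift, condition B minus A.

    Replicate Tm values are averaged within each condition; proteins
    missing from either condition give NA.  The shift is antisymmetric
    under swapping the two conditions.
    """
    mean_a = fits_a.loc[fits_a["ok"]].groupby("protein")["tm"].mean()
    mean_b = fits_b.loc[fits_b["ok"]].groupby("protein")["tm"].mean()
    proteins = sorted(set(fits_a["protein"]) | set(fits_b["protein"]))
    out = pd.DataFrame(
        {
            "tm_a": mean_a.reindex(proteins),
            "tm_b": mean_b.reindex(proteins),
        },
        index=pd.Index(proteins, name="protein"),
    )
    out["delta_tm"] = out["tm_b"] - out["tm_a"]
    out["abs_delta_tm"] = out["delta_tm"].abs()
    return out.reset_index()


def _replicate_matrix(curves: pd.DataFrame, protein: str, condition: str):
    sub = curves[(curves["protein"] == protein) & (curves["condition"] == condition)]
    if sub.empty:
        raise ValueError(f"no curves for {protein!r} in condition {condition!r}")
    wide = sub.pivot_table(
        index="replicate", columns="temperature", values="solubility", sort=True
    )
    return wide


def cross_replicate_distances(
    curves: pd.DataFrame, protein1: str, protein2: str, condition: str
) -> pd.DataFrame:
    """Euclidean distances between two proteins' replicate curves.

    Distances are computed between protein1 replicate i and protein2
    replicate j for every ordered pair with i != j, giving r*(r-1)
    comparisons (six for three replicates).  The temperature grids of the
    two proteins must match exactly.
    """
    w1 = _replicate_matrix(curves, protein1, condition)
    w2 = _replicate_matrix(curves, protein2, condition)
    if list(w1.columns) != list(w2.columns):
        raise ValueError("temperature grids of the two proteins differ")
    rows = []
    for i in w1.index:
        for j in w2.index:
            if i == j:
                continue
            d = float(
                np.sqrt(np.nansum((w1.loc[i].to_numpy() - w2.loc[j].to_numpy()) ** 2))
            )
            rows.append(
                {
                    "protein1": protein1,
                    "protein2": protein2,
                    "condition": condition,
                    "replicate_i": i,
                    "replicate_j": j,
                    "distance": d,
                }
            )
    return pd.DataFrame(rows)


def distance_shift_test(
    distances_a: np.ndarray, distances_b: np.ndarray, welch: bool = False
) -> dict:
    """Unpaired t-test comparing curve-distance sets between conditions.

    A decrease in condition B means the two proteins' curves became more
    similar (potential enhanced co-aggregation).  Degenerate (zero
    variance in both sets) inputs give p = 1 for equal means and a
    zero-adjacent sentinel otherwise.
    """
    a = np.asarray(distances_a, dtype=float)
    b = np.asarray(distances_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("at least 2 distances per condition are required")
    mean_a, mean_b = float(np.mean(a)), float(np.mean(b))
    if np.var(a) == 0 and np.var(b) == 0:
        p = 1.0 if mean_a == mean_b else float(np.nextafter(0, 1))
        degenerate = True
    else:
        p = float(stats.ttest_ind(a, b, equal_var=not welch).pvalue)
        degenerate = False
    direction = "decrease" if mean_b < mean_a else (
        "increase" if mean_b > mean_a else "none"
    )
    return {
        "p_value": p,
        "mean_a": mean_a,
        "mean_b": mean_b,
        "direction": direction,
        "degenerate_variance": degenerate,
    }
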