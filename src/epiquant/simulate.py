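"""Synthetic IP-MS, thermal-profiling and fractionation data with known truth.

Spectral counts are drawn from a negative binomial (Poisson-gamma)
distribution: counts in affinity-purification MS are overdispersed relative
to Poisson, and the gamma mixing with shape ``1/dispersion`` gives
``Var = mu + dispersion * mu**2``.  Label-free intensities are log-normal
around a bait-capture-scaled mean with logistic, intensity-dependent
dropout (left-censoring, missing-not-at-random), which is the dominant
missingness mechanism of real LFQ matrices.

True interactors are enriched over the IgG background by
``enrichment_fold`` in bait runs; disjoint subsets additionally carry
planted epitope-preference, tissue-enrichment and polyQ/age-gain folds so
that every downstream stage can be scored against ground truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SimulationConfig

__all__ = [
    "simulate_ipms",
    "simulate_melt",
    "simulate_fractions",
    "melt_model",
    "write_fixture_bundle",
]


def _slug(label: str) -> str:
    return label.replace("-", "").replace(" ", "")


def build_design(config: SimulationConfig) -> pd.DataFrame:
    """Run-design table: one row per IP run (bait pools and pooled IgG)."""
    rows = []
    for tissue in config.tissues:
        for genotype in config.genotypes:
            for age in config.ages:
                for pool in config.epitope_pools:
                    for rep in range(1, config.replicates + 1):
                        run_id = f"{tissue}_{genotype}_{age}_{_slug(pool)}_r{rep}"
                        rows.append(
                            {
                                "run_id": run_id,
                                "bait": config.bait_protein,
                                "epitope_class": pool,
                                "tissue": tissue,
                                "genotype": genotype,
                                "age": age,
                                "replicate": rep,
                                "role": "IP",
                            }
                        )
    # IgG controls are pooled across sample groups and tissues; assign the
    # design labels round-robin so the pool spans the full study design.
    groups = [
        (tissue, genotype, age)
        for tissue in config.tissues
        for genotype in config.genotypes
        for age in config.ages
    ]
    for i in range(config.n_igg_runs):
        tissue, genotype, age = groups[i % len(groups)]
        rows.append(
            {
                "run_id": f"IgG_r{i + 1:02d}",
                "bait": "IgG",
                "epitope_class": "IgG",
                "tissue": tissue,
                "genotype": genotype,
                "age": age,
                "replicate": i // len(groups) + 1,
                "role": "IP",
            }
        )
    return pd.DataFrame(rows)


def _ground_truth(config: SimulationConfig) -> pd.DataFrame:
    n_prey = config.n_proteins
    preys = [f"P{i:04d}" for i in range(1, n_prey + 1)]
    proteins = [config.bait_protein] + preys
    truth = pd.DataFrame(
        {
            "is_bait": [True] + [False] * n_prey,
            "is_interactor": [True] + [False] * n_prey,
            "epitope_class": "",
            "tissue_enriched": "",
            "polyq_gain": False,
        },
        index=pd.Index(proteins, name="Protein"),
    )
    interactors = preys[: config.n_true_interactors]
    truth.loc[interactors, "is_interactor"] = True
    # disjoint planted blocks within the interactor set
    cursor = 0
    blocks = {
        "nterm": interactors[cursor : cursor + config.n_epitope_pref],
    }
    cursor += config.n_epitope_pref
    blocks["central"] = interactors[cursor : cursor + config.n_epitope_pref]
    cursor += config.n_epitope_pref
    blocks["tissue"] = interactors[cursor : cursor + config.n_tissue_enriched]
    cursor += config.n_tissue_enriched
    blocks["polyq"] = interactors[cursor : cursor + config.n_polyq_gain]
    if blocks["nterm"]:
        truth.loc[blocks["nterm"], "epitope_class"] = config.epitope_pools[0]
    if blocks["central"]:
        truth.loc[blocks["central"], "epitope_class"] = config.epitope_pools[1]
    truth.loc[blocks["tissue"], "tissue_enriched"] = config.enriched_tissue
    truth.loc[blocks["polyq"], "polyq_gain"] = True
    return truth


def _fold_matrix(
    config: SimulationConfig, truth: pd.DataFrame, design: pd.DataFrame
) -> np.ndarray:
    """Per-protein, per-run multiplicative enrichment over background.

    1.0 everywhere except true interactors in bait runs, where the base
    enrichment fold is further multiplied by any planted effect folds.
    """
    n_prot, n_runs = len(truth), len(design)
    fold = np.ones((n_prot, n_runs))
    is_bait_run = (design["bait"] != "IgG").to_numpy()
    interactor = (truth["is_interactor"] & ~truth["is_bait"]).to_numpy()
    fold[np.ix_(interactor, is_bait_run)] = config.enrichment_fold

    pool = design["epitope_class"].to_numpy()
    tissue = design["tissue"].to_numpy()
    genotype = design["genotype"].to_numpy()
    age = design["age"].to_numpy()

    for pool_label in config.epitope_pools:
        rows = (truth["epitope_class"] == pool_label).to_numpy()
        cols = is_bait_run & (pool == pool_label)
        fold[np.ix_(rows, cols)] *= config.epitope_fold

    rows = (truth["tissue_enriched"] == config.enriched_tissue).to_numpy()
    cols = is_bait_run & (tissue == config.enriched_tissue)
    fold[np.ix_(rows, cols)] *= config.tissue_fold

    # polyQ/age gain: extra association that develops with age in the
    # expanded-polyQ genotype, restricted to the vulnerable tissue
    rows = truth["polyq_gain"].to_numpy()
    cols = (
        is_bait_run
        & (genotype == config.genotypes[-1])
        & (age == config.ages[-1])
        & (tissue == config.enriched_tissue)
    )
    fold[np.ix_(rows, cols)] *= config.polyq_fold
    return fold


def simulate_ipms(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one full IP-MS experiment.

    Returns
    -------
    counts : DataFrame (proteins x runs), integer spectral counts
    intensities : DataFrame (proteins x runs), raw LFQ with NaN for missing
    design : DataFrame, one row per run
    truth : DataFrame indexed by protein with planted ground-truth labels
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    design = build_design(config)
    truth = _ground_truth(config)
    fold = _fold_matrix(config, truth, design)
    is_bait_run = (design["bait"] != "IgG").to_numpy()
    is_bait_protein = truth["is_bait"].to_numpy()

    # --- spectral counts: negative binomial around the scaled background ---
    mu = config.background_count_mean * fold
    mu[is_bait_protein, :] = np.where(
        is_bait_run, config.bait_count_mean, config.background_count_mean
    )
    shape = 1.0 / config.dispersion
    lam = rng.gamma(shape, mu * config.dispersion)
    counts = rng.poisson(lam).astype(int)

    # --- intensities: bait-capture-scaled log-normal with MNAR dropout ---
    mu_int = config.background_intensity_mean * fold
    mu_int[is_bait_protein, :] = np.where(
        is_bait_run, config.bait_intensity_mean, config.background_intensity_mean
    )
    sigma = config.intensity_cv
    # per-run bait-capture efficiency (mean-one log-normal), shared by all
    # proteins of the run so bait normalization can cancel it exactly
    capture = rng.lognormal(-0.5 * sigma**2, sigma, size=len(design))
    mu_scaled = mu_int * capture[np.newaxis, :]
    intens = rng.lognormal(np.log(mu_scaled) - 0.5 * sigma**2, sigma)

    p_obs = 1.0 / (
        1.0
        + np.exp(-config.dropout_slope * (np.log2(intens) - config.dropout_midpoint))
    )
    observed = rng.random(intens.shape) < p_obs
    observed[is_bait_protein, :] |= is_bait_run  # bait present in every bait run
    intens = np.where(observed, intens, np.nan)

    run_ids = design["run_id"].tolist()
    counts_df = pd.DataFrame(counts, index=truth.index, columns=run_ids)
    intens_df = pd.DataFrame(intens, index=truth.index, columns=run_ids)
    return counts_df, intens_df, design, truth


# ---------------------------------------------------------------------------
# thermal profiling
# ---------------------------------------------------------------------------


def melt_model(
    temperatures: np.ndarray, tm: float, plateau: float, slope: float
) -> np.ndarray:
    """Descending logistic relative solubility.

    ``s(T) = (1 - plateau) / (1 + exp(slope * (T - tm))) + plateau``; at
    ``T = tm`` this equals ``(1 + plateau) / 2`` (the logistic midpoint).
    """
    temperatures = np.asarray(temperatures, dtype=float)
    with np.errstate(over="ignore"):  # exp overflow -> s == plateau, the limit
        return (1.0 - plateau) / (1.0 + np.exp(slope * (temperatures - tm))) + plateau


def simulate_melt(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-protein, per-condition, per-replicate melt curves.

    Returns a long-form curve table (protein, condition, replicate,
    temperature, solubility) and a truth table with the true Tm of every
    protein/condition pair.
    """
    config.validate()
    melt = config.melt
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    temps = np.asarray(melt.temperatures, dtype=float)
    proteins = [f"M{i:04d}" for i in range(1, melt.n_proteins + 1)]

    base_tm = rng.uniform(*melt.tm_range, size=melt.n_proteins)
    tm = np.tile(base_tm[:, None], (1, len(melt.conditions)))
    if len(melt.conditions) > 1:
        tm[: melt.n_shifted, 1:] += melt.tm_shift

    # (protein, condition, replicate, temperature)
    full_shape = (
        melt.n_proteins,
        len(melt.conditions),
        melt.replicates,
        len(temps),
    )
    clean = np.broadcast_to(
        melt_model(temps[None, None, None, :], tm[:, :, None, None],
                   melt.plateau, melt.slope),
        full_shape,
    )
    if melt.noise_sd > 0:
        noisy = clean + rng.normal(0.0, melt.noise_sd, size=full_shape)
    else:
        noisy = np.array(clean, copy=True)
    noisy = np.clip(noisy, 0.0, None)
    ref = np.maximum(noisy[..., [0]], 1e-9)
    noisy = noisy / ref  # re-normalize to 1 at the reference temperature

    index = pd.MultiIndex.from_product(
        [proteins, melt.conditions, range(1, melt.replicates + 1), temps],
        names=["protein", "condition", "replicate", "temperature"],
    )
    curves = pd.DataFrame(
        {"solubility": noisy.ravel()}, index=index
    ).reset_index()
    truth = pd.DataFrame(
        {
            "protein": np.repeat(proteins, len(melt.conditions)),
            "condition": np.tile(melt.conditions, melt.n_proteins),
            "true_tm": tm.ravel(),
            "plateau": melt.plateau,
            "slope": melt.slope,
        }
    )
    return curves, truth


# ---------------------------------------------------------------------------
# nuclear/cytosolic fractionation
# ---------------------------------------------------------------------------


def simulate_fractions(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate matched nuclear and cytosolic abundance matrices.

    The expected log2 nuclear/cytosolic ratio of every protein equals its
    planted truth; compartment markers are planted at ``+/- marker_log2_nc``.
    Columns are ``<genotype>_<age>_r<replicate>`` over the full
    genotype x age design.
    """
    config.validate()
    frac = config.fractions
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))

    n_ord = frac.n_proteins
    proteins = (
        [f"NUCMARK{i}" for i in range(1, frac.n_nuclear_markers + 1)]
        + [f"CYTMARK{i}" for i in range(1, frac.n_cytosolic_markers + 1)]
        + [f"F{i:04d}" for i in range(1, n_ord + 1)]
    )
    marker = (
        ["nuclear"] * frac.n_nuclear_markers
        + ["cytosolic"] * frac.n_cytosolic_markers
        + [""] * n_ord
    )
    true_nc = np.concatenate(
        [
            np.full(frac.n_nuclear_markers, frac.marker_log2_nc),
            np.full(frac.n_cytosolic_markers, -frac.marker_log2_nc),
            rng.normal(0.0, frac.nc_log2_sd, size=n_ord),
        ]
    )

    samples = [
        f"{genotype}_{age}_r{rep}"
        for genotype in config.genotypes
        for age in config.ages
        for rep in range(1, frac.replicates + 1)
    ]
    n_prot, n_samp = len(proteins), len(samples)
    base = rng.lognormal(np.log(frac.base_intensity_mean), 0.5, size=(n_prot, 1))
    noise_n = rng.normal(0.0, frac.noise_sd, size=(n_prot, n_samp))
    noise_c = rng.normal(0.0, frac.noise_sd, size=(n_prot, n_samp))
    nuclear = base * 2.0 ** (true_nc[:, None] / 2.0 + noise_n)
    cytosolic = base * 2.0 ** (-true_nc[:, None] / 2.0 + noise_c)

    idx = pd.Index(proteins, name="Protein")
    truth = pd.DataFrame(
        {"true_log2_nc": true_nc, "marker": marker}, index=idx
    )
    return (
        pd.DataFrame(nuclear, index=idx, columns=samples),
        pd.DataFrame(cytosolic, index=idx, columns=samples),
        truth,
    )


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------


def write_fixture_bundle(config: SimulationConfig, outdir) -> dict:
    """Write the standard TSV fixture bundle to ``outdir``.

    Emits counts.tsv, intensities.tsv, design.tsv, truth.tsv, melt.tsv and
    fractions.tsv (long format with a ``fraction`` column), plus the melt
    and fraction truth tables.
    """
    from pathlib import Path

    from .io import write_results

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts, intens, design, truth = simulate_ipms(config)
    curves, melt_truth = simulate_melt(config)
    nuclear, cytosolic, frac_truth = simulate_fractions(config)

    paths = {}
    paths["counts"] = write_results(counts.reset_index(), outdir / "counts.tsv")
    paths["intensities"] = write_results(
        intens.reset_index(), outdir / "intensities.tsv"
    )
    paths["design"] = write_results(design, outdir / "design.tsv")
    paths["truth"] = write_results(truth.reset_index(), outdir / "truth.tsv")
    paths["melt"] = write_results(curves, outdir / "melt.tsv")
    frac_long = pd.concat(
        [
            nuclear.reset_index().melt(
                id_vars="Protein", var_name="sample", value_name="intensity"
            ).assign(fraction="nuclear"),
            cytosolic.reset_index().melt(
                id_vars="Protein", var_name="sample", value_name="intensity"
            ).assign(fraction="cytosolic"),
        ],
        ignore_index=True,
    )
    paths["fractions"] = write_results(frac_long, outdir / "fractions.tsv")
    paths["melt_truth"] = write_results(melt_truth, outdir / "melt_truth.tsv")
    paths["fraction_truth"] = write_results(
        frac_truth.reset_index(), outdir / "fraction_truth.tsv"
    )
    return paths
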