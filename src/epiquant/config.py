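"""Simulation configuration for the synthetic multi-epitope IP-MS study design.

The default configuration mirrors the design of a multi-epitope HTT
immunoprecipitation study in HD knock-in mice: three brain regions
(striatum, cortex, cerebellum), two genotypes (Q20 and Q140), two ages
(8 and 40 weeks), two bait-antibody epitope pools (N-terminal and Central)
plus isotype-matched IgG controls pooled across conditions, with four
biological replicates per bait sample group and 37 pooled IgG runs serving
as the virtual-control population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

#: Thermal-denaturation temperatures (degrees C) of the five-point
#: cellular thermal profiling assay.
DEFAULT_TEMPERATURES = (37.0, 40.7, 44.6, 52.8, 55.3)


@dataclass
class MeltParams:
    """Parameters of the simulated thermal-denaturation (melt) experiment.

    Solubility follows a three-parameter descending logistic
    ``s(T) = (1 - plateau) / (1 + exp(slope * (T - tm))) + plateau``
    with additive Gaussian measurement noise, clipped at zero and
    re-normalized to 1 at the lowest (reference) temperature.
    """

    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES
    conditions: tuple[str, ...] = ("SCR", "KO")
    replicates: int = 3
    n_proteins: int = 40
    #: uniform range (degrees C) for per-protein baseline melting temperatures
    tm_range: tuple[float, float] = (42.0, 54.0)
    #: melting-temperature shift (degrees C) applied in the second condition
    #: to the first ``n_shifted`` proteins
    tm_shift: float = 2.5
    n_shifted: int = 10
    plateau: float = 0.05
    slope: float = 0.5
    noise_sd: float = 0.05

    def validate(self) -> None:
        temps = tuple(self.temperatures)
        if len(temps) < 3:
            raise ValueError("at least 3 temperatures are required")
        if any(b <= a for a, b in zip(temps, temps[1:])):
            raise ValueError("temperatures must be strictly increasing")
        if not (0.0 <= self.plateau < 1.0):
            raise ValueError("plateau must lie in [0, 1)")
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.replicates < 2:
            raise ValueError("at least 2 replicates are required")
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        if not (0 <= self.n_shifted <= self.n_proteins):
            raise ValueError("n_shifted must not exceed n_proteins")


@dataclass
class FractionParams:
    """Parameters of the simulated nuclear/cytosolic fractionation experiment.

    Each protein carries a true log2 nucleus/cytoplasm (N/C) ratio; nuclear
    and cytosolic abundances are drawn so that the expected log2 ratio equals
    that truth.  Designated nuclear markers are planted at ``marker_log2_nc``
    (>= 2, i.e. at least four-fold nuclear) and cytosolic markers at its
    negative.
    """

    n_proteins: int = 200
    n_nuclear_markers: int = 4
    n_cytosolic_markers: int = 4
    #: spread (sd, log2 units) of true N/C ratios across ordinary proteins
    nc_log2_sd: float = 1.0
    #: planted |log2 N/C| of compartment markers (3 -> eight-fold)
    marker_log2_nc: float = 3.0
    #: per-fraction measurement noise (sd, log2 units)
    noise_sd: float = 0.25
    replicates: int = 4
    base_intensity_mean: float = 1e5

    def validate(self) -> None:
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        if self.replicates < 2:
            raise ValueError("at least 2 replicates are required")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.marker_log2_nc < 2.0:
            raise ValueError(
                "marker_log2_nc must be >= 2 (four-fold nuclear enrichment)"
            )
        if self.n_nuclear_markers < 1 or self.n_cytosolic_markers < 1:
            raise ValueError("at least one marker per compartment is required")


@dataclass
class SimulationConfig:
    """Full synthetic study design with planted ground-truth effects.

    Planted effect subsets (epitope preference, tissue enrichment,
    polyQ/age gain) are disjoint blocks of the true-interactor set so that
    downstream recovery can be assessed unambiguously.
    """

    n_proteins: int = 1000
    n_true_interactors: int = 100

    tissues: tuple[str, ...] = ("striatum", "cortex", "cerebellum")
    genotypes: tuple[str, ...] = ("Q20", "Q140")
    ages: tuple[str, ...] = ("8wk", "40wk")
    epitope_pools: tuple[str, ...] = ("N-term", "Central")
    replicates: int = 4
    #: total IgG control runs pooled across sample groups and tissues
    n_igg_runs: int = 37

    bait_protein: str = "HTT"

    # spectral counts (negative binomial, Poisson-gamma)
    background_count_mean: float = 1.0
    enrichment_fold: float = 10.0
    dispersion: float = 0.5
    bait_count_mean: float = 60.0

    # label-free intensities (log-normal with intensity-dependent dropout)
    background_intensity_mean: float = 1e4
    bait_intensity_mean: float = 1e7
    intensity_cv: float = 0.3
    #: log2 intensity at which the observation probability is 50%
    dropout_midpoint: float = 13.0
    dropout_slope: float = 1.0

    # planted effects (disjoint blocks of the true-interactor set)
    n_epitope_pref: int = 15
    epitope_fold: float = 8.0
    n_tissue_enriched: int = 15
    tissue_fold: float = 8.0
    enriched_tissue: str = "striatum"
    n_polyq_gain: int = 15
    polyq_fold: float = 8.0

    melt: MeltParams = field(default_factory=MeltParams)
    fractions: FractionParams = field(default_factory=FractionParams)

    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins <= 0 or self.n_true_interactors <= 0:
            raise ValueError("protein counts must be positive")
        if self.n_true_interactors > self.n_proteins:
            raise ValueError("n_true_interactors cannot exceed n_proteins")
        if self.replicates < 2:
            raise ValueError("at least 2 replicates per sample group")
        if self.n_igg_runs < 2:
            raise ValueError("at least 2 IgG control runs are required")
        for name in ("enrichment_fold", "epitope_fold", "tissue_fold", "polyq_fold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.enrichment_fold <= 1:
            raise ValueError("enrichment_fold must exceed 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.background_count_mean < 0:
            raise ValueError("background_count_mean must be non-negative")
        if self.intensity_cv < 0:
            raise ValueError("intensity_cv must be non-negative")
        planted = 2 * self.n_epitope_pref + self.n_tissue_enriched + self.n_polyq_gain
        if planted > self.n_true_interactors:
            raise ValueError(
                "planted effect subsets must fit disjointly within the "
                "true-interactor set"
            )
        if self.enriched_tissue not in self.tissues:
            raise ValueError("enriched_tissue must be one of tissues")
        self.melt.validate()
        self.fractions.validate()

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        if "melt" in data and isinstance(data["melt"], dict):
            melt = dict(data["melt"])
            for key in ("temperatures", "conditions", "tm_range"):
                if key in melt and isinstance(melt[key], list):
                    melt[key] = tuple(melt[key])
            data["melt"] = MeltParams(**melt)
        if "fractions" in data and isinstance(data["fractions"], dict):
            data["fractions"] = FractionParams(**data["fractions"])
        for key in ("tissues", "genotypes", "ages", "epitope_pools"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        config = cls(**data)
        config.validate()
        return config

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=False)
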