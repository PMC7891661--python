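"""Forward simulators for every input table the pipeline consumes.

Each generator draws from a simple measurement model — linear analyte
accumulation with a hard plateau and multiplicative lognormal analytical
noise for incubations, Poisson counting noise on DPM, multinomial taxon
composition with lognormal per-cell rates for MICRO-CARD-FISH — and returns
the generated tables together with a sidecar ground-truth record, so that
every downstream estimator can be tested for parameter recovery without any
field data.

Seasonal presets bundle coherent inputs whose ground truth follows the
qualitative seasonal pattern of a coastal temperate system: a fall
phytoplankton bloom with maximal zooplankton taurine release, taurine
concentration and assimilation efficiency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .incubation import IncubationExperiment
from .tracer import TracerConfig, TracerSample

__all__ = [
    "IncubationConfig",
    "CommunityConfig",
    "generate_incubation_experiment",
    "generate_specimen_set",
    "generate_tracer_samples",
    "generate_fish_counts",
    "generate_season_scenario",
    "SeasonScenario",
    "SEASONS",
]

#: Sampling schedule, h: every 0.5 h for 2 h, then 3, 5 and 8 h.
DEFAULT_SAMPLE_TIMES = (0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 5.0, 8.0)


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative lognormal noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma2 = np.log(1.0 + cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=shape)


@dataclass
class IncubationConfig:
    """Design and ground truth of a simulated release incubation.

    ``true_release_per_individual`` maps analyte → nmol individual⁻¹ d⁻¹;
    ``plateau_time_h`` maps analyte → the hour at which release stalls
    (defaults to the last sample time); ``baseline_nmol_l`` is the ambient
    concentration at t = 0.
    """

    true_release_per_individual: dict[str, float]
    n_individuals: int
    jar_volume_l: float = 0.5
    sample_times_h: tuple = DEFAULT_SAMPLE_TIMES
    plateau_time_h: dict[str, float] = field(default_factory=dict)
    baseline_nmol_l: dict[str, float] = field(default_factory=dict)
    noise_cv: float = 0.02
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        times = np.asarray(self.sample_times_h, dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if self.jar_volume_l <= 0:
            raise ValueError("jar volume must be positive")
        if self.n_individuals < 1:
            raise ValueError("need at least one individual")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be non-negative")
        if any(r < 0 for r in self.true_release_per_individual.values()):
            raise ValueError("release rates must be non-negative")


def generate_incubation_experiment(config: IncubationConfig) -> IncubationExperiment:
    """Simulate one release incubation plus its zero-specimen control.

    concentration(t) = baseline + rate·min(t, plateau)·n/(V·24), with
    multiplicative lognormal noise of the configured CV. The control series
    stays at baseline (same noise model).
    """
    rng = np.random.default_rng(config.seed)
    times = np.asarray(config.sample_times_h, dtype=float)
    conc: dict[str, np.ndarray] = {}
    ctrl: dict[str, np.ndarray] = {}
    for analyte, rate in config.true_release_per_individual.items():
        baseline = config.baseline_nmol_l.get(analyte, 2.0)
        plateau = config.plateau_time_h.get(analyte, times[-1])
        effective_t = np.minimum(times, plateau)
        mean = baseline + rate * effective_t * config.n_individuals / (
            config.jar_volume_l * 24.0
        )
        conc[analyte] = mean * _lognormal_noise(
            rng, config.noise_cv, (config.n_replicates, len(times))
        )
        ctrl[analyte] = baseline * _lognormal_noise(rng, config.noise_cv, (1, len(times)))
    return IncubationExperiment(
        times_h=times,
        concentrations=conc,
        control_concentrations=ctrl,
        n_individuals=config.n_individuals,
        jar_volume_l=config.jar_volume_l,
    )


def generate_specimen_set(
    n: int,
    length_dist: tuple[float, float] = (1000.0, 150.0),
    diameter_dist: tuple[float, float] = (300.0, 50.0),
    seed: int = 0,
    min_um: float = 1.0,
) -> pd.DataFrame:
    """Prosome morphometrics (µm) for ``n`` specimens.

    Draws lengths and diameters from normal distributions (mean, sd),
    truncated below at ``min_um`` so every draw stays positive; an sd of 0
    is a degenerate point mass.
    """
    if n < 1:
        raise ValueError("need at least one specimen")
    rng = np.random.default_rng(seed)
    lengths = np.maximum(rng.normal(*length_dist, size=n), min_um)
    diameters = np.maximum(rng.normal(*diameter_dist, size=n), min_um)
    return pd.DataFrame({"length_um": lengths, "diameter_um": diameters})


def generate_tracer_samples(
    true_assimilation_nmol_l_d: float,
    true_respiration_nmol_l_d: float,
    config: TracerConfig,
    seed: int = 0,
    ambient_conc_nmol_l: float = 0.0,
    n_replicates: int = 2,
    poisson_noise: bool = True,
    sample_id: str = "synthetic",
) -> TracerSample:
    """Forward model of a radiotracer incubation.

    The labeled fraction of the true uptake is added/(added + ambient)
    (inverse of the external isotope-dilution correction), so
    expected filter DPM = assim/dilution · V · (t/24) · DPM-per-nmol + blank,
    and analogously for the respiration wick. Realized DPM are Poisson
    around the expectation; the killed control sits at the blank level.
    """
    if true_assimilation_nmol_l_d < 0 or true_respiration_nmol_l_d < 0:
        raise ValueError("true rates must be non-negative")
    rng = np.random.default_rng(seed)
    dilution = (ambient_conc_nmol_l + config.added_conc_nmol_l) / config.added_conc_nmol_l
    scale = config.sample_volume_l * (config.incubation_time_h / 24.0) * config.dpm_per_nmol

    def expected(rate: float) -> float:
        return rate / dilution * scale + config.blank_dpm_mean

    def realize(mean: float, size: int) -> np.ndarray:
        if poisson_noise:
            return rng.poisson(mean, size=size).astype(float)
        return np.full(size, mean)

    filter_dpm = realize(expected(true_assimilation_nmol_l_d), n_replicates)
    wick_dpm = realize(expected(true_respiration_nmol_l_d), n_replicates)
    killed = realize(config.blank_dpm_mean, 2)
    return TracerSample(
        filter_dpm=filter_dpm,
        wick_dpm=wick_dpm,
        killed_filter_dpm=float(killed[0]),
        killed_wick_dpm=float(killed[1]),
        config=config,
        ambient_conc_nmol_l=ambient_conc_nmol_l,
        sample_id=sample_id,
    )


@dataclass
class CommunityConfig:
    """Composition and single-cell activity of a simulated community.

    ``cell_rate_lognormal_params`` maps taxon → (median amol cell⁻¹ d⁻¹,
    lognormal sigma) of the per-cell assimilation-rate distribution among
    substrate-positive cells.
    """

    total_cells_per_ml: float
    taxon_fractions: dict[str, float]
    fraction_substrate_positive: dict[str, float]
    cell_rate_lognormal_params: dict[str, tuple[float, float]]
    cells_counted_per_filter: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.taxon_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("taxon fractions must sum to 1")
        for name, frac in {**self.taxon_fractions,
                           **self.fraction_substrate_positive}.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction for {name} outside [0, 1]")
        if self.total_cells_per_ml <= 0:
            raise ValueError("total cell abundance must be positive")


def generate_fish_counts(
    config: CommunityConfig,
    rate_per_area_amol_um2_d: float = 1.0,
    counting_noise: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate MICRO-CARD-FISH count and grain-area tables.

    Returns ``(counts, areas)``: per-taxon DAPI/probe/substrate-positive
    counts (multinomial taxon composition, binomial substrate positivity)
    and per-cell grain areas (per-cell rate ÷ calibration slope). With
    ``counting_noise`` off, counts are the rounded expectations and every
    positive cell assimilates at the taxon's median rate.
    """
    if rate_per_area_amol_um2_d <= 0:
        raise ValueError("calibration slope must be positive")
    rng = np.random.default_rng(config.seed)
    taxa = list(config.taxon_fractions)
    probs = np.array([config.taxon_fractions[t] for t in taxa])
    n_counted = config.cells_counted_per_filter
    if counting_noise:
        taxon_counts = rng.multinomial(n_counted, probs)
    else:
        taxon_counts = np.round(n_counted * probs).astype(int)

    count_rows, area_rows = [], []
    for taxon, probe_positive in zip(taxa, taxon_counts):
        f_pos = config.fraction_substrate_positive[taxon]
        if counting_noise:
            n_pos = rng.binomial(probe_positive, f_pos)
        else:
            n_pos = int(round(probe_positive * f_pos))
        median, sigma = config.cell_rate_lognormal_params[taxon]
        if sigma > 0 and counting_noise:
            rates = rng.lognormal(np.log(median), sigma, size=n_pos)
        else:
            rates = np.full(n_pos, float(median))
        count_rows.append(
            {
                "filter_id": "F1",
                "probe": taxon,
                "dapi_count": n_counted,
                "probe_positive": int(probe_positive),
                "probe_substrate_positive": int(n_pos),
                "total_cells_per_ml": config.total_cells_per_ml,
            }
        )
        for cell_id, rate in enumerate(rates):
            area_rows.append(
                {
                    "filter_id": "F1",
                    "probe": taxon,
                    "cell_id": cell_id,
                    "area_um2": rate / rate_per_area_amol_um2_d,
                }
            )
    counts = pd.DataFrame(count_rows)
    dapi_pos = counts["probe_substrate_positive"].sum()
    counts["dapi_substrate_positive"] = dapi_pos
    areas = pd.DataFrame(area_rows, columns=["filter_id", "probe", "cell_id", "area_um2"])
    return counts, areas


SEASONS = ("spring", "summer", "fall", "winter")

#: Seasonal presets: coastal temperate annual cycle with a fall bloom.
#: Rates in nmol L⁻¹ d⁻¹ unless noted.
_SEASON_PRESETS: dict[str, dict] = {
    "spring": dict(
        per_individual_release=0.95, copepod_abundance_ind_l=2.0,
        mean_taurine_nmol_l=1.6, true_assimilation=1.4, true_respiration=3.2,
        leucine_incorporation=1.2, n_individuals=80, total_cells_per_ml=2e5,
        fraction_substrate_positive=0.60, community_median_rate_amol_d=10.7,
    ),
    "summer": dict(
        per_individual_release=0.95, copepod_abundance_ind_l=2.0,
        mean_taurine_nmol_l=3.2, true_assimilation=1.8, true_respiration=2.4,
        leucine_incorporation=5.1, n_individuals=80, total_cells_per_ml=4e5,
        fraction_substrate_positive=0.21, community_median_rate_amol_d=12.7,
    ),
    "fall": dict(
        per_individual_release=2.2, copepod_abundance_ind_l=4.9,
        mean_taurine_nmol_l=6.8, true_assimilation=3.1, true_respiration=1.5,
        leucine_incorporation=2.9, n_individuals=100, total_cells_per_ml=1e6,
        fraction_substrate_positive=0.40, community_median_rate_amol_d=7.2,
    ),
    "winter": dict(
        per_individual_release=1.66, copepod_abundance_ind_l=5.0,
        mean_taurine_nmol_l=1.6, true_assimilation=1.4, true_respiration=1.2,
        leucine_incorporation=0.6, n_individuals=90, total_cells_per_ml=3e5,
        fraction_substrate_positive=0.65, community_median_rate_amol_d=7.7,
    ),
}

#: Taxon composition shared across seasons; per-cell rate medians follow the
#: observed ordering (SAR11 lowest, Euryarchaeota highest).
_TAXA = {
    "SAR11": (0.35, 6.5),
    "Roseobacter": (0.08, 11.0),
    "Alteromonas": (0.05, 10.0),
    "Thaumarchaeota": (0.07, 9.3),
    "Euryarchaeota": (0.15, 11.7),
    "OtherBacteria": (0.30, 9.0),
}


@dataclass
class SeasonScenario:
    """A coherent simulated input bundle plus its ground truth."""

    season: str
    incubation: IncubationExperiment
    specimens: pd.DataFrame
    tracer_sample: TracerSample
    fish_counts: pd.DataFrame
    grain_areas: pd.DataFrame
    copepod_abundance_ind_l: float
    mean_taurine_nmol_l: float
    leucine_incorporation_nmol_l_d: float
    rate_per_area_amol_um2_d: float
    ground_truth: dict

    def write(self, out_dir) -> None:
        """Write CSV tables and the JSON ground-truth sidecar."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        exp = self.incubation
        for analyte, arr in exp.concentrations.items():
            for rep in range(arr.shape[0]):
                for j, t in enumerate(exp.times_h):
                    rows.append((t, analyte, rep, arr[rep, j], 0))
        for analyte, arr in exp.control_concentrations.items():
            for rep in range(arr.shape[0]):
                for j, t in enumerate(exp.times_h):
                    rows.append((t, analyte, rep, arr[rep, j], 1))
        pd.DataFrame(
            rows, columns=["time_h", "analyte", "replicate", "conc_nmol_L", "is_control"]
        ).to_csv(out / "incubation.csv", index=False)
        self.specimens.to_csv(out / "specimens.csv", index=False)
        s = self.tracer_sample
        pd.DataFrame(
            {
                "sample_id": [s.sample_id],
                "filter_dpm_1": [s.filter_dpm[0]],
                "filter_dpm_2": [s.filter_dpm[-1]],
                "wick_dpm_1": [s.wick_dpm[0]],
                "wick_dpm_2": [s.wick_dpm[-1]],
                "killed_filter_dpm": [s.killed_filter_dpm],
                "killed_wick_dpm": [s.killed_wick_dpm],
                "volume_L": [s.config.sample_volume_l],
                "time_h": [s.config.incubation_time_h],
                "ambient_nmol_L": [s.ambient_conc_nmol_l],
            }
        ).to_csv(out / "tracer.csv", index=False)
        self.fish_counts.to_csv(out / "fish_counts.csv", index=False)
        self.grain_areas.to_csv(out / "grain_areas.csv", index=False)
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(self.ground_truth, fh, indent=2)


def generate_season_scenario(
    season: str, seed: int = 0, noise: bool = True
) -> SeasonScenario:
    """Generate the full input bundle for one seasonal preset.

    With ``noise`` off, every table carries its exact expectation so the
    complete pipeline must return the preset ground truth (closure).
    """
    if season not in _SEASON_PRESETS:
        raise ValueError(f"unknown season {season!r}; choose from {SEASONS}")
    p = _SEASON_PRESETS[season]
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=4)

    inc_config = IncubationConfig(
        true_release_per_individual={
            "taurine": p["per_individual_release"],
            "glycine": 1.3 * p["per_individual_release"],
        },
        n_individuals=p["n_individuals"],
        baseline_nmol_l={"taurine": p["mean_taurine_nmol_l"], "glycine": 5.0},
        plateau_time_h={"taurine": 8.0, "glycine": 3.0},
        noise_cv=0.02 if noise else 0.0,
        seed=int(sub[0]),
    )
    incubation = generate_incubation_experiment(inc_config)
    specimens = generate_specimen_set(
        inc_config.n_individuals,
        length_dist=(1000.0, 150.0 if noise else 0.0),
        diameter_dist=(300.0, 50.0 if noise else 0.0),
        seed=int(sub[1]),
    )
    incubation.specimens = specimens

    tracer_config = TracerConfig.taurine_14c(
        sample_volume_l=0.010, incubation_time_h=4.0
    )
    tracer_sample = generate_tracer_samples(
        p["true_assimilation"],
        p["true_respiration"],
        tracer_config,
        seed=int(sub[2]),
        ambient_conc_nmol_l=p["mean_taurine_nmol_l"],
        poisson_noise=noise,
        sample_id=season,
    )

    rate_per_area = 2.5  # amol µm⁻² d⁻¹, autoradiographic sensitivity
    community = CommunityConfig(
        total_cells_per_ml=p["total_cells_per_ml"],
        taxon_fractions={t: frac for t, (frac, _) in _TAXA.items()},
        fraction_substrate_positive={
            t: p["fraction_substrate_positive"] for t in _TAXA
        },
        cell_rate_lognormal_params={
            t: (median * p["community_median_rate_amol_d"] / 9.5,
                0.8 if noise else 0.0)
            for t, (_, median) in _TAXA.items()
        },
        seed=int(sub[3]),
    )
    fish_counts, grain_areas = generate_fish_counts(
        community, rate_per_area_amol_um2_d=rate_per_area, counting_noise=noise
    )

    ground_truth = {
        "season": season,
        "per_individual_release_nmol_d": p["per_individual_release"],
        "bulk_release_nmol_l_d": p["per_individual_release"]
        * p["copepod_abundance_ind_l"],
        "copepod_abundance_ind_l": p["copepod_abundance_ind_l"],
        "mean_taurine_nmol_l": p["mean_taurine_nmol_l"],
        "true_assimilation_nmol_l_d": p["true_assimilation"],
        "true_respiration_nmol_l_d": p["true_respiration"],
        "true_uptake_nmol_l_d": p["true_assimilation"] + p["true_respiration"],
        "assimilation_efficiency_pct": 100.0
        * p["true_assimilation"]
        / (p["true_assimilation"] + p["true_respiration"]),
        "leucine_incorporation_nmol_l_d": p["leucine_incorporation"],
        "rate_per_area_amol_um2_d": rate_per_area,
        "taxon_fractions": {t: frac for t, (frac, _) in _TAXA.items()},
    }
    return SeasonScenario(
        season=season,
        incubation=incubation,
        specimens=specimens,
        tracer_sample=tracer_sample,
        fish_counts=fish_counts,
        grain_areas=grain_areas,
        copepod_abundance_ind_l=p["copepod_abundance_ind_l"],
        mean_taurine_nmol_l=p["mean_taurine_nmol_l"],
        leucine_incorporation_nmol_l_d=p["leucine_incorporation"],
        rate_per_area_amol_um2_d=rate_per_area,
        ground_truth=ground_truth,
    )
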