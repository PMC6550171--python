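"""Synthetic honey, nectar, and stability-trial data generators.

The study's real sample data are not public, so every downstream stage of
the pipeline is exercised on synthetic tables that emulate its statistical
structure: six honey classes with class-dependent log-normal chemical
marker concentrations left-censored at the limit of reporting (1 mg/kg for
honey, 0.01 mg/L for nectar), class-dependent Cq distributions for the two
qPCR DNA markers (Cq 36 = LOR, 40 = assay maximum), region and production
year shifts on the log scale, and optional supplier-label noise.

The generative model per chemical marker and class is a two-part
(detection x concentration) model: a marker is detected with probability
``detect``; a detected concentration is log-normal with parameters
``(loc, scale)`` on the natural-log mg/kg scale. Non-detections, and
detected draws that fall below the LOR, are flagged left-censored. Cq
values are Gaussian per class, clipped to the assay range (0, 40].

Default parameters are chosen so class orderings match the qualitative
structure the analysis assumes (e.g. 2'-MAP essentially absent outside
manuka-derived and Australian honey; manuka DNA Cq lower in monofloral
manuka than in non-manuka honey); they are illustrative, not calibrated to
any real laboratory distribution.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .markers import (
    ALL_MARKERS,
    CHEMICAL_MARKERS,
    CQ_LOR,
    CQ_MAX,
    DNA_MARKERS,
    HABITATS,
    HONEY_LOR,
    NECTAR_LOR,
    NZ_REGIONS,
    YEARS,
    HoneyType,
)
from .samples import censor_col

CLASS_ORDER = ("M", "MB", "K", "NM", "AU", "NN")

#: Supplier mislabelling adjacency: a true class may be recorded as one of
#: these neighbouring classes when label noise is enabled.
LABEL_ADJACENCY: dict[str, tuple[str, ...]] = {
    "M": ("MB",),
    "MB": ("M", "K", "NM"),
    "K": ("MB", "NM"),
    "NM": ("MB", "K"),
    "AU": ("NN",),
    "NN": ("AU",),
}


def _chem(detect: float, median: float, scale: float) -> dict:
    """Two-part chemical marker model: detection prob + log-normal params."""
    return {"detect": detect, "loc": math.log(median), "scale": scale}


def _cq(mean: float, sd: float) -> dict:
    return {"mean": mean, "sd": sd}


def _default_class_params() -> dict:
    """Per-class marker models for the six honey types.

    Medians are in mg/kg on the raw scale; DNA entries are Cq mean/sd.
    """
    return {
        "M": {
            "2'-MAP": _chem(0.95, 6.0, 0.6),
            "2-MBA": _chem(0.95, 5.0, 0.6),
            "3-PA": _chem(1.0, 650.0, 0.45),
            "4-HPA": _chem(0.95, 40.0, 0.6),
            "MS": _chem(0.9, 20.0, 0.7),
            "leptosperin": _chem(0.95, 25.0, 0.6),
            "DHA": _chem(1.0, 1200.0, 0.5),
            "MG": _chem(1.0, 400.0, 0.6),
            "kojic_acid": _chem(0.9, 15.0, 0.6),
            "4-MPA": _chem(0.8, 5.0, 0.7),
            "lumichrome": _chem(0.5, 1.5, 0.6),
            "manuka_dna": _cq(27.0, 2.0),
            "kanuka_dna": _cq(33.0, 2.0),
        },
        "MB": {
            "2'-MAP": _chem(0.92, 3.0, 0.7),
            "2-MBA": _chem(0.95, 4.0, 0.6),
            "3-PA": _chem(1.0, 120.0, 0.5),
            "4-HPA": _chem(0.95, 20.0, 0.6),
            "MS": _chem(0.8, 10.0, 0.7),
            "leptosperin": _chem(0.9, 12.0, 0.6),
            "DHA": _chem(1.0, 500.0, 0.5),
            "MG": _chem(1.0, 150.0, 0.6),
            "kojic_acid": _chem(0.85, 8.0, 0.6),
            "4-MPA": _chem(0.7, 3.0, 0.7),
            "lumichrome": _chem(0.5, 1.5, 0.6),
            "manuka_dna": _cq(30.0, 2.0),
            "kanuka_dna": _cq(32.0, 2.5),
        },
        "K": {
            "2'-MAP": _chem(0.0, 1.0, 0.5),
            "2-MBA": _chem(0.6, 2.0, 0.6),
            "3-PA": _chem(1.0, 90.0, 0.5),
            "4-HPA": _chem(0.9, 60.0, 0.6),
            "MS": _chem(0.7, 8.0, 0.7),
            "leptosperin": _chem(0.4, 2.0, 0.6),
            "DHA": _chem(0.3, 3.0, 0.7),
            "MG": _chem(0.6, 20.0, 0.7),
            "kojic_acid": _chem(0.6, 5.0, 0.6),
            "4-MPA": _chem(0.9, 12.0, 0.6),
            "lumichrome": _chem(0.9, 6.0, 0.6),
            "manuka_dna": _cq(35.0, 2.5),
            "kanuka_dna": _cq(26.0, 2.0),
        },
        "NM": {
            "2'-MAP": _chem(0.0, 1.0, 0.5),
            "2-MBA": _chem(0.1, 1.2, 0.4),
            "3-PA": _chem(0.7, 6.0, 0.8),
            "4-HPA": _chem(0.5, 3.0, 0.7),
            "MS": _chem(0.2, 1.5, 0.5),
            "leptosperin": _chem(0.1, 1.3, 0.4),
            "DHA": _chem(0.1, 2.0, 0.5),
            "MG": _chem(0.4, 10.0, 0.7),
            "kojic_acid": _chem(0.3, 2.0, 0.6),
            "4-MPA": _chem(0.1, 1.3, 0.4),
            "lumichrome": _chem(0.4, 2.0, 0.6),
            "manuka_dna": _cq(37.5, 1.5),
            "kanuka_dna": _cq(37.0, 1.8),
        },
        "AU": {
            "2'-MAP": _chem(0.7, 3.0, 0.7),
            "2-MBA": _chem(0.95, 9.0, 0.6),
            "3-PA": _chem(1.0, 180.0, 0.6),
            "4-HPA": _chem(0.95, 50.0, 0.6),
            "MS": _chem(0.8, 12.0, 0.7),
            "leptosperin": _chem(0.95, 40.0, 0.6),
            "DHA": _chem(1.0, 600.0, 0.5),
            "MG": _chem(1.0, 150.0, 0.6),
            "kojic_acid": _chem(0.7, 6.0, 0.6),
            "4-MPA": _chem(0.6, 3.0, 0.7),
            "lumichrome": _chem(0.4, 1.5, 0.6),
            "manuka_dna": _cq(38.5, 1.2),
            "kanuka_dna": _cq(36.5, 2.0),
        },
        "NN": {
            "2'-MAP": _chem(0.0, 1.0, 0.5),
            "2-MBA": _chem(0.2, 1.5, 0.5),
            "3-PA": _chem(0.6, 4.0, 0.8),
            "4-HPA": _chem(0.4, 2.5, 0.6),
            "MS": _chem(0.2, 1.5, 0.5),
            "leptosperin": _chem(0.1, 1.3, 0.4),
            "DHA": _chem(0.1, 2.0, 0.5),
            "MG": _chem(0.3, 8.0, 0.7),
            "kojic_acid": _chem(0.3, 2.0, 0.6),
            "4-MPA": _chem(0.1, 1.3, 0.4),
            "lumichrome": _chem(0.3, 1.5, 0.5),
            "manuka_dna": _cq(38.5, 1.0),
            "kanuka_dna": _cq(38.5, 1.0),
        },
    }


def _default_sample_sizes() -> dict:
    """Per-class sample counts for the two production years and archive.

    Sized like the study's per-year class imbalance (monofloral manuka and
    non-manuka dominate; multifloral manuka, kanuka and the overseas groups
    are smaller) while keeping the full table around 500 rows.
    """
    return {
        "2014/15": {"M": 54, "MB": 25, "K": 15, "NM": 75, "AU": 20, "NN": 35},
        "2015/16": {"M": 60, "MB": 25, "K": 14, "NM": 72, "AU": 12, "NN": 18},
        "archive": {"M": 30, "MB": 10, "K": 5, "NM": 30, "AU": 5, "NN": 10},
    }


def _default_year_effects() -> dict:
    # Chemical marker concentrations run higher in 2014/15 than 2015/16
    # (2-MBA excepted); shifts are additive on the natural-log scale.
    return {
        "2'-MAP": {"2015/16": -0.30},
        "3-PA": {"2015/16": -0.30},
        "4-HPA": {"2015/16": -0.25},
    }


def _default_species_params() -> dict:
    """Nectar marker models per plant species (medians in mg/L)."""
    return {
        "L. scoparium NZ": {
            "2'-MAP": _chem(0.95, 1.0, 0.7),
            "2-MBA": _chem(0.9, 0.5, 0.7),
            "3-PA": _chem(1.0, 8.0, 0.6),
            "4-HPA": _chem(0.9, 1.5, 0.7),
            "MS": _chem(0.8, 0.8, 0.7),
            "leptosperin": _chem(0.9, 2.0, 0.6),
            "DHA": _chem(0.6, 0.05, 0.9),
            "4-MPA": _chem(0.4, 0.05, 0.7),
            "lumichrome": _chem(0.3, 0.02, 0.6),
            "sugar": {"mean": 40.0, "sd": 10.0},
        },
        "L. scoparium Aus": {
            "2'-MAP": _chem(0.9, 0.8, 0.7),
            "2-MBA": _chem(0.95, 1.5, 0.7),
            "3-PA": _chem(1.0, 10.0, 0.6),
            "4-HPA": _chem(0.95, 3.0, 0.7),
            "MS": _chem(0.8, 0.8, 0.7),
            "leptosperin": _chem(0.9, 2.5, 0.6),
            "DHA": _chem(0.6, 0.05, 0.9),
            "4-MPA": _chem(0.4, 0.05, 0.7),
            "lumichrome": _chem(0.2, 0.02, 0.6),
            "sugar": {"mean": 40.0, "sd": 10.0},
        },
        "K. ericoides": {
            "2'-MAP": _chem(0.0, 0.1, 0.5),
            "2-MBA": _chem(0.6, 0.3, 0.7),
            "3-PA": _chem(1.0, 6.0, 0.6),
            "4-HPA": _chem(0.95, 4.0, 0.7),
            "MS": _chem(0.7, 0.5, 0.7),
            "leptosperin": _chem(0.3, 0.1, 0.6),
            "DHA": _chem(0.0, 0.01, 0.5),
            "4-MPA": _chem(0.9, 0.5, 0.7),
            "lumichrome": _chem(0.9, 0.3, 0.6),
            "sugar": {"mean": 35.0, "sd": 10.0},
        },
        "W. racemosa": {
            "2'-MAP": _chem(0.0, 0.1, 0.5),
            "2-MBA": _chem(0.1, 0.05, 0.5),
            "3-PA": _chem(0.7, 0.5, 0.7),
            "4-HPA": _chem(0.5, 0.2, 0.7),
            "MS": _chem(0.1, 0.05, 0.5),
            "leptosperin": _chem(0.5, 0.2, 0.6),
            "DHA": _chem(0.0, 0.01, 0.5),
            "4-MPA": _chem(0.1, 0.02, 0.5),
            "lumichrome": _chem(0.8, 0.3, 0.6),
            "sugar": {"mean": 30.0, "sd": 8.0},
        },
        "T. repens": {
            "2'-MAP": _chem(0.0, 0.1, 0.5),
            "2-MBA": _chem(0.05, 0.03, 0.5),
            "3-PA": _chem(0.0, 0.1, 0.5),
            "4-HPA": _chem(0.0, 0.1, 0.5),
            "MS": _chem(0.05, 0.03, 0.5),
            "leptosperin": _chem(0.0, 0.05, 0.5),
            "DHA": _chem(0.0, 0.01, 0.5),
            "4-MPA": _chem(0.0, 0.01, 0.5),
            "lumichrome": _chem(0.1, 0.02, 0.5),
            "sugar": {"mean": 35.0, "sd": 8.0},
        },
    }


@dataclass
class GeneratorConfig:
    """Full configuration of the synthetic-data generators.

    All distribution parameters live in nested plain dictionaries so the
    configuration round-trips through YAML. ``class_params[class][marker]``
    holds either ``{detect, loc, scale}`` (chemical; ``loc``/``scale`` on
    the natural-log mg/kg scale) or ``{mean, sd}`` (DNA, Cq units).
    """

    class_params: dict = field(default_factory=_default_class_params)
    sample_sizes: dict = field(default_factory=_default_sample_sizes)
    region_effects: dict = field(default_factory=dict)  # marker -> region -> log shift
    year_effects: dict = field(default_factory=_default_year_effects)
    label_noise: float = 0.0
    honey_lor: float = HONEY_LOR
    nectar_lor: float = NECTAR_LOR
    cq_lor: float = CQ_LOR
    cq_max: float = CQ_MAX
    species_params: dict = field(default_factory=_default_species_params)
    nectar_sample_sizes: dict = field(
        default_factory=lambda: {
            "L. scoparium NZ": 60,
            "L. scoparium Aus": 8,
            "K. ericoides": 15,
            "W. racemosa": 10,
            "T. repens": 10,
        }
    )
    habitat_effects: dict = field(default_factory=dict)  # marker -> habitat -> log shift
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.label_noise <= 1.0:
            raise ValueError("label_noise must be in [0, 1]")
        if self.honey_lor <= 0 or self.nectar_lor <= 0:
            raise ValueError("LOR values must be positive")
        if not self.cq_lor < self.cq_max:
            raise ValueError("Cq LOR must be below the Cq assay maximum")
        for cls, markers in self.class_params.items():
            for m, p in markers.items():
                if "detect" in p:
                    if not 0.0 <= p["detect"] <= 1.0:
                        raise ValueError(f"{cls}/{m}: detect outside [0,1]")
                    if not np.isfinite(p["loc"]):
                        raise ValueError(f"{cls}/{m}: non-finite location")
                    if not (np.isfinite(p["scale"]) and p["scale"] >= 0):
                        raise ValueError(f"{cls}/{m}: invalid scale")
                else:
                    if not (np.isfinite(p["sd"]) and p["sd"] >= 0):
                        raise ValueError(f"{cls}/{m}: invalid Cq sd")

    # YAML round trip -------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _draw_chemical(
    rng: np.random.Generator,
    n: int,
    params: dict,
    lor: float,
    log_shift: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n values from the two-part model; return (values, censored)."""
    detected = rng.random(n) < params["detect"]
    vals = np.exp(rng.normal(params["loc"] + log_shift, params["scale"], size=n))
    censored = ~detected | (vals < lor)
    out = np.where(censored, np.nan, vals)
    return out, censored


def _draw_cq(
    rng: np.random.Generator, n: int, params: dict, cq_max: float
) -> np.ndarray:
    vals = rng.normal(params["mean"], params["sd"], size=n)
    return np.clip(vals, 1.0, cq_max)


def generate_honey_dataset(config: GeneratorConfig) -> pd.DataFrame:
    """Generate the honey sample table.

    One row per sample with metadata, chemical marker concentrations
    (mg/kg; ``NaN`` + censor flag below the 1 mg/kg LOR) and DNA marker Cq
    values. Both the ground-truth class and the (possibly noised) supplier
    label are recorded. Deterministic given the config (including its seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    regions = list(NZ_REGIONS)
    rows: list[dict] = []
    counter = 0
    for year in sorted(config.sample_sizes):
        sizes = config.sample_sizes[year]
        for cls in CLASS_ORDER:
            n = int(sizes.get(cls, 0))
            if n == 0:
                continue
            params = config.class_params[cls]
            is_nz = cls not in ("AU", "NN")
            if is_nz:
                region = [regions[i % len(regions)] for i in range(n)]
                rng.shuffle(region)
                island = [NZ_REGIONS[r] for r in region]
                country = ["NZ"] * n
            else:
                region = ["Australia" if cls == "AU" else "overseas"] * n
                island = [""] * n
                country = ["AU" if cls == "AU" else "other"] * n

            # supplier-label noise: class-conditional confusion to adjacent classes
            labels = np.array([cls] * n, dtype=object)
            noise = rng.random(n) < config.label_noise
            for i in np.flatnonzero(noise):
                labels[i] = rng.choice(LABEL_ADJACENCY[cls])

            cols: dict[str, np.ndarray] = {}
            for m in CHEMICAL_MARKERS:
                shift = config.year_effects.get(m, {}).get(year, 0.0)
                region_eff = config.region_effects.get(m, {})
                shifts = shift + np.array(
                    [region_eff.get(r, 0.0) for r in region]
                )
                p = params[m]
                detected = rng.random(n) < p["detect"]
                vals = np.exp(rng.normal(p["loc"] + shifts, p["scale"], size=n))
                censored = ~detected | (vals < config.honey_lor)
                cols[m] = np.where(censored, np.nan, vals)
                cols[censor_col(m)] = censored
            for m in DNA_MARKERS:
                cols[m] = _draw_cq(rng, n, params[m], config.cq_max)

            for i in range(n):
                row = {
                    "sample_id": f"H{counter:05d}",
                    "supplier_label": labels[i],
                    "true_class": cls,
                    "region": region[i],
                    "island": island[i],
                    "year": year,
                    "country": country[i],
                }
                for c, arr in cols.items():
                    row[c] = arr[i]
                rows.append(row)
                counter += 1
    return pd.DataFrame(rows)


def generate_nectar_dataset(config: GeneratorConfig) -> pd.DataFrame:
    """Generate the nectar sample table (concentrations in mg/L).

    Sugar content is drawn from a truncated normal on (0, 100]; chemical
    values are censored at the 0.01 mg/L nectar LOR. NZ Leptospermum
    samples are spread over the twelve regions and five habitat types.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    regions = list(NZ_REGIONS)
    rows: list[dict] = []
    counter = 0
    nectar_markers = [
        m
        for m in CHEMICAL_MARKERS
        if any(m in sp for sp in config.species_params.values())
    ]
    for species in sorted(config.nectar_sample_sizes):
        n = int(config.nectar_sample_sizes[species])
        params = config.species_params[species]
        sugar_cfg = params.get("sugar", {"mean": 40.0, "sd": 10.0})
        a = (0.5 - sugar_cfg["mean"]) / max(sugar_cfg["sd"], 1e-12)
        b = (100.0 - sugar_cfg["mean"]) / max(sugar_cfg["sd"], 1e-12)
        if sugar_cfg["sd"] > 0:
            sugar = stats.truncnorm.rvs(
                a, b, loc=sugar_cfg["mean"], scale=sugar_cfg["sd"],
                size=n, random_state=rng,
            )
        else:
            sugar = np.full(n, sugar_cfg["mean"])
        habitat = [HABITATS[i % len(HABITATS)] for i in range(n)]
        rng.shuffle(habitat)
        region = [regions[i % len(regions)] for i in range(n)]
        rng.shuffle(region)

        cols: dict[str, np.ndarray] = {}
        for m in nectar_markers:
            if m not in params:
                cols[m] = np.full(n, np.nan)
                cols[censor_col(m)] = np.ones(n, dtype=bool)
                continue
            hab_eff = config.habitat_effects.get(m, {})
            shifts = np.array([hab_eff.get(h, 0.0) for h in habitat])
            p = params[m]
            detected = rng.random(n) < p["detect"]
            vals = np.exp(rng.normal(p["loc"] + shifts, p["scale"], size=n))
            censored = ~detected | (vals < config.nectar_lor)
            cols[m] = np.where(censored, np.nan, vals)
            cols[censor_col(m)] = censored

        for i in range(n):
            row = {
                "sample_id": f"N{counter:05d}",
                "species": species,
                "region": region[i],
                "habitat": habitat[i],
                "sugar_content": float(sugar[i]),
            }
            for c, arr in cols.items():
                row[c] = arr[i]
            rows.append(row)
            counter += 1
    return pd.DataFrame(rows)


@dataclass
class DriftModel:
    """Additive log-scale storage drift for one marker.

    ``time_slope`` is log-drift per day; ``temp_slope`` is log-drift per
    degree C above the coldest storage temperature, applied only after time
    zero (time-zero aliquots have no storage temperature).
    """

    time_slope: float = 0.0
    temp_slope: float = 0.0

    def shift(self, temp: float | None, day: float, t_ref: float) -> float:
        s = self.time_slope * day
        if temp is not None and day > 0:
            s += self.temp_slope * (temp - t_ref)
        return s


def generate_stability_dataset(
    n_samples: int = 6,
    temperatures: tuple[float, ...] = (4.0, 20.0, 35.0),
    timepoints: tuple[float, ...] = (0.0, 68.0),
    effects: dict[str, DriftModel] | None = None,
    markers: tuple[str, ...] = ("2'-MAP", "2-MBA", "3-PA", "4-HPA"),
    n_replicates: int = 3,
    between_sample_sd: float = 0.4,
    replicate_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a storage-stability trial table.

    Mirrors the trial design: each honey sample is sub-sampled in
    triplicate at time zero, then again at the final timepoint for each
    storage temperature, giving a ``sample x temperature x timepoint x
    replicate`` layout. The ``temperature`` column is a factor with the
    baseline (time-zero) level coded ``"t0"``. Drift is additive on the
    natural-log concentration scale via :class:`DriftModel`.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 honey samples")
    if not temperatures or not timepoints:
        raise ValueError("temperature and timepoint lists must be non-empty")
    effects = effects or {}
    rng = np.random.default_rng(seed)
    t_ref = min(temperatures)
    base_loc = {m: math.log(50.0) for m in markers}
    base = {
        m: rng.normal(base_loc[m], between_sample_sd, size=n_samples)
        for m in markers
    }
    rows = []
    later = [t for t in sorted(timepoints) if t > 0]
    conditions: list[tuple[str, float | None, float]] = [("t0", None, 0.0)]
    for day in later:
        for temp in temperatures:
            conditions.append((f"{temp:g}", temp, day))
    for s in range(n_samples):
        for cond, temp, day in conditions:
            for rep in range(n_replicates):
                row = {
                    "sample": f"S{s + 1}",
                    "temperature": cond,
                    "day": day,
                    "replicate": rep + 1,
                }
                for m in markers:
                    drift = effects.get(m, DriftModel()).shift(temp, day, t_ref)
                    row[m] = math.exp(
                        base[m][s] + drift + rng.normal(0.0, replicate_sd)
                    )
                rows.append(row)
    return pd.DataFrame(rows)


# Planted-truth utilities ---------------------------------------------------

def class_log_likelihood(
    config: GeneratorConfig,
    marker_values: dict[str, float],
    censored: dict[str, bool] | None = None,
) -> dict[str, float]:
    """Log-likelihood of a marker vector under each class's generative model.

    Chemical markers use the two-part detection x log-normal model with
    left-censoring at the honey LOR; DNA markers use the Gaussian Cq model
    (assay-range clipping ignored). Region/year shifts are not applied, so
    this is the reference-condition likelihood.
    """
    censored = censored or {}
    out: dict[str, float] = {}
    for cls in CLASS_ORDER:
        params = config.class_params[cls]
        ll = 0.0
        for m, v in marker_values.items():
            p = params[m]
            if "detect" in p:  # chemical
                pd_ = p["detect"]
                if censored.get(m, False) or (v is not None and np.isnan(v)):
                    below = stats.norm.cdf(
                        (math.log(config.honey_lor) - p["loc"]) / p["scale"]
                    )
                    ll += math.log(max((1.0 - pd_) + pd_ * below, 1e-300))
                else:
                    ll += math.log(max(pd_, 1e-300)) + stats.norm.logpdf(
                        math.log(v), p["loc"], p["scale"]
                    ) - math.log(v)
            else:  # DNA Cq
                ll += stats.norm.logpdf(v, p["mean"], p["sd"])
        out[cls] = float(ll)
    return out


def bayes_optimal_class(
    config: GeneratorConfig,
    marker_values: dict[str, float],
    censored: dict[str, bool] | None = None,
) -> str:
    """Maximum-likelihood class for a marker vector under the generator."""
    ll = class_log_likelihood(config, marker_values, censored)
    return max(sorted(ll), key=lambda c: ll[c])
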