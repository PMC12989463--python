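"""Seeded synthetic diatom assemblages along a phosphorus gradient.

The generator emulates the statistical structure the analyses assume: a
left-heavy mat P gradient (log-uniform over ~52–1200 µg g⁻¹), Gaussian
species response curves on the log₂ gradient (each taxon has a true optimum
u_i, a log₂-scale niche breadth σ_i and a peak relative abundance h_i), few
low-P taxa dominating the low end with many high-P taxa replacing them
upslope, and fixed-effort counts: every sample is a multinomial draw of 600
valves from the normalised expected relative abundances. Latitude/longitude
are generated so that log₂(mat P) is a noisy linear function of position,
giving the geographic disturbance surrogate something to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = ["SimulationConfig", "SyntheticTruth", "simulate", "preset", "PRESETS"]


@dataclass
class SimulationConfig:
    """Knobs of the assemblage simulator (defaults = the study-like preset)."""

    n_samples: int = 80
    gradient: tuple = (52.0, 1200.0)       # µg g⁻¹ mat P range
    n_low: int = 10                        # low-P taxa
    n_high: int = 40                       # high-P taxa
    n_neutral: int = 0                     # gradient-independent taxa
    effort: int = 600                      # valves counted per sample
    optima_low: tuple = (80.0, 250.0)      # ranges for true optima (µg g⁻¹)
    optima_high: tuple = (350.0, 1400.0)
    sigma_range: tuple = (0.8, 1.8)        # log₂-scale niche breadths
    h_range: tuple = (0.05, 0.30)          # peak expected relative abundance
    low_dominance: float = 0.65            # summed low-P share at gradient min
    response: str = "gaussian"             # or "step"
    threshold: float = 400.0               # community threshold for "step"
    latlong_noise: float = 0.3             # sd of log₂ mat P around the plane


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside a simulated assemblage.

    ``trait`` and ``optimum`` describe the *realized* expected
    relative-abundance response over the gradient — the quantity any
    assignment method observes — rather than the raw response-curve block a
    taxon was drawn from (kept in ``block``). The two can differ: a taxon
    whose raw optimum sits in the high-P block but below the community
    turnover can still decline in relative terms as stronger high-P taxa
    take over, making it a genuine low-P indicator. ``optimum`` is the
    gradient value maximising the expected relative abundance.
    """

    trait: pd.Series                       # realized direction: lowP/highP/none
    optimum: pd.Series                     # µg g⁻¹ peak of expected proportion
    sigma: pd.Series                       # log₂-scale breadth
    peak: pd.Series                        # h_i
    block: pd.Series = None                # lowP / highP / none as drawn
    thresholds: list = field(default_factory=list)


PRESETS = {
    "marsh_gradient": SimulationConfig(),
    "step_threshold": SimulationConfig(
        n_low=6, n_high=6, response="step", threshold=400.0
    ),
    "null": SimulationConfig(n_low=0, n_high=0, n_neutral=50),
}


def preset(name: str) -> SimulationConfig:
    """Named simulation configurations.

    ``marsh_gradient`` — the default subtropical-marsh-like community (few
    low-P taxa dominating the low end, many high-P taxa); ``step_threshold``
    — a sharp planted community transition for changepoint-recovery tests;
    ``null`` — no gradient structure at all, for type-I calibration.
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    cfg = PRESETS[name]
    return SimulationConfig(**asdict(cfg))


def _expected_profiles(cfg: SimulationConfig, rng) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Per-taxon response-curve parameters and the truth record."""
    taxa, traits, optima, sigmas, peaks = [], [], [], [], []

    def draw(n, label, lo, hi):
        for i in range(n):
            taxa.append(f"{label}{i + 1:03d}")
            traits.append({"L": "lowP", "H": "highP", "N": "none"}[label])
            if label == "N":
                optima.append(np.nan)
            else:
                optima.append(float(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
            sigmas.append(float(rng.uniform(*cfg.sigma_range)))
            peaks.append(float(rng.uniform(*cfg.h_range)))

    draw(cfg.n_low, "L", *cfg.optima_low)
    draw(cfg.n_high, "H", *cfg.optima_high)
    draw(cfg.n_neutral, "N", np.nan, np.nan)
    if not taxa:
        raise ValueError("degenerate config: no taxa")
    idx = pd.Index(taxa, name="taxon")
    params = pd.DataFrame(
        {"trait": traits, "optimum": optima, "sigma": sigmas, "peak": peaks},
        index=idx,
    )
    truth = SyntheticTruth(
        params["trait"].copy(),
        params["optimum"].copy(),
        params["sigma"],
        params["peak"],
        block=params["trait"].copy(),
        thresholds=[cfg.threshold] if cfg.response == "step" else [],
    )
    return params, truth


def _response(params: pd.DataFrame, x: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Expected (unnormalised) abundance of each taxon at each gradient value."""
    f = np.empty((len(params), len(x)))
    lx = np.log2(x)
    for i, (_, row) in enumerate(params.iterrows()):
        if row["trait"] == "none":
            f[i] = row["peak"]
        elif cfg.response == "step":
            side = x <= cfg.threshold if row["trait"] == "lowP" else x > cfg.threshold
            f[i] = np.where(side, row["peak"], 1e-6 * row["peak"])
        else:
            lu = np.log2(row["optimum"])
            f[i] = row["peak"] * np.exp(-((lx - lu) ** 2) / (2 * row["sigma"] ** 2))
    return f


def simulate(
    config: SimulationConfig | None = None, seed=None, preset_name: str | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Draw one synthetic assemblage: ``(counts, samples, truth)``.

    Gradient values are log-uniform over ``config.gradient``; expected
    relative abundances follow each taxon's response curve, low-P peaks are
    rescaled so the summed low-P share at the gradient minimum equals
    ``low_dominance``; counts are multinomial(effort) per sample.
    """
    if config is None:
        config = preset(preset_name or "marsh_gradient")
    cfg = config
    if cfg.effort < 1 or cfg.gradient[0] <= 0:
        raise ValueError("effort must be >= 1 and gradient floor positive")
    rng_par = substream(seed, "taxa")
    params, truth = _expected_profiles(cfg, rng_par)
    if not (params["peak"] > 0).any():
        raise ValueError("degenerate config: all peak abundances zero")

    rng_x = substream(seed, "gradient")
    lo, hi = cfg.gradient
    x = np.exp(rng_x.uniform(np.log(lo), np.log(hi), cfg.n_samples))

    f = _response(params, x, cfg)
    low = (params["trait"] == "lowP").to_numpy()
    c_low = 1.0
    if low.any() and (~low).any() and cfg.response == "gaussian":
        f_min = _response(params, np.array([lo]), cfg).ravel()
        s_low, s_rest = f_min[low].sum(), f_min[~low].sum()
        if s_low > 0 and cfg.low_dominance < 1:
            c_low = cfg.low_dominance * s_rest / ((1 - cfg.low_dominance) * s_low)
            f[low] *= c_low
            truth.peak = truth.peak.where(
                ~params["trait"].eq("lowP"), truth.peak * c_low
            )
    p = f / f.sum(axis=0, keepdims=True)

    # realized truth: expected proportions over a dense log2-uniform grid
    grid = np.exp2(np.linspace(np.log2(lo), np.log2(hi), 201))
    f_grid = _response(params, grid, cfg)
    f_grid[low] *= c_low
    p_grid = f_grid / f_grid.sum(axis=0, keepdims=True)
    lg = np.log2(grid)
    trend = ((p_grid - p_grid.mean(axis=1, keepdims=True)) * (lg - lg.mean())).sum(axis=1)
    is_trait = (params["trait"] != "none").to_numpy()
    realized = np.where(trend < 0, "lowP", "highP")
    truth.trait = pd.Series(
        np.where(is_trait, realized, "none"), index=params.index, name="trait"
    )

    rng_c = substream(seed, "counts")
    counts = np.column_stack(
        [rng_c.multinomial(cfg.effort, p[:, j]) for j in range(cfg.n_samples)]
    )
    sample_ids = [f"S{j + 1:03d}" for j in range(cfg.n_samples)]
    counts = pd.DataFrame(counts, index=params.index, columns=sample_ids)

    # geography: log2(mat P) = a + b·lat + c·long + noise, solved for latitude
    rng_g = substream(seed, "geo")
    lon = rng_g.uniform(-81.6, -80.9, cfg.n_samples)
    b, c = -10.0, -1.0   # enrichment increases toward the northwest corner
    a = np.log2(np.sqrt(lo * hi)) - b * 26.1 - c * (-81.25)
    noise = rng_g.normal(0.0, cfg.latlong_noise, cfg.n_samples)
    lat = (np.log2(x) + noise - a - c * lon) / b
    region = pd.qcut(lat + lon, min(7, cfg.n_samples), labels=False) + 1
    samples = pd.DataFrame(
        {
            "mat_p": x,
            "region": [f"R{r}" for r in region],
            "latitude": lat,
            "longitude": lon,
            "year": rng_g.choice(range(2013, 2021), cfg.n_samples),
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    return counts, samples, truth
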