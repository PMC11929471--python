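"""Seeded synthetic data emulating the GBR cryptic-predator study design.

Four generators produce the tables the analysis stages consume, with the
causal and statistical structure those stages assume:

* :func:`generate_survey` — hierarchical belt-transect records
  (region/reef/site), compositional benthic cover, rubble microhabitat
  metrics, zero-inflated negative-binomial predator counts whose log-mean
  follows configured path coefficients, and an effort-normalized adult CoTS
  index responding (negatively, by default) to *Schizophrys aspera* density.
* :func:`generate_feeding_trials` — timed aquarium feeding trials with
  logistic detection decay and log-normal copy numbers peaking 9-12 h
  post-ingestion.
* :func:`generate_specimen_screen` — wild-caught decapod ddPCR screens with
  per-region positivity fractions (fixture mode reproduces exact counts).
* :func:`simulate_droplets` — Poisson-occupancy droplet counts underlying
  the ddPCR quantification oracle.

Path coefficients act on standardized (z-score) scales: a child variable is
``mu + sigma * (sum_j beta_j z_parent_j + sqrt(1 - sum beta_j^2) * eps)``, so
the configured coefficient is recovered as the standardized regression slope.
All draws flow from a single :class:`numpy.random.Generator`; equal seeds
give identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .edna import DdpcrConfig, call_positive, copies_to_lambda, estimate_copies

__all__ = [
    "SurveyConfig",
    "ConfigError",
    "COVER_CATEGORIES",
    "generate_survey",
    "generate_feeding_trials",
    "generate_specimen_screen",
    "simulate_droplets",
    "detection_probability",
    "DEFAULT_DECAY",
    "DEFAULT_TRIAL_DESIGN",
    "DEFAULT_SCREEN_DESIGN",
]


class ConfigError(ValueError):
    """Invalid generator configuration."""


COVER_CATEGORIES = (
    "live_coral",
    "dead_coral",
    "rubble",
    "macroalgae",
    "soft_coral",
    "sand",
    "other",
)

PREDATOR_TAXA = ("s_aspera", "portunidae", "xanthidae", "epialtidae")

#: Standardized path coefficients of the default habitat -> predator -> CoTS
#: causal chain (positive rubble -> bed thickness, thickness and hard
#: substrate -> S. aspera, S. aspera -> adult CoTS negative, etc.).
DEFAULT_PATHS = {
    ("depth", "sand"): 0.4,
    ("rubble", "rubble_thickness"): 0.5,
    ("sand", "mean_piece_area"): -0.3,
    ("sand", "n_pieces"): -0.3,
    ("rubble_thickness", "s_aspera"): 0.4,
    ("dead_coral", "s_aspera"): 0.3,
    ("mean_piece_area", "portunidae"): 0.15,
    ("n_pieces", "portunidae"): 0.1,
    ("s_aspera", "cots"): -0.4,
}

#: Mean benthic cover proportions used as the logistic-normal baseline.
DEFAULT_COVER_WEIGHTS = {
    "rubble": 0.35,
    "dead_coral": 0.15,
    "live_coral": 0.12,
    "sand": 0.15,
    "macroalgae": 0.08,
    "soft_coral": 0.08,
    "other": 0.07,
}

#: Regional mean predator densities (individuals per 100 m^2).  Calibrated so
#: rate-weighted community totals average ~5.4 (south), ~1.9 (central) and
#: ~1.7 (north) ind. 100 m^-2 d^-1 and screened-community totals of ~3.6 in
#: south and north, the regime the downstream extrapolations operate in.
DEFAULT_REGION_DENSITY = {
    "s_aspera": {"south": 0.73, "central": 0.20, "north": 0.05},
    "portunidae": {"south": 1.40, "central": 0.60, "north": 1.50},
    "xanthidae": {"south": 0.80, "central": 0.70, "north": 1.40},
    "epialtidae": {"south": 0.67, "central": 0.50, "north": 0.65},
}

#: Detection-decay defaults: ~97% mean detection inside 12 h falling to ~1/3
#: by 48 h post-ingestion.
DEFAULT_DECAY = {"p0": 0.99, "halftime_h": 40.0, "slope": 0.09}

#: Timed feeding-trial design: hours post-ingestion -> number of specimens.
DEFAULT_TRIAL_DESIGN = {1.0: 3, 3.0: 5, 9.0: 2, 12.0: 3, 48.0: 3}

#: Wild screening design: 12 S. aspera in the south, 63 mixed decapods in
#: the north, with the observed positivity fractions.
DEFAULT_SCREEN_DESIGN = {
    "south": {"n": 12, "p_pos": 2 / 12},
    "north": {"n": 63, "p_pos": 7 / 63},
}

_SOUTH_SPECIES = [("Schizophrys aspera", "Majidae")]
_NORTH_SPECIES = [
    ("Thalamita admete", "Portunidae"),
    ("Portunus rugosus", "Portunidae"),
    ("Cyclodius ungulatus", "Xanthidae"),
    ("Chlorodiella nigra", "Xanthidae"),
    ("Menaethius monoceros", "Epialtidae"),
    ("Schizophrys aspera", "Majidae"),
]


@dataclass
class SurveyConfig:
    """Design and effect-size configuration of the transect-survey generator.

    Counts (`sites_per_reef`, ...) and `transect_area_m2` accept either a
    single value or a per-region mapping, so the survey shape of the field
    study (six southern sites with 120 m^2 transects, 40 m^2 transects in
    the north, ...) can be reproduced exactly.
    """

    regions: tuple = ("south", "central", "north")
    reefs_per_region: int | dict = 1
    sites_per_reef: int | dict = field(
        default_factory=lambda: {"south": 6, "central": 2, "north": 8}
    )
    transects_per_site: int | dict = field(
        default_factory=lambda: {"south": 9, "central": 3, "north": 7}
    )
    transect_area_m2: float | dict = field(
        default_factory=lambda: {"south": 120.0, "central": 120.0, "north": 40.0}
    )
    depth_range_m: tuple = (2.0, 10.0)
    path_coefficients: dict = field(default_factory=lambda: dict(DEFAULT_PATHS))
    cover_weights: dict = field(default_factory=lambda: dict(DEFAULT_COVER_WEIGHTS))
    region_density: dict = field(
        default_factory=lambda: {t: dict(v) for t, v in DEFAULT_REGION_DENSITY.items()}
    )
    zero_inflation_prob: dict = field(
        default_factory=lambda: {"s_aspera": 0.25, "portunidae": 0.2, "xanthidae": 0.2, "epialtidae": 0.2}
    )
    dispersion: dict = field(
        default_factory=lambda: {t: 1.5 for t in PREDATOR_TAXA}
    )
    site_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.regions:
            raise ConfigError("need at least one region")
        for name in ("reefs_per_region", "sites_per_reef", "transects_per_site"):
            for r in self.regions:
                if self._per_region(getattr(self, name), r) < 1:
                    raise ConfigError(f"{name} must be >= 1 in every region")
        for r in self.regions:
            if self._per_region(self.transect_area_m2, r) <= 0:
                raise ConfigError("transect_area_m2 must be positive")
        if self.depth_range_m[0] < 0 or self.depth_range_m[1] <= self.depth_range_m[0]:
            raise ConfigError("depth_range_m must be an increasing nonnegative interval")
        for taxon, p in self.zero_inflation_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"zero_inflation_prob[{taxon!r}] must lie in [0, 1]")
        for taxon, th in self.dispersion.items():
            if th <= 0:
                raise ConfigError(f"dispersion[{taxon!r}] must be positive")
        if set(self.cover_weights) != set(COVER_CATEGORIES):
            raise ConfigError("cover_weights must cover exactly the benthic categories")
        total = sum(self.cover_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"cover_weights must sum to 1 (got {total:.6f})")

    @staticmethod
    def _per_region(value, region):
        if isinstance(value, dict):
            try:
                return value[region]
            except KeyError:
                raise ConfigError(f"no value configured for region {region!r}") from None
        return value


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x)
    return (x - np.mean(x)) / sd if sd > 0 else np.zeros_like(x)


def _linear_child(z_parents, betas, mu, sigma, rng, clip_low=None):
    """mu + sigma * (sum beta_j z_j + sqrt(1 - sum beta^2) eps)."""
    n = len(next(iter(z_parents.values()))) if z_parents else None
    lin = 0.0
    b2 = 0.0
    for name, beta in betas.items():
        lin = lin + beta * z_parents[name]
        b2 += beta**2
        n = len(z_parents[name])
    noise_sd = np.sqrt(max(1.0 - b2, 1e-6))
    val = mu + sigma * (lin + noise_sd * rng.normal(size=n))
    if clip_low is not None:
        val = np.clip(val, clip_low, None)
    return val


def _paths_into(paths: dict, child: str) -> dict:
    return {parent: beta for (parent, c), beta in paths.items() if c == child}


def generate_survey(config: SurveyConfig | None = None) -> pd.DataFrame:
    """Generate one hierarchical transect-survey table.

    Transects are drawn region -> reef -> site with site-level random
    effects; benthic cover is logistic-normal (softmax of Gaussian latents,
    so proportions sum to one exactly); rubble metrics, predator counts and
    the CoTS index respond to their configured parents on standardized
    scales.  Deterministic given ``config.seed``.
    """
    cfg = config if config is not None else SurveyConfig()
    rng = np.random.default_rng(cfg.seed)
    paths = cfg.path_coefficients

    rows = []
    for region in cfg.regions:
        n_reef = cfg._per_region(cfg.reefs_per_region, region)
        n_site = cfg._per_region(cfg.sites_per_reef, region)
        n_tr = cfg._per_region(cfg.transects_per_site, region)
        area = cfg._per_region(cfg.transect_area_m2, region)
        for reef_i in range(n_reef):
            for site_i in range(n_site):
                for tr_i in range(n_tr):
                    rows.append(
                        (
                            region,
                            f"{region}_reef{reef_i + 1}",
                            f"{region}_r{reef_i + 1}_site{site_i + 1}",
                            f"{region}_r{reef_i + 1}_s{site_i + 1}_t{tr_i + 1}",
                            float(area),
                        )
                    )
    df = pd.DataFrame(rows, columns=["region", "reef", "site", "transect_id", "area_m2"])
    n = len(df)
    site_codes, site_uniques = pd.factorize(df["site"])

    # depth: site mean within range plus transect jitter
    lo, hi = cfg.depth_range_m
    site_depth = rng.uniform(lo, hi, size=len(site_uniques))
    depth = np.clip(site_depth[site_codes] + rng.normal(scale=0.6, size=n), 0.3, None)
    df["depth_m"] = depth
    z = {"depth": _zscore(depth)}

    # compositional benthic cover via logistic-normal latents
    latent = np.empty((n, len(COVER_CATEGORIES)))
    for j, cat in enumerate(COVER_CATEGORIES):
        latent[:, j] = np.log(cfg.cover_weights[cat]) + rng.normal(scale=0.5, size=n)
        beta = paths.get(("depth", cat))
        if beta:
            latent[:, j] += beta * z["depth"]
    cover = np.exp(latent - latent.max(axis=1, keepdims=True))
    cover /= cover.sum(axis=1, keepdims=True)
    for j, cat in enumerate(COVER_CATEGORIES):
        df[f"cover_{cat}"] = cover[:, j]
        z[cat] = _zscore(cover[:, j])

    # rubble microhabitat metrics
    thickness = _linear_child(z, _paths_into(paths, "rubble_thickness"), 12.0, 4.0, rng, clip_low=0.5)
    df["rubble_thickness_cm"] = thickness
    z["rubble_thickness"] = _zscore(thickness)

    n_pieces = _linear_child(z, _paths_into(paths, "n_pieces"), 47.0, 18.0, rng, clip_low=1.0)
    df["n_pieces_inspected"] = np.round(n_pieces).astype(int)
    z["n_pieces"] = _zscore(df["n_pieces_inspected"].to_numpy(dtype=float))

    piece_area = _linear_child(z, _paths_into(paths, "mean_piece_area"), 160.0, 50.0, rng, clip_low=5.0)
    df["mean_piece_area_cm2"] = piece_area
    z["mean_piece_area"] = _zscore(piece_area)

    # zero-inflated negative-binomial predator counts
    area_arr = df["area_m2"].to_numpy(dtype=float)
    region_arr = df["region"].to_numpy()
    for taxon in PREDATOR_TAXA:
        pi = cfg.zero_inflation_prob.get(taxon, 0.0)
        theta = cfg.dispersion.get(taxon, 1.5)
        dens = np.array([cfg.region_density[taxon][r] for r in region_arr])
        betas = _paths_into(paths, taxon)
        lin = np.zeros(n)
        b2 = 0.0
        for parent, beta in betas.items():
            lin += beta * z[parent]
            b2 += beta**2
        site_eff = rng.normal(scale=cfg.site_sd, size=len(site_uniques))[site_codes]
        log_mu = (
            np.log(np.maximum(dens, 1e-12) * (area_arr / 100.0) / max(1.0 - pi, 1e-12))
            + lin
            + site_eff
            - 0.5 * (b2 + cfg.site_sd**2)
        )
        mu = np.exp(log_mu)
        nb = rng.negative_binomial(theta, theta / (theta + mu))
        structural_zero = rng.uniform(size=n) < pi
        counts = np.where(structural_zero, 0, nb)
        df[f"count_{taxon}"] = counts.astype(int)
        z[taxon] = _zscore(counts * 100.0 / area_arr)

    # effort-normalized adult CoTS index (nonnegative)
    cots = _linear_child(z, _paths_into(paths, "cots"), 1.0, 0.3, rng, clip_low=0.0)
    df["cots_index"] = cots
    return df


def detection_probability(hours, p0: float, halftime_h: float, slope: float):
    """Logistic detection decay: p(0) = p0 and p(halftime) ~ p0/2.

    ``p(t) = p0 * sigmoid(slope * (halftime - t)) / sigmoid(slope * halftime)``;
    with slope = 0 the curve is flat at p0.
    """
    t = np.asarray(hours, dtype=float)
    return p0 * expit(slope * (halftime_h - t)) / expit(slope * halftime_h)


def _log_copies_mean(hours, peak_copies=2.0e4, t_peak_h=10.5, shape=2.0):
    """Log copy-number curve with its mode at t_peak (between 9 and 12 h)."""
    t = np.maximum(np.asarray(hours, dtype=float), 1e-6)
    return np.log(peak_copies) + shape * (np.log(t / t_peak_h) - (t - t_peak_h) / t_peak_h)


def _droplets_for_copies(copies, detected, n_droplets, rng, ddpcr):
    """Two replicate droplet counts consistent with the detection flag."""
    lam = copies_to_lambda(copies, ddpcr) if detected else 0.0
    reps = [simulate_droplets(lam, n_droplets, rng) for _ in range(2)]
    if detected and not call_positive(reps):
        reps[0] = (1, n_droplets)  # detected specimens carry >= 1 positive droplet
    return reps


def generate_feeding_trials(
    decay_params: dict | None = None,
    design: dict | None = None,
    seed: int = 0,
    n_droplets: int = 15000,
    exact: bool = False,
    ddpcr: DdpcrConfig | None = None,
) -> pd.DataFrame:
    """Generate timed feeding-trial records with logistic detection decay.

    ``design`` maps hours post-ingestion to specimen counts (default: the
    1/3/9/12/48 h design with n = 3/5/2/3/3).  With ``exact=True`` each time
    group contains round(n * p(t)) detections instead of Bernoulli draws
    (deterministic fixture mode).  Copy numbers are log-normal around a curve
    peaking between 9 and 12 h; droplet counts are drawn from the implied
    per-droplet concentration and always agree with the detection flag.
    """
    params = dict(DEFAULT_DECAY, **(decay_params or {}))
    design = design if design is not None else dict(DEFAULT_TRIAL_DESIGN)
    if not design:
        raise ConfigError("feeding-trial design is empty")
    if any(h <= 0 for h in design):
        raise ConfigError("hours post-ingestion must be positive")
    if not 0 < params["p0"] <= 1:
        raise ConfigError("p0 must lie in (0, 1]")
    ddpcr = ddpcr if ddpcr is not None else DdpcrConfig()
    rng = np.random.default_rng(seed)

    rows = []
    idx = 0
    for hours in sorted(design):
        n_h = design[hours]
        p = float(detection_probability(hours, **params))
        if exact:
            n_pos = int(round(n_h * p))
            flags = np.zeros(n_h, dtype=bool)
            flags[:n_pos] = True
        else:
            flags = rng.uniform(size=n_h) < p
        log_mu = float(_log_copies_mean(hours))
        for det in flags:
            copies_true = float(rng.lognormal(log_mu, 0.8)) if det else 0.0
            reps = _droplets_for_copies(copies_true, det, n_droplets, rng, ddpcr)
            rows.append(
                {
                    "specimen_id": f"ft{idx:03d}",
                    "hours_post_ingestion": float(hours),
                    "rep1_positive": reps[0][0],
                    "rep1_total": reps[0][1],
                    "rep2_positive": reps[1][0],
                    "rep2_total": reps[1][1],
                    "copies_per_sample": estimate_copies(reps, ddpcr),
                    "detected": call_positive(reps),
                }
            )
            idx += 1
    return pd.DataFrame(rows)


def generate_specimen_screen(
    region_params: dict | None = None,
    seed: int = 0,
    exact_counts: bool = False,
    n_droplets: int = 15000,
    ddpcr: DdpcrConfig | None = None,
) -> pd.DataFrame:
    """Generate wild-specimen ddPCR screening records per region.

    ``region_params`` maps region -> {"n": specimens, "p_pos": positivity}.
    With ``exact_counts=True`` exactly round(n * p_pos) specimens are
    positive (fixture mode); otherwise positivity is Bernoulli(p_pos).
    """
    region_params = region_params if region_params is not None else DEFAULT_SCREEN_DESIGN
    ddpcr = ddpcr if ddpcr is not None else DdpcrConfig()
    rng = np.random.default_rng(seed)

    rows = []
    for region in region_params:
        spec = region_params[region]
        n_spec, p_pos = int(spec["n"]), float(spec["p_pos"])
        if n_spec < 0:
            raise ConfigError("specimen count must be nonnegative")
        if not 0.0 <= p_pos <= 1.0:
            raise ConfigError("p_pos must lie in [0, 1]")
        pool = _SOUTH_SPECIES if region == "south" else _NORTH_SPECIES
        if exact_counts:
            n_pos = int(round(n_spec * p_pos))
            flags = np.zeros(n_spec, dtype=bool)
            flags[:n_pos] = True
            flags = rng.permutation(flags)
        else:
            flags = rng.uniform(size=n_spec) < p_pos
        for i, det in enumerate(flags):
            species, family = pool[int(rng.integers(len(pool)))]
            copies_true = float(rng.lognormal(np.log(800.0), 1.2)) if det else 0.0
            reps = _droplets_for_copies(copies_true, det, n_droplets, rng, ddpcr)
            rows.append(
                {
                    "region": region,
                    "specimen_id": f"{region}{i:03d}",
                    "species": species,
                    "family": family,
                    "rep1_positive": reps[0][0],
                    "rep1_total": reps[0][1],
                    "rep2_positive": reps[1][0],
                    "rep2_total": reps[1][1],
                    "copies_per_sample": estimate_copies(reps, ddpcr),
                    "detected": call_positive(reps),
                }
            )
    return pd.DataFrame(rows)


def simulate_droplets(concentration_lambda: float, n_droplets: int, rng) -> tuple:
    """Draw (positive, total) droplet counts at a given copies-per-droplet.

    Each droplet is positive with probability 1 - exp(-lambda), the Poisson
    occupancy probability at mean lambda copies per droplet.
    """
    if concentration_lambda < 0:
        raise ValueError("lambda must be nonnegative")
    if n_droplets <= 0:
        raise ValueError("n_droplets must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    p = -np.expm1(-concentration_lambda)
    return (int(rng.binomial(n_droplets, p)), int(n_droplets))
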