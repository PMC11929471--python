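"""ddPCR-based eDNA detection statistics for predator gut contents.

A specimen is *positive* when any replicate assay contains at least one
positive droplet (all field and laboratory controls being clean).  Copy
numbers follow standard digital-PCR Poisson occupancy: with a fraction k/N of
N droplets positive, the per-droplet concentration is lambda = -ln(1 - k/N),
which scales to copies per sample through the droplet volume and the fraction
of the DNA extract loaded per replicate.

Detection probability as a function of time since ingestion is modelled as a
logistic-linear decay fitted by binomial maximum likelihood, with a
Firth-type penalized fallback when the outcomes are completely separated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .predation import clopper_pearson

__all__ = [
    "DdpcrConfig",
    "DecayFit",
    "PositivityRate",
    "SaturationError",
    "call_positive",
    "estimate_copies",
    "fit_detection_decay",
    "positivity_rate",
    "pooled_positivity",
]


class SaturationError(ValueError):
    """All droplets positive in every replicate: concentration off-scale."""


@dataclass(frozen=True)
class DdpcrConfig:
    """Volume constants linking droplet occupancy to copies per sample.

    Defaults: 0.85 nl droplets, 25 ul reactions loaded with 5 ul of a DNA
    extract eluted in 3 x 50 ul.  All are configurable; only their combination
    (the per-replicate scale factor) matters downstream.
    """

    droplet_volume_nl: float = 0.85
    reaction_volume_ul: float = 25.0
    template_volume_ul: float = 5.0
    elution_volume_ul: float = 150.0

    def __post_init__(self) -> None:
        for name in ("droplet_volume_nl", "reaction_volume_ul", "template_volume_ul", "elution_volume_ul"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def extract_fraction(self) -> float:
        """Fraction of the total extract loaded into one replicate."""
        return self.template_volume_ul / self.elution_volume_ul

    @property
    def copies_per_lambda(self) -> float:
        """Copies per sample corresponding to lambda = 1 copy per droplet."""
        conc = 1.0 / (self.droplet_volume_nl * 1e-3)  # copies per ul of reaction
        return conc * self.reaction_volume_ul / self.extract_fraction


@dataclass(frozen=True)
class DecayFit:
    """Logistic decay of detection probability with hours post-ingestion."""

    intercept: float
    slope_per_hour: float
    se: tuple
    separation: bool = False
    converged: bool = True

    def predict(self, hours) -> np.ndarray:
        return expit(self.intercept + self.slope_per_hour * np.asarray(hours, dtype=float))


@dataclass(frozen=True)
class PositivityRate:
    """Proportion of screened specimens positive for prey DNA (pDNA)."""

    region: str
    k: int
    n: int
    proportion: float
    ci95: tuple

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.n:
            raise ValueError("k must lie in [0, n]")


def _check_replicates(replicates) -> list:
    reps = list(replicates)
    if not reps:
        raise ValueError("assay needs at least one replicate")
    for k, n in reps:
        if n <= 0:
            raise ValueError("total droplets must be positive")
        if not 0 <= k <= n:
            raise ValueError("positive droplets must lie in [0, total]")
    return reps


def call_positive(replicates) -> bool:
    """True iff any replicate contains one or more positive droplets."""
    return any(k >= 1 for k, _ in _check_replicates(replicates))


def estimate_copies(replicates, config: DdpcrConfig | None = None) -> float:
    """Copies of target DNA per sample from droplet occupancy.

    Per replicate, lambda = -ln(1 - k/N) copies per droplet; replicate
    concentrations are averaged and scaled to the whole extract.  Returns 0
    when no droplet is positive; raises :class:`SaturationError` when every
    replicate is fully saturated (k = N), since lambda is then unbounded.
    """
    config = config if config is not None else DdpcrConfig()
    reps = _check_replicates(replicates)
    if all(k == n for k, n in reps):
        raise SaturationError("all replicates saturated (every droplet positive)")
    lams = [-np.log1p(-k / n) for k, n in reps if k < n]
    lam = float(np.mean(lams))
    return lam * config.copies_per_lambda


def copies_to_lambda(copies_per_sample: float, config: DdpcrConfig | None = None) -> float:
    """Inverse of :func:`estimate_copies`: expected copies per droplet."""
    config = config if config is not None else DdpcrConfig()
    if copies_per_sample < 0:
        raise ValueError("copies must be nonnegative")
    return copies_per_sample / config.copies_per_lambda


def _firth_logistic(X: np.ndarray, y: np.ndarray, maxiter: int = 200, tol: float = 1e-8):
    """Firth (Jeffreys-penalized) logistic regression via modified scoring."""
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        eta = X @ beta
        p = expit(eta)
        W = p * (1 - p)
        XtW = X.T * W
        info = XtW @ X
        info_inv = np.linalg.pinv(info)
        hat = np.einsum("ij,jk,ik->i", X, info_inv, X) * W
        score = X.T @ (y - p + hat * (0.5 - p))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    W = expit(eta) * (1 - expit(eta))
    se = np.sqrt(np.diag(np.linalg.pinv((X.T * W) @ X)))
    return beta, se


def fit_detection_decay(trials: pd.DataFrame) -> DecayFit:
    """Binomial-logit regression of detection on hours post-ingestion.

    Requires at least two distinct time points and both outcomes present
    overall.  Complete separation (e.g. every specimen positive) does not
    raise: the fit falls back to Firth's penalized likelihood and is flagged
    via ``separation=True``.
    """
    hours = trials["hours_post_ingestion"].to_numpy(dtype=float)
    detected = trials["detected"].to_numpy(dtype=float)
    if len(np.unique(hours)) < 2:
        raise ValueError("need >= 2 distinct time points to fit a decay curve")
    X = np.column_stack([np.ones(len(hours)), hours])

    separated = detected.min() == detected.max()
    if not separated:
        import statsmodels.api as sm

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.GLM(detected, X, family=sm.families.Binomial()).fit(maxiter=200)
                beta = np.asarray(res.params)
                se = np.asarray(res.bse)
                # quasi-separation: ML estimates drifting off to +-inf
                separated = not np.all(np.abs(beta) < 25) or not np.all(np.isfinite(se))
            except Exception:
                separated = True
    if separated:
        beta, se = _firth_logistic(X, detected)
        return DecayFit(
            intercept=float(beta[0]),
            slope_per_hour=float(beta[1]),
            se=(float(se[0]), float(se[1])),
            separation=True,
        )
    return DecayFit(
        intercept=float(beta[0]),
        slope_per_hour=float(beta[1]),
        se=(float(se[0]), float(se[1])),
        separation=False,
        converged=bool(res.converged),
    )


def positivity_rate(specimens: pd.DataFrame, region: str, conf: float = 0.95) -> PositivityRate:
    """Regional pDNA: proportion positive with an exact binomial interval."""
    sub = specimens[specimens["region"] == region]
    if len(sub) == 0:
        raise KeyError(f"no specimens from region {region!r}")
    n = len(sub)
    k = int(sub["detected"].sum())
    return PositivityRate(
        region=region, k=k, n=n, proportion=k / n, ci95=clopper_pearson(k, n, conf=conf)
    )


def pooled_positivity(specimens: pd.DataFrame, conf: float = 0.95) -> PositivityRate:
    """pDNA pooled over all screened specimens regardless of region."""
    n = len(specimens)
    if n == 0:
        raise ValueError("no specimens")
    k = int(specimens["detected"].sum())
    return PositivityRate(
        region="pooled", k=k, n=n, proportion=k / n, ci95=clopper_pearson(k, n, conf=conf)
    )
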