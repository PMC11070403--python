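"""Stage-2 analysis: which network properties predict whether a
functional signal is detected, and how strong it is.

Each region contributes one record with four candidate predictors —
number of parasites, number of hosts, network size (their product) and
connectance — plus the per-side test outcome.  Detection (a binary flag)
is modelled with a logistic mixed model and signal strength (the Mantel
correlation among significant tests) with a linear mixed model, both with
the biogeographic realm as a random intercept.  Every subset of the four
predictors (including the intercept-only model) is fitted and ranked by
AIC; the report includes Nakagawa-Schielzeth marginal and conditional R²
(for the logistic model the latent-scale residual variance is π²/3).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._glmm import GlmmFit, fit_linear_rim, fit_logistic_rim
from .datatypes import BipartiteNetwork, RegionalRecord

__all__ = [
    "PREDICTORS",
    "network_properties",
    "ModelFit",
    "fit_detection_model",
    "fit_strength_model",
    "nakagawa_r2_logistic",
    "nakagawa_r2_linear",
]

logger = logging.getLogger(__name__)

PREDICTORS = ("n_fleas", "n_hosts", "network_size", "connectance")

#: Latent-scale residual variance of the logit link.
LOGIT_RESIDUAL_VARIANCE = math.pi ** 2 / 3.0


def network_properties(network: BipartiteNetwork) -> dict:
    """Counts, size and connectance of a bipartite network."""
    r, c = network.shape
    return {
        "n_fleas": r,
        "n_hosts": c,
        "network_size": r * c,
        "connectance": network.connectance,
    }


# ------------------------------------------------------------------- R²
def nakagawa_r2_logistic(var_fixed: float, var_random: float
                         ) -> tuple[float, float]:
    """Marginal and conditional R² for a logistic random-intercept model.

    The denominator is the latent-scale total variance: fixed-effect
    variance + random-intercept variance + π²/3.
    """
    denom = var_fixed + var_random + LOGIT_RESIDUAL_VARIANCE
    return var_fixed / denom, (var_fixed + var_random) / denom


def nakagawa_r2_linear(var_fixed: float, var_random: float,
                       var_residual: float) -> tuple[float, float]:
    denom = var_fixed + var_random + var_residual
    if denom <= 0:
        return 0.0, 0.0
    return var_fixed / denom, (var_fixed + var_random) / denom


# ------------------------------------------------------------ model fits
@dataclass
class ModelFit:
    """One fitted predictor subset, with AIC and variance decomposition."""

    predictors: tuple[str, ...]
    family: str                       # "logistic" | "linear"
    coefficients: dict                # name -> (estimate, se, z, p)
    aic: float
    marginal_r2: float
    conditional_r2: float
    re_variance: float
    residual_variance: float = float("nan")
    converged: bool = True

    def __post_init__(self):
        if not (-1e-9 <= self.marginal_r2 <= self.conditional_r2 + 1e-9
                <= 1 + 1e-9):
            raise ValueError(
                f"R² out of order: marginal={self.marginal_r2}, "
                f"conditional={self.conditional_r2}")

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.predictors) if self.predictors else "1"
        return f"~ {rhs}"


def _design(records: Sequence[RegionalRecord], predictors: Sequence[str]
            ) -> np.ndarray:
    raw = np.column_stack([
        np.array([getattr(r, p) if p != "network_size" else r.network_size
                  for r in records], float)
        for p in predictors]) if predictors else np.empty((len(records), 0))
    # standardize so coefficients are comparable and optimization is stable
    if raw.size:
        mu = raw.mean(axis=0)
        sd = raw.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        raw = (raw - mu) / sd
    return np.column_stack([np.ones(len(records)), raw])


def _all_subsets() -> list[tuple[str, ...]]:
    out: list[tuple[str, ...]] = []
    for k in range(len(PREDICTORS) + 1):
        out.extend(itertools.combinations(PREDICTORS, k))
    return out


def _summarise(fit: GlmmFit, predictors: tuple[str, ...], X: np.ndarray,
               family: str) -> ModelFit:
    eta_fixed = X @ fit.beta
    var_fixed = float(np.var(eta_fixed))
    if family == "logistic":
        r2m, r2c = nakagawa_r2_logistic(var_fixed, fit.tau2)
    else:
        r2m, r2c = nakagawa_r2_linear(var_fixed, fit.tau2, fit.sigma2)
    names = ("intercept",) + predictors
    z = fit.zvalues
    p = fit.pvalues
    coefs = {nm: (float(fit.beta[i]), float(fit.se[i]), float(z[i]),
                  float(p[i])) for i, nm in enumerate(names)}
    return ModelFit(predictors=predictors, family=family,
                    coefficients=coefs, aic=float(fit.aic),
                    marginal_r2=float(r2m), conditional_r2=float(r2c),
                    re_variance=float(fit.tau2),
                    residual_variance=float(fit.sigma2),
                    converged=fit.converged)


def _rank(fits: list[ModelFit]) -> list[ModelFit]:
    ok = [f for f in fits if f.converged and np.isfinite(f.aic)]
    dropped = len(fits) - len(ok)
    if dropped:
        logger.warning("%d subset model(s) failed to converge and were "
                       "excluded from the AIC ranking", dropped)
    return sorted(ok, key=lambda f: (f.aic, len(f.predictors)))


def fit_detection_model(records: Sequence[RegionalRecord], side: str
                        ) -> list[ModelFit]:
    """All-subsets logistic mixed models for signal detection, AIC-ranked.

    Response: whether the ``side`` test was significant in the region;
    random intercept: realm.  Requires at least 2 realms and 10 records.
    """
    records = list(records)
    realms = {r.realm for r in records}
    if len(realms) < 2:
        raise ValueError("need records from at least 2 realms")
    if len(records) < 10:
        raise ValueError("need at least 10 regional records")
    y = np.array([float(r.detected(side)) for r in records])
    groups = np.array([r.realm for r in records])
    fits = []
    for subset in _all_subsets():
        X = _design(records, subset)
        try:
            fit = fit_logistic_rim(y, X, groups)
            fits.append(_summarise(fit, subset, X, "logistic"))
        except Exception as exc:  # noqa: BLE001 - flagged, not fatal
            logger.warning("logistic subset %s failed: %s", subset, exc)
    return _rank(fits)


def fit_strength_model(records: Sequence[RegionalRecord], side: str
                       ) -> list[ModelFit]:
    """All-subsets linear mixed models for signal strength, AIC-ranked.

    Only regions with a significant test on ``side`` enter (their Mantel
    correlation is the response).  Requires at least 5 usable records.
    """
    usable = [r for r in records
              if r.detected(side) and r.strength(side) is not None]
    if len(usable) < 5:
        raise ValueError(
            f"only {len(usable)} records with a significant {side} signal; "
            "at least 5 are required")
    y = np.array([float(r.strength(side)) for r in usable])
    groups = np.array([r.realm for r in usable])
    fits = []
    for subset in _all_subsets():
        X = _design(usable, subset)
        try:
            fit = fit_linear_rim(y, X, groups)
            fits.append(_summarise(fit, subset, X, "linear"))
        except Exception as exc:  # noqa: BLE001
            logger.warning("linear subset %s failed: %s", subset, exc)
    return _rank(fits)
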