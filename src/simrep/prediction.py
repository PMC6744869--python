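"""No-free-parameter predictions from single-mutant posteriors.

Two prediction tasks:

- ``predict_strain``: given a posterior fitted on one strain, predict the
  full induction profile of another strain (different operator or
  repressor copy number) by pushing posterior draws through the
  thermodynamic model and taking percentile bands.

- ``predict_double_mutant``: the additive null model for a double mutant
  carrying one DNA-binding and one inducer-binding mutation.  The free
  energy contributions of the two domains are strictly additive, so pairing
  independent draws from the ΔεRA posterior of the DNA mutant with draws
  from the joint (KA, KI, ΔεAI) posterior of the inducer mutant yields a
  parameter-free prediction of both the fold change and ΔF of the double.
  Systematic deviation of measurements from this band is the signature of
  epistasis, and its shape localises it: a constant offset implicates the
  DNA-binding energy, a concentration-dependent offset the allosteric
  parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .core_model import (
    AllostericParams,
    RepressorContext,
    bohr_free_energy,
)
from .core_model import _log_pact_arrays  # array kernel shared with the model
from .diagnostics import DeltaFProfile
from .inference import PosteriorSamples

__all__ = [
    "PredictionBand",
    "predict_strain",
    "predict_double_mutant",
    "epistasis_residual",
]


@dataclass
class PredictionBand:
    """Percentile band of a predicted quantity over a concentration grid.

    ``table`` columns: ``iptg_uM``, ``median``, ``lower``, ``upper``.
    ``kind`` is ``"fold_change"`` or ``"delta_F"``.
    """

    table: pd.DataFrame
    kind: str
    n_draws: int
    seed: int
    resampled: bool = False

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _band(values: np.ndarray, c_grid: np.ndarray, kind: str, n_draws: int,
          seed: int, mass: float, resampled: bool) -> PredictionBand:
    alpha = (1.0 - mass) / 2.0
    lo, med, hi = np.quantile(values, [alpha, 0.5, 1.0 - alpha], axis=0)
    table = pd.DataFrame({"iptg_uM": c_grid, "median": med,
                          "lower": lo, "upper": hi})
    return PredictionBand(table=table, kind=kind, n_draws=n_draws, seed=seed,
                          resampled=resampled)


def _draw_indices(posterior: PosteriorSamples, n_draws: int,
                  rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    avail = posterior.n_draws
    resampled = n_draws > avail
    if resampled:
        warnings.warn(f"requested {n_draws} draws but posterior holds {avail}; "
                      "resampling with replacement")
    return rng.choice(avail, size=n_draws, replace=True), resampled


def _posterior_params(posterior: PosteriorSamples, idx: np.ndarray,
                      fixed_allosteric: AllostericParams,
                      fixed_eps_ra: float) -> tuple[np.ndarray, ...]:
    """Per-draw (ka, ki, eps_ai, eps_ra) columns, falling back to the
    fixed values for parameters absent from the posterior."""
    n = idx.size
    names = posterior.parameter_names

    def col(name, default):
        if name in names:
            return posterior.get(name)[idx]
        return np.full(n, default)

    if "log10_ka" in names:
        ka = 10.0 ** posterior.get("log10_ka")[idx]
        ki = 10.0 ** posterior.get("log10_ki")[idx]
    else:
        ka = np.full(n, fixed_allosteric.ka)
        ki = np.full(n, fixed_allosteric.ki)
    eps_ai = col("eps_ai", fixed_allosteric.eps_ai)
    eps_ra = col("eps_ra", fixed_eps_ra)
    return ka, ki, eps_ai, eps_ra


def _fold_change_draws(c_grid: np.ndarray, ka, ki, eps_ai, eps_ra,
                       r_total: float, n_ns: float, n_sites: int) -> np.ndarray:
    lp = _log_pact_arrays(c_grid[None, :], ka[:, None], ki[:, None],
                          eps_ai[:, None], n_sites)
    log_occ = lp + np.log(r_total / n_ns) - eps_ra[:, None]
    return expit(-log_occ), -log_occ  # fold change and Bohr F per draw


def predict_strain(posterior: PosteriorSamples,
                   target_context: RepressorContext,
                   fixed_allosteric: AllostericParams,
                   c_grid,
                   n_draws: int = 10_000,
                   seed: int = 0,
                   mass: float = 0.95,
                   predictive: str = "curve",
                   n_replicates: int = 10,
                   force: bool = False) -> PredictionBand:
    """Predict a strain's induction profile from a fitted posterior.

    Each retained draw supplies whichever parameters were sampled
    (``eps_ra`` for a DNA-binding fit, the allosteric triplet for an
    inducer-binding fit); the rest come from ``fixed_allosteric`` and the
    target context.  Percentile bands across draws form the 95% credible
    prediction.

    ``predictive`` chooses what the band describes: ``"curve"`` (default)
    is the credible region of the model curve itself; ``"mean"`` adds the
    measurement noise of a replicate mean (sigma draw / sqrt(n_replicates))
    and is the right band to compare against observed replicate means;
    ``"replicate"`` adds full single-replicate noise.  The noise options
    require a posterior that sampled ``sigma``.

    A posterior failing its convergence diagnostics is refused unless
    ``force=True``.
    """
    if not posterior.converged and not force:
        raise ValueError(
            f"posterior failed convergence diagnostics (max R-hat "
            f"{posterior.max_rhat:.4f}); pass force=True to override")
    if predictive not in ("curve", "mean", "replicate"):
        raise ValueError(f"unknown predictive kind {predictive!r}")
    c_grid = np.asarray(c_grid, dtype=float)
    rng = np.random.default_rng(seed)
    idx, resampled = _draw_indices(posterior, n_draws, rng)
    ka, ki, eps_ai, eps_ra = _posterior_params(posterior, idx, fixed_allosteric,
                                               target_context.eps_ra)
    fc, _ = _fold_change_draws(c_grid, ka, ki, eps_ai, eps_ra,
                               target_context.r_total, target_context.n_ns,
                               fixed_allosteric.n_sites)
    if predictive != "curve":
        if "sigma" not in posterior.parameter_names:
            raise ValueError("posterior has no sigma draws; cannot form a "
                             "predictive band")
        sigma = posterior.get("sigma")[idx]
        scale = sigma if predictive == "replicate" else sigma / np.sqrt(n_replicates)
        fc = fc + scale[:, None] * rng.standard_normal(fc.shape)
    return _band(fc, c_grid, "fold_change", n_draws, seed, mass, resampled)


def predict_double_mutant(dna_posterior: PosteriorSamples,
                          allosteric_posterior: PosteriorSamples,
                          wt_params: AllostericParams,
                          wt_context: RepressorContext,
                          c_grid,
                          n_draws: int = 10_000,
                          seed: int = 0,
                          mass: float = 0.95,
                          force: bool = False
                          ) -> tuple[PredictionBand, PredictionBand]:
    """Additive-null prediction for a cross-domain double mutant.

    Pairs ``n_draws`` independent draws of ΔεRA (from the DNA-binding
    single mutant) with draws of (KA, KI, ΔεAI) (from the inducer-binding
    single mutant), evaluates the thermodynamic model at the measurement
    context, and returns percentile bands for the fold change and for ΔF
    relative to the wild-type strain at the same operator and copy number.
    The two posteriors come from separate experiments on separate protein
    domains and are treated as independent — correlation between them would
    itself constitute an epistasis model.
    """
    for name, post in (("dna", dna_posterior), ("allosteric", allosteric_posterior)):
        if not post.converged and not force:
            raise ValueError(f"{name} posterior failed convergence diagnostics "
                             f"(max R-hat {post.max_rhat:.4f})")
    c_grid = np.asarray(c_grid, dtype=float)
    rng = np.random.default_rng(seed)
    idx_dna, rs1 = _draw_indices(dna_posterior, n_draws, rng)
    idx_all, rs2 = _draw_indices(allosteric_posterior, n_draws, rng)

    eps_ra = dna_posterior.get("eps_ra")[idx_dna]
    ka = 10.0 ** allosteric_posterior.get("log10_ka")[idx_all]
    ki = 10.0 ** allosteric_posterior.get("log10_ki")[idx_all]
    if "eps_ai" in allosteric_posterior.parameter_names:
        eps_ai = allosteric_posterior.get("eps_ai")[idx_all]
    else:
        eps_ai = np.full(n_draws, wt_params.eps_ai)

    fc, f_double = _fold_change_draws(c_grid, ka, ki, eps_ai, eps_ra,
                                      wt_context.r_total, wt_context.n_ns,
                                      wt_params.n_sites)
    f_wt = np.asarray(bohr_free_energy(c_grid, wt_params, wt_context))
    delta_f = f_double - f_wt[None, :]

    resampled = rs1 or rs2
    return (_band(fc, c_grid, "fold_change", n_draws, seed, mass, resampled),
            _band(delta_f, c_grid, "delta_F", n_draws, seed, mass, resampled))


def epistasis_residual(predicted: PredictionBand,
                       observed: DeltaFProfile,
                       spread_tol: float = 0.5) -> tuple[pd.DataFrame, str]:
    """Compare an observed ΔF profile with the additive-null band.

    Returns a per-concentration table (residual of medians and whether the
    observed credible interval overlaps the predicted band) and a summary
    label:

    - ``consistent`` — bands overlap at >= 90% of uncensored points: no
      evidence of epistasis;
    - ``constant_offset`` — systematic deviation independent of inducer
      concentration (within ``spread_tol`` kBT): suggests epistasis in the
      DNA-binding energy;
    - ``c_dependent_offset`` — deviation varying with concentration:
      suggests epistasis in the allosteric parameters.
    """
    if predicted.kind != "delta_F":
        raise ValueError("predicted band must be a delta_F band")
    obs = observed.uncensored
    pred = predicted.table
    merged = obs.merge(pred, on="iptg_uM", how="inner",
                       suffixes=("_obs", "_pred"))
    if len(merged) == 0:
        raise ValueError("no overlapping uncensored concentrations")
    residual = merged["delta_f_median"] - merged["median"]
    overlap = ~((merged["delta_f_upper"] < merged["lower"])
                | (merged["delta_f_lower"] > merged["upper"]))
    table = pd.DataFrame({
        "iptg_uM": merged["iptg_uM"],
        "residual": residual,
        "band_overlap": overlap,
    })
    coverage = float(overlap.mean())
    if coverage >= 0.9:
        label = "consistent"
    elif float(residual.max() - residual.min()) <= spread_tol:
        label = "constant_offset"
    else:
        label = "c_dependent_offset"
    return table, label
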