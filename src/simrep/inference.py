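"""Bayesian inference for induction profiles.

Three estimation problems, all with a homoscedastic Gaussian likelihood on
replicated fold-change measurements:

1. ``fit_dna_binding_energy`` — posterior over the repressor-operator
   binding energy ΔεRA (and the noise SD σ) from one strain's induction
   profile, holding the allosteric parameters at their wild-type values.
   This encodes the hypothesis that a DNA-binding-domain mutation perturbs
   only ΔεRA.
2. ``fit_allosteric_params`` — joint posterior over the inducer
   dissociation constants (KA, KI; sampled on log10 scale since plausible
   values span several orders of magnitude) and optionally the
   conformational energy gap ΔεAI.
3. ``infer_fold_change_moments`` / ``infer_empirical_F`` — per-condition
   posterior over the mean and SD of the fold change, mapped draw-by-draw
   through ``F = log(mu / (1 - mu))`` to an empirical Bohr free energy.

Detection-limit censoring: when the posterior-median mean fold change is
within one posterior-median SD of 0 or of 1, the free-energy inference is
systematically biased (over- and underestimated respectively), so such
conditions are flagged and excluded from downstream ΔF analysis.

MCMC uses the affine-invariant ensemble sampler (emcee); walkers are
treated as chains for rank-normalised split R-hat and effective sample
size (arviz).  Per-condition moment posteriors have an exact sampling form
under the Jeffreys reference prior and are drawn directly; an emcee
backend is retained for cross-checking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .core_model import (
    AllostericParams,
    RepressorContext,
    WT_ALLOSTERIC,
    log_pact,
)

__all__ = [
    "Priors",
    "MCMCSettings",
    "DEFAULT_DNA_SETTINGS",
    "DEFAULT_ALLOSTERIC_SETTINGS",
    "PosteriorSamples",
    "FoldChangeMoments",
    "FPosterior",
    "ConvergenceWarning",
    "fit_dna_binding_energy",
    "fit_allosteric_params",
    "infer_fold_change_moments",
    "infer_empirical_F",
    "credible_interval",
]


class ConvergenceWarning(UserWarning):
    """Raised (as a warning) when MCMC diagnostics indicate trouble."""


# ---------------------------------------------------------------------------
# Priors and sampler settings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Priors:
    """Weakly informative priors, stated in sampling units.

    ΔεRA ~ Normal(-12, 6) kBT; log10(KA/μM) and log10(KI/μM) ~
    Normal(2, 2) truncated to [-3, 7]; ΔεAI ~ Normal(0, 5) kBT;
    σ ~ HalfNormal(0.1).  These span the plausible biophysical range for a
    bacterial repressor by a comfortable margin without forcing any
    particular estimate.
    """

    eps_ra_loc: float = -12.0
    eps_ra_scale: float = 6.0
    log10_k_loc: float = 2.0
    log10_k_scale: float = 2.0
    log10_k_bounds: tuple[float, float] = (-3.0, 7.0)
    eps_ai_loc: float = 0.0
    eps_ai_scale: float = 5.0
    sigma_scale: float = 0.1


@dataclass(frozen=True)
class MCMCSettings:
    """Ensemble-sampler settings.

    ``n_walkers`` walkers are run for ``n_warmup`` discarded steps then
    ``n_steps`` kept steps, giving ``n_walkers * n_steps`` posterior draws
    (>= 1000 with the defaults).
    """

    n_walkers: int = 32
    n_warmup: int = 1000
    n_steps: int = 2000
    rhat_threshold: float = 1.01

    def __post_init__(self) -> None:
        if self.n_walkers * self.n_steps < 1000:
            raise ValueError("settings yield fewer than 1000 posterior draws")


#: Defaults sized so the standard synthetic fixture (12 concentrations x
#: 10 replicates) reaches split R-hat <= 1.01.  The joint allosteric
#: posterior mixes more slowly than the single-energy fit and gets a
#: larger ensemble and longer chains.
DEFAULT_DNA_SETTINGS = MCMCSettings(n_walkers=32, n_warmup=1000, n_steps=2000)
DEFAULT_ALLOSTERIC_SETTINGS = MCMCSettings(n_walkers=48, n_warmup=1000,
                                           n_steps=4000)


# ---------------------------------------------------------------------------
# Posterior containers
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSamples:
    """Labelled MCMC draws with convergence diagnostics.

    ``draws`` has shape (n_draws, n_parameters) with walkers interleaved;
    ``chain_id`` maps each draw to its walker.  ``diagnostics`` holds
    rank-normalised split R-hat and bulk ESS per parameter.
    """

    parameter_names: list[str]
    draws: np.ndarray
    chain_id: np.ndarray
    diagnostics: dict[str, dict[str, float]]
    seed: int
    rhat_threshold: float = 1.01

    def get(self, name: str) -> np.ndarray:
        return self.draws[:, self.parameter_names.index(name)]

    def median(self, name: str) -> float:
        return float(np.median(self.get(name)))

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    @property
    def max_rhat(self) -> float:
        return max(d["rhat"] for d in self.diagnostics.values())

    @property
    def converged(self) -> bool:
        return bool(np.isfinite(self.max_rhat)
                    and self.max_rhat <= self.rhat_threshold)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.draws, columns=self.parameter_names)
        df.insert(0, "chain_id", self.chain_id)
        return df

    def to_csv(self, path) -> None:
        """One row per draw, one column per parameter plus the chain id."""
        self.to_dataframe().to_csv(path, index=False)

    def metadata(self) -> dict:
        return {
            "parameter_names": list(self.parameter_names),
            "n_draws": int(self.n_draws),
            "n_chains": int(np.unique(self.chain_id).size),
            "seed": int(self.seed),
            "diagnostics": self.diagnostics,
            "rhat_threshold": self.rhat_threshold,
            "converged": self.converged,
        }

    @classmethod
    def from_csv(cls, path, metadata_path=None) -> "PosteriorSamples":
        """Load draws exported by :meth:`to_csv`.

        Convergence diagnostics live in the JSON sidecar written alongside
        the draws; without it R-hat is unknown (NaN) and the posterior is
        treated as unconverged, so consumers must opt in with ``force``.
        """
        df = pd.read_csv(path)
        names = [c for c in df.columns if c != "chain_id"]
        meta: dict = {}
        if metadata_path is not None:
            import json
            with open(metadata_path) as fh:
                meta = json.load(fh)
        diagnostics = meta.get("diagnostics",
                               {n: {"rhat": float("nan"), "ess": float("nan")}
                                for n in names})
        return cls(parameter_names=names,
                   draws=df[names].to_numpy(dtype=float),
                   chain_id=df["chain_id"].to_numpy(dtype=int),
                   diagnostics=diagnostics,
                   seed=int(meta.get("seed", -1)),
                   rhat_threshold=float(meta.get("rhat_threshold", 1.01)))


@dataclass
class FoldChangeMoments:
    """Posterior draws of the mean and SD of one condition's fold change.

    The censoring flags implement the detection-limit rule: the condition
    is unusable for free-energy inference when median(mu) < median(sigma)
    (too close to zero) or 1 - median(mu) < median(sigma) (too close to
    full induction).
    """

    mu: np.ndarray
    sigma: np.ndarray
    censored_low: bool
    censored_high: bool
    n_replicates: int

    @property
    def censored(self) -> bool:
        return self.censored_low or self.censored_high


@dataclass
class FPosterior:
    """Empirical Bohr free-energy posterior for one condition (kBT)."""

    f_draws: np.ndarray
    median: float
    lower: float
    upper: float
    censored: bool
    n_dropped: int


# ---------------------------------------------------------------------------
# Generic ensemble-sampler driver
# ---------------------------------------------------------------------------

def _run_ensemble(log_prob: Callable[[np.ndarray], np.ndarray],
                  x0: np.ndarray,
                  parameter_names: Sequence[str],
                  settings: MCMCSettings,
                  seed: int) -> PosteriorSamples:
    """Run emcee with vectorised log-probability and collect diagnostics."""
    n_walkers, ndim = x0.shape
    # differential-evolution moves mix markedly better than the default
    # stretch move on the correlated (log KA, log KI, eps_AI) posterior
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob, vectorize=True,
                                    moves=moves)
    sampler.random_state = np.random.RandomState(seed).get_state()
    state = sampler.run_mcmc(x0, settings.n_warmup, progress=False)
    sampler.reset()
    sampler.run_mcmc(state, settings.n_steps, progress=False)
    chain = sampler.get_chain()  # (n_steps, n_walkers, ndim)

    posterior = {name: chain[:, :, i].T for i, name in enumerate(parameter_names)}
    idata = az.from_dict(posterior=posterior)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    diagnostics = {
        name: {"rhat": float(rhat[name].values), "ess": float(ess[name].values)}
        for name in parameter_names
    }

    draws = chain.reshape(-1, ndim)
    chain_id = np.tile(np.arange(n_walkers), settings.n_steps)
    post = PosteriorSamples(parameter_names=list(parameter_names), draws=draws,
                            chain_id=chain_id, diagnostics=diagnostics,
                            seed=seed, rhat_threshold=settings.rhat_threshold)
    if not post.converged:
        warnings.warn(
            f"MCMC may not have converged: max R-hat = {post.max_rhat:.4f} "
            f"(threshold {settings.rhat_threshold})", ConvergenceWarning)
    return post


def _normal_logpdf(x, loc, scale):
    return -0.5 * ((x - loc) / scale) ** 2


def _map_ball_init(log_prob: Callable[[np.ndarray], np.ndarray],
                   starts: np.ndarray,
                   ball_scale: np.ndarray,
                   n_walkers: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Initialise walkers in a small Gaussian ball around the MAP.

    The posterior mode is located with Nelder-Mead from each candidate
    start (the vectorised log-probability evaluates all simplex proposals
    one at a time); the ensemble then needs only a short warmup to expand
    from the ball to the full posterior.
    """
    from scipy.optimize import minimize

    best_x, best_val = None, -np.inf
    for s in np.atleast_2d(starts):
        res = minimize(lambda th: -float(log_prob(th[None, :])[0]), s,
                       method="Nelder-Mead",
                       options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-8})
        if -res.fun > best_val:
            best_x, best_val = res.x, -res.fun
    x0 = best_x[None, :] + ball_scale[None, :] * rng.standard_normal(
        (n_walkers, best_x.size))
    # keep every walker inside the support
    bad = ~np.isfinite(log_prob(x0))
    tries = 0
    while np.any(bad) and tries < 100:
        x0[bad] = best_x[None, :] + 0.5 * ball_scale[None, :] * \
            rng.standard_normal((int(bad.sum()), best_x.size))
        bad = ~np.isfinite(log_prob(x0))
        tries += 1
    return x0


def _check_profile_data(data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if "iptg_uM" not in data.columns or "fold_change" not in data.columns:
        raise ValueError("data must have iptg_uM and fold_change columns")
    if "strain_id" in data.columns and data["strain_id"].nunique() > 1:
        raise ValueError("data must be restricted to a single strain")
    c = data["iptg_uM"].to_numpy(dtype=float)
    y = data["fold_change"].to_numpy(dtype=float)
    if np.unique(c).size < 2:
        raise ValueError("need at least 2 distinct inducer concentrations")
    return c, y


# ---------------------------------------------------------------------------
# DNA binding energy fit (single-parameter mutation hypothesis)
# ---------------------------------------------------------------------------

def fit_dna_binding_energy(data: pd.DataFrame,
                           fixed_allosteric: AllostericParams = WT_ALLOSTERIC,
                           r_total: float = 260.0,
                           n_ns: float = 4.6e6,
                           priors: Optional[Priors] = None,
                           mcmc_settings: Optional[MCMCSettings] = None,
                           seed: int = 0) -> PosteriorSamples:
    """Posterior over (eps_ra, sigma) from one strain's induction profile.

    The allosteric triplet is held fixed (wild type by default), expressing
    the hypothesis that the mutation touches only the repressor-DNA
    interaction.  ``data`` is a tidy table with one replicate per row.
    """
    priors = priors or Priors()
    settings = mcmc_settings or DEFAULT_DNA_SETTINGS
    c, y = _check_profile_data(data)

    lp = np.asarray(log_pact(c, fixed_allosteric), dtype=float)
    log_rn = np.log(r_total / n_ns)
    n_obs = y.size

    def log_prob(theta: np.ndarray) -> np.ndarray:
        eps_ra = theta[:, 0:1]
        sigma = theta[:, 1:2]
        out = np.full(theta.shape[0], -np.inf)
        ok = sigma[:, 0] > 0
        if not np.any(ok):
            return out
        model = expit(-(lp[None, :] + log_rn - eps_ra[ok]))
        resid = y[None, :] - model
        s = sigma[ok]
        loglik = (-0.5 * np.sum(resid ** 2, axis=1) / s[:, 0] ** 2
                  - n_obs * np.log(s[:, 0]))
        prior = (_normal_logpdf(eps_ra[ok, 0], priors.eps_ra_loc, priors.eps_ra_scale)
                 - 0.5 * (s[:, 0] / priors.sigma_scale) ** 2)
        out[ok] = loglik + prior
        return out

    # crude moment estimate seeds the MAP search
    rng = np.random.default_rng(seed)
    inside = (y > 0.01) & (y < 0.99)
    if np.any(inside):
        eps_est = float(np.median(logit(y[inside]) + lp[inside] + log_rn))
    else:
        eps_est = priors.eps_ra_loc
    x0 = _map_ball_init(log_prob, np.array([[eps_est, 0.05]]),
                        np.array([0.02, 0.005]), settings.n_walkers, rng)
    return _run_ensemble(log_prob, x0, ["eps_ra", "sigma"], settings, seed)


# ---------------------------------------------------------------------------
# Joint allosteric fit (inducer-binding mutation hypotheses)
# ---------------------------------------------------------------------------

def fit_allosteric_params(data: pd.DataFrame,
                          fixed_context: RepressorContext,
                          priors: Optional[Priors] = None,
                          mcmc_settings: Optional[MCMCSettings] = None,
                          seed: int = 0,
                          mode: str = "ka_ki_epsai",
                          n_sites: int = 2,
                          wt_eps_ai: float = WT_ALLOSTERIC.eps_ai) -> PosteriorSamples:
    """Joint posterior over the allosteric parameters of one strain.

    ``mode='ka_ki_only'`` fixes ΔεAI at the wild-type value (so the
    leakiness prediction is pinned to wild type); ``mode='ka_ki_epsai'``
    fits all three.  KA and KI are sampled as log10(K/μM) with truncated
    normal priors and no ordering constraint between them (real mutants
    can invert or collapse the KA/KI ratio).

    A warning is emitted when posterior mass piles against a prior
    truncation bound — the situation summarised experimentally as only a
    lower bound on a dissociation constant (e.g. "KA > 1 mM").
    """
    if mode not in ("ka_ki_only", "ka_ki_epsai"):
        raise ValueError(f"unknown mode {mode!r}")
    priors = priors or Priors()
    settings = mcmc_settings or DEFAULT_ALLOSTERIC_SETTINGS
    c, y = _check_profile_data(data)

    log_rn = np.log(fixed_context.r_total / fixed_context.n_ns)
    eps_ra = fixed_context.eps_ra
    n_obs = y.size
    lo, hi = priors.log10_k_bounds
    fit_eps_ai = mode == "ka_ki_epsai"
    names = ["log10_ka", "log10_ki"] + (["eps_ai"] if fit_eps_ai else []) + ["sigma"]
    ln10 = np.log(10.0)

    def log_prob(theta: np.ndarray) -> np.ndarray:
        l10ka = theta[:, 0]
        l10ki = theta[:, 1]
        eps_ai = theta[:, 2] if fit_eps_ai else np.full_like(l10ka, wt_eps_ai)
        sigma = theta[:, -1]
        out = np.full(theta.shape[0], -np.inf)
        ok = ((sigma > 0) & (l10ka >= lo) & (l10ka <= hi)
              & (l10ki >= lo) & (l10ki <= hi))
        if not np.any(ok):
            return out
        ka = np.exp(ln10 * l10ka[ok, None])
        ki = np.exp(ln10 * l10ki[ok, None])
        log_a = n_sites * np.log1p(c[None, :] / ka)
        log_i = -eps_ai[ok, None] + n_sites * np.log1p(c[None, :] / ki)
        lp = log_a - np.logaddexp(log_a, log_i)
        model = expit(-(lp + log_rn - eps_ra))
        resid = y[None, :] - model
        s = sigma[ok]
        loglik = -0.5 * np.sum(resid ** 2, axis=1) / s ** 2 - n_obs * np.log(s)
        prior = (_normal_logpdf(l10ka[ok], priors.log10_k_loc, priors.log10_k_scale)
                 + _normal_logpdf(l10ki[ok], priors.log10_k_loc, priors.log10_k_scale)
                 - 0.5 * (s / priors.sigma_scale) ** 2)
        if fit_eps_ai:
            prior = prior + _normal_logpdf(theta[ok, 2], priors.eps_ai_loc,
                                           priors.eps_ai_scale)
        out[ok] = loglik + prior
        return out

    # MAP from a small grid of starts covering inducible, inverted and
    # leaky-repressor regimes, then a tight walker ball around the best
    rng = np.random.default_rng(seed)
    starts = []
    for l10ka in (1.0, 2.5):
        for l10ki in (-0.5, 1.0):
            if fit_eps_ai:
                for eps0 in (-3.0, 0.0, 4.5):
                    starts.append([l10ka, l10ki, eps0, 0.05])
            else:
                starts.append([l10ka, l10ki, 0.05])
    ball = np.array([0.05, 0.05, 0.1, 0.005] if fit_eps_ai
                    else [0.05, 0.05, 0.005])
    x0 = _map_ball_init(log_prob, np.asarray(starts), ball,
                        settings.n_walkers, rng)

    post = _run_ensemble(log_prob, x0, names, settings, seed)

    for name in ("log10_ka", "log10_ki"):
        d = post.get(name)
        pile = max(np.mean(d > hi - 0.2), np.mean(d < lo + 0.2))
        if pile > 0.05:
            warnings.warn(
                f"{name}: {100 * pile:.0f}% of posterior mass within 0.2 of a "
                "prior bound; the data constrain only a one-sided limit for "
                "this dissociation constant", ConvergenceWarning)
    return post


# ---------------------------------------------------------------------------
# Per-condition fold-change moments and empirical free energy
# ---------------------------------------------------------------------------

def infer_fold_change_moments(replicates: Sequence[float],
                              seed: int = 0,
                              n_draws: int = 4000,
                              method: str = "exact",
                              mcmc_settings: Optional[MCMCSettings] = None,
                              ) -> FoldChangeMoments:
    """Posterior over the mean mu and SD sigma of one condition's
    replicated fold-change measurements.

    With ``method='exact'`` (default) draws come from the closed-form
    posterior under the Jeffreys reference prior p(mu, sigma^2) ∝ 1/sigma^2:
    sigma^2 is scaled-inverse-chi-squared with n-1 degrees of freedom and
    mu | sigma is Gaussian around the sample mean.  ``method='emcee'`` runs
    the ensemble sampler on the same posterior as a cross-check.

    Censoring flags are set from the posterior medians (the rule's
    estimator is a design choice): ``censored_low`` when median(mu) <
    median(sigma), ``censored_high`` when 1 - median(mu) < median(sigma).
    """
    y = np.asarray(replicates, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 replicates to infer moments")
    ybar = float(np.mean(y))
    s2 = float(np.var(y, ddof=1))
    if s2 == 0.0:
        raise ValueError("replicates have zero variance; likelihood is degenerate")

    if method == "exact":
        rng = np.random.default_rng(seed)
        sigma2 = (n - 1) * s2 / rng.chisquare(n - 1, size=n_draws)
        sigma = np.sqrt(sigma2)
        mu = ybar + sigma / np.sqrt(n) * rng.standard_normal(n_draws)
    elif method == "emcee":
        settings = mcmc_settings or MCMCSettings(n_walkers=16, n_warmup=300,
                                                 n_steps=250)

        def log_prob(theta: np.ndarray) -> np.ndarray:
            m, s = theta[:, 0], theta[:, 1]
            out = np.full(theta.shape[0], -np.inf)
            ok = s > 0
            ss = s[ok]
            out[ok] = (-0.5 * np.sum((y[None, :] - m[ok, None]) ** 2, axis=1)
                       / ss ** 2 - (n + 1) * np.log(ss))
            return out

        rng = np.random.default_rng(seed)
        x0 = np.column_stack([
            ybar + np.sqrt(s2 / n) * rng.standard_normal(settings.n_walkers),
            np.sqrt(s2) * np.abs(1 + 0.2 * rng.standard_normal(settings.n_walkers)),
        ])
        post = _run_ensemble(log_prob, x0, ["mu", "sigma"], settings, seed)
        mu, sigma = post.get("mu"), post.get("sigma")
    else:
        raise ValueError(f"unknown method {method!r}")

    med_mu = float(np.median(mu))
    med_sigma = float(np.median(sigma))
    return FoldChangeMoments(mu=mu, sigma=sigma,
                             censored_low=med_mu < med_sigma,
                             censored_high=(1.0 - med_mu) < med_sigma,
                             n_replicates=n)


def infer_empirical_F(moments: FoldChangeMoments, mass: float = 0.95) -> FPosterior:
    """Map mu draws through ``F = log(mu/(1-mu))`` to a free-energy posterior.

    Draws with mu outside (0, 1) carry no free energy and are dropped (and
    counted); the censoring flag of the input condition propagates so that
    downstream ΔF profiles can exclude detection-limit points.  If no draw
    survives, the result is fully censored with no value.
    """
    mu = moments.mu
    valid = (mu > 0.0) & (mu < 1.0)
    n_dropped = int(mu.size - valid.sum())
    if valid.sum() == 0:
        return FPosterior(f_draws=np.empty(0), median=np.nan, lower=np.nan,
                          upper=np.nan, censored=True, n_dropped=n_dropped)
    f = logit(mu[valid])
    lower, upper = credible_interval(f, mass)
    return FPosterior(f_draws=f, median=float(np.median(f)), lower=lower,
                      upper=upper, censored=moments.censored,
                      n_dropped=n_dropped)


def credible_interval(draws: Sequence[float], mass: float = 0.95
                      ) -> tuple[float, float]:
    """Central credible interval (equal tail mass) from posterior draws."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("no draws")
    if not (0 < mass < 1):
        raise ValueError("mass must be in (0, 1)")
    alpha = (1.0 - mass) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
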