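"""Thermodynamic model of the inducible simple-repression motif.

The model describes a promoter whose expression is repressed by an
allosteric transcription factor (the canonical example being LacI in
*E. coli*).  The repressor switches between an active (DNA-binding) and an
inactive conformation in the Monod-Wyman-Changeux sense; an inducer such
as IPTG binds each conformation with its own dissociation constant and
thereby shifts the conformational equilibrium.

All energies are carried in units of kBT, so the thermodynamic beta is
identically 1 and no temperature parameter appears anywhere.

The central quantities are

``fold_change``
    expression of the regulated promoter relative to an unregulated one,

``pact``
    the equilibrium probability that a repressor is in the active state at
    inducer concentration ``c``,

``bohr_free_energy``
    the Bohr parameter F, the effective free-energy difference between the
    repressor-bound and unbound promoter states.  Every combination of
    parameters collapses onto a single logistic master curve
    ``fold_change = (1 + exp(-F))**-1``,

``delta_F``
    the shift in Bohr parameter caused by a mutation, which decomposes
    additively into an allosteric term, a repressor-copy-number term and a
    DNA-binding-energy term.  The shape of ``delta_F(c)`` is diagnostic of
    which biophysical parameters a mutation perturbs.

All functions broadcast over numpy arrays of concentrations and are exact
at ``c = 0`` (no epsilon offset is needed; the expressions reduce
algebraically).  Exponentials are evaluated through log-space
rearrangements so conformational or binding energies of magnitude up to
several hundred kBT do not overflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Union

import numpy as np
from scipy.special import expit, logit

__all__ = [
    "N_NS_DEFAULT",
    "OPERATOR_ENERGIES",
    "AllostericParams",
    "RepressorContext",
    "Energy",
    "WT_ALLOSTERIC",
    "wild_type_context",
    "pact",
    "log_pact",
    "fold_change",
    "bohr_free_energy",
    "fermi_fold_change",
    "empirical_free_energy",
    "DeltaFDecomposition",
    "delta_F",
    "SaturationDeltaF",
    "saturation_delta_F",
]

#: Number of nonspecific repressor binding sites; the E. coli genome length
#: in base pairs, each position being a potential nonspecific site.
N_NS_DEFAULT = 4.6e6

#: DNA binding energies (kBT) of the wild-type Lac repressor to the three
#: natural operator sequences, relative to the nonspecific background.
OPERATOR_ENERGIES = {"O1": -15.3, "O2": -13.9, "O3": -9.7}

#: Free energy in kBT units (beta == 1 by convention).
Energy = float

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class AllostericParams:
    """Allosteric (MWC) parameters of a repressor.

    Parameters
    ----------
    ka :
        Dissociation constant of the inducer to the *active* repressor
        conformation, in μM.
    ki :
        Dissociation constant of the inducer to the *inactive* conformation,
        in μM.
    eps_ai :
        Free-energy difference between the active and inactive
        conformations in the absence of inducer, in kBT.  Positive values
        favour the active (repressing) state.
    n_sites :
        Number of inducer binding sites per repressor (2 for the LacI
        tetramer's functional dimer).
    """

    ka: float
    ki: float
    eps_ai: float
    n_sites: int = 2

    def __post_init__(self) -> None:
        if not (self.ka > 0):
            raise ValueError(f"ka must be positive, got {self.ka}")
        if not (self.ki > 0):
            raise ValueError(f"ki must be positive, got {self.ki}")
        if not math.isfinite(self.eps_ai):
            raise ValueError("eps_ai must be finite")
        if int(self.n_sites) != self.n_sites or self.n_sites < 1:
            raise ValueError(f"n_sites must be a positive integer, got {self.n_sites}")

    def evolve(self, **changes) -> "AllostericParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass(frozen=True)
class RepressorContext:
    """Cellular context of one strain/operator pair.

    Parameters
    ----------
    r_total :
        Total repressors per cell, R (active plus inactive).
    eps_ra :
        Repressor-operator binding energy ΔεRA in kBT, relative to the
        nonspecific genomic background (more negative = tighter binding).
    n_ns :
        Number of nonspecific binding sites competing for repressor.
    operator_name :
        Label for the operator sequence (e.g. "O1", "O2", "O3").
    """

    r_total: float
    eps_ra: float
    n_ns: float = N_NS_DEFAULT
    operator_name: str = ""

    def __post_init__(self) -> None:
        if self.r_total < 0:
            raise ValueError(f"r_total must be >= 0, got {self.r_total}")
        if not (self.n_ns >= 1):
            raise ValueError(f"n_ns must be >= 1, got {self.n_ns}")
        if not math.isfinite(self.eps_ra):
            raise ValueError("eps_ra must be finite")

    def evolve(self, **changes) -> "RepressorContext":
        return replace(self, **changes)


#: Wild-type LacI allosteric parameters (KA = 139 μM, KI = 0.53 μM,
#: ΔεAI = 4.5 kBT, two inducer binding sites).
WT_ALLOSTERIC = AllostericParams(ka=139.0, ki=0.53, eps_ai=4.5, n_sites=2)


def wild_type_context(operator: str = "O2", r_total: float = 260.0,
                      n_ns: float = N_NS_DEFAULT) -> RepressorContext:
    """Context for a wild-type strain with a natural operator.

    Defaults to the O2 operator with ~260 repressors per cell, the strain
    used as the fitting reference throughout.
    """
    return RepressorContext(r_total=r_total, eps_ra=OPERATOR_ENERGIES[operator],
                            n_ns=n_ns, operator_name=operator)


# ---------------------------------------------------------------------------
# Active-state probability
# ---------------------------------------------------------------------------

def _check_concentration(c: ArrayLike) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("inducer concentration must be >= 0")
    return c


def _log_pact_arrays(c: np.ndarray, ka: ArrayLike, ki: ArrayLike,
                     eps_ai: ArrayLike, n_sites: ArrayLike) -> np.ndarray:
    """log pact(c), broadcasting over all arguments.

    Computed as ``log_a - logaddexp(log_a, log_i)`` with
    ``log_a = n log(1 + c/KA)`` and ``log_i = -ΔεAI + n log(1 + c/KI)``, so
    the result stays finite for |ΔεAI| up to hundreds of kBT.
    """
    log_a = n_sites * np.log1p(c / ka)
    log_i = -np.asarray(eps_ai, dtype=float) + n_sites * np.log1p(c / ki)
    return log_a - np.logaddexp(log_a, log_i)


def log_pact(c: ArrayLike, p: AllostericParams) -> ArrayLike:
    """Natural log of the active-state probability (overflow-safe)."""
    c = _check_concentration(c)
    out = _log_pact_arrays(c, p.ka, p.ki, p.eps_ai, p.n_sites)
    return out if out.ndim else float(out)


def pact(c: ArrayLike, p: AllostericParams) -> ArrayLike:
    """Probability that a repressor is in the active (DNA-binding) state.

    ``pact = (1 + c/KA)^n / [(1 + c/KA)^n + exp(-ΔεAI) (1 + c/KI)^n]``

    At ``c = 0`` this reduces exactly to ``1 / (1 + exp(-ΔεAI))``; for
    finite ΔεAI the value lies strictly inside (0, 1).
    """
    out = np.exp(log_pact(c, p))
    return out if isinstance(out, np.ndarray) else float(out)


# ---------------------------------------------------------------------------
# Fold change and the Bohr parameter
# ---------------------------------------------------------------------------

def _log_occupancy(c: np.ndarray, p: AllostericParams,
                   ctx: RepressorContext) -> np.ndarray:
    # log of pact * R / NNS * exp(-eps_ra); -inf when R == 0
    with np.errstate(divide="ignore"):
        log_r = np.log(ctx.r_total / ctx.n_ns)
    return _log_pact_arrays(c, p.ka, p.ki, p.eps_ai, p.n_sites) + log_r - ctx.eps_ra


def fold_change(c: ArrayLike, p: AllostericParams, ctx: RepressorContext) -> ArrayLike:
    """Fold change in gene expression relative to an unregulated promoter.

    ``fold_change = (1 + pact(c) R / NNS * exp(-ΔεRA))**-1``

    Lies in (0, 1] for R >= 0 and equals exactly 1 for R = 0.
    """
    c = _check_concentration(c)
    out = expit(-_log_occupancy(c, p, ctx))
    return out if out.ndim else float(out)


def bohr_free_energy(c: ArrayLike, p: AllostericParams,
                     ctx: RepressorContext) -> ArrayLike:
    """Bohr parameter F in kBT: ``F = -log pact(c) - log(R/NNS) + ΔεRA``.

    The identity ``fold_change(c) == fermi_fold_change(F)`` holds to
    floating-point precision.  F diverges as R -> 0, so a zero repressor
    count raises.
    """
    if ctx.r_total == 0:
        raise ValueError("free energy is undefined for r_total = 0 "
                         "(unregulated promoter)")
    c = _check_concentration(c)
    out = -_log_occupancy(c, p, ctx)
    return out if out.ndim else float(out)


def fermi_fold_change(F: ArrayLike) -> ArrayLike:
    """Master-curve (logistic/Fermi) map from Bohr parameter to fold change.

    ``fold_change = (1 + exp(-F))**-1``; strictly increasing in F with
    range (0, 1).
    """
    out = expit(np.asarray(F, dtype=float))
    return out if out.ndim else float(out)


def empirical_free_energy(fc: ArrayLike) -> ArrayLike:
    """Invert the master curve: ``F = log(fc / (1 - fc))`` in kBT.

    Only defined for fold change strictly inside (0, 1); measurements at or
    beyond the bounds must be censored by the caller (see the inference
    module's censoring rule).
    """
    fc = np.asarray(fc, dtype=float)
    if np.any(fc <= 0) or np.any(fc >= 1):
        raise ValueError("empirical free energy requires 0 < fold_change < 1; "
                         "censor out-of-support values first")
    out = logit(fc)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Free-energy shifts between a mutant and a reference (wild-type) strain
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeltaFDecomposition:
    """Additive decomposition of a free-energy shift ΔF (all kBT).

    ``total`` is computed as ``allosteric + copy_number + dna`` in exactly
    that left-to-right order, so the decomposition identity is exact in
    floating point.
    """

    allosteric: ArrayLike
    copy_number: float
    dna: float

    @property
    def total(self) -> ArrayLike:
        return (self.allosteric + self.copy_number) + self.dna


def delta_F(c: ArrayLike,
            mut: tuple[AllostericParams, RepressorContext],
            wt: tuple[AllostericParams, RepressorContext]) -> DeltaFDecomposition:
    """Shift in Bohr parameter caused by a mutation, term by term.

    ``ΔF = -log(pact_mut/pact_wt) - log(R_mut/R_wt) + (ΔεRA_mut - ΔεRA_wt)``

    The three terms isolate allosteric, copy-number and DNA-binding
    perturbations; ``total`` equals ``bohr_free_energy(mut) -
    bohr_free_energy(wt)`` to floating-point precision.  Both strains must
    share the nonspecific background NNS (otherwise a fourth term would
    appear) and have at least one repressor.
    """
    p_mut, ctx_mut = mut
    p_wt, ctx_wt = wt
    if ctx_mut.r_total == 0 or ctx_wt.r_total == 0:
        raise ValueError("delta_F undefined when either strain has r_total = 0")
    if ctx_mut.n_ns != ctx_wt.n_ns:
        raise ValueError("delta_F decomposition assumes a shared nonspecific "
                         "background n_ns")
    c = _check_concentration(c)
    allo = -(_log_pact_arrays(c, p_mut.ka, p_mut.ki, p_mut.eps_ai, p_mut.n_sites)
             - _log_pact_arrays(c, p_wt.ka, p_wt.ki, p_wt.eps_ai, p_wt.n_sites))
    copy = -math.log(ctx_mut.r_total / ctx_wt.r_total)
    dna = ctx_mut.eps_ra - ctx_wt.eps_ra
    allo = allo if allo.ndim else float(allo)
    return DeltaFDecomposition(allosteric=allo, copy_number=copy, dna=dna)


@dataclass(frozen=True)
class SaturationDeltaF:
    """Saturating-inducer limit of the allosteric ΔF term (kBT).

    ``eps_ai_shared`` is False when the two parameter sets differ in
    ΔεAI, in which case ``value`` is the full limit (the simple
    "returns to zero when KA/KI is preserved" rule no longer applies).
    """

    value: Energy
    eps_ai_shared: bool


def saturation_delta_F(mut: AllostericParams, wt: AllostericParams) -> SaturationDeltaF:
    """Closed-form limit of the allosteric ΔF term as c -> infinity.

    As the inducer saturates, ``pact -> (1 + exp(-ΔεAI) (KA/KI)^n)**-1``, so

    ``ΔF_allosteric(∞) = log(1 + e^(-ΔεAI_mut) (KA/KI)_mut^n)
                       - log(1 + e^(-ΔεAI_wt)  (KA/KI)_wt^n)``

    which vanishes when the mutation preserves both the KA/KI ratio and
    ΔεAI — the signature that lets a nonmonotonic ΔF(c) profile return to
    zero at saturation.
    """
    if mut.n_sites != wt.n_sites:
        raise ValueError("saturation limit assumes equal n_sites")

    def _neg_log_pact_inf(p: AllostericParams) -> float:
        return float(np.logaddexp(0.0, -p.eps_ai + p.n_sites * math.log(p.ka / p.ki)))

    shared = mut.eps_ai == wt.eps_ai
    value = _neg_log_pact_inf(mut) - _neg_log_pact_inf(wt)
    if shared and math.isclose(mut.ka / mut.ki, wt.ka / wt.ki,
                               rel_tol=0.0, abs_tol=0.0):
        value = 0.0
    return SaturationDeltaF(value=value, eps_ai_shared=shared)
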