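"""Seeded synthetic fold-change datasets for the simple-repression motif.

Emulates the structure of a flow-cytometry induction experiment: a 12-point
IPTG ladder (0 then log-spaced up to 5 mM), the three natural operators,
repressor copy numbers spanning more than an order of magnitude, and
Gaussian replicate noise on the fold change.  Replicate values are *not*
clipped to [0, 1] — real measurement noise produces values slightly outside
the physical range, and the downstream censoring logic depends on seeing
them.

The generator and the inference module share one noise model (homoscedastic
Gaussian around the thermodynamic model's fold change), so parameter
recovery on generated data is a well-posed test of the inference machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core_model import (
    N_NS_DEFAULT,
    OPERATOR_ENERGIES,
    AllostericParams,
    RepressorContext,
    WT_ALLOSTERIC,
    fold_change,
)

__all__ = [
    "DATASET_COLUMNS",
    "ExperimentDesign",
    "StrainTruth",
    "default_design",
    "generate_induction_dataset",
    "perturb_parameters",
    "wild_type_strains",
    "MUTATION_CLASSES",
]

#: Canonical column order of a tidy induction dataset (one replicate per row).
DATASET_COLUMNS = [
    "strain_id",
    "mutant_class_truth",
    "operator_name",
    "r_total",
    "iptg_uM",
    "replicate_id",
    "fold_change",
]

#: Parameter classes a point mutation may perturb, used to label fixtures
#: for the ΔF-shape classifier.
MUTATION_CLASSES = ("dna", "copy_number", "ka_ki_only", "allosteric_full")


@dataclass(frozen=True)
class StrainTruth:
    """Ground-truth parameters of one simulated strain."""

    params: AllostericParams
    context: RepressorContext
    mutant_class_truth: Optional[str] = None


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout of a simulated induction experiment.

    ``iptg_ladder`` is the inducer concentration grid in μM (ascending; a
    leading 0 represents the leakiness condition).  ``noise_sd`` is the
    replicate-level Gaussian SD on fold change.
    """

    iptg_ladder: tuple[float, ...]
    operators: tuple[tuple[str, float], ...]
    copy_numbers: tuple[float, ...]
    n_replicates: int = 10
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        ladder = tuple(self.iptg_ladder)
        if len(ladder) == 0:
            raise ValueError("iptg_ladder must be non-empty")
        if any(c < 0 for c in ladder):
            raise ValueError("iptg_ladder concentrations must be >= 0")
        if list(ladder) != sorted(ladder):
            raise ValueError("iptg_ladder must be sorted ascending")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not (self.noise_sd > 0):
            raise ValueError("noise_sd must be > 0")


def default_design() -> ExperimentDesign:
    """The study-standard design.

    Twelve IPTG concentrations — 0, then eleven log-spaced points from
    10^-2 to 5x10^3 μM — measured for the three natural operators, four
    repressor copy numbers spanning ~20x, with 10 biological replicates per
    condition and replicate noise SD 0.05 on the fold change.
    """
    ladder = (0.0,) + tuple(np.logspace(-2, np.log10(5000.0), 11))
    return ExperimentDesign(
        iptg_ladder=ladder,
        operators=tuple(sorted(OPERATOR_ENERGIES.items())),
        copy_numbers=(60.0, 124.0, 260.0, 1220.0),
        n_replicates=10,
        noise_sd=0.05,
    )


def generate_induction_dataset(truth: Mapping[str, StrainTruth],
                               design: ExperimentDesign,
                               seed: int) -> pd.DataFrame:
    """Simulate a tidy replicated fold-change table.

    Each replicate fold change is drawn from
    ``Normal(fold_change(c; truth), design.noise_sd)`` with no clipping.
    The same seed always yields a byte-identical table.

    Parameters
    ----------
    truth :
        Mapping from strain id to its true parameters.  Iteration order
        (insertion order of the mapping) fixes the row order and the random
        stream, so reordering strains changes the draws but not their
        distribution.
    """
    if len(truth) == 0:
        raise ValueError("no strains to simulate")
    if len(design.iptg_ladder) == 0:
        raise ValueError("empty design")
    rng = np.random.default_rng(seed)
    conc = np.asarray(design.iptg_ladder, dtype=float)
    frames = []
    for strain_id, st in truth.items():
        mean_fc = np.asarray(fold_change(conc, st.params, st.context), dtype=float)
        noise = rng.normal(0.0, design.noise_sd,
                           size=(design.n_replicates, conc.size))
        values = mean_fc[None, :] + noise
        rep_id, conc_idx = np.meshgrid(np.arange(1, design.n_replicates + 1),
                                       np.arange(conc.size), indexing="ij")
        frames.append(pd.DataFrame({
            "strain_id": strain_id,
            "mutant_class_truth": st.mutant_class_truth,
            "operator_name": st.context.operator_name,
            "r_total": st.context.r_total,
            "iptg_uM": conc[conc_idx.ravel()],
            "replicate_id": rep_id.ravel(),
            "fold_change": values.ravel(),
        }))
    df = pd.concat(frames, ignore_index=True)[DATASET_COLUMNS]
    return df


def perturb_parameters(wt: tuple[AllostericParams, RepressorContext],
                       mutation_class: str,
                       magnitude: float,
                       seed: int) -> tuple[AllostericParams, RepressorContext]:
    """Construct a mutant truth differing from ``wt`` only in one class
    of parameters.

    ``magnitude`` is an effect size in kBT-equivalent units:

    - ``dna``: ΔεRA is shifted by exactly ``magnitude`` (the ΔF it induces).
    - ``copy_number``: R is multiplied by ``exp(-magnitude)``, so the
      copy-number ΔF term equals ``magnitude``.
    - ``ka_ki_only``: KA and KI are each multiplied by ``exp(m_a)`` and
      ``exp(m_i)`` with ``m ~ magnitude * Uniform(0.5, 1.5)`` — both binding
      constants weaken, as observed for real inducer-binding mutants, and
      generically with different factors so the KA/KI ratio changes.
    - ``allosteric_full``: a drop in ΔεAI of ``magnitude * Uniform(3, 5)``
      kBT — the scale real conformational-equilibrium mutants show —
      together with a milder binding-constant drift
      (``m ~ 0.3 * magnitude * Uniform(0.5, 1.5)`` on each of KA, KI).
      The inactive state becomes markedly more favourable, raising the
      leakiness, while the strain stays inducible inside the measurable
      window.

    The seed controls only the random factors of the two allosteric
    classes; ``dna`` and ``copy_number`` perturbations are deterministic.
    """
    p_wt, ctx_wt = wt
    rng = np.random.default_rng(seed)
    if mutation_class == "dna":
        return p_wt, ctx_wt.evolve(eps_ra=ctx_wt.eps_ra + magnitude)
    if mutation_class == "copy_number":
        return p_wt, ctx_wt.evolve(r_total=ctx_wt.r_total * np.exp(-magnitude))
    if mutation_class == "ka_ki_only":
        fa, fi = np.exp(magnitude * rng.uniform(0.5, 1.5, size=2))
        return p_wt.evolve(ka=p_wt.ka * fa, ki=p_wt.ki * fi), ctx_wt
    if mutation_class == "allosteric_full":
        fa, fi = np.exp(0.3 * magnitude * rng.uniform(0.5, 1.5, size=2))
        d_eps = magnitude * rng.uniform(3.0, 5.0)
        return (p_wt.evolve(ka=p_wt.ka * fa, ki=p_wt.ki * fi,
                            eps_ai=p_wt.eps_ai - d_eps), ctx_wt)
    raise ValueError(
        f"unknown mutation class {mutation_class!r}; expected one of {MUTATION_CLASSES}")


def wild_type_strains(design: ExperimentDesign,
                      params: AllostericParams = WT_ALLOSTERIC,
                      n_ns: float = N_NS_DEFAULT) -> dict[str, StrainTruth]:
    """Wild-type strain truths for every operator x copy-number combination
    in the design, keyed ``wt_<operator>_R<copies>``."""
    strains: dict[str, StrainTruth] = {}
    for name, eps_ra in design.operators:
        for r in design.copy_numbers:
            ctx = RepressorContext(r_total=r, eps_ra=eps_ra, n_ns=n_ns,
                                   operator_name=name)
            strains[f"wt_{name}_R{int(round(r))}"] = StrainTruth(
                params=params, context=ctx, mutant_class_truth=None)
    return strains
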