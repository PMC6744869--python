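"""ΔF profiles, mutation classification and master-curve collapse.

The shape of the free-energy shift ΔF(c) between a mutant and its matched
wild-type strain (same operator, same repressor copy number) is diagnostic
of which biophysical parameters the mutation perturbs:

- a ΔF that is constant in inducer concentration points to the
  DNA-binding energy or the repressor copy number (the two
  concentration-independent terms of the decomposition);
- ΔF(0) = 0 with concentration dependence points to the inducer
  dissociation constants KA, KI alone — at zero inducer they drop out of
  the active-state probability entirely;
- ΔF(0) != 0 with concentration dependence implicates the conformational
  energy gap ΔεAI (alone or together with KA, KI), since it is the lone
  parameter setting the leakiness;
- nonmonotonicity of ΔF(c) can only arise from changes to KA and KI.

All constancy / zero tests are interval tests on 95% credible bounds, not
point comparisons, mirroring how overlapping credible regions are read off
an induction figure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core_model import (
    AllostericParams,
    RepressorContext,
    bohr_free_energy,
    fermi_fold_change,
)
from .inference import FPosterior, credible_interval

__all__ = [
    "DeltaFProfile",
    "MutantClass",
    "delta_F_profile",
    "detect_nonmonotonicity",
    "classify_mutation",
    "collapse_dataset",
    "plot_delta_f_profile",
    "plot_collapse",
]

PROFILE_COLUMNS = ["iptg_uM", "delta_f_median", "delta_f_lower",
                   "delta_f_upper", "censored"]


@dataclass
class DeltaFProfile:
    """Per-concentration inferred ΔF with credible bounds.

    ``table`` has one row per concentration with columns ``iptg_uM``,
    ``delta_f_median``, ``delta_f_lower``, ``delta_f_upper`` (kBT) and a
    boolean ``censored``; censored rows carry NaN in the value columns.
    ``reference`` records the (operator, r_total) of the matched wild-type
    strain.
    """

    table: pd.DataFrame
    reference: tuple[str, float]

    @property
    def uncensored(self) -> pd.DataFrame:
        return self.table.loc[~self.table["censored"]]

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["reference_operator"] = self.reference[0]
        out["reference_r_total"] = self.reference[1]
        out.to_csv(path, index=False)


@dataclass(frozen=True)
class MutantClass:
    """Classifier verdict with the evidence it rests on.

    ``label`` is one of ``dna_or_copy_number``, ``ka_ki_only``,
    ``epsai_involved``, ``no_change``, ``unclassifiable``.  The decision
    table (evaluated top-down on the evidence booleans):

    1. every interval covers 0                      -> no_change
    2. all intervals share a common constant (!= 0) -> dna_or_copy_number
    3. varies with c, ΔF at smallest c covers 0     -> ka_ki_only
    4. varies with c, ΔF at smallest c excludes 0   -> epsai_involved
    """

    label: str
    constant: bool
    zero_at_zero: bool
    nonmonotonic: Optional[bool]


def delta_F_profile(mut_F: Mapping[float, FPosterior],
                    wt_F: Mapping[float, FPosterior],
                    reference: tuple[str, float] = ("", np.nan),
                    n_draws: int = 10_000,
                    seed: int = 0,
                    mass: float = 0.95) -> DeltaFProfile:
    """ΔF(c) = F_mut(c) - F_wt(c) from two per-concentration F posteriors.

    The mutant and wild-type experiments are independent, so ΔF draws are
    formed by differencing independent bootstrap resamples (with
    replacement) of the two posteriors.  A concentration is censored — and
    carries no ΔF value — if either input is censored or empty.
    """
    c_mut = sorted(mut_F)
    c_wt = sorted(wt_F)
    if c_mut != c_wt:
        raise ValueError("mutant and wild-type concentration grids differ")
    rng = np.random.default_rng(seed)
    rows = []
    for c in c_mut:
        fm, fw = mut_F[c], wt_F[c]
        if fm.censored or fw.censored or fm.f_draws.size == 0 or fw.f_draws.size == 0:
            rows.append((c, np.nan, np.nan, np.nan, True))
            continue
        d = (rng.choice(fm.f_draws, size=n_draws, replace=True)
             - rng.choice(fw.f_draws, size=n_draws, replace=True))
        lo, hi = credible_interval(d, mass)
        rows.append((c, float(np.median(d)), lo, hi, False))
    table = pd.DataFrame(rows, columns=PROFILE_COLUMNS)
    return DeltaFProfile(table=table, reference=reference)


def detect_nonmonotonicity(profile: DeltaFProfile, tol: float = 0.2) -> bool:
    """True iff the ΔF median changes direction along the ladder.

    Successive differences of the uncensored medians (in concentration
    order) smaller than ``tol`` kBT are ignored; the profile is
    nonmonotonic iff the remaining differences change sign at least once.
    """
    med = profile.uncensored.sort_values("iptg_uM")["delta_f_median"].to_numpy()
    if med.size < 4:
        raise ValueError("need at least 4 uncensored points to assess "
                         "monotonicity")
    diffs = np.diff(med)
    signs = np.sign(diffs[np.abs(diffs) > tol])
    return bool(signs.size >= 2 and np.any(signs[1:] != signs[:-1]))


def classify_mutation(profile: DeltaFProfile, tol: float = 0.2) -> MutantClass:
    """Assign a parameter class to a mutation from its ΔF(c) signature.

    Interval logic on the 95% credible bounds (see :class:`MutantClass`
    for the decision table).  The leakiness test uses the smallest
    uncensored concentration; when the c = 0 point itself sits at a
    detection limit the next concentration stands in for it, which is
    faithful as long as that concentration is well below KA.  ``tol`` is
    only used for the nonmonotonicity evidence, which is reported but does
    not enter the decision table.
    """
    unc = profile.uncensored.sort_values("iptg_uM")
    if len(unc) == 0:
        raise ValueError("all points are censored; cannot classify")
    if len(unc) < 4:
        raise ValueError("need at least 4 uncensored points to classify")

    lo = unc["delta_f_lower"].to_numpy()
    hi = unc["delta_f_upper"].to_numpy()
    covers_zero_all = bool(np.all((lo <= 0) & (hi >= 0)))
    has_common = bool(np.max(lo) <= np.min(hi))
    zero_at_zero = bool(lo[0] <= 0 <= hi[0])
    nonmono: Optional[bool]
    try:
        nonmono = detect_nonmonotonicity(profile, tol)
    except ValueError:
        nonmono = None

    if covers_zero_all:
        label = "no_change"
    elif has_common:
        label = "dna_or_copy_number"
    elif zero_at_zero:
        label = "ka_ki_only"
    else:
        label = "epsai_involved"
    return MutantClass(label=label, constant=has_common,
                       zero_at_zero=zero_at_zero, nonmonotonic=nonmono)


def collapse_dataset(datasets: Sequence[pd.DataFrame],
                     per_strain_params: Mapping[str, tuple[AllostericParams,
                                                           RepressorContext]],
                     ) -> pd.DataFrame:
    """Collapse replicated measurements onto the Bohr master curve.

    For each (strain, concentration) the replicate-mean fold change is
    paired with the Bohr free energy computed from that strain's
    parameters; the residual is the departure from the logistic master
    curve, ``fold_change_mean - fermi_fold_change(F)``.  On correctly
    specified data residuals are mean-zero with SD ~ noise_sd/sqrt(n);
    a strain whose parameters are mis-specified sits systematically
    off-curve.
    """
    df = pd.concat(list(datasets), ignore_index=True)
    missing = sorted(set(df["strain_id"]) - set(per_strain_params))
    if missing:
        raise KeyError(f"no parameters supplied for strain(s): {missing}")
    grouped = (df.groupby(["strain_id", "iptg_uM"], sort=True)["fold_change"]
               .agg(["mean", "count"]).reset_index())
    f_vals = np.empty(len(grouped))
    for i, row in grouped.iterrows():
        p, ctx = per_strain_params[row["strain_id"]]
        f_vals[i] = bohr_free_energy(row["iptg_uM"], p, ctx)
    out = pd.DataFrame({
        "strain_id": grouped["strain_id"],
        "iptg_uM": grouped["iptg_uM"],
        "bohr_F": f_vals,
        "fold_change_mean": grouped["mean"],
        "n_replicates": grouped["count"],
    })
    out["residual"] = out["fold_change_mean"] - fermi_fold_change(out["bohr_F"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Optional figure export
# ---------------------------------------------------------------------------

def _symlog_axis(ax) -> None:
    # linear from 0 to 1e-2 uM, logarithmic above — the conventional way to
    # show a titration that includes the zero-inducer (leakiness) condition
    ax.set_xscale("symlog", linthresh=1e-2)
    ax.set_xlabel("IPTG (μM)")


def plot_delta_f_profile(profile: DeltaFProfile, path=None, ax=None):
    """ΔF vs inducer concentration with 95% credible bounds.

    Censored points are omitted.  Saves to ``path`` (format from the
    extension, e.g. .svg/.png) when given; returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    unc = profile.uncensored.sort_values("iptg_uM")
    ax.axhline(0.0, color="0.7", lw=1)
    ax.errorbar(unc["iptg_uM"], unc["delta_f_median"],
                yerr=[unc["delta_f_median"] - unc["delta_f_lower"],
                      unc["delta_f_upper"] - unc["delta_f_median"]],
                fmt="o", ms=4, capsize=2)
    _symlog_axis(ax)
    ax.set_ylabel(r"$\Delta F$ ($k_BT$)")
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
    return ax


def plot_collapse(collapsed: pd.DataFrame, path=None, ax=None):
    """Measured fold change against the Bohr free energy, with the
    logistic master curve overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    grid = np.linspace(collapsed["bohr_F"].min() - 1,
                       collapsed["bohr_F"].max() + 1, 200)
    ax.plot(grid, fermi_fold_change(grid), "k-", lw=1, label="master curve")
    for sid, grp in collapsed.groupby("strain_id"):
        ax.plot(grp["bohr_F"], grp["fold_change_mean"], "o", ms=4, label=sid)
    ax.set_xlabel(r"free energy $F$ ($k_BT$)")
    ax.set_ylabel("fold change")
    ax.legend(fontsize=6)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
    return ax
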