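"""Free-energy estimators surrounding the LIE pipeline.

* Peptide *preorganization* free energy: the cost of restricting an unbound
  peptide to its extended, binding-competent conformation, estimated from
  the fraction of MD frames spent folded:  ddG_I(i, j) = -kT ln(f_i / f_j).
* Batch-mean statistical uncertainty of a free energy component along a
  trajectory.
* Bennett Acceptance Ratio (BAR): the minimum-variance two-state free energy
  estimate from forward and reverse energy-difference samples.
* The error-decomposition identity separating model error from experimental
  and sampling noise: sigma_tot^2 = d_exp^2 + d_MD^2 + d_model^2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logsumexp

__all__ = [
    "BOLTZMANN_KCAL",
    "FoldedFractionRecord",
    "WorkSamples",
    "PreorgResult",
    "BARResult",
    "ZeroFoldedFractionError",
    "OverlapWarning",
    "preorg_ddg",
    "folded_fraction",
    "batch_uncertainty",
    "combined_uncertainty",
    "bar",
    "error_decomposition",
]

#: Boltzmann constant in kcal/mol/K; kT = 0.5925 kcal/mol at 298.15 K.
BOLTZMANN_KCAL = 0.0019872041


class ZeroFoldedFractionError(ValueError):
    """A zero folded fraction makes the preorganization free energy infinite."""


class OverlapWarning(UserWarning):
    """Forward/reverse work distributions barely overlap; BAR is unreliable."""


@dataclass(frozen=True)
class FoldedFractionRecord:
    """Folded (extended-conformation) fractions of one unbound peptide.

    One fraction per independent MD run, each in [0, 1].
    """

    peptide_id: str
    fractions_per_run: tuple[float, ...]
    n_frames_per_run: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.fractions_per_run) < 1:
            raise ValueError(f"{self.peptide_id}: at least one run required")
        for f in self.fractions_per_run:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{self.peptide_id}: fraction {f} outside [0, 1]")


@dataclass(frozen=True)
class PreorgResult:
    ddg: float
    uncertainty: float


@dataclass(frozen=True)
class WorkSamples:
    """Forward and reverse energy-difference samples for BAR (kcal/mol).

    ``forward`` holds U(lambda') - U(lambda) evaluated on configurations of
    the lambda ensemble; ``reverse`` holds U(lambda) - U(lambda') from the
    lambda' ensemble.
    """

    forward: np.ndarray
    reverse: np.ndarray
    temperature: float = 298.15

    def __post_init__(self) -> None:
        object.__setattr__(self, "forward", np.asarray(self.forward, dtype=float))
        object.__setattr__(self, "reverse", np.asarray(self.reverse, dtype=float))
        if self.forward.size == 0 or self.reverse.size == 0:
            raise ValueError("both forward and reverse samples are required")


@dataclass(frozen=True)
class BARResult:
    delta_g: float
    uncertainty: float


# --------------------------------------------------------------------------
# Preorganization free energy
# --------------------------------------------------------------------------

def preorg_ddg(
    rec_i: FoldedFractionRecord,
    rec_ref: FoldedFractionRecord,
    temperature: float = 298.15,
    run_average: str = "log",
) -> PreorgResult:
    """Preorganization free energy of peptide i relative to a reference.

    ddG_I = -kT ln(f_i / f_ref), with the run-to-run averaging controlled by
    ``run_average``: ``"log"`` (default) averages ln f over runs before the
    ratio -- equivalently the mean of -kT ln(f_i^a / f_ref^b) over all run
    pairings, which reproduces the published duplicate-run tables --
    ``"linear"`` averages the fractions arithmetically first.  The
    uncertainty is the half-range of -kT ln(f_i^a / f_ref^b) over all run
    pairings (zero when either peptide has a single run equal to the other's).
    """
    if run_average not in {"log", "linear"}:
        raise ValueError(f"unknown run_average {run_average!r}")
    kT = BOLTZMANN_KCAL * temperature
    fi = np.asarray(rec_i.fractions_per_run, dtype=float)
    fj = np.asarray(rec_ref.fractions_per_run, dtype=float)
    for rec, f in ((rec_i, fi), (rec_ref, fj)):
        if np.any(f <= 0.0):
            raise ZeroFoldedFractionError(
                f"peptide {rec.peptide_id!r}: zero folded fraction gives an "
                "infinite preorganization free energy"
            )
    if run_average == "log":
        ddg = -kT * (np.mean(np.log(fi)) - np.mean(np.log(fj)))
    else:
        ddg = -kT * math.log(fi.mean() / fj.mean())
    combos = -kT * (np.log(fi)[:, None] - np.log(fj)[None, :])
    unc = float((combos.max() - combos.min()) / 2.0)
    return PreorgResult(ddg=float(ddg), uncertainty=unc)


def folded_fraction(
    traj,
    peptide_id: str = "",
) -> FoldedFractionRecord:
    """Fraction of trajectory frames in the bound (extended) conformation.

    ``traj`` is a sequence of frames, each a set of five (phi, psi) pairs;
    frames are classified with
    :func:`pdzlie.energetics.is_bound_conformation`.
    """
    from .energetics import is_bound_conformation

    frames = list(traj)
    if len(frames) == 0:
        raise ValueError("trajectory has no frames")
    n_bound = sum(bool(is_bound_conformation(frame)) for frame in frames)
    return FoldedFractionRecord(
        peptide_id=peptide_id or "peptide",
        fractions_per_run=(n_bound / len(frames),),
        n_frames_per_run=(len(frames),),
    )


# --------------------------------------------------------------------------
# Batch-mean uncertainty
# --------------------------------------------------------------------------

def batch_uncertainty(series, batch_length: int) -> float:
    """Statistical uncertainty of a trajectory average by batch means.

    The series is split into N complete batches of ``batch_length`` frames
    (a trailing incomplete batch is dropped); the uncertainty is
    sqrt(var(batch means) / (N - 1)) with the population variance of the
    batch means -- i.e. the standard error of the mean over batches.
    """
    series = np.asarray(series, dtype=float)
    if batch_length < 1:
        raise ValueError("batch_length must be >= 1")
    n_batches = series.size // batch_length
    if n_batches < 2:
        raise ValueError("at least 2 complete batches are required")
    means = series[: n_batches * batch_length].reshape(n_batches, batch_length).mean(axis=1)
    return float(math.sqrt(np.var(means) / (n_batches - 1)))


def combined_uncertainty(sigma_a: float, sigma_b: float) -> float:
    """Uncertainty of a difference of two independent estimates."""
    return math.sqrt(sigma_a**2 + sigma_b**2)


# --------------------------------------------------------------------------
# Bennett Acceptance Ratio
# --------------------------------------------------------------------------

def _bar_objective(dg: float, wf: np.ndarray, wr: np.ndarray, beta: float) -> float:
    m = math.log(wf.size / wr.size)
    # log sum of Fermi functions on each side; root where the two sides match
    lf = logsumexp(-np.logaddexp(0.0, m + beta * (wf - dg)))
    lr = logsumexp(-np.logaddexp(0.0, -m + beta * (wr + dg)))
    return lf - lr


def bar(ws: WorkSamples) -> BARResult:
    """Bennett Acceptance Ratio free energy estimate.

    Solves the self-consistent acceptance-ratio equation

        sum_F fermi(beta (W_F - dG) + M) = sum_R fermi(beta (W_R + dG) - M),

    with M = ln(N_F / N_R), by bracketed root-finding seeded from the
    forward/reverse exponential averages.  The statistical uncertainty is
    the standard BAR asymptotic variance.  Emits :class:`OverlapWarning`
    when the work distributions barely overlap.
    """
    wf, wr = ws.forward, ws.reverse
    beta = 1.0 / (BOLTZMANN_KCAL * ws.temperature)
    m = math.log(wf.size / wr.size)

    # exponential-average seeds (numerically stable)
    dg_fwd = -(logsumexp(-beta * wf) - math.log(wf.size)) / beta
    dg_rev = (logsumexp(-beta * wr) - math.log(wr.size)) / beta
    lo, hi = sorted((dg_fwd, dg_rev))
    span = max(1.0, hi - lo)
    lo -= span
    hi += span
    for _ in range(60):
        if _bar_objective(lo, wf, wr, beta) * _bar_objective(hi, wf, wr, beta) <= 0:
            break
        lo -= span
        hi += span
        span *= 2.0
    else:
        raise RuntimeError("could not bracket the BAR root")
    if _bar_objective(lo, wf, wr, beta) == 0.0 and lo == hi:
        dg = lo
    else:
        dg = brentq(_bar_objective, lo, hi, args=(wf, wr, beta), xtol=1e-10)

    # asymptotic variance from the Fermi weights at the solution
    ff = expit(-(m + beta * (wf - dg)))
    fr = expit(-(-m + beta * (wr + dg)))
    overlap = min(ff.mean(), fr.mean())
    if overlap < 1e-6:
        warnings.warn(
            f"poor forward/reverse overlap (mean acceptance {overlap:.2e}); "
            "BAR estimate is unreliable",
            OverlapWarning,
        )
    var = (np.mean(ff**2) / np.mean(ff) ** 2 - 1.0) / ff.size + (
        np.mean(fr**2) / np.mean(fr) ** 2 - 1.0
    ) / fr.size
    return BARResult(delta_g=float(dg), uncertainty=float(math.sqrt(max(var, 0.0)) / beta))


# --------------------------------------------------------------------------
# Error decomposition
# --------------------------------------------------------------------------

def error_decomposition(
    sigma_tot: float, delta_exp: float, delta_md: float
) -> float:
    """Model error implied by the total rms deviation.

    Solves sigma_tot^2 = delta_exp^2 + delta_MD^2 + delta_model^2 for
    delta_model (kcal/mol); raises when the radicand is negative.
    """
    radicand = sigma_tot**2 - delta_exp**2 - delta_md**2
    if radicand < 0:
        raise ValueError(
            "inconsistent inputs: experimental and sampling errors exceed "
            "the total deviation"
        )
    return math.sqrt(radicand)
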