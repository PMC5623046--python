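"""Empirical significance and robustness checks for the LIE fit.

Two checks guard the three-parameter model against overfitting its 35
training observations:

* a *scrambled-data* ensemble, in which the experimental affinities are
  randomly reassigned among the complexes (the reference complexes stay
  pinned, since they define the relative free energy scale) and the
  coefficients are refit against each scrambled target vector -- the fraction
  of scrambled models that score worse than the real fit measures how
  unlikely the observed agreement is under label exchange;
* k-fold cross-validation, reporting pooled held-out errors and the spread
  of the per-fold coefficients.

Every scrambled refit is the exact closed-form least-squares solution of the
corrected linear model, so the ensemble lower-bounds nothing: each scrambled
model is the best achievable three-parameter model for its targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import Dataset, fitting_subset
from .lie import (
    FitReport,
    LIECoefficients,
    LIERegressor,
    design_matrix,
    fit_lie,
    fit_report,
)

__all__ = ["ScrambleResult", "CrossValReport", "scramble_ensemble", "crossval"]


@dataclass(frozen=True)
class ScrambleResult:
    """Outcome of a scrambled-data ensemble."""

    n_models: int
    fraction_worse: float
    fraction_strictly_better: float
    rmsd_samples: np.ndarray
    r_samples: np.ndarray
    reference_rmsd: float
    reference_r: float
    seed: int
    mode: str = "permute"


@dataclass(frozen=True)
class CrossValReport:
    """Pooled held-out and per-fold training statistics of k-fold CV."""

    k: int
    test_mue: float
    test_rmsd: float
    train_mue_mean: float
    train_mue_sd: float
    train_rmsd_mean: float
    train_rmsd_sd: float
    coeff_means: dict[str, float]
    coeff_sds: dict[str, float]
    seed: int
    test_report: FitReport | None = None


def _prepared(ds: Dataset):
    sub = fitting_subset(ds)
    if len(sub) == 0:
        raise ValueError("dataset has no fitting records")
    model = LIERegressor.from_dataset(ds)
    frame = sub.to_frame()
    D, offset, ids = design_matrix(frame, model.references, model.base_group)
    y = frame["exp_ddg"].to_numpy(dtype=float)
    return D, offset, y, ids


def scramble_ensemble(
    ds: Dataset,
    n_models: int,
    seed: int,
    reference_fit: FitReport | None = None,
    mode: str = "permute",
) -> ScrambleResult:
    """Refit the model against ``n_models`` scrambled target vectors.

    ``mode="permute"`` (default) draws a uniform random permutation of the
    experimental values over the complexes for each model; ``mode="resample"``
    draws them independently with replacement.  Reference complexes and their
    experimental values are never scrambled.  A scrambled model counts as
    *strictly better* when its rmsd is below the reference fit's rmsd **and**
    its Pearson R is above the reference fit's R; every other model (including
    ties and models with undefined R) counts as worse in at least one metric.

    Results are reproducible bit-for-bit from ``seed``.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    if mode not in {"permute", "resample"}:
        raise ValueError(f"unknown mode {mode!r}")
    D, offset, y, _ = _prepared(ds)
    if reference_fit is None:
        reference_fit = fit_lie(ds).report
    ref_rmsd = reference_fit.rmsd
    ref_r = reference_fit.pearson_r
    if ref_r is None:
        raise ValueError("reference fit has undefined Pearson R")

    rng = np.random.default_rng(seed)
    if mode == "permute":
        Y = rng.permuted(np.tile(y, (n_models, 1)), axis=1)
    else:
        Y = rng.choice(y, size=(n_models, y.size), replace=True)

    # closed-form refit of every scrambled model at once
    P = np.linalg.pinv(D)
    theta = (Y - offset) @ P.T
    pred = theta @ D.T + offset
    res = pred - Y
    rmsds = np.sqrt(np.mean(res**2, axis=1))
    yc = Y - Y.mean(axis=1, keepdims=True)
    pc = pred - pred.mean(axis=1, keepdims=True)
    denom = np.sqrt((yc**2).sum(axis=1) * (pc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rs = np.where(denom > 0, (yc * pc).sum(axis=1) / denom, np.nan)

    strictly_better = (rmsds < ref_rmsd) & (rs > ref_r)
    frac_better = float(np.mean(strictly_better))
    return ScrambleResult(
        n_models=n_models,
        fraction_worse=1.0 - frac_better,
        fraction_strictly_better=frac_better,
        rmsd_samples=rmsds,
        r_samples=rs,
        reference_rmsd=ref_rmsd,
        reference_r=ref_r,
        seed=seed,
        mode=mode,
    )


def crossval(ds: Dataset, k: int = 8, seed: int = 0) -> CrossValReport:
    """k-fold cross-validation of the LIE fit.

    Records are shuffled by ``seed`` and split into ``k`` near-equal folds
    (sizes differing by at most one).  For each fold the coefficients are
    refit on the remaining records and the fold is predicted; held-out
    residuals are pooled across folds.
    """
    D, offset, y, ids = _prepared(ds)
    n = y.size
    if not 2 <= k <= n:
        raise ValueError(f"k must be between 2 and the record count ({n})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)

    test_pred = np.empty(n)
    thetas, train_mues, train_rmsds = [], [], []
    for fold in folds:
        if fold.size == 0:
            raise ValueError("empty cross-validation fold")
        train = np.setdiff1d(order, fold)
        theta, *_ = np.linalg.lstsq(D[train], (y - offset)[train], rcond=None)
        thetas.append(theta)
        train_res = D[train] @ theta + offset[train] - y[train]
        train_mues.append(np.mean(np.abs(train_res)))
        train_rmsds.append(np.sqrt(np.mean(train_res**2)))
        test_pred[fold] = D[fold] @ theta + offset[fold]

    report = fit_report(y, test_pred, ids)
    thetas = np.array(thetas)
    names = ("alpha", "beta", "gamma")
    return CrossValReport(
        k=k,
        test_mue=report.mue,
        test_rmsd=report.rmsd,
        train_mue_mean=float(np.mean(train_mues)),
        train_mue_sd=float(np.std(train_mues, ddof=1)),
        train_rmsd_mean=float(np.mean(train_rmsds)),
        train_rmsd_sd=float(np.std(train_rmsds, ddof=1)),
        coeff_means={n_: float(m) for n_, m in zip(names, thetas.mean(axis=0))},
        coeff_sds={n_: float(s) for n_, s in zip(names, thetas.std(axis=0, ddof=1))},
        seed=seed,
        test_report=report,
    )
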