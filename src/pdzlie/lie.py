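"""The three-parameter linear interaction energy (LIE) binding model.

The relative binding free energy of a PDZ:peptide complex is scored as

    ddG = alpha * dE_vdW + beta * dG_elec + gamma * dA + E_restraint

where ``dE_vdW`` is the protein-peptide van der Waals interaction energy,
``dG_elec`` the continuum-electrostatic (PB) binding term, ``dA`` the change
in molecular surface on binding (Angstrom^2; gamma is expressed in
cal/mol/Angstrom^2 and divided by 1000 before the product), and
``E_restraint`` the mean restraint energy of the bound-state simulation.  No
intercept is fitted: the constant of the underlying ansatz cancels in
relative free energies.

Complexes scored against a secondary reference (here the quadruple-mutant
PDZ bound to Caspr4) receive an additive correction that pins the corrected
prediction of the reference complex to its experimental value:

    ddG'(X) = ddG(X) + [ddG_exp(ref) - ddG(ref)]

The corrected prediction remains affine in (alpha, beta, gamma), so the
rms-optimal coefficients are the exact solution of a three-parameter linear
least-squares problem; :class:`LIERegressor` solves it in closed form.  The
correction is recomputed from the current coefficients inside every fit, so
resampled or cross-validated refits stay self-consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .datasets import ComplexRecord, Dataset, fitting_subset, reference_records

__all__ = [
    "LIECoefficients",
    "FitReport",
    "LIERegressor",
    "LIEFit",
    "NullModel",
    "SingularDesignError",
    "ConfigurationError",
    "design_matrix",
    "predict_ddg",
    "fit_lie",
    "evaluate",
    "null_model",
    "fit_report",
]

#: conversion of the surface coefficient from cal/mol/A^2 to kcal/mol/A^2
CAL_TO_KCAL = 1.0e-3

COMPONENT_COLUMNS = ("vdw", "pb", "sa")


class SingularDesignError(ValueError):
    """Rank-deficient component matrix; message names the offending column."""


class ConfigurationError(ValueError):
    """A record references a group for which no reference complex is known."""


@dataclass(frozen=True)
class LIECoefficients:
    """Weights of the LIE free energy function.

    ``alpha`` (van der Waals) and ``beta`` (electrostatics) are
    dimensionless; ``gamma`` is in cal/mol/Angstrom^2; ``delta`` is a
    constant in kcal/mol, identically zero for relative free energies.
    """

    alpha: float
    beta: float
    gamma: float
    delta: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "delta"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite coefficient {name}")

    def as_array(self) -> np.ndarray:
        """(alpha, beta, gamma/1000): the weights of (vdw, pb, sa) in kcal/mol."""
        return np.array([self.alpha, self.beta, self.gamma * CAL_TO_KCAL])


@dataclass(frozen=True)
class FitReport:
    """Error statistics of a model against a set of records (kcal/mol).

    ``pearson_r`` is ``None`` when the correlation is undefined (constant
    predictions, e.g. the Null model, or fewer than two records); it is never
    silently reported as zero.  ``mean_signed_error`` is computed minus
    experimental, so a negative value means binding is overestimated
    (predicted relative free energies are too low).
    """

    rmsd: float
    mue: float
    pearson_r: float | None
    max_abs_error: float
    mean_signed_error: float
    n: int
    per_complex_errors: dict[str, float] = field(default_factory=dict)


def fit_report(
    y_true: Sequence[float],
    y_pred: Sequence[float],
    ids: Sequence[str] | None = None,
) -> FitReport:
    """Build a :class:`FitReport` from experimental and computed values."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size == 0:
        raise ValueError("cannot compute error statistics of an empty dataset")
    res = y_pred - y_true
    if y_true.size >= 2 and np.std(y_true) > 0 and np.std(y_pred) > 0:
        r = float(np.corrcoef(y_true, y_pred)[0, 1])
    else:
        r = None
    ids = list(ids) if ids is not None else [str(i) for i in range(len(res))]
    return FitReport(
        rmsd=float(np.sqrt(np.mean(res**2))),
        mue=float(np.mean(np.abs(res))),
        pearson_r=r,
        max_abs_error=float(np.max(np.abs(res))),
        mean_signed_error=float(np.mean(res)),
        n=int(y_true.size),
        per_complex_errors={i: float(e) for i, e in zip(ids, res)},
    )


def _reference_row(ref) -> tuple[np.ndarray, float, float]:
    """(components, restraint, exp_ddg) of a reference complex.

    Accepts a :class:`ComplexRecord` or a mapping with the same keys.
    """
    if isinstance(ref, ComplexRecord):
        comp = np.array([ref.vdw, ref.pb, ref.sa])
        return comp, ref.restraint, float(ref.exp_ddg)
    comp = np.array([ref.get("vdw", 0.0), ref.get("pb", 0.0), ref.get("sa", 0.0)])
    return comp, float(ref.get("restraint", 0.0)), float(ref["exp_ddg"])


def design_matrix(
    X,
    references: Mapping[str, ComplexRecord | Mapping] | None = None,
    base_group: str = "sdc1",
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Corrected linear design of the LIE model.

    Returns ``(D, offset, ids)`` such that the corrected prediction is
    ``D @ (alpha, beta, gamma/1000) + offset``.  Rows of ``D`` are the
    component values minus those of the row's reference complex; the offset
    absorbs the restraint energies and the reference experimental value.

    ``X`` may be a :class:`~pdzlie.datasets.Dataset`, a DataFrame with
    columns ``vdw, pb, sa`` (optionally ``restraint``, ``reference_group``,
    ``complex_id``), or an ``(n, 3)`` array of ``(vdw, pb, sa)`` components.
    """
    references = dict(references or {})
    if isinstance(X, Dataset):
        X = X.to_frame()
    if isinstance(X, pd.DataFrame):
        missing = [c for c in COMPONENT_COLUMNS if c not in X.columns]
        if missing:
            raise ValueError(f"missing component column(s): {', '.join(missing)}")
        comps = X.loc[:, list(COMPONENT_COLUMNS)].to_numpy(dtype=float)
        restraint = (
            X["restraint"].to_numpy(dtype=float)
            if "restraint" in X.columns
            else np.zeros(len(X))
        )
        groups = (
            X["reference_group"].astype(str).tolist()
            if "reference_group" in X.columns
            else [base_group] * len(X)
        )
        ids = (
            X["complex_id"].astype(str).tolist()
            if "complex_id" in X.columns
            else [str(i) for i in range(len(X))]
        )
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError("array input must have shape (n, 3): (vdw, pb, sa)")
        comps = arr
        restraint = np.zeros(len(arr))
        groups = [base_group] * len(arr)
        ids = [str(i) for i in range(len(arr))]

    D = np.empty_like(comps)
    offset = np.empty(len(comps))
    for i, g in enumerate(groups):
        if g in references:
            ref_comp, ref_rest, ref_exp = _reference_row(references[g])
        elif g == base_group:
            ref_comp, ref_rest, ref_exp = np.zeros(3), 0.0, 0.0
        else:
            raise ConfigurationError(
                f"record {ids[i]!r} belongs to reference group {g!r} "
                "but no reference complex was supplied"
            )
        D[i] = comps[i] - ref_comp
        offset[i] = restraint[i] - ref_rest + ref_exp
    D = D.copy()
    D[:, 2] *= CAL_TO_KCAL  # gamma is configured in cal/mol/A^2
    return D, offset, ids


class LIERegressor(RegressorMixin, BaseEstimator):
    """Scikit-learn style estimator for the three-parameter LIE model.

    Parameters
    ----------
    references:
        Mapping from reference-group name to the group's reference complex
        (a :class:`~pdzlie.datasets.ComplexRecord` or a mapping with keys
        ``vdw, pb, sa, restraint, exp_ddg``).  Records whose group equals
        ``base_group`` are scored directly (zero reference); any other group
        must appear in the mapping.
    base_group:
        Name of the primary reference group (components already relative to
        it); default ``"sdc1"``.

    Attributes
    ----------
    alpha_, beta_ : float
        Fitted van der Waals and electrostatic weights (dimensionless).
    gamma_ : float
        Fitted surface weight in cal/mol/Angstrom^2.
    coef_ : ndarray of shape (3,)
        ``(alpha_, beta_, gamma_)`` -- the weights of the corrected design
        columns ``(vdw, pb, sa/1000)``, so predictions come out in kcal/mol.
    corrections_ : dict
        Per-group additive correction ``exp(ref) - predicted(ref)`` implied
        by the fitted coefficients.
    """

    def __init__(self, references=None, base_group: str = "sdc1"):
        self.references = references
        self.base_group = base_group

    # -- scikit-learn API -------------------------------------------------
    def fit(self, X, y):
        D, offset, _ = design_matrix(X, self.references, self.base_group)
        y = np.asarray(y, dtype=float)
        if y.shape != (D.shape[0],):
            raise ValueError("X and y have inconsistent lengths")
        if not np.all(np.isfinite(y)):
            raise ValueError("y contains non-finite values")
        for j, col in enumerate(COMPONENT_COLUMNS):
            if np.allclose(D[:, j], 0.0):
                raise SingularDesignError(
                    f"component column {col!r} is identically zero"
                )
        if np.linalg.matrix_rank(D) < 3:
            raise SingularDesignError("component columns are collinear")
        theta, *_ = np.linalg.lstsq(D, y - offset, rcond=None)
        self.coef_ = theta
        self.alpha_ = float(theta[0])
        self.beta_ = float(theta[1])
        self.gamma_ = float(theta[2])
        self.n_features_in_ = 3
        self.corrections_ = self._corrections()
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "coef_"):
            raise AttributeError("LIERegressor instance is not fitted yet")
        D, offset, _ = design_matrix(X, self.references, self.base_group)
        return D @ self.coef_ + offset

    # -- domain helpers ----------------------------------------------------
    @property
    def coefficients_(self) -> LIECoefficients:
        return LIECoefficients(self.alpha_, self.beta_, self.gamma_)

    def set_coefficients(self, coeffs: LIECoefficients) -> "LIERegressor":
        """Install fixed coefficients without fitting (for evaluation)."""
        self.coef_ = np.array([coeffs.alpha, coeffs.beta, coeffs.gamma])
        self.alpha_, self.beta_, self.gamma_ = (
            coeffs.alpha,
            coeffs.beta,
            coeffs.gamma,
        )
        self.n_features_in_ = 3
        self.corrections_ = self._corrections()
        return self

    def _corrections(self) -> dict[str, float]:
        out = {self.base_group: 0.0}
        for g, ref in dict(self.references or {}).items():
            comp, rest, exp = _reference_row(ref)
            raw = float(
                np.array([comp[0], comp[1], comp[2] * CAL_TO_KCAL]) @ self.coef_
                + rest
            )
            out[g] = exp - raw
        return out

    @classmethod
    def from_dataset(cls, ds: Dataset, base_group: str = "sdc1") -> "LIERegressor":
        """Estimator with references resolved from the dataset itself.

        A dataset whose records all belong to the base group needs no
        reference rows; for any other group the reference must be resolvable
        or prediction raises :class:`ConfigurationError`.
        """
        from .datasets import ValidationError

        try:
            refs = {
                g: r for g, r in reference_records(ds).items() if g != base_group
            }
        except ValidationError:
            if any(r.reference_group != base_group for r in ds):
                raise
            refs = {}
        return cls(references=refs, base_group=base_group)


@dataclass(frozen=True)
class LIEFit:
    """Result of fitting the LIE model to a dataset."""

    coefficients: LIECoefficients
    report: FitReport
    model: LIERegressor


@dataclass(frozen=True)
class NullModel:
    """Baseline that assigns every complex the mean experimental value."""

    prediction: float
    report: FitReport


def _frame_and_y(ds: Dataset) -> tuple[pd.DataFrame, np.ndarray]:
    frame = ds.to_frame()
    if frame["exp_ddg"].isna().any():
        missing = frame.loc[frame["exp_ddg"].isna(), "complex_id"].tolist()
        raise ValueError(f"records without exp_ddg: {', '.join(missing)}")
    return frame, frame["exp_ddg"].to_numpy(dtype=float)


def predict_ddg(
    record: ComplexRecord,
    coeffs: LIECoefficients,
    ref_caspr: ComplexRecord | None = None,
) -> float:
    """Corrected LIE prediction for a single complex record (kcal/mol)."""
    refs = {}
    if record.reference_group != "sdc1":
        if ref_caspr is None:
            raise ConfigurationError(
                f"record {record.complex_id!r} needs the reference complex of "
                f"group {record.reference_group!r}"
            )
        refs[record.reference_group] = ref_caspr
    model = LIERegressor(references=refs).set_coefficients(coeffs)
    return float(model.predict(Dataset((record,)))[0])


def fit_lie(ds: Dataset, references=None) -> LIEFit:
    """Least-squares fit of (alpha, beta, gamma) to a dataset.

    ``ds`` is reduced to its fitting subset; references default to the
    dataset's own reference complexes.  Minimising the rms deviation of an
    affine model is ordinary least squares, solved exactly.
    """
    if references is None:
        model = LIERegressor.from_dataset(ds)
    else:
        model = LIERegressor(references=references)
    sub = fitting_subset(ds)
    frame, y = _frame_and_y(sub)
    model.fit(frame, y)
    pred = model.predict(frame)
    return LIEFit(
        coefficients=model.coefficients_,
        report=fit_report(y, pred, frame["complex_id"]),
        model=model,
    )


def evaluate(
    ds: Dataset,
    coeffs: LIECoefficients,
    references=None,
) -> FitReport:
    """Error statistics of fixed coefficients on records carrying exp_ddg."""
    model = LIERegressor(references=references).set_coefficients(coeffs)
    frame, y = _frame_and_y(ds)
    return fit_report(y, model.predict(frame), frame["complex_id"])


def null_model(ds: Dataset) -> NullModel:
    """Baseline model: every complex gets the mean experimental value.

    The Pearson correlation is undefined by construction and reported as
    ``None``.
    """
    sub = fitting_subset(ds) if any(r.in_fit for r in ds) else ds
    frame, y = _frame_and_y(sub)
    if len(y) == 0:
        raise ValueError("empty dataset")
    mean = float(np.mean(y))
    pred = np.full_like(y, mean)
    return NullModel(
        prediction=mean, report=fit_report(y, pred, frame["complex_id"])
    )
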