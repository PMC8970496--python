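"""Spectral and multivariate preprocessing.

Spectra are corrected with extended multiplicative signal correction (EMSC):
each spectrum ``x`` is modelled by ordinary least squares as

    x  ~=  a·1 + b·m + sum_j d_j·lambda^j + sum_k g_k·q_k

where ``m`` is a reference spectrum (the dataset mean by default), the
polynomial terms in the wavenumber ``lambda`` (rescaled to [-1, 1] for
conditioning) absorb additive baseline drift and curvature, and optional
interferent spectra ``q_k`` absorb known contaminants. The corrected
spectrum, ``(x - a - sum d_j lambda^j - sum g_k q_k) / b``, removes additive,
multiplicative-scatter and interference effects while preserving the
chemical signal.

Plain multivariate data (no wavenumber axis) routes to per-feature
standardization instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dataset import DatasetMatrix


@dataclass
class EMSCModel:
    """EMSC configuration.

    reference:
        Reference spectrum ``m``; defaults to the dataset mean.
    polynomial_order:
        Highest power of the rescaled wavenumber axis in the baseline model
        (default 2: offset + slope + curvature).
    interferents:
        Optional spectra of known interfering constituents, removed from
        every sample.
    b_tolerance:
        Multiplicative coefficients with ``|b|`` below this flag the
        spectrum as degenerate (division would blow up).
    """

    reference: np.ndarray | None = None
    polynomial_order: int = 2
    interferents: list = field(default_factory=list)
    b_tolerance: float = 1e-8


@dataclass
class EMSCFit:
    """Per-sample EMSC coefficients and diagnostics.

    ``coefficients`` columns are ordered [a, b, d_1..d_order, g_1..g_m]
    (``a`` is the constant/zeroth polynomial term). ``degenerate`` marks
    spectra whose multiplicative coefficient was below tolerance; those rows
    are returned uncorrected.
    """

    coefficients: np.ndarray
    reference: np.ndarray
    polynomial_order: int
    degenerate: np.ndarray


def _design_matrix(model: EMSCModel, reference: np.ndarray, axis: np.ndarray):
    lo, hi = axis.min(), axis.max()
    if hi == lo:
        raise ValueError("wavenumber axis is constant")
    lam = 2.0 * (axis - lo) / (hi - lo) - 1.0
    cols = [np.ones_like(lam), reference]
    cols += [lam**j for j in range(1, model.polynomial_order + 1)]
    cols += [np.asarray(q, dtype=float) for q in model.interferents]
    design = np.column_stack(cols)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            "rank-deficient EMSC design: reference, polynomial and "
            "interferent columns are linearly dependent"
        )
    return design


def emsc_fit_correct(
    m: DatasetMatrix, model: EMSCModel | None = None
) -> tuple[DatasetMatrix, EMSCFit]:
    """Fit and apply EMSC to every spectrum in the matrix.

    Requires a wavenumber axis with at least two points (multivariate data
    belongs in :func:`standardize`). Returns the corrected matrix and the
    per-sample fit. Degenerate spectra (|b| below tolerance) are flagged and
    passed through unchanged.
    """
    model = model or EMSCModel()
    if m.axis is None:
        raise ValueError(
            "EMSC needs a wavenumber axis; use standardize() for "
            "plain multivariate data"
        )
    if m.n_features < 2:
        raise ValueError("EMSC needs at least two wavelength points")
    reference = (
        np.asarray(model.reference, dtype=float)
        if model.reference is not None
        else m.values.mean(axis=0)
    )
    if reference.shape != (m.n_features,):
        raise ValueError("reference length does not match feature count")

    design = _design_matrix(model, reference, m.axis)
    # one least-squares solve for all spectra at once
    coeffs, *_ = np.linalg.lstsq(design, m.values.T, rcond=None)
    coeffs = coeffs.T  # n_samples x n_coeffs, columns [a, b, d.., g..]
    b = coeffs[:, 1]
    degenerate = np.abs(b) < model.b_tolerance

    background = coeffs.copy()
    background[:, 1] = 0.0  # keep everything except the b·m term
    corrected = m.values - background @ design.T
    safe_b = np.where(degenerate, 1.0, b)
    corrected = corrected / safe_b[:, None]
    corrected[degenerate] = m.values[degenerate]
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} spectra had |b| < {model.b_tolerance:g}; "
            "left uncorrected and flagged",
            RuntimeWarning,
        )
    fit = EMSCFit(
        coefficients=coeffs,
        reference=reference,
        polynomial_order=model.polynomial_order,
        degenerate=degenerate,
    )
    return m.replace(values=corrected), fit


def standardize(m: DatasetMatrix) -> DatasetMatrix:
    """Centre and scale each feature to mean 0, standard deviation 1.

    Zero-variance features cannot be scaled and are mapped to all-zero
    columns with a warning.
    """
    if m.n_samples < 2:
        raise ValueError("standardization needs at least two samples")
    mean = m.values.mean(axis=0)
    sd = m.values.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s) mapped to zero",
            RuntimeWarning,
        )
    out = (m.values - mean) / np.where(constant, 1.0, sd)
    out[:, constant] = 0.0
    return m.replace(values=out)
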