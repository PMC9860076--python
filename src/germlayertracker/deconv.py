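"""Reference-based cell-fraction estimation by non-negative least squares.

Methylation deconvolution treats each sample's marker-CpG beta vector as a
non-negative linear combination of class-specific reference profiles: with
R the (markers x classes) reference matrix of mean beta values and b the
sample's marker betas, the raw coefficients solve

    min_{f >= 0} || R f - b ||_2

(Lawson-Hanson active-set NNLS). Raw coefficients are then normalized to
sum to one, giving interpretable class fractions on the simplex, while the
raw coefficients and the fit residual (RMSD between observed and
reconstructed marker betas) are reported alongside. This is the standard
reference-based approach used for leukocyte composition estimation,
applied here to early germ-layer specification — the estimated fractions
are a surrogate for early cell-fate decisions, not an absolute cell count,
because early differentiation is a continuum rather than a defined
endpoint.

The module exposes a statsmodels-style pair: :class:`Deconvolution` is
built from a beta matrix and a reference, its :meth:`Deconvolution.fit`
returns :class:`DeconvolutionResults` carrying fractions, residuals and a
``summary()`` table. :func:`deconvolve` is the one-call convenience.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _lawson_hanson_nnls

from ._errors import UnderdeterminedError, ValidationError
from .io import Signature, validate_beta_matrix

#: Deconvolution modes: which signatures form the reference panel.
MODES = {
    "full": ("PSC", "ENDO", "MESO", "ECTO"),
    "endomeso": ("PSC", "ENDOMESO", "ECTO"),
}


def build_reference(
    matrix: pd.DataFrame,
    labels: pd.Series,
    signatures: Iterable[Signature],
    mode: str = "full",
) -> pd.DataFrame:
    """Mean marker betas per cell class, as a (probes x classes) DataFrame.

    ``mode="full"`` uses the PSC/ENDO/MESO/ECTO signatures (12 CpGs);
    ``mode="endomeso"`` uses PSC/ENDOMESO/ECTO (9 CpGs). Cell (probe,
    class) is the mean beta of that class's labeled samples at that probe.
    Provenance is recorded in ``.attrs``.
    """
    if mode not in MODES:
        raise ValidationError(f"build_reference: unknown mode {mode!r}; use one of {list(MODES)}")
    classes = MODES[mode]
    by_class = {s.target_class: s for s in signatures}
    missing_sigs = [c for c in classes if c not in by_class]
    if missing_sigs:
        raise ValidationError(f"build_reference: no signature for classes {missing_sigs}")
    probes: list[str] = []
    for c in classes:
        probes.extend(p for p in by_class[c].probe_ids if p not in probes)
    labels = labels.reindex(matrix.columns).dropna()
    missing_probes = [p for p in probes if p not in matrix.index]
    if missing_probes:
        raise ValidationError(f"build_reference: probes absent from matrix: {missing_probes}")
    empty_classes = [c for c in classes if not (labels == c).any()]
    if empty_classes:
        raise ValidationError(f"build_reference: no samples labeled {empty_classes}")
    ref = pd.DataFrame(
        {c: matrix.loc[probes, labels.index[labels == c]].mean(axis=1, skipna=True) for c in classes}
    )
    ref.index.name = "probe_id"
    ref.attrs["provenance"] = "array selection set"
    ref.attrs["mode"] = mode
    return ref


def nnls_solve(R: pd.DataFrame | np.ndarray, b: pd.Series | np.ndarray) -> np.ndarray:
    """Solve ``min_{f>=0} ||R f - b||`` for one sample's marker beta vector.

    Rows where ``b`` is missing are dropped from both R and b; fewer usable
    rows than classes raises :class:`UnderdeterminedError`. The active-set
    solution is exact and deterministic for a fixed input.
    """
    R_arr = np.asarray(R, dtype=float)
    b_arr = np.asarray(b, dtype=float)
    if R_arr.shape[0] != b_arr.shape[0]:
        raise ValidationError(
            f"nnls_solve: {R_arr.shape[0]} reference rows vs {b_arr.shape[0]} observations"
        )
    usable = ~np.isnan(b_arr)
    R_arr, b_arr = R_arr[usable], b_arr[usable]
    if np.isnan(R_arr).any():
        raise ValidationError("nnls_solve: reference matrix contains missing values")
    n_classes = R_arr.shape[1]
    if R_arr.shape[0] < n_classes:
        raise UnderdeterminedError(
            f"nnls_solve: {R_arr.shape[0]} usable markers for {n_classes} classes"
        )
    coef, _ = _lawson_hanson_nnls(R_arr, b_arr)
    return coef


class Deconvolution:
    """Reference-based NNLS mixture model for a batch of samples.

    Parameters
    ----------
    matrix
        Beta matrix (probes x samples) containing the reference's marker
        probes; extra probes are ignored.
    reference
        (marker probes x classes) reference matrix of mean beta values in
        [0, 1], e.g. from :func:`build_reference` or read from TSV.
    """

    def __init__(self, matrix: pd.DataFrame, reference: pd.DataFrame) -> None:
        validate_beta_matrix(reference, where="reference matrix")
        if reference.shape[1] < 2:
            raise ValidationError("Deconvolution: reference needs >= 2 classes")
        if reference.isna().any().any():
            raise ValidationError("Deconvolution: reference matrix has missing cells")
        missing = [p for p in reference.index if p not in matrix.index]
        if missing:
            raise ValidationError(f"Deconvolution: matrix lacks marker probes {missing}")
        self.reference = reference
        self.matrix = matrix.loc[reference.index]
        self.class_names = list(reference.columns)

    def fit(self) -> "DeconvolutionResults":
        """Estimate per-sample non-negative coefficients and simplex fractions.

        Per-sample under-determination (too many missing markers) is
        recorded as a flag with NaN estimates rather than failing the
        batch. A sample whose raw coefficients are all zero gets uniform
        fractions and a ``degenerate`` flag.
        """
        R = self.reference.to_numpy(dtype=float)
        n_classes = len(self.class_names)
        raw = np.full((self.matrix.shape[1], n_classes), np.nan)
        frac = np.full_like(raw, np.nan)
        residual = np.full(self.matrix.shape[1], np.nan)
        flags: list[str] = []
        for j, sample_id in enumerate(self.matrix.columns):
            b = self.matrix[sample_id].to_numpy(dtype=float)
            sample_flags = []
            try:
                coef = nnls_solve(R, b)
            except UnderdeterminedError:
                flags.append("underdetermined")
                continue
            raw[j] = coef
            usable = ~np.isnan(b)
            fitted = R[usable] @ coef
            residual[j] = float(np.sqrt(np.mean((fitted - b[usable]) ** 2)))
            total = coef.sum()
            if total > 0:
                frac[j] = coef / total
            else:
                frac[j] = np.full(n_classes, 1.0 / n_classes)
                sample_flags.append("degenerate")
            best = np.flatnonzero(frac[j] == frac[j].max())
            if len(best) > 1:
                sample_flags.append("tied_argmax")
            flags.append(";".join(sample_flags))
        return DeconvolutionResults(self, raw, frac, residual, flags)


class DeconvolutionResults:
    """Estimated composition of each sample, with fit diagnostics."""

    def __init__(
        self,
        model: Deconvolution,
        raw: np.ndarray,
        fractions: np.ndarray,
        residuals: np.ndarray,
        flags: Sequence[str],
    ) -> None:
        self.model = model
        samples = model.matrix.columns
        self.raw = pd.DataFrame(raw, index=samples, columns=model.class_names)
        self.fractions = pd.DataFrame(fractions, index=samples, columns=model.class_names)
        self.residuals = pd.Series(residuals, index=samples, name="residual")
        self.flags = pd.Series(list(flags), index=samples, name="flags")

    @property
    def predicted_class(self) -> pd.Series:
        """Arg-max fraction per sample (ties broken lexicographically, flagged)."""
        cols_sorted = sorted(self.model.class_names)
        pred = pd.Series(pd.NA, index=self.fractions.index, dtype=object, name="predicted_class")
        valid = self.fractions.notna().any(axis=1)
        if valid.any():
            pred[valid] = self.fractions.loc[valid, cols_sorted].idxmax(axis=1)
        return pred

    def summary(self) -> pd.DataFrame:
        """FractionTable: raw coefficients, fractions, residual, predicted class, flags."""
        out = pd.concat(
            [
                self.raw.add_prefix("raw."),
                self.fractions.add_prefix("frac."),
                self.residuals,
                self.predicted_class,
                self.flags,
            ],
            axis=1,
        )
        out.index.name = "sample_id"
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<DeconvolutionResults: {self.fractions.shape[0]} samples x "
            f"{self.fractions.shape[1]} classes, median residual "
            f"{np.nanmedian(self.residuals):.4f}>"
        )


def deconvolve(matrix: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """One-call NNLS deconvolution: returns the FractionTable summary."""
    return Deconvolution(matrix, reference).fit().summary()


def adjust_reference_with_pyro(
    reference: pd.DataFrame,
    pyro_betas: pd.DataFrame,
    class_labels: Mapping[str, str] | pd.Series,
) -> pd.DataFrame:
    """Replace reference cells with pyrosequencing class means where measured.

    ``pyro_betas`` is a beta matrix from :func:`io.pyro_to_beta` whose
    samples are labeled by class. Each covered (probe, class) cell becomes
    the mean pyro beta of that class; uncovered cells keep their array
    value. Measurements for probes or classes outside the reference are
    ignored with a warning. Cell-level provenance is recorded in ``.attrs``.
    """
    labels = pd.Series(class_labels).reindex(pyro_betas.columns).dropna()
    adjusted = reference.copy()
    adjusted.attrs = dict(reference.attrs)
    replaced: list[tuple[str, str]] = []
    unknown_classes = sorted(set(labels) - set(reference.columns))
    if unknown_classes:
        warnings.warn(
            f"adjust_reference_with_pyro: ignoring measurements for classes {unknown_classes} "
            "not in the reference",
            stacklevel=2,
        )
    unknown_probes = sorted(set(pyro_betas.index) - set(reference.index))
    if unknown_probes:
        warnings.warn(
            f"adjust_reference_with_pyro: ignoring measurements for probes {unknown_probes[:5]} "
            "not in the reference",
            stacklevel=2,
        )
    for cls in reference.columns:
        cls_samples = labels.index[labels == cls]
        if len(cls_samples) == 0:
            continue
        means = pyro_betas.loc[pyro_betas.index.isin(reference.index), cls_samples].mean(
            axis=1, skipna=True
        )
        for probe, value in means.dropna().items():
            adjusted.loc[probe, cls] = value
            replaced.append((probe, cls))
    adjusted.attrs["pyro_adjusted_cells"] = replaced
    if replaced:
        adjusted.attrs["provenance"] = "array selection set + pyrosequencing"
    return adjusted
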