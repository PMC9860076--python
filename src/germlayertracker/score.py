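"""Pluripotency and germ-layer differentiation scores.

The pluripotency score sums the complementary methylation levels of the
three pluripotency-associated CpGs (all hypomethylated in pluripotent
cells):

    pluripotency = (1 - beta_cg00661673) + (1 - beta_cg00933813) + (1 - beta_cg21699252)

so undifferentiated pluripotent cells score near 3 and differentiated or
somatic cells score near 0. The implementation is orientation-aware: a
hypothetical hyper-oriented pluripotency marker would contribute its beta
directly.

Differentiation scores measure, per marker CpG, the oriented methylation
change of a sample relative to the mean of undifferentiated pluripotent
reference samples: for hypermethylated markers the difference of beta
values, for hypomethylated markers the difference of (1 - beta). The score
is 0 when a sample equals the reference and grows toward +1 with
lineage-specific differentiation. A lineage aggregate is the arithmetic
mean of its per-CpG scores.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import pandas as pd

from ._errors import ValidationError
from .io import Signature


def _oriented(beta: float, orientation: str) -> float:
    return beta if orientation == "hyper" else 1.0 - beta


def _marker_beta(sample_betas: Mapping[str, float], probe_id: str, context: str) -> float:
    try:
        beta = float(sample_betas[probe_id])
    except KeyError:
        raise ValidationError(f"{context}: missing beta value for marker {probe_id!r}") from None
    if pd.isna(beta):
        raise ValidationError(f"{context}: missing beta value for marker {probe_id!r}")
    if not 0.0 <= beta <= 1.0:
        raise ValidationError(f"{context}: beta {beta} for {probe_id!r} outside [0, 1]")
    return beta


def pluripotency_score(sample_betas: Mapping[str, float], psc_signature: Signature) -> float:
    """Sum of oriented methylation levels over the pluripotency markers.

    For hypo-oriented markers (the published panel) each CpG contributes
    ``1 - beta``; range is [0, m] for m markers. A missing marker beta is an
    error — a partial sum is not comparable to the 0-3 scale.
    """
    return sum(
        _oriented(_marker_beta(sample_betas, m.probe_id, "pluripotency_score"), m.orientation)
        for m in psc_signature.markers
    )


def compute_reference_means(matrix: pd.DataFrame, labels: pd.Series) -> pd.Series:
    """Per-probe mean beta over PSC-labeled samples (missing values excluded)."""
    labels = labels.reindex(matrix.columns).dropna()
    psc_ids = labels.index[labels == "PSC"]
    if len(psc_ids) == 0:
        raise ValidationError("compute_reference_means: no PSC-labeled samples")
    ref = matrix[psc_ids].mean(axis=1, skipna=True)
    ref.name = "reference_mean"
    return ref


def differentiation_scores(
    sample_betas: Mapping[str, float],
    signature: Signature,
    reference: Mapping[str, float],
) -> tuple[pd.Series, float]:
    """Per-CpG oriented differences to the pluripotent reference, plus their mean.

    score_i = oriented(beta_sample_i) - oriented(reference_i), with
    oriented(x) = x for hyper markers and 1 - x for hypo markers. Scores are
    signed in [-1, 1]; 0 means no change versus the reference stem cells.
    """
    if not signature.metadata.get("orientation_verified", True):
        # warnings (not logging) so repeated batch calls surface this once
        warnings.warn(
            f"signature {signature.name}: orientations are unverified placeholders; "
            "derive them with orient_signature before interpreting differentiation scores",
            UserWarning,
            stacklevel=2,
        )
    scores = {}
    for m in signature.markers:
        beta = _marker_beta(sample_betas, m.probe_id, f"differentiation_scores[{signature.name}]")
        try:
            ref = float(reference[m.probe_id])
        except KeyError:
            raise ValidationError(
                f"differentiation_scores: reference lacks marker {m.probe_id!r}"
            ) from None
        if pd.isna(ref):
            raise ValidationError(f"differentiation_scores: reference lacks marker {m.probe_id!r}")
        scores[m.probe_id] = _oriented(beta, m.orientation) - _oriented(ref, m.orientation)
    per_cpg = pd.Series(scores, name=f"{signature.name}_score")
    return per_cpg, float(per_cpg.mean())


def score_table(
    matrix: pd.DataFrame,
    signatures: Iterable[Signature],
    reference: Mapping[str, float],
) -> pd.DataFrame:
    """Score every sample of a beta matrix against a signature panel.

    One row per sample: ``pluri_score`` (if a PSC signature is present),
    ``<signature>.<probe>`` per-CpG differentiation scores,
    ``<signature>.mean`` lineage aggregates, and a ``flags`` column naming
    scores that could not be computed for that sample (missing marker
    values); affected scores are NaN rather than silently renormalized.
    """
    signatures = list(signatures)
    rows = []
    for sample_id in matrix.columns:
        betas = matrix[sample_id]
        row: dict[str, object] = {}
        flags: list[str] = []
        for sig in signatures:
            if sig.target_class == "PSC":
                try:
                    row["pluri_score"] = pluripotency_score(betas, sig)
                except ValidationError:
                    row["pluri_score"] = float("nan")
                    flags.append("pluri_score")
            else:
                try:
                    per_cpg, aggregate = differentiation_scores(betas, sig, reference)
                except ValidationError:
                    per_cpg = pd.Series({m.probe_id: float("nan") for m in sig.markers})
                    aggregate = float("nan")
                    flags.append(f"{sig.name}.mean")
                for probe_id, value in per_cpg.items():
                    row[f"{sig.name}.{probe_id}"] = value
                row[f"{sig.name}.mean"] = aggregate
        row["flags"] = ";".join(flags)
        rows.append(pd.Series(row, name=sample_id))
    if not rows:
        return pd.DataFrame(index=pd.Index([], name="sample_id"))
    table = pd.DataFrame(rows)
    table.index.name = "sample_id"
    return table
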