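"""Sample QC, probe filtering, platform intersection, and variable-probe selection.

These mirror the standard preprocessing applied to Illumina 450K/EPIC beta
matrices before marker selection: drop low-intensity samples, drop sex-
chromosome / non-CpG / SNP-associated probes, restrict to probes shared by
both array platforms, and keep the most variable probes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._errors import ValidationError

logger = logging.getLogger(__name__)

#: Sample QC threshold: samples whose summed channel medians (log2 scale)
#: fall strictly below this are removed.
QC_INTENSITY_THRESHOLD = 20.0


def qc_filter_samples(
    summaries: pd.DataFrame,
    threshold: float = QC_INTENSITY_THRESHOLD,
) -> tuple[list[str], list[str]]:
    """Partition samples into (kept, removed) by channel-intensity QC.

    A sample is removed iff ``m_median + u_median < threshold`` (strict; a
    sample exactly at the threshold is kept). ``summaries`` needs columns
    ``sample_id``, ``m_median``, ``u_median`` (log2-scale medians of the
    methylated and unmethylated channels), or those two columns with
    sample IDs as index.
    """
    df = summaries
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    for col in ("m_median", "u_median"):
        if col not in df.columns:
            raise ValidationError(f"qc_filter_samples: missing column {col!r}")
    if df.index.has_duplicates:
        raise ValidationError("qc_filter_samples: duplicate sample IDs")
    sums = df["m_median"].astype(float) + df["u_median"].astype(float)
    if not np.isfinite(sums).all():
        bad = sums.index[~np.isfinite(sums)].tolist()
        raise ValidationError(f"qc_filter_samples: non-finite intensity for {bad[:5]}")
    removed = sums.index[sums < threshold].astype(str).tolist()
    kept = sums.index[sums >= threshold].astype(str).tolist()
    return kept, removed


def filter_probes(matrix: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Drop sex-chromosome, non-CpG (ch/rs), and SNP-associated probes.

    Probes absent from the annotation are dropped conservatively (they cannot
    be certified clean); the count is logged. Sample set and retained values
    are unchanged; probe order is preserved.
    """
    annotated = matrix.index.isin(annotation.index)
    n_unannotated = int((~annotated).sum())
    if n_unannotated:
        logger.warning("filter_probes: dropping %d unannotated probes", n_unannotated)
    ann = annotation.reindex(matrix.index[annotated])
    chrom = ann["chrom"].str.removeprefix("chr")
    keep = (~chrom.isin(["X", "Y"])) & (ann["probe_class"] == "cg") & (~ann["snp"])
    return matrix.loc[matrix.index[annotated][keep.to_numpy()]]


def intersect_platforms(matrix: pd.DataFrame, probe_universe) -> pd.DataFrame:
    """Restrict to probes present on both array platforms (a probe-ID universe).

    Original probe order is preserved. An empty intersection is an error —
    nothing would be analyzable.
    """
    universe = set(probe_universe)
    keep = matrix.index[matrix.index.isin(universe)]
    if keep.empty:
        raise ValidationError(
            "intersect_platforms: no probes shared with the platform universe"
        )
    return matrix.loc[keep]


def probe_variances(matrix: pd.DataFrame) -> pd.Series:
    """Unbiased (n-1) across-sample variance per probe over non-missing entries.

    Probes with fewer than two non-missing values get ``-inf`` so they are
    never selected as variable.
    """
    var = matrix.var(axis=1, ddof=1, skipna=True)
    var[matrix.notna().sum(axis=1) < 2] = -np.inf
    return var


def select_most_variable(matrix: pd.DataFrame, k: int = 10_000) -> pd.DataFrame:
    """Keep the ``k`` probes with the largest across-sample variance.

    Ties (and the all-constant case) are broken by probe-ID lexicographic
    order for determinism. If fewer than ``k`` probes exist, all are kept.
    The selection is invariant to sample ordering.
    """
    if k < 1:
        raise ValidationError("select_most_variable: k must be >= 1")
    var = probe_variances(matrix)
    order = sorted(matrix.index, key=lambda p: (-var[p], p))
    chosen = order[: min(k, len(order))]
    return matrix.loc[chosen]
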