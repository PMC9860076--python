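"""Reading and writing the tabular formats the toolkit consumes.

Beta-value matrices (CpG probes x samples, methylation levels in [0, 1]),
sample label tables, probe annotations, signature panels (JSON), and
targeted pyrosequencing measurements (percent methylation).

A beta matrix is represented as a :class:`pandas.DataFrame` with probe IDs
as the index and sample IDs as the columns — the array-export convention
(probes in rows). Missing measurements are ``NaN``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._errors import ParseError, ValidationError

#: Closed vocabulary of cell-class labels.
CLASS_LABELS = ("PSC", "ENDO", "MESO", "ECTO", "ENDOMESO", "OTHER")

#: Valid marker orientations (direction of methylation in the target class
#: relative to pluripotent reference cells).
ORIENTATIONS = ("hyper", "hypo")

_NA_TOKEN = "NA"


@dataclass(frozen=True)
class Marker:
    """A single marker CpG with its methylation orientation in the target class."""

    probe_id: str
    orientation: str  # "hyper" | "hypo"

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ValidationError(
                f"marker {self.probe_id}: orientation must be one of {ORIENTATIONS}, "
                f"got {self.orientation!r}"
            )


@dataclass
class Signature:
    """A named panel of marker CpGs for one cell class.

    Parameters
    ----------
    name
        Panel name (conventionally equal to the target class).
    target_class
        Cell class the signature marks, from :data:`CLASS_LABELS`.
    markers
        Marker CpGs; probe IDs must be unique within the signature.
    metadata
        Free-form provenance. The packaged germ-layer panels carry
        ``orientation_verified: False`` because per-CpG directions must be
        derived from a reference dataset (see ``select.orient_signature``).
    """

    name: str
    target_class: str
    markers: list[Marker]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValidationError(f"signature {self.name!r} has no markers")
        ids = [m.probe_id for m in self.markers]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"signature {self.name!r} has duplicate probe IDs")

    @property
    def probe_ids(self) -> list[str]:
        return [m.probe_id for m in self.markers]

    def orientation_of(self, probe_id: str) -> str:
        for m in self.markers:
            if m.probe_id == probe_id:
                return m.orientation
        raise KeyError(probe_id)


# ---------------------------------------------------------------------------
# beta matrices


def validate_beta_matrix(matrix: pd.DataFrame, *, where: str = "beta matrix") -> None:
    """Check the beta-matrix invariants; raise :class:`ParseError` naming offenders."""
    if matrix.index.has_duplicates:
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ParseError(f"{where}: duplicate probe IDs {dupes[:5]}")
    if matrix.columns.has_duplicates:
        dupes = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise ParseError(f"{where}: duplicate sample IDs {dupes[:5]}")
    values = matrix.to_numpy(dtype=float)
    bad = (values < 0) | (values > 1)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"{where}: value {values[i, j]!r} outside [0, 1] at "
            f"probe {matrix.index[i]!r}, sample {matrix.columns[j]!r}"
        )


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_beta_matrix(
    path: str | Path,
    *,
    sep: str | None = None,
    na_token: str = _NA_TOKEN,
    transpose: bool = False,
) -> pd.DataFrame:
    """Read a delimited beta matrix (first column probe IDs, header sample IDs).

    The delimiter is auto-detected among tab/comma unless ``sep`` is given.
    ``transpose=True`` accepts samples-in-rows exports. Values must lie in
    [0, 1]; the missing-value token becomes ``NaN``.
    """
    path = Path(path)
    if sep is None:
        sep = _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, na_values=[na_token], keep_default_na=False)
    except ValueError as exc:  # pragma: no cover - passthrough formatting
        raise ParseError(f"{path}: malformed table ({exc})") from exc
    if df.columns.size == 0:
        raise ParseError(f"{path}: no sample columns found (malformed header?)")
    if transpose:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric beta value ({exc})") from exc
    validate_beta_matrix(df, where=str(path))
    df.index.name = "probe_id"
    return df


def write_beta_matrix(
    matrix: pd.DataFrame,
    path: str | Path,
    *,
    sep: str = "\t",
    na_token: str = _NA_TOKEN,
    precision: int = 6,
) -> None:
    """Write a beta matrix as delimited text (round-trips with :func:`read_beta_matrix`)."""
    validate_beta_matrix(matrix)
    out = matrix.copy()
    out.index.name = out.index.name or "probe_id"
    out.to_csv(path, sep=sep, na_rep=na_token, float_format=f"%.{precision}f")


# ---------------------------------------------------------------------------
# labels and annotations


def read_labels(path: str | Path, *, sep: str | None = None) -> pd.Series:
    """Read a sample -> class table (columns ``sample_id``, ``label``)."""
    path = Path(path)
    if sep is None:
        sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected sample_id and label columns")
    sample_col, label_col = df.columns[:2]
    labels = pd.Series(
        df[label_col].to_numpy(), index=df[sample_col].astype(str), name="label"
    )
    return validate_labels(labels)


def validate_labels(labels: pd.Series) -> pd.Series:
    if labels.index.has_duplicates:
        raise ParseError("label table: duplicate sample IDs")
    bad = sorted(set(labels) - set(CLASS_LABELS))
    if bad:
        raise ParseError(
            f"label table: unknown class labels {bad}; allowed: {list(CLASS_LABELS)}"
        )
    return labels


def read_probe_annotation(path: str | Path, *, sep: str | None = None) -> pd.DataFrame:
    """Read a probe annotation table (probe_id, chrom, probe_class, snp as 0/1)."""
    path = Path(path)
    if sep is None:
        sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    required = {"probe_id", "chrom", "probe_class", "snp"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing annotation columns {sorted(missing)}")
    if df["probe_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate probe IDs in annotation")
    bad = sorted(set(df["probe_class"]) - {"cg", "ch", "rs"})
    if bad:
        raise ParseError(f"{path}: unknown probe_class values {bad}")
    df = df.set_index("probe_id")
    df["snp"] = df["snp"].astype(int).astype(bool)
    df["chrom"] = df["chrom"].astype(str)
    return df


# ---------------------------------------------------------------------------
# signatures


def _signature_from_dict(doc: Mapping) -> Signature:
    markers = [Marker(m["probe_id"], m["orientation"]) for m in doc["markers"]]
    return Signature(
        name=doc["name"],
        target_class=doc["target_class"],
        markers=markers,
        metadata=dict(doc.get("metadata", {})),
    )


def _signature_to_dict(sig: Signature) -> dict:
    return {
        "name": sig.name,
        "target_class": sig.target_class,
        "markers": [{"probe_id": m.probe_id, "orientation": m.orientation} for m in sig.markers],
        "metadata": sig.metadata,
    }


def read_signatures(path: str | Path) -> list[Signature]:
    """Read a signature panel from a JSON document."""
    with open(path) as fh:
        doc = json.load(fh)
    entries = doc["signatures"] if isinstance(doc, Mapping) and "signatures" in doc else doc
    return [_signature_from_dict(d) for d in entries]


def write_signatures(signatures: Iterable[Signature], path: str | Path, *, panel: str = "custom") -> None:
    doc = {"panel": panel, "signatures": [_signature_to_dict(s) for s in signatures]}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def load_default_signatures() -> list[Signature]:
    """Load the packaged GermLayerTracker panel.

    Five signatures (PSC, ENDO, MESO, ECTO, ENDOMESO) of three CpGs each.
    The three PSC CpGs are hypomethylated in pluripotent cells; the
    germ-layer orientations in the packaged file are unverified placeholders
    (``metadata["orientation_verified"]``) to be re-derived from a labeled
    reference dataset with ``select.orient_signature``.
    """
    text = resources.files("germlayertracker").joinpath("data/default_signatures.json").read_text()
    doc = json.loads(text)
    return [_signature_from_dict(d) for d in doc["signatures"]]


# ---------------------------------------------------------------------------
# pyrosequencing


def read_pyro_table(path: str | Path, *, sep: str | None = None) -> pd.DataFrame:
    """Read targeted pyrosequencing measurements.

    Expected columns ``sample_id, probe_id, dnam_percent`` and optionally
    ``batch``. Percent values must lie in [0, 100]; (sample, probe) pairs
    must be unique within a batch.
    """
    path = Path(path)
    if sep is None:
        sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "probe_id": str})
    required = {"sample_id", "probe_id", "dnam_percent"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing pyro columns {sorted(missing)}")
    df["dnam_percent"] = df["dnam_percent"].astype(float)
    bad = df[(df["dnam_percent"] < 0) | (df["dnam_percent"] > 100)]
    if not bad.empty:
        row = bad.iloc[0]
        raise ParseError(
            f"{path}: dnam_percent {row['dnam_percent']} outside [0, 100] "
            f"for sample {row['sample_id']!r}, probe {row['probe_id']!r}"
        )
    if "batch" not in df.columns:
        df["batch"] = ""
    dup = df.duplicated(subset=["sample_id", "probe_id", "batch"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ParseError(
            f"{path}: duplicate measurement for sample {row['sample_id']!r}, "
            f"probe {row['probe_id']!r} in batch {row['batch']!r}"
        )
    return df


def pyro_to_beta(measurements: pd.DataFrame) -> pd.DataFrame:
    """Assemble pyrosequencing percent measurements into a beta matrix.

    Beta = percent / 100, over observed probes x samples; cells without a
    measurement are missing. Batches are pooled (measurements are unique per
    batch; duplicate cells across batches are averaged).
    """
    if measurements.empty:
        raise ValidationError("pyro_to_beta: no measurements")
    beta = measurements.assign(beta=measurements["dnam_percent"] / 100.0)
    matrix = beta.pivot_table(index="probe_id", columns="sample_id", values="beta", aggfunc="mean")
    matrix.index.name = "probe_id"
    matrix.columns.name = None
    validate_beta_matrix(matrix, where="pyro-derived beta matrix")
    return matrix
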