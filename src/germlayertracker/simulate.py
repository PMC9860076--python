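"""Synthetic class-structured beta matrices and noisy cell mixtures.

The generator emulates the data this toolkit is designed for, so that
selection, scoring and deconvolution are testable without array downloads:

* a background of probes whose per-probe baseline beta is drawn from a
  bimodal Beta distribution (real methylomes concentrate near 0 and 1) and
  is shared across classes;
* per class, a set of planted marker probes whose class mean is shifted by
  the effect size (direction chosen away from the nearer boundary, clipped
  to [0, 1]), with the orientation recorded as ground truth;
* per-sample measurement noise: additive Gaussian, clipped to [0, 1].
  Additive noise keeps the mixture model exactly linear, so deconvolution
  recovery targets are well-posed; optionally Beta-distributed noise is
  available for robustness checks.
* mixtures: beta = sum_c fraction_c * profile_c + noise, the linear-mixing
  approximation of pooled DNA from a cell mixture (exact when every cell
  contributes equal DNA).

All outputs are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .io import write_beta_matrix


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults emulate a small multi-class differentiation experiment:
    four classes (pluripotent + three germ layers) of 10 samples each,
    2,000 probes, 3 markers per class with a 0.6 beta separation, and
    within-class measurement noise of sd 0.03 (typical array-scale
    replicate noise).
    """

    seed: int = 0
    n_probes: int = 2000
    class_counts: dict[str, int] = field(
        default_factory=lambda: {"PSC": 10, "ENDO": 10, "MESO": 10, "ECTO": 10}
    )
    n_markers_per_class: int = 3
    effect_size: float = 0.6
    noise_sd: float = 0.03
    background_beta: tuple[float, float] = (0.5, 0.5)
    noise_model: str = "gaussian"  # "gaussian" (clipped) | "beta"

    def validate(self) -> None:
        if not 0 < self.effect_size <= 1:
            raise ValidationError("effect_size must be in (0, 1]")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if self.noise_model not in ("gaussian", "beta"):
            raise ValidationError("noise_model must be 'gaussian' or 'beta'")
        if self.n_markers_per_class * len(self.class_counts) > self.n_probes:
            raise ValidationError("more planted markers than probes")


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside a simulated matrix."""

    markers: dict[str, list[tuple[str, str]]]  # class -> [(probe_id, orientation)]
    profiles: pd.DataFrame  # probes x classes true mean betas
    fractions: pd.DataFrame | None = None  # mixture samples x classes (mixtures only)


def _probe_ids(n: int) -> list[str]:
    return [f"cg{i:08d}" for i in range(n)]


def _add_noise(values: np.ndarray, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if config.noise_model == "beta":
        # Beta noise with matching mean and sd (variance capped by the mean)
        mean = np.clip(values, 1e-3, 1 - 1e-3)
        var = np.minimum(config.noise_sd**2, 0.9 * mean * (1 - mean))
        conc = mean * (1 - mean) / var - 1
        return rng.beta(mean * conc, (1 - mean) * conc)
    noisy = values + rng.normal(0.0, config.noise_sd, size=values.shape)
    return np.clip(noisy, 0.0, 1.0)


def simulate_class_matrix(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.Series, SimulationTruth]:
    """Simulate a labeled beta matrix with planted class-specific markers.

    Returns (beta matrix, sample labels, truth). Planted markers for a
    class shift that class's mean by exactly the effect size, upward when
    the shared baseline falls in the lower half of [0, 1] (hyper in the
    target class) and downward otherwise (hypo); the marker's baseline is
    rescaled into the sub-interval where the shift fits, so the planted
    separation never loses magnitude to the [0, 1] bounds. All other
    classes keep the baseline.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    classes = list(config.class_counts)
    probes = _probe_ids(config.n_probes)
    baseline = rng.beta(*config.background_beta, size=config.n_probes)

    profiles = pd.DataFrame(
        np.tile(baseline[:, None], (1, len(classes))), index=probes, columns=classes
    )
    marker_idx = rng.choice(
        config.n_probes, size=config.n_markers_per_class * len(classes), replace=False
    )
    markers: dict[str, list[tuple[str, str]]] = {}
    for ci, cls in enumerate(classes):
        idx = marker_idx[ci * config.n_markers_per_class : (ci + 1) * config.n_markers_per_class]
        markers[cls] = []
        for i in idx:
            up = baseline[i] <= 0.5
            # squeeze the shared baseline into the range where the full shift fits
            base = baseline[i] * (1.0 - config.effect_size)
            if not up:
                base += config.effect_size
            baseline[i] = base
            profiles.iloc[i, :] = base
            profiles.iloc[i, ci] = base + (config.effect_size if up else -config.effect_size)
            markers[cls].append((probes[i], "hyper" if up else "hypo"))

    sample_ids, labels, columns = [], [], []
    for cls in classes:
        for r in range(config.class_counts[cls]):
            sid = f"{cls}_{r + 1:02d}"
            sample_ids.append(sid)
            labels.append(cls)
            columns.append(_add_noise(profiles[cls].to_numpy(), config, rng))
    matrix = pd.DataFrame(np.column_stack(columns), index=probes, columns=sample_ids)
    matrix.index.name = "probe_id"
    label_series = pd.Series(labels, index=pd.Index(sample_ids, name="sample_id"), name="label")
    return matrix, label_series, SimulationTruth(markers=markers, profiles=profiles)


def sample_simplex(n: int, n_classes: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform draws from the (n_classes-1)-simplex (flat Dirichlet)."""
    return rng.dirichlet(np.ones(n_classes), size=n)


def simulate_mixtures(
    truth: SimulationTruth,
    fractions: np.ndarray | pd.DataFrame,
    noise_sd: float = 0.03,
    seed: int = 0,
    *,
    probes: list[str] | None = None,
    noise_model: str = "gaussian",
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Simulate mixed-population samples from true class profiles.

    Each column of the result is ``profiles @ fraction_vector`` plus
    clipped additive noise. ``fractions`` is (n_mixtures x n_classes) on
    the simplex, matching ``truth.profiles`` columns. ``probes`` restricts
    the emitted matrix to a marker subset (profiles stay the truth).
    """
    profiles = truth.profiles if probes is None else truth.profiles.loc[probes]
    frac = np.asarray(fractions, dtype=float)
    if frac.ndim != 2 or frac.shape[1] != profiles.shape[1]:
        raise ValidationError(
            f"fractions must be (n_mixtures x {profiles.shape[1]}), got {frac.shape}"
        )
    if not np.allclose(frac.sum(axis=1), 1.0, atol=1e-8) or (frac < 0).any():
        raise ValidationError("fraction vectors must lie on the simplex")
    rng = np.random.default_rng(seed)
    cfg = SimulationConfig(noise_sd=noise_sd, noise_model=noise_model)
    clean = profiles.to_numpy() @ frac.T
    noisy = _add_noise(clean, cfg, rng)
    sample_ids = [f"MIX_{i + 1:03d}" for i in range(frac.shape[0])]
    matrix = pd.DataFrame(noisy, index=profiles.index, columns=sample_ids)
    matrix.index.name = "probe_id"
    frac_df = pd.DataFrame(frac, index=sample_ids, columns=profiles.columns)
    return matrix, SimulationTruth(
        markers=truth.markers, profiles=truth.profiles, fractions=frac_df
    )


def make_fixture_suite(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the canonical small fixture set used by the docs and CLI examples.

    Emits a class-structured selection matrix with labels, 20 noisy
    mixtures with true fractions, and a truth JSON (planted markers,
    orientations, fractions). Deterministic per seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = SimulationConfig(seed=seed, n_probes=500)
    matrix, labels, truth = simulate_class_matrix(config)
    rng = np.random.default_rng(seed + 1)
    fractions = sample_simplex(20, len(truth.profiles.columns), rng)
    marker_probes = [p for ms in truth.markers.values() for p, _ in ms]
    mixtures, mix_truth = simulate_mixtures(
        truth, fractions, noise_sd=config.noise_sd, seed=seed + 2, probes=marker_probes
    )
    paths = {
        "matrix": out_dir / "selection_matrix.tsv",
        "labels": out_dir / "labels.csv",
        "mixtures": out_dir / "mixtures.tsv",
        "truth": out_dir / "truth.json",
    }
    write_beta_matrix(matrix, paths["matrix"])
    labels.rename("label").to_csv(paths["labels"], index_label="sample_id")
    write_beta_matrix(mixtures, paths["mixtures"])
    truth_doc = {
        "seed": seed,
        "markers": {c: [[p, o] for p, o in ms] for c, ms in truth.markers.items()},
        "mixture_fractions": {
            s: [float(x) for x in row]
            for s, row in mix_truth.fractions.iterrows()
        },
        "classes": list(truth.profiles.columns),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_doc, fh, indent=2)
        fh.write("\n")
    return paths
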