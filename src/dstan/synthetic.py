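"""Two-class synthetic ROI time-series generator.

Emulates resting-state BOLD data for a case/control cohort: every
subject is a ``T x n`` matrix of region-level signals drawn from a
multivariate normal whose correlation structure differs between the
two classes only on a planted subset of nodes.  Class 1 ("MCI") shifts
the pairwise correlations among the planted nodes by ``effect_delta``;
an AR(1) filter along time reproduces the temporal autocorrelation of
BOLD series without altering the cross-region correlation structure.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .types import LabeledDataset, RoiTimeSeries

logger = logging.getLogger(__name__)

__all__ = ["SyntheticConfig", "build_class_correlation", "sample_subject",
           "generate_dataset"]


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the two-class generator.

    Defaults mirror the study cohort's dimensions: 90 AAL regions,
    80 retained timepoints, 45 cases vs. 46 controls (pass
    ``n_subjects_per_class`` per class via ``generate_dataset``'s
    ``class_sizes`` override for an unbalanced cohort).
    """

    n_nodes: int = 90
    n_timepoints: int = 80
    n_subjects_per_class: int = 45
    planted_nodes: tuple[int, ...] = tuple(range(10))
    base_correlation: float = 0.1
    effect_delta: float = 0.4
    ar_coefficient: float = 0.3
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be at least 2")
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be at least 2")
        if not self.planted_nodes:
            raise ValueError("planted_nodes must be non-empty")
        if any(p < 0 or p >= self.n_nodes for p in self.planted_nodes):
            raise ValueError("planted_nodes out of range "
                             f"[0, {self.n_nodes - 1}]")
        if len(set(self.planted_nodes)) != len(self.planted_nodes):
            raise ValueError("planted_nodes contains duplicates")
        if not 0.0 <= self.base_correlation < 1.0:
            raise ValueError("base_correlation must lie in [0, 1)")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _nearest_pd(corr: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Eigenvalue clipping at ``eps`` followed by re-normalization to
    unit diagonal."""
    vals, vecs = np.linalg.eigh(corr)
    vals = np.clip(vals, eps, None)
    repaired = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return (repaired + repaired.T) / 2.0


def build_class_correlation(cfg: SyntheticConfig,
                            class_label: int) -> np.ndarray:
    """Target correlation matrix for one class.

    Class 0: ``base_correlation`` on every off-diagonal entry.  Class 1:
    additionally shifts entries among ``planted_nodes`` by
    ``effect_delta`` (clipped to (-0.99, 0.99)).  The result is repaired
    to the nearest positive-definite correlation matrix if the shift
    breaks positive definiteness.
    """
    if class_label not in (0, 1):
        raise ValueError("class_label must be 0 or 1")
    n = cfg.n_nodes
    corr = np.full((n, n), cfg.base_correlation)
    np.fill_diagonal(corr, 1.0)
    if class_label == 1 and cfg.effect_delta != 0.0:
        planted = np.asarray(sorted(cfg.planted_nodes))
        for i in planted:
            for j in planted:
                if i != j:
                    corr[i, j] = np.clip(corr[i, j] + cfg.effect_delta,
                                         -0.99, 0.99)
    min_eig = np.linalg.eigvalsh(corr).min()
    if min_eig <= 0:
        logger.warning("class-%d correlation matrix not PD (min eigenvalue "
                       "%.3g); applying nearest-PD repair", class_label,
                       min_eig)
        corr = _nearest_pd(corr)
        if np.linalg.eigvalsh(corr).min() <= 0:
            raise ValueError(
                "correlation matrix not repairable to positive definite; "
                f"offending parameters: base_correlation="
                f"{cfg.base_correlation}, effect_delta={cfg.effect_delta}, "
                f"planted_nodes={cfg.planted_nodes}")
    return corr


def sample_subject(corr: np.ndarray, T: int, ar: float, sd: float,
                   seed: int, subject_id: str = "sub-0",
                   label: int | None = None) -> RoiTimeSeries:
    """Draw one subject: correlated Gaussian rows, then AR(1) smoothing.

    Rows are i.i.d. N(0, sd^2 * corr); the AR(1) filter
    ``y_t = ar * y_{t-1} + x_t`` acts identically on every region, so
    the cross-region correlation structure is preserved (up to the
    common filter) while introducing BOLD-like temporal autocorrelation.
    """
    if T < 2:
        raise ValueError("T must be at least 2 (correlation undefined "
                         "downstream otherwise)")
    n = corr.shape[0]
    rng = np.random.default_rng(seed)
    if sd == 0.0:
        values = np.zeros((T, n))
    else:
        L = np.linalg.cholesky(corr)
        white = rng.standard_normal((T, n))
        values = sd * (white @ L.T)
        if ar > 0.0:
            for t in range(1, T):
                values[t] += ar * values[t - 1]
    return RoiTimeSeries(values=values, subject_id=subject_id, label=label)


def _subject_seed(master: int, class_label: int, index: int) -> int:
    """Stable per-subject seed derived from the master seed."""
    ss = np.random.SeedSequence(entropy=master,
                                spawn_key=(class_label, index))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def generate_dataset(cfg: SyntheticConfig,
                     class_sizes: tuple[int, int] | None = None
                     ) -> LabeledDataset:
    """Generate the full labeled cohort.

    ``class_sizes`` overrides ``n_subjects_per_class`` with an
    (n_class0, n_class1) pair, e.g. ``(46, 45)`` for the 46 NC / 45 MCI
    cohort layout.  Deterministic given ``cfg``.
    """
    sizes = class_sizes or (cfg.n_subjects_per_class,
                            cfg.n_subjects_per_class)
    subjects: list[RoiTimeSeries] = []
    k = 0
    for label in (0, 1):
        corr = build_class_correlation(cfg, label)
        for idx in range(sizes[label]):
            seed = _subject_seed(cfg.seed, label, idx)
            subjects.append(sample_subject(
                corr, cfg.n_timepoints, cfg.ar_coefficient, cfg.noise_sd,
                seed, subject_id=f"sub-{k:03d}", label=label))
            k += 1
    return LabeledDataset(subjects=subjects)
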