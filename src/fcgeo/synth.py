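"""Synthetic multi-participant, multi-condition FC study generator.

Ground-truth correlation structure follows a latent factor model: each
(participant, condition) covariance is ``L L' + noise_floor * I`` with
loadings ``L = L_base + s * L_participant + c * L_condition``, rescaled to
unit diagonal.  The shared base loadings create the group-common network
structure; participant perturbations (shared across conditions, strength
``s``) carry the identity signal that fingerprinting recovers; condition
perturbations (shared across participants, strength ``c``) reconfigure
connectivity between conditions.  Runs are i.i.d. multivariate normal
draws from the ground truth, so two runs of one participant differ only by
sampling noise — the test-retest structure identification relies on.

With ``n_frames < n_rois`` the sample correlation matrices are
rank-deficient, which makes the generator the canonical feed for the
identity-regularization path of the geodesic distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import FCDatabase, ROITimeSeries

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "Study",
    "generate_ground_truth",
    "simulate_run",
    "generate_study",
    "strong_signal_config",
]


@dataclass
class GeneratorConfig:
    """Study-design and signal-strength knobs for the generator.

    ``subject_effect`` (s) and ``condition_effect`` (c) scale the
    participant- and condition-specific loading perturbations relative to
    the shared base loadings (unit scale); ``noise_floor`` is the diagonal
    variance added before rescaling, bounding the ground truth away from
    singularity.
    """

    n_participants: int = 100
    n_rois: int = 30
    n_frames: int = 600
    n_conditions: int = 1
    n_runs: int = 2
    subject_effect: float = 1.0
    condition_effect: float = 0.2
    n_factors: int = 5
    noise_floor: float = 0.5
    ar_coefficient: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2 or self.n_rois < 2 or self.n_frames < 2:
            raise ValueError("need >= 2 participants, ROIs and frames")
        if self.n_conditions < 1 or self.n_runs < 1 or self.n_factors < 1:
            raise ValueError("n_conditions, n_runs and n_factors must be >= 1")
        if self.subject_effect < 0 or self.condition_effect < 0:
            raise ValueError("effect sizes must be >= 0")
        if self.noise_floor <= 0:
            raise ValueError("noise_floor must be > 0")
        if not -1 < self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must be in (-1, 1)")

    @property
    def participant_ids(self) -> list[str]:
        return [f"sub{p:03d}" for p in range(self.n_participants)]

    @property
    def condition_names(self) -> list[str]:
        return [f"cond{c}" for c in range(self.n_conditions)]


def strong_signal_config(seed: int = 0) -> GeneratorConfig:
    """Preset with a dominant participant effect; identification should
    approach ceiling at this frame count."""
    return GeneratorConfig(
        n_participants=100,
        n_rois=30,
        n_frames=600,
        subject_effect=1.0,
        condition_effect=0.2,
        noise_floor=0.5,
        seed=seed,
    )


@dataclass
class GroundTruth:
    """Per-(participant, condition) population correlation matrices."""

    sigma: dict[tuple[str, str], np.ndarray]
    config: GeneratorConfig

    def matrix(self, participant_id: str, condition: str) -> np.ndarray:
        return self.sigma[(participant_id, condition)]


def _rescale_to_correlation(cov: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return corr


def generate_ground_truth(cfg: GeneratorConfig) -> GroundTruth:
    """Factor-model ground truth, strictly positive definite by construction.

    ``Sigma_raw = L L' + noise_floor * I`` has minimum eigenvalue at least
    ``noise_floor``; after unit-diagonal rescaling the minimum eigenvalue
    stays at least ``noise_floor / max_ii Sigma_raw``, so every matrix is
    safely invertible.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(0,)))
    r, k = cfg.n_rois, cfg.n_factors
    scale = 1.0 / np.sqrt(k)
    l_base = rng.standard_normal((r, k)) * scale
    l_subj = rng.standard_normal((cfg.n_participants, r, k)) * scale
    l_cond = rng.standard_normal((cfg.n_conditions, r, k)) * scale
    sigma: dict[tuple[str, str], np.ndarray] = {}
    for p, pid in enumerate(cfg.participant_ids):
        for c, cond in enumerate(cfg.condition_names):
            load = l_base + cfg.subject_effect * l_subj[p] + cfg.condition_effect * l_cond[c]
            cov = load @ load.T + cfg.noise_floor * np.eye(r)
            sigma[(pid, cond)] = _rescale_to_correlation(cov)
    return GroundTruth(sigma=sigma, config=cfg)


def simulate_run(
    sigma: np.ndarray,
    n_frames: int,
    seed: int | np.random.Generator = 0,
    participant_id: str = "sub000",
    condition: str = "cond0",
    run: int = 1,
    ar_coefficient: float = 0.0,
) -> ROITimeSeries:
    """Draw one run of zero-mean multivariate normal frames from ``sigma``.

    Frames are i.i.d. by default (Cholesky transform of standard normals);
    a nonzero ``ar_coefficient`` applies an AR(1) filter across frames for
    robustness studies, preserving the stationary spatial covariance.
    """
    sigma = np.asarray(sigma, dtype=float)
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError("sigma must be strictly positive definite") from exc
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal((n_frames, sigma.shape[0]))
    if ar_coefficient:
        phi = ar_coefficient
        innov_scale = np.sqrt(1.0 - phi**2)
        for t in range(1, n_frames):
            white[t] = phi * white[t - 1] + innov_scale * white[t]
    data = white @ chol.T
    return ROITimeSeries(
        data=data,
        participant_id=participant_id,
        condition=condition,
        run=run,
    )


@dataclass
class Study:
    """A generated study: time series and FC databases per condition/run."""

    config: GeneratorConfig
    ground_truth: GroundTruth
    timeseries: dict[str, dict[int, list[ROITimeSeries]]]
    _fc_cache: dict = field(default_factory=dict, repr=False)

    def databases(self, condition: str) -> tuple[FCDatabase, ...]:
        """FC databases for each run of one condition (built once, cached)."""
        if condition not in self._fc_cache:
            runs = self.timeseries[condition]
            self._fc_cache[condition] = tuple(
                FCDatabase.from_timeseries(runs[r]) for r in sorted(runs)
            )
        return self._fc_cache[condition]

    def database_map(self) -> dict[str, tuple[FCDatabase, FCDatabase]]:
        """Mapping condition -> (run 1, run 2) databases, as transfer expects."""
        return {cond: self.databases(cond)[:2] for cond in self.timeseries}


def generate_study(cfg: GeneratorConfig) -> Study:
    """Simulate all participants x conditions x runs of a study.

    Every run is an independent draw from its (participant, condition)
    ground-truth matrix; per-run random streams are keyed on
    (participant, condition, run) so any subset regenerates identically.
    """
    truth = generate_ground_truth(cfg)
    timeseries: dict[str, dict[int, list[ROITimeSeries]]] = {}
    for c, cond in enumerate(cfg.condition_names):
        timeseries[cond] = {}
        for run in range(1, cfg.n_runs + 1):
            series = []
            for p, pid in enumerate(cfg.participant_ids):
                rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=cfg.seed, spawn_key=(1, p, c, run))
                )
                series.append(
                    simulate_run(
                        truth.matrix(pid, cond),
                        n_frames=cfg.n_frames,
                        seed=rng,
                        participant_id=pid,
                        condition=cond,
                        run=run,
                        ar_coefficient=cfg.ar_coefficient,
                    )
                )
            timeseries[cond][run] = series
    return Study(config=cfg, ground_truth=truth, timeseries=timeseries)
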