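"""Synthetic e-nose cohorts with known ground-truth class separation.

The generator emulates a two-group (asthma / control) breath-print study on a
32-sensor polymer-composite array.  Each sample's response vector is driven by
a low-dimensional latent profile of volatile organic compounds (VOCs):

    x_ij = A (mu_c + b_i) + h_ij u + eps_ij

where ``A`` is a 32 x q orthonormal-column loading matrix, ``mu_c`` the latent
class mean, ``b_i ~ N(0, sigma_subject^2 I_q)`` a subject effect shared by
duplicate samples of subject *i*, ``h_ij ~ N(0, sigma_humidity^2)`` a humidity
nuisance loading onto the humidity-sensitive sensors, and
``eps_ij ~ N(0, sigma_noise^2 I_32)`` replicate noise.

The latent class-mean difference is rescaled so the *population* Mahalanobis
distance between the groups under the marginal within-class covariance

    Sigma = sigma_subject^2 A A^T + sigma_humidity^2 u u^T + sigma_noise^2 I

equals the configured ``delta`` exactly, making downstream discrimination and
cross-validation testable against a known separation.

Raw traces wrap the same response vectors into time series
``R_s(t) = R0_s (1 + x_s g(t) + d_s t + eta_s(t))`` with a baseline window
(g = 0), a ramp, and an exposure plateau (g = 1), so the preprocessing stage
can be validated by round trip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .containers import (
    HUMIDITY_SENSORS,
    N_SENSORS,
    BreathPrint,
    BreathPrintSet,
    RawSensorTrace,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_breathprints",
    "simulate_traces",
    "simulate_duplicates",
]

# stream keys for stable keyed splitting of the master seed
_STREAM_LOADINGS = 101
_STREAM_PRINTS = 202
_STREAM_TRACES = 303
_STREAM_DUPLICATES = 404


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror a small pediatric training cohort (6 asthma vs 5 control)
    with a between-group Mahalanobis separation of 3.13 and nuisance
    magnitudes on the dR/R scale of a Cyranose-class device (responses of a
    few percent).  ``humidity_sensors`` are 1-based, matching the instrument
    convention.
    """

    n_asthma: int = 6
    n_control: int = 5
    delta: float = 3.13
    q_voc: int = 4
    sigma_subject: float = 0.04
    sigma_noise: float = 0.006
    sigma_humidity: float = 0.01
    humidity_sensors: tuple[int, ...] = HUMIDITY_SENSORS
    drift_slope_sd: float = 1e-5
    trace_noise_sd: float = 1e-4
    seed: int = 0
    trace_length: int = 200
    baseline_fraction: float = 0.25

    def validate(self) -> None:
        for name in ("n_asthma", "n_control", "q_voc", "trace_length"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("delta", "sigma_subject", "sigma_humidity", "drift_slope_sd", "trace_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sigma_noise <= 0:
            raise ValueError(
                "sigma_noise must be > 0: the within-class covariance is singular without it"
            )
        if not 0 < self.baseline_fraction < 1:
            raise ValueError("baseline_fraction must lie strictly between 0 and 1")
        if self.q_voc > N_SENSORS:
            raise ValueError(f"q_voc cannot exceed {N_SENSORS}")
        for s in self.humidity_sensors:
            if not 1 <= int(s) <= N_SENSORS:
                raise ValueError(f"humidity sensor index {s} outside 1..{N_SENSORS}")


@dataclass
class GroundTruth:
    """Population quantities implied by a :class:`SimulationConfig`."""

    class_means: np.ndarray  # (2, 32): asthma mean, control mean in sensor space
    pooled_covariance: np.ndarray  # (32, 32) within-class covariance
    realized_delta: float

    def __post_init__(self) -> None:
        d = self.class_means[0] - self.class_means[1]
        sol = np.linalg.solve(self.pooled_covariance, d)
        check = math.sqrt(float(d @ sol))
        if not math.isclose(check, self.realized_delta, rel_tol=0, abs_tol=1e-9):
            raise ValueError("realized_delta inconsistent with means and covariance")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, stream])


def _loading_matrix(config: SimulationConfig) -> np.ndarray:
    """Deterministic orthonormal-column 32 x q loading matrix from the seed."""
    rng = _rng(config, _STREAM_LOADINGS)
    G = rng.standard_normal((N_SENSORS, config.q_voc))
    Q, R = np.linalg.qr(G)
    # fix column signs so the decomposition is unique
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    return Q * signs


def _humidity_vector(config: SimulationConfig) -> np.ndarray:
    u = np.zeros(N_SENSORS)
    idx = [int(s) - 1 for s in config.humidity_sensors]
    if idx:
        u[idx] = 1.0 / math.sqrt(len(idx))
    return u


def _population(config: SimulationConfig):
    """Latent class means, loading matrix, humidity vector and Sigma."""
    A = _loading_matrix(config)
    u = _humidity_vector(config)
    Sigma = (
        config.sigma_subject**2 * (A @ A.T)
        + config.sigma_humidity**2 * np.outer(u, u)
        + config.sigma_noise**2 * np.eye(N_SENSORS)
    )
    try:
        L = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by validate()
        raise ValueError("within-class covariance not positive definite (sigma_noise)") from exc
    # latent mean difference along the first VOC axis, rescaled so the
    # population Mahalanobis distance equals delta exactly
    v = A[:, 0]
    sol = np.linalg.solve(L.T, np.linalg.solve(L, v))
    qform = float(v @ sol)
    c = config.delta / math.sqrt(qform) if config.delta > 0 else 0.0
    mu_asthma = np.zeros(config.q_voc)
    mu_control = np.zeros(config.q_voc)
    mu_asthma[0] = +c / 2.0
    mu_control[0] = -c / 2.0
    return A, u, Sigma, mu_asthma, mu_control


def ground_truth(config: SimulationConfig) -> GroundTruth:
    config.validate()
    A, _, Sigma, mu_a, mu_c = _population(config)
    means = np.vstack([A @ mu_a, A @ mu_c])
    d = means[0] - means[1]
    realized = math.sqrt(float(d @ np.linalg.solve(Sigma, d)))
    return GroundTruth(class_means=means, pooled_covariance=Sigma, realized_delta=realized)


def _draw_prints(
    config: SimulationConfig,
    rng: np.random.Generator,
    n_replicates: int,
) -> list[BreathPrint]:
    A, u, _, mu_a, mu_c = _population(config)
    prints: list[BreathPrint] = []
    groups = [("asthma", mu_a, config.n_asthma, "A"), ("control", mu_c, config.n_control, "C")]
    for group, mu, n, tag in groups:
        for i in range(n):
            subject = f"{tag}{i + 1:03d}"
            b = rng.standard_normal(config.q_voc) * config.sigma_subject
            for rep in range(1, n_replicates + 1):
                h = rng.standard_normal() * config.sigma_humidity
                eps = rng.standard_normal(N_SENSORS) * config.sigma_noise
                x = A @ (mu + b) + h * u + eps
                suffix = f"-r{rep}" if n_replicates > 1 else ""
                prints.append(
                    BreathPrint(
                        sample_id=f"{subject}{suffix}",
                        subject_id=subject,
                        group=group,
                        response=x,
                        replicate=rep,
                    )
                )
    return prints


def simulate_breathprints(config: SimulationConfig) -> tuple[BreathPrintSet, GroundTruth]:
    """Draw one breath print per subject; deterministic given the seed."""
    config.validate()
    rng = _rng(config, _STREAM_PRINTS)
    prints = _draw_prints(config, rng, n_replicates=1)
    return BreathPrintSet(prints), ground_truth(config)


def simulate_duplicates(config: SimulationConfig, n_subjects: int) -> BreathPrintSet:
    """Paired duplicate prints (two per subject, shared subject effect).

    Subjects are split between the groups (asthma gets the extra one when
    ``n_subjects`` is odd), emulating a short-interval duplicate-sampling
    design where replicate pairs share the subject's latent VOC profile but
    get fresh humidity and replicate noise.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    config.validate()
    n_a = (n_subjects + 1) // 2
    n_c = n_subjects - n_a
    rng = _rng(config, _STREAM_DUPLICATES)
    A, u, _, mu_a, mu_c = _population(config)
    prints: list[BreathPrint] = []
    groups = [("asthma", mu_a, n_a, "A"), ("control", mu_c, n_c, "C")]
    for group, mu, n, tag in groups:
        for i in range(n):
            subject = f"{tag}{i + 1:03d}"
            b = rng.standard_normal(config.q_voc) * config.sigma_subject
            for rep in (1, 2):
                h = rng.standard_normal() * config.sigma_humidity
                eps = rng.standard_normal(N_SENSORS) * config.sigma_noise
                x = A @ (mu + b) + h * u + eps
                prints.append(
                    BreathPrint(
                        sample_id=f"{subject}-r{rep}",
                        subject_id=subject,
                        group=group,
                        response=x,
                        replicate=rep,
                    )
                )
    return BreathPrintSet(prints)


def trace_windows(config: SimulationConfig) -> tuple[tuple[int, int], tuple[int, int]]:
    """Baseline and exposure-plateau index windows for simulated traces."""
    T = config.trace_length
    n_baseline = int(round(config.baseline_fraction * T))
    ramp = max(1, int(round(0.2 * T)))
    e0 = n_baseline + ramp
    if e0 >= T:
        raise ValueError("trace_length too short for baseline + ramp + exposure windows")
    return (0, n_baseline), (e0, T)


def simulate_traces(
    config: SimulationConfig, sg_window: int = 11
) -> tuple[list[RawSensorTrace], GroundTruth]:
    """Raw time-series form of the cohort that :func:`simulate_breathprints`
    would produce under the same seed.

    Each sensor's trace is ``R0 (1 + x g(t) + d t + eta(t))`` with ``g`` zero
    over the baseline window, ramping linearly, and exactly 1 over the
    exposure plateau, so preprocessing recovers the generating dR/R values in
    the noise- and drift-free limit.
    """
    config.validate()
    (b0, b1), (e0, e1) = trace_windows(config)
    if (b1 - b0) < sg_window or (e1 - e0) < sg_window:
        raise ValueError(
            f"trace_length {config.trace_length} too short: both windows must span "
            f"at least the smoothing window ({sg_window} points)"
        )
    prints, gt = simulate_breathprints(config)
    rng = _rng(config, _STREAM_TRACES)
    T = config.trace_length
    t = np.arange(T, dtype=float)
    g = np.zeros(T)
    ramp = np.linspace(0.0, 1.0, e0 - b1 + 2)[1:-1]
    g[b1:e0] = ramp
    g[e0:] = 1.0
    traces = []
    for bp in prints:
        R0 = rng.uniform(5.0, 15.0, size=N_SENSORS)
        d = rng.standard_normal(N_SENSORS) * config.drift_slope_sd
        eta = rng.standard_normal((N_SENSORS, T)) * config.trace_noise_sd
        rel = 1.0 + np.outer(bp.response, g) + np.outer(d, t) + eta
        R = R0[:, None] * rel
        if np.any(R <= 0):
            raise ValueError("simulated resistance went non-positive; reduce noise/drift")
        traces.append(
            RawSensorTrace(
                sample_id=bp.sample_id,
                sensor_values=R,
                time_axis=t,
                baseline_window=(b0, b1),
                exposure_window=(e0, e1),
                subject_id=bp.subject_id,
                group=bp.group,
            )
        )
    return traces, gt
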