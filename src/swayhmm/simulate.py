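"""Synthetic COP cohorts with known ground truth.

Real stabilometric cohorts of healthy and parkinsonian subjects are rarely
shareable, so this module generates two-channel (ML, AP) sway-like signals
from generators whose parameters are known exactly, which makes training,
classification, cross-validation and the sweep harness fully testable.

Two generator families:

* ``hmm`` (default): each subject is sampled from a 3-state bivariate
  Gaussian HMM.  The healthy and PD generators share topology; a single
  ``separation`` knob displaces the PD state means, inflates its sway
  variance, and shortens its state dwell times — a qualitative caricature of
  impaired postural control (larger, faster, less regular sway), not a
  biomechanical model.  ``separation = 0`` makes the class generators
  identical, so any downstream classifier must fall to chance.
* ``ar2``: each channel is a stable AR(2) process with class-dependent
  coefficients and innovation scale.  AR output is smoother than
  regime-switching output and closer in texture to real COP traces; it also
  puts the HMM classifier in a misspecified-model setting.

Default cohort geometry mirrors the clinical study being emulated:
28 healthy + 32 PD subjects, 60 s per recording.  The default sampling rate
is 100 Hz (desk scale); 1000 Hz is available via the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.signal import lfilter

from .errors import SequenceError
from .hmm import (
    GaussianHMM,
    GaussianMixtureEmission,
    MarkovChainParams,
    ObservationSequence,
    sample_sequence,
)
from .io import CohortManifest, ManifestRecord


@dataclass
class CohortSimConfig:
    """Cohort geometry and generator settings."""

    n_healthy: int = 28
    n_pd: int = 32
    duration_s: float = 60.0
    sampling_rate_hz: float = 100.0
    mode: str = "hmm"
    separation: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_healthy < 0 or self.n_pd < 0:
            raise ValueError("class counts must be nonnegative")
        if self.separation < 0:
            raise ValueError("separation must be nonnegative")
        if self.mode not in ("hmm", "ar2"):
            raise ValueError(f"mode must be 'hmm' or 'ar2', got {self.mode!r}")
        if self.duration_s <= 0 or self.sampling_rate_hz <= 0:
            raise ValueError("duration and sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate_hz))


# Base healthy generator, in mm of COP displacement: three sway regimes
# (centered, forward-right lean, backward-left lean) with AP variance larger
# than ML, and slow switching (~2 s dwell at 100 Hz).
_BASE_MEANS = np.array([[0.0, 0.0], [1.8, 2.6], [-1.8, -2.6]])
_BASE_VARS = np.array([[1.0, 2.0], [1.2, 2.4], [1.2, 2.4]])
_BASE_STAY = 0.995
# Per-state displacement direction applied to the PD means per unit separation.
_PD_SHIFT = np.array([[1.2, 1.8], [2.0, 2.8], [-2.0, -2.8]])


def _build_model(means, variances, stay) -> GaussianHMM:
    K = means.shape[0]
    A = np.full((K, K), (1.0 - stay) / (K - 1))
    np.fill_diagonal(A, stay)
    chain = MarkovChainParams(K=K, A=A, pi=np.full(K, 1.0 / K))
    emissions = [
        GaussianMixtureEmission(
            weights=np.array([1.0]),
            means=means[k][None, :],
            covariances=np.diag(variances[k])[None, :, :],
        )
        for k in range(K)
    ]
    return GaussianHMM(chain=chain, d=2, emissions=emissions)


def make_ground_truth_models(
    separation: float, seed: int
) -> Tuple[GaussianHMM, GaussianHMM]:
    """Healthy and PD ground-truth generators sharing topology.

    Per unit ``separation`` the PD generator's state means are displaced,
    its per-channel variances inflated (x(1 + 0.8 s)) and its dwell times
    shortened; ``separation = 0`` returns two identical models.  ``seed``
    jitters the common base geometry so repeated studies are not clones.
    """
    if separation < 0:
        raise ValueError("separation must be nonnegative")
    rng = np.random.default_rng(seed)
    means_h = _BASE_MEANS + rng.normal(scale=0.2, size=_BASE_MEANS.shape)
    vars_h = _BASE_VARS * rng.uniform(0.9, 1.1, size=_BASE_VARS.shape)
    healthy = _build_model(means_h, vars_h, _BASE_STAY)
    means_pd = means_h + separation * _PD_SHIFT
    vars_pd = vars_h * (1.0 + 0.8 * separation)
    stay_pd = max(0.6, _BASE_STAY - 0.05 * separation)
    pd_model = _build_model(means_pd, vars_pd, stay_pd)
    return healthy, pd_model


def _ar2_params(separation: float) -> Dict[str, Tuple[np.ndarray, float]]:
    """Per-class AR(2) coefficients and innovation SD (both channels).

    Roots are placed on the real axis inside the unit circle; the PD process
    is less damped and noisier in proportion to ``separation``.
    """
    r1_h, r2_h = 0.90, 0.80
    shift = min(0.08 * separation, 0.085)
    r1_p, r2_p = r1_h + shift, r2_h + shift
    out = {}
    for name, (r1, r2, sd) in {
        "healthy": (r1_h, r2_h, 0.5),
        "pd": (r1_p, r2_p, 0.5 * (1.0 + 0.6 * separation)),
    }.items():
        phi = np.array([r1 + r2, -r1 * r2])
        roots = np.roots([1.0, -phi[0], -phi[1]])
        if np.any(np.abs(roots) >= 1.0):
            raise SequenceError(
                f"AR(2) coefficients for class {name!r} are unstable "
                f"(root magnitudes {np.abs(roots)})"
            )
        out[name] = (phi, sd)
    return out


def _sample_ar2(phi, sd, n, d, rng) -> np.ndarray:
    burn = 500
    eps = rng.normal(scale=sd, size=(n + burn, d))
    x = lfilter([1.0], [1.0, -phi[0], -phi[1]], eps, axis=0)
    return x[burn:]


@dataclass
class SimulatedCohort:
    """A generated cohort plus everything needed for ground-truth checks."""

    manifest: CohortManifest
    sequences: List[ObservationSequence]
    hidden_paths: Dict[str, np.ndarray]
    healthy_model: Optional[GaussianHMM] = None
    pd_model: Optional[GaussianHMM] = None
    ar_params: Optional[dict] = None
    config: Optional[CohortSimConfig] = None

    @property
    def healthy(self) -> List[ObservationSequence]:
        return [s for s in self.sequences if s.label == "healthy"]

    @property
    def pd(self) -> List[ObservationSequence]:
        return [s for s in self.sequences if s.label == "pd"]


def simulate_cohort(config: CohortSimConfig) -> SimulatedCohort:
    """Generate a labeled cohort; fully reproducible from ``config.seed``."""
    n = config.n_samples
    rng = np.random.default_rng(config.seed)
    h_model = pd_model = None
    ar_params = None
    if config.mode == "hmm":
        h_model, pd_model = make_ground_truth_models(config.separation, config.seed)
    else:
        ar_params = _ar2_params(config.separation)

    sequences: List[ObservationSequence] = []
    hidden: Dict[str, np.ndarray] = {}
    records: List[ManifestRecord] = []
    specs = [("healthy", i) for i in range(config.n_healthy)] + [
        ("pd", i) for i in range(config.n_pd)
    ]
    for label, i in specs:
        sid = f"{'H' if label == 'healthy' else 'PD'}{i + 1:03d}"
        if config.mode == "hmm":
            model = h_model if label == "healthy" else pd_model
            seq, states = sample_sequence(
                model,
                n,
                rng,
                sampling_rate_hz=config.sampling_rate_hz,
                subject_id=sid,
                label=label,
            )
            hidden[sid] = states
        else:
            phi, sd = ar_params[label]
            seq = ObservationSequence(
                values=_sample_ar2(phi, sd, n, 2, rng),
                sampling_rate_hz=config.sampling_rate_hz,
                channels=("ML", "AP"),
                subject_id=sid,
                label=label,
            )
        sequences.append(seq)
        records.append(
            ManifestRecord(subject_id=sid, path=f"{sid}.csv", label=label)
        )
    manifest = CohortManifest(
        records=records,
        sampling_rate_hz=config.sampling_rate_hz,
        duration_s=config.duration_s,
    )
    return SimulatedCohort(
        manifest=manifest,
        sequences=sequences,
        hidden_paths=hidden,
        healthy_model=h_model,
        pd_model=pd_model,
        ar_params=ar_params,
        config=config,
    )


def gaussian_symmetric_kl(
    mu0: np.ndarray, S0: np.ndarray, mu1: np.ndarray, S1: np.ndarray
) -> float:
    """Closed-form symmetric KL divergence between two Gaussians (test oracle)."""
    d = len(mu0)
    S0i, S1i = np.linalg.inv(S0), np.linalg.inv(S1)
    dm = mu1 - mu0
    kl01 = 0.5 * (
        np.trace(S1i @ S0)
        + dm @ S1i @ dm
        - d
        + np.log(np.linalg.det(S1) / np.linalg.det(S0))
    )
    kl10 = 0.5 * (
        np.trace(S0i @ S1)
        + dm @ S0i @ dm
        - d
        + np.log(np.linalg.det(S0) / np.linalg.det(S1))
    )
    return float(kl01 + kl10)
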