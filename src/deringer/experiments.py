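"""Reproducible synthetic study harness.

Builds the simulated study cases (phantom -> Radon sinogram -> Gaussian
noise -> 16-bit dynamic range -> injected ring artifacts), runs the
detection / correction procedures and scores them.  All randomness
derives from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hra import HRAParams, HRAResult, detect_hra, remove_hra
from .lra import LRAParams, remove_lra
from .metrics import DetectionScore, detection_score, psnr, ssim
from .phantoms import add_noise, forward_project, make_phantom
from .recon import fbp_reconstruct, zscore
from .rtv import RTVParams
from .simulate import (
    GroundTruthArtifacts,
    RingSimulationSpec,
    simulate_ring_artifacts,
    to_dynamic_range,
)

__all__ = [
    "StudyCase",
    "build_study_case",
    "detection_experiment",
    "correction_experiment",
    "noise_sweep",
]


@dataclass
class StudyCase:
    """One simulated acquisition with ground truth."""

    phantom: np.ndarray
    clean_sinogram: np.ndarray  # noisy but artifact-free, detector counts
    corrupted_sinogram: np.ndarray
    truth: GroundTruthArtifacts
    n_angles: int
    det_width: int


def build_study_case(
    kind: str = "shepp_logan",
    det_width: int = 1648,
    n_angles: int = 800,
    noise_sigma: float = 0.01,
    sim_spec: RingSimulationSpec | None = None,
    seed: int = 0,
) -> StudyCase:
    """Simulate one acquisition of the given phantom.

    The phantom side length is ``floor(det_width / sqrt(2))`` so its
    diagonal fits the detector.  The sinogram is normalized to [0, 1],
    Gaussian noise of standard deviation ``noise_sigma`` is added on
    that scale, the result is stretched to the 16-bit dynamic range and
    ring artifacts are injected.  The noise and artifact-layout RNG
    streams are both derived from ``seed``.
    """
    rng = np.random.default_rng(seed)
    noise_seed, artifact_seed = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    sim_spec = sim_spec or RingSimulationSpec()
    sim_spec = sim_spec.with_seed(artifact_seed)

    size = int(det_width / np.sqrt(2))
    phantom = make_phantom(kind, size)
    sino = forward_project(phantom, n_angles=n_angles, det_width=det_width)
    sino = sino / sino.max()
    noisy = add_noise(sino, noise_sigma, seed=noise_seed)
    clean = to_dynamic_range(noisy, sim_spec.dynamic_range_max)
    corrupted, truth = simulate_ring_artifacts(clean, sim_spec)
    return StudyCase(
        phantom=phantom,
        clean_sinogram=clean,
        corrupted_sinogram=corrupted,
        truth=truth,
        n_angles=n_angles,
        det_width=det_width,
    )


def detection_experiment(
    kind: str = "shepp_logan",
    det_width: int = 1648,
    n_angles: int = 800,
    noise_sigma: float = 0.01,
    seed: int = 0,
    hra_params: HRAParams | None = None,
    rtv_params: RTVParams | None = None,
    sim_spec: RingSimulationSpec | None = None,
) -> tuple[DetectionScore, HRAResult]:
    """Simulate, detect HRA columns and score against ground truth."""
    case = build_study_case(kind, det_width, n_angles, noise_sigma, sim_spec, seed)
    result = detect_hra(case.corrupted_sinogram, hra_params, rtv_params)
    score = detection_score(set(result.columns), case.truth.hra_set, det_width)
    return score, result


def correction_experiment(
    kind: str = "shepp_logan",
    det_width: int = 1648,
    n_angles: int = 800,
    noise_sigma: float = 0.01,
    seed: int = 0,
    hra_params: HRAParams | None = None,
    lra_params: LRAParams | None = None,
    rtv_params: RTVParams | None = None,
    sim_spec: RingSimulationSpec | None = None,
    filter_name: str = "cosine",
) -> dict:
    """Full two-step correction plus tomogram-domain scoring.

    Returns PSNR / SSIM of the corrected and of the uncorrected
    tomogram against the artifact-free reference (all Z-scored), along
    with the HRA detection score.
    """
    case = build_study_case(kind, det_width, n_angles, noise_sigma, sim_spec, seed)
    after_hra, hra_result = remove_hra(case.corrupted_sinogram, hra_params, rtv_params)
    corrected, lra_result = remove_lra(after_hra, lra_params, rtv_params)

    reference = zscore(fbp_reconstruct(case.clean_sinogram, filter_name))
    corrected_tomo = zscore(fbp_reconstruct(corrected, filter_name))
    uncorrected_tomo = zscore(fbp_reconstruct(case.corrupted_sinogram, filter_name))
    return {
        "psnr": psnr(corrected_tomo, reference),
        "ssim": ssim(corrected_tomo, reference),
        "psnr_uncorrected": psnr(uncorrected_tomo, reference),
        "ssim_uncorrected": ssim(uncorrected_tomo, reference),
        "detection": detection_score(
            set(hra_result.columns), case.truth.hra_set, det_width
        ),
        "hra_result": hra_result,
        "lra_result": lra_result,
        "corrected_sinogram": corrected,
    }


def noise_sweep(
    kind: str = "shepp_logan",
    sigmas=(0.005, 0.01, 0.02, 0.04),
    seeds=(0, 1, 2, 3, 4),
    det_width: int = 1648,
    n_angles: int = 800,
    hra_params: HRAParams | None = None,
    rtv_params: RTVParams | None = None,
    sim_spec: RingSimulationSpec | None = None,
) -> list[dict]:
    """HRA detection accuracy versus sinogram noise level.

    Returns one row per noise sigma with TPR / PPV / DSC averaged over
    the given seeds.
    """
    rows = []
    for sigma in sigmas:
        if sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        scores = [
            detection_experiment(
                kind, det_width, n_angles, sigma, seed, hra_params, rtv_params, sim_spec
            )[0]
            for seed in seeds
        ]
        rows.append(
            {
                "sigma": float(sigma),
                "tpr": float(np.mean([s.tpr for s in scores])),
                "ppv": float(np.mean([s.ppv for s in scores])),
                "dsc": float(np.mean([s.dsc for s in scores])),
            }
        )
    return rows
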