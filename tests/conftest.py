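import numpy as np
import pytest

import ramagg as rg
from ramagg.synthetic import (
    MARKERS_AGGREGATED,
    SS_AGGREGATED,
    SS_FOLDED,
)


@pytest.fixture(scope="session")
def folded_gt() -> rg.GroundTruthSlice:
    """Ground truth of the folded (pH 7.0-like) state: alpha 50%, beta 23%."""
    return rg.GroundTruthSlice(time_h=0.0, ss=dict(SS_FOLDED))


@pytest.fixture(scope="session")
def aggregated_gt() -> rg.GroundTruthSlice:
    """Ground truth of the 240 h aggregated state: alpha 20%, beta 45%."""
    return rg.GroundTruthSlice(
        time_h=240.0, ss=dict(SS_AGGREGATED), markers=dict(MARKERS_AGGREGATED),
        regime="isodesmic",
    )


@pytest.fixture(scope="session")
def folded_spectrum(folded_gt) -> rg.Spectrum:
    return rg.generate_spectrum(folded_gt, noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def folded_preprocessed(folded_spectrum) -> rg.Spectrum:
    return rg.preprocess(folded_spectrum)


@pytest.fixture(scope="session")
def aggregated_preprocessed(aggregated_gt) -> rg.Spectrum:
    return rg.preprocess(rg.generate_spectrum(aggregated_gt, noise_sd=0.0, seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def rotation_grid_rmsd(frame: np.ndarray, ref: np.ndarray) -> float:
    """Brute-force superposition oracle: axis-angle rotation grid with local
    refinement; independent of the Kabsch/align_vectors implementation."""
    from scipy.spatial.transform import Rotation

    a = frame - frame.mean(axis=0)
    b = ref - ref.mean(axis=0)

    def rmsd_of(axis: np.ndarray, angle: float) -> float:
        axis = axis / np.linalg.norm(axis)
        rot = Rotation.from_rotvec(angle * axis).as_matrix()
        return float(np.sqrt(np.mean(np.sum((a - b @ rot.T) ** 2, axis=1))))

    # Fibonacci sphere of rotation axes x dense angle sweep
    n_axes, n_angles = 400, 90
    golden = np.pi * (3.0 - np.sqrt(5.0))
    i = np.arange(n_axes)
    z = 1.0 - 2.0 * (i + 0.5) / n_axes
    r = np.sqrt(1.0 - z**2)
    axes = np.stack([r * np.cos(golden * i), r * np.sin(golden * i), z], axis=1)
    angles = np.linspace(0.0, np.pi, n_angles)
    best = (np.inf, axes[0], 0.0)
    for axis in axes:
        for angle in angles:
            v = rmsd_of(axis, angle)
            if v < best[0]:
                best = (v, axis, angle)
    # local refinement: perturb the axis in its tangent plane, narrow the angle
    d_axis, d_angle = 2.0 / np.sqrt(n_axes), np.pi / n_angles
    for _ in range(4):
        _, axis0, angle0 = best
        e1 = np.cross(axis0, [1.0, 0.3, 0.2])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(axis0, e1)
        for u in np.linspace(-d_axis, d_axis, 9):
            for v in np.linspace(-d_axis, d_axis, 9):
                axis = axis0 + u * e1 + v * e2
                for angle in angle0 + np.linspace(-d_angle, d_angle, 9):
                    val = rmsd_of(axis, abs(angle))
                    if val < best[0]:
                        best = (val, axis / np.linalg.norm(axis), abs(angle))
        d_axis /= 4.0
        d_angle /= 4.0
    return best[0]
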