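"""Random-chain (Gaussian / freely jointed) linker model.

The disordered linker tethering each kinase domain to the hub is treated as
an ideal random walk of N residue-steps with effective step length b, so the
root-mean-square end-to-end distance is b*sqrt(N). b is not a physical bond
length: it is calibrated from an observed mean linker extension
(b = extension / sqrt(N)) and absorbs all chain physics (excluded volume,
stiffness, projection). The model serves as the null expectation for linker
extensions and parameterizes the ``chain`` radial model of the generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ChainModel", "expected_end_to_end", "calibrate_step",
           "sample_chain_extensions"]


@dataclass(frozen=True)
class ChainModel:
    n_residues: int
    step_length_b: float  # nm per residue step

    def __post_init__(self):
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if self.step_length_b <= 0:
            raise ValueError("step_length_b must be positive")

    @property
    def expected_extension(self) -> float:
        return expected_end_to_end(self.n_residues, self.step_length_b)


def expected_end_to_end(n_residues: int, step_b: float) -> float:
    """RMS end-to-end distance of an ideal chain: b * sqrt(N)."""
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    if step_b <= 0:
        raise ValueError("step_b must be positive")
    return step_b * np.sqrt(n_residues)


def calibrate_step(observed_extension_nm: float, n_residues: int) -> float:
    """Effective step length from an observed mean extension: b = ext/sqrt(N).

    Exact inverse of :func:`expected_end_to_end`.
    """
    if observed_extension_nm <= 0:
        raise ValueError("observed extension must be positive")
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    return observed_extension_nm / np.sqrt(n_residues)


def sample_chain_extensions(n_residues: int, step_b: float, n_samples: int,
                            seed: int | None = None,
                            projected: bool = False) -> np.ndarray:
    """Sample ideal-chain end-to-end distances.

    End-to-end vectors are 3D Gaussian with per-axis SD b*sqrt(N/3);
    ``projected=True`` drops one axis (orthographic projection onto the
    micrograph plane), so the sample RMS converges to b*sqrt(N) in 3D and
    b*sqrt(2N/3) projected.
    """
    model = ChainModel(n_residues, step_b)  # validates
    rng = np.random.default_rng(seed)
    sd = model.step_length_b * np.sqrt(model.n_residues / 3.0)
    vec = rng.normal(0.0, sd, (n_samples, 3))
    if projected:
        vec = vec[:, :2]
    return np.linalg.norm(vec, axis=1)
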