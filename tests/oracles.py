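"""Independent reference implementations used only for verification.

Each oracle is written straight from the defining formula, not from the
package code paths it checks.
"""

import numpy as np
import scipy.linalg


def closed_form_second_direction(s_b: np.ndarray, s_w: np.ndarray) -> np.ndarray:
    """Unit second discriminant direction via the explicit closed form.

    d2 = alpha2 * (S_W^-1 - [s' (S^-1)^2 s / s' (S^-1)^3 s] (S_W^-1)^2) s_b,
    using explicit matrix inverses (acceptable at oracle scale).
    """
    inv = np.linalg.inv(s_w)
    inv2 = inv @ inv
    inv3 = inv2 @ inv
    ratio = (s_b @ inv2 @ s_b) / (s_b @ inv3 @ s_b)
    d = (inv - ratio * inv2) @ s_b
    return d / np.linalg.norm(d)


def leading_generalized_eigvec(s_b: np.ndarray, s_w: np.ndarray) -> np.ndarray:
    """Leading eigenvector of the (between, within) generalized problem."""
    s_between = np.outer(s_b, s_b)
    vals, vecs = scipy.linalg.eigh(s_between, s_w)
    d = vecs[:, np.argmax(vals)]
    return d / np.linalg.norm(d)


def rayleigh(d: np.ndarray, s_b: np.ndarray, s_w: np.ndarray) -> float:
    """Fisher criterion from first principles (rank-one numerator)."""
    return float((s_b @ d) ** 2 / (d @ s_w @ d))


def random_unit_in_complement(
    rng: np.random.Generator, constraints: np.ndarray, n_draws: int
) -> np.ndarray:
    """Unit vectors orthogonal to the rows of ``constraints``."""
    m = constraints.shape[1]
    q, _ = np.linalg.qr(constraints.T, mode="complete")
    comp = q[:, constraints.shape[0] :]  # (m, m-k) orthonormal complement basis
    coeffs = rng.normal(size=(n_draws, comp.shape[1]))
    coeffs /= np.linalg.norm(coeffs, axis=1, keepdims=True)
    return coeffs @ comp.T


def standard_cam(weights: np.ndarray, fmap_tensor: np.ndarray) -> np.ndarray:
    """Textbook CAM: channel maps weighted by the class weights and summed."""
    return np.sum(weights[:, None, None] * fmap_tensor, axis=0)


def random_spd(rng: np.random.Generator, m: int, spread: float = 3.0) -> np.ndarray:
    """Random symmetric positive definite matrix with moderate conditioning."""
    q, _ = np.linalg.qr(rng.normal(size=(m, m)))
    eigs = np.exp(rng.uniform(-spread / 2, spread / 2, size=m))
    return (q * eigs) @ q.T
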