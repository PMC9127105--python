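"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the isochromat ensemble
integrates Bloch rotations spin by spin, and the SSIM oracle evaluates the
textbook formula with an explicit convolution kernel.
"""

import numpy as np
from scipy.signal import convolve2d


def isochromat_fse_train(t1_ms, t2_ms, esp_ms, etl, exc_deg, refoc_deg,
                         n_spins: int = 4096) -> np.ndarray:
    """FSE echo train from a uniformly dephased Bloch isochromat ensemble.

    Ideal crushers are modeled as one unit of dephasing per half echo
    period: spin i accumulates phase theta_i with theta uniform on [0, 2pi).
    Excitation about +y, refocusing about +x, relaxation per half period.
    """
    theta = 2 * np.pi * (np.arange(n_spins) + 0.5) / n_spins
    c, s = np.cos(theta), np.sin(theta)
    M = np.zeros((3, n_spins))
    M[2] = 1.0

    def rot_x(ang):
        ca, sa = np.cos(ang), np.sin(ang)
        return np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])

    def rot_y(ang):
        ca, sa = np.cos(ang), np.sin(ang)
        return np.array([[ca, 0, sa], [0, 1, 0], [-sa, 0, ca]])

    def relax(M, t):
        e1, e2 = np.exp(-t / t1_ms), np.exp(-t / t2_ms)
        M[0] *= e2
        M[1] *= e2
        M[2] = M[2] * e1 + (1 - e1)
        return M

    def precess(M):
        x = M[0] * c - M[1] * s
        y = M[0] * s + M[1] * c
        M[0], M[1] = x, y
        return M

    M = rot_y(np.deg2rad(exc_deg)) @ M
    refoc = np.broadcast_to(np.asarray(refoc_deg, float), (etl,))
    out = np.empty(etl)
    for j in range(etl):
        M = relax(M, esp_ms / 2)
        M = precess(M)
        M = rot_x(np.deg2rad(refoc[j])) @ M
        M = precess(M)
        M = relax(M, esp_ms / 2)
        out[j] = abs(np.mean(M[0] + 1j * M[1]))
    return out


def ssim_map_oracle(x: np.ndarray, y: np.ndarray, sigma: float = 1.5,
                    data_range: float = 255.0) -> np.ndarray:
    """Direct SSIM formula with an explicit truncated Gaussian window.

    Kernel radius 5 (truncate 3.5 sigma), population statistics, valid-mode
    convolution: corresponds to the interior of a padded local-SSIM map.
    """
    r = 5
    g = np.exp(-0.5 * (np.arange(-r, r + 1) / sigma) ** 2)
    g /= g.sum()
    k2 = np.outer(g, g)

    def f(im):
        return convolve2d(im, k2, mode="valid")

    mx, my = f(x), f(y)
    vx = f(x * x) - mx ** 2
    vy = f(y * y) - my ** 2
    cxy = f(x * y) - mx * my
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    return ((2 * mx * my + c1) * (2 * cxy + c2)) / ((mx ** 2 + my ** 2 + c1) * (vx + vy + c2))


def nrmse_oracle(ref: np.ndarray, test: np.ndarray) -> float:
    diff = np.asarray(test, float).ravel() - np.asarray(ref, float).ravel()
    rms = np.sqrt(np.sum(diff * diff) / diff.size)
    return rms / (np.max(ref) - np.min(ref))
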