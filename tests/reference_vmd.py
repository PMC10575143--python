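"""Independent VMD oracle for cross-checking the package implementation.

This is a direct transcription of the original published VMD reference code
(two-sided fftshifted spectrum, updates applied on the positive half, alpha
folded into the Wiener denominator without the factor of two, lambda with the
opposite but equivalent sign convention). It deliberately shares no code or
spectral conventions with ``vmdseiz.vmd``, so agreement between the two is a
meaningful check. Test oracle only -- not part of the package surface.
"""

from __future__ import annotations

import numpy as np


def reference_vmd(
    f: np.ndarray,
    alpha: float,
    tau: float,
    K: int,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (modes [K x N], center frequencies in cycles/sample, ascending)."""
    f = np.asarray(f, dtype=float).ravel()
    save_T = f.size
    T0 = save_T
    f_mirror = np.concatenate([f[: T0 // 2][::-1], f, f[T0 - T0 // 2 :][::-1]])
    T = f_mirror.size

    t = np.arange(1, T + 1) / T
    freqs = t - 0.5 - 1.0 / T

    f_hat = np.fft.fftshift(np.fft.fft(f_mirror))
    f_hat_plus = f_hat.copy()
    f_hat_plus[: T // 2] = 0

    omega = np.zeros((max_iter + 1, K))
    omega[0] = (0.5 / K) * np.arange(K)

    u_hat_plus = np.zeros((K, T), dtype=complex)
    lambda_hat = np.zeros(T, dtype=complex)

    n = 0
    u_diff = tol + np.spacing(1)
    alpha_k = alpha * np.ones(K)
    while u_diff > tol and n < max_iter:
        u_prev = u_hat_plus.copy()
        sum_uk = u_hat_plus.sum(axis=0) - u_hat_plus[0]
        for k in range(K):
            if k > 0:
                sum_uk = sum_uk + u_hat_plus[k - 1] - u_hat_plus[k]
            u_hat_plus[k] = (f_hat_plus - sum_uk - lambda_hat / 2.0) / (
                1.0 + alpha_k[k] * (freqs - omega[n, k]) ** 2
            )
            power = np.abs(u_hat_plus[k, T // 2 :]) ** 2
            omega[n + 1, k] = np.dot(freqs[T // 2 :], power) / power.sum()
        lambda_hat = lambda_hat + tau * (u_hat_plus.sum(axis=0) - f_hat_plus)
        n += 1
        u_diff = np.spacing(1)
        for k in range(K):
            d = u_hat_plus[k] - u_prev[k]
            u_diff += (1.0 / T) * np.real(np.vdot(d, d))

    omega_final = omega[n]

    # reconstruct time-domain modes via hermitian completion
    u_hat = np.zeros((K, T), dtype=complex)
    u_hat[:, T // 2 :] = u_hat_plus[:, T // 2 :]
    u_hat[:, 1 : T // 2 + 1] = np.conj(u_hat_plus[:, T // 2 :][:, ::-1])
    u_hat[:, 0] = np.conj(u_hat[:, -1])
    u = np.real(np.fft.ifft(np.fft.ifftshift(u_hat, axes=-1), axis=-1))
    u = u[:, T // 4 : 3 * T // 4]

    order = np.argsort(omega_final)
    return u[order], omega_final[order]
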