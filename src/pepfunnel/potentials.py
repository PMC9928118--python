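"""Double-rectified linear (dReLU) hidden-unit potential.

Each hidden unit h carries the energy

    U(h) = gamma_plus * h_+^2 / 2 + gamma_minus * h_-^2 / 2
           + theta_plus * h_+ + theta_minus * h_-

with h_+ = max(h, 0), h_- = min(h, 0). Marginalizing h against a linear
input I gives the cumulant generating function

    Gamma(I) = log[ Phi((-I + theta_plus) / sqrt(gamma_plus)) / sqrt(gamma_plus)
                  + Phi((I - theta_minus) / sqrt(gamma_minus)) / sqrt(gamma_minus) ]

with Phi(x) = exp(x^2/2) sqrt(pi/2) erfc(x / sqrt(2)). Gamma is strictly
convex; Gamma'(I) and Gamma''(I) are the mean and variance of the
conditional p(h | I), a two-branch truncated-Gaussian mixture. With
theta_plus = theta_minus = 0 and equal curvatures gamma the potential is
exactly quadratic, Gamma(I) = I^2 / (2 gamma) + log(2 pi / gamma) / 2, which
is the Gaussian/Potts limit used as an enumeration oracle in the tests.

All branch computations are carried in log space; contracts hold for inputs
up to |I| ~ 1e3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr, ndtri_exp

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def log_phi(x: np.ndarray) -> np.ndarray:
    """log of Phi(x) = exp(x^2/2) sqrt(pi/2) erfc(x/sqrt(2)), stable for all x."""
    x = np.asarray(x, dtype=float)
    return 0.5 * x**2 + _LOG_SQRT_2PI + log_ndtr(-x)


def _truncnorm_lower_moments(alpha: np.ndarray):
    """lambda, E[z], E[z^2] of a standard normal truncated to [alpha, inf)."""
    log_pdf = -0.5 * alpha**2 - _LOG_SQRT_2PI
    lam = np.exp(log_pdf - log_ndtr(-alpha))  # phi(alpha) / (1 - Phi(alpha))
    mean = lam
    second = 1.0 + alpha * lam
    return lam, mean, second


def _sample_truncnorm_lower(alpha: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Standard normal truncated to [alpha, inf), via survival inversion.

    S(z) is uniform on (0, S(alpha)]; z = -ndtri_exp(log u + log S(alpha)).
    Stable far into the tail (alpha >> 0).
    """
    u = rng.random(alpha.shape)
    u = np.clip(u, 1e-300, 1.0)
    return -ndtri_exp(np.log(u) + log_ndtr(-alpha))


@dataclass
class DReLU:
    """Vector of M dReLU potentials with trainable parameters."""

    gamma_plus: np.ndarray
    gamma_minus: np.ndarray
    theta_plus: np.ndarray
    theta_minus: np.ndarray

    @classmethod
    def initial(cls, n_hidden: int) -> "DReLU":
        ones = np.ones(n_hidden)
        zeros = np.zeros(n_hidden)
        return cls(ones.copy(), ones.copy(), zeros.copy(), zeros.copy())

    @classmethod
    def quadratic(cls, n_hidden: int, gamma: float = 1.0) -> "DReLU":
        """theta = 0, equal curvatures: Gamma(I) = I^2/(2 gamma) + const."""
        g = np.full(n_hidden, float(gamma))
        z = np.zeros(n_hidden)
        return cls(g.copy(), g.copy(), z.copy(), z.copy())

    def _branches(self, I: np.ndarray):
        """Log branch weights and standardized truncation points.

        Positive branch: h ~ N(mu_p, 1/gamma_p) truncated to [0, inf),
        mu_p = (I - theta_plus)/gamma_plus; weight Z_p = Phi(alpha_p)/sqrt(gamma_p)
        with alpha_p = -mu_p sqrt(gamma_p). The negative branch mirrors it in
        u = -h.
        """
        sqrt_gp = np.sqrt(self.gamma_plus)
        sqrt_gm = np.sqrt(self.gamma_minus)
        alpha_p = (self.theta_plus - I) / sqrt_gp
        alpha_m = (I - self.theta_minus) / sqrt_gm
        log_zp = log_phi(alpha_p) - np.log(sqrt_gp)
        log_zm = log_phi(alpha_m) - np.log(sqrt_gm)
        return alpha_p, alpha_m, log_zp, log_zm

    def gamma(self, I: np.ndarray) -> np.ndarray:
        """Gamma(I), broadcasting over leading axes of I (last axis = M)."""
        _, _, log_zp, log_zm = self._branches(np.asarray(I, dtype=float))
        return np.logaddexp(log_zp, log_zm)

    def _branch_stats(self, I: np.ndarray):
        I = np.asarray(I, dtype=float)
        alpha_p, alpha_m, log_zp, log_zm = self._branches(I)
        p_plus = 1.0 / (1.0 + np.exp(np.clip(log_zm - log_zp, -700, 700)))
        sig_p = 1.0 / np.sqrt(self.gamma_plus)
        sig_m = 1.0 / np.sqrt(self.gamma_minus)
        mu_p = (I - self.theta_plus) / self.gamma_plus
        mu_m = (I - self.theta_minus) / self.gamma_minus
        _, ez_p, ez2_p = _truncnorm_lower_moments(alpha_p)
        _, ez_m, ez2_m = _truncnorm_lower_moments(alpha_m)
        # positive branch: h = mu_p + sig_p * z, z truncated at alpha_p
        mean_p = mu_p + sig_p * ez_p
        second_p = mu_p**2 + 2 * mu_p * sig_p * ez_p + sig_p**2 * ez2_p
        # negative branch: h = -(u), u = -mu_m + sig_m * z truncated at alpha_m
        mean_u = -mu_m + sig_m * ez_m
        second_u = mu_m**2 - 2 * mu_m * sig_m * ez_m + sig_m**2 * ez2_m
        return p_plus, mean_p, second_p, mean_u, second_u

    def mean(self, I: np.ndarray) -> np.ndarray:
        """Gamma'(I) = E[h | I]."""
        p_plus, mean_p, _, mean_u, _ = self._branch_stats(I)
        return p_plus * mean_p - (1 - p_plus) * mean_u

    def variance(self, I: np.ndarray) -> np.ndarray:
        """Gamma''(I) = Var[h | I]."""
        p_plus, mean_p, second_p, mean_u, second_u = self._branch_stats(I)
        mean = p_plus * mean_p - (1 - p_plus) * mean_u
        second = p_plus * second_p + (1 - p_plus) * second_u
        return second - mean**2

    def sample(self, I: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Draw h ~ p(h | I) for every entry of I (last axis = M)."""
        I = np.asarray(I, dtype=float)
        alpha_p, alpha_m, log_zp, log_zm = self._branches(I)
        p_plus = 1.0 / (1.0 + np.exp(np.clip(log_zm - log_zp, -700, 700)))
        pick_plus = rng.random(I.shape) < p_plus
        z_p = _sample_truncnorm_lower(alpha_p, rng)
        z_m = _sample_truncnorm_lower(alpha_m, rng)
        sig_p = 1.0 / np.sqrt(self.gamma_plus)
        sig_m = 1.0 / np.sqrt(self.gamma_minus)
        h_plus = (I - self.theta_plus) / self.gamma_plus + sig_p * z_p
        h_minus = -((self.theta_minus - I) / self.gamma_minus + sig_m * z_m)
        return np.where(pick_plus, h_plus, h_minus)

    def parameter_gradients(self, I: np.ndarray):
        """d Gamma / d (theta_plus, theta_minus, gamma_plus, gamma_minus) at I.

        Returned with the same shape as I; callers average data-minus-model.
        """
        p_plus, mean_p, second_p, mean_u, second_u = self._branch_stats(I)
        d_theta_p = -p_plus * mean_p
        d_theta_m = (1 - p_plus) * mean_u
        d_gamma_p = -p_plus * second_p / 2.0
        d_gamma_m = -(1 - p_plus) * second_u / 2.0
        return d_theta_p, d_theta_m, d_gamma_p, d_gamma_m
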