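"""Free-energy profile models along the membrane normal.

The central analytic form is the sum of two Gaussians,

    G(eta) = A1 exp(-(eta - mu1)^2 / 2 sigma1^2) + A2 exp(-(eta - mu2)^2 / 2 sigma2^2),

which represents both the barrier shapes fitted to simulation profiles and the
synthetic landscapes driven by the Langevin generator.  ``PMFSpec`` wraps this and
a few simpler forms (flat, square barrier, tabulated) behind a single interface
exposing the energy and, where defined, its spatial derivative.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Tuple

import numpy as np


def double_gaussian(eta, a1, mu1, s1, a2, mu2, s2):
    """Sum of two Gaussian bumps, the standard bilayer barrier/well model."""
    eta = np.asarray(eta, dtype=float)
    return a1 * np.exp(-((eta - mu1) ** 2) / (2.0 * s1 ** 2)) + a2 * np.exp(
        -((eta - mu2) ** 2) / (2.0 * s2 ** 2)
    )


def double_gaussian_grad(eta, a1, mu1, s1, a2, mu2, s2):
    """dG/deta of :func:`double_gaussian`."""
    eta = np.asarray(eta, dtype=float)
    g1 = a1 * np.exp(-((eta - mu1) ** 2) / (2.0 * s1 ** 2))
    g2 = a2 * np.exp(-((eta - mu2) ** 2) / (2.0 * s2 ** 2))
    return -(eta - mu1) / s1 ** 2 * g1 - (eta - mu2) / s2 ** 2 * g2


def double_gaussian_jac(eta, a1, mu1, s1, a2, mu2, s2):
    """Jacobian wrt the six parameters, for least-squares fitting."""
    eta = np.asarray(eta, dtype=float)
    e1 = np.exp(-((eta - mu1) ** 2) / (2.0 * s1 ** 2))
    e2 = np.exp(-((eta - mu2) ** 2) / (2.0 * s2 ** 2))
    d1 = eta - mu1
    d2 = eta - mu2
    return np.stack(
        [
            e1,
            a1 * e1 * d1 / s1 ** 2,
            a1 * e1 * d1 ** 2 / s1 ** 3,
            e2,
            a2 * e2 * d2 / s2 ** 2,
            a2 * e2 * d2 ** 2 / s2 ** 3,
        ],
        axis=-1,
    )


@dataclass(frozen=True)
class PMFSpec:
    """A one-dimensional free-energy landscape G(eta) on a finite domain.

    Parameters are in kcal/mol and nm.  ``energy`` extends naturally beyond the
    domain (analytic forms decay to the bulk reference 0; tabulated profiles are
    edge-extended), so the landscape can live inside a larger periodic box.
    """

    form: str
    domain: Tuple[float, float]
    params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        lo, hi = self.domain
        if not (np.isfinite(lo) and np.isfinite(hi) and hi > lo):
            raise ValueError(f"invalid domain {self.domain}")
        if self.form not in ("flat", "square_barrier", "double_gaussian", "tabulated"):
            raise ValueError(f"unknown PMF form {self.form!r}")
        if not np.all(np.isfinite(self.energy(np.linspace(lo, hi, 257)))):
            raise ValueError("PMF must be finite on its domain")

    # -- constructors -------------------------------------------------
    @classmethod
    def flat(cls, domain=(-6.0, 6.0)) -> "PMFSpec":
        return cls("flat", tuple(domain))

    @classmethod
    def square_barrier(cls, height, half_width, center=0.0, domain=(-6.0, 6.0)) -> "PMFSpec":
        return cls(
            "square_barrier",
            tuple(domain),
            {"height": float(height), "half_width": float(half_width), "center": float(center)},
        )

    @classmethod
    def double_gaussian(cls, a1, mu1, s1, a2, mu2, s2, domain=(-6.0, 6.0)) -> "PMFSpec":
        if s1 <= 0 or s2 <= 0:
            raise ValueError("Gaussian widths must be positive")
        return cls(
            "double_gaussian",
            tuple(domain),
            {"a1": float(a1), "mu1": float(mu1), "s1": float(s1),
             "a2": float(a2), "mu2": float(mu2), "s2": float(s2)},
        )

    @classmethod
    def symmetric_barrier(cls, amplitude, mu, sigma, domain=(-6.0, 6.0)) -> "PMFSpec":
        """Two equal Gaussians at +-mu: maxima flanking a central minimum."""
        return cls.double_gaussian(amplitude, -abs(mu), sigma, amplitude, abs(mu), sigma, domain)

    @classmethod
    def tabulated(cls, eta, g, domain=None) -> "PMFSpec":
        eta = np.asarray(eta, dtype=float)
        g = np.asarray(g, dtype=float)
        if eta.ndim != 1 or eta.shape != g.shape or eta.size < 2:
            raise ValueError("tabulated PMF needs matching 1-D eta and G arrays")
        if not np.all(np.diff(eta) > 0):
            raise ValueError("tabulated eta must be strictly increasing")
        if not np.all(np.isfinite(g)):
            raise ValueError("tabulated G must be finite")
        if domain is None:
            domain = (float(eta[0]), float(eta[-1]))
        return cls("tabulated", tuple(domain), {"eta": eta, "g": g})

    # -- evaluation ---------------------------------------------------
    @property
    def differentiable(self) -> bool:
        return self.form != "square_barrier"

    def energy(self, eta):
        """G(eta) in kcal/mol; vectorized."""
        eta = np.asarray(eta, dtype=float)
        p = self.params
        if self.form == "flat":
            return np.zeros_like(eta)
        if self.form == "square_barrier":
            inside = np.abs(eta - p["center"]) <= p["half_width"]
            return np.where(inside, p["height"], 0.0)
        if self.form == "double_gaussian":
            return double_gaussian(eta, p["a1"], p["mu1"], p["s1"], p["a2"], p["mu2"], p["s2"])
        return np.interp(eta, p["eta"], p["g"])

    def grad(self, eta):
        """dG/deta in kcal/mol/nm; undefined for square barriers."""
        eta = np.asarray(eta, dtype=float)
        p = self.params
        if self.form == "flat":
            return np.zeros_like(eta)
        if self.form == "square_barrier":
            raise ValueError("square_barrier PMF is not differentiable")
        if self.form == "double_gaussian":
            return double_gaussian_grad(eta, p["a1"], p["mu1"], p["s1"], p["a2"], p["mu2"], p["s2"])
        dg = np.gradient(p["g"], p["eta"])
        return np.interp(eta, p["eta"], dg)

    def max_abs_grad(self, n=2049) -> float:
        lo, hi = self.domain
        return float(np.max(np.abs(self.grad(np.linspace(lo, hi, n)))))
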