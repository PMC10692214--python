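"""Spatiotemporal pacemaker activation field.

A lymphangion chain contracts where and when its pacemaking sites fire.  Each
site contributes a bivariate Gaussian signal in the space-time plane whose
spatial width encodes how far the contraction wave travels before decaying,
whose temporal width encodes how long the twitch lasts relative to the
contraction period, and whose space-time correlation rho encodes the
conduction (propagation) speed of the wave.  Summing the signals of all sites
(and of the periodic repetitions of each signal in time) and normalizing by
the global maximum yields the dimensionless activation t_act(z, t) in [0, 1]
that drives the wall mechanics.

Parameter rules
---------------
With ``L_pm = 1/sites_per_length`` the pacemaking distance and ``T`` the
contraction period:

* ``sigma_z = L_pm / 8`` -- the wave decays (~4 standard deviations) over half
  the distance to the next pacemaker, so contractions vanish between sites;
* ``sigma_t = T / 4``    -- one decay per contraction period;
* ``rho = sigma_z / (c * sigma_t)`` -- the conditional-mean ridge of the
  bivariate Gaussian has slope ``rho * sigma_t / sigma_z`` in the (z, t)
  plane; equating it to ``1/c`` recovers the conduction speed ``c``.  Fast
  conduction gives rho ~ 0 (synchronous, unskewed signal); slow conduction
  gives a visibly skewed wave.

Retrograde signals are represented by a negative rho (the wave ridge runs
backward in z as time advances).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ANTEGRADE",
    "RETROGRADE",
    "PacemakerSite",
    "ActivationParams",
    "ActivationField",
    "derive_activation_params",
    "place_pacemakers",
    "bivariate_gaussian",
    "build_activation_field",
]

ANTEGRADE = "antegrade"
RETROGRADE = "retrograde"

#: number of periodic temporal images summed on each side of the base signal
N_TEMPORAL_IMAGES = 1

#: hard cap on |rho|; the covariance matrix must stay positive definite
RHO_MAX_DEFAULT = 0.99


class InvalidParameterError(ValueError):
    """Raised when a physical parameter is outside its admissible range."""


@dataclass(frozen=True)
class PacemakerSite:
    """A contraction-initiation locus on the chain.

    Attributes
    ----------
    position_z : float
        Axial coordinate of the site in cm (0 at the chain inlet).
    mu_t : float
        Temporal centre of firing within a contraction period, in s.
    direction : str
        ``"antegrade"`` (wave travels downstream) or ``"retrograde"``.
    """

    position_z: float
    mu_t: float
    direction: str = ANTEGRADE

    def __post_init__(self) -> None:
        if self.direction not in (ANTEGRADE, RETROGRADE):
            raise InvalidParameterError(
                f"direction must be {ANTEGRADE!r} or {RETROGRADE!r}, "
                f"got {self.direction!r}"
            )


@dataclass(frozen=True)
class ActivationParams:
    """Parameters of the bivariate-Gaussian activation signals."""

    sites_per_length: float  # 1/cm
    conduction_speed: float  # cm/s
    frequency: float  # 1/min
    period_T: float  # s
    sigma_z: float  # cm
    sigma_t: float  # s
    rho: float  # dimensionless, >= 0; sign is applied per site direction
    rho_max: float = RHO_MAX_DEFAULT

    def __post_init__(self) -> None:
        for name in ("sites_per_length", "conduction_speed", "frequency",
                     "period_T", "sigma_z", "sigma_t"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if not 0.0 <= abs(self.rho) <= self.rho_max < 1.0:
            raise InvalidParameterError(
                f"need 0 <= |rho| <= rho_max < 1, got rho={self.rho}, "
                f"rho_max={self.rho_max}"
            )


def derive_activation_params(
    sites_per_length: float,
    conduction_speed: float,
    frequency: float,
    period_T: float,
    rho_max: float = RHO_MAX_DEFAULT,
) -> ActivationParams:
    """Derive Gaussian widths and correlation from contractility metrics.

    Parameters are the experimentally measured pacemaking metrics: initiation
    sites per length (1/cm), conduction speed (cm/s), contraction frequency
    (1/min) and contraction period (s).
    """
    for name, val in (
        ("sites_per_length", sites_per_length),
        ("conduction_speed", conduction_speed),
        ("frequency", frequency),
        ("period_T", period_T),
    ):
        if not val > 0:
            raise InvalidParameterError(f"{name} must be > 0, got {val}")
    l_pacemaker = 1.0 / sites_per_length
    sigma_z = l_pacemaker / 8.0
    sigma_t = period_T / 4.0
    rho = float(np.clip(sigma_z / (conduction_speed * sigma_t), 0.0, rho_max))
    return ActivationParams(
        sites_per_length=sites_per_length,
        conduction_speed=conduction_speed,
        frequency=frequency,
        period_T=period_T,
        sigma_z=sigma_z,
        sigma_t=sigma_t,
        rho=rho,
        rho_max=rho_max,
    )


_PATTERNS = {
    "antegrade": lambda i: ANTEGRADE,
    "alternating": lambda i: ANTEGRADE if i % 2 == 0 else RETROGRADE,
    "retrograde": lambda i: RETROGRADE,
}


def place_pacemakers(
    chain_length: float,
    sites_per_length: float,
    pattern: str = "antegrade",
    mu_t: float | None = None,
    period_T: float | None = None,
    conduction_speed: float | None = None,
) -> list[PacemakerSite]:
    """Place pacemaker sites evenly along the chain.

    Sites are spaced at the pacemaking distance ``1/sites_per_length`` and the
    comb is centred on the chain.  ``pattern`` assigns signal directions:
    ``"antegrade"`` (all sites), ``"alternating"`` (antegrade, retrograde,
    antegrade, ...) or ``"retrograde"`` (all sites).

    Firing phase: when ``conduction_speed`` is given (and ``period_T``), each
    site fires when a contraction wave travelling at that speed in the site's
    own direction reaches it from the first pacemaker of that direction,
    ``mu_t_i = (mu_t + delay_i) mod T`` with ``delay_i = (z_i - z_first) / c``
    for an antegrade signal and ``(z_last - z_i) / c`` for a retrograde one
    (``z_first``/``z_last`` the most upstream/downstream site).  For fast
    conduction the delays are negligible and firing is near-simultaneous;
    for slow conduction they are a substantial fraction of the period and
    the sites desynchronize into a travelling sweep.  When
    ``conduction_speed`` is omitted all sites fire at the same ``mu_t``
    (default: mid-period if ``period_T`` is given, else 0).
    """
    if sites_per_length <= 0:
        raise InvalidParameterError("sites_per_length must be > 0")
    if chain_length <= 0:
        raise InvalidParameterError("chain_length must be > 0")
    if pattern not in _PATTERNS:
        raise InvalidParameterError(
            f"pattern must be one of {sorted(_PATTERNS)}, got {pattern!r}"
        )
    if conduction_speed is not None and period_T is None:
        raise InvalidParameterError(
            "period_T is required when conduction_speed is given"
        )
    if mu_t is None:
        mu_t = period_T / 2.0 if period_T is not None else 0.0

    spacing = 1.0 / sites_per_length
    n_sites = int(np.floor(chain_length * sites_per_length + 1e-9))
    direction_of = _PATTERNS[pattern]
    if n_sites < 1:
        warnings.warn(
            "pacemaking distance exceeds chain length; placing a single "
            "midpoint site",
            stacklevel=2,
        )
        positions = [chain_length / 2.0]
    else:
        offset = (chain_length - (n_sites - 1) * spacing) / 2.0
        positions = [offset + i * spacing for i in range(max(n_sites, 1))]

    z_first, z_last = positions[0], positions[-1]
    sites = []
    for i, z in enumerate(positions):
        direction = direction_of(i)
        if conduction_speed is not None:
            delay = (
                (z - z_first) / conduction_speed
                if direction == ANTEGRADE
                else (z_last - z) / conduction_speed
            )
            t_fire = (mu_t + delay) % period_T
        else:
            t_fire = mu_t
        sites.append(PacemakerSite(z, t_fire, direction))
    return sites


def _signed_rho(site: PacemakerSite, params: ActivationParams) -> float:
    rho = abs(params.rho)
    return rho if site.direction == ANTEGRADE else -rho


def bivariate_gaussian(
    z: np.ndarray | float,
    t: np.ndarray | float,
    site: PacemakerSite,
    params: ActivationParams,
) -> np.ndarray | float:
    """Evaluate one pacemaker's bivariate Gaussian signal (units 1/(cm s)).

    The correlation is signed by the site's direction: positive for an
    antegrade wave (later activation downstream of the site), negative for a
    retrograde wave.
    """
    rho = _signed_rho(site, params)
    if not abs(rho) < 1.0:
        raise InvalidParameterError("|rho| must be < 1 for a valid covariance")
    sz, st = params.sigma_z, params.sigma_t
    zh = (np.asarray(z, dtype=float) - site.position_z) / sz
    th = (np.asarray(t, dtype=float) - site.mu_t) / st
    one_m_r2 = 1.0 - rho * rho
    expo = -(zh * zh - 2.0 * rho * zh * th + th * th) / (2.0 * one_m_r2)
    amp = 1.0 / (2.0 * np.pi * sz * st * np.sqrt(one_m_r2))
    out = amp * np.exp(expo)
    if np.isscalar(z) and np.isscalar(t):
        return float(out)
    return out


@dataclass(frozen=True)
class ActivationField:
    """Normalized activation t_act on a (node, time-step) grid for one period.

    ``values[j, i]`` is t_act at node ``z_grid[j]`` and time ``t_grid[i]``;
    the field is periodically extended outside ``[0, period_T)``.  ``gamma``
    is the normalization constant (maximum raw summed signal).
    """

    z_grid: np.ndarray
    t_grid: np.ndarray
    values: np.ndarray
    gamma: float
    period_T: float

    @property
    def dt(self) -> float:
        return float(self.t_grid[1] - self.t_grid[0])

    def step_index(self, t: float) -> int:
        """Index of the time sample for (periodically wrapped) time ``t``."""
        n = self.values.shape[1]
        return int(round((t % self.period_T) / self.dt)) % n

    def at_time(self, t: float) -> np.ndarray:
        """Activation column at time ``t`` (periodic lookup)."""
        return self.values[:, self.step_index(t)]

    def to_dataframe(self):
        """Field as a DataFrame (rows = nodes, columns = time samples)."""
        import pandas as pd

        return pd.DataFrame(self.values, index=self.z_grid, columns=self.t_grid)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="z_cm")

    def plot_kymograph(self, path=None, ax=None):
        """Time-space map of the activation (contraction kymograph)."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3))
        m = ax.pcolormesh(self.t_grid, self.z_grid * 1e1, self.values,
                          cmap="cool", vmin=0.0, vmax=1.0, shading="auto")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("z (mm)")
        plt.colorbar(m, ax=ax, label=r"$t_{act}$")
        if path is not None:
            ax.figure.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(ax.figure)
        return ax


def build_activation_field(
    sites: Sequence[PacemakerSite],
    params: ActivationParams,
    z_grid: Iterable[float],
    t_grid: Iterable[float],
) -> ActivationField:
    """Sum all pacemaker signals, periodize in time and normalize to [0, 1].

    The raw field is the sum over sites and over the periodic temporal images
    ``mu_t + k*T`` (k = -1, 0, +1) of each site's Gaussian, evaluated on the
    given grids; it is then divided by its global maximum so that
    ``max(values) == 1`` exactly.
    """
    z = np.asarray(list(z_grid), dtype=float)
    t = np.asarray(list(t_grid), dtype=float)
    if len(sites) == 0:
        raise InvalidParameterError("at least one pacemaker site is required")
    if z.size < 1 or t.size < 2:
        raise InvalidParameterError("z/t grids must span a non-empty domain")
    dts = np.diff(t)
    if not np.allclose(dts, dts[0], rtol=1e-9, atol=1e-12):
        raise InvalidParameterError("t_grid must be uniformly spaced")
    T = params.period_T
    zz = z[:, None]
    raw = np.zeros((z.size, t.size))
    for site in sites:
        for k in range(-N_TEMPORAL_IMAGES, N_TEMPORAL_IMAGES + 1):
            shifted = replace(site, mu_t=site.mu_t + k * T)
            raw += bivariate_gaussian(zz, t[None, :], shifted, params)
    gamma = float(raw.max())
    if gamma <= 0.0:
        raise InvalidParameterError("raw activation field is identically zero")
    values = raw / gamma
    return ActivationField(z_grid=z, t_grid=t, values=values, gamma=gamma,
                           period_T=T)
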