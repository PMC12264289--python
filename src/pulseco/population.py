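"""Synthetic two-group virtual cohort of arterial pressure waveforms.

The cohort emulates a virtual database of hemodynamic cases with a
normodynamic subpopulation (normal cardiac output, higher mean pressure)
and a hyperdynamic subpopulation (elevated output, vasodilated, lower
mean pressure).  Each subject carries a single periodic cardiac cycle of
pressure at the ascending aorta and at three tonometry-ready peripheral
sites (left common carotid, left superficial temporal, left radial).

The aortic waveform is produced by a 3-element Windkessel
(``C dP_wk/dt = Q(t) - (P_wk - P_ven)/R``, ``P_ao = P_wk + Zc Q``)
driven by a half-sine systolic ejection, integrated cycle-by-cycle to
periodic steady state.  Peripheral waveforms are obtained from the
aortic one with a single-tube transmission-line (tube-load) transfer
function applied harmonic-by-harmonic, which reproduces the
central-to-peripheral pulse-pressure amplification seen in vivo.

This is a reduced-order stand-in for a distributed 1D arterial-tree
model: it is calibrated to the target cohort's printed group statistics,
not derived from anatomy.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    CalibrationError,
    ConfigurationError,
    ConvergenceError,
    DomainError,
)

NORMODYNAMIC = "normodynamic"
HYPERDYNAMIC = "hyperdynamic"

SITE_AORTA = "ascending_aorta"
SITE_CAROTID = "left_common_carotid"
SITE_TEMPORAL = "left_superficial_temporal"
SITE_RADIAL = "left_radial"

#: Peripheral sites in the order they are reported.
PERIPHERAL_SITES = (SITE_TEMPORAL, SITE_CAROTID, SITE_RADIAL)
ALL_SITES = (SITE_AORTA,) + PERIPHERAL_SITES


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CardiacParameters:
    """Lumped cardiac/vascular parameters of one virtual subject.

    Units: heart_rate bpm, stroke_volume mL, cardiac_output L/min,
    target_map mmHg, resistances mmHg·s/mL, total_compliance mL/mmHg,
    venous_pressure mmHg, pulse_wave_velocity m/s.
    """

    group: str
    heart_rate: float
    stroke_volume: float
    cardiac_output: float
    target_map: float
    peripheral_resistance: float
    total_compliance: float
    characteristic_impedance: float
    ejection_fraction_of_cycle: float
    venous_pressure: float
    pulse_wave_velocity: float

    def __post_init__(self) -> None:
        if self.group not in (NORMODYNAMIC, HYPERDYNAMIC):
            raise DomainError(f"unknown group {self.group!r}")
        for name in (
            "heart_rate",
            "stroke_volume",
            "cardiac_output",
            "target_map",
            "peripheral_resistance",
            "total_compliance",
            "characteristic_impedance",
            "venous_pressure",
            "pulse_wave_velocity",
        ):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be strictly positive")
        if not 0 < self.ejection_fraction_of_cycle <= 0.6:
            raise DomainError("ejection_fraction_of_cycle must lie in (0, 0.6]")
        if abs(self.cardiac_output - self.heart_rate * self.stroke_volume / 1000.0) > 1e-9:
            raise DomainError("cardiac_output must equal HR × SV / 1000")

    @property
    def period(self) -> float:
        """Cardiac cycle duration in seconds."""
        return 60.0 / self.heart_rate

    @property
    def ejection_time(self) -> float:
        """Systolic ejection duration in seconds."""
        return self.ejection_fraction_of_cycle * self.period


@dataclass(frozen=True)
class ArterialSiteSpec:
    """Topology and transmission parameters of one arterial site.

    ``path_length`` is the proximal distance from the heart in cm and
    ``bifurcation_count`` the number of branching junctions along that
    path (metadata only; it does not enter the transfer function).
    """

    name: str
    path_length: float
    bifurcation_count: int
    reflection_coefficient: float
    attenuation_per_cm: float
    mean_pressure_drop_per_cm: float

    def __post_init__(self) -> None:
        if not 0 <= self.reflection_coefficient < 1:
            raise DomainError("reflection coefficient must lie in [0, 1)")
        if self.path_length < 0 or self.attenuation_per_cm < 0:
            raise DomainError("path length and attenuation must be non-negative")


def default_site_specs() -> dict[str, ArterialSiteSpec]:
    """Default site table.

    Path lengths and bifurcation counts follow the reference arterial
    arborescence (carotid 20 cm / 2 bifurcations, temporal 46 cm / 6,
    radial 79 cm / 4).  Reflection coefficients, attenuations and mean
    pressure drops are calibrated so that the default cohort reproduces
    the target table's peripheral amplification ordering
    (PP radial > PP carotid > PP aorta) and approximate mean levels.
    """
    return {
        SITE_AORTA: ArterialSiteSpec(SITE_AORTA, 0.0, 0, 0.0, 0.0, 0.0),
        SITE_CAROTID: ArterialSiteSpec(SITE_CAROTID, 20.0, 2, 0.55, 0.001, 0.0),
        SITE_TEMPORAL: ArterialSiteSpec(SITE_TEMPORAL, 46.0, 6, 0.40, 0.004, 0.13),
        SITE_RADIAL: ArterialSiteSpec(SITE_RADIAL, 79.0, 4, 0.50, 0.002, 0.11),
    }


@dataclass(frozen=True)
class PressureWaveform:
    """One periodic cardiac cycle of pressure at a named site.

    ``time`` spans ``[0, period)`` uniformly; ``pressure`` is in mmHg.
    """

    site: str
    period: float
    time: np.ndarray
    pressure: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        p = np.asarray(self.pressure, dtype=float)
        if t.shape != p.shape or t.ndim != 1 or t.size < 2:
            raise DomainError("time and pressure must be matching 1-D arrays")
        if not np.all(np.isfinite(p)):
            raise DomainError("pressure must be finite")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "pressure", p)

    @property
    def mean(self) -> float:
        return float(np.mean(self.pressure))

    @property
    def systolic(self) -> float:
        return float(np.max(self.pressure))

    @property
    def diastolic(self) -> float:
        return float(np.min(self.pressure))

    @property
    def pulse_pressure(self) -> float:
        return self.systolic - self.diastolic

    @property
    def summary(self) -> tuple[float, float, float, float]:
        """(mean, systolic, diastolic, pulse pressure) in mmHg."""
        return (self.mean, self.systolic, self.diastolic, self.pulse_pressure)


@dataclass(frozen=True)
class VirtualSubject:
    """One row of the virtual database: parameters plus 4 site waveforms."""

    id: int
    params: CardiacParameters
    waveforms: dict[str, PressureWaveform]
    quality_flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        periods = {round(w.period, 12) for w in self.waveforms.values()}
        if len(periods) > 1:
            raise DomainError("all site waveforms must share the same period")


@dataclass(frozen=True)
class GroupSampling:
    """Per-group sampling distributions for the cohort generator.

    ``co_map_correlation`` couples cardiac output and mean aortic
    pressure within the group (a near-constant group vasomotor tone);
    ``compliance_scale`` is the constant ``c_g`` of the pressure- and
    period-dependent compliance law
    ``C = c_g · T / (0.06 · (MAP − P_ven)) · exp(ε)`` with
    ``ε ~ N(0, compliance_jitter²)``; it equals the ratio of cardiac
    output (L/min) to the per-cycle diastolic decay exponent.
    """

    co_mean: float
    co_sd: float
    map_mean: float
    map_sd: float
    hr_mean: float
    hr_sd: float
    hr_bounds: tuple[float, float]
    co_map_correlation: float = 0.95
    compliance_scale: float = 1.0
    compliance_jitter: float = 0.05
    truncation_sd: float = 3.5  # symmetric box truncation for CO and MAP

    def validate(self) -> None:
        for name in ("co_sd", "map_sd", "hr_sd"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be positive")
        lo, hi = self.hr_bounds
        if not lo < hi:
            raise ConfigurationError("hr_bounds must be increasing")
        if lo > self.hr_mean + 3 * self.hr_sd or hi < self.hr_mean - 3 * self.hr_sd:
            raise ConfigurationError("hr truncation bounds exclude the mean by > 3 SD")
        if not -1 < self.co_map_correlation < 1:
            raise ConfigurationError("co_map_correlation must lie in (-1, 1)")
        if self.compliance_scale <= 0 or self.compliance_jitter < 0:
            raise ConfigurationError("invalid compliance parameters")


def default_group_sampling() -> dict[str, GroupSampling]:
    """Group distributions calibrated to the target cohort statistics.

    CO/MAP/HR means, SDs and HR min–max bounds are the printed group
    statistics; compliance scales are calibrated so the group mean
    aortic pulse pressures land near 33 (normodynamic) and 63
    (hyperdynamic) mmHg.
    """
    return {
        NORMODYNAMIC: GroupSampling(
            co_mean=5.5,
            co_sd=1.0,
            map_mean=108.1,
            map_sd=20.2,
            hr_mean=81.9,
            hr_sd=8.3,
            hr_bounds=(61.1, 101.6),
            compliance_scale=_COMPLIANCE_SCALE[NORMODYNAMIC],
        ),
        HYPERDYNAMIC: GroupSampling(
            co_mean=6.9,
            co_sd=1.0,
            map_mean=85.8,
            map_sd=11.8,
            hr_mean=83.9,
            hr_sd=7.7,
            hr_bounds=(62.5, 101.6),
            compliance_scale=_COMPLIANCE_SCALE[HYPERDYNAMIC],
        ),
    }


# Compliance scales c_g (L/min per unit diastolic decay exponent)
# calibrated once against the group mean aortic pulse-pressure targets
# 33 / 63 mmHg.
_COMPLIANCE_SCALE = {NORMODYNAMIC: 14.6, HYPERDYNAMIC: 5.8}


@dataclass(frozen=True)
class PopulationConfig:
    """Full configuration of the cohort generator (seeded)."""

    n_normodynamic: int = 2620
    n_hyperdynamic: int = 1198
    groups: dict[str, GroupSampling] = field(default_factory=default_group_sampling)
    sites: dict[str, ArterialSiteSpec] = field(default_factory=default_site_specs)
    venous_pressure: float = 5.0
    pwv_range: tuple[float, float] = (6.0, 10.0)
    # characteristic impedance fraction Zc / R_total: lognormal(median, sigma)
    zc_fraction_median: float = 0.03
    zc_fraction_sigma: float = 0.5
    # systolic-time-interval relation (seconds):
    # T_ej = lvet_intercept + lvet_slope·HR + lvet_sv_slope·(SV − 70 mL),
    # the classic left-ventricular ejection-time regression on heart rate
    # with its positive stroke-volume dependence
    lvet_intercept: float = 0.413
    lvet_slope: float = -0.0017
    lvet_sv_slope: float = 0.0010
    samples_per_cycle: int = 512
    max_resample_fraction: float = 0.10
    seed: int = 0

    @property
    def n_total(self) -> int:
        return self.n_normodynamic + self.n_hyperdynamic

    def validate(self) -> None:
        if self.n_normodynamic <= 0 or self.n_hyperdynamic <= 0:
            raise ConfigurationError("group counts must be positive")
        if self.samples_per_cycle < 300:
            raise ConfigurationError("samples_per_cycle must be ≥ 300")
        if not self.venous_pressure > 0:
            raise ConfigurationError("venous pressure must be positive")
        for g in (NORMODYNAMIC, HYPERDYNAMIC):
            if g not in self.groups:
                raise ConfigurationError(f"missing sampling config for group {g!r}")
            self.groups[g].validate()

    def replace(self, **kw) -> "PopulationConfig":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# parameter sampling
# ---------------------------------------------------------------------------


def _sample_truncated_bivariate(
    rng: np.random.Generator,
    n: int,
    means: tuple[float, float],
    sds: tuple[float, float],
    rho: float,
    n_sd: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Correlated bivariate normal, rejection-truncated to a symmetric
    ``mean ± n_sd·sd`` box (which preserves both marginal means)."""
    out_x = np.empty(n)
    out_y = np.empty(n)
    filled = 0
    cov = np.array(
        [
            [sds[0] ** 2, rho * sds[0] * sds[1]],
            [rho * sds[0] * sds[1], sds[1] ** 2],
        ]
    )
    chol = np.linalg.cholesky(cov)
    while filled < n:
        m = max(256, 2 * (n - filled))
        z = rng.standard_normal((m, 2)) @ chol.T
        x = means[0] + z[:, 0]
        y = means[1] + z[:, 1]
        ok = (
            (np.abs(x - means[0]) <= n_sd * sds[0])
            & (np.abs(y - means[1]) <= n_sd * sds[1])
            & (x > 0)
            & (y > 0)
        )
        x, y = x[ok], y[ok]
        take = min(x.size, n - filled)
        out_x[filled : filled + take] = x[:take]
        out_y[filled : filled + take] = y[:take]
        filled += take
    return out_x, out_y


def _sample_truncated_normal(
    rng: np.random.Generator,
    n: int,
    mean: float,
    sd: float,
    bounds: tuple[float, float],
) -> np.ndarray:
    """Rejection-sampled truncated normal on ``[bounds[0], bounds[1]]``."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = max(256, 2 * (n - filled))
        x = rng.normal(mean, sd, size=m)
        x = x[(x >= bounds[0]) & (x <= bounds[1])]
        take = min(x.size, n - filled)
        out[filled : filled + take] = x[:take]
        filled += take
    return out


def _sample_group_arrays(
    config: PopulationConfig, group: str, n: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Vectorized parameter draw for one group (internal representation)."""
    gs = config.groups[group]
    if gs.co_sd <= 0 or gs.map_sd <= 0:  # defensive; validate() also checks
        raise ConfigurationError("SDs must be positive")
    co, mean_map = _sample_truncated_bivariate(
        rng,
        n,
        (gs.co_mean, gs.map_mean),
        (max(gs.co_sd, 1e-9), max(gs.map_sd, 1e-9)),
        gs.co_map_correlation,
        gs.truncation_sd,
    )
    hr = _sample_truncated_normal(rng, n, gs.hr_mean, max(gs.hr_sd, 1e-9), gs.hr_bounds)
    sv = 1000.0 * co / hr
    period = 60.0 / hr
    t_ej = (
        config.lvet_intercept
        + config.lvet_slope * hr
        + config.lvet_sv_slope * (sv - 70.0)
    )
    t_ej = np.clip(t_ej, 0.05, 0.6 * period)
    pv = config.venous_pressure
    q_mean = co * 1000.0 / 60.0  # mL/s
    r_total = (mean_map - pv) / q_mean
    zeta = np.exp(rng.normal(np.log(config.zc_fraction_median), config.zc_fraction_sigma, n))
    zeta = np.clip(zeta, 0.01, 0.20)
    zc = zeta * r_total
    r_periph = r_total - zc
    eps = rng.normal(0.0, gs.compliance_jitter, n)
    # Pressure-dependent compliance: C = c_g · T / (0.06 (MAP − Pv)) · e^ε.
    # With R_total = 0.06 (MAP − Pv)/CO this gives R·C ≈ c_g T e^ε / CO, so
    # the per-cycle diastolic decay exponent T/(RC) ≈ CO/(c_g e^ε): waveform
    # shape carries cardiac output, as it does in the emulated cohort.
    compliance = gs.compliance_scale * period / (0.06 * (mean_map - pv)) * np.exp(eps)
    pwv = rng.uniform(config.pwv_range[0], config.pwv_range[1], n)
    return {
        "group": np.full(n, group, dtype=object),
        "heart_rate": hr,
        "stroke_volume": sv,
        "cardiac_output": co,
        "target_map": mean_map,
        "peripheral_resistance": r_periph,
        "total_compliance": compliance,
        "characteristic_impedance": zc,
        "ejection_fraction_of_cycle": t_ej / period,
        "venous_pressure": np.full(n, pv),
        "pulse_wave_velocity": pwv,
    }


def _arrays_to_params(arrays: dict[str, np.ndarray]) -> list[CardiacParameters]:
    n = arrays["heart_rate"].size
    fields = [f.name for f in dataclasses.fields(CardiacParameters)]
    out = []
    for i in range(n):
        kw = {}
        for name in fields:
            v = arrays[name][i]
            kw[name] = v if name == "group" else float(v)
        # enforce the CO = HR·SV/1000 identity exactly despite float round-off
        kw["cardiac_output"] = kw["heart_rate"] * kw["stroke_volume"] / 1000.0
        out.append(CardiacParameters(**kw))
    return out


def sample_parameters(
    config: PopulationConfig, rng: np.random.Generator
) -> list[CardiacParameters]:
    """Draw ``n_total`` cardiac/vascular parameter sets (no waveforms)."""
    config.validate()
    arrays = _concat_arrays(
        _sample_group_arrays(config, NORMODYNAMIC, config.n_normodynamic, rng),
        _sample_group_arrays(config, HYPERDYNAMIC, config.n_hyperdynamic, rng),
    )
    return _arrays_to_params(arrays)


def _concat_arrays(*parts: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    keys = parts[0].keys()
    return {k: np.concatenate([p[k] for p in parts]) for k in keys}


# ---------------------------------------------------------------------------
# Windkessel simulation
# ---------------------------------------------------------------------------


def _half_sine_flow(t: np.ndarray, sv: np.ndarray, t_ej: np.ndarray) -> np.ndarray:
    """Half-sine systolic ejection; integrates to the stroke volume."""
    q = np.where(
        t < t_ej,
        (np.pi * sv) / (2.0 * t_ej) * np.sin(np.pi * np.minimum(t, t_ej) / t_ej),
        0.0,
    )
    return q


def _simulate_windkessel_cohort(
    arrays: dict[str, np.ndarray],
    n_steps: int,
    max_cycles: int = 50,
    tol: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the 3-element Windkessel to periodic steady state.

    Vectorized over subjects with per-subject time steps (fixed number
    of steps per cycle).  Returns ``(P_ao, converged)`` where ``P_ao``
    has shape (n_subjects, n_steps), sampled at ``k·T/n_steps``.

    RK4 on ``C dP/dt = Q(t) − (P − Pv)/R`` with analytic inflow, then
    ``P_ao = P + Zc·Q``.
    """
    hr = arrays["heart_rate"]
    n = hr.size
    period = 60.0 / hr
    dt = period / n_steps
    sv = arrays["stroke_volume"]
    t_ej = arrays["ejection_fraction_of_cycle"] * period
    r = arrays["peripheral_resistance"]
    c = arrays["total_compliance"]
    zc = arrays["characteristic_impedance"]
    pv = arrays["venous_pressure"]
    if np.any(r <= 0) or np.any(c <= 0) or np.any(sv <= 0):
        raise DomainError("R, C and SV must be strictly positive")

    # flow at RK4 sample points: full steps and half steps
    k_idx = np.arange(n_steps)
    t_full = k_idx[None, :] * dt[:, None]  # (n, n_steps)
    t_half = t_full + 0.5 * dt[:, None]
    t_next = t_full + dt[:, None]
    q_full = _half_sine_flow(t_full, sv[:, None], t_ej[:, None])
    q_half = _half_sine_flow(t_half, sv[:, None], t_ej[:, None])
    q_next = _half_sine_flow(t_next, sv[:, None], t_ej[:, None])

    inv_rc = 1.0 / (r * c)
    inv_c = 1.0 / c

    def one_cycle(p0: np.ndarray, record: bool = False):
        p = p0.copy()
        trace = np.empty((n, n_steps)) if record else None
        for k in range(n_steps):
            if record:
                trace[:, k] = p
            h = dt
            f1 = q_full[:, k] * inv_c - (p - pv) * inv_rc
            p2 = p + 0.5 * h * f1
            f2 = q_half[:, k] * inv_c - (p2 - pv) * inv_rc
            p3 = p + 0.5 * h * f2
            f3 = q_half[:, k] * inv_c - (p3 - pv) * inv_rc
            p4 = p + h * f3
            f4 = q_next[:, k] * inv_c - (p4 - pv) * inv_rc
            p = p + (h / 6.0) * (f1 + 2 * f2 + 2 * f3 + f4)
        return p, trace

    p0 = arrays["target_map"].copy()  # good initial guess for the cycle start
    converged = np.zeros(n, dtype=bool)
    for _ in range(max_cycles):
        p_end, _ = one_cycle(p0)
        converged = np.abs(p_end - p0) < tol
        p0 = p_end
        if converged.all():
            break
    _, trace = one_cycle(p0, record=True)
    p_ao = trace + zc[:, None] * q_full
    return p_ao, converged


def simulate_aortic_pressure(params: CardiacParameters, dt: float | None = None) -> PressureWaveform:
    """Aortic pressure for one subject via the 3-element Windkessel.

    ``dt`` must satisfy ``dt ≤ period/300``; default is ``period/512``.
    Raises :class:`ConvergenceError` if periodic steady state
    (|P(0) − P(period)| < 0.01 mmHg) is not reached within 50 cycles.
    """
    period = params.period
    if dt is None:
        n_steps = 512
    else:
        if dt > period / 300.0 + 1e-12:
            raise DomainError("dt must be ≤ period/300")
        n_steps = int(round(period / dt))
    arrays = {
        "heart_rate": np.array([params.heart_rate]),
        "stroke_volume": np.array([params.stroke_volume]),
        "ejection_fraction_of_cycle": np.array([params.ejection_fraction_of_cycle]),
        "peripheral_resistance": np.array([params.peripheral_resistance]),
        "total_compliance": np.array([params.total_compliance]),
        "characteristic_impedance": np.array([params.characteristic_impedance]),
        "venous_pressure": np.array([params.venous_pressure]),
        "target_map": np.array([params.target_map]),
    }
    p_ao, converged = _simulate_windkessel_cohort(arrays, n_steps)
    if not converged.all():
        raise ConvergenceError("Windkessel did not reach periodic steady state in 50 cycles")
    time = np.arange(n_steps) * (period / n_steps)
    return PressureWaveform(SITE_AORTA, period, time, p_ao[0])


# ---------------------------------------------------------------------------
# tube-load propagation
# ---------------------------------------------------------------------------


def _tube_load_transfer(
    freqs: np.ndarray, site: ArterialSiteSpec, pwv: np.ndarray
) -> np.ndarray:
    """Single-tube load transfer function H(ω) on the given frequencies.

    ``H(ω) = (1+Γ) e^{−(jω/c + α)L} / (1 + Γ e^{−2(jω/c + α)L})`` with
    the path length L in cm, attenuation α per cm and wave speed c in
    m/s (converted to cm/s).
    """
    if site.reflection_coefficient >= 1:
        raise DomainError("reflection coefficient ≥ 1 gives an unstable transfer")
    gamma = site.reflection_coefficient
    c_cm = pwv * 100.0
    omega = 2.0 * np.pi * freqs
    prop = (1j * omega / c_cm[..., None] + site.attenuation_per_cm) * site.path_length
    h = (1.0 + gamma) * np.exp(-prop) / (1.0 + gamma * np.exp(-2.0 * prop))
    return h


def _propagate_cohort(
    p_ao: np.ndarray,
    period: np.ndarray,
    pwv: np.ndarray,
    site: ArterialSiteSpec,
) -> np.ndarray:
    """Apply the site transfer to every subject's aortic cycle (FFT)."""
    n, n_steps = p_ao.shape
    mean = p_ao.mean(axis=1, keepdims=True)
    spec = np.fft.rfft(p_ao - mean, axis=1)
    k = np.arange(spec.shape[1])
    freqs = k[None, :] / period[:, None]  # harmonic frequencies, Hz
    h = _tube_load_transfer(freqs, site, pwv)
    h[:, 0] = 1.0  # mean level handled separately
    out = np.fft.irfft(spec * h, n=n_steps, axis=1)
    out += mean - site.mean_pressure_drop_per_cm * site.path_length
    return out


def propagate_to_site(
    aortic: PressureWaveform, site: ArterialSiteSpec, params: CardiacParameters
) -> PressureWaveform:
    """Propagate an aortic cycle to a peripheral site (tube-load model)."""
    if site.name == SITE_AORTA:
        raise DomainError("propagation target must be a peripheral site")
    p = aortic.pressure[None, :]
    out = _propagate_cohort(
        p,
        np.array([aortic.period]),
        np.array([params.pulse_wave_velocity]),
        site,
    )
    return PressureWaveform(site.name, aortic.period, aortic.time.copy(), out[0])


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _plausible(
    p_sites: dict[str, np.ndarray], converged: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Physical-plausibility mask plus a low-diastolic warning mask."""
    ok = converged.copy()
    warn = np.zeros_like(converged)
    for name, p in p_sites.items():
        dia = p.min(axis=1)
        sys_ = p.max(axis=1)
        pp = sys_ - dia
        ok &= np.isfinite(p).all(axis=1)
        ok &= (dia > 15.0) & (sys_ < 260.0) & (pp > 5.0) & (pp < 160.0)
        warn |= dia <= 0.0
    return ok, warn


def _simulate_site_matrix(
    arrays: dict[str, np.ndarray], config: PopulationConfig
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    p_ao, converged = _simulate_windkessel_cohort(arrays, config.samples_per_cycle)
    period = 60.0 / arrays["heart_rate"]
    p_sites = {SITE_AORTA: p_ao}
    for name in PERIPHERAL_SITES:
        p_sites[name] = _propagate_cohort(
            p_ao, period, arrays["pulse_wave_velocity"], config.sites[name]
        )
    return p_sites, converged


def generate_population(config: PopulationConfig) -> list[VirtualSubject]:
    """Generate the full seeded cohort (deterministic given config.seed).

    Subjects failing physical-plausibility checks (non-convergence,
    non-physiological pressures) are resampled from their group; a
    resample rate above ``config.max_resample_fraction`` raises
    :class:`CalibrationError`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    per_group: dict[str, dict[str, np.ndarray]] = {}
    resampled = 0
    for group, n_req in (
        (NORMODYNAMIC, config.n_normodynamic),
        (HYPERDYNAMIC, config.n_hyperdynamic),
    ):
        kept: list[dict[str, np.ndarray]] = []
        kept_sites: list[dict[str, np.ndarray]] = []
        n_have = 0
        attempts = 0
        while n_have < n_req:
            n_draw = n_req - n_have
            arrays = _sample_group_arrays(config, group, n_draw, rng)
            p_sites, converged = _simulate_site_matrix(arrays, config)
            ok, _ = _plausible(p_sites, converged)
            resampled += int((~ok).sum())
            if attempts > 0 and resampled > config.max_resample_fraction * config.n_total:
                raise CalibrationError(
                    f"resample rate exceeded {config.max_resample_fraction:.0%}: "
                    "generator mis-specified"
                )
            kept.append({k: v[ok] for k, v in arrays.items()})
            kept_sites.append({k: v[ok] for k, v in p_sites.items()})
            n_have += int(ok.sum())
            attempts += 1
            if attempts > 20:
                raise CalibrationError("generator failed to produce enough plausible subjects")
        per_group[group] = {
            "arrays": _concat_arrays(*kept),
            "sites": _concat_arrays(*kept_sites),
        }
    if resampled > config.max_resample_fraction * config.n_total:
        raise CalibrationError(
            f"{resampled} of {config.n_total} subjects resampled "
            f"(> {config.max_resample_fraction:.0%}): generator mis-specified"
        )
    if resampled:
        logging.getLogger("pulseco").info(
            "resampled %d implausible subjects (%.2f%%)",
            resampled, 100.0 * resampled / config.n_total,
        )

    subjects: list[VirtualSubject] = []
    sid = 0
    for group in (NORMODYNAMIC, HYPERDYNAMIC):
        arrays = per_group[group]["arrays"]
        sites = per_group[group]["sites"]
        params_list = _arrays_to_params(arrays)
        n_steps = config.samples_per_cycle
        for i, params in enumerate(params_list):
            period = params.period
            time = np.arange(n_steps) * (period / n_steps)
            waveforms = {
                name: PressureWaveform(name, period, time, sites[name][i])
                for name in ALL_SITES
            }
            flags = tuple(
                f"low_diastolic:{name}"
                for name in ALL_SITES
                if sites[name][i].min() <= 0
            )
            subjects.append(VirtualSubject(sid, params, waveforms, flags))
            sid += 1
    return subjects


# ---------------------------------------------------------------------------
# summaries and export
# ---------------------------------------------------------------------------


def summarize_population(pop: list[VirtualSubject]):
    """Per-group, per-site table of pressure summaries.

    Rows are (group, site); columns are (quantity, statistic) with
    quantity in {mean_bp, systolic_bp, diastolic_bp, pulse_pressure}
    and statistic in {min, max, mean, sd}; values in mmHg.
    """
    import pandas as pd

    if not pop:
        raise DomainError("population must be non-empty")
    records = []
    for s in pop:
        for name, w in s.waveforms.items():
            m, sy, di, ppr = w.summary
            records.append((s.params.group, name, m, sy, di, ppr))
    df = pd.DataFrame(
        records,
        columns=["group", "site", "mean_bp", "systolic_bp", "diastolic_bp", "pulse_pressure"],
    )
    agg = df.groupby(["group", "site"]).agg(["min", "max", "mean", lambda x: x.std(ddof=0)])
    agg.columns = agg.columns.set_levels(
        [lev if i == 0 else ["min", "max", "mean", "sd"] for i, lev in enumerate(agg.columns.levels)],
        verify_integrity=False,
    )
    return agg


def parameters_frame(pop: list[VirtualSubject]):
    """Wide per-subject parameter table (one row per subject)."""
    import pandas as pd

    rows = []
    for s in pop:
        d = dataclasses.asdict(s.params)
        d["subject_id"] = s.id
        d["quality_flags"] = ";".join(s.quality_flags)
        rows.append(d)
    df = pd.DataFrame(rows)
    cols = ["subject_id"] + [c for c in df.columns if c != "subject_id"]
    return df[cols]


def waveforms_frame(pop: list[VirtualSubject], sites: tuple[str, ...] = ALL_SITES):
    """Long waveform-sample table (subject_id, site, time_s, pressure_mmhg)."""
    import pandas as pd

    frames = []
    for s in pop:
        for name in sites:
            w = s.waveforms[name]
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": s.id,
                        "site": name,
                        "time_s": w.time,
                        "pressure_mmhg": w.pressure,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
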