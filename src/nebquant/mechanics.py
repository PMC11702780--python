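"""Ex vivo muscle mechanics: PCSA, force-frequency sigmoid, fatigue.

Peak forces measured at increasing stimulation frequencies are normalized by
the physiological cross-sectional area (PCSA) to give specific force, then
summarized by a four-parameter sigmoid

    P0(F) = P0min + (P0max - P0min) / (1 + exp((Fhalf - F) / k))

where P0min and P0max are the minimum and maximum specific force, Fhalf the
half-activation frequency and 1/k the steepness.  Curves from two genotypes
are compared with the extra-sum-of-squares F-test (one shared sigmoid versus
two separate ones).  Fatigue is summarized as the ratio of the mean of the
last five to the mean of the first five tetanic peak forces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import f as f_dist

MUSCLE_DENSITY_G_PER_CM3 = 1.056  # physiological density of skeletal muscle

# stimulation protocols (Hz)
SOL_FREQUENCIES = (1.0, 5.0, 10.0, 20.0, 40.0, 60.0, 80.0, 100.0, 150.0)
EDL_FREQUENCIES = SOL_FREQUENCIES + (200.0, 250.0)

FATIGUE_REPETITIONS = 74
FATIGUE_INTERVAL_S = 3.0


@dataclass(frozen=True)
class MusclePhysio:
    """Anatomical inputs of the PCSA computation.

    mass in g, optimal length L0 in cm, pennation angle in degrees,
    fiber-to-muscle length ratio dimensionless, density in g/cm^3.
    """

    mass: float
    optimal_length: float
    pennation_angle: float = 0.0
    fiber_length_ratio: float = 1.0
    density: float = MUSCLE_DENSITY_G_PER_CM3

    def __post_init__(self) -> None:
        if min(self.mass, self.optimal_length, self.fiber_length_ratio, self.density) <= 0:
            raise ValueError("mass, length, ratio and density must be positive")
        if not (0 <= self.pennation_angle < 90):
            raise ValueError("pennation angle must be in [0, 90) degrees")


@dataclass
class ForceFrequencyData:
    frequencies: np.ndarray
    peak_forces: np.ndarray
    pcsa: float | None = None

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.peak_forces = np.asarray(self.peak_forces, dtype=float)
        if self.frequencies.shape != self.peak_forces.shape:
            raise ValueError("frequencies and forces differ in length")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(self.frequencies <= 0) or np.any(self.peak_forces < 0):
            raise ValueError("frequencies must be positive, forces non-negative")


@dataclass
class SigmoidParams:
    p0min: float
    p0max: float
    fhalf: float
    k: float
    residual_ss: float = math.nan

    def __post_init__(self) -> None:
        if self.p0max < self.p0min:
            raise ValueError("p0max must be >= p0min")
        if self.k <= 0 or self.fhalf <= 0:
            raise ValueError("k and fhalf must be positive")


@dataclass
class CurveComparison:
    f_statistic: float
    df_numerator: int
    df_denominator: int
    p_value: float


@dataclass
class FatigueTrace:
    tetanus_peak_forces: np.ndarray
    stimulation_frequency: float = 40.0
    interval: float = FATIGUE_INTERVAL_S
    repetitions: int = field(default=0)

    def __post_init__(self) -> None:
        self.tetanus_peak_forces = np.asarray(self.tetanus_peak_forces, dtype=float)
        if self.repetitions == 0:
            self.repetitions = self.tetanus_peak_forces.size
        if self.tetanus_peak_forces.size != self.repetitions:
            raise ValueError("trace length must equal repetitions")
        if np.any(self.tetanus_peak_forces < 0):
            raise ValueError("forces must be non-negative")


def compute_pcsa(physio: MusclePhysio) -> float:
    """PCSA (cm^2) = mass * cos(theta) / (density * L0 * fiber_length_ratio)."""
    fiber_length = physio.optimal_length * physio.fiber_length_ratio
    return (
        physio.mass * math.cos(math.radians(physio.pennation_angle))
        / (physio.density * fiber_length)
    )


def specific_force(forces: np.ndarray | float, pcsa: float, unit: str = "mN/cm2") -> np.ndarray | float:
    """Normalize forces (mN) by PCSA (cm^2); ``unit='N/cm2'`` divides by 1000."""
    if pcsa <= 0:
        raise ValueError("pcsa must be positive")
    scale = {"mN/cm2": 1.0, "N/cm2": 1e-3}[unit]
    return np.asarray(forces, dtype=float) / pcsa * scale if np.ndim(forces) else forces / pcsa * scale


def sigmoid_eval(freq, p0min: float, p0max: float, fhalf: float, k: float):
    """Evaluate the force-frequency sigmoid at frequency ``freq`` (Hz)."""
    freq = np.asarray(freq, dtype=float)
    out = p0min + (p0max - p0min) / (1.0 + np.exp((fhalf - freq) / k))
    return out if out.ndim else float(out)


def fit_force_frequency(data: ForceFrequencyData) -> SigmoidParams:
    """Bounded least-squares fit of the four-parameter sigmoid.

    Initialization: P0min at the minimum force, P0max at the maximum, Fhalf
    at the frequency whose force is nearest the mid-range, k at a quarter of
    the frequency span.  A flat force profile (dynamic range below 1e-9 of
    the maximum) cannot constrain the sigmoid and raises.
    """
    x, y = data.frequencies, data.peak_forces
    if x.size < 5:
        raise ValueError("need at least 5 points to fit 4 parameters")
    ymin, ymax = float(y.min()), float(y.max())
    if ymax - ymin <= 1e-9 * max(ymax, 1.0):
        raise ValueError("degenerate fit: forces are constant (P0max ~ P0min)")
    mid = 0.5 * (ymin + ymax)
    p0 = [ymin, ymax, float(x[np.argmin(np.abs(y - mid))]), float(x[-1] - x[0]) / 4.0]
    lower = [0.0, 0.0, 1e-9, 1e-9]
    upper = [np.inf, np.inf, np.inf, np.inf]
    popt, _ = curve_fit(sigmoid_eval, x, y, p0=p0, bounds=(lower, upper), maxfev=20000)
    rss = float(np.sum((sigmoid_eval(x, *popt) - y) ** 2))
    p0min, p0max, fhalf, k = map(float, popt)
    if p0max < p0min:  # bounded fit can land here only within tolerance
        p0min, p0max = p0max, p0min
    return SigmoidParams(p0min=p0min, p0max=p0max, fhalf=fhalf, k=k, residual_ss=rss)


def _pooled_rss(datasets: list[ForceFrequencyData]) -> float:
    x = np.concatenate([d.frequencies for d in datasets])
    y = np.concatenate([d.peak_forces for d in datasets])
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    ymin, ymax = float(y.min()), float(y.max())
    mid = 0.5 * (ymin + ymax)
    p0 = [ymin, ymax, float(x[np.argmin(np.abs(y - mid))]), max(float(x[-1] - x[0]) / 4.0, 1e-6)]
    popt, _ = curve_fit(
        sigmoid_eval, x, y, p0=p0,
        bounds=([0.0, 0.0, 1e-9, 1e-9], [np.inf] * 4), maxfev=20000,
    )
    return float(np.sum((sigmoid_eval(x, *popt) - y) ** 2))


def extra_ss_f_test(
    dataset_a: ForceFrequencyData, dataset_b: ForceFrequencyData
) -> CurveComparison:
    """Nested-model comparison of two force-frequency curves.

    Null model: one shared sigmoid fitted to the pooled points (4
    parameters).  Alternative: a separate sigmoid per dataset (8).  The F
    statistic is the per-degree-of-freedom reduction in residual sum of
    squares relative to the alternative model's residual variance; its upper
    tail under F(df_num, df_den) gives the p-value.
    """
    n_total = dataset_a.frequencies.size + dataset_b.frequencies.size
    df_shared = n_total - 4
    df_sep = n_total - 8
    if df_sep <= 0:
        raise ValueError("too few points: denominator degrees of freedom <= 0")
    ss_shared = _pooled_rss([dataset_a, dataset_b])
    ss_sep = fit_force_frequency(dataset_a).residual_ss + fit_force_frequency(dataset_b).residual_ss
    if ss_sep <= 0:
        # perfect separate fits: identical datasets give F=0, otherwise infinite evidence
        f_stat = 0.0 if ss_shared <= 1e-12 else math.inf
    else:
        f_stat = max(((ss_shared - ss_sep) / (df_shared - df_sep)) / (ss_sep / df_sep), 0.0)
    p_value = float(f_dist.sf(f_stat, df_shared - df_sep, df_sep))
    return CurveComparison(
        f_statistic=float(f_stat),
        df_numerator=df_shared - df_sep,
        df_denominator=df_sep,
        p_value=p_value,
    )


def fatigue_index(trace: FatigueTrace | np.ndarray) -> float:
    """Mean of the last five tetanic forces over the mean of the first five.

    1.0 means no fatigue; the standard repeated-stimulation protocol is 74
    tetani at 3 s intervals.
    """
    forces = trace.tetanus_peak_forces if isinstance(trace, FatigueTrace) else np.asarray(trace, float)
    if forces.size < 10:
        raise ValueError("need at least 10 tetani for the fatigue index")
    first = float(np.mean(forces[:5]))
    if first == 0:
        raise ValueError("mean of the first 5 forces is zero")
    return float(np.mean(forces[-5:])) / first
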