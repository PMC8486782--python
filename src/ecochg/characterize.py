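"""I/O curves, growth slopes, and two-component sensory/neural decomposition.

A low-frequency eCochG input/output curve is modeled as the magnitude sum
of a linear sensory component (1 dB/dB) and a compressive neural
component (< 1 dB/dB):

    A(L) = 20 log10( 10**((g_s + L)/20) + 10**((g_n + c*L)/20) )

with sensory gain g_s (dB), neural gain g_n (dB) and compressive exponent
c (dB/dB).  The level where the two components are equal (the breakpoint)
marks the transition from the shallow, neural-dominated to the steep,
sensory-dominated region.  Damage moves the fitted gains: a neural loss
drops g_n and shifts the breakpoint to lower levels with no change at
high levels; a sensory loss drops g_s more than g_n and shifts the whole
curve down while the shallow tail becomes more prominent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats


class CharacterizationError(ValueError):
    pass


@dataclass
class IOCurve:
    """Response amplitude versus stimulus level at one frequency/channel."""

    frequency: float
    levels_db_spl: np.ndarray
    amplitude_db: np.ndarray      # dB re 1 V RMS (or channel unit)
    valid: np.ndarray | None = None
    channel: str = ""

    def __post_init__(self) -> None:
        self.levels_db_spl = np.asarray(self.levels_db_spl, dtype=float)
        self.amplitude_db = np.asarray(self.amplitude_db, dtype=float)
        if np.any(np.diff(self.levels_db_spl) <= 0):
            raise CharacterizationError("levels must be strictly increasing")
        if self.valid is None:
            self.valid = np.ones(self.levels_db_spl.size, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)

    def valid_points(self) -> tuple[np.ndarray, np.ndarray]:
        return self.levels_db_spl[self.valid], self.amplitude_db[self.valid]


def io_slopes(curve: IOCurve) -> tuple[np.ndarray, np.ndarray]:
    """Growth slope (dB/dB) per adjacent pair of valid levels.

    Returns ``(midpoint_levels, slopes)``.
    """
    levels, amps = curve.valid_points()
    if levels.size < 2:
        raise CharacterizationError("need at least 2 valid points for slopes")
    slopes = np.diff(amps) / np.diff(levels)
    midpoints = 0.5 * (levels[:-1] + levels[1:])
    return midpoints, slopes


@dataclass(frozen=True)
class SlopeTestResult:
    mean_slope: float
    t: float
    df: int
    p_one_sided: float       # H1: mean slope < 1
    ci95: tuple[float, float]
    n: int


def slope_vs_unity_test(slopes: np.ndarray) -> SlopeTestResult:
    """One-sample, one-sided t-test of H0: mean slope = 1 vs H1: < 1.

    One slope per replicate animal at a fixed stimulus level.  With zero
    variance the decision is exact by sign (p = 0.5 at the boundary).
    """
    slopes = np.asarray(slopes, dtype=float)
    n = slopes.size
    if n < 3:
        raise CharacterizationError("need >= 3 replicates for the slope test")
    mean = float(slopes.mean())
    sd = float(slopes.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        p = 0.5 if mean == 1.0 else (0.0 if mean < 1.0 else 1.0)
        t_stat = -np.inf if mean < 1.0 else (np.inf if mean > 1.0 else 0.0)
        return SlopeTestResult(mean, t_stat, df, p, (mean, mean), n)
    t_stat = (mean - 1.0) / (sd / np.sqrt(n))
    p = float(stats.t.cdf(t_stat, df))
    half = stats.t.ppf(0.975, df) * sd / np.sqrt(n)
    return SlopeTestResult(mean, float(t_stat), df, p,
                           (mean - half, mean + half), n)


@dataclass
class TwoComponentFit:
    """Linear-plus-compressive decomposition of one I/O curve."""

    g_sensory: float          # dB gain of the 1 dB/dB component
    g_neural: float           # dB gain of the compressive component
    c_neural: float           # compressive exponent, dB/dB (< 1)
    breakpoint_db_spl: float  # level where the components are equal
    residual_db: float        # RMS residual of the fit
    converged: bool = True
    extrapolated: bool = False  # breakpoint outside the fitted level range
    levels_range: tuple[float, float] = (np.nan, np.nan)

    def predict(self, levels: np.ndarray) -> np.ndarray:
        return _two_component_db(np.asarray(levels, dtype=float),
                                 self.g_sensory, self.g_neural, self.c_neural)


def _two_component_db(levels, g_s, g_n, c):
    lin = 10.0 ** ((g_s + levels) / 20.0)
    comp = 10.0 ** ((g_n + c * levels) / 20.0)
    return 20.0 * np.log10(lin + comp)


def fit_two_component(curve: IOCurve,
                      c_starts=(0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)
                      ) -> TwoComponentFit:
    """Least-squares fit of the two-component model in the dB domain.

    Multistart over the compressive exponent; the best solution by
    residual is kept.  A curve with no resolvable compressive component
    (pure 1 dB/dB growth) yields a collapsed g_neural and a breakpoint
    flagged as extrapolated.
    """
    levels, amps = curve.valid_points()
    if levels.size < 4:
        raise CharacterizationError("need >= 4 valid points for the fit")

    def residuals(theta):
        g_s, g_n, c = theta
        return _two_component_db(levels, g_s, g_n, c) - amps

    # data-driven starting gains: anchor the linear component at the top
    # level and the compressive one at the bottom level
    g_s0 = amps[-1] - levels[-1]
    best = None
    for c0 in c_starts:
        g_n0 = amps[0] - c0 * levels[0]
        try:
            sol = optimize.least_squares(
                residuals, x0=[g_s0, g_n0 - 3.0, c0],
                bounds=([-300.0, -300.0, 0.05], [100.0, 100.0, 0.85]))
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return TwoComponentFit(np.nan, np.nan, np.nan, np.nan, np.nan,
                               converged=False,
                               levels_range=(levels[0], levels[-1]))
    g_s, g_n, c = best.x
    resid = float(np.sqrt(np.mean(best.fun ** 2)))
    breakpoint = (g_n - g_s) / (1.0 - c)
    extrapolated = not (levels[0] <= breakpoint <= levels[-1])
    return TwoComponentFit(float(g_s), float(g_n), float(c),
                           float(breakpoint), resid,
                           converged=bool(best.success),
                           extrapolated=bool(extrapolated),
                           levels_range=(float(levels[0]), float(levels[-1])))


@dataclass(frozen=True)
class LossClassification:
    label: str                 # normal | neural | sensory | mixed | indeterminate
    delta_g_sensory: float     # dB reduction re baseline (positive = loss)
    delta_g_neural: float
    evidence: dict = field(default_factory=dict)


def classify_loss(fit_baseline: TwoComponentFit, fit_test: TwoComponentFit,
                  threshold_db: float = 6.0) -> LossClassification:
    """Classify sensorineural loss from baseline/test two-component fits.

    Decision table with threshold T (default 6 dB) on the component-gain
    reductions ``d_s = g_sensory(base) - g_sensory(test)`` and ``d_n``
    likewise:

        d_s < T, d_n < T                      -> normal
        d_n >= T, d_s < T                     -> neural
        d_s >= T, (d_s - d_n) >= T/2          -> sensory
        d_s >= T otherwise                    -> mixed
    """
    if not (fit_baseline.converged and fit_test.converged):
        return LossClassification("indeterminate", np.nan, np.nan,
                                  {"converged": False})
    d_s = fit_baseline.g_sensory - fit_test.g_sensory
    d_n = fit_baseline.g_neural - fit_test.g_neural
    t = threshold_db
    ev = {"sensory_loss": bool(d_s >= t), "neural_loss": bool(d_n >= t),
          "sensory_dominant": bool((d_s - d_n) >= t / 2.0)}
    if d_s < t and d_n < t:
        label = "normal"
    elif d_n >= t and d_s < t:
        label = "neural"
    elif d_s >= t and (d_s - d_n) >= t / 2.0:
        label = "sensory"
    else:
        label = "mixed"
    return LossClassification(label, float(d_s), float(d_n), ev)
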