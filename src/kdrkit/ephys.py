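"""Voltage-clamp tail-current analysis of pyrethroid-modified sodium channels.

Pyrethroids lock a fraction of sodium channels in a slowly deactivating state.
Under a repetitive depolarizing train, the modified channels accumulate and
produce a tail current after the final repolarization.  The percentage of
modified channels is

    M = { [I_tail / (E_h - E_Na)] / [I_Na / (E_t - E_Na)] } * 100,

a ratio of tail to peak chord conductance, where I_tail is the maximal tail
current amplitude, I_Na the peak current during depolarization before drug
exposure, E_h the repolarization potential, E_t the step potential and E_Na
the sodium reversal potential from the current-voltage relation.

M as a function of drug concentration follows a Hill curve

    M(c) = M_max * c**h / (c**h + EC50**h);

EC50 shifts between channel variants quantify changes in pyrethroid
sensitivity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.ndimage import uniform_filter1d
from sklearn.base import BaseEstimator

from . import synergy

__all__ = [
    "VoltageProtocol",
    "CurrentTrace",
    "ModificationResult",
    "HillRegressor",
    "FoldShift",
    "peak_current",
    "tail_amplitude",
    "reversal_potential",
    "percent_modified",
    "modification_result",
    "fit_hill",
    "sensitivity_shift",
    "compare_variants",
]


@dataclass(frozen=True)
class VoltageProtocol:
    """Pulse-train clamp protocol.

    Defaults are the standard tail-current protocol: a 100-pulse train of 5-ms
    step depolarizations from -120 to 0 mV with 5-ms interpulse intervals,
    preceded by ``pre_ms`` at holding potential and followed by ``tail_ms`` of
    post-train repolarization in which the tail current is measured.
    """

    v_hold: float = -120.0
    v_step: float = 0.0
    n_pulses: int = 100
    pulse_ms: float = 5.0
    inter_ms: float = 5.0
    pre_ms: float = 20.0
    tail_ms: float = 50.0

    def __post_init__(self):
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")
        for name in ("pulse_ms", "inter_ms", "pre_ms", "tail_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.v_step == self.v_hold:
            raise ValueError("step and holding potentials must differ")

    def segments(self):
        """(duration_ms, voltage_mV) pieces of the piecewise-constant command."""
        segs = [(self.pre_ms, self.v_hold)]
        for k in range(self.n_pulses):
            segs.append((self.pulse_ms, self.v_step))
            gap = self.inter_ms if k < self.n_pulses - 1 else self.tail_ms
            segs.append((gap, self.v_hold))
        return segs

    @property
    def total_ms(self) -> float:
        return sum(d for d, _ in self.segments())

    @property
    def final_repolarization_ms(self) -> float:
        """Time at which the last pulse ends and the tail window starts."""
        return (
            self.pre_ms
            + self.n_pulses * self.pulse_ms
            + (self.n_pulses - 1) * self.inter_ms
        )


@dataclass
class CurrentTrace:
    """Uniformly sampled clamp current, optionally paired with a pre-drug trace.

    ``current`` is the recording in the drug-exposed condition; ``pre_current``
    (same grid) is the paired recording before drug exposure, used for the
    peak current I_Na.  Inward current is negative.
    """

    sample_interval: float
    current: np.ndarray
    protocol: VoltageProtocol
    meta: dict = field(default_factory=dict)
    pre_current: np.ndarray | None = None

    def __post_init__(self):
        self.current = np.asarray(self.current, dtype=float)
        expected = int(round(self.protocol.total_ms / self.sample_interval))
        if abs(len(self.current) - expected) > 1:
            raise ValueError(
                f"trace length {len(self.current)} does not span the protocol "
                f"({expected} samples at {self.sample_interval} ms)"
            )

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.current)) * self.sample_interval


def _smooth(x: np.ndarray, dt: float, smooth_ms: float) -> np.ndarray:
    w = max(1, int(round(smooth_ms / dt)))
    return uniform_filter1d(x, size=w, mode="nearest")


def _baseline(arr: np.ndarray, dt: float, protocol: VoltageProtocol) -> float:
    # mean holding current before pulse 1, excluding the last 0.5 ms
    stop = max(1, int(round((protocol.pre_ms - 0.5) / dt)))
    return float(np.mean(arr[:stop]))


def peak_current(trace: CurrentTrace, smooth_ms: float = 0.2) -> float:
    """Peak current magnitude I_Na during the first depolarizing pulse.

    Measured on the paired pre-drug trace when present, baseline-subtracted
    (baseline = mean holding current before pulse 1) after light boxcar
    smoothing; the magnitude of the extremum is returned.
    """
    arr = trace.pre_current if trace.pre_current is not None else trace.current
    dt = trace.sample_interval
    p = trace.protocol
    base = _baseline(arr, dt, p)
    i0 = int(round(p.pre_ms / dt))
    i1 = int(round((p.pre_ms + p.pulse_ms) / dt))
    window = arr[i0:i1]
    if window.size == 0:
        raise ValueError("trace does not cover the first depolarizing pulse")
    # smooth inside the window only, so holding-level samples cannot leak in
    window = _smooth(window, dt, smooth_ms) - base
    return float(np.max(np.abs(window)))


def tail_amplitude(
    trace: CurrentTrace, blank_ms: float = 0.3, smooth_ms: float = 0.5
) -> float:
    """Maximal tail current magnitude I_tail after the final repolarization.

    The first ``blank_ms`` after the final voltage step is excluded (capacitive
    blanking); the trace is boxcar-smoothed over ``smooth_ms`` before taking
    the extremum, which suppresses the max-of-noise bias of a raw maximum.
    """
    dt = trace.sample_interval
    p = trace.protocol
    t_rep = p.final_repolarization_ms
    i0 = int(round((t_rep + blank_ms) / dt))
    if i0 >= len(trace.current):
        raise ValueError(
            f"tail window shorter than the {blank_ms} ms blanking period"
        )
    base = _baseline(trace.current, dt, p)
    # smooth inside the post-blanking window only: the repolarization step and
    # the blanked fast-deactivation spike must not leak into the boxcar
    window = _smooth(trace.current[i0:], dt, smooth_ms) - base
    return float(np.max(np.abs(window)))


def reversal_potential(iv) -> float:
    """Reversal potential from a current-voltage curve by linear interpolation.

    ``iv`` is a sequence of (test potential mV, peak current uA) pairs with
    strictly increasing potentials.  The zero crossing between the two
    bracketing points is returned; if the current never changes sign the
    reversal potential is undefined and a ValueError is raised.
    """
    pts = np.asarray(iv, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("IV curve must be a sequence of >= 2 (V, I) pairs")
    v, i = pts[:, 0], pts[:, 1]
    if np.any(np.diff(v) <= 0):
        raise ValueError("test potentials must be strictly increasing")
    zero = np.where(i == 0.0)[0]
    if zero.size:
        return float(v[zero[0]])
    sign_change = np.where(np.diff(np.sign(i)) != 0)[0]
    if sign_change.size == 0:
        raise ValueError("current does not change sign: reversal potential undefined")
    j = sign_change[0]
    frac = -i[j] / (i[j + 1] - i[j])
    return float(v[j] + frac * (v[j + 1] - v[j]))


def percent_modified(i_tail, i_na, e_h, e_na, e_t) -> float:
    """Percentage of pyrethroid-modified channels.

    M = {[I_tail/(E_h - E_Na)]/[I_Na/(E_t - E_Na)]} * 100.  Amplitudes may be
    passed as magnitudes; the signed driving forces make M >= 0 for physically
    consistent inputs.
    """
    if e_h == e_na:
        raise ValueError("repolarization potential equals E_Na: zero driving force")
    if e_t == e_na:
        raise ValueError("step potential equals E_Na: zero driving force")
    if i_na == 0:
        raise ValueError("peak current is zero: modification ratio undefined")
    return float((i_tail / (e_h - e_na)) / (i_na / (e_t - e_na)) * 100.0)


@dataclass(frozen=True)
class ModificationResult:
    i_tail: float
    i_na: float
    e_h: float
    e_na: float
    e_t: float
    m_percent: float


def modification_result(trace: CurrentTrace, e_na: float, **extract_kwargs) -> ModificationResult:
    """Extract I_tail and I_Na from a paired trace and compute M."""
    i_na = peak_current(trace)
    i_tail = tail_amplitude(trace, **extract_kwargs)
    p = trace.protocol
    m = percent_modified(i_tail, i_na, p.v_hold, e_na, p.v_step)
    return ModificationResult(
        i_tail=i_tail, i_na=i_na, e_h=p.v_hold, e_na=e_na, e_t=p.v_step, m_percent=m
    )


class HillConvergenceError(RuntimeError):
    """No Hill-fit start converged."""


class HillRegressor(BaseEstimator):
    """Least-squares Hill dose-response fit M(c) = m_max c^h / (c^h + ec50^h).

    Multi-start Levenberg-Marquardt style optimisation over (m_max,
    log10 ec50, h); starts combine EC50 guesses at the concentration quantiles
    with Hill slopes {0.5, 1, 2}.  Fitted attributes: ``ec50_``, ``hill_``,
    ``m_max_`` with standard errors ``ec50_se_``, ``hill_se_``, ``m_max_se_``,
    plus ``residuals_`` and ``rss_``.
    """

    def __init__(self, n_starts: int = 12, m_max_bound: float = 200.0):
        self.n_starts = n_starts
        self.m_max_bound = m_max_bound

    @staticmethod
    def _model(params, c):
        m_max, log_ec50, h = params
        ch = np.power(c, h)
        return m_max * ch / (ch + (10.0 ** log_ec50) ** h)

    def fit(self, concentration, m_percent):
        c = np.asarray(concentration, dtype=float)
        m = np.asarray(m_percent, dtype=float)
        if c.shape != m.shape:
            raise ValueError("concentration and M arrays must have equal length")
        if np.any(c <= 0):
            raise ValueError("concentrations must be positive")
        if len(np.unique(c)) < 3:
            raise ValueError("need >= 3 distinct concentrations")

        def resid(params):
            return self._model(params, c) - m

        lc = np.log10(np.unique(c))
        ec50_starts = np.quantile(lc, [0.25, 0.5, 0.75])
        m_top = max(m.max(), 1e-6) * 1.05
        starts = [
            (m_top, e, h)
            for e, h in itertools.product(ec50_starts, (0.5, 1.0, 2.0))
        ][: max(self.n_starts, 1)]
        lo = (0.0, lc.min() - 4.0, 0.05)
        hi = (self.m_max_bound, lc.max() + 4.0, 10.0)
        best = None
        for x0 in starts:
            x0 = np.clip(x0, lo, hi)
            try:
                res = optimize.least_squares(resid, x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12)
            except Exception:  # numerical failure of one start is not fatal
                continue
            if not res.success:
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise HillConvergenceError("Hill fit failed to converge from all starts")

        m_max, log_ec50, h = best.x
        resids = best.fun
        dof = max(len(c) - 3, 1)
        s2 = float(resids @ resids) / dof
        jtj = best.jac.T @ best.jac
        try:
            cov = s2 * np.linalg.inv(jtj)
        except np.linalg.LinAlgError:
            cov = s2 * np.linalg.pinv(jtj)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))

        self.m_max_ = float(m_max)
        self.ec50_ = float(10.0 ** log_ec50)
        self.hill_ = float(h)
        self.log10_ec50_se_ = float(se[1])
        self.ec50_se_ = float(self.ec50_ * np.log(10.0) * se[1])
        self.m_max_se_ = float(se[0])
        self.hill_se_ = float(se[2])
        self.residuals_ = resids
        self.rss_ = float(resids @ resids)
        self.n_points_ = len(c)
        return self

    def predict(self, concentration):
        c = np.asarray(concentration, dtype=float)
        return self._model((self.m_max_, np.log10(self.ec50_), self.hill_), c)


def fit_hill(points, **kwargs) -> HillRegressor:
    """Fit a Hill curve to (concentration, M%) pairs."""
    pts = np.asarray(points, dtype=float)
    return HillRegressor(**kwargs).fit(pts[:, 0], pts[:, 1])


@dataclass(frozen=True)
class FoldShift:
    fold: float
    ci95: tuple


def sensitivity_shift(fit_variant: HillRegressor, fit_reference: HillRegressor) -> FoldShift:
    """EC50 fold-shift of a channel variant relative to a reference.

    fold = EC50_variant / EC50_reference; the CI propagates the standard
    errors of the two log10 EC50 estimates.
    """
    for f in (fit_variant, fit_reference):
        if not hasattr(f, "ec50_"):
            raise ValueError("both Hill fits must be fitted (converged)")
    fold = fit_variant.ec50_ / fit_reference.ec50_
    se = float(np.sqrt(fit_variant.log10_ec50_se_ ** 2 + fit_reference.log10_ec50_se_ ** 2))
    z = stats.norm.ppf(0.975)
    ci = (10.0 ** (np.log10(fold) - z * se), 10.0 ** (np.log10(fold) + z * se))
    return FoldShift(fold=float(fold), ci95=(float(ci[0]), float(ci[1])))


def compare_variants(m_by_variant, alpha: float = 0.05):
    """One-way ANOVA with Scheffe contrasts over per-variant M values."""
    return synergy.scheffe_posthoc(m_by_variant, alpha=alpha)
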