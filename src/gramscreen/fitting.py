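"""Nonlinear least-squares fitting of stopped-flow quench traces.

The quencher-mix signal is fitted with the three-compartment
stretched-exponential model (`gramscreen.quench_model`) with the
Stern–Volmer coefficient and external Tl⁺ concentration fixed and
F(0,q), F(∞,q), β, τ₀ free, over a window that excludes the instrument
dead time (default 2 ms – 1 s).  The initial quench rate
Rate(0) = (1 + K_SV[Tl+]_e)·β/τ₀ is the per-trace potency readout.

`QuenchTraceFitter` is a scikit-learn-style estimator (``fit`` /
``predict`` / ``score``, fitted attributes with trailing underscores,
``get_params``/``set_params`` via ``BaseEstimator``) so it composes with
sklearn tooling; `fit_trace` is the thin functional wrapper over it.
Session-level QC (median/MAD outlier rejection standing in for the
bench practice of discarding visibly bad mixing reactions) and the
duplicate-preparation summary rule live here too.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit, logit
from sklearn.base import BaseEstimator

from .quench_model import QuenchModelParams, initial_rate, predict_fluorescence

__all__ = [
    "FluorescenceTrace",
    "TraceFitResult",
    "ReplicateSummary",
    "QuenchTraceFitter",
    "FitFailureError",
    "SessionQualityError",
    "fit_trace",
    "reject_bad_traces",
    "average_rates",
    "summarize_replicates",
]

MIN_WINDOW_SAMPLES = 50


class FitFailureError(RuntimeError):
    """Raised when the fitter cannot converge even after multi-start."""


class SessionQualityError(RuntimeError):
    """Raised when too many traces in a session fail QC."""


@dataclass(frozen=True)
class FluorescenceTrace:
    """One stopped-flow mixing reaction record."""

    time: np.ndarray
    signal: np.ndarray
    mix_type: str                 # 'buffer' or 'quencher'
    replicate_id: str = "r0"

    def __post_init__(self) -> None:
        t = np.asarray(self.time, float)
        s = np.asarray(self.signal, float)
        if t.shape != s.shape or t.ndim != 1:
            raise ValueError("time and signal must be matching 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if self.mix_type not in ("buffer", "quencher"):
            raise ValueError(f"unknown mix_type {self.mix_type!r}")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "signal", s)


@dataclass(frozen=True)
class TraceFitResult:
    """Fit of the quench model to one (or an average of) trace(s)."""

    params: QuenchModelParams
    rate0: float                  # 1/s, equals initial_rate(params)
    r2: float
    qc_flags: frozenset[str] = field(default_factory=frozenset)
    n_traces_used: int = 1
    converged: bool = True
    replicate_id: str = "r0"


@dataclass(frozen=True)
class ReplicateSummary:
    """Across-preparation summary of mean quench rates.

    Duplicates are summarized as mean ± range/2; if the relative
    half-range range/(2·mean) exceeds 0.3 the sample is flagged for
    escalation to triplicate, after which the sample SD is reported.
    """

    mean_rate: float
    dispersion: float
    dispersion_kind: str          # 'half_range' or 'sd'
    n_preps: int
    needs_triplicate: bool = False


class QuenchTraceFitter(BaseEstimator):
    """Fit the stretched-exponential quench model to a fluorescence trace.

    Parameters
    ----------
    ksv, tl_ext : float
        Fixed Stern–Volmer coefficient (1/M) and external quencher
        concentration (M); defaults 60 M⁻¹ and 25 mM.
    window : tuple of float
        Fit window (s); the default (0.002, 1.0) excludes the dead time.
    r2_flag_level : float
        Fits with r² below this are flagged ``low_r2``.
    n_restarts : int
        Jittered restarts attempted on non-convergence.
    seed : int
        Seed for the restart jitter.

    Attributes
    ----------
    f0q_, finfq_, beta_, tau0_ : float
        Recovered model parameters.
    rate0_ : float
        Initial quench rate (1 + K_SV[Tl+]_e)·β/τ₀ (1/s).
    r2_ : float
        Coefficient of determination over the fitted window.
    params_ : QuenchModelParams
    qc_flags_ : frozenset of str
    converged_ : bool

    Notes
    -----
    The bounds 0 < β ≤ 1 and τ₀ > 0 are enforced by fitting in an
    unconstrained parameterization (logistic for β, log for τ₀ and for
    the amplitude/plateau), avoiding active-set artifacts at the β = 1
    boundary.
    """

    def __init__(
        self,
        ksv: float = 60.0,
        tl_ext: float = 0.025,
        window: tuple[float, float] = (0.002, 1.0),
        r2_flag_level: float = 0.95,
        n_restarts: int = 3,
        seed: int = 0,
    ) -> None:
        self.ksv = ksv
        self.tl_ext = tl_ext
        self.window = window
        self.r2_flag_level = r2_flag_level
        self.n_restarts = n_restarts
        self.seed = seed

    # -- internal transformed parameterization ----------------------------
    # theta = (log amplitude, log finfq, logit beta, log tau0)

    @staticmethod
    def _unpack(theta: np.ndarray) -> tuple[float, float, float, float]:
        amp = np.exp(theta[0])
        finfq = np.exp(theta[1])
        beta = expit(theta[2])
        tau0 = np.exp(theta[3])
        return amp + finfq, finfq, beta, tau0

    def _model(self, t: np.ndarray, theta: np.ndarray) -> np.ndarray:
        f0q, finfq, beta, tau0 = self._unpack(theta)
        p = QuenchModelParams(self.ksv, self.tl_ext, tau0, beta, f0q, finfq)
        return predict_fluorescence(t, p)

    def _initial_theta(self, t: np.ndarray, y: np.ndarray) -> np.ndarray:
        n_edge = max(5, t.size // 20)
        f0q0 = float(np.mean(y[:n_edge]))
        finfq0 = float(np.mean(y[-n_edge:]))
        amp0 = max(f0q0 - finfq0, 1e-6 * max(abs(f0q0), 1.0))
        finfq0 = max(finfq0, 1e-9 * max(abs(f0q0), 1.0))
        half = f0q0 - amp0 / 2.0
        below = np.nonzero(y <= half)[0]
        tau0_0 = float(t[below[0]]) if below.size else float(t[t.size // 2])
        tau0_0 = max(tau0_0, float(t[0]))
        return np.array([np.log(amp0), np.log(finfq0), logit(0.9), np.log(tau0_0)])

    def fit(self, t, y) -> "QuenchTraceFitter":
        """Fit the model to samples ``(t, y)`` within the window."""
        t = np.asarray(t, float).ravel()
        y = np.asarray(y, float).ravel()
        if t.size != y.size:
            raise ValueError("t and y must have the same length")
        lo, hi = self.window
        mask = (t >= lo) & (t <= hi)
        if mask.sum() < MIN_WINDOW_SAMPLES:
            raise ValueError(
                f"need >= {MIN_WINDOW_SAMPLES} samples in window, got {mask.sum()}"
            )
        tw, yw = t[mask], y[mask]

        theta0 = self._initial_theta(tw, yw)
        rng = np.random.default_rng(self.seed)
        best = None
        for attempt in range(1 + self.n_restarts):
            start = theta0 if attempt == 0 else theta0 + rng.normal(0, 0.3, 4)
            try:
                res = least_squares(
                    lambda th: self._model(tw, th) - yw, start, method="trf",
                    xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
            except (ValueError, FloatingPointError):
                continue
            if best is None or res.cost < best.cost:
                best = res
            if res.success and attempt == 0:
                break
        if best is None:
            raise FitFailureError("quench-model fit failed on all starts")

        f0q, finfq, beta, tau0 = self._unpack(best.x)
        self.f0q_, self.finfq_, self.beta_, self.tau0_ = f0q, finfq, beta, tau0
        self.params_ = QuenchModelParams(self.ksv, self.tl_ext, tau0, beta, f0q, finfq)
        self.rate0_ = initial_rate(self.params_)
        ss_res = float(np.sum((self._model(tw, best.x) - yw) ** 2))
        ss_tot = float(np.sum((yw - yw.mean()) ** 2))
        self.r2_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        self.converged_ = bool(best.success)
        flags = set()
        if not self.converged_:
            flags.add("fit_failed")
        if np.isnan(self.r2_) or self.r2_ < self.r2_flag_level:
            flags.add("low_r2")
        if f0q - finfq < 1e-9 * max(abs(f0q), 1.0):
            flags.add("nonphysical_plateau")
        self.qc_flags_ = frozenset(flags)
        self.n_window_samples_ = int(mask.sum())
        return self

    def predict(self, t) -> np.ndarray:
        """Model fluorescence at times ``t`` with the fitted parameters."""
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted")
        return np.asarray(predict_fluorescence(np.asarray(t, float), self.params_))

    def score(self, t, y) -> float:
        """Coefficient of determination of the fit on ``(t, y)``."""
        y = np.asarray(y, float).ravel()
        resid = y - self.predict(t)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        return 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")


def fit_trace(
    trace: FluorescenceTrace,
    ksv: float = 60.0,
    tl_ext: float = 0.025,
    window: tuple[float, float] = (0.002, 1.0),
    r2_flag_level: float = 0.95,
    seed: int = 0,
) -> TraceFitResult:
    """Fit one quencher-mix trace and return the QC-annotated result."""
    if trace.mix_type != "quencher":
        raise ValueError("only quencher-mix traces can be fitted")
    est = QuenchTraceFitter(
        ksv=ksv, tl_ext=tl_ext, window=window,
        r2_flag_level=r2_flag_level, seed=seed,
    ).fit(trace.time, trace.signal)
    return TraceFitResult(
        params=est.params_,
        rate0=est.rate0_,
        r2=est.r2_,
        qc_flags=est.qc_flags_,
        n_traces_used=1,
        converged=est.converged_,
        replicate_id=trace.replicate_id,
    )


def reject_bad_traces(
    results: list[TraceFitResult],
    k: float = 5.0,
    max_reject_frac: float = 0.3,
) -> list[TraceFitResult]:
    """Flag outlying per-trace rates (automated bad-trace surrogate).

    A trace is flagged ``outlier_rejected`` when its rate deviates from
    the session median by more than k times the scaled MAD.  The MAD is
    floored at 2% of the median so a near-identical session does not
    reject ordinary noise.  More than ``max_reject_frac`` rejections is
    a session-quality failure.
    """
    if len(results) < 3:
        raise ValueError("need at least 3 fit results")
    rates = np.array([r.rate0 for r in results])
    med = float(np.median(rates))
    mad = float(np.median(np.abs(rates - med)))
    scale = max(1.4826 * mad, 0.02 * abs(med))
    out = []
    n_rejected = 0
    for r in results:
        if scale > 0 and abs(r.rate0 - med) > k * scale:
            out.append(
                dataclasses.replace(r, qc_flags=r.qc_flags | {"outlier_rejected"})
            )
            n_rejected += 1
        else:
            out.append(r)
    if n_rejected > max_reject_frac * len(results):
        raise SessionQualityError(
            f"{n_rejected}/{len(results)} traces rejected "
            f"(limit {max_reject_frac:.0%})"
        )
    return out


def average_rates(results: list[TraceFitResult]) -> float:
    """Mean rate over traces not flagged ``outlier_rejected``."""
    kept = [r.rate0 for r in results if "outlier_rejected" not in r.qc_flags]
    if not kept:
        raise SessionQualityError("no traces left after outlier rejection")
    return float(np.mean(kept))


def summarize_replicates(rates_by_prep: list[float]) -> ReplicateSummary:
    """Summarize per-preparation mean rates across LUV preparations."""
    rates = np.asarray(rates_by_prep, float)
    n = rates.size
    if n < 2:
        raise ValueError("need rates from at least 2 preparations")
    mean = float(rates.mean())
    if n == 2:
        half_range = float(abs(rates[0] - rates[1]) / 2.0)
        needs_tri = mean != 0 and half_range / mean > 0.3
        return ReplicateSummary(mean, half_range, "half_range", n, needs_tri)
    return ReplicateSummary(mean, float(rates.std(ddof=1)), "sd", n, False)
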