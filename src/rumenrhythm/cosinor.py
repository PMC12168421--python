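"""Single-component cosinor rhythmometry.

The cosinor model describes a periodic measurement ``y`` sampled at clock
times ``t`` (hours) as

    y(t) = M + A * cos(2*pi*(t - phi) / P) + e(t)

with mesor ``M`` (rhythm-adjusted mean), amplitude ``A`` (half the
peak-to-trough swing), peak time ``phi`` (acrophase expressed in hours), and
period ``P`` fixed at 24 h for a daily feeding cycle.  The model is linear in
the equivalent parameterization

    y(t) = M + beta * cos(w*t) + gamma * sin(w*t),      w = 2*pi/P

with ``A = sqrt(beta^2 + gamma^2)`` and ``phi = atan2(gamma, beta) / w mod P``,
so single-group fits are ordinary least squares.  Rhythmicity is tested with
the 2-degree-of-freedom F-test of ``beta = gamma = 0`` against the
intercept-only model.  Repeated-measures designs (several cows sampled over
the cycle) are handled by a per-subject random intercept estimated by REML.

Between-group comparisons fit a joint model in which a group indicator
interacts with the intercept and both harmonic terms; differences in mesor,
amplitude and peak time and their Wald p-values are obtained on the
(M, A, phi) scale via the delta method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, InvalidParameterError, RankDeficiencyError

__all__ = [
    "CosinorFit",
    "RhythmComparison",
    "fit_cosinor",
    "fit_cosinor_mixed",
    "circular_peak_diff",
    "compare_rhythms",
]

# Relative tolerance used to declare a sum of squares "exactly zero".
_SS_RTOL = 1e-10


@dataclass
class CosinorFit:
    """Result of a cosinor fit for one series in one group.

    ``subject_var`` is the variance of the per-subject random intercepts and is
    0 for plain (non-mixed) fits or when the REML estimate degenerates.
    ``flags`` collects qualitative conditions: ``degenerate`` (zero residual
    variance with a nonzero amplitude), ``single_subject_fallback``, and
    ``phase_unidentifiable``.
    """

    mesor: float
    amplitude: float
    peak_time: float
    rhythm_p: float
    beta: float
    gamma: float
    residual_sd: float
    n_obs: int
    subject_var: float = 0.0
    period: float = 24.0
    flags: frozenset[str] = frozenset()
    cov: np.ndarray | None = field(default=None, repr=False, compare=False)


@dataclass
class RhythmComparison:
    """Parameter differences (group b minus group a) between two cosinor fits.

    ``d_peak`` is the circular difference of the two peak times mapped into
    (-period/2, period/2]; p-values are Wald tests of a zero group difference
    on the (mesor, amplitude, acrophase) scale.
    """

    fit_a: CosinorFit
    fit_b: CosinorFit
    d_mesor: float
    d_amplitude: float
    d_peak: float
    p_mesor: float
    p_amplitude: float
    p_peak: float
    flags: frozenset[str] = frozenset()


def _design(times: np.ndarray, period: float) -> np.ndarray:
    w = 2.0 * np.pi / period
    return np.column_stack([np.ones_like(times), np.cos(w * times), np.sin(w * times)])


def _check_series(values, times, period: float) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(values, dtype=float).ravel()
    t = np.asarray(times, dtype=float).ravel()
    if y.shape != t.shape:
        raise InvalidParameterError("values and times must have equal length")
    if y.size < 4:
        raise InsufficientDataError(f"need at least 4 observations, got {y.size}")
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(t)):
        raise InvalidParameterError("values and times must be finite")
    distinct = np.unique(np.round(np.mod(t, period), 9))
    if distinct.size < 3:
        raise RankDeficiencyError(
            f"need at least 3 distinct times mod {period}, got {distinct.size}"
        )
    return y, t


def _params_from_coefs(coefs: np.ndarray, period: float) -> tuple[float, float, float, float, float]:
    mesor, beta, gamma = (float(c) for c in coefs)
    amplitude = float(np.hypot(beta, gamma))
    peak_time = float((np.arctan2(gamma, beta) * period / (2.0 * np.pi)) % period)
    return mesor, beta, gamma, amplitude, peak_time


def fit_cosinor(values, times, period: float = 24.0) -> CosinorFit:
    """Fit the fixed-period cosinor model to one series by OLS.

    Parameters
    ----------
    values, times
        Measurement series and sampling times (hours); equal length, >= 4
        observations covering at least 3 distinct times modulo ``period``.
    period
        Cycle length in hours (24 by default; no period estimation is done).

    Returns
    -------
    CosinorFit with the F-test rhythmicity p-value.  A constant series is
    defined to have ``rhythm_p = 1`` (no evidence of rhythm); a perfect
    nonconstant fit gets ``rhythm_p = 0`` and the ``degenerate`` flag.
    """
    if period <= 0:
        raise InvalidParameterError("period must be positive")
    y, t = _check_series(values, times, period)
    n = y.size
    X = _design(t, period)
    coefs, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coefs
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    mesor, beta, gamma, amplitude, peak_time = _params_from_coefs(coefs, period)

    tol = _SS_RTOL * max(1.0, float(y @ y))
    flags: set[str] = set()
    df_res = n - 3
    if ss_tot <= tol:
        # Constant series: amplitude ~ 0 and no evidence of rhythm.
        rhythm_p = 1.0
        residual_sd = 0.0
    elif ss_res <= tol:
        rhythm_p = 0.0
        residual_sd = 0.0
        flags.add("degenerate")
    else:
        f_stat = ((ss_tot - ss_res) / 2.0) / (ss_res / df_res)
        rhythm_p = float(stats.f.sf(f_stat, 2, df_res))
        residual_sd = float(np.sqrt(ss_res / df_res))

    if residual_sd > 0.0:
        cov = residual_sd**2 * np.linalg.inv(X.T @ X)
    else:
        cov = np.zeros((3, 3))
    return CosinorFit(
        mesor=mesor,
        amplitude=amplitude,
        peak_time=peak_time,
        rhythm_p=rhythm_p,
        beta=beta,
        gamma=gamma,
        residual_sd=residual_sd,
        n_obs=n,
        subject_var=0.0,
        period=period,
        flags=frozenset(flags),
        cov=cov,
    )


def fit_cosinor_mixed(values, times, subject_ids, period: float = 24.0) -> CosinorFit:
    """Cosinor fit with a per-subject random intercept (REML).

    The fixed-effect structure is identical to :func:`fit_cosinor`; subjects
    (cows) contribute Gaussian random intercepts whose variance is reported as
    ``subject_var``.  With a single subject the fit falls back to
    :func:`fit_cosinor` with a warning; when the REML variance estimate is
    <= 0 the fit likewise degenerates to OLS with ``subject_var = 0``.
    """
    y, t = _check_series(values, times, period)
    subjects = np.asarray(subject_ids)
    if subjects.shape != y.shape:
        raise InvalidParameterError("subject_ids must match values in length")
    uniq, codes = np.unique(subjects, return_inverse=True)
    if uniq.size < 2:
        warnings.warn("only one subject: falling back to a plain cosinor fit", stacklevel=2)
        fit = fit_cosinor(y, t, period)
        return CosinorFit(
            **{**fit.__dict__, "flags": fit.flags | {"single_subject_fallback"}}
        )
    counts = np.bincount(codes)
    if counts.min() < 3:
        raise InsufficientDataError("every subject needs at least 3 observations")

    X = _design(t, period)

    # Exact path: when subject dummies + harmonics reproduce the data to
    # machine precision, REML has no residual variance to work with.  The
    # parameters are then read off the saturated linear fit directly.
    D = np.zeros((y.size, uniq.size))
    D[np.arange(y.size), codes] = 1.0
    Z = np.hstack([D, X[:, 1:]])
    coefs_z, _, _, _ = np.linalg.lstsq(Z, y, rcond=None)
    resid_z = y - Z @ coefs_z
    tol = _SS_RTOL * max(1.0, float(y @ y))
    if float(resid_z @ resid_z) <= tol:
        intercepts = coefs_z[: uniq.size]
        beta, gamma = float(coefs_z[-2]), float(coefs_z[-1])
        mesor = float(intercepts.mean())
        amplitude = float(np.hypot(beta, gamma))
        peak_time = float((np.arctan2(gamma, beta) * period / (2.0 * np.pi)) % period)
        subject_var = float(np.var(intercepts, ddof=1))
        flags = {"degenerate"} if amplitude > np.sqrt(tol) else set()
        rhythm_p = 0.0 if amplitude > np.sqrt(tol) else 1.0
        return CosinorFit(
            mesor=mesor,
            amplitude=amplitude,
            peak_time=peak_time,
            rhythm_p=rhythm_p,
            beta=beta,
            gamma=gamma,
            residual_sd=0.0,
            n_obs=int(y.size),
            subject_var=subject_var,
            period=period,
            flags=frozenset(flags),
            cov=np.zeros((3, 3)),
        )

    import statsmodels.api as sm

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, X, groups=codes)
            result = model.fit(reml=True)
        subject_var = float(np.asarray(result.cov_re)[0, 0])
    except (np.linalg.LinAlgError, ValueError):
        # REML hits the tau^2 = 0 boundary (e.g. identical subjects): the
        # random intercept is not needed and the fit degenerates to OLS.
        subject_var = 0.0
    if subject_var <= 1e-10:
        fit = fit_cosinor(y, t, period)
        return CosinorFit(**{**fit.__dict__, "subject_var": 0.0})

    fe = np.asarray(result.fe_params, dtype=float)
    cov_fe = np.asarray(result.cov_params())[:3, :3]
    mesor, beta, gamma, amplitude, peak_time = _params_from_coefs(fe, period)
    b = fe[1:3]
    v = cov_fe[1:3, 1:3]
    try:
        wald = float(b @ np.linalg.solve(v, b))
        rhythm_p = float(stats.chi2.sf(wald, 2))
    except np.linalg.LinAlgError:
        rhythm_p = 1.0
    return CosinorFit(
        mesor=mesor,
        amplitude=amplitude,
        peak_time=peak_time,
        rhythm_p=rhythm_p,
        beta=beta,
        gamma=gamma,
        residual_sd=float(np.sqrt(result.scale)),
        n_obs=int(y.size),
        subject_var=subject_var,
        period=period,
        flags=frozenset(),
        cov=cov_fe,
    )


def circular_peak_diff(peak_a: float, peak_b: float, period: float = 24.0) -> float:
    """Signed circular difference ``peak_a - peak_b`` mapped into (-P/2, P/2].

    The boundary value -P/2 is mapped to +P/2, so an exact half-cycle shift is
    always reported as +12 h for a 24-h period.
    """
    if not (0.0 <= peak_a < period and 0.0 <= peak_b < period):
        raise InvalidParameterError("peak times must lie in [0, period)")
    d = (peak_a - peak_b + period / 2.0) % period - period / 2.0
    if d <= -period / 2.0 + 1e-12 * period:
        d = period / 2.0
    return float(d)


def _wald_p(diff: float, var: float) -> float:
    """Two-sided Wald p with a convention for degenerate (zero-variance) fits."""
    if var <= 0.0 or not np.isfinite(var):
        return 1.0 if abs(diff) <= 1e-9 else 0.0
    z = diff / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def compare_rhythms(
    values_a,
    times_a,
    values_b,
    times_b,
    period: float = 24.0,
    subject_ids_a=None,
    subject_ids_b=None,
) -> RhythmComparison:
    """Compare cosinor rhythm parameters between two groups.

    A joint model with a group indicator interacting with the intercept,
    cosine and sine terms is fitted (OLS, or REML with per-subject random
    intercepts when subject ids are supplied for both groups).  Differences
    are reported as group b minus group a; ``d_peak`` uses
    :func:`circular_peak_diff`.  When either group's amplitude is estimated
    with amplitude/SE < 2 the peak time is treated as unidentifiable:
    ``p_peak`` is set to 1 and the ``phase_unidentifiable`` flag raised.
    """
    mixed = subject_ids_a is not None and subject_ids_b is not None
    try:
        fit_a = (
            fit_cosinor_mixed(values_a, times_a, subject_ids_a, period)
            if mixed
            else fit_cosinor(values_a, times_a, period)
        )
    except (InvalidParameterError, InsufficientDataError, RankDeficiencyError) as exc:
        raise InsufficientDataError(f"group 'a' fails fit preconditions: {exc}") from exc
    try:
        fit_b = (
            fit_cosinor_mixed(values_b, times_b, subject_ids_b, period)
            if mixed
            else fit_cosinor(values_b, times_b, period)
        )
    except (InvalidParameterError, InsufficientDataError, RankDeficiencyError) as exc:
        raise InsufficientDataError(f"group 'b' fails fit preconditions: {exc}") from exc

    ya = np.asarray(values_a, dtype=float).ravel()
    yb = np.asarray(values_b, dtype=float).ravel()
    ta = np.asarray(times_a, dtype=float).ravel()
    tb = np.asarray(times_b, dtype=float).ravel()
    y = np.concatenate([ya, yb])
    t = np.concatenate([ta, tb])
    g = np.concatenate([np.zeros(ya.size), np.ones(yb.size)])
    base = _design(t, period)
    X = np.column_stack([base, g, g * base[:, 1], g * base[:, 2]])
    # Column order: [1, cos, sin, g, g*cos, g*sin]

    if mixed:
        import statsmodels.api as sm

        subj = np.concatenate(
            [
                np.char.add("a:", np.asarray(subject_ids_a).astype(str)),
                np.char.add("b:", np.asarray(subject_ids_b).astype(str)),
            ]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = sm.MixedLM(y, X, groups=subj).fit(reml=True)
        theta = np.asarray(result.fe_params, dtype=float)
        V = np.asarray(result.cov_params())[:6, :6]
    else:
        theta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ theta
        ss_res = float(resid @ resid)
        df_res = y.size - 6
        tol = _SS_RTOL * max(1.0, float(y @ y))
        if ss_res <= tol or df_res <= 0:
            V = np.zeros((6, 6))
        else:
            V = (ss_res / df_res) * np.linalg.inv(X.T @ X)

    m_a, beta_a, gamma_a = theta[0], theta[1], theta[2]
    beta_b, gamma_b = theta[1] + theta[4], theta[2] + theta[5]
    amp_a = float(np.hypot(beta_a, gamma_a))
    amp_b = float(np.hypot(beta_b, gamma_b))

    flags: set[str] = set()
    d_mesor = float(theta[3])
    p_mesor = _wald_p(d_mesor, float(V[3, 3]))

    tiny = 1e-12
    d_amp = amp_b - amp_a
    if amp_a > tiny and amp_b > tiny:
        grad = np.zeros(6)
        grad[1] = beta_b / amp_b - beta_a / amp_a
        grad[2] = gamma_b / amp_b - gamma_a / amp_a
        grad[4] = beta_b / amp_b
        grad[5] = gamma_b / amp_b
        p_amp = _wald_p(d_amp, float(grad @ V @ grad))
    else:
        p_amp = _wald_p(d_amp, float(V[4, 4] + V[5, 5]))

    d_peak = circular_peak_diff(fit_b.peak_time, fit_a.peak_time, period)
    # Amplitude-to-SE ratio per group decides whether the phase is identifiable.
    def _amp_se(bb: float, gg: float, amp: float, idx: tuple[int, ...]) -> float:
        if amp <= tiny:
            return np.inf
        grad = np.zeros(6)
        if 1 in idx:
            grad[1] = bb / amp
            grad[2] = gg / amp
        if 4 in idx:
            grad[4] = bb / amp
            grad[5] = gg / amp
        var = float(grad @ V @ grad)
        return np.sqrt(var) if var > 0 else 0.0

    se_amp_a = _amp_se(beta_a, gamma_a, amp_a, (1,))
    se_amp_b = _amp_se(beta_b, gamma_b, amp_b, (1, 4))
    ratio_a = np.inf if se_amp_a == 0 else amp_a / se_amp_a
    ratio_b = np.inf if se_amp_b == 0 else amp_b / se_amp_b
    if amp_a <= tiny or amp_b <= tiny or ratio_a < 2.0 or ratio_b < 2.0:
        p_peak = 1.0
        flags.add("phase_unidentifiable")
    else:
        # phi = atan2(gamma, beta); dphi/dbeta = -gamma/A^2, dphi/dgamma = beta/A^2.
        # phi_b depends on theta[1,2,4,5], phi_a on theta[1,2].
        grad = np.zeros(6)
        grad[1] = (-gamma_b / amp_b**2) - (-gamma_a / amp_a**2)
        grad[2] = (beta_b / amp_b**2) - (beta_a / amp_a**2)
        grad[4] = -gamma_b / amp_b**2
        grad[5] = beta_b / amp_b**2
        var_phi = float(grad @ V @ grad)  # radians^2
        d_phi = d_peak * 2.0 * np.pi / period
        p_peak = _wald_p(d_phi, var_phi)

    return RhythmComparison(
        fit_a=fit_a,
        fit_b=fit_b,
        d_mesor=d_mesor,
        d_amplitude=float(d_amp),
        d_peak=float(d_peak),
        p_mesor=p_mesor,
        p_amplitude=p_amp,
        p_peak=p_peak,
        flags=frozenset(flags),
    )
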