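"""Two-state equilibrium unfolding fits for urea titrations.

The folded <-> unfolded equilibrium is modeled with a free energy linear
in denaturant, dG(u) = dG_unf - m*u, so the folded fraction is logistic
in urea with midpoint Cm = dG_unf/m. Two assays are supported:

* CD titrations: full maximum-likelihood fit with linear folded and
  unfolded baselines and normal noise whose scale grows linearly with
  urea (heteroscedastic);
* pulse proteolysis (band intensities): constant baselines, the m-value
  fixed to its CD estimate, constant noise — equivalent to nonlinear
  least squares.

The observed signal mean follows the parametrization

    mean(u) = (s_unf + b_unf*u) + (s_fold + b_fold*u) * f_folded(u)

i.e. an unfolded baseline plus a folded component modulated by the
folded fraction (slopes fixed to zero for proteolysis).

A nucleotide ligand-contribution term converts between stabilities
measured at different GDP concentrations:
RT*ln((1 + [GDP]_new/K_D) / (1 + [GDP]_old/K_D)), which tends to
RT*ln(new/old) for tight binding (K_D -> 0) and to 0 for weak binding.

Units: kJ/mol for free energies, kJ/(mol*M) for m-values, Kelvin for
temperature; R = 8.314e-3 kJ/(mol*K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, minimize
from scipy.special import expit
from scipy.stats import norm
from statsmodels.tools.numdiff import approx_hess

R_KJ = 8.314e-3  # kJ mol^-1 K^-1
DEFAULT_TEMPERATURE = 298.15  # 25 degC


class FitFailureError(RuntimeError):
    """The optimizer did not produce a credible two-state fit."""


def fraction_folded(
    urea: float | np.ndarray,
    dG: float,
    m: float,
    temperature: float = DEFAULT_TEMPERATURE,
) -> float | np.ndarray:
    """Equilibrium folded fraction at a urea concentration.

    Overflow-safe logistic: exp((dG - m*u)/RT) / (1 + exp(...)).
    Equals 1/2 at the midpoint u = dG/m.
    """
    if m <= 0 or temperature <= 0:
        raise ValueError("m and temperature must be positive")
    u = np.asarray(urea, dtype=float)
    out = expit((dG - m * u) / (R_KJ * temperature))
    return float(out) if np.isscalar(urea) else out


def ligand_contribution(
    gdp_new: float,
    gdp_old: float,
    K_D: float,
    temperature: float = DEFAULT_TEMPERATURE,
) -> float:
    """Stability increment from changing the GDP concentration.

    RT*ln((1 + new/K_D)/(1 + old/K_D)) in kJ/mol; concentrations and K_D
    in the same units (conventionally µM). ``K_D=0`` gives the
    tight-binding limit RT*ln(new/old); ``K_D=inf`` gives 0.
    """
    if gdp_new <= 0 or gdp_old <= 0 or K_D < 0:
        raise ValueError("concentrations must be positive and K_D non-negative")
    RT = R_KJ * temperature
    if K_D == 0:
        return RT * math.log(gdp_new / gdp_old)
    if math.isinf(K_D):
        return 0.0
    return RT * math.log((1 + gdp_new / K_D) / (1 + gdp_old / K_D))


@dataclass
class UnfoldingCurve:
    """One urea titration: concentrations and signal, with assay label."""

    urea: np.ndarray
    signal: np.ndarray
    assay: str = "cd"  # or "proteolysis"
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        self.urea = np.asarray(self.urea, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.urea.shape != self.signal.shape or self.urea.size < 6:
            raise ValueError("urea/signal must be equal-length with >=6 points")
        if np.any(self.urea < 0):
            raise ValueError("urea concentrations must be >= 0")
        if self.assay not in ("cd", "proteolysis"):
            raise ValueError("assay must be 'cd' or 'proteolysis'")


@dataclass
class StabilityFit:
    """Results of a two-state fit (Results object; see ``summary()``).

    ``baselines`` is (signal_unfolded, slope_unfolded, signal_folded,
    slope_folded); slopes are exactly 0 for proteolysis. ``noise`` is
    (sigma_constant, sigma_proportional) for CD and (sigma,) for
    proteolysis. Standard errors are observed-information (Hessian) for
    CD and covariance-based for proteolysis; NaN when unavailable.
    """

    dG_unf: float
    m_value: float
    baselines: tuple[float, float, float, float]
    noise: tuple[float, ...]
    log_likelihood: float
    assay: str
    n_obs: int
    temperature: float
    dG_se: float = float("nan")
    m_se: float = float("nan")

    @property
    def midpoint_Cm(self) -> float:
        return self.dG_unf / self.m_value

    def predict(self, urea: np.ndarray) -> np.ndarray:
        s_u, b_u, s_f, b_f = self.baselines
        f = fraction_folded(urea, self.dG_unf, self.m_value, self.temperature)
        return (s_u + b_u * np.asarray(urea)) + (s_f + b_f * np.asarray(urea)) * f

    def summary(self) -> str:
        lines = [
            f"Two-state unfolding fit ({self.assay}, n={self.n_obs}, "
            f"T={self.temperature:.2f} K)",
            f"  dG_unf     {self.dG_unf:10.3f} +/- {self.dG_se:.3f} kJ/mol",
            f"  m-value    {self.m_value:10.3f} +/- {self.m_se:.3f} kJ/(mol*M)",
            f"  midpoint   {self.midpoint_Cm:10.3f} M (dG_unf/m)",
            f"  baselines  s_unf={self.baselines[0]:.4g} b_unf={self.baselines[1]:.4g}"
            f" s_fold={self.baselines[2]:.4g} b_fold={self.baselines[3]:.4g}",
            f"  noise      {tuple(round(x, 5) for x in self.noise)}",
            f"  loglik     {self.log_likelihood:10.3f}",
        ]
        return "\n".join(lines)


class CDUnfoldingModel:
    """Maximum-likelihood two-state model for a CD urea titration.

    Parameters (in order): dG_unf, m, s_unf, b_unf, s_fold, b_fold,
    sigma_constant, sigma_proportional. The noise scale is
    sigma_constant + sigma_proportional*u.
    """

    _names = ("dG", "m", "s_unf", "b_unf", "s_fold", "b_fold", "sig_c", "sig_p")

    def __init__(
        self,
        urea: np.ndarray,
        signal: np.ndarray,
        temperature: float = DEFAULT_TEMPERATURE,
    ) -> None:
        self.urea = np.asarray(urea, dtype=float)
        self.signal = np.asarray(signal, dtype=float)
        self.temperature = temperature
        if self.urea.size < 8:
            raise ValueError("CD fit needs >=8 points spanning the transition")

    def _mean(self, params: np.ndarray) -> np.ndarray:
        dG, m, s_u, b_u, s_f, b_f = params[:6]
        f = fraction_folded(self.urea, dG, max(m, 1e-9), self.temperature)
        return s_u + b_u * self.urea + (s_f + b_f * self.urea) * f

    def loglike(self, params: np.ndarray) -> float:
        scale = params[6] + params[7] * self.urea
        if np.any(scale <= 0):
            return -np.inf
        return float(np.sum(norm.logpdf(self.signal, self._mean(params), scale)))

    def _mean_curve(self, u: np.ndarray, dG: float, m: float, s_u: float,
                    b_u: float, s_f: float, b_f: float) -> np.ndarray:
        f = fraction_folded(u, dG, max(m, 1e-9), self.temperature)
        return s_u + b_u * u + (s_f + b_f * u) * f

    def _fit_mean(self, n_starts: int, weights: np.ndarray | None):
        """Multistart (weighted) least squares over the six mean params."""
        u, y = self.urea, self.signal
        span = float(y[np.argmin(u)] - y[np.argmax(u)])
        s_unf0 = float(y[np.argmax(u)])
        mids = np.linspace(u.min() + 0.5, u.max() - 0.5, n_starts)
        m0 = 5.0  # kJ/(mol*M), typical small-protein m-value
        best = None
        sigma = None if weights is None else 1.0 / weights
        for cm in mids:
            p0 = [m0 * cm, m0, s_unf0, 0.0, span, 0.0]
            try:
                popt, pcov = curve_fit(
                    self._mean_curve, u, y, p0=p0, sigma=sigma,
                    bounds=([-20, 0.05, -np.inf, -np.inf, -np.inf, -np.inf],
                            [120, 40, np.inf, np.inf, np.inf, np.inf]),
                    maxfev=20000,
                )
            except RuntimeError:
                continue
            r = (y - self._mean_curve(u, *popt)) * (
                np.ones_like(u) if weights is None else weights
            )
            ssr = float(np.sum(r**2))
            if best is None or ssr < best[0]:
                best = (ssr, popt, pcov)
        if best is None:
            raise FitFailureError("least-squares stage failed from every start")
        return best[1], best[2]

    def _fit_noise(self, resid: np.ndarray) -> np.ndarray:
        """ML estimate of (sigma_constant, sigma_proportional) given residuals."""
        u = self.urea
        floor = max(1e-9 * (np.abs(self.signal).max() + 1e-12), 1e-12)

        def nll(q):
            scale = q[0] + q[1] * u
            if np.any(scale <= 0):
                return np.inf
            return float(np.sum(np.log(scale) + resid**2 / (2 * scale**2)))

        q0 = [max(float(np.std(resid)), floor), 0.0]
        res = minimize(nll, q0, method="L-BFGS-B",
                       bounds=[(floor, None), (0.0, None)])
        return res.x

    def fit(self, n_starts: int = 8) -> StabilityFit:
        """Multistart maximum-likelihood fit.

        Stage 1 fits the mean curve by least squares from a grid of
        midpoint guesses; stage 2 estimates the linear noise law from the
        residuals; a joint L-BFGS-B polish of all eight parameters then
        maximizes the full likelihood. Standard errors come from the
        weighted-least-squares covariance at the fitted noise law, with
        the usual residual degrees-of-freedom correction.
        """
        u, y = self.urea, self.signal
        amp = float(np.ptp(y)) + 1e-12
        # stage 1+2: unweighted mean fit, noise law, one reweighted pass
        p_mean, _ = self._fit_mean(n_starts, weights=None)
        q = self._fit_noise(y - self._mean_curve(u, *p_mean))
        w = 1.0 / (q[0] + q[1] * u)
        p_mean, pcov = self._fit_mean(n_starts, weights=w)
        q = self._fit_noise(y - self._mean_curve(u, *p_mean))
        # joint ML polish
        bounds = [
            (-20.0, 120.0), (0.05, 40.0),
            (None, None), (None, None), (None, None), (None, None),
            (max(1e-9 * amp, 1e-12), None), (0.0, None),
        ]
        x0 = np.concatenate([p_mean, q])
        res = minimize(
            lambda p: -self.loglike(p), x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 5000, "ftol": 1e-13, "gtol": 1e-12},
        )
        p = res.x if np.isfinite(res.fun) and -res.fun >= self.loglike(x0) else x0
        ll = self.loglike(p)
        if not np.isfinite(ll):
            raise FitFailureError("likelihood not finite after multistart")
        dG, m = p[0], p[1]
        cm = dG / m
        scale_mid = p[6] + p[7] * min(max(cm, u.min()), u.max())
        folded_amp = abs(p[4] + p[5] * cm)
        if not (u.min() < cm < u.max()) or folded_amp < 2 * scale_mid:
            raise FitFailureError(
                f"no credible transition in range (midpoint {cm:.2f} M, "
                f"folded amplitude {folded_amp:.3g} vs noise {scale_mid:.3g})"
            )
        if dG >= bounds[0][1] - 1e-6 or m >= bounds[1][1] - 1e-6:
            raise FitFailureError("fit pinned at parameter bounds; no transition")
        # a genuine transition must beat a straight line decisively
        lin = np.polyfit(u, y, 1)
        lin_resid = y - np.polyval(lin, u)
        lin_sd = max(float(np.std(lin_resid)), 1e-12)
        ll_lin = float(np.sum(norm.logpdf(lin_resid, 0.0, lin_sd)))
        if 2 * (ll - ll_lin) < 10.0:
            raise FitFailureError(
                "two-state model does not improve on a linear baseline "
                f"(likelihood ratio {2 * (ll - ll_lin):.2f})"
            )
        # dof-corrected WLS covariance at the fitted noise law
        dG_se = m_se = float("nan")
        try:
            scale = p[6] + p[7] * u
            _, pcov = curve_fit(
                self._mean_curve, u, y, p0=p[:6], sigma=scale,
                absolute_sigma=False, maxfev=20000,
            )
            if np.isfinite(pcov[0, 0]) and pcov[0, 0] > 0:
                dG_se = float(np.sqrt(pcov[0, 0]))
            if np.isfinite(pcov[1, 1]) and pcov[1, 1] > 0:
                m_se = float(np.sqrt(pcov[1, 1]))
        except RuntimeError:
            pass
        if not np.isfinite(dG_se):  # observed-information fallback
            try:
                hess = approx_hess(p, lambda z: -self.loglike(z))
                cov = np.linalg.inv(hess)
                if cov[0, 0] > 0:
                    dG_se = float(np.sqrt(cov[0, 0]))
                if cov[1, 1] > 0:
                    m_se = float(np.sqrt(cov[1, 1]))
            except np.linalg.LinAlgError:
                pass
        return StabilityFit(
            dG_unf=float(dG),
            m_value=float(m),
            baselines=(float(p[2]), float(p[3]), float(p[4]), float(p[5])),
            noise=(float(p[6]), float(p[7])),
            log_likelihood=float(ll),
            assay="cd",
            n_obs=len(u),
            temperature=self.temperature,
            dG_se=dG_se,
            m_se=m_se,
        )


class PulseProteolysisModel:
    """Two-state fit of band intensities with the m-value fixed.

    Constant baselines and homoscedastic normal noise make the maximum
    likelihood fit equivalent to nonlinear least squares in
    (dG, s_unf, s_fold).
    """

    def __init__(
        self,
        urea: np.ndarray,
        signal: np.ndarray,
        m_fixed: float,
        temperature: float = DEFAULT_TEMPERATURE,
    ) -> None:
        if m_fixed <= 0:
            raise ValueError("m_fixed must be positive")
        self.urea = np.asarray(urea, dtype=float)
        self.signal = np.asarray(signal, dtype=float)
        self.m_fixed = float(m_fixed)
        self.temperature = temperature

    def fit(self) -> StabilityFit:
        u, y = self.urea, self.signal
        T, m = self.temperature, self.m_fixed

        def model(uu, dG, s_unf, s_fold):
            return s_unf + s_fold * fraction_folded(uu, dG, m, T)

        s_unf0 = float(y[np.argmax(u)])
        span0 = float(y[np.argmin(u)] - y[np.argmax(u)])
        best = None
        for cm0 in np.linspace(u.min() + 0.5, u.max() - 0.5, 8):
            try:
                popt, pcov = curve_fit(
                    model, u, y, p0=[m * cm0, s_unf0, span0], maxfev=20000
                )
            except RuntimeError:
                continue
            ssr = float(np.sum((y - model(u, *popt)) ** 2))
            if best is None or ssr < best[0]:
                best = (ssr, popt, pcov)
        if best is None:
            raise FitFailureError("least squares failed from every start")
        _, popt, pcov = best
        dG, s_unf, s_fold = (float(v) for v in popt)
        resid = y - model(u, *popt)
        dof = max(len(u) - 3, 1)
        sigma = float(np.sqrt(np.sum(resid**2) / dof))
        cm = dG / m
        if not (u.min() < cm < u.max()) or abs(s_fold) < 2 * sigma:
            raise FitFailureError(
                f"no credible transition in range (midpoint {cm:.2f} M)"
            )
        ll = float(np.sum(norm.logpdf(y, model(u, *popt), max(sigma, 1e-12))))
        dG_se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else float("nan")
        return StabilityFit(
            dG_unf=dG,
            m_value=m,
            baselines=(s_unf, 0.0, s_fold, 0.0),
            noise=(sigma,),
            log_likelihood=ll,
            assay="proteolysis",
            n_obs=len(u),
            temperature=T,
            dG_se=dG_se,
            m_se=0.0,
        )


def fit_cd_curve(curve: UnfoldingCurve) -> StabilityFit:
    """Maximum-likelihood two-state fit of a CD titration."""
    if curve.assay != "cd":
        raise ValueError("expected a CD curve")
    return CDUnfoldingModel(curve.urea, curve.signal, curve.temperature).fit()


def fit_proteolysis_curve(curve: UnfoldingCurve, m_fixed: float) -> StabilityFit:
    """Least-squares two-state fit of a proteolysis titration, m fixed."""
    if curve.assay != "proteolysis":
        raise ValueError("expected a proteolysis curve")
    return PulseProteolysisModel(
        curve.urea, curve.signal, m_fixed, curve.temperature
    ).fit()


def replicate_summary(fits: list[StabilityFit]) -> dict[str, float]:
    """Across-replicate mean and SD of dG_unf and the midpoint."""
    if not fits:
        raise ValueError("no fits")
    dgs = np.array([f.dG_unf for f in fits])
    cms = np.array([f.midpoint_Cm for f in fits])
    return {
        "dG_unf_mean": float(dgs.mean()),
        "dG_unf_sd": float(dgs.std(ddof=1)) if len(fits) > 1 else 0.0,
        "Cm_mean": float(cms.mean()),
        "Cm_sd": float(cms.std(ddof=1)) if len(fits) > 1 else 0.0,
        "n_replicates": len(fits),
    }
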