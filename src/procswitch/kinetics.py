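"""Four-state processivity-switch kinetics and global first-passage fitting.

The model: a helicase bound at a hairpin interconverts between a
low-processivity state (its initial state) and a high-processivity state
with rates k1 (concentration-dependent: the ssDNA-binding protein shifts
the equilibrium) and k_minus1.  From the high state it crosses a 25 bp
classification threshold at rate k2, after which it is scored
high-processivity; from the low state it can dissociate at rate k_off
(dissociation from the high state, k'_off, is zero in the reference model).
Master equations for the state probabilities:

    dP_low/dt  = k_minus1 P_high - (k_off + k1) P_low
    dP_high/dt = k1 P_low - (k'_off + k_minus1 + k2) P_high
    dP_off/dt  = k_off P_low + k'_off P_high
    dP_>25/dt  = k2 P_high

with P_low(0) = 1.  The probability of having crossed by time t has the
closed form

    P_>25(t) = k D / (lam_minus - lam_plus)
               * [ (1 - exp(-lam_plus t))/lam_plus
                 - (1 - exp(-lam_minus t))/lam_minus ],

where lam_+- are the eigenvalues of the transient 2x2 generator block.
Grouping concentration-dependent and -independent terms gives five fit
parameters A, B, C, D and k = k([c]), related to the rates by
k1 = k, k2 = D, k_minus1 = C - A, k'_off = A - D, k_off = B, and

    lam_+- = (k + B + C)/2 +- sqrt( ((k + B + C)/2)^2 - (A k + B C) ).

The global fit shares A, B, C, D across concentrations with one k per
concentration; the reference constraint k'_off = 0 makes A = D and leaves
four kinds of parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import least_squares, minimize

from .simulate import (FirstPassageDataset, KineticRates,
                       simulate_first_passage)

_REL_DEGENERATE = 1e-9


@dataclass(frozen=True)
class FitParams:
    """Grouped fit parameterisation {A, B, C, D} + k per concentration.

    ``k`` maps concentration in nM to the low->high switching rate there.
    """

    A: float
    B: float
    C: float
    D: float
    k: dict = field(default_factory=dict)   # conc_nM -> s^-1

    def rates_at(self, conc_nM: float) -> KineticRates:
        """Map the grouped parameters back to rate constants at ``conc_nM``."""
        return KineticRates(k1=self.k[conc_nM], k_minus1=self.C - self.A,
                            k2=self.D, k_off=self.B,
                            k_off_prime=self.A - self.D)

    @classmethod
    def from_rates(cls, rates_by_conc: dict[float, KineticRates]) -> "FitParams":
        any_rates = next(iter(rates_by_conc.values()))
        A = any_rates.k2 + any_rates.k_off_prime
        return cls(A=A, B=any_rates.k_off, C=any_rates.k_minus1 + A,
                   D=any_rates.k2,
                   k={c: r.k1 for c, r in rates_by_conc.items()})


@dataclass(frozen=True)
class LinearRateLaw:
    """k1 = slope * [c] + intercept, with standard errors."""

    slope: float            # M^-1 s^-1
    intercept: float        # s^-1
    slope_se: float
    intercept_se: float


@dataclass
class StateProbabilities:
    """Time courses of the four state probabilities."""

    time: np.ndarray
    P_low: np.ndarray
    P_high: np.ndarray
    P_off: np.ndarray
    P_gt25: np.ndarray


def _eigvals(k: float, A: float, B: float, C: float) -> tuple[float, float]:
    s = 0.5 * (k + B + C)
    disc = s * s - (A * k + B * C)
    if disc < -1e-12 * max(s * s, 1.0):
        raise FloatingPointError(
            "negative eigenvalue discriminant: unphysical parameters")
    root = np.sqrt(max(disc, 0.0))
    return s + root, s - root


def eigenvalues(params: FitParams, conc_nM: float) -> tuple[float, float]:
    """Decay constants (lam_plus, lam_minus) of the transient block, s^-1.

    Both are real and non-negative for physical rate constants; a negative
    discriminant signals an unphysical parameter combination.
    """
    return _eigvals(params.k[conc_nM], params.A, params.B, params.C)


def _phi(lam, t):
    """(1 - exp(-lam t)) / lam, with the lam -> 0 limit t."""
    lam = np.asarray(lam, dtype=float)
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(lam > 0, -np.expm1(-lam * t) / np.where(lam > 0, lam, 1.0), t)
    return out


def p_gt25_raw(t, k: float, A: float, B: float, C: float, D: float):
    """Closed-form crossing probability from the grouped parameters."""
    t = np.asarray(t, dtype=float)
    lam_p, lam_m = _eigvals(k, A, B, C)
    if lam_p <= 0:
        return np.zeros_like(t)
    if (lam_p - lam_m) < _REL_DEGENERATE * lam_p:
        # repeated-root limit: k D [ (1 - e^{-lam t}) - lam t e^{-lam t} ] / lam^2
        lam = lam_p
        out = k * D * (-np.expm1(-lam * t) - lam * t * np.exp(-lam * t)) / lam**2
    else:
        out = (k * D / (lam_m - lam_p)) * (_phi(lam_p, t) - _phi(lam_m, t))
    return out if out.ndim else float(out)


def p_gt25(t, params: FitParams, conc_nM: float):
    """Probability that a molecule has crossed the 25 bp threshold by ``t``.

    Non-decreasing in t, 0 at t = 0, with limit k D / (k A + B C) as
    t -> infinity.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    return p_gt25_raw(t, params.k[conc_nM], params.A, params.B,
                      params.C, params.D)


def p_gt25_infinity(params: FitParams, conc_nM: float) -> float:
    """Long-time crossing probability k D / (k A + B C)."""
    k = params.k[conc_nM]
    denom = k * params.A + params.B * params.C
    if denom == 0:
        return 0.0
    return k * params.D / denom


def generator_matrix(rates: KineticRates) -> np.ndarray:
    """4x4 generator over states (low, high, off, crossed); columns sum to 0."""
    k1, km1, k2 = rates.k1, rates.k_minus1, rates.k2
    koff, koffp = rates.k_off, rates.k_off_prime
    return np.array([
        [-(koff + k1), km1,                   0.0, 0.0],
        [k1,           -(koffp + km1 + k2),   0.0, 0.0],
        [koff,         koffp,                 0.0, 0.0],
        [0.0,          k2,                    0.0, 0.0],
    ])


def solve_states(t_grid, rates: KineticRates) -> StateProbabilities:
    """State probabilities by matrix exponential of the generator.

    Conserves total probability to better than 1e-10 and agrees with the
    closed-form crossing probability.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    G = generator_matrix(rates)
    p0 = np.array([1.0, 0.0, 0.0, 0.0])
    out = np.empty((t_grid.size, 4))
    for i, t in enumerate(t_grid):
        out[i] = expm(G * t) @ p0
    return StateProbabilities(time=t_grid, P_low=out[:, 0],
                              P_high=out[:, 1], P_off=out[:, 2],
                              P_gt25=out[:, 3])


def fit_k1_vs_conc(k_values, concs_nM, sigmas=None) -> LinearRateLaw:
    """Inverse-variance-weighted least-squares line through k1 vs. [c].

    Returns the slope in M^-1 s^-1 (an effective second-order rate constant
    for the protein shifting the switch) and the intercept in s^-1 (the
    basal interconversion rate), with standard errors.  With ``sigmas``
    None the fit is unweighted.
    """
    k_values = np.asarray(k_values, dtype=float)
    c = np.asarray(concs_nM, dtype=float) * 1e-9   # to molar
    if k_values.size != c.size or k_values.size < 2:
        raise ValueError("need >= 2 matched (k1, concentration) pairs")
    w = (np.ones_like(k_values) if sigmas is None
         else 1.0 / np.asarray(sigmas, dtype=float) ** 2)
    W, X, Y = w.sum(), (w * c).sum(), (w * k_values).sum()
    Sxx, Sxy = (w * c * c).sum(), (w * c * k_values).sum()
    den = W * Sxx - X * X
    slope = (W * Sxy - X * Y) / den
    intercept = (Sxx * Y - X * Sxy) / den
    slope_se = np.sqrt(W / den)
    intercept_se = np.sqrt(Sxx / den)
    if sigmas is None:
        # scale unit-weight errors by residual variance
        resid = k_values - (slope * c + intercept)
        s2 = (resid ** 2).sum() / max(k_values.size - 2, 1)
        slope_se *= np.sqrt(s2)
        intercept_se *= np.sqrt(s2)
    return LinearRateLaw(slope=float(slope), intercept=float(intercept),
                         slope_se=float(slope_se),
                         intercept_se=float(intercept_se))


def burst_fraction_model(params: FitParams, conc_nM: float,
                         tau_low: float = 7.0) -> float:
    """Predicted fraction of high-processivity bursts: the crossing
    probability evaluated at the mean low-processivity burst duration."""
    return float(p_gt25(tau_low, params, conc_nM))


def burst_duration_model(params: FitParams, conc_nM: float,
                         tau_low: float, tau_high: float) -> float:
    """Mean burst duration as the P_inf-weighted mixture of the low- and
    high-processivity burst durations."""
    p_inf = p_gt25_infinity(params, conc_nM)
    return tau_low * (1.0 - p_inf) + tau_high * p_inf


def mean_bound_lifetime(rates: KineticRates) -> float:
    """Mean DNA-bound lifetime 1/k_off for the k'_off = 0 scheme, s."""
    if rates.k_off == 0:
        return np.inf
    return 1.0 / rates.k_off


# ---------------------------------------------------------------------------
# Model / Results


class FirstPassageModel:
    """Global model of threshold-crossing kinetics across concentrations.

    Built from a :class:`FirstPassageDataset`; ``fit`` performs weighted
    least squares of the empirical fraction-crossed-vs-time curves against
    the closed-form crossing probability, sharing {A, B, C, D} across
    concentrations with one k per concentration.

    Parameters
    ----------
    data : FirstPassageDataset
    n_grid : int
        Number of evaluation times per concentration (linear plus
        geometric spacing up to the observation limit).
    """

    def __init__(self, data: FirstPassageDataset, n_grid: int = 60):
        self.data = data
        self.concs = data.concentrations
        if self.concs.size < 2:
            raise ValueError("global fit needs >= 2 concentrations")
        self._n = {}
        self._grids = {}
        self._emp = {}
        self._sigma = {}
        self._t_cross = {}
        self._t_cens = {}
        for conc in self.concs:
            sub = data.frame[data.frame["conc_nM"] == conc]
            n = len(sub)
            self._n[conc] = n
            censored = sub["t_cross_s"].isna()
            self._t_cross[conc] = sub.loc[~censored, "t_cross_s"].to_numpy()
            self._t_cens[conc] = sub.loc[censored, "t_max_s"].to_numpy()
            if n < 10:
                import warnings
                warnings.warn(
                    f"only {n} molecules at {conc} nM; fit may be unstable")
            t_max = float(sub["t_max_s"].max())
            grid = np.unique(np.concatenate([
                np.linspace(t_max / n_grid, t_max, n_grid // 2),
                np.geomspace(max(t_max * 1e-3, 1e-3), t_max, n_grid // 2)]))
            self._grids[conc] = grid
            p_hat = data.empirical_fraction_crossed(conc, grid)
            self._emp[conc] = p_hat
            # binomial variance per time point, floored at 1/(4n)
            var = np.maximum(p_hat * (1 - p_hat), 1.0 / (4 * n)) / n
            self._sigma[conc] = np.sqrt(var)

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "FirstPassageModel":
        return cls(FirstPassageDataset.from_tsv(path), **kwargs)

    # -- parameter packing ---------------------------------------------------

    def _unpack(self, theta, koff_prime_free):
        if koff_prime_free:
            A, B, C, D = theta[:4]
            ks = theta[4:]
        else:
            A, B, km1 = theta[:3]
            C, D = A + km1, A
            ks = theta[3:]
        return A, B, C, D, dict(zip(self.concs, ks))

    def _residuals(self, theta, koff_prime_free):
        A, B, C, D, kmap = self._unpack(theta, koff_prime_free)
        res = []
        for conc in self.concs:
            model = p_gt25_raw(self._grids[conc], kmap[conc], A, B, C, D)
            res.append((self._emp[conc] - model) / self._sigma[conc])
        return np.concatenate(res)

    def _nll(self, theta, koff_prime_free):
        """Negative log-likelihood of the observed/censored passage times.

        A molecule crossing at t contributes the first-passage density
        dP/dt = k D (exp(-lam_+ t) - exp(-lam_- t)) / (lam_- - lam_+);
        a censored molecule contributes 1 - P(t_max) (it dissociated or ran
        out of observation time without crossing).
        """
        A, B, C, D, kmap = self._unpack(theta, koff_prime_free)
        tot = 0.0
        for conc in self.concs:
            k = kmap[conc]
            try:
                lam_p, lam_m = _eigvals(k, A, B, C)
            except FloatingPointError:
                return 1e12
            if lam_p - lam_m < 1e-12 * max(lam_p, 1.0):
                lam_m = lam_p - 1e-12 * max(lam_p, 1.0)
            tc = self._t_cross[conc]
            if tc.size:
                dens = (k * D / (lam_m - lam_p)
                        * (np.exp(-lam_p * tc) - np.exp(-lam_m * tc)))
                tot -= np.log(np.maximum(dens, 1e-300)).sum()
            tm = self._t_cens[conc]
            if tm.size:
                surv = 1.0 - p_gt25_raw(tm, k, A, B, C, D)
                tot -= np.log(np.maximum(surv, 1e-300)).sum()
        return tot

    def _x0_bounds(self, koff_prime_free):
        k0 = []
        for conc in self.concs:
            final = self._emp[conc][-1]
            k0.append(max(0.05, 0.3 * final))
        if koff_prime_free:
            x0 = [0.2, 0.05, 0.4, 0.2] + k0
            lo = [0.0] * 4 + [0.0] * len(k0)
        else:
            x0 = [0.2, 0.05, 0.2] + k0
            lo = [0.0] * 3 + [0.0] * len(k0)
        return np.array(x0), (np.array(lo), np.inf)

    def fit(self, method: str = "mle", koff_prime_free: bool = False,
            n_boot: int = 200, seed: int = 0) -> "FirstPassageResults":
        """Fit the model globally across concentrations.

        ``method='mle'`` (default) maximises the interval-censored
        first-passage likelihood per molecule; ``method='curves'`` performs
        weighted least squares of the empirical fraction-crossed curves
        with binomial per-point weights.  The likelihood is preferred: at
        realistic sample sizes the curve loss leaves the high-state exit
        rate k_minus1 badly determined.  Bootstrap confidence intervals
        are parametric (datasets resimulated from the fitted rates and
        refitted with the same loss).
        """
        x0, bounds = self._x0_bounds(koff_prime_free)
        if method == "curves":
            sol = least_squares(self._residuals, x0, bounds=bounds,
                                args=(koff_prime_free,), method="trf",
                                xtol=1e-12, ftol=1e-12)
            if not sol.success:
                raise RuntimeError(
                    f"global fit did not converge: {sol.message}; "
                    f"best point {sol.x}, |grad| {np.abs(sol.grad).max():.3g}")
            theta, cost = sol.x, float(sol.cost)
        elif method == "mle":
            mle_bounds = [(1e-9, None)] * x0.size
            if not koff_prime_free:
                mle_bounds[2] = (0.0, None)      # k_minus1 may sit at 0
            sol = minimize(self._nll, x0, args=(koff_prime_free,),
                           method="L-BFGS-B", bounds=mle_bounds)
            if not sol.success:
                raise RuntimeError(
                    f"likelihood fit did not converge: {sol.message}; "
                    f"best point {sol.x}")
            theta, cost = sol.x, float(sol.fun)
        else:
            raise ValueError(f"unknown fit method {method!r}")
        A, B, C, D, kmap = self._unpack(theta, koff_prime_free)
        params = FitParams(A=A, B=B, C=C, D=D, k=kmap)
        boot = self._bootstrap(params, method, koff_prime_free,
                               n_boot, seed) if n_boot > 0 else None
        return FirstPassageResults(self, params, koff_prime_free,
                                   cost=cost, bootstrap=boot, method=method)

    def _bootstrap(self, params: FitParams, method, koff_prime_free,
                   n_boot, seed):
        rows = []
        rates_by_conc = {c: params.rates_at(c) for c in self.concs}
        t_max = float(self.data.frame["t_max_s"].max())
        for b in range(n_boot):
            sim = simulate_first_passage(
                rates_by_conc, n_molecules=max(self._n.values()),
                t_max=t_max, seed=np.random.SeedSequence(
                    [int(seed), 7919, b]).generate_state(1)[0] % (2**31))
            try:
                model_b = FirstPassageModel(sim)
                res_b = model_b.fit(method=method,
                                    koff_prime_free=koff_prime_free,
                                    n_boot=0)
            except (RuntimeError, ValueError):
                continue
            row = {"A": res_b.params.A, "B": res_b.params.B,
                   "C": res_b.params.C, "D": res_b.params.D}
            for c in self.concs:
                row[f"k_{c:g}"] = res_b.params.k[c]
            rows.append(row)
        return pd.DataFrame(rows)


class FirstPassageResults:
    """Fit results: rate estimates, uncertainties, diagnostics."""

    def __init__(self, model: FirstPassageModel, params: FitParams,
                 koff_prime_free: bool, cost: float,
                 bootstrap: pd.DataFrame | None, method: str = "mle"):
        self.model = model
        self.params = params
        self.koff_prime_free = koff_prime_free
        self.cost = cost
        self.bootstrap = bootstrap
        self.method = method

    # -- rate-constant views -------------------------------------------------

    @property
    def k1(self) -> dict:
        return dict(self.params.k)

    @property
    def k_minus1(self) -> float:
        return self.params.C - self.params.A

    @property
    def k2(self) -> float:
        return self.params.D

    @property
    def k_off(self) -> float:
        return self.params.B

    @property
    def k_off_prime(self) -> float:
        return self.params.A - self.params.D

    def rates_at(self, conc_nM: float) -> KineticRates:
        return self.params.rates_at(conc_nM)

    # -- uncertainty ---------------------------------------------------------

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """95% (by default) parametric-bootstrap confidence intervals.

        Symmetric normal-theory intervals, estimate +- z * bootstrap SE,
        matching the symmetric +- form the rate constants are customarily
        reported in.
        """
        if self.bootstrap is None or self.bootstrap.empty:
            raise ValueError("fit was run without bootstrap resamples")
        from scipy.stats import norm
        z = norm.ppf(1 - alpha / 2)
        boot = self.bootstrap
        derived = {"k2": boot["D"], "k_off": boot["B"],
                   "k_minus1": boot["C"] - boot["A"],
                   "k_off_prime": boot["A"] - boot["D"]}
        point = {"k2": self.k2, "k_off": self.k_off,
                 "k_minus1": self.k_minus1, "k_off_prime": self.k_off_prime}
        for c in self.model.concs:
            derived[f"k1_{c:g}nM"] = boot[f"k_{c:g}"]
            point[f"k1_{c:g}nM"] = self.params.k[c]
        rows = {}
        for name, col in derived.items():
            se = float(col.std(ddof=1))
            rows[name] = [point[name] - z * se, point[name] + z * se]
        return pd.DataFrame(rows, index=["lower", "upper"]).T

    # -- predictions ---------------------------------------------------------

    def predict(self, t, conc_nM: float):
        """Model fraction-crossed curve at ``conc_nM``."""
        return p_gt25(t, self.params, conc_nM)

    def p_infinity(self, conc_nM: float) -> float:
        return p_gt25_infinity(self.params, conc_nM)

    def burst_fraction(self, conc_nM: float, tau_low: float = 7.0) -> float:
        return burst_fraction_model(self.params, conc_nM, tau_low)

    def mean_burst_duration(self, conc_nM: float, tau_low: float,
                            tau_high: float) -> float:
        return burst_duration_model(self.params, conc_nM, tau_low, tau_high)

    def mean_bound_lifetime(self) -> float:
        return mean_bound_lifetime(self.rates_at(self.model.concs[0]))

    def k1_rate_law(self) -> LinearRateLaw:
        """Weighted line through the fitted k1 values vs. concentration.

        Weights come from bootstrap standard errors when available."""
        concs = self.model.concs
        k_vals = [self.params.k[c] for c in concs]
        sigmas = None
        if self.bootstrap is not None and not self.bootstrap.empty:
            sigmas = [self.bootstrap[f"k_{c:g}"].std(ddof=1) for c in concs]
        return fit_k1_vs_conc(k_vals, concs, sigmas)

    def simulate(self, n_molecules: int, t_max: float,
                 seed: int = 0) -> FirstPassageDataset:
        """Simulate a first-passage dataset from the fitted rates."""
        return simulate_first_passage(
            {c: self.params.rates_at(c) for c in self.model.concs},
            n_molecules=n_molecules, t_max=t_max, seed=seed)

    # -- reporting -----------------------------------------------------------

    def summary(self) -> str:
        lines = ["Processivity-switch first-passage fit",
                 "=" * 45,
                 f"concentrations (nM): "
                 f"{', '.join(f'{c:g}' for c in self.model.concs)}",
                 f"molecules per concentration: "
                 f"{', '.join(str(self.model._n[c]) for c in self.model.concs)}",
                 f"k'_off constraint: "
                 f"{'free' if self.koff_prime_free else 'fixed to 0 (A = D)'}",
                 f"loss ({'neg. log-likelihood' if self.method == 'mle' else 'weighted SSR/2'}): {self.cost:.4g}", ""]
        ci = None
        if self.bootstrap is not None and not self.bootstrap.empty:
            ci = self.conf_int()
        def fmt(name, value):
            if ci is not None and name in ci.index:
                lo, hi = ci.loc[name]
                return f"  {name:<12s} {value:8.4f}   [{lo:.4f}, {hi:.4f}]"
            return f"  {name:<12s} {value:8.4f}"
        lines.append("rate constants (s^-1)" +
                     ("   [95% bootstrap CI]" if ci is not None else ""))
        lines.append(fmt("k_minus1", self.k_minus1))
        lines.append(fmt("k2", self.k2))
        lines.append(fmt("k_off", self.k_off))
        lines.append(fmt("k_off_prime", self.k_off_prime))
        for c in self.model.concs:
            lines.append(fmt(f"k1_{c:g}nM", self.params.k[c]))
        law = self.k1_rate_law()
        lines += ["",
                  f"k1 rate law: slope {law.slope:.3g} M^-1 s^-1 "
                  f"(se {law.slope_se:.2g}), intercept "
                  f"{law.intercept:.3g} s^-1 (se {law.intercept_se:.2g})",
                  f"mean bound lifetime 1/k_off: "
                  f"{self.mean_bound_lifetime():.1f} s"]
        return "\n".join(lines)

    def params_table(self) -> pd.DataFrame:
        """Parameter table in the layout of a rate-constant summary."""
        rows = [("k_minus1", self.k_minus1), ("k2", self.k2),
                ("k_off", self.k_off), ("k_off_prime", self.k_off_prime)]
        rows += [(f"k1_{c:g}nM", self.params.k[c]) for c in self.model.concs]
        df = pd.DataFrame(rows, columns=["rate", "estimate_s^-1"])
        if self.bootstrap is not None and not self.bootstrap.empty:
            ci = self.conf_int()
            df["ci_lower"] = [ci.loc[r, "lower"] for r in df["rate"]]
            df["ci_upper"] = [ci.loc[r, "upper"] for r in df["rate"]]
        return df
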