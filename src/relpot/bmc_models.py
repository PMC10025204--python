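"""The nine continuous concentration-response models for gene-wise BMC analysis.

Each model is a mean function m(x; theta) for the log2 expression of one
probe, fitted by maximum likelihood under additive normal errors (the
values are already on the log scale, unlike the endpoint engine which
logs raw responses). Parameterisations follow the EPA-BMDS continuous
conventions:

    Exp2    a * exp(b*x)                      (b signed)
    Exp3    a * exp(s*(b*x)**d)               (s = trend sign, b > 0)
    Exp4    a * (c - (c-1)*exp(-b*x))         (c > 1 up, c < 1 down)
    Exp5    a * (c - (c-1)*exp(-(b*x)**d))
    Linear  a + b*x
    Poly2   a + b1*x + b2*x**2
    Poly3   a + b1*x + b2*x**2 + b3*x**3
    Hill    a + v*x**n / (k**n + x**n)        (v signed)
    Power   a + b*x**g                        (b signed)

The benchmark concentration (BMC, reported as ``bmd``) is where the
fitted mean departs from its value at zero by the benchmark response;
BMDL/BMDU come from profile likelihood, with one magnitude parameter
eliminated in closed form given the candidate BMC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = ["ModelFit", "MODEL_NAMES", "fit_model_suite", "fit_one_model"]

MODEL_NAMES = ("Exp2", "Exp3", "Exp4", "Exp5", "Linear", "Poly2", "Poly3",
               "Hill", "Power")

_BIG = 1e10


@dataclass
class ModelFit:
    """One model's maximum-likelihood fit for one probe."""

    model_name: str
    params: dict
    sigma: float          # ML residual SD on the log2 scale
    loglik: float
    n_mean_params: int
    aic: float
    converged: bool
    bmd: float | None = None
    bmdl: float | None = None
    bmdu: float | None = None
    fit_p: float | None = None

    def predict(self, x):
        return _MODELS[self.model_name].func(np.asarray(x, dtype=float), self.params)


@dataclass
class _ModelDef:
    name: str
    param_names: tuple
    func: callable                     # (x, params dict) -> mean
    inits: callable                    # (x, y) -> list of init dicts
    bounds: callable                   # (x, y) -> dict name -> (lo, hi)
    eliminate: callable                # see _profile_nll
    profile_free: tuple                # params refitted during the profile
    closed_form: callable | None = None


def _trend_sign(x, y):
    ctrl = y[x == 0]
    a0 = ctrl.mean() if ctrl.size else y.mean()
    top = y[x >= np.quantile(x[x > 0], 0.67)] if np.any(x > 0) else y
    return 1.0 if top.mean() >= a0 else -1.0


def _basics(x, y):
    ctrl = y[x == 0]
    a0 = float(ctrl.mean()) if ctrl.size else float(y.mean())
    xmax = float(x.max()) if np.any(x > 0) else 1.0
    top = y[x >= np.quantile(x[x > 0], 0.67)] if np.any(x > 0) else y
    t = float(top.mean()) - a0
    return a0, xmax, t


# ---------------------------------------------------------------------------
# model definitions
# ---------------------------------------------------------------------------

def _poly_closed_form(degree):
    def fit(x, y):
        coeffs = np.polyfit(x, y, degree)  # highest power first
        names = ["a"] + [f"b{i}" for i in range(1, degree + 1)]
        ordered = coeffs[::-1]
        return {n: float(v) for n, v in zip(names, ordered)}
    return fit


def _poly_func(degree):
    def func(x, p):
        out = np.full_like(x, p["a"], dtype=float)
        for i in range(1, degree + 1):
            out = out + p[f"b{i}"] * x ** i
        return out
    return func


def _poly_eliminate(degree):
    # constraint: sum_i b_i * delta**i = target; solve for b1
    def eliminate(delta, target, free, p0):
        rest = sum(free.get(f"b{i}", p0[f"b{i}"]) * delta ** i
                   for i in range(2, degree + 1))
        p = dict(p0)
        p.update(free)
        p["b1"] = (target - rest) / delta
        return p
    return eliminate


def _linear_def():
    def eliminate(delta, target, free, p0):
        p = dict(p0)
        p.update(free)
        p["b1"] = target / delta
        return p
    return _ModelDef(
        "Linear", ("a", "b1"), _poly_func(1),
        inits=lambda x, y: [dict()],
        bounds=lambda x, y: {},
        eliminate=eliminate, profile_free=("a",),
        closed_form=_poly_closed_form(1))


def _poly_def(name, degree):
    return _ModelDef(
        name, tuple(["a"] + [f"b{i}" for i in range(1, degree + 1)]),
        _poly_func(degree),
        inits=lambda x, y: [dict()],
        bounds=lambda x, y: {},
        eliminate=_poly_eliminate(degree),
        profile_free=tuple(["a"] + [f"b{i}" for i in range(2, degree + 1)]),
        closed_form=_poly_closed_form(degree))


def _power_def():
    def func(x, p):
        with np.errstate(invalid="ignore"):
            return p["a"] + p["b"] * np.power(x, p["g"])

    def inits(x, y):
        a0, xmax, t = _basics(x, y)
        return [dict(a=a0, b=t / xmax, g=1.0),
                dict(a=a0, b=t / xmax ** 2, g=2.0),
                dict(a=a0, b=t / np.sqrt(xmax), g=0.5)]

    def bounds(x, y):
        return dict(a=(-np.inf, np.inf), b=(-np.inf, np.inf), g=(0.3, 8.0))

    def eliminate(delta, target, free, p0):
        p = dict(p0)
        p.update(free)
        p["b"] = target / delta ** p["g"]
        return p

    return _ModelDef("Power", ("a", "b", "g"), func, inits, bounds,
                     eliminate, profile_free=("a", "g"))


def _hill_def():
    def func(x, p):
        k, n = p["k"], p["n"]
        with np.errstate(invalid="ignore", over="ignore"):
            xn = np.power(x, n)
            return p["a"] + p["v"] * xn / (k ** n + xn)

    def inits(x, y):
        a0, xmax, t = _basics(x, y)
        xmid = float(np.median(x[x > 0])) if np.any(x > 0) else 1.0
        return [dict(a=a0, v=2 * t, k=xmid, n=1.0),
                dict(a=a0, v=2 * t, k=xmax / 2, n=3.0),
                dict(a=a0, v=2 * t, k=xmid / 4, n=1.5)]

    def bounds(x, y):
        xpos = x[x > 0]
        klo = float(xpos.min()) / 10 if xpos.size else 1e-3
        khi = 10 * float(x.max()) if np.any(x > 0) else 1e3
        return dict(a=(-np.inf, np.inf), v=(-np.inf, np.inf),
                    k=(klo, khi), n=(0.3, 8.0))

    def eliminate(delta, target, free, p0):
        p = dict(p0)
        p.update(free)
        k, n = p["k"], p["n"]
        dn = delta ** n
        p["v"] = target * (k ** n + dn) / dn
        return p

    return _ModelDef("Hill", ("a", "v", "k", "n"), func, inits, bounds,
                     eliminate, profile_free=("a", "k", "n"))


def _exp2_def():
    def func(x, p):
        with np.errstate(over="ignore"):
            return p["a"] * np.exp(np.clip(p["b"] * x, -700, 700))

    def inits(x, y):
        a0, xmax, t = _basics(x, y)
        a0 = max(a0, 1e-3)
        return [dict(a=a0, b=t / (a0 * xmax)),
                dict(a=a0, b=3 * t / (a0 * xmax))]

    def bounds(x, y):
        xmax = float(x.max()) if np.any(x > 0) else 1.0
        return dict(a=(1e-6, 1e6), b=(-100 / xmax, 100 / xmax))

    def eliminate(delta, target, free, p0):
        p = dict(p0)
        p.update(free)
        arg = 1.0 + target / p["a"]
        if arg <= 0:
            return None
        p["b"] = np.log(arg) / delta
        return p

    return _ModelDef("Exp2", ("a", "b"), func, inits, bounds,
                     eliminate, profile_free=("a",))


def _exp3_def():
    def func(x, p):
        with np.errstate(over="ignore", invalid="ignore"):
            t = np.power(np.abs(p["b"]) * x, p["d"])
            return p["a"] * np.exp(np.clip(p["sign"] * t, -700, 700))

    def inits(x, y):
        a0, xmax, t = _basics(x, y)
        a0 = max(a0, 1e-3)
        s = _trend_sign(x, y)
        b0 = abs(t) / (a0 * xmax) + 1e-12
        return [dict(a=a0, b=b0, d=1.0, sign=s),
                dict(a=a0, b=b0, d=2.0, sign=s)]

    def bounds(x, y):
        xmax = float(x.max()) if np.any(x > 0) else 1.0
        return dict(a=(1e-6, 1e6), b=(1e-12, 100 / xmax), d=(0.3, 8.0),
                    sign=None)

    def eliminate(delta, target, free, p0):
        p = dict(p0)
        p.update(free)
        arg = 1.0 + target / p["a"]
        if arg <= 0:
            return None
        v = p["sign"] * np.log(arg)
        if v <= 0:
            return None
        p["b"] = v ** (1.0 / p["d"]) / delta
        return p

    return _ModelDef("Exp3", ("a", "b", "d"), func, inits, bounds,
                     eliminate, profile_free=("a", "d"))


def _exp4_def():
    def func(x, p):
        with np.errstate(over="ignore"):
            return p["a"] * (p["c"] - (p["c"] - 1.0) * np.exp(-p["b"] * x))

    def inits(x, y):
        a0, xmax, t = _basics(x, y)
        a0 = max(a0, 1e-3)
        c0 = max((a0 + 1.5 * t) / a0, 1e-3)
        return [dict(a=a0, b=2.0 / xmax, c=c0),
                dict(a=a0, b=0.3 / xmax, c=c0)]

    def bounds(x, y):
        xmax = float(x.max()) if np.any(x > 0) else 1.0
        return dict(a=(1e-6, 1e6), b=(1e-12, 100 / xmax), c=(1e-3, 1e3))

    def eliminate(delta, target, free, p0):
        p = dict(p0)
        p.update(free)
        denom = p["a"] * (p["c"] - 1.0)
        if denom == 0:
            return None
        r = target / denom
        if not (0 < r < 1):
            return None
        p["b"] = -np.log1p(-r) / delta
        return p

    return _ModelDef("Exp4", ("a", "b", "c"), func, inits, bounds,
                     eliminate, profile_free=("a", "c"))


def _exp5_def():
    def func(x, p):
        with np.errstate(over="ignore", invalid="ignore"):
            t = np.power(p["b"] * x, p["d"])
            return p["a"] * (p["c"] - (p["c"] - 1.0) * np.exp(-np.minimum(t, 700)))

    def inits(x, y):
        a0, xmax, t = _basics(x, y)
        a0 = max(a0, 1e-3)
        c0 = max((a0 + 1.5 * t) / a0, 1e-3)
        return [dict(a=a0, b=2.0 / xmax, c=c0, d=1.0),
                dict(a=a0, b=0.3 / xmax, c=c0, d=2.0)]

    def bounds(x, y):
        xmax = float(x.max()) if np.any(x > 0) else 1.0
        return dict(a=(1e-6, 1e6), b=(1e-12, 100 / xmax), c=(1e-3, 1e3),
                    d=(0.3, 8.0))

    def eliminate(delta, target, free, p0):
        p = dict(p0)
        p.update(free)
        denom = p["a"] * (p["c"] - 1.0)
        if denom == 0:
            return None
        r = target / denom
        if not (0 < r < 1):
            return None
        v = -np.log1p(-r)
        p["b"] = v ** (1.0 / p["d"]) / delta
        return p

    return _ModelDef("Exp5", ("a", "b", "c", "d"), func, inits, bounds,
                     eliminate, profile_free=("a", "c", "d"))


_MODELS: dict[str, _ModelDef] = {m.name: m for m in (
    _exp2_def(), _exp3_def(), _exp4_def(), _exp5_def(),
    _linear_def(), _poly_def("Poly2", 2), _poly_def("Poly3", 3),
    _hill_def(), _power_def(),
)}


def _loglik_from_rss(rss, n):
    sigma2 = max(rss / n, 1e-30)
    return -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)


def fit_one_model(name: str, x, y) -> ModelFit:
    """ML fit of one model; non-convergence is reported, never raised."""
    mdef = _MODELS[name]
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    n_mean = len(mdef.param_names)
    if mdef.closed_form is not None:
        params = mdef.closed_form(x, y)
        resid = y - mdef.func(x, params)
        rss = float(resid @ resid)
        ll = _loglik_from_rss(rss, n)
        return ModelFit(name, params, float(np.sqrt(max(rss / n, 0.0))), ll,
                        n_mean, 2 * (n_mean + 1) - 2 * ll, True)

    bounds = mdef.bounds(x, y)
    fit_names = [p for p in mdef.param_names if bounds.get(p) is not None]
    lo = np.array([bounds[p][0] for p in fit_names])
    hi = np.array([bounds[p][1] for p in fit_names])

    best = None
    for init in mdef.inits(x, y):
        fixed = {k: v for k, v in init.items() if k not in fit_names}
        x0 = np.clip([init[p] for p in fit_names], lo, hi)
        x0 = np.where(np.isfinite(x0), x0, 0.0)

        def resid_fn(vec, fixed=fixed):
            p = dict(zip(fit_names, vec))
            p.update(fixed)
            r = y - mdef.func(x, p)
            return np.where(np.isfinite(r), r, 1e6)

        try:
            sol = optimize.least_squares(resid_fn, x0, bounds=(lo, hi),
                                         method="trf", xtol=1e-12, ftol=1e-12)
        except Exception:  # noqa: BLE001
            continue
        if best is None or sol.cost < best[0].cost:
            best = (sol, fixed)
    if best is None:
        return ModelFit(name, {}, np.nan, -np.inf, n_mean, np.inf, False)
    sol, fixed = best
    params = dict(zip(fit_names, (float(v) for v in sol.x)))
    params.update(fixed)
    rss = 2 * float(sol.cost)
    ll = _loglik_from_rss(rss, n)
    return ModelFit(name, params, float(np.sqrt(max(rss / n, 0.0))), ll,
                    n_mean, 2 * (n_mean + 1) - 2 * ll, bool(sol.success))


def fit_model_suite(concentrations, values, models=MODEL_NAMES) -> list[ModelFit]:
    """Fit every model of the suite to one probe's samples."""
    return [fit_one_model(name, concentrations, values) for name in models]


# ---------------------------------------------------------------------------
# BMC point estimate and profile bounds
# ---------------------------------------------------------------------------

def _bmr_delta(fit: ModelFit, bmr_factor: float, bmr_mode: str) -> float:
    """Absolute benchmark response on the log2 scale."""
    if bmr_mode == "sd":
        return bmr_factor * fit.sigma
    if bmr_mode == "fold":
        return float(np.log2(bmr_factor))
    raise ValueError(f"unknown bmr_mode {bmr_mode!r}")


def compute_bmd_point(fit: ModelFit, max_dose: float, bmr_factor: float = 1.021,
                      bmr_mode: str = "sd"):
    """First concentration where |m(x) - m(0)| reaches the BMR.

    Searched on (0, 10*max_dose]; returns ``(bmd, signed_target)`` or
    ``(None, None)`` when the fitted curve never departs that far.
    """
    if not fit.converged:
        return None, None
    bmr = _bmr_delta(fit, bmr_factor, bmr_mode)
    if not np.isfinite(bmr) or bmr <= 0:
        return None, None
    m0 = float(fit.predict(0.0))
    grid = np.geomspace(max_dose * 1e-6, max_dose * 10, 400)
    g = fit.predict(grid) - m0
    hit = np.nonzero(np.abs(g) >= bmr)[0]
    if hit.size == 0:
        return None, None
    j = hit[0]
    s = float(np.sign(g[j]))
    target = s * bmr

    def h(xv):
        # signed departure minus BMR: negative before the crossing
        return s * (float(fit.predict(xv)) - m0) - bmr

    lo = grid[j - 1] if j > 0 else max_dose * 1e-9
    if h(lo) >= 0:  # already past the BMR at the bracket start
        return float(lo), target
    bmd = optimize.brentq(h, lo, grid[j], xtol=1e-12 * max_dose, rtol=1e-13)
    return float(bmd), target


def _nm_minimize(fun, x0):
    res = optimize.minimize(fun, x0, method="Nelder-Mead",
                            options=dict(fatol=1e-9, xatol=1e-8,
                                         maxiter=2000, adaptive=True))
    return res


def _profile_nll(mdef, x, y, delta, target, p_hat, bounds):
    """Max log-lik at a fixed candidate BMC (constraint eliminates one param)."""
    free_names = [p for p in mdef.profile_free
                  if bounds.get(p, (None,)) is not None]
    n = y.size

    def nll(vec):
        free = dict(zip(free_names, vec))
        pen = 0.0
        for k, v in free.items():
            b = bounds.get(k)
            if b is not None and b[0] is not None:
                lo, hi = b
                if np.isfinite(lo) and v < lo:
                    pen += (lo - v) ** 2
                    free[k] = lo
                if np.isfinite(hi) and v > hi:
                    pen += (v - hi) ** 2
                    free[k] = hi
        p = mdef.eliminate(delta, target, free, p_hat)
        if p is None:
            return _BIG
        r = y - mdef.func(x, p)
        if not np.all(np.isfinite(r)):
            return _BIG
        rss = float(r @ r)
        return 0.5 * n * (np.log(2 * np.pi * max(rss / n, 1e-30)) + 1.0) + 1e4 * pen

    x0 = np.array([p_hat[p] for p in free_names], dtype=float)
    if x0.size == 0:
        return -(-nll(x0))  # no free params: evaluate directly
    res = _nm_minimize(nll, x0)
    return res.fun


def profile_bmd_bounds(fit: ModelFit, x, y, max_dose: float,
                       bmr_factor: float = 1.021, bmr_mode: str = "sd",
                       level: float = 0.90):
    """Profile-likelihood BMDL/BMDU for a fit with a BMC point estimate.

    The benchmark response is anchored at the MLE residual SD (sd mode),
    so the constraint |m(delta) - m(0)| = BMR couples only the mean
    parameters; at each candidate delta one magnitude parameter is solved
    from the constraint and the rest are refitted. The two-sided bound is
    where the log-likelihood drops by chi2_1(level)/2. A side whose drop
    never reaches the threshold inside the search bracket
    [max_dose*1e-6, max_dose*10] is reported at the bracket end (the
    interval extends at least that far).
    """
    from scipy.stats import chi2

    if fit.bmd is None:
        bmd, target = compute_bmd_point(fit, max_dose, bmr_factor, bmr_mode)
    else:
        bmd = fit.bmd
        _, target = compute_bmd_point(fit, max_dose, bmr_factor, bmr_mode)
    if bmd is None or target is None:
        return None, None
    mdef = _MODELS[fit.model_name]
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    bounds = mdef.bounds(x, y)
    thresh = chi2.ppf(level, 1) / 2.0
    nll_hat = -fit.loglik

    def drop(delta):
        return _profile_nll(mdef, x, y, delta, target, fit.params, bounds) \
            - nll_hat - thresh

    lo_lim, hi_lim = max_dose * 1e-6, max_dose * 10

    def search(direction):
        lim = lo_lim if direction < 0 else hi_lim
        prev = bmd
        for frac in (1.5, 2.5, 5.0, 20.0, 100.0, None):
            cand = lim if frac is None else (bmd / frac if direction < 0 else bmd * frac)
            cand = max(lo_lim, min(hi_lim, cand))
            if drop(cand) > 0:
                a, b = sorted((prev, cand))
                return float(optimize.brentq(drop, a, b, xtol=1e-6 * max_dose,
                                             rtol=1e-6))
            prev = cand
            if cand == lim:
                break
        return float(lim)

    bmdl = search(-1)
    bmdu = search(+1)
    bmdl = min(bmdl, bmd)
    bmdu = max(bmdu, bmd)
    return bmdl, bmdu
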