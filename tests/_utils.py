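"""Test-side helpers and independent oracles.

The oracles here deliberately avoid the package's estimation code paths:
side-wise intercepts come from hand-written normal equations (Cramer's rule
on explicit scalar sums), and the reference bandwidth selector is a separate
transcription of the MSE-optimal plug-in rule built on statsmodels OLS and
grid integration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from rdalert import Cohort


def make_cohort(x, threshold=65.0, **columns) -> Cohort:
    x = np.asarray(x, dtype=float)
    frame = pd.DataFrame({"id": [f"r{i}" for i in range(x.size)], "max_score": x})
    for name, values in columns.items():
        frame[name] = values
    return Cohort(frame, threshold=threshold)


def make_event_cohort(x, y, threshold=65.0, **extra) -> Cohort:
    """Cohort whose primary composite equals the supplied binary y (all RRT)."""
    y = np.asarray(y)
    zeros = np.zeros(len(y), dtype=int)
    return make_cohort(
        x, threshold,
        rrt=y.astype(int), icu_transfer=zeros, arrest=zeros, death=zeros,
        treated=(np.asarray(x) >= threshold).astype(int), **extra,
    )


# ----------------------------------------------------------------------
# closed-form local-polynomial intercept oracles
# ----------------------------------------------------------------------

def ols_intercept_linear(x, y, c) -> float:
    """Plain OLS intercept at c of y ~ 1 + (x - c), via Cramer's rule."""
    d = np.asarray(x, float) - c
    y = np.asarray(y, float)
    n = d.size
    s1, s2 = d.sum(), (d * d).sum()
    sy, sdy = y.sum(), (d * y).sum()
    det = n * s2 - s1 * s1
    return (sy * s2 - s1 * sdy) / det


def wls_intercept_linear(x, y, c, w) -> float:
    """Weighted LS intercept at c of y ~ 1 + (x - c), via Cramer's rule."""
    d = np.asarray(x, float) - c
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    s0, s1, s2 = w.sum(), (w * d).sum(), (w * d * d).sum()
    sy, sdy = (w * y).sum(), (w * d * y).sum()
    det = s0 * s2 - s1 * s1
    return (sy * s2 - s1 * sdy) / det


def ols_intercept_poly(x, y, c, order) -> float:
    """OLS intercept at c of a centered polynomial fit of given order."""
    d = np.asarray(x, float) - c
    coeffs = np.polynomial.polynomial.polyfit(d, np.asarray(y, float), order)
    return float(coeffs[0])


def oracle_rd_uniform(x, y, c, h, order=1) -> float:
    """RD jump via side-wise plain-OLS intercepts inside an open uniform window."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    inside = np.abs(x - c) < h
    below = inside & (x < c)
    above = inside & (x >= c)
    if order == 1:
        return ols_intercept_linear(x[above], y[above], c) - ols_intercept_linear(
            x[below], y[below], c
        )
    return ols_intercept_poly(x[above], y[above], c, order) - ols_intercept_poly(
        x[below], y[below], c, order
    )


def oracle_rd_triangular(x, y, c, h) -> float:
    """RD jump via side-wise closed-form WLS with triangular weights."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.maximum(0.0, 1.0 - np.abs(x - c) / h)
    below = (w > 0) & (x < c)
    above = (w > 0) & (x >= c)
    return wls_intercept_linear(x[above], y[above], c, w[above]) - wls_intercept_linear(
        x[below], y[below], c, w[below]
    )


# ----------------------------------------------------------------------
# reference MSE-optimal bandwidth (independent transcription)
# ----------------------------------------------------------------------

def _kernel_constants_grid(kernel: str, p: int) -> tuple:
    from scipy.integrate import simpson

    u = np.linspace(0.0, 1.0, 20001)
    K = (1.0 - u) if kernel == "triangular" else np.ones_like(u)
    r = np.vstack([u**j for j in range(p + 1)])
    G = np.array([[simpson(K * r[i] * r[j], x=u) for j in range(p + 1)] for i in range(p + 1)])
    P = np.array([[simpson(K**2 * r[i] * r[j], x=u) for j in range(p + 1)] for i in range(p + 1)])
    t = np.array([simpson(K * u ** (p + 1) * r[i], x=u) for i in range(p + 1)])
    Ginv = np.linalg.inv(G)
    return float(Ginv[0] @ t), float(Ginv[0] @ P @ Ginv[0])


def _reference_pilot(x, y, c, p):
    import statsmodels.api as sm

    q = p + 2
    d = np.asarray(x, float) - c
    X = sm.add_constant(np.column_stack([d**k for k in range(1, q + 1)]))
    res = sm.OLS(np.asarray(y, float), X).fit(cov_type="HC1")
    j = p + 1
    resid = res.resid
    h_v = 1.84 * np.std(d + c) * d.size ** (-0.2)
    for _ in range(30):
        w = np.maximum(0.0, 1.0 - np.abs(d) / h_v)
        if (w > 0).sum() >= max(5, q + 2):
            break
        h_v *= 2.0
    sigma2 = float((w * resid**2).sum() / w.sum())
    return float(res.params[j]), float(res.cov_params()[j, j]), sigma2


def reference_cct_bandwidth(x, y, c, p=1, kernel="triangular", regularization=True) -> float:
    """Independent transcription of the MSE-optimal plug-in bandwidth rule."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    below, above = x < c, x >= c
    b_m, v_m, s2_m = _reference_pilot(x[below], y[below], c, p)
    b_p, v_p, s2_p = _reference_pilot(x[above], y[above], c, p)
    c1, c2 = _kernel_constants_grid(kernel, p)

    n = x.size
    sd = np.std(x)
    iqr = np.quantile(x, 0.75) - np.quantile(x, 0.25)
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    hd = 0.9 * spread * n ** (-0.2)
    f_c = float(np.mean(np.exp(-0.5 * ((c - x) / hd) ** 2) / np.sqrt(2 * np.pi)) / hd)

    sign = (-1.0) ** (p + 1)
    B = c1 * (b_p - sign * b_m)
    R = 3.0 * c1**2 * (v_p + v_m) if regularization else 0.0
    V = c2 * (s2_p + s2_m) / f_c
    h = (V / (2.0 * (p + 1) * n * (B**2 + R))) ** (1.0 / (2.0 * p + 3.0))
    return float(min(h, max(x.max() - c, c - x.min())))


def cct_fixture(seed: int, n: int = 2000):
    """Continuous-outcome fixture with distinct curvature on each side."""
    rng = np.random.default_rng(seed)
    nh = n // 2
    x = np.concatenate([65.0 - 30.0 * rng.beta(1.5, 2.5, nh), 65.0 + 25.0 * rng.beta(1.3, 3.0, n - nh)])
    d = x - 65.0
    m = np.where(d < 0, 0.40 + 0.010 * d + 0.0025 * d**2, 0.30 - 0.008 * d - 0.0035 * d**2)
    y = m + rng.normal(0.0, 0.15, n)
    return x, y
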