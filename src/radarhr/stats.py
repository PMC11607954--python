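"""Method-comparison statistics and a priori sample-size planning.

Implements the agreement/equivalence chain for comparing a candidate HR
monitor against a reference: square scatter plot with OLS regression,
modified Bland-Altman analysis (difference against the *reference*, not the
pair mean), Schuirmann's two one-sided tests (TOST) for equivalence with
+-5 bpm bounds, the standardized one-sample effect size Hedges g(z), and
the two a priori sample-size calculations (limits-of-agreement precision
and TOST power via the noncentral t distribution).

Sample standard deviations (n-1 denominator) are used throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats as sps

__all__ = [
    "BlandAltmanResult",
    "RegressionFit",
    "TOSTResult",
    "SampleSizeResult",
    "bland_altman",
    "fit_regression",
    "tost_paired",
    "tost_from_summary",
    "hedges_gz",
    "sample_size_loa",
    "sample_size_tost",
    "tost_power_parallel",
    "scatter_plot",
    "bland_altman_plot",
    "format_p",
]

Z_CRIT = 1.959963984540054  # Phi^-1(0.975)
DEFAULT_BOUNDS = (-5.0, 5.0)  # bpm, clinical irrelevance band


@dataclass
class BlandAltmanResult:
    n_pairs: int
    mean_diff: float                # bpm
    sd_diff: float                  # bpm, sample SD
    loa_low: float                  # mean - 1.96 sd
    loa_high: float                 # mean + 1.96 sd
    frac_within_band: float         # fraction of |diff| <= agreement_band
    frac_within_loa: float
    agreement_band: float = 5.0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RegressionFit:
    slope: float
    intercept: float                # bpm
    r_value: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TOSTResult:
    n: int
    estimate: float                 # bpm, mean of diffs
    se: float                       # bpm
    df: int
    t_raw: float
    t_lower: float
    t_upper: float
    p_raw: float
    p_lower: float
    p_upper: float
    ci90_low: float
    ci90_high: float
    bounds: tuple
    hedges_gz: float
    gz_bounds: tuple
    gz_ci90: tuple
    equivalent: bool
    degenerate: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bounds"] = list(self.bounds)
        d["gz_bounds"] = list(self.gz_bounds)
        d["gz_ci90"] = list(self.gz_ci90)
        return d


@dataclass
class SampleSizeResult:
    method: str                     # loa_precision | tost_parallel
    n: int                          # patients (total)
    inputs: dict

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# agreement
# ---------------------------------------------------------------------------

def bland_altman(pairs, agreement_band: float = 5.0) -> BlandAltmanResult:
    """Modified Bland-Altman statistics over the valid pairs.

    ``pairs`` may be a PairedHRSeries or a plain array of differences.
    Limits of agreement are mean +- 1.96 * sample SD of the differences.
    """
    diffs = np.asarray(pairs.valid_diffs() if hasattr(pairs, "valid_diffs")
                       else pairs, dtype=float)
    diffs = diffs[np.isfinite(diffs)]
    if diffs.size < 2:
        raise ValueError("need at least 2 valid pairs")
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    loa_low, loa_high = mean - 1.96 * sd, mean + 1.96 * sd
    return BlandAltmanResult(
        n_pairs=int(diffs.size),
        mean_diff=mean,
        sd_diff=sd,
        loa_low=loa_low,
        loa_high=loa_high,
        frac_within_band=float(np.mean(np.abs(diffs) <= agreement_band)),
        frac_within_loa=float(np.mean((diffs >= loa_low) & (diffs <= loa_high))),
        agreement_band=agreement_band,
    )


def fit_regression(pairs) -> RegressionFit:
    """OLS of radar HR on reference HR (reference on the x-axis)."""
    if hasattr(pairs, "included"):
        inc = pairs.included
        x = inc["ref_hr"].to_numpy(dtype=float)
        y = inc["radar_hr"].to_numpy(dtype=float)
    else:
        x, y = (np.asarray(v, dtype=float) for v in pairs)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct reference values")
    res = sps.linregress(x, y)
    return RegressionFit(slope=float(res.slope), intercept=float(res.intercept),
                         r_value=float(res.rvalue), n=int(x.size))


# ---------------------------------------------------------------------------
# equivalence testing
# ---------------------------------------------------------------------------

def hedges_gz(mean: float, sd: float, n: int) -> float:
    """Standardized one-sample effect size with small-sample correction.

    g(z) = (mean / sd) * J(df), J(df) = 1 - 3/(4*df - 1), df = n - 1.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    df = n - 1
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    return (mean / sd) * j


def _tost_core(n: int, mean: float, sd: float, bounds: tuple,
               alpha: float, degenerate: bool = False) -> TOSTResult:
    lower, upper = bounds
    df = n - 1
    se = sd / math.sqrt(n)
    tcrit = float(sps.t.ppf(1.0 - alpha, df))
    if se > 0:
        t_raw = mean / se
        t_lower = (mean - lower) / se
        t_upper = (mean - upper) / se
        p_raw = float(2.0 * sps.t.sf(abs(t_raw), df))
        p_lower = float(sps.t.sf(t_lower, df))      # H0: mean <= lower
        p_upper = float(sps.t.cdf(t_upper, df))     # H0: mean >= upper
        ci_low = mean - tcrit * se
        ci_high = mean + tcrit * se
        equivalent = (p_lower < alpha) and (p_upper < alpha)
        g = hedges_gz(mean, sd, n)
        j = 1.0 - 3.0 / (4.0 * df - 1.0)
        gz_bounds = (lower / sd * j, upper / sd * j)
        gz_ci90 = (ci_low / sd * j, ci_high / sd * j)
    else:
        # zero spread: the t statistics diverge; take the limiting values
        # and decide on the mean alone
        t_raw = 0.0 if mean == 0 else math.copysign(math.inf, mean)
        t_lower = math.inf if mean > lower else -math.inf
        t_upper = -math.inf if mean < upper else math.inf
        p_lower = 0.0 if mean > lower else 1.0
        p_upper = 0.0 if mean < upper else 1.0
        p_raw = 1.0 if mean == 0 else 0.0
        ci_low = ci_high = mean
        equivalent = lower < mean < upper
        g, gz_bounds, gz_ci90 = math.nan, (math.nan, math.nan), (math.nan, math.nan)
        degenerate = True
    return TOSTResult(
        n=n, estimate=mean, se=se, df=df,
        t_raw=t_raw, t_lower=t_lower, t_upper=t_upper,
        p_raw=p_raw, p_lower=p_lower, p_upper=p_upper,
        ci90_low=ci_low, ci90_high=ci_high, bounds=tuple(bounds),
        hedges_gz=g, gz_bounds=gz_bounds, gz_ci90=gz_ci90,
        equivalent=bool(equivalent), degenerate=degenerate,
    )


def tost_paired(diffs, bounds: tuple = DEFAULT_BOUNDS,
                alpha: float = 0.05) -> TOSTResult:
    """Schuirmann's two one-sided tests on paired differences.

    Equivalence is declared iff both one-sided tests reject at ``alpha``,
    equivalently iff the (1 - 2*alpha) CI (90% at alpha = 0.05) lies
    strictly inside the bounds.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[np.isfinite(d)]
    if d.size < 3:
        raise ValueError("need at least 3 finite differences")
    return _tost_core(int(d.size), float(d.mean()), float(d.std(ddof=1)),
                      bounds, alpha)


def tost_from_summary(n: int, mean: float, sd: float | None = None,
                      se: float | None = None,
                      ci90: tuple | None = None,
                      bounds: tuple = DEFAULT_BOUNDS,
                      alpha: float = 0.05) -> TOSTResult:
    """TOST from printed summary statistics.

    Exactly one dispersion input must be given: ``sd``, ``se``, or a
    ``ci90`` (lower, upper) pair from which the SE is recovered via the
    one-sided t critical value.  This lets published summary tables be
    re-derived and checked for self-consistency.
    """
    given = [v is not None for v in (sd, se, ci90)]
    if sum(given) != 1:
        raise ValueError("specify exactly one of sd, se, ci90")
    if n < 3:
        raise ValueError("need n >= 3")
    df = n - 1
    if ci90 is not None:
        halfwidth = (ci90[1] - ci90[0]) / 2.0
        tcrit = float(sps.t.ppf(1.0 - alpha, df))
        se = halfwidth / tcrit
    if se is not None:
        sd = se * math.sqrt(n)
    return _tost_core(n, mean, float(sd), bounds, alpha)


# ---------------------------------------------------------------------------
# a priori sample size
# ---------------------------------------------------------------------------

def sample_size_loa(sd: float = 4.0, ci_halfwidth: float = 2.5,
                    conf: float = 0.95) -> SampleSizeResult:
    """Patients needed for the stated precision of the limits of agreement.

    The LoA estimate mean +- 1.96*sd has standard error ~ sd*sqrt(3/n);
    the smallest n with z * sd * sqrt(3/n) <= halfwidth is
    n = ceil(3 * (z * sd / halfwidth)^2).
    """
    if sd <= 0 or ci_halfwidth <= 0:
        raise ValueError("sd and ci_halfwidth must be positive")
    z = float(sps.norm.ppf(0.5 + conf / 2.0))
    n = max(1, math.ceil(3.0 * (z * sd / ci_halfwidth) ** 2))
    return SampleSizeResult(method="loa_precision", n=int(n),
                            inputs={"sd": sd, "ci_halfwidth": ci_halfwidth,
                                    "conf": conf})


def tost_power_parallel(n_total: int, sd: float, bounds: tuple,
                        theta0: float, alpha: float) -> float:
    """Exact TOST power for a parallel two-group additive design.

    Equal allocation n/2 per group, df = n - 2, SE = sd * sqrt(4/n); the
    rejection probability of both one-sided tests is evaluated with the
    noncentral t distribution.
    """
    if n_total < 4:
        return 0.0
    df = n_total - 2
    se = sd * math.sqrt(4.0 / n_total)
    tcrit = float(sps.t.ppf(1.0 - alpha, df))
    d_lo = (theta0 - bounds[0]) / se
    d_hi = (theta0 - bounds[1]) / se
    power = float(sps.nct.cdf(-tcrit, df, d_hi) - sps.nct.cdf(tcrit, df, d_lo))
    return max(power, 0.0)


def sample_size_tost(sd: float = 4.0, bounds: tuple = DEFAULT_BOUNDS,
                     theta0: float = 1.0, power: float = 0.80,
                     alpha: float = 0.05) -> SampleSizeResult:
    """Total sample size for a parallel-group additive-scale TOST.

    Starting from the normal-approximation estimate, the even total n is
    iterated upward until the exact noncentral-t power reaches the target,
    then walked back down to the smallest even total still meeting it.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    if not bounds[0] < theta0 < bounds[1]:
        raise ValueError("theta0 must lie strictly inside the bounds "
                         "(power can never reach the target otherwise)")
    z_a = float(sps.norm.ppf(1.0 - alpha))
    z_b = float(sps.norm.ppf(power if abs(theta0) > 1e-12 else (1 + power) / 2))
    margin = min(bounds[1] - theta0, theta0 - bounds[0])
    n = 4.0 * sd ** 2 * (z_a + z_b) ** 2 / margin ** 2
    n = max(4, int(2 * math.ceil(n / 2.0)))
    while tost_power_parallel(n, sd, bounds, theta0, alpha) < power:
        n += 2
        if n > 10_000_000:
            raise RuntimeError("sample size search failed to converge")
    while n > 4 and tost_power_parallel(n - 2, sd, bounds, theta0, alpha) >= power:
        n -= 2
    return SampleSizeResult(
        method="tost_parallel", n=int(n),
        inputs={"sd": sd, "bounds": list(bounds), "theta0": theta0,
                "power": power, "alpha": alpha})


# ---------------------------------------------------------------------------
# reporting helpers
# ---------------------------------------------------------------------------

def format_p(p: float) -> str:
    """Rendered p-value: '< 0.001' below that threshold, else 3 decimals."""
    if not np.isfinite(p):
        return "NA"
    return "< 0.001" if p < 0.001 else f"{p:.3f}"


def scatter_plot(pairs, path) -> None:
    """Square scatter of radar vs reference HR with bisector and OLS line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    inc = pairs.included
    x = inc["ref_hr"].to_numpy(dtype=float)
    y = inc["radar_hr"].to_numpy(dtype=float)
    fit = fit_regression(pairs)
    lo = float(min(x.min(), y.min())) - 5
    hi = float(max(x.max(), y.max())) + 5
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.plot(x, y, ".", ms=2, alpha=0.4)
    ax.plot([lo, hi], [lo, hi], "--", color="gray", label="bisector")
    xs = np.array([lo, hi])
    ax.plot(xs, fit.intercept + fit.slope * xs, "-", color="C1",
            label=f"y = {fit.intercept:.2f} + {fit.slope:.2f} x")
    ax.set_xlim(lo, hi)
    ax.set_ylim(lo, hi)
    ax.set_xlabel("reference HR [bpm]")
    ax.set_ylabel("radar HR [bpm]")
    ax.legend()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def bland_altman_plot(pairs, path, agreement_band: float = 5.0) -> None:
    """Modified Bland-Altman plot: difference against the reference HR."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    inc = pairs.included
    x = inc["ref_hr"].to_numpy(dtype=float)
    d = inc["diff"].to_numpy(dtype=float)
    res = bland_altman(pairs, agreement_band)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.plot(x, d, ".", ms=2, alpha=0.4)
    ax.axhline(res.mean_diff, color="C0",
               label=f"mean = {res.mean_diff:.3f} bpm")
    for y in (res.loa_low, res.loa_high):
        ax.axhline(y, color="C3", ls="-",
                   label="mean ± 1.96 σ" if y == res.loa_high else None)
    ax.set_xlabel("reference HR [bpm]")
    ax.set_ylabel("radar − reference [bpm]")
    ax.legend()
    fig.savefig(path, dpi=110)
    plt.close(fig)
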