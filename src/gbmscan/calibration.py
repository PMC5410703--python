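"""Read downsampling and the deep-vs-1× linear calibration.

Per-site sequencing depth near 1× biases naive methylation estimates, so
shallow data are calibrated against deep data: methylation levels of reads
thinned to ~1× (y) are regressed on the matching deep-coverage levels (x)
across reference species, and the fitted line is inverted to estimate the
deep-coverage level — with a 95% interval — for species sequenced shallowly.

Thinning keeps each read independently with probability target/current mean
coverage, which preserves expected weighted methylation. The interval on the
inverse prediction is obtained by inverting the 95% prediction band of the
y-on-x fit (the set of x whose band covers the observed y), the standard
construction for a calibration problem.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


def downsample_records(
    records: pd.DataFrame, target_mean_coverage: float, seed: int
) -> pd.DataFrame:
    """Binomial read-thinning to a target mean per-site coverage.

    Each site's methylated and unmethylated reads are thinned independently
    with the same retention probability r = target / current mean, leaving
    the expected weighted methylation unchanged. When the data are already
    at or below the target they are returned unchanged with a warning.
    """
    if target_mean_coverage <= 0:
        raise ValueError("target coverage must be > 0")
    current = float(records["cov"].mean())
    if target_mean_coverage >= current:
        warnings.warn(
            f"target coverage {target_mean_coverage} ≥ current mean {current:.3g}; "
            "records returned unchanged",
            stacklevel=2,
        )
        return records.copy()
    r = target_mean_coverage / current
    rng = np.random.default_rng(seed)
    mc = records["mc"].to_numpy()
    cov = records["cov"].to_numpy()
    new_mc = rng.binomial(mc, r)
    new_un = rng.binomial(cov - mc, r)
    out = records.copy()
    out["mc"] = new_mc
    out["cov"] = new_mc + new_un
    return out


class CoverageCalibration:
    """Linear model of shallow (~1×) on deep methylation levels.

    Parameters
    ----------
    deep, shallow : array-like
        Paired per-species methylation levels at deep and thinned coverage
        (the model regresses shallow on deep).
    context : str, optional
        Sequence-context label carried through to outputs; calibration is
        fitted per context.
    reverse : bool
        When True, regress deep on shallow directly ("reverse fit"); deep
        levels are then plain predictions rather than band inversions. The
        default inverse-prediction construction is less biased.
    """

    def __init__(self, deep, shallow, context: str | None = None, reverse: bool = False):
        x = np.asarray(deep, dtype=float)
        y = np.asarray(shallow, dtype=float)
        if reverse:
            x, y = y, x  # x = shallow predictor, y = deep response
        if x.size != y.size:
            raise ValueError("deep and shallow must be paired")
        if x.size < 3:
            raise ValueError("need at least 3 calibration pairs")
        if np.ptp(x) == 0:
            raise ValueError("degenerate calibration: predictor levels all equal")
        self.x, self.y, self.context = x, y, context
        self.reverse = reverse

    @classmethod
    def from_frame(cls, pairs: pd.DataFrame, context: str | None = None, reverse: bool = False):
        """Build from a tidy table with deep_level / shallow_level columns
        (optionally filtered to one context)."""
        df = pairs if context is None else pairs[pairs["context"] == context]
        return cls(df["deep_level"], df["shallow_level"], context, reverse=reverse)

    def fit(self) -> "CalibrationResults":
        ols = sm.OLS(self.y, sm.add_constant(self.x)).fit()
        intercept, slope = ols.params
        resid_sd = float(np.sqrt(ols.ssr / ols.df_resid)) if ols.df_resid > 0 else 0.0
        return CalibrationResults(
            model=self,
            slope=float(slope),
            intercept=float(intercept),
            resid_sd=resid_sd,
            n_points=self.x.size,
            _ols=ols,
        )


@dataclass
class CalibrationResults:
    """Fitted deep-vs-shallow line with inverse-prediction machinery."""

    model: CoverageCalibration
    slope: float
    intercept: float
    resid_sd: float
    n_points: int
    _ols: object = None

    @property
    def df_resid(self) -> int:
        return self.n_points - 2

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        lo, hi = self._ols.conf_int(alpha=1 - level)[1]
        return float(lo), float(hi)

    def predict(self, deep_level) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(deep_level, dtype=float)

    def extrapolate(self, shallow_level: float, level: float = 0.95) -> tuple[float, tuple[float, float]]:
        """Deep-coverage level consistent with an observed shallow level.

        Returns the point estimate x̂ = (y − intercept)/slope and the
        interval of x whose ``level`` prediction band covers y, truncated to
        [0, 1]. With zero residual scatter the interval collapses to x̂.
        With a reverse fit the estimate is the direct prediction at the
        shallow level with its prediction interval.
        """
        if self.slope <= 0:
            raise ValueError("calibration invalid: slope must be positive")
        if self.model.reverse:
            return self._predict_deep(float(shallow_level), level)
        y = float(shallow_level)
        xhat = (y - self.intercept) / self.slope
        if self.resid_sd == 0:
            xhat = float(np.clip(xhat, 0.0, 1.0))
            return xhat, (xhat, xhat)
        x = self.model.x
        xbar = float(x.mean())
        sxx = float(((x - xbar) ** 2).sum())
        t = stats.t.ppf((1 + level) / 2, self.df_resid)
        T2 = (t * self.resid_sd) ** 2
        # prediction band: (y - a - b·x)² = T²(1 + 1/n + (x - x̄)²/Sxx);
        # expanding gives a quadratic in x (Fieller construction)
        b, a = self.slope, self.intercept
        A = b**2 - T2 / sxx
        B = -2 * b * (y - a) + 2 * T2 * xbar / sxx
        C = (y - a) ** 2 - T2 * (1 + 1 / self.n_points + xbar**2 / sxx)
        lo, hi = 0.0, 1.0
        if A > 0:
            disc = B**2 - 4 * A * C
            if disc >= 0:
                r = np.sqrt(disc)
                lo, hi = (-B - r) / (2 * A), (-B + r) / (2 * A)
        # A ≤ 0 or no real roots: band never excludes extreme x → whole range
        lo = float(np.clip(lo, 0.0, 1.0))
        hi = float(np.clip(hi, 0.0, 1.0))
        xhat = float(np.clip(xhat, lo, hi))
        return xhat, (lo, hi)

    def _predict_deep(self, shallow: float, level: float) -> tuple[float, tuple[float, float]]:
        x = self.model.x
        xbar = float(x.mean())
        sxx = float(((x - xbar) ** 2).sum())
        xhat = self.intercept + self.slope * shallow
        t = stats.t.ppf((1 + level) / 2, self.df_resid) if self.resid_sd else 0.0
        half = t * self.resid_sd * np.sqrt(1 + 1 / self.n_points + (shallow - xbar) ** 2 / sxx)
        lo = float(np.clip(xhat - half, 0.0, 1.0))
        hi = float(np.clip(xhat + half, 0.0, 1.0))
        return float(np.clip(xhat, lo, hi)), (lo, hi)

    def summary(self) -> str:
        slo, shi = self.slope_ci()
        ctx = self.model.context or "-"
        direction = ("y = deep, x = shallow (reverse fit)" if self.model.reverse
                     else "y = shallow, x = deep")
        return "\n".join(
            [
                f"Deep-vs-shallow methylation calibration (OLS, {direction})",
                "=" * 60,
                f"context      : {ctx}",
                f"n pairs      : {self.n_points}",
                f"slope        : {self.slope:.6g}  (95% CI {slo:.6g} – {shi:.6g})",
                f"intercept    : {self.intercept:.6g}",
                f"residual SD  : {self.resid_sd:.6g}",
                "intervals on extrapolated deep levels invert the 95% prediction band",
            ]
        )

    def to_keyvalue(self, path) -> None:
        """Serialise as a plain-text key-value file (round-trips via
        :func:`load_calibration`)."""
        with open(path, "wt") as fh:
            fh.write(f"context\t{self.model.context or ''}\n")
            fh.write(f"slope\t{self.slope!r}\n")
            fh.write(f"intercept\t{self.intercept!r}\n")
            fh.write(f"resid_sd\t{self.resid_sd!r}\n")
            fh.write(f"n_points\t{self.n_points}\n")
            fh.write(f"reverse\t{int(self.model.reverse)}\n")
            fh.write("x\t" + ",".join(repr(float(v)) for v in self.model.x) + "\n")
            fh.write("y\t" + ",".join(repr(float(v)) for v in self.model.y) + "\n")


def load_calibration(path) -> CalibrationResults:
    """Load a calibration serialised by :meth:`CalibrationResults.to_keyvalue`."""
    kv = {}
    with open(path) as fh:
        for line in fh:
            key, _, val = line.rstrip("\n").partition("\t")
            kv[key] = val
    x = np.array([float(v) for v in kv["x"].split(",")])
    y = np.array([float(v) for v in kv["y"].split(",")])
    reverse = bool(int(kv.get("reverse", "0")))
    if reverse:
        x, y = y, x  # constructor swaps back
    return CoverageCalibration(x, y, kv["context"] or None, reverse=reverse).fit()


def fit_calibration(pairs, context: str | None = None, reverse: bool = False) -> CalibrationResults:
    """Functional wrapper: OLS fit of shallow-on-deep level pairs.

    ``pairs`` is a tidy DataFrame (deep_level, shallow_level[, context]) or a
    sequence of (deep, shallow) tuples.
    """
    if isinstance(pairs, pd.DataFrame):
        return CoverageCalibration.from_frame(pairs, context, reverse=reverse).fit()
    arr = np.asarray(pairs, dtype=float)
    return CoverageCalibration(arr[:, 0], arr[:, 1], context, reverse=reverse).fit()


def extrapolate_level(results: CalibrationResults, shallow_level: float):
    """Functional wrapper around :meth:`CalibrationResults.extrapolate`."""
    return results.extrapolate(shallow_level)
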