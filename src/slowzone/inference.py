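"""Speed models and distributional tests on per-transit DWAS.

Three linear mixed-model designs (Gaussian response, year random intercept,
REML, Wald intervals) answer: does the measure change speed; does compliance
improve by year; and which covariates (pilotage, flag, ship class, transit
direction) explain speed when the measures are active.  Year-to-year
distribution shifts are tested with the two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

Z95 = sps.norm.ppf(0.975)


@dataclass
class SpeedModelFit:
    """Fixed-effect table (knots), year-intercept variance and sample size."""

    terms: pd.DataFrame          # index: term; columns estimate, ci_low, ci_high, p
    re_var: float
    n_obs: int
    dropped_terms: list[str] = field(default_factory=list)

    def estimate(self, term: str) -> float:
        return float(self.terms.loc[term, "estimate"])

    def ci(self, term: str) -> tuple[float, float]:
        r = self.terms.loc[term]
        return float(r["ci_low"]), float(r["ci_high"])

    def covers(self, term: str, value: float) -> bool:
        lo, hi = self.ci(term)
        return lo <= value <= hi


def _fit_mixed(formula: str, df: pd.DataFrame, groups: str) -> SpeedModelFit:
    with warnings.catch_warnings():
        # the year variance may legitimately sit on the zero boundary
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.filterwarnings("ignore", message=".*covariance.*singular.*")
        warnings.filterwarnings("ignore", message=".*Random effects.*")
        model = smf.mixedlm(formula, df, groups=df[groups])
        res = model.fit(reml=True)
    k = model.k_fe
    names = res.model.exog_names[:k]
    est = np.asarray(res.params)[:k]
    bse = np.asarray(res.bse)[:k]
    pvals = 2 * sps.norm.sf(np.abs(est / bse))
    terms = pd.DataFrame({
        "estimate": est, "ci_low": est - Z95 * bse, "ci_high": est + Z95 * bse,
        "p": pvals,
    }, index=names)
    re_var = float(res.cov_re.iloc[0, 0]) if res.cov_re.size else 0.0
    return SpeedModelFit(terms=terms, re_var=re_var, n_obs=len(df))


def fit_active_effect(table: pd.DataFrame) -> SpeedModelFit:
    """Effect of the measures being active on transit DWAS.

    ``table`` needs columns dwas, active (bool/0-1) and year.  The intercept
    is the inactive-period mean; the ``active`` term is the speed change when
    the measures are in force.
    """
    df = table.copy()
    df["active"] = df["active"].astype(int)
    if df["active"].nunique() < 2:
        raise ValueError("both active and inactive transits are required")
    return _fit_mixed("dwas ~ active", df, "year")


def fit_year_effects(table: pd.DataFrame) -> SpeedModelFit:
    """Per-active-year speed effects, with the inactive period as intercept.

    One dummy per (year, active) combination present in the data; inactive
    rows of every year share the intercept.
    """
    df = table.copy()
    df["active"] = df["active"].astype(int)
    if df["active"].nunique() < 2:
        raise ValueError("both active and inactive transits are required")
    years = sorted(df.loc[df["active"] == 1, "year"].unique())
    cols = []
    for y in years:
        name = f"active_{y}"
        df[name] = ((df["year"] == y) & (df["active"] == 1)).astype(int)
        cols.append(name)
    return _fit_mixed("dwas ~ " + " + ".join(cols), df, "year")


_COVARIATES = [
    ("pilot_onboard", 'C(pilot_onboard, Treatment(reference=False))'),
    ("flag", 'C(flag, Treatment(reference="Canadian"))'),
    ("ship_class", 'C(ship_class, Treatment(reference="tanker"))'),
    ("direction", 'C(direction, Treatment(reference="upstream"))'),
]


def fit_covariate_model(table: pd.DataFrame) -> SpeedModelFit:
    """Covariate effects on active-period DWAS.

    Reference levels — tanker, no pilot, Canadian flag, upstream — are
    absorbed into the intercept.  Constant or collinear factors are dropped
    with a warning rather than failing the fit.
    """
    df = table.copy()
    df["pilot_onboard"] = df["pilot_onboard"].astype(bool)
    dropped = []
    rhs_terms: list[str] = []
    # greedy rank check: a factor that is constant or aliased by the terms
    # already in the design (e.g. pilotage fully determined by flag) is
    # dropped with a warning instead of failing the fit
    for col, term in _COVARIATES:
        if df[col].nunique() < 2:
            warnings.warn(f"covariate {col!r} has a single level; dropped")
            dropped.append(col)
            continue
        trial = rhs_terms + [term]
        exog = smf.mixedlm("dwas ~ " + " + ".join(trial), df,
                           groups=df["year"]).exog
        if np.linalg.matrix_rank(exog) < exog.shape[1]:
            warnings.warn(f"covariate {col!r} is collinear with earlier terms; dropped")
            dropped.append(col)
        else:
            rhs_terms = trial
    if not rhs_terms:
        raise ValueError("no identifiable covariates")
    fit = _fit_mixed("dwas ~ " + " + ".join(rhs_terms), df, "year")
    fit.dropped_terms = dropped
    # friendlier term names
    rename = {}
    for name in fit.terms.index:
        new = name
        if name.startswith("C(pilot_onboard"):
            new = "pilot_onboard[True]"
        elif name.startswith("C(flag"):
            new = "flag[" + name.split("[T.")[-1].rstrip("]") + "]"
        elif name.startswith("C(ship_class"):
            new = "ship_class[" + name.split("[T.")[-1].rstrip("]") + "]"
        elif name.startswith("C(direction"):
            new = "direction[" + name.split("[T.")[-1].rstrip("]") + "]"
        rename[name] = new
    fit.terms = fit.terms.rename(index=rename)
    return fit


@dataclass
class KSResult:
    D: float
    p: float
    alternative: str


def ks_two_sample(a, b, alternative: str = "two-sided") -> KSResult:
    """Two-sample Kolmogorov-Smirnov test.

    ``alternative='greater'`` tests whether sample ``a`` is stochastically
    greater than ``b`` (its empirical CDF lies below), matching the
    year-comparison convention "left-side year faster than right-side year".
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    # scipy orients 'less'/'greater' by the CDF, which is the reverse of the
    # stochastic ordering of the values
    scipy_alt = {"two-sided": "two-sided", "greater": "less", "less": "greater"}
    r = sps.ks_2samp(a, b, alternative=scipy_alt[alternative], method="asymp")
    return KSResult(D=float(r.statistic), p=float(r.pvalue), alternative=alternative)


def ks_year_table(table: pd.DataFrame) -> pd.DataFrame:
    """Consecutive-year one-sided KS comparisons of active-period DWAS.

    For each adjacent pair of years, tests whether the earlier year's speeds
    are stochastically greater (compliance improving over time).  The first
    comparison contrasts the earliest (pre-measure or inactive) speeds with
    the first active year.
    """
    df = table.dropna(subset=["dwas"])
    years = sorted(df["year"].unique())
    rows = []
    for y0, y1 in zip(years[:-1], years[1:]):
        a = df.loc[(df["year"] == y0), "dwas"].to_numpy()
        b = df.loc[(df["year"] == y1) & (df["active"] == True), "dwas"].to_numpy()  # noqa: E712
        if a.size == 0 or b.size == 0:
            continue
        r = ks_two_sample(a, b, alternative="greater")
        rows.append({"comparison": f"{y0} > {y1}", "D": r.D, "p": r.p})
    return pd.DataFrame(rows, columns=["comparison", "D", "p"])


def fit_to_csv(fit: SpeedModelFit, path) -> None:
    out = fit.terms.copy()
    out.index.name = "term"
    out["re_var_year"] = fit.re_var
    out["n_obs"] = fit.n_obs
    out.to_csv(path)
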