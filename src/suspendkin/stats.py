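"""Mixed-effects ANCOVA layer: transforms, model fits, EMMs, Tukey tests.

Each kinematic response (mid-joint angle, segment abductions, limb
protraction, excursion) is compared across factor levels -- support-phase
event (TD/MS/LO), limb girdle, or species -- while controlling for
stride speed as a covariate and for individual animal and trial as
random intercepts (trial nested within individual).  Responses whose
distribution is strongly skewed (|skewness| > 1) are Box-Cox
transformed, with a positivity shift when needed, before fitting.

Fixed-effect terms are tested with Wald F statistics on the REML fit
(denominator df = n - number of fixed-effect parameters).  When a factor
interacts with speed (non-homogeneous slopes), factor levels are
compared at the minimum, mean and maximum of the speed range common to
all levels; otherwise at the overall mean speed.  Estimated marginal
means (EMMs) are model predictions on that reference grid with 95%
confidence limits, and all pairwise level contrasts are adjusted with
Tukey's studentized-range method.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from patsy import build_design_matrices
from scipy import stats as sps
from scipy.special import inv_boxcox
from statsmodels.regression.mixed_linear_model import MixedLM

from .errors import EmptyOverlapError
from .kinematics import ANGLE_VARS, EVENTS

logger = logging.getLogger(__name__)

SKEWNESS_THRESHOLD = 1.0

#: published estimated marginal mean elbow/knee angles (deg) for Linnaeus's
#: two-toed sloth (Choloepus didactylus), used for the descriptive species
#: comparison when no stride-level table for that species is supplied.
CHOLOEPUS_EMM = pd.DataFrame(
    {
        "species": ["Choloepus didactylus"] * 6,
        "response": ["midjoint_angle"] * 6,
        "girdle": ["fore", "fore", "fore", "hind", "hind", "hind"],
        "event": ["td", "ms", "lo", "td", "ms", "lo"],
        "emmean": [64.2, 51.6, 73.1, 100.0, 82.4, 75.8],
        "lower_cl": [52.2, 43.4, 63.8, 93.5, 74.6, 68.5],
        "upper_cl": [76.2, 59.9, 82.5, 107.0, 90.2, 83.0],
    }
)


# ---------------------------------------------------------------------------
# normality screening / Box-Cox


def screen_and_transform(
    values: np.ndarray,
    residuals: np.ndarray | None = None,
) -> tuple[np.ndarray, float | None, float]:
    """Box-Cox transform a response when its skewness warrants it.

    Returns ``(values', lambda or None, shift)``.  The transform is
    applied only when |skewness| > 1; the skewness is judged on
    ``residuals`` when given (e.g. after removing group means, so a
    genuine factor effect is not mistaken for non-normality) and on the
    raw values otherwise.  A shift of ``1 - min`` makes non-positive
    samples admissible.  Constant input is returned untouched with a
    warning.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 10:
        raise ValueError("screening needs n >= 10")
    if np.ptp(values) == 0:
        warnings.warn("constant response; no transform applied", stacklevel=2)
        return values, None, 0.0
    basis = values if residuals is None else np.asarray(residuals, dtype=float)
    skew = float(sps.skew(basis))
    if abs(skew) <= SKEWNESS_THRESHOLD:
        return values, None, 0.0
    shift = float(1.0 - values.min()) if values.min() <= 0 else 0.0
    transformed, lam = sps.boxcox(values + shift)
    logger.info(
        "Box-Cox applied (skew %.2f): lambda=%.3f shift=%.3f", skew, lam, shift
    )
    return transformed, float(lam), shift


# ---------------------------------------------------------------------------
# model specification and fitting


@dataclass
class ModelSpec:
    """What to fit: a response, fixed factors, speed covariate, randoms."""

    response: str
    factors: tuple[str, ...] = ("event",)
    include_interaction: bool = True
    random_trial: bool = True
    transform: str = "auto"       # 'auto' | 'none'

    def formula(self) -> str:
        terms = [f"C({f})" for f in self.factors] + ["speed"]
        op = " * " if self.include_interaction else " + "
        return f"{self.response} ~ {op.join(terms)}"


@dataclass
class AncovaFit:
    """A fitted mixed-effects ANCOVA plus the context needed downstream."""

    result: object
    spec: ModelSpec
    data: pd.DataFrame
    formula: str
    boxcox_lambda: float | None = None
    boxcox_shift: float = 0.0
    trial_dropped: bool = False
    _design_info: object = field(default=None, repr=False)

    @property
    def df_resid(self) -> float:
        return float(self.result.nobs - self.result.k_fe)

    def term_names(self) -> list[str]:
        return list(self._design_info.term_names)

    def term_test(self, term: str) -> dict:
        """Wald F test of all coefficients belonging to one model term."""
        sl = self._design_info.term_name_slices[term]
        beta = np.asarray(self.result.fe_params)[sl]
        cov = np.asarray(self.result.cov_params())[: self.result.k_fe, : self.result.k_fe]
        sub = cov[sl, sl]
        q = len(beta)
        wald = float(beta @ np.linalg.solve(sub, beta))
        fstat = wald / q
        p = float(sps.f.sf(fstat, q, self.df_resid))
        return {"term": term, "F": fstat, "df_num": q, "df_den": self.df_resid, "p": p}

    def interaction_test(self, factor: str) -> dict:
        return self.term_test(f"C({factor}):speed")

    def back_transform(self, x: np.ndarray) -> np.ndarray:
        if self.boxcox_lambda is None:
            return x
        return inv_boxcox(x, self.boxcox_lambda) - self.boxcox_shift


def fit_mixed_ancova(table: pd.DataFrame, spec: ModelSpec) -> AncovaFit:
    """REML fit of a mixed-effects ANCOVA on stride-summary rows.

    Random intercepts for individual, and for trial nested within
    individual; the trial term is dropped (with a log message) when the
    fit is singular or fails to converge with it.
    """
    data = table.dropna(subset=[spec.response, "speed", *spec.factors]).copy()
    if data["individual"].nunique() < 2:
        raise ValueError("mixed ANCOVA needs >= 2 individuals")
    lam: float | None = None
    shift = 0.0
    if spec.transform == "auto":
        group_means = data.groupby(list(spec.factors))[spec.response].transform("mean")
        vals, lam, shift = screen_and_transform(
            data[spec.response].to_numpy(),
            residuals=(data[spec.response] - group_means).to_numpy(),
        )
        data[spec.response] = vals
    formula = spec.formula()

    def _sane(res) -> bool:
        """Guard against boundary pathologies: when a variance component
        hits zero some optimizers return a wildly inflated (or
        non-finite) fixed-effects covariance."""
        cov = np.asarray(res.cov_params())[: res.k_fe, : res.k_fe]
        diag = np.diag(cov)
        return bool(np.all(np.isfinite(diag)) and diag.max() < 1e6 * max(res.scale, 1e-12))

    def _fit(with_trial: bool):
        vc = {"trial": "0 + C(trial)"} if with_trial else None
        model = MixedLM.from_formula(
            formula, data, groups=data["individual"],
            re_formula="1", vc_formula=vc,
        )
        res = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for method in ("lbfgs", "powell", "nm"):
                try:
                    candidate = model.fit(reml=True, method=method, maxiter=500)
                except np.linalg.LinAlgError:
                    logger.info("MixedLM %s step failed; trying next optimizer", method)
                    continue
                res = candidate
                if _sane(candidate):
                    break
                logger.info("MixedLM %s fit degenerate; trying next optimizer", method)
        if res is None:
            raise np.linalg.LinAlgError("all MixedLM optimizers failed")
        return model, res

    trial_dropped = False
    use_trial = spec.random_trial and data["trial"].nunique() > data["individual"].nunique()
    model = res = None
    if use_trial:
        try:
            model, res = _fit(True)
            singular = (not res.converged) or np.any(np.asarray(res.vcomp) < 1e-10)
        except (np.linalg.LinAlgError, ValueError):
            singular = True
        if singular:
            logger.info("singular/failed fit with trial term; refitting without it")
            trial_dropped = True
    if not use_trial or trial_dropped:
        model, res = _fit(False)

    return AncovaFit(
        result=res,
        spec=spec,
        data=data,
        formula=formula,
        boxcox_lambda=lam,
        boxcox_shift=shift,
        trial_dropped=trial_dropped,
        _design_info=model.data.design_info,
    )


# ---------------------------------------------------------------------------
# speed grids, EMMs, Tukey contrasts


def overlapping_speed_grid(
    table: pd.DataFrame, factor: str
) -> tuple[float, float, float]:
    """(min, mean, max) of the speed range common to all factor levels.

    The overlap is [max of per-level minima, min of per-level maxima];
    the mean is taken over observations falling inside the overlap.
    """
    groups = table.groupby(factor)["speed"]
    if (groups.count() < 2).any():
        raise ValueError("every factor level needs >= 2 speed observations")
    lo = float(groups.min().max())
    hi = float(groups.max().min())
    if lo > hi:
        mins, maxs = groups.min(), groups.max()
        culprits = ", ".join(
            f"{lev}: [{mins[lev]:.3g}, {maxs[lev]:.3g}]" for lev in mins.index
        )
        raise EmptyOverlapError(f"factor levels have disjoint speed ranges ({culprits})")
    inside = table["speed"].between(lo, hi)
    return lo, float(table.loc[inside, "speed"].mean()), hi


def _reference_rows(fit: AncovaFit, factor: str, level, speed: float) -> np.ndarray:
    """One averaged fixed-effects design row for (factor level, speed).

    Other categorical factors are averaged over their observed levels
    with equal weight; other numeric covariates sit at their mean.
    """
    others = [f for f in fit.spec.factors if f != factor]
    grids = [fit.data[f].unique() for f in others]
    combos = [()] if not grids else list(itertools.product(*grids))
    rows = []
    for combo in combos:
        rec = {factor: [level], "speed": [speed]}
        rec.update({f: [val] for f, val in zip(others, combo)})
        (x,) = build_design_matrices([fit._design_info], pd.DataFrame(rec))
        rows.append(np.asarray(x)[0])
    return np.mean(rows, axis=0)


def tukey_emm(
    fit: AncovaFit,
    factor: str,
    at_speeds: list[float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Estimated marginal means and Tukey-adjusted pairwise contrasts.

    ``at_speeds`` defaults to the overall mean speed (homogeneous-slopes
    handling); pass the overlapping-range (min, mean, max) when the
    factor x speed interaction is significant.  EMMs (and their
    confidence limits) are reported on the response's original scale,
    back-transformed endpoint-wise if Box-Cox was applied.
    """
    if at_speeds is None:
        at_speeds = [float(fit.data["speed"].mean())]
    levels = list(pd.unique(fit.data[factor]))
    k = len(levels)
    beta = np.asarray(fit.result.fe_params)
    cov = np.asarray(fit.result.cov_params())[: fit.result.k_fe, : fit.result.k_fe]
    df = fit.df_resid
    tcrit = sps.t.ppf(0.975, df)

    emm_rows, con_rows = [], []
    for speed in at_speeds:
        X = {lev: _reference_rows(fit, factor, lev, speed) for lev in levels}
        for lev in levels:
            est = float(X[lev] @ beta)
            se = float(np.sqrt(X[lev] @ cov @ X[lev]))
            lo_raw, hi_raw = est - tcrit * se, est + tcrit * se
            lo_bt, mid_bt, hi_bt = fit.back_transform(np.array([lo_raw, est, hi_raw]))
            emm_rows.append(
                {
                    factor: lev, "speed": speed,
                    "emmean": mid_bt, "se": se,
                    "lower_cl": min(lo_bt, hi_bt), "upper_cl": max(lo_bt, hi_bt),
                    "df": df,
                }
            )
        for i in range(k):
            for j in range(i + 1, k):
                L = X[levels[i]] - X[levels[j]]
                est = float(L @ beta)
                var = float(L @ cov @ L)
                if var <= 0:
                    con_rows.append(
                        {
                            "contrast": f"{levels[i]} - {levels[j]}", "speed": speed,
                            "estimate": np.nan, "se": np.nan, "p_tukey": np.nan,
                            "estimable": False,
                        }
                    )
                    continue
                se = np.sqrt(var)
                qstat = abs(est) / se * np.sqrt(2.0)
                p = float(np.clip(sps.studentized_range.sf(qstat, k, df), 0.0, 1.0))
                con_rows.append(
                    {
                        "contrast": f"{levels[i]} - {levels[j]}", "speed": speed,
                        "estimate": est, "se": float(se), "p_tukey": p,
                        "estimable": True,
                    }
                )
    return pd.DataFrame(emm_rows), pd.DataFrame(con_rows)


# ---------------------------------------------------------------------------
# tidy helpers over stride summaries


def stride_table_to_long(
    summary: pd.DataFrame, response: str, girdle: str | None = None
) -> pd.DataFrame:
    """Melt a wide stride-summary table to one row per stride x event."""
    if response not in ANGLE_VARS:
        raise ValueError(f"response must be one of {ANGLE_VARS}")
    df = summary if girdle is None else summary[summary["limb"] == girdle]
    keep = [c for c in ("species", "individual", "trial", "stride_id",
                        "limb", "side", "speed") if c in df.columns]
    rows = []
    for ev in EVENTS:
        part = df[keep].copy()
        part["event"] = ev
        part[response] = df[f"{response}_{ev}"].to_numpy()
        rows.append(part)
    return pd.concat(rows, ignore_index=True)


def analyze_response(
    summary: pd.DataFrame,
    response: str,
    girdle: str | None = None,
    factor: str = "event",
    alpha: float = 0.05,
) -> dict:
    """Standard single-response workflow: fit, interaction check, EMMs.

    Fits ``response ~ C(factor) * speed`` with the study random effects,
    tests the factor x speed interaction, chooses the evaluation speeds
    accordingly, and returns the fit plus EMM/contrast tables and raw
    per-event means.
    """
    if response == "excursion":
        if factor == "event":
            factor = "limb"      # excursion is per-stride; compare girdles
        long = summary if girdle is None else summary[summary["limb"] == girdle]
        long = long.copy()
    else:
        long = stride_table_to_long(summary, response, girdle)
    spec = ModelSpec(response=response, factors=(factor,))
    fit = fit_mixed_ancova(long, spec)
    inter = fit.interaction_test(factor)
    if inter["p"] < alpha:
        at_speeds = list(overlapping_speed_grid(long, factor))
    else:
        at_speeds = [float(long["speed"].mean())]
    emm, contrasts = tukey_emm(fit, factor, at_speeds)
    raw_means = long.groupby(factor)[response].mean().to_dict()
    return {
        "fit": fit,
        "interaction": inter,
        "factor_test": fit.term_test(f"C({factor})"),
        "speed_test": fit.term_test("speed"),
        "emm": emm,
        "contrasts": contrasts,
        "raw_means": raw_means,
        "at_speeds": at_speeds,
    }


def compare_species_descriptive(
    bradypus_emm: pd.DataFrame, girdle: str
) -> pd.DataFrame:
    """Descriptive elbow/knee comparison against published two-toed sloth EMMs.

    Used when only summary values (not stride-level data) are available
    for the comparison species: reports the EMM difference per event and
    whether the 95% intervals overlap.
    """
    ref = CHOLOEPUS_EMM[CHOLOEPUS_EMM["girdle"] == girdle].set_index("event")
    rows = []
    for _, r in bradypus_emm.iterrows():
        ev = r["event"]
        if ev not in ref.index:
            continue
        c = ref.loc[ev]
        rows.append(
            {
                "event": ev,
                "bradypus_emm": r["emmean"],
                "choloepus_emm": c["emmean"],
                "difference": r["emmean"] - c["emmean"],
                "ci_overlap": not (
                    r["lower_cl"] > c["upper_cl"] or r["upper_cl"] < c["lower_cl"]
                ),
            }
        )
    return pd.DataFrame(rows)
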