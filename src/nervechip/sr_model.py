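"""Linear response-surface model for the VSR success rate.

SR is modelled as an ordinary least-squares linear function of the design
and waveform factors

    SR ~ a0 + a1*N_E + a2*pitch + a3*width + a4*exp(1/v) + a5*SNR

with velocity entering through ``exp(1/v)`` (v in m/s).  Effects are
reported as standardized half effects: the SR change from the midpoint of
a factor's observed range to its extreme, ``a_j * range_j / 2``, i.e. the
coefficient under [-1, 1] coding of the factors.  Term significance uses
type-II F tests at alpha = 0.05.  Predictions are clipped to [0, 1].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .simulate import channel_gain_scale
from .sigproc import snr_after_averaging

__all__ = [
    "FACTORS",
    "build_design_matrix",
    "fit_sr_model",
    "standardized_half_effects",
    "predict_sr",
    "safe_region",
    "SRLinearModel",
    "HalfEffect",
]

#: Model factor columns, in fitting order (intercept excluded).
FACTORS = ("n_electrodes", "pitch", "width", "exp_inv_velocity", "snr_db")

_FORMULA = "sr ~ " + " + ".join(FACTORS)


def _augment(dataset: pd.DataFrame) -> pd.DataFrame:
    df = dataset.copy()
    required = {"n_electrodes", "pitch", "width", "velocity", "snr_db", "sr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dataset is missing columns: {sorted(missing)}")
    if np.any(df["velocity"] <= 0):
        raise ValueError("velocity must be positive for the exp(1/v) term")
    if np.any((df["sr"] < 0) | (df["sr"] > 1)):
        raise ValueError("sr values must lie in [0, 1]")
    df["exp_inv_velocity"] = np.exp(1.0 / df["velocity"].to_numpy(dtype=float))
    return df


def build_design_matrix(dataset: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Design matrix ``[1, N_E, pitch, width, exp(1/v), SNR]`` and names."""
    df = _augment(dataset)
    cols = ["intercept"] + list(FACTORS)
    X = np.column_stack(
        [np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in FACTORS]
    )
    return X, cols


@dataclass
class SRLinearModel:
    """Fitted SR response surface with its coding ranges and diagnostics."""

    coefficients: dict  # name -> a_j (incl. "intercept")
    std_errors: dict
    p_values: dict  # per-term type-II F p-values
    ranges: dict  # factor -> (min, max) observed during fitting
    r_squared: float
    df_resid: float
    n_obs: int
    mean_sr: float
    source: str = "simulated"

    def predict_row(self, **factors) -> float:
        x = self.coefficients["intercept"]
        for name in FACTORS:
            x += self.coefficients[name] * factors[name]
        return float(np.clip(x, 0.0, 1.0))

    def to_json(self) -> str:
        payload = {
            "coefficients": self.coefficients,
            "std_errors": self.std_errors,
            "p_values": self.p_values,
            "ranges": {k: list(v) for k, v in self.ranges.items()},
            "r_squared": self.r_squared,
            "df_resid": self.df_resid,
            "n_obs": self.n_obs,
            "mean_sr": self.mean_sr,
            "source": self.source,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SRLinearModel":
        d = json.loads(text)
        d["ranges"] = {k: tuple(v) for k, v in d["ranges"].items()}
        return cls(**d)


def fit_sr_model(dataset: pd.DataFrame, source: str = "simulated") -> SRLinearModel:
    """OLS fit of the SR response surface.

    Raises on a rank-deficient design matrix, naming the collinear terms.
    """
    df = _augment(dataset)
    if len(df) < len(FACTORS) + 2:
        raise ValueError(
            f"need at least {len(FACTORS) + 2} rows to fit {len(FACTORS)} terms"
        )
    X, cols = build_design_matrix(dataset)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns: ones whose removal restores full rank
        bad = [
            cols[j]
            for j in range(1, X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ValueError(f"design matrix is rank deficient; collinear terms: {bad}")
    fit = smf.ols(_FORMULA, data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # anova_lm warns on tiny residuals
        anova = anova_lm(fit, typ=2)
    p_values = {
        name: float(anova.loc[name, "PR(>F)"]) for name in FACTORS
    }
    coef = {"intercept": float(fit.params["Intercept"])}
    se = {"intercept": float(fit.bse["Intercept"])}
    for name in FACTORS:
        coef[name] = float(fit.params[name])
        se[name] = float(fit.bse[name])
    ranges = {
        name: (float(df[name].min()), float(df[name].max())) for name in FACTORS
    }
    return SRLinearModel(
        coefficients=coef,
        std_errors=se,
        p_values=p_values,
        ranges=ranges,
        r_squared=float(fit.rsquared),
        df_resid=float(fit.df_resid),
        n_obs=int(fit.nobs),
        mean_sr=float(df["sr"].mean()),
        source=source,
    )


@dataclass(frozen=True)
class HalfEffect:
    """Standardized half effect of one model term, in SR units."""

    term: str
    half_effect: float
    ci_low: float
    ci_high: float
    p_value: float
    significant: bool
    degenerate: bool = False  # zero observed range

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.half_effect <= self.ci_high):
            raise ValueError("confidence interval must contain the point estimate")


def standardized_half_effects(
    model: SRLinearModel, alpha: float = 0.05
) -> list[HalfEffect]:
    """Per-term SR change from range midpoint to extreme, with 95% CI.

    ``half_effect_j = a_j * range_j / 2``; the CI scales the coefficient's
    standard error by the same half range.  A factor observed at a single
    level gets a zero, flagged half effect.
    """
    out: list[HalfEffect] = []
    for name in FACTORS:
        lo, hi = model.ranges[name]
        half_range = (hi - lo) / 2.0
        if half_range == 0:
            out.append(
                HalfEffect(
                    term=name,
                    half_effect=0.0,
                    ci_low=0.0,
                    ci_high=0.0,
                    p_value=np.nan,
                    significant=False,
                    degenerate=True,
                )
            )
            continue
        he = model.coefficients[name] * half_range
        margin = 1.96 * model.std_errors[name] * half_range
        p = model.p_values[name]
        out.append(
            HalfEffect(
                term=name,
                half_effect=he,
                ci_low=he - margin,
                ci_high=he + margin,
                p_value=p,
                significant=bool(p < alpha),
            )
        )
    return out


def predict_sr(
    model: SRLinearModel,
    n_electrodes: float,
    pitch: float,
    width: float,
    velocity: float,
    snr_db: float,
    extrapolation_warning: bool = True,
) -> float:
    """Clipped linear SR prediction at one operating point."""
    if velocity <= 0:
        raise ValueError("velocity must be positive")
    factors = {
        "n_electrodes": n_electrodes,
        "pitch": pitch,
        "width": width,
        "exp_inv_velocity": float(np.exp(1.0 / velocity)),
        "snr_db": snr_db,
    }
    if extrapolation_warning:
        for name, value in factors.items():
            lo, hi = model.ranges[name]
            span = (hi - lo) or 1.0
            if value < lo - 0.5 * span or value > hi + 0.5 * span:
                warnings.warn(
                    f"{name} = {value:g} is far outside the fitted range "
                    f"[{lo:g}, {hi:g}]; prediction is an extrapolation"
                )
    return model.predict_row(**factors)


def safe_region(
    model: SRLinearModel,
    snr_values: Sequence[float],
    velocities: Sequence[float],
    channel_lengths: Sequence[float],
    width: float,
    n_electrodes: float,
    pitch: float,
    sr_threshold: float = 0.8,
    reference_length: float = 10.0,
    gain_calibration: Optional[Sequence[tuple[float, float]]] = None,
) -> pd.DataFrame:
    """Map the SR >= threshold "safe" region and the averaging needed below it.

    The channel length shifts the attainable SNR through the length-gain
    calibration (``snr + 20*log10(scale(L))``).  For grid points below the
    threshold the minimal number of coherent averages ``n`` such that
    ``predict_sr(snr + 10*log10(n)) >= threshold`` is reported
    (``inf`` when the SNR coefficient cannot reach it).
    """
    if not 0 < sr_threshold <= 1:
        raise ValueError("sr_threshold must lie in (0, 1]")
    a_snr = model.coefficients["snr_db"]
    rows = []
    for L in channel_lengths:
        gain_db = 20.0 * np.log10(
            channel_gain_scale(L, gain_calibration, reference_length)
        )
        for v in velocities:
            for snr in snr_values:
                snr_eff = snr + gain_db
                sr = predict_sr(
                    model, n_electrodes, pitch, width, v, snr_eff,
                    extrapolation_warning=False,
                )
                if sr >= sr_threshold:
                    n_avg: float = 1
                else:
                    if a_snr <= 0:
                        n_avg = np.inf
                    else:
                        # linear (unclipped) prediction solves in closed form
                        x0 = model.coefficients["intercept"]
                        for name, val in (
                            ("n_electrodes", n_electrodes),
                            ("pitch", pitch),
                            ("width", width),
                            ("exp_inv_velocity", np.exp(1.0 / v)),
                        ):
                            x0 += model.coefficients[name] * val
                        snr_needed = (sr_threshold - x0) / a_snr
                        exponent = (snr_needed - snr_eff) / 10.0
                        if exponent > 9:  # > 1e9 averages: unreachable in practice
                            rows.append(
                                {
                                    "channel_length": L,
                                    "velocity": v,
                                    "snr_db": snr,
                                    "snr_effective_db": snr_eff,
                                    "sr_predicted": sr,
                                    "safe": False,
                                    "n_averages": np.inf,
                                }
                            )
                            continue
                        n_avg = max(int(np.ceil(10.0**exponent)), 1)
                        # guard against rounding at the boundary
                        while (
                            predict_sr(
                                model, n_electrodes, pitch, width, v,
                                snr_after_averaging(snr_eff, n_avg),
                                extrapolation_warning=False,
                            )
                            < sr_threshold
                        ):
                            n_avg *= 2
                rows.append(
                    {
                        "channel_length": L,
                        "velocity": v,
                        "snr_db": snr,
                        "snr_effective_db": snr_eff,
                        "sr_predicted": sr,
                        "safe": sr >= sr_threshold,
                        "n_averages": n_avg,
                    }
                )
    return pd.DataFrame(rows)
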