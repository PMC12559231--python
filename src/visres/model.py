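"""Eccentricity-dependent resolution-limit model and population statistics.

The sensitivity model is log-linear in spatial frequency with an
eccentricity-dependent slope.  For a colour channel c with baseline
sensitivity ``S0``, frequency slope ``k_rho < 0`` and eccentricity factor
``k_e > 0``, contrast sensitivity at eccentricity ``e`` (degrees) and
spatial frequency ``rho`` (cpd) is

    log10 S(e, rho) = log10 S0 + k_rho * (1 + k_e * e) * rho.

A stimulus of fixed contrast ``c`` is at threshold when ``S = 1/c``;
solving for the frequency gives the resolution limit

    rho(e) = A / (1 + k_e * e),       A = log10(S / S0) / k_rho  [cpd],

so the threshold in ppd is ``2 * rho(e)``.  With the contrast fixed per
channel, ``S0`` and ``k_rho`` are not separately identifiable from
threshold data: only their combination ``A`` (the foveal cutoff frequency)
enters the prediction.  The fit is therefore parameterised as ``(A, k_e)``;
``k_rho`` can be reported when ``S0`` is pinned by configuration.  The
choice of logarithm base cancels in ``A`` and so cannot affect thresholds.

Population variability is modelled by a per-channel Gaussian over observer
thresholds at each measured eccentricity, with the mean and standard
deviation interpolated linearly in eccentricity between the measured knots
(and continued linearly, floored at zero, beyond them).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import units

__all__ = [
    "CHANNELS",
    "DEFAULT_CONTRASTS",
    "ChannelParams",
    "ThresholdRecord",
    "PopulationModel",
    "sensitivity",
    "threshold_frequency",
    "threshold_ppd",
    "ke_from_decline",
    "fit_channel_params",
    "fit_population",
    "fit_populations",
    "population_percentile",
    "ideal_display_curve",
    "read_thresholds",
    "write_thresholds",
    "records_from_frame",
    "params_to_json",
    "params_from_json",
    "default_channel_params",
]

#: Colour-channel vocabulary: achromatic (L+M), red-green (L-M) and
#: yellow-violet (S-(L+M)) directions of the DKL opponent space.
CHANNELS = ("Ach", "RG", "YV")

#: Stimulus contrast per channel used in the threshold measurements; chosen
#: to be faithfully reproducible on a display.
DEFAULT_CONTRASTS = {"Ach": 0.96, "RG": 0.23, "YV": 0.89}

#: Conventional baseline sensitivity used when reporting k_rho; only the
#: identifiable combination A = log10(S/S0)/k_rho affects thresholds.
DEFAULT_S0 = 200.0


@dataclass(frozen=True)
class ChannelParams:
    """Per-channel parameters of the resolution-limit model.

    ``A`` is the foveal cutoff frequency in cpd (the threshold frequency at
    eccentricity 0) and ``k_e`` the per-degree eccentricity factor.  ``S0``
    is the (conventional) baseline sensitivity; ``k_rho`` is derived from it
    and is negative.  ``residual_rmse`` is populated by
    :func:`fit_channel_params`.
    """

    channel: str
    A: float
    k_e: float
    contrast: float
    S0: float = DEFAULT_S0
    residual_rmse: float | None = None
    negative_ke_warning: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")
        if not self.A > 0:
            raise ValueError(f"A (foveal cutoff, cpd) must be positive, got {self.A}")
        if not (0 < self.contrast <= 1):
            raise ValueError(f"contrast must be in (0, 1], got {self.contrast}")
        if not self.S0 > 1.0 / self.contrast:
            raise ValueError(
                "S0 must exceed the threshold sensitivity 1/contrast "
                f"({1.0 / self.contrast:.3g}), got {self.S0}"
            )

    @property
    def S(self) -> float:
        """Sensitivity at threshold: the reciprocal of the stimulus contrast."""
        return 1.0 / self.contrast

    @property
    def k_rho(self) -> float:
        """Frequency slope implied by the pinned S0 (negative)."""
        return np.log10(self.S / self.S0) / self.A


@dataclass(frozen=True)
class ThresholdRecord:
    """One observer x channel x eccentricity resolution threshold."""

    observer_id: str
    channel: str
    eccentricity_deg: float
    threshold_ppd: float
    estimate_sd: float | None = None

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.eccentricity_deg < 0:
            raise ValueError("eccentricity must be >= 0")
        if not (np.isfinite(self.threshold_ppd) and self.threshold_ppd > 0):
            raise ValueError(f"threshold_ppd must be finite and positive, got {self.threshold_ppd}")
        if self.estimate_sd is not None and self.estimate_sd < 0:
            raise ValueError("estimate_sd must be >= 0")


def sensitivity(params: ChannelParams, e: float, rho) -> np.ndarray | float:
    """Contrast sensitivity at eccentricity ``e`` (deg) and frequency ``rho``
    (cpd); strictly decreasing in both for valid parameters."""
    if e < 0:
        raise ValueError("eccentricity must be >= 0")
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("rho must be positive")
    log_s = np.log10(params.S0) + params.k_rho * (1.0 + params.k_e * e) * rho
    out = 10.0 ** log_s
    return float(out) if out.ndim == 0 else out


def threshold_frequency(params: ChannelParams, e) -> np.ndarray | float:
    """Resolution limit in cpd at eccentricity ``e``: ``A / (1 + k_e * e)``."""
    e = np.asarray(e, dtype=float)
    if np.any(e < 0):
        raise ValueError("eccentricity must be >= 0")
    denom = 1.0 + params.k_e * e
    if np.any(denom <= 0):
        raise ValueError("1 + k_e * e must be positive")
    out = params.A / denom
    return float(out) if out.ndim == 0 else out


def threshold_ppd(params: ChannelParams, e) -> np.ndarray | float:
    """Resolution limit in ppd (twice the cpd cutoff)."""
    out = 2.0 * np.asarray(threshold_frequency(params, e))
    return float(out) if out.ndim == 0 else out


def ke_from_decline(decline: float, e: float) -> float:
    """Closed-form eccentricity factor from a fold-decline at eccentricity e:
    rho(0)/rho(e) = decline  =>  k_e = (decline - 1) / e."""
    if decline <= 0 or e <= 0:
        raise ValueError("decline and e must be positive")
    return (decline - 1.0) / e


def _as_frame(records: Iterable[ThresholdRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([asdict(r) for r in records])


def fit_channel_params(
    records: Iterable[ThresholdRecord] | pd.DataFrame,
    contrast: float | None = None,
    channel: str | None = None,
    S0: float = DEFAULT_S0,
    aggregate: str | None = None,
) -> ChannelParams:
    """Least-squares fit of the resolution-limit curve to threshold data.

    Fits ``rho(e) = A / (1 + k_e e)`` (in linear cpd space) to the per-record
    cutoff frequencies ``rho = threshold_ppd / 2`` by local least squares
    with a multi-start over ``k_e``.  With ``aggregate="median"`` the fit
    targets per-eccentricity medians instead of individual observations.

    Parameters
    ----------
    records:
        Threshold records or an equivalent DataFrame.  If more than one
        channel is present, ``channel`` selects which to fit.
    contrast:
        Stimulus contrast of the channel; defaults to the study value for
        the channel.
    S0:
        Conventional baseline sensitivity pinned so a ``k_rho`` can be
        reported; does not influence the fitted thresholds.
    """
    df = _as_frame(records)
    if channel is not None:
        df = df[df["channel"] == channel]
    chans = df["channel"].unique()
    if len(chans) != 1:
        raise ValueError(f"records must contain exactly one channel, got {list(chans)}")
    chan = str(chans[0])
    if contrast is None:
        contrast = DEFAULT_CONTRASTS[chan]

    if aggregate == "median":
        agg = df.groupby("eccentricity_deg")["threshold_ppd"].median().reset_index()
        e = agg["eccentricity_deg"].to_numpy(float)
        rho = agg["threshold_ppd"].to_numpy(float) / 2.0
    elif aggregate is None:
        e = df["eccentricity_deg"].to_numpy(float)
        rho = df["threshold_ppd"].to_numpy(float) / 2.0
    else:
        raise ValueError("aggregate must be None or 'median'")

    if np.any(rho <= 0):
        raise ValueError("all thresholds must be positive")
    if np.unique(e).size < 2:
        raise ValueError("fit is underdetermined: need >= 2 distinct eccentricities")

    def resid(theta: np.ndarray) -> np.ndarray:
        a, ke = theta
        return a / (1.0 + ke * e) - rho

    a0 = float(np.max(rho))
    best = None
    for ke0 in (0.05, 0.1, 0.13, 0.2, 0.3, 0.4, 0.5):
        sol = optimize.least_squares(resid, x0=[a0, ke0], method="lm", xtol=1e-14, ftol=1e-14)
        if best is None or sol.cost < best.cost - 1e-15:
            best = sol
    a_hat, ke_hat = best.x
    rmse = float(np.sqrt(np.mean(resid(best.x) ** 2)))
    neg = bool(ke_hat < 0)
    if neg:
        warnings.warn(
            f"fitted k_e is negative ({ke_hat:.4g}) for channel {chan}: thresholds "
            "increase with eccentricity",
            stacklevel=2,
        )
    return ChannelParams(
        channel=chan,
        A=float(a_hat),
        k_e=float(ke_hat),
        contrast=float(contrast),
        S0=float(S0),
        residual_rmse=rmse,
        negative_ke_warning=neg,
    )


@dataclass(frozen=True)
class PopulationModel:
    """Gaussian population of resolution thresholds for one channel.

    ``knots`` holds ``(eccentricity_deg, mu_ppd, sigma_ppd)`` at the
    measured eccentricities; mean and SD are interpolated linearly between
    knots and continued linearly beyond them, floored at zero.
    """

    channel: str
    knots: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if len(self.knots) == 0:
            raise ValueError("empty population model")
        ecc = [k[0] for k in self.knots]
        if sorted(ecc) != ecc or len(set(ecc)) != len(ecc):
            raise ValueError("knots must be sorted by eccentricity and unique")
        for e, mu, sigma in self.knots:
            if sigma < 0:
                raise ValueError(f"sigma must be >= 0 at knot e={e}")

    def _interp(self, e, column: int) -> np.ndarray:
        e = np.atleast_1d(np.asarray(e, dtype=float))
        xs = np.array([k[0] for k in self.knots])
        ys = np.array([k[column] for k in self.knots])
        if xs.size == 1:
            return np.full_like(e, ys[0])
        out = np.interp(e, xs, ys)
        # np.interp clamps; continue the edge segments linearly instead.
        lo, hi = e < xs[0], e > xs[-1]
        if np.any(lo):
            slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
            out[lo] = ys[0] + slope * (e[lo] - xs[0])
        if np.any(hi):
            slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
            out[hi] = ys[-1] + slope * (e[hi] - xs[-1])
        return np.maximum(out, 0.0)

    def mu(self, e) -> np.ndarray | float:
        out = self._interp(e, 1)
        return float(out[0]) if np.isscalar(e) or np.asarray(e).ndim == 0 else out

    def sigma(self, e) -> np.ndarray | float:
        out = self._interp(e, 2)
        return float(out[0]) if np.isscalar(e) or np.asarray(e).ndim == 0 else out

    def is_extrapolated(self, e) -> np.ndarray | bool:
        xs = [k[0] for k in self.knots]
        e_arr = np.asarray(e, dtype=float)
        out = (e_arr < xs[0]) | (e_arr > xs[-1])
        return bool(out) if out.ndim == 0 else out


def fit_population(
    records: Iterable[ThresholdRecord] | pd.DataFrame,
    channel: str | None = None,
) -> PopulationModel:
    """Fit the Gaussian population model for one channel.

    Per (channel, eccentricity) knot: ``mu`` is the sample mean and
    ``sigma`` the sample standard deviation (n-1 denominator) of the
    per-observer thresholds.  Every knot needs at least two observers.
    """
    df = _as_frame(records)
    if channel is not None:
        df = df[df["channel"] == channel]
    chans = df["channel"].unique()
    if len(chans) != 1:
        raise ValueError(f"records must contain exactly one channel, got {list(chans)}")
    chan = str(chans[0])
    knots = []
    for e, grp in sorted(df.groupby("eccentricity_deg"), key=lambda t: t[0]):
        vals = grp["threshold_ppd"].to_numpy(float)
        if vals.size < 2:
            raise ValueError(
                f"knot (channel={chan}, e={e}) has {vals.size} observer(s); need >= 2"
            )
        knots.append((float(e), float(np.mean(vals)), float(np.std(vals, ddof=1))))
    return PopulationModel(channel=chan, knots=tuple(knots))


def fit_populations(
    records: Iterable[ThresholdRecord] | pd.DataFrame,
) -> dict[str, PopulationModel]:
    """Fit one :class:`PopulationModel` per channel present in the records."""
    df = _as_frame(records)
    return {
        str(c): fit_population(df, channel=str(c))
        for c in sorted(df["channel"].unique(), key=list(CHANNELS).index)
    }


def population_percentile(model: PopulationModel, e, p: float) -> np.ndarray | float:
    """Threshold ppd of the ``p``-th percentile observer at eccentricity
    ``e``: ``mu(e) + z_p * sigma(e)``, floored at 0.  Higher percentiles are
    more acute observers (higher ppd)."""
    if not (0 < p < 100):
        raise ValueError("percentile must be in (0, 100)")
    z = stats.norm.ppf(p / 100.0)
    out = np.maximum(np.atleast_1d(model._interp(e, 1) + z * model._interp(e, 2)), 0.0)
    return float(out[0]) if np.isscalar(e) or np.asarray(e).ndim == 0 else out


def ideal_display_curve(
    model: PopulationModel,
    percentile: float,
    distances: Sequence[float],
    kind: str = "lines",
    eccentricity: float = 0.0,
) -> pd.DataFrame:
    """Minimum display resolution meeting a population percentile.

    For each viewing distance, the smallest vertical line count
    (``kind="lines"``, distance in display heights) or pixel density
    (``kind="ppi"``, distance in metres) whose centre-of-screen ppd reaches
    the percentile threshold at the given eccentricity.
    """
    target = population_percentile(model, eccentricity, percentile)
    rows = []
    for d in distances:
        if kind == "lines":
            exact = units.required_lines(target, d)
            rows.append({"distance_H": d, "required_lines": int(np.ceil(exact)),
                         "required_lines_exact": exact})
        elif kind == "ppi":
            rows.append({"distance_m": d, "required_ppi": units.required_ppi(target, d)})
        else:
            raise ValueError("kind must be 'lines' or 'ppi'")
    out = pd.DataFrame(rows)
    out.attrs["target_ppd"] = float(target)
    out.attrs["percentile"] = float(percentile)
    return out


# ---------------------------------------------------------------------------
# IO

THRESHOLD_COLUMNS = ["observer_id", "channel", "eccentricity_deg", "threshold_ppd", "estimate_sd"]


def read_thresholds(path: str | Path) -> pd.DataFrame:
    """Read a threshold table CSV; validates the schema and channel names."""
    df = pd.read_csv(path)
    missing = [c for c in THRESHOLD_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"threshold CSV missing columns: {missing}")
    bad = set(df["channel"].unique()) - set(CHANNELS)
    if bad:
        raise ValueError(f"unknown channel value(s) {sorted(bad)}; expected {CHANNELS}")
    if (df["threshold_ppd"] <= 0).any() or not np.isfinite(df["threshold_ppd"]).all():
        raise ValueError("threshold_ppd must be finite and positive")
    return df


def write_thresholds(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def records_from_frame(df: pd.DataFrame) -> list[ThresholdRecord]:
    return [
        ThresholdRecord(
            observer_id=str(r.observer_id),
            channel=str(r.channel),
            eccentricity_deg=float(r.eccentricity_deg),
            threshold_ppd=float(r.threshold_ppd),
            estimate_sd=float(r.estimate_sd)
            if "estimate_sd" in df.columns and pd.notna(getattr(r, "estimate_sd", None))
            else None,
        )
        for r in df.itertuples(index=False)
    ]


def params_to_json(params: ChannelParams | Iterable[ChannelParams], path: str | Path | None = None) -> str:
    """Serialise fitted parameters (channel, A, k_e, contrast, residuals)."""
    if isinstance(params, ChannelParams):
        params = [params]
    payload = [
        {
            "channel": p.channel,
            "A_cpd": p.A,
            "k_e": p.k_e,
            "contrast": p.contrast,
            "S0": p.S0,
            "k_rho": p.k_rho,
            "residual_rmse": p.residual_rmse,
        }
        for p in params
    ]
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def params_from_json(source: str | Path) -> dict[str, ChannelParams]:
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    payload = json.loads(text)
    out = {}
    for item in payload:
        out[item["channel"]] = ChannelParams(
            channel=item["channel"],
            A=item["A_cpd"],
            k_e=item["k_e"],
            contrast=item["contrast"],
            S0=item.get("S0", DEFAULT_S0),
            residual_rmse=item.get("residual_rmse"),
        )
    return out


def default_channel_params() -> dict[str, ChannelParams]:
    """Model parameters calibrated to the measured median thresholds.

    Foveal cutoffs follow the median foveal limits (94, 89 and 53 ppd for
    Ach, RG and YV, i.e. A = 47, 44.5 and 26.5 cpd); the eccentricity
    factors follow the fold-declines between the fovea and 10 degrees
    (2.3x achromatic, 4.9x red-green, 4.8x yellow-violet) via
    :func:`ke_from_decline`.
    """
    declines = {"Ach": 2.3, "RG": 4.9, "YV": 4.8}
    foveal_cpd = {"Ach": 47.0, "RG": 44.5, "YV": 26.5}
    return {
        c: ChannelParams(
            channel=c,
            A=foveal_cpd[c],
            k_e=ke_from_decline(declines[c], 10.0),
            contrast=DEFAULT_CONTRASTS[c],
        )
        for c in CHANNELS
    }
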