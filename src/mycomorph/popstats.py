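"""Per-timepoint population statistics.

Mean projected area, elongation and morphology number per
(experiment, culture, time, species, fraction) stratum, with Student-t
confidence half-widths at 1-α; coculture-vs-monoculture comparisons use the
Welch (unequal-variance) two-sided t-test with Welch–Satterthwaite degrees of
freedom.  Strata with fewer than ``min_n`` objects (default 30, the usual
rule for morphological means) are emitted but flagged and excluded from
downstream outcome calls.

Statistics are computed on per-object values pooled over all images of a
sampling timepoint, not on per-image means; p-values are reported raw per
timepoint, without multiple-testing correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .fractionation import ClassifiedObject, classified_to_frame

PARAMETERS = {"A": "area_um2", "E": "elongation", "Mo": "morphology_number"}


@dataclass(frozen=True)
class StatConfig:
    alpha: float = 0.05
    min_n: int = 30
    tiers: tuple[float, ...] = (0.05, 0.01, 0.001)
    pooled_variance: bool = False  # Student's pooled-variance t instead of Welch

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ParameterError("alpha must lie in (0, 1)")
        if self.min_n < 2:
            raise ParameterError("min_n must be >= 2")


@dataclass(frozen=True)
class FractionSummary:
    experiment: str
    culture: str
    time_h: float
    species: str
    fraction: str
    n: int
    mean_A: float
    mean_E: float
    mean_Mo: float
    ci_A: float
    ci_E: float
    ci_Mo: float
    below_min_n: bool


@dataclass(frozen=True)
class ComparisonResult:
    experiment: str
    time_h: float
    species: str
    fraction: str
    parameter: str  # "A" | "E" | "Mo"
    mean_co: float
    mean_mono: float
    t_statistic: float
    df: float
    p_value: float
    tier: str
    status: str = "ok"  # "ok" | "absent" | "below_min_n"


def _ci_halfwidth(values: np.ndarray, alpha: float) -> float:
    n = values.size
    if n < 2:
        return float("nan")
    s = float(np.std(values, ddof=1))
    if s == 0:
        return 0.0
    return float(stats.t.ppf(1 - alpha / 2, n - 1) * s / np.sqrt(n))


def _as_frame(objects) -> pd.DataFrame:
    if isinstance(objects, pd.DataFrame):
        df = objects
    else:
        df = classified_to_frame(list(objects))
    if not df.empty:
        # empty metadata round-trips through CSV as NaN; normalize so
        # grouping keys stay intact
        df = df.copy()
        for col in ("experiment", "culture"):
            if col in df.columns:
                df[col] = df[col].fillna("")
    return df


def summarize(objects, cfg: StatConfig | None = None) -> list[FractionSummary]:
    """Group classified objects by stratum and compute means with t confidence bands.

    ``objects`` may be a sequence of :class:`ClassifiedObject` or a classified
    DataFrame; any number of (experiment, culture, time) groups may be mixed.
    """
    cfg = cfg or StatConfig()
    df = _as_frame(objects)
    out: list[FractionSummary] = []
    if df.empty:
        return out
    keys = ["experiment", "culture", "time_h", "species", "fraction"]
    for (exp, cult, t, sp, fr), g in df.groupby(keys, sort=True, dropna=False):
        n = len(g)
        a = g["area_um2"].to_numpy(float)
        e = g["elongation"].to_numpy(float)
        mo = g["morphology_number"].to_numpy(float)
        out.append(
            FractionSummary(
                experiment=exp,
                culture=cult,
                time_h=float(t),
                species=sp,
                fraction=fr,
                n=n,
                mean_A=float(a.mean()),
                mean_E=float(e.mean()),
                mean_Mo=float(mo.mean()),
                ci_A=_ci_halfwidth(a, cfg.alpha),
                ci_E=_ci_halfwidth(e, cfg.alpha),
                ci_Mo=_ci_halfwidth(mo, cfg.alpha),
                below_min_n=n < cfg.min_n,
            )
        )
    return out


def summaries_to_frame(summaries: Sequence[FractionSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def assemble_timecourse(summaries: Sequence[FractionSummary] | pd.DataFrame) -> pd.DataFrame:
    """Tidy table keyed by (experiment, culture, time, species, fraction).

    Missing strata stay absent rather than being filled with zeros; duplicate
    keys raise.
    """
    df = summaries if isinstance(summaries, pd.DataFrame) else summaries_to_frame(summaries)
    if df.empty:
        return df
    keys = ["experiment", "culture", "time_h", "species", "fraction"]
    if df.duplicated(subset=keys).any():
        dup = df[df.duplicated(subset=keys, keep=False)][keys]
        raise ParameterError(f"duplicate summary keys:\n{dup}")
    return df.sort_values(keys).reset_index(drop=True)


def welch_test(x, y, *, pooled_variance: bool = False) -> tuple[float, float, float]:
    """Two-sided unequal-variance t-test: returns (t, df, p).

    Degenerate input with zero variance in both samples falls back to an
    exact comparison of means (p = 1 if equal, p = 0 otherwise) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ParameterError("each sample needs n >= 2")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        warnings.warn("both samples have zero variance; exact mean comparison", stacklevel=2)
        equal = np.isclose(x.mean(), y.mean())
        return 0.0 if equal else float("inf"), float(x.size + y.size - 2), 1.0 if equal else 0.0
    res = stats.ttest_ind(x, y, equal_var=pooled_variance)
    return float(res.statistic), float(res.df), float(res.pvalue)


def tier_label(p: float, tiers: tuple[float, ...] = (0.05, 0.01, 0.001)) -> str:
    """Map a p-value onto the ordered significance tiers, e.g. 'p<0.001' or 'n.s.'."""
    label = "n.s."
    for thr in sorted(tiers, reverse=True):
        if p < thr:
            label = f"p<{thr:g}"
    return label


def compare_timepoint(
    co,
    mono,
    parameter: str = "A",
    cfg: StatConfig | None = None,
    *,
    experiment: str = "",
    time_h: float = 0.0,
    species: str = "",
    fraction: str = "fully_evolved_pellet",
) -> ComparisonResult:
    """Welch comparison of one stratum's per-object values, coculture vs monoculture.

    An empty coculture stratum facing a populated monoculture yields an
    ``absent`` record (consumed by the outcome stage as pellet-disappearance
    evidence); strata below ``min_n`` yield a flagged, uncomputed record.
    """
    cfg = cfg or StatConfig()
    if parameter not in PARAMETERS:
        raise ParameterError(f"parameter must be one of {tuple(PARAMETERS)}")
    col = PARAMETERS[parameter]
    co_df, mono_df = _as_frame(co), _as_frame(mono)
    x = co_df[col].to_numpy(float) if not co_df.empty else np.array([])
    y = mono_df[col].to_numpy(float) if not mono_df.empty else np.array([])

    def _rec(status, t=float("nan"), df=float("nan"), p=float("nan"), tier=""):
        return ComparisonResult(
            experiment=experiment,
            time_h=time_h,
            species=species,
            fraction=fraction,
            parameter=parameter,
            mean_co=float(x.mean()) if x.size else float("nan"),
            mean_mono=float(y.mean()) if y.size else float("nan"),
            t_statistic=t,
            df=df,
            p_value=p,
            tier=tier,
            status=status,
        )

    if x.size == 0 and y.size > 0:
        return _rec("absent")
    if x.size < cfg.min_n or y.size < cfg.min_n:
        return _rec("below_min_n")
    t, df, p = welch_test(x, y, pooled_variance=cfg.pooled_variance)
    return _rec("ok", t, df, p, tier_label(p, cfg.tiers))


def compare_all(classified, cfg: StatConfig | None = None, parameters=("A", "E", "Mo")) -> pd.DataFrame:
    """All coculture-vs-monoculture comparisons in a classified object table.

    For every (experiment, time, species, fraction) stratum present in the
    coculture or the species' own monoculture, compares each requested
    parameter.  Coculture hyphae/clumps are species-undetermined and are
    compared against the pooled dispersed fraction of the matching
    monoculture only when a species call exists, so in practice pellet strata
    drive the comparisons.
    """
    cfg = cfg or StatConfig()
    df = _as_frame(classified)
    records: list[ComparisonResult] = []
    if df.empty:
        return pd.DataFrame()
    for exp, g in df.groupby("experiment"):
        co = g[g["culture"] == "coculture"]
        for species, mono_name in (("A", "monoA"), ("B", "monoB")):
            mono = g[g["culture"] == mono_name]
            for fraction in sorted(set(co["fraction"]).union(mono["fraction"])):
                times = sorted(
                    set(co.loc[co["fraction"] == fraction, "time_h"]).union(
                        mono.loc[mono["fraction"] == fraction, "time_h"]
                    )
                )
                for t in times:
                    co_stratum = co[
                        (co["fraction"] == fraction)
                        & (co["species"] == species)
                        & (co["time_h"] == t)
                    ]
                    mono_stratum = mono[
                        (mono["fraction"] == fraction) & (mono["time_h"] == t)
                    ]
                    if mono_stratum.empty:
                        continue
                    for param in parameters:
                        records.append(
                            compare_timepoint(
                                co_stratum,
                                mono_stratum,
                                param,
                                cfg,
                                experiment=exp,
                                time_h=float(t),
                                species=species,
                                fraction=fraction,
                            )
                        )
    return pd.DataFrame([r.__dict__ for r in records])
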