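"""Coculture outcome calls: morphological domination, advantage, or none.

The decision rule formalizes how coculture outcomes are read off a
mono-/coculture time course:

* **domination** — the losing species' fully evolved pellet stratum is absent
  at every evaluated timepoint of the coculture while pellets are present in
  that species' own monoculture (pellet development inhibited outright);
* **advantage** — the losing species' pellets persist, but their projected
  area is significantly smaller (Welch test, at least p < 0.05) than in the
  monoculture at a strict majority of the usable timepoints;
* **none** — neither rule fires, or both species qualify symmetrically
  (flagged as a conflict).

Domination takes precedence: advantage is only evaluated when no species is
dominated.  The evaluation window excludes a settling period (default 24 h)
after the second organism's introduction, during which preculture-formed
pellets of the eventual loser may still be visible.

A second, independent indicator compares bioreactor process profiles (air
flowrate and stirring speed): the coculture's profile resembles the
monoculture of whichever organism drives oxygen consumption, i.e. the
dominant one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ParameterError
from .fractionation import PELLET
from .popstats import StatConfig

AIR_RANGE = (1.5, 5.5)  # l_air / min
STIR_RANGE = (220.0, 300.0)  # 1 / min


@dataclass
class ProcessProfile:
    """Logged bioreactor control trajectories for one vessel."""

    time_h: np.ndarray
    air_flow_l_min: np.ndarray
    stirring_min1: np.ndarray
    vessel: str = ""

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.air_flow_l_min = np.asarray(self.air_flow_l_min, dtype=float)
        self.stirring_min1 = np.asarray(self.stirring_min1, dtype=float)
        if not (self.time_h.size == self.air_flow_l_min.size == self.stirring_min1.size):
            raise ParameterError("profile channels must share the time grid")
        if self.time_h.size and np.any(np.diff(self.time_h) <= 0):
            raise ParameterError("profile times must be strictly increasing")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, vessel: str) -> "ProcessProfile":
        sub = df[df["vessel"] == vessel].sort_values("time_h")
        return cls(
            sub["time_h"].to_numpy(),
            sub["air_flow_l_min"].to_numpy(),
            sub["stirring_min1"].to_numpy(),
            vessel=vessel,
        )


@dataclass
class OutcomeCall:
    experiment: str
    winner: str  # "A" | "B" | "none"
    verdict: str  # "domination" | "advantage" | "none"
    evidence: pd.DataFrame
    evaluation_window: tuple[float, float]
    conflict: bool = False

    def __str__(self) -> str:  # human-readable one-liner
        if self.verdict == "none":
            tag = " (conflict)" if self.conflict else ""
            return f"{self.experiment}: no morphological winner{tag}"
        return f"{self.experiment}: morphological {self.verdict} by species {self.winner}"


def _stratum_n(summaries: pd.DataFrame, culture: str, species: str, time_h: float) -> int:
    sub = summaries[
        (summaries["culture"] == culture)
        & (summaries["species"] == species)
        & (summaries["fraction"] == PELLET)
        & (summaries["time_h"] == time_h)
    ]
    return int(sub["n"].sum())


def call_outcome(
    summaries: pd.DataFrame,
    comparisons: pd.DataFrame,
    *,
    cfg: StatConfig | None = None,
    second_introduction_h: float = 0.0,
    settling_h: float = 24.0,
    window_start: float | None = None,
    min_usable: int = 2,
) -> OutcomeCall:
    """Call the coculture outcome from tidy summaries and area comparisons.

    ``summaries`` is the assembled time-course table (one row per stratum);
    ``comparisons`` the coculture-vs-monoculture table.  Presence below the
    min-n rule still counts as presence for the domination logic (a stratum
    that exists but is unquantifiable is conservatively treated as present).
    """
    cfg = cfg or StatConfig()
    if summaries.empty:
        raise InsufficientDataError("no summaries provided")
    experiment = str(summaries["experiment"].iloc[0])
    start = window_start if window_start is not None else second_introduction_h + settling_h
    all_times = np.array(sorted(summaries["time_h"].unique()), dtype=float)
    window_times = [t for t in all_times if t > start]
    end = max(all_times) if all_times.size else start
    if len(window_times) < min_usable:
        raise InsufficientDataError(
            f"only {len(window_times)} timepoints after the settling window ({start} h)"
        )

    area_cmp = comparisons[
        (comparisons["parameter"] == "A") & (comparisons["fraction"] == PELLET)
    ] if not comparisons.empty else pd.DataFrame()

    evidence_rows: list[dict] = []
    dominated: dict[str, bool] = {}
    advantaged_over: dict[str, bool] = {}

    for species, mono in (("A", "monoA"), ("B", "monoB")):
        mono_present = [t for t in window_times if _stratum_n(summaries, mono, species, t) > 0]
        co_present = [t for t in window_times if _stratum_n(summaries, "coculture", species, t) > 0]
        dominated[species] = len(mono_present) >= min_usable and len(co_present) == 0

        sig_times: list[float] = []
        usable: list[float] = []
        if not area_cmp.empty:
            sp_cmp = area_cmp[area_cmp["species"] == species]
            for t in window_times:
                rec = sp_cmp[sp_cmp["time_h"] == t]
                if rec.empty:
                    continue
                r = rec.iloc[0]
                if r["status"] == "ok":
                    usable.append(t)
                    if r["p_value"] < cfg.tiers[0] and r["mean_co"] < r["mean_mono"]:
                        sig_times.append(t)
                evidence_rows.append(
                    {
                        "time_h": t,
                        "species": species,
                        "co_pellets_present": t in co_present,
                        "mono_pellets_present": t in mono_present,
                        "status": r["status"],
                        "tier": r["tier"],
                        "mean_co": r["mean_co"],
                        "mean_mono": r["mean_mono"],
                    }
                )
        advantaged_over[species] = len(usable) >= min_usable and len(sig_times) > len(usable) / 2

    evidence = pd.DataFrame(evidence_rows)
    window = (float(start), float(end))

    dom = [s for s in ("A", "B") if dominated[s]]
    if len(dom) == 1:
        loser = dom[0]
        winner = "B" if loser == "A" else "A"
        return OutcomeCall(experiment, winner, "domination", evidence, window)
    if len(dom) == 2:
        return OutcomeCall(experiment, "none", "none", evidence, window, conflict=True)

    adv = [s for s in ("A", "B") if advantaged_over[s]]
    if len(adv) == 1:
        loser = adv[0]
        winner = "B" if loser == "A" else "A"
        return OutcomeCall(experiment, winner, "advantage", evidence, window)
    if len(adv) == 2:
        return OutcomeCall(experiment, "none", "none", evidence, window, conflict=True)
    return OutcomeCall(experiment, "none", "none", evidence, window)


# ---------------------------------------------------------------------------
# Process-profile similarity
# ---------------------------------------------------------------------------


def profile_similarity(co: ProcessProfile, mono: ProcessProfile, grid_step_h: float = 1.0) -> float:
    """Mean Pearson correlation of the air and stirring channels on a common grid.

    Profiles are linearly interpolated onto a uniform grid spanning the
    overlap of their time ranges; a constant channel is skipped with a
    warning.  The score is symmetric and invariant to affine rescaling of a
    channel; it lies in [-1, 1].
    """
    lo = max(co.time_h.min(), mono.time_h.min())
    hi = min(co.time_h.max(), mono.time_h.max())
    if hi <= lo:
        raise ParameterError("profiles do not overlap in time")
    grid = np.arange(lo, hi + grid_step_h / 2, grid_step_h)
    scores = []
    for attr in ("air_flow_l_min", "stirring_min1"):
        a = np.interp(grid, co.time_h, getattr(co, attr))
        b = np.interp(grid, mono.time_h, getattr(mono, attr))
        if np.std(a) == 0 or np.std(b) == 0:
            warnings.warn(f"constant {attr} channel skipped in profile similarity", stacklevel=2)
            continue
        scores.append(float(np.corrcoef(a, b)[0, 1]))
    if not scores:
        raise ParameterError("no informative channels for profile similarity")
    return float(np.mean(scores))


def dominant_from_profiles(
    co: ProcessProfile,
    monoA: ProcessProfile,
    monoB: ProcessProfile,
    *,
    tie_margin: float = 0.05,
) -> str:
    """Which monoculture the coculture's process profile resembles: 'A', 'B' or 'tie'."""
    sa = profile_similarity(co, monoA)
    sb = profile_similarity(co, monoB)
    if abs(sa - sb) <= tie_margin:
        return "tie"
    return "A" if sa > sb else "B"
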