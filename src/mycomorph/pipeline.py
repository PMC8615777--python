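"""End-to-end drivers: manifest → measurements → classification → statistics → outcome."""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io as mio
from .fractionation import FilterConfig, classified_to_frame, classify_all
from .morphometrics import measure_all
from .outcome import OutcomeCall, call_outcome
from .popstats import StatConfig, assemble_timecourse, compare_all, summarize
from .segmentation import SegmentationParams, segment
from .synth.scenario import ScenarioSpec, generate_timecourse


@dataclass
class PipelineResult:
    objects: pd.DataFrame  # classified per-object table
    summaries: pd.DataFrame  # tidy time-course stratum summaries
    comparisons: pd.DataFrame  # coculture-vs-monoculture Welch results
    outcome: OutcomeCall | None


def analyze_manifest(
    manifest: pd.DataFrame,
    base_dir,
    *,
    seg_params: SegmentationParams | None = None,
    filter_cfg: FilterConfig | None = None,
    stat_cfg: StatConfig | None = None,
    second_introduction_h: float = 0.0,
    overrides=None,
    with_outcome: bool = True,
) -> PipelineResult:
    """Run segmentation, morphometrics and classification over every manifest image.

    Per-object values from all images of one (experiment, culture, time)
    sampling group are pooled before the statistics stage.
    """
    base = Path(base_dir)
    seg_params = seg_params or SegmentationParams()
    filter_cfg = filter_cfg or FilterConfig()
    stat_cfg = stat_cfg or StatConfig()

    frames = []
    for row in manifest.itertuples():
        img = mio.read_image(
            base / row.image,
            float(row.scale_um_per_px),
            experiment=str(row.experiment),
            culture=str(row.culture),
            time_h=float(row.time_h),
        )
        mask = segment(img, seg_params)
        measurements = measure_all(mask, img)
        classified = classify_all(measurements, filter_cfg, overrides)
        df = classified_to_frame(classified)
        df.insert(0, "image", row.image)
        frames.append(df)
    objects = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    summaries = assemble_timecourse(summarize(objects, stat_cfg)) if not objects.empty else pd.DataFrame()
    comparisons = compare_all(objects, stat_cfg) if not objects.empty else pd.DataFrame()
    outcome = None
    if with_outcome and not summaries.empty:
        outcome = call_outcome(
            summaries,
            comparisons,
            cfg=stat_cfg,
            second_introduction_h=second_introduction_h,
        )
    return PipelineResult(objects, summaries, comparisons, outcome)


def analyze_scenario(
    scenario: ScenarioSpec,
    seed: int,
    workdir=None,
    **kwargs,
) -> PipelineResult:
    """Generate a scenario's synthetic time course and analyze it end to end.

    The scenario's per-experiment filter overrides (the "operator-set limits")
    are applied on top of the default :class:`FilterConfig` unless an explicit
    one is passed.
    """
    if "filter_cfg" not in kwargs or kwargs["filter_cfg"] is None:
        kwargs["filter_cfg"] = FilterConfig(**scenario.filter_overrides)
    kwargs.setdefault("second_introduction_h", scenario.second_introduction_h)

    if workdir is None:
        with tempfile.TemporaryDirectory() as tmp:
            manifest = generate_timecourse(scenario, seed, tmp)
            return analyze_manifest(manifest, tmp, **kwargs)
    manifest = generate_timecourse(scenario, seed, workdir)
    return analyze_manifest(manifest, workdir, **kwargs)
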