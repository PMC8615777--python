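"""Shared builders for statistics/outcome tests: synthetic classified tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from mycomorph.fractionation import PELLET


def stratum_frame(values, *, culture="coculture", species="A", fraction=PELLET,
                  time_h=24.0, experiment="X"):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        {
            "experiment": experiment,
            "culture": culture,
            "time_h": time_h,
            "species": species,
            "fraction": fraction,
            "area_um2": values,
            "elongation": np.full(values.size, 1.2),
            "morphology_number": np.full(values.size, 0.5),
        }
    )


def lognormal(mean, cv, n, rng):
    s2 = np.log1p(cv**2)
    return rng.lognormal(np.log(mean) - s2 / 2, np.sqrt(s2), n)
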