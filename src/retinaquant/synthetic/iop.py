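"""Synthetic intraocular-pressure time courses after laser treatment.

Pressure rises from baseline within hours of photocoagulation, peaks
around 24 h and returns to baseline by about one week; the contralateral
untreated eye stays at baseline.  Series are used downstream to test the
cohort inclusion rule (peak > 25 mmHg within the first 48 h).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["generate_iop_series", "DEFAULT_TIMES_H"]

#: Tonometry schedule (hours post-laser) out to 7 days.
DEFAULT_TIMES_H = (0.0, 1.0, 6.0, 24.0, 48.0, 72.0, 96.0, 120.0, 168.0)


def generate_iop_series(
    peak_mmHg: float,
    peak_time_h: float = 24.0,
    baseline_mmHg: float = 15.0,
    times_h=DEFAULT_TIMES_H,
    noise_sd: float = 0.5,
    eye: str = "LE",
    seed: int = 0,
) -> pd.DataFrame:
    """One eye's IOP readings (time_h, iop_mmHg, eye).

    The noiseless shape rises linearly from baseline to the peak at
    ``peak_time_h`` and decays exponentially back to baseline by the end
    of the first week.  Noise is added to every sample except the peak
    one, and the series is clipped at ``peak_mmHg``, so the maximum
    occurs exactly at the peak time and never exceeds the designed peak.
    """
    if peak_mmHg < 0 or baseline_mmHg < 0:
        raise ValueError("pressures must be non-negative")
    times = np.asarray(times_h, dtype=float)
    if peak_time_h < times.min() or peak_time_h > times.max():
        raise ValueError("peak_time_h must lie within the sampled grid")
    rng = np.random.default_rng(seed)
    amp = peak_mmHg - baseline_mmHg
    tau = 36.0  # decay time constant (h): back to ~baseline by day 7
    rise = np.where(
        times <= peak_time_h,
        baseline_mmHg + amp * np.divide(times, peak_time_h, where=peak_time_h > 0,
                                        out=np.ones_like(times)),
        baseline_mmHg + amp * np.exp(-(times - peak_time_h) / tau),
    )
    iop = rise + rng.normal(0.0, noise_sd, times.shape)
    at_peak = np.isclose(times, peak_time_h)
    iop[at_peak] = peak_mmHg
    iop = np.clip(iop, 0.0, peak_mmHg)
    return pd.DataFrame({"time_h": times, "iop_mmHg": iop, "eye": eye})
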