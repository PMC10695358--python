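"""I/O for real or simulated inputs: NIfTI volumes + masks, event tables,
and ROI time-series CSVs.

Voxel aggregation offers both the mean (the default for anatomical ROI
extraction) and the median (used for trial-window summaries over functional
clusters).  The repetition time is honored from the NIfTI header; a
conflicting user-supplied TR produces a warning and is ignored.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional, Union

import nibabel as nib
import numpy as np
import pandas as pd

from .bold_sim import RoiTimeSeries

EVENT_COLUMNS = ["onset", "duration", "trial_type", "ssd", "response_time",
                 "outcome", "subject_id", "wave"]
_NUMERIC_EVENT_COLUMNS = ["onset", "duration", "ssd", "response_time"]


def _load_img(img_or_path):
    if isinstance(img_or_path, (str, Path)):
        return nib.load(str(img_or_path))
    return img_or_path


def roi_timeseries_from_volume(volume, mask, stat: str = "mean",
                               roi: str = "roi",
                               tr: Optional[float] = None) -> RoiTimeSeries:
    """Collapse a 4D volume to one ROI time series through a binary mask.

    Each time point is the chosen statistic (mean or median) over in-mask
    voxels.  The TR is taken from the volume header; if ``tr`` is also given
    and disagrees, the header wins with a warning.
    """
    vol = _load_img(volume)
    msk = _load_img(mask)
    data = np.asarray(vol.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D volume, got shape {data.shape}")
    mask_data = np.asarray(msk.dataobj) > 0
    if mask_data.shape != data.shape[:3]:
        raise ValueError(
            f"mask grid {mask_data.shape} != volume grid {data.shape[:3]}")
    if not mask_data.any():
        raise ValueError("mask is empty")
    header_tr = float(vol.header.get_zooms()[3]) if len(vol.header.get_zooms()) > 3 else 0.0
    if header_tr <= 0:
        if tr is None:
            raise ValueError("volume header carries no TR; pass tr explicitly")
        header_tr = tr
    elif tr is not None and not np.isclose(tr, header_tr):
        warnings.warn(
            f"user TR {tr} conflicts with header TR {header_tr}; using header",
            stacklevel=2)
    voxels = data[mask_data]  # (n_voxels, n_volumes)
    if stat == "mean":
        values = voxels.mean(axis=0)
    elif stat == "median":
        values = np.median(voxels, axis=0)
    else:
        raise ValueError(f"stat must be 'mean' or 'median', got {stat!r}")
    return RoiTimeSeries(roi=roi, tr=header_tr, values=values)


def write_events(table: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a BIDS-events-style TSV; missing values serialized as 'n/a'."""
    table.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events(path: Union[str, Path]) -> pd.DataFrame:
    """Read an event TSV into a typed table.

    Required columns: onset, duration, trial_type, ssd, response_time,
    outcome.  'n/a' maps to missing; stop rows must carry a numeric SSD (the
    stop-signal time is onset + ssd).
    """
    table = pd.read_csv(path, sep="\t", na_values=["n/a"], keep_default_na=True)
    required = ["onset", "duration", "trial_type", "ssd", "response_time",
                "outcome"]
    for col in required:
        if col not in table.columns:
            raise ValueError(f"event table missing required column {col!r}")
    for col in _NUMERIC_EVENT_COLUMNS:
        try:
            table[col] = pd.to_numeric(table[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"column {col!r} is not numeric: {exc}") from exc
    stop_rows = table["trial_type"] == "stop"
    if stop_rows.any() and table.loc[stop_rows, "ssd"].isna().any():
        bad = table.index[stop_rows & table["ssd"].isna()].tolist()
        raise ValueError(f"stop rows without a valid ssd: rows {bad}")
    if (table["onset"] < 0).any():
        raise ValueError("onsets must be non-negative")
    if not table["onset"].is_monotonic_increasing:
        raise ValueError("onsets must be sorted")
    return table


def write_timeseries(series: RoiTimeSeries, path: Union[str, Path],
                     subject: str = "n/a", wave=0) -> None:
    """Write one ROI time series as a tidy CSV (time, value, roi, subject, wave)."""
    pd.DataFrame({
        "time": series.acq_onsets,
        "value": series.values,
        "roi": series.roi,
        "subject": subject,
        "wave": wave,
    }).to_csv(path, index=False)


def read_timeseries(path: Union[str, Path]) -> RoiTimeSeries:
    """Read a tidy ROI time-series CSV back into a RoiTimeSeries."""
    table = pd.read_csv(path)
    for col in ("time", "value", "roi"):
        if col not in table.columns:
            raise ValueError(f"time-series CSV missing column {col!r}")
    times = table["time"].to_numpy(dtype=float)
    if len(times) < 2:
        raise ValueError("time series needs at least two samples to infer TR")
    steps = np.diff(times)
    if not np.allclose(steps, steps[0]):
        raise ValueError("acquisition times are not evenly spaced")
    return RoiTimeSeries(roi=str(table["roi"].iloc[0]), tr=float(steps[0]),
                         values=table["value"].to_numpy(dtype=float),
                         t0=float(times[0]))
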