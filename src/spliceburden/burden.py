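"""Per-sample differential-splicing calls and the Splicing Burden Index.

Without matched normals, a sample's event is called differential when its
PSI is an outlier against the cohort distribution of that event: the
z-score of the sample's PSI relative to the per-event cohort mean and
(sample) standard deviation exceeds |2| (strict).  The Splicing Burden
Index (SBI) of a sample is then the fraction of its measured events that
were called differential — computed per splice type.

Call codes: +1 inclusion gain (z > threshold), -1 skipping
(z < -threshold), 0 no call, NaN not measured / non-informative event.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .rmats_io import PsiMatrix

logger = logging.getLogger(__name__)

INCLUSION_GAIN = 1.0
SKIPPING = -1.0
NO_CALL = 0.0

CALL_LABELS = {1.0: "inclusion_gain", -1.0: "skipping", 0.0: "none"}


def event_zscores(
    m: PsiMatrix | pd.DataFrame,
    sd_floor: float = 0.01,
    leave_one_out: bool = False,
) -> pd.DataFrame:
    """Z-score each cell against its event's cohort distribution.

    Events with fewer than 3 measured samples or cohort sd below
    ``sd_floor`` are non-informative: their whole row is missing.  By
    default the focal sample is included in the moments (single-sample
    design, no control group); ``leave_one_out=True`` excludes it.
    """
    values = m.values if isinstance(m, PsiMatrix) else m
    x = values.to_numpy(dtype=float)
    mask = np.isfinite(x)
    n = mask.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.nanmean(np.where(mask, x, np.nan), axis=1)
        sd = np.nanstd(np.where(mask, x, np.nan), axis=1, ddof=1)

    if not leave_one_out:
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (x - mean[:, None]) / sd[:, None]
    else:
        # leave-one-out moments from sufficient statistics
        s1 = np.nansum(np.where(mask, x, np.nan), axis=1)
        s2 = np.nansum(np.where(mask, x * x, np.nan), axis=1)
        n_i = (n[:, None] - mask).astype(float)  # n excluding the cell itself
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_i = (s1[:, None] - np.where(mask, x, 0.0)) / n_i
            ss = s2[:, None] - np.where(mask, x * x, 0.0) - n_i * mean_i**2
            sd_i = np.sqrt(np.maximum(ss, 0.0) / (n_i - 1))
            z = np.where(sd_i >= sd_floor, (x - mean_i) / sd_i, np.nan)
        sd = np.where(n >= 2, sd, np.nan)

    informative = (n >= 3) & np.isfinite(sd) & (sd >= sd_floor)
    z = np.where(informative[:, None] & mask, z, np.nan)
    return pd.DataFrame(z, index=values.index, columns=values.columns)


def call_differential(z: pd.DataFrame, threshold: float = 2.0) -> pd.DataFrame:
    """Sign-aware outlier calls at strict ``|z| > threshold``."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    zv = z.to_numpy(dtype=float)
    calls = np.where(zv > threshold, INCLUSION_GAIN,
                     np.where(zv < -threshold, SKIPPING, NO_CALL))
    calls = np.where(np.isfinite(zv), calls, np.nan)
    return pd.DataFrame(calls, index=z.index, columns=z.columns)


def calls_to_labels(calls: pd.DataFrame) -> pd.DataFrame:
    """String view of a call matrix for TSV export."""
    out = calls.replace(CALL_LABELS)
    return out.where(calls.notna(), "missing")


def splicing_burden_index(
    calls: pd.DataFrame,
    splice_type: str = "SE",
) -> pd.DataFrame:
    """SBI per sample: called events / measured events, with quartile strata.

    Strata follow the cohort quartiles of the SBI vector itself:
    ``high`` when sbi >= Q3, ``low`` when sbi <= Q1, else ``mid`` (ties at
    the boundary fall inside the stratum).
    """
    cv = calls.to_numpy(dtype=float)
    measured = np.isfinite(cv).sum(axis=0)
    differential = np.nansum(np.abs(cv) > 0, axis=0).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        sbi = np.where(measured > 0, differential / np.maximum(measured, 1), np.nan)
    if (measured == 0).any():
        logger.warning("%d samples had no measured events; SBI missing",
                       int((measured == 0).sum()))

    finite = sbi[np.isfinite(sbi)]
    if finite.size:
        q1, q3 = np.percentile(finite, [25, 75])
        stratum = np.where(sbi >= q3, "high", np.where(sbi <= q1, "low", "mid"))
        stratum = np.where(np.isfinite(sbi), stratum, "missing")
    else:
        stratum = np.full(sbi.shape, "missing", dtype=object)

    return pd.DataFrame(
        {
            "sample_id": calls.columns,
            "splice_type": splice_type,
            "n_differential": differential,
            "n_measured": measured,
            "sbi": sbi,
            "stratum": stratum,
        }
    ).reset_index(drop=True)
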