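"""Conversion of relative normalized counts to absolute diploid copy number.

Counts are proportional to copy number with an unknown probe-specific
efficiency, so absolute scale comes from an external anchor: read-depth
copy-number estimates available for a subset of samples shared between the
two assays.  For each probe,

    CN(p, s) = count(p, s) / median_shared(count(p, ·)) × median_shared(rd_cn(p, ·))

with both medians taken over the shared calibration subset only and the
conversion applied to every sample.  Medians make the anchor robust to
outlying read-depth estimates in under half the calibration samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import FeatureMatrix, ValidationError
from .counts import NormalizedCounts

logger = logging.getLogger(__name__)


@dataclass
class CopyNumberEstimates:
    matrix: FeatureMatrix  # absolute diploid CN, probes × samples
    median_ns: pd.Series  # per-probe median normalized count over shared subset
    median_rd_cn: pd.Series  # per-probe median read-depth CN over shared subset
    n_calibration_samples: pd.Series  # per probe
    uncalibratable: dict[str, str] = field(default_factory=dict)  # probe -> reason

    @property
    def values(self) -> pd.DataFrame:
        return self.matrix.values


def collapse_readdepth(rd: pd.DataFrame) -> pd.DataFrame:
    """Collapse long-form read-depth records to one value per probe × sample.

    ``rd`` has columns probe_id, sample_id, cn; duplicate entries for a cell
    are averaged.  Returns a probes × samples grid (NaN where absent).
    """
    required = {"probe_id", "sample_id", "cn"}
    if not required.issubset(rd.columns):
        raise ValidationError(f"read-depth table needs columns {sorted(required)}")
    collapsed = rd.groupby(["probe_id", "sample_id"])["cn"].mean()
    return collapsed.unstack("sample_id")


def calibrate(
    normalized: NormalizedCounts | FeatureMatrix,
    rd: pd.DataFrame,
    shared_samples: list[str] | None = None,
    min_shared: int = 3,
) -> CopyNumberEstimates:
    """Anchor each probe's counts to read-depth CN via shared-subset medians.

    ``rd`` is a collapsed probes × samples grid (see
    :func:`collapse_readdepth`).  ``shared_samples`` restricts the
    calibration subset; by default it is the intersection of the two sample
    sets.  Probes absent from ``rd``, with fewer than ``min_shared``
    complete shared samples, or with a zero median count are emitted as
    all-missing with a recorded reason.  Copy numbers stay continuous (no
    integer rounding).
    """
    fm = normalized.matrix if isinstance(normalized, NormalizedCounts) else normalized
    counts = fm.values
    if shared_samples is None:
        shared_samples = [s for s in counts.columns if s in rd.columns]
    else:
        shared_samples = [
            s for s in shared_samples if s in counts.columns and s in rd.columns
        ]

    cn = pd.DataFrame(np.nan, index=counts.index, columns=counts.columns)
    med_ns = pd.Series(np.nan, index=counts.index)
    med_rd = pd.Series(np.nan, index=counts.index)
    n_cal = pd.Series(0, index=counts.index, dtype=int)
    uncal: dict[str, str] = {}

    for pid in counts.index:
        if pid not in rd.index:
            uncal[pid] = "absent from read-depth data"
            continue
        both = (
            counts.loc[pid, shared_samples].notna()
            & rd.loc[pid, shared_samples].notna()
        )
        shared = [s for s, ok in both.items() if ok]
        if len(shared) < min_shared:
            uncal[pid] = f"only {len(shared)} shared calibration samples (< {min_shared})"
            continue
        m_ns = float(counts.loc[pid, shared].median())
        m_rd = float(rd.loc[pid, shared].median())
        if m_ns == 0:
            uncal[pid] = "median normalized count is 0"
            continue
        cn.loc[pid] = counts.loc[pid] / m_ns * m_rd
        med_ns[pid] = m_ns
        med_rd[pid] = m_rd
        n_cal[pid] = len(shared)

    for pid, reason in uncal.items():
        logger.warning("probe %s uncalibratable: %s", pid, reason)
    return CopyNumberEstimates(
        matrix=FeatureMatrix(cn, fm.coords),
        median_ns=med_ns,
        median_rd_cn=med_rd,
        n_calibration_samples=n_cal,
        uncalibratable=uncal,
    )
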