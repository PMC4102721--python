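"""Threshold-based calling of per-pool genotyping signals.

A pool's normalised intensity (R) and allele-frequency angle (Theta)
classify it into one of four states: below the intensity threshold the
pool is negative; otherwise Theta <= theta_low means nucleotide 1,
Theta >= theta_high means nucleotide 2, and anything in between means the
pool contains clones carrying both nucleotides.  All thresholds are
inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

CALL_CLASSES = ("negative", "allele1", "allele2", "both")


@dataclass(frozen=True)
class CallingParams:
    r_min: float = 0.2
    theta_low: float = 0.05
    theta_high: float = 0.95

    def __post_init__(self):
        if not (0.0 <= self.theta_low < self.theta_high <= 1.0):
            raise ValueError("require 0 <= theta_low < theta_high <= 1")
        if self.r_min < 0:
            raise ValueError("r_min must be non-negative")


def classify_pool(norm_r: float, norm_theta: float,
                  params: CallingParams = CallingParams()) -> str:
    """Classify a single (R, Theta) signal; total over the half-plane."""
    if not (math.isfinite(norm_r) and math.isfinite(norm_theta)):
        raise ValueError(f"non-finite signal (R={norm_r}, theta={norm_theta})")
    if norm_r < 0 or not (0.0 <= norm_theta <= 1.0):
        raise ValueError(
            f"signal out of range (R={norm_r}, theta={norm_theta})")
    if norm_r < params.r_min:
        return "negative"
    if norm_theta <= params.theta_low:
        return "allele1"
    if norm_theta >= params.theta_high:
        return "allele2"
    return "both"


def call_table(signals: pd.DataFrame,
               params: CallingParams = CallingParams()) -> pd.DataFrame:
    """Vectorised :func:`classify_pool` over a signal table.

    Expects columns ``pool``, ``assay_id``, ``norm_R``, ``norm_theta``;
    returns a copy with a ``call`` column appended.
    """
    r = signals["norm_R"].to_numpy(dtype=float)
    theta = signals["norm_theta"].to_numpy(dtype=float)
    bad = ~(np.isfinite(r) & np.isfinite(theta)
            & (r >= 0) & (theta >= 0) & (theta <= 1))
    if bad.any():
        first = signals.index[bad][0]
        raise ValueError(
            f"invalid signal at row {first} "
            f"(pool {signals.loc[first, 'pool']}, "
            f"assay {signals.loc[first, 'assay_id']})")
    call = np.full(len(signals), "both", dtype=object)
    call[theta <= params.theta_low] = "allele1"
    call[theta >= params.theta_high] = "allele2"
    call[r < params.r_min] = "negative"
    out = signals.copy()
    out["call"] = call
    return out


def normalize_raw(channel1: np.ndarray, channel2: np.ndarray
                  ) -> pd.DataFrame:
    """Reference two-channel normalisation (simulator-side only).

    Theta = (2/pi) * atan2(channel2, channel1); R = channel1 + channel2.
    Real screens consume vendor-normalised values directly.
    """
    channel1 = np.asarray(channel1, dtype=float)
    channel2 = np.asarray(channel2, dtype=float)
    if (channel1 < 0).any() or (channel2 < 0).any():
        raise ValueError("raw channel intensities must be non-negative")
    theta = (2.0 / np.pi) * np.arctan2(channel2, channel1)
    return pd.DataFrame({"norm_R": channel1 + channel2, "norm_theta": theta})


def plate_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-assay counts of pools by call class; counts conserve pool totals."""
    counts = (calls.groupby(["assay_id", "call"]).size()
              .unstack(fill_value=0))
    for c in CALL_CLASSES:
        if c not in counts.columns:
            counts[c] = 0
    counts = counts[list(CALL_CLASSES)]
    counts["n_pools"] = counts.sum(axis=1)
    return counts.reset_index()
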