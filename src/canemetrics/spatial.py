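"""Spatial analytics for the intensive line transect and the weather net.

The empirical variogram summarizes how TCH estimates decorrelate along a
measurement line: 2*gamma(h) is the mean squared difference of all value
pairs whose separation falls in the lag bin around h.  No variogram model
is fitted and no kriging is performed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

__all__ = ["VariogramBin", "VariogramResult", "empirical_variogram",
           "precipitation_agreement"]


@dataclass
class VariogramBin:
    h: float  # bin centre, m
    two_gamma: float  # mean squared difference; NaN when the bin is empty
    n_pairs: int


@dataclass
class VariogramResult:
    bins: list[VariogramBin]
    n_dropped: int  # pairs whose separation fell outside every bin

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(b.h, b.two_gamma, b.n_pairs) for b in self.bins],
            columns=["h", "two_gamma", "n_pairs"],
        )


def empirical_variogram(positions, values, bin_edges) -> VariogramResult:
    """Empirical variogram 2*gamma(h) over half-open lag bins [lo, hi).

    Every unordered point pair contributes its squared value difference to
    the bin containing its separation distance; a bin's 2*gamma is the mean
    of its squared differences.  Empty bins are reported with
    ``n_pairs=0`` and ``two_gamma=NaN``; pairs outside all bins are counted
    in ``n_dropped``.
    """
    positions = np.asarray(positions, float)
    values = np.asarray(values, float)
    if positions.shape != values.shape:
        raise InputError("positions and values must have equal length")
    if positions.size < 2:
        raise InputError("need at least 2 points")
    edges = np.asarray(bin_edges, float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise InputError("bin_edges must be increasing with at least 2 edges")

    i, j = np.triu_indices(positions.size, k=1)
    lags = np.abs(positions[i] - positions[j])
    sq = (values[i] - values[j]) ** 2
    # half-open [lo, hi): index b means edges[b] <= lag < edges[b+1]
    idx = np.searchsorted(edges, lags, side="right") - 1
    in_range = (idx >= 0) & (idx < edges.size - 1) & (lags < edges[-1])

    bins = []
    for b in range(edges.size - 1):
        mask = in_range & (idx == b)
        n = int(mask.sum())
        bins.append(VariogramBin(
            h=float((edges[b] + edges[b + 1]) / 2.0),
            two_gamma=float(sq[mask].mean()) if n else float("nan"),
            n_pairs=n,
        ))
    return VariogramResult(bins=bins, n_dropped=int((~in_range).sum()))


def precipitation_agreement(detections, method: str = "pairwise") -> float:
    """Agreement rate of daily precipitation detection across stations.

    ``detections`` is a (stations x days) binary matrix (1 = the daily
    cumulative precipitation exceeded zero); NaN marks a missing record.

    ``pairwise`` (default): the fraction of station-pair-days on which both
    stations report the same status, averaged over all pairs and days with
    both stations present.  ``unanimous``: the fraction of days on which
    every reporting station agrees.  Days with fewer than two reporting
    stations are dropped.
    """
    det = np.asarray(detections, float)
    if det.ndim != 2 or det.shape[0] < 2 or det.shape[1] < 1:
        raise InputError("need a (stations x days) matrix with >= 2 stations")
    finite = np.isfinite(det)
    if not np.all((det[finite] == 0) | (det[finite] == 1)):
        raise InputError("detection entries must be binary (0/1) or NaN")

    if method == "pairwise":
        agree = same = 0
        n_st = det.shape[0]
        for a in range(n_st):
            for b in range(a + 1, n_st):
                ok = finite[a] & finite[b]
                agree += int(np.sum(det[a, ok] == det[b, ok]))
                same += int(ok.sum())
        if same == 0:
            raise InputError("no station-pair-days with data")
        return agree / same
    if method == "unanimous":
        n_ok = 0
        n_unanimous = 0
        for day in range(det.shape[1]):
            col = det[finite[:, day], day]
            if col.size < 2:
                continue
            n_ok += 1
            n_unanimous += int(np.all(col == col[0]))
        if n_ok == 0:
            raise InputError("no days with >= 2 reporting stations")
        return n_unanimous / n_ok
    raise ConfigurationError(f"unknown agreement method {method!r}")
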