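"""Fork-progression readouts: early-origin meta-coverage and timepoint matching.

``meta_coverage`` pools fragment-midpoint counts in a +/- ``halfwidth`` window
around selected (typically early-firing) origins and normalises by the single
maximum raw value across the whole range, so a fully replicated window is a
flat line at exactly 1.0.  "Stranded" mode keeps only Watson counts on
``[-halfwidth, -exclusion)`` and Crick counts on ``[+exclusion, +halfwidth)``,
isolating the leftward and rightward forks that emanated from the origins.

``match_timepoints`` pairs timepoints of two conditions by similarity of their
depth-normalised total genome coverage, the device used to compare conditions
at equivalent replication extent rather than equal clock time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fragments import CRICK, CoverageTrack, Origin, fragment_frame


def select_early_origins(table: pd.DataFrame, origins: Sequence[Origin], *,
                         min_oem: float | None = None,
                         top_n: int | None = None) -> list[Origin]:
    """Select origins by their earliest-timepoint OEM.

    Exactly one criterion must be given: ``min_oem`` keeps origins with
    ``OEM >= min_oem``; ``top_n`` keeps the top-n by OEM (undefined OEMs rank
    last, ties broken by origin order).  Deterministic; raises if nothing is
    selected.
    """
    if (min_oem is None) == (top_n is None):
        raise ValueError("give exactly one of min_oem or top_n")
    by_id = {o.id: o for o in origins}
    missing = [i for i in table["id"] if i not in by_id]
    if missing:
        raise ValueError(f"table rows without matching origins: {missing[:3]}...")
    vals = table["oem"].to_numpy(float)
    if min_oem is not None:
        keep = [i for i, v in zip(table["id"], vals) if not math.isnan(v) and v >= min_oem]
    else:
        if top_n < 1:
            raise ValueError("top_n must be >= 1")
        order = np.argsort(np.where(np.isnan(vals), np.inf, -vals), kind="stable")
        keep_idx = sorted(order[: top_n].tolist())
        keep = [table["id"].iloc[k] for k in keep_idx]
    if not keep:
        raise ValueError("early-origin criterion selects zero origins")
    return [by_id[i] for i in keep]


@dataclass
class MetaCoverageProfile:
    """Pooled origin-anchored coverage, max-normalised over the whole range."""

    halfwidth: int
    bin_width: int
    mode: str                 # "total" or "stranded"
    exclusion: int            # central exclusion half-width (stranded mode only)
    rel_start: np.ndarray
    raw: np.ndarray
    n_origins: int

    @property
    def norm_constant(self) -> float:
        return float(self.raw.max())

    @property
    def normalized(self) -> np.ndarray:
        return self.raw / self.norm_constant

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rel_bin_start": self.rel_start, "raw": self.raw, "normalized": self.normalized}
        )


def meta_coverage(frags, origins: Sequence[Origin], mode: str = "total",
                  halfwidth: int = 20_000, bin_width: int = 100,
                  exclusion: int = 1_000) -> MetaCoverageProfile:
    """Pooled fragment-midpoint coverage around origins, max-normalised.

    ``mode="total"`` counts both strands over the full range; ``mode="stranded"``
    gates Watson to the left arm and Crick to the right arm outside the central
    ``exclusion`` zone.  Raises when the profile is identically zero
    (normalisation undefined).
    """
    if mode not in ("total", "stranded"):
        raise ValueError(f"mode must be 'total' or 'stranded', got {mode!r}")
    if halfwidth % bin_width or (mode == "stranded" and exclusion % bin_width):
        raise ValueError("bin width must divide halfwidth (and the exclusion zone)")
    frame = fragment_frame(frags)
    nb = 2 * halfwidth // bin_width
    rel_start = np.arange(-halfwidth, halfwidth, bin_width, dtype=np.int64)
    mids_all = (frame["start"].to_numpy(np.int64) + frame["end"].to_numpy(np.int64)) // 2
    crick_all = frame["strand"].to_numpy() == CRICK
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, idx in frame.groupby("chrom", sort=False).indices.items():
        order = np.argsort(mids_all[idx], kind="stable")
        by_chrom[chrom] = (mids_all[idx][order], crick_all[idx][order])
    watson_hist = np.zeros(nb, dtype=np.int64)
    crick_hist = np.zeros(nb, dtype=np.int64)
    for o in origins:
        if o.chrom not in by_chrom:
            continue
        mids, is_crick = by_chrom[o.chrom]
        m = o.midpoint
        lo, hi = np.searchsorted(mids, [m - halfwidth, m + halfwidth], side="left")
        if lo == hi:
            continue
        idx = (mids[lo:hi] - m + halfwidth) // bin_width
        sel = is_crick[lo:hi]
        crick_hist += np.bincount(idx[sel], minlength=nb)
        watson_hist += np.bincount(idx[~sel], minlength=nb)
    if mode == "total":
        raw = (watson_hist + crick_hist).astype(float)
    else:
        raw = np.zeros(nb)
        left = rel_start + bin_width <= -exclusion   # bins fully within [-hw, -excl)
        right = rel_start >= exclusion               # bins fully within [+excl, +hw)
        raw[left] = watson_hist[left]
        raw[right] = crick_hist[right]
    if raw.max() == 0:
        raise ValueError("meta-coverage is zero everywhere; normalization undefined")
    return MetaCoverageProfile(
        halfwidth=halfwidth, bin_width=bin_width, mode=mode, exclusion=exclusion,
        rel_start=rel_start, raw=raw, n_origins=len(origins),
    )


class FrontPositions(NamedTuple):
    """Distance (bp) from the origin at which the profile first drops below a level.

    ``inf`` means the profile never crosses the level on that side
    (beyond-range).
    """

    left: float
    right: float


def front_position(profile: MetaCoverageProfile, level: float = 0.5,
                   start_offset: int = 0) -> FrontPositions:
    """Locate the fork front on each arm of a meta-coverage profile.

    The front is the outermost position where the normalized profile still
    reaches *level* (scanning from the range edge inward, which is robust to
    per-bin counting noise on the replicated plateau), linearly interpolated
    between the straddling bin centers.  Bins with ``|position| < start_offset``
    (e.g. a stranded-mode exclusion zone) are ignored.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    centers = profile.rel_start + profile.bin_width / 2
    norm = profile.normalized

    def scan(side_centers: np.ndarray, side_vals: np.ndarray) -> float:
        # ordered inner -> outer
        dist = np.abs(side_centers)
        keep = dist >= start_offset
        d = dist[keep]
        v = side_vals[keep]
        at_or_above = np.nonzero(v >= level)[0]
        if len(at_or_above) == 0:
            return float(d[0])  # already below the level at the innermost bin
        k = at_or_above[-1]
        if k == len(d) - 1:
            return math.inf  # still at level at the range edge: beyond range
        # linear interpolation between the straddling bin centers
        return float(d[k] + (v[k] - level) / (v[k] - v[k + 1]) * (d[k + 1] - d[k]))

    right_mask = centers > 0
    left_mask = centers < 0
    right = scan(centers[right_mask], norm[right_mask])
    left = scan(centers[left_mask][::-1], norm[left_mask][::-1])
    return FrontPositions(left=left, right=right)


@dataclass
class MatchResult:
    """Best B-timepoint per A-timepoint plus the full dissimilarity matrix."""

    pairs: list[tuple[int, int, float]]
    matrix: np.ndarray
    metric: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["index_a", "index_b", "dissimilarity"])


def _dissimilarity(a: np.ndarray, b: np.ndarray, metric: str) -> float:
    if metric == "spearman":
        if np.all(a == a[0]) or np.all(b == b[0]):
            return 0.0 if np.array_equal(a, b) else 1.0
        rho = stats.spearmanr(a, b).statistic
        return float(1.0 - rho)
    if metric == "l1":
        return float(np.abs(a / a.sum() - b / b.sum()).sum())
    raise ValueError(f"unknown metric {metric!r}")


def match_timepoints(tracks_a: Sequence[CoverageTrack], tracks_b: Sequence[CoverageTrack],
                     metric: str = "spearman") -> MatchResult:
    """Pair each A coverage track with the most similar B track.

    Tracks must share the bin grid.  The default metric, 1 - Spearman
    correlation of total per-bin coverage, is invariant to sequencing depth and
    to any monotone distortion of counts.
    """
    if not tracks_a or not tracks_b:
        raise ValueError("need at least one track per condition")
    ref = tracks_a[0]
    for t in list(tracks_a) + list(tracks_b):
        if not ref.same_grid(t):
            raise ValueError("coverage tracks have mismatched bin grids")
    chroms = list(ref.counts)
    vecs_a = [t.total_vector(chroms).astype(float) for t in tracks_a]
    vecs_b = [t.total_vector(chroms).astype(float) for t in tracks_b]
    matrix = np.empty((len(vecs_a), len(vecs_b)))
    for i, va in enumerate(vecs_a):
        for j, vb in enumerate(vecs_b):
            matrix[i, j] = _dissimilarity(va, vb, metric)
    pairs = [
        (i, int(np.argmin(matrix[i])), float(matrix[i].min())) for i in range(len(vecs_a))
    ]
    return MatchResult(pairs=pairs, matrix=matrix, metric=metric)
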