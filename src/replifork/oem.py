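"""Origin efficiency metric (OEM), strand-bias metaprofiles and condition comparison.

OEM for one origin is computed from fragment counts in the +/- ``flank`` bp
windows around its midpoint:

    OEM = W_L / (W_L + C_L) - W_R / (W_R + C_R)

where W/C are Watson/Crick fragment counts and L/R the left/right flank.  A
fully efficient, divergently replicating origin scores 1; no strand bias
scores 0.  The value is undefined (NaN) when either flank is empty; undefined
values are excluded from all aggregates, never imputed.

Flank membership is by fragment midpoint with half-open boundaries: left flank
``[mid - flank, mid)``, right flank ``[mid, mid + flank)`` — a fragment whose
midpoint sits exactly on the origin midpoint counts right.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fragments import CRICK, WATSON, Origin, fragment_frame

OEM_COLUMNS = ("id", "chrom", "midpoint", "w_l", "c_l", "w_r", "c_r", "oem")


def oem(w_l: int, c_l: int, w_r: int, c_r: int) -> float:
    """The origin efficiency metric for one origin's flank counts (NaN if undefined)."""
    if min(w_l, c_l, w_r, c_r) < 0:
        raise ValueError("flank counts must be >= 0")
    denom_l = w_l + c_l
    denom_r = w_r + c_r
    if denom_l == 0 or denom_r == 0:
        return math.nan
    return w_l / denom_l - w_r / denom_r


def count_flanks(frags, origin: Origin, flank: int = 10_000) -> tuple[int, int, int, int]:
    """(W_L, C_L, W_R, C_R) fragment-midpoint counts around one origin.

    Flanks extending past chromosome ends are implicitly truncated (no
    fragment can map there).
    """
    if flank <= 0:
        raise ValueError("flank must be > 0")
    frame = fragment_frame(frags)
    sub = frame[frame["chrom"] == origin.chrom]
    mids = (sub["start"].to_numpy(np.int64) + sub["end"].to_numpy(np.int64)) // 2
    watson = sub["strand"].to_numpy() == WATSON
    m = origin.midpoint
    left = (mids >= m - flank) & (mids < m)
    right = (mids >= m) & (mids < m + flank)
    return (
        int((left & watson).sum()), int((left & ~watson).sum()),
        int((right & watson).sum()), int((right & ~watson).sum()),
    )


def _sorted_mids_by_chrom_strand(frame: pd.DataFrame):
    out: dict[tuple[str, str], np.ndarray] = {}
    mids = (frame["start"].to_numpy(np.int64) + frame["end"].to_numpy(np.int64)) // 2
    for (chrom, strand), idx in frame.groupby(["chrom", "strand"], sort=False).indices.items():
        out[(chrom, strand)] = np.sort(mids[idx])
    return out


def oem_table(frags, origins: Sequence[Origin], flank: int = 10_000) -> pd.DataFrame:
    """Per-origin flank counts and OEM, one row per origin in origin order."""
    if not origins:
        raise ValueError("origin list is empty")
    if flank <= 0:
        raise ValueError("flank must be > 0")
    frame = fragment_frame(frags)
    lookup = _sorted_mids_by_chrom_strand(frame)
    empty = np.empty(0, dtype=np.int64)
    rows = []
    for o in origins:
        m = o.midpoint
        counts = []
        for strand in (WATSON, CRICK):
            mids = lookup.get((o.chrom, strand), empty)
            lo, mid_i, hi = np.searchsorted(mids, [m - flank, m, m + flank], side="left")
            counts.append((int(mid_i - lo), int(hi - mid_i)))  # (left, right)
        w_l, w_r = counts[0]
        c_l, c_r = counts[1]
        rows.append((o.id, o.chrom, m, w_l, c_l, w_r, c_r, oem(w_l, c_l, w_r, c_r)))
    return pd.DataFrame(rows, columns=list(OEM_COLUMNS))


def oem_summary(table: pd.DataFrame) -> dict:
    """Mean/min/max over defined OEMs plus how many origins were usable."""
    vals = table["oem"].to_numpy(float)
    defined = vals[~np.isnan(vals)]
    return {
        "mean": float(defined.mean()) if len(defined) else math.nan,
        "min": float(defined.min()) if len(defined) else math.nan,
        "max": float(defined.max()) if len(defined) else math.nan,
        "n_defined": int(len(defined)),
        "n_origins": int(len(vals)),
    }


def compare_conditions(table_a: pd.DataFrame, table_b: pd.DataFrame) -> dict:
    """Paired two-sided t-test on per-origin OEM differences (A - B).

    Both tables must cover the same origin list; pairs where either OEM is
    undefined are dropped and the effective n reported.
    """
    if list(table_a["id"]) != list(table_b["id"]):
        raise ValueError("tables must cover the same origin list in the same order")
    a = table_a["oem"].to_numpy(float)
    b = table_b["oem"].to_numpy(float)
    mask = ~(np.isnan(a) | np.isnan(b))
    n = int(mask.sum())
    if n < 2:
        raise ValueError(f"fewer than 2 usable origin pairs (got {n})")
    diff = a[mask] - b[mask]
    mean = float(diff.mean())
    if np.allclose(diff.std(ddof=1), 0.0):
        # degenerate: identical differences everywhere
        t_stat = 0.0 if math.isclose(mean, 0.0, abs_tol=1e-300) else math.copysign(math.inf, mean)
        p_value = 1.0 if t_stat == 0.0 else 0.0
    else:
        res = stats.ttest_rel(a[mask], b[mask])
        t_stat, p_value = float(res.statistic), float(res.pvalue)
    return {"mean_difference": mean, "t_statistic": t_stat, "p_value": p_value, "n_pairs": n}


@dataclass
class StrandBiasProfile:
    """Origin-anchored aggregate of per-relative-bin Crick fractions.

    ``rel_start`` holds the left edge of each relative-position bin, spanning
    ``[-halfwidth, +halfwidth)`` symmetrically about the origin midpoints.
    ``fraction_crick`` is NaN where a bin received no reads.
    """

    halfwidth: int
    bin_width: int
    rel_start: np.ndarray
    crick: np.ndarray
    total: np.ndarray
    n_origins: int
    fraction_override: np.ndarray | None = field(default=None, repr=False)

    @property
    def watson(self) -> np.ndarray:
        return self.total - self.crick

    @property
    def fraction_crick(self) -> np.ndarray:
        if self.fraction_override is not None:
            return self.fraction_override
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total > 0, self.crick / np.maximum(self.total, 1), np.nan)

    def assert_same_grid(self, other: "StrandBiasProfile") -> None:
        if (self.halfwidth, self.bin_width) != (other.halfwidth, other.bin_width):
            raise ValueError("mismatched bin grids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rel_bin_start": self.rel_start, "crick": self.crick,
             "total": self.total, "fraction_crick": self.fraction_crick}
        )


def strand_bias_profile(frags, origins: Sequence[Origin], halfwidth: int = 10_000,
                        bin_width: int = 100, *, per_origin: bool = False) -> StrandBiasProfile:
    """Fraction of Crick-mapped reads per relative-position bin around origins.

    Counts are pooled across origins before the fraction is taken (the
    count-weighted convention); ``per_origin=True`` instead averages the
    per-origin fractions, ignoring empty bins.
    """
    if halfwidth % bin_width:
        raise ValueError("bin width must divide halfwidth")
    frame = fragment_frame(frags)
    nb = 2 * halfwidth // bin_width
    rel_start = np.arange(-halfwidth, halfwidth, bin_width, dtype=np.int64)
    mids_all = (frame["start"].to_numpy(np.int64) + frame["end"].to_numpy(np.int64)) // 2
    crick_all = frame["strand"].to_numpy() == CRICK
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, idx in frame.groupby("chrom", sort=False).indices.items():
        order = np.argsort(mids_all[idx], kind="stable")
        by_chrom[chrom] = (mids_all[idx][order], crick_all[idx][order])
    crick = np.zeros(nb, dtype=np.int64)
    total = np.zeros(nb, dtype=np.int64)
    frac_sum = np.zeros(nb)
    frac_n = np.zeros(nb, dtype=np.int64)
    for o in origins:
        if o.chrom not in by_chrom:
            continue
        mids, is_crick = by_chrom[o.chrom]
        m = o.midpoint
        lo, hi = np.searchsorted(mids, [m - halfwidth, m + halfwidth], side="left")
        if lo == hi:
            continue
        idx = (mids[lo:hi] - m + halfwidth) // bin_width
        t = np.bincount(idx, minlength=nb)
        c = np.bincount(idx[is_crick[lo:hi]], minlength=nb)
        total += t
        crick += c
        if per_origin:
            nz = t > 0
            frac_sum[nz] += c[nz] / t[nz]
            frac_n[nz] += 1
    override = None
    if per_origin:
        with np.errstate(invalid="ignore", divide="ignore"):
            override = np.where(frac_n > 0, frac_sum / np.maximum(frac_n, 1), np.nan)
    return StrandBiasProfile(
        halfwidth=halfwidth, bin_width=bin_width, rel_start=rel_start,
        crick=crick, total=total, n_origins=len(origins), fraction_override=override,
    )


@dataclass
class DeltaProfile:
    """Per-bin difference between two strand-bias profiles (A - B)."""

    halfwidth: int
    bin_width: int
    rel_start: np.ndarray
    delta: np.ndarray  # NaN where either parent fraction is undefined

    def assert_same_grid(self, other) -> None:
        if (self.halfwidth, self.bin_width) != (other.halfwidth, other.bin_width):
            raise ValueError("mismatched bin grids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"rel_bin_start": self.rel_start, "delta": self.delta})


def delta_profile(profile_a: StrandBiasProfile, profile_b: StrandBiasProfile) -> DeltaProfile:
    """Per-bin ``fraction_crick(A) - fraction_crick(B)`` on identical grids."""
    profile_a.assert_same_grid(profile_b)
    return DeltaProfile(
        halfwidth=profile_a.halfwidth, bin_width=profile_a.bin_width,
        rel_start=profile_a.rel_start.copy(),
        delta=profile_a.fraction_crick - profile_b.fraction_crick,
    )
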