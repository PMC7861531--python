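"""Ribonucleotide (HydEn-seq) end-read analytics.

Single-base 5'-end reads mark genomic ribonucleotides.  Reads falling inside
restriction (SbfI) site intervals are split off and their count used as a
depth loading control; genome-wide totals exclude configured chromosomes
(default intent: the rDNA-bearing chromosome).  The origin-anchored strand
bias of the remaining reads, contrasted with the Okazaki-fragment bias under a
chosen polarity, reads out which polymerase synthesized each strand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .fragments import CRICK, WATSON, Origin, fragment_frame
from .oem import DeltaProfile, StrandBiasProfile, strand_bias_profile


def _site_lookup(sites: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Merge per-chromosome site intervals into sorted (starts, ends) arrays."""
    out = {}
    for chrom, sub in sites.groupby("chrom", sort=False):
        ivs = sub.sort_values("start")[["start", "end"]].to_numpy(np.int64)
        merged = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        arr = np.array(merged, dtype=np.int64)
        out[chrom] = (arr[:, 0], arr[:, 1])
    return out


def filter_site_reads(reads, sites: pd.DataFrame,
                      exclude: Iterable[str] = ()) -> tuple[pd.DataFrame, int]:
    """Partition end reads into (non-site reads, count of site reads).

    A read belongs to a site iff its single 5'-end base (the ``start``
    coordinate) lies inside a site interval, half-open.  Site reads on
    *exclude* chromosomes are dropped from the returned count, mirroring the
    exclusion later applied to the numerator.
    """
    frame = fragment_frame(reads)
    lookup = _site_lookup(sites)
    excluded = frozenset(exclude)
    inside = np.zeros(len(frame), dtype=bool)
    pos = frame["start"].to_numpy(np.int64)
    for chrom, idx in frame.groupby("chrom", sort=False).indices.items():
        if chrom not in lookup:
            continue
        starts, ends = lookup[chrom]
        k = np.searchsorted(starts, pos[idx], side="right") - 1
        hit = (k >= 0) & (pos[idx] < ends[np.maximum(k, 0)])
        inside[idx] = hit
    clean = frame[~inside].reset_index(drop=True)
    keep = inside & ~frame["chrom"].isin(excluded).to_numpy()
    return clean, int(keep.sum())


@dataclass
class HydEnSummary:
    """Per-chromosome ribo counts and the SbfI-normalised genome-wide density."""

    per_chrom: pd.DataFrame   # chrom, watson, crick
    excluded: tuple[str, ...]
    ribo_total: int           # summed over both strands, exclusions removed
    sbfi_total: int

    @property
    def defined(self) -> bool:
        return self.sbfi_total > 0

    @property
    def density(self) -> float:
        return self.ribo_total / self.sbfi_total if self.defined else math.nan

    def to_frame(self) -> pd.DataFrame:
        return self.per_chrom.assign(
            excluded=self.per_chrom["chrom"].isin(self.excluded)
        )


def normalized_total(ribo_clean, site_read_count: int,
                     exclude: Iterable[str] = ()) -> HydEnSummary:
    """SbfI-normalised total ribonucleotide density.

    ``density = (ribo reads off excluded chromosomes) / site_read_count``; the
    caller must have computed ``site_read_count`` with the same exclusion set
    (see :func:`filter_site_reads`).  Density is NaN when the denominator is
    zero.  The per-chromosome breakdown retains excluded chromosomes for
    inspection.
    """
    frame = fragment_frame(ribo_clean)
    excluded = tuple(sorted(set(exclude)))
    counts = (
        frame.assign(is_crick=frame["strand"] == CRICK)
        .groupby("chrom", sort=False)["is_crick"]
        .agg(crick="sum", total="count")
        .reset_index()
    )
    counts["watson"] = counts["total"] - counts["crick"]
    per_chrom = counts[["chrom", "watson", "crick"]].astype({"watson": int, "crick": int})
    mask = ~per_chrom["chrom"].isin(excluded)
    ribo_total = int((per_chrom.loc[mask, "watson"] + per_chrom.loc[mask, "crick"]).sum())
    return HydEnSummary(
        per_chrom=per_chrom, excluded=excluded,
        ribo_total=ribo_total, sbfi_total=int(site_read_count),
    )


def ribo_strand_bias_profile(ribo_clean, origins: Sequence[Origin],
                             halfwidth: int = 10_000, bin_width: int = 100, *,
                             invert_strand: bool = False) -> StrandBiasProfile:
    """Origin-anchored Crick-fraction profile of ribo end reads.

    Identical aggregation to the Okazaki strand-bias profile, applied to 1-bp
    records.  ``invert_strand`` flips read strands first, accommodating
    end-mapping protocols that report the complementary strand.
    """
    frame = fragment_frame(ribo_clean)
    if invert_strand:
        frame = frame.assign(
            strand=np.where(frame["strand"] == WATSON, CRICK, WATSON)
        )
    return strand_bias_profile(frame, origins, halfwidth=halfwidth, bin_width=bin_width)


POLARITIES = ("flip_okazaki_strand", "same")


def polarity_matched_delta(ribo_delta: DeltaProfile, okz_delta: DeltaProfile,
                           polarity: str = "flip_okazaki_strand") -> tuple[pd.DataFrame, dict]:
    """Pair a ribo strand-bias delta with an Okazaki delta under matched polarity.

    With ``polarity="flip_okazaki_strand"`` the Okazaki delta is re-expressed
    on Watson fractions (the leading-strand tracer convention); ``"same"``
    keeps Crick fractions (the lagging-strand tracer convention).  The summary
    reports whether the ribo delta magnitude stays below the Okazaki delta
    magnitude — the no-polymerase-take-over criterion — plus per-bin sign
    agreement.
    """
    if polarity not in POLARITIES:
        raise ValueError(f"polarity must be one of {POLARITIES}, got {polarity!r}")
    ribo_delta.assert_same_grid(okz_delta)
    okz = -okz_delta.delta if polarity == "flip_okazaki_strand" else okz_delta.delta
    table = pd.DataFrame(
        {"rel_bin_start": ribo_delta.rel_start, "ribo_delta": ribo_delta.delta,
         "okazaki_delta": okz}
    )
    both = ~(np.isnan(ribo_delta.delta) | np.isnan(okz))
    max_ribo = float(np.nanmax(np.abs(ribo_delta.delta))) if np.any(~np.isnan(ribo_delta.delta)) else math.nan
    max_okz = float(np.nanmax(np.abs(okz))) if np.any(~np.isnan(okz)) else math.nan
    agree = float(np.mean(np.sign(ribo_delta.delta[both]) == np.sign(okz[both]))) if both.any() else math.nan
    summary = {
        "max_abs_ribo_delta": max_ribo,
        "max_abs_okazaki_delta": max_okz,
        "ribo_delta_smaller": bool(max_ribo < max_okz),
        "sign_agreement": agree,
        "polarity": polarity,
    }
    return table, summary
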