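"""Stochastic S-phase simulator with known ground truth.

A population of cells replicates a genome from a fixed origin list.  Each cell
draws, per origin, a Bernoulli "competence" outcome (does the origin fire in
this cell?) and a firing time from a zero-truncated normal law.  Forks move
bidirectionally at constant speed; a locus is replicated at the sample time iff
the first-passage time ``min_i [t_i + |x - x_i| / v]`` over fired origins is
reached, and its fork direction is rightward iff the arg-min origin lies to the
left (ties to the leftmost origin).  Passive replication falls out of the
first-passage rule: an origin overrun by a neighbouring fork before its own
firing time never wins the arg-min anywhere.

Emission layers place Okazaki fragments on lagging strands (rightward fork ->
Crick), polymerase-specific ribonucleotide 5'-end reads, and depth-only reads
at restriction (SbfI) sites.  ``expected_oem_oracle`` computes per-origin
expected OEM by exact probability calculus on a discretised firing-time grid —
independent of both the sampling path and the analysis pipeline.

A "depletion" condition multiplies origin competences and/or fork speed by a
factor ``d <= 1``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fragments import CRICK, WATSON, Genome, Origin

__all__ = [
    "SPhaseModel",
    "CellReplicationState",
    "simulate_cell",
    "emit_okazaki_fragments",
    "emit_ribo_reads",
    "emit_sbfi_reads",
    "simulate_sample",
    "expected_oem_oracle",
    "productive_firing_fraction",
    "replicated_fraction",
    "time_at_replicated_fraction",
    "cell_rng",
    "random_model",
]


@dataclass(frozen=True)
class SPhaseModel:
    """Simulator parameters; arrays are aligned with the origin list order.

    Rates are per kilobase of the relevant nascent strand.  ``depletion``
    multiplies competence and/or fork speed (both by default), modelling a
    global reduction in origin firing and fork progression.
    """

    competence: np.ndarray            # per-origin firing probability in [0, 1]
    firing_mean: np.ndarray           # minutes, >= 0
    firing_sd: np.ndarray             # minutes, >= 0 (0 => deterministic time)
    fork_speed: float                 # bp / minute
    okazaki_mean: float = 165.0
    okazaki_sd: float = 30.0
    okazaki_min: float = 30.0
    fragment_rate: float = 1.0        # fragments per replicated lagging-strand kb
    ribo_rate_pol_eps: float = 0.0    # leading-strand events per nascent kb
    ribo_rate_pol_alpha: float = 0.0  # lagging-strand, fragment-5'-biased
    ribo_rate_pol_delta: float = 0.0  # lagging-strand, uniform
    pol_eps_lagging_fraction: float = 0.0  # fraction of r_pol_eps rerouted to lagging strands
    sbfi_sites: tuple = ()            # ((chrom, position), ...)
    depletion: float = 1.0
    deplete_competence: bool = True
    deplete_speed: bool = True
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "competence", np.asarray(self.competence, dtype=float))
        object.__setattr__(self, "firing_mean", np.asarray(self.firing_mean, dtype=float))
        object.__setattr__(self, "firing_sd", np.asarray(self.firing_sd, dtype=float))
        n = len(self.competence)
        if len(self.firing_mean) != n or len(self.firing_sd) != n:
            raise ValueError("competence, firing_mean and firing_sd must have equal length")
        if np.any((self.competence < 0) | (self.competence > 1)):
            raise ValueError("competences must lie in [0, 1]")
        if np.any(self.firing_mean < 0) or np.any(self.firing_sd < 0):
            raise ValueError("firing-time parameters must be >= 0")
        if not 0 < self.depletion <= 1:
            raise ValueError("depletion factor must be in (0, 1]")
        if self.fork_speed <= 0 or self.effective_speed <= 0:
            raise ValueError("fork speed (after depletion) must be > 0")
        for rate in (self.fragment_rate, self.ribo_rate_pol_eps,
                     self.ribo_rate_pol_alpha, self.ribo_rate_pol_delta):
            if rate < 0:
                raise ValueError("rates must be >= 0")
        if not 0 <= self.pol_eps_lagging_fraction <= 1:
            raise ValueError("pol_eps_lagging_fraction must be in [0, 1]")
        if self.okazaki_mean <= 0 or self.okazaki_min <= 0:
            raise ValueError("Okazaki fragment lengths must be positive")

    @property
    def n_origins(self) -> int:
        return len(self.competence)

    @property
    def effective_competence(self) -> np.ndarray:
        if self.deplete_competence:
            return self.competence * self.depletion
        return self.competence

    @property
    def effective_speed(self) -> float:
        return self.fork_speed * (self.depletion if self.deplete_speed else 1.0)

    def with_depletion(self, d: float, *, competence: bool = True,
                       speed: bool = True) -> "SPhaseModel":
        return dataclasses.replace(
            self, depletion=d, deplete_competence=competence, deplete_speed=speed
        )


@dataclass
class CellReplicationState:
    """Replicated, direction-annotated intervals of one cell at the sample time.

    ``intervals[chrom]`` is an ``(m, 4)`` int array with columns
    ``start, end, direction (+1 rightward / -1 leftward), origin_index``;
    intervals are disjoint and sorted.
    """

    sample_time: float
    fired: np.ndarray
    firing_times: np.ndarray
    intervals: dict[str, np.ndarray]

    def replicated_length(self) -> int:
        return int(sum((arr[:, 1] - arr[:, 0]).sum() for arr in self.intervals.values()))


def cell_rng(seed: int, cell_index: int) -> np.random.Generator:
    """Deterministic per-cell substream: reproducible under any execution order."""
    return np.random.default_rng([int(seed), int(cell_index)])


def _layout(genome: Genome, origins: Sequence[Origin]):
    """Group origin midpoints by chromosome, keeping global indices."""
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in genome.names:
        idx = [i for i, o in enumerate(origins) if o.chrom == chrom]
        if idx:
            pos = np.array([origins[i].midpoint for i in idx], dtype=np.int64)
            order = np.argsort(pos, kind="stable")
            out[chrom] = (np.array(idx, dtype=np.int64)[order], pos[order])
    return out


def _truncated_normal(rng: np.random.Generator, mean: np.ndarray,
                      sd: np.ndarray) -> np.ndarray:
    """Zero-truncated normal draws (vectorised rejection; exact, not clipped)."""
    out = rng.normal(mean, sd)
    bad = out < 0
    tries = 0
    while bad.any():
        out[bad] = rng.normal(mean[bad], sd[bad])
        bad = out < 0
        tries += 1
        if tries > 500:  # pathological mean << -sd; give up gracefully
            out[out < 0] = 0.0
            break
    return out


def _direction_intervals(pos: np.ndarray, times: np.ndarray, speed: float,
                         chrom_len: int, sample_time: float,
                         gidx: np.ndarray) -> np.ndarray:
    """Replicated direction-annotated intervals for one chromosome of one cell.

    ``pos`` must be sorted midpoints of *fired* origins.  Ownership boundaries
    between adjacent surviving origins sit where first-passage times are equal;
    the tie base belongs to the left origin.
    """
    n = len(pos)
    # stack of (local index, first base owned); 1-D additively weighted Voronoi
    stack: list[tuple[int, int]] = []
    for j in range(n):
        xj = float(pos[j])
        tj = float(times[j])
        start = 0
        dominated = False
        while stack:
            i, si = stack[-1]
            b = 0.5 * (float(pos[i]) + xj + speed * (tj - float(times[i])))
            if b >= xj:  # j's fork never outruns i anywhere -> j owns nothing
                dominated = True
                break
            s = int(math.floor(b)) + 1  # tie base at b goes to the left origin
            if s <= si:
                stack.pop()  # i fully shadowed between its own start and j
                continue
            start = s
            break
        if dominated:
            continue
        stack.append((j, start))

    out: list[tuple[int, int, int, int]] = []
    for k, ((j, s0), nxt) in enumerate(zip(stack, stack[1:] + [(-1, chrom_len)])):
        e0 = min(nxt[1], chrom_len)
        x = int(pos[j])
        r = speed * (sample_time - float(times[j]))
        if r < 0:
            continue
        lo = max(s0, int(math.ceil(x - r)), 0)
        hi = min(e0, int(math.floor(x + r)) + 1, chrom_len)
        if lo >= hi:
            continue
        split = x + 1  # the origin base itself counts as leftward
        if lo < min(hi, split):
            out.append((lo, min(hi, split), -1, int(gidx[j])))
        if max(lo, split) < hi:
            out.append((max(lo, split), hi, +1, int(gidx[j])))
    if not out:
        return np.empty((0, 4), dtype=np.int64)
    return np.array(out, dtype=np.int64)


def simulate_cell(model: SPhaseModel, genome: Genome, origins: Sequence[Origin],
                  sample_time: float, rng: np.random.Generator,
                  _layout_cache=None) -> CellReplicationState:
    """Draw one cell's firing configuration and compute its replication state."""
    if sample_time < 0:
        raise ValueError("sample_time must be >= 0")
    layout = _layout_cache if _layout_cache is not None else _layout(genome, origins)
    fired = rng.random(model.n_origins) < model.effective_competence
    times = _truncated_normal(rng, model.firing_mean, model.firing_sd)
    intervals: dict[str, np.ndarray] = {
        chrom: np.empty((0, 4), dtype=np.int64) for chrom in genome.names
    }
    speed = model.effective_speed
    for chrom, (gidx, pos) in layout.items():
        f = fired[gidx]
        if not f.any():
            continue
        intervals[chrom] = _direction_intervals(
            pos[f], times[gidx][f], speed, genome[chrom], sample_time, gidx[f]
        )
    return CellReplicationState(
        sample_time=sample_time, fired=fired, firing_times=times, intervals=intervals
    )


# ---------------------------------------------------------------------------
# read emission


def _frame_from_parts(parts) -> pd.DataFrame:
    if not parts:
        return pd.DataFrame(
            {"chrom": pd.Series(dtype=str), "start": pd.Series(dtype=np.int64),
             "end": pd.Series(dtype=np.int64), "strand": pd.Series(dtype=str)}
        )
    chroms = np.concatenate([np.repeat(c, len(s)) for c, s, _, _ in parts])
    starts = np.concatenate([s for _, s, _, _ in parts])
    ends = np.concatenate([e for _, _, e, _ in parts])
    strands = np.concatenate([st for _, _, _, st in parts])
    return pd.DataFrame(
        {"chrom": chroms, "start": starts.astype(np.int64),
         "end": ends.astype(np.int64), "strand": strands}
    )


def _okazaki_parts(state: CellReplicationState, model: SPhaseModel,
                   rng: np.random.Generator) -> list:
    parts = []
    for chrom, ivs in state.intervals.items():
        if len(ivs) == 0:
            continue
        s = ivs[:, 0].astype(float)
        e = ivs[:, 1].astype(float)
        lens = e - s
        n = rng.poisson(model.fragment_rate * lens / 1000.0)
        total = int(n.sum())
        if total == 0:
            continue
        reps = np.repeat(np.arange(len(ivs)), n)
        centers = s[reps] + rng.random(total) * lens[reps]
        flen = np.clip(rng.normal(model.okazaki_mean, model.okazaki_sd, total),
                       model.okazaki_min, None)
        # symmetric clipping preserves the fragment midpoint near interval edges
        half = np.maximum(np.minimum.reduce([flen / 2, centers - s[reps], e[reps] - centers]), 0.0)
        starts = np.floor(centers - half).astype(np.int64)
        ends = np.minimum(np.ceil(centers + half), e[reps]).astype(np.int64)
        ends = np.maximum(ends, starts + 1)
        strands = np.where(ivs[reps, 2] > 0, CRICK, WATSON)
        parts.append((chrom, starts, ends, strands))
    return parts


def emit_okazaki_fragments(state: CellReplicationState, model: SPhaseModel,
                           rng: np.random.Generator) -> pd.DataFrame:
    """Sample Okazaki fragments from one cell's lagging strands.

    Fragment counts are Poisson at ``fragment_rate`` per replicated lagging kb;
    lengths follow the configured normal law, clipped to the replicated
    interval; rightward-fork intervals yield Crick fragments, leftward Watson.
    """
    return _frame_from_parts(_okazaki_parts(state, model, rng))


def _uniform_positions(rng, s, e, reps, total):
    lens = e[reps] - s[reps]
    return (s[reps] + np.floor(rng.random(total) * lens)).astype(np.int64)


def _ribo_parts(state: CellReplicationState, model: SPhaseModel,
                rng: np.random.Generator) -> list:
    parts = []
    for chrom, ivs in state.intervals.items():
        if len(ivs) == 0:
            continue
        s = ivs[:, 0].astype(float)
        e = ivs[:, 1].astype(float)
        kb = (e - s) / 1000.0
        rightward = ivs[:, 2] > 0
        leading = np.where(rightward, WATSON, CRICK)
        lagging = np.where(rightward, CRICK, WATSON)

        def _emit(rate_kb, strand_per_iv, fivep_bias=False):
            n = rng.poisson(rate_kb * kb)
            total = int(n.sum())
            if total == 0:
                return
            reps = np.repeat(np.arange(len(ivs)), n)
            pos = _uniform_positions(rng, s, e, reps, total)
            if fivep_bias:
                # nudge towards the 5' ends of notional lagging fragments:
                # 5' ends sit origin-distal, i.e. high coords on rightward forks
                off = np.minimum(rng.exponential(0.1 * model.okazaki_mean, total),
                                 model.okazaki_mean).astype(np.int64)
                pos = np.where(rightward[reps], pos - off, pos + off)
                pos = np.clip(pos, s[reps].astype(np.int64),
                              e[reps].astype(np.int64) - 1)
            parts.append((chrom, pos, pos + 1, strand_per_iv[reps]))

        eps = model.ribo_rate_pol_eps
        if eps > 0:
            _emit(eps, leading)
            if model.pol_eps_lagging_fraction > 0:
                _emit(eps * model.pol_eps_lagging_fraction, lagging)
        if model.ribo_rate_pol_delta > 0:
            _emit(model.ribo_rate_pol_delta, lagging)
        if model.ribo_rate_pol_alpha > 0:
            _emit(model.ribo_rate_pol_alpha, lagging, fivep_bias=True)
    return parts


def emit_ribo_reads(state: CellReplicationState, model: SPhaseModel,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Sample single-base ribonucleotide 5'-end reads from one cell.

    Pol-epsilon events land on the nascent leading strand (Watson under a
    rightward fork), Pol-delta uniformly on lagging strands, Pol-alpha on
    lagging strands with a bias towards Okazaki-fragment 5' ends.  A nonzero
    ``pol_eps_lagging_fraction`` reroutes that share of Pol-epsilon synthesis
    to lagging strands (polymerase take-over scenario).
    """
    return _frame_from_parts(_ribo_parts(state, model, rng))


def emit_sbfi_reads(model: SPhaseModel, depth: float,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Replication-independent single-base reads at restriction sites.

    Each configured site receives a Poisson(depth) read count with random
    strand; serves as the loading-control denominator.
    """
    if not model.sbfi_sites:
        raise ValueError("no SbfI sites configured in the model")
    if depth <= 0:
        raise ValueError("depth must be > 0")
    counts = rng.poisson(depth, len(model.sbfi_sites))
    total = int(counts.sum())
    chroms = np.repeat([c for c, _ in model.sbfi_sites], counts)
    pos = np.repeat(np.array([p for _, p in model.sbfi_sites], dtype=np.int64), counts)
    strands = np.where(rng.random(total) < 0.5, WATSON, CRICK)
    return pd.DataFrame({"chrom": chroms, "start": pos, "end": pos + 1, "strand": strands})


@dataclass
class SimulatedSample:
    """Pooled reads from many simulated cells at one sample time."""

    okazaki: pd.DataFrame
    ribo: pd.DataFrame
    n_cells: int
    sample_time: float


def simulate_sample(model: SPhaseModel, genome: Genome, origins: Sequence[Origin],
                    sample_time: float, n_cells: int, *, seed: int | None = None,
                    with_ribo: bool = False) -> SimulatedSample:
    """Simulate ``n_cells`` independent cells and pool their reads.

    Cell ``c`` uses the deterministic substream ``cell_rng(seed, c)``, so
    results are reproducible regardless of batching.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    base = model.seed if seed is None else seed
    layout = _layout(genome, origins)
    ok_parts: list = []
    ribo_parts: list = []
    for c in range(n_cells):
        rng = cell_rng(base, c)
        state = simulate_cell(model, genome, origins, sample_time, rng, _layout_cache=layout)
        ok_parts.extend(_okazaki_parts(state, model, rng))
        if with_ribo:
            ribo_parts.extend(_ribo_parts(state, model, rng))
    return SimulatedSample(
        okazaki=_frame_from_parts(ok_parts),
        ribo=_frame_from_parts(ribo_parts),
        n_cells=n_cells,
        sample_time=sample_time,
    )


# ---------------------------------------------------------------------------
# analytic / enumeration oracles


def _time_support(model: SPhaseModel, i: int, n_points: int) -> np.ndarray:
    """Quantile-midpoint discretisation of origin i's zero-truncated firing law."""
    mu = float(model.firing_mean[i])
    sd = float(model.firing_sd[i])
    if sd == 0:
        return np.array([mu])
    q = (np.arange(n_points) + 0.5) / n_points
    a = (0.0 - mu) / sd
    return stats.truncnorm.ppf(q, a, np.inf, loc=mu, scale=sd)


def _min_pmf(values: list[np.ndarray], weights: list[float], horizon: float):
    """PMF of the minimum of independent discrete arrival variables.

    Each variable k takes value ``values[k][j]`` with probability
    ``weights[k] / len(values[k])`` and +inf otherwise.  Returns the support
    (sorted, <= horizon) and pmf of the minimum, plus a survival evaluator
    ``geq(t) = P(min >= t)`` / ``gt(t) = P(min > t)``.
    """
    if not values:
        empty = np.empty(0)

        def one(_t):
            return 1.0

        return empty, empty, one, one

    def survival(t, strict: bool):
        # P(min > t) (strict) or P(min >= t)
        out = 1.0
        side = "right" if strict else "left"
        for vals, w in zip(values, weights):
            cnt = np.searchsorted(vals, t, side=side)
            out *= 1.0 - (w / len(vals)) * cnt
        return out

    support = np.unique(np.concatenate(values))
    support = support[support <= horizon]
    if len(support) == 0:
        return support, support, (lambda t: survival(t, False)), (lambda t: survival(t, True))
    surv_at = np.array([survival(t, True) for t in support])  # P(min > t)
    prev = np.concatenate([[1.0], surv_at[:-1]])
    # P(min = t_j) = P(min > t_{j-1}) - P(min > t_j); supports are strictly increasing
    pmf = prev - surv_at
    return support, pmf, (lambda t: survival(t, False)), (lambda t: survival(t, True))


def expected_oem_oracle(model: SPhaseModel, genome: Genome, origins: Sequence[Origin],
                        sample_time: float, *, flank: int = 10_000,
                        grid_step: int = 100, time_points: int = 32,
                        budget: float = 5e8) -> pd.DataFrame:
    """Per-origin expected OEM by exact calculus over the firing-configuration law.

    For each flank grid point the probability of being replicated rightward /
    leftward by the sample time is computed from the distributions of the
    minimum arrival time over origins to the left (A) and right (B) of the
    point — independent by construction, so no joint enumeration over firing
    patterns is needed:

        P(rightward) = sum_{a <= t_s} P(A = a) * P(B >= a)
        P(leftward)  = sum_{b <= t_s} P(B = b) * P(A > b)

    (ties go to the left origin).  Firing-time laws are discretised on a
    ``time_points`` quantile-midpoint grid.  Expected Watson/Crick flank masses
    are the grid averages of these probabilities, combined with the OEM
    formula.  Raises if the work estimate exceeds *budget* (run per chromosome
    or coarsen ``grid_step``).
    """
    if flank % grid_step:
        raise ValueError("grid_step must divide flank")
    layout = _layout(genome, origins)
    p_eff = model.effective_competence
    v = model.effective_speed
    n_pts_side = flank // grid_step
    work = sum(
        len(gidx) ** 2 * time_points * 2 * n_pts_side for gidx, _ in layout.values()
    )
    if work > budget:
        raise ValueError(
            f"oracle work estimate {work:.2g} exceeds budget {budget:.2g}; "
            "run chromosome-wise or increase grid_step"
        )
    supports = {int(i): _time_support(model, int(i), time_points)
                for gidx, _ in layout.values() for i in gidx}

    rows = []
    for chrom, (gidx, pos) in layout.items():
        chrom_len = genome[chrom]
        for local, i in enumerate(gidx):
            m = int(pos[local])
            masses = {}
            for side, sign in (("L", -1), ("R", +1)):
                base = m if sign > 0 else m - flank
                pts = base + (np.arange(n_pts_side) + 0.5) * grid_step
                pts = pts[(pts >= 0) & (pts < chrom_len)]  # flank truncation
                wmass = cmass = 0.0
                for x in pts:
                    left = pos < x
                    vals_l, w_l, vals_r, w_r = [], [], [], []
                    for k, g in enumerate(gidx):
                        arr = supports[int(g)] + abs(float(pos[k]) - x) / v
                        if arr.min() > sample_time:
                            # cannot arrive by t_s: contributes neither pmf mass
                            # below t_s nor survival deficit at any a <= t_s
                            continue
                        (vals_l if left[k] else vals_r).append(arr)
                        (w_l if left[k] else w_r).append(float(p_eff[g]))
                    suppA, pmfA, geqA, gtA = _min_pmf(vals_l, w_l, sample_time)
                    suppB, pmfB, geqB, gtB = _min_pmf(vals_r, w_r, sample_time)
                    p_right = sum(
                        pa * geqB(a) for a, pa in zip(suppA, pmfA) if a <= sample_time
                    )
                    p_left = sum(
                        pb * gtA(b) for b, pb in zip(suppB, pmfB) if b <= sample_time
                    )
                    cmass += p_right  # rightward fork -> Crick Okazaki fragments
                    wmass += p_left
                npts = max(len(pts), 1)
                masses[f"w_{side.lower()}"] = wmass / npts
                masses[f"c_{side.lower()}"] = cmass / npts
            denom_l = masses["w_l"] + masses["c_l"]
            denom_r = masses["w_r"] + masses["c_r"]
            oem = (masses["w_l"] / denom_l - masses["w_r"] / denom_r
                   if denom_l > 0 and denom_r > 0 else math.nan)
            rows.append(
                (origins[i].id, chrom, m, masses["w_l"], masses["c_l"],
                 masses["w_r"], masses["c_r"], oem)
            )
    frame = pd.DataFrame(
        rows, columns=["id", "chrom", "midpoint", "w_l", "c_l", "w_r", "c_r", "oem"]
    )
    id_order = {o.id: k for k, o in enumerate(origins)}
    return frame.sort_values("id", key=lambda s: s.map(id_order),
                             kind="stable").reset_index(drop=True)


def productive_firing_fraction(model: SPhaseModel, genome: Genome,
                               origins: Sequence[Origin], *, n_draws: int = 20_000,
                               seed: int = 0, chunk: int = 500) -> np.ndarray:
    """Monte-Carlo ground truth: P(origin fires before any fork overruns it).

    This is the quantity OEM estimates ("productive firing"), computed directly
    from firing-configuration draws with no read sampling or geometry.
    """
    rng = np.random.default_rng([int(seed), 0x9E3779B9])
    layout = _layout(genome, origins)
    out = np.zeros(model.n_origins)
    v = model.effective_speed
    for chrom, (gidx, pos) in layout.items():
        k = len(gidx)
        dist = np.abs(pos[:, None] - pos[None, :]) / v
        np.fill_diagonal(dist, np.inf)  # an origin cannot passively replicate itself
        p = model.effective_competence[gidx]
        mu = model.firing_mean[gidx]
        sd = model.firing_sd[gidx]
        acc = np.zeros(k)
        done = 0
        while done < n_draws:
            nd = min(chunk, n_draws - done)
            fired = rng.random((nd, k)) < p
            t = _truncated_normal(rng, np.broadcast_to(mu, (nd, k)).copy(),
                                  np.broadcast_to(sd, (nd, k)).copy())
            src = np.where(fired, t, np.inf)
            overrun = (src[:, :, None] + dist[None, :, :]).min(axis=1)  # (nd, k targets)
            acc += (fired & (t <= overrun)).sum(axis=0)
            done += nd
        out[gidx] = acc / n_draws
    return out


def _arrival_samples(model: SPhaseModel, genome: Genome, origins: Sequence[Origin],
                     *, n_draws: int, grid_step: int, seed: int) -> np.ndarray:
    """First-passage times at genome grid points over firing-configuration draws."""
    rng = np.random.default_rng([int(seed), 0x51ED2701])
    layout = _layout(genome, origins)
    v = model.effective_speed
    samples = []
    for chrom in genome.names:
        grid = np.arange(grid_step // 2, genome[chrom], grid_step, dtype=float)
        if chrom not in layout:
            samples.append(np.full(n_draws * len(grid), np.inf))
            continue
        gidx, pos = layout[chrom]
        k = len(gidx)
        p = model.effective_competence[gidx]
        mu = model.firing_mean[gidx]
        sd = model.firing_sd[gidx]
        dist = np.abs(grid[:, None] - pos[None, :].astype(float)) / v  # (g, k)
        for _ in range(n_draws):
            fired = rng.random(k) < p
            if not fired.any():
                samples.append(np.full(len(grid), np.inf))
                continue
            t = _truncated_normal(rng, mu.copy(), sd.copy())
            samples.append((dist[:, fired] + t[fired]).min(axis=1))
    return np.concatenate(samples)


def replicated_fraction(model: SPhaseModel, genome: Genome, origins: Sequence[Origin],
                        sample_time: float, *, n_draws: int = 100,
                        grid_step: int = 1000, seed: int = 0) -> float:
    """Expected fraction of the genome replicated by *sample_time* (Monte Carlo)."""
    arr = _arrival_samples(model, genome, origins, n_draws=n_draws,
                           grid_step=grid_step, seed=seed)
    return float(np.mean(arr <= sample_time))


def time_at_replicated_fraction(model: SPhaseModel, genome: Genome,
                                origins: Sequence[Origin], target: float, *,
                                n_draws: int = 100, grid_step: int = 1000,
                                seed: int = 0) -> float:
    """Sample time at which the expected replicated fraction reaches *target*."""
    if not 0 < target < 1:
        raise ValueError("target fraction must be in (0, 1)")
    arr = _arrival_samples(model, genome, origins, n_draws=n_draws,
                           grid_step=grid_step, seed=seed)
    finite = np.isfinite(arr).mean()
    if target >= finite:
        raise ValueError(
            f"target fraction {target} unreachable (asymptote {finite:.3f})"
        )
    return float(np.quantile(arr[np.isfinite(arr)], target / finite))


# ---------------------------------------------------------------------------
# model factories


def random_model(rng: np.random.Generator, *, n_origins: int = 4,
                 chrom_len: int = 240_000, chrom: str = "chrI",
                 fragment_rate: float = 1.0, seed: int | None = None,
                 **overrides) -> tuple[Genome, list[Origin], SPhaseModel]:
    """A random single-chromosome model for property tests and demos.

    Origins are spread with jitter; competences, firing times and fork speed
    are drawn from broad ranges.  Extra keyword arguments override
    :class:`SPhaseModel` fields.
    """
    genome = Genome({chrom: chrom_len})
    spacing = chrom_len / (n_origins + 1)
    centers = (np.arange(1, n_origins + 1) * spacing
               + rng.uniform(-0.2 * spacing, 0.2 * spacing, n_origins)).astype(int)
    centers = np.clip(np.sort(centers), 1000, chrom_len - 1000)
    origins = [
        Origin(chrom, int(c) - 100, int(c) + 100, f"origin_{i + 1:04d}")
        for i, c in enumerate(centers)
    ]
    params = dict(
        competence=rng.uniform(0.3, 0.95, n_origins),
        firing_mean=rng.uniform(5.0, 20.0, n_origins),
        firing_sd=rng.uniform(1.0, 4.0, n_origins),
        fork_speed=float(rng.uniform(1000.0, 2000.0)),
        fragment_rate=fragment_rate,
        seed=int(rng.integers(0, 2**31)) if seed is None else seed,
    )
    params.update(overrides)
    return genome, origins, SPhaseModel(**params)
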