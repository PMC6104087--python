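"""Reaction coordinates, dimer occupancy, and free-energy surfaces.

Two coordinates characterise tethered G-domain dimerisation:

* ``d`` — distance between the centres of mass of two marker groups
  (nucleotide proxies or pocket residues), the docked reference being
  below 20 Å;
* ``Q_int`` — the fraction of interface contacts formed, a contact
  counting as formed when its distance is within 120% of its reference
  distance in the docked model.

Occupancy is the fraction of frames classified dimerised (default rule
``Q_int >= 0.5``) with a circular block-bootstrap confidence interval
(frames are autocorrelated, so an i.i.d. SEM would be overconfident).
Free-energy surfaces are −T*·ln P over binned coordinates, shifted so the
minimum is zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .contacts import ContactMap
from .dynamics import Trajectory

logger = logging.getLogger(__name__)

#: a contact is "formed" within this factor of its reference distance
DEFAULT_FORMATION_FACTOR = 1.2
DEFAULT_Q_THRESHOLD = 0.5
DEFAULT_DISTANCE_THRESHOLD = 20.0  # Å, the alternative d-based rule
DEFAULT_BURN_IN = 0.1


@dataclass
class CoordinateSeries:
    values: np.ndarray
    kind: str                      # "distance" | "q_interface"
    frame_indices: np.ndarray = None
    formation_factor: float = DEFAULT_FORMATION_FACTOR

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.frame_indices is None:
            self.frame_indices = np.arange(len(self.values))
        if self.kind == "q_interface" and (
                np.any(self.values < 0) or np.any(self.values > 1)):
            raise ValueError("Q_int outside [0, 1]")
        if self.kind == "distance" and np.any(self.values < 0):
            raise ValueError("negative distance")

    def __len__(self):
        return len(self.values)


@dataclass
class OccupancyResult:
    fraction: float
    ci_low: float
    ci_high: float
    rule: str
    block_length: int
    n_frames: int

    def covers(self, target: float) -> bool:
        return self.ci_low <= target <= self.ci_high


@dataclass
class FreeEnergySurface:
    edges: tuple                    # one (1D) or two (2D) edge arrays
    probability: np.ndarray
    free_energy: np.ndarray         # −T* ln P, min-shifted; NaN on empty bins
    occupied: np.ndarray
    temperature: float


def _group_com(frames: np.ndarray, group: np.ndarray) -> np.ndarray:
    """Unweighted centroid per frame (all bead masses are 1)."""
    return frames[:, group, :].mean(axis=1)


def com_distance_series(t: Trajectory, group_a, group_b) -> CoordinateSeries:
    """Per-frame distance between the centroids of two bead groups."""
    a = np.asarray(group_a, dtype=int)
    b = np.asarray(group_b, dtype=int)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("marker groups must be non-empty")
    if set(a.tolist()) & set(b.tolist()):
        raise ValueError("marker groups must be disjoint")
    d = np.linalg.norm(_group_com(t.frames, a) - _group_com(t.frames, b), axis=1)
    return CoordinateSeries(d, "distance")


def interface_q_series(
    t: Trajectory,
    interface: ContactMap,
    bead_index: dict,
    formation_factor: float = DEFAULT_FORMATION_FACTOR,
) -> CoordinateSeries:
    """Fraction of interface contacts formed per frame.

    ``bead_index`` maps (chain, residue) to bead index in the trajectory.
    """
    if len(interface) == 0:
        raise ValueError("interface map is empty")
    ii = np.array([bead_index[c.a] for c in interface])
    jj = np.array([bead_index[c.b] for c in interface])
    r0 = np.array([c.r0 for c in interface])
    diff = t.frames[:, ii, :] - t.frames[:, jj, :]
    r = np.linalg.norm(diff, axis=2)
    q = (r <= formation_factor * r0).mean(axis=1)
    return CoordinateSeries(q, "q_interface", formation_factor=formation_factor)


# ---------------------------------------------------------------------------
# occupancy


def _autocorrelation_time(x: np.ndarray) -> float:
    """Integrated autocorrelation time via the initial-positive-sequence sum."""
    x = np.asarray(x, float)
    n = len(x)
    xc = x - x.mean()
    var = float(xc @ xc) / n
    if var == 0:
        return 1.0
    tau = 1.0
    for lag in range(1, n // 2):
        rho = float(xc[:-lag] @ xc[lag:]) / ((n - lag) * var)
        if rho <= 0:
            break
        tau += 2.0 * rho
    return max(tau, 1.0)


def classify_dimerised(series: CoordinateSeries,
                       rule: str = "q",
                       q_threshold: float = DEFAULT_Q_THRESHOLD,
                       d_threshold: float = DEFAULT_DISTANCE_THRESHOLD) -> np.ndarray:
    if rule == "q":
        if series.kind != "q_interface":
            raise ValueError("rule 'q' needs a Q_int series")
        return series.values >= q_threshold
    if rule == "distance":
        if series.kind != "distance":
            raise ValueError("rule 'distance' needs a distance series")
        return series.values < d_threshold
    raise ValueError(f"unknown dimer rule {rule!r}")


def occupancy(
    series: CoordinateSeries,
    rule: str = "q",
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    d_threshold: float = DEFAULT_DISTANCE_THRESHOLD,
    burn_in: float = DEFAULT_BURN_IN,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> OccupancyResult:
    """Dimerised fraction with a circular block-bootstrap 95% CI.

    The first ``burn_in`` fraction of frames is discarded as
    equilibration.  The block length is the estimated integrated
    autocorrelation time of the indicator series.
    """
    if len(series) < 10:
        raise ValueError("need at least 10 frames")
    flags = classify_dimerised(series, rule, q_threshold, d_threshold)
    start = int(np.floor(burn_in * len(flags)))
    flags = flags[start:]
    n = len(flags)
    frac = float(flags.mean())

    if flags.all() or not flags.any():
        logger.warning("occupancy: degenerate all-%s series; CI collapses",
                       "dimerised" if frac else "undimerised")
        return OccupancyResult(frac, frac, frac, rule, 1, n)

    # blocks of twice the integrated autocorrelation time keep the
    # resampled means honestly independent
    block = int(round(2 * _autocorrelation_time(flags.astype(float))))
    block = max(1, min(block, n // 4))
    n_blocks = int(np.ceil(n / block))
    rng = np.random.default_rng(seed)
    stats = np.empty(n_bootstrap)
    ext = np.concatenate([flags, flags])  # circular
    for b in range(n_bootstrap):
        starts = rng.integers(0, n, n_blocks)
        sample = np.concatenate([ext[s:s + block] for s in starts])[:n]
        stats[b] = sample.mean()
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return OccupancyResult(frac, float(lo), float(hi), rule, block, n)


# ---------------------------------------------------------------------------
# free-energy surfaces


def free_energy_surface(
    series,
    bins=40,
    temperature: float = 0.92,
    range_=None,
) -> FreeEnergySurface:
    """Binned −T*·ln P surface over one or two coordinate series.

    ``series`` is a CoordinateSeries or a pair of them (2D mode over
    (d, Q_int)).  Empty bins are flagged and carry NaN free energy rather
    than an arbitrary cap.
    """
    if isinstance(series, CoordinateSeries):
        vals = series.values
        if len(vals) == 0:
            raise ValueError("empty series")
        counts, edges = np.histogram(vals, bins=bins, range=range_)
        edges = (edges,)
    else:
        s1, s2 = series
        if len(s1) == 0 or len(s1) != len(s2):
            raise ValueError("series must be equal-length and non-empty")
        counts, e1, e2 = np.histogram2d(s1.values, s2.values, bins=bins,
                                        range=range_)
        edges = (e1, e2)
    p = counts.astype(float) / counts.sum()
    occupied = p > 0
    if not occupied.any():
        raise ValueError("no occupied bins")
    f = np.full_like(p, np.nan)
    f[occupied] = -temperature * np.log(p[occupied])
    f -= np.nanmin(f)
    return FreeEnergySurface(edges, p, f, occupied, temperature)


# ---------------------------------------------------------------------------
# interface-strength tuning


@dataclass
class TuneResult:
    strength: float
    occupancy: OccupancyResult
    trials: list = field(default_factory=list)  # (factor, OccupancyResult)


def tune_interface_strength(
    evaluate,
    target: float = 0.5,
    lo: float = 0.0,
    hi: float = 2.0,
    max_trials: int = 8,
    tolerance: float = 0.05,
) -> TuneResult:
    """Bisect the interface strength factor to a target occupancy.

    ``evaluate(factor) -> OccupancyResult`` must run a seeded simulation
    and measure occupancy.  The search accepts a factor whose occupancy CI
    covers the target (or whose point estimate is within ``tolerance``);
    the trial ladder is recorded.  A trial sequence that is non-monotone
    beyond the CI widths aborts: at that budget occupancy is not a usable
    function of strength.
    """
    if not 0 < target < 1:
        raise ValueError("target occupancy must be in (0, 1)")
    trials: list[tuple[float, OccupancyResult]] = []

    def run(factor):
        res = evaluate(factor)
        trials.append((factor, res))
        _check_monotone(trials)
        return res

    r_lo, r_hi = run(lo), run(hi)
    if r_hi.fraction < target and not r_hi.covers(target):
        raise RuntimeError(
            f"occupancy at maximum strength {hi} is {r_hi.fraction:.2f} < target")
    best = min((r_lo, r_hi), key=lambda r: abs(r.fraction - target))
    best_f = lo if best is r_lo else hi
    for _ in range(max_trials - 2):
        mid = 0.5 * (lo + hi)
        r_mid = run(mid)
        if abs(r_mid.fraction - target) < abs(best.fraction - target):
            best, best_f = r_mid, mid
        if r_mid.covers(target) or abs(r_mid.fraction - target) <= tolerance:
            return TuneResult(mid, r_mid, trials)
        if r_mid.fraction < target:
            lo = mid
        else:
            hi = mid
    return TuneResult(best_f, best, trials)


#: extra slack on the CI-aware monotonicity check: a single-trajectory
#: bootstrap CI reflects within-run autocorrelation noise but not the
#: between-run variance of rare binding/unbinding events near the
#: transition, so only gross inversions abort the search
_MONOTONE_SLACK = 0.25


def _check_monotone(trials):
    """Occupancy should not decrease with strength beyond CI + run noise."""
    ordered = sorted(trials, key=lambda t: t[0])
    for (f1, r1), (f2, r2) in zip(ordered, ordered[1:]):
        if r2.ci_high < r1.ci_low - _MONOTONE_SLACK:
            raise RuntimeError(
                "occupancy not monotone in strength at this budget: "
                f"factor {f1:g} → [{r1.ci_low:.2f}, {r1.ci_high:.2f}] but "
                f"factor {f2:g} → [{r2.ci_low:.2f}, {r2.ci_high:.2f}]")
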