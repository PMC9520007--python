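"""Neurite-outgrowth (NOG) quantification from fluorescence line profiles.

Microfluidic chambers separate cell bodies from neurites by a microgroove
sidewall; β-III-tubulin intensity versus distance from the wall (ImageJ
Plot-Profile style: distance, mean gray value) quantifies outgrowth.  The
pipeline:

1. resample every profile onto a uniform 0.1 μm grid (linear interpolation),
2. merge overlapping images of one chamber without double-counting,
3. quality-control the cell-body side: the tubulin ridge must produce a
   peak within 50 μm of the wall at >= 85% of the 100 μm-window maximum,
   otherwise the axotomy damaged the cell bodies and the sample is dropped,
4. normalize all neurite-side profiles of an experiment to the control
   mean at 100 μm (= 100%),
5. locate the distances where the control mean first falls to 75/50/25%,
6. compare knockdown intensities at those distances to the reference
   levels with a one-sample two-sided t-test, after removing at most one
   outlier per level with Dixon's Q test (confidence 0.9, n >= 4).

A gene is classified ``significant`` if any level has p <= 0.05,
``may_influence`` if none does but some p <= 0.1, else ``none``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

STEP = 0.1  # μm grid spacing
REFERENCE_LEVELS = (75.0, 50.0, 25.0)  # percent of control at the anchor
NORMALIZATION_ANCHOR = 100.0  # μm
PEAK_SEARCH_LIMIT = 50.0  # μm
PEAK_WINDOW = 5.0  # μm
QC_MIN_PEAK = 85.0  # percent
Side = Literal["cell_body", "neurite"]


class ProfileError(ValueError):
    """Malformed or insufficient profile input."""


def _tenths(distance: float) -> int:
    return int(round(distance / STEP))


@dataclass(frozen=True)
class IntensityProfile:
    """Fluorescence intensity on a uniform 0.1 μm grid.

    ``start_index`` is the first grid point in units of 0.1 μm from the
    microgroove wall (index 0 = wall edge); cell-body distances run
    leftward of the wall, neurite distances rightward, both stored as
    non-negative distances from the wall.
    """

    intensities: np.ndarray
    start_index: int = 0
    side: Side = "neurite"
    chamber_id: str = ""
    experiment_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise ProfileError("profile needs at least two grid points")
        if np.any(~np.isfinite(arr)) or np.any(arr < 0):
            raise ProfileError("intensities must be finite and non-negative")
        object.__setattr__(self, "intensities", arr)

    @property
    def distances(self) -> np.ndarray:
        return (self.start_index + np.arange(self.intensities.size)) * STEP

    @property
    def end_index(self) -> int:
        return self.start_index + self.intensities.size - 1

    def covers(self, distance: float) -> bool:
        i = _tenths(distance)
        return self.start_index <= i <= self.end_index

    def value_at(self, distance: float) -> float:
        """Linearly interpolated intensity at an arbitrary covered distance."""
        pos = distance / STEP - self.start_index
        if pos < -1e-9 or pos > self.intensities.size - 1 + 1e-9:
            raise ProfileError(f"distance {distance} outside profile coverage")
        pos = min(max(pos, 0.0), self.intensities.size - 1.0)
        lo = int(math.floor(pos))
        hi = min(lo + 1, self.intensities.size - 1)
        frac = pos - lo
        return float((1 - frac) * self.intensities[lo] + frac * self.intensities[hi])

    def scaled(self, factor: float) -> "IntensityProfile":
        return replace(self, intensities=self.intensities * factor)


def resample_profile(
    raw: Sequence[tuple[float, float]],
    **meta,
) -> IntensityProfile:
    """Linearly interpolate raw (distance, intensity) pairs onto the 0.1 μm grid.

    The grid covers [first, last] raw distance without extrapolation.
    Distances must be strictly increasing.
    """
    if len(raw) < 2:
        raise ProfileError("need at least two measured points")
    d = np.asarray([p[0] for p in raw], dtype=float)
    v = np.asarray([p[1] for p in raw], dtype=float)
    if np.any(np.diff(d) <= 0):
        raise ProfileError("distances must be strictly increasing")
    i0 = int(math.ceil(d[0] / STEP - 1e-9))
    i1 = int(math.floor(d[-1] / STEP + 1e-9))
    if i1 - i0 + 1 < 2:
        raise ProfileError("raw points span less than two grid steps")
    grid = np.arange(i0, i1 + 1) * STEP
    return IntensityProfile(intensities=np.interp(grid, d, v), start_index=i0, **meta)


def read_plot_profile(source: str | Path) -> list[tuple[float, float]]:
    """Read an ImageJ Plot-Profile style two-column CSV (distance, mean gray)."""
    df = pd.read_csv(source)
    if df.shape[1] < 2:
        raise ProfileError(f"{source}: expected two columns")
    cols = df.columns[:2]
    return [(float(a), float(b)) for a, b in zip(df[cols[0]], df[cols[1]])]


def merge_image_profiles(
    profiles: Sequence[IntensityProfile],
    offsets: Sequence[float] | None = None,
) -> IntensityProfile:
    """Average overlapping image profiles of one chamber onto a common axis.

    ``offsets`` (μm, snapped to the grid) shift each image onto the chamber
    axis.  Each grid point receives the mean over images covering it —
    overlap regions are counted once per image, never doubled.  A coverage
    gap is an error: the chamber cannot be quantified as one profile.
    """
    if not profiles:
        raise ProfileError("no profiles to merge")
    if offsets is None:
        offsets = [0.0] * len(profiles)
    if len(offsets) != len(profiles):
        raise ProfileError("offsets must match profiles one-to-one")
    sides = {p.side for p in profiles}
    chambers = {p.chamber_id for p in profiles}
    if len(sides) > 1 or len(chambers) > 1:
        raise ProfileError("can only merge profiles of one chamber side")

    shifted = [(p.start_index + _tenths(off), p) for off, p in zip(offsets, profiles)]
    lo = min(s for s, _ in shifted)
    hi = max(s + p.intensities.size - 1 for s, p in shifted)
    total = np.zeros(hi - lo + 1)
    count = np.zeros(hi - lo + 1, dtype=int)
    for s, p in shifted:
        a = s - lo
        total[a : a + p.intensities.size] += p.intensities
        count[a : a + p.intensities.size] += 1
    if np.any(count == 0):
        gaps = np.flatnonzero(count == 0)
        raise ProfileError(
            f"coverage gap between images at {((lo + gaps[0]) * STEP):.1f}-"
            f"{((lo + gaps[-1]) * STEP):.1f} μm"
        )
    return replace(profiles[0], intensities=total / count, start_index=lo)


# ---------------------------------------------------------------------------
# cell-body quality control
# ---------------------------------------------------------------------------

def find_highest_peak(
    profile: IntensityProfile,
    search_limit: float = PEAK_SEARCH_LIMIT,
    window: float = PEAK_WINDOW,
    norm_window: float = NORMALIZATION_ANCHOR,
) -> tuple[float, float] | None:
    """Highest strict-window peak within ``search_limit`` of the wall.

    Intensities are normalized to the maximum within the first
    ``norm_window`` μm (scaled to 100%).  A grid point is a peak iff it is
    the strict maximum of the ``window``-wide interval centered on it
    (truncated at profile boundaries; exact ties yield no peak).  Returns
    (distance, normalized percent) of the highest peak, or ``None``.
    """
    v = profile.intensities
    dist = profile.distances
    in_norm = dist <= norm_window + 1e-9
    if not np.any(in_norm):
        raise ProfileError("profile does not cover the normalization window")
    norm_max = v[in_norm].max()
    if norm_max <= 0:
        return None
    half = int(round(window / (2 * STEP)))
    best: tuple[float, float] | None = None
    candidate_idx = np.flatnonzero(dist <= search_limit + 1e-9)
    for i in candidate_idx:
        lo = max(0, i - half)
        hi = min(v.size, i + half + 1)
        win = v[lo:hi]
        if np.sum(win == win.max()) == 1 and v[i] == win.max():
            height = 100.0 * v[i] / norm_max
            if best is None or height > best[1]:
                best = (float(dist[i]), height)
    return best


def qc_cell_body(
    profile: IntensityProfile,
    min_peak_percent: float = QC_MIN_PEAK,
) -> str:
    """Classify a cell-body profile as ``pass``, ``damaged`` or ``inconclusive``.

    Damage criterion: after axotomy injury, the intense tubulin line
    retracts from the wall, so the highest peak within 50 μm either
    disappears or drops below ``min_peak_percent`` of the 100 μm-window
    maximum.  Coverage below 100 μm cannot be judged automatically.
    """
    if profile.side != "cell_body":
        raise ProfileError("QC applies to cell-body profiles")
    if not profile.covers(NORMALIZATION_ANCHOR):
        logger.warning("chamber %s: coverage < 100 μm, QC inconclusive", profile.chamber_id)
        return "inconclusive"
    peak = find_highest_peak(profile)
    if peak is None or peak[1] < min_peak_percent:
        return "damaged"
    return "pass"


# ---------------------------------------------------------------------------
# normalization and reference distances
# ---------------------------------------------------------------------------

def control_mean_profile(controls: Sequence[IntensityProfile]) -> IntensityProfile:
    """Pointwise mean of the control profiles (each covering point counted once)."""
    if not controls:
        raise ProfileError("no control profiles")
    lo = min(p.start_index for p in controls)
    hi = max(p.end_index for p in controls)
    total = np.zeros(hi - lo + 1)
    count = np.zeros(hi - lo + 1, dtype=int)
    for p in controls:
        a = p.start_index - lo
        total[a : a + p.intensities.size] += p.intensities
        count[a : a + p.intensities.size] += 1
    covered = count > 0
    mean = np.full(total.shape, np.nan)
    mean[covered] = total[covered] / count[covered]
    first, last = np.flatnonzero(covered)[[0, -1]]
    return replace(
        controls[0],
        condition="control_mean",
        intensities=mean[first : last + 1],
        start_index=lo + first,
    )


def normalize_to_control(
    profiles: Sequence[IntensityProfile],
    controls: Sequence[IntensityProfile],
    anchor: float = NORMALIZATION_ANCHOR,
) -> tuple[list[IntensityProfile], IntensityProfile]:
    """Scale an experiment so the control mean equals 100 at the anchor distance.

    Returns the scaled profiles (same order) and the scaled control mean.
    """
    mean = control_mean_profile(controls)
    if not mean.covers(anchor):
        raise ProfileError(f"control mean does not cover the {anchor} μm anchor")
    ref = mean.value_at(anchor)
    if not (ref > 0):
        raise ProfileError(f"control mean at {anchor} μm is {ref}; cannot normalize")
    factor = 100.0 / ref
    return [p.scaled(factor) for p in profiles], mean.scaled(factor)


def find_reference_distances(
    control_mean: IntensityProfile,
    levels: Sequence[float] = REFERENCE_LEVELS,
    start: float = NORMALIZATION_ANCHOR,
) -> dict[float, float | None]:
    """First distances >= ``start`` where the control mean falls to each level.

    The crossing is linearly interpolated between bracketing grid points.
    A level never reached within coverage maps to ``None``.
    """
    v = control_mean.intensities
    dist = control_mean.distances
    begin = int(np.searchsorted(dist, start - 1e-9))
    out: dict[float, float | None] = {}
    for level in levels:
        below = np.flatnonzero(v[begin:] <= level)
        if below.size == 0:
            logger.warning("control never reaches %.0f%% within coverage", level)
            out[level] = None
            continue
        i = begin + int(below[0])
        if i == begin or v[i - 1] <= level:
            out[level] = float(max(dist[i], start)) if i == begin else float(dist[i])
        else:
            frac = (v[i - 1] - level) / (v[i - 1] - v[i])
            out[level] = float(dist[i - 1] + frac * STEP)
    return out


# ---------------------------------------------------------------------------
# outlier removal and significance classification
# ---------------------------------------------------------------------------

# Critical values of the two-sided Dixon r10 (Q) statistic.  The 90%-
# confidence column is the classic Dean-Dixon table, which Monte-Carlo
# simulation of max(Q_low, Q_high) on normal samples reproduces to ~1e-3;
# the 95% column is the two-sided table of Rorabacher (1991).
_DIXON_Q = {
    0.90: {
        3: 0.941, 4: 0.765, 5: 0.642, 6: 0.560, 7: 0.507, 8: 0.468, 9: 0.437,
        10: 0.412, 11: 0.392, 12: 0.376, 13: 0.361, 14: 0.349, 15: 0.338,
        16: 0.329, 17: 0.320, 18: 0.313, 19: 0.306, 20: 0.300, 21: 0.295,
        22: 0.290, 23: 0.285, 24: 0.281, 25: 0.277, 26: 0.273, 27: 0.269,
        28: 0.266, 29: 0.263, 30: 0.260,
    },
    0.95: {
        3: 0.970, 4: 0.829, 5: 0.710, 6: 0.625, 7: 0.568, 8: 0.526, 9: 0.493,
        10: 0.466, 11: 0.444, 12: 0.426, 13: 0.410, 14: 0.396, 15: 0.384,
        16: 0.374, 17: 0.365, 18: 0.356, 19: 0.349, 20: 0.342, 21: 0.337,
        22: 0.331, 23: 0.326, 24: 0.321, 25: 0.317, 26: 0.312, 27: 0.308,
        28: 0.305, 29: 0.301, 30: 0.298,
    },
}


def dixon_outliers(values: Sequence[float], confidence: float = 0.9) -> list[int]:
    """Indices to remove under Dixon's Q test (r10, two-sided, one removal max).

    Applied only for 4 <= n <= 30; smaller samples and zero-range samples
    are no-ops.  The suspect is the more extreme end (larger gap/range Q);
    it is removed when Q exceeds the tabulated critical value.
    """
    try:
        table = _DIXON_Q[round(confidence, 2)]
    except KeyError:
        raise ValueError(f"unsupported confidence {confidence}; use 0.9 or 0.95") from None
    n = len(values)
    if n < 4:
        logger.info("Dixon's Q skipped: n=%d < 4", n)
        return []
    if n > 30:
        raise ValueError(f"Dixon's Q table supports n <= 30, got {n}")
    arr = np.asarray(values, dtype=float)
    order = np.argsort(arr, kind="stable")
    s = arr[order]
    rng = s[-1] - s[0]
    if rng == 0:
        return []
    q_low = (s[1] - s[0]) / rng
    q_high = (s[-1] - s[-2]) / rng
    q, pos = (q_low, order[0]) if q_low >= q_high else (q_high, order[-1])
    if q > table[n]:
        return [int(pos)]
    return []


@dataclass(frozen=True)
class ReplicateMeasurement:
    """Normalized intensity of one knockdown replicate at one reference level."""

    gene: str
    experiment_id: str
    level: float
    normalized_intensity: float

    def __post_init__(self) -> None:
        if self.level not in REFERENCE_LEVELS:
            raise ValueError(f"level must be one of {REFERENCE_LEVELS}")


@dataclass(frozen=True)
class KnockdownResult:
    """Per-gene significance classification across the three reference levels."""

    gene: str
    p_values: dict[float, float | None]
    classification: Literal["significant", "may_influence", "none", "undetermined"]
    direction: Literal["inhibit", "stimulate", "mixed", "undetermined"]
    n_replicates: dict[float, int] = field(default_factory=dict)
    removed_outliers: dict[float, int] = field(default_factory=dict)


def knockdown_test(
    measurements: Sequence[ReplicateMeasurement],
    alpha: float = 0.05,
    borderline_alpha: float = 0.1,
    outlier_confidence: float = 0.9,
    remove_outliers: bool = True,
) -> KnockdownResult:
    """Classify one gene's effect on outgrowth from replicate measurements.

    Per reference level, replicate intensities (percent of control) are
    tested against the level constant with a one-sample two-sided t-test,
    after Dixon outlier removal for n >= 4.  The gene is ``significant``
    when min p <= ``alpha``, ``may_influence`` when min p is in
    (alpha, borderline_alpha], otherwise ``none``.  Direction follows the
    sign of the mean deviation at the most significant level (``mixed`` on
    conflicting ties).
    """
    genes = {m.gene for m in measurements}
    if len(genes) != 1:
        raise ValueError(f"measurements must belong to one gene, got {sorted(genes)}")
    gene = genes.pop()

    p_values: dict[float, float | None] = {lvl: None for lvl in REFERENCE_LEVELS}
    deviations: dict[float, float] = {}
    n_replicates: dict[float, int] = {}
    removed: dict[float, int] = {}
    for level in REFERENCE_LEVELS:
        vals = [m.normalized_intensity for m in measurements if m.level == level]
        if remove_outliers and len(vals) >= 4:
            drop = dixon_outliers(vals, confidence=outlier_confidence)
            removed[level] = len(drop)
            vals = [v for i, v in enumerate(vals) if i not in drop]
        n_replicates[level] = len(vals)
        if len(vals) < 2:
            continue
        arr = np.asarray(vals)
        if np.ptp(arr) == 0:
            p = 1.0 if arr[0] == level else 0.0
        else:
            p = float(stats.ttest_1samp(arr, popmean=level).pvalue)
        p_values[level] = p
        deviations[level] = float(arr.mean() - level)

    tested = {lvl: p for lvl, p in p_values.items() if p is not None}
    if not tested:
        return KnockdownResult(gene, p_values, "undetermined", "undetermined",
                               n_replicates, removed)
    min_p = min(tested.values())
    if min_p <= alpha:
        classification = "significant"
    elif min_p <= borderline_alpha:
        classification = "may_influence"
    else:
        classification = "none"
    best_levels = [lvl for lvl, p in tested.items() if p == min_p]
    signs = {math.copysign(1.0, deviations[lvl]) for lvl in best_levels}
    direction = "mixed" if len(signs) > 1 else ("inhibit" if signs.pop() < 0 else "stimulate")
    return KnockdownResult(gene, p_values, classification, direction, n_replicates, removed)


# ---------------------------------------------------------------------------
# experiment-level assembly
# ---------------------------------------------------------------------------

def measure_experiment(
    knockdown_profiles: Sequence[IntensityProfile],
    control_profiles: Sequence[IntensityProfile],
) -> list[ReplicateMeasurement]:
    """Produce per-gene reference-level measurements for one experiment.

    Knockdown profiles must carry ``condition`` (the gene) and
    ``experiment_id``.  Profiles of the experiment are normalized to the
    control mean at 100 μm; each knockdown profile is then read out at the
    control's 75/50/25% reference distances.  Levels unavailable in the
    control, or not covered by a knockdown profile, are skipped.
    """
    normalized, mean = normalize_to_control(list(knockdown_profiles), control_profiles)
    distances = find_reference_distances(mean)
    out: list[ReplicateMeasurement] = []
    for prof in normalized:
        for level, dist in distances.items():
            if dist is None or not prof.covers(dist):
                continue
            out.append(
                ReplicateMeasurement(
                    gene=prof.condition,
                    experiment_id=prof.experiment_id,
                    level=level,
                    normalized_intensity=prof.value_at(dist),
                )
            )
    return out


def results_to_frame(results: Iterable[KnockdownResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                **{f"p_{int(lvl)}": r.p_values.get(lvl) for lvl in REFERENCE_LEVELS},
                "classification": r.classification,
                "direction": r.direction,
            }
            for r in results
        ]
    )
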