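"""Cyclic tensile-test processing for tendon load–displacement traces.

A tensometer run stretches a tendon through five triangular strain ramps
at constant crosshead speed, logging load (N) and displacement (mm) at a
nominal 50 Hz. This module turns one such trace into material properties:

1. segment the trace into cycles (apex/trough detection);
2. remove the pre-tension offset — the zero-load point is the average of
   the per-trough minimum load over the last three cycles;
3. the per-leg "final load" is the mean of the cycle-2..4 peak loads
   (cycle 1 is a pre-stress cycle; cycle 5 is not used), offset-subtracted;
4. convert each cycle to a stress–strain hysteresis loop
   (sigma = (load - offset)/A0, eps = displacement/L0);
5. fit regional elastic moduli on the rising curve: the curve is split
   into three equal regions (toe, early linear, late linear) and the OLS
   slope of the central five points of each region is reported; the late
   ("end") slope is the working Young's modulus E;
6. integrate the rising and falling curves trapezoidally; resilience is
   the falling/rising area ratio (fraction of strain energy returned);
7. aggregate per species: loads averaged across legs, modulus and
   resilience averaged over the six cycle-by-leg values (2 legs x cycles
   2–4).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

ANALYSIS_CYCLES = (2, 3, 4)  # 1-based; cycle 1 pre-stress, cycle 5 unused


class SegmentationError(RuntimeError):
    """Cycle detection found an unexpected number of apexes."""


@dataclass
class TensileTrace:
    """One tensometer export: uniform time base, load (N), displacement (mm).

    ``L0`` is the resting tendon length (mm) and ``A0`` the cross-sectional
    area at the bone junction (mm^2). ``metadata`` carries sidecar fields;
    synthetic traces store their ground truth under ``metadata["ground_truth"]``.
    """

    species: str
    leg: str
    increment_pct: int
    time: np.ndarray
    load: np.ndarray
    displacement: np.ndarray
    L0: float
    A0: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.load = np.asarray(self.load, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        n = self.time.size
        if n < 2 or self.load.size != n or self.displacement.size != n:
            raise ValueError("time/load/displacement must be equal length >= 2")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.L0 <= 0 or self.A0 <= 0:
            raise ValueError("L0 and A0 must be positive")

    def __len__(self) -> int:
        return self.time.size


@dataclass(frozen=True)
class CycleFeature:
    """Index geometry and load extrema of one strain cycle.

    The rising segment runs from the cycle's start trough to the apex
    (apex included); the falling segment starts at the next sample and
    ends at the cycle's end trough.
    """

    cycle_index: int
    start_index: int
    apex_index: int
    end_index: int
    peak_load: float
    trough_load: float

    @property
    def rising(self) -> slice:
        return slice(self.start_index, self.apex_index + 1)

    @property
    def falling(self) -> slice:
        return slice(self.apex_index + 1, self.end_index + 1)


def segment_cycles(trace: TensileTrace, n_cycles: int = 5) -> list[CycleFeature]:
    """Locate the ``n_cycles`` apexes and bounding troughs of a trace.

    Apexes are local maxima of displacement separated by at least half the
    nominal cycle period (len(trace)/n_cycles samples); troughs are the
    displacement minima between consecutive apexes, with the trace ends
    closing the first and last cycles. Raises :class:`SegmentationError`
    with diagnostics when the apex count disagrees with ``n_cycles``.
    """
    disp = trace.displacement
    min_distance = max(1, int(len(trace) / n_cycles / 2))
    apexes, _ = signal.find_peaks(disp, distance=min_distance)
    # A flat-topped apex (repeated samples) is reported once by find_peaks;
    # a ramp ending at the final sample would not be a cycle at all.
    if apexes.size != n_cycles:
        raise SegmentationError(
            f"expected {n_cycles} displacement apexes, found {apexes.size} "
            f"at indices {apexes.tolist()} (trace length {len(trace)})"
        )
    starts = []
    ends = []
    prev_end = 0
    for k, apex in enumerate(apexes):
        starts.append(prev_end)
        if k + 1 < apexes.size:
            seg = disp[apex : apexes[k + 1] + 1]
            end = apex + int(np.argmin(seg))
        else:
            end = apex + int(np.argmin(disp[apex:]))
        ends.append(end)
        prev_end = end
    features = []
    for k, (s, a, e) in enumerate(zip(starts, apexes, ends), start=1):
        if not s <= a <= e:
            raise SegmentationError(
                f"cycle {k}: inconsistent indices start={s}, apex={a}, end={e}"
            )
        features.append(
            CycleFeature(
                cycle_index=k,
                start_index=int(s),
                apex_index=int(a),
                end_index=int(e),
                peak_load=float(trace.load[s : e + 1].max()),
                trough_load=float(trace.load[s : e + 1].min()),
            )
        )
    return features


def zero_load_offset(
    cycles: list[CycleFeature],
    trace: TensileTrace,
    rule: str = "trough-min",
) -> float:
    """Zero-load point from the troughs of the last three cycles, in N.

    ``rule="trough-min"`` (default) averages one minimum load per end
    trough of the last three cycles. ``rule="global-min"`` instead pools
    the last three cycles' falling samples and averages the three lowest
    load values overall.
    """
    if len(cycles) < 3:
        raise ValueError(f"need >= 3 cycles to set the zero point, got {len(cycles)}")
    last3 = cycles[-3:]
    if rule == "trough-min":
        minima = [float(trace.load[c.falling].min()) for c in last3]
        return float(np.mean(minima))
    if rule == "global-min":
        pooled = np.concatenate([trace.load[c.falling] for c in last3])
        return float(np.mean(np.sort(pooled)[:3]))
    raise ValueError(f"unknown zero rule {rule!r}")


def final_leg_load(
    cycles: list[CycleFeature],
    trace: TensileTrace,
    zero_offset: float,
) -> float:
    """Mean peak load of cycles 2–4 minus the zero offset, in N."""
    if len(cycles) < 4:
        raise ValueError(f"need >= 4 cycles for the final load, got {len(cycles)}")
    peaks = [
        float(trace.load[cycles[c - 1].start_index : cycles[c - 1].end_index + 1].max())
        for c in ANALYSIS_CYCLES
    ]
    return float(np.mean(peaks)) - zero_offset


def stress(F_t: float, A0: float):
    """Engineering stress sigma = F_t / A0 in MPa (N/mm^2)."""
    if A0 <= 0:
        raise ValueError("A0 must be positive")
    return F_t / A0


def strain(delta: float, L0: float):
    """Engineering strain eps = delta / L0 (dimensionless)."""
    if L0 <= 0:
        raise ValueError("L0 must be positive")
    return delta / L0


def rising_falling_split(
    cycle: CycleFeature,
    trace: TensileTrace,
    zero_offset: float,
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Stress–strain curves (eps, sigma) for one cycle's two legs.

    The apex sample belongs to the rising curve; the falling curve starts
    at the next sample. Stress is offset-corrected; both curves keep
    sample order.
    """
    eps = trace.displacement / trace.L0
    sig = (trace.load - zero_offset) / trace.A0
    r, f = cycle.rising, cycle.falling
    if eps[r].size == 0 or eps[f].size == 0:
        raise ValueError(f"cycle {cycle.cycle_index}: empty rising/falling segment")
    return (eps[r], sig[r]), (eps[f], sig[f])


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0:
        raise ValueError("degenerate modulus window: zero strain spread")
    return float(xc @ (np.asarray(y, dtype=float) - np.mean(y)) / denom)


def region_windows(n: int, n_regions: int = 3, window: int = 5) -> list[np.ndarray]:
    """Index windows for regional slope fits on an ``n``-point rising curve.

    The samples are split into ``n_regions`` contiguous regions equal in
    sample count (remainder going to the earlier regions); within each, a
    ``window``-point span centred on the region's middle index is
    returned. Regions shorter than the window fall back to all of their
    points (degraded mode requires >= 2 points per region).
    """
    if n < 2 * n_regions:
        raise ValueError(f"rising curve too short for {n_regions} regions: {n} points")
    base, rem = divmod(n, n_regions)
    sizes = [base + (1 if i < rem else 0) for i in range(n_regions)]
    bounds = np.cumsum([0] + sizes)
    windows = []
    for i in range(n_regions):
        lo, hi = int(bounds[i]), int(bounds[i + 1])
        size = hi - lo
        if size < window:
            windows.append(np.arange(lo, hi))
            continue
        centre = lo + size // 2
        half = window // 2
        start = min(max(lo, centre - half), hi - window)
        windows.append(np.arange(start, start + window))
    return windows


def region_moduli(
    eps: np.ndarray,
    sigma: np.ndarray,
    n_regions: int = 3,
    window: int = 5,
) -> dict:
    """Toe / early-linear / late-linear moduli of a rising curve, in MPa.

    Returns the three OLS slopes, the index windows used (so an oracle can
    be evaluated on identical strain values), and a degraded flag when any
    region was shorter than the requested window.
    """
    eps = np.asarray(eps, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if eps.size != sigma.size:
        raise ValueError("eps and sigma must be equal length")
    windows = region_windows(eps.size, n_regions=n_regions, window=window)
    slopes = [_ols_slope(eps[w], sigma[w]) for w in windows]
    return {
        "toe": slopes[0],
        "early": slopes[1],
        "late": slopes[-1],
        "slopes": slopes,
        "windows": windows,
        "degraded": any(w.size < window for w in windows),
    }


def loop_areas_resilience(
    rising: tuple[np.ndarray, np.ndarray],
    falling: tuple[np.ndarray, np.ndarray],
) -> tuple[float, float, float]:
    """Trapezoidal loop areas and resilience of one hysteresis cycle.

    Areas are under sigma(eps) in MPa (stress x strain units); the falling
    curve's area is sign-corrected to positive. Resilience is the
    falling/rising ratio — the fraction of strain energy recovered.
    """
    eps_r, sig_r = rising
    eps_f, sig_f = falling
    if eps_r.size < 2 or eps_f.size < 2:
        raise ValueError("both curves need >= 2 points")
    rising_area = float(np.trapezoid(sig_r, eps_r))
    falling_area = float(abs(np.trapezoid(sig_f, eps_f)))
    if rising_area <= 0:
        raise ValueError(f"non-positive rising area {rising_area}")
    return rising_area, falling_area, falling_area / rising_area


@dataclass
class LegResult:
    """Per-leg tensile results at one extension increment."""

    species: str
    leg: str
    increment_pct: int
    L0: float
    A0: float
    zero_offset: float
    final_load: float
    peak_stress: float
    peak_strain: float
    cycles: pd.DataFrame  # one row per analysis cycle
    modulus: float  # mean late-region slope of cycles 2-4
    resilience: float


@dataclass
class SpeciesResult:
    """Leg-averaged tensile results for one species/increment."""

    species: str
    increment_pct: int
    n_legs: int
    final_load: float
    final_load_sd: float
    peak_stress: float
    modulus: float
    modulus_sd: float
    resilience: float
    resilience_sd: float
    single_leg: bool
    cycles: pd.DataFrame  # the pooled leg-by-cycle table (6 rows for 2 legs)


def process_trace(
    trace: TensileTrace,
    n_cycles: int = 5,
    zero_rule: str = "trough-min",
    window: int = 5,
) -> LegResult:
    """Run the full per-leg pipeline on one trace.

    Regional moduli, loop areas and resilience are computed for each of
    cycles 2–4. For integration the hysteresis loop is closed by
    prepending the apex sample to the falling curve (the split convention
    assigns that sample to the rising curve).
    """
    cycles = segment_cycles(trace, n_cycles=n_cycles)
    offset = zero_load_offset(cycles, trace, rule=zero_rule)
    load = final_leg_load(cycles, trace, offset)
    rows = []
    for c in ANALYSIS_CYCLES:
        feat = cycles[c - 1]
        rising, falling = rising_falling_split(feat, trace, offset)
        moduli = region_moduli(*rising, window=window)
        closed_falling = (
            np.concatenate([rising[0][-1:], falling[0]]),
            np.concatenate([rising[1][-1:], falling[1]]),
        )
        up_area, down_area, resilience = loop_areas_resilience(rising, closed_falling)
        rows.append(
            {
                "species": trace.species,
                "leg": trace.leg,
                "increment_pct": trace.increment_pct,
                "cycle": c,
                "peak_load": feat.peak_load - offset,
                "toe_modulus": moduli["toe"],
                "early_modulus": moduli["early"],
                "late_modulus": moduli["late"],
                "degraded": moduli["degraded"],
                "rising_area": up_area,
                "falling_area": down_area,
                "loop_area": up_area - down_area,
                "resilience": resilience,
            }
        )
    table = pd.DataFrame(rows)
    return LegResult(
        species=trace.species,
        leg=trace.leg,
        increment_pct=trace.increment_pct,
        L0=trace.L0,
        A0=trace.A0,
        zero_offset=offset,
        final_load=load,
        peak_stress=stress(load, trace.A0),
        peak_strain=strain(float(trace.displacement.max()), trace.L0),
        cycles=table,
        modulus=float(table["late_modulus"].mean()),
        resilience=float(table["resilience"].mean()),
    )


def aggregate_results(legs: list[LegResult]) -> SpeciesResult:
    """Average per-leg results into a species result.

    The species final load is the mean of the leg loads; the species
    modulus and resilience are means over the pooled cycle-by-leg values
    (six for two legs); peak stress is recomputed from the species load.
    SDs are across the pooled cycle-by-leg values.
    """
    if not len(legs) or len(legs) > 2:
        raise ValueError("expected 1 or 2 legs per species/increment")
    species = {r.species for r in legs}
    increments = {r.increment_pct for r in legs}
    if len(species) > 1 or len(increments) > 1:
        raise ValueError("legs must share species and increment")
    A0s = {r.A0 for r in legs}
    pooled = pd.concat([r.cycles for r in legs], ignore_index=True)
    final_load = float(np.mean([r.final_load for r in legs]))
    return SpeciesResult(
        species=species.pop(),
        increment_pct=increments.pop(),
        n_legs=len(legs),
        final_load=final_load,
        final_load_sd=float(pooled["peak_load"].std(ddof=1)),
        peak_stress=stress(final_load, float(np.mean(sorted(A0s)))),
        modulus=float(pooled["late_modulus"].mean()),
        modulus_sd=float(pooled["late_modulus"].std(ddof=1)),
        resilience=float(pooled["resilience"].mean()),
        resilience_sd=float(pooled["resilience"].std(ddof=1)),
        single_leg=len(legs) == 1,
        cycles=pooled,
    )


# --------------------------------------------------------------------------
# Trace I/O: tensometer-style CSV plus JSON sidecar
# --------------------------------------------------------------------------


def write_trace(trace: TensileTrace, csv_path: str | Path) -> None:
    """Write a trace as CSV (time_s, load_N, displacement_mm) + sidecar.

    The sidecar ``<stem>.meta.json`` carries species, leg, increment, L0,
    A0 and any extra metadata (ground truth for synthetic traces).
    """
    csv_path = Path(csv_path)
    pd.DataFrame(
        {
            "time_s": trace.time,
            "load_N": trace.load,
            "displacement_mm": trace.displacement,
        }
    ).to_csv(csv_path, index=False)
    meta = {
        "species": trace.species,
        "leg": trace.leg,
        "increment_pct": trace.increment_pct,
        "rest_length_mm": trace.L0,
        "csa_mm2": trace.A0,
    }
    extra = dict(trace.metadata)
    if "ground_truth" in extra:
        gt = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in extra["ground_truth"].items()
        }
        meta["ground_truth"] = gt
    csv_path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))


def read_trace(csv_path: str | Path) -> TensileTrace:
    """Read a tensometer CSV written by :func:`write_trace`."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = json.loads(csv_path.with_suffix(".meta.json").read_text())
    extra = {}
    if "ground_truth" in meta:
        extra["ground_truth"] = meta["ground_truth"]
    return TensileTrace(
        species=meta["species"],
        leg=meta["leg"],
        increment_pct=int(meta["increment_pct"]),
        time=df["time_s"].to_numpy(),
        load=df["load_N"].to_numpy(),
        displacement=df["displacement_mm"].to_numpy(),
        L0=float(meta["rest_length_mm"]),
        A0=float(meta["csa_mm2"]),
        metadata=extra,
    )


def species_summary_frame(results: list[SpeciesResult]) -> pd.DataFrame:
    """One row per species: loads, stress, modulus, resilience (full precision)."""
    return pd.DataFrame(
        [
            {
                "species": r.species,
                "increment_pct": r.increment_pct,
                "n_legs": r.n_legs,
                "final_load_N": r.final_load,
                "final_load_sd_N": r.final_load_sd,
                "peak_stress_MPa": r.peak_stress,
                "modulus_MPa": r.modulus,
                "modulus_sd_MPa": r.modulus_sd,
                "resilience": r.resilience,
                "resilience_sd": r.resilience_sd,
            }
            for r in results
        ]
    )
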