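"""Tarsometatarsus morphometrics and nonparametric group comparisons.

Per-specimen skeletal measurements are summarised into a representative
individual per species (arithmetic means of the raw metrics), from which
two dimensionless descriptors are derived:

* aspect ratio = total length / mediolateral width at the midpoint
  (rendered as "1:N" in reports);
* proportional tubercle position = distance from the proximal margin to
  the centre of the m. tibialis cranialis tubercle, divided by total
  length — the relative position of the dorsiflexor's insertion, hence of
  the lever inlever.

Hawk-vs-owl contrasts use Mann–Whitney U tests (the measurement
distributions are small-sample and frequently non-normal with unequal
variances, so the pipeline is nonparametric by design).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

MEASUREMENT_COLUMNS = [
    "tmt_length",
    "tmt_width",
    "tubercle_distance",
    "tubercle_to_trochlea",
]


@dataclass(frozen=True)
class SpecimenMeasurement:
    """One skeleton's tarsometatarsus metrics, lengths in millimetres."""

    specimen_id: str
    species: str
    group: str
    tmt_length: float
    tmt_width: float
    tubercle_distance: float
    tubercle_to_trochlea: float | None = None
    tubercle_face_length: float | None = None
    tubercle_surface_area: float | None = None
    sex: str | None = None
    extinct: bool = False

    def __post_init__(self) -> None:
        if self.tmt_length <= 0:
            raise ValueError(f"tmt_length must be > 0, got {self.tmt_length}")
        if self.tmt_width <= 0:
            raise ValueError(f"tmt_width must be > 0, got {self.tmt_width}")
        if not 0 < self.tubercle_distance < self.tmt_length:
            raise ValueError(
                "tubercle_distance must lie strictly between 0 and "
                f"tmt_length ({self.tmt_length}), got {self.tubercle_distance}"
            )


@dataclass(frozen=True)
class SpeciesSummary:
    """Species-representative individual: per-metric mean/SD and ratios."""

    species: str
    group: str
    n: int
    means: dict
    sds: dict
    aspect_ratio: float
    tubercle_prop: float
    single_specimen: bool = False


def aspect_ratio(length_mm: float, width_mm: float) -> float:
    """Tarsometatarsus aspect ratio: total length over midpoint width."""
    if length_mm <= 0 or width_mm <= 0:
        raise ValueError("length and width must both be positive")
    return length_mm / width_mm


def format_aspect_ratio(ratio: float) -> str:
    """Render an aspect ratio the conventional way, e.g. 11.12 -> '1:11'."""
    return f"1:{round(ratio):d}"


def tubercle_proportion(tubercle_distance_mm: float, tmt_length_mm: float) -> float:
    """Relative distal position of the tubercle along the tarsometatarsus."""
    if tmt_length_mm <= 0:
        raise ValueError("tmt_length must be positive")
    if not 0 < tubercle_distance_mm < tmt_length_mm:
        raise ValueError(
            "tubercle distance must lie strictly between 0 and tmt length"
        )
    return tubercle_distance_mm / tmt_length_mm


def summarize_species(
    measurements: Sequence[SpecimenMeasurement],
) -> SpeciesSummary:
    """Average raw metrics into a representative individual.

    Derived ratios are computed from the averaged raw metrics (mean length
    over mean width), not as means of per-specimen ratios. Sample SDs use
    the n-1 denominator; a single specimen yields SD 0 with a flag.
    """
    if not measurements:
        raise ValueError("need at least one measurement")
    species = {m.species for m in measurements}
    if len(species) > 1:
        raise ValueError(f"mixed species in one summary: {sorted(species)}")
    groups = {m.group for m in measurements}
    if len(groups) > 1:
        raise ValueError(f"mixed group labels: {sorted(groups)}")

    n = len(measurements)
    means: dict = {}
    sds: dict = {}
    for col in MEASUREMENT_COLUMNS:
        vals = [getattr(m, col) for m in measurements]
        if any(v is None for v in vals):
            means[col] = None
            sds[col] = None
            continue
        arr = np.asarray(vals, dtype=float)
        means[col] = float(arr.mean())
        sds[col] = float(arr.std(ddof=1)) if n > 1 else 0.0

    return SpeciesSummary(
        species=species.pop(),
        group=groups.pop(),
        n=n,
        means=means,
        sds=sds,
        aspect_ratio=aspect_ratio(means["tmt_length"], means["tmt_width"]),
        tubercle_prop=tubercle_proportion(
            means["tubercle_distance"], means["tmt_length"]
        ),
        single_specimen=n == 1,
    )


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
) -> dict:
    """Mann–Whitney U test for two independent samples.

    U counts pairs (x_i, y_j) with x_i > y_j, plus half of the ties (the
    rank-sum convention). W = min(U, n1*n2 - U) is also reported, the
    orientation-free form usually printed. The p value is exact (full
    U-distribution) when n1*n2 <= 400 and there are no ties, and uses the
    tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")

    n1, n2 = x.size, y.size
    has_ties = np.unique(np.concatenate([x, y])).size < n1 + n2
    exact = n1 * n2 <= 400 and not has_ties
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method="exact" if exact else "asymptotic"
    )
    U = float(res.statistic)
    return {
        "U": U,
        "W": min(U, n1 * n2 - U),
        "p": float(res.pvalue),
        "n1": n1,
        "n2": n2,
        "exact": exact,
    }


def compare_groups(
    values: Sequence[float],
    groups: Sequence[str],
    alternative: str = "two-sided",
) -> dict:
    """Two-group Mann–Whitney comparison of a metric.

    ``values`` may be per-specimen or per-species numbers; the caller
    chooses the unit of analysis. Returns the test statistics plus the
    group medians, keyed by group label.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    a, b = labels
    xa = values[groups == a]
    xb = values[groups == b]
    result = mann_whitney_u(xa, xb, alternative=alternative)
    result["groups"] = (a, b)
    result["medians"] = {a: float(np.median(xa)), b: float(np.median(xb))}
    return result


def summaries_to_frame(summaries: Sequence[SpeciesSummary]) -> pd.DataFrame:
    """Tabulate species summaries (one row per species) for export."""
    rows = []
    for s in summaries:
        row: dict = {"species": s.species, "group": s.group, "n": s.n}
        for col in MEASUREMENT_COLUMNS:
            row[f"{col}_mean"] = s.means[col]
            row[f"{col}_sd"] = s.sds[col]
        row["aspect_ratio"] = s.aspect_ratio
        row["aspect_ratio_str"] = format_aspect_ratio(s.aspect_ratio)
        row["tubercle_prop"] = s.tubercle_prop
        rows.append(row)
    return pd.DataFrame(rows)


def measurements_from_frame(df: pd.DataFrame) -> list[SpecimenMeasurement]:
    """Build specimen records from a morphometric CSV table."""
    optional = [
        "tubercle_to_trochlea",
        "tubercle_face_length",
        "tubercle_surface_area",
        "sex",
    ]
    out = []
    for _, r in df.iterrows():
        kwargs = {
            k: r[k]
            for k in optional
            if k in df.columns and pd.notna(r[k])
        }
        out.append(
            SpecimenMeasurement(
                specimen_id=str(r["specimen_id"]),
                species=str(r["species"]),
                group=str(r["group"]),
                tmt_length=float(r["tmt_length"]),
                tmt_width=float(r["tmt_width"]),
                tubercle_distance=float(r["tubercle_distance"]),
                extinct=bool(r["extinct"]) if "extinct" in df.columns else False,
                **kwargs,
            )
        )
    return out


def measurements_to_frame(
    measurements: Sequence[SpecimenMeasurement],
) -> pd.DataFrame:
    """Tabulate specimen records (one row each) for CSV export."""
    cols = [
        "specimen_id",
        "species",
        "group",
        "sex",
        "tmt_length",
        "tmt_width",
        "tubercle_distance",
        "tubercle_to_trochlea",
        "extinct",
    ]
    return pd.DataFrame([{c: getattr(m, c) for c in cols} for m in measurements])
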