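"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators:

* cyclic tensometer traces from a closed-form J-shaped constitutive model,
  so that modulus, loop areas and resilience have exact analytic values;
* Gaussian specimen populations around species-level morphometric means;
* Brownian-motion traits on phylogenies with a tunable Pagel's lambda.

The tendon model uses an exponential toe curve for loading,

    sigma_up(eps) = a * (exp(b*eps) - 1),        0 <= eps <= eps_max,

which is strictly increasing and convex (a J-curve), and a power-law
unloading curve

    sigma_down(eps) = sigma_m * (eps/eps_max)**q,   sigma_m = sigma_up(eps_max).

Both areas are closed-form, so the unloading exponent q can be chosen to
make the falling/rising area ratio — the resilience — equal any requested
r in (0, 1]:

    A_up   = a * ((exp(b*eps_max) - 1)/b - eps_max)
    A_down = sigma_m * eps_max / (q + 1)
    q      = sigma_m * eps_max / (r * A_up) - 1

q >= 1 is required (q = 1 is triangular unloading; q < 1 would demand more
recovered than a convex loop can return and raises an error). The model is
quasi-static and cycle-stationary: no creep, rate dependence, or damage
accumulation across cycles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from raptormech import datasets


class InfeasibleResilienceError(ValueError):
    """Requested resilience cannot be met by the loading-curve family."""


# --------------------------------------------------------------------------
# Tendon constitutive model
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TendonModelParams:
    """Ground-truth parameters of one synthetic tensometer run.

    Parameters
    ----------
    a, b
        Stress scale (MPa) and toe-curvature exponent of the loading curve.
    eps_max
        Maximum strain of each ramp (0.10 = the 10 % elongation increment).
    resilience
        Target falling/rising area ratio r in (0, 1].
    A0, L0
        Tendon cross-sectional area (mm^2) and resting length (mm).
    pretension
        Constant load offset (N) emulating the starting tension applied
        before testing; recovered downstream by the zero-load rule.
    noise_sd
        SD of iid Gaussian load noise (N); the gauge resolves 0.001 N, so a
        few millinewtons is a realistic noise floor.
    rate, sample_hz, n_cycles
        Crosshead speed (mm/min), sampling rate (Hz) and cycle count of
        the test protocol.
    """

    a: float = 0.5
    b: float = 20.0
    eps_max: float = 0.10
    resilience: float = 0.75
    A0: float = 5.0
    L0: float = 15.0
    pretension: float = 0.0
    noise_sd: float = 0.005
    rate: float = 50.0
    sample_hz: float = 50.0
    n_cycles: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("a", "b", "eps_max", "A0", "L0", "rate", "sample_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.resilience <= 1:
            raise ValueError(f"resilience must be in (0, 1], got {self.resilience}")
        if self.pretension < 0 or self.noise_sd < 0:
            raise ValueError("pretension and noise_sd must be >= 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        # q >= 1 is checked here, and the unloading curve is verified to
        # stay at or below the loading curve on a dense grid.
        q = analytic_unloading_exponent(self)
        eps = np.linspace(0.0, self.eps_max, 1000)
        up = analytic_loading_stress(eps, self)
        down = analytic_unloading_stress(eps, self, q=q)
        if np.any(down > up + 1e-12 * max(1.0, up.max())):
            raise InfeasibleResilienceError(
                "unloading curve exceeds loading curve; model infeasible"
            )

    @property
    def sigma_m(self) -> float:
        """Peak loading stress sigma_up(eps_max), MPa."""
        return self.a * (math.expm1(self.b * self.eps_max))


def analytic_loading_stress(eps, params: TendonModelParams):
    """Loading-curve stress sigma_up(eps) = a*(exp(b*eps) - 1), MPa."""
    eps = np.asarray(eps, dtype=float)
    if np.any(eps < 0) or np.any(eps > params.eps_max + 1e-12):
        raise ValueError(f"strain outside [0, {params.eps_max}]")
    out = params.a * np.expm1(params.b * eps)
    return float(out) if out.ndim == 0 else out


def analytic_loading_area(params: TendonModelParams) -> float:
    """Closed-form area under the loading curve on [0, eps_max] (MPa)."""
    return params.a * (
        math.expm1(params.b * params.eps_max) / params.b - params.eps_max
    )


def analytic_unloading_exponent(params: TendonModelParams) -> float:
    """Exponent q of the power-law unloading curve that yields resilience r.

    Solves A_down / A_up = r with A_down = sigma_m*eps_max/(q+1); raises
    :class:`InfeasibleResilienceError` when the solution has q < 1 (the
    loop would have to bulge above a straight unloading chord).
    """
    A_up = analytic_loading_area(params)
    q = params.sigma_m * params.eps_max / (params.resilience * A_up) - 1.0
    if q < 1.0 - 1e-12:
        raise InfeasibleResilienceError(
            f"resilience {params.resilience} infeasible for this loading "
            f"curve (requires unloading exponent q={q:.4f} < 1)"
        )
    return q


def analytic_unloading_stress(eps, params: TendonModelParams, q: float | None = None):
    """Unloading-curve stress sigma_m * (eps/eps_max)**q, MPa."""
    if q is None:
        q = analytic_unloading_exponent(params)
    eps = np.asarray(eps, dtype=float)
    out = params.sigma_m * (eps / params.eps_max) ** q
    return float(out) if out.ndim == 0 else out


def analytic_unloading_area(params: TendonModelParams) -> float:
    """Closed-form area under the unloading curve on [0, eps_max] (MPa)."""
    q = analytic_unloading_exponent(params)
    return params.sigma_m * params.eps_max / (q + 1.0)


def samples_per_leg(params: TendonModelParams) -> int:
    """Number of sampling intervals on one rising (or falling) ramp leg."""
    leg_seconds = params.eps_max * params.L0 / (params.rate / 60.0)
    return max(2, round(leg_seconds * params.sample_hz))


def generate_tendon_trace(params: TendonModelParams, species: str = "synthetic",
                          leg: str = "L", increment_pct: int = 10):
    """Simulate one cyclic tensile test as a :class:`~raptormech.tensile.TensileTrace`.

    Displacement follows ``n_cycles`` triangular ramps 0 -> eps_max*L0 -> 0
    at the programmed crosshead rate; a sample is placed exactly at every
    apex and trough so that peak/trough detection is unambiguous at any
    sampling rate. Load is the constitutive stress times A0, plus the
    pre-tension offset and iid Gaussian noise. The trace metadata carries
    the full ground truth (curve parameters, apex/trough indices, analytic
    areas) for use as test oracles.
    """
    from raptormech.tensile import TensileTrace

    rng = np.random.default_rng(params.seed)
    q = analytic_unloading_exponent(params)
    n_leg = samples_per_leg(params)
    leg_seconds = params.eps_max * params.L0 / (params.rate / 60.0)
    dt = leg_seconds / n_leg

    eps_up = np.linspace(0.0, params.eps_max, n_leg + 1)
    eps_down = eps_up[::-1]
    sig_up = analytic_loading_stress(eps_up, params)
    sig_down = analytic_unloading_stress(eps_down, params, q=q)

    # Concatenate cycles, sharing the apex/trough samples between legs.
    eps_parts = [eps_up[:1]]
    sig_parts = [sig_up[:1]]
    for _ in range(params.n_cycles):
        eps_parts.extend([eps_up[1:], eps_down[1:]])
        sig_parts.extend([sig_up[1:], sig_down[1:]])
    eps = np.concatenate(eps_parts)
    sigma = np.concatenate(sig_parts)

    n = eps.size
    time = np.arange(n) * dt
    load = sigma * params.A0 + params.pretension
    if params.noise_sd > 0:
        load = load + rng.normal(0.0, params.noise_sd, size=n)

    apex_indices = np.array(
        [n_leg * (2 * c + 1) for c in range(params.n_cycles)], dtype=int
    )
    trough_indices = np.array(
        [2 * n_leg * (c + 1) for c in range(params.n_cycles)], dtype=int
    )
    metadata = {
        "ground_truth": {
            "a": params.a,
            "b": params.b,
            "eps_max": params.eps_max,
            "resilience": params.resilience,
            "q": q,
            "sigma_m": params.sigma_m,
            "loading_area": analytic_loading_area(params),
            "unloading_area": analytic_unloading_area(params),
            "pretension": params.pretension,
            "noise_sd": params.noise_sd,
            "apex_indices": apex_indices,
            "trough_indices": trough_indices,
            "samples_per_leg": n_leg,
        }
    }
    return TensileTrace(
        species=species,
        leg=leg,
        increment_pct=increment_pct,
        time=time,
        load=load,
        displacement=eps * params.L0,
        L0=params.L0,
        A0=params.A0,
        metadata=metadata,
    )


def params_for_target(
    peak_stress: float,
    A0: float,
    L0: float,
    b: float = 20.0,
    eps_max: float = 0.10,
    **kwargs,
) -> TendonModelParams:
    """Choose the stress scale ``a`` so the loading curve peaks at a target.

    Convenience for emulating a species whose measured peak stress at
    eps_max is known: a = peak_stress / (exp(b*eps_max) - 1).
    """
    a = peak_stress / math.expm1(b * eps_max)
    return TendonModelParams(a=a, b=b, eps_max=eps_max, A0=A0, L0=L0, **kwargs)


# --------------------------------------------------------------------------
# Morphometric populations
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SpeciesSpec:
    """Gaussian population spec for one species' skeletal metrics (mm).

    Each metric is (mean, sd); draws are truncated to be positive and to
    keep the tubercle proximal to the distal end of the bone.
    """

    species: str
    group: str
    tmt_length: tuple[float, float]
    tmt_width: tuple[float, float]
    tubercle_distance: tuple[float, float]
    tubercle_to_trochlea: tuple[float, float] | None = None
    n: int = 10

    def __post_init__(self) -> None:
        metrics = {
            "tmt_length": self.tmt_length,
            "tmt_width": self.tmt_width,
            "tubercle_distance": self.tubercle_distance,
        }
        if self.tubercle_to_trochlea is not None:
            metrics["tubercle_to_trochlea"] = self.tubercle_to_trochlea
        for name, (mean, sd) in metrics.items():
            if mean <= 0:
                raise ValueError(f"{name} mean must be > 0")
            if sd < 0:
                raise ValueError(f"{name} sd must be >= 0")
        if self.tubercle_distance[0] >= self.tmt_length[0]:
            raise ValueError("tubercle distance mean must be < tmt length mean")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def _truncated_normal(rng, mean, sd, size, lower=0.0):
    """Gaussian draws redrawn until strictly greater than ``lower``."""
    if sd == 0:
        return np.full(size, float(mean))
    out = rng.normal(mean, sd, size=size)
    for _ in range(1000):
        bad = out <= lower
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    raise RuntimeError("truncated-normal sampling failed to converge")


def generate_morphometric_population(spec: SpeciesSpec, seed: int):
    """Draw ``spec.n`` synthetic skeletal specimens; reproducible by seed."""
    from raptormech.morphometrics import SpecimenMeasurement

    rng = np.random.default_rng(seed)
    lengths = _truncated_normal(rng, *spec.tmt_length, size=spec.n)
    widths = _truncated_normal(rng, *spec.tmt_width, size=spec.n)
    tubercles = _truncated_normal(rng, *spec.tubercle_distance, size=spec.n)
    # Keep the insertion proximal to the bone's distal end.
    for _ in range(1000):
        bad = tubercles >= lengths
        if not bad.any():
            break
        tubercles[bad] = _truncated_normal(
            rng, *spec.tubercle_distance, size=int(bad.sum())
        )
    if spec.tubercle_to_trochlea is not None:
        t2t = _truncated_normal(rng, *spec.tubercle_to_trochlea, size=spec.n)
    else:
        t2t = [None] * spec.n

    return [
        SpecimenMeasurement(
            specimen_id=f"{spec.species.replace(' ', '_')}_{i + 1:03d}",
            species=spec.species,
            group=spec.group,
            tmt_length=float(lengths[i]),
            tmt_width=float(widths[i]),
            tubercle_distance=float(tubercles[i]),
            tubercle_to_trochlea=None if t2t[i] is None else float(t2t[i]),
        )
        for i in range(spec.n)
    ]


def focal_species_specs(n: int = 10) -> list[SpeciesSpec]:
    """Population specs for the six focal species, from the bundled means."""
    return [
        SpeciesSpec(
            species=sp,
            group=rec["group"],
            tmt_length=rec["tmt_length"],
            tmt_width=rec["tmt_width"],
            tubercle_distance=rec["tubercle_distance"],
            tubercle_to_trochlea=rec["tubercle_to_trochlea"],
            n=n,
        )
        for sp, rec in datasets.FOCAL_MORPHOMETRICS.items()
    ]


# --------------------------------------------------------------------------
# Brownian-motion traits on trees
# --------------------------------------------------------------------------


def balanced_tree(n_tips: int, edge: float = 1.0):
    """Fully balanced ultrametric tree (n_tips a power of two), unit edges."""
    if n_tips < 2 or n_tips & (n_tips - 1):
        raise ValueError("n_tips must be a power of two >= 2")
    from raptormech.phylocomp import read_newick

    def build(lo: int, hi: int) -> str:
        if hi - lo == 1:
            return f"t{lo + 1}:{edge}"
        mid = (lo + hi) // 2
        return f"({build(lo, mid)},{build(mid, hi)}):{edge}"

    mid = n_tips // 2
    return read_newick(f"({build(0, mid)},{build(mid, n_tips)});")


def random_tree(n_tips: int, seed: int, ultrametric: bool = True):
    """Random bifurcating tree by sequential pairwise joins.

    Ultrametric trees use coalescent-style node heights (exponential
    waiting times), so every tip sits at the same distance from the root;
    otherwise branch lengths are iid uniform on (0.1, 2).
    """
    if n_tips < 2:
        raise ValueError("need >= 2 tips")
    from raptormech.phylocomp import read_newick

    rng = np.random.default_rng(seed)
    nodes = [(f"t{i + 1}", 0.0) for i in range(n_tips)]
    height = 0.0
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (s1, h1) = nodes.pop(j)
        (s2, h2) = nodes.pop(i)
        if ultrametric:
            height += float(rng.exponential(1.0))
            merged = f"({s1}:{height - h1},{s2}:{height - h2})"
            nodes.append((merged, height))
        else:
            b1, b2 = rng.uniform(0.1, 2.0, size=2)
            merged = f"({s1}:{b1:.6f},{s2}:{b2:.6f})"
            nodes.append((merged, 0.0))
    return read_newick(nodes[0][0] + ";")


def simulate_bm_traits(
    tree,
    sigma2: float = 1.0,
    lam: float = 1.0,
    n_traits: int = 1,
    seed: int = 0,
    trait_prefix: str = "trait",
) -> pd.DataFrame:
    """Simulate continuous traits under lambda-scaled Brownian motion.

    Traits are iid draws from N(0, sigma2 * C(lambda)), where C is the
    phylogenetic variance–covariance matrix of ``tree`` and C(lambda)
    multiplies its off-diagonals by ``lam``. Returns a species-by-trait
    DataFrame indexed by tip label.
    """
    from raptormech.phylocomp import lambda_transform, phylo_vcv

    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if n_traits < 1:
        raise ValueError("n_traits must be >= 1")
    C = phylo_vcv(tree)
    Cl = lambda_transform(C, lam)
    try:
        L = np.linalg.cholesky(sigma2 * Cl.to_numpy())
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"covariance sigma2*C(lambda={lam}) is not positive definite: {exc}"
        ) from exc
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((len(Cl), n_traits))
    X = L @ Z
    return pd.DataFrame(
        X, index=Cl.index, columns=[f"{trait_prefix}_{j + 1}" for j in range(n_traits)]
    )
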