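"""Synthetic intensive-longitudinal-data generator.

Simulates multi-item questionnaire responses for ``n`` persons measured on
``t`` occasions each, under a two-level (occasions nested in persons) single
factor measurement model.  Within-person *nonuniform* measurement bias is
introduced by letting item loadings differ between the first and second half
of each person's measurement occasions.  Item scores are emitted on a 0-100
visual analog scale (VAS).

The generative model for item ``j`` of person ``i`` at occasion ``s`` is::

    y_ijs = tau_j + lambda_js * (gamma_b * xi_i + zeta_is) + eps_ijs

with ``xi_i ~ N(0, sd_b^2)`` the person trait, ``zeta_is`` a unit-variance
occasion state (non-normal per person, via a Fleishman polynomial), and
``eps_ijs ~ N(0, theta_w)`` the occasion-level residual.  The time-varying
loading multiplies both the trait pathway and the occasion state, so biased
items lose between-person as well as within-person signal and their ICC
drops.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "N_ITEMS",
    "BASE_LOADING",
    "REDUCED_LOADINGS",
    "BiasPatternError",
    "FleishmanInfeasibleError",
    "UnbalancedDataError",
    "LoadingSchedule",
    "SimCondition",
    "MeasurementDesign",
    "SubjectShape",
    "ILDDataset",
    "resolve_bias_pattern",
    "solve_fleishman",
    "fleishman_moments",
    "simulate_person",
    "simulate_dataset",
    "to_vas",
    "calibrate_gamma_b",
    "default_design",
    "write_csv",
    "read_csv",
    "condition_seed",
]

N_ITEMS = 6
BASE_LOADING = 0.7
#: reduced loading used in the biased half of the occasions, by bias strength
REDUCED_LOADINGS = {"low": 0.4, "high": 0.2}

BIAS_LEVELS = ("none", 1, 2, 3, 4)
STRENGTHS = ("low", "high")


class BiasPatternError(ValueError):
    """Unknown bias condition or bias strength."""


class FleishmanInfeasibleError(ValueError):
    """(skewness, excess kurtosis) outside the Fleishman-feasible region."""


class UnbalancedDataError(ValueError):
    """Long-format data whose persons do not share a common occasion count."""


# ---------------------------------------------------------------------------
# loading schedules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LoadingSchedule:
    """Per-item loadings for the first vs. second half of occasions."""

    first: tuple[float, ...]
    second: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.first) != len(self.second):
            raise ValueError("first/second loading vectors differ in length")

    @property
    def n_items(self) -> int:
        return len(self.first)

    @property
    def biased_items(self) -> tuple[int, ...]:
        """0-based indices of items whose loading changes across halves."""
        return tuple(
            j for j, (a, b) in enumerate(zip(self.first, self.second)) if a != b
        )

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.first, float), np.asarray(self.second, float)

    def mean_loadings(self) -> np.ndarray:
        """Per-item loading averaged over the two halves."""
        a, b = self.as_arrays()
        return 0.5 * (a + b)


def resolve_bias_pattern(bias, strength: str = "low") -> LoadingSchedule:
    """Return the six-item loading schedule for one bias condition.

    Bias conditions (items are 1-based in the description, indices 0-based
    in the returned tuples; items 1 and 2 are always invariant):

    - ``"none"``: all items load 0.7 in both halves.
    - ``1``: item 6 drops to the reduced loading in the second half.
    - ``2``: items 5 and 6 drop in the second half.
    - ``3``: item 3 drops in the second half, item 5 in the *first* half.
    - ``4``: items 3 and 4 drop in the second half, items 5 and 6 in the
      first half.

    The reduced loading is 0.4 for ``strength="low"`` and 0.2 for ``"high"``.
    """
    if strength not in REDUCED_LOADINGS:
        raise BiasPatternError(f"unknown bias strength: {strength!r}")
    if bias not in BIAS_LEVELS:
        raise BiasPatternError(f"unknown bias condition: {bias!r}")
    r = REDUCED_LOADINGS[strength]
    b = BASE_LOADING
    first = [b] * N_ITEMS
    second = [b] * N_ITEMS
    if bias == 1:
        second[5] = r
    elif bias == 2:
        second[4] = r
        second[5] = r
    elif bias == 3:
        second[2] = r
        first[4] = r
    elif bias == 4:
        second[2] = r
        second[3] = r
        first[4] = r
        first[5] = r
    return LoadingSchedule(tuple(first), tuple(second))


# ---------------------------------------------------------------------------
# design parameters
# ---------------------------------------------------------------------------


def calibrate_gamma_b(target_icc: float = 0.219, sd_b: float = 1.0,
                      lambda_w: float = BASE_LOADING) -> float:
    """Between-pathway scale that yields ``target_icc`` at trait SD ``sd_b``.

    With unit within-item variance the item ICC is
    ``lam^2 g^2 sd_b^2 / (lam^2 g^2 sd_b^2 + 1)``; solve for ``g``.
    """
    if not 0.0 < target_icc < 1.0:
        raise ValueError("target ICC must be in (0, 1)")
    ratio = target_icc / (1.0 - target_icc)
    return math.sqrt(ratio) / (lambda_w * sd_b)


@dataclass(frozen=True)
class MeasurementDesign:
    """Population measurement parameters shared by all simulated persons.

    The defaults give each unbiased item unit marginal within-person variance
    (``0.7^2 * 1 + 0.51 = 1``) and calibrate the between pathway so an
    unbiased item at trait SD 1 has ICC 0.219.  The VAS map is affine
    (centre 50) with a scale such that +-4 marginal SDs of an unbiased item
    at trait SD 1 span 0-100, then clipped to the scale.
    """

    p: int = N_ITEMS
    lambda_w: float = BASE_LOADING
    phi_w: float = 1.0
    theta_w: float = 1.0 - BASE_LOADING ** 2
    gamma_b: float = field(default_factory=calibrate_gamma_b)
    theta_b: float = 0.0
    tau: tuple[float, ...] = (0.0,) * N_ITEMS
    vas_center: float = 50.0
    vas_scale: float | None = None
    vas_clip: bool = True

    def __post_init__(self) -> None:
        if self.theta_w < 0 or self.theta_b < 0:
            raise ValueError("residual variances must be non-negative")
        if self.gamma_b <= 0:
            raise ValueError("gamma_b must be positive")
        if len(self.tau) != self.p:
            raise ValueError("tau must have one intercept per item")
        if self.vas_scale is None:
            sd = math.sqrt(self.marginal_variance(sd_b=1.0))
            object.__setattr__(self, "vas_scale", 100.0 / (8.0 * sd))

    def marginal_variance(self, sd_b: float) -> float:
        """Latent-scale marginal variance of an unbiased item."""
        return (self.lambda_w ** 2 * (self.gamma_b ** 2 * sd_b ** 2 + self.phi_w)
                + self.theta_w + self.theta_b)


def default_design() -> MeasurementDesign:
    return MeasurementDesign()


# ---------------------------------------------------------------------------
# Fleishman power-method transform
# ---------------------------------------------------------------------------


def fleishman_moments(b, c, d):
    """Skewness and excess kurtosis of ``-c + b z + c z^2 + d z^3``.

    Assumes the coefficients satisfy the unit-variance constraint; returns
    ``(variance, skew, exkurt)`` so callers can verify all three.
    """
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    d = np.asarray(d, float)
    var = b ** 2 + 6 * b * d + 2 * c ** 2 + 15 * d ** 2
    skew = 2 * c * (b ** 2 + 24 * b * d + 105 * d ** 2 + 2)
    kurt = 24 * (b * d + c ** 2 * (1 + b ** 2 + 28 * b * d)
                 + d ** 2 * (12 + 48 * b * d + 141 * c ** 2 + 225 * d ** 2))
    return var, skew, kurt


def _fleishman_newton(skew: np.ndarray, exkurt: np.ndarray,
                      tol: float = 1e-10, maxit: int = 60):
    """Vectorised Newton solve of the Fleishman moment equations.

    Returns ``(b, c, d, ok)`` where ``ok`` flags convergence per element.
    """
    skew = np.atleast_1d(np.asarray(skew, float))
    exkurt = np.atleast_1d(np.asarray(exkurt, float))
    n = skew.shape[0]
    b = np.ones(n)
    c = np.zeros(n)
    d = np.zeros(n)
    ok = np.zeros(n, bool)
    for _ in range(maxit):
        var, sk, ku = fleishman_moments(b, c, d)
        f = np.stack([var - 1.0, sk - skew, ku - exkurt], axis=-1)
        ok = np.all(np.abs(f) < tol, axis=-1)
        if ok.all():
            break
        jac = np.empty((n, 3, 3))
        jac[:, 0, 0] = 2 * b + 6 * d
        jac[:, 0, 1] = 4 * c
        jac[:, 0, 2] = 6 * b + 30 * d
        jac[:, 1, 0] = 2 * c * (2 * b + 24 * d)
        jac[:, 1, 1] = 2 * (b ** 2 + 24 * b * d + 105 * d ** 2 + 2)
        jac[:, 1, 2] = 2 * c * (24 * b + 210 * d)
        jac[:, 2, 0] = 24 * (d + c ** 2 * (2 * b + 28 * d) + 48 * d ** 3)
        jac[:, 2, 1] = 24 * (2 * c + 2 * b ** 2 * c + 56 * b * c * d
                             + 282 * c * d ** 2)
        jac[:, 2, 2] = 24 * (b + 28 * b * c ** 2 + 24 * d + 144 * b * d ** 2
                             + 282 * c ** 2 * d + 900 * d ** 3)
        try:
            step = np.linalg.solve(jac, f[..., None])[..., 0]
        except np.linalg.LinAlgError:
            break
        upd = ~ok
        b[upd] -= step[upd, 0]
        c[upd] -= step[upd, 1]
        d[upd] -= step[upd, 2]
    return b, c, d, ok


def solve_fleishman(skew: float, exkurt: float) -> tuple[float, float, float]:
    """Coefficients ``(b, c, d)`` of the Fleishman polynomial.

    ``y = -c + b z + c z^2 + d z^3`` with ``z`` standard normal then has mean
    0, variance 1, skewness ``skew`` and excess kurtosis ``exkurt``.

    Raises
    ------
    FleishmanInfeasibleError
        If no real solution exists for the requested moment pair.
    """
    b, c, d, ok = _fleishman_newton(skew, exkurt)
    if not ok[0] or not np.all(np.isfinite([b[0], c[0], d[0]])):
        raise FleishmanInfeasibleError(
            f"no Fleishman coefficients for skew={skew}, exkurt={exkurt}")
    return float(b[0]), float(c[0]), float(d[0])


@dataclass(frozen=True)
class SubjectShape:
    """Per-subject response-shape: target skewness / excess kurtosis."""

    skew: float
    exkurt: float
    coef: tuple[float, float, float]  # Fleishman (b, c, d)

    @classmethod
    def from_moments(cls, skew: float, exkurt: float) -> "SubjectShape":
        return cls(skew, exkurt, solve_fleishman(skew, exkurt))

    @classmethod
    def normal(cls) -> "SubjectShape":
        return cls(0.0, 0.0, (1.0, 0.0, 0.0))

    def transform(self, z: np.ndarray) -> np.ndarray:
        b, c, d = self.coef
        return -c + z * (b + z * (c + z * d))


# ---------------------------------------------------------------------------
# simulation conditions and datasets
# ---------------------------------------------------------------------------

#: in-paper factorial grid
GRID_N = (50, 100, 200)
GRID_T = (10, 20, 30, 50, 80)
GRID_SD_B = (1.0, 2.0, 3.0)


@dataclass(frozen=True)
class SimCondition:
    """One cell of the factorial simulation grid."""

    n: int
    t: int
    sd_b: float
    bias: object = "none"  # "none" or 1..4
    strength: str = "low"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.t < 2:
            raise ValueError("need n >= 1 persons and t >= 2 occasions")
        if self.sd_b <= 0:
            raise ValueError("sd_b must be positive")
        if self.bias not in BIAS_LEVELS:
            raise BiasPatternError(f"unknown bias condition: {self.bias!r}")
        if self.strength not in STRENGTHS:
            raise BiasPatternError(f"unknown bias strength: {self.strength!r}")

    @property
    def schedule(self) -> LoadingSchedule:
        return resolve_bias_pattern(self.bias, self.strength)

    def label(self) -> str:
        s = "-" if self.bias == "none" else self.strength
        return f"n{self.n}_t{self.t}_sd{self.sd_b:g}_b{self.bias}_{s}"


ITEM_COLUMNS = tuple(f"item{j + 1}" for j in range(N_ITEMS))


@dataclass(frozen=True)
class ILDDataset:
    """Long-format table of item scores: one row per person x occasion."""

    df: pd.DataFrame
    condition: SimCondition | None = None

    @property
    def n_persons(self) -> int:
        return self.df["person"].nunique()

    @property
    def n_occasions(self) -> int:
        counts = self.df["person"].value_counts()
        if counts.nunique() != 1:
            raise UnbalancedDataError("persons differ in occasion counts")
        return int(counts.iloc[0])

    @property
    def item_columns(self) -> tuple[str, ...]:
        return tuple(c for c in self.df.columns if c.startswith("item"))

    def values(self) -> np.ndarray:
        """(n*t, p) array of item scores, ordered by person then occasion."""
        df = self.df.sort_values(["person", "occasion"], kind="stable")
        return df[list(self.item_columns)].to_numpy(float)

    def person_index(self) -> np.ndarray:
        df = self.df.sort_values(["person", "occasion"], kind="stable")
        return pd.factorize(df["person"].to_numpy())[0]


def _person_param_rng(seed: int, person_id: int) -> np.random.Generator:
    """Stream for a person's trait and shape draws."""
    return np.random.default_rng(np.random.SeedSequence((seed, person_id, 0)))


def _person_data_rng(seed: int, person_id: int) -> np.random.Generator:
    """Stream for a person's occasion-level noise."""
    return np.random.default_rng(np.random.SeedSequence((seed, person_id, 1)))


def simulate_person(design: MeasurementDesign, schedule: LoadingSchedule,
                    eta: float, t: int, shape: SubjectShape,
                    rng: np.random.Generator) -> np.ndarray:
    """(t, p) latent-scale response matrix for one person.

    Occasions ``1..ceil(t/2)`` use the schedule's first-half loadings, the
    rest the second-half loadings.  ``eta`` is the person's between-level
    trait draw; the occasion state is a Fleishman-perturbed standard variate.
    """
    if t < 2:
        raise ValueError("need at least two occasions")
    lam_first, lam_second = schedule.as_arrays()
    half = -(-t // 2)  # ceil
    lam = np.empty((t, design.p))
    lam[:half] = lam_first
    lam[half:] = lam_second
    zeta = shape.transform(rng.standard_normal(t))
    eps = rng.standard_normal((t, design.p)) * math.sqrt(design.theta_w)
    if design.theta_b > 0:
        eps = eps + rng.standard_normal(design.p) * math.sqrt(design.theta_b)
    state = design.gamma_b * eta + zeta
    return np.asarray(design.tau) + lam * state[:, None] + eps


def to_vas(raw: np.ndarray, design: MeasurementDesign,
           clip: bool | None = None) -> np.ndarray:
    """Affine map of latent-scale scores onto the 0-100 visual analog scale."""
    y = design.vas_center + design.vas_scale * np.asarray(raw, float)
    if design.vas_clip if clip is None else clip:
        y = np.clip(y, 0.0, 100.0)
    return y


def _draw_subject_shape(rng: np.random.Generator) -> SubjectShape:
    """Draw (skew, exkurt) uniformly on [-0.5, 0.5]^2, resampling until the
    pair is Fleishman-feasible (the box lies inside the feasible region, so
    resampling is a safeguard for widened boxes)."""
    while True:
        sk, ku = rng.uniform(-0.5, 0.5, size=2)
        b, c, d, ok = _fleishman_newton(sk, ku)
        if ok[0] and np.all(np.isfinite([b[0], c[0], d[0]])):
            return SubjectShape(float(sk), float(ku),
                                (float(b[0]), float(c[0]), float(d[0])))


def simulate_dataset(cond: SimCondition,
                     design: MeasurementDesign | None = None,
                     apply_vas: bool = True) -> ILDDataset:
    """Simulate one long-format dataset for a grid condition.

    Persons are simulated individually (trait draw, subject shape, ``t``
    occasions) and concatenated; scores are then mapped to the 0-100 VAS
    unless ``apply_vas`` is False (latent scale, used for diagnostics).
    Each person has two streams seeded by ``(cond.seed, person)`` — one for
    the trait/shape draws, one for occasion noise — so the Fleishman solves
    can be batched across persons without touching the noise streams.
    """
    design = design or default_design()
    schedule = cond.schedule
    prngs = [_person_param_rng(cond.seed, i) for i in range(cond.n)]
    etas = np.array([r.normal(0.0, cond.sd_b) for r in prngs])
    pairs = np.array([r.uniform(-0.5, 0.5, size=2) for r in prngs])
    b, c, d, ok = _fleishman_newton(pairs[:, 0], pairs[:, 1])
    shapes = []
    for i in range(cond.n):
        if ok[i] and np.all(np.isfinite([b[i], c[i], d[i]])):
            shapes.append(SubjectShape(float(pairs[i, 0]), float(pairs[i, 1]),
                                       (float(b[i]), float(c[i]), float(d[i]))))
        else:
            shapes.append(_draw_subject_shape(prngs[i]))
    blocks = np.empty((cond.n, cond.t, design.p))
    for i in range(cond.n):
        blocks[i] = simulate_person(design, schedule, etas[i], cond.t,
                                    shapes[i], _person_data_rng(cond.seed, i))
    y = blocks.reshape(cond.n * cond.t, design.p)
    if apply_vas:
        y = to_vas(y, design)
    df = pd.DataFrame(y, columns=list(ITEM_COLUMNS))
    df.insert(0, "occasion", np.tile(np.arange(1, cond.t + 1), cond.n))
    df.insert(0, "person", np.repeat(np.arange(1, cond.n + 1), cond.t))
    return ILDDataset(df, cond)


# ---------------------------------------------------------------------------
# CSV I/O and seeding helpers
# ---------------------------------------------------------------------------


def write_csv(data: ILDDataset, path) -> None:
    """Write long-format CSV: ``person,occasion,item1..item6`` (UTF-8)."""
    data.df.to_csv(path, index=False, encoding="utf-8")


def read_csv(path) -> ILDDataset:
    df = pd.read_csv(path, encoding="utf-8")
    required = {"person", "occasion"}
    if not required.issubset(df.columns):
        raise ValueError("CSV must have 'person' and 'occasion' columns")
    items = [c for c in df.columns if c.startswith("item")]
    if not items:
        raise ValueError("CSV must have at least one itemK column")
    return ILDDataset(df, None)


def condition_seed(root_seed: int, cond_key: Sequence) -> int:
    """Stable per-condition seed below 2**31 from a root seed and a key."""
    text = "|".join(str(k) for k in (root_seed, *cond_key))
    return zlib.crc32(text.encode()) & 0x7FFFFFFF
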