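"""Between-lineage divergence and mutation-rate dating.

Pairwise distances use the Tamura–Nei (1993) model, which separates the
two transition classes (A<->G among purines, C<->T among pyrimidines)
from transversions and weights them by base frequencies estimated from
the pooled sequence pair. Between-population divergence D_xy is the mean
pairwise distance across populations; the net divergence

    D_A = D_xy - (D_x + D_y) / 2

subtracts mean within-population distances, and its standard error comes
from a site (column) bootstrap. Divergence time follows the strict
molecular clock D_T = D_A / (2 mu) for a substitution rate mu per site
per year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations

import numpy as np

from .seqio import LocusAlignment, MultilocusDataset, clone_correct, concatenate
from .diversity import encode

#: ITS substitution-rate priors (substitutions/site/year) from lichenized
#: and non-lichenized ascomycete calibrations.
DEFAULT_RATES = {
    "Melanelixia": 2.43e-9,
    "Oropogon": 2.38e-9,
    "Erysiphales": 2.52e-9,
}


@dataclass
class RatePrior:
    name: str
    mu: float  # substitutions/site/year

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")


# ---------------------------------------------------------------------------
# Tamura–Nei distance
# ---------------------------------------------------------------------------

def _tn93_from_counts(N: np.ndarray) -> float:
    """TN93 distance from a 4x4 substitution count matrix (ACGT order).

    Base frequencies are taken from the pooled pair (symmetrized counts).
    Returns +inf when a logarithm argument is non-positive (saturation).
    """
    total = N.sum()
    if total == 0:
        raise ValueError("no shared determinate columns")
    g = (N.sum(axis=0) + N.sum(axis=1)) / (2.0 * total)
    gA, gC, gG, gT = g
    gR, gY = gA + gG, gC + gT
    P1 = (N[0, 2] + N[2, 0]) / total  # A<->G transitions
    P2 = (N[1, 3] + N[3, 1]) / total  # C<->T transitions
    Q = (
        N[0, 1] + N[1, 0] + N[0, 3] + N[3, 0]
        + N[2, 1] + N[1, 2] + N[2, 3] + N[3, 2]
    ) / total
    if P1 == 0 and P2 == 0 and Q == 0:
        return 0.0
    k1 = 2.0 * gA * gG / gR if gR > 0 else 0.0
    k2 = 2.0 * gC * gT / gY if gY > 0 else 0.0
    k3 = 2.0 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY) \
        if gR > 0 and gY > 0 else 0.0
    d = 0.0
    try:
        if k1 > 0:
            w1 = 1.0 - P1 / k1 - Q / (2.0 * gR)
            d -= k1 * math.log(w1)
        if k2 > 0:
            w2 = 1.0 - P2 / k2 - Q / (2.0 * gY)
            d -= k2 * math.log(w2)
        if k3 != 0:
            w3 = 1.0 - Q / (2.0 * gR * gY)
            d -= k3 * math.log(w3)
    except ValueError:
        return math.inf
    return d


def _count_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    ok = (x >= 0) & (y >= 0)
    N = np.zeros((4, 4))
    np.add.at(N, (x[ok], y[ok]), 1.0)
    return N


def tn93_distance(s1: str | np.ndarray, s2: str | np.ndarray) -> float:
    """Tamura–Nei (1993) pairwise distance in substitutions per site.

    Accepts raw sequences or integer-encoded rows; columns where either
    sequence is non-determinate are excluded.
    """
    if isinstance(s1, str):
        aln = LocusAlignment("pair", len(s1), {"x": s1, "y": s2})
        X = encode(aln)
        s1, s2 = X[0], X[1]
    if len(s1) != len(s2):
        raise ValueError("length mismatch")
    return _tn93_from_counts(_count_matrix(np.asarray(s1), np.asarray(s2)))


# ---------------------------------------------------------------------------
# Mean within/between distances and net divergence
# ---------------------------------------------------------------------------

def mean_between(X: np.ndarray, Y: np.ndarray) -> float:
    """D_xy: mean TN93 distance over all between-population pairs.

    Comparing a population against itself excludes self-pairs, so
    D_xy(X, X) equals the within mean and the net divergence is zero.
    """
    if len(X) == 0 or len(Y) == 0:
        raise ValueError("empty population")
    if X.shape == Y.shape and np.array_equal(X, Y):
        return mean_within(X)
    vals = [tn93_distance(x, y) for x in X for y in Y]
    return float(np.mean(vals))


def mean_within(X: np.ndarray) -> float:
    """D_x: mean TN93 distance over unordered within-population pairs.

    A singleton population has no pairs; its mean within distance is 0.
    """
    if len(X) < 2:
        return 0.0
    vals = [tn93_distance(X[i], X[j]) for i, j in combinations(range(len(X)), 2)]
    return float(np.mean(vals))


def net_divergence(X: np.ndarray, Y: np.ndarray) -> float:
    """D_A = D_xy - (D_x + D_y)/2; may be negative for unstructured data."""
    return mean_between(X, Y) - (mean_within(X) + mean_within(Y)) / 2.0


# ---------------------------------------------------------------------------
# Site bootstrap for the standard error of D_A
# ---------------------------------------------------------------------------

def _pair_joint_codes(X: np.ndarray, pairs: list[tuple[int, int]]) -> np.ndarray:
    """Per-pair, per-column joint base codes 4*a+b (16 = missing)."""
    J = np.full((len(pairs), X.shape[1]), 16, dtype=np.int8)
    for r, (i, j) in enumerate(pairs):
        ok = (X[i] >= 0) & (X[j] >= 0)
        J[r, ok] = 4 * X[i, ok] + X[j, ok]
    return J


def _tn93_batch(counts17: np.ndarray) -> np.ndarray:
    """TN93 for a batch of 17-class joint-code count vectors."""
    out = np.empty(len(counts17))
    for r, c in enumerate(counts17):
        out[r] = _tn93_from_counts(c[:16].reshape(4, 4).astype(float))
    return out


def bootstrap_se_DA(
    X: np.ndarray,
    Y: np.ndarray,
    reps: int = 1000,
    seed: int | None = None,
) -> tuple[float, tuple[float, float]]:
    """Site-bootstrap SE of D_A and the D_A ± 2 SE interval (floored at 0).

    Alignment columns are resampled with replacement jointly for both
    populations; D_A is recomputed per replicate and SE is the standard
    deviation across replicates.
    """
    L = X.shape[1]
    if L < 2:
        raise ValueError("need >= 2 columns")
    nx, ny = len(X), len(Y)
    Z = np.vstack([X, Y])
    between = [(i, nx + j) for i in range(nx) for j in range(ny)]
    within_x = list(combinations(range(nx), 2))
    within_y = [(nx + i, nx + j) for i, j in combinations(range(ny), 2)]
    pairs = between + within_x + within_y
    J = _pair_joint_codes(Z, pairs)
    npairs = len(pairs)
    base = (np.arange(npairs) * 17)[:, None]
    rng = np.random.default_rng(seed)
    point = _da_from_counts(J, np.arange(L), base, npairs, nx, ny,
                            len(between), len(within_x))
    vals = np.empty(reps)
    for r in range(reps):
        idx = rng.integers(0, L, size=L)
        vals[r] = _da_from_counts(J, idx, base, npairs, nx, ny,
                                  len(between), len(within_x))
    se = float(np.std(vals, ddof=1))
    low = max(0.0, point - 2 * se)
    high = max(0.0, point + 2 * se)
    return se, (low, high)


def _da_from_counts(J, idx, base, npairs, nx, ny, n_between, n_wx):
    sub = J[:, idx]
    counts = np.bincount(
        (base + sub).ravel(), minlength=npairs * 17
    ).reshape(npairs, 17)
    d = _tn93_batch(counts)
    dxy = d[:n_between].mean()
    dx = d[n_between:n_between + n_wx].mean() if n_wx else 0.0
    wy = d[n_between + n_wx:]
    dy = wy.mean() if len(wy) else 0.0
    return dxy - (dx + dy) / 2.0


# ---------------------------------------------------------------------------
# Dating
# ---------------------------------------------------------------------------

def divergence_time(DA_bound: float, rate: RatePrior) -> float:
    """Years since divergence: D_T = D_A / (2 mu)."""
    if DA_bound < 0:
        raise ValueError("negative net divergence")
    return DA_bound / (2.0 * rate.mu)


def to_myr(years: float) -> float:
    """Half-up rounding to one decimal of Myr, the table convention."""
    return float(
        Decimal(years / 1e6).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


# ---------------------------------------------------------------------------
# Table-2-style report
# ---------------------------------------------------------------------------

@dataclass
class DivergenceReport:
    pair: tuple[str, str]
    Dxy: float
    Dx: float
    Dy: float
    DA: float
    SE: float
    DA_interval: tuple[float, float]
    DT_intervals: dict[str, tuple[float, float]]  # rate name -> (low, high) years

    def as_row(self) -> dict:
        row = {
            "pair": f"{self.pair[0]}-{self.pair[1]}",
            "Dxy": round(self.Dxy, 4),
            "DA": round(self.DA, 4),
            "SE": round(self.SE, 4),
            "DA_low": round(self.DA_interval[0], 4),
            "DA_high": round(self.DA_interval[1], 4),
        }
        for name, (lo, hi) in self.DT_intervals.items():
            row[f"DT_{name}_low_Myr"] = to_myr(lo)
            row[f"DT_{name}_high_Myr"] = to_myr(hi)
        return row


def divergence_table(
    ds: MultilocusDataset,
    rates: list[RatePrior] | None = None,
    reps: int = 1000,
    seed: int | None = None,
    clone_correct_first: bool = True,
    missing_policy: str = "drop_incomplete",
) -> list[DivergenceReport]:
    """One report per unordered population pair.

    Distances are computed on the concatenated alignment (clone-corrected
    by default). D_T intervals apply each rate prior to both endpoints of
    the D_A ± 2 SE interval.
    """
    if rates is None:
        rates = [RatePrior(n, mu) for n, mu in DEFAULT_RATES.items()]
    concat, _ = concatenate(ds, missing_policy)
    pops = ds.populations()
    mats = {}
    for pop, ids in pops.items():
        sub = concat.subset(ids)
        if clone_correct_first:
            sub, _ = clone_correct(sub, "strict")
        mats[pop] = encode(sub)
    reports = []
    for k, (a, b) in enumerate(combinations(pops, 2)):
        X, Y = mats[a], mats[b]
        dxy = mean_between(X, Y)
        dx, dy = mean_within(X), mean_within(Y)
        da = dxy - (dx + dy) / 2.0
        se, interval = bootstrap_se_DA(
            X, Y, reps, None if seed is None else seed + k
        )
        dts = {
            r.name: (divergence_time(interval[0], r), divergence_time(interval[1], r))
            for r in rates
        }
        reports.append(DivergenceReport((a, b), dxy, dx, dy, da, se, interval, dts))
    return reports
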