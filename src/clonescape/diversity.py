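"""Within-lineage diversity and neutrality statistics.

Implements the per-population summary row of a clonal population survey:
sample and genotype counts (m, m*), genotypic diversity Gdiv = m*/m,
nucleotide diversity pi with resampling confidence intervals, Tajima's D
and Fu's Fs. D and Fs are computed on clone-corrected sequences; pi is
reported both with and without clone correction.

Numerical notes
---------------
* pi_total (mean pairwise difference *count*) uses complete deletion:
  columns containing any gap or N are excluded globally before pairwise
  comparison. This is the quantity fed to both D and Fs.
* Fu's Fs evaluates the Ewens sampling distribution with unsigned
  Stirling numbers of the first kind in log space, so it is stable for
  samples of hundreds of sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .seqio import DETERMINATE, LocusAlignment, MultilocusDataset, clone_correct, concatenate

_CODE = {c: i for i, c in enumerate("ACGT")}


def encode(aln: LocusAlignment) -> np.ndarray:
    """Alignment as an int8 matrix (A=0 C=1 G=2 T=3, missing/ambiguous=-1)."""
    n, L = aln.n_samples, aln.length
    X = np.full((n, L), -1, dtype=np.int8)
    for r, seq in enumerate(aln.records.values()):
        X[r] = [_CODE.get(c, -1) for c in seq]
    return X


def _complete_columns(X: np.ndarray) -> np.ndarray:
    return X[:, (X >= 0).all(axis=0)]


# ---------------------------------------------------------------------------
# Genotypic and nucleotide diversity
# ---------------------------------------------------------------------------

def gdiv(m: int, m_star: int) -> float:
    """Genotypic diversity: genotypes over individuals, m*/m."""
    if m <= 0:
        raise ValueError("m must be positive")
    if not 1 <= m_star <= m:
        raise ValueError("require 1 <= m_star <= m")
    return m_star / m


def nucleotide_diversity(
    aln: LocusAlignment | np.ndarray, site_mode: str = "complete_deletion"
) -> tuple[float, int]:
    """Per-site nucleotide diversity pi and the number of sites used.

    pi is the mean over unordered sequence pairs of the per-pair
    difference proportion. ``complete_deletion`` drops columns with any
    gap/N globally (n_eff = retained columns); ``pairwise_deletion``
    evaluates each pair on its own determinate columns (n_eff = full
    alignment length).
    """
    X = aln if isinstance(aln, np.ndarray) else encode(aln)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need >= 2 sequences")
    if site_mode == "complete_deletion":
        Xc = _complete_columns(X)
        n_eff = Xc.shape[1]
        if n_eff == 0:
            raise ValueError("no comparable sites")
        total = 0.0
        for i, j in combinations(range(n), 2):
            total += np.count_nonzero(Xc[i] != Xc[j]) / n_eff
        return total / math.comb(n, 2), n_eff
    if site_mode == "pairwise_deletion":
        total = 0.0
        for i, j in combinations(range(n), 2):
            ok = (X[i] >= 0) & (X[j] >= 0)
            m = int(ok.sum())
            if m == 0:
                raise ValueError("no comparable sites")
            total += np.count_nonzero(X[i, ok] != X[j, ok]) / m
        return total / math.comb(n, 2), X.shape[1]
    raise ValueError(f"unknown site_mode: {site_mode}")


def mean_pairwise_differences(X: np.ndarray) -> tuple[float, int]:
    """pi_total: mean pairwise difference count on complete-deletion columns."""
    n = X.shape[0]
    Xc = _complete_columns(X)
    total = sum(
        int(np.count_nonzero(Xc[i] != Xc[j]))
        for i, j in combinations(range(n), 2)
    )
    return total / math.comb(n, 2), Xc.shape[1]


def segregating_sites(X: np.ndarray) -> int:
    """Segregating sites on complete-deletion columns (multiallelic count once)."""
    Xc = _complete_columns(X)
    return int(np.count_nonzero((Xc != Xc[0]).any(axis=0)))


# ---------------------------------------------------------------------------
# Resampling confidence intervals for pi
# ---------------------------------------------------------------------------

def _pair_diff_matrix(X: np.ndarray, site_mode: str) -> np.ndarray:
    """Symmetric matrix of per-pair difference proportions."""
    n = X.shape[0]
    D = np.zeros((n, n))
    if site_mode == "complete_deletion":
        Xc = _complete_columns(X)
        if Xc.shape[1] == 0:
            raise ValueError("no comparable sites")
        for i, j in combinations(range(n), 2):
            D[i, j] = D[j, i] = np.count_nonzero(Xc[i] != Xc[j]) / Xc.shape[1]
    else:
        for i, j in combinations(range(n), 2):
            ok = (X[i] >= 0) & (X[j] >= 0)
            m = int(ok.sum())
            if m == 0:
                raise ValueError("no comparable sites")
            D[i, j] = D[j, i] = np.count_nonzero(X[i, ok] != X[j, ok]) / m
    return D


def pi_confidence_interval(
    aln: LocusAlignment | np.ndarray,
    method: str = "bootstrap_sequences",
    reps: int = 1000,
    seed: int | None = None,
    site_mode: str = "complete_deletion",
) -> tuple[float, float]:
    """95% percentile interval for pi by resampling sequences.

    ``bootstrap_sequences`` resamples the n sequences with replacement and
    recomputes pi per replicate; ``subsample_permutation`` draws 2 distinct
    sequences without replacement per replicate and records their pairwise
    difference proportion. Monomorphic input yields (0, 0).
    """
    X = aln if isinstance(aln, np.ndarray) else encode(aln)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need >= 2 sequences")
    D = _pair_diff_matrix(X, site_mode)
    if not D.any():
        return (0.0, 0.0)
    rng = np.random.default_rng(seed)
    vals = np.empty(reps)
    if method == "bootstrap_sequences":
        npairs = math.comb(n, 2)
        iu = np.triu_indices(n, k=1)
        for r in range(reps):
            idx = rng.integers(0, n, size=n)
            sub = D[np.ix_(idx, idx)]
            vals[r] = sub[iu].sum() / npairs
    elif method == "subsample_permutation":
        for r in range(reps):
            i, j = rng.choice(n, size=2, replace=False)
            vals[r] = D[i, j]
    else:
        raise ValueError(f"unknown method: {method}")
    low, high = np.percentile(vals, [2.5, 97.5])
    return float(low), float(high)


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajima_constants(n: int) -> dict[str, float]:
    """The canonical n-dependent constants of Tajima's D."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_D(aln: LocusAlignment | np.ndarray) -> float | None:
    """Tajima's D: (pi_total - S/a1) / sqrt(e1*S + e2*S*(S-1)).

    Returns None when S = 0 (no segregating sites) or when the variance
    term degenerates to zero.
    """
    X = aln if isinstance(aln, np.ndarray) else encode(aln)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need >= 2 sequences")
    S = segregating_sites(X)
    if S == 0:
        return None
    pi_total, _ = mean_pairwise_differences(X)
    k = tajima_constants(n)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    if var <= 0:
        return None
    return (pi_total - S / k["a1"]) / math.sqrt(var)


# ---------------------------------------------------------------------------
# Fu's Fs
# ---------------------------------------------------------------------------

def _log_stirling_first_row(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 0..n via the triangular recurrence in log space."""
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0  # |s(0,0)| = 1
    for m in range(1, n + 1):
        new = np.full(n + 1, -np.inf)
        # |s(m,k)| = |s(m-1,k-1)| + (m-1)|s(m-1,k)|
        new[1:m + 1] = row[0:m]
        if m > 1:
            with np.errstate(divide="ignore"):
                new[1:m] = np.logaddexp(new[1:m], math.log(m - 1) + row[1:m])
        row = new
    return row


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log P(K = k | theta, n) under the Ewens sampling distribution, k=0..n."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    ls = _log_stirling_first_row(n)
    log_denom = sum(math.log(theta + i) for i in range(n))
    ks = np.arange(n + 1)
    return ls + ks * math.log(theta) - log_denom


def count_haplotypes(X: np.ndarray) -> int:
    """Distinct sequences on complete-deletion columns."""
    Xc = _complete_columns(X)
    return len({row.tobytes() for row in Xc})


def fus_Fs(aln: LocusAlignment | np.ndarray) -> float | None:
    """Fu's Fs = ln(S'/(1-S')) with S' = P(K >= k_obs | theta=pi_total, n).

    Returns None when the data are monomorphic (theta = 0 or a single
    haplotype); signed infinity when S' underflows to 0 or 1.
    """
    X = aln if isinstance(aln, np.ndarray) else encode(aln)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need >= 3 sequences")
    pi_total, _ = mean_pairwise_differences(X)
    k_obs = count_haplotypes(X)
    if pi_total == 0 or k_obs <= 1:
        return None
    logp = ewens_log_pmf(n, pi_total)
    from scipy.special import logsumexp

    log_sp = logsumexp(logp[k_obs:])
    log_1m = logsumexp(logp[:k_obs]) if k_obs > 0 else -np.inf
    if not np.isfinite(log_sp):
        return -math.inf
    if not np.isfinite(log_1m):
        return math.inf
    return float(log_sp - log_1m)


# ---------------------------------------------------------------------------
# Table-1-style report
# ---------------------------------------------------------------------------

@dataclass
class DiversityReport:
    dataset_label: str
    population: str
    m: int
    m_star: int
    Gdiv: float
    pi: float
    pi_CI: tuple[float, float]
    pi_star: float | None
    pi_star_CI: tuple[float, float] | None
    tajima_D: float | None
    fu_Fs: float | None
    S: int
    n_eff: int

    def as_row(self) -> dict:
        fmt = lambda v, d: (round(v, d) if v is not None else "n/a")
        return {
            "dataset": self.dataset_label,
            "population": self.population,
            "m": self.m,
            "m_star": self.m_star,
            "Gdiv": round(self.Gdiv, 3),
            "pi": round(self.pi, 4),
            "pi_CI_low": round(self.pi_CI[0], 4),
            "pi_CI_high": round(self.pi_CI[1], 4),
            "pi_star": fmt(self.pi_star, 4),
            "pi_star_CI_low": fmt(self.pi_star_CI[0] if self.pi_star_CI else None, 4),
            "pi_star_CI_high": fmt(self.pi_star_CI[1] if self.pi_star_CI else None, 4),
            "tajima_D": fmt(self.tajima_D, 4),
            "fu_Fs": fmt(self.fu_Fs, 3),
            "S": self.S,
            "n_eff": self.n_eff,
        }


def diversity_table(
    ds: MultilocusDataset,
    dataset_label: str = "dataset",
    missing_policy: str = "drop_incomplete",
    clone_missing_mode: str = "strict",
    ci_method: str = "bootstrap_sequences",
    reps: int = 1000,
    seed: int | None = None,
) -> list[DiversityReport]:
    """One Table-1-style row per population.

    Statistics run on the concatenated alignment. Tajima's D and Fu's Fs
    are computed on clone-corrected sequences and reported n/a for
    populations with fewer than three genotypes. Empty or singleton
    populations are skipped.
    """
    concat, _ = concatenate(ds, missing_policy)
    pops = ds.populations()
    reports = []
    for pi_seed_offset, (pop, sample_ids) in enumerate(pops.items()):
        sub = concat.subset(sample_ids)
        if sub.n_samples < 2:
            continue
        unique, clone_map = clone_correct(sub, clone_missing_mode)
        m, m_star = sub.n_samples, unique.n_samples
        X = encode(sub)
        pi, n_eff = nucleotide_diversity(X)
        sub_seed = None if seed is None else seed + pi_seed_offset
        ci = pi_confidence_interval(X, ci_method, reps, sub_seed)
        if m_star >= 2:
            Xs = encode(unique)
            pi_star, _ = nucleotide_diversity(Xs)
            ci_star = pi_confidence_interval(
                Xs, ci_method, reps,
                None if sub_seed is None else sub_seed + 10_000,
            )
        else:
            Xs, pi_star, ci_star = None, None, None
        if m_star >= 3:
            D = tajimas_D(Xs)
            Fs = fus_Fs(Xs)
        else:
            D = Fs = None
        reports.append(
            DiversityReport(
                dataset_label, pop, m, m_star, gdiv(m, m_star),
                pi, ci, pi_star, ci_star, D, Fs,
                segregating_sites(X), n_eff,
            )
        )
    return reports
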