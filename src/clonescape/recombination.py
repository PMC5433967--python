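"""Recombination detection in clonal multilocus data.

Three complementary signals:

* the four-gamete test (4GT): pairs of biallelic sites exhibiting all
  four allele combinations imply recombination or recurrent mutation;
* the Hudson–Kaplan lower bound Rm on the number of recombination
  events, from non-overlapping incompatible intervals;
* the index of association I_A and its locus-standardized form r̄_d on
  multilocus genotypes, with a within-locus allele-permutation null.

The suite applies these hierarchically: within each lineage and with all
lineages pooled, on clone-corrected data by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .seqio import LocusAlignment, MultilocusDataset, clone_correct, concatenate, _wildcard_collapse
from .diversity import encode


# ---------------------------------------------------------------------------
# Four-gamete test and Hudson–Kaplan Rm
# ---------------------------------------------------------------------------

def biallelic_sites(aln: LocusAlignment | np.ndarray) -> list[int]:
    """0-based indices of sites with exactly two determinate states.

    Gaps/N are excluded as states; sequences missing at a site simply do
    not vote there.
    """
    X = aln if isinstance(aln, np.ndarray) else encode(aln)
    out = []
    for i in range(X.shape[1]):
        col = X[:, i]
        states = np.unique(col[col >= 0])
        if len(states) == 2:
            out.append(i)
    return out


def four_gamete_pairs(aln: LocusAlignment | np.ndarray) -> list[tuple[int, int]]:
    """Unordered biallelic site pairs showing all four gametes.

    Only sequences determinate at both sites contribute gametes.
    """
    X = aln if isinstance(aln, np.ndarray) else encode(aln)
    sites = biallelic_sites(X)
    pairs = []
    for a, b in combinations(sites, 2):
        ca, cb = X[:, a], X[:, b]
        ok = (ca >= 0) & (cb >= 0)
        gametes = {(int(x), int(y)) for x, y in zip(ca[ok], cb[ok])}
        if len(gametes) == 4:
            pairs.append((a, b))
    return pairs


def hudson_kaplan_Rm(incompatible_pairs: list[tuple[int, int]]) -> int:
    """Minimum number of recombination events (Hudson & Kaplan, 1985).

    Each incompatible pair (i, j), i < j, demands a recombination event
    strictly between the two sites. The classic two-pass interval
    reduction applies: keep only minimal intervals (none containing
    another), then greedily count disjoint intervals left to right —
    intervals sharing an endpoint do not overlap, because the events they
    require lie strictly inside.
    """
    if not incompatible_pairs:
        return 0
    ivals = sorted({(min(a, b), max(a, b)) for a, b in incompatible_pairs})
    minimal = [
        iv for iv in ivals
        if not any(
            other != iv and iv[0] <= other[0] and other[1] <= iv[1]
            for other in ivals
        )
    ]
    minimal.sort(key=lambda iv: iv[1])
    count, cursor = 0, -np.inf
    for left, right in minimal:
        if left >= cursor:
            count += 1
            cursor = right
    return count


# ---------------------------------------------------------------------------
# Multilocus genotypes and the index of association
# ---------------------------------------------------------------------------

@dataclass
class MLGTable:
    """Per-sample, per-locus allele indices (dense from 0; -1 = missing)."""

    samples: list[str]
    loci: list[str]
    alleles: np.ndarray  # (n_samples, n_loci) int

    def complete(self) -> "MLGTable":
        ok = (self.alleles >= 0).all(axis=1)
        return MLGTable(
            [s for s, k in zip(self.samples, ok) if k],
            list(self.loci),
            self.alleles[ok],
        )


def mlg_table(ds: MultilocusDataset, sample_ids: list[str] | None = None) -> MLGTable:
    """Transform per-locus sequences into multilocus genotypes.

    An allele is a distinct locus sequence, with gaps treated as missing
    and sequences differing only at missing positions collapsed together.
    A sample absent from a locus (or all-missing there) gets a missing
    allele.
    """
    samples = sample_ids if sample_ids is not None else ds.samples
    n, p = len(samples), len(ds.loci)
    A = np.full((n, p), -1, dtype=int)
    for j, aln in enumerate(ds.loci):
        present = [
            s for s in samples
            if s in aln.records and any(c not in "N-" for c in aln.records[s])
        ]  # an entirely missing sequence carries no allele
        classes = _wildcard_collapse(
            {s: aln.records[s] for s in present}, frozenset("N-")
        )
        allele_of: dict[str, int] = {}
        for k, (_, members) in enumerate(classes):
            for s in members:
                allele_of[s] = k
        for i, s in enumerate(samples):
            A[i, j] = allele_of.get(s, -1)
    return MLGTable(list(samples), list(ds.locus_names), A)


def _pair_mismatch(alleles: np.ndarray) -> np.ndarray:
    """Binary per-locus mismatch indicators over all sample pairs.

    Returns a (n_pairs, n_loci) float matrix.
    """
    n = alleles.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    return (alleles[iu] != alleles[ju]).astype(float)


def _ia_stats(d: np.ndarray) -> tuple[float, float]:
    """(IA, rbarD) from a pair x locus mismatch matrix."""
    var_j = d.var(axis=0, ddof=1)
    keep = var_j > 0
    V_E = var_j[keep].sum()
    if V_E == 0:
        return np.nan, np.nan
    V_O = d.sum(axis=1).var(ddof=1)
    IA = V_O / V_E - 1.0
    sd = np.sqrt(var_j[keep])
    denom = 2.0 * (np.outer(sd, sd).sum() - (sd**2).sum()) / 2.0
    rbarD = (V_O - V_E) / denom if denom > 0 else np.nan
    return float(IA), float(rbarD)


def index_of_association(
    mlg: MLGTable,
    n_permutations: int = 999,
    seed: int | None = None,
) -> tuple[float, float, float, float]:
    """I_A, r̄_d and their permutation p-values.

    Incomplete multilocus genotypes are dropped. The null shuffles alleles
    among samples independently within each locus; p = (1 + #{perm >=
    observed}) / (1 + n_permutations). Monomorphic loci contribute no
    variance and drop out of the r̄_d denominator; if every locus is
    monomorphic the statistics are undefined (NaN).
    """
    mlg = mlg.complete()
    n, p = mlg.alleles.shape
    if p < 2:
        raise ValueError("need >= 2 loci")
    if n < 3:
        raise ValueError("need >= 3 complete multilocus genotypes")
    d = _pair_mismatch(mlg.alleles)
    IA, rbarD = _ia_stats(d)
    if not np.isfinite(IA):
        return np.nan, np.nan, np.nan, np.nan
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, k=1)
    ge_ia = ge_rd = 0
    perm = mlg.alleles.copy()
    for _ in range(n_permutations):
        for j in range(p):
            perm[:, j] = rng.permutation(perm[:, j])
        dp = (perm[iu] != perm[ju]).astype(float)
        ia_p, rd_p = _ia_stats(dp)
        if np.isfinite(ia_p) and ia_p >= IA:
            ge_ia += 1
        if np.isfinite(rd_p) and rd_p >= rbarD:
            ge_rd += 1
    p_IA = (1 + ge_ia) / (1 + n_permutations)
    p_rbarD = (
        (1 + ge_rd) / (1 + n_permutations) if np.isfinite(rbarD) else np.nan
    )
    return IA, rbarD, p_IA, p_rbarD


# ---------------------------------------------------------------------------
# Hierarchical suite
# ---------------------------------------------------------------------------

@dataclass
class RecombinationReport:
    scope: str
    n_samples: int
    n_genotypes: int
    n_biallelic_sites: int
    n_incompatible_pairs: int
    Rm: int
    IA: float | None
    rbarD: float | None
    p_IA: float | None
    p_rbarD: float | None
    n_permutations: int
    seed: int | None

    def as_row(self) -> dict:
        fmt = lambda v, d: (round(v, d) if v is not None and np.isfinite(v) else "n/a")
        return {
            "scope": self.scope,
            "n_samples": self.n_samples,
            "n_genotypes": self.n_genotypes,
            "n_biallelic_sites": self.n_biallelic_sites,
            "n_incompatible_pairs": self.n_incompatible_pairs,
            "Rm": self.Rm,
            "IA": fmt(self.IA, 4),
            "rbarD": fmt(self.rbarD, 4),
            "p_IA": fmt(self.p_IA, 4),
            "p_rbarD": fmt(self.p_rbarD, 4),
            "n_permutations": self.n_permutations,
        }


def recombination_suite(
    ds: MultilocusDataset,
    clone_correct_first: bool = True,
    n_permutations: int = 999,
    seed: int | None = None,
    missing_policy: str = "drop_incomplete",
) -> list[RecombinationReport]:
    """4GT/Rm and I_A reports per lineage and for all lineages pooled.

    4GT and Rm run on the concatenated sequences (clone-corrected when
    flagged); I_A and r̄_d run on multilocus genotypes of the same
    genotype set, and are n/a for scopes with fewer than three genotypes
    or fewer than two loci.
    """
    pops = ds.populations()
    scopes = [(f"within:{p}", ids) for p, ids in pops.items()]
    scopes.append(("pooled", [s for ids in pops.values() for s in ids]))
    concat, _ = concatenate(ds, missing_policy)
    reports = []
    for k, (scope, sample_ids) in enumerate(scopes):
        sub = concat.subset(sample_ids)
        if sub.n_samples < 2:
            continue
        if clone_correct_first:
            unique, _ = clone_correct(sub, "strict")
        else:
            unique = sub
        genotype_ids = unique.sample_ids
        X = encode(unique)
        sites = biallelic_sites(X)
        pairs = four_gamete_pairs(X)
        rm = hudson_kaplan_Rm(pairs)
        IA = rbarD = p_IA = p_rbarD = None
        scope_seed = None if seed is None else seed + k
        if len(genotype_ids) >= 3 and len(ds.loci) >= 2:
            mlg = mlg_table(ds, genotype_ids).complete()
            if mlg.alleles.shape[0] >= 3:
                IA, rbarD, p_IA, p_rbarD = index_of_association(
                    mlg, n_permutations, scope_seed
                )
        reports.append(
            RecombinationReport(
                scope, sub.n_samples, len(genotype_ids), len(sites),
                len(pairs), rm, IA, rbarD, p_IA, p_rbarD,
                n_permutations, scope_seed,
            )
        )
    return reports


def incompatibility_matrix(aln: LocusAlignment | np.ndarray) -> pd.DataFrame:
    """Per-pair incompatibility table (site_i, site_j, incompatible)."""
    X = aln if isinstance(aln, np.ndarray) else encode(aln)
    bad = set(four_gamete_pairs(X))
    sites = biallelic_sites(X)
    rows = [
        {"site_i": a, "site_j": b, "incompatible": (a, b) in bad}
        for a, b in combinations(sites, 2)
    ]
    return pd.DataFrame(rows, columns=["site_i", "site_j", "incompatible"])
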