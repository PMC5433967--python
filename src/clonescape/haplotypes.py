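"""Haplotype collapsing and TCS-style statistical-parsimony networks.

Aligned haploid sequences are collapsed into haplotypes (gaps treated as
missing data by default), joined into a minimum-spanning network whose
multi-step links are expanded through inferred median nodes, and
cross-tabulated against phenotype labels (chemotype, morphotype).

The connection limit follows the statistical-parsimony criterion: the
largest number of mutational steps that can still be attributed to
unique (non-superimposed) substitutions with the requested confidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .seqio import DETERMINATE, LocusAlignment, _wildcard_collapse

GAP_MODES = ("missing", "fifth_state")
#: characters ignored in the ``missing`` gap mode
_MISSING_CHARS = frozenset("N-")


@dataclass
class Haplotype:
    """A collapsed haplotype (or an inferred median node, frequency 0)."""

    hap_id: str
    sequence: str
    members: list[str] = field(default_factory=list)
    is_median: bool = False

    @property
    def frequency(self) -> int:
        return len(self.members)


def collapse_haplotypes(
    aln: LocusAlignment, gap_mode: str = "missing"
) -> list[Haplotype]:
    """Collapse aligned sequences into haplotypes.

    Under ``missing``, positions where either sequence has ``-`` or ``N``
    are ignored in the identity comparison (resolved transitively by
    merging into the most-complete representative); ``fifth_state``
    requires exact identity. Haplotypes are numbered H1, H2, ... by
    descending frequency, ties broken lexicographically by representative
    sequence.
    """
    if gap_mode not in GAP_MODES:
        raise ValueError(f"unknown gap_mode: {gap_mode}")
    wildcard = _MISSING_CHARS if gap_mode == "missing" else frozenset()
    classes = _wildcard_collapse(aln.records, wildcard)
    classes.sort(key=lambda c: (-len(c[1]), c[0]))
    return [
        Haplotype(f"H{i + 1}", cons, list(members))
        for i, (cons, members) in enumerate(classes)
    ]


def pairwise_steps(h1: Haplotype, h2: Haplotype, gap_mode: str = "missing") -> int:
    """Mutational steps (Hamming distance) between two haplotypes.

    ``missing`` counts only columns where both characters are determinate;
    ``fifth_state`` counts every differing column.
    """
    if len(h1.sequence) != len(h2.sequence):
        raise ValueError("haplotype length mismatch")
    if gap_mode == "missing":
        return sum(
            1
            for a, b in zip(h1.sequence, h2.sequence)
            if a in DETERMINATE and b in DETERMINATE and a != b
        )
    return sum(1 for a, b in zip(h1.sequence, h2.sequence) if a != b)


# ---------------------------------------------------------------------------
# Statistical parsimony connection limit
# ---------------------------------------------------------------------------

def parsimony_probability(j: int, seq_length: int) -> float:
    """Probability that j observed differences over ``seq_length`` sites all
    represent single substitutions (no multiple hits at the differing sites).

    Substitutions per site are modelled as Poisson with Jukes–Cantor state
    change; the per-site substitution intensity is the maximum-likelihood
    estimate from the observed difference fraction j/m. A site that differs
    is parsimonious when exactly one event occurred there, and the j
    differing sites are treated as independent.
    """
    if j <= 0:
        return 1.0
    m = seq_length
    p = j / m
    if p >= 0.75:  # beyond Jukes–Cantor saturation
        return 0.0
    lam = -0.75 * math.log1p(-4.0 * p / 3.0)
    p_diff = 0.75 * (1.0 - math.exp(-4.0 * lam / 3.0))
    p_single = lam * math.exp(-lam)
    return (p_single / p_diff) ** j


def parsimony_connection_limit(
    n_haplotypes: int,
    seq_length: int,
    confidence: float = 0.95,
    override: int | None = None,
) -> int:
    """Largest step count still parsimonious at the given confidence.

    A user-supplied ``override`` wins regardless of the inputs. The limit
    is floored at 1: single-step connections are always admitted.
    """
    if override is not None:
        return int(override)
    if seq_length < 1:
        raise ValueError("seq_length must be >= 1")
    j = 1
    while j < seq_length and parsimony_probability(j + 1, seq_length) >= confidence:
        j += 1
    return j


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeNetwork:
    """Observed + median haplotypes joined by unit mutational-step edges."""

    nodes: dict[str, Haplotype]
    graph: nx.Graph
    connection_limit: int

    @property
    def observed(self) -> list[Haplotype]:
        return [h for h in self.nodes.values() if not h.is_median]

    @property
    def medians(self) -> list[Haplotype]:
        return [h for h in self.nodes.values() if h.is_median]

    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.graph)]

    def ancestral_haplotype(self) -> str:
        """Heuristic root: observed haplotype maximizing frequency x degree
        (degree floored at 1 so isolated high-frequency haplotypes still
        score). This mimics, but does not replicate, TCS outgroup weights."""
        best = min(
            self.observed,
            key=lambda h: (
                -h.frequency * max(self.graph.degree(h.hap_id), 1),
                h.hap_id,
            ),
        )
        return best.hap_id


def _median_path(a: Haplotype, b: Haplotype, gap_mode: str) -> list[str]:
    """Intermediate sequences from a to b, flipping differing determinate
    columns one at a time in left-to-right column order."""
    cols = []
    for i, (x, y) in enumerate(zip(a.sequence, b.sequence)):
        if gap_mode == "missing" and (x in _MISSING_CHARS or y in _MISSING_CHARS):
            continue
        if x != y:
            cols.append(i)
    seq = list(a.sequence)
    out = []
    for i in cols[:-1]:
        seq[i] = b.sequence[i]
        out.append("".join(seq))
    return out


def build_parsimony_network(
    haps: list[Haplotype],
    limit: int,
    gap_mode: str = "missing",
) -> HaplotypeNetwork:
    """Greedy minimum-spanning network with median-node expansion.

    Candidate pairs are processed in order of increasing step distance
    (ties: higher combined frequency first, then lexicographic ids). Within
    one distance class, a pair is admitted if its endpoints lay in distinct
    components at the start of the class — so alternative equal-distance
    connections are retained as reticulations. Admitted multi-step links
    are expanded through distance−1 inferred median nodes, leaving every
    rendered edge at exactly one step.
    """
    if not haps:
        raise ValueError("no haplotypes")
    nodes = {h.hap_id: h for h in haps}
    dist = {}
    for i, a in enumerate(haps):
        for b in haps[i + 1:]:
            u, v = sorted((a.hap_id, b.hap_id))
            dist[(u, v)] = pairwise_steps(a, b, gap_mode)
    graph = nx.Graph()
    for h in haps:
        graph.add_node(h.hap_id)
    admitted: list[tuple[str, str, int]] = []
    # union-find over observed haplotypes
    parent = {h.hap_id: h.hap_id for h in haps}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    pairs = sorted(
        dist.items(),
        key=lambda kv: (
            kv[1],
            -(nodes[kv[0][0]].frequency + nodes[kv[0][1]].frequency),
            kv[0],
        ),
    )
    i = 0
    while i < len(pairs):
        d = pairs[i][1]
        if d > limit:
            break
        level = [kv for kv in pairs[i:] if kv[1] == d]
        i += len(level)
        if d == 0:
            continue  # identical under gap equivalence; already collapsed
        comp_at_start = {h: find(h) for h in parent}
        merges = []
        for (u, v), _ in level:
            if comp_at_start[u] != comp_at_start[v]:
                admitted.append((u, v, d))
                merges.append((u, v))
        for u, v in merges:
            ru, rv = find(u), find(v)
            if ru != rv:
                parent[rv] = ru
    # expand admitted links through median nodes
    m_count = 0
    for u, v, d in admitted:
        if d == 1:
            graph.add_edge(u, v, steps=1)
            continue
        prev = u
        for seq in _median_path(nodes[u], nodes[v], gap_mode):
            m_count += 1
            mid = f"M{m_count}"
            nodes[mid] = Haplotype(mid, seq, [], is_median=True)
            graph.add_node(mid)
            graph.add_edge(prev, mid, steps=1)
            prev = mid
        graph.add_edge(prev, v, steps=1)
    return HaplotypeNetwork(nodes, graph, limit)


# ---------------------------------------------------------------------------
# Phenotype cross-tabulation
# ---------------------------------------------------------------------------

def phenotype_crosstab(
    haps: list[Haplotype], meta: pd.DataFrame
) -> pd.DataFrame:
    """Contingency counts of haplotype x (chemotype, morphotype).

    Members missing from the metadata are counted as ``unknown`` (a warning
    column ``n_unknown_samples`` records how many). ``chem_mixed`` /
    ``morph_mixed`` flag haplotypes containing both known classes.
    """
    lookup = meta.set_index("sample_id")[["chemotype", "morphotype"]]
    rows = []
    for h in haps:
        if h.is_median:
            continue
        chem = {"UVplus": 0, "UVminus": 0, "unknown": 0}
        morph = {"cylindrical_hollow": 0, "flat_wide": 0, "unknown": 0}
        unknown_samples = 0
        for sid in h.members:
            if sid in lookup.index:
                c, m = lookup.loc[sid, "chemotype"], lookup.loc[sid, "morphotype"]
            else:
                unknown_samples += 1
                c = m = "unknown"
            chem[c if c in chem else "unknown"] += 1
            morph[m if m in morph else "unknown"] += 1
        rows.append(
            {
                "hap_id": h.hap_id,
                "frequency": h.frequency,
                "UVplus": chem["UVplus"],
                "UVminus": chem["UVminus"],
                "chem_unknown": chem["unknown"],
                "cylindrical_hollow": morph["cylindrical_hollow"],
                "flat_wide": morph["flat_wide"],
                "morph_unknown": morph["unknown"],
                "chem_mixed": chem["UVplus"] > 0 and chem["UVminus"] > 0,
                "morph_mixed": morph["cylindrical_hollow"] > 0
                and morph["flat_wide"] > 0,
                "n_unknown_samples": unknown_samples,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def network_node_table(net: HaplotypeNetwork, meta: pd.DataFrame | None = None):
    tallies = {}
    if meta is not None:
        ct = phenotype_crosstab(net.observed, meta)
        tallies = ct.set_index("hap_id").to_dict("index")
    attrs = {}
    for hap_id, h in net.nodes.items():
        a = {
            "frequency": h.frequency,
            "median": int(h.is_median),
        }
        if hap_id in tallies:
            a["UVplus"] = int(tallies[hap_id]["UVplus"])
            a["UVminus"] = int(tallies[hap_id]["UVminus"])
        attrs[hap_id] = a
    return attrs


def write_gml(net: HaplotypeNetwork, path, meta: pd.DataFrame | None = None) -> None:
    g = net.graph.copy()
    nx.set_node_attributes(g, network_node_table(net, meta))
    nx.write_gml(g, str(path))


def write_dot(net: HaplotypeNetwork, path, meta: pd.DataFrame | None = None) -> None:
    attrs = network_node_table(net, meta)
    lines = ["graph haplotype_network {"]
    for node, a in attrs.items():
        shape = "point" if a["median"] else "circle"
        label = node if not a["median"] else ""
        lines.append(
            f'  "{node}" [label="{label}" shape={shape} '
            f'frequency={a["frequency"]}];'
        )
    for u, v in sorted(net.graph.edges()):
        lines.append(f'  "{u}" -- "{v}";')
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
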