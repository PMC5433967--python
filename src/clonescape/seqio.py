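"""Alignment and metadata I/O for haploid multilocus sequence data.

This module owns the on-disk interface of the package: per-locus FASTA
alignments, a sample-metadata TSV, and the bookkeeping transformations
that precede every downstream statistic — ambiguous-column removal,
locus concatenation, and clone correction.

Conventions
-----------
* Sequences are uppercase-normalized on ingest; RNA ``U`` becomes ``T``.
* All column coordinates are 0-based, half-open.
* ``N`` and ``-`` are the missing-data characters; every other non-ACGT
  letter is an IUPAC ambiguity code.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DETERMINATE = frozenset("ACGT")
MISSING = frozenset("N-")
#: IUPAC ambiguity letters, N included (it is removed by column stripping
#: but tolerated as missing data everywhere else).
IUPAC_AMBIGUOUS = frozenset("RYSWKMBDHVN")
VALID_CHARS = DETERMINATE | MISSING | IUPAC_AMBIGUOUS

CHEMOTYPES = ("UVplus", "UVminus", "unknown")
MORPHOTYPES = ("cylindrical_hollow", "flat_wide", "unknown")

METADATA_COLUMNS = [
    "sample_id",
    "population",
    "chemotype",
    "morphotype",
    "locality",
    "lat",
    "lon",
]


class AlignmentError(ValueError):
    """Raised for malformed or degenerate alignments."""


@dataclass
class LocusAlignment:
    """One locus: aligned haploid sequences keyed by sample id."""

    locus_name: str
    length: int
    records: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm: dict[str, str] = {}
        for sid, seq in self.records.items():
            s = seq.upper().replace("U", "T")
            if len(s) != self.length:
                raise AlignmentError(
                    f"unaligned input: sample {sid!r} has length {len(s)}, "
                    f"expected {self.length}"
                )
            bad = set(s) - VALID_CHARS
            if bad:
                raise AlignmentError(
                    f"invalid characters {sorted(bad)} in sample {sid!r}"
                )
            norm[sid] = s
        self.records = norm

    @property
    def sample_ids(self) -> list[str]:
        return list(self.records)

    @property
    def n_samples(self) -> int:
        return len(self.records)

    def subset(self, sample_ids: Iterable[str]) -> "LocusAlignment":
        """Restrict to the given samples, preserving this alignment's order."""
        keep = set(sample_ids)
        return LocusAlignment(
            self.locus_name,
            self.length,
            {s: q for s, q in self.records.items() if s in keep},
        )

    def column(self, i: int) -> str:
        return "".join(seq[i] for seq in self.records.values())


@dataclass
class MultilocusDataset:
    """Several loci over a shared sample set plus sample metadata."""

    loci: list[LocusAlignment]
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        names = [a.locus_name for a in self.loci]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate locus names: {names}")

    @property
    def locus_names(self) -> list[str]:
        return [a.locus_name for a in self.loci]

    @property
    def samples(self) -> list[str]:
        """Samples present in at least one locus, in first-seen order."""
        seen: dict[str, None] = {}
        for aln in self.loci:
            for sid in aln.records:
                seen.setdefault(sid)
        return list(seen)

    def populations(self) -> dict[str, list[str]]:
        """Map population label -> sample ids (metadata order)."""
        out: dict[str, list[str]] = {}
        present = set(self.samples)
        for _, row in self.metadata.iterrows():
            if row["sample_id"] in present:
                out.setdefault(str(row["population"]), []).append(row["sample_id"])
        return out


# ---------------------------------------------------------------------------
# FASTA / TSV ingest and export
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, locus_name: str | None = None) -> LocusAlignment:
    """Read an aligned FASTA file into a :class:`LocusAlignment`.

    All records must share one length ("unaligned input" otherwise) and
    ids must be unique ("duplicate sample").
    """
    path = Path(path)
    if locus_name is None:
        locus_name = path.stem
    records: dict[str, str] = {}
    length: int | None = None
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise AlignmentError(f"duplicate sample: {rec.id!r} in {path}")
        seq = str(rec.seq)
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise AlignmentError(
                f"unaligned input: {rec.id!r} has length {len(seq)}, "
                f"expected {length} in {path}"
            )
        records[rec.id] = seq
    if length is None:
        raise AlignmentError(f"empty FASTA: {path}")
    return LocusAlignment(locus_name, length, records)


def write_fasta(aln: LocusAlignment, path: str | Path) -> None:
    """Write an alignment as FASTA wrapped at 80 columns."""
    recs = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in aln.records.items()
    ]
    buf = io.StringIO()
    writer = SeqIO.FastaIO.FastaWriter(buf, wrap=80)
    writer.write_file(recs)
    Path(path).write_text(buf.getvalue())


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample-metadata TSV (header: sample_id population chemotype
    morphotype locality lat lon). Unknown phenotype values are normalized to
    ``unknown``; one row per sample id is enforced."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in METADATA_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    for col in ("lat", "lon"):
        if col not in df.columns:
            df[col] = pd.NA
    df = df[METADATA_COLUMNS].copy()
    df["chemotype"] = df["chemotype"].fillna("unknown").where(
        df["chemotype"].isin(CHEMOTYPES), "unknown"
    )
    df["morphotype"] = df["morphotype"].fillna("unknown").where(
        df["morphotype"].isin(MORPHOTYPES), "unknown"
    )
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id rows in metadata: {dups}")
    return df


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Column filtering
# ---------------------------------------------------------------------------

def strip_ambiguous_columns(
    aln: LocusAlignment,
    policy: str = "drop_iupac",
    gap_threshold: float = 0.5,
) -> tuple[LocusAlignment, list[int]]:
    """Remove alignment columns containing IUPAC ambiguity characters.

    ``drop_iupac`` removes every column in which any sequence carries an
    ambiguity code (N included); ``drop_iupac_and_gapfraction`` additionally
    removes columns whose gap fraction exceeds ``gap_threshold``. Returns
    the filtered alignment and the removed column indices (0-based,
    original coordinates).
    """
    if policy not in ("drop_iupac", "drop_iupac_and_gapfraction"):
        raise ValueError(f"unknown policy: {policy}")
    n = aln.n_samples
    removed: list[int] = []
    for i in range(aln.length):
        col = aln.column(i)
        if any(c in IUPAC_AMBIGUOUS for c in col):
            removed.append(i)
        elif policy == "drop_iupac_and_gapfraction" and n:
            if col.count("-") / n > gap_threshold:
                removed.append(i)
    if len(removed) == aln.length:
        raise AlignmentError("empty alignment: all columns removed")
    drop = set(removed)
    keep = [i for i in range(aln.length) if i not in drop]
    records = {
        sid: "".join(seq[i] for i in keep) for sid, seq in aln.records.items()
    }
    return LocusAlignment(aln.locus_name, len(keep), records), removed


# ---------------------------------------------------------------------------
# Concatenation
# ---------------------------------------------------------------------------

def concatenate(
    ds: MultilocusDataset,
    missing_policy: str = "drop_incomplete",
    name: str = "concat",
) -> tuple[LocusAlignment, list[tuple[str, int, int]]]:
    """Concatenate loci per sample in the dataset's locus order.

    ``drop_incomplete`` keeps only samples present in every locus;
    ``pad_with_N`` fills absent loci with N blocks. Returns the
    concatenated alignment and locus boundary offsets as
    ``(locus_name, start, end)`` half-open spans.
    """
    if not ds.loci:
        raise ValueError("no loci to concatenate")
    if missing_policy not in ("drop_incomplete", "pad_with_N"):
        raise ValueError(f"unknown missing_policy: {missing_policy}")
    offsets: list[tuple[str, int, int]] = []
    pos = 0
    for aln in ds.loci:
        offsets.append((aln.locus_name, pos, pos + aln.length))
        pos += aln.length
    if missing_policy == "drop_incomplete":
        samples = [
            s for s in ds.samples if all(s in a.records for a in ds.loci)
        ]
        if not samples:
            raise AlignmentError("no complete samples")
    else:
        samples = ds.samples
    records = {
        s: "".join(
            a.records.get(s, "N" * a.length) for a in ds.loci
        )
        for s in samples
    }
    return LocusAlignment(name, pos, records), offsets


# ---------------------------------------------------------------------------
# Clone correction and wildcard collapsing
# ---------------------------------------------------------------------------

def _wildcard_collapse(
    records: Mapping[str, str], wildcard: frozenset[str]
) -> list[tuple[str, list[str]]]:
    """Group sequences identical up to wildcard positions.

    Sequences join, in input order, the first existing class whose running
    consensus they match at every mutually determinate position; the class
    consensus then absorbs their determinate characters, so chains of
    partially missing sequences resolve transitively toward the
    most-complete representative. Returns ``(consensus, member_ids)`` per
    class, input order preserved.
    """
    classes: list[tuple[list[str], list[str]]] = []  # (consensus chars, members)
    for sid, seq in records.items():
        placed = False
        for cons, members in classes:
            ok = True
            for a, b in zip(cons, seq):
                if a not in wildcard and b not in wildcard and a != b:
                    ok = False
                    break
            if ok:
                for i, b in enumerate(seq):
                    if cons[i] in wildcard and b not in wildcard:
                        cons[i] = b
                members.append(sid)
                placed = True
                break
        if not placed:
            classes.append((list(seq), [sid]))
    return [("".join(cons), members) for cons, members in classes]


def clone_correct(
    aln: LocusAlignment, missing_mode: str = "strict"
) -> tuple[LocusAlignment, dict[str, list[str]]]:
    """Collapse identical sequences into one genotype per clone class.

    ``strict`` treats N/- as ordinary characters; ``missing_matches_any``
    merges sequences that differ only where one carries N. The class
    representative is the first member in input order; its id keys the
    clone map. The returned alignment has one record per genotype (m*),
    keeping the representative's observed sequence.
    """
    if missing_mode == "strict":
        groups: dict[str, list[str]] = {}
        for sid, seq in aln.records.items():
            groups.setdefault(seq, []).append(sid)
        classes = [(seq, members) for seq, members in groups.items()]
    elif missing_mode == "missing_matches_any":
        classes = _wildcard_collapse(aln.records, frozenset("N"))
    else:
        raise ValueError(f"unknown missing_mode: {missing_mode}")
    unique_records = {}
    clone_map: dict[str, list[str]] = {}
    for cons, members in classes:
        rep = members[0]
        # under wildcard matching keep the class consensus (most-complete
        # sequence): final consensuses are pairwise incompatible, so the
        # correction is idempotent
        unique_records[rep] = cons if missing_mode == "missing_matches_any" else aln.records[rep]
        clone_map[rep] = list(members)
    return LocusAlignment(aln.locus_name, aln.length, unique_records), clone_map


def clone_report_frame(clone_map: dict[str, list[str]]) -> pd.DataFrame:
    """Clone classes as a tidy table (genotype_id, sample_id)."""
    rows = [
        {"genotype_id": rep, "sample_id": sid}
        for rep, members in clone_map.items()
        for sid in members
    ]
    return pd.DataFrame(rows, columns=["genotype_id", "sample_id"])
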