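"""Aligned-sequence and strain-metadata IO.

Loci arrive as pre-aligned FASTA files (one per gene).  This module loads
them into :class:`GeneAlignment` objects, concatenates the core loci into a
single partitioned supermatrix, and produces bootstrap pseudo-alignments by
resampling columns.  Strain metadata (host plant, geographic region, and
whether a strain is a *focal* isolate under study or a *reference* strain of
known provenance) is carried in a :class:`MetadataTable`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_CHARS = frozenset(b"ACGT-")
_MISSING_CODE = 255

# nucleotide -> small integer code; gap and ambiguity share the "missing" code
_CODE_LUT = np.full(256, _MISSING_CODE, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _CODE_LUT[_c] = _i


@dataclass
class GeneAlignment:
    """One aligned locus: ordered strains x aligned columns.

    ``data`` is a 2-D uint8 array of ASCII codes over ``{A,C,G,T,-,N}``.
    """

    locus_name: str
    strain_ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.uint8)
        if self.data.ndim != 2:
            raise ValueError("alignment data must be 2-D (strains x sites)")
        if len(self.strain_ids) != self.data.shape[0]:
            raise ValueError("strain_ids length does not match row count")
        if len(set(self.strain_ids)) != len(self.strain_ids):
            raise ValueError(f"duplicate strain ids in locus {self.locus_name!r}")
        if self.data.shape[1] < 1:
            raise ValueError("alignment must have at least one site")

    @property
    def n_strains(self) -> int:
        return self.data.shape[0]

    @property
    def length(self) -> int:
        return self.data.shape[1]

    def codes(self) -> np.ndarray:
        """Integer codes: A,C,G,T -> 0..3; gap/N -> 255 (missing)."""
        return _CODE_LUT[self.data]

    def sequence(self, strain_id: str) -> str:
        row = self.data[self.strain_ids.index(strain_id)]
        return row.tobytes().decode("ascii")

    def subset(self, strain_ids: list[str]) -> "GeneAlignment":
        idx = [self.strain_ids.index(s) for s in strain_ids]
        return GeneAlignment(self.locus_name, list(strain_ids), self.data[idx])


@dataclass
class PartitionMap:
    """Locus boundaries in concatenated coordinates, 0-based half-open."""

    intervals: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        pos = 0
        for name, start, end in self.intervals:
            if start != pos or end <= start:
                raise ValueError("partition intervals must be contiguous and non-empty")
            pos = end

    @property
    def total_length(self) -> int:
        return self.intervals[-1][2] if self.intervals else 0

    def slice(self, aln: GeneAlignment, locus_name: str) -> GeneAlignment:
        for name, start, end in self.intervals:
            if name == locus_name:
                return GeneAlignment(locus_name, list(aln.strain_ids), aln.data[:, start:end])
        raise KeyError(locus_name)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("locus\tstart\tend\n")
            for name, start, end in self.intervals:
                fh.write(f"{name}\t{start}\t{end}\n")

    @classmethod
    def read(cls, path) -> "PartitionMap":
        df = pd.read_csv(path, sep="\t")
        return cls([(r.locus, int(r.start), int(r.end)) for r in df.itertuples()])


def _normalize_seq(seq: str) -> bytes:
    raw = seq.upper().encode("ascii")
    arr = np.frombuffer(raw, dtype=np.uint8).copy()
    valid = np.isin(arr, np.frombuffer(b"ACGT-", dtype=np.uint8))
    arr[~valid] = ord("N")
    return arr.tobytes()


def read_alignment(path, locus_name: str | None = None) -> GeneAlignment:
    """Read an aligned FASTA file.

    Residues are uppercased; anything outside ``{A,C,G,T,-}`` becomes ``N``.
    Ragged records and duplicate ids are rejected.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    ids: list[str] = []
    rows: list[bytes] = []
    length = None
    for rec in records:
        if rec.id in ids:
            raise ValueError(f"duplicate strain id {rec.id!r} in {path}")
        seq = _normalize_seq(str(rec.seq))
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise ValueError(
                f"record {rec.id!r} has length {len(seq)}, expected {length} ({path})"
            )
        ids.append(rec.id)
        rows.append(seq)
    if length == 0:
        raise ValueError(f"zero-length alignment in {path}")
    name = locus_name if locus_name is not None else _stem(path)
    data = np.frombuffer(b"".join(rows), dtype=np.uint8).reshape(len(rows), length)
    return GeneAlignment(name, ids, data.copy())


def _stem(path) -> str:
    import os

    base = os.path.basename(str(path))
    return base.rsplit(".", 1)[0] if "." in base else base


def write_alignment(aln: GeneAlignment, path) -> None:
    """Write FASTA, wrapped at 80 columns."""
    records = [
        SeqRecord(Seq(aln.data[i].tobytes().decode("ascii")), id=sid, description="")
        for i, sid in enumerate(aln.strain_ids)
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(records)


def concatenate_core(
    alignments: list[GeneAlignment],
    min_loci: int | None = None,
    missing_policy: str = "gap_fill",
) -> tuple[GeneAlignment, PartitionMap]:
    """Concatenate loci into a supermatrix, matching strains by id.

    Strains present in fewer than ``min_loci`` loci (default: all of them,
    i.e. only strains with the maximum of sequence data are retained) are
    dropped; a retained strain missing from a locus gets a gap block.
    """
    if not alignments:
        raise ValueError("need at least one alignment")
    if missing_policy != "gap_fill":
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if min_loci is None:
        min_loci = len(alignments)
    order: list[str] = []
    counts: dict[str, int] = {}
    for aln in alignments:
        for sid in aln.strain_ids:
            if sid not in counts:
                counts[sid] = 0
                order.append(sid)
            counts[sid] += 1
    kept = [sid for sid in order if counts[sid] >= min_loci]
    if len(kept) < 4:
        raise ValueError(
            f"only {len(kept)} strains present in >= {min_loci} loci; "
            "tree inference needs at least 4"
        )
    total = sum(a.length for a in alignments)
    data = np.full((len(kept), total), ord("-"), dtype=np.uint8)
    intervals = []
    pos = 0
    for aln in alignments:
        end = pos + aln.length
        index = {sid: i for i, sid in enumerate(aln.strain_ids)}
        for row, sid in enumerate(kept):
            if sid in index:
                data[row, pos:end] = aln.data[index[sid]]
        intervals.append((aln.locus_name, pos, end))
        pos = end
    return GeneAlignment("concat", kept, data), PartitionMap(intervals)


def bootstrap_resample(
    aln: GeneAlignment, seed: int | np.random.Generator
) -> GeneAlignment:
    """Draw alignment columns uniformly with replacement (same length)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cols = rng.integers(0, aln.length, size=aln.length)
    return GeneAlignment(aln.locus_name, list(aln.strain_ids), aln.data[:, cols])


ROLES = ("focal", "reference")


@dataclass
class MetadataTable:
    """Per-strain host, region and role (focal vs reference)."""

    df: pd.DataFrame = field(repr=False)

    REQUIRED = ("strain_id", "host", "region", "role")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.df.columns:
                raise ValueError(f"metadata missing column {col!r}")
        if self.df["strain_id"].duplicated().any():
            dups = self.df.loc[self.df["strain_id"].duplicated(), "strain_id"].tolist()
            raise ValueError(f"duplicate strain ids in metadata: {dups}")
        bad = set(self.df["role"]) - set(ROLES)
        if bad:
            raise ValueError(f"unknown roles {sorted(bad)}; allowed: {ROLES}")
        if (self.df["region"].astype(str).str.len() == 0).any():
            raise ValueError("empty region label in metadata")
        self.df = self.df.reset_index(drop=True)

    @classmethod
    def from_rows(cls, rows: list[tuple[str, str, str, str]]) -> "MetadataTable":
        return cls(pd.DataFrame(rows, columns=list(cls.REQUIRED)))

    @classmethod
    def read(cls, path) -> "MetadataTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def role(self, strain_id: str) -> str:
        return self._lookup(strain_id, "role")

    def region(self, strain_id: str) -> str:
        return self._lookup(strain_id, "region")

    def _lookup(self, strain_id: str, col: str) -> str:
        hit = self.df.loc[self.df["strain_id"] == strain_id, col]
        if hit.empty:
            raise KeyError(strain_id)
        return str(hit.iloc[0])

    @property
    def focal_ids(self) -> list[str]:
        return self.df.loc[self.df["role"] == "focal", "strain_id"].tolist()

    @property
    def reference_ids(self) -> list[str]:
        return self.df.loc[self.df["role"] == "reference", "strain_id"].tolist()
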