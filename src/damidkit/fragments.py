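"""GATC fragment maps: the genomic coordinate system of DamID signal.

DpnI cuts methylated GATC between the A and the T (GA^TC), so a motif at
offset ``s`` produces a cut at ``s + 2``.  The intervals between consecutive
cuts tile each chromosome exactly and are the unit at which all DamID
counts and ratios are expressed.  All coordinates are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation import Annotation

MOTIF = "GATC"
CUT_OFFSET = 2  # GA^TC


def find_gatc_sites(sequence: str) -> np.ndarray:
    """Return start offsets of every GATC occurrence (case-insensitive).

    GATC is its own reverse complement, so a single-strand scan is
    strand-complete, and self-overlap is impossible.
    """
    seq = sequence.upper()
    sites = []
    pos = seq.find(MOTIF)
    while pos != -1:
        sites.append(pos)
        pos = seq.find(MOTIF, pos + 1)
    return np.asarray(sites, dtype=np.int64)


@dataclass
class FragmentMap:
    """Ordered GATC fragments tiling a set of chromosomes.

    Fragments are stored flat, ordered by chromosome (in ``chrom_names``
    order) then position.  Within a chromosome they are contiguous:
    each start equals the previous end, the first start is 0 and the last
    end is the chromosome length.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: dict[str, int]
    starts: np.ndarray
    ends: np.ndarray
    chrom_index: np.ndarray  # per-fragment index into chrom_names
    _chrom_offsets: dict[str, tuple[int, int]] = field(default=None, repr=False)

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.chrom_index = np.asarray(self.chrom_index, dtype=np.int64)
        if self._chrom_offsets is None:
            offsets = {}
            for i, name in enumerate(self.chrom_names):
                idx = np.flatnonzero(self.chrom_index == i)
                offsets[name] = (int(idx[0]), int(idx[-1]) + 1) if idx.size else (0, 0)
            self._chrom_offsets = offsets
        self._validate()

    def _validate(self) -> None:
        lengths = self.ends - self.starts
        if np.any(lengths < 1):
            raise ValueError("fragment with length < 1")
        for name in self.chrom_names:
            lo, hi = self._chrom_offsets[name]
            if lo == hi:
                raise ValueError(f"chromosome {name} has no fragments")
            s, e = self.starts[lo:hi], self.ends[lo:hi]
            if s[0] != 0 or e[-1] != self.chrom_lengths[name]:
                raise ValueError(f"fragments do not tile chromosome {name}")
            if np.any(s[1:] != e[:-1]):
                raise ValueError(f"fragments not contiguous on chromosome {name}")

    @property
    def n_fragments(self) -> int:
        return int(self.starts.size)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    def chrom_slice(self, chrom: str) -> slice:
        lo, hi = self._chrom_offsets[chrom]
        return slice(lo, hi)

    def same_map(self, other: "FragmentMap") -> bool:
        return (
            self.chrom_names == other.chrom_names
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.ends, other.ends)
            and np.array_equal(self.chrom_index, other.chrom_index)
        )

    def overlapping(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Global indices of fragments with nonempty intersection of [start, end)."""
        if chrom not in self._chrom_offsets:
            raise KeyError(f"unknown chromosome {chrom!r}")
        lo, hi = self._chrom_offsets[chrom]
        s, e = self.starts[lo:hi], self.ends[lo:hi]
        # contiguous sorted tiles: binary search both boundaries
        first = int(np.searchsorted(e, start, side="right"))
        last = int(np.searchsorted(s, end, side="left"))
        return np.arange(lo + first, lo + last, dtype=np.int64)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for i in range(self.n_fragments):
                chrom = self.chrom_names[self.chrom_index[i]]
                fh.write(f"{chrom}\t{self.starts[i]}\t{self.ends[i]}\n")

    @classmethod
    def from_bed(cls, path) -> "FragmentMap":
        names: list[str] = []
        chrom_of: list[int] = []
        starts: list[int] = []
        ends: list[int] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                chrom, s, e = line.split("\t")[:3]
                if not names or names[-1] != chrom:
                    if chrom in names:
                        raise ValueError(f"non-consecutive chromosome blocks: {chrom}")
                    names.append(chrom)
                chrom_of.append(len(names) - 1)
                starts.append(int(s))
                ends.append(int(e))
        starts_a = np.asarray(starts, dtype=np.int64)
        ends_a = np.asarray(ends, dtype=np.int64)
        chrom_idx = np.asarray(chrom_of, dtype=np.int64)
        lengths = {
            name: int(ends_a[chrom_idx == i].max()) for i, name in enumerate(names)
        }
        return cls(tuple(names), lengths, starts_a, ends_a, chrom_idx)


def build_fragment_map(genome: dict[str, str]) -> FragmentMap:
    """Digest a genome at GATC motifs into a :class:`FragmentMap`.

    A chromosome without any motif yields one whole-chromosome fragment.
    """
    if not genome:
        raise ValueError("genome has no chromosomes")
    names = tuple(genome)
    lengths = {}
    starts, ends, chrom_idx = [], [], []
    for ci, name in enumerate(names):
        seq = genome[name]
        L = len(seq)
        lengths[name] = L
        cuts = find_gatc_sites(seq) + CUT_OFFSET
        bounds = np.concatenate([[0], cuts, [L]])
        starts.append(bounds[:-1])
        ends.append(bounds[1:])
        chrom_idx.append(np.full(bounds.size - 1, ci, dtype=np.int64))
    return FragmentMap(
        names,
        lengths,
        np.concatenate(starts),
        np.concatenate(ends),
        np.concatenate(chrom_idx),
    )


@dataclass
class FragmentAssignment:
    """Fragment indices overlapping each transcript span (strand-agnostic).

    Transcripts whose span overlaps no fragment interval are kept in
    ``excluded_transcripts`` rather than dropped silently.  A fragment may
    belong to several transcripts.
    """

    fmap: FragmentMap
    transcript_fragments: dict[str, np.ndarray]
    transcript_gene: dict[str, str]
    excluded_transcripts: list[str]

    def fragment_transcripts(self) -> dict[int, list[str]]:
        rev: dict[int, list[str]] = {}
        for tid, idx in self.transcript_fragments.items():
            for i in idx:
                rev.setdefault(int(i), []).append(tid)
        return rev

    def gene_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for tid in self.transcript_fragments:
            seen.setdefault(self.transcript_gene[tid], None)
        return list(seen)

    def gene_fragments(self, gene_id: str) -> np.ndarray:
        """Sorted union of fragment indices over the gene's transcripts."""
        parts = [
            idx
            for tid, idx in self.transcript_fragments.items()
            if self.transcript_gene[tid] == gene_id
        ]
        if not parts:
            raise KeyError(f"gene {gene_id!r} has no assigned fragments")
        return np.unique(np.concatenate(parts))


def write_assignment_tsv(assignment: FragmentAssignment, path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tgene_id\tfragment_indices\n")
        for tid, idx in assignment.transcript_fragments.items():
            gid = assignment.transcript_gene[tid]
            fh.write(f"{tid}\t{gid}\t{','.join(map(str, idx))}\n")
        for tid in assignment.excluded_transcripts:
            fh.write(f"{tid}\t{assignment.transcript_gene[tid]}\t\n")


def read_assignment_tsv(path, fmap: FragmentMap) -> FragmentAssignment:
    transcript_fragments: dict[str, np.ndarray] = {}
    transcript_gene: dict[str, str] = {}
    excluded: list[str] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("transcript_id"):
            raise ValueError("missing assignment header")
        for line in fh:
            tid, gid, raw = line.rstrip("\n").split("\t")
            transcript_gene[tid] = gid
            if raw:
                transcript_fragments[tid] = np.array(
                    raw.split(","), dtype=np.int64
                )
            else:
                excluded.append(tid)
    return FragmentAssignment(fmap, transcript_fragments, transcript_gene, excluded)


def map_fragments_to_transcripts(
    fmap: FragmentMap, annotation: Annotation
) -> FragmentAssignment:
    """Assign fragments to transcripts by interval overlap of the transcript span.

    Dam methylation is strand-symmetric, so strand is ignored.
    """
    transcript_fragments: dict[str, np.ndarray] = {}
    transcript_gene: dict[str, str] = {}
    excluded: list[str] = []
    for gene in annotation.genes:
        for tx in gene.transcripts:
            if tx.chrom not in fmap.chrom_lengths:
                raise ValueError(
                    f"transcript {tx.transcript_id!r} references unknown "
                    f"chromosome {tx.chrom!r}"
                )
            idx = fmap.overlapping(tx.chrom, tx.start, tx.end)
            transcript_gene[tx.transcript_id] = gene.gene_id
            if idx.size == 0:
                excluded.append(tx.transcript_id)
            else:
                transcript_fragments[tx.transcript_id] = idx
    return FragmentAssignment(fmap, transcript_fragments, transcript_gene, excluded)
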