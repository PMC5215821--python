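"""Sequence containers and FASTA I/O.

Two thin containers are used throughout the package:

* :class:`SequenceSet` — ordered, unaligned protein sequences keyed by id.
* :class:`Alignment` — equal-length gapped rows; de-gapping any row must
  reproduce the corresponding input sequence exactly.

Residues are encoded against the PAML amino-acid order used by the
substitution-model constants; ``-`` (and any unknown symbol, when
tolerated) encodes as :data:`GAP_CODE` and is treated as missing data by
the likelihood machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from typing import Iterable, Iterator, Mapping

import numpy as np
from Bio import SeqIO

from ._aa_data import AA_ORDER

__all__ = ["SequenceSet", "Alignment", "GAP", "GAP_CODE", "encode", "decode"]

GAP = "-"
GAP_CODE = 20

_CODE = np.full(128, -1, dtype=np.int8)
for _i, _a in enumerate(AA_ORDER):
    _CODE[ord(_a)] = _i
    _CODE[ord(_a.lower())] = _i
_CODE[ord(GAP)] = GAP_CODE


def encode(seq: str, allow_gap: bool = True) -> np.ndarray:
    """Encode a residue string to int8 codes (0..19, gap = 20)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[arr]
    if np.any(codes < 0) or (not allow_gap and np.any(codes == GAP_CODE)):
        bad = sorted({seq[i] for i in np.nonzero((codes < 0) | ((codes == GAP_CODE) & (not allow_gap)))[0]})
        raise ValueError(f"unknown residue symbol(s) {bad} in sequence")
    return codes


def decode(codes: np.ndarray) -> str:
    alphabet = AA_ORDER + GAP
    return "".join(alphabet[c] for c in codes)


@dataclass
class SequenceSet:
    """Ordered unaligned sequences; ids are unique."""

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "SequenceSet":
        return cls(list(mapping), list(mapping.values()))

    @classmethod
    def read_fasta(cls, path) -> "SequenceSet":
        ids, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            seqs.append(str(rec.seq))
        if not ids:
            raise ValueError(f"no FASTA records in {path}")
        return cls(ids, seqs)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_fasta())

    def to_fasta(self, width: int = 70) -> str:
        out = StringIO()
        for sid, seq in zip(self.ids, self.seqs):
            out.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")
        return out.getvalue()

    def select(self, ids: Iterable[str]) -> "SequenceSet":
        ids = list(ids)
        lookup = dict(zip(self.ids, self.seqs))
        missing = [i for i in ids if i not in lookup]
        if missing:
            raise KeyError(f"ids not in sequence set: {missing}")
        return SequenceSet(ids, [lookup[i] for i in ids])

    def concat(self, other: "SequenceSet") -> "SequenceSet":
        return SequenceSet(self.ids + other.ids, self.seqs + other.seqs)

    def encoded(self) -> list[np.ndarray]:
        return [encode(s, allow_gap=False) for s in self.seqs]

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(zip(self.ids, self.seqs))

    def __getitem__(self, sid: str) -> str:
        try:
            return self.seqs[self.ids.index(sid)]
        except ValueError:
            raise KeyError(sid) from None


@dataclass
class Alignment:
    """Equal-length gapped rows over the amino-acid alphabet plus '-'.

    ``source`` records how the homology estimate was produced:
    ``"progressive"`` (our aligner), ``"identity"`` (unaligned stacking of
    equal-length sequences), or ``"external"``.
    """

    ids: list[str]
    rows: list[str]
    source: str = "external"

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate row ids")
        if self.rows:
            n = len(self.rows[0])
            if any(len(r) != n for r in self.rows):
                raise ValueError("alignment rows must all have equal length")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @classmethod
    def read_fasta(cls, path, source: str = "external") -> "Alignment":
        ss = SequenceSet.read_fasta(path)
        return cls(ss.ids, ss.seqs, source=source)

    @classmethod
    def read_phylip(cls, path, source: str = "external") -> "Alignment":
        """Read a relaxed-PHYLIP alignment (via Biopython)."""
        from Bio import AlignIO

        msa = AlignIO.read(str(path), "phylip-relaxed")
        return cls([r.id for r in msa], [str(r.seq) for r in msa], source=source)

    def write_fasta(self, path) -> None:
        SequenceSet(self.ids, self.rows).write_fasta(path)

    def to_fasta(self) -> str:
        return SequenceSet(self.ids, self.rows).to_fasta()

    def matrix(self) -> np.ndarray:
        """(n_rows, n_columns) int8 codes, gap/unknown = 20."""
        if not self.rows:
            return np.zeros((0, 0), dtype=np.int8)
        return np.vstack([encode(r) for r in self.rows])

    def degapped(self) -> SequenceSet:
        return SequenceSet(list(self.ids), [r.replace(GAP, "") for r in self.rows])

    def select(self, ids: Iterable[str]) -> "Alignment":
        ids = list(ids)
        lookup = dict(zip(self.ids, self.rows))
        missing = [i for i in ids if i not in lookup]
        if missing:
            raise KeyError(f"ids not in alignment: {missing}")
        return Alignment(ids, [lookup[i] for i in ids], source=self.source)

    def gap_fraction(self) -> float:
        total = self.n_rows * self.n_columns
        if total == 0:
            return 0.0
        return sum(r.count(GAP) for r in self.rows) / total

    def observed_frequencies(self, floor: float = 1e-8) -> np.ndarray:
        """Empirical residue frequencies (gaps excluded), floored away from 0."""
        m = self.matrix()
        counts = np.bincount(m[m != GAP_CODE].astype(np.int64), minlength=20)[:20].astype(float)
        if counts.sum() == 0:
            raise ValueError("alignment contains no residues")
        freqs = np.maximum(counts / counts.sum(), floor)
        return freqs / freqs.sum()
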