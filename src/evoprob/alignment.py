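"""Protein multiple sequence alignments over the 20-letter alphabet.

Sequences are stored as an integer code matrix (taxa × sites); any
symbol outside the 20 canonical amino acids — gaps ``-``, missing ``?``,
``X`` and the rarer ambiguity codes ``B``/``Z``/``J``/``U``/``O``/``*`` —
is coded as -1 and treated as fully ambiguous by the likelihood engine
and as invalid for time-span bookkeeping.

Sites are 1-based in all I/O and 0-based internally.
"""

from __future__ import annotations

import io
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
AMBIGUOUS = -1

__all__ = ["AMINO_ACIDS", "AA_INDEX", "AMBIGUOUS", "ProteinAlignment"]


class ProteinAlignment:
    """Taxon-indexed aligned protein sequences.

    Parameters
    ----------
    names:
        Unique taxon labels, one per row.
    codes:
        Integer matrix (n_taxa × n_sites); 0–19 index ``AMINO_ACIDS``,
        -1 marks gap/missing/ambiguous positions.
    """

    def __init__(self, names: Sequence[str], codes: np.ndarray):
        names = list(names)
        codes = np.asarray(codes, dtype=np.int8)
        if codes.ndim != 2 or codes.shape[0] != len(names):
            raise ValueError("codes must be a (n_taxa, n_sites) matrix")
        if len(set(names)) != len(names):
            raise ValueError("duplicate taxon names in alignment")
        if codes.size and (codes.max() > 19 or codes.min() < -1):
            raise ValueError("codes must lie in {-1, 0..19}")
        self.names = names
        self.codes = codes
        self._index = {n: i for i, n in enumerate(names)}

    # -- construction ----------------------------------------------------

    @classmethod
    def from_sequences(cls, seqs: Mapping[str, str] | Iterable[tuple[str, str]]) -> "ProteinAlignment":
        items = list(seqs.items()) if isinstance(seqs, Mapping) else list(seqs)
        if not items:
            raise ValueError("empty alignment")
        lengths = {len(s) for _, s in items}
        if len(lengths) != 1:
            raise ValueError(f"sequences are not aligned (lengths {sorted(lengths)})")
        n_sites = lengths.pop()
        codes = np.full((len(items), n_sites), AMBIGUOUS, dtype=np.int8)
        for row, (_, seq) in enumerate(items):
            for col, ch in enumerate(seq.upper()):
                codes[row, col] = AA_INDEX.get(ch, AMBIGUOUS)
        return cls([n for n, _ in items], codes)

    @classmethod
    def read_fasta(cls, handle) -> "ProteinAlignment":
        """Read an aligned FASTA file (path or file-like)."""
        records = list(SeqIO.parse(handle, "fasta"))
        if not records:
            raise ValueError("no sequences in FASTA input")
        return cls.from_sequences([(r.id, str(r.seq)) for r in records])

    def write_fasta(self, handle) -> None:
        records = [SeqRecord(Seq(self.sequence(n)), id=n, description="") for n in self.names]
        SeqIO.write(records, handle, "fasta")

    # -- access ----------------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return self.codes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    def row(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"taxon {name!r} not in alignment") from None

    def sequence(self, name: str) -> str:
        return "".join(AMINO_ACIDS[c] if c >= 0 else "-" for c in self.codes[self.row(name)])

    def column(self, site0: int) -> dict[str, int]:
        """Residue codes per taxon at a 0-based site."""
        return {n: int(self.codes[i, site0]) for n, i in self._index.items()}

    @property
    def valid(self) -> np.ndarray:
        """Boolean (taxa × sites) matrix of valid (unambiguous) residues."""
        return self.codes >= 0

    def subset(self, taxa: Iterable[str]) -> "ProteinAlignment":
        taxa = list(taxa)
        rows = [self.row(t) for t in taxa]
        return ProteinAlignment(taxa, self.codes[rows])

    def __repr__(self) -> str:  # pragma: no cover
        return f"ProteinAlignment({self.n_taxa} taxa, {self.n_sites} sites)"
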