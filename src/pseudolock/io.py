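"""Small format helpers: aligned FASTA via Biopython, TSV via pandas."""

from __future__ import annotations

from typing import Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InvalidArgumentError

__all__ = ["read_msa_fasta", "write_msa_fasta"]


def read_msa_fasta(path) -> dict[str, str]:
    """Read an aligned FASTA into an ordered id -> sequence mapping."""
    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise InvalidArgumentError(f"no sequences in {path}")
    widths = {len(s) for s in records.values()}
    if len(widths) > 1:
        raise InvalidArgumentError(f"{path} is not aligned (unequal row lengths)")
    return records


def write_msa_fasta(alignment: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in alignment.items()
    ]
    SeqIO.write(records, str(path), "fasta")
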