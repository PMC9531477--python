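"""Readers and writers for the formats the pipeline touches.

FASTA via Biopython, newick via :mod:`selscan.tree`, the standard
12-column tabular homology-search format, and the packaged fixture
tables (per-gene selection statistics for the two night-heron species,
transcribed to TSV).  Coordinates are 1-based inclusive at the file
boundary; internal arithmetic is 0-based half-open.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .rubric import GeneSelectionRecord
from .tree import PhyloTree, parse_newick, read_newick  # re-export  # noqa: F401

logger = logging.getLogger("selscan")

__all__ = [
    "SequenceSet",
    "HomologyHit",
    "FixtureTable",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "read_homology_table",
    "load_fixture_table",
    "load_fixture_tree",
]

_NUC_CORE = set("ACGTUN-")

# sha256 of the packaged fixture files; guards against silent edits.
_FIXTURE_SHA256 = {
    "table3": "b735656bc55b32ce8bd5134352841f86075c492725c4086daecdf21aa78a02e5",
    "table4": "0a83788ec0205ca7d8be55983b98ffc7086aed0cfabbf4e05d5d857ff5babea7",
    "fig1_tree": "573d02cf613f2ce8a17cddba435709eecffe5ddfb8f8ba3800f7fe95e171a02a",
}

_FIXTURE_ROWS = {"table3": 40, "table4": 24}
_FIXTURE_FILES = {
    "table3": "table3.tsv",
    "table4": "table4.tsv",
    "fig1_tree": "fig1_tree.nwk",
}


@dataclass
class SequenceSet:
    """An ordered set of uniquely named sequences over one alphabet."""

    records: list[tuple[str, str]]

    def __post_init__(self):
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence identifiers: {dup}")
        if any(not seq for _, seq in self.records):
            raise ValueError("empty sequence")
        kinds = {self._kind(seq) for _, seq in self.records}
        if len(kinds) > 1:
            raise ValueError("mixed nucleotide/protein alphabets in one set")

    @staticmethod
    def _kind(seq: str) -> str:
        # IUPAC ambiguity codes overlap the amino-acid alphabet, so use the
        # fraction of core nucleotide characters rather than set inclusion
        s = seq.upper()
        frac = sum(c in _NUC_CORE for c in s) / len(s)
        return "nucleotide" if frac >= 0.9 else "protein"

    @property
    def alphabet(self) -> str:
        return self._kind(self.records[0][1])

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, name: str) -> str:
        for rid, seq in self.records:
            if rid == name:
                return seq
        raise KeyError(name)

    def ids(self) -> list[str]:
        return [r[0] for r in self.records]


@dataclass(frozen=True)
class HomologyHit:
    """One row of the 12-column tabular protein-vs-DNA search format.

    Subject coordinates are normalized: start <= end always, with the
    original orientation kept in ``subject_strand``.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    evalue: float
    bitscore: float
    subject_strand: str = "+"

    def __post_init__(self):
        if self.subject_start > self.subject_end or self.query_start > self.query_end:
            raise ValueError("start > end after strand normalization")
        if self.evalue < 0:
            raise ValueError("negative E-value")
        if self.subject_strand not in "+-":
            raise ValueError(f"bad strand {self.subject_strand!r}")


@dataclass
class FixtureTable:
    name: str
    rows: list[GeneSelectionRecord]

    def __len__(self) -> int:
        return len(self.rows)

    def get(self, gene: str) -> GeneSelectionRecord:
        for row in self.rows:
            if row.gene == gene:
                return row
        raise KeyError(gene)


def read_fasta(path) -> SequenceSet:
    """Read FASTA, preserving record order; sequences are upper-cased and
    line wrapping is joined away.  Duplicate identifiers and empty files
    are rejected."""
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return SequenceSet(records)


def write_fasta(path, seqs: SequenceSet | Iterable[tuple[str, str]], width: int = 70) -> None:
    records = seqs.records if isinstance(seqs, SequenceSet) else list(seqs)
    bio = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_homology_table(path) -> list[HomologyHit]:
    """Parse the 12-column tab-separated homology format (qseqid sseqid
    pident length mismatch gapopen qstart qend sstart send evalue
    bitscore).  Minus-strand hits are inferred from sstart > send and
    normalized to forward coordinates."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(parts)}"
                )
            try:
                qid, sid = parts[0], parts[1]
                pident = float(parts[2])
                length = int(parts[3])
                qstart, qend = int(parts[6]), int(parts[7])
                sstart, send = int(parts[8]), int(parts[9])
                evalue = float(parts[10])
                bits = float(parts[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            strand = "+"
            if sstart > send:
                strand = "-"
                sstart, send = send, sstart
            hits.append(
                HomologyHit(qid, sid, pident, length, qstart, qend, sstart, send,
                            evalue, bits, strand)
            )
    return hits


def _fixture_bytes(name: str) -> bytes:
    fname = _FIXTURE_FILES[name]
    return resources.files("selscan.fixtures").joinpath(fname).read_bytes()


def _check_fixture(name: str) -> bytes:
    data = _fixture_bytes(name)
    digest = hashlib.sha256(data).hexdigest()
    expected = _FIXTURE_SHA256[name]
    if digest != expected:
        raise ValueError(
            f"fixture {name!r} checksum mismatch: packaged copy was modified"
        )
    return data


def load_fixture_table(name: str) -> FixtureTable:
    """Load a packaged per-gene selection-statistics table.

    ``table3`` holds the 40 N. nycticorax rows and ``table4`` the 24
    C. cochlearius rows.  Values are the printed numbers ("E" notation
    parsed case-insensitively; q-values printed as "0" stored as 0.0).
    The packaged copy is checksum-verified and validated at load.
    """
    if name not in _FIXTURE_ROWS:
        raise KeyError(f"unknown fixture table {name!r}; choose table3 or table4")
    data = _check_fixture(name)
    from io import StringIO

    df = pd.read_csv(StringIO(data.decode()), sep="\t", dtype=str)
    rows = [
        GeneSelectionRecord(
            gene=r.gene.strip(),
            species=r.species.strip(),
            paml_omega_bg=float(r.paml_omega0),
            paml_omega_fg=float(r.paml_omega1),
            paml_p=float(r.paml_p),
            paml_q=float(r.paml_q),
            busted_p=float(r.busted_p),
            busted_q=float(r.busted_q),
            relax_k=float(r.relax_k),
            relax_p=float(r.relax_p),
            relax_q=float(r.relax_q),
        )
        for r in df.itertuples()
    ]
    if len(rows) != _FIXTURE_ROWS[name]:
        raise ValueError(f"{name}: expected {_FIXTURE_ROWS[name]} rows, got {len(rows)}")
    genes = [r.gene for r in rows]
    if len(set(genes)) != len(genes):
        raise ValueError(f"{name}: duplicate gene rows")
    return FixtureTable(name, rows)


def read_selection_table(path) -> FixtureTable:
    """Read a user-supplied table with the nine statistic columns (same
    header as the packaged fixtures)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {
        "gene", "species", "paml_omega0", "paml_omega1", "paml_p", "paml_q",
        "busted_p", "busted_q", "relax_k", "relax_p", "relax_q",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rows = [
        GeneSelectionRecord(
            gene=r.gene.strip(),
            species=r.species.strip(),
            paml_omega_bg=float(r.paml_omega0),
            paml_omega_fg=float(r.paml_omega1),
            paml_p=float(r.paml_p),
            paml_q=float(r.paml_q),
            busted_p=float(r.busted_p),
            busted_q=float(r.busted_q),
            relax_k=float(r.relax_k),
            relax_p=float(r.relax_p),
            relax_q=float(r.relax_q),
        )
        for r in df.itertuples()
    ]
    return FixtureTable(Path(path).stem, rows)


def load_fixture_tree() -> PhyloTree:
    """The packaged seven-taxon Pelecaniformes topology used throughout.

    The heron clade is ((Egretta_garzetta, Nycticorax_nycticorax),
    Cochlearius_cochlearius) with Gallus_gallus as the outgroup.  Branch
    lengths are desk-scale stand-ins (expected substitutions per codon),
    not estimates from data.
    """
    data = _check_fixture("fig1_tree")
    return parse_newick(data.decode())
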