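"""Readers and writers for the four annotation inputs and the tabular outputs.

All coordinates are 1-based inclusive throughout the package (the
HMMER/Pfam convention); conversion, where a dialect requires any, happens
here at parse time and nowhere downstream.

Supported dialects
------------------
* proteins        — FASTA (first whitespace-delimited header token = protein id)
* domain hits     — HMMER 3 per-domain tabular output (``hmmer_domtbl``,
                    envelope coordinates) or a 7-column TSV
* TM helices      — TMHMM short format (``Topology=`` strings) or 3-column TSV
* signal peptides — SignalP-style summary rows or 2-column TSV
* taxonomy        — 2-column TSV (species_id, slash-separated taxon path)
* census          — TSV, species rows x class columns
"""

from __future__ import annotations

import io
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

from Bio import SeqIO

__all__ = [
    "ProteinRecord",
    "DomainHit",
    "TMHelix",
    "SignalPeptide",
    "SpeciesTaxonomy",
    "ParseError",
    "ValidationError",
    "read_proteins",
    "read_domain_hits",
    "read_tm_helices",
    "read_signal_peptides",
    "read_taxonomy",
    "write_taxonomy",
    "write_census",
    "read_census",
    "atomic_write_text",
]

_PFAM_RE = re.compile(r"^PF\d{5}(\.\d+)?$")
_GAP_CHARS = frozenset("-.")

Source = Union[str, os.PathLike, io.TextIOBase]


class ParseError(ValueError):
    """A malformed input line; carries the 1-based line number when known."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(ValueError):
    """A record that violates a type invariant or cross-references nothing."""


@dataclass(frozen=True)
class ProteinRecord:
    """One predicted protein from a proteome."""

    protein_id: str
    species_id: str
    length: int
    sequence: Optional[str] = None

    def __post_init__(self):
        if self.length < 1:
            raise ValidationError(f"{self.protein_id}: length must be >= 1, got {self.length}")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValidationError(
                f"{self.protein_id}: sequence length {len(self.sequence)} != declared length {self.length}"
            )


@dataclass(frozen=True, order=True)
class DomainHit:
    """One Pfam-model match on a protein (1-based inclusive envelope)."""

    protein_id: str
    accession: str
    start: int
    end: int
    bit_score: float = 0.0
    e_value: float = 0.0
    name: Optional[str] = field(default=None, compare=False)

    def __post_init__(self):
        if not _PFAM_RE.match(self.accession):
            raise ValidationError(f"{self.protein_id}: malformed Pfam accession {self.accession!r}")
        if self.accession != self.accession.split(".")[0]:
            object.__setattr__(self, "accession", self.accession.split(".")[0])
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"{self.protein_id}: invalid hit interval {self.start}-{self.end}"
            )
        if self.e_value < 0:
            raise ValidationError(f"{self.protein_id}: negative e-value {self.e_value}")


@dataclass(frozen=True, order=True)
class TMHelix:
    """One predicted transmembrane helix (1-based inclusive)."""

    protein_id: str
    start: int
    end: int

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"{self.protein_id}: invalid helix interval {self.start}-{self.end}"
            )


@dataclass(frozen=True)
class SignalPeptide:
    """A predicted signal peptide occupying residues 1..end."""

    protein_id: str
    end: int

    def __post_init__(self):
        if self.end < 1:
            raise ValidationError(f"{self.protein_id}: signal peptide end must be >= 1")


@dataclass(frozen=True)
class SpeciesTaxonomy:
    """A species and its ordered taxonomic group labels (broad to narrow)."""

    species_id: str
    taxon_path: tuple

    def __post_init__(self):
        object.__setattr__(self, "taxon_path", tuple(self.taxon_path))
        if not self.taxon_path:
            raise ValidationError(f"{self.species_id}: empty taxon path")


def _open(source: Source, mode: str = "r"):
    if isinstance(source, (str, os.PathLike)):
        return open(source, mode), True
    return source, False


def _iter_lines(source: Source):
    handle, close = _open(source)
    try:
        for lineno, raw in enumerate(handle, start=1):
            yield lineno, raw.rstrip("\n")
    finally:
        if close:
            handle.close()


def read_proteins(fasta_source: Source, species_id: str) -> list[ProteinRecord]:
    """Read a per-species protein FASTA into :class:`ProteinRecord` objects.

    The first whitespace-delimited token of each header is the protein id.
    Duplicate ids are a hard error; an empty file yields an empty list.
    """
    handle, close = _open(fasta_source)
    try:
        records: list[ProteinRecord] = []
        seen: set[str] = set()
        for seq_record in SeqIO.parse(handle, "fasta"):
            pid = seq_record.id
            if pid in seen:
                raise ValidationError(f"duplicate protein_id {pid!r} in {species_id} FASTA")
            seen.add(pid)
            seq = str(seq_record.seq)
            records.append(
                ProteinRecord(protein_id=pid, species_id=species_id, length=len(seq), sequence=seq)
            )
        return records
    finally:
        if close:
            handle.close()


def _cross_reference(
    records: Iterable,
    proteins: Optional[Mapping[str, ProteinRecord]],
    strict: bool,
    check_end,
):
    """Filter records against a protein table; strict -> raise, lenient -> drop."""
    if proteins is None:
        return list(records)
    kept = []
    for rec in records:
        prot = proteins.get(rec.protein_id)
        if prot is None:
            if strict:
                raise ValidationError(
                    f"record references unknown protein {rec.protein_id!r} (use lenient mode to drop)"
                )
            continue
        check_end(rec, prot)
        kept.append(rec)
    return kept


def read_domain_hits(
    table_source: Source,
    dialect: str = "tsv",
    proteins: Optional[Mapping[str, ProteinRecord]] = None,
    strict: bool = True,
    max_e_value: Optional[float] = None,
) -> list[DomainHit]:
    """Read Pfam domain hits from a TSV or HMMER 3 per-domain table.

    The HMMER dialect takes the *envelope* coordinates (``env from``/``env to``),
    the boundaries pfam_scan reports, with the independent per-domain e-value.
    Upstream significance filtering (Pfam gathering cutoffs) is assumed done by
    the scan; ``max_e_value`` is an optional extra filter, off by default.
    """
    if dialect not in ("tsv", "hmmer_domtbl"):
        raise ValueError(f"unknown domain-hit dialect {dialect!r}")
    hits: list[DomainHit] = []
    for lineno, line in _iter_lines(table_source):
        if not line.strip() or line.startswith("#"):
            continue
        try:
            if dialect == "tsv":
                parts = line.split("\t")
                if len(parts) != 7:
                    raise ParseError(f"expected 7 tab-separated fields, got {len(parts)}", lineno)
                pid, acc, name, start, end, score, evalue = parts
            else:  # hmmer_domtbl: target = Pfam model, query = protein
                parts = line.split()
                if len(parts) < 22:
                    raise ParseError(f"expected >=22 whitespace fields, got {len(parts)}", lineno)
                acc = parts[1]
                pid = parts[3]
                name = parts[0]
                start, end = parts[19], parts[20]  # env from / env to
                evalue = parts[12]  # independent per-domain e-value
                score = parts[13]
            hit = DomainHit(
                protein_id=pid,
                accession=acc,
                name=name or None,
                start=int(start),
                end=int(end),
                bit_score=float(score),
                e_value=float(evalue),
            )
        except ParseError:
            raise
        except (ValueError, ValidationError) as exc:
            raise ParseError(str(exc), lineno) from exc
        if max_e_value is not None and hit.e_value > max_e_value:
            continue
        hits.append(hit)

    def check_end(hit: DomainHit, prot: ProteinRecord):
        if hit.end > prot.length:
            raise ValidationError(
                f"{hit.protein_id}: hit {hit.accession} ends at {hit.end} beyond protein length {prot.length}"
            )

    return _cross_reference(hits, proteins, strict, check_end)


_TOPOLOGY_SPAN_RE = re.compile(r"(\d+)-(\d+)")
_TOPOLOGY_VALID_RE = re.compile(r"^[io](\d+-\d+[io])*$")


def parse_topology(protein_id: str, topology: str) -> list[TMHelix]:
    """Parse a TMHMM topology string such as ``i5-20o45-60i`` into helices."""
    if not _TOPOLOGY_VALID_RE.match(topology):
        raise ParseError(f"{protein_id}: unparsable topology string {topology!r}")
    return [
        TMHelix(protein_id=protein_id, start=int(a), end=int(b))
        for a, b in _TOPOLOGY_SPAN_RE.findall(topology)
    ]


def read_tm_helices(
    source: Source,
    dialect: str = "tmhmm_short",
    proteins: Optional[Mapping[str, ProteinRecord]] = None,
    strict: bool = True,
) -> list[TMHelix]:
    """Read TM-helix predictions from TMHMM short format or a 3-column TSV."""
    if dialect not in ("tmhmm_short", "tsv"):
        raise ValueError(f"unknown TM dialect {dialect!r}")
    helices: list[TMHelix] = []
    for lineno, line in _iter_lines(source):
        if not line.strip() or line.startswith("#"):
            continue
        try:
            if dialect == "tsv":
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ParseError(f"expected 3 tab-separated fields, got {len(parts)}", lineno)
                helices.append(
                    TMHelix(protein_id=parts[0], start=int(parts[1]), end=int(parts[2]))
                )
            else:
                fields = line.split("\t") if "\t" in line else line.split()
                pid = fields[0]
                topo = None
                for fld in fields[1:]:
                    if fld.startswith("Topology="):
                        topo = fld[len("Topology="):]
                if topo is None:
                    raise ParseError(f"{pid}: no Topology= field", lineno)
                helices.extend(parse_topology(pid, topo))
        except ParseError:
            raise
        except (ValueError, ValidationError) as exc:
            raise ParseError(str(exc), lineno) from exc

    def check_end(helix: TMHelix, prot: ProteinRecord):
        if helix.end > prot.length:
            raise ValidationError(
                f"{helix.protein_id}: helix ends at {helix.end} beyond protein length {prot.length}"
            )

    return _cross_reference(helices, proteins, strict, check_end)


def read_signal_peptides(
    source: Source,
    dialect: str = "signalp_summary",
    proteins: Optional[Mapping[str, ProteinRecord]] = None,
    strict: bool = True,
) -> list[SignalPeptide]:
    """Read signal-peptide predictions; only positive proteins yield records.

    Summary rows look like ``p1 YES 22`` (positive, cleavage boundary after
    residue 22) or ``p2 NO``. The TSV dialect lists only positives as
    ``protein_id<TAB>end``.
    """
    if dialect not in ("signalp_summary", "tsv"):
        raise ValueError(f"unknown signal-peptide dialect {dialect!r}")
    peptides: list[SignalPeptide] = []
    for lineno, line in _iter_lines(source):
        if not line.strip() or line.startswith("#"):
            continue
        try:
            if dialect == "tsv":
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ParseError(f"expected 2 tab-separated fields, got {len(parts)}", lineno)
                peptides.append(SignalPeptide(protein_id=parts[0], end=int(parts[1])))
            else:
                parts = line.split()
                if len(parts) < 2:
                    raise ParseError("expected at least protein_id and YES/NO", lineno)
                pid, verdict = parts[0], parts[1].upper()
                if verdict == "NO":
                    continue
                if verdict != "YES":
                    raise ParseError(f"{pid}: expected YES or NO, got {parts[1]!r}", lineno)
                if len(parts) < 3:
                    raise ParseError(f"{pid}: YES row missing cleavage position", lineno)
                peptides.append(SignalPeptide(protein_id=pid, end=int(parts[2])))
        except ParseError:
            raise
        except (ValueError, ValidationError) as exc:
            raise ParseError(str(exc), lineno) from exc

    def check_end(sp: SignalPeptide, prot: ProteinRecord):
        if sp.end >= prot.length:
            raise ValidationError(
                f"{sp.protein_id}: signal peptide end {sp.end} not below protein length {prot.length}"
            )

    return _cross_reference(peptides, proteins, strict, check_end)


def read_taxonomy(source: Source) -> list[SpeciesTaxonomy]:
    """Read the 2-column species/taxonomy TSV (species_id, A/B/C path)."""
    out = []
    seen = set()
    for lineno, line in _iter_lines(source):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"expected 2 tab-separated fields, got {len(parts)}", lineno)
        sid, path = parts
        if sid in seen:
            raise ParseError(f"duplicate species_id {sid!r}", lineno)
        seen.add(sid)
        out.append(SpeciesTaxonomy(species_id=sid, taxon_path=tuple(path.split("/"))))
    return out


def write_taxonomy(taxa: Sequence[SpeciesTaxonomy], sink: Source) -> None:
    lines = [f"{t.species_id}\t{'/'.join(t.taxon_path)}" for t in taxa]
    _write_lines(lines, sink)


def write_census(census, sink: Source) -> None:
    """Write a census as a TSV: header of class names, one row per species.

    Species rows are sorted lexically so output is deterministic; the table
    round-trips losslessly through :func:`read_census`.
    """
    lines = ["species\t" + "\t".join(census.classes)]
    for sid in sorted(census.species):
        lines.append(sid + "\t" + "\t".join(str(census.count(sid, c)) for c in census.classes))
    _write_lines(lines, sink)


def read_census(source: Source):
    """Read a census TSV written by :func:`write_census`."""
    from .classifier import CensusTable  # deferred: classifier imports this module

    rows = list(_iter_lines(source))
    if not rows:
        raise ParseError("empty census file (expected at least a header)", 1)
    header = rows[0][1].split("\t")
    if header[0] != "species":
        raise ParseError("census header must start with 'species'", 1)
    classes = tuple(header[1:])
    counts = {}
    species = []
    for lineno, line in rows[1:]:
        parts = line.split("\t")
        if len(parts) != len(header):
            raise ParseError(f"expected {len(header)} fields, got {len(parts)}", lineno)
        sid = parts[0]
        species.append(sid)
        for cname, value in zip(classes, parts[1:]):
            counts[(sid, cname)] = int(value)
    return CensusTable(species=tuple(species), classes=classes, counts=counts)


def _write_lines(lines: Sequence[str], sink: Source) -> None:
    text = "\n".join(lines) + "\n" if lines else ""
    if isinstance(sink, (str, os.PathLike)):
        atomic_write_text(sink, text)
    else:
        sink.write(text)


def atomic_write_text(path: Union[str, os.PathLike], text: str) -> None:
    """Write a file via temp-and-rename so partial runs never leave truncated tables."""
    path = os.fspath(path)
    tmp = path + ".tmp"
    with open(tmp, "w") as handle:
        handle.write(text)
    os.replace(tmp, path)
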