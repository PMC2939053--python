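"""Detection of gene-model anomalies that create false membrane receptors.

Automated gene prediction sometimes grafts a spurious N-terminal extension
onto a protein model; when the only predicted transmembrane helix falls in
that extension, the protein is mis-counted as a membrane receptor. Two
detectors reproduce the curation logic used in comparative receptor
surveys:

* ``detect_nterm_extension`` — align the query against close homologs; if
  the query has a long run of N-terminal residues in columns where most
  homologs are gapped, the overhang is a suspect extension (the classic
  case is a fungal adenylate cyclase with an extra 560 residues carrying
  the family's only predicted TM helix).
* ``detect_misplaced_nterm_domain`` — an "LRR N-terminal cap" domain found
  in the middle of the protein suggests the true start lies there, so the
  residues before it are a suspect 5'-extension.

``apply_corrections`` removes TM helices inside flagged overhangs; the
symmetric defect (a helix *lost* to an in-frame intron in the gene model)
cannot be detected from protein-space evidence, so it is supported only as
a manual addition record.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO

from .annotation_io import Source, TMHelix, ValidationError, _open, atomic_write_text
from .architecture import ProteinArchitecture

__all__ = [
    "HomologFamily",
    "AnomalyReport",
    "ManualTMAddition",
    "read_alignment_fasta",
    "detect_nterm_extension",
    "detect_misplaced_nterm_domain",
    "apply_corrections",
    "write_anomaly_reports",
]

_GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class HomologFamily:
    """A query protein aligned with close homologs (aligned FASTA rows)."""

    query_id: str
    rows: Mapping[str, str]  # row label -> aligned sequence (gaps allowed)

    def __post_init__(self):
        rows = dict(self.rows)
        object.__setattr__(self, "rows", rows)
        if len(rows) < 2:
            raise ValidationError(f"{self.query_id}: family needs >= 2 aligned rows")
        if self.query_id not in rows:
            raise ValidationError(f"query {self.query_id!r} absent from alignment rows")
        widths = {len(s) for s in rows.values()}
        if len(widths) != 1:
            raise ValidationError(f"{self.query_id}: aligned rows differ in column count")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))


@dataclass(frozen=True)
class AnomalyReport:
    """One flagged gene model and the correction it suggests."""

    protein_id: str
    kind: str  # "NTERM_EXTENSION" | "MISPLACED_NTERM_DOMAIN"
    overhang_length: int
    contains_tm: bool
    suggested_action: str  # "drop_tm" | "none"

    def __post_init__(self):
        if self.kind not in ("NTERM_EXTENSION", "MISPLACED_NTERM_DOMAIN"):
            raise ValidationError(f"unknown anomaly kind {self.kind!r}")
        if self.overhang_length < 0:
            raise ValidationError("overhang_length must be >= 0")
        if self.suggested_action not in ("drop_tm", "none"):
            raise ValidationError(f"unknown action {self.suggested_action!r}")
        if self.suggested_action == "drop_tm" and not self.contains_tm:
            raise ValidationError("drop_tm suggested but no TM in the overhang")


@dataclass(frozen=True)
class ManualTMAddition:
    """A curator-supplied helix missing from the predictions (e.g. lost to an
    in-frame intron in the gene model); applied by :func:`apply_corrections`."""

    protein_id: str
    start: int
    end: int


def read_alignment_fasta(source: Source, query_id: str) -> HomologFamily:
    """Read an aligned FASTA (any aligner's output) into a :class:`HomologFamily`."""
    handle, close = _open(source)
    try:
        rows = {}
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in rows:
                raise ValidationError(f"duplicate row label {rec.id!r} in alignment")
            rows[rec.id] = str(rec.seq)
    finally:
        if close:
            handle.close()
    return HomologFamily(query_id=query_id, rows=rows)


def _tm_in_overhang(arch: ProteinArchitecture, overhang: int) -> bool:
    """True when some corrected helix lies entirely within residues 1..overhang."""
    return any(h.end <= overhang for h in arch.tm_corrected)


def detect_nterm_extension(
    family: HomologFamily,
    arch: ProteinArchitecture,
    occupancy: float = 0.5,
    min_overhang: int = 100,
) -> Optional[AnomalyReport]:
    """Flag a query whose N-terminus extends far past its aligned homologs.

    The homolog-supported region starts at the first alignment column where
    at least ``occupancy`` of the non-query rows are non-gap; the overhang
    is the number of query residues before that column. A report is issued
    only when the overhang reaches ``min_overhang`` residues, with
    ``drop_tm`` suggested if a corrected TM helix lies wholly inside it.
    """
    if family.query_id != arch.protein_id:
        raise ValidationError(
            f"family query {family.query_id!r} does not match architecture {arch.protein_id!r}"
        )
    if not (0 < occupancy <= 1):
        raise ValueError("occupancy must be in (0, 1]")
    query = family.rows[family.query_id]
    homologs = [s for label, s in family.rows.items() if label != family.query_id]
    n_hom = len(homologs)
    first_supported = family.n_columns
    for col in range(family.n_columns):
        support = sum(1 for s in homologs if s[col] not in _GAP_CHARS)
        if support / n_hom >= occupancy:
            first_supported = col
            break
    overhang = sum(1 for c in query[:first_supported] if c not in _GAP_CHARS)
    if overhang < min_overhang:
        return None
    contains_tm = _tm_in_overhang(arch, overhang)
    return AnomalyReport(
        protein_id=arch.protein_id,
        kind="NTERM_EXTENSION",
        overhang_length=overhang,
        contains_tm=contains_tm,
        suggested_action="drop_tm" if contains_tm else "none",
    )


def detect_misplaced_nterm_domain(
    arch: ProteinArchitecture,
    nterm_accessions: frozenset,
    position_fraction: float = 0.25,
) -> Optional[AnomalyReport]:
    """Flag a protein whose N-terminal cap domain sits mid-sequence.

    If a hit from ``nterm_accessions`` (e.g. the LRRNT cap family) starts
    after ``position_fraction`` of the protein length, the residues before
    it are treated as a suspect 5'-extension of the gene model.
    """
    if not nterm_accessions:
        raise ValueError("nterm_accessions must be configured and non-empty")
    candidates = [h for h in arch.domains if h.accession in frozenset(nterm_accessions)]
    if not candidates:
        return None
    first = min(candidates, key=lambda h: (h.start, h.end, h.accession))
    if first.start <= position_fraction * arch.length:
        return None
    overhang = first.start - 1
    contains_tm = _tm_in_overhang(arch, overhang)
    return AnomalyReport(
        protein_id=arch.protein_id,
        kind="MISPLACED_NTERM_DOMAIN",
        overhang_length=overhang,
        contains_tm=contains_tm,
        suggested_action="drop_tm" if contains_tm else "none",
    )


def apply_corrections(
    archs: Sequence[ProteinArchitecture],
    reports: Iterable[AnomalyReport],
    tm_additions: Iterable[ManualTMAddition] = (),
) -> list[ProteinArchitecture]:
    """Apply suggested corrections, returning new architectures.

    For each ``drop_tm`` report the corrected-helix list loses every helix
    lying wholly inside the flagged overhang; manual additions append a
    helix to both raw and corrected lists. All other architectures pass
    through unchanged. Dropping helices can only remove the
    single-TM-receptor label from a protein, never confer it on another.
    """
    by_id = {a.protein_id: a for a in archs}
    drop_spans: dict[str, int] = {}
    for rep in reports:
        if rep.protein_id not in by_id:
            raise ValidationError(f"anomaly report for unknown protein {rep.protein_id!r}")
        if rep.suggested_action == "drop_tm":
            drop_spans[rep.protein_id] = max(drop_spans.get(rep.protein_id, 0), rep.overhang_length)
    additions: dict[str, list[TMHelix]] = {}
    for add in tm_additions:
        if add.protein_id not in by_id:
            raise ValidationError(f"manual TM addition for unknown protein {add.protein_id!r}")
        additions.setdefault(add.protein_id, []).append(
            TMHelix(protein_id=add.protein_id, start=add.start, end=add.end)
        )
    out = []
    for arch in archs:
        overhang = drop_spans.get(arch.protein_id, 0)
        extra = additions.get(arch.protein_id, [])
        if not overhang and not extra:
            out.append(arch)
            continue
        corrected = [h for h in arch.tm_corrected if h.end > overhang]
        if extra:
            tm_raw = tuple(sorted([*arch.tm_raw, *extra], key=lambda h: (h.start, h.end)))
            corrected = sorted([*corrected, *extra], key=lambda h: (h.start, h.end))
            arch = ProteinArchitecture(
                protein_id=arch.protein_id,
                species_id=arch.species_id,
                length=arch.length,
                domains=arch.domains,
                tm_raw=tm_raw,
                tm_corrected=tuple(corrected),
                signal_peptide=arch.signal_peptide,
            )
        else:
            arch = arch.with_tm_corrected(corrected)
        out.append(arch)
    return out


def write_anomaly_reports(reports: Sequence[AnomalyReport], sink) -> None:
    """Write reports as TSV: protein_id, kind, overhang, contains_tm, action."""
    lines = ["protein_id\tkind\toverhang_length\tcontains_tm\tsuggested_action"]
    for rep in sorted(reports, key=lambda r: (r.protein_id, r.kind)):
        lines.append(
            f"{rep.protein_id}\t{rep.kind}\t{rep.overhang_length}"
            f"\t{int(rep.contains_tm)}\t{rep.suggested_action}"
        )
    text = "\n".join(lines) + "\n"
    import os

    if isinstance(sink, (str, os.PathLike)):
        atomic_write_text(sink, text)
    else:
        sink.write(text)
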