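"""Per-protein domain architectures and the TM/signal-peptide overlap correction.

Topology predictors based on hidden Markov models can mistake a hydrophobic
N-terminal signal peptide for a transmembrane helix. A protein whose only
"helix" is really its signal peptide would otherwise be counted as a
membrane receptor, so helices overlapping the predicted signal-peptide
region (residues 1..sp_end) are removed before anything downstream counts
transmembrane segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .annotation_io import DomainHit, ProteinRecord, SignalPeptide, TMHelix, ValidationError

__all__ = [
    "ProteinArchitecture",
    "correct_tm_helices",
    "build_architecture",
    "architecture_string",
    "count_lrr_domains",
    "LRR_ACCESSIONS",
]

#: The three leucine-rich-repeat families tracked by default (LRR_1, LRR_2, LRR_4).
LRR_ACCESSIONS = frozenset({"PF00560", "PF07723", "PF07725"})

_DOMAIN_SORT_KEY = lambda h: (h.start, h.end, h.accession)


@dataclass(frozen=True)
class ProteinArchitecture:
    """The joined per-protein evidence: ordered domains, helices, signal peptide.

    ``tm_corrected`` is always a subset of ``tm_raw``; classification reads
    only the corrected list.
    """

    protein_id: str
    species_id: str
    length: int
    domains: tuple[DomainHit, ...] = ()
    tm_raw: tuple[TMHelix, ...] = ()
    tm_corrected: tuple[TMHelix, ...] = ()
    signal_peptide: Optional[SignalPeptide] = None

    def __post_init__(self):
        object.__setattr__(self, "domains", tuple(self.domains))
        object.__setattr__(self, "tm_raw", tuple(self.tm_raw))
        object.__setattr__(self, "tm_corrected", tuple(self.tm_corrected))
        if list(self.domains) != sorted(self.domains, key=_DOMAIN_SORT_KEY):
            raise ValidationError(f"{self.protein_id}: domains not sorted by (start, end, accession)")
        raw = set(self.tm_raw)
        if not set(self.tm_corrected) <= raw:
            raise ValidationError(f"{self.protein_id}: tm_corrected is not a subset of tm_raw")
        if self.signal_peptide is not None:
            for helix in self.tm_corrected:
                if _overlap(helix, self.signal_peptide.end) > 0:
                    raise ValidationError(
                        f"{self.protein_id}: corrected helix {helix.start}-{helix.end} "
                        f"overlaps signal peptide 1-{self.signal_peptide.end}"
                    )

    @property
    def accessions(self) -> frozenset:
        return frozenset(h.accession for h in self.domains)

    def with_tm_corrected(self, helices: Sequence[TMHelix]) -> "ProteinArchitecture":
        return ProteinArchitecture(
            protein_id=self.protein_id,
            species_id=self.species_id,
            length=self.length,
            domains=self.domains,
            tm_raw=self.tm_raw,
            tm_corrected=tuple(helices),
            signal_peptide=self.signal_peptide,
        )


def _overlap(helix: TMHelix, sp_end: int) -> int:
    """Residues shared between a helix and the signal-peptide region 1..sp_end."""
    return max(0, min(helix.end, sp_end) - helix.start + 1)


def correct_tm_helices(
    tm_raw: Sequence[TMHelix],
    sp: Optional[SignalPeptide],
    min_overlap: int = 1,
) -> list[TMHelix]:
    """Drop predicted TM helices that overlap the predicted signal peptide.

    A helix is removed when it shares at least ``min_overlap`` residues with
    the signal-peptide region (residues 1..``sp.end``). With no signal
    peptide the input is returned unchanged. Order is preserved, so the
    operation is idempotent and monotone in the helix list.
    """
    if sp is None:
        return list(tm_raw)
    return [h for h in tm_raw if _overlap(h, sp.end) < min_overlap]


def build_architecture(
    protein: ProteinRecord,
    hits: Iterable[DomainHit] = (),
    tm_helices: Iterable[TMHelix] = (),
    sp: Optional[SignalPeptide] = None,
) -> ProteinArchitecture:
    """Join one protein's evidence into a :class:`ProteinArchitecture`.

    All evidence must reference ``protein.protein_id``; domains are sorted by
    (start, end, accession), identical hits are all retained, and the
    corrected helix list is computed via :func:`correct_tm_helices`.
    """
    hits = list(hits)
    tm_helices = list(tm_helices)
    for rec in [*hits, *tm_helices, *( [sp] if sp else [] )]:
        if rec.protein_id != protein.protein_id:
            raise ValidationError(
                f"evidence for {rec.protein_id!r} attached to protein {protein.protein_id!r}"
            )
    tm_raw = sorted(tm_helices, key=lambda h: (h.start, h.end))
    return ProteinArchitecture(
        protein_id=protein.protein_id,
        species_id=protein.species_id,
        length=protein.length,
        domains=tuple(sorted(hits, key=_DOMAIN_SORT_KEY)),
        tm_raw=tuple(tm_raw),
        tm_corrected=tuple(correct_tm_helices(tm_raw, sp)),
        signal_peptide=sp,
    )


def architecture_string(arch: ProteinArchitecture) -> str:
    """Render an architecture as a hyphen-joined token string.

    Tokens are Pfam accessions in domain order with ``TM`` interleaved at
    corrected-helix start positions and an ``SP`` prefix when a signal
    peptide is present; at equal start the domain precedes the helix.
    Example: ``SP-PF00560-TM-PF00069``.
    """
    events = [(h.start, 0, h.accession) for h in arch.domains]
    events += [(h.start, 1, "TM") for h in arch.tm_corrected]
    tokens = [token for _, _, token in sorted(events)]
    if arch.signal_peptide is not None:
        tokens.insert(0, "SP")
    return "-".join(tokens)


def count_lrr_domains(
    arch: ProteinArchitecture, lrr_accessions: frozenset = LRR_ACCESSIONS
) -> int:
    """Count LRR hits on a protein; hits are counted individually, not merged."""
    if not lrr_accessions:
        raise ValueError("lrr_accessions must be non-empty")
    return sum(1 for h in arch.domains if h.accession in lrr_accessions)
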