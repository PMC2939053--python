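"""Declarative receptor-class rules, per-species census and taxon summaries.

A class rule is a conjunction of clauses over a protein's architecture:
required accession groups (the protein needs at least one hit from *each*
group), forbidden accessions, a constraint on the number of corrected
transmembrane helices, and a signal-peptide requirement. Classes are
non-exclusive labels — a protein carrying both a TIR and a kinase domain is
counted as both a Toll-like receptor and an LRR-receptor kinase.

The built-in rule set encodes the receptor definitions used in comparative
surveys of LRR innate-immunity receptors: an LRR-receptor is a protein with
at least one LRR domain and a single (corrected) transmembrane helix; a
Toll-like receptor additionally carries a TIR domain (PF01582); an
LRR-receptor kinase a protein kinase domain (PF07714/PF00069); a secreted
LRR protein has a signal peptide and no transmembrane helix; fungal-style
LRR adenylate cyclases pair LRR domains with the adenylate/guanylate
cyclase catalytic domain (PF00211); plant-style NBS-LRR resistance proteins
pair NB-ARC (PF00931) with LRRs; STAND proteins combine a HET effector, a
NACHT domain (PF05729) and WD repeats.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .annotation_io import ProteinRecord, SpeciesTaxonomy, ValidationError
from .architecture import LRR_ACCESSIONS, ProteinArchitecture

__all__ = [
    "TMConstraint",
    "ClassRule",
    "ClassificationResult",
    "CensusTable",
    "TaxonSummary",
    "KINASE_ACCESSIONS",
    "PRR_ACCESSORY_DOMAINS",
    "DEFAULT_ACCESSORY_ACCESSIONS",
    "builtin_rules",
    "classify",
    "classify_all",
    "census",
    "summarize",
    "architecture_order_check",
    "validate_nesting",
    "rules_to_yaml",
    "rules_from_yaml",
]

#: Intracellular effector kinase domains of plant-style LRR-receptor kinases.
KINASE_ACCESSIONS = frozenset({"PF07714", "PF00069"})

#: Accessory domains of animal pattern-recognition receptors screened for
#: individually: immunoglobulin, C-type lectin, TIR, NOD, NODP, ITAM, Pyrin,
#: caspase recruitment (CARD).
PRR_ACCESSORY_DOMAINS: dict[str, frozenset] = {
    "PRR_IG": frozenset({"PF00047"}),
    "PRR_LECTIN_C": frozenset({"PF00059"}),
    "PRR_TIR": frozenset({"PF01582"}),
    "PRR_NOD": frozenset({"PF06816"}),
    "PRR_NODP": frozenset({"PF07684"}),
    "PRR_ITAM": frozenset({"PF02189", "PF10538"}),
    "PRR_PYRIN": frozenset({"PF02758"}),
    "PRR_CARD": frozenset({"PF00619"}),
}

#: Package defaults for the domain families whose Pfam accessions are
#: deployment configuration rather than part of the rule definitions
#: (current Pfam family accessions; override to match your Pfam release).
DEFAULT_ACCESSORY_ACCESSIONS: dict[str, frozenset] = {
    "het": frozenset({"PF06985"}),       # HET cell-death effector
    "wd": frozenset({"PF00400"}),        # WD40 repeat
    "lysm": frozenset({"PF01476"}),      # LysM
    "lrr_nt": frozenset({"PF01462"}),    # LRR N-terminal cap (LRRNT)
}


@dataclass(frozen=True)
class TMConstraint:
    """Constraint on the number of corrected transmembrane helices."""

    kind: str = "any"  # "any" | "exact" | "at_least"
    k: int = 0

    @classmethod
    def exactly(cls, k: int) -> "TMConstraint":
        return cls("exact", k)

    @classmethod
    def at_least(cls, k: int) -> "TMConstraint":
        return cls("at_least", k)

    @classmethod
    def any_(cls) -> "TMConstraint":
        return cls("any", 0)

    def satisfied_by(self, n_helices: int) -> bool:
        if self.kind == "any":
            return True
        if self.kind == "exact":
            return n_helices == self.k
        if self.kind == "at_least":
            return n_helices >= self.k
        raise ValueError(f"unknown TM constraint kind {self.kind!r}")


@dataclass(frozen=True)
class ClassRule:
    """One receptor-class definition over domain content, TM count and SP status."""

    name: str
    required_groups: tuple[frozenset, ...] = ()
    forbidden: frozenset = frozenset()
    tm: TMConstraint = TMConstraint.any_()
    signal_peptide: str = "any"  # "required" | "forbidden" | "any"

    def __post_init__(self):
        object.__setattr__(
            self, "required_groups", tuple(frozenset(g) for g in self.required_groups)
        )
        object.__setattr__(self, "forbidden", frozenset(self.forbidden))
        if self.signal_peptide not in ("required", "forbidden", "any"):
            raise ValueError(f"{self.name}: bad signal_peptide constraint {self.signal_peptide!r}")
        if any(not g for g in self.required_groups):
            raise ValueError(f"{self.name}: empty required accession group")
        constrained = (
            self.required_groups
            or self.forbidden
            or self.tm.kind != "any"
            or self.signal_peptide != "any"
        )
        if not constrained:
            raise ValueError(f"{self.name}: rule constrains nothing")

    def matches(self, arch: ProteinArchitecture) -> bool:
        accs = arch.accessions
        if any(not (group & accs) for group in self.required_groups):
            return False
        if self.forbidden & accs:
            return False
        if not self.tm.satisfied_by(len(arch.tm_corrected)):
            return False
        has_sp = arch.signal_peptide is not None
        if self.signal_peptide == "required" and not has_sp:
            return False
        if self.signal_peptide == "forbidden" and has_sp:
            return False
        return True


@dataclass(frozen=True)
class ClassificationResult:
    protein_id: str
    labels: frozenset


def builtin_rules(
    lrr_accessions: frozenset = LRR_ACCESSIONS,
    kinase_accessions: frozenset = KINASE_ACCESSIONS,
    het_accessions: Optional[frozenset] = None,
    wd_accessions: Optional[frozenset] = None,
    lysm_accessions: Optional[frozenset] = None,
) -> dict[str, ClassRule]:
    """The built-in receptor-class rule set, keyed by class name.

    ``het``/``wd``/``lysm`` accessions are deployment configuration: when
    omitted, the STAND and LysM-receptor-kinase rules are left out rather
    than guessed (``DEFAULT_ACCESSORY_ACCESSIONS`` offers current Pfam
    choices).
    """
    lrr = frozenset(lrr_accessions)
    kin = frozenset(kinase_accessions)
    one_tm = TMConstraint.exactly(1)
    rules = [
        ClassRule("LRR_PROTEIN", required_groups=(lrr,)),
        ClassRule("LRR_RECEPTOR", required_groups=(lrr,), tm=one_tm),
        ClassRule("TLR", required_groups=(lrr, frozenset({"PF01582"})), tm=one_tm),
        ClassRule("LRR_RK", required_groups=(lrr, kin), tm=one_tm),
        ClassRule(
            "SECRETED_LRR",
            required_groups=(lrr,),
            tm=TMConstraint.exactly(0),
            signal_peptide="required",
        ),
        ClassRule("LRR_AC", required_groups=(lrr, frozenset({"PF00211"}))),
        ClassRule("AC_PROTEIN", required_groups=(frozenset({"PF00211"}),)),
        ClassRule("NBS_LRR", required_groups=(frozenset({"PF00931"}), lrr)),
        ClassRule("NACHT_PROTEIN", required_groups=(frozenset({"PF05729"}),)),
        ClassRule("LRR_NACHT", required_groups=(lrr, frozenset({"PF05729"}))),
    ]
    if het_accessions and wd_accessions:
        rules.append(
            ClassRule(
                "STAND",
                required_groups=(
                    frozenset(het_accessions),
                    frozenset({"PF05729"}),
                    frozenset(wd_accessions),
                ),
            )
        )
    rules.extend(
        ClassRule(name, required_groups=(accs,)) for name, accs in PRR_ACCESSORY_DOMAINS.items()
    )
    if lysm_accessions:
        rules.append(
            ClassRule("LYSM_RK", required_groups=(frozenset(lysm_accessions), kin), tm=one_tm)
        )
    return {rule.name: rule for rule in rules}


def classify(arch: ProteinArchitecture, rules: Mapping[str, ClassRule]) -> ClassificationResult:
    """Label one architecture with every rule it satisfies.

    TM constraints are evaluated on the corrected helix list only; the
    signal-peptide overlap correction precedes all counting.
    """
    return ClassificationResult(
        protein_id=arch.protein_id,
        labels=frozenset(name for name, rule in rules.items() if rule.matches(arch)),
    )


def classify_all(
    archs: Iterable[ProteinArchitecture], rules: Mapping[str, ClassRule]
) -> list[ClassificationResult]:
    return [classify(a, rules) for a in archs]


@dataclass(frozen=True)
class CensusTable:
    """Species x class count matrix with explicit zeros and fixed orders."""

    species: tuple
    classes: tuple
    counts: Mapping

    def __post_init__(self):
        counts = dict(self.counts)
        for sid in self.species:
            for cname in self.classes:
                counts.setdefault((sid, cname), 0)
        for key, value in counts.items():
            if value < 0:
                raise ValidationError(f"negative census count for {key}")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "classes", tuple(self.classes))

    def count(self, species_id: str, class_name: str) -> int:
        return self.counts[(species_id, class_name)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [[self.count(s, c) for c in self.classes] for s in self.species],
            index=list(self.species),
            columns=list(self.classes),
        )


def census(
    results: Iterable[ClassificationResult],
    proteins: Iterable[ProteinRecord],
    rules: Mapping[str, ClassRule],
) -> CensusTable:
    """Count labelled proteins per species and class.

    Absent combinations are explicit zeros; species rows are sorted
    lexically so the census is independent of input order.
    """
    species_of = {p.protein_id: p.species_id for p in proteins}
    species = tuple(sorted(set(species_of.values())))
    classes = tuple(rules.keys())
    counts: dict = {(s, c): 0 for s in species for c in classes}
    for res in results:
        if res.protein_id not in species_of:
            raise ValidationError(f"classification for unknown protein {res.protein_id!r}")
        unknown = res.labels - set(classes)
        if unknown:
            raise ValidationError(f"{res.protein_id}: labels not in rule set: {sorted(unknown)}")
        sid = species_of[res.protein_id]
        for label in res.labels:
            counts[(sid, label)] += 1
    return CensusTable(species=species, classes=classes, counts=counts)


def validate_nesting(table: CensusTable) -> None:
    """Assert the class-containment laws the rule definitions imply.

    Within every species: TLR <= LRR_RECEPTOR <= LRR_PROTEIN and
    LRR_RK <= LRR_RECEPTOR (each stricter class adds a requirement).
    """
    chains = [("TLR", "LRR_RECEPTOR"), ("LRR_RK", "LRR_RECEPTOR"),
              ("LRR_RECEPTOR", "LRR_PROTEIN"), ("LRR_AC", "AC_PROTEIN"),
              ("LRR_NACHT", "NACHT_PROTEIN"), ("SECRETED_LRR", "LRR_PROTEIN")]
    for sid in table.species:
        for narrow, broad in chains:
            if narrow in table.classes and broad in table.classes:
                if table.count(sid, narrow) > table.count(sid, broad):
                    raise AssertionError(
                        f"{sid}: {narrow} count {table.count(sid, narrow)} exceeds "
                        f"{broad} count {table.count(sid, broad)}"
                    )


@dataclass(frozen=True)
class TaxonSummary:
    """Per-taxon aggregation of a census."""

    taxon: str
    n_species: int
    n_high_lrr: int        # species with >= `high` LRR proteins
    n_low_lrr: int         # species with < `low` LRR proteins
    n_receptor_free: int   # species with zero LRR receptors
    class_min: Mapping     # class -> (species_id, count)
    class_max: Mapping     # class -> (species_id, count)


def summarize(
    table: CensusTable,
    taxonomy: Sequence[SpeciesTaxonomy],
    high: int = 20,
    low: int = 10,
    level: int = 0,
    lrr_class: str = "LRR_PROTEIN",
    receptor_class: str = "LRR_RECEPTOR",
) -> dict[str, TaxonSummary]:
    """Aggregate a census per taxon group at one level of the taxon path.

    Reports, per group: species count, how many species carry at least
    ``high`` LRR proteins, how many carry fewer than ``low``, how many lack
    LRR receptors entirely, and the extreme species per class.
    """
    path_of = {t.species_id: t.taxon_path for t in taxonomy}
    missing = [s for s in table.species if s not in path_of]
    if missing:
        raise ValidationError(f"species in census but not in taxonomy: {missing}")
    groups: dict[str, list] = {}
    for sid in table.species:
        path = path_of[sid]
        label = path[level] if level < len(path) else path[-1]
        groups.setdefault(label, []).append(sid)
    out: dict[str, TaxonSummary] = {}
    for label in sorted(groups):
        members = groups[label]
        lrr_counts = {s: table.count(s, lrr_class) for s in members}
        class_min, class_max = {}, {}
        for cname in table.classes:
            per = [(table.count(s, cname), s) for s in members]
            lo, hi = min(per), max(per)
            class_min[cname] = (lo[1], lo[0])
            class_max[cname] = (hi[1], hi[0])
        out[label] = TaxonSummary(
            taxon=label,
            n_species=len(members),
            n_high_lrr=sum(1 for v in lrr_counts.values() if v >= high),
            n_low_lrr=sum(1 for v in lrr_counts.values() if v < low),
            n_receptor_free=sum(1 for s in members if table.count(s, receptor_class) == 0),
            class_min=class_min,
            class_max=class_max,
        )
    return out


def architecture_order_check(
    arch: ProteinArchitecture, expected_order: Sequence[str]
) -> bool:
    """Check that tracked domains appear N-to-C in the expected order.

    Restricted to accessions named in ``expected_order``, the protein's hits
    (in start order) must be a sequence whose accession ranks never
    decrease; accessions absent from the protein are simply skipped, so an
    architecture missing an optional N-terminal domain still passes.
    """
    if not expected_order:
        raise ValueError("expected_order must be non-empty")
    rank = {acc: i for i, acc in enumerate(expected_order)}
    ranks = [rank[h.accession] for h in arch.domains if h.accession in rank]
    return all(a <= b for a, b in zip(ranks, ranks[1:]))


# ---------------------------------------------------------------------------
# rule-set serialization (so users can add classes without code changes)

def rules_to_yaml(rules: Mapping[str, ClassRule]) -> str:
    doc = []
    for rule in rules.values():
        entry: dict = {"name": rule.name}
        if rule.required_groups:
            entry["required_groups"] = [sorted(g) for g in rule.required_groups]
        if rule.forbidden:
            entry["forbidden"] = sorted(rule.forbidden)
        if rule.tm.kind != "any":
            entry["tm"] = {"kind": rule.tm.kind, "k": rule.tm.k}
        if rule.signal_peptide != "any":
            entry["signal_peptide"] = rule.signal_peptide
        doc.append(entry)
    return yaml.safe_dump(doc, sort_keys=False)


def rules_from_yaml(text: str) -> dict[str, ClassRule]:
    doc = yaml.safe_load(text)
    if not isinstance(doc, list):
        raise ValueError("rule file must be a YAML list of rule mappings")
    rules = {}
    for entry in doc:
        tm_entry = entry.get("tm", {"kind": "any", "k": 0})
        rule = ClassRule(
            name=entry["name"],
            required_groups=tuple(frozenset(g) for g in entry.get("required_groups", [])),
            forbidden=frozenset(entry.get("forbidden", [])),
            tm=TMConstraint(tm_entry["kind"], tm_entry.get("k", 0)),
            signal_peptide=entry.get("signal_peptide", "any"),
        )
        if rule.name in rules:
            raise ValueError(f"duplicate rule name {rule.name!r}")
        rules[rule.name] = rule
    return rules
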