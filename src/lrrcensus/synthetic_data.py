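"""Synthetic annotated proteomes, similarity graphs and homolog families.

The generator emulates the statistical structure a receptor census reads:
each species draws proteins from a mixture of domain-architecture
templates (LRR-only, single-TM LRR receptors with TIR or kinase effectors,
secreted LRR proteins, multi-domain fungal adenylate cyclases, NACHT/STAND
combinations, untracked background), at species-specific frequencies, plus
two annotation artifacts with known ground truth:

* ``SP_TM_OVERLAP`` — a false transmembrane helix planted inside the
  signal-peptide region, emulating a topology predictor mistaking the
  signal peptide for a helix;
* ``NTERM_EXTENSION`` — a spurious N-terminal gene-model extension that
  carries the protein's only predicted TM helix, together with an aligned
  homolog family in which the extension is unsupported.

Planted truth labels are computed by running the classifier on the clean,
artifact-free architecture at generation time, so truth and rule set can
never drift apart. Residue content is uniform random: the pipeline
consumes annotations, not motifs, so sequence realism matters only where
slicing does.

Every stream is seeded per species from (seed, crc32(species_id)), making
species independently reproducible and whole datasets byte-identical for a
fixed seed.
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np

from .annotation_io import (
    DomainHit,
    ProteinRecord,
    SignalPeptide,
    TMHelix,
    atomic_write_text,
)
from .anomaly import HomologFamily
from .architecture import build_architecture
from .classifier import DEFAULT_ACCESSORY_ACCESSIONS, builtin_rules, classify
from .lrr_clustering import SimilarityEdge

__all__ = [
    "ArtifactRates",
    "SpeciesSpec",
    "LengthModel",
    "SimConfig",
    "TruthRecord",
    "ConfigError",
    "TEMPLATE_NAMES",
    "generate",
    "generate_dataset",
    "generate_similarity_graph",
    "generate_homolog_family",
    "write_family_fasta",
    "read_truth",
    "demo_config",
]

_AMINO_ACIDS = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype="S1")

#: Pfam families with no role in any built-in rule, used for background noise.
_DECOY_ACCESSIONS = ("PF00004", "PF00076", "PF00096")


class ConfigError(ValueError):
    """An invalid simulation configuration."""


@dataclass(frozen=True)
class ArtifactRates:
    sp_tm_overlap: float = 0.0
    nterm_extension: float = 0.0
    extension_length: int = 560

    def __post_init__(self):
        for rate in (self.sp_tm_overlap, self.nterm_extension):
            if not (0 <= rate <= 1):
                raise ConfigError(f"artifact rate {rate} outside [0, 1]")
        if self.extension_length < 1:
            raise ConfigError("extension_length must be >= 1")


@dataclass(frozen=True)
class SpeciesSpec:
    species_id: str
    taxon_path: tuple
    n_proteins: int
    architecture_frequencies: Mapping[str, float]
    artifact_rates: ArtifactRates = ArtifactRates()

    def __post_init__(self):
        object.__setattr__(self, "taxon_path", tuple(self.taxon_path))
        freqs = dict(self.architecture_frequencies)
        object.__setattr__(self, "architecture_frequencies", freqs)
        unknown = set(freqs) - set(TEMPLATE_NAMES)
        if unknown:
            raise ConfigError(f"{self.species_id}: unknown templates {sorted(unknown)}")
        if any(not (0 <= p <= 1) for p in freqs.values()):
            raise ConfigError(f"{self.species_id}: template probabilities outside [0, 1]")
        if sum(freqs.values()) > 1 + 1e-9:
            raise ConfigError(
                f"{self.species_id}: template frequencies sum to {sum(freqs.values()):.3f} > 1"
            )
        if self.n_proteins < 0:
            raise ConfigError(f"{self.species_id}: negative n_proteins")


@dataclass(frozen=True)
class LengthModel:
    """Length distribution (residues) for background proteins."""

    mean: float = 450.0
    sd: float = 150.0


@dataclass(frozen=True)
class SimConfig:
    seed: int
    species_specs: tuple
    length_model: LengthModel = LengthModel()

    def __post_init__(self):
        object.__setattr__(self, "species_specs", tuple(self.species_specs))
        ids = [s.species_id for s in self.species_specs]
        if len(ids) != len(set(ids)):
            raise ConfigError("duplicate species_id in config")


@dataclass(frozen=True)
class TruthRecord:
    protein_id: str
    template: str
    labels: frozenset
    artifacts: frozenset


# ---------------------------------------------------------------------------
# architecture templates

def _lrr_block(rng, n_min=1, n_max=4):
    k = int(rng.integers(n_min, n_max + 1))
    accs = ["PF00560"] * k
    # occasionally use the rarer LRR families
    for i in range(k):
        if rng.random() < 0.15:
            accs[i] = "PF07723" if rng.random() < 0.5 else "PF07725"
    return [("domain", acc, int(rng.integers(22, 29))) for acc in accs]


def _t_background(rng, acc):
    if rng.random() < 0.5:
        return []
    n = int(rng.integers(1, 3))
    return [
        ("domain", str(rng.choice(_DECOY_ACCESSIONS)), int(rng.integers(60, 200)))
        for _ in range(n)
    ]


def _t_lrr_only(rng, acc):
    return _lrr_block(rng)


def _t_lrr_1tm(rng, acc):
    return _lrr_block(rng) + [("tm", 21)]


def _t_lrr_1tm_tir(rng, acc):
    return _lrr_block(rng) + [("tm", 21), ("domain", "PF01582", 135)]


def _t_lrr_1tm_kinase(rng, acc):
    kin = "PF00069" if rng.random() < 0.8 else "PF07714"
    return _lrr_block(rng) + [("tm", 21), ("domain", kin, 250)]


def _t_sp_lrr_secreted(rng, acc):
    return [("sp",)] + _lrr_block(rng)


def _t_fungal_ac(rng, acc):
    # conserved N-to-C order: G-alpha binding, Ras association, LRR repeats,
    # protein phosphatase 2C, adenylate cyclase catalytic domain
    elements = []
    if rng.random() < 0.8:
        elements.append(("domain", "PF08509", 120))
        if rng.random() < 0.8:
            elements.append(("domain", "PF00788", 90))
    elements += _lrr_block(rng, 2, 5)
    elements.append(("domain", "PF00481", 250))
    elements.append(("domain", "PF00211", 180))
    return elements


def _t_nacht_wd(rng, acc):
    wd = sorted(acc["wd"])[0]
    return [("domain", "PF05729", 160)] + [("domain", wd, 40) for _ in range(3)]


def _t_het_nacht_wd(rng, acc):
    het = sorted(acc["het"])[0]
    return [("domain", het, 170)] + _t_nacht_wd(rng, acc)


_TEMPLATES: dict[str, Callable] = {
    "background": _t_background,
    "LRR_only": _t_lrr_only,
    "LRR_1TM": _t_lrr_1tm,
    "LRR_1TM_TIR": _t_lrr_1tm_tir,
    "LRR_1TM_KINASE": _t_lrr_1tm_kinase,
    "SP_LRR_secreted": _t_sp_lrr_secreted,
    "fungal_AC": _t_fungal_ac,
    "NACHT_WD": _t_nacht_wd,
    "HET_NACHT_WD": _t_het_nacht_wd,
}

TEMPLATE_NAMES = tuple(_TEMPLATES)


def _random_residues(rng, n: int) -> str:
    return _AMINO_ACIDS[rng.integers(0, 20, size=n)].tobytes().decode()


def _layout(rng, elements, length_model: LengthModel):
    """Place template elements N-to-C with random linkers; return evidence."""
    sp_end = None
    pos = 1
    if elements and elements[0][0] == "sp":
        sp_end = int(rng.integers(18, 31))
        pos = sp_end + 1
        elements = elements[1:]
    pos += int(rng.integers(5, 40))
    domains, tms = [], []
    for element in elements:
        if element[0] == "domain":
            _, accession, size = element
            domains.append((accession, pos, pos + size - 1))
        else:
            _, size = element
            tms.append((pos, pos + size - 1))
        pos += element[-1] + int(rng.integers(10, 60))
    if domains or tms:
        length = pos + int(rng.integers(20, 80))
    else:
        length = max(50, int(rng.normal(length_model.mean, length_model.sd)))
    return domains, tms, sp_end, length


def _species_rng(seed: int, species_id: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(species_id.encode())])


@dataclass
class _Proteome:
    proteins: list = field(default_factory=list)
    hits: list = field(default_factory=list)
    helices: list = field(default_factory=list)
    peptides: list = field(default_factory=list)
    truth: dict = field(default_factory=dict)
    families: dict = field(default_factory=dict)  # protein_id -> HomologFamily


def generate_dataset(config: SimConfig, rules=None) -> _Proteome:
    """Generate the in-memory dataset: records, truth labels, homolog families."""
    if rules is None:
        rules = builtin_rules(
            het_accessions=DEFAULT_ACCESSORY_ACCESSIONS["het"],
            wd_accessions=DEFAULT_ACCESSORY_ACCESSIONS["wd"],
            lysm_accessions=DEFAULT_ACCESSORY_ACCESSIONS["lysm"],
        )
    data = _Proteome()
    for spec in sorted(config.species_specs, key=lambda s: s.species_id):
        rng = _species_rng(config.seed, spec.species_id)
        names = sorted(spec.architecture_frequencies)
        probs = np.array([spec.architecture_frequencies[n] for n in names])
        for index in range(spec.n_proteins):
            pid = f"{spec.species_id}_p{index:05d}"
            u = rng.random()
            cum = np.cumsum(probs)
            chosen = "background"
            for name, edge in zip(names, cum):
                if u < edge:
                    chosen = name
                    break
            elements = _TEMPLATES[chosen](rng, DEFAULT_ACCESSORY_ACCESSIONS)
            domains, tms, sp_end, length = _layout(rng, elements, config.length_model)

            artifacts = set()
            rates = spec.artifact_rates
            has_lrr = any(
                acc in ("PF00560", "PF07723", "PF07725") for acc, _, _ in domains
            )
            if sp_end is not None and not tms and rng.random() < rates.sp_tm_overlap:
                artifacts.add("SP_TM_OVERLAP")
            if (
                sp_end is None
                and not tms
                and has_lrr
                and rng.random() < rates.nterm_extension
            ):
                artifacts.add("NTERM_EXTENSION")

            ext = rates.extension_length if "NTERM_EXTENSION" in artifacts else 0
            full_length = length + ext
            sequence = _random_residues(rng, full_length)

            hit_records = [
                DomainHit(
                    protein_id=pid,
                    accession=acc,
                    name=acc,
                    start=start + ext,
                    end=end + ext,
                    bit_score=round(float(rng.uniform(25, 300)), 1),
                    e_value=float(10.0 ** -rng.uniform(6, 40)),
                )
                for acc, start, end in domains
            ]
            tm_records = [
                TMHelix(protein_id=pid, start=s + ext, end=e + ext) for s, e in tms
            ]
            sp_record = SignalPeptide(protein_id=pid, end=sp_end) if sp_end else None
            if "SP_TM_OVERLAP" in artifacts:
                tm_records.append(TMHelix(protein_id=pid, start=2, end=sp_end))
            if ext:
                mid = ext // 2
                tm_records.append(TMHelix(protein_id=pid, start=mid + 1, end=mid + 21))
                data.families[pid] = _extension_family(rng, pid, sequence, ext)

            protein = ProteinRecord(
                protein_id=pid,
                species_id=spec.species_id,
                length=full_length,
                sequence=sequence,
            )
            # truth labels come from the clean architecture: no planted
            # artifact helix, no spurious extension coordinates
            clean_hits = [
                DomainHit(
                    protein_id=pid, accession=h.accession, name=h.name,
                    start=h.start - ext, end=h.end - ext,
                    bit_score=h.bit_score, e_value=h.e_value,
                )
                for h in hit_records
            ]
            clean_tm = [
                TMHelix(protein_id=pid, start=s, end=e) for s, e in tms
            ]
            clean_protein = ProteinRecord(
                protein_id=pid, species_id=spec.species_id, length=length,
                sequence=sequence[ext:],
            )
            clean_arch = build_architecture(clean_protein, clean_hits, clean_tm, sp_record)
            labels = classify(clean_arch, rules).labels

            data.proteins.append(protein)
            data.hits.extend(sorted(hit_records, key=lambda h: (h.start, h.end, h.accession)))
            data.helices.extend(sorted(tm_records, key=lambda h: (h.start, h.end)))
            if sp_record:
                data.peptides.append(sp_record)
            data.truth[pid] = TruthRecord(
                protein_id=pid,
                template=chosen,
                labels=frozenset(labels),
                artifacts=frozenset(artifacts),
            )
    return data


def _extension_family(rng, pid: str, sequence: str, ext: int, n_homologs: int = 4,
                      mutation_rate: float = 0.1) -> HomologFamily:
    """Aligned family in which homologs lack the query's N-terminal extension."""
    core = sequence[ext:]
    rows = {pid: sequence}
    for i in range(n_homologs):
        mutated = _mutate(rng, core, mutation_rate)
        rows[f"{pid}_hom{i}"] = "-" * ext + mutated
    return HomologFamily(query_id=pid, rows=rows)


def _mutate(rng, residues: str, rate: float) -> str:
    arr = np.frombuffer(residues.encode(), dtype="S1").copy()
    mask = rng.random(len(arr)) < rate
    arr[mask] = _AMINO_ACIDS[rng.integers(0, 20, size=int(mask.sum()))]
    return arr.tobytes().decode()


def generate(config: SimConfig, out_dir: Union[str, os.PathLike], rules=None) -> dict:
    """Generate a dataset and write it to ``out_dir`` in the dialects the
    readers consume; returns the ground-truth mapping.

    Files: proteins.fasta, domains.tsv, tm.tsv, sp.tsv, taxonomy.tsv,
    truth.tsv, and alignments/<protein_id>.afa for each planted
    N-terminal-extension family. Byte-identical for a fixed seed.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    data = generate_dataset(config, rules=rules)

    fasta = "".join(f">{p.protein_id}\n{p.sequence}\n" for p in data.proteins)
    atomic_write_text(os.path.join(out_dir, "proteins.fasta"), fasta)

    dom_lines = [
        f"{h.protein_id}\t{h.accession}\t{h.name or h.accession}\t{h.start}\t{h.end}"
        f"\t{h.bit_score}\t{h.e_value:.3g}"
        for h in data.hits
    ]
    atomic_write_text(os.path.join(out_dir, "domains.tsv"), "\n".join(dom_lines) + ("\n" if dom_lines else ""))

    tm_lines = [f"{h.protein_id}\t{h.start}\t{h.end}" for h in data.helices]
    atomic_write_text(os.path.join(out_dir, "tm.tsv"), "\n".join(tm_lines) + ("\n" if tm_lines else ""))

    sp_lines = [f"{p.protein_id}\t{p.end}" for p in data.peptides]
    atomic_write_text(os.path.join(out_dir, "sp.tsv"), "\n".join(sp_lines) + ("\n" if sp_lines else ""))

    tax_lines = [
        f"{s.species_id}\t{'/'.join(s.taxon_path)}"
        for s in sorted(config.species_specs, key=lambda s: s.species_id)
    ]
    atomic_write_text(os.path.join(out_dir, "taxonomy.tsv"), "\n".join(tax_lines) + "\n")

    truth_lines = [
        f"{t.protein_id}\t{t.template}\t{';'.join(sorted(t.labels))}\t{';'.join(sorted(t.artifacts))}"
        for t in (data.truth[p.protein_id] for p in data.proteins)
    ]
    atomic_write_text(os.path.join(out_dir, "truth.tsv"), "\n".join(truth_lines) + ("\n" if truth_lines else ""))

    if data.families:
        align_dir = os.path.join(out_dir, "alignments")
        os.makedirs(align_dir, exist_ok=True)
        for pid in sorted(data.families):
            write_family_fasta(data.families[pid], os.path.join(align_dir, f"{pid}.afa"))
    return data.truth


def write_family_fasta(family: HomologFamily, path) -> None:
    chunks = [f">{family.query_id}\n{family.rows[family.query_id]}\n"]
    chunks += [
        f">{label}\n{row}\n" for label, row in family.rows.items() if label != family.query_id
    ]
    atomic_write_text(path, "".join(chunks))


def read_truth(source) -> dict:
    """Read truth.tsv back into a protein_id -> TruthRecord mapping."""
    from .annotation_io import _iter_lines

    out = {}
    for _, line in _iter_lines(source):
        if not line.strip():
            continue
        pid, template, labels, artifacts = line.split("\t")
        out[pid] = TruthRecord(
            protein_id=pid,
            template=template,
            labels=frozenset(l for l in labels.split(";") if l),
            artifacts=frozenset(a for a in artifacts.split(";") if a),
        )
    return out


def generate_similarity_graph(
    cluster_sizes: Union[int, Sequence[int]],
    n_clusters: Optional[int] = None,
    within_e: tuple = (-50.0, -20.0),
    between_e: tuple = (-10.0, -1.0),
    seed: int = 0,
    separable: bool = True,
    between_density: float = 0.3,
):
    """Planted-partition similarity graph: (edges, node -> cluster index).

    Within-cluster pairs all get e-values drawn as 10**U(within_e);
    between-cluster pairs appear with ``between_density`` and e-values from
    ``between_e``. In separable mode the within range must lie entirely
    below the between range so an e-value cutoff between them removes
    every between-cluster edge.
    """
    if isinstance(cluster_sizes, int):
        if n_clusters is None:
            raise ConfigError("n_clusters required when cluster_sizes is a single int")
        sizes = [cluster_sizes] * n_clusters
    else:
        sizes = list(cluster_sizes)
    if separable and within_e[1] >= between_e[0]:
        raise ConfigError(
            f"separable mode needs within_e < between_e, got {within_e} vs {between_e}"
        )
    rng = np.random.default_rng(seed)
    partition: dict[str, int] = {}
    members: list[list[str]] = []
    for ci, size in enumerate(sizes):
        ids = [f"c{ci:02d}_n{ni:02d}" for ni in range(size)]
        members.append(ids)
        for node in ids:
            partition[node] = ci
    edges = []
    for ids in members:
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                e_val = float(10.0 ** rng.uniform(*within_e))
                edges.append(SimilarityEdge(a=a, b=b, e_value=e_val))
    for ci, ids_a in enumerate(members):
        for ids_b in members[ci + 1 :]:
            for a in ids_a:
                for b in ids_b:
                    if rng.random() < between_density:
                        e_val = float(10.0 ** rng.uniform(*between_e))
                        edges.append(SimilarityEdge(a=a, b=b, e_value=e_val))
    return edges, partition


def generate_homolog_family(
    query_length: int,
    overhang: int,
    n_homologs: int,
    seed: int = 0,
    query_id: str = "query",
    mutation_rate: float = 0.1,
):
    """Planted homolog family: the query's first ``overhang`` residues are
    unsupported by every homolog. Returns (family, planted overhang)."""
    if n_homologs < 1:
        raise ConfigError("n_homologs must be >= 1")
    if not (0 <= overhang < query_length):
        raise ConfigError("overhang must satisfy 0 <= overhang < query_length")
    rng = np.random.default_rng(seed)
    query = _random_residues(rng, query_length)
    rows = {query_id: query}
    core = query[overhang:]
    for i in range(n_homologs):
        rows[f"{query_id}_hom{i}"] = "-" * overhang + _mutate(rng, core, mutation_rate)
    return HomologFamily(query_id=query_id, rows=rows), overhang


#: Per-taxon architecture-frequency profiles emulating the broad cross-taxon
#: differences a receptor census is designed to resolve: fungi carry LRR-only
#: proteins, one multi-domain LRR adenylate cyclase lineage, secreted LRRs and
#: NACHT/STAND proteins but (almost) no single-TM LRR receptors; land-plant-like
#: and oomycete-like proteomes are rich in LRR-receptor kinases; metazoan-like
#: proteomes in Toll-like receptors.
_TAXON_PROFILES: dict[str, dict] = {
    "fungi": {
        "LRR_only": 0.012, "fungal_AC": 0.002, "SP_LRR_secreted": 0.003,
        "NACHT_WD": 0.004, "HET_NACHT_WD": 0.002,
    },
    "viridiplantae": {
        "LRR_only": 0.03, "LRR_1TM": 0.01, "LRR_1TM_KINASE": 0.04,
        "SP_LRR_secreted": 0.006,
    },
    "metazoa": {
        "LRR_only": 0.025, "LRR_1TM": 0.012, "LRR_1TM_TIR": 0.015,
        "SP_LRR_secreted": 0.005,
    },
    "stramenopiles": {
        "LRR_only": 0.015, "LRR_1TM": 0.006, "LRR_1TM_KINASE": 0.015,
        "SP_LRR_secreted": 0.004,
    },
}


def benchmark_config(
    seed: int,
    n_species: int = 20,
    n_proteins: int = 500,
    sp_tm_overlap: float = 0.0,
    nterm_extension: float = 0.0,
) -> SimConfig:
    """Multi-taxon benchmark proteome set: ``n_species`` species cycled over
    the four taxon profiles, ``n_proteins`` proteins each."""
    taxa = sorted(_TAXON_PROFILES)
    specs = []
    for i in range(n_species):
        taxon = taxa[i % len(taxa)]
        specs.append(
            SpeciesSpec(
                species_id=f"{taxon[:4]}{i:03d}",
                taxon_path=(taxon,),
                n_proteins=n_proteins,
                architecture_frequencies=_TAXON_PROFILES[taxon],
                artifact_rates=ArtifactRates(
                    sp_tm_overlap=sp_tm_overlap, nterm_extension=nterm_extension
                ),
            )
        )
    return SimConfig(seed=seed, species_specs=tuple(specs))


def demo_config(seed: int = 7) -> SimConfig:
    """A small three-species demonstration configuration."""
    fungal = {
        "LRR_only": 0.10, "fungal_AC": 0.02, "SP_LRR_secreted": 0.03,
        "NACHT_WD": 0.03, "HET_NACHT_WD": 0.01,
    }
    plant_like = {
        "LRR_only": 0.15, "LRR_1TM": 0.05, "LRR_1TM_KINASE": 0.10,
        "SP_LRR_secreted": 0.03,
    }
    animal_like = {
        "LRR_only": 0.12, "LRR_1TM": 0.05, "LRR_1TM_TIR": 0.08,
        "SP_LRR_secreted": 0.02,
    }
    return SimConfig(
        seed=seed,
        species_specs=(
            SpeciesSpec("fungus_a", ("fungi", "ascomycota"), 40, fungal,
                        ArtifactRates(sp_tm_overlap=0.2, nterm_extension=0.2)),
            SpeciesSpec("oomycete_a", ("stramenopiles", "oomycota"), 40, plant_like),
            SpeciesSpec("metazoan_a", ("metazoa", "chordata"), 40, animal_like),
        ),
    )
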