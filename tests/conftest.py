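import pytest

from lrrcensus.annotation_io import DomainHit, ProteinRecord, SignalPeptide, TMHelix
from lrrcensus.architecture import build_architecture
from lrrcensus.classifier import DEFAULT_ACCESSORY_ACCESSIONS, builtin_rules


@pytest.fixture(scope="session")
def rules():
    """Built-in rule set with the package's default accessory accessions."""
    return builtin_rules(
        het_accessions=DEFAULT_ACCESSORY_ACCESSIONS["het"],
        wd_accessions=DEFAULT_ACCESSORY_ACCESSIONS["wd"],
        lysm_accessions=DEFAULT_ACCESSORY_ACCESSIONS["lysm"],
    )


def make_arch(
    pid="p1",
    species="s1",
    length=1000,
    domains=(),   # iterable of (accession, start, end)
    helices=(),   # iterable of (start, end)
    sp_end=None,
):
    """Build a ProteinArchitecture from compact domain/helix descriptions."""
    protein = ProteinRecord(protein_id=pid, species_id=species, length=length)
    hits = [
        DomainHit(protein_id=pid, accession=acc, start=start, end=end)
        for acc, start, end in domains
    ]
    tms = [TMHelix(protein_id=pid, start=s, end=e) for s, e in helices]
    sp = SignalPeptide(protein_id=pid, end=sp_end) if sp_end else None
    return build_architecture(protein, hits, tms, sp)


@pytest.fixture
def arch_factory():
    return make_arch
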