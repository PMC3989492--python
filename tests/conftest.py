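import pytest

from primerforge.pipeline import design_primer_pairs
from primerforge.seqio import Lineage, SeqRecord
from primerforge.synthetic_data import default_community_spec, generate_alignment
from primerforge.window_scan import WindowResult


@pytest.fixture(scope="session")
def community():
    """A deterministic synthetic community shared across the suite."""
    return generate_alignment(default_community_spec(seed=3))


@pytest.fixture(scope="session")
def pipeline_result(community):
    refs = community.references_by_origin()
    return design_primer_pairs(
        community.prokaryote_alignment(),
        reference_id="REF",
        prok_records=community.prokaryote_records(),
        mito_records=refs.get("mitochondrion", []),
        euk_records=refs.get("eukaryote", []),
    )


def make_window(ref_pos, consensus, coverage=None, start_col=None, freq=1):
    """Minimal WindowResult factory for merge/selection tests."""
    return WindowResult(
        start_col=start_col if start_col is not None else ref_pos,
        ref_pos=ref_pos,
        width=len(consensus),
        consensus=consensus,
        consensus_freq=freq,
        phylum_coverage=dict(coverage or {}),
    )


def make_record(seq, rec_id="r", phylum=None, genus=None, origin=None, species=None):
    lineage = None
    if phylum or genus or species:
        lineage = Lineage(phylum=phylum, genus=genus, species=species)
    return SeqRecord(id=rec_id, sequence=seq, lineage=lineage, origin=origin)
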