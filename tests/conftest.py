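import pytest

from famsurvey import identify, io, phylo
from famsurvey.simulate import FamilySimConfig, simulate_family_genome

SIM_SEED = 11


@pytest.fixture(scope="session")
def sim():
    """The default synthetic family genome used across the suite."""
    return simulate_family_genome(FamilySimConfig(seed=SIM_SEED))


@pytest.fixture(scope="session")
def sim_dir(sim, tmp_path_factory):
    out = tmp_path_factory.mktemp("simfix")
    sim.write(out)
    return out


@pytest.fixture(scope="session")
def annotation(sim_dir):
    return io.read_gff3(sim_dir / "genes.gff3")


@pytest.fixture(scope="session")
def named_family(sim, sim_dir, annotation):
    """Identified, subfamily-assigned and named family from the fixture."""
    proteome = io.read_fasta(sim_dir / "proteome.fa")
    anchors = io.read_fasta(sim_dir / "anchors.fa")
    dom, _ = identify.domain_screen(proteome)
    hom = identify.homology_screen(anchors, proteome)
    key = identify.keyword_screen(io.read_tsv(sim_dir / "annotations.tsv"))
    family = identify.merge_and_deduplicate([dom, hom, key], proteome, annotation)
    recs = [(g.locus.locus_id, g.protein.sequence) for g in family] + anchors
    dm = phylo.pairwise_poisson_matrix(recs)
    subs = phylo.assign_subfamilies(dm, sim.anchor_map)
    return identify.assign_family_names(family, subs)
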