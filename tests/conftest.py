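import pytest

from slimtriage.fixtures import FixtureSpec, generate, write_bundle
from slimtriage.motifs import compile_motif_pattern


@pytest.fixture(scope="session")
def ptb_motif():
    """The 4-residue phosphotyrosine-binding-domain ligand pattern."""
    return compile_motif_pattern("NP.[YF]", identifier="LIG_PTB")


@pytest.fixture(scope="session")
def calmodulin_motif():
    """The 8-residue helical calmodulin-binding pattern."""
    return compile_motif_pattern(
        "W[^P][^P][^P][IL][^P][AGS][AT]", identifier="LIG_CAM"
    )


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """One noise-free planted bundle, generated once per session."""
    spec = FixtureSpec(seed=7)
    bundle = generate(spec)
    root = write_bundle(bundle, tmp_path_factory.mktemp("bundle") / "b7")
    return bundle, root


@pytest.fixture(scope="session")
def toy_ontology():
    """Small cellular-component hierarchy parsed from OBO text."""
    import obonet

    from slimtriage.fixtures import _TOY_OBO

    path = None
    import io

    return obonet.read_obo(io.StringIO(_TOY_OBO))
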