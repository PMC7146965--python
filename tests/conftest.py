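import pytest

from macroforge.model import Fragment, FragmentKind, FragmentLibrary
from macroforge.stereo import classify_join_stereo


def library_from_bodies(bodies, kind="SM"):
    """Build an in-memory library straight from SMILES bodies."""
    kind = FragmentKind(kind)
    return FragmentLibrary(
        [
            Fragment(
                id=f"{kind.value}{i + 1:03d}",
                kind=kind,
                body=body,
                join_stereo=classify_join_stereo(body),
            )
            for i, body in enumerate(bodies)
        ],
        kind=kind,
    )


def make_chain_core_text(p_sm: int, p_sugar: int) -> str:
    """A small macrolactone core with the requested slot counts, slots
    in-chain inside the ring."""
    return (
        "CC1OC(=O)"
        + "[*]C" * p_sm
        + "[*sugar*]C" * p_sugar
        + "CC1"
    )


@pytest.fixture
def sm_file(tmp_path):
    path = tmp_path / "sms.txt"
    path.write_text("[R]C(C)[R]\n[R][C@H](C)O[R]\n[R]CC[R]\n")
    return path


@pytest.fixture
def sugar_file(tmp_path):
    path = tmp_path / "sugars.txt"
    path.write_text("[R][C@H](OCC(O)C(O)CO)[R]\n[R]C(OCC(O)C(O)CO)[R]\n")
    return path
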