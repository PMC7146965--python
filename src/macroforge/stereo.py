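"""Stereocenter handling at fragment joining atoms.

A fragment's *joining atom* is its first body atom — the one bonded into the
macrocycle through the leading ``[R]`` anchor.  When stereo enumeration is
enabled, fragments whose joining atom carries a defined tetrahedral tag are
expanded into both parity configurations (``@`` and ``@@``).  No CIP R/S
assignment is attempted: the two parities are generated and both kept, since
which configuration is biosynthetically accessible is an open question.

Detection is performed on the fragment capped with a dummy atom ``*`` in
place of each anchor, so that neighbour-count-dependent chirality perception
is well defined.  A tagged joining atom that is not a true stereocenter after
capping (e.g. two identical substituents) is not expanded.
"""

from __future__ import annotations

from rdkit import Chem
from rdkit import RDLogger

from .model import (
    Fragment,
    FragmentLibrary,
    JoinStereo,
    StereoExpansionResult,
)

RDLogger.DisableLog("rdApp.warning")


class FragmentChemistryError(ValueError):
    """Raised when a fragment body cannot be parsed as capped SMILES."""


def cap_body(body: str) -> str:
    """Substitute each anchor position with a dummy-atom neighbour."""
    return "*" + body + "*"


def _capped_mol(body: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(cap_body(body))
    if mol is None:
        raise FragmentChemistryError(
            f"fragment body {body!r} does not parse as SMILES when capped"
        )
    return mol


def classify_join_stereo(body: str) -> JoinStereo:
    """Classify the stereo status of a body's joining atom.

    The capped molecule's atom 1 (atom 0 is the leading dummy cap) is the
    joining atom; SMILES atom order follows the text.
    """
    mol = _capped_mol(body)
    centers = dict(
        Chem.FindMolChiralCenters(
            mol, includeUnassigned=True, useLegacyImplementation=False
        )
    )
    code = centers.get(1)
    if code is None:
        return JoinStereo.NONE
    if code == "?":
        return JoinStereo.UNDEFINED
    return JoinStereo.DEFINED


def flip_join_parity(body: str) -> str:
    """Return the body with the joining atom's parity tag inverted.

    The joining atom is the first atom token of the body; DEFINED fragments
    always spell it as a bracket atom carrying ``@`` or ``@@``.  The rest of
    the body is preserved byte-for-byte.
    """
    if not body.startswith("["):
        raise FragmentChemistryError(
            f"joining atom of {body!r} is not a bracket atom; no parity tag"
        )
    end = body.index("]")
    token = body[: end + 1]
    if "@@" in token:
        flipped = token.replace("@@", "@", 1)
    elif "@" in token:
        flipped = token.replace("@", "@@", 1)
    else:
        raise FragmentChemistryError(
            f"joining atom token {token!r} carries no parity tag"
        )
    return flipped + body[end + 1 :]


def _parity_of(body: str) -> str:
    end = body.index("]")
    return "@@" if "@@" in body[: end + 1] else "@"


def expand_fragment_stereocenters(fragment: Fragment) -> StereoExpansionResult:
    """Expand a fragment into both joining-atom configurations.

    Fragments with a DEFINED joining stereocenter yield two variants — the
    original plus a tag-flipped copy — tagged with their parity and suffixed
    ``a`` / ``b`` in emission order.  UNDEFINED or NONE fragments are passed
    through unchanged, as are fragments whose tag survives capping as a
    non-stereocenter.
    """
    if fragment.join_stereo is not JoinStereo.DEFINED:
        return StereoExpansionResult(fragment.id, (fragment,), False)
    flipped_body = flip_join_parity(fragment.body)
    original = fragment.with_body(
        fragment.body, id=fragment.id + "a", variant_tag=_parity_of(fragment.body)
    )
    flipped = fragment.with_body(
        flipped_body, id=fragment.id + "b", variant_tag=_parity_of(flipped_body)
    )
    return StereoExpansionResult(fragment.id, (original, flipped), True)


def expand_library(lib: FragmentLibrary, enabled: bool = True) -> FragmentLibrary:
    """Stereo-expand a whole library, preserving file order.

    With expansion disabled the library is returned as-is (anchors were
    already stripped at load time).  Enabled, each DEFINED fragment
    contributes its two variants consecutively, so the expanded size is
    ``2*k + (n - k)`` for ``k`` DEFINED fragments out of ``n``.
    """
    if not enabled:
        return lib
    expanded: list[Fragment] = []
    for frag in lib:
        expanded.extend(expand_fragment_stereocenters(frag).variants)
    return FragmentLibrary(expanded, kind=lib.kind, source_path=lib.source_path)
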