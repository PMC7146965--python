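"""Deterministic toy inputs and an independent brute-force oracle.

Everything needed to exercise the full pipeline without any external input:
small marked cores, fragment libraries with a controlled number of defined
joining-atom stereocenters, and an exhaustive reference enumerator that
materializes every constrained product by its own textual machinery.  Toy
fragment bodies come from fixed whitelists of short in-chain units, verified
chiral (or not) at generation time, so engine tests isolate combinatorial
logic from chemistry edge cases; none of them uses ring-closure digits.
"""

from __future__ import annotations

import itertools
import random
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from rdkit import Chem

from .model import (
    ANCHOR,
    DEFAULT_HYDROXYL_BODY,
    Fragment,
    FragmentKind,
    FragmentLibrary,
    JoinStereo,
)
from .stereo import classify_join_stereo

#: a small macrocyclic core: a 12-membered lactone with two SM slots and
#: one sugar slot, structurally analogous to the published erythromycin
#: core (slots in-chain, ring digit 1 spanning the slots).
TOY_MACROCYCLE_CORE = "CC1OC(=O)[*]C[*sugar*]CC[*]C(=O)C1"

#: the marked erythromycin core used for the V1B build (5 SM slots,
#: 2 sugar slots), whitespace-cleaned.
ERYTHROMYCIN_CORE = (
    "CC[C@H]1OC(=O)[*][*sugar*][C@H](C)[*sugar*][*]C[*]C(=O)[*]"
    "[C@@H](O)[*]1"
)

# candidate in-chain bodies; each is filtered through the stereo classifier
# at generation time so counts are guaranteed, not assumed.
_ACHIRAL_SM_BODIES = [
    "C(C)", "CC", "CCC", "C(C)(C)", "CC(C)C", "CCCC", "C(C)C", "CCC(C)",
]
_CHIRAL_SM_BODIES = [
    "[C@H](C)O", "[C@@H](C)N", "[C@H](F)CC", "[C@@H](O)CC", "[C@H](Cl)C",
    "[C@H](C)CO", "[C@@H](F)CO", "[C@H](N)CC", "[C@@H](Cl)CC",
    "[C@H](O)CO", "[C@@H](C)CN", "[C@H](C)CC", "[C@@H](N)CO",
    "[C@H](F)C", "[C@@H](O)CN",
]
# sugar-like bodies: an in-chain carbon bearing a polyol ether chain, each
# adding well over 100 g/mol to the product.
_ACHIRAL_SUGAR_BODIES = [
    "C(OCC(O)C(O)CO)", "C(OCC(O)C(O)CO)C", "C(OCC(O)CC(O)CO)",
    "C(OCC(O)C(O)CO)CC", "C(OCC(O)CC(O)CO)C", "C(OCC(O)C(O)CCO)",
]
_CHIRAL_SUGAR_BODIES = [
    "[C@H](OCC(O)C(O)CO)", "[C@@H](OCC(O)C(O)CO)C",
    "[C@H](OCC(O)CC(O)CO)", "[C@@H](OCC(O)C(O)CO)CC",
    "[C@H](OCC(O)C(O)CO)C(C)", "[C@@H](OCC(O)CC(O)CO)C",
    "[C@H](OCC(O)C(O)CO)CC", "[C@@H](OCC(O)C(O)CO)CO",
    "[C@H](OCC(O)CC(O)CO)CC",
]


@dataclass(frozen=True)
class ToyLibrarySpec:
    """Recipe for a deterministic toy fragment library."""

    n_fragments: int
    n_with_join_stereo: int
    kind: FragmentKind = FragmentKind.SM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_with_join_stereo > self.n_fragments:
            raise ValueError("n_with_join_stereo cannot exceed n_fragments")


def _verified(bodies: Sequence[str], defined: bool) -> list[str]:
    """Keep bodies whose joining atom does (or does not) expand."""
    out = []
    for body in bodies:
        is_defined = classify_join_stereo(body) is JoinStereo.DEFINED
        if is_defined == defined:
            out.append(body)
    return out


def make_toy_fragments(spec: ToyLibrarySpec) -> FragmentLibrary:
    """Build a toy library with exactly the requested stereo composition.

    Bodies are drawn from the whitelists (shuffled deterministically by the
    seed) and re-verified against the joining-atom classifier, so a library
    of ``n`` fragments with ``k`` defined joining stereocenters expands to
    exactly ``2k + (n - k)`` fragments under stereo enumeration.
    """
    kind = FragmentKind(spec.kind)
    if kind is FragmentKind.SUGAR:
        chiral = _verified(_CHIRAL_SUGAR_BODIES, defined=True)
        achiral = _verified(_ACHIRAL_SUGAR_BODIES, defined=False)
    else:
        chiral = _verified(_CHIRAL_SM_BODIES, defined=True)
        achiral = _verified(_ACHIRAL_SM_BODIES, defined=False)
    rng = random.Random(spec.seed)
    rng.shuffle(chiral)
    rng.shuffle(achiral)
    n_plain = spec.n_fragments - spec.n_with_join_stereo
    if spec.n_with_join_stereo > len(chiral) or n_plain > len(achiral):
        raise ValueError(
            f"whitelists too small for {spec.n_fragments} fragments "
            f"({spec.n_with_join_stereo} chiral)"
        )
    bodies = chiral[: spec.n_with_join_stereo] + achiral[:n_plain]
    fragments = [
        Fragment(
            id=f"{kind.value}{i + 1:03d}",
            kind=kind,
            body=body,
            join_stereo=classify_join_stereo(body),
        )
        for i, body in enumerate(bodies)
    ]
    return FragmentLibrary(fragments, kind=kind, source_path=None)


def write_fragment_file(lib: FragmentLibrary, path: str | Path) -> Path:
    """Serialize a library to the anchored one-fragment-per-line format."""
    path = Path(path)
    path.write_text(
        "".join(f"{ANCHOR}{frag.body}{ANCHOR}\n" for frag in lib)
    )
    return path


_ORACLE_MARKER_RE = re.compile(r"(\[\d*\*\]|\[\*sugar\*\])")


def brute_force_enumerate(
    core_text: str,
    sm_bodies: Sequence[str],
    sugar_bodies: Sequence[str],
    max_repeats: int,
    min_sugars: int,
    hydroxyl_body: str = DEFAULT_HYDROXYL_BODY,
    limit: int = 10**6,
) -> set[str]:
    """Exhaustive reference enumeration, independent of the engine.

    Splits the core with its own marker regex, materializes the full
    unconstrained product (sugar slots draw from sugars plus the hydroxyl
    filler), filters by the repeat and min-sugars constraints, splices
    textually, canonicalizes and deduplicates.  Intentionally shares no
    code with the streaming enumerator.
    """
    pieces = _ORACLE_MARKER_RE.split("".join(core_text.split()))
    slot_kinds = []  # parallel to marker pieces
    choices: list[list[tuple[str, str]]] = []  # (identity, body)
    for piece in pieces[1::2]:
        if piece == "[*sugar*]":
            slot_kinds.append("SUGAR")
            choices.append(
                [(f"G{i}", b) for i, b in enumerate(sugar_bodies)]
                + [("OH", hydroxyl_body)]
            )
        else:
            slot_kinds.append("SM")
            choices.append([(f"M{i}", b) for i, b in enumerate(sm_bodies)])
    total = 1
    for c in choices:
        total *= len(c)
    if total > limit:
        raise ValueError(f"raw product {total} exceeds oracle limit {limit}")

    results: set[str] = set()
    for combo in itertools.product(*choices):
        sm_ids = [ident for (ident, _), k in zip(combo, slot_kinds) if k == "SM"]
        if sm_ids and max(sm_ids.count(x) for x in set(sm_ids)) > max_repeats:
            continue
        n_sugars = sum(
            1
            for (ident, _), k in zip(combo, slot_kinds)
            if k == "SUGAR" and ident != "OH"
        )
        if n_sugars < min_sugars:
            continue
        smiles = pieces[0]
        for (_, body), fixed in zip(combo, pieces[2::2]):
            smiles += body + fixed
        mol = Chem.MolFromSmiles(smiles)
        if mol is not None:
            results.add(Chem.MolToSmiles(mol))
    return results
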