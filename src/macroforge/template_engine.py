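"""String-level template preparation.

These are the small, deliberately textual helpers that turn a marked core
plus fragment lists into a fully specified enumeration template: marker
normalization, marker-preserving splitting, sugar-slot planning for the
minimum-sugar constraint, and attachment of concrete choice lists to every
slot.  Products are assembled by pure text splicing and only then parsed
and sanitized, mirroring the string-based pipeline the file format implies
while still guaranteeing chemical validity of emitted records downstream.
"""

from __future__ import annotations

import itertools
import re
from typing import Sequence

from .model import (
    CoreTemplate,
    Fragment,
    FragmentKind,
    FragmentLibrary,
    PreparedTemplate,
    SlotKind,
    SlotRole,
    SugarSlotPlan,
)

_SM_DIGIT_RE = re.compile(r"\[\d+\*\]")


class TemplateError(ValueError):
    pass


def remove_sm_digits(smiles: str) -> str:
    """Normalize every digit-labelled SM marker ``[n*]`` to plain ``[*]``.

    Labels are display-only; slot identity is positional.  Idempotent, and
    a no-op on strings without labelled markers.
    """
    return _SM_DIGIT_RE.sub("[*]", smiles)


def string_splitter(text: str, symbol: str) -> list[str]:
    """Split ``text`` at ``symbol`` keeping the symbol entries in place.

    The output alternates fixed-text and symbol entries and concatenates
    back to the input exactly; adjacent symbols produce empty fixed-text
    entries.
    """
    parts = text.split(symbol)
    out = [parts[0]]
    for part in parts[1:]:
        out.append(symbol)
        out.append(part)
    return out


def generate_sugar_slot_plans(
    p: int, min_sugars: int, mode: str = "disjoint"
) -> list[SugarSlotPlan]:
    """Enumerate role assignments for ``p`` sugar slots with >= ``min_sugars``.

    ``disjoint`` mode (default) conditions on the positions of the *first*
    ``min_sugars`` sugars: those slots are SUGARS, earlier gaps are forced
    HYDROXYL, and everything after the last required sugar is FULL_LIST.
    The induced concrete arrangements partition exactly the arrangements
    with at least ``min_sugars`` sugars, so counting them reproduces
    ``sum_{k=s..p} C(p,k) * m^k``.

    ``paper_literal`` mode reproduces the historical rotation scheme
    (distinct rotations of ``(SUGARS,)*s + (FULL_LIST,)*(p-s)``), which
    double-counts arrangements where several slots hold sugars; it is kept
    for fidelity comparisons.
    """
    if not 0 <= min_sugars <= p:
        raise TemplateError(
            f"min_sugars must be in [0, {p}], got {min_sugars}"
        )
    if p == 0:
        return [SugarSlotPlan(roles=(), mode=mode)]
    if mode == "disjoint":
        if min_sugars == 0:
            return [SugarSlotPlan((SlotRole.FULL_LIST,) * p, mode)]
        plans = []
        for positions in itertools.combinations(range(p), min_sugars):
            last = positions[-1]
            roles = tuple(
                SlotRole.SUGARS
                if i in positions
                else (SlotRole.HYDROXYL if i < last else SlotRole.FULL_LIST)
                for i in range(p)
            )
            plans.append(SugarSlotPlan(roles, mode))
        return plans
    if mode == "paper_literal":
        base = (SlotRole.SUGARS,) * min_sugars + (SlotRole.FULL_LIST,) * (
            p - min_sugars
        )
        seen: list[tuple[SlotRole, ...]] = []
        for shift in range(p):
            rot = base[-shift:] + base[:-shift] if shift else base
            if rot not in seen:
                seen.append(rot)
        return [SugarSlotPlan(r, mode) for r in seen]
    raise TemplateError(f"unknown plan mode {mode!r}")


_ROLE_DUMMIES = {
    SlotRole.SUGARS: "SUGARS",
    SlotRole.FULL_LIST: "Full_List",
    SlotRole.HYDROXYL: "HYDROXYL",
}


def dummy_sugar_templates(
    p: int, min_sugars: int, mode: str = "paper_literal"
) -> list[tuple[str, ...]]:
    """Sugar-slot plans as the historical dummy-string tuples.

    ``p=2, min_sugars=1`` in ``paper_literal`` mode yields
    ``[('SUGARS', 'Full_List'), ('Full_List', 'SUGARS')]``.
    """
    return [
        tuple(_ROLE_DUMMIES[r] for r in plan.roles)
        for plan in generate_sugar_slot_plans(p, min_sugars, mode)
    ]


def insert_sms(
    segments_with_markers: Sequence[str], sm_choices: Sequence[Fragment]
) -> list:
    """Replace every ``[*]`` entry of a split template with the SM list."""
    n_markers = sum(1 for s in segments_with_markers if s == "[*]")
    if n_markers and not sm_choices:
        raise TemplateError("SM slots present but the SM library is empty")
    return [
        list(sm_choices) if s == "[*]" else s for s in segments_with_markers
    ]


def apply_sugar_plan(
    plan: SugarSlotPlan,
    sugars: Sequence[Fragment],
    hydroxyl: Fragment,
) -> list[list[Fragment]]:
    """Concrete per-sugar-slot choice lists for one plan.

    SUGARS -> the sugar list; FULL_LIST -> sugars plus the hydroxyl filler;
    HYDROXYL -> the filler alone (the slot stays unglycosylated).
    """
    out: list[list[Fragment]] = []
    for role in plan.roles:
        if role is SlotRole.SUGARS:
            if not sugars:
                raise TemplateError("SUGARS slot with an empty sugar list")
            out.append(list(sugars))
        elif role is SlotRole.FULL_LIST:
            out.append(list(sugars) + [hydroxyl])
        else:
            out.append([hydroxyl])
    return out


def ring_closure_digits(smiles_text: str) -> set[str]:
    """Ring-bond digits used outside bracket atoms (including ``%nn``)."""
    digits: set[str] = set()
    in_bracket = False
    i = 0
    while i < len(smiles_text):
        ch = smiles_text[i]
        if ch == "[":
            in_bracket = True
        elif ch == "]":
            in_bracket = False
        elif not in_bracket:
            if ch == "%" and i + 2 < len(smiles_text):
                digits.add(smiles_text[i : i + 3])
                i += 2
            elif ch.isdigit():
                digits.add(ch)
        i += 1
    return digits


def validate_fragment_ring_digits(
    core: CoreTemplate, *libraries: Sequence[Fragment]
) -> None:
    """Reject fragment bodies reusing a ring-closure digit of the core.

    The core's ring bonds are still open where fragments are spliced in, so
    a fragment reopening the same digit corrupts the macrocycle.  This is
    validated, not repaired.
    """
    core_digits = ring_closure_digits("".join(core.segments))
    if not core_digits:
        return
    for lib in libraries:
        for frag in lib:
            clash = ring_closure_digits(frag.body) & core_digits
            if clash:
                raise TemplateError(
                    f"fragment {frag.id} reuses core ring digit(s) "
                    f"{sorted(clash)}"
                )


def prepare_template(
    core: CoreTemplate,
    sm_choices: Sequence[Fragment],
    sugar_choices: Sequence[Fragment],
    min_sugars: int,
    plan_mode: str = "disjoint",
    hydroxyl_body: str = "C(O)",
) -> PreparedTemplate:
    """Bundle a parsed core with choice lists and sugar-slot plans."""
    if core.sm_slots and not sm_choices:
        raise TemplateError("core has SM slots but the SM library is empty")
    if core.sugar_slots and min_sugars > 0 and not sugar_choices:
        raise TemplateError("min_sugars > 0 but the sugar library is empty")
    hydroxyl = Fragment(
        id="OH", kind=FragmentKind.HYDROXYL, body=hydroxyl_body
    )
    validate_fragment_ring_digits(core, sm_choices, sugar_choices, [hydroxyl])
    plans = generate_sugar_slot_plans(
        len(core.sugar_slots), min_sugars, plan_mode
    )
    prepared = PreparedTemplate(
        segments=list(core.segments),
        slots=list(core.slots),
        sm_choices=list(sm_choices),
        sugar_plans=plans,
        hydroxyl=hydroxyl,
    )
    prepared._sugar_pool = list(sugar_choices)
    return prepared


def splice(segments: Sequence[str], bodies: Sequence[str]) -> str:
    """Interleave fixed segments with fragment bodies into one SMILES."""
    out = [segments[0]]
    for body, seg in zip(bodies, segments[1:]):
        out.append(body)
        out.append(seg)
    return "".join(out)
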