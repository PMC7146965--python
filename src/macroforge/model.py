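"""Core domain types for template-based macrolide enumeration.

The enumerator assembles glycosylated macrolactones from three ingredients:
a *core template* (a SMILES string with marked substitution slots), a library
of *structural motifs* (short in-chain building blocks, "SMs"), and a library
of *sugars*.  Slots come in two flavours: SM slots written ``[*]`` (optionally
digit-labelled ``[1*]``, ``[2*]``, ...) and sugar slots written ``[*sugar*]``.
Fragments are stored anchor-stripped: the file format wraps each fragment body
in ``[R]`` connection anchors, which are removed at load time.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

SM_MARKER = "[*]"
SUGAR_MARKER = "[*sugar*]"
ANCHOR = "[R]"

#: default body spliced into an unfilled sugar slot: an in-chain carbon
#: bearing a hydroxyl, so the macrocycle backbone stays intact.
DEFAULT_HYDROXYL_BODY = "C(O)"


class SlotKind(str, enum.Enum):
    SM = "SM"
    SUGAR = "SUGAR"


class FragmentKind(str, enum.Enum):
    SM = "SM"
    SUGAR = "SUGAR"
    HYDROXYL = "HYDROXYL"


class JoinStereo(str, enum.Enum):
    """Stereo status of a fragment's joining atom (first body atom).

    DEFINED   — carries a tetrahedral parity tag and is perceived as a real
                stereocenter once the anchors are capped; eligible for
                two-variant expansion.
    UNDEFINED — a potential stereocenter with no parity tag; left unchanged.
    NONE      — not a stereocenter at all.
    """

    DEFINED = "DEFINED"
    UNDEFINED = "UNDEFINED"
    NONE = "NONE"


class SlotRole(str, enum.Enum):
    """Role of a sugar slot within one slot plan.

    SUGARS    — the slot draws from the sugar list only.
    FULL_LIST — the slot draws from the sugar list plus the hydroxyl filler.
    HYDROXYL  — the slot is forced to the hydroxyl filler.
    """

    SUGARS = "SUGARS"
    FULL_LIST = "FULL_LIST"
    HYDROXYL = "HYDROXYL"


@dataclass(frozen=True)
class Slot:
    kind: SlotKind
    index: int
    label: int | None = None  # digit of a labelled [n*] marker, display only

    @property
    def marker(self) -> str:
        return SM_MARKER if self.kind is SlotKind.SM else SUGAR_MARKER


@dataclass
class CoreTemplate:
    """A core SMILES split into fixed segments and an ordered slot list.

    Invariant: ``len(segments) == len(slots) + 1`` and re-interleaving
    segments with canonical slot markers reproduces the cleaned input text
    (digit labels removed).
    """

    raw_text: str
    segments: list[str]
    slots: list[Slot]

    @property
    def sm_slots(self) -> list[Slot]:
        return [s for s in self.slots if s.kind is SlotKind.SM]

    @property
    def sugar_slots(self) -> list[Slot]:
        return [s for s in self.slots if s.kind is SlotKind.SUGAR]

    def reassemble(self) -> str:
        """Interleave segments with canonical markers (labels dropped)."""
        out = [self.segments[0]]
        for slot, seg in zip(self.slots, self.segments[1:]):
            out.append(slot.marker)
            out.append(seg)
        return "".join(out)


@dataclass(frozen=True)
class Fragment:
    """One building block: an anchor-stripped SMILES body.

    ``parent_id`` tracks the pre-expansion fragment for stereo variants so
    that repeat constraints can optionally be counted per parent motif.
    """

    id: str
    kind: FragmentKind
    body: str
    join_stereo: JoinStereo = JoinStereo.NONE
    variant_tag: str | None = None  # "@" or "@@" for stereo variants
    parent_id: str | None = None

    def __post_init__(self) -> None:
        if not self.body:
            raise ValueError(f"fragment {self.id!r} has an empty body")
        if ANCHOR in self.body:
            raise ValueError(
                f"fragment {self.id!r} still contains an {ANCHOR} anchor"
            )

    @property
    def repeat_parent(self) -> str:
        return self.parent_id if self.parent_id is not None else self.id

    def with_body(self, body: str, *, id: str, variant_tag: str) -> "Fragment":
        return replace(
            self, body=body, id=id, variant_tag=variant_tag,
            parent_id=self.repeat_parent,
        )


@dataclass
class FragmentLibrary:
    fragments: list[Fragment]
    kind: FragmentKind
    source_path: str | None = None

    def __post_init__(self) -> None:
        ids = [f.id for f in self.fragments]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate fragment ids in {self.source_path}")

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self) -> Iterator[Fragment]:
        return iter(self.fragments)

    def __getitem__(self, i: int) -> Fragment:
        return self.fragments[i]


@dataclass(frozen=True)
class StereoExpansionResult:
    parent_id: str
    variants: tuple[Fragment, ...]
    expanded: bool


@dataclass(frozen=True)
class SugarSlotPlan:
    """An assignment of roles to the sugar slots, realizing min-sugars.

    In ``disjoint`` mode the family of plans partitions the concrete sugar
    arrangements with >= min_sugars sugars (no overlap, no gap); in
    ``paper_literal`` mode it reproduces the original rotation scheme, which
    over-counts the all-sugars region.
    """

    roles: tuple[SlotRole, ...]
    mode: str = "disjoint"

    def arrangement_count(self, n_sugars: int) -> int:
        count = 1
        for role in self.roles:
            if role is SlotRole.SUGARS:
                count *= n_sugars
            elif role is SlotRole.FULL_LIST:
                count *= n_sugars + 1
        return count


@dataclass
class PreparedTemplate:
    """A core template with concrete choice lists attached to every slot."""

    segments: list[str]
    slots: list[Slot]
    sm_choices: list[Fragment]
    sugar_plans: list[SugarSlotPlan]
    hydroxyl: Fragment

    def per_slot_choices(self, plan: SugarSlotPlan) -> list[list[Fragment]]:
        """Ordered choice list for each slot under one sugar-slot plan."""
        from .template_engine import apply_sugar_plan  # local: avoid cycle

        sugar_lists = apply_sugar_plan(plan, self._sugar_pool, self.hydroxyl)
        out: list[list[Fragment]] = []
        sugar_i = 0
        for slot in self.slots:
            if slot.kind is SlotKind.SM:
                out.append(self.sm_choices)
            else:
                out.append(sugar_lists[sugar_i])
                sugar_i += 1
        return out

    # set by prepare_template; the sugar pool is shared across plans
    _sugar_pool: list[Fragment] = field(default_factory=list, repr=False)


@dataclass
class EnumerationConfig:
    """Everything needed for one enumeration run.

    ``max_sm_repeats`` — maximum number of times any single SM identity may
    occur across the SM slots of one product (default 3).
    ``min_sugars`` — minimum number of actual sugars per product (default 1);
    unfilled sugar slots receive the hydroxyl filler.
    ``library_size`` — cap on emitted records; constraint violators and
    invalid splices do not consume this budget.
    """

    core: CoreTemplate
    sm_library: FragmentLibrary
    sugar_library: FragmentLibrary
    library_size: int
    max_sm_repeats: int = 3
    min_sugars: int = 1
    enumerate_sm_stereo: bool = True
    enumerate_sugar_stereo: bool = True
    chunk_size: int = 1_000_000
    out_dir: str | Path | None = None
    seed: int = 0
    plan_mode: str = "disjoint"
    hydroxyl_body: str = DEFAULT_HYDROXYL_BODY
    count_repeats_by_parent: bool = False

    def validate(self) -> None:
        if self.max_sm_repeats < 1:
            raise ValueError("max_sm_repeats must be >= 1")
        p_sugar = len(self.core.sugar_slots)
        if not 0 <= self.min_sugars <= p_sugar:
            raise ValueError(
                f"min_sugars must be in [0, {p_sugar}], got {self.min_sugars}"
            )
        if self.library_size < 0:
            raise ValueError("library_size must be >= 0")
        if self.chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")
        if self.plan_mode not in ("disjoint", "paper_literal"):
            raise ValueError(f"unknown plan_mode {self.plan_mode!r}")


@dataclass(frozen=True)
class MoleculeRecord:
    """One emitted product with its per-slot provenance (fragment ids)."""

    smiles: str
    index: int
    provenance: tuple[str, ...]
    plan_index: int


@dataclass(frozen=True)
class SpaceSizeParams:
    """Parameters of the chemical-space-size arithmetic.

    n_sm / m_sugar are counts AFTER stereo expansion; p_sm / p_sugar are the
    slot counts; r is the max-repeat bound; s the minimum number of sugars.
    """

    n_sm: int
    p_sm: int
    r: int
    m_sugar: int
    p_sugar: int
    s: int

    def __post_init__(self) -> None:
        for name in ("n_sm", "p_sm", "r", "m_sugar", "p_sugar", "s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.s > self.p_sugar:
            raise ValueError("min sugars s cannot exceed sugar slot count")


@dataclass(frozen=True)
class PropertyProfile:
    """The six 2D drug-likeness descriptors of one molecule."""

    mw: float      # molecular weight, g/mol
    mollogp: float  # Wildman-Crippen octanol/water logP
    tpsa: float    # topological polar surface area, A^2
    hba: int       # H-bond acceptors (Lipinski N/O count by default)
    hbd: int       # H-bond donors (Lipinski NH/OH count by default)
    nrb: int       # rotatable bonds


PROPERTY_NAMES: tuple[str, ...] = ("mw", "mollogp", "tpsa", "hba", "hbd", "nrb")

#: strict-inequality rule thresholds (Lipinski + Veber); a value on the
#: boundary does not count as a violation.
RULE_THRESHOLDS: dict[str, float] = {
    "mw": 500.0,
    "tpsa": 140.0,
    "hba": 10,
    "hbd": 5,
    "nrb": 10,
    "mollogp": 5.0,
}


@dataclass
class DistributionSummary:
    """Per-property summary statistics plus rule-violation rates.

    ``stats`` maps property name -> {mean, sd, min, max}; ``violations`` maps
    keys like ``pct_mw_gt_500`` -> percentage of molecules strictly above the
    threshold.
    """

    n: int
    stats: dict[str, dict[str, float]]
    violations: dict[str, float]
    ddof: int = 1

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.stats).T[["mean", "sd", "min", "max"]]
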