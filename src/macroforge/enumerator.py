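"""Streaming enumeration of the constrained cartesian product, plus the
chemical-space-size arithmetic.

The enumerator walks the prepared template's choice lists in deterministic
order — sugar-slot plans in plan order, and within a plan the nested product
with the rightmost slot varying fastest, fragments in library order.  Each
candidate is checked against the max-SM-repeat constraint, spliced textually
into the core, parsed and sanitized; only valid products are emitted and
count toward the library-size cap.  Memory use is constant: nothing is
accumulated, so the stream scales to arbitrarily many records.

Two space-size computations are provided: ``formula_space_size``, the
truncated-falling-factorial convention used to report the V1B coverage
figure, and ``exact_space_size``, the true constrained count (the two differ
in general; the exact count is the engine's correctness oracle).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterator

from rdkit import Chem
from rdkit import RDLogger

from . import fragment_io
from .model import (
    EnumerationConfig,
    MoleculeRecord,
    SlotKind,
    SpaceSizeParams,
)
from .stereo import expand_library
from .template_engine import prepare_template, splice

RDLogger.DisableLog("rdApp.error")


class EnumerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SpliceFailure:
    """An unparseable spliced product, kept for the error report."""

    smiles: str
    provenance: tuple[str, ...]
    plan_index: int


@dataclass
class EnumerationReport:
    emitted: int = 0
    skipped_repeat: int = 0
    attempted: int = 0
    failures: list[SpliceFailure] = field(default_factory=list)
    chunk_paths: list[Path] = field(default_factory=list)
    info_path: Path | None = None


def check_repeat_constraint(
    sm_assignment: tuple[str, ...] | list[str], max_repeats: int
) -> bool:
    """True iff no single SM identity fills more than max_repeats SM slots."""
    if not sm_assignment:
        return True
    counts: dict[str, int] = {}
    for sm_id in sm_assignment:
        counts[sm_id] = counts.get(sm_id, 0) + 1
        if counts[sm_id] > max_repeats:
            return False
    return True


def enumerate_library(
    config: EnumerationConfig, report: EnumerationReport | None = None
) -> Iterator[MoleculeRecord]:
    """Stream valid products for one configuration.

    Violators of the repeat constraint are skipped without consuming the
    ``library_size`` budget; unparseable splices are recorded on the report
    (with provenance) and likewise skipped.  The stream stops at exactly
    ``library_size`` emitted records or at exhaustion.  If every attempted
    splice failed, an EnumerationError summarizes the run.
    """
    config.validate()
    if report is None:
        report = EnumerationReport()

    sms = expand_library(config.sm_library, config.enumerate_sm_stereo)
    sugars = expand_library(config.sugar_library, config.enumerate_sugar_stereo)
    prepared = prepare_template(
        config.core,
        list(sms),
        list(sugars),
        config.min_sugars,
        plan_mode=config.plan_mode,
        hydroxyl_body=config.hydroxyl_body,
    )
    sm_positions = [
        i for i, slot in enumerate(prepared.slots) if slot.kind is SlotKind.SM
    ]
    by_parent = config.count_repeats_by_parent

    if config.library_size == 0:
        return
    for plan_index, plan in enumerate(prepared.sugar_plans):
        choice_lists = prepared.per_slot_choices(plan)
        for combo in itertools.product(*choice_lists):
            report.attempted += 1
            sm_ids = tuple(
                combo[i].repeat_parent if by_parent else combo[i].id
                for i in sm_positions
            )
            if not check_repeat_constraint(sm_ids, config.max_sm_repeats):
                report.skipped_repeat += 1
                continue
            smiles = splice(prepared.segments, [f.body for f in combo])
            provenance = tuple(f.id for f in combo)
            if Chem.MolFromSmiles(smiles) is None:
                report.failures.append(
                    SpliceFailure(smiles, provenance, plan_index)
                )
                continue
            yield MoleculeRecord(
                smiles=smiles,
                index=report.emitted,
                provenance=provenance,
                plan_index=plan_index,
            )
            report.emitted += 1
            if report.emitted >= config.library_size:
                return
    if report.attempted and not report.emitted and report.failures:
        raise EnumerationError(
            f"all {report.attempted} attempted products failed to splice "
            "into valid molecules"
        )


def run_enumeration(
    config: EnumerationConfig, timestamp=None
) -> EnumerationReport:
    """Enumerate and write chunked ``.smiles`` output plus the run manifest.

    Requires ``config.out_dir``.  Passing a fixed ``timestamp`` makes repeat
    runs byte- and filename-identical.
    """
    if config.out_dir is None:
        raise ValueError("config.out_dir is required for run_enumeration")
    report = EnumerationReport()
    stream = (rec.smiles for rec in enumerate_library(config, report))
    report.chunk_paths = fragment_io.write_library_chunks(
        stream, config.out_dir, config.chunk_size, timestamp=timestamp
    )
    report.info_path = fragment_io.write_info_file(
        config, config.out_dir, timestamp=timestamp
    )
    return report


def sugar_arrangement_count(m: int, p: int, s: int) -> int:
    """Number of sugar-slot fillings with at least ``s`` of ``p`` slots
    holding one of ``m`` sugars: sum_{k=s..p} C(p,k) * m^k."""
    if not 0 <= s <= p:
        raise ValueError("need 0 <= s <= p")
    return sum(math.comb(p, k) * m**k for k in range(s, p + 1))


def formula_space_size(params: SpaceSizeParams) -> int:
    """Space size under the truncated-falling-factorial convention.

    The SM term is ``n^r * prod_{i=1..p_sm-r} (n - i)`` — the first ``r``
    slots unrestricted, each later slot avoiding one more symbol — and the
    sugar term is ``sum_{k=s..p_sugar} C(p_sugar,k) * m^k``.  This is the
    arithmetic behind the published V1B figure of 1,566,867,456 possible
    compounds; it is *not* the exact constrained count (see
    ``exact_space_size``), but it is the convention coverage percentages
    are quoted against.
    """
    n, p, r = params.n_sm, params.p_sm, params.r
    if p > r and n <= p - r:
        raise ValueError(
            "formula undefined: need n_sm > p_sm - r for the falling factor"
        )
    sm_term = n ** min(r, p)
    for i in range(1, p - r + 1):
        sm_term *= n - i
    return sm_term * sugar_arrangement_count(
        params.m_sugar, params.p_sugar, params.s
    )


def _sequences_with_bounded_repeats(n: int, p: int, r: int) -> int:
    """Exact number of length-``p`` sequences over ``n`` symbols with every
    symbol used at most ``r`` times: ``p! * [x^p] (sum_{j<=r} x^j/j!)^n``."""
    if r >= p:
        return n**p
    if r == 0:
        return 1 if p == 0 else 0
    base = [Fraction(1, math.factorial(j)) for j in range(min(r, p) + 1)]
    poly = [Fraction(1)]
    for _ in range(n):
        new = [Fraction(0)] * (p + 1)
        for i, a in enumerate(poly):
            if a == 0:
                continue
            for j, b in enumerate(base):
                if i + j > p:
                    break
                new[i + j] += a * b
        poly = new
    count = poly[p] * math.factorial(p) if p < len(poly) else Fraction(0)
    assert count.denominator == 1
    return int(count)


def exact_space_size(params: SpaceSizeParams) -> int:
    """Exact constrained product count.

    SM tuples with no identity repeated more than ``r`` times, multiplied by
    the exact sugar-arrangement count.  For V1B-scale parameters the SM term
    is 7,959,840 — larger than the 6,994,944 the falling-factorial
    convention yields, because that convention undercounts tuples that
    revisit early symbols.
    """
    sm_term = _sequences_with_bounded_repeats(
        params.n_sm, params.p_sm, params.r
    )
    return sm_term * sugar_arrangement_count(
        params.m_sugar, params.p_sugar, params.s
    )


def coverage_fraction(library_size: float, params: SpaceSizeParams) -> float:
    """Percent of the formula-convention space covered by a finite library,
    reported to one decimal (e.g. 10^9 of the V1B space -> 63.8)."""
    space = formula_space_size(params)
    if space <= 0:
        raise ValueError("space size is zero; coverage undefined")
    return round(100.0 * library_size / space, 1)
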