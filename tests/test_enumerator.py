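"""Streaming enumeration, constraints, and space-size arithmetic."""

import itertools
from pathlib import Path

import pytest
from rdkit import Chem

from macroforge.enumerator import (
    EnumerationError,
    EnumerationReport,
    check_repeat_constraint,
    coverage_fraction,
    enumerate_library,
    exact_space_size,
    formula_space_size,
    run_enumeration,
    sugar_arrangement_count,
)
from macroforge.fixtures import (
    TOY_MACROCYCLE_CORE,
    ToyLibrarySpec,
    brute_force_enumerate,
    make_toy_fragments,
)
from macroforge.fragment_io import parse_core_template
from macroforge.model import (
    EnumerationConfig,
    Fragment,
    FragmentKind,
    FragmentLibrary,
    SpaceSizeParams,
)

from conftest import library_from_bodies, make_chain_core_text

V1B = SpaceSizeParams(n_sm=24, p_sm=5, r=3, m_sugar=14, p_sugar=2, s=1)


def toy_config(core_text, sm_bodies, sugar_bodies, **kw):
    defaults = dict(
        library_size=10**6,
        max_sm_repeats=2,
        min_sugars=1,
        enumerate_sm_stereo=False,
        enumerate_sugar_stereo=False,
    )
    defaults.update(kw)
    return EnumerationConfig(
        core=parse_core_template(core_text),
        sm_library=library_from_bodies(sm_bodies, "SM"),
        sugar_library=library_from_bodies(sugar_bodies, "SUGAR"),
        **defaults,
    )


class TestRepeatConstraint:
    @pytest.mark.parametrize(
        "ids,max_repeats,ok",
        [
            (("A", "A", "A", "B", "C"), 3, True),
            (("A", "A", "A", "A", "B"), 3, False),
            (("A", "B", "C"), 1, True),
            ((), 1, True),
        ],
    )
    def test_examples(self, ids, max_repeats, ok):
        assert check_repeat_constraint(ids, max_repeats) is ok


class TestSpaceSizeArithmetic:
    def test_v1b_formula_value(self):
        """24^3 * 23 * 22 SM tuples times (14 + 14 + 196) sugar fillings."""
        assert formula_space_size(V1B) == 1_566_867_456
        assert formula_space_size(V1B) == (24**3 * 23 * 22) * (
            14 * 1 + 1 * 14 + 14 * 14
        )

    def test_unrestricted_repeats_collapse_to_power(self):
        params = SpaceSizeParams(5, 3, 3, 2, 1, 0)
        assert formula_space_size(params) == 5**3 * (1 + 2)
        assert exact_space_size(params) == 5**3 * 3

    def test_injective_case_equals_brute_force(self):
        """r=1 makes the formula the falling factorial, which IS the exact
        injective count — checked by enumeration."""
        params = SpaceSizeParams(3, 3, 1, 1, 1, 1)
        assert formula_space_size(params) == 3 * 2 * 1 * 1
        brute = sum(
            1
            for t in itertools.product(range(3), repeat=3)
            if len(set(t)) == 3
        )
        assert exact_space_size(params) == brute * 1

    def test_exact_tiny_brute_force(self):
        """n=2, p=3, r=2: the two constant tuples are the only violators."""
        params = SpaceSizeParams(2, 3, 2, 1, 0, 0)
        assert exact_space_size(params) == 6
        brute = sum(
            1
            for t in itertools.product(range(2), repeat=3)
            if max(t.count(x) for x in set(t)) <= 2
        )
        assert brute == 6

    @pytest.mark.parametrize("n,p,r", [(2, 4, 2), (3, 4, 2), (3, 5, 3), (4, 3, 1)])
    def test_exact_sm_term_matches_enumeration(self, n, p, r):
        brute = sum(
            1
            for t in itertools.product(range(n), repeat=p)
            if max(t.count(x) for x in set(t)) <= r
        )
        assert exact_space_size(SpaceSizeParams(n, p, r, 1, 0, 0)) == brute

    def test_formula_precondition(self):
        with pytest.raises(ValueError):
            formula_space_size(SpaceSizeParams(2, 5, 1, 1, 0, 0))

    def test_sugar_term(self):
        assert sugar_arrangement_count(14, 2, 1) == 224
        assert sugar_arrangement_count(14, 2, 2) == 196
        assert sugar_arrangement_count(3, 0, 0) == 1

    def test_coverage_values(self):
        assert coverage_fraction(1e9, V1B) == 63.8
        assert coverage_fraction(formula_space_size(V1B), V1B) == 100.0
        assert coverage_fraction(0, V1B) == 0.0


class TestEnumeration:
    def test_toy_counts_match_oracle(self):
        """2 SMs at 2 slots, 1 sugar slot with 1 sugar, min 1 -> 4
        products, equal as a set to the brute-force oracle."""
        core = "C[*]C[*]C[*sugar*]C"
        cfg = toy_config(core, ["C(C)", "CC"], ["C(O)C"], max_sm_repeats=2)
        recs = list(enumerate_library(cfg))
        assert len(recs) == 4
        engine = {
            Chem.MolToSmiles(Chem.MolFromSmiles(r.smiles)) for r in recs
        }
        oracle = brute_force_enumerate(core, ["C(C)", "CC"], ["C(O)C"], 2, 1)
        assert engine == oracle

    def test_max_repeats_one_keeps_permutations_only(self):
        cfg = toy_config(
            "C[*]C[*]C[*sugar*]C", ["C(C)", "CC"], ["C(O)C"], max_sm_repeats=1
        )
        recs = list(enumerate_library(cfg))
        assert len(recs) == 2
        sm_ids = {tuple(r.provenance[:2]) for r in recs}
        assert sm_ids == {("SM001", "SM002"), ("SM002", "SM001")}

    def test_zero_library_size_is_empty(self):
        cfg = toy_config(
            "C[*]C[*sugar*]C", ["C(C)"], ["C(O)C"], library_size=0
        )
        assert list(enumerate_library(cfg)) == []

    def test_cap_counts_only_emitted_records(self):
        """Repeat violators consume no budget: with cap 3 and max_repeats 1
        the stream still finds all 2 valid permutations."""
        report = EnumerationReport()
        cfg = toy_config(
            "C[*]C[*]C[*sugar*]C", ["C(C)", "CC"], ["C(O)C"],
            max_sm_repeats=1, library_size=3,
        )
        recs = list(enumerate_library(cfg, report))
        assert len(recs) == 2
        assert report.skipped_repeat == 2

    def test_deterministic_order_and_indices(self):
        cfg = toy_config("C[*]C[*sugar*]C", ["C(C)", "CC"], ["C(O)C"])
        a = [r.smiles for r in enumerate_library(cfg)]
        b = [r.smiles for r in enumerate_library(cfg)]
        assert a == b
        assert [r.index for r in enumerate_library(cfg)] == list(range(len(a)))

    def test_invalid_splice_reported_not_emitted(self):
        bad = Fragment(id="SM001", kind=FragmentKind.SM, body="C(=O)(=O)(=O)")
        good = Fragment(id="SM002", kind=FragmentKind.SM, body="C(C)")
        cfg = EnumerationConfig(
            core=parse_core_template("C[*]C"),
            sm_library=FragmentLibrary([bad, good], kind=FragmentKind.SM),
            sugar_library=library_from_bodies(["C(O)C"], "SUGAR"),
            library_size=10,
            min_sugars=0,
            enumerate_sm_stereo=False,
            enumerate_sugar_stereo=False,
        )
        report = EnumerationReport()
        recs = list(enumerate_library(cfg, report))
        assert len(recs) == 1 and recs[0].provenance == ("SM002",)
        assert len(report.failures) == 1
        assert report.failures[0].provenance == ("SM001",)

    def test_all_invalid_raises_summary_error(self):
        bad = Fragment(id="SM001", kind=FragmentKind.SM, body="C(=O)(=O)(=O)")
        cfg = EnumerationConfig(
            core=parse_core_template("C[*]C"),
            sm_library=FragmentLibrary([bad], kind=FragmentKind.SM),
            sugar_library=library_from_bodies(["C(O)C"], "SUGAR"),
            library_size=10,
            min_sugars=0,
            enumerate_sm_stereo=False,
            enumerate_sugar_stereo=False,
        )
        with pytest.raises(EnumerationError):
            list(enumerate_library(cfg))

    def test_plan_modes_agree_after_dedup(self):
        """paper_literal over-emits but the deduplicated chemical set is
        identical to disjoint mode."""
        core = make_chain_core_text(1, 2)
        sms, sugars = ["C(C)"], ["C(O)C", "C(N)C"]
        sets = {}
        counts = {}
        for mode in ("disjoint", "paper_literal"):
            cfg = toy_config(core, sms, sugars, plan_mode=mode)
            recs = list(enumerate_library(cfg))
            counts[mode] = len(recs)
            sets[mode] = {
                Chem.MolToSmiles(Chem.MolFromSmiles(r.smiles)) for r in recs
            }
        assert sets["disjoint"] == sets["paper_literal"]
        assert counts["disjoint"] == sugar_arrangement_count(2, 2, 1) == 8
        assert counts["paper_literal"] > counts["disjoint"]

    def test_stereo_expansion_multiplies_choices(self):
        cfg = toy_config(
            "C[*]C[*sugar*]C", ["[C@H](C)O"], ["C(O)C"],
            enumerate_sm_stereo=True,
        )
        recs = list(enumerate_library(cfg))
        assert len(recs) == 2
        assert {r.provenance[0] for r in recs} == {"SM001a", "SM001b"}

    def test_repeat_counting_by_parent_motif(self):
        """With parent counting, the R and S variants of one SM share a
        repeat budget."""
        core = "C[*]C[*]C[*sugar*]C"
        base = dict(
            core=parse_core_template(core),
            sm_library=library_from_bodies(["[C@H](C)O"], "SM"),
            sugar_library=library_from_bodies(["C(O)C"], "SUGAR"),
            library_size=100,
            max_sm_repeats=1,
            min_sugars=1,
            enumerate_sm_stereo=True,
            enumerate_sugar_stereo=False,
        )
        by_variant = list(
            enumerate_library(EnumerationConfig(**base))
        )
        by_parent = list(
            enumerate_library(
                EnumerationConfig(**base, count_repeats_by_parent=True)
            )
        )
        assert len(by_variant) == 2  # (a,b) and (b,a)
        assert len(by_parent) == 0   # both variants count as one motif


class TestRunEnumeration:
    def test_chunked_run_writes_files_and_manifest(self, tmp_path):
        import datetime

        cfg = toy_config(
            TOY_MACROCYCLE_CORE,
            ["C(C)", "CC"],
            ["C(O)C"],
            max_sm_repeats=2,
            out_dir=tmp_path / "run",
            chunk_size=3,
        )
        ts = datetime.datetime(2024, 1, 2, 3, 4, 5)
        report = run_enumeration(cfg, timestamp=ts)
        assert report.emitted == 4
        assert [p.name for p in report.chunk_paths] == [
            "2024-01-02-03-04-05_mcrl_1.smiles",
            "2024-01-02-03-04-05_mcrl_2.smiles",
        ]
        assert report.info_path.exists()

    def test_byte_identical_reruns(self, tmp_path):
        import datetime

        ts = datetime.datetime(2024, 1, 2, 3, 4, 5)
        contents = []
        for sub in ("a", "b"):
            cfg = toy_config(
                TOY_MACROCYCLE_CORE,
                ["C(C)", "CC", "CCC"],
                ["C(O)C", "C(N)C"],
                max_sm_repeats=1,
                out_dir=tmp_path / sub,
                chunk_size=5,
            )
            report = run_enumeration(cfg, timestamp=ts)
            contents.append(
                [p.read_bytes() for p in report.chunk_paths]
            )
        assert contents[0] == contents[1]
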