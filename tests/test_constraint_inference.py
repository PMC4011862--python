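"""Inverting digestion products into pairing statuses and constraints."""

import random

import pytest

from rnacleave import (
    CompatibilityError,
    EvidenceItem,
    ReferenceLengthError,
    RnaSequence,
    Status,
    builtin_enzyme,
    digest_panel,
    format_mfold_constraints,
    infer_constraints,
    locate_fragments,
    make_custom_enzyme,
    resolve_status,
    validate_products,
)
from rnacleave.constraint_inference import ResidueStatusArray, constraint_lines
from rnacleave.fixtures import FixtureConfig, synthetic_experiment

REF = RnaSequence.from_string("AGCAUGG", id="ref")


def evidence(residue, status, length, enzyme="T1", seq=None, start=1, kind="fragment_end"):
    return EvidenceItem(
        residue=residue,
        implied_status=status,
        enzyme=enzyme,
        fragment_sequence=seq or "N" * length,
        fragment_length=length,
        occurrence_start=start,
        boundary_kind=kind,
    )


class TestValidateProducts:
    def test_short_product_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="omitted"):
            kept = validate_products(REF, {"T1": ["AG", "CAUG", "G"]})
        assert kept == {"T1": ["AG", "CAUG"]}

    def test_incompatible_product_rejected(self):
        with pytest.raises(CompatibilityError, match="AGX"):
            validate_products(REF, {"T1": ["AGX"]})

    def test_absent_product_rejected(self):
        with pytest.raises(CompatibilityError, match="UUUU"):
            validate_products(REF, {"T1": ["UUUU"]})

    def test_reference_length_cap(self):
        long_ref = RnaSequence.from_string("A" * 201)
        with pytest.raises(ReferenceLengthError, match="200"):
            validate_products(long_ref, {"T1": []})
        # exactly at the cap is accepted
        validate_products(RnaSequence.from_string("A" * 200), {"T1": []})

    def test_cap_is_parameterisable(self):
        validate_products(RnaSequence.from_string("A" * 201), {"T1": []}, max_length=250)

    def test_products_normalised_like_sequences(self):
        kept = validate_products(REF, {"T1": ["ca ug", "agt"[:2].upper()]})
        assert kept["T1"][0] == "CAUG"


class TestLocateFragments:
    def test_interior_product_gives_two_boundaries(self, t1):
        usable, excluded = locate_fragments(REF, "CAUG", t1)
        assert {(e.residue, e.implied_status, e.boundary_kind) for e in usable} == {
            (6, Status.UNPAIRED, "fragment_end"),
            (2, Status.UNPAIRED, "fragment_start_upstream"),
        }
        assert excluded == []

    def test_product_at_five_prime_terminus(self, t1):
        usable, _ = locate_fragments(REF, "AG", t1)
        assert [(e.residue, e.boundary_kind) for e in usable] == [(2, "fragment_end")]

    def test_product_reaching_three_prime_end_gives_no_end_evidence(self, t1):
        # "CAUGG" occupies 3..7; no bond exists beyond residue 7
        usable, _ = locate_fragments(REF, "CAUGG", t1)
        assert [(e.residue, e.boundary_kind) for e in usable] == [
            (2, "fragment_start_upstream")
        ]

    def test_chemically_impossible_boundary_excluded(self, t1):
        # "GCA" sits at 2..4: end residue A4 and upstream residue A1 are not G
        usable, excluded = locate_fragments(REF, "GCA", t1)
        assert usable == []
        assert {e.residue for e in excluded} == {1, 4}

    def test_all_occurrences_contribute(self, t2):
        ref = RnaSequence.from_string("AGCAGCA")
        usable, _ = locate_fragments(ref, "AGC", t2)
        assert {(e.residue, e.boundary_kind) for e in usable} == {
            (3, "fragment_end"),
            (3, "fragment_start_upstream"),
            (6, "fragment_end"),
        }

    def test_five_prime_cutter_shifts_evidence_downstream(self):
        spec = make_custom_enzyme("X5", "ACGU", "unpaired", "5prime")
        usable, _ = locate_fragments(REF, "CAUG", spec)
        assert {(e.residue, e.boundary_kind) for e in usable} == {
            (7, "fragment_end"),
            (3, "fragment_start_upstream"),
        }

    def test_interior_inference_opposite_status(self, t1):
        ref = RnaSequence.from_string("AGGA")
        usable, _ = locate_fragments(ref, "AGG", t1, interior_inference=True)
        interior = [e for e in usable if e.boundary_kind == "interior"]
        assert [(e.residue, e.implied_status) for e in interior] == [(2, Status.PAIRED)]


class TestResolveStatus:
    def test_agreeing_evidence(self):
        array = resolve_status(REF, [evidence(2, Status.UNPAIRED, 4)])
        assert array.status(2) is Status.UNPAIRED
        assert array.notes[1] is None

    def test_rule1_longer_fragment_wins(self):
        array = resolve_status(
            REF,
            [evidence(3, Status.UNPAIRED, 5), evidence(3, Status.PAIRED, 3)],
        )
        assert array.status(3) is Status.UNPAIRED
        assert "length" in array.notes[2]

    def test_rule2_majority_wins_at_equal_length(self):
        array = resolve_status(
            REF,
            [
                evidence(3, Status.PAIRED, 4),
                evidence(3, Status.PAIRED, 4, start=2),
                evidence(3, Status.UNPAIRED, 4),
            ],
        )
        assert array.status(3) is Status.PAIRED
        assert "count" in array.notes[2]

    def test_rule3_balanced_conflict_undefined(self):
        array = resolve_status(
            REF,
            [evidence(3, Status.PAIRED, 4), evidence(3, Status.UNPAIRED, 4)],
        )
        assert array.status(3) is Status.UNDEFINED
        assert array.notes[2] is not None

    def test_rule1_unchanged_by_shorter_conflicting_evidence(self):
        base = [evidence(3, Status.UNPAIRED, 6)]
        extra = [evidence(3, Status.PAIRED, k) for k in (2, 3, 4, 5)]
        assert resolve_status(REF, base + extra).status(3) is Status.UNPAIRED

    def test_no_evidence_is_undefined(self):
        array = resolve_status(REF, [])
        assert all(s is Status.UNDEFINED for s in array.statuses)

    @pytest.mark.parametrize("seed", range(5))
    def test_permutation_invariant(self, seed):
        items = [
            evidence(2, Status.UNPAIRED, 5),
            evidence(2, Status.PAIRED, 5),
            evidence(2, Status.PAIRED, 3),
            evidence(5, Status.PAIRED, 4),
            evidence(5, Status.UNPAIRED, 2),
        ]
        shuffled = items[:]
        random.Random(seed).shuffle(shuffled)
        a = resolve_status(REF, items)
        b = resolve_status(REF, shuffled)
        assert a.statuses == b.statuses


class TestFormatConstraints:
    def _array(self, statuses):
        ref = RnaSequence.from_string("A" * len(statuses))
        array = ResidueStatusArray.undefined(ref)
        for i, s in enumerate(statuses, start=1):
            array.set_status(i, s)
        return array

    def test_isolated_unpaired_residues(self):
        u, d = Status.UNPAIRED, Status.UNDEFINED
        array = self._array([d, u, d, d, d, u, d])
        lines = [c.to_line() for c in format_mfold_constraints(array)]
        assert lines == ["P 2 0 1", "P 6 0 1"]

    def test_paired_run(self):
        p, d = Status.PAIRED, Status.UNDEFINED
        array = self._array([d, d, p, p, p, d, d])
        lines = [c.to_line() for c in format_mfold_constraints(array)]
        assert lines == ["F 3 0 3"]

    def test_all_undefined_emits_nothing(self):
        array = self._array([Status.UNDEFINED] * 5)
        assert format_mfold_constraints(array) == []
        assert constraint_lines([]) == ""

    @pytest.mark.parametrize("seed", range(20))
    def test_encoding_is_lossless(self, seed):
        rng = random.Random(seed)
        statuses = [rng.choice(list(Status)) for _ in range(rng.randint(1, 60))]
        array = self._array(statuses)
        decoded = [Status.UNDEFINED] * len(statuses)
        for c in format_mfold_constraints(array):
            kind = Status.PAIRED if c.kind == "force_paired" else Status.UNPAIRED
            for pos in range(c.start, c.start + c.run_length):
                decoded[pos - 1] = kind
        assert decoded == statuses


class TestInferConstraints:
    def test_worked_example(self, t1):
        array, constraints = infer_constraints(REF, {"T1": ["AG", "CAUG"]}, [t1])
        expected = {2: Status.UNPAIRED, 6: Status.UNPAIRED}
        for pos in range(1, 8):
            assert array.status(pos) is expected.get(pos, Status.UNDEFINED)
        assert [c.to_line() for c in constraints] == ["P 2 0 1", "P 6 0 1"]

    def test_no_products_all_undefined(self, t1):
        array, constraints = infer_constraints(REF, {"T1": []}, [t1])
        assert all(s is Status.UNDEFINED for s in array.statuses)
        assert constraints == []

    def test_impossible_evidence_warned_and_excluded(self, t2, t1):
        # label a T2-style fragment as T1: boundaries fall on non-G residues
        with pytest.warns(UserWarning, match="impossible"):
            array, _ = infer_constraints(REF, {"T1": ["GCA"]}, [t1])
        assert all(s is Status.UNDEFINED for s in array.statuses)
        assert len(array.excluded_evidence) == 2

    def test_product_for_unknown_enzyme_rejected(self, t1):
        with pytest.raises(CompatibilityError):
            infer_constraints(REF, {"V1": ["AG"]}, [t1])

    def test_status_editable_before_formatting(self, t1):
        array, _ = infer_constraints(REF, {"T1": ["AG", "CAUG"]}, [t1])
        array.set_status(4, Status.PAIRED)
        lines = [c.to_line() for c in format_mfold_constraints(array)]
        assert "F 4 0 1" in lines

    @pytest.mark.parametrize("seed", range(15))
    @pytest.mark.parametrize("density", [0.2, 0.5])
    def test_unambiguous_products_never_contradict_truth(self, seed, density):
        """Products whose sequence occurs once in the reference carry only
        true boundary evidence, so every verdict matches the structure."""
        cfg = FixtureConfig(length=120, pairing_density=density, seed=seed)
        exp = synthetic_experiment(cfg)
        products = {
            lane.enzyme: [f.sequence for f in lane.analysis_fragments()
                          if f.occurrence_count == 1]
            for lane in exp.digest.lanes.values()
        }
        panel = [builtin_enzyme(n) for n in cfg.panel]
        array, _ = infer_constraints(exp.reference, products, panel)
        for pos in range(1, exp.structure.length + 1):
            status = array.status(pos)
            if status is Status.UNDEFINED:
                continue
            truth = Status.PAIRED if exp.structure.is_paired(pos) else Status.UNPAIRED
            assert status is truth, f"seed {seed}: residue {pos} misassigned"

    def test_interior_inference_flag(self, t1):
        ref = RnaSequence.from_string("AGGA")
        with_flag, _ = infer_constraints(
            ref, {"T1": ["AGG"]}, [t1], interior_inference=True
        )
        without, _ = infer_constraints(ref, {"T1": ["AGG"]}, [t1])
        assert with_flag.status(2) is Status.PAIRED
        assert without.status(2) is Status.UNDEFINED
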