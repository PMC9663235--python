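"""Knowledge-base types, serialization round-trips, validation, traversal."""

import json

import pytest

from sdm import (
    CATEGORIES,
    CATEGORY_RANK,
    Category,
    GeneratorSpec,
    KBFormatError,
    KBValidationError,
    TraversalError,
    generate_kb,
    load_kb,
    resolve_symptom_sequence,
    save_kb,
    validate_kb,
)
from sdm.fixtures import EXCESS_COLD, YANG_DEFICIENCY
from sdm.knowledge_base import kb_from_dict, kb_to_dict

from conftest import small_spec

MINIMAL_KB = {
    "schema_version": "1",
    "questions": [
        {
            "id": 1,
            "text": "Fear of cold?",
            "category": "cold-and-heat",
            "answers": [
                {"id": "A1", "text": "Yes", "next_question": None, "next_syndrome": "chill"}
            ],
        }
    ],
    "syndromes": [{"name": "chill", "symptoms": [{"question": 1, "answer": "A1"}]}],
}


class TestCategories:
    def test_thirteen_fixed_categories_with_bijective_ranks(self):
        assert len(CATEGORIES) == 13
        assert CATEGORIES[0] == "cold-and-heat"
        assert CATEGORIES[1] == "sweat"
        assert CATEGORIES[2] == "pain"
        assert sorted(CATEGORY_RANK.values()) == list(range(1, 14))
        assert Category.of("sweat").rank == 2

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            Category.of("pulse")


class TestLoadSave:
    def test_minimal_json_kb(self, tmp_path):
        path = tmp_path / "kb.json"
        path.write_text(json.dumps(MINIMAL_KB), encoding="utf-8")
        kb = load_kb(path)
        assert len(kb.questions) == 1
        assert len(kb.syndromes) == 1

    def test_table1_csv_import(self, tmp_path, kb_table1):
        path = tmp_path / "kb.csv"
        save_kb(kb_table1, path, format="csv")
        kb = load_kb(path, format="csv")
        assert len(kb.questions) == 3
        assert [a.id for q in kb.questions for a in q.answers] == [
            "A1", "A2", "A3", "A4", "A5", "A6",
        ]
        terminals = {
            a.next_syndrome
            for q in kb.questions
            for a in q.answers
            if a.next_syndrome is not None
        }
        assert terminals == {YANG_DEFICIENCY, EXCESS_COLD}

    def test_json_round_trip_identity(self, tmp_path, kb_table1):
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        save_kb(kb_table1, p1)
        kb = load_kb(p1)
        save_kb(kb, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert kb_to_dict(kb) == kb_to_dict(kb_table1)

    def test_csv_round_trip_is_idempotent(self, tmp_path, kb_table1):
        # CSV carries the question base; after one import the representation
        # is stable under further save/load cycles
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        save_kb(kb_table1, p1, format="csv")
        kb_a = load_kb(p1)
        save_kb(kb_a, p2, format="csv")
        kb_b = load_kb(p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert kb_to_dict(kb_a) == kb_to_dict(kb_b)

    @pytest.mark.parametrize("seed", range(100))
    def test_json_round_trip_over_random_kbs(self, tmp_path, seed):
        kb = generate_kb(small_spec(seed))
        path = tmp_path / "kb.json"
        save_kb(kb, path)
        assert kb_to_dict(load_kb(path)) == kb_to_dict(kb)

    def test_save_is_deterministic(self, tmp_path, kb_table2):
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        save_kb(kb_table2, p1)
        save_kb(kb_table2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_syndromes_serialize_as_empty_list(self, tmp_path):
        kb = kb_from_dict({"schema_version": "1", "questions": [], "syndromes": []})
        path = tmp_path / "kb.json"
        save_kb(kb, path)
        assert json.loads(path.read_text())["syndromes"] == []

    def test_text_fields_are_trimmed_and_nfc_normalized(self, tmp_path):
        data = json.loads(json.dumps(MINIMAL_KB))
        # "e" + combining acute (NFD) with padding; must equal precomposed form
        data["syndromes"][0]["name"] = "  chillé  "
        data["questions"][0]["answers"][0]["next_syndrome"] = "chillé"
        path = tmp_path / "kb.json"
        path.write_text(json.dumps(data), encoding="utf-8")
        kb = load_kb(path)
        assert kb.syndromes[0].name == "chillé"

    def test_parse_error_names_position(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json", encoding="utf-8")
        with pytest.raises(KBFormatError, match="line 1"):
            load_kb(path)

    def test_csv_bad_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b,c\n1,2,3\n", encoding="utf-8")
        with pytest.raises(KBFormatError, match="header"):
            load_kb(path, format="csv")

    def test_dangling_reference_raises_on_load(self, tmp_path):
        data = json.loads(json.dumps(MINIMAL_KB))
        data["questions"][0]["answers"][0]["next_syndrome"] = "missing syndrome"
        path = tmp_path / "kb.json"
        path.write_text(json.dumps(data), encoding="utf-8")
        with pytest.raises(KBValidationError, match="missing syndrome"):
            load_kb(path)


class TestValidate:
    def test_fixtures_yield_empty_reports(self, kb_table1, kb_table2):
        assert len(validate_kb(kb_table1, strict=True)) == 0
        assert len(validate_kb(kb_table2, strict=True)) == 0

    def test_dangling_next_to_missing_syndrome(self, kb_table1):
        data = kb_to_dict(kb_table1)
        data["questions"][2]["answers"][0]["next_syndrome"] = "nonexistent"
        report = validate_kb(kb_from_dict(data))
        assert "DANGLING_NEXT" in report.codes()

    def test_category_order_warning_becomes_error_in_strict(self, kb_table1):
        data = kb_to_dict(kb_table1)
        data["questions"][0]["category"] = "stool-and-urine"  # rank 13 at id 1
        kb = kb_from_dict(data)
        lax = validate_kb(kb, strict=False)
        assert lax.ok and {f.code for f in lax.warnings} == {"CATEGORY_ORDER"}
        strict = validate_kb(kb, strict=True)
        assert not strict.ok and "CATEGORY_ORDER" in {f.code for f in strict.errors}


def _mutate_delete_syndrome(data, rng):
    victim = rng.choice(data["syndromes"])
    data["syndromes"] = [h for h in data["syndromes"] if h["name"] != victim["name"]]
    return "DANGLING_NEXT", victim["name"]


def _mutate_backward_next(data, rng):
    in_seq = {
        (z["question"], z["answer"])
        for h in data["syndromes"]
        for z in h["symptoms"]
    }
    pool = [
        (q, a)
        for q in data["questions"]
        for a in q["answers"]
        if a["next_question"] is not None and (q["id"], a["id"]) not in in_seq
    ]
    q, a = rng.choice(pool)
    a["next_question"] = q["id"]
    return "CYCLE", a["id"]


def _mutate_dangling_question(data, rng):
    pool = [
        a for q in data["questions"] for a in q["answers"] if a["next_question"] is not None
    ]
    a = rng.choice(pool)
    a["next_question"] = 10_000
    return "DANGLING_NEXT", a["id"]


def _mutate_duplicate_answer_id(data, rng):
    in_seq = {
        (z["question"], z["answer"]) for h in data["syndromes"] for z in h["symptoms"]
    }
    pool = [
        (q, a) for q in data["questions"] for a in q["answers"]
        if (q["id"], a["id"]) not in in_seq
    ]
    (_, a1), (_, a2) = rng.sample(pool, 2)
    a2["id"] = a1["id"]
    return "DUPLICATE_ID", a1["id"]


def _mutate_retarget_terminal(data, rng):
    victim = rng.choice(data["syndromes"])
    other = rng.choice([h for h in data["syndromes"] if h["name"] != victim["name"]])
    term = victim["symptoms"][-1]
    for q in data["questions"]:
        if q["id"] == term["question"]:
            for a in q["answers"]:
                if a["id"] == term["answer"]:
                    a["next_syndrome"] = other["name"]
    return "NO_TERMINAL", victim["name"]


def _mutate_reverse_sequence(data, rng):
    pool = [h for h in data["syndromes"] if len(h["symptoms"]) >= 2]
    victim = rng.choice(pool)
    victim["symptoms"] = victim["symptoms"][::-1]
    return "SEQUENCE_ORDER", victim["name"]


def _mutate_dangling_symptom(data, rng):
    victim = rng.choice(data["syndromes"])
    victim["symptoms"][0]["question"] = 10_000
    return "DANGLING_SYMPTOM", victim["name"]


MUTATIONS = [
    _mutate_delete_syndrome,
    _mutate_backward_next,
    _mutate_dangling_question,
    _mutate_duplicate_answer_id,
    _mutate_retarget_terminal,
    _mutate_reverse_sequence,
    _mutate_dangling_symptom,
]


class TestDefectInjection:
    """Single-defect mutations must each be flagged at the mutated element."""

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("mutate", MUTATIONS, ids=lambda m: m.__name__[8:])
    def test_validator_flags_the_mutated_element(self, seed, mutate):
        import random

        kb = generate_kb(small_spec(seed, symptoms_min=2))
        assert validate_kb(kb).ok
        data = kb_to_dict(kb)
        code, element = mutate(data, random.Random(seed))
        report = validate_kb(kb_from_dict(data))
        hits = [f for f in report.findings if f.code == code]
        assert hits, f"expected {code}, got {sorted(report.codes())}"
        assert any(element in f.where or element in f.message for f in hits)


class TestResolve:
    def test_short_duration_chain_terminates_at_excess_cold(self, kb_table1):
        symptoms, terminal = resolve_symptom_sequence(kb_table1, 1, ["A1", "A3", "A6"])
        assert len(symptoms) == 3
        assert terminal == EXCESS_COLD

    def test_long_duration_chain_terminates_at_yang_deficiency(self, kb_table1):
        symptoms, terminal = resolve_symptom_sequence(kb_table1, 1, ["A1", "A3", "A5"])
        assert len(symptoms) == 3
        assert terminal == YANG_DEFICIENCY

    def test_single_step_chain(self, kb_table1):
        symptoms, terminal = resolve_symptom_sequence(kb_table1, 3, ["A5"])
        assert len(symptoms) == 1
        assert terminal == YANG_DEFICIENCY

    def test_non_terminal_prefix_returns_none(self, kb_table1):
        symptoms, terminal = resolve_symptom_sequence(kb_table1, 1, ["A1", "A4"])
        assert [z.question for z in symptoms] == [1, 2]
        assert terminal is None

    def test_invalid_answer_names_the_step(self, kb_table1):
        with pytest.raises(TraversalError, match="step 2"):
            resolve_symptom_sequence(kb_table1, 1, ["A1", "A9"])

    @pytest.mark.parametrize("seed", range(20))
    def test_every_syndrome_replays_to_its_own_name(self, seed):
        kb = generate_kb(small_spec(seed))
        for h in kb.syndromes:
            symptoms, terminal = resolve_symptom_sequence(
                kb, h.symptoms[0].question, [z.answer for z in h.symptoms]
            )
            assert terminal == h.name
            assert [z.key() for z in symptoms] == [z.key() for z in h.symptoms]
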