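"""Inquiry knowledge base: domain types, serialization, and validation.

The knowledge base ``D = H ∪ Q`` couples a question base ``Q`` (questions with
closed candidate-answer lists, grouped into the thirteen Ten-Brief-Inquiries
categories and numbered so that ids encode consultation order) with a syndrome
base ``H`` (named symptom sequences).  A symptom is the atomic unit of inquiry
evidence: a ``(question, chosen answer)`` pair ``z = (q, a)``.  Each answer
carries a ``next`` pointer — either a forward question reference (the
consultation is contextual: the chosen answer decides what is asked next) or a
syndrome name, marking the terminal pair of that syndrome's sequence and
serving as the reverse index from question-answer pairs to syndromes.

Canonical on-disk format is JSON (schema_version "1").  A five-column CSV
dialect mirroring the question-base table layout is supported for import and
export; it carries the question base only, so syndromes are recovered from
their terminal links as single-symptom sequences.
"""

from __future__ import annotations

import csv
import json
import unicodedata
from pathlib import Path
from typing import Iterable, Literal, Optional, Union

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .errors import KBFormatError, KBValidationError, TraversalError, UnknownSyndromeError

SCHEMA_VERSION = "1"

#: The thirteen inquiry categories, in fixed Ten-Brief-Inquiries order.
CATEGORIES: tuple[str, ...] = (
    "cold-and-heat",
    "sweat",
    "pain",
    "taste",
    "ears",
    "eyes",
    "chest",
    "hypochondrium",
    "stomach-and-abdomen",
    "sleep",
    "thirst",
    "appetite",
    "stool-and-urine",
)

#: Category name -> rank 1..13 (a bijection).
CATEGORY_RANK: dict[str, int] = {name: i + 1 for i, name in enumerate(CATEGORIES)}


def _norm(text: str) -> str:
    """NFC-normalize and trim a text field (names are matched after this)."""
    return unicodedata.normalize("NFC", text).strip()


class Category(BaseModel):
    """One of the 13 fixed inquiry categories with its consultation rank."""

    model_config = ConfigDict(frozen=True)

    name: str
    rank: int

    @model_validator(mode="after")
    def _check(self) -> "Category":
        if self.name not in CATEGORY_RANK:
            raise ValueError(f"unknown category {self.name!r}")
        if self.rank != CATEGORY_RANK[self.name]:
            raise ValueError(f"category {self.name!r} has rank {CATEGORY_RANK[self.name]}, not {self.rank}")
        return self

    @classmethod
    def of(cls, name: str) -> "Category":
        name = _norm(name)
        if name not in CATEGORY_RANK:
            raise ValueError(f"unknown category {name!r}")
        return cls(name=name, rank=CATEGORY_RANK[name])


class Answer(BaseModel):
    """A candidate answer with its forward pointer.

    Exactly one of ``next_question`` / ``next_syndrome`` is set: the chosen
    answer either routes the consultation to a later question or terminates a
    syndrome's sequence by naming it.
    """

    model_config = ConfigDict(frozen=True)

    id: str
    text: str
    next_question: Optional[int] = None
    next_syndrome: Optional[str] = None

    @field_validator("id", "text", mode="before")
    @classmethod
    def _norm_text(cls, v: str) -> str:
        return _norm(v)

    @field_validator("next_syndrome", mode="before")
    @classmethod
    def _norm_opt(cls, v):
        return _norm(v) if isinstance(v, str) else v

    @model_validator(mode="after")
    def _exactly_one_next(self) -> "Answer":
        if (self.next_question is None) == (self.next_syndrome is None):
            raise ValueError(
                f"answer {self.id!r} must have exactly one of next_question / next_syndrome"
            )
        return self

    @property
    def is_terminal(self) -> bool:
        return self.next_syndrome is not None


class Question(BaseModel):
    """A question with its ordered candidate answers ``q = (q_i, s_i)``."""

    model_config = ConfigDict(frozen=True)

    id: int = Field(gt=0)
    text: str
    category: str
    answers: tuple[Answer, ...] = Field(min_length=1)

    @field_validator("text", mode="before")
    @classmethod
    def _norm_text(cls, v: str) -> str:
        return _norm(v)

    @field_validator("category", mode="before")
    @classmethod
    def _norm_cat(cls, v: str) -> str:
        v = _norm(v)
        if v not in CATEGORY_RANK:
            raise ValueError(f"unknown category {v!r}")
        return v

    @property
    def rank(self) -> int:
        return CATEGORY_RANK[self.category]

    def answer(self, answer_id: str) -> Answer:
        for a in self.answers:
            if a.id == answer_id:
                return a
        raise KeyError(answer_id)

    def has_answer(self, answer_id: str) -> bool:
        return any(a.id == answer_id for a in self.answers)


class Symptom(BaseModel):
    """Atomic inquiry evidence: a (question, chosen answer) pair ``z = (q, a)``.

    Identity is the id pair, never the display text.
    """

    model_config = ConfigDict(frozen=True)

    question: int
    answer: str

    @field_validator("answer", mode="before")
    @classmethod
    def _norm_ans(cls, v: str) -> str:
        return _norm(v)

    def key(self) -> tuple[int, str]:
        return (self.question, self.answer)


class Syndrome(BaseModel):
    """A named syndrome ``h = {z_i}``: an ordered chain of symptoms.

    The sequence follows the answer chain (ascending question ids) and its
    last symptom's answer carries this syndrome's name as terminal ``next``.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    symptoms: tuple[Symptom, ...] = Field(min_length=1)

    @field_validator("name", mode="before")
    @classmethod
    def _norm_name(cls, v: str) -> str:
        return _norm(v)

    @property
    def terminal(self) -> Symptom:
        return self.symptoms[-1]

    def question_ids(self) -> list[int]:
        return [z.question for z in self.symptoms]

    def symptom_set(self) -> frozenset[tuple[int, str]]:
        return frozenset(z.key() for z in self.symptoms)


class InquiryKnowledgeBase(BaseModel):
    """The full inquiry knowledge base ``D = H ∪ Q``."""

    model_config = ConfigDict(frozen=True)

    schema_version: str = SCHEMA_VERSION
    questions: tuple[Question, ...] = ()
    syndromes: tuple[Syndrome, ...] = ()

    def question_map(self) -> dict[int, Question]:
        return {q.id: q for q in self.questions}

    def syndrome_map(self) -> dict[str, Syndrome]:
        return {h.name: h for h in self.syndromes}

    def question(self, qid: int) -> Question:
        for q in self.questions:
            if q.id == qid:
                return q
        raise KeyError(qid)

    def syndrome(self, name: str) -> Syndrome:
        name = _norm(name)
        for h in self.syndromes:
            if h.name == name:
                return h
        raise UnknownSyndromeError([name])

    def syndrome_names(self) -> list[str]:
        return [h.name for h in self.syndromes]

    def sorted(self) -> "InquiryKnowledgeBase":
        """Canonical ordering: questions by id, syndromes by name."""
        return InquiryKnowledgeBase(
            schema_version=self.schema_version,
            questions=tuple(sorted(self.questions, key=lambda q: q.id)),
            syndromes=tuple(sorted(self.syndromes, key=lambda h: h.name)),
        )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

DANGLING_NEXT = "DANGLING_NEXT"
DANGLING_SYMPTOM = "DANGLING_SYMPTOM"
DUPLICATE_ID = "DUPLICATE_ID"
CATEGORY_ORDER = "CATEGORY_ORDER"
UNREACHABLE_QUESTION = "UNREACHABLE_QUESTION"
NO_TERMINAL = "NO_TERMINAL"
CYCLE = "CYCLE"
SEQUENCE_ORDER = "SEQUENCE_ORDER"
BROKEN_CHAIN = "BROKEN_CHAIN"


class ValidationFinding(BaseModel):
    model_config = ConfigDict(frozen=True)

    code: str
    severity: Literal["error", "warning"]
    where: str
    message: str


class ValidationReport(BaseModel):
    findings: tuple[ValidationFinding, ...] = ()

    @property
    def errors(self) -> list[ValidationFinding]:
        return [f for f in self.findings if f.severity == "error"]

    @property
    def warnings(self) -> list[ValidationFinding]:
        return [f for f in self.findings if f.severity == "warning"]

    @property
    def ok(self) -> bool:
        """True when no error-severity findings exist."""
        return not self.errors

    def codes(self) -> set[str]:
        return {f.code for f in self.findings}

    def __len__(self) -> int:
        return len(self.findings)


def validate_kb(kb: InquiryKnowledgeBase, strict: bool = False) -> ValidationReport:
    """Check every cross-reference and ordering rule; return coded findings.

    Rules checked (codes in parentheses):

    * unique question ids, globally unique answer ids, unique syndrome names
      (DUPLICATE_ID);
    * every ``next_question`` points to an existing, strictly later question —
      forward-only chains guarantee every consultation terminates
      (DANGLING_NEXT / CYCLE);
    * every ``next_syndrome`` names an existing syndrome (DANGLING_NEXT);
    * every syndrome symptom resolves to an existing question/answer
      (DANGLING_SYMPTOM);
    * symptom sequences are strictly ascending in question id with no repeated
      question (SEQUENCE_ORDER) and are next-consistent chains, i.e. each
      non-terminal symptom's answer points to the next symptom's question
      (BROKEN_CHAIN);
    * the last symptom's answer carries the syndrome's own name, and no two
      syndromes share a terminal pair (NO_TERMINAL);
    * question ids monotone with category rank (CATEGORY_ORDER — warning by
      default, error under ``strict``);
    * questions that appear in no syndrome sequence and are the target of no
      answer (UNREACHABLE_QUESTION — warning).

    Findings are returned, never raised; an all-invariants-hold KB yields an
    empty report.
    """
    findings: list[ValidationFinding] = []

    def add(code: str, severity: str, where: str, message: str) -> None:
        findings.append(
            ValidationFinding(code=code, severity=severity, where=where, message=message)
        )

    # duplicate ids
    seen_q: set[int] = set()
    for q in kb.questions:
        if q.id in seen_q:
            add(DUPLICATE_ID, "error", f"question {q.id}", f"duplicate question id {q.id}")
        seen_q.add(q.id)
    seen_a: set[str] = set()
    for q in kb.questions:
        for a in q.answers:
            if a.id in seen_a:
                add(DUPLICATE_ID, "error", f"answer {a.id}", f"duplicate answer id {a.id!r}")
            seen_a.add(a.id)
    seen_h: set[str] = set()
    for h in kb.syndromes:
        if h.name in seen_h:
            add(DUPLICATE_ID, "error", f"syndrome {h.name!r}", f"duplicate syndrome name {h.name!r}")
        seen_h.add(h.name)

    qmap = {q.id: q for q in kb.questions}
    hnames = {h.name for h in kb.syndromes}

    # next pointers
    for q in kb.questions:
        for a in q.answers:
            if a.next_question is not None:
                if a.next_question not in qmap:
                    add(
                        DANGLING_NEXT,
                        "error",
                        f"answer {a.id}",
                        f"next question {a.next_question} of answer {a.id!r} does not exist",
                    )
                elif a.next_question <= q.id:
                    add(
                        CYCLE,
                        "error",
                        f"answer {a.id}",
                        f"answer {a.id!r} of question {q.id} points backward/self to "
                        f"{a.next_question}; next pointers must be forward-only",
                    )
            elif a.next_syndrome is not None and a.next_syndrome not in hnames:
                add(
                    DANGLING_NEXT,
                    "error",
                    f"answer {a.id}",
                    f"next syndrome {a.next_syndrome!r} of answer {a.id!r} does not exist",
                )

    # syndrome sequences
    terminals: dict[tuple[int, str], str] = {}
    for h in kb.syndromes:
        resolved = True
        for z in h.symptoms:
            q = qmap.get(z.question)
            if q is None:
                add(
                    DANGLING_SYMPTOM,
                    "error",
                    f"syndrome {h.name!r}",
                    f"symptom references missing question {z.question}",
                )
                resolved = False
            elif not q.has_answer(z.answer):
                add(
                    DANGLING_SYMPTOM,
                    "error",
                    f"syndrome {h.name!r}",
                    f"symptom references answer {z.answer!r} absent from question {z.question}",
                )
                resolved = False
        qids = h.question_ids()
        if len(set(qids)) != len(qids) or qids != sorted(qids):
            add(
                SEQUENCE_ORDER,
                "error",
                f"syndrome {h.name!r}",
                "symptom sequence must have strictly ascending, non-repeating question ids",
            )
        if not resolved:
            continue
        # chain consistency: replaying the sequence must follow next pointers
        for z, z_next in zip(h.symptoms, h.symptoms[1:]):
            a = qmap[z.question].answer(z.answer)
            if a.next_question != z_next.question:
                add(
                    BROKEN_CHAIN,
                    "error",
                    f"syndrome {h.name!r}",
                    f"answer {z.answer!r} of question {z.question} points to "
                    f"{a.next_question or a.next_syndrome!r}, not to the next symptom's "
                    f"question {z_next.question}",
                )
        term = h.terminal
        term_answer = qmap[term.question].answer(term.answer)
        if term_answer.next_syndrome != h.name:
            add(
                NO_TERMINAL,
                "error",
                f"syndrome {h.name!r}",
                f"terminal pair (q{term.question}, {term.answer!r}) does not carry the "
                f"syndrome's name as next",
            )
        if term.key() in terminals:
            add(
                NO_TERMINAL,
                "error",
                f"syndrome {h.name!r}",
                f"terminal pair (q{term.question}, {term.answer!r}) already terminates "
                f"syndrome {terminals[term.key()]!r}",
            )
        terminals[term.key()] = h.name

    # category/id monotonicity
    by_id = sorted(kb.questions, key=lambda q: q.id)
    for prev, cur in zip(by_id, by_id[1:]):
        if cur.rank < prev.rank:
            add(
                CATEGORY_ORDER,
                "error" if strict else "warning",
                f"question {cur.id}",
                f"question {cur.id} ({cur.category}, rank {cur.rank}) has a larger id than "
                f"question {prev.id} ({prev.category}, rank {prev.rank})",
            )

    # reachability: part of some sequence, or the target of some answer
    in_sequence = {z.question for h in kb.syndromes for z in h.symptoms}
    targeted = {
        a.next_question
        for q in kb.questions
        for a in q.answers
        if a.next_question is not None
    }
    for q in kb.questions:
        if q.id not in in_sequence and q.id not in targeted:
            add(
                UNREACHABLE_QUESTION,
                "warning",
                f"question {q.id}",
                f"question {q.id} appears in no syndrome sequence and is never pointed to",
            )

    return ValidationReport(findings=tuple(findings))


def resolve_symptom_sequence(
    kb: InquiryKnowledgeBase,
    start_question: int,
    answers: Iterable[str],
) -> tuple[list[Symptom], Optional[str]]:
    """Follow the answer chain from ``start_question`` through ``answers``.

    Emits one :class:`Symptom` per (question, chosen answer) step.  Returns
    the terminal syndrome name when the final answer's ``next`` is a syndrome
    reference, else ``None``.  Forward-only next pointers make every chain
    finite.
    """
    answers = list(answers)
    qmap = kb.question_map()
    if start_question not in qmap:
        raise TraversalError(f"start question {start_question} does not exist")
    symptoms: list[Symptom] = []
    current: Optional[int] = start_question
    for step, answer_id in enumerate(answers, start=1):
        if current is None:
            raise TraversalError(
                f"step {step}: chain already terminated but answers remain"
            )
        question = qmap.get(current)
        if question is None:
            raise TraversalError(f"step {step}: question {current} does not exist")
        answer_id = _norm(answer_id)
        if not question.has_answer(answer_id):
            raise TraversalError(
                f"step {step}: answer {answer_id!r} is not a candidate answer of "
                f"question {current}"
            )
        answer = question.answer(answer_id)
        symptoms.append(Symptom(question=current, answer=answer_id))
        if answer.is_terminal:
            if step != len(answers):
                raise TraversalError(
                    f"step {step}: chain terminated at syndrome "
                    f"{answer.next_syndrome!r} but answers remain"
                )
            return symptoms, answer.next_syndrome
        current = answer.next_question
    return symptoms, None


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

CSV_HEADER = ["Question no.", "Question", "Answer no.", "Answer", "Next"]

Format = Literal["json", "csv"]


def _infer_format(path: Path, format: Optional[str]) -> Format:
    if format is not None:
        if format not in ("json", "csv"):
            raise ValueError(f"unknown format {format!r}")
        return format  # type: ignore[return-value]
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    return "json"


def kb_to_dict(kb: InquiryKnowledgeBase) -> dict:
    """Canonical JSON-ready dict: questions by id, syndromes by name."""
    kb = kb.sorted()
    return {
        "schema_version": kb.schema_version,
        "questions": [
            {
                "id": q.id,
                "text": q.text,
                "category": q.category,
                "answers": [
                    {
                        "id": a.id,
                        "text": a.text,
                        "next_question": a.next_question,
                        "next_syndrome": a.next_syndrome,
                    }
                    for a in q.answers
                ],
            }
            for q in kb.questions
        ],
        "syndromes": [
            {
                "name": h.name,
                "symptoms": [
                    {"question": z.question, "answer": z.answer} for z in h.symptoms
                ],
            }
            for h in kb.syndromes
        ],
    }


def kb_from_dict(data: dict) -> InquiryKnowledgeBase:
    try:
        questions = tuple(
            Question(
                id=q["id"],
                text=q["text"],
                category=q.get("category", CATEGORIES[0]),
                answers=tuple(
                    Answer(
                        id=a["id"],
                        text=a["text"],
                        next_question=a.get("next_question"),
                        next_syndrome=a.get("next_syndrome"),
                    )
                    for a in q["answers"]
                ),
            )
            for q in data.get("questions", [])
        )
        syndromes = tuple(
            Syndrome(
                name=h["name"],
                symptoms=tuple(
                    Symptom(question=z["question"], answer=z["answer"])
                    for z in h["symptoms"]
                ),
            )
            for h in data.get("syndromes", [])
        )
    except (KeyError, TypeError) as exc:
        raise KBFormatError(f"malformed knowledge-base record: {exc}") from exc
    return InquiryKnowledgeBase(
        schema_version=str(data.get("schema_version", SCHEMA_VERSION)),
        questions=questions,
        syndromes=syndromes,
    )


def _check_references(kb: InquiryKnowledgeBase) -> InquiryKnowledgeBase:
    report = validate_kb(kb, strict=False)
    if not report.ok:
        details = "; ".join(f.message for f in report.errors)
        raise KBValidationError(
            f"knowledge base failed validation: {details}", findings=report.errors
        )
    return kb


def load_kb(
    path: Union[str, Path], format: Optional[str] = None
) -> InquiryKnowledgeBase:
    """Load and cross-reference-check a knowledge base from JSON or CSV.

    Text fields are whitespace-trimmed and Unicode-normalized (NFC) on the way
    in.  Unresolved references raise :class:`KBValidationError` listing every
    dangling id; parse failures raise :class:`KBFormatError`.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        try:
            with path.open("r", encoding="utf-8") as fh:
                data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise KBFormatError(
                f"{path}: invalid JSON at line {exc.lineno}, column {exc.colno}: {exc.msg}"
            ) from exc
        if not isinstance(data, dict):
            raise KBFormatError(f"{path}: top-level JSON value must be an object")
        return _check_references(kb_from_dict(data))
    return _check_references(_load_csv(path))


def _load_csv(path: Path) -> InquiryKnowledgeBase:
    """Import the five-column question-base table.

    Continuation rows (blank question cells) attach answers to the preceding
    question.  ``Next`` is an integer question reference or a bare syndrome
    name.  Syndromes are recovered from terminal links: each distinct syndrome
    name becomes a single-symptom syndrome whose pair is the last (by question
    id, then answer position) answer naming it.
    """
    rows: list[dict] = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise KBFormatError(f"{path}: empty CSV file") from None
        if [h.strip() for h in header] != CSV_HEADER:
            raise KBFormatError(
                f"{path}: line 1: expected header {','.join(CSV_HEADER)!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not any(cell.strip() for cell in row):
                continue
            if len(row) != 5:
                raise KBFormatError(f"{path}: line {lineno}: expected 5 columns, got {len(row)}")
            rows.append({"lineno": lineno, "cells": [c.strip() for c in row]})

    questions: list[dict] = []
    for row in rows:
        qno, qtext, ano, atext, nxt = row["cells"]
        if qno:
            try:
                qid = int(qno)
            except ValueError:
                raise KBFormatError(
                    f"{path}: line {row['lineno']}: question number {qno!r} is not an integer"
                ) from None
            questions.append({"id": qid, "text": qtext, "answers": []})
        elif not questions:
            raise KBFormatError(
                f"{path}: line {row['lineno']}: answer row before any question row"
            )
        if not ano:
            raise KBFormatError(f"{path}: line {row['lineno']}: missing answer number")
        try:
            next_q: Optional[int] = int(nxt)
            next_h: Optional[str] = None
        except ValueError:
            next_q, next_h = None, nxt
        if next_h == "":
            raise KBFormatError(f"{path}: line {row['lineno']}: empty Next cell")
        questions[-1]["answers"].append(
            {"id": ano, "text": atext, "next_question": next_q, "next_syndrome": next_h}
        )

    # recover syndromes from terminal links (last reference wins as terminal)
    terminal: dict[str, tuple[int, str]] = {}
    for q in questions:
        for a in q["answers"]:
            if a["next_syndrome"] is not None:
                terminal[_norm(a["next_syndrome"])] = (q["id"], a["id"])
    syndromes = [
        {"name": name, "symptoms": [{"question": qid, "answer": aid}]}
        for name, (qid, aid) in sorted(terminal.items())
    ]
    for q in questions:
        q["category"] = CATEGORIES[0]
    return kb_from_dict(
        {"schema_version": SCHEMA_VERSION, "questions": questions, "syndromes": syndromes}
    )


def save_kb(
    kb: InquiryKnowledgeBase, path: Union[str, Path], format: Optional[str] = None
) -> None:
    """Write a knowledge base deterministically (sorted records, stable bytes)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        payload = json.dumps(kb_to_dict(kb), ensure_ascii=False, indent=2) + "\n"
        path.write_text(payload, encoding="utf-8")
        return
    kb = kb.sorted()
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(CSV_HEADER)
        for q in kb.questions:
            for i, a in enumerate(q.answers):
                nxt = str(a.next_question) if a.next_question is not None else a.next_syndrome
                writer.writerow(
                    [str(q.id) if i == 0 else "", q.text if i == 0 else "", a.id, a.text, nxt]
                )
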