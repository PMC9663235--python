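"""Consultation: present the Q&A list and collect one answer per question.

Step 2 of the inquiry reasoning loop.  Questions are asked strictly in Q&A-list
order; for each, the patient (or a simulated answer policy) picks one candidate
answer or the "none" sentinel, which records the question as skipped and
contributes no symptom.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Callable, Literal, Optional

from pydantic import BaseModel, ConfigDict

from .deduction import QAList
from .errors import PolicyError
from .knowledge_base import InquiryKnowledgeBase, Question, Symptom

#: Sentinel answer meaning "I have no such symptom"; contributes no symptom.
NONE_ANSWER = "none"


class PatientRecord(BaseModel):
    """The patient's collected inquiry evidence."""

    model_config = ConfigDict(frozen=True)

    symptoms: frozenset[Symptom] = frozenset()
    skipped: frozenset[int] = frozenset()

    def symptom_keys(self) -> frozenset[tuple[int, str]]:
        return frozenset(z.key() for z in self.symptoms)

    def sorted_symptoms(self) -> list[Symptom]:
        return sorted(self.symptoms, key=lambda z: (z.question, z.answer))


@dataclass
class AnswerPolicy:
    """How answers are produced during a consultation.

    * ``scripted`` — every question must be covered by ``script`` (question id
      -> answer id or "none").
    * ``random`` — one answer drawn uniformly from the question's candidate
      answers (imitating a patient with arbitrary symptoms); requires ``seed``
      unless the caller supplies its own random stream.  ``none_prob`` adds an
      optional "none" probability for robustness studies (default 0: the
      simulated patient always picks a concrete answer).
    * ``oracle`` — a planted ground truth: answers with the ``truth``
      syndrome's own answer whenever the question lies on its symptom
      sequence, otherwise "none".
    * ``interactive`` — delegates to an ``ask`` callable (the CLI wires this
      to a terminal prompt).
    """

    kind: Literal["interactive", "scripted", "random", "oracle"]
    script: Optional[dict[int, str]] = None
    truth: Optional[str] = None
    seed: Optional[int] = None
    none_prob: float = 0.0
    ask: Optional[Callable[[Question], str]] = None

    def __post_init__(self) -> None:
        if self.kind == "scripted" and self.script is None:
            raise PolicyError("scripted policy requires a script")
        if self.kind == "oracle" and self.truth is None:
            raise PolicyError("oracle policy requires a truth syndrome name")
        if self.kind == "interactive" and self.ask is None:
            raise PolicyError("interactive policy requires an ask callable")
        if not 0.0 <= self.none_prob <= 1.0:
            raise PolicyError("none_prob must lie in [0, 1]")


def run_consultation(
    kb: InquiryKnowledgeBase,
    qalist: QAList,
    policy: AnswerPolicy,
    rng: Optional[random.Random] = None,
) -> PatientRecord:
    """Iterate the Q&A list in order and assemble the patient's symptom set.

    Every question receives exactly one response (an answer id or "none"), so
    ``|symptoms| + |skipped|`` always equals the list length.  Random policies
    are reproducible: equal seeds yield equal records.
    """
    if policy.kind == "random" and rng is None:
        if policy.seed is None:
            raise PolicyError("random policy requires a seed (or an explicit rng)")
        rng = random.Random(policy.seed)

    truth_answers: dict[int, str] = {}
    if policy.kind == "oracle":
        truth = kb.syndrome(policy.truth)  # raises UnknownSyndromeError if absent
        truth_answers = {z.question: z.answer for z in truth.symptoms}

    symptoms: set[Symptom] = set()
    skipped: set[int] = set()
    for question in qalist.items:
        answer_id = _obtain_answer(question, policy, rng, truth_answers)
        if answer_id == NONE_ANSWER:
            skipped.add(question.id)
            continue
        if not question.has_answer(answer_id):
            raise PolicyError(
                f"answer {answer_id!r} is not a candidate answer of question {question.id}"
            )
        symptoms.add(Symptom(question=question.id, answer=answer_id))
    return PatientRecord(symptoms=frozenset(symptoms), skipped=frozenset(skipped))


def _obtain_answer(
    question: Question,
    policy: AnswerPolicy,
    rng: Optional[random.Random],
    truth_answers: dict[int, str],
) -> str:
    if policy.kind == "scripted":
        if question.id not in policy.script:
            raise PolicyError(f"script has no entry for question {question.id}")
        return policy.script[question.id]
    if policy.kind == "random":
        if policy.none_prob > 0 and rng.random() < policy.none_prob:
            return NONE_ANSWER
        return rng.choice([a.id for a in question.answers])
    if policy.kind == "oracle":
        return truth_answers.get(question.id, NONE_ANSWER)
    return policy.ask(question)
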