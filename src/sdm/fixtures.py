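"""Built-in example knowledge bases and a seeded synthetic-KB generator.

Two small hand-authored knowledge bases cover the classic worked examples of
the method — a cold-and-heat chain that separates Yang deficiency from an
internal-and-external excess-cold pattern, and a pain-category pair used to
demonstrate deduction and differentiation.  The generator produces arbitrary
structurally valid bases (ordered ids, category grouping, forward-only answer
chains, unique terminal links) for property tests and simulations.

The pain-category syndromes' symptom sequences are reconstructions: the source
material prints the questions and the differentiation outcome, not the
sequences, so the smallest sequences consistent with both are used (matching
degrees 1.0 vs 0.5 under the default threshold).
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .consultation import PatientRecord
from .errors import GenerationError
from .knowledge_base import (
    CATEGORIES,
    Answer,
    InquiryKnowledgeBase,
    Question,
    Symptom,
    Syndrome,
)

YANG_DEFICIENCY = "Yang deficiency"
EXCESS_COLD = "Pattern of internal and external excess-cold"

WAIST_SYNDROME = "syndrome of cold and dampness invading the waist"
IMPEDIMENT_SYNDROME = "syndrome of wind and cold and dampness impediment"


def fixture_table1() -> InquiryKnowledgeBase:
    """Three chained cold-and-heat questions separating two cold patterns.

    Question 1 (fear of cold) routes to question 2 (fever) routes to question
    3 (duration), whose two answers terminate at "Yang deficiency" (long
    duration) and "Pattern of internal and external excess-cold" (short
    duration).  Both syndromes share the first two symptoms and diverge only
    at the terminal pair.
    """
    questions = (
        Question(
            id=1,
            text="Fear of cold?",
            category="cold-and-heat",
            answers=(
                Answer(id="A1", text="Fear of cold", next_question=2),
                Answer(id="A2", text="No fear of cold", next_question=2),
            ),
        ),
        Question(
            id=2,
            text="Fever?",
            category="cold-and-heat",
            answers=(
                Answer(id="A3", text="Fever", next_question=3),
                Answer(id="A4", text="No fever", next_question=3),
            ),
        ),
        Question(
            id=3,
            text="Does it last long or short?",
            category="cold-and-heat",
            answers=(
                Answer(id="A5", text="Long duration", next_syndrome=YANG_DEFICIENCY),
                Answer(id="A6", text="Short duration", next_syndrome=EXCESS_COLD),
            ),
        ),
    )
    syndromes = (
        Syndrome(
            name=EXCESS_COLD,
            symptoms=(
                Symptom(question=1, answer="A1"),
                Symptom(question=2, answer="A3"),
                Symptom(question=3, answer="A6"),
            ),
        ),
        Syndrome(
            name=YANG_DEFICIENCY,
            symptoms=(
                Symptom(question=1, answer="A1"),
                Symptom(question=2, answer="A3"),
                Symptom(question=3, answer="A5"),
            ),
        ),
    )
    return InquiryKnowledgeBase(questions=questions, syndromes=syndromes)


def fixture_table2() -> InquiryKnowledgeBase:
    """Pain-category pair: cold-damp waist invasion vs wind-cold-damp impediment.

    Question 1 locates the pain (nine candidate answers); questions 2 and 3
    qualify waist and back pain.  The waist syndrome is (Lumbago, cold pain
    worse on rainy days); the impediment syndrome is (Back pain, fixed or
    scurrying pain under wind-cold).  The two non-terminal answers of the last
    question carry syndrome-reference nexts (there is no later question to
    point to).
    """
    q1_answers = [
        "Headache",
        "Chest pain",
        "Flank pain",
        "Stomach duct pain",
        "Lumbago",
        "Abdominal pain",
        "Back pain",
        "Pain in limbs",
        "Body pain",
    ]
    q2_answers = [
        "Frequent soreness",
        "Cold pain and feeling heavy worsens on rainy days",
        "Stabbing pain",
        "Pain extending to lower limbs",
        "Sudden sharp pain",
        "Pain that cannot be tilted",
    ]
    q3_answers = [
        "Pain that cannot be tilted",
        "Nape back pain",
        "Fixed or scurrying pain rises when exposed to wind-cold",
    ]
    questions = (
        Question(
            id=1,
            text="Which part of the body is in pain?",
            category="pain",
            answers=tuple(
                Answer(
                    id=f"A{i + 1}",
                    text=text,
                    next_question=3 if text == "Back pain" else 2,
                )
                for i, text in enumerate(q1_answers)
            ),
        ),
        Question(
            id=2,
            text="What is the pain in the waist?",
            category="pain",
            answers=tuple(
                Answer(
                    id=f"A{i + 10}",
                    text=text,
                    next_question=None if i == 1 else 3,
                    next_syndrome=WAIST_SYNDROME if i == 1 else None,
                )
                for i, text in enumerate(q2_answers)
            ),
        ),
        Question(
            id=3,
            text="What kind of back pain is it?",
            category="pain",
            answers=tuple(
                Answer(id=f"A{i + 16}", text=text, next_syndrome=IMPEDIMENT_SYNDROME)
                for i, text in enumerate(q3_answers)
            ),
        ),
    )
    syndromes = (
        Syndrome(
            name=WAIST_SYNDROME,
            symptoms=(
                Symptom(question=1, answer="A5"),  # Lumbago
                Symptom(question=2, answer="A11"),  # cold pain, worse on rainy days
            ),
        ),
        Syndrome(
            name=IMPEDIMENT_SYNDROME,
            symptoms=(
                Symptom(question=1, answer="A7"),  # Back pain
                Symptom(question=3, answer="A18"),  # fixed/scurrying pain, wind-cold
            ),
        ),
    )
    return InquiryKnowledgeBase(questions=questions, syndromes=syndromes)


def table3_patient() -> PatientRecord:
    """The worked-example patient: lumbago, cold-damp waist pain, wind-cold back pain."""
    return PatientRecord(
        symptoms=frozenset(
            {
                Symptom(question=1, answer="A5"),
                Symptom(question=2, answer="A11"),
                Symptom(question=3, answer="A18"),
            }
        ),
        skipped=frozenset(),
    )


# ---------------------------------------------------------------------------
# Synthetic generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneratorSpec:
    """Structural parameters of a synthetic inquiry knowledge base.

    Defaults are a desk-scale base: all 13 categories, 3 questions each with 4
    candidate answers (39 questions), 12 syndromes of 2–4 symptoms, and a 0.3
    chance per step of re-using already-used questions/answers (question
    sharing between syndromes).
    """

    n_syndromes: int = 12
    n_categories: int = 13
    questions_per_category: int = 3
    answers_per_question: int = 4
    symptoms_min: int = 2
    symptoms_max: int = 4
    overlap: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_categories <= 13:
            raise GenerationError("n_categories must lie in 1..13")
        if self.answers_per_question < 2:
            raise GenerationError("answers_per_question must be at least 2")
        if self.n_syndromes < 1:
            raise GenerationError("at least one syndrome is required")
        if not 1 <= self.symptoms_min <= self.symptoms_max:
            raise GenerationError("symptom count range must satisfy 1 <= min <= max")
        if not 0.0 <= self.overlap <= 1.0:
            raise GenerationError("overlap must lie in [0, 1]")
        n_questions = self.n_categories * self.questions_per_category
        if self.symptoms_max > n_questions:
            raise GenerationError(
                f"sequences of up to {self.symptoms_max} symptoms cannot fit in "
                f"{n_questions} questions"
            )
        # expected fresh questions needed, discounted by expected re-use;
        # residual unlucky draws surface as a generation error at run time
        mean_len = (self.symptoms_min + self.symptoms_max) / 2.0
        demand = self.n_syndromes * mean_len * (1.0 - self.overlap)
        if demand > n_questions:
            raise GenerationError(
                f"about {demand:.0f} fresh questions needed for "
                f"{self.n_syndromes} syndromes at overlap {self.overlap}, "
                f"but only {n_questions} exist"
            )

    @property
    def n_questions(self) -> int:
        return self.n_categories * self.questions_per_category


def generate_kb(spec: GeneratorSpec) -> InquiryKnowledgeBase:
    """Generate a structurally valid KB fully determined by ``spec.seed``.

    Categories are assigned first and questions numbered sequentially across
    category ranks, so id/category monotonicity holds by construction.
    Syndromes are built as forward random walks over the answer chains: with
    probability ``overlap`` a step re-uses an existing chain edge or an
    already-used question, sharing symptoms/questions between syndromes
    (``overlap=0`` yields pairwise disjoint sequences).  Each syndrome gets a
    fresh terminal answer, so terminal pairs are unique.  Remaining answers
    are wired to random later questions (preferring not-yet-reachable ones) or,
    on the last question, to random syndromes.
    """
    rng = random.Random(spec.seed)
    n = spec.n_questions

    # answer bookkeeping: (qid, aid) -> ("q", target) | ("h", name), unset absent
    next_of: dict[tuple[int, str], tuple[str, object]] = {}
    answer_ids: dict[int, list[str]] = {}
    counter = 1
    for qid in range(1, n + 1):
        answer_ids[qid] = [f"A{counter + i}" for i in range(spec.answers_per_question)]
        counter += spec.answers_per_question

    used_questions: set[int] = set()
    syndromes: list[Syndrome] = []

    def walk(length: int, name: str, force_start: int | None = None) -> list[Symptom] | None:
        """One attempt at a forward chain of ``length`` symptoms."""
        max_start = n - (length - 1)
        used_ok = [q for q in sorted(used_questions) if q <= max_start]
        fresh_ok = [q for q in range(1, max_start + 1) if q not in used_questions]
        if force_start is not None:
            current = force_start
        elif spec.overlap > 0 and used_ok and rng.random() < spec.overlap:
            current = rng.choice(used_ok)
        elif fresh_ok:
            current = rng.choice(fresh_ok)
        elif used_ok and spec.overlap > 0:
            current = rng.choice(used_ok)
        else:
            return None

        path: list[Symptom] = []
        staged: dict[tuple[int, str], tuple[str, object]] = {}
        visited_q: set[int] = set()
        for step in range(length):
            visited_q.add(current)
            steps_left = length - step - 1
            if steps_left == 0:
                free = [a for a in answer_ids[current] if (current, a) not in next_of and (current, a) not in staged]
                if not free:
                    return None
                aid = rng.choice(free)
                staged[(current, aid)] = ("h", name)
                path.append(Symptom(question=current, answer=aid))
                break
            max_target = n - (steps_left - 1)
            # re-usable existing chain edges from this question
            reuse = [
                (a, tgt)
                for a in answer_ids[current]
                for kind, tgt in [next_of.get((current, a), (None, None))]
                if kind == "q" and current < tgt <= max_target
            ]
            if spec.overlap > 0 and reuse and rng.random() < spec.overlap:
                aid, target = rng.choice(reuse)
            else:
                free = [a for a in answer_ids[current] if (current, a) not in next_of and (current, a) not in staged]
                if not free:
                    if reuse and spec.overlap > 0:
                        aid, target = rng.choice(reuse)
                        path.append(Symptom(question=current, answer=aid))
                        current = target
                        continue
                    return None
                aid = rng.choice(free)
                candidates = [
                    t
                    for t in range(current + 1, max_target + 1)
                    if t not in visited_q
                ]
                fresh_targets = [t for t in candidates if t not in used_questions]
                if spec.overlap == 0:
                    pool = fresh_targets
                elif fresh_targets and rng.random() >= spec.overlap:
                    pool = fresh_targets
                else:
                    pool = candidates or fresh_targets
                if not pool:
                    return None
                target = rng.choice(pool)
                staged[(current, aid)] = ("q", target)
            path.append(Symptom(question=current, answer=aid))
            current = target
        next_of.update(staged)
        return path

    for j in range(spec.n_syndromes):
        name = f"syndrome-{j + 1:03d}"
        length = rng.randint(spec.symptoms_min, spec.symptoms_max)
        # the first syndrome is anchored at question 1: the inquiry always has
        # an entry point ("inquire first about the cold and heat"), and no
        # forward pointer can ever target the first question
        for _ in range(100):
            path = walk(length, name, force_start=1 if j == 0 else None)
            if path is not None:
                break
        else:
            raise GenerationError(
                f"could not place syndrome {name} (length {length}); the spec is too "
                f"dense — add questions or raise overlap"
            )
        used_questions.update(z.question for z in path)
        syndromes.append(Syndrome(name=name, symptoms=tuple(path)))

    syndrome_names = [h.name for h in syndromes]

    # wire up the remaining answers
    targeted = {tgt for kind, tgt in next_of.values() if kind == "q"}
    reachable = used_questions | targeted
    for qid in range(1, n + 1):
        for aid in answer_ids[qid]:
            if (qid, aid) in next_of:
                continue
            later = list(range(qid + 1, n + 1))
            if not later:
                next_of[(qid, aid)] = ("h", rng.choice(syndrome_names))
                continue
            # cover the earliest not-yet-reachable question first so that
            # almost every question ends up on some chain
            uncovered = [t for t in later if t not in reachable]
            target = uncovered[0] if uncovered else rng.choice(later)
            next_of[(qid, aid)] = ("q", target)
            reachable.add(target)

    questions = []
    for qid in range(1, n + 1):
        cat = CATEGORIES[(qid - 1) * spec.n_categories // n]
        answers = []
        for aid in answer_ids[qid]:
            kind, tgt = next_of[(qid, aid)]
            answers.append(
                Answer(
                    id=aid,
                    text=f"Answer {aid[1:]} to question {qid}",
                    next_question=tgt if kind == "q" else None,
                    next_syndrome=tgt if kind == "h" else None,
                )
            )
        questions.append(
            Question(
                id=qid,
                text=f"Question {qid} ({cat})?",
                category=cat,
                answers=tuple(answers),
            )
        )

    return InquiryKnowledgeBase(
        questions=tuple(questions), syndromes=tuple(sorted(syndromes, key=lambda h: h.name))
    )
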