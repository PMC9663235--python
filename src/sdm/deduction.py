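"""Q&A list deduction: from candidate syndromes to an ordered question list.

Step 1 of the inquiry reasoning loop.  Given the candidate syndromes shortlisted
by the other three diagnostic methods (inspection, auscultation, palpation),
look up each candidate's symptom sequence in the syndrome base, retrieve the
corresponding questions with their full candidate-answer lists, deduplicate,
and order by question id — which, by construction of the knowledge base,
encodes Ten-Brief-Inquiries category order.
"""

from __future__ import annotations

from typing import Iterable

from pydantic import BaseModel, ConfigDict

from .errors import UnknownSyndromeError
from .knowledge_base import InquiryKnowledgeBase, Question


class QAList(BaseModel):
    """The ordered, deduplicated question list shown to the patient.

    Each item is a question together with its full candidate-answer list; no
    question id appears twice and items ascend by id.
    """

    model_config = ConfigDict(frozen=True)

    items: tuple[Question, ...] = ()

    def question_ids(self) -> list[int]:
        return [q.id for q in self.items]

    def __len__(self) -> int:
        return len(self.items)


def deduce_qa_list(kb: InquiryKnowledgeBase, candidates: Iterable[str]) -> QAList:
    """Deduce the Q&A list for a set of candidate syndromes.

    The item set is the union of the questions referenced by any candidate's
    symptom sequence.  Duplicate candidate names and candidate ordering do not
    affect the result.  Unknown names raise :class:`UnknownSyndromeError`
    listing every offender.
    """
    names = {n for n in candidates}
    smap = kb.syndrome_map()
    missing = {n for n in names if n not in smap}
    if missing:
        raise UnknownSyndromeError(missing)
    qids: set[int] = set()
    for name in names:
        qids.update(smap[name].question_ids())
    qmap = kb.question_map()
    return QAList(items=tuple(qmap[qid] for qid in sorted(qids)))
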