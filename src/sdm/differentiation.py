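"""Syndrome differentiation: match, confirm, and rank candidate syndromes.

Step 3 of the inquiry reasoning loop.  Each candidate syndrome's symptom set is
compared with the patient's reported symptoms; the matching degree is the
containment fraction

    degree(h) = |symptoms(h) ∩ symptoms(patient)| / |symptoms(h)|

intersecting on (question id, answer id) identity.  Candidates at or above the
confirmation threshold τ (default 0.6) are confirmed; the primary syndrome is
the confirmed candidate with the highest degree.  Symptoms the patient reports
outside a syndrome's sequence neither help nor penalize it.
"""

from __future__ import annotations

from typing import Iterable, Optional

from pydantic import BaseModel, ConfigDict

from .consultation import PatientRecord
from .errors import UnknownSyndromeError
from .knowledge_base import InquiryKnowledgeBase

#: Default confirmation threshold τ: confirms full matches, rejects half matches.
DEFAULT_THRESHOLD = 0.6


class ScoredSyndrome(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: str
    matching_degree: float
    matched_count: int


class DifferentiationResult(BaseModel):
    """Ranked candidates with the confirmed subset and primary syndrome.

    ``scored`` is sorted by (degree desc, matched count desc, name asc), so
    ``confirmed`` — every entry with degree ≥ τ — is a prefix of it.
    """

    model_config = ConfigDict(frozen=True)

    scored: tuple[ScoredSyndrome, ...]
    confirmed: tuple[ScoredSyndrome, ...]
    primary: Optional[str]
    threshold: float


def matching_degree(
    kb: InquiryKnowledgeBase, syndrome: str, patient: PatientRecord
) -> float:
    """Fraction of the syndrome's symptom set present in the patient's symptoms."""
    h = kb.syndrome(syndrome)  # raises UnknownSyndromeError if absent
    return _degree(h.symptom_set(), patient.symptom_keys())[0]


def _degree(
    sequence: frozenset[tuple[int, str]], reported: frozenset[tuple[int, str]]
) -> tuple[float, int]:
    matched = len(sequence & reported)
    return matched / len(sequence), matched


def differentiate(
    kb: InquiryKnowledgeBase,
    candidates: Iterable[str],
    patient: PatientRecord,
    threshold: float = DEFAULT_THRESHOLD,
) -> DifferentiationResult:
    """Score, rank, and confirm every candidate syndrome.

    Deterministic: candidate-order invariant, with ties broken by matched
    count then name.  All scores are returned even when nothing is confirmed.
    """
    names = set(candidates)
    smap = kb.syndrome_map()
    missing = names - smap.keys()
    if missing:
        raise UnknownSyndromeError(missing)
    reported = patient.symptom_keys()
    scored = []
    for name in names:
        degree, matched = _degree(smap[name].symptom_set(), reported)
        scored.append(
            ScoredSyndrome(name=name, matching_degree=degree, matched_count=matched)
        )
    scored.sort(key=lambda s: (-s.matching_degree, -s.matched_count, s.name))
    confirmed = tuple(s for s in scored if s.matching_degree >= threshold)
    return DifferentiationResult(
        scored=tuple(scored),
        confirmed=confirmed,
        primary=confirmed[0].name if confirmed else None,
        threshold=threshold,
    )
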