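"""Bayesian diagnostic framework: posteriors and four-modality combination.

This is the probabilistic view of TCM diagnosis that motivates the inquiry
model: with syndrome ``y`` and symptom ``x``,

    P(y | x) = P(x | y) P(y) / P(x),

where symptoms caused by a given lesion are taken to be conditionally
independent.  Evidence from the four diagnostic modalities — inspection,
auscultation, inquiry, palpation — each yields a per-modality posterior
P(y | s_i) over its symptom set s_i, and the combined score is the plain sum

    score(y) = Σ_{i=1..4} P(y | s_i),

which is faithful to the framework as stated but is not itself a probability
(it can exceed 1); an optional ``normalize`` flag rescales scores to sum to 1
across syndromes, which never changes the ranking.

This scoring path is decoupled from the set-overlap differentiation engine; it
is an optional alternative, with :func:`model_from_kb` offering a simple
hit/miss likelihood construction over a knowledge base's candidate syndromes.
"""

from __future__ import annotations

import math
from typing import Iterable, Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .consultation import PatientRecord
from .errors import SDMError
from .knowledge_base import InquiryKnowledgeBase

MODALITIES = ("inspection", "auscultation", "inquiry", "palpation")

_PRIOR_TOL = 1e-9


class UndefinedEvidenceError(SDMError):
    """P(x) is zero (or all candidate scores vanish), so no posterior exists."""


class BayesModel(BaseModel):
    """Priors P(y), likelihoods P(x|y), and optional fixed evidence P(x).

    When ``evidence`` is absent, P(x) is computed by total probability,
    Σ_y P(x|y) P(y), which makes posteriors sum to 1 over the syndromes.
    """

    model_config = ConfigDict(frozen=True)

    priors: dict[str, float]
    likelihoods: dict[str, dict[str, float]]
    evidence: Optional[dict[str, float]] = None

    @model_validator(mode="after")
    def _check(self) -> "BayesModel":
        if not self.priors:
            raise ValueError("at least one syndrome is required")
        for y, p in self.priors.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prior P({y}) = {p} outside [0, 1]")
        total = sum(self.priors.values())
        if not math.isclose(total, 1.0, abs_tol=_PRIOR_TOL):
            raise ValueError(f"priors sum to {total}, not 1")
        for y, lk in self.likelihoods.items():
            if y not in self.priors:
                raise ValueError(f"likelihoods given for unknown syndrome {y!r}")
            for x, p in lk.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"likelihood P({x}|{y}) = {p} outside [0, 1]")
        if self.evidence is not None:
            for x, p in self.evidence.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"evidence P({x}) = {p} outside [0, 1]")
        return self

    @property
    def syndromes(self) -> list[str]:
        return list(self.priors)

    def likelihood(self, y: str, x: str) -> float:
        try:
            return self.likelihoods[y][x]
        except KeyError:
            raise KeyError(f"no likelihood P({x!r}|{y!r}) in model") from None

    def evidence_of(self, x: str) -> float:
        """P(x): supplied, or computed by total probability."""
        if self.evidence is not None and x in self.evidence:
            return self.evidence[x]
        return sum(self.likelihood(y, x) * self.priors[y] for y in self.priors)


class ModalityEvidence(BaseModel):
    """One diagnostic modality's observed symptom set s_i."""

    model_config = ConfigDict(frozen=True)

    modality: Literal["inspection", "auscultation", "inquiry", "palpation"]
    symptoms: frozenset[str] = frozenset()


def posterior(model: BayesModel, y: str, x: str) -> float:
    """Single-symptom posterior P(y|x) = P(x|y) P(y) / P(x)."""
    if y not in model.priors:
        raise KeyError(f"unknown syndrome {y!r}")
    px = model.evidence_of(x)
    if px <= 0.0:
        raise UndefinedEvidenceError(f"P({x!r}) = 0; posterior undefined")
    return model.likelihood(y, x) * model.priors[y] / px


def modality_posterior(model: BayesModel, y: str, symptoms: Iterable[str]) -> float:
    """Posterior P(y | s_i) over one modality's symptom set.

    Under conditional independence the joint likelihood factorizes, so the
    posterior is the product P(y) ∏_x P(x|y), normalized across syndromes.
    An empty symptom set carries no evidence and returns the prior.
    """
    if y not in model.priors:
        raise KeyError(f"unknown syndrome {y!r}")
    symptoms = list(symptoms)
    weights = {}
    for cand in model.priors:
        w = model.priors[cand]
        for x in symptoms:
            w *= model.likelihood(cand, x)
        weights[cand] = w
    total = sum(weights.values())
    if total <= 0.0:
        raise UndefinedEvidenceError(
            "all syndromes have zero posterior weight for this symptom set"
        )
    return weights[y] / total


def combine_modalities(
    model: BayesModel,
    y: str,
    evidence: list[ModalityEvidence],
    normalize: bool = False,
) -> float:
    """Combined score Σ_i P(y | s_i) over 1–4 distinct modalities.

    With ``normalize`` the scores are rescaled to sum to 1 across the model's
    syndromes (ranking-preserving); unnormalized scores are only guaranteed
    non-negative.
    """
    if not evidence:
        raise ValueError("at least one modality's evidence is required")
    mods = [e.modality for e in evidence]
    if len(set(mods)) != len(mods):
        raise ValueError("modalities must be distinct within one combination")
    scores = {
        cand: sum(modality_posterior(model, cand, e.symptoms) for e in evidence)
        for cand in model.priors
    }
    if not normalize:
        return scores[y]
    total = sum(scores.values())
    if total <= 0.0:
        raise UndefinedEvidenceError("combined scores sum to zero; cannot normalize")
    return scores[y] / total


def model_from_kb(
    kb: InquiryKnowledgeBase,
    candidates: Iterable[str],
    p_hit: float = 0.9,
) -> BayesModel:
    """Build a hit/miss model over candidate syndromes for exploratory scoring.

    Uniform priors; each symptom label "q<id>:<answer>" from the union of the
    candidates' sequences gets likelihood ``p_hit`` if the syndrome's sequence
    contains the pair and ``1 - p_hit`` otherwise.
    """
    names = sorted(set(candidates))
    smap = kb.syndrome_map()
    for name in names:
        kb.syndrome(name)  # raises UnknownSyndromeError if absent
    labels = sorted(
        {f"q{q}:{a}" for name in names for (q, a) in smap[name].symptom_set()}
    )
    priors = {name: 1.0 / len(names) for name in names}
    likelihoods = {
        name: {
            label: p_hit
            if label in {f"q{q}:{a}" for (q, a) in smap[name].symptom_set()}
            else 1.0 - p_hit
            for label in labels
        }
        for name in names
    }
    return BayesModel(priors=priors, likelihoods=likelihoods)


def patient_inquiry_evidence(patient: PatientRecord) -> ModalityEvidence:
    """Wrap a consultation record as inquiry-modality evidence."""
    return ModalityEvidence(
        modality="inquiry",
        symptoms=frozenset(f"q{z.question}:{z.answer}" for z in patient.symptoms),
    )
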