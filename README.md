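# tcm-sdm — syndrome differentiation by simulated TCM inquiry

In Traditional Chinese Medicine, inspection, auscultation and palpation
typically narrow a patient down to a handful of *candidate syndromes*; the
inquiry (questioning) step must then discriminate among them. `tcm-sdm` is a
rule-based clinical decision-support toolkit that models this step for
researchers in medical knowledge representation and adaptive questionnaires:

1. **Inquiry knowledge base** `D = H ∪ Q`: a question base `Q` of questions
   with closed candidate-answer lists, grouped into the 13 Ten-Brief-Inquiries
   categories (cold and heat first, sweat second, …) and numbered so that ids
   encode consultation order; and a syndrome base `H` of named symptom
   sequences. A *symptom* is a question–answer pair `z = (q, a)`; a *syndrome*
   is an ordered chain `h = {z_i}` whose last answer names the syndrome
   (the terminal link). Answers carry forward-only `next` pointers, so every
   consultation chain terminates.
2. **Deduction**: from a candidate syndrome set, collect the union of the
   candidates' questions, deduplicate, and order by id — the targeted Q&A
   list shown to the patient.
3. **Consultation**: ask each question in order; the patient picks one
   candidate answer or `"none"`. Scripted, random, oracle (planted ground
   truth) and interactive answer policies are built in.
4. **Differentiation**: score each candidate by its *matching degree*
   `|symptoms(h) ∩ symptoms(patient)| / |symptoms(h)|`, confirm candidates at
   or above a threshold τ (default 0.6), and rank; the primary syndrome is
   the confirmed candidate with the highest degree.
5. **Evaluation protocol**: sample random candidate sets (sizes 2 and 3, ten
   sets each by default), simulate consultations, and report question counts
   and — under the oracle policy — the recovery rate of the planted truth.

A separate module implements the underlying Bayesian diagnostic framework
(`P(y|x) = P(x|y)P(y)/P(x)` with per-modality posteriors summed across the
four diagnostic methods) as an optional scoring path.

No clinical knowledge base is distributed; the package ships two small
hand-authored example bases and a seeded generator for structurally valid
synthetic bases.

## Worked example

The built-in pain-category base holds two syndromes — *cold and dampness
invading the waist* and *wind, cold and dampness impediment*:

```python
from sdm import deduce_qa_list, differentiate, fixture_table2, table3_patient
from sdm.fixtures import IMPEDIMENT_SYNDROME, WAIST_SYNDROME

kb = fixture_table2()
candidates = [WAIST_SYNDROME, IMPEDIMENT_SYNDROME]

qalist = deduce_qa_list(kb, candidates)
print([q.text for q in qalist.items])

result = differentiate(kb, candidates, table3_patient())
for s in result.scored:
    print(f"{s.matching_degree:.1f}  {s.name}")
print("primary:", result.primary)
```

prints

```
['Which part of the body is in pain?', 'What is the pain in the waist?', 'What kind of back pain is it?']
1.0  syndrome of cold and dampness invading the waist
0.5  syndrome of wind and cold and dampness impediment
primary: syndrome of cold and dampness invading the waist
```

Three questions suffice for the pair. The example patient reports lumbago,
cold waist pain that worsens on rainy days, and wind-cold back pain: both
symptoms of the waist syndrome are present (degree 1.0, confirmed at
τ = 0.6), but only one of the impediment syndrome's two (degree 0.5,
unconfirmed), so the waist syndrome is the primary diagnosis.

The same pipeline is available from the shell:

```sh
sdm generate-kb --seed 42 --out kb.json
sdm validate kb.json
sdm deduce --kb kb.json --candidates "syndrome-001,syndrome-002"
sdm simulate --kb kb.json --set-sizes 2,3 --sets-per-size 10 --policy oracle --seed 7
```

All subcommands emit deterministic JSON; repeated runs with the same seed are
byte-identical.

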