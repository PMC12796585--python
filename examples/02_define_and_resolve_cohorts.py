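"""Define a computable phenotype as JSON and resolve it to a cohort.

The definition below mirrors a classic transplant question: patients
entered at their first kidney transplant (OPCS-4 M01) who never went on to
renal replacement therapy (OPCS-4 X40) afterwards.
"""

import json

from clintel import (
    evaluate_cohort,
    make_example_scenario,
    parse_cohort_definition,
    simulate_dataset,
)

definition_doc = json.dumps({
    "name": "Transplant Success",
    "criteria": [
        {"domain": "procedure", "code_system": "OPCS-4", "code_prefix": "M01",
         "mode": "include", "role": "index_candidate"},
        {"domain": "procedure", "code_system": "OPCS-4", "code_prefix": "X40",
         "mode": "exclude", "temporal": "on_or_after_index"},
    ],
})

definition = parse_cohort_definition(definition_doc)
dataset, _ = simulate_dataset(make_example_scenario("transplant_consult",
                                                    n_patients=150, seed=0))
cohort = evaluate_cohort(dataset, definition)
print(f"cohort {cohort.name!r}: {len(cohort)} members")
print(cohort.members.head().to_string(index=False))
# each member carries an index date: the date of their first qualifying
# transplant, the time-zero for every downstream analysis.
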