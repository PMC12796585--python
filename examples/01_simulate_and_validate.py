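"""Generate a synthetic EHR dataset, validate it, and write it to Parquet.

The generator stands in for a hospital data warehouse: it emits coded
diagnosis/procedure/medication events and numeric observations in the
package's common data model, with known ground truth for every rate.
"""

from pathlib import Path

from clintel import (
    make_example_scenario,
    read_dataset,
    simulate_dataset,
    validate_dataset,
    write_dataset,
)

config = make_example_scenario("dialysis_meds", n_patients=200, seed=0)
dataset, truth = simulate_dataset(config)

report = validate_dataset(dataset)
print("row counts:", report.row_counts)
print("validation issues:", report.issues or "none")
# row counts show patients plus one event table per domain; an empty issue
# list means every invariant (referential integrity, dates, values) holds.

out = Path("scratch_example_dataset")
write_dataset(dataset, out)
back = read_dataset(out)
print("round trip identical:", back.equals(dataset))
print("configured heparin prevalence:",
      truth.prevalence["dialysis|medication|HEPARIN"])
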