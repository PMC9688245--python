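"""Generate a synthetic multi-block gait/questionnaire cohort.

Draws the default cohort: 1240 subjects, eleven analysis data sets built
from nine physical feature blocks (428 distinct features), ~13.9% fallers,
and severity-linked loss of whole sensor assessments.
"""

import fallfs

spec = fallfs.CohortSpec(seed=42)
blocks, y = fallfs.generate_cohort(spec)

print(f"subjects: {spec.n_samples}, fallers: {y.sum()} ({100 * y.mean():.1f}%)")
for name in fallfs.DATASET_NAMES:
    table = fallfs.dataset_table(blocks, name)
    complete = (~table.mask.to_numpy().all(axis=1)).sum() if name != "All" else None
    missing_pct = 100 * table.mask.to_numpy().mean()
    print(f"  {name:<10} {len(table.features):>3} features, {missing_pct:4.1f}% cells missing")

# The faller fraction tracks the requested 13.9% prevalence up to binomial
# noise; sensor blocks (GR_*, ML_*) lose whole recordings for more severely
# affected subjects, questionnaires almost none.
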