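"""Generate the emulated matched case-control cohort.

4990 cases matched 1:4 to controls (24,950 subjects), 50 zero-inflated
predictors with a log1p-scale tail effect — the study conditions every later
stage analyses.  The cohort TSV itself is bulky and fully reproducible, so
it goes to scratch/; the per-predictor summary table goes to results/.
"""

from pathlib import Path

from amcsuite import SimConfig, generate_cohort, population_summary
from amcsuite.io import write_cohort, write_dictionary_map

ROOT = Path(__file__).resolve().parents[1]
(ROOT / "results").mkdir(exist_ok=True)
(ROOT / "scratch").mkdir(exist_ok=True)

CONFIG = SimConfig(seed=0)  # generator defaults are the study conditions

cohort = generate_cohort(CONFIG)
write_cohort(cohort, ROOT / "scratch" / "cohort.tsv")
write_dictionary_map(cohort.dictionary_map, ROOT / "scratch" / "dictionary_map.tsv")

summary = population_summary(cohort)
summary.round(4).to_csv(ROOT / "results" / "cohort_summary.tsv", sep="\t", index=False)

print(f"cohort: {cohort.n_cases} cases + {cohort.n_controls} controls, "
      f"{len(cohort.predictor_names)} predictors")
print(f"zero fraction: mean {summary['zero_fraction'].mean():.3f}")
print(f"skewness:      mean {summary['skewness'].mean():.1f} (right-skewed positives)")
print("wrote scratch/cohort.tsv and results/cohort_summary.tsv")
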