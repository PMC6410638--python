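"""Generate a synthetic two-group panel cohort and look at its structure.

The simulator draws 36 precursor-lesion (EIN) and 79 carcinoma (EEC)
samples with per-gene mutation prevalences, a small DDR-driven hypermutator
subpopulation, paired tumor/normal region-depth profiles carrying a VEGFB
amplification, and annotated germline variants.
"""

from endopanel import CohortConfig, generate_cohort

cohort = generate_cohort(CohortConfig(seed=1))

print(f"samples: {len(cohort.samples)} "
      f"({cohort.group_sizes()['EIN']} EIN, {cohort.group_sizes()['EEC']} EEC)")
print(f"somatic variants: {len(cohort.somatic)}")
print(f"germline variants: {len(cohort.germline)}")
print(f"region-depth rows: {len(cohort.region_depths)}")
print(f"true hypermutators: {cohort.truth['hypermutators']}")
print(f"true VEGFB amplification carriers: "
      f"{len(cohort.truth['cnv_carriers']['VEGFB'])}")

counts = {s: len(v) for s, v in cohort.somatic_by_sample().items()}
hyper = [counts[s] for s in cohort.truth["hypermutators"]]
rest = [c for s, c in counts.items() if s not in cohort.truth["hypermutators"]]
print(f"mutations per hypermutator: {min(hyper)}-{max(hyper)}")
print(f"mutations per other sample: {min(rest)}-{max(rest)}")
# Hypermutators carry an order of magnitude more mutations, mirroring the
# separation a DDR-defective subpopulation shows in real tumor cohorts.
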