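"""Per-sample tumor mutational burden and group comparison.

TMB counts qualifying SNVs (tumor depth > 150 reads, VAF >= 0.03) per
megabase of interrogated territory. Samples with somatic mutations in
DNA-damage-repair genes (POLE/POLQ/MMR) drive the hypermutated tail; the
comparison is run with and without them.
"""

from endopanel import CohortConfig, compare_tmb, generate_cohort, tmb_report

cohort = generate_cohort(CohortConfig(seed=1))
panel_mb = sum(cohort.panel.values()) / 1e6

results = tmb_report(cohort.somatic_by_sample(), panel_mb)
hyper = [r for r in results if r.hypermutated]
print(f"panel footprint: {panel_mb:.3f} Mb")
print(f"hypermutated samples: {len(hyper)}; "
      f"DDR-mutated: {sum(r.ddr_mutated for r in results)}")

for label, exclude in [("all samples", False), ("excluding DDR-mutated", True)]:
    cmp = compare_tmb(results, cohort.groups, exclude_ddr=exclude)
    print(f"{label}: median TMB EEC={cmp.medians['EEC']:.2f} "
          f"EIN={cmp.medians['EIN']:.2f}  p={cmp.p_two_sided:.3g} ({cmp.test})")
# Removing DDR-mutated samples strips the hypermutator tail from the
# carcinoma group, shrinking (or erasing) the apparent TMB difference.
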