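"""Germline pathogenic-variant screening with Lynch-syndrome handling.

Variants arrive with ClinVar-style labels; the screen keeps pathogenic and
likely-pathogenic findings, splits Lynch (MLH1/MSH2/MSH6/PMS2) from other
predisposition genes, and treats monoallelic hits in recessive genes
(MUTYH) as non-actionable carrier states.
"""

from endopanel import fixture_with_germline, germline_summary, screen_germline

cohort = fixture_with_germline(n_eec=79, n_ein=36)
findings = screen_germline(cohort.germline)
summary = germline_summary(findings, cohort.samples)

print(summary.findings.to_string(index=False))
print(f"\ncarriers: {summary.n_carriers}/{summary.n_patients} "
      f"({100 * summary.overall_carrier_rate:.1f}%)")
print(f"Lynch-gene carriers among EEC: {summary.n_lynch_carriers_eec}/{summary.n_eec} "
      f"({100 * summary.lynch_rate_eec:.1f}%)")
# The heterozygous MUTYH stop-gain is reported but flagged non-actionable:
# its phenotype requires biallelic inactivation, unlike the homozygous
# splice-site carrier who counts as a deleterious finding.
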