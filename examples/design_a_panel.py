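"""Design an identity panel from annotated candidate variants.

Builds a synthetic annotated candidate set with known planted filter
failures, runs the primary and secondary criterion cascades with their
audit reports, and prioritises the survivors into a small panel by
closeness of their allele frequencies to 0.5.
"""

import snptrace as st

candidates, _ = st.generate_design_fixture(seed=42, n_passing=12,
                                           n_single_fail=8, n_multi_fail=4)
print(f"candidates in: {len(candidates)}")

primary, report1 = st.apply_primary_filters(candidates)
print("\nprimary criteria audit (n_in / n_pass / n_fail):")
print(report1.to_frame().to_string(index=False))

secondary, report2 = st.apply_secondary_filters(primary)
print(f"\nafter secondary criteria: {len(secondary)} candidates")

panel = st.prioritize(secondary, k=min(6, len(secondary)), max_per_chrom=2)
print("\nselected panel (ranked by AF balance):")
for s in panel:
    score = sum(abs(af - 0.5) for af in s.afs.values())
    print(f"  {s.rsid}  chr{s.chrom}:{s.pos}  {s.allele_a}/{s.allele_b}  "
          f"balance score {score:.2f}")

print(
    "\nEach audit row counts every candidate against one criterion "
    "independently, so failures of several criteria are visible per "
    "criterion; survivors pass all of them. Lower balance scores mean "
    "allele frequencies closer to 0.5, i.e. more discriminatory SNPs."
)
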