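"""Find duplicate samples hiding in a cohort.

Plants one duplicated DNA source under a second identifier among 200
simulated samples, screens all pairwise profile distances, and
confirms the hit over an extended SNP set with concordance.
"""

import numpy as np

import snptrace as st

panel = st.load_panel()
spec = st.ScenarioSpec(n=200, population="CEU", seed=5, duplicates=[(17, "RESAMPLED")])
truth, cohort, _, ledger = st.generate_cohort(spec, panel)

mism, info, summary = st.pairwise_matrix(cohort)
print(
    f"pairwise mismatches over {summary['n_pairs']} pairs: "
    f"mean {summary['mean']:.1f}, sd {summary['sd']:.2f}, "
    f"range {summary['min']}..{summary['max']}"
)

dups = st.find_duplicates(cohort)
for d in dups:
    print(f"duplicate candidate: {d.sample_a} vs {d.sample_b} "
          f"(0 mismatches over {d.n_informative} SNPs)")

# confirm over an extended SNP set (here: simulated 1,662 sites with
# 1% genotyping error between the two aliquots of the same DNA)
rng = np.random.default_rng(5)
ext_a = rng.integers(0, 3, size=1662)
ext_b = ext_a.copy()
err = rng.random(1662) < 0.01
ext_b[err] = (ext_b[err] + 1) % 3
conc = st.extended_concordance(ext_a, ext_b)
print(f"extended concordance of the flagged pair: {conc:.3f} (threshold 0.98)")
print(
    "\nUnrelated pairs differ at ~18 of 48 alleles, so a 0-mismatch pair "
    "is an extreme outlier; near-1 extended concordance confirms the two "
    "identifiers hold genetically identical material."
)
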