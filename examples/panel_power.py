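"""Analytic discriminatory power of the packaged 24-SNP panel.

For each population's allele frequencies, print the probability that
two unrelated people share the whole profile, the expected number of
indistinguishable pairs ("collisions") in a 10,000-sample cohort, and
how much power survives the worst single-SNP dropout.
"""

import snptrace as st

panel = st.load_panel()
print(f"panel: {len(panel)} SNPs = {2 * len(panel)} points of allelic comparison\n")

for pop in ("perfect", "CEU", "CHB", "JPT", "YRI"):
    afs = st.panel_afs(panel, pop)
    p_match = st.profile_match_prob(afs)
    e_coll = st.expected_collisions(afs, 10_000)
    drop = st.dropout_analysis(afs, 10_000)
    mean, var = st.mismatch_moments(afs)
    print(
        f"{pop:>8}: P(profile match) = {p_match:.2e}; "
        f"E[collisions | n=10,000] = {e_coll:.4f}; "
        f"mean pairwise mismatch = {mean:.1f}; "
        f"worst dropout fold = {drop['max_fold']:.2f}"
    )

print(
    "\nA collision is a pair of samples with identical 24-SNP profiles; "
    "expected counts well below 1 mean the panel separates every sample "
    "in a cohort of this size. Dropout folds below 3 show a single "
    "failed assay cannot break the panel."
)
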